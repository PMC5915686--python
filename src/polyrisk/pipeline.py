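"""End-to-end orchestration: HWE filter -> single-locus -> MDR -> CART -> GRS.

The pipeline runs every stage on the full cohort and, optionally, on
each requested cataract-subtype subset (cases of that subtype against
the full control group). All randomness flows from one seed recorded
in the report, so a config + seed pair reproduces the report exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, cart, grs, mdr
from .io import GenotypeDataset, filter_hwe, read_genotype_table

log = logging.getLogger("polyrisk")


@dataclass
class PipelineConfig:
    genotypes: str = ""
    manifest: str = ""
    hwe_alpha: float = 0.05
    bonferroni_m: int | None = None
    mdr_k_min: int = 1
    mdr_k_max: int = 3
    mdr_folds: int = 10
    mdr_permutations: int = 0
    cart_min_split: int = 20
    cart_min_bucket: int = 7
    cart_cp: float = 0.01
    cart_prune: str = "one-se"
    grs_bin_width: int = 2
    grs_pool_top_from: int | None = None
    subtypes: list[str] = field(default_factory=list)
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _mdr_stage(ds: GenotypeDataset, cfg: PipelineConfig) -> dict:
    search = mdr.MDRSearchConfig(
        k_min=cfg.mdr_k_min,
        k_max=min(cfg.mdr_k_max, ds.n_snps),
        folds=cfg.mdr_folds,
        n_perm=max(cfg.mdr_permutations, 1),
        seed=cfg.seed,
    )
    models = mdr.mdr_search(ds, search)
    out = {}
    for k, model in models.items():
        if cfg.mdr_permutations > 0:
            model.perm_p = mdr.permutation_test(ds, search, model.testing_ba, k)
        hr = model.high_risk_or
        out[k] = {
            "loci": model.loci,
            "training_ba": model.training_ba,
            "testing_ba": model.testing_ba,
            "cvc": model.cvc,
            "folds": model.folds,
            "perm_p": model.perm_p,
            "high_risk_or": None
            if hr is None
            else {
                "odds_ratio": hr.odds_ratio,
                "ci_low": hr.ci_low,
                "ci_high": hr.ci_high,
                "p": hr.p_value,
                "defined": hr.defined,
            },
        }
    return out


def _cart_stage(ds: GenotypeDataset, cfg: PipelineConfig) -> dict:
    tree_cfg = cart.CartConfig(
        min_split=cfg.cart_min_split,
        min_bucket=cfg.cart_min_bucket,
        cp=cfg.cart_cp,
        prune=cfg.cart_prune,
        seed=cfg.seed,
    )
    tree = cart.grow_tree(ds, tree_cfg)
    pruned = cart.prune_tree(tree, ds, tree_cfg)
    stage: dict = {
        "n_terminal_grown": tree.n_leaves(),
        "n_terminal_pruned": pruned.n_leaves(),
        "rendered": pruned.render(ds),
    }
    if pruned.n_leaves() >= 2:
        report = cart.terminal_node_report(pruned, ds)
        stage["nodes"] = report.to_dict(orient="records")
        if len(report) >= 3:
            stage["p_trend"] = cart.trend_test(report)
    return stage


def _grs_stage(ds: GenotypeDataset, cfg: PipelineConfig) -> dict:
    orientation = grs.orientation_from_dataset(ds)
    profile = grs.compute_grs(ds, orientation)
    stage = {
        "orientation": orientation.risk_allele,
        "group_stats": grs.grs_group_stats(profile).to_dict(orient="records"),
        "bins": grs.grs_binned_or(
            profile, cfg.grs_bin_width, cfg.grs_pool_top_from
        ).to_dict(orient="records"),
    }
    return stage, profile


def run_pipeline(
    cfg: PipelineConfig, ds: GenotypeDataset | None = None
) -> dict:
    """Run every stage; returns the JSON-serialisable analysis report."""
    if ds is None:
        if not cfg.genotypes or not cfg.manifest:
            raise ValueError("config must name genotype and manifest files")
        ds = read_genotype_table(cfg.genotypes, cfg.manifest)
    report: dict = {
        "config": asdict(cfg),
        "n_cases": ds.n_cases,
        "n_controls": ds.n_controls,
        "n_snps_input": ds.n_snps,
    }
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    filtered, removed = filter_hwe(ds, cfg.hwe_alpha)
    report["hwe"] = {"alpha": cfg.hwe_alpha, "removed": removed,
                     "n_snps_retained": filtered.n_snps}
    log.info("HWE filter removed %d SNP(s): %s", len(removed), removed)

    m = cfg.bonferroni_m if cfg.bonferroni_m is not None else ds.n_snps
    cohorts = [("all", filtered)] + [
        (st, filtered.subtype_view(st)) for st in cfg.subtypes
    ]
    stages: dict[str, dict] = {}
    for name, cohort in cohorts:
        try:
            assoc = association.association_table(cohort, bonferroni_m=m)
            entry: dict = {
                "n_cases": cohort.n_cases,
                "n_controls": cohort.n_controls,
                "single_locus": assoc.to_dict(orient="records"),
            }
            entry["mdr"] = _mdr_stage(cohort, cfg)
            entry["cart"] = _cart_stage(cohort, cfg)
            grs_out, profile = _grs_stage(cohort, cfg)
            entry["grs"] = grs_out
            stages[name] = entry
            if out_dir:
                assoc.to_csv(out_dir / f"assoc_{name}.tsv", sep="\t", index=False)
                profile.to_dataframe().to_csv(
                    out_dir / f"grs_{name}.tsv", sep="\t", index=False
                )
        except Exception as exc:
            if out_dir:
                (out_dir / "partial_report.json").write_text(
                    json.dumps(stages, default=_json_default, indent=1)
                )
            raise RuntimeError(f"pipeline stage failed for cohort {name!r}: {exc}") from exc
    report["cohorts"] = stages
    if out_dir:
        (out_dir / "report.json").write_text(
            json.dumps(report, default=_json_default, indent=1)
        )
        (out_dir / "report.md").write_text(render_report(report))
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def render_report(report: dict) -> str:
    """Human-readable markdown summary of a pipeline report."""
    lines = ["# Case-control SNP interaction analysis report", ""]
    lines.append(
        f"Cohort: {report['n_cases']} cases / {report['n_controls']} controls, "
        f"{report['n_snps_input']} SNPs genotyped."
    )
    hwe = report["hwe"]
    lines.append(
        f"HWE screen (controls, alpha={hwe['alpha']}): removed "
        f"{len(hwe['removed'])} SNP(s) {hwe['removed']}; "
        f"{hwe['n_snps_retained']} retained."
    )
    for name, entry in report.get("cohorts", {}).items():
        lines += ["", f"## Cohort: {name} "
                      f"({entry['n_cases']} cases / {entry['n_controls']} controls)"]
        sig = [
            r for r in entry["single_locus"]
            if r["model"] == "allelic" and r["p"] == r["p"] and r["p"] < 0.05
        ]
        if sig:
            lines.append("Allelic associations with p < 0.05:")
            for r in sig:
                lines.append(
                    f"- {r['snp_id']} ({r['gene']}): OR {r['odds_ratio']:.2f} "
                    f"({r['ci_low']:.2f}-{r['ci_high']:.2f}), p={r['p']:.3g}, "
                    f"Bonferroni p={r['p_bonferroni']:.3g}"
                )
        else:
            lines.append("No allelic association reached p < 0.05.")
        lines.append("")
        lines.append("MDR best models:")
        lines.append("| k | loci | testing BA | CVC | perm p | high-risk OR |")
        lines.append("|---|------|-----------|-----|--------|--------------|")
        for k, model in entry["mdr"].items():
            hr = model["high_risk_or"]
            hr_txt = (
                f"{hr['odds_ratio']:.2f} ({hr['ci_low']:.2f}-{hr['ci_high']:.2f})"
                if hr and hr["defined"]
                else "-"
            )
            perm = "-" if model["perm_p"] is None else f"{model['perm_p']:.3g}"
            lines.append(
                f"| {k} | {', '.join(model['loci'])} | {model['testing_ba']:.4f} "
                f"| {model['cvc']}/{model['folds']} | {perm} | {hr_txt} |"
            )
        c = entry["cart"]
        lines.append("")
        lines.append(
            f"CART: {c['n_terminal_grown']} terminal nodes grown, "
            f"{c['n_terminal_pruned']} after pruning."
            + (f" Trend p across risk-ordered nodes: {c['p_trend']:.3g}."
               if "p_trend" in c else "")
        )
        g = entry["grs"]["group_stats"]
        for row in g:
            if row["group"] == "all":
                lines.append(
                    f"GRS: cases {row['case_mean']:.2f}±{row['case_sd']:.2f} vs "
                    f"controls {row['control_mean']:.2f}±{row['control_sd']:.2f} "
                    f"(t={row['t']:.2f}, p={row['p']:.3g})"
                )
    lines.append("")
    return "\n".join(lines)
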