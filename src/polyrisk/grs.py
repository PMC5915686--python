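"""Unweighted genetic risk scores (risk-allele counts).

Each SNP contributes 0/1/2 copies of its risk allele; the risk allele
is the minor allele when its case-control odds ratio is >= 1, otherwise
the major allele. Scores are the sum over the panel. Because the
orientation is usually estimated from the same data the score is built
on, case-control score differences carry an in-sample optimism; see the
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeDataset, SUBTYPES
from .association import (
    AssociationResult,
    TwoByTwo,
    allele_table,
    odds_ratio_ci,
)


@dataclass(frozen=True)
class RiskOrientation:
    """Per-SNP risk-allele choice with the odds ratio that produced it."""

    risk_allele: dict[str, str]  # snp_id -> "minor" | "major"
    source_or: dict[str, float]

    def is_minor_risk(self, snp_id: str) -> bool:
        return self.risk_allele[snp_id] == "minor"


@dataclass
class GrsProfile:
    score: np.ndarray  # per-individual risk-allele count
    n_snps_used: np.ndarray  # non-missing SNPs entering each score
    phenotype: np.ndarray
    subtype: np.ndarray
    n_snps: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "score": self.score,
                "n_snps_used": self.n_snps_used,
                "phenotype": np.where(self.phenotype == 1, "case", "control"),
                "subtype": self.subtype,
            }
        )


def orient_risk_alleles(
    assoc: dict[str, AssociationResult] | list[AssociationResult],
) -> RiskOrientation:
    """Choose each SNP's risk allele from its allelic odds ratio.

    Minor allele if OR >= 1, major allele otherwise. An undefined OR
    (zero cell without correction) cannot orient the SNP.
    """
    if not isinstance(assoc, dict):
        assoc = {r.snp_id: r for r in assoc}
    risk, source = {}, {}
    for snp_id, r in assoc.items():
        if not r.defined or not np.isfinite(r.odds_ratio):
            raise ValueError(
                f"{snp_id}: allelic OR undefined (zero cell); recompute with "
                "the Haldane-Anscombe correction to orient this SNP"
            )
        risk[snp_id] = "minor" if r.odds_ratio >= 1 else "major"
        source[snp_id] = float(r.odds_ratio)
    return RiskOrientation(risk, source)


def orientation_from_dataset(ds: GenotypeDataset, correction: str = "haldane") -> RiskOrientation:
    """Convenience: allelic ORs on ``ds`` itself, then orientation."""
    assoc = {
        s: odds_ratio_ci(allele_table(ds, s), correction, snp_id=s)
        for s in ds.snp_ids
    }
    return orient_risk_alleles(assoc)


def compute_grs(ds: GenotypeDataset, orientation: RiskOrientation) -> GrsProfile:
    """Sum of risk-allele counts per individual.

    Missing genotypes are dropped from the sum; ``n_snps_used`` records
    how many SNPs entered each individual's score.
    """
    missing_snps = [s for s in ds.snp_ids if s not in orientation.risk_allele]
    if missing_snps:
        raise ValueError(f"orientation lacks SNPs {missing_snps}")
    geno = ds.genotypes.astype(float)
    geno[geno == MISSING] = np.nan
    for j, snp_id in enumerate(ds.snp_ids):
        if not orientation.is_minor_risk(snp_id):
            geno[:, j] = 2 - geno[:, j]
    score = np.nansum(geno, axis=1).astype(int)
    used = (~np.isnan(geno)).sum(axis=1)
    return GrsProfile(score, used, ds.phenotype.copy(), ds.subtype.copy(), ds.n_snps)


def grs_group_stats(profile: GrsProfile) -> pd.DataFrame:
    """Mean +/- SD of the score per group with equal-variance t-tests.

    Cases (overall and per subtype) are each compared with the same
    control group.
    """
    ctrl = profile.score[profile.phenotype == 0]
    if len(ctrl) < 2:
        raise ValueError("control group too small for a t-test")
    rows = []
    groups = [("all", profile.phenotype == 1)]
    for st in SUBTYPES:
        mask = (profile.phenotype == 1) & (profile.subtype == st)
        if mask.any():
            groups.append((st, mask))
    for name, mask in groups:
        cases = profile.score[mask]
        if len(cases) < 2:
            raise ValueError(f"case group {name!r} too small for a t-test")
        t, p = stats.ttest_ind(ctrl, cases, equal_var=True)
        rows.append(
            {
                "group": name,
                "n_control": len(ctrl),
                "control_mean": float(ctrl.mean()),
                "control_sd": float(ctrl.std(ddof=1)),
                "n_case": len(cases),
                "case_mean": float(cases.mean()),
                "case_sd": float(cases.std(ddof=1)),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def grs_binned_or(
    profile: GrsProfile,
    bin_width: int = 2,
    pool_top_from: int | None = None,
    correction: str = "none",
) -> pd.DataFrame:
    """Odds ratios of consecutive score bins against the lowest bin.

    Bins of ``bin_width`` consecutive scores start at the observed
    minimum; scores >= ``pool_top_from`` (if given) are pooled into a
    single top bin. The lowest bin is the reference.
    """
    scores = profile.score
    y = profile.phenotype
    lo = int(scores.min())
    hi = int(scores.max())
    if pool_top_from is not None and pool_top_from <= lo:
        raise ValueError("pool_top_from must exceed the lowest observed score")
    edges: list[tuple[int, int]] = []
    start = lo
    top = pool_top_from if pool_top_from is not None else hi + 1
    while start < top:
        end = min(start + bin_width - 1, top - 1)
        edges.append((start, end))
        start = end + 1
    if pool_top_from is not None and hi >= pool_top_from:
        edges.append((pool_top_from, hi))
    bins = [(scores >= a) & (scores <= b) for a, b in edges]
    occupied = [i for i, m in enumerate(bins) if m.any()]
    if len(occupied) < 2:
        raise ValueError("scores span fewer than 2 occupied bins")
    ref = bins[occupied[0]]
    ref_case = int(y[ref].sum())
    ref_ctrl = int((~y.astype(bool))[ref].sum())
    if ref_case == 0 or ref_ctrl == 0:
        raise ValueError("reference bin lacks cases or controls")
    rows = []
    for i in occupied:
        a, b = edges[i]
        mask = bins[i]
        n_case = int(y[mask].sum())
        n_ctrl = int(mask.sum()) - n_case
        if mask is ref or i == occupied[0]:
            orr, lo_ci, hi_ci, p = 1.0, np.nan, np.nan, np.nan
        else:
            res = odds_ratio_ci(
                TwoByTwo(n_case, n_ctrl, ref_case, ref_ctrl),
                correction,
                model="grs-bin",
            )
            orr, lo_ci, hi_ci, p = res.odds_ratio, res.ci_low, res.ci_high, res.p_value
        rows.append(
            {
                "bin": f"{a}-{b}" if a != b else str(a),
                "score_min": a,
                "score_max": b,
                "n_case": n_case,
                "n_control": n_ctrl,
                "odds_ratio": orr,
                "ci_low": lo_ci,
                "ci_high": hi_ci,
                "p": p,
                "reference": i == occupied[0],
            }
        )
    return pd.DataFrame(rows)
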