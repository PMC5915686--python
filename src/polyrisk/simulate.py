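"""Synthetic case-control genotype data with known generative truth.

Controls-to-be are drawn in Hardy-Weinberg equilibrium at configured
minor-allele frequencies; disease status follows a logistic-type model
whose odds compose a baseline prevalence, per-risk-allele odds-ratio
multipliers and (optionally) a multi-locus penetrance table, so purely
epistatic architectures (no marginal effects) can be generated for
stress-testing the interaction detectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import GenotypeCounts, GenotypeDataset, SnpDescriptor


@dataclass
class PenetranceModel:
    """Disease probability for every multi-locus genotype combination."""

    loci: list[str]
    table: np.ndarray  # shape (3,) * len(loci)

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        expected = (3,) * len(self.loci)
        if self.table.shape != expected:
            raise ValueError(f"penetrance table must have shape {expected}")
        if (self.table < 0).any() or (self.table > 1).any():
            raise ValueError("penetrance values must lie in [0, 1]")

    def probability(self, codes: np.ndarray) -> np.ndarray:
        """Penetrance per row of an (n, k) genotype-code matrix."""
        return self.table[tuple(np.asarray(codes).T)]

    def marginal_penetrance(self, locus: int, maf: float = 0.5) -> np.ndarray:
        """Average penetrance per genotype of one locus, others at HWE."""
        k = len(self.loci)
        probs = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
        weights = np.ones((3,) * k)
        for ax in range(k):
            if ax == locus:
                continue
            shape = [1] * k
            shape[ax] = 3
            weights = weights * probs.reshape(shape)
        axes = tuple(ax for ax in range(k) if ax != locus)
        return (self.table * weights).sum(axis=axes) / weights.sum(axis=axes)


def epistatic_penetrance(
    kind: str, p_high: float, p_low: float, loci: Sequence[str]
) -> PenetranceModel:
    """Purely epistatic two-locus penetrance tables.

    ``xor``: high penetrance iff exactly one locus carries a minor
    allele. ``checkerboard``: high penetrance on cells where the
    genotype codes have even sum, which has exactly zero marginal
    effects when both MAFs are 0.5.
    """
    if not 0 <= p_low < p_high <= 1:
        raise ValueError("need 0 <= p_low < p_high <= 1")
    loci = list(loci)
    if len(loci) != 2:
        raise ValueError("epistatic penetrance templates are two-locus")
    g = np.indices((3, 3))
    if kind == "xor":
        high = (g[0] >= 1) ^ (g[1] >= 1)
    elif kind == "checkerboard":
        high = (g[0] + g[1]) % 2 == 0
    else:
        raise ValueError(f"unknown penetrance kind {kind!r}")
    table = np.where(high, p_high, p_low)
    return PenetranceModel(loci, table)


@dataclass
class SimulationConfig:
    mafs: Sequence[float]
    n_cases: int
    n_controls: int
    marginal_ors: Mapping[str, float] | Sequence[float] | None = None
    penetrance: PenetranceModel | None = None
    baseline_prevalence: float = 0.3
    seed: int = 0
    snp_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if any(not 0 < m < 1 for m in self.mafs):
            raise ValueError("MAFs must lie strictly in (0, 1)")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("sample sizes must be >= 1")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline prevalence must be in (0, 1)")


def _default_manifest(n: int, snp_ids: Sequence[str] | None) -> list[SnpDescriptor]:
    ids = list(snp_ids) if snp_ids is not None else [f"snp{j + 1:02d}" for j in range(n)]
    return [SnpDescriptor(i, "SIM", "A", "G") for i in ids]


def simulate_hwe_genotypes(
    mafs: Sequence[float],
    n: int,
    seed: int | np.random.Generator = 0,
    snp_ids: Sequence[str] | None = None,
) -> GenotypeDataset:
    """Unlabelled genotypes: per SNP, code ~ Binomial(2, MAF)."""
    rng = np.random.default_rng(seed)
    mafs = np.asarray(list(mafs), dtype=float)
    if ((mafs < 0) | (mafs > 1)).any():
        raise ValueError("MAFs must lie in [0, 1]")
    geno = rng.binomial(2, mafs, size=(n, len(mafs))).astype(np.int8)
    snps = _default_manifest(len(mafs), snp_ids)
    return GenotypeDataset(snps, geno, np.zeros(n, dtype=np.int8))


def disease_probability(cfg: SimulationConfig, codes: np.ndarray, snp_ids: Sequence[str]) -> np.ndarray:
    """Per-individual disease probability under the configured model.

    Baseline odds (or the penetrance table's odds, when supplied) are
    multiplied by OR^(risk-allele count) for each SNP with a marginal
    odds ratio.
    """
    odds0 = cfg.baseline_prevalence / (1 - cfg.baseline_prevalence)
    if cfg.penetrance is not None:
        idx = [list(snp_ids).index(l) for l in cfg.penetrance.loci]
        p = cfg.penetrance.probability(codes[:, idx])
        if ((p <= 0) | (p >= 1)).all() and (np.all(p == 0) or np.all(p == 1)):
            raise ValueError("degenerate penetrance: cannot fill both groups")
        with np.errstate(divide="ignore"):
            odds = np.where(p >= 1, np.inf, p / np.maximum(1 - p, 1e-300))
    else:
        odds = np.full(codes.shape[0], odds0)
    if cfg.marginal_ors is not None:
        ors = (
            np.array([cfg.marginal_ors.get(s, 1.0) for s in snp_ids])
            if isinstance(cfg.marginal_ors, Mapping)
            else np.asarray(list(cfg.marginal_ors), dtype=float)
        )
        odds = odds * np.prod(ors ** codes, axis=1)
    return odds / (1 + odds)


def simulate_case_control(cfg: SimulationConfig) -> tuple[GenotypeDataset, dict]:
    """Rejection-sample a case-control dataset of the configured sizes.

    Genotypes are drawn under HWE, status by Bernoulli(disease
    probability); draws accumulate until both groups are filled. The
    returned truth dict records every generative parameter.
    """
    if cfg.marginal_ors is None and cfg.penetrance is None:
        raise ValueError("supply marginal_ors and/or a penetrance model")
    rng = np.random.default_rng(cfg.seed)
    snps = _default_manifest(len(cfg.mafs), cfg.snp_ids)
    snp_ids = [s.snp_id for s in snps]
    mafs = np.asarray(list(cfg.mafs), dtype=float)
    need = {1: cfg.n_cases, 0: cfg.n_controls}
    got: dict[int, list[np.ndarray]] = {0: [], 1: []}
    counts = {0: 0, 1: 0}
    max_draws = 2000 * (cfg.n_cases + cfg.n_controls)
    drawn = 0
    batch = max(1024, cfg.n_cases + cfg.n_controls)
    while counts[0] < need[0] or counts[1] < need[1]:
        if drawn >= max_draws:
            raise ValueError(
                "rejection sampling failed to fill both groups; the disease "
                "model is too close to deterministic"
            )
        codes = rng.binomial(2, mafs, size=(batch, len(mafs))).astype(np.int8)
        drawn += batch
        p = disease_probability(cfg, codes, snp_ids)
        status = rng.random(batch) < p
        for label in (0, 1):
            sel = codes[status == bool(label)]
            take = min(len(sel), need[label] - counts[label])
            if take > 0:
                got[label].append(sel[:take])
                counts[label] += take
    geno = np.vstack([np.vstack(got[1]), np.vstack(got[0])])
    phenotype = np.concatenate(
        [np.ones(cfg.n_cases, dtype=np.int8), np.zeros(cfg.n_controls, dtype=np.int8)]
    )
    ds = GenotypeDataset(snps, geno, phenotype)
    truth = {
        "mafs": mafs.tolist(),
        "n_cases": cfg.n_cases,
        "n_controls": cfg.n_controls,
        "baseline_prevalence": cfg.baseline_prevalence,
        "marginal_ors": (
            dict(cfg.marginal_ors)
            if isinstance(cfg.marginal_ors, Mapping)
            else (list(cfg.marginal_ors) if cfg.marginal_ors is not None else None)
        ),
        "penetrance": (
            {"loci": cfg.penetrance.loci, "table": cfg.penetrance.table.tolist()}
            if cfg.penetrance is not None
            else None
        ),
        "seed": cfg.seed,
    }
    return ds, truth


def marginal_matched_dataset(
    counts: Mapping[str, tuple[GenotypeCounts, GenotypeCounts]],
    manifest: Sequence[SnpDescriptor],
    seed: int = 0,
    subtype_counts: Mapping[str, int] | None = None,
) -> GenotypeDataset:
    """Cohort whose per-SNP, per-group genotype counts are exact.

    ``counts`` maps snp_id to (control_counts, case_counts). Each SNP's
    genotype vector is an independent within-group shuffle, so every
    marginal (single-SNP) statistic is reproduced exactly while the
    joint genotype structure is random.
    """
    rng = np.random.default_rng(seed)
    ids = [s.snp_id for s in manifest]
    missing = [s for s in ids if s not in counts]
    if missing:
        raise ValueError(f"counts missing for SNPs {missing}")
    group_sizes = {
        g: {counts[s][i].total for s in ids} for i, g in ((0, "control"), (1, "case"))
    }
    for g, sizes in group_sizes.items():
        if len(sizes) != 1:
            raise ValueError(f"inconsistent {g} totals across SNPs: {sorted(sizes)}")
    n_control = counts[ids[0]][0].total
    n_case = counts[ids[0]][1].total
    geno = np.empty((n_case + n_control, len(ids)), dtype=np.int8)
    for j, s in enumerate(ids):
        for offset, size, gc in (
            (0, n_case, counts[s][1]),
            (n_case, n_control, counts[s][0]),
        ):
            col = np.repeat(np.array([0, 1, 2], np.int8), gc.as_tuple())
            rng.shuffle(col)
            geno[offset : offset + size, j] = col
    phenotype = np.concatenate(
        [np.ones(n_case, np.int8), np.zeros(n_control, np.int8)]
    )
    subtype = np.full(n_case + n_control, "", dtype=object)
    if subtype_counts is not None:
        if sum(subtype_counts.values()) > n_case:
            raise ValueError("subtype counts exceed the number of cases")
        labels = np.concatenate(
            [np.full(n, st, dtype=object) for st, n in subtype_counts.items()]
        )
        labels = np.concatenate(
            [labels, np.full(n_case - len(labels), "", dtype=object)]
        )
        rng.shuffle(labels)
        subtype[:n_case] = labels
    return GenotypeDataset(list(manifest), geno, phenotype, subtype)
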