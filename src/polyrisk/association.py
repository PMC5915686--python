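"""Single-locus case-control association statistics.

Odds ratios are oriented as case minor-allele odds over control
minor-allele odds, with Woolf (log-OR normal approximation) confidence
intervals. P-values use the Pearson chi-square without continuity
correction, switching to Fisher's exact test on 2x2 tables when any
expected cell count falls below 5 (Cochran's criterion).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeCounts, GenotypeDataset, genotype_counts, recode


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 table: (group1 exposed, group1 unexposed, group2 ...).

    For allele tables group1 is cases, "exposed" is the minor allele.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")

    @property
    def has_empty_margin(self) -> bool:
        arr = self.as_array()
        return bool((arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any())

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class AssociationResult:
    snp_id: str
    model: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    defined: bool = True


def allele_table(
    ds: GenotypeDataset, snp_id: str, group1: str = "case", group2: str = "control"
) -> TwoByTwo:
    """Minor/major allele counts per group as a 2x2 table."""
    g1 = genotype_counts(ds, snp_id, group1)
    g2 = genotype_counts(ds, snp_id, group2)
    for g, name in ((g1, group1), (g2, group2)):
        if g.total == 0:
            raise ValueError(f"SNP {snp_id} entirely missing in group {name!r}")
    return TwoByTwo(
        g1.n_minor_alleles, g1.n_major_alleles, g2.n_minor_alleles, g2.n_major_alleles
    )


def counts_allele_table(case: GenotypeCounts, control: GenotypeCounts) -> TwoByTwo:
    """Allele 2x2 straight from genotype class counts (summary-level data)."""
    return TwoByTwo(
        case.n_minor_alleles,
        case.n_major_alleles,
        control.n_minor_alleles,
        control.n_major_alleles,
    )


def odds_ratio_ci(
    t: TwoByTwo,
    correction: str = "none",
    alpha: float = 0.05,
    snp_id: str = "",
    model: str = "allelic",
) -> AssociationResult:
    """Cross-product odds ratio with Woolf confidence interval.

    With ``correction="haldane"`` 0.5 is added to every cell whenever any
    cell is zero; with ``correction="none"`` a zero cell yields an
    undefined result (``defined=False``).
    """
    if correction not in ("none", "haldane"):
        raise ValueError(f"unknown correction {correction!r}")
    if t.has_empty_margin and correction == "none":
        raise ValueError("table has an empty margin; use the haldane correction")
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    try:
        p = assoc_test(t)
    except ValueError:
        p = float("nan")
    if min(a, b, c, d) == 0:
        if correction == "none":
            return AssociationResult(snp_id, model, np.nan, np.nan, np.nan, p, False)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    return AssociationResult(
        snp_id,
        model,
        orr,
        float(np.exp(np.log(orr) - z * se)),
        float(np.exp(np.log(orr) + z * se)),
        p,
        True,
    )


def assoc_test(table: TwoByTwo | np.ndarray) -> float:
    """Chi-square (or Fisher's exact, small 2x2 expecteds) p-value.

    Accepts a 2x2 ``TwoByTwo`` or a 2xk count array (e.g. a 2x3 genotype
    table). Pearson chi-square without continuity correction is the
    default; on 2x2 tables with any expected count < 5 Fisher's exact
    two-sided test is used instead.
    """
    arr = table.as_array() if isinstance(table, TwoByTwo) else np.asarray(table, float)
    if arr.ndim != 2 or arr.shape[0] != 2 or arr.shape[1] < 2:
        raise ValueError(f"expected a 2xk table, got shape {arr.shape}")
    keep = arr.sum(axis=0) > 0
    arr = arr[:, keep]
    if arr.shape[1] < 2 or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: an entire row or all columns empty")
    expected = np.outer(arr.sum(1), arr.sum(0)) / arr.sum()
    if arr.shape == (2, 2) and (expected < 5).any():
        return float(stats.fisher_exact(arr.astype(int))[1])
    chi2 = float(((arr - expected) ** 2 / expected).sum())
    df = arr.shape[1] - 1
    return float(stats.chi2.sf(chi2, df))


def genotype_table(ds: GenotypeDataset, snp_id: str) -> np.ndarray:
    """2x3 genotype count table (rows case, control; columns 0/1/2)."""
    case = genotype_counts(ds, snp_id, "case")
    control = genotype_counts(ds, snp_id, "control")
    return np.array([case.as_tuple(), control.as_tuple()], dtype=float)


def dominant_recessive(
    ds: GenotypeDataset, snp_id: str, correction: str = "none"
) -> tuple[AssociationResult, AssociationResult]:
    """Dominant (carrier vs non-carrier) and recessive ORs for one SNP."""
    case = genotype_counts(ds, snp_id, "case")
    control = genotype_counts(ds, snp_id, "control")
    return counts_dominant_recessive(case, control, snp_id, correction)


def counts_dominant_recessive(
    case: GenotypeCounts,
    control: GenotypeCounts,
    snp_id: str = "",
    correction: str = "none",
) -> tuple[AssociationResult, AssociationResult]:
    dom = TwoByTwo(
        case.n_het + case.n_minor_hom,
        case.n_major_hom,
        control.n_het + control.n_minor_hom,
        control.n_major_hom,
    )
    rec = TwoByTwo(
        case.n_minor_hom,
        case.n_major_hom + case.n_het,
        control.n_minor_hom,
        control.n_major_hom + control.n_het,
    )
    out = []
    for table, model in ((dom, "dominant"), (rec, "recessive")):
        try:
            out.append(odds_ratio_ci(table, correction, snp_id=snp_id, model=model))
        except ValueError:
            # empty margin (e.g. no minor homozygote in either group)
            out.append(
                AssociationResult(snp_id, model, np.nan, np.nan, np.nan, np.nan, False)
            )
    return out[0], out[1]


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, p * m)."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return min(1.0, p * m)


def association_table(
    ds: GenotypeDataset,
    models: Sequence[str] = ("allelic", "genotypic", "dominant", "recessive"),
    bonferroni_m: int | None = None,
    correction: str = "none",
) -> pd.DataFrame:
    """Per-SNP association summary across coding models.

    ``bonferroni_m`` defaults to the number of SNPs in the dataset; the
    study design may call for correcting over the number of SNPs
    originally genotyped rather than those surviving quality filters.
    """
    m = bonferroni_m if bonferroni_m is not None else ds.n_snps

    def safe(fn, snp_id, model):
        # degenerate tables (e.g. no minor homozygote in either group of a
        # small subtype cohort) become undefined rows, not failures
        try:
            return fn()
        except ValueError:
            return AssociationResult(snp_id, model, np.nan, np.nan, np.nan, np.nan, False)

    rows = []
    for snp in ds.snps:
        results: list[AssociationResult] = []
        if "allelic" in models:
            results.append(
                safe(
                    lambda: odds_ratio_ci(
                        allele_table(ds, snp.snp_id), correction, snp_id=snp.snp_id
                    ),
                    snp.snp_id,
                    "allelic",
                )
            )
        if "genotypic" in models:
            results.append(
                safe(
                    lambda: AssociationResult(
                        snp.snp_id, "genotypic", np.nan, np.nan, np.nan,
                        assoc_test(genotype_table(ds, snp.snp_id)),
                    ),
                    snp.snp_id,
                    "genotypic",
                )
            )
        if "dominant" in models or "recessive" in models:
            both = safe(
                lambda: dominant_recessive(ds, snp.snp_id, correction),
                snp.snp_id,
                "dominant",
            )
            if isinstance(both, AssociationResult):
                rec = AssociationResult(
                    snp.snp_id, "recessive", np.nan, np.nan, np.nan, np.nan, False
                )
                dom = both
            else:
                dom, rec = both
            if "dominant" in models:
                results.append(dom)
            if "recessive" in models:
                results.append(rec)
        for r in results:
            rows.append(
                {
                    "snp_id": r.snp_id,
                    "gene": snp.gene,
                    "model": r.model,
                    "odds_ratio": r.odds_ratio,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p": r.p_value,
                    "p_bonferroni": bonferroni(r.p_value, m),
                    "defined": r.defined,
                }
            )
    return pd.DataFrame(rows)


# -- logistic-regression interaction check and CV-AUC ------------------


@dataclass
class InteractionTestResult:
    snp_ids: list[str]
    lr_chi2: float
    df: int
    p_value: float
    converged: bool
    note: str = ""


def _design(ds: GenotypeDataset, snp_ids: Sequence[str], coding: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    cols = [recode(ds, s, coding) for s in snp_ids]
    X = np.column_stack(cols)
    keep = ~np.isnan(X).any(axis=1)
    return X[keep], ds.phenotype[keep].astype(float), list(snp_ids)


def lr_interaction_test(
    ds: GenotypeDataset, snp_ids: Sequence[str], coding: str = "dominant"
) -> InteractionTestResult:
    """Likelihood-ratio test for pairwise SNP-SNP interaction terms.

    Compares a logistic model with all main effects plus all pairwise
    products against main effects only. Only pairwise products enter
    (a fully saturated multi-way model is unstable on sparse genotype
    cells). Non-convergence or separation is flagged, not raised.
    """
    import statsmodels.api as sm

    if not 2 <= len(snp_ids) <= 8:
        raise ValueError("interaction test needs between 2 and 8 SNPs")
    X, y, _ = _design(ds, snp_ids, coding)
    pairs = list(combinations(range(X.shape[1]), 2))
    inter = np.column_stack([X[:, i] * X[:, j] for i, j in pairs])
    try:
        with np.errstate(all="ignore"):
            reduced = sm.Logit(y, sm.add_constant(X)).fit(disp=0, maxiter=200)
            full = sm.Logit(y, sm.add_constant(np.hstack([X, inter]))).fit(
                disp=0, maxiter=200, method="bfgs"
            )
        converged = bool(reduced.mle_retvals.get("converged", True)) and bool(
            full.mle_retvals.get("converged", True)
        )
        note = "" if converged else "optimizer did not converge"
    except Exception as exc:  # separation / singular design
        return InteractionTestResult(
            list(snp_ids), np.nan, len(pairs), np.nan, False, str(exc)
        )
    lr = 2 * (full.llf - reduced.llf)
    if lr < 0:  # numerical noise on flat likelihoods
        lr = 0.0
    p = float(stats.chi2.sf(lr, len(pairs)))
    return InteractionTestResult(list(snp_ids), float(lr), len(pairs), p, converged, note)


def cv_auc_compare(
    ds: GenotypeDataset,
    snp_ids: Sequence[str],
    folds: int = 10,
    seed: int = 0,
    coding: str = "dominant",
) -> dict[str, float]:
    """Training vs held-out AUC of the main + pairwise-interaction model.

    Stratified k-fold cross-validation of a logistic model; the
    train-test AUC gap measures over-fitting of the selected SNP panel.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    if folds < 2:
        raise ValueError("need at least 2 folds")
    X, y, _ = _design(ds, snp_ids, coding)
    pairs = list(combinations(range(X.shape[1]), 2))
    if pairs:
        X = np.hstack([X, np.column_stack([X[:, i] * X[:, j] for i, j in pairs])])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    train_aucs, test_aucs = [], []
    for train, test in skf.split(X, y):
        clf = LogisticRegression(C=1e6, max_iter=2000)
        clf.fit(X[train], y[train])
        train_aucs.append(roc_auc_score(y[train], clf.decision_function(X[train])))
        test_aucs.append(roc_auc_score(y[test], clf.decision_function(X[test])))
    train_auc = float(np.mean(train_aucs))
    test_auc = float(np.mean(test_aucs))
    return {
        "train_auc": train_auc,
        "test_auc": test_auc,
        "difference": train_auc - test_auc,
    }


def power_two_proportions(
    n1: int, n2: int, p0: float, target_or: float, alpha: float = 0.05
) -> float:
    """Power of the two-sided two-proportion z-test at a target OR.

    ``n1``/``n2`` are the comparison-group sizes (allele counts for an
    allelic test); ``p0`` the baseline proportion in group 1; the group-2
    proportion comes from ``target_or`` on the odds scale.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if target_or <= 0:
        raise ValueError("target OR must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    odds1 = p0 / (1 - p0) * target_or
    p1 = odds1 / (1 + odds1)
    pbar = (n1 * p0 + n2 * p1) / (n1 + n2)
    se0 = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    se1 = np.sqrt(p0 * (1 - p0) / n1 + p1 * (1 - p1) / n2)
    z = stats.norm.ppf(1 - alpha / 2)
    delta = abs(p1 - p0)
    return float(
        stats.norm.cdf((delta - z * se0) / se1) + stats.norm.cdf((-delta - z * se0) / se1)
    )
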