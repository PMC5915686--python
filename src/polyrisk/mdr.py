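"""Multifactor dimensionality reduction (MDR).

MDR collapses a k-locus genotype table into one binary attribute: each
of the 3^k genotype cells is labelled high- or low-risk by comparing its
within-cell case:control ratio against a threshold (by default the
case:control ratio of the training fold, the standard choice for
unbalanced designs). Models are scored by balanced accuracy on held-out
cross-validation folds (TBA); the reported k-locus model is the subset
chosen most often across folds (CVC), and significance comes from a
label-permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .io import MISSING, GenotypeDataset
from .association import AssociationResult, TwoByTwo, odds_ratio_ci

HIGH, LOW, EMPTY = 1, 0, -1


@dataclass
class MDRSearchConfig:
    k_min: int = 1
    k_max: int = 4
    folds: int = 10
    n_perm: int = 1000
    threshold_ratio: float | None = None  # None = adaptive (train case:control)
    empty_cells_high: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.k_min <= self.k_max:
            raise ValueError("need 1 <= k_min <= k_max")
        if self.folds < 2:
            raise ValueError("need >= 2 folds")


@dataclass
class MDRModel:
    loci: list[str]
    risk_map: np.ndarray  # length 3^k, values HIGH/LOW/EMPTY
    training_ba: float
    testing_ba: float
    cvc: int
    folds: int
    perm_p: float | None = None
    high_risk_or: AssociationResult | None = None
    fold_winners: list[tuple[int, ...]] = field(default_factory=list)


def _cell_index(codes: np.ndarray) -> np.ndarray:
    """Mixed-radix index of each individual's k-locus genotype cell."""
    k = codes.shape[1]
    weights = 3 ** np.arange(k - 1, -1, -1)
    return codes @ weights


def classify_cells(
    codes: np.ndarray, y: np.ndarray, threshold: float | None = None
) -> np.ndarray:
    """Label every k-locus genotype cell high/low risk from counts.

    A cell is high-risk when cases/controls >= threshold (ties high, for
    determinism); cells with no training individuals are EMPTY. The
    default threshold is the overall case:control ratio of ``y``.

    ``codes`` is an (n, k) matrix of 0/1/2 genotype codes without
    missing values; ``y`` the 0/1 phenotype.
    """
    codes = np.asarray(codes)
    y = np.asarray(y)
    if codes.shape[0] == 0:
        raise ValueError("no training individuals")
    k = codes.shape[1]
    n_cells = 3**k
    idx = _cell_index(codes)
    case_counts = np.bincount(idx[y == 1], minlength=n_cells)
    ctrl_counts = np.bincount(idx[y == 0], minlength=n_cells)
    if threshold is None:
        n_ctrl = max(int((y == 0).sum()), 1)
        threshold = float((y == 1).sum()) / n_ctrl
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    risk = np.full(n_cells, EMPTY, dtype=np.int8)
    occupied = (case_counts + ctrl_counts) > 0
    # cases/controls >= T  <=>  cases >= T*controls (safe when controls=0)
    high = occupied & (case_counts >= threshold * ctrl_counts)
    risk[occupied] = LOW
    risk[high] = HIGH
    return risk


def predict(risk_map: np.ndarray, codes: np.ndarray, empty_high: bool = False) -> np.ndarray:
    """Predicted case status per individual; EMPTY cells predict low."""
    labels = risk_map[_cell_index(np.asarray(codes))]
    if empty_high:
        return (labels != LOW).astype(np.int8)
    return (labels == HIGH).astype(np.int8)


def balanced_accuracy(
    risk_map: np.ndarray, codes: np.ndarray, y: np.ndarray, empty_high: bool = False
) -> float:
    """(sensitivity + specificity) / 2 of the high-risk classifier."""
    y = np.asarray(y)
    n_case = int((y == 1).sum())
    n_ctrl = int((y == 0).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("evaluation set must contain both classes")
    pred = predict(risk_map, codes, empty_high)
    sens = float((pred[y == 1] == 1).sum()) / n_case
    spec = float((pred[y == 0] == 0).sum()) / n_ctrl
    return (sens + spec) / 2


def _fold_indices(y: np.ndarray, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def _search_order_k(
    geno: np.ndarray,
    y: np.ndarray,
    snp_ids: list[str],
    k: int,
    cfg: MDRSearchConfig,
    splits: list[tuple[np.ndarray, np.ndarray]],
) -> MDRModel:
    m = geno.shape[1]
    if k > m:
        raise ValueError(f"k={k} exceeds the {m} available SNPs")
    combos = list(combinations(range(m), k))
    winners: list[tuple[int, ...]] = []
    for train, _test in splits:
        best: tuple[float, tuple[int, ...]] | None = None
        for combo in combos:
            sub = geno[:, combo]
            ok = (sub != MISSING).all(axis=1)
            tr = train[ok[train]]
            if len(tr) == 0 or len(set(y[tr])) < 2:
                continue
            rm = classify_cells(sub[tr], y[tr], cfg.threshold_ratio)
            ba = balanced_accuracy(rm, sub[tr], y[tr], cfg.empty_cells_high)
            # ties broken toward the lexicographically earliest subset
            if best is None or ba > best[0] + 1e-12:
                best = (ba, combo)
        assert best is not None
        winners.append(best[1])
    uniq, counts = np.unique(np.array(winners, dtype=int), axis=0, return_counts=True)
    order = np.lexsort(uniq.T[::-1])
    uniq, counts = uniq[order], counts[order]
    cvc = int(counts.max())
    candidates = [tuple(u) for u, c in zip(uniq, counts) if c == cvc]
    if len(candidates) > 1:
        # CVC tie: prefer the candidate with higher mean held-out BA
        scored = [
            (_model_tba(geno, y, cand, cfg, splits)[1], cand) for cand in candidates
        ]
        scored.sort(key=lambda t: (-t[0], t[1]))
        chosen = scored[0][1]
    else:
        chosen = candidates[0]
    train_ba, test_ba = _model_tba(geno, y, chosen, cfg, splits)
    sub = geno[:, chosen]
    ok = (sub != MISSING).all(axis=1)
    full_map = classify_cells(sub[ok], y[ok], cfg.threshold_ratio)
    return MDRModel(
        loci=[snp_ids[j] for j in chosen],
        risk_map=full_map,
        training_ba=train_ba,
        testing_ba=test_ba,
        cvc=cvc,
        folds=cfg.folds,
        fold_winners=winners,
    )


def _model_tba(
    geno: np.ndarray,
    y: np.ndarray,
    combo: tuple[int, ...],
    cfg: MDRSearchConfig,
    splits: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[float, float]:
    """Mean training / held-out balanced accuracy of one locus subset."""
    sub = geno[:, combo]
    ok = (sub != MISSING).all(axis=1)
    tr_bas, te_bas = [], []
    for train, test in splits:
        tr = train[ok[train]]
        te = test[ok[test]]
        rm = classify_cells(sub[tr], y[tr], cfg.threshold_ratio)
        tr_bas.append(balanced_accuracy(rm, sub[tr], y[tr], cfg.empty_cells_high))
        if len(te) and len(set(y[te])) == 2:
            te_bas.append(balanced_accuracy(rm, sub[te], y[te], cfg.empty_cells_high))
    return float(np.mean(tr_bas)), float(np.mean(te_bas))


def mdr_search(ds: GenotypeDataset, cfg: MDRSearchConfig) -> dict[int, MDRModel]:
    """Exhaustive MDR search: the best k-locus model for each order k.

    For every k in [k_min, k_max] all C(m, k) locus subsets are scored;
    within each stratified CV fold the subset with highest training
    balanced accuracy wins, the most frequent winner is reported with
    its cross-validation consistency (CVC) and mean held-out BA.
    Individuals missing any locus of a candidate subset are dropped for
    that subset only.
    """
    if cfg.k_max > ds.n_snps:
        raise ValueError(f"k_max={cfg.k_max} exceeds the {ds.n_snps} SNPs available")
    y = ds.phenotype.astype(int)
    splits = _fold_indices(y, cfg.folds, cfg.seed)
    out: dict[int, MDRModel] = {}
    for k in range(cfg.k_min, cfg.k_max + 1):
        model = _search_order_k(ds.genotypes, y, ds.snp_ids, k, cfg, splits)
        try:
            model.high_risk_or = highrisk_or(model, ds)
        except ValueError:
            model.high_risk_or = None  # degenerate: everyone in one risk group
        out[k] = model
    return out


def evaluate_subset(
    ds: GenotypeDataset, loci: Sequence[str], cfg: MDRSearchConfig
) -> tuple[float, float]:
    """Cross-validated (training BA, testing BA) of one fixed locus subset.

    No model selection is involved, so under label permutation the
    testing BA of a fixed subset is an unbiased chance-level estimate
    (selection across subsets, by contrast, inflates the null TBA).
    """
    y = ds.phenotype.astype(int)
    splits = _fold_indices(y, cfg.folds, cfg.seed)
    combo = tuple(ds.snp_index(s) for s in loci)
    return _model_tba(ds.genotypes, y, combo, cfg, splits)


def permutation_test(
    ds: GenotypeDataset,
    cfg: MDRSearchConfig,
    observed_tba: float,
    k: int,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Label-permutation p-value for a k-locus testing balanced accuracy.

    Each permutation shuffles phenotypes and re-runs the full order-k
    search; p = (1 + #{null TBA >= observed}) / (n_perm + 1).
    """
    if cfg.n_perm < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    y = ds.phenotype.astype(int)
    exceed = 0
    for i in range(cfg.n_perm):
        y_perm = rng.permutation(y)
        fold_seed = int(rng.integers(0, 2**31 - 1))
        splits = _fold_indices(y_perm, cfg.folds, fold_seed)
        null = _search_order_k(ds.genotypes, y_perm, ds.snp_ids, k, cfg, splits)
        if null.testing_ba >= observed_tba - 1e-12:
            exceed += 1
    return (1 + exceed) / (cfg.n_perm + 1)


def highrisk_or(
    model: MDRModel, ds: GenotypeDataset, correction: str = "none"
) -> AssociationResult:
    """Odds ratio of case status for high- vs low-risk group membership.

    The risk map is rebuilt on the full dataset before the 2x2 is formed.
    """
    idx = [ds.snp_index(s) for s in model.loci]
    sub = ds.genotypes[:, idx]
    ok = (sub != MISSING).all(axis=1)
    y = ds.phenotype[ok].astype(int)
    codes = sub[ok]
    rm = classify_cells(codes, y)
    pred = predict(rm, codes)
    a = int(((pred == 1) & (y == 1)).sum())  # high-risk cases
    b = int(((pred == 0) & (y == 1)).sum())
    c = int(((pred == 1) & (y == 0)).sum())
    d = int(((pred == 0) & (y == 0)).sum())
    if (a + c) == 0 or (b + d) == 0:
        raise ValueError("all individuals fell in one risk group")
    return odds_ratio_ci(
        TwoByTwo(a, b, c, d), correction, snp_id="+".join(model.loci), model="mdr-highrisk"
    )


def best_model(models: dict[int, MDRModel]) -> MDRModel:
    """Pick the reported model across orders: highest CVC, then TBA, then smaller k."""
    return max(
        models.items(), key=lambda kv: (kv[1].cvc, kv[1].testing_ba, -kv[0])
    )[1]
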