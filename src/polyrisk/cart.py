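"""Classification trees over SNP genotypes (binary recursive partitioning).

Each split groups the genotype categories of one SNP into two sets (all
three proper bipartitions of {major-hom, het, minor-hom} are candidates,
so dominant-, recessive- and het-vs-rest-style groupings can all be
chosen). Splits maximise the decrease in Gini impurity; growth is
limited by rpart-style controls (min_split, min_bucket, max_depth, a
complexity-parameter gate) and the grown tree is reduced by weakest-link
cost-complexity pruning, optionally with the cross-validated one-SE
rule. Terminal nodes are risk groups: each is compared with the
lowest-case-fraction node by odds ratio, and a Cochran-Armitage test
checks the trend in case fraction across risk-ordered nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeDataset
from .association import AssociationResult, TwoByTwo, assoc_test, odds_ratio_ci


@dataclass
class CartConfig:
    min_split: int = 20
    min_bucket: int = 7
    cp: float = 0.01
    max_depth: int = 30
    prune: str = "one-se"  # "one-se" | "cp" | "none"
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_bucket > self.min_split:
            raise ValueError("min_bucket must be <= min_split")
        if self.cp < 0:
            raise ValueError("cp must be >= 0")
        if self.prune not in ("one-se", "cp", "none"):
            raise ValueError(f"unknown pruning mode {self.prune!r}")


@dataclass
class SplitRule:
    snp_id: str
    left_genotypes: frozenset[int]  # genotype codes routed left

    def describe(self, ds: GenotypeDataset) -> str:
        snp = ds.snps[ds.snp_index(self.snp_id)]
        names = {
            0: snp.major_allele * 2,
            1: snp.major_allele + snp.minor_allele,
            2: snp.minor_allele * 2,
        }
        left = "/".join(names[c] for c in sorted(self.left_genotypes))
        return f"{self.snp_id} in {{{left}}}"


@dataclass
class TreeNode:
    n_case: int
    n_control: int
    depth: int = 0
    split: Optional[SplitRule] = None
    missing_to_left: bool = True
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    node_path: list[tuple[str, frozenset[int]]] = field(default_factory=list)

    @property
    def is_terminal(self) -> bool:
        return self.split is None

    @property
    def n(self) -> int:
        return self.n_case + self.n_control

    @property
    def case_fraction(self) -> float:
        return self.n_case / self.n if self.n else 0.0

    def leaves(self) -> list["TreeNode"]:
        if self.is_terminal:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def n_leaves(self) -> int:
        return len(self.leaves())

    def copy(self) -> "TreeNode":
        node = TreeNode(
            self.n_case, self.n_control, self.depth, self.split,
            self.missing_to_left, None, None, list(self.node_path),
        )
        if not self.is_terminal:
            node.left = self.left.copy()
            node.right = self.right.copy()
        return node

    def render(self, ds: GenotypeDataset, indent: str = "") -> str:
        label = f"[{self.n_case} case / {self.n_control} control]"
        if self.is_terminal:
            return f"{indent}leaf {label}\n"
        out = f"{indent}split {self.split.describe(ds)} {label}\n"
        out += self.render_child(self.left, ds, indent + "  ")
        out += self.render_child(self.right, ds, indent + "  ")
        return out

    @staticmethod
    def render_child(child: "TreeNode", ds: GenotypeDataset, indent: str) -> str:
        return child.render(ds, indent)


def _gini(n_case: int, n_control: int) -> float:
    n = n_case + n_control
    if n == 0:
        return 0.0
    p = n_case / n
    return 2 * p * (1 - p)


def _bipartitions(categories: Sequence[int]) -> list[frozenset[int]]:
    """Proper bipartitions of the observed categories, one side each.

    Each partition is represented by its left set, chosen as the
    lexicographically smaller of the two complementary representations
    so every bipartition appears exactly once, in deterministic order.
    """
    cats = sorted(categories)
    if len(cats) < 2:
        return []
    if len(cats) == 2:
        return [frozenset([cats[0]])]
    return [frozenset([c]) for c in cats]  # 3 categories -> singleton sides


def gini_best_split(
    geno: np.ndarray,
    y: np.ndarray,
    rows: np.ndarray,
    candidate_snps: Sequence[int],
) -> tuple[Optional[tuple[int, frozenset[int]]], float]:
    """Best genotype bipartition of any candidate SNP at one node.

    Returns ((snp_index, left_code_set), impurity_decrease) where the
    decrease is n*gini(parent) - nL*gini(L) - nR*gini(R) over the
    individuals non-missing at that SNP. Ties break toward the earlier
    manifest SNP, then the lexicographically first partition.
    """
    best_rule: Optional[tuple[int, frozenset[int]]] = None
    best_gain = 0.0
    y_rows = y[rows]
    for j in candidate_snps:
        codes = geno[rows, j]
        ok = codes != MISSING
        if ok.sum() < 2:
            continue
        c_ok, y_ok = codes[ok], y_rows[ok]
        case_per = np.bincount(c_ok[y_ok == 1], minlength=3)
        ctrl_per = np.bincount(c_ok[y_ok == 0], minlength=3)
        present = [c for c in (0, 1, 2) if case_per[c] + ctrl_per[c] > 0]
        n_case, n_ctrl = int(case_per.sum()), int(ctrl_per.sum())
        parent = (n_case + n_ctrl) * _gini(n_case, n_ctrl)
        for left in _bipartitions(present):
            lc = int(sum(case_per[c] for c in left))
            lt = int(sum(case_per[c] + ctrl_per[c] for c in left))
            rc, rt = n_case - lc, (n_case + n_ctrl) - lt
            gain = (
                parent
                - lt * _gini(lc, lt - lc)
                - rt * _gini(rc, rt - rc)
            )
            if gain > best_gain + 1e-12:
                best_gain = gain
                best_rule = (j, left)
    return best_rule, best_gain


def grow_tree(ds: GenotypeDataset, cfg: CartConfig | None = None) -> TreeNode:
    """Grow the full classification tree by recursive Gini splitting.

    A split is kept only when its impurity decrease is at least
    ``cp`` times the root impurity and both children receive at least
    ``min_bucket`` individuals (missing genotypes follow the majority
    side of their split).
    """
    cfg = cfg or CartConfig()
    y = ds.phenotype.astype(int)
    if len(set(y)) < 2:
        raise ValueError("dataset must contain both cases and controls")
    geno = ds.genotypes
    root_rows = np.arange(ds.n_individuals)
    n_case = int(y.sum())
    root_scale = ds.n_individuals * _gini(n_case, ds.n_individuals - n_case)

    def build(rows: np.ndarray, depth: int, path: list) -> TreeNode:
        nc = int(y[rows].sum())
        node = TreeNode(nc, len(rows) - nc, depth, node_path=list(path))
        if (
            depth >= cfg.max_depth
            or len(rows) < cfg.min_split
            or nc == 0
            or nc == len(rows)
        ):
            return node
        rule, gain = gini_best_split(geno, y, rows, range(ds.n_snps))
        if rule is None or gain < cfg.cp * root_scale - 1e-12:
            return node
        j, left_set = rule
        codes = geno[rows, j]
        in_left = np.isin(codes, list(left_set))
        in_right = (~in_left) & (codes != MISSING)
        missing = codes == MISSING
        missing_to_left = in_left.sum() >= in_right.sum()
        if missing_to_left:
            in_left |= missing
        else:
            in_right |= missing
        if in_left.sum() < cfg.min_bucket or in_right.sum() < cfg.min_bucket:
            return node
        snp_id = ds.snps[j].snp_id
        node.split = SplitRule(snp_id, left_set)
        node.missing_to_left = missing_to_left
        right_set = frozenset({0, 1, 2}) - left_set
        node.left = build(rows[in_left], depth + 1, path + [(snp_id, left_set)])
        node.right = build(rows[in_right], depth + 1, path + [(snp_id, right_set)])
        return node

    return build(root_rows, 0, [])


def assign_leaves(tree: TreeNode, ds: GenotypeDataset) -> np.ndarray:
    """Index of the terminal node (in tree.leaves() order) per individual."""
    leaves = tree.leaves()
    leaf_ids = {id(leaf): i for i, leaf in enumerate(leaves)}
    out = np.empty(ds.n_individuals, dtype=int)
    for i in range(ds.n_individuals):
        node = tree
        while not node.is_terminal:
            j = ds.snp_index(node.split.snp_id)
            code = ds.genotypes[i, j]
            if code == MISSING:
                go_left = node.missing_to_left
            else:
                go_left = code in node.split.left_genotypes
            node = node.left if go_left else node.right
        out[i] = leaf_ids[id(node)]
    return out


def predict(tree: TreeNode, ds: GenotypeDataset) -> np.ndarray:
    """Majority-class (case=1) prediction per individual."""
    leaves = tree.leaves()
    cls = np.array([1 if l.n_case >= l.n_control else 0 for l in leaves])
    return cls[assign_leaves(tree, ds)]


# -- cost-complexity pruning ------------------------------------------


def _subtree_risk(node: TreeNode) -> tuple[int, int]:
    """(misclassified count of the leaves, number of leaves)."""
    if node.is_terminal:
        return min(node.n_case, node.n_control), 1
    rl, ll = _subtree_risk(node.left)
    rr, lr = _subtree_risk(node.right)
    return rl + rr, ll + lr


def _weakest_link_alphas(tree: TreeNode) -> list[float]:
    """Sorted distinct critical alphas of the cost-complexity sequence."""
    alphas: set[float] = set()
    t = tree.copy()
    while not t.is_terminal:
        best = None

        def visit(node: TreeNode):
            nonlocal best
            if node.is_terminal:
                return
            risk_sub, leaves = _subtree_risk(node)
            g = (min(node.n_case, node.n_control) - risk_sub) / (leaves - 1)
            if best is None or g < best[0] - 1e-12:
                best = (g, node)
            visit(node.left)
            visit(node.right)

        visit(t)
        g, node = best
        alphas.add(max(g, 0.0))
        node.split = None
        node.left = node.right = None
    return sorted(alphas)


def _prune_at(tree: TreeNode, alpha: float) -> TreeNode:
    """Collapse every subtree whose weakest link is below ``alpha``."""
    t = tree.copy()
    changed = True
    while changed:
        changed = False

        def visit(node: TreeNode):
            nonlocal changed
            if node.is_terminal:
                return
            risk_sub, leaves = _subtree_risk(node)
            g = (min(node.n_case, node.n_control) - risk_sub) / (leaves - 1)
            if g <= alpha + 1e-12:
                node.split = None
                node.left = node.right = None
                changed = True
                return
            visit(node.left)
            visit(node.right)

        visit(t)
    return t


def prune_tree(tree: TreeNode, ds: GenotypeDataset, cfg: CartConfig | None = None) -> TreeNode:
    """Weakest-link cost-complexity pruning of a grown tree.

    ``prune="cp"`` collapses links weaker than cp x (root error count);
    ``prune="one-se"`` chooses, by stratified cross-validation, the
    smallest subtree whose CV misclassification risk is within one
    standard error of the minimum. ``prune="none"`` is the identity.
    """
    cfg = cfg or CartConfig()
    if cfg.prune == "none" or tree.is_terminal:
        return tree.copy()
    if cfg.prune == "cp":
        if cfg.cp == 0:
            return tree.copy()
        return _prune_at(tree, cfg.cp * min(tree.n_case, tree.n_control))
    # one-SE rule
    from sklearn.model_selection import StratifiedKFold

    alphas = _weakest_link_alphas(tree)
    # evaluation grid: geometric midpoints between successive critical alphas
    grid = [0.0]
    for lo, hi in zip(alphas, alphas[1:]):
        grid.append(float(np.sqrt(max(lo, 1e-9) * hi)) if lo > 0 else hi / 2)
    grid.append(alphas[-1] + 1.0 if alphas else 1.0)
    y = ds.phenotype.astype(int)
    n = ds.n_individuals
    folds = min(cfg.folds, int((y == 1).sum()), int((y == 0).sum()))
    if folds < 2:
        return tree.copy()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    errors = np.zeros(len(grid))
    for train, test in skf.split(np.zeros(n), y):
        sub = ds.subset_individuals(np.isin(np.arange(n), train))
        held = ds.subset_individuals(np.isin(np.arange(n), test))
        try:
            fold_tree = grow_tree(sub, CartConfig(
                cfg.min_split, cfg.min_bucket, cfg.cp, cfg.max_depth, "none",
                cfg.folds, cfg.seed,
            ))
        except ValueError:
            continue
        for gi, alpha in enumerate(grid):
            pruned = _prune_at(fold_tree, alpha)
            errors[gi] += int((predict(pruned, held) != held.phenotype).sum())
    risk = errors / n
    i_min = int(np.argmin(risk))
    se = float(np.sqrt(risk[i_min] * (1 - risk[i_min]) / n))
    threshold = risk[i_min] + se
    chosen = max(i for i in range(len(grid)) if risk[i] <= threshold + 1e-12)
    return _prune_at(tree, grid[chosen])


# -- terminal-node reporting ------------------------------------------


def terminal_node_report(
    tree: TreeNode,
    ds: GenotypeDataset,
    correction: str = "none",
) -> pd.DataFrame:
    """Risk table of terminal nodes ordered by case fraction.

    The node with the lowest case fraction is the reference; every node
    is compared with it in a 2x2 (node vs reference, case vs control)
    giving an odds ratio with Woolf CI and a chi-square/Fisher p-value.
    """
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise ValueError("need at least 2 terminal nodes to report risks")
    order = sorted(range(len(leaves)), key=lambda i: (leaves[i].case_fraction, i))
    ref = leaves[order[0]]
    rows = []
    for rank, i in enumerate(order, start=1):
        leaf = leaves[i]
        path = "; ".join(
            SplitRule(snp, codes).describe(ds) for snp, codes in leaf.node_path
        )
        if leaf is ref:
            orr, lo, hi, p = 1.0, np.nan, np.nan, np.nan
        else:
            t = TwoByTwo(leaf.n_case, leaf.n_control, ref.n_case, ref.n_control)
            res = odds_ratio_ci(t, correction, model="node-vs-reference")
            orr, lo, hi, p = res.odds_ratio, res.ci_low, res.ci_high, res.p_value
        rows.append(
            {
                "node": rank,
                "conditions": path,
                "n_case": leaf.n_case,
                "n_control": leaf.n_control,
                "case_fraction": leaf.case_fraction,
                "odds_ratio": orr,
                "ci_low": lo,
                "ci_high": hi,
                "p": p,
                "reference": leaf is ref,
            }
        )
    return pd.DataFrame(rows)


def trend_test(report: pd.DataFrame) -> float:
    """Cochran-Armitage trend p across risk-ordered terminal nodes.

    Node rank is the score; tests whether the case fraction rises
    monotonically along the ordered node sequence (two-sided).
    """
    if len(report) < 3:
        raise ValueError("trend test needs at least 3 nodes")
    cases = report["n_case"].to_numpy(float)
    controls = report["n_control"].to_numpy(float)
    return cochran_armitage(cases, controls, np.arange(1, len(report) + 1, dtype=float))


def cochran_armitage(cases: np.ndarray, controls: np.ndarray, scores: np.ndarray) -> float:
    """Two-sided Cochran-Armitage test for trend in proportions."""
    totals = cases + controls
    n = totals.sum()
    r = cases.sum()
    t_stat = float((scores * cases).sum())
    mean_t = r * float((scores * totals).sum()) / n
    var_t = (
        r * (n - r) / (n * (n - 1))
        * (float((scores**2 * totals).sum()) - float((scores * totals).sum()) ** 2 / n)
    )
    if var_t <= 0:
        return 1.0
    z = (t_stat - mean_t) / np.sqrt(var_t)
    return float(2 * stats.norm.sf(abs(z)))
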