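"""Independent brute-force reference implementations used only in tests.

These deliberately avoid the package's vectorised code paths: plain
Python loops and dictionaries, so that agreement with the library is a
meaningful cross-check rather than a tautology.
"""

from __future__ import annotations

import itertools
from collections import Counter


def oracle_genotype_counts(genotypes, phenotype, snp_col, group):
    """Direct loop tally of genotype classes 0/1/2 in one group."""
    want = 1 if group == "case" else 0
    tally = Counter()
    for row, y in zip(genotypes, phenotype):
        if y == want and row[snp_col] in (0, 1, 2):
            tally[row[snp_col]] += 1
    return (tally[0], tally[1], tally[2])


def oracle_cell_risk(rows, labels, threshold):
    """Cell label dict for an MDR locus subset: 'high'/'low' per tuple."""
    cases = Counter()
    ctrls = Counter()
    for row, y in zip(rows, labels):
        key = tuple(row)
        if y == 1:
            cases[key] += 1
        else:
            ctrls[key] += 1
    out = {}
    for key in set(cases) | set(ctrls):
        ratio_high = cases[key] >= threshold * ctrls[key]
        out[key] = "high" if ratio_high else "low"
    return out


def oracle_balanced_accuracy(risk, rows, labels):
    tp = fn = tn = fp = 0
    for row, y in zip(rows, labels):
        pred = risk.get(tuple(row), "low") == "high"
        if y == 1:
            tp += pred
            fn += not pred
        else:
            tn += not pred
            fp += pred
    return (tp / (tp + fn) + tn / (tn + fp)) / 2


def oracle_mdr_fold_winner(genotypes, labels, k, train_idx):
    """Best k-subset by training balanced accuracy, lexicographic ties."""
    m = len(genotypes[0])
    n_case = sum(labels[i] for i in train_idx)
    n_ctrl = len(train_idx) - n_case
    threshold = n_case / n_ctrl
    best = None
    for combo in itertools.combinations(range(m), k):
        rows = [[genotypes[i][j] for j in combo] for i in train_idx]
        ys = [labels[i] for i in train_idx]
        risk = oracle_cell_risk(rows, ys, threshold)
        ba = oracle_balanced_accuracy(risk, rows, ys)
        if best is None or ba > best[0] + 1e-12:
            best = (ba, combo)
    return best


def _gini_count(n_case, n_ctrl):
    n = n_case + n_ctrl
    if n == 0:
        return 0.0
    p = n_case / n
    return n * 2 * p * (1 - p)


def oracle_best_split(rows, labels):
    """Exhaustive bipartition search over all SNPs at one node.

    rows: list of genotype lists (codes 0/1/2, no missing).
    Returns ((snp, left_codes_tuple), gain) or (None, 0).
    """
    m = len(rows[0])
    best_rule, best_gain = None, 0.0
    for j in range(m):
        cats = sorted({r[j] for r in rows})
        if len(cats) < 2:
            continue
        if len(cats) == 2:
            partitions = [(cats[0],)]
        else:
            partitions = [(c,) for c in cats]
        n_case = sum(labels)
        n_ctrl = len(labels) - n_case
        parent = _gini_count(n_case, n_ctrl)
        for left in partitions:
            lc = sum(1 for r, y in zip(rows, labels) if r[j] in left and y == 1)
            lt = sum(1 for r in rows if r[j] in left)
            rc, rt = n_case - lc, len(rows) - lt
            gain = parent - _gini_count(lc, lt - lc) - _gini_count(rc, rt - rc)
            if gain > best_gain + 1e-12:
                best_gain, best_rule = gain, (j, left)
    return best_rule, best_gain


def oracle_grow(rows, labels, min_split, min_bucket, cp, max_depth, root_scale=None):
    """Brute-force recursive partitioner; returns a nested dict tree."""
    n_case = sum(labels)
    if root_scale is None:
        root_scale = _gini_count(n_case, len(labels) - n_case)
    node = {"n_case": n_case, "n_control": len(labels) - n_case}
    if (
        max_depth <= 0
        or len(rows) < min_split
        or n_case == 0
        or n_case == len(rows)
    ):
        return node
    rule, gain = oracle_best_split(rows, labels)
    if rule is None or gain < cp * root_scale - 1e-12:
        return node
    j, left = rule
    left_rows = [(r, y) for r, y in zip(rows, labels) if r[j] in left]
    right_rows = [(r, y) for r, y in zip(rows, labels) if r[j] not in left]
    if len(left_rows) < min_bucket or len(right_rows) < min_bucket:
        return node
    node["split"] = (j, tuple(sorted(left)))
    node["left"] = oracle_grow(
        [r for r, _ in left_rows], [y for _, y in left_rows],
        min_split, min_bucket, cp, max_depth - 1, root_scale,
    )
    node["right"] = oracle_grow(
        [r for r, _ in right_rows], [y for _, y in right_rows],
        min_split, min_bucket, cp, max_depth - 1, root_scale,
    )
    return node


def tree_to_dict(node, ds):
    """Convert a library TreeNode to the oracle's nested-dict shape."""
    out = {"n_case": node.n_case, "n_control": node.n_control}
    if not node.is_terminal:
        out["split"] = (
            ds.snp_index(node.split.snp_id),
            tuple(sorted(node.split.left_genotypes)),
        )
        out["left"] = tree_to_dict(node.left, ds)
        out["right"] = tree_to_dict(node.right, ds)
    return out
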