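"""Independent brute-force oracles for small-instance checks.

Everything here is deliberately naive (enumeration, double loops, exact
fractions) and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np
from scipy.stats import hypergeom


def fisher_exact_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing hypergeometric point probabilities.

    All tables with the observed margins whose probability does not exceed
    the observed table's (within a 1e-7 relative tolerance for float
    equality) contribute to p.
    """
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    p_obs = hypergeom.pmf(a, n, row1, col1)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = hypergeom.pmf(k, n, row1, col1)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


def delta_argmax_scan(case_counts: dict, case_total: int,
                      control_counts: dict, control_total: int):
    """Exhaustive per-allele delta scan with exact rational arithmetic.

    Returns (allele, delta) maximising delta; ties broken by higher case
    frequency then smaller label.  Alleles fixed in controls are skipped.
    """
    best = None
    for allele in sorted(set(case_counts) | set(control_counts)):
        pd = Fraction(case_counts.get(allele, 0), case_total)
        pn = Fraction(control_counts.get(allele, 0), control_total)
        if pn == 1:
            continue
        delta = (pd - pn) / (1 - pn)
        key = (delta, pd, -allele)
        if best is None or key > best[0]:
            best = (key, allele, float(delta))
    return best[1], best[2]


def mann_whitney_enumeration(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p over all rank splits (no ties)."""
    a, b = list(a), list(b)
    m, n = len(a), len(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == m + n, "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in a) - m * (m + 1) / 2
    null = []
    for combo in itertools.combinations(range(1, m + n + 1), m):
        null.append(sum(combo) - m * (m + 1) / 2)
    null = np.array(null)
    lo, hi = min(u_obs, m * n - u_obs), max(u_obs, m * n - u_obs)
    p = ((null <= lo).sum() + (null >= hi).sum()) / len(null)
    return u_obs, min(p, 1.0)


def wilcoxon_enumeration(before, after) -> tuple[float, float]:
    """Exact two-sided signed-rank p over all 2^n sign patterns (no ties)."""
    diffs = np.asarray(before, dtype=float) - np.asarray(after, dtype=float)
    diffs = diffs[diffs != 0]
    n = diffs.size
    mags = np.abs(diffs)
    assert len(set(mags)) == n, "oracle requires tie-free magnitudes"
    ranks = np.argsort(np.argsort(mags)) + 1
    w_pos = ranks[diffs > 0].sum()
    total = n * (n + 1) / 2
    null = []
    for signs in itertools.product([0, 1], repeat=n):
        null.append(sum(r for s, r in zip(signs, ranks) if s))
    null = np.array(null)
    lo, hi = min(w_pos, total - w_pos), max(w_pos, total - w_pos)
    p = ((null <= lo).sum() + (null >= hi).sum()) / len(null)
    return float(min(w_pos, total - w_pos)), min(p, 1.0)


def pairwise_distance_loop(dosages: np.ndarray):
    """Per-pair double loop over sites, skipping missing."""
    n, s = dosages.shape
    dist = np.zeros((n, n))
    compared = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            for k in range(s):
                xi, xj = dosages[i, k], dosages[j, k]
                if np.isnan(xi) or np.isnan(xj):
                    continue
                dist[i, j] += abs(xi - xj)
                compared[i, j] += 1
    return dist, compared


def tree_path_lengths(tree, labels):
    """Leaf-to-leaf path-length matrix of a TreeNode (recursive gather)."""

    def gather(node, depth, acc):
        if node.is_leaf:
            acc[node.label] = depth
            return
        for child, length in node.children:
            gather(child, depth + length, acc)

    # distance via recursion over subtrees: for each internal node, pairs
    # split across children get depth_i + depth_j
    n = len(labels)
    index = {l: i for i, l in enumerate(labels)}
    dist = np.zeros((n, n))

    def visit(node):
        groups = []
        for child, length in node.children:
            acc: dict = {}
            gather(child, length, acc)
            groups.append(acc)
            visit(child)
        for gi, gj in itertools.combinations(groups, 2):
            for li, di in gi.items():
                for lj, dj in gj.items():
                    dist[index[li], index[lj]] = dist[index[lj], index[li]] = di + dj

    visit(tree)
    return dist


def tree_splits(tree) -> set[frozenset]:
    """Non-trivial leaf bipartition sides (as frozensets) of a TreeNode."""
    all_leaves = frozenset(tree.leaves())
    splits = set()

    def visit(node):
        for child, _ in node.children:
            side = frozenset(child.leaves())
            if 1 < len(side) < len(all_leaves) - 1:
                splits.add(min(side, all_leaves - side, key=lambda s: (len(s), sorted(s))))
            visit(child)

    visit(tree)
    return splits
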