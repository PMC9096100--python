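"""Pairwise genetic distances and neighbor-joining trees.

Takes a multi-sample alternate-allele dosage matrix (from a VCF), computes
pairwise allele-sharing distances over pairwise-complete sites, and builds
an unrooted tree with the canonical Saitou–Nei neighbor-joining algorithm.
Used to ask whether mutation-homozygous cases cluster apart from population
controls — the expected signature of a single recent founder.

The NJ implementation is native to this package; scikit-bio's version
serves only as an independent cross-check in the test suite.  Newick text
is parsed through scikit-bio and serialised by a small local writer.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cohort_io import VariantMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "pairwise_distance",
    "nj_tree",
    "monophyly_check",
    "to_newick",
    "from_newick",
    "write_distance_tsv",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair compared-site counts."""

    sample_ids: list[str]
    values: np.ndarray
    n_compared: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.diag(self.values).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (self.values < 0).any():
            raise ValueError("distances must be nonnegative")


@dataclass
class TreeNode:
    """Tree node: internal nodes hold children, leaves hold a label."""

    label: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label] if self.label is not None else []
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


def pairwise_distance(matrix: VariantMatrix, mode: str = "diff_count") -> DistanceMatrix:
    """Pairwise dosage distances over pairwise-complete sites.

    ``diff_count``: sum over shared non-missing sites of the absolute
    dosage difference (two homozygotes for opposite alleles differ by 2 per
    site).  ``normalized`` divides by twice the number of compared sites,
    mapping into [0, 1].  A pair with no site called in both samples is an
    error (no imputation is attempted).
    """
    if mode not in ("diff_count", "normalized"):
        raise ValueError(f"unknown mode {mode!r}")
    d = matrix.dosages
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    present = ~np.isnan(d)
    filled = np.nan_to_num(d)
    # |xi - xj| summed over shared sites, computed pair-by-pair on masks
    values = np.zeros((n, n))
    compared = np.zeros((n, n), dtype=int)
    for i in range(n):
        shared = present[i] & present
        diffs = np.abs(filled[i] - filled) * shared
        values[i] = diffs.sum(axis=1)
        compared[i] = shared.sum(axis=1)
    np.fill_diagonal(values, 0.0)
    off = ~np.eye(n, dtype=bool)
    if (compared[off] == 0).any():
        bad = [
            (matrix.sample_ids[i], matrix.sample_ids[j])
            for i in range(n)
            for j in range(i + 1, n)
            if compared[i, j] == 0
        ]
        raise ValueError(f"no shared called sites for pair(s): {bad}")
    if mode == "normalized":
        values = np.where(off, values / (2.0 * np.maximum(compared, 1)), 0.0)
    return DistanceMatrix(list(matrix.sample_ids), values, compared)


def nj_tree(dist: DistanceMatrix) -> TreeNode:
    """Canonical neighbor-joining (Saitou–Nei, Studier–Keppler Q-criterion).

    Deterministic: ties in the Q matrix are broken by lowest sample index
    pair.  Negative branch lengths are clamped to zero with the total
    clamped deficit logged.  On an additive distance matrix the generating
    tree's topology and branch lengths are recovered exactly.  The returned
    tree is rooted at the final three-way join (standard unrooted-NJ
    convention).
    """
    n = len(dist.sample_ids)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 samples")
    d = dist.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(label=s) for s in dist.sample_ids]
    active = list(range(n))
    deficit = 0.0

    def _clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lexicographically first (i, j) minimising Q
        fi, fj = divmod(int(np.argmin(q)), m)
        if fi > fj:
            fi, fj = fj, fi
        i, j = active[fi], active[fj]
        dij = d[i, j]
        li = 0.5 * dij + (r[fi] - r[fj]) / (2.0 * (m - 2))
        lj = dij - li
        parent = TreeNode(children=[(nodes[i], _clamp(li)), (nodes[j], _clamp(lj))])
        # distances from the new node to every remaining node
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = TreeNode(
        children=[
            (nodes[i], _clamp(li)),
            (nodes[j], _clamp(lj)),
            (nodes[k], _clamp(lk)),
        ]
    )
    if deficit > 0:
        logger.info("nj_tree: clamped %.6g of negative branch length to zero", deficit)
    return root


def _clades(node: TreeNode) -> list[frozenset[str]]:
    out = [frozenset(node.leaves())]
    for child, _ in node.children:
        out.extend(_clades(child))
    return out


def monophyly_check(tree: TreeNode, subset: Sequence[str]) -> tuple[bool, frozenset[str]]:
    """Is ``subset`` a clade of the (unrooted) tree?

    Returns ``(monophyletic, smallest_containing_clade)``.  Because an NJ
    tree is unrooted, the subset also counts as monophyletic when its
    complement forms a clade (the subset then sits on one side of a single
    edge).  The reported clade is the smallest rooted clade containing the
    subset under the tree's conventional rooting.
    """
    want = frozenset(subset)
    leaves = frozenset(tree.leaves())
    unknown = want - leaves
    if unknown:
        raise ValueError(f"unknown leaf label(s): {sorted(unknown)}")
    clades = _clades(tree)
    containing = min((c for c in clades if want <= c), key=len)
    mono = containing == want or (leaves - want) in clades
    return mono, containing


def to_newick(tree: TreeNode, digits: int = 6) -> str:
    """Serialise to newick with branch lengths (6 significant digits)."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return node.label or ""
        inner = ",".join(
            f"{fmt(child)}:{length:.{digits}g}" for child, length in node.children
        )
        return f"({inner})"

    return fmt(tree) + ";"


def from_newick(text: str) -> TreeNode:
    """Parse newick text (via scikit-bio) into this module's TreeNode."""
    import skbio

    sk = skbio.TreeNode.read(io.StringIO(text))

    def convert(node) -> TreeNode:
        if node.is_tip():
            return TreeNode(label=node.name)
        return TreeNode(
            children=[
                (convert(c), float(c.length) if c.length is not None else 0.0)
                for c in node.children
            ]
        )

    return convert(sk)


def write_distance_tsv(dist: DistanceMatrix, path) -> None:
    """PHYLIP-style square distance matrix as TSV (header row of ids)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\t" + "\t".join(dist.sample_ids) + "\n")
        for sid, row in zip(dist.sample_ids, dist.values):
            fh.write(sid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
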