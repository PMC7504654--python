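"""Distance-based phylogenetics: p-distances, neighbor-joining, bootstrap
support and clade-based subgroup assignment.

The tree builder is the Saitou-Nei neighbor-joining algorithm on a pairwise
distance matrix; it reconstructs topology and branch lengths exactly from any
additive matrix.  Support values come from column bootstrap: the alignment's
columns are resampled with replacement, a tree is built per replicate, and
each internal bipartition of the point-estimate tree is scored by the
percentage of replicate trees containing it.
"""
from __future__ import annotations

import dataclasses
from typing import Callable, Mapping, Sequence

import numpy as np

from .io_core import GAP, SequenceRecord


@dataclasses.dataclass
class PhyloNode:
    """A rooted-representation tree node; the unrooted NJ result is held as a
    trifurcating root surrogate."""

    name: str | None = None
    length: float | None = None
    support: int | None = None
    parent: "PhyloNode | None" = None
    children: list["PhyloNode"] = dataclasses.field(default_factory=list)

    def add(self, child: "PhyloNode", length: float | None = None) -> "PhyloNode":
        child.parent = self
        if length is not None:
            child.length = length
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def tips(self) -> list["PhyloNode"]:
        if self.is_tip:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.tips())
        return out

    def traverse(self):
        yield self
        for c in self.children:
            yield from c.traverse()

    def tip_names(self) -> frozenset[str]:
        return frozenset(t.name for t in self.tips())


@dataclasses.dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix has non-finite entries")


# ---------------------------------------------------------------------------
# distances

def p_distance(aligned: Sequence[SequenceRecord]) -> DistanceMatrix:
    """Proportion of mismatching columns, with pairwise deletion of columns
    where either sequence has a gap."""
    return _distance(aligned, lambda p: p)


def poisson_distance(aligned: Sequence[SequenceRecord]) -> DistanceMatrix:
    """Poisson-corrected protein distance, -ln(1 - p)."""
    def corr(p):
        if p >= 1.0:
            raise ValueError("p-distance 1.0 cannot be Poisson corrected")
        return -np.log(1.0 - p)
    return _distance(aligned, corr)


def _distance(aligned: Sequence[SequenceRecord],
              correction: Callable[[float], float]) -> DistanceMatrix:
    lengths = {len(rec) for rec in aligned}
    if len(lengths) > 1:
        raise ValueError("aligned sequences must have equal lengths")
    n = len(aligned)
    d = np.zeros((n, n))
    rows = [rec.residues for rec in aligned]
    for i in range(n):
        for j in range(i + 1, n):
            compared = mismatches = 0
            for a, b in zip(rows[i], rows[j]):
                if a == GAP or b == GAP:
                    continue
                compared += 1
                mismatches += a != b
            if compared == 0:
                raise ValueError(
                    f"no comparable columns between {aligned[i].id!r} "
                    f"and {aligned[j].id!r}")
            d[i, j] = d[j, i] = correction(mismatches / compared)
    return DistanceMatrix([rec.id for rec in aligned], d)


# ---------------------------------------------------------------------------
# neighbor joining

def nj_tree(dm: DistanceMatrix) -> PhyloNode:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j
    (ties broken by index order for determinism); branch lengths use the
    standard formulas, with negative estimates clamped to zero and the
    deficit moved to the sibling edge.  The result is unrooted, represented
    with a trifurcating root surrogate.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    nodes: list[PhyloNode] = [PhyloNode(name=lab) for lab in dm.labels]
    d = dm.d.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = divmod(int(np.argmin(q)), m)
        if i > j:
            i, j = j, i
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = d[i, j] - vi
        if vi < 0:
            vj, vi = vj + vi, 0.0
        if vj < 0:
            vi, vj = max(vi + vj, 0.0), 0.0
        parent = PhyloNode()
        parent.add(nodes[i], length=vi)
        parent.add(nodes[j], length=vj)
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        d = d2

    root = PhyloNode()
    lens = [
        0.5 * (d[0, 1] + d[0, 2] - d[1, 2]),
        0.5 * (d[0, 1] + d[1, 2] - d[0, 2]),
        0.5 * (d[0, 2] + d[1, 2] - d[0, 1]),
    ]
    for node, ln in zip(nodes, lens):
        root.add(node, length=max(ln, 0.0))
    return root


# ---------------------------------------------------------------------------
# bootstrap

def bipartitions(tree: PhyloNode) -> set[frozenset[str]]:
    """Canonical internal bipartitions (side not containing the reference
    taxon, which is the lexicographically smallest tip name)."""
    all_tips = tree.tip_names()
    ref = min(all_tips)
    parts: set[frozenset[str]] = set()
    for node in tree.traverse():
        if node is tree or node.is_tip:
            continue
        side = node.tip_names()
        if 1 < len(side) < len(all_tips) - 1:
            parts.add(side if ref not in side else all_tips - side)
    return parts


def bootstrap_support(aligned: Sequence[SequenceRecord], replicates: int,
                      seed: int,
                      distance: Callable[[Sequence[SequenceRecord]],
                                         DistanceMatrix] = p_distance
                      ) -> PhyloNode:
    """Point-estimate NJ tree with bootstrap supports on internal nodes."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    tree = nj_tree(distance(aligned))
    ncol = len(aligned[0])
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {p: 0 for p in bipartitions(tree)}
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        resampled = [SequenceRecord(rec.id,
                                    "".join(rec.residues[c] for c in cols),
                                    rec.alphabet)
                     for rec in aligned]
        reps = bipartitions(nj_tree(distance(resampled)))
        for part in counts:
            if part in reps:
                counts[part] += 1
    all_tips = tree.tip_names()
    ref = min(all_tips)
    for node in tree.traverse():
        if node is tree or node.is_tip:
            continue
        side = node.tip_names()
        if 1 < len(side) < len(all_tips) - 1:
            key = side if ref not in side else all_tips - side
            node.support = round(100 * counts[key] / replicates)
    return tree


# ---------------------------------------------------------------------------
# subgroup assignment

UNPLACED = "unplaced"


def assign_subgroups(tree: PhyloNode,
                     references: Mapping[str, str]) -> dict[str, str]:
    """Label each query tip with the subgroup of the smallest clade that
    contains it together with at least one reference tip, provided all
    reference tips in that clade agree; conflicting clades give "unplaced".
    """
    if not references:
        raise ValueError("at least one reference label is required")
    tips = tree.tip_names()
    missing = set(references) - tips
    if missing:
        raise KeyError(f"reference leaves absent from tree: {sorted(missing)}")
    out: dict[str, str] = {}
    for tip in tree.tips():
        if tip.name in references:
            out[tip.name] = references[tip.name]
            continue
        node = tip
        label = UNPLACED
        while node is not None:
            ref_labels = {references[n] for n in node.tip_names()
                          if n in references}
            if ref_labels:
                label = ref_labels.pop() if len(ref_labels) == 1 else UNPLACED
                break
            node = node.parent
        out[tip.name] = label
    return out
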