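"""Uncorrected p-distances, neighbor-joining, and monophyly checks.

These are the verification tools behind the pipeline's topology-class
dichotomy: columns tracing duplication history split each species' paralogs
into two deep clusters, while columns under concerted evolution group
sequences by species. NJ trees on p-distance matrices let simulated data be
checked for reciprocal monophyly of the true lineages versus conspecific
clustering.

p-distances use pairwise deletion: a column contributes to a pair only when
neither sequence has a gap or N there.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io import MISSING_CHARS, Alignment, CrossReferenceError, DataError


@dataclass
class DistanceMatrix:
    """A labeled symmetric distance matrix with zero diagonal.

    Entries are in [0, 1] when produced by :func:`p_distance_matrix`;
    ``nan`` marks pairs with no comparable columns.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T), atol=1e-12
        ):
            raise ValueError("distance matrix must be symmetric")
        self._index = {lab: k for k, lab in enumerate(self.labels)}

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    @property
    def n(self) -> int:
        return len(self.labels)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        df.to_csv(path, sep="\t", index_label="id", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        return cls(labels=tuple(str(c) for c in df.columns), values=df.to_numpy(float))


def _codes(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Character matrix and a boolean mask of informative (non-gap, non-N) cells."""
    arr = aln.array
    valid = ~np.isin(arr, list(MISSING_CHARS))
    return arr, valid


def p_distance(aln: Alignment, i: str, j: str) -> float:
    """Proportion of differing sites between rows ``i`` and ``j``.

    Columns where either sequence carries a gap or N are excluded (pairwise
    deletion). Returns ``nan`` when no column is comparable.
    """
    arr, valid = _codes(aln)
    a, b = aln.index_of(i), aln.index_of(j)
    both = valid[a] & valid[b]
    n_comp = int(both.sum())
    if n_comp == 0:
        return float("nan")
    return float((arr[a, both] != arr[b, both]).sum() / n_comp)


def p_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Pairwise-deletion p-distances over all sequence pairs."""
    arr, valid = _codes(aln)
    n = aln.n_seqs
    vals = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            both = valid[a] & valid[b]
            n_comp = int(both.sum())
            if n_comp == 0:
                d = np.nan
            else:
                d = (arr[a, both] != arr[b, both]).sum() / n_comp
            vals[a, b] = vals[b, a] = d
    return DistanceMatrix(labels=aln.ids, values=vals)


# ---------------------------------------------------------------------------
# Neighbor joining

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; returns an unrooted dendropy tree.

    Ties in the Q criterion are broken by the lexicographically smallest
    label pair (internal nodes carry the smallest leaf label beneath them),
    so the result is deterministic. Negative branch lengths are clamped to
    zero. Missing distances are rejected.
    """
    if dm.n < 3:
        raise DataError(f"neighbor joining needs >=3 labels, got {dm.n}")
    if dm.has_missing():
        raise DataError(
            "distance matrix contains missing values; filter sequences first"
        )

    taxa = dendropy.TaxonNamespace(list(dm.labels))
    tree = dendropy.Tree(taxon_namespace=taxa)

    nodes: list[dendropy.Node] = []
    for lab in dm.labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(nd)
    # sort key per working node: smallest leaf label beneath it
    keys = list(dm.labels)
    d = dm.values.copy()
    active = list(range(dm.n))

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for ai, bi in zip(*np.where(np.isclose(q, qmin, rtol=0, atol=1e-12))):
            if ai >= bi:
                continue
            ka, kb = keys[active[ai]], keys[active[bi]]
            pair = tuple(sorted((ka, kb)))
            if best is None or pair < best[0]:
                best = (pair, int(ai), int(bi))
        _, ai, bi = best
        ia, ib = active[ai], active[bi]
        dij = sub[ai, bi]
        la = 0.5 * dij + (r[ai] - r[bi]) / (2 * (m - 2))
        lb = dij - la
        la, lb = max(la, 0.0), max(lb, 0.0)

        parent = dendropy.Node()
        ca, cb = nodes[ia], nodes[ib]
        parent.add_child(ca)
        parent.add_child(cb)
        ca.edge.length = float(la)
        cb.edge.length = float(lb)

        # distances from the new node to every other active node
        new_row = np.zeros(d.shape[0] + 1)
        for ci in active:
            if ci in (ia, ib):
                continue
            new_row[ci] = 0.5 * (d[ia, ci] + d[ib, ci] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : d.shape[0] - 1] = new_row[: d.shape[0] - 1]
        d[: d.shape[0] - 1, -1] = new_row[: d.shape[0] - 1]
        nodes.append(parent)
        keys.append(min(keys[ia], keys[ib]))
        active = [x for x in active if x not in (ia, ib)] + [len(nodes) - 1]

    ia, ib = active
    root = dendropy.Node()
    half = max(d[ia, ib], 0.0) / 2.0
    for ci in (ia, ib):
        child = nodes[ci]
        root.add_child(child)
        child.edge.length = float(half)
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def is_monophyletic(tree: dendropy.Tree, leaf_subset: Iterable[str]) -> bool:
    """True iff some edge bipartitions the leaves into exactly (subset, rest).

    The tree is treated as unrooted: the subset's complement qualifying is
    enough. The full leaf set and singletons are trivially monophyletic.
    """
    subset = set(leaf_subset)
    all_leaves = leaf_labels(tree)
    unknown = subset - all_leaves
    if unknown:
        raise CrossReferenceError(f"labels not in tree: {sorted(unknown)}")
    if not subset:
        raise DataError("leaf_subset is empty")
    if subset == all_leaves or len(subset) == 1:
        return True
    complement = all_leaves - subset
    # the pendant edge of a single leftover leaf already separates the rest
    if len(complement) == 1:
        return True
    for node in tree.preorder_internal_node_iter():
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below == subset or below == complement:
            return True
    return False


def nearest_neighbor(dm: DistanceMatrix, label: str) -> str:
    """The other label at minimum distance; ties broken lexicographically."""
    i = dm.labels.index(label)
    best = None
    for j, other in enumerate(dm.labels):
        if j == i or np.isnan(dm.values[i, j]):
            continue
        cand = (dm.values[i, j], other)
        if best is None or cand < best:
            best = cand
    if best is None:
        raise DataError(f"no comparable neighbors for {label!r}")
    return best[1]
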