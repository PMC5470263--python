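"""Segmentation of alignment columns into local phylogenetic classes ("cacti").

Each cactus is a pairwise-distance pattern over all sequences plus the set
of columns assigned to it. Columns are assigned by dynamic programming (a
Viterbi pass over per-column emission costs with a fixed switch penalty).
New cacti are proposed by binary change-point splits: each iteration finds
the split of a current segment that most reduces the squared deviation
around per-side centroids, seeds a trial assignment with that split, and
refines it by alternating centroid re-estimation with the Viterbi pass; a
proposal is kept only when it lowers the total cost. Deterministic — no RNG.

This is a deliberately simple, self-contained segmenter: the HMM half of a
Saguaro-style analysis, with the self-organising-map stage replaced by
change-point proposals. It is a functional analog validated on
breakpoint-recovery fixtures, not a reimplementation of that method.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .distances import DistanceMatrix
from .io import MISSING_CHARS, Alignment, DataError


@dataclass
class Cactus:
    """One local phylogenetic class.

    ``matrix`` is the max-normalized mean of the 0/1 column-difference
    matrices of the assigned columns; ``columns`` are 0-based alignment
    columns.
    """

    matrix: DistanceMatrix
    columns: tuple[int, ...]

    @property
    def columns_1based(self) -> list[int]:
        return [c + 1 for c in self.columns]


@dataclass
class Segmentation:
    """Result of partitioning the analyzed (variable) columns into cacti."""

    cacti: list[Cactus]
    path: np.ndarray  # cactus index per analyzed column
    analyzed_columns: tuple[int, ...]  # 0-based variable columns, ascending
    full_path: np.ndarray  # cactus index per alignment column
    switch_penalty: float
    n_iterations: int
    total_cost: float
    labels: tuple[str, ...]  # sequence ids

    @property
    def n_cacti(self) -> int:
        return len(self.cacti)

    def boundaries(self) -> list[int]:
        """0-based columns where the full-column path switches cactus."""
        fp = self.full_path
        return [int(c) for c in np.nonzero(fp[1:] != fp[:-1])[0] + 1]

    def to_json(self, path: str | Path, seed: int | None = None) -> None:
        payload = {
            "tool": "duptrace",
            "seed": seed,
            "labels": list(self.labels),
            "switch_penalty": self.switch_penalty,
            "n_iterations": self.n_iterations,
            "total_cost": self.total_cost,
            "analyzed_columns": [c + 1 for c in self.analyzed_columns],
            "path": [int(x) for x in self.path],
            "full_path": [int(x) for x in self.full_path],
            "cacti": [
                {
                    "columns": c.columns_1based,
                    "matrix": c.matrix.values.tolist(),
                }
                for c in self.cacti
            ],
        }
        Path(path).write_text(json.dumps(payload) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Segmentation":
        payload = json.loads(Path(path).read_text())
        labels = tuple(payload["labels"])
        cacti = [
            Cactus(
                matrix=DistanceMatrix(labels, np.array(c["matrix"])),
                columns=tuple(col - 1 for col in c["columns"]),
            )
            for c in payload["cacti"]
        ]
        return cls(
            cacti=cacti,
            path=np.array(payload["path"], dtype=int),
            analyzed_columns=tuple(c - 1 for c in payload["analyzed_columns"]),
            full_path=np.array(payload["full_path"], dtype=int),
            switch_penalty=float(payload["switch_penalty"]),
            n_iterations=int(payload["n_iterations"]),
            total_cost=float(payload["total_cost"]),
            labels=labels,
        )


# ---------------------------------------------------------------------------
# Column patterns

def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu


def _condensed_column_diffs(aln: Alignment, columns: Sequence[int]) -> np.ndarray:
    """(n_columns, n_pairs) matrix of 0/1 differences; nan where either
    sequence is gap/N at the column."""
    arr = aln.array
    valid = ~np.isin(arr, list(MISSING_CHARS))
    iu, ju = _pair_indices(aln.n_seqs)
    cols = np.asarray(columns, dtype=int)
    a = arr[:, cols]  # (n_seqs, n_cols)
    v = valid[:, cols]
    diff = (a[iu] != a[ju]).astype(float).T  # (n_cols, n_pairs)
    ok = (v[iu] & v[ju]).T
    diff[~ok] = np.nan
    return diff


def _square_from_condensed(vec: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, n))
    iu, ju = _pair_indices(n)
    out[iu, ju] = vec
    out[ju, iu] = vec
    return out


def column_diff_matrix(aln: Alignment, col: int) -> DistanceMatrix:
    """0/1 difference matrix of one column (0-based); gap/N pairs are nan."""
    if not (0 <= col < aln.n_cols):
        raise DataError(f"column {col} out of range for {aln.n_cols} columns")
    vec = _condensed_column_diffs(aln, [col])[0]
    return DistanceMatrix(aln.ids, _square_from_condensed(vec, aln.n_seqs))


def _cactus_vector(diffs: np.ndarray) -> np.ndarray:
    """Condensed cactus pattern: nanmean over columns, max-normalized."""
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(diffs, axis=0)
    mean = np.nan_to_num(mean, nan=0.0)
    peak = mean.max()
    if peak > 0:
        mean = mean / peak
    return mean


def _emission_costs(diffs: np.ndarray, cacti: np.ndarray) -> np.ndarray:
    """(n_cols, n_cacti) mean squared deviation over non-missing pairs."""
    dev = diffs[:, None, :] - cacti[None, :, :]
    with np.errstate(invalid="ignore"):
        cost = np.nanmean(dev**2, axis=2)
    return np.nan_to_num(cost, nan=0.0)


def emission_cost(aln: Alignment, col: int, cactus: Cactus) -> float:
    """Mean squared deviation between one column's 0/1 differences and a
    cactus pattern, over pairs where the column is informative."""
    vec = _condensed_column_diffs(aln, [col])
    iu, ju = _pair_indices(aln.n_seqs)
    cvec = cactus.matrix.values[iu, ju][None, :]
    return float(_emission_costs(vec, cvec)[0, 0])


# ---------------------------------------------------------------------------
# Viterbi assignment

def viterbi_assign(costs: np.ndarray, switch_penalty: float) -> np.ndarray:
    """Minimum-cost state path over columns.

    Total cost = sum of per-column emissions + switch_penalty per state
    change. Ties resolve to the smallest state index, so the path is
    deterministic.
    """
    costs = np.asarray(costs, dtype=float)
    if costs.ndim != 2 or costs.size == 0:
        raise DataError("cost table must be a nonempty 2-D array")
    n_cols, n_states = costs.shape
    best = costs[0].copy()
    back = np.zeros((n_cols, n_states), dtype=int)
    for t in range(1, n_cols):
        # staying beats switching at equal cost; argmin takes smallest index
        stay = best
        switch_from = int(np.argmin(best))
        switch_cost = best[switch_from] + switch_penalty
        prev = np.where(stay <= switch_cost, np.arange(n_states), switch_from)
        base = np.minimum(stay, switch_cost)
        # a "switch" into the same state is just staying; handled since
        # stay <= switch_cost whenever switch_from == state
        best = base + costs[t]
        back[t] = prev
    path = np.zeros(n_cols, dtype=int)
    path[-1] = int(np.argmin(best))
    for t in range(n_cols - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def path_cost(costs: np.ndarray, path: np.ndarray, switch_penalty: float) -> float:
    emis = float(costs[np.arange(len(path)), path].sum())
    switches = int((np.asarray(path)[1:] != np.asarray(path)[:-1]).sum())
    return emis + switch_penalty * switches


# ---------------------------------------------------------------------------
# Iterative partition fit

def _variable_columns(aln: Alignment) -> np.ndarray:
    arr = aln.array
    var = []
    for c in range(aln.n_cols):
        chars = set(arr[:, c]) - MISSING_CHARS
        if len(chars) >= 2:
            var.append(c)
    return np.array(var, dtype=int)


def _centroid(diffs: np.ndarray) -> np.ndarray:
    """Mean 0/1 difference pattern over columns (the MSE-optimal
    representative); missing pairs contribute nothing."""
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(diffs, axis=0)
    return np.nan_to_num(mean, nan=0.0)


def _runs(path: np.ndarray) -> list[tuple[int, int]]:
    """Maximal half-open runs of constant state along the path."""
    bounds = [0] + [i for i in range(1, len(path)) if path[i] != path[i - 1]]
    bounds.append(len(path))
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def _best_split(
    cum1: np.ndarray, a: int, b: int, min_segment: int
) -> tuple[int, float] | None:
    """Best change point of run [a, b): split position and estimated gain.

    Gain is the drop in summed squared deviation (around per-side centroids
    versus the whole run's centroid), in per-pair units; both sides must
    keep at least ``min_segment`` columns. Missing pairs are scored as no
    difference here — the proposal is a heuristic; acceptance always uses
    the exact total cost.
    """
    if b - a < 2 * min_segment:
        return None

    def sse(i: int, j: int) -> np.ndarray:
        s1 = cum1[j] - cum1[i]
        return s1 - s1**2 / (j - i)

    splits = np.arange(a + min_segment, b - min_segment + 1)
    s1l = cum1[splits] - cum1[a]  # (n_splits, P)
    s1r = cum1[b] - cum1[splits]
    wl = (splits - a)[:, None].astype(float)
    wr = (b - splits)[:, None].astype(float)
    sse_l = (s1l - s1l**2 / wl).sum(axis=1)
    sse_r = (s1r - s1r**2 / wr).sum(axis=1)
    gains = sse(a, b).sum() - (sse_l + sse_r)
    k = int(np.argmax(gains))
    return int(splits[k]), float(gains[k])


def _refine(
    diffs: np.ndarray,
    vecs: list[np.ndarray],
    path: np.ndarray,
    switch_penalty: float,
    max_rounds: int = 20,
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray, float]:
    """Alternate recomputing cactus patterns from their assigned columns and
    re-running the Viterbi assignment until the total cost stops dropping.

    Cacti left without columns keep their previous pattern so states are
    never lost mid-fit (final pruning drops them). Deterministic; the cost
    is non-increasing by construction.
    """
    costs = _emission_costs(diffs, np.array(vecs))
    total = path_cost(costs, path, switch_penalty)
    for _ in range(max_rounds):
        new_vecs = [
            _centroid(diffs[path == k]) if np.any(path == k) else vecs[k]
            for k in range(len(vecs))
        ]
        new_costs = _emission_costs(diffs, np.array(new_vecs))
        new_path = viterbi_assign(new_costs, switch_penalty)
        new_total = path_cost(new_costs, new_path, switch_penalty)
        if new_total < total - 1e-12:
            vecs, costs, path, total = new_vecs, new_costs, new_path, new_total
        else:
            break
    return vecs, costs, path, total


def fit_partition(
    aln: Alignment,
    n_iterations: int = 5,
    min_segment: int = 10,
    switch_penalty: float | None = None,
) -> Segmentation:
    """Iteratively propose and test cacti, then assign every column.

    Starts from a single cactus (the mean pattern over all variable
    columns). Each iteration proposes one new cactus at the change point
    that most reduces the squared deviation around per-side centroids
    (both sides at least ``min_segment`` analyzed columns), refines the
    seeded assignment, and keeps the proposal only if the total path cost
    drops; proposing stops early once no split improves. Monomorphic
    columns carry no signal; they are assigned afterwards to the preceding
    variable column's cactus.

    ``switch_penalty`` defaults to twice the median per-column emission
    cost of the initial single-cactus fit (scale-free).
    """
    if aln.n_seqs < 4:
        raise DataError("fit_partition needs an alignment with >=4 sequences")
    if min_segment < 1:
        raise DataError("min_segment must be >= 1")
    if min_segment > aln.n_cols:
        raise DataError(
            f"min_segment={min_segment} exceeds alignment length {aln.n_cols}"
        )
    if n_iterations < 0:
        raise DataError("n_iterations must be >= 0")

    var_cols = _variable_columns(aln)
    if len(var_cols) == 0:
        raise DataError("alignment has no variable columns to segment")
    diffs = _condensed_column_diffs(aln, var_cols)
    cum1 = np.concatenate(
        [np.zeros((1, diffs.shape[1])), np.cumsum(np.nan_to_num(diffs), axis=0)]
    )

    cacti_vecs = [_centroid(diffs)]
    costs = _emission_costs(diffs, np.array(cacti_vecs))
    if switch_penalty is None:
        switch_penalty = 2.0 * float(np.median(costs[:, 0]))
    path = np.zeros(len(var_cols), dtype=int)
    total = path_cost(costs, path, switch_penalty)

    for _ in range(n_iterations):
        # propose a new cactus from the change point, within one current
        # segment, that most reduces the squared deviation around centroids
        best = None
        for a, b in _runs(path):
            split = _best_split(cum1, a, b, min_segment)
            if split is None:
                continue
            s, gain = split
            if best is None or gain > best[0]:
                best = (gain, a, s, b)
        if best is None:
            break
        _, a, s, b = best
        accepted = False
        for lo, hi in ((s, b), (a, s)):
            # seed the trial with the split applied, then let refinement
            # re-estimate patterns and re-run the assignment
            candidate = _centroid(diffs[lo:hi])
            trial_vecs = cacti_vecs + [candidate]
            trial_path = path.copy()
            trial_path[lo:hi] = len(cacti_vecs)
            trial_vecs, trial_costs, trial_path, trial_total = _refine(
                diffs, trial_vecs, trial_path, switch_penalty
            )
            if trial_total < total - 1e-12:
                cacti_vecs, costs, path, total = (
                    trial_vecs,
                    trial_costs,
                    trial_path,
                    trial_total,
                )
                accepted = True
                break
        if not accepted:
            break

    # final pruning: recompute each cactus from its assigned columns, drop
    # empty ones, remap the path; reported matrices are max-normalized
    kept = [k for k in range(len(cacti_vecs)) if np.any(path == k)]
    remap = {old: new for new, old in enumerate(kept)}
    final_vecs = []
    for old in kept:
        cols_mask = path == old
        final_vecs.append(_cactus_vector(diffs[cols_mask]))
    path = np.array([remap[p] for p in path], dtype=int)

    # monomorphic columns take the preceding variable column's state
    full_path = np.zeros(aln.n_cols, dtype=int)
    current = path[0]
    vi = 0
    var_set = {int(c): int(p) for c, p in zip(var_cols, path)}
    for c in range(aln.n_cols):
        if c in var_set:
            current = var_set[c]
        full_path[c] = current
    # leading monomorphic columns take the first analyzed state
    full_path[: int(var_cols[0])] = path[0]

    n = aln.n_seqs
    cacti = []
    for k, vec in enumerate(final_vecs):
        cols = tuple(int(c) for c in var_cols[path == k])
        cacti.append(
            Cactus(
                matrix=DistanceMatrix(aln.ids, _square_from_condensed(vec, n)),
                columns=cols,
            )
        )
    return Segmentation(
        cacti=cacti,
        path=path,
        analyzed_columns=tuple(int(c) for c in var_cols),
        full_path=full_path,
        switch_penalty=float(switch_penalty),
        n_iterations=n_iterations,
        total_cost=float(total),
        labels=aln.ids,
    )
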