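"""Co-linear anchor chaining: exact DP, bounded-lookback DP, and the
sub-partitioned inner-loop variant that models a fixed-trip-count
hardware pipeline.

The recurrence scores a predecessor j of anchor i as ``alpha - beta``
with ``alpha = min(y_i - y_j, x_i - x_j, w_i)`` and, for diagonal
difference ``d = |(y_i - y_j) - (x_i - x_j)|``,
``beta = 0`` if ``d == 0`` else
``beta = gap_scale * mean_span * d + 0.5 * log2(d)``.

The bounded variant examines at most ``H`` predecessors per anchor (the
inner loop's maximum trip count); the sub-partitioned variant processes
that candidate range in consecutive slices of at most ``P`` candidates,
carrying a running maximum, and must reproduce the bounded results
exactly.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass, field

import numpy as np

from .anchors import Anchor, ChainTask

__all__ = [
    "UNBOUNDED",
    "NO_PARENT",
    "ChainingParams",
    "DPResult",
    "Chain",
    "task_mean_span",
    "transition_score",
    "chain_scores",
    "chain_scores_subpartitioned",
    "backtrack_chains",
    "brute_force_best_score",
]

#: Sentinel lookback bound meaning "examine every in-window predecessor".
UNBOUNDED: int = sys.maxsize

#: Parent-pointer value for chain starts.
NO_PARENT: int = -1


@dataclass(frozen=True)
class ChainingParams:
    """Chaining thresholds and engine bounds.

    ``H`` is the maximum number of predecessors examined per anchor
    (:data:`UNBOUNDED` disables the bound); ``P`` is the sub-partition
    size of the restructured inner loop.
    """

    max_dist_x: int = 5000
    max_dist_y: int = 5000
    bandwidth: int = 500
    gap_scale: float = 0.01
    H: int = 512
    P: int = 64
    min_score: float = 40.0
    min_cnt: int = 3

    def __post_init__(self) -> None:
        for name in ("max_dist_x", "max_dist_y", "bandwidth", "min_cnt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.gap_scale < 0:
            raise ValueError(f"gap_scale must be >= 0, got {self.gap_scale}")
        if self.H != UNBOUNDED and self.H < 1:
            raise ValueError(f"H must be >= 1 or UNBOUNDED, got {self.H}")
        if self.P < 1:
            raise ValueError(f"P must be >= 1, got {self.P}")

    @property
    def bounded(self) -> bool:
        return self.H != UNBOUNDED


@dataclass
class DPResult:
    """Per-anchor chaining DP output.

    ``f[i]`` is the best chain score ending at anchor i, ``parent[i]`` its
    best predecessor (:data:`NO_PARENT` for chain starts) and
    ``trip_count[i]`` the number of predecessor candidates the inner loop
    examined.  ``subparts`` is filled by the sub-partitioned engine only.
    """

    f: np.ndarray
    parent: np.ndarray
    trip_count: np.ndarray
    subparts: np.ndarray | None = None

    @classmethod
    def empty(cls) -> "DPResult":
        return cls(
            f=np.empty(0, dtype=np.float64),
            parent=np.empty(0, dtype=np.int64),
            trip_count=np.empty(0, dtype=np.int64),
        )

    @property
    def n(self) -> int:
        return len(self.f)

    def best_score(self) -> float | None:
        if self.n == 0:
            return None
        return float(self.f.max())


@dataclass(frozen=True)
class Chain:
    """A backtracked chain: strictly increasing anchor indices and its score."""

    anchor_indices: tuple[int, ...]
    score: float

    @property
    def n_anchors(self) -> int:
        return len(self.anchor_indices)


def task_mean_span(task: ChainTask) -> int:
    """Arithmetic mean of anchor spans, rounded to nearest integer, min 1."""
    if not task.anchors:
        return 1
    mean = sum(a.w for a in task.anchors) / len(task.anchors)
    return max(1, int(round(mean)))


def transition_score(
    a_j: Anchor, a_i: Anchor, params: ChainingParams, mean_span: int
) -> float | None:
    """Score of extending a chain from predecessor ``a_j`` to ``a_i``.

    Returns ``None`` (ineligible) unless ``a_j`` strictly precedes ``a_i``
    on both axes within the distance and bandwidth ceilings.
    """
    dx = a_i.x - a_j.x
    dy = a_i.y - a_j.y
    if dx <= 0 or dy <= 0 or dx > params.max_dist_x or dy > params.max_dist_y:
        return None
    d = abs(dy - dx)
    if d > params.bandwidth:
        return None
    alpha = min(dy, dx, a_i.w)
    if d == 0:
        return float(alpha)
    beta = params.gap_scale * mean_span * d + 0.5 * math.log2(d)
    return float(alpha - beta)


def _candidate_values(
    i: int,
    lo: int,
    hi: int,
    xs: np.ndarray,
    ys: np.ndarray,
    w_i: int,
    f: np.ndarray,
    params: ChainingParams,
    mean_span: int,
) -> np.ndarray:
    """f[j] + transition_score(j, i) for j in [lo, hi); -inf where ineligible."""
    dx = xs[i] - xs[lo:hi]
    dy = ys[i] - ys[lo:hi]
    d = np.abs(dy - dx)
    eligible = (
        (dx > 0)
        & (dy > 0)
        & (dx <= params.max_dist_x)
        & (dy <= params.max_dist_y)
        & (d <= params.bandwidth)
    )
    alpha = np.minimum(np.minimum(dx, dy), w_i).astype(np.float64)
    d_safe = np.where(d > 0, d, 1).astype(np.float64)
    beta = np.where(
        d > 0, params.gap_scale * mean_span * d + 0.5 * np.log2(d_safe), 0.0
    )
    # grouping matches the scalar recurrence f[j] + (alpha - beta) bit-for-bit
    values = f[lo:hi] + (alpha - beta)
    values[~eligible] = -np.inf
    return values


def _best_descending(values: np.ndarray, lo: int) -> tuple[float, int]:
    """Max of ``values`` (indexed from ``lo``), ties to the largest j —
    the predecessor met first when scanning j downward."""
    rev = values[::-1]
    k = int(np.argmax(rev))
    return float(rev[k]), lo + len(values) - 1 - k


def chain_scores(task: ChainTask, params: ChainingParams) -> DPResult:
    """Chaining DP over a sorted task.

    For each anchor i the candidate window starts at ``st_i``, the
    smallest index with ``x_i - x_st <= max_dist_x`` (binary search), and
    the inner loop scans j from i-1 down to ``max(st_i, i - H)``.
    """
    n = task.n
    if n == 0:
        return DPResult.empty()
    xs, ys, ws = task.coord_arrays()
    mean_span = task_mean_span(task)
    f = np.empty(n, dtype=np.float64)
    parent = np.full(n, NO_PARENT, dtype=np.int64)
    trip_count = np.zeros(n, dtype=np.int64)
    for i in range(n):
        w_i = float(ws[i])
        st = int(np.searchsorted(xs, xs[i] - params.max_dist_x, side="left"))
        lo = max(st, i - params.H) if params.bounded else st
        f[i] = w_i
        trip_count[i] = i - lo
        if lo < i:
            values = _candidate_values(i, lo, i, xs, ys, ws[i], f, params, mean_span)
            best, j_best = _best_descending(values, lo)
            if best > w_i:
                f[i] = best
                parent[i] = j_best
    return DPResult(f=f, parent=parent, trip_count=trip_count)


def chain_scores_subpartitioned(task: ChainTask, params: ChainingParams) -> DPResult:
    """Bounded-H DP computed in sub-partitions of at most ``P`` candidates.

    Processes each anchor's candidate range in consecutive descending
    slices, carrying a partial running maximum, and returns results
    identical to :func:`chain_scores` at the same finite ``H`` plus the
    per-anchor sub-partition count.
    """
    if not params.bounded:
        raise ValueError(
            "the sub-partitioned engine models fixed-bound hardware; H must be finite"
        )
    n = task.n
    if n == 0:
        res = DPResult.empty()
        res.subparts = np.empty(0, dtype=np.int64)
        return res
    xs, ys, ws = task.coord_arrays()
    mean_span = task_mean_span(task)
    P = params.P
    f = np.empty(n, dtype=np.float64)
    parent = np.full(n, NO_PARENT, dtype=np.int64)
    trip_count = np.zeros(n, dtype=np.int64)
    subparts = np.zeros(n, dtype=np.int64)
    for i in range(n):
        w_i = float(ws[i])
        st = int(np.searchsorted(xs, xs[i] - params.max_dist_x, side="left"))
        lo = max(st, i - params.H)
        trip_count[i] = i - lo
        best = -np.inf
        j_best = NO_PARENT
        hi = i
        while hi > lo:
            part_lo = max(lo, hi - P)
            values = _candidate_values(
                i, part_lo, hi, xs, ys, ws[i], f, params, mean_span
            )
            part_best, part_j = _best_descending(values, part_lo)
            # strict comparison keeps the higher-j (earlier-scanned) winner
            if part_best > best:
                best, j_best = part_best, part_j
            subparts[i] += 1
            hi = part_lo
        if best > w_i:
            f[i] = best
            parent[i] = j_best
        else:
            f[i] = w_i
    return DPResult(f=f, parent=parent, trip_count=trip_count, subparts=subparts)


def backtrack_chains(
    task: ChainTask, dp: DPResult, params: ChainingParams
) -> list[Chain]:
    """Extract anchor-disjoint chains from the DP arrays.

    Anchors are visited in descending ``f``; from each unused anchor the
    parent pointers are followed while the predecessor is unused.  When
    the walk hits an anchor already claimed by a better chain, the shared
    prefix's score is subtracted.  Chains failing ``min_score``/``min_cnt``
    are dropped (their anchors stay consumed).
    """
    n = dp.n
    if n == 0:
        return []
    order = sorted(range(n), key=lambda i: (-dp.f[i], i))
    used = np.zeros(n, dtype=bool)
    chains: list[Chain] = []
    for terminal in order:
        if used[terminal]:
            continue
        path = [terminal]
        used[terminal] = True
        j = int(dp.parent[terminal])
        base = 0.0
        while j != NO_PARENT:
            if used[j]:
                base = float(dp.f[j])
                break
            path.append(j)
            used[j] = True
            j = int(dp.parent[j])
        score = float(dp.f[terminal]) - base
        if score >= params.min_score and len(path) >= params.min_cnt:
            path.reverse()
            chains.append(Chain(anchor_indices=tuple(path), score=score))
    chains.sort(key=lambda c: (-c.score, c.anchor_indices[-1]))
    return chains


def brute_force_best_score(task: ChainTask, params: ChainingParams) -> float | None:
    """Best chain score by the plain quadratic recurrence.

    Every j < i passing eligibility is a candidate — no start-window
    binary search and no trip-count bound.  Test oracle; O(n^2).
    """
    n = task.n
    if n == 0:
        return None
    mean_span = task_mean_span(task)
    anchors = task.anchors
    f = [0.0] * n
    for i in range(n):
        best = float(anchors[i].w)
        for j in range(i):
            s = transition_score(anchors[j], anchors[i], params, mean_span)
            if s is not None and f[j] + s > best:
                best = f[j] + s
        f[i] = best
    return max(f)
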