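"""Distances between persistence diagrams and between diagram sequences.

Three diagram comparisons are provided:

* ``modified_hausdorff`` — the Hausdorff construction with each directed
  supremum replaced by an average of point-to-set minima (Euclidean ground
  metric).  Symmetric, nonnegative, zero on identical diagrams, but it
  does not satisfy the triangle inequality: a semimetric.  Robust to a
  single outlying diagram point, which is why it is the default for noisy
  activity data.
* ``hausdorff`` — the classical max-of-directed-suprema set distance,
  Euclidean ground metric.
* ``wasserstein`` — the q-Wasserstein diagram distance: an optimal
  assignment between the two point sets augmented by the diagonal y = x,
  L-infinity ground metric, so an unmatched point (b, d) may retire to the
  diagonal at cost (d - b) / 2.  A true metric.

Two windowed signals are compared window-by-window: the k-th diagram of
one sequence against the k-th of the other, producing a distance signal
whose mean is the scalar summary used at cohort level.

Empty diagrams occur (a monotone window has no min-max pair).  The default
policy treats the diagonal as the empty diagram: the distance from a
nonempty diagram to an empty one is the directed (average resp. supremum)
Euclidean distance of its points to the line y = x, and two empty diagrams
are at distance zero.  Wasserstein needs no special case — diagonal
augmentation already encodes it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .persistence import PersistenceDiagram
from .windowing import DiagramSequence

__all__ = [
    "DistanceConfig",
    "DistanceSignal",
    "point_distance",
    "directed_average_distance",
    "modified_hausdorff",
    "hausdorff",
    "wasserstein",
    "diagram_distance",
    "distance_signal",
    "mean_distance",
]

METRICS = ("modified_hausdorff", "hausdorff", "wasserstein")
EMPTY_POLICIES = ("diagonal", "zero")

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class DistanceConfig:
    """Which diagram comparison to use and how to handle empty diagrams.

    metric : one of {"modified_hausdorff", "hausdorff", "wasserstein"}.
    q : Wasserstein order, >= 1 (default 1; ignored by the other metrics).
    empty_diagram_policy : "diagonal" (default) measures a nonempty diagram
        against the line y = x when its partner is empty; "zero" makes any
        comparison involving an empty diagram zero.  Wasserstein ignores
        the policy (augmentation subsumes it).
    """

    metric: str = "modified_hausdorff"
    q: float = 1.0
    empty_diagram_policy: str = "diagonal"

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if self.q < 1:
            raise ValueError(f"Wasserstein order q must be >= 1, got {self.q}")
        if self.empty_diagram_policy not in EMPTY_POLICIES:
            raise ValueError(
                f"empty_diagram_policy must be one of {EMPTY_POLICIES}, "
                f"got {self.empty_diagram_policy!r}"
            )


@dataclass(frozen=True)
class DistanceSignal:
    """Per-window distances between two windowed signals, temporal order."""

    values: np.ndarray
    window_length: int
    id_a: Optional[str] = None
    id_b: Optional[str] = None
    metric: str = "modified_hausdorff"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("distance signal must be one-dimensional")
        if vals.size and (np.any(vals < 0) or not np.all(np.isfinite(vals))):
            raise ValueError("distances must be finite and nonnegative")
        vals = vals.copy()
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return int(self.values.size)


def point_distance(
    a: Tuple[float, float], b: Tuple[float, float], ground: str = "euclidean"
) -> float:
    """Distance between two diagram points under the given ground metric."""
    dx = a[0] - b[0]
    dy = a[1] - b[1]
    if ground == "euclidean":
        return float(np.hypot(dx, dy))
    if ground == "chebyshev":
        return float(max(abs(dx), abs(dy)))
    raise ValueError(f"unknown ground metric {ground!r}")


def _cross_distances(A: np.ndarray, B: np.ndarray, ground: str) -> np.ndarray:
    """|A| x |B| matrix of ground distances between diagram points."""
    diff = A[:, None, :] - B[None, :, :]
    if ground == "euclidean":
        return np.sqrt(np.sum(diff * diff, axis=2))
    if ground == "chebyshev":
        return np.max(np.abs(diff), axis=2)
    raise ValueError(f"unknown ground metric {ground!r}")


def directed_average_distance(A: PersistenceDiagram, B: PersistenceDiagram) -> float:
    """Mean over points of A of the Euclidean distance to the nearest point of B."""
    if len(A) == 0 or len(B) == 0:
        raise ValueError("directed average distance requires nonempty diagrams")
    D = _cross_distances(A.points, B.points, "euclidean")
    return float(np.mean(np.min(D, axis=1)))


def _diagonal_directed(points: np.ndarray, reduce_fn) -> float:
    """Directed Euclidean distance from points to the line y = x."""
    return float(reduce_fn(np.abs(points[:, 1] - points[:, 0]) / _SQRT2))


def _set_distance(
    A: PersistenceDiagram,
    B: PersistenceDiagram,
    reduce_fn,
    empty_policy: str,
) -> float:
    if len(A) == 0 and len(B) == 0:
        return 0.0
    if len(A) == 0 or len(B) == 0:
        if empty_policy == "zero":
            return 0.0
        pts = (B if len(A) == 0 else A).points
        return _diagonal_directed(pts, reduce_fn)
    D = _cross_distances(A.points, B.points, "euclidean")
    return float(
        max(reduce_fn(np.min(D, axis=1)), reduce_fn(np.min(D, axis=0)))
    )


def modified_hausdorff(
    A: PersistenceDiagram,
    B: PersistenceDiagram,
    empty_policy: str = "diagonal",
) -> float:
    """Modified Hausdorff semimetric: max of the two directed averages.

    d(A, B) = max( mean_a min_b |a-b|, mean_b min_a |b-a| ), Euclidean
    ground metric.  Does not satisfy the triangle inequality.
    """
    return _set_distance(A, B, np.mean, empty_policy)


def hausdorff(
    A: PersistenceDiagram,
    B: PersistenceDiagram,
    empty_policy: str = "diagonal",
) -> float:
    """Hausdorff distance: max of the two directed sup-min distances."""
    return _set_distance(A, B, np.max, empty_policy)


def wasserstein(
    A: PersistenceDiagram, B: PersistenceDiagram, q: float = 1.0
) -> float:
    """q-Wasserstein distance with diagonal augmentation, L-infinity ground.

    Both point sets are augmented with diagonal slots: a point (b, d) may
    match the diagonal at cost (d - b) / 2, its L-infinity distance to the
    nearest diagonal point.  The optimal assignment over the augmented
    sets is solved exactly (Hungarian algorithm) and the cost is
    (sum of matched costs^q)^(1/q).
    """
    if q < 1:
        raise ValueError(f"Wasserstein order q must be >= 1, got {q}")
    m, n = len(A), len(B)
    if m == 0 and n == 0:
        return 0.0
    cost = np.zeros((m + n, n + m), dtype=float)
    if m and n:
        cost[:m, :n] = _cross_distances(A.points, B.points, "chebyshev") ** q
    if m:
        # A point i may retire to any diagonal slot
        cost[:m, n:] = ((A.deaths - A.births)[:, None] / 2.0) ** q
    if n:
        cost[m:, :n] = ((B.deaths - B.births)[None, :] / 2.0) ** q
    # diagonal-to-diagonal matches cost nothing (already zero)
    rows, cols = linear_sum_assignment(cost)
    total = float(cost[rows, cols].sum())
    return total ** (1.0 / q)


def diagram_distance(
    A: PersistenceDiagram,
    B: PersistenceDiagram,
    config: DistanceConfig = DistanceConfig(),
) -> float:
    """Distance between two diagrams under the configured comparison."""
    if config.metric == "modified_hausdorff":
        return modified_hausdorff(A, B, config.empty_diagram_policy)
    if config.metric == "hausdorff":
        return hausdorff(A, B, config.empty_diagram_policy)
    return wasserstein(A, B, config.q)


def _padded_points(seq: DiagramSequence) -> Tuple[np.ndarray, np.ndarray]:
    """Stack a sequence's diagrams into (W, R, 2) padded array plus mask."""
    W = len(seq)
    R = max((len(d) for d in seq.diagrams), default=0)
    pts = np.zeros((W, max(R, 1), 2), dtype=float)
    mask = np.zeros((W, max(R, 1)), dtype=bool)
    for k, d in enumerate(seq.diagrams):
        r = len(d)
        if r:
            pts[k, :r, 0] = d.births
            pts[k, :r, 1] = d.deaths
            mask[k, :r] = True
    return pts, mask


def _batch_set_distances(
    seqA: DiagramSequence,
    seqB: DiagramSequence,
    use_mean: bool,
    empty_policy: str,
) -> np.ndarray:
    """Vectorised per-window Hausdorff / modified-Hausdorff distances.

    Equivalent to calling the scalar functions window by window; padding
    plus masking keeps the whole sweep in a handful of array operations,
    which matters when a cohort requires millions of window comparisons.
    """
    PA, MA = _padded_points(seqA)
    PB, MB = _padded_points(seqB)
    diff = PA[:, :, None, :] - PB[:, None, :, :]
    D = np.sqrt(np.sum(diff * diff, axis=3))  # (W, R, S)
    big = np.inf
    D_a = np.where(MB[:, None, :], D, big)  # invalid B columns masked out
    D_b = np.where(MA[:, :, None], D, big)
    min_over_B = np.min(D_a, axis=2)  # (W, R)
    min_over_A = np.min(D_b, axis=1)  # (W, S)
    cntA = MA.sum(axis=1)
    cntB = MB.sum(axis=1)
    both = (cntA > 0) & (cntB > 0)
    out = np.zeros(len(seqA), dtype=float)
    if np.any(both):
        if use_mean:
            dirAB = np.sum(np.where(MA, min_over_B, 0.0), axis=1) / np.maximum(cntA, 1)
            dirBA = np.sum(np.where(MB, min_over_A, 0.0), axis=1) / np.maximum(cntB, 1)
        else:
            dirAB = np.max(np.where(MA, min_over_B, -big), axis=1)
            dirBA = np.max(np.where(MB, min_over_A, -big), axis=1)
        out[both] = np.maximum(dirAB, dirBA)[both]
    # windows where at least one diagram is empty
    reduce_fn = np.mean if use_mean else np.max
    for k in np.flatnonzero(~both):
        if empty_policy == "zero" or (cntA[k] == 0 and cntB[k] == 0):
            out[k] = 0.0
        else:
            pts = PA[k][MA[k]] if cntA[k] else PB[k][MB[k]]
            out[k] = _diagonal_directed(pts, reduce_fn)
    return out


def distance_signal(
    seqA: DiagramSequence,
    seqB: DiagramSequence,
    config: DistanceConfig = DistanceConfig(),
) -> DistanceSignal:
    """Window-by-window distances between two diagram sequences.

    Window k of one signal is compared to window k of the other; the
    sequences must have equal length and window size.
    """
    if len(seqA) != len(seqB):
        raise ValueError(
            f"diagram sequences have different lengths: {len(seqA)} vs {len(seqB)}"
        )
    if seqA.window_length != seqB.window_length:
        raise ValueError(
            "diagram sequences were built with different window lengths: "
            f"{seqA.window_length} vs {seqB.window_length}"
        )
    if config.metric in ("modified_hausdorff", "hausdorff"):
        values = _batch_set_distances(
            seqA,
            seqB,
            use_mean=(config.metric == "modified_hausdorff"),
            empty_policy=config.empty_diagram_policy,
        )
    else:
        values = np.array(
            [
                wasserstein(a, b, config.q)
                for a, b in zip(seqA.diagrams, seqB.diagrams)
            ],
            dtype=float,
        )
    return DistanceSignal(
        values=values,
        window_length=seqA.window_length,
        id_a=seqA.source_id,
        id_b=seqB.source_id,
        metric=config.metric,
    )


def mean_distance(ds: DistanceSignal) -> float:
    """Arithmetic mean of a distance signal: the scalar pairwise summary."""
    if len(ds) == 0:
        raise ValueError("cannot average an empty distance signal")
    return float(np.mean(ds.values))
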