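"""0-dimensional sublevel-set persistence of a discrete signal.

A signal f on {1, ..., n} is extended by the sentinel conventions
f(0) = +inf and f(n+1) = -inf, and ties between equal sample values are
broken by an infinitesimal perturbation f~(i) = f(i) + eps*i.  The
perturbation is realised exactly as lexicographic comparison of
(value, index) keys; no floating-point epsilon is ever added to the data.

Under the tie-broken total order, local minima are births of connected
components of the sublevel sets {i : f~(i) <= t} and local maxima are the
merge (death) levels.  The pairing of minima to maxima is computed by an
explicit inductive rule that realises the elder rule: each maximum, taken
in ascending order, kills the youngest still-unpaired minimum it can reach
without crossing another candidate minimum.  The result is the persistence
diagram: a multiset of (birth, death) value pairs, one per min-max pair.

The right sentinel makes the count of minima and maxima equal, so every
diagram point is a finite pair; there is no essential (infinite) class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .signal import Signal

__all__ = [
    "ExtremaSet",
    "PersistenceDiagram",
    "order_precedes",
    "find_extrema",
    "pair_extrema",
    "compute_diagram",
    "diagram_to_barcode",
]


@dataclass(frozen=True)
class ExtremaSet:
    """Tie-broken local extrema of a signal, 1-based indices.

    ``minima`` and ``maxima`` each hold the same number r of indices and
    are sorted ascending by the (value, index) order, i.e. ``minima[0]``
    is the global minimum under tie-breaking.  Along the signal, minima
    and maxima strictly alternate.
    """

    minima: Tuple[int, ...]
    maxima: Tuple[int, ...]

    @property
    def r(self) -> int:
        return len(self.minima)


@dataclass(frozen=True)
class PersistenceDiagram:
    """Multiset of (birth, death) pairs with extremum provenance.

    ``births[k]`` is the signal value at the local minimum paired with the
    k-th local maximum (in ascending value order); ``deaths[k]`` the value
    at that maximum.  ``min_indices`` / ``max_indices`` record the 1-based
    signal indices the pair came from.  death >= birth always holds, with
    equality only when the paired extrema share a sample value and the tie
    is resolved by index order.
    """

    births: np.ndarray
    deaths: np.ndarray
    min_indices: Tuple[int, ...] = ()
    max_indices: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        births = np.asarray(self.births, dtype=float)
        deaths = np.asarray(self.deaths, dtype=float)
        if births.shape != deaths.shape or births.ndim != 1:
            raise ValueError("births and deaths must be 1-d arrays of equal length")
        births = births.copy()
        deaths = deaths.copy()
        births.setflags(write=False)
        deaths.setflags(write=False)
        object.__setattr__(self, "births", births)
        object.__setattr__(self, "deaths", deaths)

    def __len__(self) -> int:
        return int(self.births.size)

    @property
    def points(self) -> np.ndarray:
        """(r, 2) array of (birth, death) pairs."""
        return np.column_stack([self.births, self.deaths])

    @property
    def persistences(self) -> np.ndarray:
        """Lifetimes death - birth, all >= 0."""
        return self.deaths - self.births

    def as_multiset(self) -> List[Tuple[float, float]]:
        """Sorted list of (birth, death) tuples; canonical for comparison."""
        return sorted(zip(self.births.tolist(), self.deaths.tolist()))


def _keys(signal: Signal) -> np.ndarray:
    """Sample values with sentinels at positions 0 and n+1.

    Index i of the returned array is the 1-based signal index;
    comparison of (arr[i], i) tuples realises the tie-broken total order.
    """
    values = signal.values
    ext = np.empty(values.size + 2, dtype=float)
    ext[0] = np.inf
    ext[1:-1] = values
    ext[-1] = -np.inf
    return ext


def order_precedes(i: int, j: int, signal: Signal) -> bool:
    """The tie-broken sublevel order on {0, 1, ..., n+1}.

    True iff f(i) < f(j), or f(i) = f(j) and i <= j, with the sentinel
    values f(0) = +inf, f(n+1) = -inf.  A reflexive total order.
    """
    n = len(signal)
    if not (0 <= i <= n + 1) or not (0 <= j <= n + 1):
        raise IndexError(f"indices must lie in [0, {n + 1}], got ({i}, {j})")
    f = _keys(signal)
    return bool((f[i], i) <= (f[j], j))


def find_extrema(signal: Signal) -> ExtremaSet:
    """Tie-broken local minima and maxima of a signal.

    Index i (1 <= i <= n) is a minimum iff it strictly precedes both
    neighbours in the tie-broken order, a maximum iff both neighbours
    strictly precede it; the sentinels make index sets of equal size r.
    Both sets are returned sorted ascending by (value, index).
    Signals of length <= 1 have no extrema.
    """
    n = len(signal)
    if n == 0:
        return ExtremaSet((), ())
    f = _keys(signal)
    idx = np.arange(n + 2)
    # strict precedence i < j in the tie-broken order, vectorised over
    # adjacent positions: f[i] < f[j], or equal values and smaller index
    def precedes(i: np.ndarray, j: np.ndarray) -> np.ndarray:
        return (f[i] < f[j]) | ((f[i] == f[j]) & (i < j))

    interior = idx[1:-1]
    is_min = precedes(interior, interior - 1) & precedes(interior, interior + 1)
    is_max = precedes(interior - 1, interior) & precedes(interior + 1, interior)
    minima = interior[is_min]
    maxima = interior[is_max]
    order_min = np.lexsort((minima, f[minima]))
    order_max = np.lexsort((maxima, f[maxima]))
    return ExtremaSet(
        tuple(int(i) for i in minima[order_min]),
        tuple(int(i) for i in maxima[order_max]),
    )


def pair_extrema(signal: Signal, extrema: ExtremaSet) -> PersistenceDiagram:
    """Pair each local maximum with a local minimum by the inductive rule.

    Maxima b_1 < b_2 < ... < b_r (tie-broken value order) are processed in
    turn.  For b_k the candidate set U_k holds the still-unpaired minima
    that precede b_k in the order; among them the chosen partner is the
    largest-value minimum a_i such that no smaller candidate minimum lies
    strictly between positions a_i and b_k.  This is the elder rule: the
    component whose minimum is youngest dies at the merge level b_k.

    Returns the diagram {(f(a_sigma(k)), f(b_k)) : k = 1..r} with the
    originating indices recorded.  O(r^2) worst case, which is fine for
    the short windows this package works on.
    """
    if len(extrema.minima) != len(extrema.maxima):
        raise ValueError("extrema set is inconsistent: unequal minima/maxima counts")
    r = extrema.r
    if r == 0:
        return PersistenceDiagram(np.empty(0), np.empty(0))
    f = _keys(signal)
    a = extrema.minima  # positions, ascending by (value, index)
    b = extrema.maxima
    unassigned = list(range(r))  # candidate ranks, kept ascending
    sigma = [0] * r
    for k in range(r):
        b_pos = b[k]
        b_key = (f[b_pos], b_pos)
        # U_k: unpaired minima strictly preceding b_k in the order
        U = [i for i in unassigned if (f[a[i]], a[i]) < b_key]
        if not U:
            raise AssertionError(
                "empty candidate set while pairing: invariant violated"
            )
        chosen = None
        for pos_i, i in enumerate(reversed(U)):
            lo, hi = min(a[i], b_pos), max(a[i], b_pos)
            blocked = any(lo < a[j] < hi for j in U[: len(U) - 1 - pos_i])
            if not blocked:
                chosen = i
                break
        assert chosen is not None  # U[0] is always admissible
        sigma[k] = chosen
        unassigned.remove(chosen)
    births = np.array([f[a[sigma[k]]] for k in range(r)], dtype=float)
    deaths = np.array([f[b[k]] for k in range(r)], dtype=float)
    return PersistenceDiagram(
        births,
        deaths,
        min_indices=tuple(a[sigma[k]] for k in range(r)),
        max_indices=tuple(b),
    )


def compute_diagram(signal: Signal) -> PersistenceDiagram:
    """Persistence diagram of a signal: detect extrema, then pair them.

    Empty and length-1 signals yield an empty diagram.
    """
    return pair_extrema(signal, find_extrema(signal))


def diagram_to_barcode(diagram: PersistenceDiagram) -> List[List[float]]:
    """Diagram as a list of [birth, death] bars sorted by (birth, death).

    Lossless up to ordering; zero-length bars are kept.
    """
    return [list(p) for p in sorted(zip(diagram.births.tolist(), diagram.deaths.tolist()))]
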