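"""Independent reference implementations used only to check the package.

These deliberately share no code with the production paths: the
persistence oracle is a union-find sweep over the sublevel filtration of
the extended sequence on a path graph, and the Wasserstein oracle
enumerates every augmented matching explicitly.
"""

from __future__ import annotations

import itertools
from typing import List, Sequence, Tuple

import numpy as np


def unionfind_sublevel_diagram(values: Sequence[float]) -> List[Tuple[float, float]]:
    """0-dim sublevel persistence of [+inf, f(1..n), -inf] on a path graph.

    Vertices are added in ascending (value, index) order; when a vertex
    joins two existing components the one with the younger (larger-key)
    minimum dies there (elder rule).  Pairs whose birth or death index
    falls on a sentinel are discarded.  Returns a sorted list of
    (birth, death) value pairs.
    """
    n = len(values)
    f = [np.inf] + [float(v) for v in values] + [-np.inf]
    order = sorted(range(n + 2), key=lambda i: (f[i], i))
    parent: dict = {}
    comp_min: dict = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pairs: List[Tuple[float, float]] = []
    for i in order:
        roots = []
        for nb in (i - 1, i + 1):
            if nb in parent:
                r = find(nb)
                if r not in roots:
                    roots.append(r)
        parent[i] = i
        comp_min[i] = i
        if len(roots) == 2:
            ma, mb = comp_min[roots[0]], comp_min[roots[1]]
            if (f[ma], ma) < (f[mb], mb):
                younger = mb
            else:
                younger = ma
            if 1 <= younger <= n and 1 <= i <= n:
                pairs.append((f[younger], f[i]))
        members = [comp_min[r] for r in roots] + [i]
        for r in roots:
            parent[r] = i
        comp_min[i] = min(members, key=lambda m: (f[m], m))
    return sorted(pairs)


def brute_force_wasserstein(
    A: np.ndarray, B: np.ndarray, q: float = 1.0
) -> float:
    """q-Wasserstein by exhaustive enumeration of augmented matchings.

    Every point of A either matches a distinct point of B (L-infinity
    cost) or retires to the diagonal at cost (death - birth) / 2; B
    points left unmatched retire likewise.  Feasible only for tiny
    diagrams (a handful of points each).
    """
    A = np.asarray(A, dtype=float).reshape(-1, 2)
    B = np.asarray(B, dtype=float).reshape(-1, 2)
    m, n = len(A), len(B)

    def diag_cost(p: np.ndarray) -> float:
        return (p[1] - p[0]) / 2.0

    def linf(a: np.ndarray, b: np.ndarray) -> float:
        return float(np.max(np.abs(a - b)))

    best = np.inf
    idx_B = range(n)
    for k in range(min(m, n) + 1):
        for a_sub in itertools.combinations(range(m), k):
            for b_perm in itertools.permutations(idx_B, k):
                cost = 0.0
                for ai, bi in zip(a_sub, b_perm):
                    cost += linf(A[ai], B[bi]) ** q
                matched_a = set(a_sub)
                matched_b = set(b_perm)
                for i in range(m):
                    if i not in matched_a:
                        cost += diag_cost(A[i]) ** q
                for j in range(n):
                    if j not in matched_b:
                        cost += diag_cost(B[j]) ** q
                best = min(best, cost)
    return float(best ** (1.0 / q))
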