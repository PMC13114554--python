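"""Distances between Q-shapes.

Two families are provided:

* ``row_sum`` — the distance of two Q-shapes is the sum of a base distance
  over corresponding repertoire rows.  The default base distance is the
  0/1 indicator (0 for equal rows, 1 for rows that differ), which is the
  unit-normalized member of the "natural class" of measures sensitive only
  to how many entries two rows differ in.  A count-of-differing-entries
  base and optional Earth Mover's / symmetrized-KL bases are also
  available.
* ``p_norm`` — entrywise p-norm of the matrix difference for p >= 1,
  Euclidean at p = 2.

``pattern_from_table`` extracts the qualitative two-valued separation
pattern (a, b) with a < b from a pairwise distance table; for the dyad the
diagonal pairs {(0,0),(1,1)} and {(0,1),(1,0)} carry the large value b.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

from .network import NetState, NetworkSpec
from .qshape import QShape, compute_qshape

__all__ = [
    "DistanceSpec",
    "SeparationPattern",
    "qshape_distance",
    "distance_table",
    "pattern_from_table",
    "row_emd_hamming",
    "row_kl_sym",
]

_Row = Sequence[Fraction]


# ------------------------------------------------------------ base distances

def row_unit(q: _Row, r: _Row) -> Fraction:
    """0 if the rows are equal, 1 otherwise (the unit-normalized base)."""
    return Fraction(0) if list(q) == list(r) else Fraction(1)


def row_count(q: _Row, r: _Row) -> Fraction:
    """Number of entries on which the rows differ."""
    return Fraction(sum(1 for x, y in zip(q, r) if x != y))


def _hamming(i: int, k: int, n: int, d: int) -> int:
    si = NetState.from_index(i, n, d).values
    sk = NetState.from_index(k, n, d).values
    return sum(1 for a, b in zip(si, sk) if a != b)


def row_emd_hamming(q: _Row, r: _Row, n: int | None = None, d: int = 2) -> float:
    """Earth Mover's distance between rows, Hamming ground metric on states.

    Solved as a small transportation LP.  Provided for completeness; not a
    member of the natural class (it is sensitive to where mass moves, not
    only to how many entries differ).
    """
    from scipy.optimize import linprog

    size = len(q)
    if n is None:
        n = round(math.log(size, d))
    p = [float(x) for x in q]
    s = [float(x) for x in r]
    cost = [_hamming(i, k, n, d) for i in range(size) for k in range(size)]
    a_eq = []
    b_eq = []
    for i in range(size):  # row marginals
        row = [0.0] * (size * size)
        for k in range(size):
            row[i * size + k] = 1.0
        a_eq.append(row)
        b_eq.append(p[i])
    for k in range(size):  # column marginals
        col = [0.0] * (size * size)
        for i in range(size):
            col[i * size + k] = 1.0
        a_eq.append(col)
        b_eq.append(s[k])
    res = linprog(cost, A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - transportation LP is always feasible
        raise RuntimeError(f"EMD transportation LP failed: {res.message}")
    return float(res.fun)


def row_kl_sym(q: _Row, r: _Row) -> float:
    """Symmetrized Kullback-Leibler divergence (bits); infinite mass ratios error."""
    total = 0.0
    for x, y in zip(q, r):
        fx, fy = float(x), float(y)
        if (fx > 0) != (fy > 0):
            raise ValueError("KL undefined: supports differ")
        if fx > 0:
            total += 0.5 * fx * math.log2(fx / fy) + 0.5 * fy * math.log2(fy / fx)
    return total


_BASES: dict[str, Callable] = {
    "unit": row_unit,
    "count": row_count,
    "emd": row_emd_hamming,
    "kl": row_kl_sym,
}


@dataclass
class DistanceSpec:
    """Choice of Q-shape metric: row_sum with a base distance, or p_norm."""

    kind: str = "row_sum"
    base: str = "unit"
    p: float = 2.0

    def __post_init__(self):
        if self.kind not in ("row_sum", "p_norm"):
            raise ValueError(f"unknown distance kind {self.kind!r}")
        if self.kind == "row_sum" and self.base not in _BASES:
            raise ValueError(f"unknown base distance {self.base!r}")
        if self.kind == "p_norm" and self.p < 1:
            raise ValueError("p-norm requires p >= 1")


def qshape_distance(q1: QShape, q2: QShape, spec: DistanceSpec | None = None):
    """Distance between two Q-shapes under the chosen metric."""
    spec = spec or DistanceSpec()
    if q1.shape != q2.shape:
        raise ValueError(f"shape mismatch: {q1.shape} vs {q2.shape}")
    if spec.kind == "row_sum":
        base = _BASES[spec.base]
        return sum(base(a, b) for a, b in zip(q1.rows, q2.rows))
    total = sum(
        abs(float(x) - float(y)) ** spec.p
        for ra, rb in zip(q1.rows, q2.rows)
        for x, y in zip(ra, rb)
    )
    return total ** (1.0 / spec.p)


def distance_table(
    spec: NetworkSpec,
    states: Sequence[NetState],
    metric: DistanceSpec | None = None,
):
    """Symmetric pairwise Q-shape distance table for the given states."""
    if len(states) < 1:
        raise ValueError("need at least one state")
    metric = metric or DistanceSpec()
    shapes = [compute_qshape(spec, s) for s in states]
    m = len(states)
    table = [[Fraction(0) if metric.kind == "row_sum" and metric.base in ("unit", "count") else 0.0 for _ in range(m)] for _ in range(m)]
    for i, k in itertools.combinations(range(m), 2):
        dist = qshape_distance(shapes[i], shapes[k], metric)
        table[i][k] = dist
        table[k][i] = dist
    return table


@dataclass
class SeparationPattern:
    """Two-valued qualitative separation: small value a, large value b.

    ``assignment[(i, k)]`` is ``"a"`` or ``"b"`` for every label pair i < k.
    """

    labels: list[str]
    a: object
    b: object
    assignment: dict[tuple[int, int], str] = field(default_factory=dict)

    def value(self, i: int, k: int):
        if i == k:
            return 0
        key = (min(i, k), max(i, k))
        return self.a if self.assignment[key] == "a" else self.b

    def b_pairs(self) -> set[tuple[int, int]]:
        return {p for p, v in self.assignment.items() if v == "b"}

    def with_values(self, a, b) -> "SeparationPattern":
        if not (0 < a < b):
            raise ValueError("need 0 < a < b")
        return SeparationPattern(self.labels, a, b, dict(self.assignment))


def pattern_from_table(
    table: Sequence[Sequence], labels: Sequence[str] | None = None, tol: float = 1e-9
) -> SeparationPattern:
    """Extract the (a, b) pattern from a two-valued symmetric distance table."""
    m = len(table)
    if labels is None:
        labels = [str(i) for i in range(m)]
    values: list = []
    for i, k in itertools.combinations(range(m), 2):
        v = table[i][k]
        if not any(abs(float(v) - float(w)) <= tol for w in values):
            values.append(v)
    if len(values) != 2:
        raise ValueError(
            f"off-diagonal entries take {len(values)} distinct values, need exactly 2"
        )
    a, b = sorted(values, key=float)
    if float(a) <= 0:
        raise ValueError("separation values must be positive")
    assignment = {}
    for i, k in itertools.combinations(range(m), 2):
        near_a = abs(float(table[i][k]) - float(a)) <= tol
        assignment[(i, k)] = "a" if near_a else "b"
    return SeparationPattern(list(labels), a, b, assignment)
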