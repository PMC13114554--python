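"""Design of collapse-operator spectra.

Single-operator design: given required pairwise separations D(i,k) between
the eigenvalues attached to the collapse-basis states, minimize the sum of
the (non-negative) eigenvalues subject to |λ_i − λ_k| ≥ D(i,k).  The
absolute-value constraints are non-convex, but fixing a total order of the
eigenvalues makes them linear, and the componentwise-minimal point of the
resulting difference-constraint system (a longest-path / greedy solution)
is the unique sum-minimizer for that order.  Enumerating all orders is
exact and cheap for the handful of labels this model needs.

``check_monotone_embedding`` decides the no-go question: can the pairwise
eigenvalue gaps be *exactly* a strictly increasing function of a two-valued
qualitative separation pattern?  For the dyad pattern the answer is no for
every 0 < a < b.

Multi-operator design: one commuting diagonal operator per Q-shape
coordinate makes the squared Euclidean gap ‖a⃗_i − a⃗_k‖² equal the squared
Euclidean distance between the Q-shapes themselves, so collapse rates track
qualitative distances exactly — at the cost of an operator count that grows
like (2^n − 1)(2 d^n + 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

from .qshape import QShape

__all__ = [
    "SeparationProblem",
    "EigenSolution",
    "CollapseOperatorSet",
    "solve_min_sum",
    "canonical_solution",
    "FeasibilityReport",
    "check_monotone_embedding",
    "affine_dimension",
    "build_multi_operator_set",
    "count_operators",
]


@dataclass
class SeparationProblem:
    """Minimize Σ λ_i subject to λ_i ≥ 0 and |λ_i − λ_k| ≥ D(i, k)."""

    labels: list[str]
    separations: list[list[Fraction]]

    def __post_init__(self):
        m = len(self.labels)
        D = [[Fraction(x) if not isinstance(x, Fraction) else x for x in row]
             for row in self.separations]
        if len(D) != m or any(len(row) != m for row in D):
            raise ValueError("separation matrix must be square over the labels")
        for i in range(m):
            if D[i][i] != 0:
                raise ValueError("separation diagonal must be zero")
            for k in range(m):
                if D[i][k] != D[k][i]:
                    raise ValueError("separations must be symmetric")
                if D[i][k] < 0:
                    raise ValueError("separations must be non-negative")
        self.separations = D

    @classmethod
    def from_table(cls, labels: Sequence[str], table) -> "SeparationProblem":
        return cls(list(labels), [list(row) for row in table])


@dataclass(frozen=True)
class EigenSolution:
    """Map label -> eigenvalue, all non-negative."""

    labels: tuple[str, ...]
    values: tuple[Fraction, ...]

    def __getitem__(self, label: str) -> Fraction:
        return self.values[self.labels.index(label)]

    def gap(self, label_i: str, label_k: str) -> Fraction:
        return abs(self[label_i] - self[label_k])

    def total(self) -> Fraction:
        return sum(self.values)

    def satisfies(self, problem: SeparationProblem) -> bool:
        idx = {lab: i for i, lab in enumerate(self.labels)}
        for i, li in enumerate(problem.labels):
            for k, lk in enumerate(problem.labels):
                if i < k and self.gap(li, lk) < problem.separations[i][k]:
                    return False
        return all(v >= 0 for v in self.values)


def solve_min_sum(
    problem: SeparationProblem,
) -> tuple[Fraction, list[EigenSolution]]:
    """Exact global optimum and the set of distinct optimal solutions.

    Enumerates all total orders of the labels (factorial — intended for
    ≤ ~8 labels); per order takes the componentwise-minimal feasible point.
    """
    m = len(problem.labels)
    if m > 8:
        raise ValueError("ordering enumeration is factorial; use <= 8 labels")
    D = problem.separations
    best: Fraction | None = None
    solutions: dict[tuple[Fraction, ...], EigenSolution] = {}
    for order in itertools.permutations(range(m)):
        lam = [Fraction(0)] * m
        for pos, j in enumerate(order):
            lam[j] = max(
                [Fraction(0)]
                + [lam[order[q]] + D[order[q]][j] for q in range(pos)]
            )
        total = sum(lam)
        if best is None or total < best:
            best = total
            solutions = {}
        if total == best:
            solutions[tuple(lam)] = EigenSolution(
                tuple(problem.labels), tuple(lam)
            )
    assert best is not None
    return best, sorted(solutions.values(), key=lambda s: s.values)


def canonical_solution(
    solutions: Sequence[EigenSolution], order: Sequence[str]
) -> EigenSolution:
    """The unique optimal solution strictly increasing along ``order``.

    For the dyad with state order (0,1), (0,0), (1,0), (1,1) this selects
    (λ00, λ01, λ10, λ11) = (2, 0, 4, 6).
    """
    matches = [
        s
        for s in solutions
        if all(s[order[i]] < s[order[i + 1]] for i in range(len(order) - 1))
    ]
    if len(matches) != 1:
        raise ValueError(
            f"{len(matches)} solutions are strictly increasing along {list(order)}"
        )
    return matches[0]


# ------------------------------------------------------------------- no-go

@dataclass
class FeasibilityReport:
    """Outcome of the monotone-embedding check.

    When feasible, ``witness`` holds eigenvalues and mapped values
    (x, y) = (f(a), f(b)) realizing every gap exactly.  When infeasible,
    ``contradictions`` holds one derivation chain per eigenvalue ordering.
    """

    feasible: bool
    witness: dict | None = None
    contradictions: list[str] = field(default_factory=list)


def check_monotone_embedding(pattern) -> FeasibilityReport:
    """Can eigenvalue gaps be exactly f(pattern value) for increasing f?

    Seeks eigenvalues λ and values 0 < x < y (x = f(a), y = f(b)) with
    |λ_i − λ_k| equal to x on the a-pairs and y on the b-pairs.  Fixing a
    total order of the eigenvalues, each adjacent gap is itself a pair
    value, and every longer-range pair equation becomes a linear relation
    c_a·x + c_b·y = x or y, hence a rational ratio constraint on x/y.  An
    ordering is a witness iff its ratio constraints are consistent with
    0 < x < y; the pattern is embeddable iff some ordering is.
    """
    m = len(pattern.labels)
    if m < 3:
        raise ValueError("monotone embedding needs at least 3 labels")

    def pair_kind(i: int, k: int) -> str:
        key = (min(i, k), max(i, k))
        return pattern.assignment[key]

    contradictions: list[str] = []
    for order in itertools.permutations(range(m)):
        if order[0] > order[-1]:
            continue  # reversing an order yields the mirrored solution
        gaps = [pair_kind(order[q], order[q + 1]) for q in range(m - 1)]
        # ratio constraints x/y collected from long-range pair equations
        ratio: Fraction | None = None
        failure: str | None = None
        for i, k in itertools.combinations(range(m), 2):
            if k - i == 1:
                continue
            ca = sum(1 for g in gaps[i:k] if g == "a")
            cb = (k - i) - ca
            # ca*x + cb*y must equal the pair's own value (x or y)
            if pair_kind(order[i], order[k]) == "a":
                ca -= 1
            else:
                cb -= 1
            lhs = (
                " + ".join(["x"] * (ca if ca > 0 else 0) + ["y"] * (cb if cb > 0 else 0))
                or "0"
            )
            if ca == 0 and cb == 0:
                continue
            if ca >= 0 and cb >= 0:  # positive sum of positives cannot vanish
                failure = f"order {order}: {lhs} = 0 impossible for x, y > 0"
                break
            # exactly one of ca, cb is negative: ratio x/y forced
            if ca > 0 and cb < 0:
                r = Fraction(-cb, ca)  # x/y = -cb/ca
            elif cb > 0 and ca < 0:
                r = Fraction(-ca, cb)
                r = 1 / r  # derived y-multiple of x; invert to x/y
            else:  # ca < 0 and cb < 0 with the subtracted unknown repeated
                failure = f"order {order}: negative combination {lhs}"
                break
            if r >= 1:
                failure = (
                    f"order {order}: forces x/y = {r} >= 1, violating x < y"
                )
                break
            if ratio is None:
                ratio = r
            elif ratio != r:
                failure = (
                    f"order {order}: inconsistent ratios x/y = {ratio} and {r}"
                )
                break
        if failure is not None:
            contradictions.append(failure)
            continue
        # consistent: build a witness with y = 1
        x = ratio if ratio is not None else Fraction(1, 2)
        lam = [Fraction(0)] * m
        acc = Fraction(0)
        for q in range(m - 1):
            acc += x if gaps[q] == "a" else Fraction(1)
            lam[order[q + 1]] = acc
        return FeasibilityReport(
            feasible=True,
            witness={
                "x": x,
                "y": Fraction(1),
                "eigenvalues": {pattern.labels[i]: lam[i] for i in range(m)},
                "order": [pattern.labels[i] for i in order],
            },
        )
    return FeasibilityReport(feasible=False, contradictions=contradictions)


# --------------------------------------------------- multi-operator design

def affine_dimension(qshapes: Sequence[QShape], tol: float = 1e-9) -> int:
    """Dimension of the affine span of the Q-shapes as flattened vectors."""
    if not qshapes:
        raise ValueError("need at least one Q-shape")
    coords = np.array([[float(x) for x in q.flatten()] for q in qshapes])
    centered = coords[1:] - coords[0]
    if centered.size == 0:
        return 0
    return int(np.linalg.matrix_rank(centered, tol=tol))


@dataclass
class CollapseOperatorSet:
    """M commuting diagonal operators given by per-basis-state eigenvalue vectors.

    ``vectors[i]`` is a⃗_i, the length-M tuple of the i-th eigenvalue of
    each operator.  The squared gap ‖a⃗_i − a⃗_k‖² sets the decay rate of
    the (i, k) coherence (up to the global rate ω).
    """

    labels: list[str]
    vectors: np.ndarray  # shape (num basis states, M)
    provenance: str = "explicit"

    def __post_init__(self):
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if self.vectors.shape[0] != len(self.labels):
            raise ValueError("one eigenvalue vector per basis label required")

    @property
    def num_operators(self) -> int:
        return self.vectors.shape[1]

    def squared_gap(self, i: int, k: int) -> float:
        diff = self.vectors[i] - self.vectors[k]
        return float(diff @ diff)

    def gap_matrix(self) -> np.ndarray:
        n = len(self.labels)
        return np.array(
            [[self.squared_gap(i, k) for k in range(n)] for i in range(n)]
        )

    @classmethod
    def from_eigensolution(cls, solution: EigenSolution) -> "CollapseOperatorSet":
        vecs = np.array([[float(v)] for v in solution.values])
        return cls(list(solution.labels), vecs, provenance="single-operator")


def build_multi_operator_set(
    qshapes: Sequence[QShape],
    labels: Sequence[str],
    reduced: bool = False,
) -> CollapseOperatorSet:
    """One diagonal operator per Q-shape coordinate (or per affine-span axis).

    Basis state i gets the coordinates of Q-shape i, so pairwise squared
    gaps equal squared Euclidean Q-shape distances.  With ``reduced=True``
    the coordinates are re-expressed in an orthonormal basis of the affine
    span, which preserves all pairwise gaps with only
    ``affine_dimension(qshapes)`` operators.
    """
    if len(qshapes) != len(labels):
        raise ValueError("need exactly one Q-shape per basis label")
    coords = np.array([[float(x) for x in q.flatten()] for q in qshapes])
    if not reduced:
        return CollapseOperatorSet(list(labels), coords, provenance="qshape-coordinates")
    centered = coords - coords[0]
    # orthonormal basis of the affine span via SVD
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(s > 1e-9 * (s[0] if s.size else 1.0)))
    reduced_coords = centered @ vt[:rank].T
    return CollapseOperatorSet(
        list(labels), reduced_coords, provenance="qshape-affine-basis"
    )


def count_operators(n: int, d: int, quantum: bool = False) -> int:
    """Collapse operators needed to span the full Q-shape structure.

    Classical: (2^n − 1)(2 d^n + 1) — per non-empty subsystem, two
    repertoires over d^n states plus one phi value.  Quantum: repertoires
    become density matrices with d^(2n) real parameters each, giving
    (2^n − 1)(2 d^(2n) + 1).
    """
    if n < 1 or d < 2:
        raise ValueError("need n >= 1 and d >= 2")
    exponent = 2 * n if quantum else n
    return (2**n - 1) * (2 * d**exponent + 1)
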