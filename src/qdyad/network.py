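"""Small discrete dynamical networks: units, states and transition matrices.

A network of ``n`` units, each with ``d`` states, is specified by a
row-stochastic transition probability matrix (TPM) over its ``d**n`` joint
states.  The TPM is the system's counterfactual causal specification: row
``i`` gives the distribution of the next joint state conditional on the
current joint state ``i``.  Joint states are ordered lexicographically with
unit 0 most significant, so for a two-unit binary network the order is
(0,0), (0,1), (1,0), (1,1).

All probabilities are stored as exact :class:`fractions.Fraction` values;
floating point enters only when a caller asks for ``as_float`` views.
"""

from __future__ import annotations

import csv
import itertools
import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TransitionModel",
    "NetState",
    "Mechanism",
    "NetworkSpec",
    "build_swap_dyad",
    "build_not_monad",
    "evolve",
    "noise_units",
]

#: tolerance for float row-stochasticity checks (exact rationals need none)
ROW_SUM_TOL = 1e-12


def _to_fraction(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, str):
        return Fraction(x)
    if isinstance(x, (int, np.integer)):
        return Fraction(int(x))
    if isinstance(x, (float, np.floating)):
        return Fraction(x).limit_denominator(10**12)
    raise TypeError(f"cannot interpret {x!r} as a probability")


class TransitionModel:
    """Row-stochastic matrix of exact conditional probabilities.

    Rows that fail stochasticity beyond :data:`ROW_SUM_TOL` raise
    ``ValueError`` rather than being renormalized: silent renormalization
    would mask malformed fixtures.
    """

    def __init__(self, rows: Sequence[Sequence]):
        mat = [[_to_fraction(x) for x in row] for row in rows]
        size = len(mat)
        for i, row in enumerate(mat):
            if len(row) != size:
                raise ValueError(f"TPM must be square; row {i} has {len(row)} entries")
            for x in row:
                if x < 0 or x > 1:
                    raise ValueError(f"TPM entry {x} outside [0, 1] in row {i}")
            if sum(row) != 1:
                # exact rationals must sum exactly; allow float-derived slack
                if abs(float(sum(row)) - 1.0) > ROW_SUM_TOL:
                    raise ValueError(f"row {i} sums to {float(sum(row))}, not 1")
        self._rows = mat

    @property
    def size(self) -> int:
        return len(self._rows)

    @property
    def rows(self) -> list[list[Fraction]]:
        return [list(r) for r in self._rows]

    def __getitem__(self, ik) -> Fraction:
        i, k = ik
        return self._rows[i][k]

    def as_float(self) -> np.ndarray:
        return np.array([[float(x) for x in row] for row in self._rows])

    def apply(self, dist: Sequence[Fraction]) -> list[Fraction]:
        """One forward step: returns ``dist @ P``."""
        if len(dist) != self.size:
            raise ValueError("distribution length does not match TPM size")
        return [
            sum(dist[i] * self._rows[i][k] for i in range(self.size))
            for k in range(self.size)
        ]

    def is_deterministic(self) -> bool:
        return all(max(row) == 1 for row in self._rows)

    def is_permutation(self) -> bool:
        if not self.is_deterministic():
            return False
        cols = [row.index(1) for row in self._rows]
        return sorted(cols) == list(range(self.size))

    def __eq__(self, other) -> bool:
        return isinstance(other, TransitionModel) and self._rows == other._rows

    def __repr__(self) -> str:
        return f"TransitionModel(size={self.size})"


@dataclass(frozen=True)
class NetState:
    """Joint state of the network: one value in ``0..d-1`` per unit."""

    values: tuple[int, ...]
    d: int = 2

    def __post_init__(self):
        if not all(0 <= v < self.d for v in self.values):
            raise ValueError(f"state values {self.values} out of range for d={self.d}")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def index(self) -> int:
        """Lexicographic index with unit 0 most significant."""
        idx = 0
        for v in self.values:
            idx = idx * self.d + v
        return idx

    @classmethod
    def from_index(cls, index: int, n: int, d: int = 2) -> "NetState":
        vals = []
        for _ in range(n):
            vals.append(index % d)
            index //= d
        if index:
            raise ValueError("index out of range")
        return cls(tuple(reversed(vals)), d)


@dataclass(frozen=True)
class Mechanism:
    """A non-empty subset of units frozen at their current values."""

    units: tuple[int, ...]
    values: tuple[int, ...]

    def __post_init__(self):
        if not self.units:
            raise ValueError("mechanism must contain at least one unit")
        if len(self.units) != len(self.values):
            raise ValueError("units and values must have equal length")
        if len(set(self.units)) != len(self.units):
            raise ValueError("duplicate units in mechanism")

    @classmethod
    def from_state(cls, state: NetState, units: Iterable[int]) -> "Mechanism":
        units = tuple(sorted(units))
        return cls(units, tuple(state.values[u] for u in units))

    def consistent_with(self, state: NetState) -> bool:
        return all(state.values[u] == v for u, v in zip(self.units, self.values))


@dataclass
class NetworkSpec:
    """A network: unit count, per-unit state count, labels and TPM."""

    n: int
    d: int
    labels: tuple[str, ...]
    tpm: TransitionModel
    name: str = field(default="network")

    def __post_init__(self):
        if self.n < 1 or self.d < 2:
            raise ValueError("need n >= 1 units with d >= 2 states each")
        if len(self.labels) != self.n or len(set(self.labels)) != self.n:
            raise ValueError("labels must be unique, one per unit")
        if self.tpm.size != self.d**self.n:
            raise ValueError(
                f"TPM size {self.tpm.size} does not match d**n = {self.d ** self.n}"
            )

    @property
    def num_states(self) -> int:
        return self.d**self.n

    def state(self, *values: int) -> NetState:
        return NetState(tuple(values), self.d)

    def all_states(self) -> list[NetState]:
        return [
            NetState(v, self.d)
            for v in itertools.product(range(self.d), repeat=self.n)
        ]

    def state_label(self, state: NetState) -> str:
        return "(" + ",".join(str(v) for v in state.values) + ")"

    # ------------------------------------------------------------------ io
    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "d": self.d,
                "labels": list(self.labels),
                "name": self.name,
                "tpm": [[str(x) for x in row] for row in self.tpm.rows],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        obj = json.loads(text)
        return cls(
            n=int(obj["n"]),
            d=int(obj["d"]),
            labels=tuple(obj["labels"]),
            tpm=TransitionModel(obj["tpm"]),
            name=obj.get("name", "network"),
        )

    def write_tpm_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            for row in self.tpm.rows:
                writer.writerow([str(x) for x in row])


# ---------------------------------------------------------------- fixtures

def build_swap_dyad() -> NetworkSpec:
    """The feedback dyad: two binary units that exchange values each step.

    The TPM is the permutation matrix of the SWAP map (a, b) -> (b, a), so
    e.g. (0,1) -> (1,0) -> (0,1) under iteration.
    """
    size = 4
    rows = [[Fraction(0)] * size for _ in range(size)]
    for a in range(2):
        for b in range(2):
            src = NetState((a, b)).index
            dst = NetState((b, a)).index
            rows[src][dst] = Fraction(1)
    return NetworkSpec(2, 2, ("A", "B"), TransitionModel(rows), name="swap-dyad")


def build_not_monad() -> NetworkSpec:
    """A single self-looping binary unit driven by a NOT gate: 0 -> 1 -> 0."""
    rows = [[Fraction(0), Fraction(1)], [Fraction(1), Fraction(0)]]
    return NetworkSpec(1, 2, ("A",), TransitionModel(rows), name="not-monad")


# -------------------------------------------------------------- operations

def evolve(
    spec: NetworkSpec, dist: Sequence, steps: int
) -> list[Fraction]:
    """Propagate a distribution over joint states ``steps`` times forward."""
    if steps < 0:
        raise ValueError("steps must be non-negative")
    vec = [_to_fraction(x) for x in dist]
    if len(vec) != spec.num_states:
        raise ValueError("distribution length must be d**n")
    if sum(vec) != 1 and abs(float(sum(vec)) - 1.0) > ROW_SUM_TOL:
        raise ValueError("distribution must sum to 1")
    for _ in range(steps):
        vec = spec.tpm.apply(vec)
    return vec


def noise_units(
    spec: NetworkSpec, state: NetState, subset: Iterable[int]
) -> list[Fraction]:
    """Replace ``subset``'s values by an equiprobable distribution.

    Returns the joint distribution that is uniform over the noised units'
    values and a point mass on the remaining units' values from ``state``.
    """
    subset = set(subset)
    if not subset.issubset(range(spec.n)):
        raise ValueError(f"invalid unit subset {subset} for n={spec.n}")
    kept = [u for u in range(spec.n) if u not in subset]
    weight = Fraction(1, spec.d ** len(subset))
    out = [Fraction(0)] * spec.num_states
    for s in spec.all_states():
        if all(s.values[u] == state.values[u] for u in kept):
            out[s.index] = weight
    return out
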