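"""Q-shapes: stacked cause/effect repertoires of a network state.

A mechanism is a subset of units frozen at its current values.  Its effect
repertoire is obtained by replacing the complement by noise (an
equiprobable distribution) and evolving one step forward; its cause
repertoire is the uniform-prior Bayesian posterior over the previous joint
state given that the mechanism's units took their observed values.  The
Q-shape of a state stacks these rows (effect before cause, mechanism by
mechanism) into one matrix — the model's coordinate representation of the
state's qualitative character.

For the SWAP dyad the default mechanisms are the two single units A and B,
giving a 4x4 matrix per state; the whole-system mechanism AB is excluded
because its integrated information vanishes, and the uniform phi-weights of
the two single-unit concepts are suppressed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

from .network import Mechanism, NetState, NetworkSpec, noise_units

__all__ = [
    "QShape",
    "effect_repertoire",
    "cause_repertoire",
    "compute_qshape",
    "default_mechanisms",
    "UnreachableStateError",
]


class UnreachableStateError(ValueError):
    """Raised when a mechanism state has zero likelihood under every past state."""


def _check_mechanism(spec: NetworkSpec, state: NetState, mech: Mechanism) -> None:
    if not set(mech.units).issubset(range(spec.n)):
        raise ValueError(f"mechanism units {mech.units} out of range")
    if not mech.consistent_with(state):
        raise ValueError(
            f"mechanism values {mech.values} inconsistent with state {state.values}"
        )


def effect_repertoire(
    spec: NetworkSpec, state: NetState, mech: Mechanism
) -> list[Fraction]:
    """Forward distribution over next joint states with the complement noised."""
    _check_mechanism(spec, state, mech)
    complement = [u for u in range(spec.n) if u not in mech.units]
    dist = noise_units(spec, state, complement)
    return spec.tpm.apply(dist)


def cause_repertoire(
    spec: NetworkSpec, state: NetState, mech: Mechanism
) -> list[Fraction]:
    """Posterior over previous joint states given the mechanism's values.

    Uniform prior over previous states; the likelihood of a previous state
    is the probability that it produces the mechanism's observed values
    (the complement's current values are marginalized out).
    """
    _check_mechanism(spec, state, mech)
    size = spec.num_states
    likelihood = []
    for prev in spec.all_states():
        row = spec.tpm.rows[prev.index]
        lk = sum(
            p
            for nxt, p in zip(spec.all_states(), row)
            if all(nxt.values[u] == v for u, v in zip(mech.units, mech.values))
        )
        likelihood.append(lk)
    total = sum(likelihood)
    if total == 0:
        raise UnreachableStateError(
            f"mechanism state {mech.values} on units {mech.units} is unreachable"
        )
    return [lk / total for lk in likelihood]


def default_mechanisms(spec: NetworkSpec, state: NetState) -> list[Mechanism]:
    """One single-unit mechanism per unit, in unit order."""
    return [Mechanism.from_state(state, (u,)) for u in range(spec.n)]


@dataclass
class QShape:
    """Ordered stack of (mechanism, effect row, cause row, weight) entries."""

    state: NetState
    mechanisms: list[Mechanism]
    rows: list[list[Fraction]]
    weights: list[Fraction] = field(default_factory=list)

    def __post_init__(self):
        if not self.weights:
            self.weights = [Fraction(1)] * len(self.mechanisms)
        for row in self.rows:
            if sum(row) != 1:
                raise ValueError("every Q-shape row must sum to 1")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.rows), len(self.rows[0]))

    def matrix(self) -> list[list[Fraction]]:
        return [list(r) for r in self.rows]

    def as_float(self) -> np.ndarray:
        return np.array([[float(x) for x in row] for row in self.rows])

    def flatten(self) -> list[Fraction]:
        return [x for row in self.rows for x in row]

    def __eq__(self, other) -> bool:
        return isinstance(other, QShape) and self.rows == other.rows

    # ------------------------------------------------------------------ io
    def to_json(self) -> str:
        return json.dumps(
            {
                "state": list(self.state.values),
                "mechanisms": [list(m.units) for m in self.mechanisms],
                "rows": [[str(x) for x in row] for row in self.rows],
            },
            indent=2,
        )

    def to_csv(self) -> str:
        return "\n".join(",".join(str(x) for x in row) for row in self.rows)


def compute_qshape(
    spec: NetworkSpec,
    state: NetState,
    mechanisms: Sequence[Mechanism] | None = None,
    weights: Sequence[Fraction] | None = None,
) -> QShape:
    """Stack effect then cause repertoires for each mechanism in order."""
    if mechanisms is None:
        mechanisms = default_mechanisms(spec, state)
    if not mechanisms:
        raise ValueError("need at least one mechanism")
    rows: list[list[Fraction]] = []
    for mech in mechanisms:
        rows.append(effect_repertoire(spec, state, mech))
        rows.append(cause_repertoire(spec, state, mech))
    return QShape(
        state=state,
        mechanisms=list(mechanisms),
        rows=rows,
        weights=list(weights) if weights else [],
    )
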