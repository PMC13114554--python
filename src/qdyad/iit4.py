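"""IIT4.0 computations at monad/dyad scale.

IIT4.0 replaces IIT3.0's Earth Mover's distance by the *intrinsic
difference*: for distributions p, q over the same states,

    ID(p, q) = max_s  p(s) · log2( p(s) / q(s) ),

an information measure that selects the single state the system specifies
most strongly.  System integrated information φ_s compares the cause and
effect probabilities the system specifies for its selected cause/effect
states against those under the minimum partition, where a partition severs
every connection between its parts.  Mechanism-level distinctions and the
relations among their cause/effect specifications make up the ϕ-structure,
IIT4.0's description of an experience.

The relations machinery is implemented only to the depth needed at
monad/dyad scale (n ≤ 2): a relation is a set of two or more cause/effect
faces whose purviews jointly overlap and whose specified states agree on
the overlap; its strength is limited by the faces' distinction values and
their overlap fraction.  Full combinatorial relation enumeration for
larger substrates is out of scope.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .iit3 import _Engine, _bipartitions, _combine
from .network import NetState, NetworkSpec
from .qshape import UnreachableStateError

__all__ = [
    "intrinsic_difference",
    "system_phi_iit4",
    "Distinction",
    "Relation",
    "PhiStructure",
    "phi_structure",
]

_EPS = 1e-9

Units = tuple[int, ...]


def intrinsic_difference(p: Sequence, q: Sequence, return_state: bool = False):
    """ID(p, q) = max_s p(s) log2(p(s)/q(s)); zero iff p = q at the selected state.

    Raises on an undefined ratio (q(s) = 0 where p(s) > 0).
    """
    if len(p) != len(q):
        raise ValueError("distributions must have equal length")
    best = None
    best_state = None
    for s, (x, y) in enumerate(zip(p, q)):
        fx, fy = float(x), float(y)
        if fx <= 0:
            continue
        if fy <= 0:
            raise ZeroDivisionError(
                f"intrinsic difference undefined: q vanishes at state {s} where p > 0"
            )
        val = fx * math.log2(fx / fy)
        if best is None or val > best:
            best = val
            best_state = s
    if best is None:
        best, best_state = 0.0, 0
    best = max(best, 0.0)
    return (best, best_state) if return_state else best


def _pointwise_id(p_sel: float, q_sel: float) -> float:
    """p(s̄)·log2(p(s̄)/q(s̄)) for an already-selected state, clipped at 0."""
    if p_sel <= 0:
        return 0.0
    if q_sel <= 0:
        return math.inf
    return max(0.0, p_sel * math.log2(p_sel / q_sel))


# ------------------------------------------------------------ system level

def _set_partitions(n: int):
    """All partitions of the unit set into at least two parts."""
    units = list(range(n))

    def rec(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in rec(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1 :]
            yield [[first]] + part

    for parts in rec(units):
        if len(parts) >= 2:
            yield [tuple(sorted(p)) for p in parts]


def _cross_edges(parts) -> frozenset[tuple[int, int]]:
    edges = set()
    for p1, p2 in itertools.permutations(parts, 2):
        edges.update((i, j) for i in p1 for j in p2)
    return frozenset(edges)


def _system_effect(engine: _Engine, state: NetState, cut=frozenset()):
    units = engine.units
    return engine.effect_rep(units, state.values, units, cut)


def _system_cause(engine: _Engine, state: NetState, cut=frozenset()):
    units = engine.units
    return engine.cause_rep(units, state.values, units, cut)


def system_phi_iit4(spec: NetworkSpec, state: NetState) -> float:
    """System integrated information: intrinsic-difference loss of the
    specified cause and effect states under the minimum partition."""
    engine = _Engine(spec)
    units = engine.units

    effect = _system_effect(engine, state)
    unconstrained_e = engine.effect_rep((), (), units)
    _, sel_e = intrinsic_difference(effect, unconstrained_e, return_state=True)

    cause = _system_cause(engine, state)
    size = spec.num_states
    uniform = [Fraction(1, size)] * size
    _, sel_c = intrinsic_difference(cause, uniform, return_state=True)

    if spec.n == 1:
        # a monad admits only the complete cut: severing its self-loop
        cuts = [frozenset({(0, 0)})]
    else:
        cuts = [_cross_edges(parts) for parts in _set_partitions(spec.n)]
    best = None
    for cut in cuts:
        effect_cut = _system_effect(engine, state, cut)
        phi_e = _pointwise_id(float(effect[sel_e]), float(effect_cut[sel_e]))
        try:
            cause_cut = _system_cause(engine, state, cut)
            phi_c = _pointwise_id(float(cause[sel_c]), float(cause_cut[sel_c]))
        except UnreachableStateError:
            phi_c = math.inf
        total = phi_c + phi_e
        if best is None or total < best:
            best = total
    return float(best) if best is not None else 0.0


# -------------------------------------------------------- distinction level

def _phi_side_id(engine: _Engine, side: str, mech, mech_state, purview):
    """Core machinery for one side: selected state and MIP intrinsic difference."""
    intact = engine.repertoire(side, mech, mech_state, purview)
    if side == "effect":
        unconstrained = engine.effect_rep((), (), purview)
    else:
        size = engine.spec.d ** len(purview)
        unconstrained = [Fraction(1, size)] * size
    ii, sel = intrinsic_difference(intact, unconstrained, return_state=True)
    if ii <= _EPS:
        return 0.0, sel, intact
    state_map = dict(zip(mech, mech_state))
    best = None
    for parts in _bipartitions(mech, purview):
        try:
            partitioned = _combine(engine, side, parts, state_map, purview, frozenset())
        except UnreachableStateError:
            continue
        val = _pointwise_id(float(intact[sel]), float(partitioned[sel]))
        if best is None or val < best:
            best = val
    return (best if best is not None else 0.0), sel, intact


@dataclass
class Distinction:
    """A mechanism's maximally irreducible cause-effect specification."""

    mechanism: Units
    mech_state: tuple[int, ...]
    cause_purview: Units
    cause_state: tuple[int, ...]
    effect_purview: Units
    effect_state: tuple[int, ...]
    phi_cause: float
    phi_effect: float

    @property
    def phi(self) -> float:
        return min(self.phi_cause, self.phi_effect)

    def face(self, side: str):
        if side == "cause":
            return (self.mechanism, "cause", self.cause_purview, self.cause_state)
        return (self.mechanism, "effect", self.effect_purview, self.effect_state)


@dataclass
class Relation:
    """Congruent overlap among two or more cause/effect faces."""

    faces: list[tuple]
    overlap: Units
    phi: float


@dataclass
class PhiStructure:
    """Distinctions + relations + system Φ: IIT4.0's picture of a state."""

    distinctions: list[Distinction]
    relations: list[Relation]
    system_phi: float

    def signature(self):
        """State-independent skeleton: which mechanisms specify which
        purviews with what strength, and how the specifications overlap.
        The specified values themselves track the physical state labels
        and are excluded."""
        dsig = tuple(
            sorted(
                (d.mechanism, d.cause_purview, d.effect_purview,
                 round(d.phi_cause, 9), round(d.phi_effect, 9))
                for d in self.distinctions
            )
        )
        rsig = tuple(
            sorted(
                (
                    tuple(sorted((f[0], f[1]) for f in r.faces)),
                    r.overlap,
                    round(r.phi, 9),
                )
                for r in self.relations
            )
        )
        return (dsig, rsig, round(self.system_phi, 9))


def _core_side_id(engine: _Engine, side: str, mech, mech_state):
    best = None
    for size in range(1, engine.spec.n + 1):
        for purview in itertools.combinations(engine.units, size):
            phi, sel, _rep = _phi_side_id(engine, side, mech, mech_state, purview)
            key = (round(phi, 10), len(purview), purview)
            if best is None or key > best[0]:
                pv_states = engine.purview_states(purview)
                best = (key, phi, purview, pv_states[sel])
    _, phi, purview, sel_state = best
    return phi, purview, sel_state


def _distinctions(spec: NetworkSpec, state: NetState) -> list[Distinction]:
    engine = _Engine(spec)
    out = []
    for size in range(1, spec.n + 1):
        for mech in itertools.combinations(range(spec.n), size):
            mech_state = tuple(state.values[u] for u in mech)
            try:
                phi_c, pv_c, st_c = _core_side_id(engine, "cause", mech, mech_state)
                phi_e, pv_e, st_e = _core_side_id(engine, "effect", mech, mech_state)
            except UnreachableStateError:
                continue
            d = Distinction(
                mechanism=mech,
                mech_state=mech_state,
                cause_purview=pv_c,
                cause_state=st_c,
                effect_purview=pv_e,
                effect_state=st_e,
                phi_cause=phi_c,
                phi_effect=phi_e,
            )
            if d.phi > _EPS:
                out.append(d)
    return out


def _relations(distinctions: list[Distinction]) -> list[Relation]:
    faces = []
    for d in distinctions:
        faces.append((d, d.face("cause")))
        faces.append((d, d.face("effect")))
    out = []
    for r in range(2, len(faces) + 1):
        for combo in itertools.combinations(faces, r):
            purviews = [set(f[1][2]) for f in combo]
            overlap = set.intersection(*purviews)
            if not overlap:
                continue
            congruent = True
            for u in overlap:
                vals = {
                    f[1][3][f[1][2].index(u)]
                    for f in combo
                }
                if len(vals) != 1:
                    congruent = False
                    break
            if not congruent:
                continue
            phi_r = min(
                d.phi * len(overlap) / len(face[2]) for d, face in combo
            )
            out.append(
                Relation(
                    faces=[f[1] for f in combo],
                    overlap=tuple(sorted(overlap)),
                    phi=phi_r,
                )
            )
    return out


def phi_structure(spec: NetworkSpec, state: NetState) -> PhiStructure:
    """Enumerate distinctions and their relations; attach system Φ."""
    if spec.n > 2:
        raise ValueError(
            "relation enumeration is implemented for monad/dyad scale (n <= 2)"
        )
    dists = _distinctions(spec, state)
    rels = _relations(dists)
    return PhiStructure(
        distinctions=dists,
        relations=rels,
        system_phi=system_phi_iit4(spec, state),
    )
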