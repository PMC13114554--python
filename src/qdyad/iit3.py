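"""Minimal IIT3.0 engine for networks of at most three binary units.

Implements mechanism-level integrated information (cause/effect repertoires
over purviews, minimum-information partitions, Earth Mover's distance with
a Hamming ground metric) and system-level Φ (unidirectional system cuts and
the extended-EMD distance between conceptual structures).  The scope is
deliberately capped at tiny networks: the module exists to analyze the
feedback dyad and comparable fixtures, not to be a general IIT engine.

Conventions (documented next to their code paths):

* Repertoires factorize over purview units; multi-unit mechanisms
  contribute a product of per-unit likelihoods (conditional independence
  of units given the previous joint state).
* The minimum-information partition of a (mechanism, purview) pair ranges
  over bipartitions ((M1, Z1), (M2, Z2)) with no part equal to the whole
  and no part empty on both sides; an empty mechanism part contributes the
  unconstrained repertoire over its purview part.
* A mechanism's core purview maximizes the partitioned-vs-intact EMD per
  side; the concept's transportable mass in the system-level comparison is
  the limiting (minimum) side, the standard IIT3.0 weight.
* The reported mechanism value ``phi`` is the concept-level irreducibility
  phi_cause + phi_effect — the distance the minimum-information partition
  moves the concept in concept space, whose metric is the sum of the two
  sides' EMDs.  This is the granularity at which the collapse model's
  Q-shape formalism weighs mechanisms (both of the dyad's single-unit
  mechanisms carry value 1); the per-side values remain available on the
  :class:`Concept`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linprog

from .network import NetState, NetworkSpec
from .qshape import UnreachableStateError

__all__ = [
    "Concept",
    "small_phi",
    "concept",
    "constellation",
    "big_phi_iit3",
    "SystemCut",
]

_EPS = 1e-9

Units = tuple[int, ...]
Edge = tuple[int, int]


# ------------------------------------------------------------- repertoires

def _node_conditionals(spec: NetworkSpec) -> list[list[list[Fraction]]]:
    """cond[j][u][v] = P(unit j next = v | previous joint state u)."""
    cond = []
    for j in range(spec.n):
        table = []
        for u in range(spec.num_states):
            row = spec.tpm.rows[u]
            dist = [Fraction(0)] * spec.d
            for nxt, p in zip(spec.all_states(), row):
                dist[nxt.values[j]] += p
            table.append(dist)
        cond.append(table)
    return cond


class _Engine:
    """Caches per-node conditionals and purview state enumerations."""

    def __init__(self, spec: NetworkSpec):
        if spec.d != 2 or spec.n > 3:
            raise ValueError("IIT3.0 engine supports at most 3 binary units")
        self.spec = spec
        self.cond = _node_conditionals(spec)
        self.units = tuple(range(spec.n))

    # -- single-unit next-state distribution with chosen inputs fixed
    def node_dist(
        self, j: int, fixed: dict[int, int], cut: frozenset[Edge]
    ) -> list[Fraction]:
        eff_fixed = {u: v for u, v in fixed.items() if (u, j) not in cut}
        free = [u for u in self.units if u not in eff_fixed]
        total = [Fraction(0)] * self.spec.d
        count = 0
        for vals in itertools.product(range(self.spec.d), repeat=len(free)):
            assign = dict(eff_fixed)
            assign.update(zip(free, vals))
            u = NetState(tuple(assign[i] for i in self.units), self.spec.d).index
            for v in range(self.spec.d):
                total[v] += self.cond[j][u][v]
            count += 1
        return [x / count for x in total]

    def purview_states(self, purview: Units) -> list[tuple[int, ...]]:
        return list(itertools.product(range(self.spec.d), repeat=len(purview)))

    def effect_rep(
        self,
        mech: Units,
        mech_state: tuple[int, ...],
        purview: Units,
        cut: frozenset[Edge] = frozenset(),
    ) -> list[Fraction]:
        """Product over purview units of their next-state distributions."""
        if not purview:
            return [Fraction(1)]
        fixed = dict(zip(mech, mech_state))
        dists = [self.node_dist(j, fixed, cut) for j in purview]
        out = []
        for zvals in self.purview_states(purview):
            p = Fraction(1)
            for dist, v in zip(dists, zvals):
                p *= dist[v]
            out.append(p)
        return out

    def cause_rep(
        self,
        mech: Units,
        mech_state: tuple[int, ...],
        purview: Units,
        cut: frozenset[Edge] = frozenset(),
    ) -> list[Fraction]:
        """Uniform-prior posterior over purview states of the previous step."""
        if not purview:
            return [Fraction(1)]
        if not mech:
            size = self.spec.d ** len(purview)
            return [Fraction(1, size)] * size
        # likelihood of each previous joint state
        lk = []
        for prev in self.spec.all_states():
            fixed = dict(zip(self.units, prev.values))
            p = Fraction(1)
            for i, v in zip(mech, mech_state):
                p *= self.node_dist(i, fixed, cut)[v]
            lk.append(p)
        total = sum(lk)
        if total == 0:
            raise UnreachableStateError(
                f"mechanism state {mech_state} on units {mech} is unreachable"
            )
        # marginalize the posterior onto the purview
        out = [Fraction(0)] * (self.spec.d ** len(purview))
        pv_states = self.purview_states(purview)
        index = {z: i for i, z in enumerate(pv_states)}
        for prev, p in zip(self.spec.all_states(), lk):
            z = tuple(prev.values[u] for u in purview)
            out[index[z]] += p / total
        return out

    def repertoire(self, side: str, mech, mech_state, purview, cut=frozenset()):
        if side == "cause":
            return self.cause_rep(mech, mech_state, purview, cut)
        return self.effect_rep(mech, mech_state, purview, cut)

    # -- expansion of a purview repertoire to the full state space
    def expand(
        self,
        side: str,
        rep: Sequence[Fraction],
        purview: Units,
        cut: frozenset[Edge] = frozenset(),
    ) -> list[Fraction]:
        complement = tuple(u for u in self.units if u not in purview)
        if side == "cause":
            # unconstrained past: uniform over the complement
            comp = [Fraction(1, self.spec.d ** len(complement))] * (
                self.spec.d ** len(complement)
            )
        else:
            # unconstrained future of the complement under the same cut
            comp = self.effect_rep((), (), complement, cut)
        pv_states = self.purview_states(purview)
        comp_states = self.purview_states(complement)
        out = [Fraction(0)] * self.spec.num_states
        for z, pz in zip(pv_states, rep):
            for c, pc in zip(comp_states, comp):
                assign = dict(zip(purview, z))
                assign.update(zip(complement, c))
                full = NetState(
                    tuple(assign[i] for i in self.units), self.spec.d
                )
                out[full.index] = pz * pc
        return out


# --------------------------------------------------------------------- EMD

def _emd(p: Sequence, q: Sequence, states: Sequence[tuple[int, ...]]) -> float:
    """Earth Mover's distance, Hamming ground metric over value tuples."""
    pf = np.array([float(x) for x in p])
    qf = np.array([float(x) for x in q])
    if np.allclose(pf, qf, atol=1e-12):
        return 0.0
    m = len(states)
    cost = np.array(
        [
            [sum(1 for a, b in zip(si, sk) if a != b) for sk in states]
            for si in states
        ],
        dtype=float,
    ).ravel()
    a_eq = np.zeros((2 * m, m * m))
    for i in range(m):
        a_eq[i, i * m : (i + 1) * m] = 1.0
        a_eq[m + i, i::m] = 1.0
    b_eq = np.concatenate([pf, qf])
    res = linprog(cost, A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"EMD LP failed: {res.message}")
    return float(res.fun)


# -------------------------------------------------------- mechanism level

def _bipartitions(mech: Units, purview: Units):
    """Valid IIT3.0 partitions of a (mechanism, purview) pair."""
    for r in range(len(mech) + 1):
        for m1 in itertools.combinations(mech, r):
            m2 = tuple(u for u in mech if u not in m1)
            for s in range(len(purview) + 1):
                for z1 in itertools.combinations(purview, s):
                    z2 = tuple(u for u in purview if u not in z1)
                    if (m1, z1) == (mech, purview) or (m2, z2) == (mech, purview):
                        continue  # identity partition
                    if (not m1 and not z1) or (not m2 and not z2):
                        continue  # a part empty on both sides
                    yield (m1, z1), (m2, z2)


def _combine(
    engine: _Engine,
    side: str,
    parts,
    mech_state: dict[int, int],
    purview: Units,
    cut: frozenset[Edge],
) -> list[Fraction]:
    """Product of per-part repertoires, aligned on the purview coordinates."""
    pv_states = engine.purview_states(purview)
    out = [Fraction(1)] * len(pv_states)
    for m_part, z_part in parts:
        if not z_part:
            continue
        state_part = tuple(mech_state[u] for u in m_part)
        rep = engine.repertoire(side, m_part, state_part, z_part, cut)
        part_states = engine.purview_states(z_part)
        index = {z: i for i, z in enumerate(part_states)}
        pos = [purview.index(u) for u in z_part]
        for i, z in enumerate(pv_states):
            out[i] *= rep[index[tuple(z[j] for j in pos)]]
    return out


def _phi_side(
    engine: _Engine,
    side: str,
    mech: Units,
    mech_state: tuple[int, ...],
    purview: Units,
    cut: frozenset[Edge] = frozenset(),
):
    """MIP value for one side over a fixed purview: min-partition EMD."""
    intact = engine.repertoire(side, mech, mech_state, purview, cut)
    states = engine.purview_states(purview)
    state_map = dict(zip(mech, mech_state))
    best = None
    best_partition = None
    for parts in _bipartitions(mech, purview):
        try:
            partitioned = _combine(engine, side, parts, state_map, purview, cut)
        except UnreachableStateError:
            continue
        d = _emd(intact, partitioned, states)
        if best is None or d < best - _EPS:
            best = d
            best_partition = parts
    if best is None:
        best = 0.0
    return best, intact, best_partition


@dataclass
class Concept:
    """A mechanism's maximally irreducible cause-effect specification."""

    mechanism: Units
    mech_state: tuple[int, ...]
    cause_purview: Units
    effect_purview: Units
    cause_rep: list[Fraction]
    effect_rep: list[Fraction]
    cause_expanded: list[Fraction]
    effect_expanded: list[Fraction]
    phi_cause: float
    phi_effect: float
    mip_cause: object = None
    mip_effect: object = None

    @property
    def phi(self) -> float:
        """Concept-level irreducibility: cause side plus effect side."""
        return self.phi_cause + self.phi_effect

    @property
    def weight(self) -> float:
        """Transportable mass in system-level comparisons (limiting side)."""
        return min(self.phi_cause, self.phi_effect)


def _core_side(engine: _Engine, side: str, mech, mech_state, cut=frozenset()):
    best = None
    for size in range(1, engine.spec.n + 1):
        for purview in itertools.combinations(engine.units, size):
            try:
                phi, rep, mip = _phi_side(engine, side, mech, mech_state, purview, cut)
            except UnreachableStateError:
                raise
            key = (round(phi, 10), len(purview), purview)
            if best is None or key > best[0]:
                best = (key, phi, purview, rep, mip)
    _, phi, purview, rep, mip = best
    return phi, purview, rep, mip


def concept(
    spec: NetworkSpec,
    state: NetState,
    mech_units: Iterable[int],
    cut: frozenset[Edge] = frozenset(),
) -> Concept:
    """Build the concept of a mechanism: core purviews per side and phis."""
    engine = _Engine(spec)
    mech = tuple(sorted(mech_units))
    mech_state = tuple(state.values[u] for u in mech)
    phi_c, pv_c, rep_c, mip_c = _core_side(engine, "cause", mech, mech_state, cut)
    phi_e, pv_e, rep_e, mip_e = _core_side(engine, "effect", mech, mech_state, cut)
    return Concept(
        mechanism=mech,
        mech_state=mech_state,
        cause_purview=pv_c,
        effect_purview=pv_e,
        cause_rep=rep_c,
        effect_rep=rep_e,
        cause_expanded=engine.expand("cause", rep_c, pv_c, cut),
        effect_expanded=engine.expand("effect", rep_e, pv_e, cut),
        phi_cause=phi_c,
        phi_effect=phi_e,
        mip_cause=mip_c,
        mip_effect=mip_e,
    )


def small_phi(
    spec: NetworkSpec, state: NetState, mech_units: Iterable[int]
) -> tuple[float, Concept]:
    """Mechanism-level integrated information and the concept carrying it."""
    c = concept(spec, state, mech_units)
    return c.phi, c


# ----------------------------------------------------------- system level

def constellation(
    spec: NetworkSpec, state: NetState, cut: frozenset[Edge] = frozenset()
) -> list[Concept]:
    """All concepts with non-vanishing irreducibility on both sides."""
    out = []
    for size in range(1, spec.n + 1):
        for mech in itertools.combinations(range(spec.n), size):
            try:
                c = concept(spec, state, mech, cut)
            except UnreachableStateError:
                continue
            if c.weight > _EPS:
                out.append(c)
    return out


@dataclass
class SystemCut:
    """Unidirectional cut severing all connections from one part to the other."""

    severed_from: Units
    severed_to: Units

    @property
    def edges(self) -> frozenset[Edge]:
        return frozenset(
            (i, j) for i in self.severed_from for j in self.severed_to
        )


def _system_cuts(n: int) -> list[SystemCut]:
    cuts = []
    units = range(n)
    for size in range(1, n):
        for part in itertools.combinations(units, size):
            rest = tuple(u for u in units if u not in part)
            cuts.append(SystemCut(part, rest))
            cuts.append(SystemCut(rest, part))
    return cuts


def _concept_distance(engine: _Engine, c1, c2) -> float:
    """Extended-EMD ground distance between concepts over full states."""
    states = [s.values for s in engine.spec.all_states()]
    return _emd(c1[0], c2[0], states) + _emd(c1[1], c2[1], states)


def _null_concept(engine: _Engine):
    size = engine.spec.num_states
    uniform = [Fraction(1, size)] * size
    unconstrained_effect = engine.effect_rep((), (), engine.units)
    return (uniform, unconstrained_effect)


def _constellation_distance(
    engine: _Engine, intact: list[Concept], cut: list[Concept]
) -> float:
    """Transport phi mass between constellations; the null concept absorbs
    created/destroyed mass."""
    null = _null_concept(engine)
    supply_nodes = [(c.cause_expanded, c.effect_expanded) for c in intact] + [null]
    demand_nodes = [(c.cause_expanded, c.effect_expanded) for c in cut] + [null]
    supplies = [c.weight for c in intact] + [sum(c.weight for c in cut)]
    demands = [c.weight for c in cut] + [sum(c.weight for c in intact)]
    ns, nd = len(supply_nodes), len(demand_nodes)
    cost = np.array(
        [
            [_concept_distance(engine, s, t) for t in demand_nodes]
            for s in supply_nodes
        ]
    ).ravel()
    a_eq = np.zeros((ns + nd, ns * nd))
    for i in range(ns):
        a_eq[i, i * nd : (i + 1) * nd] = 1.0
    for j in range(nd):
        a_eq[ns + j, j::nd] = 1.0
    b_eq = np.array(supplies + demands, dtype=float)
    if b_eq.sum() < _EPS:
        return 0.0
    res = linprog(cost, A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"constellation transport LP failed: {res.message}")
    return float(res.fun)


def big_phi_iit3(spec: NetworkSpec, state: NetState) -> float:
    """System-level integrated information: extended-EMD loss under the
    minimum-information unidirectional system cut."""
    engine = _Engine(spec)
    intact = constellation(spec, state)
    if not intact:
        return 0.0
    best = None
    for cut in _system_cuts(spec.n):
        cut_constellation = constellation(spec, state, cut.edges)
        d = _constellation_distance(engine, intact, cut_constellation)
        if best is None or d < best:
            best = d
    return float(best)
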