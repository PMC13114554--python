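# Methods

This note records the model implemented by `qdyad`, the conventions chosen
where the formalism leaves room, and what the numerical choices and tests
do and do not establish.

## The system

The *feedback dyad* is a network of two binary units, A and B, whose joint
state evolves by a SWAP: (a, b) → (b, a).  Its transition probability
matrix (TPM) over the four joint states — ordered lexicographically
(0,0), (0,1), (1,0), (1,1) with unit A most significant — is a permutation
matrix, so every classical orbit has period one or two.  The *NOT monad*
is a single self-looping binary unit driven by a NOT gate.  Both fixtures,
and all user-supplied networks, are row-stochastic TPMs over `d**n` states;
rows that fail stochasticity are rejected rather than renormalized.
Q-shape-critical arithmetic uses exact rationals (`fractions.Fraction`)
throughout; floating point enters only in dynamics, optimization and the
integrated-information measures that need logarithms or linear programs,
where comparisons use a 1e−9 tolerance.

## Q-shapes

A mechanism is a non-empty unit subset frozen at its current values.  Its
*effect repertoire* replaces the complement by an equiprobable distribution
and applies one forward TPM step; its *cause repertoire* is the
uniform-prior Bayesian posterior over the previous joint state given the
mechanism's values, with the complement's current values marginalized out.
The cause rule is stated here as a design choice: the source formalism
exhibits only the dyad's repertoires, and uniform-prior inversion
reproduces all of them while extending to arbitrary TPMs.  For stochastic
TPMs a mechanism state of zero likelihood raises an explicit
"unreachable" error instead of returning an arbitrary distribution.

The Q-shape of a state stacks, mechanism by mechanism (effect row before
cause row), these repertoires over the full `d**n` state space.  For the
dyad the default mechanism list is the two single units: the composite AB
is excluded because its integrated information vanishes, and the two
single-unit ϕ-weights are equal in every state, so they are suppressed.
The general API accepts arbitrary mechanism lists and weights.

The four dyad Q-shapes satisfy the exact parallelogram identity
Q(0,0) + Q(1,1) = Q(0,1) + Q(1,0), so their affine span has dimension 2 —
they form a (planar) parallelogram, not a full 3-simplex, despite the
informal description of the four points as a tetrahedron sometimes used
for this construction.  `affine_dimension` computes the rank rather than
assuming either value, and the test suite pins the computed value against
an exact rational rank oracle.

## Distances and the separation pattern

`row_sum` distances add a base distance over corresponding rows.  The
default base is the 0/1 indicator — the unit-normalized member of the
"natural class" of measures sensitive only to how many entries two rows
differ in; a count-of-differing-entries base is provided as the general
member.  Earth Mover's (Hamming ground metric) and symmetrized
Kullback–Leibler bases are included for completeness; neither enters any
headline number.  The `p_norm` family treats Q-shapes as matrices and
takes the entrywise p-norm of the difference (p ≥ 1).  On the dyad the
closed forms are a = ½·8^(1/p) (near pairs) and b = ½·16^(1/p) (far
pairs), i.e. a = √2, b = 2 at p = 2; an informal statement elsewhere that
the Euclidean case gives a = 2 conflicts with this closed form and is not
followed.  With the unit base the dyad's row-sum table (0/2/4) equals the
squared Euclidean table entrywise.

`pattern_from_table` reduces a two-valued distance table to its
qualitative separation pattern (a < b plus the pair assignment); for the
dyad the far pairs are {(0,0),(1,1)} and {(0,1),(1,0)}.

## Single-operator design and the no-go result

Given required pairwise separations D(i,k), the design problem minimizes
Σλ subject to λ ≥ 0 and |λ_i − λ_k| ≥ D(i,k).  The absolute-value
constraints are non-convex; the solver enumerates all total orders of the
labels (24 for four), under which the constraints become a
difference-constraint system whose componentwise-minimal point — computed
greedily, in exact rationals — is the unique per-order sum minimizer.
Exhaustive enumeration was preferred over mixed-integer programming for
exactness and zero solver dependencies at this scale (≤ 8 labels).  For
the dyad table the optimum is 12, attained by exactly eight eigenvalue
assignments; the *canonical* solution is defined as the unique optimum
whose eigenvalues increase strictly in the state order (0,1), (0,0),
(1,0), (1,1), namely (λ00, λ01, λ10, λ11) = (2, 0, 4, 6).  Its
(0,1)–(1,1) gap is 6, three times the required separation 2 — the
over-separation phenomenon that motivates the no-go question.

`check_monotone_embedding` decides whether gaps can *exactly* equal
f(pattern value) for some strictly increasing f with f(0) = 0, i.e.
whether values 0 < x < y exist realizing every gap.  Fixing an eigenvalue
order, each adjacent gap is itself a pair value and every longer-range
pair equation becomes a rational ratio constraint on x/y; an ordering is a
witness iff its constraints are consistent with 0 < x < y.  For the dyad
pattern every ordering yields a contradiction (typically "y = 0"), for all
0 < a < b; the tests confirm agreement with an exhaustive integer-grid
oracle on random patterns of 3–4 labels.

## Multi-operator construction and operator counts

With M commuting diagonal operators, the (i,k) coherence decays at rate
(ω/2)‖a⃗_i − a⃗_k‖², where a⃗_i collects the i-th eigenvalue of each
operator.  Choosing a⃗_i as the coordinates of Q-shape i makes every decay
rate equal the squared Euclidean Q-shape distance — the faithful
construction; an orthonormal basis of the affine span (`reduced=True`)
preserves all gaps with only `affine_dimension` operators.  Spanning the
full structure of an n-unit, d-state system needs
(2^n − 1)(2 d^n + 1) operators classically (per non-empty subsystem: two
repertoires of d^n entries plus one ϕ value) and (2^n − 1)(2 d^(2n) + 1)
when repertoires become density matrices: 27, 385 and 99 for the classical
dyad, the n = d = 3 system and the quantum dyad respectively.

## Collapse dynamics

The master equation is dρ/dt = −i[H₀, ρ] − (ω/2) Σ_m [A_m, [A_m, ρ]] with
all A_m diagonal in the collapse basis.  With H₀ = 0 it is solved in
closed form (entrywise exponential decay; populations frozen); with H₀ ≠ 0
an adaptive DOP853 integration at rtol 1e−10 is used, and the closed form
doubles as its regression check.  ω defaults to 1 in internal units: the
absolute collapse time scale is an experimental parameter of such models,
so all reported rates are relative.

The stochastic unraveling is quantum-state diffusion in Itô form,

  dψ = [−iH₀ dt − (ω/2) Σ_m (A_m − ⟨A_m⟩)² dt + √ω Σ_m (A_m − ⟨A_m⟩) dW_m] ψ,

with one independent real Wiener process per operator, integrated by
Euler–Maruyama with per-step renormalization.  The √ω noise coefficient is
the one whose Itô expansion reproduces the ω/2 double-commutator rate for
every ω (a linear-in-ω noise term would do so only at ω = 1).  The default
step keeps ω·(max gap²)·dt ≤ 0.01, and a guard rejects steps above 0.1 in
those units.  Only ensemble-level behavior is asserted: the integration
scheme and the single-vs-shared-noise choice (independent noises, the
standard unraveling) are design choices invisible to the master equation
in the dt → 0 limit.  One master seed drives the whole ensemble through a
single `numpy` generator, so runs are reproducible bit-for-bit.

The circuit module treats the SWAP as a fixed unitary; continuous-time
collapse acts between discrete gate steps with a configurable per-step
duration, since gate dynamics and collapse dynamics are specified
separately and their interleaving is a modeling choice.

## IIT3.0 conventions

The `iit3` module is a minimal engine for ≤ 3 binary units.  Repertoires
over purviews factorize per purview unit (conditional independence of
units given the previous joint state); partitions of a
(mechanism, purview) pair range over bipartitions with no part equal to
the whole and none empty on both sides; repertoire comparisons use Earth
Mover's distance with a Hamming ground metric (solved as a small
transportation LP); core purviews maximize the per-side
minimum-information-partition value.

Two granularities of mechanism-level value coexist in the literature this
model draws on, and both printed dyad values are reproducible only by
keeping them distinct:

* `small_phi` reports the **concept-level irreducibility**
  φ_cause + φ_effect — the distance the MIP moves the concept in concept
  space, whose metric is the sum of the cause- and effect-side EMDs.  For
  the dyad this gives φ(A) = φ(B) = 1 (each side contributes ½) and
  φ(AB) = 0, the values at which the Q-shape construction weighs
  mechanisms.  The per-side values are exposed on the `Concept`.
* System-level Φ uses the **limiting-side weight** min(φ_cause, φ_effect)
  as each concept's transportable mass, the standard convention.  Φ is the
  minimum over unidirectional system cuts (all connections from one part
  to the other replaced by noise) of the extended-EMD transport cost
  between the intact and cut constellations, with destroyed mass moved to
  the null concept (uniform cause, unconstrained effect).  For the dyad
  either cut destroys both single-unit concepts (each at distance 1 from
  the null concept), giving Φ = ½·1 + ½·1 = 1 in every classical state.

## IIT4.0 conventions

The intrinsic difference is ID(p, q) = max_s p(s)·log2(p(s)/q(s)), with an
explicit error on undefined ratios.  System integrated information
evaluates the cause and effect probabilities of the *selected* (maximally
informative) cause and effect states against those under the minimum
partition, summing the two directions; a partition severs **all**
connections between its parts.  Under this reading the dyad loses its full
two bits of cause and two bits of effect specification under its only
bipartition, giving Φ = 4 in every classical state (a one-directional cut
would instead give 2; the all-connections reading is the one consistent
with the headline dyad value and is adopted throughout).  A monad admits
only the complete cut of its self-loop, giving the NOT monad Φ = 2.

Distinctions evaluate mechanisms over core purviews with the same
partition scheme and φ_d = min(cause, effect); the dyad has two
distinctions (each unit specifying its partner, φ_d = 1) and the composite
AB is reducible.  A *relation* is a set of two or more cause/effect faces
of distinctions whose purviews jointly overlap and whose specified states
agree on the overlap; its strength is the minimum over faces of
φ_d × (overlap size / purview size).  A single distinction's cause and
effect faces may form a (self-)relation — this is what gives the monad its
one distinction and one relation.  Relation enumeration is implemented for
n ≤ 2 only; the combinatorial growth of relations in larger substrates is
precisely the scaling phenomenon the model highlights, not something this
package attempts to enumerate.

The `PhiStructure.signature()` method captures the state-independent
skeleton (mechanisms, purviews, φ values, relation pattern) and is the
sense in which the dyad's ϕ-structure is *identical* across its four
classical states: the specified unit values track the physical state; the
causal organization does not.

## Synthetic fixtures

`generate_fixture` produces seeded random permutation TPMs (deterministic,
measure-preserving — the closed-system analogue of the dyad) and
row-stochastic TPMs (Dirichlet-flat rows snapped to an exact rational
10^-6 grid so validation invariants hold exactly).  These emulate the
*class* of small discrete causal networks the formalism quantifies over;
they do not emulate noise correlations, per-unit differing state counts,
or continuous degrees of freedom, so property tests passing on them speak
to the combinatorial machinery, not to physical realism.

## Problem sizes and tolerances

All headline quantities are desk-scale: exact rational arithmetic for
Q-shapes, distances and eigenvalue design; 1e−6 agreement between closed
form and integrator; 1% tolerance on fitted decay rates; stochastic
checks with 2000 trajectories at 3-standard-error bounds and a χ²
outcome test at α = 0.01, all under fixed seeds.  The routine test suite
uses 400-trajectory ensembles for the same checks; the acceptance test
runs the full 2000-trajectory protocol.  The no-go check enumerates 24
orderings per draw and its oracle searches an integer grid of ~10^5
eigenvalue tuples.

## Known limitations

* Cause repertoires assume conditional independence of units given the
  previous joint state (exact for deterministic TPMs, an approximation
  for correlated stochastic ones).
* The IIT3.0 engine caps at 3 binary units and does not implement
  exclusion over overlapping candidate systems; the IIT4.0 relations
  machinery caps at n = 2.
* IIT2.0 values are not computed.
* Non-commuting collapse-operator sets, thermal Lindblad terms and
  measurement records are out of scope.
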