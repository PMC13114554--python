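"""Integrated-information values of the dyad and the NOT monad.

Runs the IIT3.0 mechanism and system computations on the SWAP dyad and
the IIT4.0 computations on both fixtures, printing the values the model's
analysis rests on.
"""

import qdyad as q

dyad = q.build_swap_dyad()
monad = q.build_not_monad()

print("IIT3.0, SWAP dyad:")
s = dyad.state(1, 0)
phi_a, concept_a = q.small_phi(dyad, s, (0,))
phi_b, _ = q.small_phi(dyad, s, (1,))
phi_ab, _ = q.small_phi(dyad, s, (0, 1))
print(f"  mechanism phi: A={phi_a:.3f}  B={phi_b:.3f}  AB={phi_ab:.3f}")
print(f"  (A's sides: cause {concept_a.phi_cause:.2f} + effect {concept_a.phi_effect:.2f})")
for st in dyad.all_states():
    print(f"  big Phi in state {dyad.state_label(st)}: {q.big_phi_iit3(dyad, st):.3f}")
# Each single unit is an irreducible mechanism (phi = 1); the composite AB
# adds nothing; severing either direction of the loop destroys both
# concepts, giving system Phi = 1 in every classical state.

print("\nIIT4.0, SWAP dyad:")
for st in dyad.all_states():
    print(f"  system phi in state {dyad.state_label(st)}: "
          f"{q.system_phi_iit4(dyad, st):.3f}")
sigs = {q.phi_structure(dyad, st).signature() for st in dyad.all_states()}
ps = q.phi_structure(dyad, dyad.state(1, 0))
print(f"  structure: {len(ps.distinctions)} distinctions, "
      f"{len(ps.relations)} relations; identical across states: {len(sigs) == 1}")
# IIT4.0 assigns the dyad Phi = 4 (two bits of cause and two of effect
# erased by the partition) but one and the same phi-structure in all four
# states: what varies between states are unit values, not the
# counterfactual causal organization.

print("\nIIT4.0, NOT monad:")
ps = q.phi_structure(monad, monad.state(0))
print(f"  system phi: {ps.system_phi:.3f}")
print(f"  structure: {len(ps.distinctions)} distinction, "
      f"{len(ps.relations)} relation")
d = ps.distinctions[0]
print(f"  the unit in state 0 specifies cause state {d.cause_state[0]} and "
      f"effect state {d.effect_state[0]} with phi {d.phi:.2f}")
# The monad is the smallest IIT4.0 system: one distinction (the unit
# specifying its own past and future) and one relation binding the two.
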