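"""Designing a single collapse operator — and why it cannot suffice.

Solves the min-sum eigenvalue optimization for the dyad's qualitative
distance table, shows that the canonical solution over-separates one pair,
runs the monotone-embedding feasibility check (the no-go result), and
prints the operator counts the faithful multi-operator construction needs.
"""

from fractions import Fraction

import qdyad as q

dyad = q.build_swap_dyad()
states = dyad.all_states()
labels = [dyad.state_label(s) for s in states]
table = q.distance_table(dyad, states)

problem = q.SeparationProblem.from_table(labels, table)
objective, solutions = q.solve_min_sum(problem)
print(f"minimal eigenvalue sum: {objective}")
print(f"number of optimal solutions: {len(solutions)}")
for s in solutions:
    print("  (λ00, λ01, λ10, λ11) =", tuple(str(v) for v in s.values))

canon = q.canonical_solution(solutions, ["(0,1)", "(0,0)", "(1,0)", "(1,1)"])
print("\ncanonical solution:", tuple(str(v) for v in canon.values))
print("gap |λ01 − λ11| =", canon.gap("(0,1)", "(1,1)"),
      "although the qualitative distance only asks for",
      table[1][3])
# The superposition of (0,1) and (1,1) decays three times faster than its
# qualitative distance alone would suggest: a single operator cannot make
# every gap track the distance.

pattern = q.pattern_from_table(table, labels)
report = q.check_monotone_embedding(pattern.with_values(Fraction(2), Fraction(4)))
print("\nmonotone embedding feasible?", report.feasible)
print("example contradiction:", report.contradictions[0])
# No strictly increasing function of the two-valued distance pattern can be
# realized by the gaps of four eigenvalues: the no-go holds for every
# 0 < a < b.

shapes = [q.compute_qshape(dyad, s) for s in states]
ops = q.build_multi_operator_set(shapes, labels)
print("\nmulti-operator squared gaps (= squared Euclidean Q-shape distances):")
print(ops.gap_matrix())
print("affine dimension of the four Q-shapes:", q.affine_dimension(shapes))
print("operators for the full structure: classical dyad",
      q.count_operators(2, 2), "| n=d=3:", q.count_operators(3, 3),
      "| quantum dyad:", q.count_operators(2, 2, quantum=True))
# Faithful tracking is possible with one operator per Q-shape coordinate,
# but the operator count explodes combinatorially with system size.
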