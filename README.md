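# qdyad

Integrated-information collapse dynamics for minimal discrete networks.

`qdyad` models the *feedback dyad* — two binary units that exchange their
values through a SWAP gate each time step — as a testbed for
consciousness-based wave-function-collapse proposals built on integrated
information theory (IIT).  It is written for researchers in quantum
foundations and mathematical consciousness science who want the full
pipeline of such a model as runnable, exactly-tested code:

* **Q-shapes** — each classical state's qualitative description: the stack
  of cause and effect repertoires of its mechanisms, computed in exact
  rational arithmetic by noising a mechanism's complement and evolving the
  TPM forward/backward.
* **Qualitative distances** — row-sum metrics over Q-shape rows and the
  entrywise p-norm family, plus the two-valued separation pattern (a < b)
  they induce on the dyad.
* **Collapse-operator design** — the min-sum eigenvalue optimization
  (minimize Σλ subject to |λ_i − λ_k| ≥ D(i,k)), solved exactly by
  ordering enumeration; the monotone-embedding *no-go* check showing that
  no single operator's gaps can be a strictly increasing function of the
  dyad's qualitative distances; the faithful multi-operator construction
  (one diagonal operator per Q-shape coordinate) and the operator-count
  formulas (2ⁿ−1)(2dⁿ+1) and (2ⁿ−1)(2d²ⁿ+1).
* **Collapse dynamics** — the dephasing Lindblad equation
  dρ/dt = −i[H₀,ρ] − (ω/2)Σ_m[A_m,[A_m,ρ]], its closed-form off-diagonal
  decay ρ_ik(t) = ρ_ik(0)·e^{−(ω/2)‖a⃗_i−a⃗_k‖²t}, and the
  quantum-state-diffusion unraveling whose trajectories collapse onto
  basis states with Born-rule frequencies.
* **IIT3.0 / IIT4.0** — mechanism-level φ and system-level Φ for the dyad
  (IIT3.0: φ(A)=φ(B)=1, Φ=1; IIT4.0: Φ=4) and the ϕ-structure
  (distinctions + relations) of the NOT monad and the dyad.

## Worked example

```python
import qdyad as q

dyad = q.build_swap_dyad()
states = dyad.all_states()
labels = [dyad.state_label(s) for s in states]

# qualitative distances between the four classical states
table = q.distance_table(dyad, states)
# -> rows (0,2,2,4), (2,0,4,2), (2,4,0,2), (4,2,2,0)

# design a single collapse operator for those separations
problem = q.SeparationProblem.from_table(labels, table)
objective, solutions = q.solve_min_sum(problem)
print(objective, len(solutions))          # 12 8
canon = q.canonical_solution(solutions, ["(0,1)", "(0,0)", "(1,0)", "(1,1)"])
print(tuple(map(int, canon.values)))      # (2, 0, 4, 6)
print(int(canon.gap("(0,1)", "(1,1)")))   # 6

# collapse Schrödinger's dyad: (|0,0> + |1,0>)/sqrt(2)
psi0 = q.apply_swap(q.prepare_product(("0", "+")))
model = q.CollapseModel(q.CollapseOperatorSet.from_eigensolution(canon))
res = q.simulate_ensemble(model, psi0, t=4.0, ntraj=2000, seed=42)
print(list(res["histogram"]))             # [1015, 0, 985, 0]
```

The distance table says superpositions of (0,1) and (1,0) (distance 4)
should decay twice as fast as those of (0,0) and (0,1) (distance 2).  The
optimization has exactly eight optimal eigenvalue assignments summing to
12; the canonical one, (2, 0, 4, 6), separates (0,1) from (1,1) by 6 even
though their qualitative distance is only 2 — no single operator can track
all pairwise distances, which `q.check_monotone_embedding` proves for
every scaling of the pattern.  The ensemble run shows 2000 stochastic
trajectories splitting ≈ 50/50 between the two superposed branches, the
Born weights of the prepared state.

The `examples/` directory has one narrative script per capability
(`qshapes_and_distances.py`, `eigenvalue_design_and_nogo.py`,
`collapse_dynamics.py`, `schrodingers_dyad_circuit.py`,
`integrated_information.py`).  A thin CLI mirrors the library:

```
qdyad qshape --network swap-dyad --state 1,0
qdyad optimize --network swap-dyad
qdyad nogo --a 2 --b 4
qdyad collapse --operators single --sde --ntraj 2000 --seed 42
qdyad phi --formalism iit4 --network not-monad --state 0
```

On the physical side, the dyad can be read as two polarization qubits at
fixed spatial locations in a crossed-fiber feedback loop; identifying the
causal units with the locations (rather than the photons) is what makes
the system integrated rather than two independent channels.  See
`docs/methods.md` for the model's conventions, numerical choices and
limitations.

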