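# crnemu — reaction-network morphisms and kinetic emulation

`crnemu` is a toolkit for relating chemical reaction networks (CRNs) to one
another *structurally* and proving that the structural relationship implies
a *kinetic* one.  It is aimed at systems biologists and molecular
programmers who want to show that a complex network — a cell-cycle switch,
a toggle, a signaling cascade — can exactly reproduce the mass-action
kinetics of a simpler network for every choice of the simpler network's
rates and initial conditions.

## The model

A CRN is a finite species set `S` and finite reaction set `R` of
irreversible reactions `ρ →ᵏ π` (complexes `ρ, π ∈ ℕ^S`, rate `k > 0`,
mass-action kinetics).  Its syntax is gathered in the *instantaneous
stoichiometry* matrix `φ(s, r) = k·(π_s − ρ_s)`, and its kinetics in the
differential system

    dv_s/dt = F(v)(s) = Σ_r φ(s, r) · v^ρ(r)

A *morphism* `m = (m_S, m_R)` is a pair of total maps between the species
and reactions of two networks.  Three conditions, all checkable by integer
matrix algebra on the networks' structure, do the work (`mS`, `mR` are the
0–1 characteristic matrices of the maps):

- **reactant morphism** — `mSᵀ·ρ = ρ̂·mRᵀ`: image reactions have the mapped
  reactants;
- **homomorphism** — `m_R(ρ →ᵏ π) = m_S(ρ) →ᵏ m_S(π)`: the reaction map is
  determined by the species map;
- **stoichiomorphism** — `φ·mR = mS·φ̂`: instantaneous stoichiometry is
  preserved summed over reaction fibers.

A morphism that is both a reactant morphism and a stoichiomorphism is a
**kinetic emulation**: `F(v̂∘m) = F̂(v̂)∘m` for every target state `v̂`, so
source trajectories started at pulled-back (copied, never summed) initial
states retrace target trajectories *exactly*.  A change-of-rates theorem
lifts any rate reassignment of the target across a stoichiomorphism via
`k′ = k·k̂′/k̂`, so one unit-rate check certifies emulation for all rates.

The package also compiles *influence networks* (nodes with
activation/inhibition inputs and high/low outputs) into CRNs through the
**triplet motif**: each node becomes species `x_0, x_1, x_2` with four
catalyzed transitions, whose steady-state dose response is a generalized
Hill function with limiting coefficient 2.  The bundled two-node
mutual-inhibition network MI compiles to 6 species / 8 reactions and
collapses, by the dual-collapse species map, onto the three-species
approximate-majority switch AM — the canonical fast bistable consensus
network — which it therefore emulates exactly.

## Worked example

```python
import numpy as np
import crnemu as ce

mi = ce.netlib.builtin("mi")                       # influence network + compilation
m = ce.netlib.builtin("mi_to_am_morphism").morphism  # dual-collapse map onto AM

print("compiled MI:", mi.compiled.n_species, "species,",
      mi.compiled.n_reactions, "reactions")
print("reactant morphism:", ce.is_reactant_morphism(m).holds)
print("homomorphism:     ", ce.is_homomorphism(m).holds)
print("stoichiomorphism: ", ce.is_stoichiomorphism(m).holds)

states = ce.sample_states(m.target, 100, seed=0)
print("max derivative residual:", ce.check_emulation_derivative(m, states))

rep = ce.check_emulation_trajectory(m, {"x0": 1.2, "x1": 0.1, "x2": 0.7}, t_end=50.0)
print("max trajectory deviation:", rep.trajectory_deviation)

print("Hill coefficient:", ce.hill_coefficient((1, 1, 1, 1), np.logspace(-4, 4, 81)))
```

prints

```
compiled MI: 6 species, 8 reactions
reactant morphism: True
homomorphism:      True
stoichiomorphism:  True
max derivative residual: 0.0
max trajectory deviation: 2.220446049250313e-16
Hill coefficient: 1.9982781503908367
```

The three static verdicts certify emulation; the derivative residual is
exactly zero (both sides are the same floating-point sums), the paired
MI/AM trajectories agree to machine precision over `t ∈ [0, 50]`, and the
triplet motif's limiting log-log slope is 2 to within 0.1%.

## Command line

The `crn-emu` entry point wires the same operations for shell use:

```sh
crn-emu fixtures dump mi -o mi.txt
crn-emu check --source mi.crn --target am.crn --map collapse.json
crn-emu emulate --source mi.crn --target am.crn --map collapse.json --t 50
crn-emu search --source mi.crn --target am.crn
crn-emu simulate am.crn --init init.json --t 50 -o traj.csv
```

Exit codes: 0 positive verdict, 1 negative verdict, 2 usage/input error;
reports are JSON (schema 1).

## Layout

- `crnemu.network` — CRN data model, stoichiometric matrices, homomorphic
  projection; `crnemu.crnio` — the `.crn` text format.
- `crnemu.influence` — influence networks, triplet compilation, duals,
  closed-form motif steady state and Hill coefficient.
- `crnemu.morphism` — morphism objects, the three static checks (with
  witness certificates), composition, change-of-rates lifting.
- `crnemu.kinetics` — mass-action ODEs (scipy `solve_ivp`), emulation
  verification on derivatives and trajectories, steady-state transfer.
- `crnemu.search` — brute-force unit-rate homomorphism search with the
  triplet restriction, plus a capped exhaustive mode.
- `crnemu.netlib` — bundled fixtures (AM, MI, the triplet, the dual-collapse
  morphism, counterexamples) and seeded random generators.
- `contrib/` — reconstructed influence-network transcriptions (see its
  README); illustrative, not part of the trusted fixture set.
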