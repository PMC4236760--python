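# Methods

## Scope and objects

The package manipulates mass-action chemical reaction networks (CRNs):
finite ordered species lists and finite ordered lists of irreversible
reactions `ρ →ᵏ π` with `k > 0`.  Complexes may be empty on either side, so
inflows and outflows are expressible and no conservation of mass or energy
is assumed.  Two reactions with identical reactant and product complexes
are kinetically indistinguishable from a single reaction with summed rate;
`make_network` therefore merges duplicates at construction (logged), and a
network object never contains two reactions with the same complex pair.
All matrix-level checks index species and reactions by their list order, so
every verdict is reproducible bit for bit.

## Static morphism conditions

For a morphism `m = (m_S, m_R)` between networks with reactant matrices
`ρ, ρ̂` and instantaneous stoichiometry `φ = k·(π − ρ)`, the package checks:

- reactant morphism: `mSᵀ·ρ = ρ̂·mRᵀ` (exact, int64);
- homomorphism: per reaction, image = mapped complexes at the same rate
  (complex images are computed by fiber-summing multiplicities);
- stoichiomorphism: `φ·mR = mS·φ̂`;
- net stoichiomorphism: the same with the rate-free `η = π − ρ` (exact).

The stoichiomorphism comparison is exact in integer arithmetic whenever
every rate constant is integer-valued (the common unit-rate case), and
otherwise a floating comparison with absolute tolerance 1e−12; the result
carries the maximum residual so borderline cases are visible.  Every check
returns a certificate holding up to 10 failing `(species, reaction)`
entries with both sides' values.  Reaction identity is positional (index in
the ordered list); morphism JSON uses index pairs, with a
`"homomorphic": true` shorthand that derives the reaction map from the
species map and errors when an image reaction is missing.  Partial maps are
rejected: restriction to a subnetwork must be explicit.

Reactant morphism + stoichiomorphism together imply kinetic emulation
(`F(v̂∘m) = F̂(v̂)∘m`), which the dynamic layer verifies independently.
The change-of-rates lift multiplies each source rate by `k̂′/k̂` of its
image reaction; since complexes are untouched, no duplicate merge can arise,
and when the morphism is a homomorphism (`k = k̂`) the lifted rates are
bitwise copies of the new target rates.

## Homomorphic projection

Projecting a network through a species map sends each reaction to its
complex-mapped image at the same rate.  The image is a *set* of reactions:
source reactions with identical image triples collapse to one target
reaction (this is what makes the 8-reaction MI compilation collapse onto
the 4-reaction AM with all fibers of size 2), and the returned epimorphism
records the fiber structure.  If two images agree on both complexes but
carry different rates, no homomorphic image CRN exists and the projection
raises rather than silently rate-summing — a situation only a non-injective
species map on an already-heterogeneous network can produce.

## Influence compilation and the triplet motif

Each influence node `x` becomes species `x_0` (active), `x_1`
(intermediary), `x_2` (inactive).  Each edge contributes two catalytic
transition reactions, the catalyst being the source node's `x_0` (high
output) or `x_2` (low output).  Edges carry two rates, one per transition,
defaulting to 1; a node with exactly one activator and one inhibitor
recovers the classical four-rate motif, and multi-input nodes are
unambiguous.  The intermediary of a node only ever appears in that node's
own transitions, and every compiled reaction is catalytic (the catalyst's
instantaneous stoichiometry is zero), both checked by tests.

Duals: replacing `x` by `~x` swaps `x_0` and `x_2`.  `dualize` implements
this as a pure relabeling at the influence level — outgoing edges flip
polarity, incoming edges flip mode *and* swap their two rates — so the
compiled CRN is unchanged up to the species swap and dualizing twice is the
identity.

For the motif's analysis the catalyst levels `a` (activation) and `b`
(inhibition) are clamped: catalysts are never consumed, matching the
catalytic reading.  Flux balance gives the closed-form fixed point ratios
`x0 : x1 : x2 = (ka1·a)/(kb1·b) : 1 : (kb2·b)/(ka2·a)`; with unit rates the
active fraction is `r²/(r² + r + 1)` in the input ratio `r = a/b`, which is
1/3 at `r = 1` and behaves as `r²` for small `r`.  `hill_coefficient`
estimates the limiting exponent by a least-squares log-log slope over the
two smallest decades of a grid that must span at least four decades; on a
1e−4..1e4 grid this yields 2 to well within 1% (the finite-`r` correction
is O(r) at the top of the fitting window).  Boundary inputs (`a = 0` or
`b = 0`) return the corresponding boundary fixed point with an explicit
flag rather than an error.

## Kinetics and dynamic verification

Mass action uses the convention `0⁰ = 1` (a species with zero reactant
multiplicity contributes no factor), so boundary states are well defined.
Simulation uses scipy's `solve_ivp` with the stiff-capable LSODA method at
`rtol = atol = 1e−9` by default on a uniform evaluation grid; these systems
(polynomial right-hand sides, a handful of species) are cheap at tight
tolerance.  Nonnegativity is asserted after the fact — values below
`−10·atol` fail the run — never enforced by clipping, so a genuinely
inadmissible integration is reported, not masked.

Emulation is verified two ways.  The derivative check evaluates
`max_s |F(v̂∘m)(s) − F̂(v̂)(m(s))|` over sampled target states (componentwise
uniform on `[0, 2]` plus seeded boundary states with zeroed subsets); it
has no integration error and is the check used throughout the property
tests.  The trajectory check integrates both networks from matched initial
states (pulled back by copying through the species map) on one grid and
reports the maximum paired deviation; the default verdict threshold of
1e−6 exists only to absorb solver error, since the theory predicts exact
coincidence — in practice the observed deviations sit at 1e−16..1e−13.
Steady-state transfer requires the target residual below ten times the
check tolerance as a precondition, verifies the pulled-back state's
residual on every source species, and for species-bijective morphisms also
checks the converse direction.

## Search

`find_emulations` implements the practical strategy: set all rates to 1,
enumerate total species maps in deterministic lexicographic order, keep
maps whose induced reaction map exists (every image reaction present in the
target), and test the exact net-stoichiomorphism condition.  Each hit is a
unit-rate homomorphism/stoichiomorphism and therefore extends to an
emulation for every rate assignment of the target with rates copied
through the reaction map.  The triplet-respecting restriction maps whole
triplets to whole triplets, directly or dually, shrinking MI→AM from 729
maps to 4.  Enumeration is capped (`max_maps`, truncation flagged in the
result).  A separate exhaustive mode also enumerates reaction maps freely
and tests the raw reactant + stoichiomorphism matrix conditions, catching
non-homomorphic stoichiomorphisms such as the bundled rate-trade example;
it is hard-capped because its cost is `|Ŝ|^|S| · |R̂|^|R|` and no scalable
matching algorithm is attempted.

## Bundled fixtures and generators

`netlib` constructs everything in code: AM (3 species, 4 unit-rate
reactions), the MI influence network and its 6/8 compilation, the minimal
self-wired triplet node (its activation driven by its own active form and
its inhibition by its own inactive form — the smallest closed motif, and
structurally AM itself), the dual-collapse MI→AM morphism, and four small
morphism examples with known verdicts: the disjoint-copies map (all
conditions hold), two homomorphisms that fail the stoichiomorphism
condition with witness values −2 vs −1 and 1 vs 2, and a reactant
morphism/stoichiomorphism that trades a doubled rate against a doubled
product multiplicity and is not a homomorphism.  Fixtures whose topology is
reconstructed from drawings rather than explicit reaction lists are flagged
`reconstructed=True`; the larger quad-inhibition transcription lives in
`contrib/` outside the trusted set, with its reconstruction caveats in
`contrib/README.md`.

`random_crn` draws seeded networks (default 5 species, 6 reactions,
stoichiometric numbers ≤ 2, rates uniform on [0.1, 2], duplicate merging
applied, no-op reactions excluded) and `random_state` seeded states uniform
on `[0, scale]`; both are deterministic given the seed and drive the
round-trip, validation, and property tests.

## What the synthetic inputs do and do not show

The bundled and generated networks are small (≤ 12 species) and the random
states are moderate concentrations; passing tests demonstrate the exactness
of the morphism-to-kinetics link and the correctness of the matrix checks
at machine precision, at problem sizes where exhaustive enumeration is
feasible (e.g. all 729 MI→AM species maps).  They do not demonstrate
scalability of the search to large biological networks, behavior under
non-mass-action kinetics, stochastic semantics, or robustness of emulation
under approximation — all outside this package's model.  Trajectory
agreement is verified over finite horizons (t ≤ 50 by default, chosen to
include effective convergence of the bistable examples) at
`rtol = atol = 1e−9`.

## Known limitations

- Reaction maps are positional; structurally identical networks with
  permuted reaction lists need their morphism JSON re-indexed.
- The exhaustive (non-homomorphic) search mode is combinatorial and capped;
  it exists as a reference, not a tool for large instances.
- Reversible reactions are modeled as two irreversible ones; there is no
  SBML-native pathway.
- Approximate emulation (bounded rather than exact deviation) is not
  defined or checked; the dynamic thresholds only absorb solver error.
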