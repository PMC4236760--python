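"""Bundled networks, morphisms, counterexamples, and random generators.

Everything the test suite and the examples need is constructed here in
code: the approximate-majority switch AM, the two-node mutual-inhibition
influence network MI, the self-wired single-node triplet, the dual-collapse
morphism from compiled MI onto AM, and four small morphism examples and
counterexamples (one condition holding, another failing, with known witness
values).  Fixtures whose topology is reconstructed from a drawing rather
than stated as a reaction list carry ``reconstructed=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .influence import InfluenceEdge, InfluenceNetwork, TripletBinding, compile_influence
from .morphism import NetworkMorphism
from .network import Complex, Reaction, ReactionNetwork, make_network

__all__ = ["Fixture", "builtin", "builtin_names", "random_crn", "random_state"]


@dataclass(frozen=True)
class Fixture:
    """A named bundled object with its provenance description."""

    name: str
    network: ReactionNetwork | InfluenceNetwork | None
    provenance: str
    reconstructed: bool = False
    compiled: ReactionNetwork | None = None
    bindings: tuple[TripletBinding, ...] | None = None
    morphism: NetworkMorphism | None = None


def _rx(reactants: dict, products: dict, rate: float = 1.0) -> Reaction:
    return Reaction(Complex(reactants), Complex(products), rate)


def _am() -> ReactionNetwork:
    # two species in mutual inhibition and self-activation through a shared
    # intermediary: the approximate-majority population switch
    return ReactionNetwork(
        ("x0", "x1", "x2"),
        (
            _rx({"x0": 1, "x2": 1}, {"x0": 1, "x1": 1}),
            _rx({"x2": 1, "x0": 1}, {"x2": 1, "x1": 1}),
            _rx({"x0": 1, "x1": 1}, {"x0": 2}),
            _rx({"x2": 1, "x1": 1}, {"x2": 2}),
        ),
    )


def _mi() -> InfluenceNetwork:
    # y activates itself and inhibits z; z activates itself and inhibits y
    return InfluenceNetwork(
        ("y", "z"),
        (
            InfluenceEdge("y", "y", "activate"),
            InfluenceEdge("y", "z", "inhibit"),
            InfluenceEdge("z", "z", "activate"),
            InfluenceEdge("z", "y", "inhibit"),
        ),
    )


def _triplet() -> InfluenceNetwork:
    # one node, activated by its own active form and inhibited by its own
    # inactive form: the minimal closed triplet motif (3 species, 4 reactions)
    return InfluenceNetwork(
        ("x",),
        (
            InfluenceEdge("x", "x", "activate", polarity="high"),
            InfluenceEdge("x", "x", "inhibit", polarity="low"),
        ),
    )


def _mi_to_am() -> tuple[ReactionNetwork, NetworkMorphism]:
    from .search import induced_reaction_map

    mi_net, _ = compile_influence(_mi())
    am = _am()
    # collapse y directly and z dually onto the single AM triplet
    m_S = {"y_0": "x0", "y_1": "x1", "y_2": "x2",
           "z_0": "x2", "z_1": "x1", "z_2": "x0"}
    rmap, err = induced_reaction_map(m_S, mi_net, am, unit_rate=False)
    assert err is None, err
    return mi_net, NetworkMorphism(mi_net, am, m_S, rmap)


def _fig6a() -> NetworkMorphism:
    src = make_network(
        (), [_rx({"s0": 1}, {"s1": 1}), _rx({"s2": 1}, {"s3": 1})]
    )
    tgt = make_network((), [_rx({"t0": 1}, {"t1": 1})])
    return NetworkMorphism(src, tgt,
                           {"s0": "t0", "s1": "t1", "s2": "t0", "s3": "t1"},
                           (0, 0))


def _fig6b() -> NetworkMorphism:
    src = make_network(
        (), [_rx({"s0": 1}, {"s1": 1}), _rx({"s0": 1}, {"s2": 1})]
    )
    tgt = make_network((), [_rx({"t0": 1}, {"t1": 1})])
    return NetworkMorphism(src, tgt,
                           {"s0": "t0", "s1": "t1", "s2": "t1"}, (0, 0))


def _fig6d() -> NetworkMorphism:
    src = make_network((), [_rx({"s0": 1}, {"s1": 1, "s2": 1})])
    tgt = make_network((), [_rx({"t0": 1}, {"t1": 2})])
    return NetworkMorphism(src, tgt,
                           {"s0": "t0", "s1": "t1", "s2": "t1"}, (0,))


def _fig6f() -> NetworkMorphism:
    src = make_network(
        (), [_rx({"s0": 1}, {"s0": 1, "s1": 2}), _rx({"s0": 1}, {"s0": 1})]
    )
    tgt = make_network((), [_rx({"t0": 1}, {"t0": 1, "t1": 1}, rate=2.0)])
    return NetworkMorphism(src, tgt, {"s0": "t0", "s1": "t1"}, (0, 0))


def builtin_names() -> tuple[str, ...]:
    return ("am", "mi", "triplet", "mi_to_am_morphism",
            "fig6a", "fig6b", "fig6d", "fig6f")


def builtin(name: str) -> Fixture:
    """Fetch a bundled fixture by name (see :func:`builtin_names`)."""
    if name == "am":
        return Fixture("am", _am(),
                       "classic three-species approximate-majority switch")
    if name == "mi":
        inet = _mi()
        net, bindings = compile_influence(inet)
        return Fixture("mi", inet,
                       "two-node mutual-inhibition influence network",
                       compiled=net, bindings=tuple(bindings))
    if name == "triplet":
        inet = _triplet()
        net, bindings = compile_influence(inet)
        return Fixture("triplet", inet,
                       "single self-wired influence node (minimal triplet motif)",
                       compiled=net, bindings=tuple(bindings))
    if name == "mi_to_am_morphism":
        mi_net, m = _mi_to_am()
        return Fixture("mi_to_am_morphism", mi_net,
                       "dual-collapse emulation morphism from compiled MI onto AM",
                       morphism=m)
    if name == "fig6a":
        m = _fig6a()
        return Fixture("fig6a", m.source,
                       "two disjoint copies mapped componentwise: "
                       "homomorphism and stoichiomorphism",
                       reconstructed=True, morphism=m)
    if name == "fig6b":
        m = _fig6b()
        return Fixture("fig6b", m.source,
                       "branching collapse: homomorphism that fails the "
                       "fiber-summed stoichiometry condition (-2 vs -1)",
                       reconstructed=True, morphism=m)
    if name == "fig6d":
        m = _fig6d()
        return Fixture("fig6d", m.source,
                       "product-splitting collapse: homomorphism that fails "
                       "the stoichiomorphism condition (1 vs 2)",
                       reconstructed=True, morphism=m)
    if name == "fig6f":
        m = _fig6f()
        return Fixture("fig6f", m.source,
                       "rate/stoichiometry trade: reactant morphism and "
                       "stoichiomorphism that is not a homomorphism",
                       reconstructed=True, morphism=m)
    raise KeyError(f"unknown fixture {name!r}; known: {builtin_names()}")


def random_crn(seed: int, n_species: int = 5, n_reactions: int = 6,
               max_stoich: int = 2) -> ReactionNetwork:
    """Seeded random network for property tests (duplicates merged)."""
    if n_species < 1 or n_reactions < 0 or max_stoich < 1:
        raise ValueError("need n_species >= 1, n_reactions >= 0, max_stoich >= 1")
    rng = np.random.default_rng(seed)
    species = tuple(f"S{i}" for i in range(n_species))
    reactions = []
    for _ in range(n_reactions):
        while True:
            rho = {s: int(n) for s in species
                   if (n := rng.integers(0, max_stoich + 1)) > 0 and rng.random() < 0.6}
            pi = {s: int(n) for s in species
                  if (n := rng.integers(0, max_stoich + 1)) > 0 and rng.random() < 0.6}
            if Complex(rho) != Complex(pi):  # skip no-op s -> s style identities
                break
        reactions.append(Reaction(Complex(rho), Complex(pi),
                                  float(rng.uniform(0.1, 2.0))))
    return make_network(species, reactions)


def random_state(seed: int, net: ReactionNetwork, scale: float = 2.0,
                 zero_mask=None) -> dict[str, float]:
    """Seeded componentwise-uniform state on [0, scale]."""
    if not scale > 0:
        raise ValueError("scale must be > 0")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, scale, net.n_species)
    if zero_mask is not None:
        for i, z in enumerate(zero_mask):
            if z:
                x[i] = 0.0
    return dict(zip(net.species, x.tolist()))
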