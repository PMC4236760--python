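"""Brute-force discovery of emulation morphisms between two networks.

The practical strategy: set every rate constant to 1, enumerate total
species maps, keep those that induce a homomorphism (every image reaction
exists in the target), and check the rate-free net-stoichiomorphism
condition.  A unit-rate homomorphism/stoichiomorphism extends to an
emulation for *every* rate assignment of the target (rates are simply
copied through the reaction map), so each hit certifies a whole family of
kinetic emulations.

When both networks are influence compilations, maps can be restricted to
send triplets onto triplets, directly (x0->x0, x1->x1, x2->x2) or dually
(x0->x2, x1->x1, x2->x0), which shrinks the space from |T|^|S| to
(2 * n_target_triplets)^n_source_triplets.

An exhaustive mode that also enumerates reaction maps freely (catching
stoichiomorphisms that are not homomorphisms) is available behind a hard
cap; no scalable algorithm is attempted.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterator, Mapping, Sequence
from dataclasses import dataclass, field

from .influence import TripletBinding
from .morphism import (
    NetworkMorphism,
    is_net_stoichiomorphism,
    is_reactant_morphism,
    is_stoichiomorphism,
)
from .network import ReactionNetwork, apply_complex_map

__all__ = [
    "SearchConfig",
    "SearchResult",
    "enumerate_species_maps",
    "induced_reaction_map",
    "find_emulations",
    "find_morphisms_exhaustive",
]


@dataclass(frozen=True)
class SearchConfig:
    """Knobs for the enumeration.

    ``unit_rate=True`` replaces all rates by 1 before matching, per the
    copy-rates strategy; ``respect_triplets`` restricts maps to whole
    triplets (direct or dual) and requires bindings for both networks.
    """

    max_maps: int = 100_000
    respect_triplets: bool = False
    unit_rate: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.max_maps <= 0:
            raise ValueError("max_maps must be > 0")


class SearchResult(Sequence):
    """Sequence of found morphisms, plus enumeration metadata."""

    def __init__(self, morphisms, maps_tried: int, truncated: bool):
        self.morphisms = list(morphisms)
        self.maps_tried = maps_tried
        self.truncated = truncated

    def __getitem__(self, i):
        return self.morphisms[i]

    def __len__(self):
        return len(self.morphisms)

    def __repr__(self):
        return (f"SearchResult({len(self.morphisms)} morphisms, "
                f"{self.maps_tried} maps tried, truncated={self.truncated})")


def enumerate_species_maps(
    src: ReactionNetwork,
    tgt: ReactionNetwork,
    cfg: SearchConfig,
    src_triplets: Sequence[TripletBinding] | None = None,
    tgt_triplets: Sequence[TripletBinding] | None = None,
) -> Iterator[dict[str, str]]:
    """Yield total species maps src -> tgt in deterministic lexicographic order.

    Unconstrained: the full |tgt.species|^|src.species| product.  With
    ``respect_triplets``, each source triplet goes onto a target triplet
    either directly or dually; species outside any triplet are not allowed
    in this mode.  Yields at most ``cfg.max_maps`` maps (truncation is
    reported by the callers that consume the iterator).
    """
    if cfg.respect_triplets:
        if src_triplets is None or tgt_triplets is None:
            raise ValueError("respect_triplets needs bindings for both networks")
        bound = {s for b in src_triplets for s in b.species}
        loose = [s for s in src.species if s not in bound]
        if loose:
            raise ValueError(f"species outside any triplet: {loose}")
        choices = []
        for tb in tgt_triplets:
            x0, x1, x2 = tb.species
            choices.append(((x0, x1, x2), (x2, x1, x0)))  # direct, dual
        flat = [img for pair in choices for img in pair]
        count = 0
        for combo in itertools.product(flat, repeat=len(src_triplets)):
            if count >= cfg.max_maps:
                return
            m: dict[str, str] = {}
            for sb, img in zip(src_triplets, combo):
                for s, t in zip(sb.species, img):
                    m[s] = t
            count += 1
            yield m
        return
    count = 0
    if not src.species:
        yield {}
        return
    for combo in itertools.product(tgt.species, repeat=src.n_species):
        if count >= cfg.max_maps:
            return
        count += 1
        yield dict(zip(src.species, combo))


def induced_reaction_map(
    m_S: Mapping[str, str],
    src: ReactionNetwork,
    tgt: ReactionNetwork,
    unit_rate: bool = True,
):
    """Reaction map determined by a species map, or a failure message.

    For each source reaction, finds the target reaction equal to
    ``m(rho) -> m(pi)`` (rate ignored when ``unit_rate``; equal rate
    required otherwise).  Returns ``(tuple_of_indices, None)`` on success or
    ``(None, message)`` naming the first unmatched reaction.
    """
    if unit_rate:
        index = {(r.reactants, r.products): j for j, r in enumerate(tgt.reactions)}
        def key(rho, pi, k):
            return (rho, pi)
    else:
        index = {(r.reactants, r.products, r.rate): j
                 for j, r in enumerate(tgt.reactions)}
        def key(rho, pi, k):
            return (rho, pi, k)
    out = []
    for i, r in enumerate(src.reactions):
        k = key(apply_complex_map(m_S, r.reactants),
                apply_complex_map(m_S, r.products), r.rate)
        j = index.get(k)
        if j is None:
            return None, f"source reaction {i} ({r}) has no image in the target"
        out.append(j)
    return tuple(out), None


def find_emulations(
    src: ReactionNetwork,
    tgt: ReactionNetwork,
    cfg: SearchConfig = SearchConfig(),
    src_triplets: Sequence[TripletBinding] | None = None,
    tgt_triplets: Sequence[TripletBinding] | None = None,
) -> SearchResult:
    """All species maps (up to the cap) whose induced homomorphism is a
    net-stoichiomorphism at unit rates.

    Each returned morphism runs between the unit-rate versions of the
    networks and certifies an emulation for every rate assignment of the
    target, with rates copied through the reaction map.
    """
    s = src.unit_rates() if cfg.unit_rate else src
    t = tgt.unit_rates() if cfg.unit_rate else tgt
    found = []
    tried = 0
    truncated = False
    gen = enumerate_species_maps(s, t, cfg, src_triplets, tgt_triplets)
    for m_S in gen:
        tried += 1
        rmap, err = induced_reaction_map(m_S, s, t, unit_rate=cfg.unit_rate)
        if rmap is None:
            continue
        m = NetworkMorphism(s, t, m_S, rmap)
        if is_net_stoichiomorphism(m).holds:
            found.append(m)
    if tried >= cfg.max_maps:
        truncated = True
    return SearchResult(found, tried, truncated)


def find_morphisms_exhaustive(
    src: ReactionNetwork,
    tgt: ReactionNetwork,
    cfg: SearchConfig = SearchConfig(),
    max_total: int = 2_000_000,
) -> SearchResult:
    """Free enumeration of (species map, reaction map) pairs.

    Checks the raw reactant-morphism and stoichiomorphism matrix conditions
    for every pair, so it also finds morphisms that are not homomorphisms.
    Combinatorially explosive; hard-capped at ``max_total`` pairs.
    """
    total = (tgt.n_species ** src.n_species) * (
        max(tgt.n_reactions, 1) ** src.n_reactions
    )
    if total > max_total:
        raise ValueError(
            f"{total} candidate pairs exceed the exhaustive-mode cap {max_total}"
        )
    s = src.unit_rates() if cfg.unit_rate else src
    t = tgt.unit_rates() if cfg.unit_rate else tgt
    found = []
    tried = 0
    for m_S in enumerate_species_maps(s, t, cfg):
        for rmap in itertools.product(range(t.n_reactions), repeat=s.n_reactions):
            tried += 1
            m = NetworkMorphism(s, t, m_S, rmap)
            if is_reactant_morphism(m).holds and is_stoichiomorphism(m).holds:
                found.append(m)
    return SearchResult(found, tried, False)
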