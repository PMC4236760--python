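"""Morphisms between reaction networks and their static checks.

A network morphism is a pair of total maps, one on species and one on
reactions.  Three structural conditions matter for kinetics:

* **reactant morphism** — each reaction's image has reactants equal to the
  species-map image of its reactants: ``mS^T . rho = rho_hat . mR^T``.
* **homomorphism** — the reaction map is fully determined by the species
  map: image reaction = mapped reactants -> mapped products at the same
  rate.  Every homomorphism is a reactant morphism and preserves
  instantaneous stoichiometry summed over *species* fibers.
* **stoichiomorphism** — instantaneous stoichiometry is preserved summed
  over *reaction* fibers: ``phi . mR = mS . phi_hat``.  Together with the
  reactant condition this guarantees kinetic emulation (see
  :mod:`crnemu.kinetics`).  The *net* variant replaces ``phi`` by the
  rate-free ``eta`` and suffices at unit rates.

Checks return a :class:`CheckResult` certificate with failing witnesses, so
a negative verdict is actionable.  The change-of-rates construction lifts a
rate reassignment of the target across a stoichiomorphism via
``k' = k * k_hat' / k_hat``, preserving every condition the morphism had.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .network import (
    MappingError,
    Reaction,
    ReactionNetwork,
    ValidationError,
    apply_complex_map,
)

__all__ = [
    "NetworkMorphism",
    "CheckResult",
    "RateChange",
    "fibers",
    "is_reactant_morphism",
    "is_homomorphism",
    "is_stoichiomorphism",
    "is_net_stoichiomorphism",
    "compose",
    "change_of_rates_lift",
    "identity_morphism",
    "morphism_from_json",
    "morphism_to_json",
]

MAX_WITNESSES = 10
PHI_ATOL = 1e-12


@dataclass(frozen=True)
class CheckResult:
    """Verdict of a matrix condition plus witnesses where it fails.

    ``witnesses`` holds up to ``MAX_WITNESSES`` tuples
    ``((row_label, col_label), lhs, rhs)`` for entries where the defining
    equation fails; ``holds`` iff there are none.  ``max_residual`` is the
    largest |lhs - rhs| over all entries (0.0 when the check is exact and
    passes), so borderline floating comparisons are visible.
    """

    holds: bool
    witnesses: tuple = ()
    max_residual: float = 0.0
    condition: str = ""

    def __bool__(self) -> bool:
        return self.holds

    def to_json(self) -> dict:
        return {
            "condition": self.condition,
            "holds": self.holds,
            "max_residual": self.max_residual,
            "witnesses": [
                {"at": list(at), "lhs": _jsonable(l), "rhs": _jsonable(r)}
                for at, l, r in self.witnesses
            ],
        }


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    return x


@dataclass(frozen=True)
class NetworkMorphism:
    """Total species map and total reaction map between two networks.

    ``reaction_map[i]`` is the index in ``target.reactions`` of the image of
    ``source.reactions[i]``.  Characteristic matrices are 0-1 with exactly
    one 1 per row.
    """

    source: ReactionNetwork
    target: ReactionNetwork
    species_map: Mapping[str, str]
    reaction_map: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "species_map", dict(self.species_map))
        object.__setattr__(self, "reaction_map", tuple(int(i) for i in self.reaction_map))
        tgt = set(self.target.species)
        for s in self.source.species:
            if s not in self.species_map:
                raise MappingError(f"species map is not total: {s!r} unmapped")
            if self.species_map[s] not in tgt:
                raise MappingError(
                    f"species map sends {s!r} to {self.species_map[s]!r}, "
                    "not a target species"
                )
        if len(self.reaction_map) != self.source.n_reactions:
            raise MappingError(
                f"reaction map has {len(self.reaction_map)} entries for "
                f"{self.source.n_reactions} source reactions"
            )
        for i, j in enumerate(self.reaction_map):
            if not 0 <= j < self.target.n_reactions:
                raise MappingError(f"reaction {i} mapped to invalid target index {j}")

    # characteristic 0-1 matrices ------------------------------------------------
    @property
    def species_matrix(self) -> np.ndarray:
        """(n_source_species, n_target_species) characteristic matrix of m_S."""
        tgt_idx = self.target.species_index()
        M = np.zeros((self.source.n_species, self.target.n_species), dtype=np.int64)
        for i, s in enumerate(self.source.species):
            M[i, tgt_idx[self.species_map[s]]] = 1
        return M

    @property
    def reaction_matrix(self) -> np.ndarray:
        """(n_source_reactions, n_target_reactions) characteristic matrix of m_R."""
        M = np.zeros((self.source.n_reactions, self.target.n_reactions), dtype=np.int64)
        for i, j in enumerate(self.reaction_map):
            M[i, j] = 1
        return M

    def species_fibers(self) -> dict[str, set]:
        return fibers(self.species_map, self.target.species)

    def reaction_fibers(self) -> dict[int, set]:
        return fibers(dict(enumerate(self.reaction_map)), range(self.target.n_reactions))

    def map_state(self, v: Mapping[str, float]) -> dict[str, float]:
        """Pull a target state back along the species map (copy, never sum)."""
        return {s: float(v[self.species_map[s]]) for s in self.source.species}


def fibers(m: Mapping, codomain) -> dict:
    """Inverse images of singletons: codomain element -> set of preimages."""
    out = {c: set() for c in codomain}
    for x, y in m.items():
        if y not in out:
            raise MappingError(f"map image {y!r} is outside the stated codomain")
        out[y].add(x)
    return out


def _matrix_check(lhs: np.ndarray, rhs: np.ndarray, rows, cols, condition: str,
                  atol: float = 0.0) -> CheckResult:
    diff = np.abs(np.asarray(lhs, dtype=float) - np.asarray(rhs, dtype=float))
    max_res = float(diff.max()) if diff.size else 0.0
    bad = np.argwhere(diff > atol)
    witnesses = tuple(
        ((rows[i], cols[j]), _jsonable(lhs[i, j]), _jsonable(rhs[i, j]))
        for i, j in bad[:MAX_WITNESSES]
    )
    return CheckResult(len(bad) == 0, witnesses, max_res, condition)


def is_reactant_morphism(m: NetworkMorphism) -> CheckResult:
    """Check ``mS^T . rho = rho_hat . mR^T`` in exact integer arithmetic."""
    rho = m.source.stoich_matrices().reactant
    rho_hat = m.target.stoich_matrices().reactant
    lhs = m.species_matrix.T @ rho
    rhs = rho_hat @ m.reaction_matrix.T
    return _matrix_check(lhs, rhs, list(m.target.species),
                         list(range(m.source.n_reactions)), "reactant_morphism")


def is_homomorphism(m: NetworkMorphism) -> CheckResult:
    """Check that each image reaction is the species-map image, rate included."""
    witnesses = []
    n_bad = 0
    for i, r in enumerate(m.source.reactions):
        image = m.target.reactions[m.reaction_map[i]]
        want = Reaction(
            apply_complex_map(m.species_map, r.reactants),
            apply_complex_map(m.species_map, r.products),
            r.rate,
        )
        if image != want:
            n_bad += 1
            if len(witnesses) < MAX_WITNESSES:
                witnesses.append(((i, m.reaction_map[i]), str(want), str(image)))
    return CheckResult(n_bad == 0, tuple(witnesses),
                       float(n_bad), "homomorphism")


def _phi_pair(m: NetworkMorphism):
    return m.source.stoich_matrices(), m.target.stoich_matrices()


def is_stoichiomorphism(m: NetworkMorphism) -> CheckResult:
    """Check ``phi . mR = mS . phi_hat``: fiber-summed instantaneous stoichiometry.

    Exact when every rate constant is integer-valued; otherwise a floating
    comparison with absolute tolerance ``PHI_ATOL``.
    """
    sm, tm = _phi_pair(m)
    all_int = all(float(k).is_integer() for k in np.concatenate([sm.rates, tm.rates])) \
        if sm.rates.size or tm.rates.size else True
    if all_int:
        phi = sm.net * sm.rates.astype(np.int64)[np.newaxis, :] if sm.rates.size else sm.net
        phi_hat = tm.net * tm.rates.astype(np.int64)[np.newaxis, :] if tm.rates.size else tm.net
        atol = 0.0
    else:
        phi, phi_hat, atol = sm.instantaneous, tm.instantaneous, PHI_ATOL
    lhs = phi @ m.reaction_matrix
    rhs = m.species_matrix @ phi_hat
    return _matrix_check(lhs, rhs, list(m.source.species),
                         list(range(m.target.n_reactions)), "stoichiomorphism", atol)


def is_net_stoichiomorphism(m: NetworkMorphism) -> CheckResult:
    """The stoichiomorphism condition with rate-free net stoichiometry (exact)."""
    sm, tm = _phi_pair(m)
    lhs = sm.net @ m.reaction_matrix
    rhs = m.species_matrix @ tm.net
    return _matrix_check(lhs, rhs, list(m.source.species),
                         list(range(m.target.n_reactions)), "net_stoichiomorphism")


def compose(m1: NetworkMorphism, m2: NetworkMorphism) -> NetworkMorphism:
    """Componentwise composition; requires ``m1.target == m2.source``."""
    if m1.target != m2.source:
        raise MappingError("cannot compose: first target differs from second source")
    species_map = {s: m2.species_map[m1.species_map[s]] for s in m1.source.species}
    reaction_map = tuple(m2.reaction_map[j] for j in m1.reaction_map)
    return NetworkMorphism(m1.source, m2.target, species_map, reaction_map)


def identity_morphism(net: ReactionNetwork) -> NetworkMorphism:
    return NetworkMorphism(net, net, {s: s for s in net.species},
                           tuple(range(net.n_reactions)))


@dataclass(frozen=True)
class RateChange:
    """A rate-only reassignment of a network's reactions.

    ``assignment`` maps target reaction index to its new positive rate;
    complexes are untouched.
    """

    assignment: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for i, k in self.assignment.items():
            k = float(k)
            if not k > 0:
                raise ValidationError(f"rate change for reaction {i} must be > 0, got {k}")
            clean[int(i)] = k
        object.__setattr__(self, "assignment", clean)

    def apply(self, net: ReactionNetwork) -> ReactionNetwork:
        missing = [i for i in range(net.n_reactions) if i not in self.assignment]
        if missing:
            raise ValidationError(f"rate change misses reactions {missing}")
        return net.with_rates([self.assignment[i] for i in range(net.n_reactions)])


def change_of_rates_lift(m: NetworkMorphism, rc: RateChange):
    """Lift a target rate change across a stoichiomorphism.

    Each source reaction of rate ``k`` whose image had rate ``k_hat`` and is
    reassigned ``k_hat'`` gets rate ``k * k_hat' / k_hat``.  Returns
    ``(new_source, new_morphism)`` where the new morphism (same maps) runs
    between the re-rated networks and is again a stoichiomorphism; if ``m``
    was a homomorphism the lifted rates are exact copies of the new target
    rates.
    """
    new_target = rc.apply(m.target)
    new_rates = []
    for i, r in enumerate(m.source.reactions):
        j = m.reaction_map[i]
        k_hat = m.target.reactions[j].rate
        new_rates.append(r.rate * rc.assignment[j] / k_hat)
    # distinct source reactions keep distinct complexes, so no duplicate
    # merge can arise from a pure rate change
    new_source = m.source.with_rates(new_rates)
    lifted = NetworkMorphism(new_source, new_target, m.species_map, m.reaction_map)
    return new_source, lifted


def morphism_from_json(obj: Mapping, source: ReactionNetwork,
                       target: ReactionNetwork) -> NetworkMorphism:
    """Build a morphism from its JSON form.

    Either ``{"species": {...}, "reactions": [[i, j], ...]}`` with explicit
    index pairs, or ``{"species": {...}, "homomorphic": true}`` which derives
    the reaction map from the species map and errors if some image reaction
    is absent from the target.
    """
    species_map = dict(obj["species"])
    if obj.get("homomorphic"):
        index = {(r.reactants, r.products, r.rate): j
                 for j, r in enumerate(target.reactions)}
        reaction_map = []
        for i, r in enumerate(source.reactions):
            key = (apply_complex_map(species_map, r.reactants),
                   apply_complex_map(species_map, r.products), r.rate)
            if key not in index:
                raise MappingError(
                    f"no target reaction matches the image of source reaction {i} "
                    f"({key[0]} ->{{{key[2]:g}}} {key[1]})"
                )
            reaction_map.append(index[key])
    else:
        pairs = obj.get("reactions")
        if pairs is None:
            raise MappingError('morphism JSON needs "reactions" or "homomorphic": true')
        reaction_map = [-1] * source.n_reactions
        for i, j in pairs:
            reaction_map[int(i)] = int(j)
        if any(j < 0 for j in reaction_map):
            raise MappingError("reaction map in JSON is not total")
    return NetworkMorphism(source, target, species_map, tuple(reaction_map))


def morphism_to_json(m: NetworkMorphism) -> dict:
    return {
        "species": dict(m.species_map),
        "reactions": [[i, j] for i, j in enumerate(m.reaction_map)],
    }
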