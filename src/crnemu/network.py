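"""Chemical reaction network data model and stoichiometric matrices.

A reaction network is a finite ordered list of species together with a
finite ordered list of irreversible reactions ``reactants ->{k} products``
with a strictly positive mass-action rate constant ``k``.  Reactant and
product sides are *complexes*: multisets of species (functions from species
to nonnegative integers).  The empty complex is legal on either side, so
open systems (inflows/outflows) are expressible; no conservation of mass is
assumed.

Two reactions with identical reactant and product complexes are kinetically
equivalent to a single reaction whose rate is the sum of theirs, so networks
never contain duplicates: :func:`make_network` merges them at construction.

The network's syntactic structure is gathered in four matrices (species x
reactions): the reactant matrix ``rho``, the product matrix ``pi``, the net
stoichiometry ``eta = pi - rho`` and the *instantaneous* stoichiometry
``phi = k * eta``, which bundles the rate constant with the net
stoichiometry and is the state-independent factor of the mass-action ODE.
"""

from __future__ import annotations

import logging
import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Complex",
    "Reaction",
    "ReactionNetwork",
    "StoichMatrices",
    "CRNError",
    "ValidationError",
    "MappingError",
    "make_network",
    "stoich_matrices",
    "apply_complex_map",
    "homomorphic_projection",
]

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*\Z")


class CRNError(Exception):
    """Base class for reaction-network errors."""


class ValidationError(CRNError):
    """A network, reaction or species failed a structural invariant."""


class MappingError(CRNError):
    """A species/reaction map is not total or not well formed."""


def _check_token(name: str) -> str:
    if not isinstance(name, str) or not _TOKEN_RE.match(name):
        raise ValidationError(
            f"invalid species token {name!r}: must match [A-Za-z_][A-Za-z0-9_]*"
        )
    return name


class Complex(Mapping):
    """A multiset of species: species name -> positive multiplicity.

    Zero entries are dropped, so two complexes are equal iff they assign the
    same multiplicity to every species; the empty complex is ``Complex()``.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        items = counts.items() if isinstance(counts, Mapping) else counts
        store: dict[str, int] = {}
        for name, n in items:
            _check_token(name)
            if not isinstance(n, (int, np.integer)) or isinstance(n, bool):
                raise ValidationError(f"multiplicity of {name!r} must be an integer, got {n!r}")
            if n < 0:
                raise ValidationError(f"multiplicity of {name!r} must be >= 0, got {n}")
            if n > 0:
                store[name] = store.get(name, 0) + int(n)
        self._counts = store

    def __getitem__(self, species: str) -> int:
        return self._counts.get(species, 0)

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, species) -> bool:
        return species in self._counts

    def __eq__(self, other) -> bool:
        if isinstance(other, Complex):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    @property
    def order(self) -> int:
        """Total multiplicity (the reaction order when used as a reactant side)."""
        return sum(self._counts.values())

    @property
    def species(self) -> frozenset:
        return frozenset(self._counts)

    def __str__(self) -> str:
        if not self._counts:
            return "0"
        terms = []
        for name in sorted(self._counts):
            n = self._counts[name]
            terms.append(name if n == 1 else f"{n}{name}")
        return " + ".join(terms)

    def __repr__(self) -> str:
        return f"Complex({self._counts!r})"


@dataclass(frozen=True)
class Reaction:
    """An irreversible reaction ``reactants ->{rate} products``, mass action.

    The rate constant has dimension s^-1 * M^(1-order) where order is the
    total reactant multiplicity; it must be strictly positive.
    """

    reactants: Complex
    products: Complex
    rate: float

    def __post_init__(self):
        if not isinstance(self.reactants, Complex):
            object.__setattr__(self, "reactants", Complex(self.reactants))
        if not isinstance(self.products, Complex):
            object.__setattr__(self, "products", Complex(self.products))
        rate = float(self.rate)
        if not rate > 0:
            raise ValidationError(
                f"reaction {self.reactants} -> {self.products} has nonpositive "
                f"rate {self.rate!r}; rates must be > 0"
            )
        object.__setattr__(self, "rate", rate)

    @property
    def order(self) -> int:
        return self.reactants.order

    @property
    def species(self) -> frozenset:
        return self.reactants.species | self.products.species

    def __str__(self) -> str:
        return f"{self.reactants} ->{{{self.rate:g}}} {self.products}"


@dataclass(frozen=True)
class ReactionNetwork:
    """An ordered species list plus an ordered, duplicate-free reaction list.

    Use :func:`make_network` to build one with duplicate merging and
    automatic species collection; the constructor only validates.
    """

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        seen = set()
        for s in self.species:
            _check_token(s)
            if s in seen:
                raise ValidationError(f"duplicate species {s!r} in species list")
            seen.add(s)
        pairs = set()
        for r in self.reactions:
            missing = r.species - seen
            if missing:
                raise ValidationError(
                    f"reaction {r} mentions species not in the species list: "
                    f"{sorted(missing)}"
                )
            key = (r.reactants, r.products)
            if key in pairs:
                raise ValidationError(
                    f"duplicate reaction {r.reactants} -> {r.products}: merge rates "
                    "with make_network first"
                )
            pairs.add(key)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.species)}

    def stoich_matrices(self) -> "StoichMatrices":
        return stoich_matrices(self)

    def with_rates(self, rates: Iterable[float]) -> "ReactionNetwork":
        """Same complexes, new rate constants (a change of rates)."""
        rates = list(rates)
        if len(rates) != self.n_reactions:
            raise ValidationError(
                f"expected {self.n_reactions} rates, got {len(rates)}"
            )
        return ReactionNetwork(
            self.species,
            tuple(Reaction(r.reactants, r.products, k) for r, k in zip(self.reactions, rates)),
        )

    def unit_rates(self) -> "ReactionNetwork":
        return self.with_rates([1.0] * self.n_reactions)

    def __str__(self) -> str:
        lines = ["species: " + " ".join(self.species)]
        lines += [str(r) for r in self.reactions]
        return "\n".join(lines)


@dataclass(frozen=True)
class StoichMatrices:
    """Stoichiometric matrices of a network, all shaped (n_species, n_reactions).

    ``net = product - reactant`` exactly (integers); ``instantaneous`` scales
    each net column by that reaction's rate constant.
    """

    species: tuple[str, ...]
    reactant: np.ndarray
    product: np.ndarray
    net: np.ndarray
    instantaneous: np.ndarray
    rates: np.ndarray = field(repr=False, default=None)


def make_network(
    species: Iterable[str] = (),
    reactions: Iterable[Reaction] = (),
) -> ReactionNetwork:
    """Build a network, merging duplicate reactions and collecting species.

    Reactions sharing both complexes are kinetically equivalent to a single
    reaction with summed rate and are merged (logged).  Species mentioned
    only inside complexes are appended to the given species order in first
    mention order.
    """
    order: list[str] = []
    seen: set[str] = set()
    for s in species:
        _check_token(s)
        if s in seen:
            raise ValidationError(f"duplicate species {s!r} in species list")
        seen.add(s)
        order.append(s)

    merged: dict[tuple[Complex, Complex], float] = {}
    for r in reactions:
        if not isinstance(r, Reaction):
            r = Reaction(*r)
        for s in sorted(r.species):
            if s not in seen:
                seen.add(s)
                order.append(s)
        key = (r.reactants, r.products)
        if key in merged:
            logger.info(
                "merging duplicate reaction %s -> %s: rates %g + %g",
                r.reactants, r.products, merged[key], r.rate,
            )
            merged[key] += r.rate
        else:
            merged[key] = r.rate

    # first mention inside a complex must respect a stable order per reaction;
    # sorted() above makes the appended order deterministic within a reaction
    return ReactionNetwork(
        tuple(order),
        tuple(Reaction(rx, px, k) for (rx, px), k in merged.items()),
    )


def stoich_matrices(net: ReactionNetwork) -> StoichMatrices:
    """Reactant, product, net and instantaneous matrices of ``net``."""
    idx = net.species_index()
    ns, nr = net.n_species, net.n_reactions
    rho = np.zeros((ns, nr), dtype=np.int64)
    pi = np.zeros((ns, nr), dtype=np.int64)
    rates = np.empty(nr, dtype=float)
    for j, r in enumerate(net.reactions):
        rates[j] = r.rate
        for s, n in r.reactants.items():
            rho[idx[s], j] = n
        for s, n in r.products.items():
            pi[idx[s], j] = n
    eta = pi - rho
    phi = eta * rates[np.newaxis, :]
    return StoichMatrices(net.species, rho, pi, eta, phi, rates)


def apply_complex_map(m_S: Mapping[str, str], c: Complex) -> Complex:
    """Image of a complex under a species map, summing over fibers.

    Species mapped to the same image have their multiplicities summed; the
    result is zero on species outside the image.
    """
    out: dict[str, int] = {}
    for s, n in c.items():
        if s not in m_S:
            raise MappingError(f"species {s!r} is not mapped by the species map")
        t = m_S[s]
        out[t] = out.get(t, 0) + n
    return Complex(out)


def homomorphic_projection(net: ReactionNetwork, m_S: Mapping[str, str]):
    """Collapse a network through a species map; reactions follow the map.

    Each reaction ``rho ->{k} pi`` is sent to ``m(rho) ->{k} m(pi)``;
    reactions with identical images collapse to a single target reaction
    (the image is a set, not a rate sum).  Returns the image network and the
    epimorphism onto it.  Raises :class:`ValidationError` if two images agree
    on both complexes but differ in rate, in which case no homomorphic image
    network exists.
    """
    from .morphism import NetworkMorphism  # circular at import time only

    missing = [s for s in net.species if s not in m_S]
    if missing:
        raise MappingError(f"species map is not total; missing {missing}")

    tgt_species: list[str] = []
    seen: set[str] = set()
    for s in net.species:
        t = _check_token(m_S[s])
        if t not in seen:
            seen.add(t)
            tgt_species.append(t)

    images: list[Reaction] = []
    image_index: dict[tuple[Complex, Complex, float], int] = {}
    by_pair: dict[tuple[Complex, Complex], float] = {}
    reaction_map: list[int] = []
    for r in net.reactions:
        rho = apply_complex_map(m_S, r.reactants)
        pi = apply_complex_map(m_S, r.products)
        key = (rho, pi, r.rate)
        if key not in image_index:
            pair = (rho, pi)
            if pair in by_pair and by_pair[pair] != r.rate:
                raise ValidationError(
                    f"projection images {rho} -> {pi} carry conflicting rates "
                    f"{by_pair[pair]:g} and {r.rate:g}; no homomorphic image exists"
                )
            by_pair[pair] = r.rate
            image_index[key] = len(images)
            images.append(Reaction(rho, pi, r.rate))
        reaction_map.append(image_index[key])

    target = ReactionNetwork(tuple(tgt_species), tuple(images))
    morphism = NetworkMorphism(net, target, dict(m_S), tuple(reaction_map))
    return target, morphism
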