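"""Influence networks and their compilation to mass-action CRNs.

An influence network is a graph of nodes that range between an activated
and an inhibited state, with edges that push target nodes toward activation
or inhibition.  Each node ``x`` compiles to a *triplet motif* of three
chemical species — ``x_0`` (active), ``x_1`` (intermediary), ``x_2``
(inactive) — and, per incoming edge, two catalytic transition reactions.
The catalyst is the source node's active species ``x_0`` for a high-polarity
output and ``x_2`` for a low-polarity output:

* activate:  ``c + x_1 -> c + x_0``  and  ``c + x_2 -> c + x_1``
* inhibit:   ``c + x_0 -> c + x_1``  and  ``c + x_1 -> c + x_2``

The intermediary ``x_1`` introduces the nonlinearity: at steady state, with
clamped catalyst levels ``a`` (activation) and ``b`` (inhibition), the
active fraction is a generalized Hill function of the input ratio with
limiting Hill coefficient 2.

Every node has a *dual* ``~x`` obtained by swapping ``x_0`` and ``x_2``;
dualizing a node (flipping its output polarities, and the mode and rate
order of its incoming edges) leaves the compiled CRN unchanged up to that
species swap.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field, replace

import numpy as np

from .network import Complex, CRNError, Reaction, ReactionNetwork, ValidationError, make_network

__all__ = [
    "InfluenceEdge",
    "InfluenceNetwork",
    "TripletBinding",
    "compile_influence",
    "clamped_triplet_network",
    "dualize",
    "triplet_steady_state",
    "triplet_fraction_active",
    "hill_coefficient",
    "influence_from_json",
    "influence_to_json",
]


@dataclass(frozen=True)
class InfluenceEdge:
    """One influence: ``source`` (at the given output polarity) pushes
    ``target`` toward activation or inhibition.

    ``rate_first`` is the rate of the first catalyzed transition (into the
    intermediary for inhibition, out of it for activation); ``rate_second``
    the rate of the second.  Defaults of 1 recover the unit-rate motif.
    """

    source: str
    target: str
    mode: str  # "activate" | "inhibit"
    polarity: str = "high"  # "high" | "low" output of the source node
    rate_first: float = 1.0
    rate_second: float = 1.0

    def __post_init__(self):
        if self.mode not in ("activate", "inhibit"):
            raise ValidationError(f"edge mode must be activate/inhibit, got {self.mode!r}")
        if self.polarity not in ("high", "low"):
            raise ValidationError(f"edge polarity must be high/low, got {self.polarity!r}")
        for k in (self.rate_first, self.rate_second):
            if not float(k) > 0:
                raise ValidationError(f"edge rates must be > 0, got {k!r}")


@dataclass(frozen=True)
class InfluenceNetwork:
    """Ordered node list plus influence edges.

    At most one edge per (source, polarity, target, mode) combination.
    """

    nodes: tuple[str, ...]
    edges: tuple[InfluenceEdge, ...]

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", tuple(self.edges))
        known = set(self.nodes)
        if len(known) != len(self.nodes):
            raise ValidationError("duplicate node names")
        seen = set()
        for e in self.edges:
            if e.source not in known or e.target not in known:
                raise ValidationError(
                    f"edge {e.source}->{e.target} references an unknown node"
                )
            key = (e.source, e.polarity, e.target, e.mode)
            if key in seen:
                raise ValidationError(f"duplicate edge of kind {key}")
            seen.add(key)


@dataclass(frozen=True)
class TripletBinding:
    """Which three chemical species realize an influence node."""

    node: str
    species: tuple[str, str, str]  # (x0, x1, x2)


def _triplet_names(node: str) -> tuple[str, str, str]:
    return (f"{node}_0", f"{node}_1", f"{node}_2")


def compile_influence(inet: InfluenceNetwork):
    """Compile to a reaction network via the triplet motif.

    Returns ``(network, bindings)``.  Species are named ``<node>_0/_1/_2``
    in node order; each edge contributes its two catalytic transitions, with
    duplicate reactions merged by rate sum as usual.
    """
    species: list[str] = []
    bindings: list[TripletBinding] = []
    for n in inet.nodes:
        trip = _triplet_names(n)
        species.extend(trip)
        bindings.append(TripletBinding(n, trip))

    reactions: list[Reaction] = []
    for e in inet.edges:
        s0, _, s2 = _triplet_names(e.source)
        cat = s0 if e.polarity == "high" else s2
        x0, x1, x2 = _triplet_names(e.target)
        if e.mode == "activate":
            steps = [(x1, x0, e.rate_first), (x2, x1, e.rate_second)]
        else:
            steps = [(x0, x1, e.rate_first), (x1, x2, e.rate_second)]
        for sub, prod, k in steps:
            # tuple-pair form sums multiplicities when catalyst == substrate/product
            reactions.append(
                Reaction(Complex([(cat, 1), (sub, 1)]), Complex([(cat, 1), (prod, 1)]), k)
            )
    return make_network(species, reactions), bindings


def clamped_triplet_network(
    rates: tuple[float, float, float, float],
    activator: str = "a",
    inhibitor: str = "b",
    node: str = "x",
) -> ReactionNetwork:
    """The single-node motif with explicit external catalyst species.

    The catalysts appear with equal multiplicity on both sides of every
    reaction, so their concentrations are constant (clamped) under the
    kinetics; useful for checking the closed-form steady state against the
    ODE right-hand side.
    """
    ka1, ka2, kb1, kb2 = rates
    x0, x1, x2 = _triplet_names(node)
    return make_network(
        (activator, inhibitor, x0, x1, x2),
        (
            Reaction(Complex({activator: 1, x1: 1}), Complex({activator: 1, x0: 1}), ka1),
            Reaction(Complex({activator: 1, x2: 1}), Complex({activator: 1, x1: 1}), ka2),
            Reaction(Complex({inhibitor: 1, x0: 1}), Complex({inhibitor: 1, x1: 1}), kb1),
            Reaction(Complex({inhibitor: 1, x1: 1}), Complex({inhibitor: 1, x2: 1}), kb2),
        ),
    )


def dualize(inet: InfluenceNetwork, node: str) -> InfluenceNetwork:
    """Replace ``node`` by its dual ``~node`` (swap its 0/2 species roles).

    Outgoing edges flip polarity; incoming edges flip mode and swap their
    two rates.  The compiled CRN is unchanged up to renaming
    ``node_0 <-> node_2``; dualizing twice is the identity.
    """
    if node not in inet.nodes:
        raise ValidationError(f"unknown node {node!r}")
    new_edges = []
    for e in inet.edges:
        if e.target == node:
            e = replace(
                e,
                mode="inhibit" if e.mode == "activate" else "activate",
                rate_first=e.rate_second,
                rate_second=e.rate_first,
            )
        if e.source == node:
            e = replace(e, polarity="low" if e.polarity == "high" else "high")
        new_edges.append(e)
    return InfluenceNetwork(inet.nodes, tuple(new_edges))


def triplet_steady_state(
    rates: tuple[float, float, float, float],
    a: float,
    b: float,
    total: float,
):
    """Closed-form fixed point of the single-node motif with clamped inputs.

    ``rates = (ka1, ka2, kb1, kb2)``: the activator (level ``a``) catalyzes
    ``x1 -> x0`` at ``ka1`` and ``x2 -> x1`` at ``ka2``; the inhibitor
    (level ``b``) catalyzes ``x0 -> x1`` at ``kb1`` and ``x1 -> x2`` at
    ``kb2``.  Flux balance forces the ratios

        x0 : x1 : x2 = (ka1 a)/(kb1 b) : 1 : (kb2 b)/(ka2 a)

    and the unique fixed point with ``x0 + x1 + x2 = total`` is returned as
    ``(x0, x1, x2)``.  With ``a == 0`` or ``b == 0`` the boundary fixed
    point (all mass in ``x2`` resp. ``x0``) is returned and
    ``boundary=True`` flagged; the return value is then a 4-tuple
    ``(x0, x1, x2, boundary_flag)`` — at interior inputs the flag is False.
    """
    ka1, ka2, kb1, kb2 = (float(k) for k in rates)
    if any(k <= 0 for k in (ka1, ka2, kb1, kb2)):
        raise ValidationError("all four motif rates must be > 0")
    total = float(total)
    if not total > 0:
        raise ValidationError("total mass must be > 0")
    a, b = float(a), float(b)
    if a < 0 or b < 0:
        raise ValidationError("catalyst levels must be >= 0")
    if a == 0 and b == 0:
        raise ValidationError("at least one catalyst level must be positive")
    if a == 0:
        return (0.0, 0.0, total, True)
    if b == 0:
        return (total, 0.0, 0.0, True)
    w0 = (ka1 * a) / (kb1 * b)
    w2 = (kb2 * b) / (ka2 * a)
    z = w0 + 1.0 + w2
    return (total * w0 / z, total / z, total * w2 / z, False)


def triplet_fraction_active(
    rates: tuple[float, float, float, float], ratio: float
) -> float:
    """Steady-state active fraction x0/total as a function of r = a/b."""
    x0, _, _, _ = triplet_steady_state(rates, ratio, 1.0, 1.0)
    return x0


def hill_coefficient(
    rates: tuple[float, float, float, float],
    ratio_grid: Iterable[float],
) -> float:
    """Limiting log-log slope of the active fraction versus input ratio.

    The motif's dose response ``x0/total`` against ``r = a/b`` behaves like
    ``r^h`` as ``r -> 0``; ``h`` is the (generalized) Hill coefficient,
    estimated here by least-squares slope over the two smallest decades of
    the supplied grid.  The grid must span at least four decades.  For unit
    rates the exact response is ``r^2 / (r^2 + r + 1)`` and the slope is 2.
    """
    grid = np.asarray(sorted(float(r) for r in ratio_grid))
    if grid.size < 4 or grid[0] <= 0:
        raise ValidationError("ratio grid must hold >= 4 positive points")
    span = np.log10(grid[-1] / grid[0])
    if span < 4:
        raise ValidationError(
            f"ratio grid spans {span:.2f} decades; need at least 4"
        )
    lo = grid[grid <= grid[0] * 100.0]  # two smallest decades
    if lo.size < 2:
        raise ValidationError("grid too sparse in its two smallest decades")
    logr = np.log(lo)
    logf = np.log([triplet_fraction_active(rates, r) for r in lo])
    slope = np.polyfit(logr, logf, 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# JSON form
# ---------------------------------------------------------------------------

def influence_from_json(obj: Mapping) -> InfluenceNetwork:
    """Read ``{"nodes": [...], "edges": [{"from","polarity","to","mode","rates"}]}``."""
    edges = []
    for e in obj.get("edges", ()):
        rates = e.get("rates", [1.0, 1.0])
        edges.append(
            InfluenceEdge(
                source=e["from"],
                target=e["to"],
                mode=e["mode"],
                polarity=e.get("polarity", "high"),
                rate_first=float(rates[0]),
                rate_second=float(rates[1]),
            )
        )
    return InfluenceNetwork(tuple(obj["nodes"]), tuple(edges))


def influence_to_json(inet: InfluenceNetwork) -> dict:
    return {
        "nodes": list(inet.nodes),
        "edges": [
            {
                "from": e.source,
                "polarity": e.polarity,
                "to": e.target,
                "mode": e.mode,
                "rates": [e.rate_first, e.rate_second],
            }
            for e in inet.edges
        ],
    }
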