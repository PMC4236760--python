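"""Mass-action kinetics, simulation, and dynamic emulation checks.

A state assigns a nonnegative concentration to every species.  The mass
action of a reaction in a state is the product of reactant concentrations
raised to their multiplicities (empty product = 1, and 0^0 = 1 so boundary
states are well defined).  The differential system is

    dv_s/dt = F(v)(s) = sum_r phi(s, r) * [r]_v

i.e. instantaneous-stoichiometry matrix times the mass-action vector.

A morphism m from (S, R) to (S^, R^) is a *kinetic emulation* when
F(v^ o m) = F^(v^) o m for every target state v^: pulling a target state
back through the species map (copying, never summing) makes the source
derivative field a copy of the target's, hence source trajectories started
at pulled-back initial states retrace target trajectories exactly.  The
static reactant-morphism + stoichiomorphism conditions guarantee this; the
functions here verify it dynamically — on the derivative field at sampled
states (cheap, no integration error) and on integrated trajectories (the
user-facing demonstration, thresholds only absorbing solver error).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .morphism import (
    CheckResult,
    NetworkMorphism,
    is_homomorphism,
    is_reactant_morphism,
    is_stoichiomorphism,
)
from .network import CRNError, Reaction, ReactionNetwork

__all__ = [
    "Trajectory",
    "EmulationReport",
    "SimulationError",
    "mass_action",
    "mass_action_vector",
    "derivatives",
    "simulate",
    "pullback_state",
    "check_emulation_derivative",
    "check_emulation_trajectory",
    "steady_state_transfer",
    "sample_states",
]

DEFAULT_RTOL = 1e-9
DEFAULT_ATOL = 1e-9
DEFAULT_EMULATION_TOL = 1e-6


class SimulationError(CRNError):
    """ODE integration failed or produced inadmissible (negative) states."""


def _state_vector(net: ReactionNetwork, v: Mapping[str, float]) -> np.ndarray:
    out = np.zeros(net.n_species)
    for i, s in enumerate(net.species):
        x = float(v.get(s, 0.0))
        if x < 0:
            raise CRNError(f"negative concentration {x} for species {s!r}")
        out[i] = x
    return out


def mass_action(r: Reaction, v: Mapping[str, float]) -> float:
    """[r]_v = prod_s v_s^rho_s, with 0^0 = 1 (empty product is 1)."""
    out = 1.0
    for s, n in r.reactants.items():
        x = float(v.get(s, 0.0))
        if x < 0:
            raise CRNError(f"negative concentration {x} for species {s!r}")
        out *= x**n
    return out


def mass_action_vector(net: ReactionNetwork, x: np.ndarray) -> np.ndarray:
    """Mass action of every reaction at a concentration vector (net order)."""
    rho = net.stoich_matrices().reactant
    # exact product form; species with zero multiplicity contribute nothing,
    # so 0^0 never arises
    out = np.ones(net.n_reactions)
    for i, j in zip(*np.nonzero(rho)):
        out[j] *= x[i] ** rho[i, j]
    return out


def derivatives(net: ReactionNetwork, v: Mapping[str, float]) -> dict[str, float]:
    """F(v): species -> instantaneous concentration derivative."""
    sm = net.stoich_matrices()
    x = _state_vector(net, v)
    dv = sm.instantaneous @ mass_action_vector(net, x)
    return dict(zip(net.species, dv.tolist()))


@dataclass(frozen=True)
class Trajectory:
    """Numerical solution on a uniform time grid.

    ``values[i, j]`` is the concentration of ``species[j]`` at ``times[i]``.
    """

    species: tuple[str, ...]
    times: np.ndarray
    values: np.ndarray
    rtol: float
    atol: float
    success: bool = True
    message: str = ""

    def state_at(self, i: int) -> dict[str, float]:
        return dict(zip(self.species, self.values[i].tolist()))

    def to_csv(self) -> str:
        lines = ["time," + ",".join(self.species)]
        for t, row in zip(self.times, self.values):
            lines.append(f"{t!r}," + ",".join(repr(float(x)) for x in row))
        return "\n".join(lines) + "\n"


def simulate(
    net: ReactionNetwork,
    v0: Mapping[str, float],
    t_end: float,
    grid: int = 201,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the mass-action ODE system on a uniform grid.

    Uses a stiff-capable solver at tight default tolerances.  Nonnegativity
    is asserted post hoc (values below ``-10*atol`` fail), never enforced by
    clipping.
    """
    if not t_end > 0:
        raise CRNError(f"t_end must be > 0, got {t_end}")
    sm = net.stoich_matrices()
    phi = sm.instantaneous
    rho = sm.reactant
    nz = [(np.nonzero(rho[:, j])[0], rho[rho[:, j] > 0, j]) for j in range(net.n_reactions)]

    def rhs(_t, x):
        ma = np.empty(net.n_reactions)
        for j, (rows, exps) in enumerate(nz):
            ma[j] = np.prod(x[rows] ** exps) if rows.size else 1.0
        return phi @ ma

    x0 = _state_vector(net, v0)
    t_eval = np.linspace(0.0, float(t_end), int(grid))
    sol = solve_ivp(rhs, (0.0, float(t_end)), x0, method=method,
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise SimulationError(f"solver failed: {sol.message}")
    values = sol.y.T
    if values.min(initial=0.0) < -10 * atol:
        raise SimulationError(
            f"trajectory dipped to {values.min():g}, below the -10*atol "
            f"admissibility bound ({-10 * atol:g})"
        )
    return Trajectory(net.species, t_eval, values, rtol, atol, True, sol.message)


def pullback_state(m_S: Mapping[str, str], v_hat: Mapping[str, float]) -> dict[str, float]:
    """Pull a target state back along the species map: v(s) = v^(m(s)).

    Concentrations are copied through the map, never summed.
    """
    return {s: float(v_hat[t]) for s, t in m_S.items()}


def sample_states(net: ReactionNetwork, n: int, seed: int, scale: float = 2.0,
                  boundary_fraction: float = 0.25) -> list[dict[str, float]]:
    """Seeded random states: uniform on [0, scale], some with zeroed subsets."""
    rng = np.random.default_rng(seed)
    states = []
    for i in range(n):
        x = rng.uniform(0.0, scale, net.n_species)
        if i >= int(n * (1 - boundary_fraction)) and net.n_species:
            mask = rng.random(net.n_species) < 0.5
            x[mask] = 0.0
        states.append(dict(zip(net.species, x.tolist())))
    return states


def check_emulation_derivative(
    m: NetworkMorphism, states: Iterable[Mapping[str, float]]
) -> float:
    """Max over states and source species of |F(v^ o m)(s) - F^(v^)(m(s))|."""
    worst = 0.0
    for v_hat in states:
        fv = derivatives(m.source, pullback_state(m.species_map, v_hat))
        fv_hat = derivatives(m.target, v_hat)
        for s in m.source.species:
            worst = max(worst, abs(fv[s] - fv_hat[m.species_map[s]]))
    return worst


@dataclass(frozen=True)
class EmulationReport:
    """Static certificates plus dynamic residuals for one morphism.

    ``verdict`` is True only when the two static conditions sufficient for
    emulation (reactant morphism and stoichiomorphism) hold and every
    computed dynamic residual is below its threshold.
    """

    static: dict[str, CheckResult]
    derivative_residual: float | None
    trajectory_deviation: float | None
    tol: float
    verdict: bool
    source_trajectory: Trajectory | None = None
    target_trajectory: Trajectory | None = None

    def to_json(self) -> dict:
        return {
            "static": {k: v.to_json() for k, v in self.static.items()},
            "derivative_residual": self.derivative_residual,
            "trajectory_deviation": self.trajectory_deviation,
            "tol": self.tol,
            "verdict": self.verdict,
        }


def check_emulation_trajectory(
    m: NetworkMorphism,
    v_hat0: Mapping[str, float],
    t_end: float = 50.0,
    grid: int = 201,
    tol: float = DEFAULT_EMULATION_TOL,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    derivative_states: Sequence[Mapping[str, float]] | None = None,
) -> EmulationReport:
    """Simulate source and target on one grid and compare paired traces.

    The source starts from the pulled-back initial state; the deviation is
    the max over grid times and source species of
    |f_s(t) - f^_{m(s)}(t)|, on the common solver horizon.
    """
    static = {
        "reactant_morphism": is_reactant_morphism(m),
        "homomorphism": is_homomorphism(m),
        "stoichiomorphism": is_stoichiomorphism(m),
    }
    src_traj = simulate(m.source, pullback_state(m.species_map, v_hat0),
                        t_end, grid, rtol, atol)
    tgt_traj = simulate(m.target, v_hat0, t_end, grid, rtol, atol)
    tgt_idx = m.target.species_index()
    cols = [tgt_idx[m.species_map[s]] for s in m.source.species]
    deviation = float(np.abs(src_traj.values - tgt_traj.values[:, cols]).max())
    deriv = (check_emulation_derivative(m, derivative_states)
             if derivative_states is not None else None)
    verdict = (
        static["reactant_morphism"].holds
        and static["stoichiomorphism"].holds
        and deviation < tol
        and (deriv is None or deriv < tol)
    )
    return EmulationReport(static, deriv, deviation, tol, verdict,
                           src_traj, tgt_traj)


def steady_state_transfer(
    m: NetworkMorphism,
    v_hat_ss: Mapping[str, float],
    tol: float = 1e-12,
) -> CheckResult:
    """Verify that a target steady state pulls back to a source steady state.

    Requires F^(v^ss) ~ 0 (residual below ``10*tol``) as a precondition,
    then checks F(v^ss o m) ~ 0 on every source species.  When the species
    map is a bijection the converse direction is checked as well (a source
    steady state of pulled-back form pushes forward).
    """
    tgt_resid = max(abs(x) for x in derivatives(m.target, v_hat_ss).values()) \
        if m.target.species else 0.0
    if tgt_resid > 10 * tol:
        raise CRNError(
            f"target state is not steady: residual {tgt_resid:g} > {10 * tol:g}"
        )
    v = pullback_state(m.species_map, v_hat_ss)
    fv = derivatives(m.source, v)
    witnesses = []
    worst = 0.0
    for s in m.source.species:
        worst = max(worst, abs(fv[s]))
        if abs(fv[s]) > tol and len(witnesses) < 10:
            witnesses.append(((s, None), fv[s], 0.0))
    bijective = (len(set(m.species_map.values())) == m.source.n_species
                 == m.target.n_species)
    if bijective and not witnesses:
        inv = {t: s for s, t in m.species_map.items()}
        fwd = derivatives(m.target, {t: v[inv[t]] for t in m.target.species})
        for t in m.target.species:
            worst = max(worst, abs(fwd[t]))
            if abs(fwd[t]) > tol and len(witnesses) < 10:
                witnesses.append(((t, "converse"), fwd[t], 0.0))
    return CheckResult(not witnesses, tuple(witnesses), worst, "steady_state_transfer")
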