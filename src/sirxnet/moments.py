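"""Pair-approximation (moment-closure) ODEs for adaptive SIR and SIRX.

The exact moment hierarchy for the network process couples node counts to
link counts and link counts to centred triples (SSI, ISI), and so on
without end.  The pair approximation truncates it at second order with the
standard closure

    [ABC] ≈ m(A,B) m(B,C) [AB][BC] / [B],    m(A,B) = 2 if A = B else 1,

yielding closed systems in the per-node densities ρ_S, ρ_I, ρ_R (and ρ_X
by conservation) and the per-node link densities ρ_SI, ρ_SS.

Adaptive SIR (self-distancing only; ρ_S = 1 − ρ_I − ρ_R):

    ρ̇_I  = β ρ_SI − γ ρ_I
    ρ̇_R  = γ ρ_I
    ρ̇_SI = −(β+γ+w) ρ_SI + β ρ_SI (2ρ_SS − ρ_SI)/(1−ρ_I−ρ_R)
    ρ̇_SS = −2β ρ_SI ρ_SS/(1−ρ_I−ρ_R) + w [(1−ρ_I−ρ_R)/(1−ρ_I)] ρ_SI

Adaptive SIRX (self-distancing + quarantine):

    ρ̇_S  = −β ρ_SI
    ρ̇_I  = β ρ_SI − (κ+γ) ρ_I
    ρ̇_R  = γ ρ_I + δ (1 − ρ_S − ρ_I − ρ_R)
    ρ̇_SI = −(β+γ+w+κ) ρ_SI + β ρ_SI (2ρ_SS − ρ_SI)/ρ_S
    ρ̇_SS = −2β ρ_SI ρ_SS/ρ_S + w [ρ_S/(ρ_S+ρ_R)] ρ_SI

The two systems are kept exactly as stated (including the differing
bracketed rewiring factors, which coincide when ρ_X ≡ 0) and are not
harmonised.  Right-hand sides accept complex inputs so that derivatives
can be taken by complex-step differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from .gillespie import ModelParams

__all__ = [
    "MomentState",
    "MomentTrajectory",
    "IntegrationError",
    "closure_triple",
    "sir_rhs",
    "sirx_rhs",
    "integrate",
    "default_init",
    "disease_free",
    "r_infinity",
    "peak_prevalence",
    "rescale_time",
]

# Below this susceptible density the closure terms ρ_SI(...)/ρ_S are set to
# zero: ρ_SI vanishes at least as fast as ρ_S, so the singularity is
# removable (the epidemic has consumed all susceptibles).
_S_GUARD = 1e-14


class IntegrationError(RuntimeError):
    """Integrator failure; carries the partial trajectory when available."""

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial


@dataclass(frozen=True)
class MomentState:
    """Pair-approximation state: node densities + per-node link densities.

    ``rho_x`` is derived from node conservation, 1 − ρ_S − ρ_I − ρ_R.
    Link densities are per node (link count / N), so the disease-free
    all-SS state has ρ_SS = μ/2.
    """

    rho_s: float
    rho_i: float
    rho_r: float
    rho_si: float
    rho_ss: float

    def __post_init__(self):
        tol = 1e-12
        for name in ("rho_s", "rho_i", "rho_r", "rho_si", "rho_ss"):
            if getattr(self, name) < -tol:
                raise ValueError(f"{name} must be nonnegative")
        if self.rho_s + self.rho_i + self.rho_r > 1 + 1e-9:
            raise ValueError("node densities exceed 1")

    @property
    def rho_x(self) -> float:
        return 1.0 - self.rho_s - self.rho_i - self.rho_r

    def as_array(self) -> np.ndarray:
        return np.array([self.rho_s, self.rho_i, self.rho_r,
                         self.rho_si, self.rho_ss])


def closure_triple(pair_ab: float, pair_bc: float, node_b: float,
                   a_eq_b: bool = False, b_eq_c: bool = False) -> float:
    """Pair closure for a centred triple: m(A,B) m(B,C) [AB][BC]/[B].

    The multiplicity m is 2 when the two states coincide and 1 otherwise;
    with the centred ordered-ends triple convention this is the consistent
    estimator (e.g. [SSI] ≈ 2[SS][SI]/[S], [ISI] ≈ [SI]²/[S]).
    """
    if node_b <= 0:
        raise ValueError("closure undefined for node_b <= 0")
    m_ab = 2.0 if a_eq_b else 1.0
    m_bc = 2.0 if b_eq_c else 1.0
    return m_ab * m_bc * pair_ab * pair_bc / node_b


def _sirx_rhs(y, beta, gamma, w, kappa, delta):
    """SIRX vector field on y = (ρ_S, ρ_I, ρ_R, ρ_SI, ρ_SS); complex-safe."""
    s, i, r, si, ss = y
    if np.real(s) > _S_GUARD:
        closure = si * (2.0 * ss - si) / s
        ss_loss = 2.0 * si * ss / s
    else:
        closure = ss_loss = 0.0 * s
    denom = s + r
    gain = w * (s / denom) * si if np.real(denom) > _S_GUARD else 0.0 * s
    return np.array([
        -beta * si,
        beta * si - (kappa + gamma) * i,
        gamma * i + delta * (1.0 - s - i - r),
        -(beta + gamma + w + kappa) * si + beta * closure,
        -beta * ss_loss + gain,
    ])


def _sir_rhs(y, beta, gamma, w):
    """Adaptive-SIR vector field on y = (ρ_I, ρ_R, ρ_SI, ρ_SS); complex-safe."""
    i, r, si, ss = y
    denom = 1.0 - i - r
    if np.real(denom) > _S_GUARD:
        closure = si * (2.0 * ss - si) / denom
        ss_loss = 2.0 * si * ss / denom
    else:
        closure = ss_loss = 0.0 * si
    denom_i = 1.0 - i
    gain = w * (denom / denom_i) * si if np.real(denom_i) > _S_GUARD else 0.0 * si
    return np.array([
        beta * si - gamma * i,
        gamma * i,
        -(beta + gamma + w) * si + beta * closure,
        -beta * ss_loss + gain,
    ])


def sirx_rhs(state: MomentState, params: ModelParams) -> np.ndarray:
    """Time derivatives (ρ̇_S, ρ̇_I, ρ̇_R, ρ̇_SI, ρ̇_SS) of the SIRX system."""
    if state.rho_s <= 0 and state.rho_si > _S_GUARD:
        raise ValueError("rho_s must be positive while SI links remain")
    return _sirx_rhs(state.as_array(), params.beta, params.gamma,
                     params.w, params.kappa, params.delta)


def sir_rhs(state: MomentState, params: ModelParams) -> np.ndarray:
    """Time derivatives (ρ̇_I, ρ̇_R, ρ̇_SI, ρ̇_SS) of the adaptive SIR system.

    The state must have ρ_X = 0 (ρ_S = 1 − ρ_I − ρ_R); κ and δ in
    ``params`` are ignored — quarantine is absent from this system.
    """
    if abs(state.rho_x) > 1e-9:
        raise ValueError("adaptive SIR requires rho_x = 0")
    y = np.array([state.rho_i, state.rho_r, state.rho_si, state.rho_ss])
    return _sir_rhs(y, params.beta, params.gamma, params.w)


@dataclass
class MomentTrajectory:
    """Dense-sampled solution of one of the closed moment systems.

    ``ys`` has columns (ρ_S, ρ_I, ρ_R, ρ_SI, ρ_SS, ρ_X); for the SIR
    system ρ_X is identically zero and ρ_S = 1 − ρ_I − ρ_R.  ``dense``
    (when present) maps times to the full column vector for refinement.
    """

    times: np.ndarray
    ys: np.ndarray
    params: ModelParams
    init: MomentState
    system: str
    terminated: bool
    dense: object = field(default=None, repr=False)

    @property
    def rho_s(self):
        return self.ys[:, 0]

    @property
    def rho_i(self):
        return self.ys[:, 1]

    @property
    def rho_r(self):
        return self.ys[:, 2]

    @property
    def rho_si(self):
        return self.ys[:, 3]

    @property
    def rho_ss(self):
        return self.ys[:, 4]

    @property
    def rho_x(self):
        return self.ys[:, 5]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "rho_s": self.rho_s, "rho_i": self.rho_i, "rho_r": self.rho_r,
            "rho_x": self.rho_x, "rho_si": self.rho_si, "rho_ss": self.rho_ss,
        })


def default_init(mu: float, rho_i0: float, rho_si0: float | None = None,
                 rho_ss0: float | None = None) -> MomentState:
    """Standard initial condition for a freshly seeded ER population.

    ρ_I(0) = rho_i0, ρ_R(0) = 0, ρ_SI(0) = μ·ρ_I(0) (each infected seed
    sits among μ susceptible contacts on average) and
    ρ_SS(0) = (μ/2)(1−ρ_I(0))², the expected SS-link density when seeds
    are placed uniformly at random.  Both link densities can be
    overridden.
    """
    if not 0 < rho_i0 < 1:
        raise ValueError("rho_i0 must lie in (0, 1)")
    if rho_si0 is None:
        rho_si0 = mu * rho_i0
    if rho_ss0 is None:
        rho_ss0 = 0.5 * mu * (1.0 - rho_i0) ** 2
    return MomentState(rho_s=1.0 - rho_i0, rho_i=rho_i0, rho_r=0.0,
                       rho_si=rho_si0, rho_ss=rho_ss0)


def disease_free(mu: float) -> MomentState:
    """The disease-free equilibrium: all nodes S, all links S–S."""
    return MomentState(rho_s=1.0, rho_i=0.0, rho_r=0.0,
                       rho_si=0.0, rho_ss=0.5 * mu)


def _system_name(rhs) -> str:
    if rhs in ("sir", "sirx"):
        return rhs
    if rhs is sir_rhs:
        return "sir"
    if rhs is sirx_rhs:
        return "sirx"
    raise ValueError("rhs must be sir_rhs, sirx_rhs, 'sir' or 'sirx'")


def integrate(rhs, init: MomentState, params: ModelParams, t_max: float = 1e5,
              stop_epsilon: float = 1e-10, rtol: float = 1e-8,
              atol: float = 1e-12, n_samples: int = 1001) -> MomentTrajectory:
    """Integrate a closed moment system with a stiff-capable solver.

    Runs until ``t_max`` or until both ρ_I and ρ_SI drop below
    ``stop_epsilon`` (epidemic extinct to working precision).  For the
    SIRX system ρ_X is integrated explicitly as a redundant conservation
    check.  Returns a trajectory sampled on ``n_samples`` uniform points
    with the dense interpolant attached.
    """
    system = _system_name(rhs)
    p = params
    if system == "sirx":
        y0 = np.array([init.rho_s, init.rho_i, init.rho_r,
                       init.rho_si, init.rho_ss, init.rho_x])

        def f(t, y):
            dy5 = _sirx_rhs(y[:5], p.beta, p.gamma, p.w, p.kappa, p.delta)
            dx = p.kappa * y[1] - p.delta * y[5]
            return np.append(dy5, dx)
    else:
        y0 = np.array([init.rho_i, init.rho_r, init.rho_si, init.rho_ss])

        def f(t, y):
            return _sir_rhs(y, p.beta, p.gamma, p.w)

    i_idx, si_idx = (1, 3) if system == "sirx" else (0, 2)

    def extinct(t, y):
        return max(y[i_idx], y[si_idx]) - stop_epsilon

    extinct.terminal = True
    extinct.direction = -1

    sol = solve_ivp(f, (0.0, t_max), y0, method="LSODA", rtol=rtol, atol=atol,
                    dense_output=True, events=extinct)
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}")
    t_end = sol.t[-1]
    times = np.linspace(0.0, t_end, n_samples)
    raw = sol.sol(times).T
    if np.min(raw) < -1e-6:
        raise IntegrationError("negative-density excursion beyond tolerance",
                               partial=raw)
    if system == "sirx":
        # conservation: s+i+r+x == 1 (x integrated redundantly)
        drift = np.abs(raw[:, 0] + raw[:, 1] + raw[:, 2] + raw[:, 5] - 1.0)
        if drift.max() > 1e-6:
            raise IntegrationError("node-conservation drift beyond tolerance",
                                   partial=raw)
        ys = raw[:, [0, 1, 2, 3, 4, 5]]
        dense = sol.sol
    else:
        i_col, r_col, si_col, ss_col = raw.T
        s_col = 1.0 - i_col - r_col
        ys = np.column_stack([s_col, i_col, r_col, si_col, ss_col,
                              np.zeros_like(i_col)])
        dense = sol.sol
    terminated = len(sol.t_events[0]) > 0
    return MomentTrajectory(times=times, ys=ys, params=params, init=init,
                            system=system, terminated=terminated, dense=dense)


def r_infinity(params: ModelParams, init: MomentState, t_max: float = 1e6,
               stop_epsilon: float = 1e-10) -> float:
    """Final epidemic size r∞ = 1 − ρ_S(∞) from the SIRX pair approximation.

    Integrates until ρ_I and ρ_SI fall below ``stop_epsilon``; because the
    I and X compartments drain completely, 1 − ρ_S at extinction equals
    the final recovered density, and it is independent of the release rate
    δ by construction.  Raises :class:`IntegrationError` (with the partial
    trajectory attached) if the epidemic has not burnt out by ``t_max``.
    """
    traj = integrate(sirx_rhs, init, params, t_max=t_max,
                     stop_epsilon=stop_epsilon)
    if not traj.terminated and (traj.rho_i[-1] > stop_epsilon
                                or traj.rho_si[-1] > stop_epsilon):
        raise IntegrationError(
            f"epidemic not extinct by t_max={t_max}", partial=traj)
    return float(1.0 - traj.rho_s[-1])


def peak_prevalence(traj: MomentTrajectory) -> float:
    """Maximum infected density over the trajectory.

    The grid maximum is refined by a bounded scalar optimisation on the
    dense interpolant around the discrete argmax.
    """
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    k = int(np.argmax(traj.rho_i))
    best = float(traj.rho_i[k])
    if traj.dense is not None and 0 < k < len(traj.times) - 1:
        i_idx = 1 if traj.system == "sirx" else 0
        res = minimize_scalar(
            lambda t: -float(traj.dense(t)[i_idx]),
            bounds=(traj.times[k - 1], traj.times[k + 1]), method="bounded",
            options={"xatol": 1e-10})
        best = max(best, float(-res.fun))
    return best


def rescale_time(params: ModelParams, by: str = "gamma") -> ModelParams:
    """Express all rates in units of one of them (documented convenience).

    All parameters enter the dynamics linearly, so dividing every rate by
    e.g. γ is equivalent to measuring time in units of the mean infectious
    period; trajectories are identical up to the time axis.
    """
    scale = getattr(params, by)
    if not scale > 0:
        raise ValueError(f"cannot rescale by {by} = {scale}")
    return ModelParams(beta=params.beta / scale, gamma=params.gamma / scale,
                       w=params.w / scale, kappa=params.kappa / scale,
                       delta=params.delta / scale)
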