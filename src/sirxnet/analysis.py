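"""Epidemic thresholds, the transcendental final-size bound and positivity.

Linearising the closed SIRX system at the disease-free state
(ρ_S = 1, ρ_I = ρ_R = ρ_SI = 0, ρ_SS = μ/2) gives the epidemic threshold

    β_c = (γ + w + κ) / (μ − 1),

so rewiring and quarantine raise the threshold through the same linear
combination w + κ (with κ = 0 this is the adaptive-SIR threshold).  The
module provides the closed form, an independent numerical route through
the Jacobian eigenvalue crossing, and the operational proxy used with
simulations: the infection rate at which the final size r∞ crosses an
outbreak cutoff (0.05 by default).

For the final size, integrating the ρ_R equation and applying the pair
closure directly at the level of the observable yields — under the
positivity condition ρ̇_SI ≥ 2ρ̇_SS along the trajectory — the
transcendental upper bound: r∞ is at most the smallest root ρ* of

    ρ = ρ_I(0) + β/(β+γ+w+κ) · [ρ_SI(0)
            + (2ρ_SS(0) − ρ_SI(0)) · ln((1−ρ_I(0))/(1−ρ))].

Both intervention rates enter only through the inverse prefactor
β/(β+γ+w+κ), so the bound is non-increasing in w and in κ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .gillespie import ModelParams, ensemble_run
from .moments import (
    IntegrationError,
    MomentState,
    MomentTrajectory,
    _sirx_rhs,
    default_init,
    integrate,
    r_infinity,
    sirx_rhs,
)
from .network import NetworkConfig

__all__ = [
    "ThresholdResult",
    "BoundResult",
    "PositivityResult",
    "beta_critical",
    "jacobian_threshold",
    "beta_c_proxy",
    "critical_combination",
    "final_size_bound",
    "positivity_check",
    "positivity_region",
    "scenario_init",
    "SCENARIO_FACTORS",
]

# Initial-SI-link scenarios: ρ_SI(0) = factor · μ · ρ_I(0).
SCENARIO_FACTORS = {"meanfield": 1.0, "dense": 6.0, "sparse": 0.2}


@dataclass(frozen=True)
class ThresholdResult:
    """A located epidemic threshold and how it was obtained."""

    beta_c: float
    method: str  # formula_eq_closed / jacobian_numeric / r_inf_proxy
    proxy_threshold: float | None = None

    def __post_init__(self):
        if not self.beta_c > 0:
            raise ValueError("beta_c must be positive")


@dataclass(frozen=True)
class BoundResult:
    """Final-size upper bound from the transcendental inequality.

    ``k0`` is the constant ρ_I(0) + β/(β+γ+w+κ)·ρ_SI(0); ``bound`` is the
    smallest root of the implicit equation (1.0 when no root exists — the
    bound is then vacuous but still valid).  ``positivity_ok`` records
    whether the condition ρ̇_SI ≥ 2ρ̇_SS held along the pair-approximation
    trajectory from the same initial state, which is what makes the bound
    rigorous for that trajectory.
    """

    bound: float
    k0: float
    positivity_ok: bool | None
    root_bracket: tuple[float, float] | None


@dataclass(frozen=True)
class PositivityResult:
    ok: bool
    first_violation_time: float | None
    min_margin: float


def beta_critical(gamma: float, w: float, kappa: float, mu: float) -> float:
    """Closed-form threshold (γ+w+κ)/(μ−1); κ = 0 gives the SIR case."""
    if mu <= 1:
        raise ValueError("mu must exceed 1")
    return (gamma + w + kappa) / (mu - 1.0)


def critical_combination(beta: float, gamma: float, mu: float) -> float:
    """The critical combined intervention rate: w + κ = β(μ−1) − γ.

    Cells with w + κ above this value are subcritical at infection rate β.
    """
    return beta * (mu - 1.0) - gamma


def _complex_step_jacobian(f, y0: np.ndarray, h: float = 1e-20) -> np.ndarray:
    n = len(y0)
    jac = np.empty((n, n))
    for j in range(n):
        yc = y0.astype(complex)
        yc[j] += 1j * h
        jac[:, j] = np.imag(f(yc)) / h
    return jac


def _epidemic_growth_rate(beta, gamma, w, kappa, delta, mu) -> float:
    """Leading eigenvalue of the disease-free linearisation on the
    epidemic modes (the invariant subspace spanned by ρ_I and ρ_SI).

    At the disease-free state the derivatives of ρ̇_I and ρ̇_SI with
    respect to ρ_S, ρ_R and ρ_SS all vanish (every such term carries a
    factor ρ_SI = 0), so the (ρ_I, ρ_SI) block of the Jacobian is exactly
    invariant and carries the epidemic growth rate.  The remaining
    directions are neutral or purely decaying (shifting mass between
    ρ_S/ρ_R/ρ_SS is again an equilibrium, giving structural zero
    eigenvalues that never change sign), so restricting is what makes the
    crossing well defined.  The block decoupling is asserted numerically.
    """
    y_star = np.array([1.0, 0.0, 0.0, 0.0, 0.5 * mu])
    jac = _complex_step_jacobian(
        lambda y: _sirx_rhs(y, beta, gamma, w, kappa, delta), y_star)
    epi = [1, 3]
    coupling = jac[np.ix_(epi, [0, 2, 4])]
    if np.max(np.abs(coupling)) > 1e-9:
        raise RuntimeError("epidemic block unexpectedly coupled at the "
                           "disease-free state")
    block = jac[np.ix_(epi, epi)]
    return float(np.max(np.linalg.eigvals(block).real))


def jacobian_threshold(gamma: float, w: float, kappa: float, mu: float,
                       delta: float = 0.01, tol: float = 1e-14,
                       bracket: tuple[float, float] = (1e-9, 10.0)) -> float:
    """Numerically locate β where the epidemic growth rate crosses zero.

    Uses a complex-step Jacobian of the closed SIRX vector field at the
    disease-free state and root-finds the leading epidemic eigenvalue in
    β.  Independent of the closed-form expression; agrees with it to the
    bisection tolerance.
    """
    if mu <= 1:
        raise ValueError("mu must exceed 1")

    def growth(beta):
        return _epidemic_growth_rate(beta, gamma, w, kappa, delta, mu)

    lo, hi = bracket
    if growth(lo) >= 0 or growth(hi) <= 0:
        raise ValueError(f"no sign change of the growth rate in {bracket}")
    return float(brentq(growth, lo, hi, xtol=tol))


def beta_c_proxy(gamma: float, w: float, kappa: float, mu: float,
                 delta: float = 0.01, rho_i0: float = 0.01,
                 init: MomentState | None = None,
                 outbreak_cutoff: float = 0.05,
                 bracket: tuple[float, float] = (1e-4, 0.05),
                 mode: str = "ode", n_nodes: int = 500, n_runs: int = 20,
                 seed: int = 0, xtol: float = 1e-7,
                 record_t_max: float = 2000.0) -> ThresholdResult:
    """Infection rate at which the final size r∞ crosses ``outbreak_cutoff``.

    This is the operational threshold proxy used when comparing against
    simulations, where the linear-stability boundary is not directly
    observable.  ``mode="ode"`` bisects on the pair-approximation r∞;
    ``mode="stochastic"`` bisects on the ensemble-mean final size over
    ``n_runs`` network realisations of size ``n_nodes`` per evaluation
    (seeded deterministically per β, so the scan is reproducible).
    """
    if init is None:
        init = default_init(mu, rho_i0)

    if mode == "ode":
        def excess(beta):
            params = ModelParams(beta=beta, gamma=gamma, w=w, kappa=kappa,
                                 delta=delta)
            return r_infinity(params, init) - outbreak_cutoff
    elif mode == "stochastic":
        cfg = NetworkConfig(n_nodes, mu, 0)
        grid = np.linspace(0.0, record_t_max, 11)

        def excess(beta):
            params = ModelParams(beta=beta, gamma=gamma, w=w, kappa=kappa,
                                 delta=delta)
            beta_tag = int(round(beta * 1e12)) & 0x7FFFFFFF
            ens = ensemble_run(cfg, params, init.rho_i, n_runs,
                               seed=(seed ^ beta_tag) & 0x7FFFFFFF,
                               record_grid=grid)
            return float(ens.final_sizes.mean()) - outbreak_cutoff
    else:
        raise ValueError(f"unknown mode {mode!r}")

    lo, hi = bracket
    f_lo, f_hi = excess(lo), excess(hi)
    if not (f_lo < 0 < f_hi):
        raise ValueError(
            f"r_inf does not cross {outbreak_cutoff} on bracket {bracket} "
            f"(values {f_lo + outbreak_cutoff:.4g}, {f_hi + outbreak_cutoff:.4g}); "
            "widen the bracket")
    beta_c = float(brentq(excess, lo, hi, xtol=xtol))
    return ThresholdResult(beta_c=beta_c, method="r_inf_proxy",
                           proxy_threshold=outbreak_cutoff)


def final_size_bound(params: ModelParams, rho_i0: float, rho_si0: float,
                     rho_ss0: float, check_positivity: bool = True,
                     n_scan: int = 10_000) -> BoundResult:
    """Smallest root of the transcendental final-size inequality.

    Scans the implicit function on a dense grid over [ρ_I(0), 1), then
    bisects the first sign change; when the function never returns to
    zero the bound is vacuous and 1.0 is reported.  Requires
    2ρ_SS(0) − ρ_SI(0) > 0 (positive coefficient of the logarithm) and
    ρ_I(0) ∈ (0, 1).  With ``check_positivity`` the pair-approximation
    trajectory from the same initial state is integrated and the
    condition ρ̇_SI ≥ 2ρ̇_SS verified along it.
    """
    if not 0 < rho_i0 < 1:
        raise ValueError("rho_i0 must lie in (0, 1)")
    coef = 2.0 * rho_ss0 - rho_si0
    if coef <= 0:
        raise ValueError(
            "bound requires 2*rho_ss0 - rho_si0 > 0 "
            f"(got {coef:.4g})")
    c = params.beta / (params.beta + params.gamma + params.w + params.kappa)
    k0 = rho_i0 + c * rho_si0

    def g(rho):
        return (rho_i0 + c * (rho_si0 + coef * np.log((1.0 - rho_i0) / (1.0 - rho)))
                - rho)

    grid = np.linspace(rho_i0, 1.0 - 1e-12, n_scan)
    vals = g(grid)
    below = np.where(vals <= 0)[0]
    if len(below) == 0:
        bound, root_bracket = 1.0, None
    elif below[0] == 0:
        # g(rho_i0) = c*rho_si0 <= 0 only when rho_si0 = 0: the smallest
        # root is the initial density itself.
        bound, root_bracket = float(rho_i0), (float(rho_i0), float(rho_i0))
    else:
        lo, hi = grid[below[0] - 1], grid[below[0]]
        bound = float(brentq(g, lo, hi, xtol=1e-14))
        root_bracket = (float(lo), float(hi))

    positivity_ok = None
    if check_positivity:
        init = MomentState(rho_s=1.0 - rho_i0, rho_i=rho_i0, rho_r=0.0,
                           rho_si=rho_si0, rho_ss=rho_ss0)
        traj = integrate(sirx_rhs, init, params)
        positivity_ok = positivity_check(traj).ok
    return BoundResult(bound=bound, k0=k0, positivity_ok=positivity_ok,
                       root_bracket=root_bracket)


def positivity_check(traj: MomentTrajectory, slack: float | None = None,
                     n_points: int = 2001) -> PositivityResult:
    """Check ρ̇_SI − 2ρ̇_SS ≥ 0 along a SIRX pair-approximation trajectory.

    Evaluates the derivative combination from the vector field at
    ``n_points`` dense-output times; passes iff the minimum stays above
    −slack (default: 1e-12 times the derivative scale, to absorb
    floating-point noise at equilibria).
    """
    if traj.system != "sirx":
        raise ValueError("positivity condition is defined for the SIRX system")
    p = traj.params
    times = np.linspace(traj.times[0], traj.times[-1], n_points)
    if traj.dense is not None:
        states = traj.dense(times).T[:, :5]
    else:
        times = traj.times
        states = traj.ys[:, :5]
    margins = np.empty(len(times))
    for k, y in enumerate(states):
        dy = _sirx_rhs(y, p.beta, p.gamma, p.w, p.kappa, p.delta)
        margins[k] = dy[3] - 2.0 * dy[4]
    if slack is None:
        slack = 1e-12 * max(1.0, float(np.max(np.abs(margins))))
    bad = np.where(margins < -slack)[0]
    ok = len(bad) == 0
    first = None if ok else float(times[bad[0]])
    return PositivityResult(ok=ok, first_violation_time=first,
                            min_margin=float(margins.min()))


def scenario_init(mu: float, rho_i0: float, scenario: str) -> MomentState:
    """Initial state for a named initial-SI-link scenario.

    ρ_SI(0) = ξ·μ·ρ_I(0) with ξ = 1 ("meanfield", the standard seeding),
    6 ("dense": disproportionately many initial S–I contacts) or 1/5
    ("sparse": very few).  ρ_SS(0) keeps its random-seeding expectation.
    """
    try:
        factor = SCENARIO_FACTORS[scenario]
    except KeyError:
        raise ValueError(f"unknown scenario {scenario!r}; "
                         f"choose from {sorted(SCENARIO_FACTORS)}") from None
    return default_init(mu, rho_i0, rho_si0=factor * mu * rho_i0)


def positivity_region(beta_list, scenarios, w_grid, kappa_grid, gamma: float,
                      mu: float, delta: float = 0.01,
                      rho_i0: float = 0.01) -> pd.DataFrame:
    """Map where the positivity condition holds in the (w, κ) plane.

    Runs :func:`positivity_check` on the pair-approximation trajectory for
    every (β, scenario, w, κ) cell and returns one record per cell with
    the outcome and first violation time (NaN when none).
    """
    records = []
    for beta in beta_list:
        for scenario in scenarios:
            init = scenario_init(mu, rho_i0, scenario)
            for w in w_grid:
                for kappa in kappa_grid:
                    params = ModelParams(beta=beta, gamma=gamma, w=w,
                                         kappa=kappa, delta=delta)
                    try:
                        traj = integrate(sirx_rhs, init, params)
                        res = positivity_check(traj)
                        ok, first = res.ok, res.first_violation_time
                    except IntegrationError:
                        ok, first = False, np.nan
                    records.append({
                        "beta": beta, "scenario": scenario,
                        "w": float(w), "kappa": float(kappa), "ok": ok,
                        "first_violation_time":
                            np.nan if first is None else first,
                    })
    return pd.DataFrame.from_records(records)
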