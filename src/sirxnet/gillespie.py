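"""Exact event-driven simulation of the adaptive SIRX Markov process.

The process runs on a simple undirected graph with conserved node and link
counts.  Five Poissonian event channels act on the current configuration:

* infection    — each S–I link fires at rate β, turning its S endpoint I;
* recovery     — each I node fires at rate γ, turning R;
* rewiring     — each S–I link fires at rate w: the susceptible endpoint
                 drops the link to the infected node and reattaches to a
                 uniformly random susceptible or recovered node (social
                 self-distancing that preserves the number of contacts);
* quarantine   — each I node fires at rate κ, moving to the inert state X
                 (links are retained but X neither transmits nor is an
                 eligible rewiring target);
* release      — each X node fires at rate δ, moving to R.  The expected
                 quarantine duration is 1/δ; δ affects neither the infected
                 time course nor the final recovered fraction.

Simulation is a direct Gillespie/SSA: exponential waiting times at the
total rate, channel chosen proportionally to its aggregate rate, target
chosen uniformly within the channel.  Observables are resampled onto a
regular time grid by last-value-carried-forward so ensembles can be
averaged pointwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import I, R, S, X, NetworkConfig, NetworkState, generate_er_graph, initialize_states

__all__ = [
    "INFECTION",
    "RECOVERY",
    "REWIRING",
    "QUARANTINE",
    "RELEASE",
    "CHANNELS",
    "ModelParams",
    "EventTrajectory",
    "EnsembleResult",
    "total_rates",
    "apply_event",
    "rewire_edge",
    "gillespie_step",
    "run_gillespie",
    "ensemble_run",
]

INFECTION, RECOVERY, REWIRING, QUARANTINE, RELEASE = range(5)
CHANNELS = ("infection", "recovery", "rewiring", "quarantine", "release")

_COLUMNS = ("s", "i", "r", "x", "si", "ss")


@dataclass(frozen=True)
class ModelParams:
    """Epidemic and intervention rates, all per unit time.

    beta : infection rate per S–I link (> 0)
    gamma : recovery rate per I node (> 0)
    w : rewiring (self-distancing) rate per S–I link (≥ 0)
    kappa : quarantine rate per I node (≥ 0)
    delta : release rate per X node (> 0); 1/delta is the mean quarantine
        duration.
    """

    beta: float
    gamma: float
    w: float = 0.0
    kappa: float = 0.0
    delta: float = 1.0

    def __post_init__(self):
        if not self.beta > 0:
            raise ValueError("beta must be positive")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        if self.w < 0 or self.kappa < 0:
            raise ValueError("w and kappa must be nonnegative")

    @classmethod
    def degenerate(cls, beta, gamma, w=0.0, kappa=0.0, delta=1.0) -> "ModelParams":
        """Construct without the positivity validation.

        Only for degenerate test scenarios (e.g. beta = 0, which switches
        off transmission entirely); the model proper requires beta > 0.
        """
        obj = object.__new__(cls)
        for name, val in (("beta", beta), ("gamma", gamma), ("w", w),
                          ("kappa", kappa), ("delta", delta)):
            object.__setattr__(obj, name, val)
        return obj

    def replace(self, **kw) -> "ModelParams":
        d = dict(beta=self.beta, gamma=self.gamma, w=self.w,
                 kappa=self.kappa, delta=self.delta)
        d.update(kw)
        return ModelParams(**d)


def total_rates(net: NetworkState, params: ModelParams) -> np.ndarray:
    """Aggregate channel rates (infection, recovery, rewiring, quarantine, release).

    infection = β·|SI|, recovery = γ·#I, rewiring = w·|SI|,
    quarantine = κ·#I, release = δ·#X.
    """
    n_si = len(net.si_links)
    n_i = len(net.by_state[I])
    n_x = len(net.by_state[X])
    return np.array([
        params.beta * n_si,
        params.gamma * n_i,
        params.w * n_si,
        params.kappa * n_i,
        params.delta * n_x,
    ])


def rewire_edge(net: NetworkState, si_edge: tuple[int, int], rng: np.random.Generator,
                target_rule: str = "uniform") -> bool:
    """Rewire one S–I link: the S endpoint reattaches to an S or R node.

    ``target_rule="uniform"`` (default) draws the new partner uniformly
    from the union of all current S and R nodes, excluding the susceptible
    endpoint itself and its existing neighbours — so S–S and S–R outcomes
    occur in proportion to compartment abundance, matching the mean-field
    gain term w·ρ_S/(ρ_S+ρ_R)·ρ_SI.  ``target_rule="compartment"`` instead
    flips a fair coin between the (eligible) S and R compartments first.

    Returns True if a rewiring happened, False for a no-op (no eligible
    target).  The total edge count is unchanged either way.
    """
    s_node, i_node = si_edge
    if net.node_state[s_node] != S or net.node_state[i_node] != I:
        raise ValueError(f"edge {si_edge} is not an S–I link")

    target = _draw_rewire_target(net, s_node, rng, target_rule)
    if target is None:
        return False
    net.remove_edge(s_node, i_node)
    net.add_edge(s_node, target)
    return True


def _draw_rewire_target(net, s_node, rng, target_rule):
    s_set, r_set = net.by_state[S], net.by_state[R]
    if target_rule == "uniform":
        total = len(s_set) + len(r_set)
        # Rejection sampling is O(1) in the typical sparse regime; fall
        # back to explicit enumeration if the eligible set is tiny.
        for _ in range(64):
            if total == 0:
                return None
            k = int(rng.integers(total))
            cand = s_set._items[k] if k < len(s_set) else r_set._items[k - len(s_set)]
            if cand != s_node and cand not in net.adj[s_node]:
                return cand
        eligible = [v for v in list(s_set) + list(r_set)
                    if v != s_node and v not in net.adj[s_node]]
        if not eligible:
            return None
        return eligible[int(rng.integers(len(eligible)))]
    if target_rule == "compartment":
        elig_s = [v for v in s_set if v != s_node and v not in net.adj[s_node]]
        elig_r = [v for v in r_set if v not in net.adj[s_node]]
        pools = [p for p in (elig_s, elig_r) if p]
        if not pools:
            return None
        pool = pools[0] if len(pools) == 1 else pools[int(rng.integers(2))]
        return pool[int(rng.integers(len(pool)))]
    raise ValueError(f"unknown target_rule {target_rule!r}")


def apply_event(net: NetworkState, channel: int, rng: np.random.Generator,
                target_rule: str = "uniform") -> None:
    """Draw a uniform target within ``channel`` and apply the transition.

    Raises ``RuntimeError`` if the channel is empty (zero rate), since the
    SSA must never select such a channel.
    """
    try:
        if channel == INFECTION:
            s_node, _ = net.si_links.sample(rng)
            net.set_state(s_node, I)
        elif channel == RECOVERY:
            net.set_state(net.by_state[I].sample(rng), R)
        elif channel == REWIRING:
            rewire_edge(net, net.si_links.sample(rng), rng, target_rule)
        elif channel == QUARANTINE:
            net.set_state(net.by_state[I].sample(rng), X)
        elif channel == RELEASE:
            net.set_state(net.by_state[X].sample(rng), R)
        else:
            raise ValueError(f"unknown channel {channel}")
    except IndexError:
        raise RuntimeError(
            f"event drawn on empty channel {CHANNELS[channel]}") from None


def gillespie_step(net: NetworkState, params: ModelParams, rng: np.random.Generator,
                   target_rule: str = "uniform"):
    """One SSA step: returns (waiting_time, channel), or None when absorbed."""
    rates = total_rates(net, params)
    total = rates.sum()
    if total <= 0.0:
        return None
    dt = rng.exponential(1.0 / total)
    u = rng.random() * total
    acc = 0.0
    channel = len(rates) - 1
    for k, rk in enumerate(rates):
        acc += rk
        if u < acc:
            channel = k
            break
    apply_event(net, channel, rng, target_rule)
    return dt, channel


@dataclass
class EventTrajectory:
    """A single realisation resampled onto a regular time grid.

    ``counts`` maps the observable names s, i, r, x, si, ss to integer
    arrays aligned with ``times`` (last value carried forward between
    events).  ``peak_i`` is the event-exact maximum of the infected count,
    ``ever_infected`` the final count of nodes that ever left S.
    """

    times: np.ndarray
    counts: dict[str, np.ndarray]
    final_state: NetworkState
    final_time: float
    n_events: int
    peak_i: int
    absorbed: bool

    @property
    def n(self) -> int:
        return self.final_state.n

    @property
    def ever_infected(self) -> int:
        return self.n - len(self.final_state.by_state[S])

    def density(self, name: str) -> np.ndarray:
        """Per-node density of an observable (node or link counts / N)."""
        return self.counts[name] / self.n

    def frame(self) -> pd.DataFrame:
        data = {"time": self.times}
        for name in _COLUMNS:
            data[f"rho_{name}"] = self.density(name)
        return pd.DataFrame(data)


def run_gillespie(net: NetworkState, params: ModelParams, t_max: float | None,
                  seed, record_grid: np.ndarray | None = None,
                  target_rule: str = "uniform",
                  check_every: int | None = None) -> EventTrajectory:
    """Simulate the adaptive SIRX process exactly until t_max or absorption.

    Parameters
    ----------
    net : NetworkState
        Initial configuration; mutated in place (pass ``net.copy()`` to
        keep the original).
    t_max : float or None
        Time horizon; ``None`` runs to absorption (no event channel has
        positive rate), which is almost surely finite for this process.
    seed : int or numpy Generator
        All randomness flows through this single stream, so runs are
        reproducible bit-for-bit.
    record_grid : array, optional
        Strictly increasing recording times; observables are carried
        forward from the most recent event.  Defaults to 201 uniform
        points on [0, t_max] (required if t_max is None).
    check_every : int, optional
        Validate the full cache consistency every that-many events
        (testing aid; O(N+M) per check).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if record_grid is None:
        if t_max is None:
            raise ValueError("record_grid is required when t_max is None")
        record_grid = np.linspace(0.0, t_max, 201)
    grid = np.asarray(record_grid, dtype=float)
    rec = np.empty((len(grid), 6), dtype=np.int64)

    t = 0.0
    gi = 0
    n_events = 0
    peak_i = len(net.by_state[I])
    cur = net.counts()
    absorbed = False

    while True:
        rates = total_rates(net, params)
        total = rates.sum()
        if total <= 0.0:
            absorbed = len(net.by_state[I]) == 0 and len(net.by_state[X]) == 0
            break
        t_next = t + rng.exponential(1.0 / total)
        if t_max is not None and t_next > t_max:
            # The next event lies beyond the horizon: the state at t_max
            # is the current one, so stop before drawing the channel.
            t = t_max
            break
        u = rng.random() * total
        acc = 0.0
        channel = len(rates) - 1
        for k, rk in enumerate(rates):
            acc += rk
            if u < acc:
                channel = k
                break
        apply_event(net, channel, rng, target_rule)
        while gi < len(grid) and grid[gi] < t_next:
            rec[gi] = cur
            gi += 1
        t = t_next
        n_events += 1
        cur = net.counts()
        if cur[1] > peak_i:
            peak_i = cur[1]
        if check_every and n_events % check_every == 0:
            net.validate()
    while gi < len(grid):
        rec[gi] = cur
        gi += 1

    counts = {name: rec[:, k].copy() for k, name in enumerate(_COLUMNS)}
    return EventTrajectory(times=grid, counts=counts, final_state=net,
                           final_time=t, n_events=n_events, peak_i=peak_i,
                           absorbed=absorbed)


@dataclass
class EnsembleResult:
    """Summary of an ensemble of independent realisations.

    Mean and standard-error trajectories are pointwise on the shared
    recording grid.  Peak prevalence is reported both ways: the mean of
    per-run maxima (event-exact) and the maximum of the mean trajectory;
    the former is never smaller, because each run's maximum dominates its
    value at the argmax time of the mean.
    """

    times: np.ndarray
    mean: dict[str, np.ndarray]
    stderr: dict[str, np.ndarray]
    final_sizes: np.ndarray
    peaks: np.ndarray
    n_runs: int
    n_nodes: int

    @property
    def mean_of_maxima(self) -> float:
        return float(self.peaks.mean())

    @property
    def max_of_means(self) -> float:
        return float(self.mean["i"].max())

    def density_mean(self, name: str) -> np.ndarray:
        return self.mean[name]

    def frame(self) -> pd.DataFrame:
        data = {"time": self.times}
        for name in _COLUMNS:
            data[f"rho_{name}"] = self.mean[name]
            data[f"rho_{name}_se"] = self.stderr[name]
        return pd.DataFrame(data)


def _run_seeds(seed, k: int) -> tuple[int, int, np.random.Generator]:
    ss = np.random.SeedSequence(entropy=(int(seed), int(k)))
    graph_seed, init_seed = (int(s) & 0x7FFFFFFF for s in ss.generate_state(2))
    return graph_seed, init_seed, np.random.default_rng(ss)


def ensemble_run(net_config: NetworkConfig, params: ModelParams, rho_i0: float,
                 n_runs: int, seed: int, record_grid: np.ndarray,
                 t_max: float | None = None,
                 target_rule: str = "uniform") -> EnsembleResult:
    """Run ``n_runs`` independent realisations, each on a fresh ER graph.

    Per-run seeds are derived from ``(seed, run_index)`` so any single run
    can be reproduced in isolation.  Each run continues to absorption (or
    ``t_max``), so per-run final sizes equal the density of ever-infected
    nodes exactly.  Densities are averaged pointwise on ``record_grid``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    grid = np.asarray(record_grid, dtype=float)
    dens = np.empty((n_runs, len(grid), 6))
    final_sizes = np.empty(n_runs)
    peaks = np.empty(n_runs)
    n = net_config.n_nodes
    for k in range(n_runs):
        graph_seed, init_seed, rng = _run_seeds(seed, k)
        net = generate_er_graph(NetworkConfig(n, net_config.mean_degree, graph_seed))
        initialize_states(net, rho_i0, init_seed)
        traj = run_gillespie(net, params, t_max, rng, record_grid=grid,
                             target_rule=target_rule)
        for c, name in enumerate(_COLUMNS):
            dens[k, :, c] = traj.density(name)
        final_sizes[k] = traj.ever_infected / n
        peaks[k] = traj.peak_i / n
    mean = {name: dens[:, :, c].mean(axis=0) for c, name in enumerate(_COLUMNS)}
    stderr = {
        name: dens[:, :, c].std(axis=0, ddof=1) / np.sqrt(n_runs) if n_runs > 1
        else np.zeros(len(grid))
        for c, name in enumerate(_COLUMNS)
    }
    return EnsembleResult(times=grid, mean=mean, stderr=stderr,
                          final_sizes=final_sizes, peaks=peaks,
                          n_runs=n_runs, n_nodes=n)
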