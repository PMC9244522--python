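"""Parameter-plane sweeps over the rewiring and quarantine rates.

A sweep evaluates one observable — final epidemic size r∞, peak prevalence,
or the outbreak-proxy critical infection rate — on a (w, κ) grid, either
from the pair-approximation ODEs (deterministic) or from ensembles of
stochastic network realisations.  Cells are seeded independently from
(seed, cell_index) so any row can be recomputed in isolation and the grid
is invariant to evaluation order.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .analysis import beta_c_proxy, critical_combination
from .gillespie import ModelParams, ensemble_run
from .moments import default_init, integrate, peak_prevalence, r_infinity, sirx_rhs
from .network import NetworkConfig

__all__ = ["SweepConfig", "SweepGrid", "ComparisonResult", "sweep",
           "compare_modes", "preset_config", "load_config", "PRESETS"]

OBSERVABLES = ("r_inf", "peak", "beta_c_proxy")
MODES = ("ode", "stochastic")


@dataclass
class SweepConfig:
    """Full specification of a (w, κ) parameter-plane sweep."""

    w_grid: list[float]
    kappa_grid: list[float]
    beta: float = 0.0025
    gamma: float = 0.025
    delta: float = 0.01
    mu: float = 15.0
    rho_i0: float = 0.01
    observable: str = "r_inf"
    mode: str = "ode"
    n_nodes: int = 500
    runs_per_cell: int = 20
    seed: int = 0
    t_max: float = 2000.0
    outbreak_cutoff: float = 0.05

    def __post_init__(self):
        for name in ("w_grid", "kappa_grid"):
            g = [float(v) for v in getattr(self, name)]
            if not g or any(b <= a for a, b in zip(g, g[1:])):
                raise ValueError(f"{name} must be nonempty and strictly ascending")
            setattr(self, name, g)
        if self.observable not in OBSERVABLES:
            raise ValueError(f"observable must be one of {OBSERVABLES}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.mode == "stochastic" and self.runs_per_cell < 1:
            raise ValueError("runs_per_cell must be >= 1 in stochastic mode")

    def params(self, w: float, kappa: float) -> ModelParams:
        return ModelParams(beta=self.beta, gamma=self.gamma, w=w,
                           kappa=kappa, delta=self.delta)


@dataclass
class SweepGrid:
    """Per-cell sweep results plus the configuration that produced them.

    ``table`` has one row per (w, κ) cell with columns w, kappa, value,
    stderr, n_runs, mode, observable.  ``metadata`` echoes the full config
    and the critical combined intervention rate w + κ = β(μ−1) − γ.
    """

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def value_matrix(self) -> np.ndarray:
        """Values as a |w_grid| × |kappa_grid| matrix."""
        w_grid = self.metadata["config"]["w_grid"]
        kappa_grid = self.metadata["config"]["kappa_grid"]
        piv = self.table.pivot(index="w", columns="kappa", values="value")
        return piv.loc[w_grid, kappa_grid].to_numpy()

    def to_csv(self, path) -> None:
        """Lossless round-trip CSV: metadata as a JSON header comment."""
        with open(path, "w", newline="") as fh:
            fh.write("# " + json.dumps(self.metadata) + "\n")
            self.table.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "SweepGrid":
        with open(path) as fh:
            first = fh.readline()
            metadata = json.loads(first.lstrip("# ").strip()) if first.startswith("#") else {}
            table = pd.read_csv(fh, float_precision="round_trip")
        return cls(table=table, metadata=metadata)


def _cell_seed(seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=(int(seed), int(index)))
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def _log(quiet: bool, msg: str) -> None:
    if not quiet:
        stamp = time.strftime("%H:%M:%S")
        print(f"[{stamp}] {msg}", file=sys.stderr, flush=True)


def _evaluate_cell(config: SweepConfig, w: float, kappa: float, index: int):
    """Observable value and standard error for one grid cell."""
    params = config.params(w, kappa)
    init = default_init(config.mu, config.rho_i0)
    if config.observable == "beta_c_proxy":
        res = beta_c_proxy(config.gamma, w, kappa, config.mu,
                           delta=config.delta, rho_i0=config.rho_i0,
                           outbreak_cutoff=config.outbreak_cutoff,
                           mode=config.mode, n_nodes=config.n_nodes,
                           n_runs=config.runs_per_cell,
                           seed=_cell_seed(config.seed, index))
        return res.beta_c, 0.0, 1
    if config.mode == "ode":
        if config.observable == "r_inf":
            return r_infinity(params, init), 0.0, 1
        traj = integrate(sirx_rhs, init, params)
        return peak_prevalence(traj), 0.0, 1
    cfg = NetworkConfig(config.n_nodes, config.mu, 0)
    grid = np.linspace(0.0, config.t_max, 201)
    ens = ensemble_run(cfg, params, config.rho_i0, config.runs_per_cell,
                       seed=_cell_seed(config.seed, index), record_grid=grid)
    n = config.runs_per_cell
    if config.observable == "r_inf":
        vals = ens.final_sizes
    else:  # peak: mean of per-run event-exact maxima
        vals = ens.peaks
    se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(vals.mean()), se, n


def sweep(config: SweepConfig, quiet: bool = True) -> SweepGrid:
    """Evaluate the configured observable on the full (w, κ) grid.

    ODE mode is deterministic; stochastic mode derives an independent seed
    per cell from (config.seed, cell_index).  Per-cell failures are
    recorded (NaN value + error string) and the sweep continues.
    """
    rows = []
    n_cells = len(config.w_grid) * len(config.kappa_grid)
    index = 0
    for w in config.w_grid:
        for kappa in config.kappa_grid:
            try:
                value, se, n_runs = _evaluate_cell(config, w, kappa, index)
                err = ""
            except Exception as exc:  # noqa: BLE001 — per-cell isolation
                value, se, n_runs, err = np.nan, np.nan, 0, str(exc)
            rows.append({"w": w, "kappa": kappa, "value": value,
                         "stderr": se, "n_runs": n_runs, "mode": config.mode,
                         "observable": config.observable, "error": err})
            index += 1
            if index % 25 == 0 or index == n_cells:
                _log(quiet, f"sweep {config.observable}/{config.mode}: "
                            f"{index}/{n_cells} cells")
    metadata = {
        "config": asdict(config),
        "critical_combination": critical_combination(config.beta, config.gamma,
                                                     config.mu),
    }
    return SweepGrid(table=pd.DataFrame(rows), metadata=metadata)


@dataclass
class ComparisonResult:
    """Paired ODE/stochastic sweep with per-cell differences."""

    ode: SweepGrid
    stochastic: SweepGrid
    table: pd.DataFrame  # w, kappa, value_ode, value_stoch, diff, stderr, outlier


def compare_modes(config: SweepConfig, k_sigma: float = 3.0,
                  quiet: bool = True) -> ComparisonResult:
    """Run both modes on the same grid and flag cells beyond k·stderr.

    The signed difference is stochastic − ODE; ``outlier`` marks cells
    whose difference exceeds ``k_sigma`` standard errors of the ensemble
    mean (always False when both runs are deterministic).
    """
    import copy

    cfg_ode = copy.deepcopy(config)
    cfg_ode.mode = "ode"
    cfg_sto = copy.deepcopy(config)
    grid_ode = sweep(cfg_ode, quiet=quiet)
    grid_sto = sweep(cfg_sto, quiet=quiet)
    merged = grid_ode.table[["w", "kappa", "value"]].merge(
        grid_sto.table[["w", "kappa", "value", "stderr"]],
        on=["w", "kappa"], suffixes=("_ode", "_stoch"))
    merged["diff"] = merged["value_stoch"] - merged["value_ode"]
    merged["outlier"] = np.abs(merged["diff"]) > k_sigma * merged["stderr"]
    return ComparisonResult(ode=grid_ode, stochastic=grid_sto, table=merged)


# Named presets covering the intervention plane near the critical curve at
# the reference infection rate β = 0.0025 (ranges are a package choice; the
# [0, 0.02]² envelope comfortably contains w + κ = β(μ−1) − γ = 0.01).
PRESETS = {
    "size-plane": dict(observable="r_inf", mode="ode",
                       w_grid=np.linspace(0, 0.02, 21).tolist(),
                       kappa_grid=np.linspace(0, 0.02, 21).tolist()),
    "peak-plane": dict(observable="peak", mode="ode",
                       w_grid=np.linspace(0, 0.02, 21).tolist(),
                       kappa_grid=np.linspace(0, 0.02, 21).tolist()),
    "threshold-plane": dict(observable="beta_c_proxy", mode="ode",
                            w_grid=np.linspace(0, 0.02, 11).tolist(),
                            kappa_grid=np.linspace(0, 0.02, 11).tolist()),
    "stochastic-size-plane": dict(observable="r_inf", mode="stochastic",
                                  n_nodes=500, runs_per_cell=20,
                                  w_grid=np.linspace(0, 0.02, 11).tolist(),
                                  kappa_grid=np.linspace(0, 0.02, 11).tolist()),
}


def preset_config(name: str, seed: int = 0, **overrides) -> SweepConfig:
    """A ready-made SweepConfig by preset name (see ``PRESETS``)."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    kw.update(overrides)
    return SweepConfig(seed=seed, **kw)


def load_config(path) -> SweepConfig:
    """Read a SweepConfig from a flat YAML mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError("sweep config must be a flat key/value mapping")
    return SweepConfig(**data)
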