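"""Event rates, bookkeeping, rewiring law and whole-process properties."""

import numpy as np
import pytest

from sirxnet.gillespie import (
    INFECTION,
    QUARANTINE,
    RECOVERY,
    RELEASE,
    ModelParams,
    apply_event,
    ensemble_run,
    gillespie_step,
    rewire_edge,
    run_gillespie,
    total_rates,
)
from sirxnet.network import I, R, S, X, NetworkConfig, count_motifs, generate_er_graph, initialize_states

from conftest import build_net


class TestModelParams:
    @pytest.mark.parametrize("bad", [
        dict(beta=0.0, gamma=0.1), dict(beta=0.1, gamma=0.0),
        dict(beta=0.1, gamma=0.1, delta=0.0),
        dict(beta=0.1, gamma=0.1, w=-1e-9), dict(beta=0.1, gamma=0.1, kappa=-1.0),
    ])
    def test_invalid_rates_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParams(**bad)

    def test_degenerate_constructor_skips_validation(self):
        p = ModelParams.degenerate(beta=0.0, gamma=0.1)
        assert p.beta == 0.0


class TestTotalRates:
    def test_absorbing_state_has_zero_rates(self):
        net = build_net(3, [(0, 1)], [S, R, R])
        assert total_rates(net, ModelParams(1.0, 1.0, 1.0, 1.0, 1.0)).sum() == 0

    def test_hand_computed_rates(self):
        # one I node with two S neighbours
        net = build_net(3, [(0, 1), (0, 2)], [I, S, S])
        p = ModelParams(beta=0.005, gamma=0.025, w=0.0025, kappa=0.0025,
                        delta=0.001)
        assert total_rates(net, p) == pytest.approx(
            [0.01, 0.025, 0.005, 0.0025, 0.0])

    def test_link_channels_scale_linearly_in_si_count(self):
        p = ModelParams(beta=0.005, gamma=0.025, w=0.0025, kappa=0.0025,
                        delta=0.001)
        one = build_net(3, [(0, 1)], [I, S, S])
        two = build_net(3, [(0, 1), (0, 2)], [I, S, S])
        r1, r2 = total_rates(one, p), total_rates(two, p)
        assert r2[INFECTION] == 2 * r1[INFECTION]
        assert r2[2] == 2 * r1[2]  # rewiring
        assert r2[RECOVERY] == r1[RECOVERY]


class TestApplyEvent:
    def test_quarantine_deactivates_si_links_but_keeps_edges(self):
        net = build_net(2, [(0, 1)], [I, S])
        apply_event(net, QUARANTINE, np.random.default_rng(0))
        assert net.node_state[0] == X
        assert len(net.si_links) == 0
        assert net.n_edges == 1

    def test_release_relabels_to_recovered(self):
        net = build_net(2, [(0, 1)], [X, S])
        apply_event(net, RELEASE, np.random.default_rng(0))
        assert net.node_state[0] == R
        assert net.counts()[2] == 1

    def test_infection_along_path_updates_si_cache(self):
        # S-S-I: infecting the middle node leaves one SI link (outer S).
        net = build_net(3, [(0, 1), (1, 2)], [S, S, I])
        apply_event(net, INFECTION, np.random.default_rng(0))
        assert net.node_state[1] == I
        assert net.si_links.as_set() == {(0, 1)}

    def test_empty_channel_is_an_error(self):
        net = build_net(2, [(0, 1)], [S, S])
        with pytest.raises(RuntimeError):
            apply_event(net, RECOVERY, np.random.default_rng(0))


class TestRewireEdge:
    def test_single_eligible_target_gives_ss_link(self):
        net = build_net(3, [(0, 1)], [S, I, S])
        assert rewire_edge(net, (0, 1), np.random.default_rng(0))
        assert net.edges == {(0, 2)}
        assert net.ss_links.as_set() == {(0, 2)}
        assert net.n_edges == 1

    def test_no_eligible_target_is_a_noop(self):
        net = build_net(4, [(0, 1)], [S, I, I, X])
        assert not rewire_edge(net, (0, 1), np.random.default_rng(0))
        assert net.edges == {(0, 1)}

    def test_non_si_edge_rejected(self):
        net = build_net(2, [(0, 1)], [S, S])
        with pytest.raises(ValueError):
            rewire_edge(net, (0, 1), np.random.default_rng(0))

    def test_targets_drawn_uniformly_over_s_and_r(self):
        # eligible pool: 3 S nodes + 1 R node -> S chosen w.p. 3/4
        rng = np.random.default_rng(42)
        n_draws, hits = 10_000, 0
        for _ in range(n_draws):
            net = build_net(6, [(0, 1)], [S, I, S, S, S, R])
            rewire_edge(net, (0, 1), rng)
            (u, v), = net.edges
            target = v if u == 0 else u
            hits += net.node_state[target] == S
        p_hat = hits / n_draws
        se = np.sqrt(0.75 * 0.25 / n_draws)
        assert abs(p_hat - 0.75) < 4 * se

    def test_compartment_rule_splits_evenly_between_s_and_r(self):
        # alternative 50/50-coin rule: S chosen w.p. 1/2 despite 3 S vs 1 R
        rng = np.random.default_rng(7)
        n_draws, hits = 10_000, 0
        for _ in range(n_draws):
            net = build_net(6, [(0, 1)], [S, I, S, S, S, R])
            rewire_edge(net, (0, 1), rng, target_rule="compartment")
            (u, v), = net.edges
            target = v if u == 0 else u
            hits += net.node_state[target] == S
        se = np.sqrt(0.25 / n_draws)
        assert abs(hits / n_draws - 0.5) < 4 * se


def _small_system(seed=0, n=200, mu=8.0, rho_i0=0.05):
    net = generate_er_graph(NetworkConfig(n, mu, seed))
    return initialize_states(net, rho_i0, seed + 1)


class TestRunGillespie:
    def test_no_transmission_when_beta_is_zero(self):
        net = _small_system()
        p = ModelParams.degenerate(beta=0.0, gamma=0.1, w=0.0, kappa=0.05,
                                   delta=0.2)
        traj = run_gillespie(net, p, None, seed=3,
                             record_grid=np.linspace(0, 200, 21))
        assert traj.absorbed
        assert traj.ever_infected == 10  # exactly the initial seeds
        assert traj.counts["r"][-1] == 10

    def test_no_quarantine_channel_means_x_never_populated(self):
        net = _small_system(seed=5)
        p = ModelParams(beta=0.05, gamma=0.05, w=0.02, kappa=0.0, delta=0.1)
        traj = run_gillespie(net, p, None, seed=6,
                             record_grid=np.linspace(0, 300, 31))
        assert traj.counts["x"].max() == 0

    def test_kappa_zero_runs_are_independent_of_delta(self):
        # with no quarantine the release channel never fires, so the same
        # seed stream produces bit-identical adaptive-SIR trajectories
        p1 = ModelParams(beta=0.05, gamma=0.05, w=0.02, kappa=0.0, delta=0.001)
        p2 = p1.replace(delta=0.5)
        grid = np.linspace(0, 300, 31)
        t1 = run_gillespie(_small_system(seed=8), p1, None, 9, record_grid=grid)
        t2 = run_gillespie(_small_system(seed=8), p2, None, 9, record_grid=grid)
        assert t1.n_events == t2.n_events
        for name in ("s", "i", "r", "x", "si", "ss"):
            assert np.array_equal(t1.counts[name], t2.counts[name])

    def test_node_and_edge_counts_conserved_through_all_events(self):
        net = _small_system(seed=11, n=120, mu=6.0)
        m0 = net.n_edges
        p = ModelParams(beta=0.08, gamma=0.04, w=0.06, kappa=0.03, delta=0.1)
        traj = run_gillespie(net, p, None, seed=12,
                             record_grid=np.linspace(0, 200, 41),
                             check_every=1)  # full validation at every event
        tot = sum(traj.counts[k] for k in ("s", "i", "r", "x"))
        assert np.all(tot == 120)
        assert traj.final_state.n_edges == m0

    def test_expected_susceptible_outflow_matches_beta_si(self):
        """At t=0 the expected per-event drop of #S equals the infection
        channel share beta*[SI]/R_total (the first exact moment identity)."""
        base = _small_system(seed=20)
        p = ModelParams(beta=0.03, gamma=0.02, w=0.01, kappa=0.01, delta=0.1)
        rates = total_rates(base, p)
        p_inf = rates[INFECTION] / rates.sum()
        m = 4000
        rng = np.random.default_rng(21)
        drops = 0
        for _ in range(m):
            net = base.copy()
            s_before = len(net.by_state[S])
            gillespie_step(net, p, rng)
            drops += s_before - len(net.by_state[S])
        se = np.sqrt(p_inf * (1 - p_inf) / m)
        assert abs(drops / m - p_inf) < 4 * se

    def test_delta_does_not_shift_infection_statistics(self):
        """Ensemble means of final size and peak agree across a 100-fold
        change of the release rate (within combined Monte-Carlo error)."""
        cfg = NetworkConfig(300, 10.0, 0)
        grid = np.linspace(0, 400, 41)
        res = {}
        for d in (0.001, 0.1):
            p = ModelParams(beta=0.02, gamma=0.05, w=0.01, kappa=0.02, delta=d)
            res[d] = ensemble_run(cfg, p, 0.02, 30, seed=int(d * 1e4),
                                  record_grid=grid)
        for attr in ("final_sizes", "peaks"):
            a, b = getattr(res[0.001], attr), getattr(res[0.1], attr)
            se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
            assert abs(a.mean() - b.mean()) < 3 * se


class TestEnsembleRun:
    def test_single_run_mean_is_the_run_itself(self):
        cfg = NetworkConfig(150, 6.0, 0)
        p = ModelParams(beta=0.05, gamma=0.05, w=0.01, kappa=0.01, delta=0.1)
        grid = np.linspace(0, 100, 11)
        ens = ensemble_run(cfg, p, 0.05, 1, seed=5, record_grid=grid)
        assert np.all(ens.stderr["i"] == 0)
        assert ens.final_sizes.shape == (1,)
        assert ens.mean_of_maxima == ens.peaks[0]

    def test_mean_of_maxima_dominates_max_of_means(self):
        cfg = NetworkConfig(200, 8.0, 0)
        p = ModelParams(beta=0.03, gamma=0.03, w=0.005, kappa=0.01, delta=0.05)
        ens = ensemble_run(cfg, p, 0.02, 12, seed=3,
                           record_grid=np.linspace(0, 300, 61))
        assert ens.mean_of_maxima >= ens.max_of_means

    def test_final_sizes_at_least_initial_infected_density(self):
        cfg = NetworkConfig(200, 8.0, 0)
        p = ModelParams(beta=0.01, gamma=0.1, w=0.01, kappa=0.05, delta=0.1)
        ens = ensemble_run(cfg, p, 0.05, 10, seed=9,
                           record_grid=np.linspace(0, 200, 21))
        assert np.all(ens.final_sizes >= 0.05 - 1e-12)
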