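"""Recurrent LIF network with per-neuron metabolic currents."""

import numpy as np
import pytest
from dataclasses import replace

from metaspike.errors import DomainError
from metaspike.network import (
    NetworkConfig,
    RasterWindow,
    SimResult,
    build_network,
    i_m_from_ms,
    ms_update,
    persistence_time,
    simulate,
    summarize_activity,
)


class TestBuild:
    def test_in_degree_binomial(self, small_net_config):
        net = build_network(small_net_config)
        deg = net.in_degrees()
        n, p = small_net_config.n_total, small_net_config.p_connect
        mean, sd = p * (n - 1), np.sqrt(n * p * (1 - p))
        assert abs(deg.mean() - mean) < 3 * sd / np.sqrt(n)

    def test_no_autapses(self, small_net_config):
        net = build_network(small_net_config)
        assert not np.any(np.diag(net.adjacency()))

    def test_seed_reproducible(self, small_net_config):
        a = build_network(small_net_config).adjacency()
        b = build_network(small_net_config).adjacency()
        assert np.array_equal(a, b)


class TestMsUpdate:
    def test_rest_is_fixed_point(self, scaled_config):
        assert ms_update(scaled_config.ms_rest, (0, 0, False), scaled_config) \
            == pytest.approx(scaled_config.ms_rest)

    def test_events_deplete(self, scaled_config):
        ms = scaled_config.ms_rest
        for _ in range(200):
            new = ms_update(ms, (3, 1, True), scaled_config)
            assert new <= ms
            ms = new
        assert ms == 0.0  # clamped at the floor under heavy load

    def test_recovery_matches_exponential(self, scaled_config):
        cfg = scaled_config
        ms = 0.0
        n = 3000
        for _ in range(n):
            ms = ms_update(ms, (0, 0, False), cfg)
        t = n * cfg.dt
        expected = cfg.ms_rest * (1 - (1 - cfg.dt / cfg.tau_ms) ** (t / cfg.dt))
        assert ms == pytest.approx(expected, rel=1e-9)
        # and the discrete relaxation tracks the continuous exponential
        assert ms == pytest.approx(cfg.ms_rest * (1 - np.exp(-t / cfg.tau_ms)), rel=2e-4)


class TestMetabolicCurrent:
    def test_neutral_point_zero(self, scaled_config):
        assert i_m_from_ms(scaled_config.ms_neutral, scaled_config) == 0.0

    def test_saturates_at_bounds(self, scaled_config):
        cfg = scaled_config
        assert i_m_from_ms(cfg.ms_max, cfg) == cfg.im_bound
        assert i_m_from_ms(0.0, cfg) == -cfg.im_bound

    def test_monotone(self, scaled_config):
        grid = np.linspace(0, scaled_config.ms_max, 30)
        vals = i_m_from_ms(grid, scaled_config)
        assert np.all(np.diff(vals) >= 0)

    def test_domain_error(self, scaled_config):
        with pytest.raises(DomainError):
            i_m_from_ms(-0.1, scaled_config)


@pytest.fixture(scope="module")
def short_run(scaled_config):
    return simulate(scaled_config, duration=3000.0, stim_off_time=1500.0)


class TestSimulate:
    def test_deterministic(self, small_net_config):
        r1 = simulate(small_net_config, 500.0, 500.0)
        r2 = simulate(small_net_config, 500.0, 500.0)
        assert np.array_equal(r1.spike_ids, r2.spike_ids)
        assert np.array_equal(r1.spike_times, r2.spike_times)
        assert np.array_equal(r1.spike_ms, r2.spike_ms)

    def test_ms_bounds_respected(self, short_run):
        cfg = short_run.config
        assert short_run.spike_ms.min() >= 0.0
        assert short_run.spike_ms.max() <= cfg.ms_max
        for rec in short_run.records:
            assert rec.ms.min() >= 0.0 and rec.ms.max() <= cfg.ms_max

    def test_energy_accounting_exact(self, short_run):
        """Cumulative MS debits equal events x per-event cost exactly."""
        cfg = short_run.config
        ev = short_run.event_counts
        expected = (ev[:, 0] * cfg.cost_exc + ev[:, 1] * cfg.cost_inh
                    + ev[:, 2] * cfg.cost_spike)
        assert np.allclose(short_run.cumulative_cost, expected, rtol=0, atol=1e-12)

    def test_metabolic_current_sustains_activity(self, short_run):
        # active until the end of the run, well past stimulus removal
        assert persistence_time(short_run) >= 1400.0
        last_second = short_run.window.counts[-1000:]
        assert last_second.sum() > 0

    def test_ablated_network_collapses(self, scaled_config):
        cfg = replace(scaled_config, im_gain=0.0)
        res = simulate(cfg, duration=3000.0, stim_off_time=1500.0)
        assert persistence_time(res) < 500.0

    def test_stim_off_after_duration_rejected(self, scaled_config):
        with pytest.raises(DomainError):
            simulate(scaled_config, 100.0, 200.0)

    def test_robustness_band_wider_with_metabolic_current(self, scaled_config):
        """Across E/I weight scalings, the metabolic current rescues
        persistence in strictly more settings than the ablated network."""
        ok = {True: 0, False: 0}
        for enabled in (True, False):
            for fe in (0.8, 1.2):
                for fi in (0.8, 1.2):
                    cfg = replace(
                        scaled_config,
                        w_exc=scaled_config.w_exc * fe,
                        w_inh=scaled_config.w_inh * fi,
                        im_gain=scaled_config.im_gain if enabled else 0.0,
                    )
                    res = simulate(cfg, duration=2500.0, stim_off_time=1000.0)
                    rates = summarize_activity(res, (1500.0, 2500.0))["rates_hz"]
                    persistent = persistence_time(res) >= 1400.0
                    saturated = rates.mean() > 100.0
                    ok[enabled] += int(persistent and not saturated)
        assert ok[True] > ok[False]


class TestSummaries:
    def _result_from_trains(self, trains, duration, cfg):
        ids = np.concatenate([np.full(len(t), i) for i, t in enumerate(trains)])
        times = np.concatenate(trains)
        order = np.argsort(times, kind="stable")
        n_bins = int(np.ceil(duration))
        return SimResult(
            config=cfg, duration=duration, stim_off_time=duration,
            spike_ids=ids[order].astype(np.int64), spike_times=times[order],
            spike_ms=np.zeros(len(times)),
            window=RasterWindow(np.zeros(n_bins, dtype=np.int64), 1.0, cfg.n_total),
            records=[], cumulative_cost=np.zeros(cfg.n_total),
            event_counts=np.zeros((cfg.n_total, 3), dtype=np.int64),
        )

    def test_periodic_neuron_has_zero_cv(self, small_net_config):
        trains = [np.arange(10.0, 990.0, 50.0)] + \
                 [np.empty(0)] * (small_net_config.n_total - 1)
        res = self._result_from_trains(trains, 1000.0, small_net_config)
        s = summarize_activity(res, (0.0, 1000.0))
        assert s["cv_isi"].size == 1
        assert s["cv_isi"][0] == pytest.approx(0.0, abs=1e-12)

    def test_poisson_surrogate_cv_near_one(self, small_net_config):
        from metaspike.stimuli import poisson_fixture

        trains = poisson_fixture(20.0, 60_000.0, 10, seed=7)
        trains += [np.empty(0)] * (small_net_config.n_total - len(trains))
        res = self._result_from_trains(trains, 60_000.0, small_net_config)
        s = summarize_activity(res, (0.0, 60_000.0))
        assert s["cv_isi"].mean() == pytest.approx(1.0, abs=0.1)

    def test_ms_at_spike_higher_after_transition(self, scaled_config):
        res = simulate(scaled_config, duration=4000.0, stim_off_time=1500.0)
        driven = summarize_activity(res, (500.0, 1500.0))["ms_at_spike"]
        sustained = summarize_activity(res, (2500.0, 4000.0))["ms_at_spike"]
        assert sustained.mean() > driven.mean()

    def test_asynchronous_irregular_signature(self, scaled_config):
        """Self-sustained phase: irregular ISIs, rate fluctuations above
        the Poisson floor, but no global saturation."""
        res = simulate(scaled_config, duration=4000.0, stim_off_time=1500.0)
        s = summarize_activity(res, (2000.0, 4000.0))
        assert 0.3 < s["cv_isi"].mean() < 1.5
        counts = res.window.counts[2000:4000]
        fano = counts.var() / counts.mean()
        assert fano > 1.0
        assert s["rates_hz"].mean() < 100.0

    def test_empty_window_rejected(self, scaled_config):
        res = simulate(scaled_config, 200.0, 200.0)
        with pytest.raises(DomainError):
            summarize_activity(res, (100.0, 100.0))
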