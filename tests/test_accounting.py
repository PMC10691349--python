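"""Accounting neuron: MS gating, firing patterns, ROS homeostasis."""

import numpy as np
import pytest
from dataclasses import replace

from metaspike import mito
from metaspike.accounting import (
    AccountingParams,
    AccountingState,
    PatternCriteria,
    SpikeTrain,
    classify_pattern,
    initial_state,
    metabolic_signal,
    phase_diagram,
    simulate_accounting,
    step_accounting,
)
from metaspike.errors import DomainError
from metaspike.mito import EnergyBudget


def episodes(times, gap_ms=15.0):
    """Spike counts of quenching episodes (runs split at long gaps)."""
    if len(times) == 0:
        return np.array([])
    cuts = np.flatnonzero(np.diff(times) > gap_ms)
    return np.diff(np.concatenate(([0], cuts + 1, [len(times)])))


class TestMetabolicSignal:
    @pytest.mark.parametrize("ros,atp,bar,expected", [
        (0.5, 0.7, 0.7, 0.0),
        (0.0, 1.0, 0.5, 0.0),
        (2.0, 1.25, 0.75, 1.0),
        (1.0, 0.5, 0.75, -0.25),
    ])
    def test_product(self, ros, atp, bar, expected):
        assert metabolic_signal(ros, atp, bar) == pytest.approx(expected)


class TestGating:
    """Single-step threshold logic with the instantaneous MS readout."""

    def params(self, **kw):
        kw.setdefault("tau_ms", 0.0)
        return AccountingParams(**kw)

    def state(self, params, atp):
        ros = params.ros_target(params.budget.baseline_cost)
        return AccountingState(atp=atp, ros=ros,
                               ms=metabolic_signal(ros, atp, params.atp_bar),
                               c_slow=params.budget.baseline_cost)

    def test_high_ms_fires_metabolic_without_input(self):
        p = self.params()
        s = self.state(p, atp=0.95)  # MS well above theta_ret
        _, label = step_accounting(s, p, input_drive=False, dt=0.1)
        assert label == "metabolic"

    def test_intermediate_ms_no_spike_without_input(self):
        p = self.params()
        s = self.state(p, atp=p.atp_bar + 0.01)  # theta_fet < MS < theta_ret
        _, label = step_accounting(s, p, input_drive=False, dt=0.1)
        assert label is None

    def test_intermediate_ms_synaptic_with_input(self):
        p = self.params()
        s = self.state(p, atp=p.atp_bar + 0.01)
        _, label = step_accounting(s, p, input_drive=True, dt=0.1)
        assert label == "synaptic"

    def test_low_ms_blocks_input_spikes(self):
        p = self.params()
        s = self.state(p, atp=0.2)  # MS far below theta_fet
        new, label = step_accounting(s, p, input_drive=True, dt=0.1)
        assert new.ms < p.theta_fet and label is None

    def test_refractory_blocks_everything(self):
        p = self.params()
        s = replace(self.state(p, atp=0.95), refractory_remaining=1.0)
        _, label = step_accounting(s, p, input_drive=True, dt=0.1)
        assert label is None

    def test_threshold_order_enforced(self):
        with pytest.raises(DomainError):
            AccountingParams(theta_ret=-0.2, theta_fet=0.1)


class TestSimulation:
    def test_gating_soundness_on_traces(self):
        """No spike below theta_fet; metabolic spikes only above theta_ret."""
        p = AccountingParams()
        train, traces = simulate_accounting(p, 3000.0)
        assert len(train) > 10
        idx = np.searchsorted(traces["time_ms"].to_numpy(), train.times)
        ms_at_spike = traces["ms"].to_numpy()[idx]
        assert np.all(ms_at_spike > p.theta_fet)
        metabolic = train.labels == "metabolic"
        assert np.all(ms_at_spike[metabolic] > p.theta_ret)

    def test_refractory_bound(self):
        p = AccountingParams()
        train, _ = simulate_accounting(p, 3000.0)
        assert np.diff(train.times).min() >= p.refractory - 0.11

    def test_large_q_isolated_spikes(self):
        p = AccountingParams(budget=EnergyBudget(baseline_cost=0.005, q=0.3))
        train, _ = simulate_accounting(p, 3000.0)
        assert episodes(train.times).mean() < 1.5

    def test_small_q_multi_spike_bursts(self):
        p = AccountingParams(budget=EnergyBudget(baseline_cost=0.005, q=0.01))
        train, _ = simulate_accounting(p, 3000.0)
        assert episodes(train.times).mean() > 2.0

    def test_q_monotone_spikes_per_episode(self):
        """More expensive spikes quench in fewer spikes per episode.

        A 0.05-spike tolerance absorbs discreteness noise once episodes
        reach the one-spike floor.
        """
        means = []
        for q in (0.01, 0.05, 0.15, 0.3):
            p = AccountingParams(budget=EnergyBudget(baseline_cost=0.005, q=q))
            train, _ = simulate_accounting(p, 3000.0)
            eps = episodes(train.times)
            means.append(eps.mean() if eps.size else 0.0)
        assert all(b <= a + 0.05 for a, b in zip(means, means[1:]))

    def test_metabolic_spiking_lowers_ros(self):
        """The homeostatic point: self-initiated spikes quench ROS."""
        p = AccountingParams()
        _, on = simulate_accounting(p, 3000.0)
        _, off = simulate_accounting(p, 3000.0, metabolic_enabled=False)
        assert on["ros"].mean() < off["ros"].mean()

    def test_deterministic(self):
        p = AccountingParams()
        t1, tr1 = simulate_accounting(p, 800.0, seed=5)
        t2, tr2 = simulate_accounting(p, 800.0, seed=5)
        assert np.array_equal(t1.times, t2.times)
        assert tr1.equals(tr2)

    def test_shorter_refractory_raises_in_burst_rate(self):
        rates = []
        for refr in (2.0, 5.0):
            p = AccountingParams(refractory=refr,
                                 budget=EnergyBudget(baseline_cost=0.005, q=0.02))
            train, _ = simulate_accounting(p, 4000.0)
            isi = np.diff(train.times)
            in_burst = isi[isi <= 15.0]
            rates.append(1000.0 / in_burst.mean())
        assert rates[0] > rates[1]


class TestMitoBackend:
    def test_ros_trace_matches_standalone_mito(self):
        """The adapter must reproduce the standalone model under the same load."""
        ss_bar = mito.find_steady_state(mito.MitoParams(), 0.0156)
        p = AccountingParams(
            ros_backend="mito", atp_bar=ss_bar.atp_c, theta_ret=0.015,
            budget=EnergyBudget(baseline_cost=0.005, q=0.05),
        )
        train, traces = simulate_accounting(p, 400.0, dt=0.05)
        # replay the recorded consumption through the raw integrator
        y = mito.find_steady_state(p.mito_params, 0.005).as_array()
        cons = traces["consumption"].to_numpy()
        spike_steps = set(np.round(train.times / 0.05).astype(int))
        ros = np.empty(len(cons))
        from metaspike.mito import _rk4_step
        for i in range(len(cons)):
            y = _rk4_step(y, p.mito_params, cons[i], 0.05)
            if (i + 1) in spike_steps:
                y[2] = max(0.0, y[2] - p.mito_params.ca_coupling)
                y[6] += 1.0
            ros[i] = y[5]
        assert np.allclose(ros, traces["ros"].to_numpy(), atol=1e-6)


class TestClassifier:
    def test_empty_is_silent(self):
        train = SpikeTrain(np.empty(0), np.empty(0, dtype=object))
        assert classify_pattern(train, 2000.0) == "silent"

    def test_periodic_below_cutoff_is_tonic(self):
        times = np.arange(100.0, 2000.0, 100.0)  # 10 Hz, CV = 0
        train = SpikeTrain(times, np.full(len(times), "metabolic", dtype=object))
        assert classify_pattern(train, 2000.0) == "tonic"

    def test_fast_pauseless_is_continuous(self):
        times = np.arange(10.0, 2000.0, 25.0)  # 40 Hz, no gaps
        train = SpikeTrain(times, np.full(len(times), "metabolic", dtype=object))
        assert classify_pattern(train, 2000.0) == "continuous"

    def test_gapped_runs_are_bursting(self):
        """Runs of short ISIs separated by >= 5x median gaps."""
        times = []
        t = 0.0
        for _ in range(10):
            for _ in range(5):
                t += 4.0
                times.append(t)
            t += 120.0
        times = np.asarray(times)
        train = SpikeTrain(times, np.full(len(times), "metabolic", dtype=object))
        assert classify_pattern(train, times[-1] + 10) == "bursting"


class TestPhaseDiagram:
    def test_high_baseline_without_input_is_silent(self):
        p = AccountingParams()
        labels = phase_diagram(p, [0.018, 0.02], [0.01, 0.1], duration=1500.0)
        assert set(labels.ravel()) == {"silent"}

    def test_low_baseline_small_q_band_active(self):
        p = AccountingParams()
        labels = phase_diagram(p, [0.004], [0.005, 0.02], duration=1500.0)
        assert set(labels.ravel()) <= {"continuous", "bursting", "tonic"}

    def test_empty_grid_rejected(self):
        with pytest.raises(DomainError):
            phase_diagram(AccountingParams(), [], [0.1])
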