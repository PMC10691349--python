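"""The metabolic-accounting neuron: threshold spiking driven by MS.

A deliberately membrane-free neuron model that keeps books on its
energy budget.  ATP relaxes toward a level set by the current net
consumption; ROS relaxes (with ``tau_ros``) toward a V-shaped function
of low-pass-filtered consumption whose minimum sits at the reference
expenditure where ROS production bottoms out, and each spike's calcium
influx instantly quenches a fraction of ROS.  The metabolic signal

    MS = ROS * (ATP - ATP_bar)

is positive in the RETROS regime (surplus ATP, high ROS) and negative
in the FETROS regime (depleted ATP, high ROS).  Two thresholds gate
spiking:

* ``MS > theta_ret``: the neuron elicits ATP-consuming, ROS-quenching
  *metabolic* spikes on its own;
* ``theta_fet < MS <= theta_ret``: only input-driven *synaptic* spikes
  are allowed;
* ``MS < theta_fet``: all spiking is blocked, input or not.

Each spike spends the per-spike cost Q over the budget's kernel window,
which moves consumption toward the ROS minimum and closes the loop.
The spike-initiation machinery senses MS through first-order messenger
kinetics (``tau_ms``); because the sensed signal lags the true one, MS
swings across the thresholds instead of riding them, which is what
groups metabolic spikes into the burst-patterned quenching episodes
seen at low per-spike cost.  The full mitochondrial ODE model can be
swapped in as the ROS/ATP backend (``ros_backend="mito"``) at the cost
of speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError
from .mito import EnergyBudget, MitoParams, _rk4_step, find_steady_state

__all__ = [
    "AccountingParams",
    "AccountingState",
    "SpikeTrain",
    "PatternCriteria",
    "metabolic_signal",
    "step_accounting",
    "simulate_accounting",
    "classify_pattern",
    "phase_diagram",
]


@dataclass(frozen=True)
class AccountingParams:
    """Thresholds, budget, and backend parameters of the accounting neuron.

    The phenomenological backend's defaults are calibrated against the
    mitochondrial model's steady-state sweep: ``c_bar`` matches the
    consumption rate at the ROS minimum and ``atp_bar`` is the ATP level
    attained there.
    """

    theta_ret: float = 0.04    #: MS threshold starting metabolic spiking
    theta_fet: float = -0.1    #: MS threshold below which all spiking is blocked
    atp_bar: float = 0.75      #: ATP level at the ROS minimum (reference)
    refractory: float = 2.0    #: absolute refractory period (ms)
    budget: EnergyBudget = field(default_factory=EnergyBudget)
    ros_backend: str = "phenomenological"  #: "phenomenological" | "mito"
    # phenomenological backend
    tau_atp: float = 15.0      #: ATP relaxation time constant (ms)
    tau_ros: float = 50.0      #: ROS relaxation time constant (ms)
    tau_c: float = 50.0        #: consumption low-pass for the ROS target (ms)
    c_max: float = 0.06        #: consumption at which ATP is fully depleted
    c_bar: float = 0.015       #: consumption rate at the ROS minimum
    ros_min: float = 0.1       #: ROS floor at the bottom of the V
    ros_slope: float = 30.0    #: ROS rise per unit consumption deviation from c_bar
    ros_quench: float = 0.05   #: fractional ROS drop per spike (Ca2+-driven quench)
    tau_ms: float = 15.0       #: MS sensing lag (ms); 0 = instantaneous readout
    # mito backend
    mito_params: MitoParams = field(default_factory=MitoParams)

    def __post_init__(self):
        if not self.theta_ret > self.theta_fet:
            raise DomainError("theta_ret must exceed theta_fet")
        if self.refractory <= 0:
            raise DomainError("refractory must be > 0")
        if self.ros_backend not in ("phenomenological", "mito"):
            raise DomainError(f"unknown ros_backend {self.ros_backend!r}")

    def atp_target(self, consumption: float) -> float:
        return min(1.0, max(0.0, 1.0 - consumption / self.c_max))

    def ros_target(self, c_slow: float) -> float:
        """V-shaped ROS production versus sustained consumption.

        The argument is the low-pass-filtered consumption rate (ROS
        production responds to sustained demand, not to single 5-ms
        spike kernels): below ``c_bar`` the ETC stalls (RETROS side),
        above it the chain is hard-driven (FETROS side), and the minimum
        sits at the reference expenditure ``c_bar``.
        """
        return self.ros_min + self.ros_slope * abs(c_slow - self.c_bar)


@dataclass(frozen=True)
class AccountingState:
    """Bookkeeping variables of the accounting neuron at one instant."""

    atp: float
    ros: float
    ms: float
    c_slow: float = 0.0             #: low-pass-filtered consumption rate
    refractory_remaining: float = 0.0
    kernel_remaining: float = 0.0   #: ms left on the active per-spike cost kernel
    t: float = 0.0

    def __post_init__(self):
        if self.refractory_remaining < 0:
            raise DomainError("refractory_remaining must be >= 0")


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times with per-spike labels ('metabolic' or 'synaptic')."""

    times: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=object))
        if len(self.times) != len(self.labels):
            raise DomainError("times and labels must align")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise DomainError("spike times must be strictly increasing")

    def __len__(self):
        return len(self.times)

    def rate_hz(self, duration_ms: float) -> float:
        return 1000.0 * len(self.times) / duration_ms if duration_ms > 0 else 0.0


def metabolic_signal(ros: float, atp: float, atp_bar: float) -> float:
    """MS = ROS x (ATP - ATP_bar); the signed readout of metabolic state."""
    return ros * (atp - atp_bar)


def initial_state(params: AccountingParams) -> AccountingState:
    """Rest state at the baseline consumption (before any spiking)."""
    c = params.budget.baseline_cost
    atp = params.atp_target(c)
    ros = params.ros_target(c)
    return AccountingState(atp=atp, ros=ros, c_slow=c,
                           ms=metabolic_signal(ros, atp, params.atp_bar))


def step_accounting(state: AccountingState, params: AccountingParams,
                    input_drive: bool, dt: float = 0.1):
    """Advance one step; returns ``(new_state, spike_label_or_None)``.

    Consumption for the step is the baseline plus the active spike-cost
    kernel; ATP and ROS follow exact exponential relaxation toward their
    consumption-dependent targets.  Spike emission is evaluated on the
    updated MS, and a spike starts both the refractory clock and a fresh
    cost kernel.  (With ``refractory >= q_kernel_duration`` — the
    default — kernels never overlap; a new spike otherwise restarts the
    kernel rather than stacking it.)
    """
    b = params.budget
    c = b.baseline_cost + (b.q / b.q_kernel_duration if state.kernel_remaining > 0 else 0.0)
    atp_inf = params.atp_target(c)
    atp = atp_inf + (state.atp - atp_inf) * math.exp(-dt / params.tau_atp)
    c_slow = c + (state.c_slow - c) * math.exp(-dt / params.tau_c)
    ros_inf = params.ros_target(c_slow)
    ros = ros_inf + (state.ros - ros_inf) * math.exp(-dt / params.tau_ros)
    ms_now = metabolic_signal(ros, atp, params.atp_bar)
    if params.tau_ms > 0:
        # the spike-initiation machinery senses MS through first-order
        # messenger kinetics; the lag lets MS swing across the thresholds
        # instead of riding them, producing burst-patterned quenching
        ms = ms_now + (state.ms - ms_now) * math.exp(-dt / params.tau_ms)
    else:
        ms = ms_now

    label = None
    refractory = max(0.0, state.refractory_remaining - dt)
    kernel = max(0.0, state.kernel_remaining - dt)
    if state.refractory_remaining <= 0.0 and ms > params.theta_fet:
        if ms > params.theta_ret:
            label = "metabolic"
        elif input_drive:
            label = "synaptic"
    if label is not None:
        refractory = params.refractory
        kernel = b.q_kernel_duration
        # calcium influx during the spike partially collapses the proton
        # gradient, instantly quenching a fraction of ROS production
        ros *= 1.0 - params.ros_quench
        if params.tau_ms <= 0:
            ms = metabolic_signal(ros, atp, params.atp_bar)
    new = AccountingState(atp=atp, ros=ros, ms=ms, c_slow=c_slow,
                          refractory_remaining=refractory,
                          kernel_remaining=kernel, t=state.t + dt)
    return new, label


def _simulate_mito_backend(params, duration, drive, dt, metabolic_enabled):
    """Closed loop with the full mitochondrial ODE as the ROS/ATP source."""
    y = find_steady_state(params.mito_params, params.budget.baseline_cost).as_array()
    b = params.budget
    n = len(drive)
    times, labels = [], []
    traces = np.empty((n, 4))
    cons_hist = np.empty(n)
    refractory = 0.0
    kernel = 0.0
    for i in range(n):
        c = b.baseline_cost + (b.q / b.q_kernel_duration if kernel > 0 else 0.0)
        cons_hist[i] = c
        y = _rk4_step(y, params.mito_params, c, dt)
        atp, ros = float(y[4]), float(y[5])
        ms = metabolic_signal(ros, atp, params.atp_bar)
        label = None
        if refractory <= 0.0 and ms > params.theta_fet:
            if ms > params.theta_ret and metabolic_enabled:
                label = "metabolic"
            elif drive[i]:
                label = "synaptic"
        refractory = max(0.0, refractory - dt)
        kernel = max(0.0, kernel - dt)
        if label is not None:
            times.append((i + 1) * dt)
            labels.append(label)
            refractory = params.refractory
            kernel = b.q_kernel_duration
            y[2] = max(0.0, y[2] - params.mito_params.ca_coupling)
            y[6] += 1.0
        traces[i] = ((i + 1) * dt, atp, ros, ms)
    df = pd.DataFrame(traces, columns=["time_ms", "atp", "ros", "ms"])
    df["consumption"] = cons_hist
    return SpikeTrain(np.array(times), np.array(labels, dtype=object)), df


def simulate_accounting(params: AccountingParams, duration: float,
                        input_times=None, seed: int | None = None, *,
                        dt: float = 0.1, sustained_input: bool = False,
                        input_pulse_ms: float = 2.0,
                        metabolic_enabled: bool = True):
    """Closed-loop run of the accounting neuron.

    ``input_times`` marks moments of suprathreshold external drive (each
    opens a window of ``input_pulse_ms``); ``sustained_input`` drives
    every step instead.  ``metabolic_enabled=False`` disables the
    self-initiated (MS > theta_ret) pathway, which is the ablation used
    to measure how much metabolic spiking actually lowers ROS.  The run
    is deterministic given its inputs; ``seed`` is accepted for
    interface symmetry with the stochastic modules and ignored here.

    Returns ``(SpikeTrain, traces)`` with traces on the fixed dt grid
    (columns ``time_ms, atp, ros, ms``).
    """
    if duration <= 0:
        raise DomainError("duration must be > 0")
    n = int(round(duration / dt))
    drive = np.zeros(n, dtype=bool)
    if sustained_input:
        drive[:] = True
    elif input_times is not None:
        for t0 in np.atleast_1d(np.asarray(input_times, dtype=float)):
            i0 = int(round(t0 / dt))
            drive[max(0, i0): i0 + max(1, int(round(input_pulse_ms / dt)))] = True

    if params.ros_backend == "mito":
        return _simulate_mito_backend(params, duration, drive, dt, metabolic_enabled)

    state = initial_state(params)
    times, labels = [], []
    traces = np.empty((n, 4))
    gate = params if metabolic_enabled else replace(params, theta_ret=np.inf)
    for i in range(n):
        state, label = step_accounting(state, gate, bool(drive[i]), dt)
        if label is not None:
            times.append(state.t)
            labels.append(label)
        traces[i] = (state.t, state.atp, state.ros, state.ms)
    df = pd.DataFrame(traces, columns=["time_ms", "atp", "ros", "ms"])
    return SpikeTrain(np.array(times), np.array(labels, dtype=object)), df


@dataclass(frozen=True)
class PatternCriteria:
    """Quantitative cutoffs for the firing-pattern classifier.

    The labels are defined operationally: *silent* below a rate floor;
    *continuous* when firing never pauses (no gap beyond a small factor
    of the median ISI) at a sustained rate; *bursting* when long gaps
    separate runs of short ISIs (clearly bimodal ISI distribution);
    *tonic* otherwise.
    """

    silent_rate_hz: float = 0.1
    continuous_rate_hz: float = 20.0
    continuous_gap_factor: float = 2.0
    burst_gap_factor: float = 5.0
    burst_ratio: float = 5.0


def classify_pattern(train: SpikeTrain, duration: float,
                     criteria: PatternCriteria | None = None) -> str:
    """Deterministic firing-pattern label from rate and ISI statistics."""
    cr = criteria or PatternCriteria()
    rate = train.rate_hz(duration)
    if rate < cr.silent_rate_hz:
        return "silent"
    if len(train) < 3:
        return "tonic"
    isi = np.diff(train.times)
    med = float(np.median(isi))
    if rate >= cr.continuous_rate_hz and isi.max() <= cr.continuous_gap_factor * med:
        return "continuous"
    gaps = isi > cr.burst_gap_factor * med
    if gaps.any():
        in_burst = isi[~gaps]
        if in_burst.size and isi[gaps].mean() >= cr.burst_ratio * in_burst.mean():
            return "bursting"
    return "tonic"


def phase_diagram(params_base: AccountingParams, baseline_grid, q_grid, *,
                  input_drive: bool = False, duration: float = 2000.0,
                  dt: float = 0.1, criteria: PatternCriteria | None = None,
                  seed: int | None = None) -> np.ndarray:
    """Firing-pattern label over a (baseline cost, Q) grid.

    The RETROS variant (``input_drive=False``) probes intrinsic firing;
    the FETROS variant (``input_drive=True``) applies sustained external
    drive.  Returns an object array of labels with shape
    ``(len(q_grid), len(baseline_grid))`` — Q down the rows.
    """
    baseline_grid = np.asarray(baseline_grid, dtype=float)
    q_grid = np.asarray(q_grid, dtype=float)
    if baseline_grid.size == 0 or q_grid.size == 0:
        raise DomainError("grids must be nonempty")
    labels = np.empty((q_grid.size, baseline_grid.size), dtype=object)
    for i, q in enumerate(q_grid):
        for j, b in enumerate(baseline_grid):
            p = replace(params_base,
                        budget=replace(params_base.budget, baseline_cost=float(b), q=float(q)))
            train, _ = simulate_accounting(p, duration, dt=dt, seed=seed,
                                           sustained_input=input_drive)
            labels[i, j] = classify_pattern(train, duration, criteria)
    return labels
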