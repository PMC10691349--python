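"""Extended mitochondrial respiration model with ROS dynamics.

The model is a minimal six-variable backbone of oxidative ATP production
— pyruvate supply, NADH generation in the TCA cycle, proton pumping by
the electron transport chain (ETC), ATP synthesis at complex V, ANT
exchange of mitochondrial ATP for cytosolic ADP, and proton leak — with
reactive-oxygen-species (ROS) production layered on top.  Electron flux
(pumping) and ATP flux (synthesis) are coupled only through the proton
gradient ``delta_psi``, which is what produces the two characteristic
corners of the respiratory state space:

* low demand stalls complex V, ``atp_m`` and ``delta_psi`` saturate high
  (reverse-electron-transport ROS, "RETROS" corner);
* high demand drains both (forward-electron-transport ROS, "FETROS"
  corner).

Instantaneous ROS relaxes with time constant ``tau_ros`` toward a steady
state set by a cubic function of mitochondrial ATP fraction and the
proton gradient::

    ROS_inf(atp_m, dpsi) = (atp_m * dpsi * f_ret
                            + (1 - atp_m) * (1 - dpsi) * f_fet) ** 3

so ROS is high in both corners and minimal at an intermediate demand:
the V-shaped ROS-versus-consumption curve.

All pools are normalized (fractions in [0, 1] where a conserved partner
exists: ``adp_m = 1 - atp_m``, ``nad = 1 - nadh``); rate constants are
per millisecond.  Physical units (mM, mV) are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .errors import DomainError, IntegrationError, SteadyStateError

__all__ = [
    "MitoParams",
    "MitoState",
    "EnergyBudget",
    "RespiratoryTrajectory",
    "ros_steady_state",
    "relax_ros",
    "step",
    "find_steady_state",
    "spike_excursion",
    "ros_vs_baseline_curve",
    "spike_effect_on_ros",
    "DEFAULT_BASELINE_GRID",
    "RETROS_BASELINE",
    "FETROS_BASELINE",
]

#: Default grid of baseline (non-spiking) ATP consumption rates, spanning
#: the RETROS corner through the ROS minimum into the FETROS regime.
DEFAULT_BASELINE_GRID = np.linspace(0.001, 0.04, 50)

#: Reference baselines used throughout examples and tests: a low-demand
#: operating point well inside the RETROS region and a high-demand one in
#: the FETROS region (the "black" and "gold" stars of the state space).
RETROS_BASELINE = 0.005
FETROS_BASELINE = 0.03

_STATE_FIELDS = ("pyr", "nadh", "delta_psi", "atp_m", "atp_c", "ros", "ca_m")


@dataclass(frozen=True)
class MitoParams:
    """Rate constants and ROS parameters of the respiration backbone.

    All rates are per millisecond on normalized pools.  Defaults are
    calibrated so that the steady-state ROS curve over the default
    baseline grid is V-shaped with its minimum at an interior demand,
    and so that spiking from the RETROS corner lowers ROS.
    """

    f_ret: float = 1.0       #: RETROS gain in the cubic ROS formula
    f_fet: float = 1.0       #: FETROS gain in the cubic ROS formula
    tau_ros: float = 50.0    #: ROS relaxation time constant (ms)
    k_pyr: float = 0.02      #: pyruvate supply rate (saturating at pyr_max)
    pyr_max: float = 2.0     #: pyruvate pool capacity
    k_tca: float = 0.05      #: NADH production rate via the TCA cycle
    k_etc: float = 0.1       #: proton-pumping rate per NADH oxidised
    k_atp: float = 0.1       #: ATP-synthesis rate through complex V
    k_ant: float = 0.5       #: ANT exchange rate (ATP_M out, ADP_C in)
    k_leak: float = 0.002    #: proton leak rate
    p_etc: float = 1.0       #: protons pumped per unit ETC flux
    p_syn: float = 1.0       #: protons consumed per unit ATP synthesized
    ca_coupling: float = 0.01  #: delta_psi decrement per unit Ca2+ influx (per spike)
    tau_ca: float = 100.0    #: matrix calcium clearance time constant (ms)

    def __post_init__(self):
        for name in ("f_ret", "f_fet", "k_pyr", "k_tca", "k_etc", "k_atp",
                     "k_ant", "k_leak", "p_etc", "p_syn", "ca_coupling"):
            if getattr(self, name) < 0:
                raise DomainError(f"MitoParams.{name} must be >= 0")
        for name in ("tau_ros", "tau_ca", "pyr_max"):
            if getattr(self, name) <= 0:
                raise DomainError(f"MitoParams.{name} must be > 0")


@dataclass(frozen=True)
class MitoState:
    """Instantaneous metabolic state.

    ``adp_m`` and ``nad`` are derived, not stored, so the adenine and
    NAD pools are conserved exactly by construction.
    """

    pyr: float
    nadh: float
    delta_psi: float
    atp_m: float
    atp_c: float
    ros: float
    ca_m: float = 0.0

    @property
    def adp_m(self) -> float:
        return 1.0 - self.atp_m

    @property
    def nad(self) -> float:
        return 1.0 - self.nadh

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _STATE_FIELDS])

    @classmethod
    def from_array(cls, y) -> "MitoState":
        return cls(**dict(zip(_STATE_FIELDS, map(float, y))))


@dataclass(frozen=True)
class EnergyBudget:
    """Baseline (non-spiking) ATP consumption plus the per-spike cost Q.

    ``q`` is the total excess ATP consumed per action potential, spread
    over ``q_kernel_duration`` ms after each spike.  The rectangular
    kernel is the default; an exponential profile with the same integral
    is available.
    """

    baseline_cost: float = RETROS_BASELINE  #: non-spiking consumption (ATP/ms)
    q: float = 0.05                         #: per-spike ATP cost (total)
    q_kernel_duration: float = 5.0          #: kernel window (ms)
    q_kernel_shape: str = "rectangular"     #: "rectangular" | "exponential"

    def __post_init__(self):
        if self.baseline_cost < 0:
            raise DomainError("EnergyBudget.baseline_cost must be >= 0")
        if self.q < 0:
            raise DomainError("EnergyBudget.q must be >= 0")
        if self.q_kernel_duration <= 0:
            raise DomainError("EnergyBudget.q_kernel_duration must be > 0")
        if self.q_kernel_shape not in ("rectangular", "exponential"):
            raise DomainError(
                f"unknown q_kernel_shape {self.q_kernel_shape!r}")


@dataclass
class RespiratoryTrajectory:
    """A time-aligned sequence of metabolic states."""

    times: np.ndarray                 #: strictly increasing (ms)
    values: np.ndarray                #: shape (len(times), 7), columns _STATE_FIELDS

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise DomainError("times and states must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise DomainError("times must be strictly increasing")

    def state(self, i: int) -> MitoState:
        return MitoState.from_array(self.values[i])

    @property
    def states(self) -> list[MitoState]:
        return [MitoState.from_array(v) for v in self.values]

    def __getattr__(self, name):
        if name in _STATE_FIELDS:
            return self.values[:, _STATE_FIELDS.index(name)]
        raise AttributeError(name)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values[:, :6], columns=_STATE_FIELDS[:6])
        df.insert(0, "time_ms", self.times)
        return df


def ros_steady_state(atp_m, delta_psi, params: MitoParams):
    """Steady-state ROS level for given ATP fraction and proton gradient.

    Vectorized over ``atp_m`` / ``delta_psi``.  Both corners of the
    respiratory state space produce ROS: the (1,1) corner through the
    ``f_ret`` term, the (0,0) corner through ``f_fet``.
    """
    a = np.asarray(atp_m, dtype=float)
    p = np.asarray(delta_psi, dtype=float)
    if np.any(a < 0) or np.any(a > 1) or np.any(p < 0) or np.any(p > 1):
        raise DomainError("atp_m and delta_psi must lie in [0, 1]")
    val = (a * p * params.f_ret + (1.0 - a) * (1.0 - p) * params.f_fet) ** 3
    return float(val) if val.ndim == 0 else val


def relax_ros(ros: float, ros_inf: float, tau_ros: float, dt: float) -> float:
    """One exact relaxation step of dROS/dt = (ROS_inf - ROS) / tau_ros.

    The exponential update is exact for a frozen target, so the result
    always lies between ``ros`` and ``ros_inf``.
    """
    if tau_ros <= 0 or dt <= 0:
        raise DomainError("tau_ros and dt must be > 0")
    return ros_inf + (ros - ros_inf) * math.exp(-dt / tau_ros)


def _deriv(y: np.ndarray, params: MitoParams, consumption_rate) -> np.ndarray:
    """Time derivative of the state vector; vectorized over a trailing batch axis."""
    pyr, nadh, psi, a, c, ros, ca = y
    pr = params
    j_sup = pr.k_pyr * (1.0 - pyr / pr.pyr_max)
    j_tca = pr.k_tca * pyr * (1.0 - nadh)
    j_etc = pr.k_etc * nadh * (1.0 - psi)
    j_syn = pr.k_atp * psi * (1.0 - a)
    j_ant = pr.k_ant * a * (1.0 - c)
    ros_inf = (a * psi * pr.f_ret + (1.0 - a) * (1.0 - psi) * pr.f_fet) ** 3
    return np.array([
        j_sup - j_tca,
        j_tca - j_etc,
        pr.p_etc * j_etc - pr.p_syn * j_syn - pr.k_leak * psi,
        j_syn - j_ant,
        j_ant - consumption_rate * c,
        (ros_inf - ros) / pr.tau_ros,
        -ca / pr.tau_ca,
    ])


_BOUNDS_TOL = 1e-9


def _check_bounds(y: np.ndarray, t: float | None = None):
    """Raise if any fractional pool left its admissible interval."""
    pyr, nadh, psi, a, c, ros, ca = y
    checks = [
        ("pyr", pyr, 0.0, None), ("nadh", nadh, 0.0, 1.0),
        ("delta_psi", psi, 0.0, 1.0), ("atp_m", a, 0.0, 1.0),
        ("atp_c", c, 0.0, 1.0), ("ros", ros, 0.0, None),
        ("ca_m", ca, 0.0, None),
    ]
    for name, v, lo, hi in checks:
        bad = np.any(v < lo - _BOUNDS_TOL) or (hi is not None and np.any(v > hi + _BOUNDS_TOL))
        if bad:
            where = "" if t is None else f" at t = {t:g} ms"
            raise IntegrationError(
                f"state variable {name!r} left its bounds{where}; "
                "use a smaller dt or check parameters")


def _rk4_step(y: np.ndarray, params: MitoParams, cons, dt: float) -> np.ndarray:
    k1 = _deriv(y, params, cons)
    k2 = _deriv(y + 0.5 * dt * k1, params, cons)
    k3 = _deriv(y + 0.5 * dt * k2, params, cons)
    k4 = _deriv(y + dt * k3, params, cons)
    return y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def step(state: MitoState, params: MitoParams, consumption_rate: float,
         dt: float = 0.01) -> MitoState:
    """Advance the full state one fixed 4th-order Runge-Kutta step.

    The adenine and NAD pools are conserved exactly because only the ATP
    fractions are integrated; a step that drives any fraction outside
    [0, 1] raises :class:`IntegrationError` rather than clipping.
    """
    if dt <= 0:
        raise DomainError("dt must be > 0")
    if consumption_rate < 0:
        raise DomainError("consumption_rate must be >= 0")
    y = _rk4_step(state.as_array(), params, consumption_rate, dt)
    _check_bounds(y)
    return MitoState.from_array(y)


_STANDARD_INIT = np.array([1.0, 0.5, 0.5, 0.5, 0.5, 0.1, 0.0])


def find_steady_state(params: MitoParams, baseline, *,
                      tol: float = 1e-9, t_max: float = 5e5) -> MitoState:
    """Fixed point of the backbone at a given baseline consumption rate.

    Integrates from a standard initial condition until transients decay,
    then polishes with a Newton-type root solve.  ``baseline`` may be an
    :class:`EnergyBudget` (its ``baseline_cost`` is used) or a rate.

    Raises
    ------
    SteadyStateError
        If the residual time-derivative exceeds ``tol``.
    """
    b = baseline.baseline_cost if isinstance(baseline, EnergyBudget) else float(baseline)
    if b < 0:
        raise DomainError("baseline consumption must be >= 0")

    def rhs(t, y):
        return _deriv(y, params, b)

    sol = solve_ivp(rhs, (0.0, t_max), _STANDARD_INIT, method="LSODA",
                    rtol=1e-10, atol=1e-12)
    y = sol.y[:, -1]
    res = root(lambda x: _deriv(x, params, b), y, tol=1e-13)
    if res.success:
        y = res.x
    resid = float(np.abs(_deriv(y, params, b)).max())
    if resid > tol:
        raise SteadyStateError(
            f"fixed-point residual {resid:.3e} exceeds tolerance {tol:g} "
            f"at baseline {b:g}")
    _check_bounds(y)
    y[6] = 0.0  # no calcium influx at rest
    return MitoState.from_array(y)


def _consumption_series(budget: EnergyBudget, spike_times, n_steps: int,
                        dt: float) -> np.ndarray:
    """Per-step consumption rate: baseline plus the per-spike kernels."""
    cons = np.full(n_steps, budget.baseline_cost)
    dur = budget.q_kernel_duration
    for ts in np.atleast_1d(np.asarray(spike_times, dtype=float)):
        i0 = int(round(ts / dt))
        if budget.q_kernel_shape == "rectangular":
            i1 = min(n_steps, i0 + max(1, int(round(dur / dt))))
            if i0 < n_steps:
                cons[i0:i1] += budget.q / dur
        else:  # exponential with time constant dur/3, same integral q
            tau_k = dur / 3.0
            idx = np.arange(i0, n_steps)
            cons[idx] += (budget.q / tau_k) * np.exp(-(idx - i0) * dt / tau_k)
    return cons


def spike_excursion(params: MitoParams, budget: EnergyBudget,
                    spike_times, duration: float, *,
                    dt: float = 0.01, record_every: int = 10) -> RespiratoryTrajectory:
    """Trajectory through respiratory state space driven by a spike train.

    Starts at the baseline steady state; each spike adds its cost Q
    (spread over the kernel) to consumption and decrements the proton
    gradient by ``ca_coupling`` (calcium influx into the matrix).
    """
    spike_times = np.sort(np.atleast_1d(np.asarray(spike_times, dtype=float)))
    if spike_times.size and (spike_times.min() < 0 or spike_times.max() > duration):
        raise DomainError("spike_times must lie within [0, duration]")
    y = find_steady_state(params, budget).as_array()
    n_steps = int(round(duration / dt))
    cons = _consumption_series(budget, spike_times, n_steps, dt)
    kick_steps = np.unique(np.round(spike_times / dt).astype(int))
    kicks = np.zeros(n_steps + 1)
    counts = np.bincount(kick_steps[kick_steps <= n_steps], minlength=n_steps + 1)
    kicks[: len(counts)] = counts

    times = [0.0]
    recs = [y.copy()]
    for i in range(n_steps):
        if kicks[i]:
            y = y.copy()
            y[2] = max(0.0, y[2] - params.ca_coupling * kicks[i])
            y[6] += kicks[i]
        y = _rk4_step(y, params, cons[i], dt)
        if (i + 1) % record_every == 0 or i == n_steps - 1:
            _check_bounds(y, t=(i + 1) * dt)
            times.append((i + 1) * dt)
            recs.append(y.copy())
    return RespiratoryTrajectory(np.array(times), np.array(recs))


def ros_vs_baseline_curve(params: MitoParams, baseline_grid=None) -> pd.DataFrame:
    """Steady-state ROS (and the fixed point) across baseline consumption rates.

    Returns a DataFrame with columns ``baseline, atp_m_ss, delta_psi_ss,
    ros_ss``; the ``baseline`` at which ``ros_ss`` is minimal is the
    demand rate at which ROS production bottoms out between the RETROS
    and FETROS regimes.
    """
    grid = DEFAULT_BASELINE_GRID if baseline_grid is None else np.asarray(baseline_grid, dtype=float)
    rows = []
    for b in grid:
        ss = find_steady_state(params, b)
        rows.append((b, ss.atp_m, ss.delta_psi, ss.ros))
    return pd.DataFrame(rows, columns=["baseline", "atp_m_ss", "delta_psi_ss", "ros_ss"])


def min_ros_baseline(curve: pd.DataFrame) -> float:
    """Baseline consumption rate minimizing steady-state ROS on a computed curve."""
    return float(curve["baseline"].iloc[int(curve["ros_ss"].idxmin())])


def _integrate_batch(y0: np.ndarray, params: MitoParams, cons: np.ndarray,
                     dt: float, kicks: np.ndarray | None = None) -> np.ndarray:
    """Integrate a batch of trajectories; returns ROS traces, shape (n_steps+1, m).

    ``y0`` has shape (7, m) and ``cons`` shape (n_steps, m).  Used
    internally where many conditions share a clock (seed sweeps).
    """
    y = y0.copy()
    n_steps = cons.shape[0]
    ros_trace = np.empty((n_steps + 1, y.shape[1]))
    ros_trace[0] = y[5]
    check_every = max(1, int(round(1.0 / dt)))
    for i in range(n_steps):
        if kicks is not None:
            k = kicks[i]
            y[2] = np.maximum(0.0, y[2] - params.ca_coupling * k)
            y[6] += k
        y = _rk4_step(y, params, cons[i], dt)
        ros_trace[i + 1] = y[5]
        if (i + 1) % check_every == 0:
            _check_bounds(y, t=(i + 1) * dt)
    _check_bounds(y)
    return ros_trace


def spike_effect_on_ros(params: MitoParams, budget: EnergyBudget, *,
                        spike_rate_hz: float = 20.0, duration: float = 3000.0,
                        transient: float = 500.0, dt: float = 0.05,
                        seed: int | None = None) -> float:
    """Signed change in time-averaged ROS caused by additional spiking.

    Runs the model from the baseline steady state twice over an
    identical window — once silent, once with spikes (periodic at
    ``spike_rate_hz`` by default, Poisson when ``seed`` is given) — and
    returns ``mean ROS with spiking - mean ROS without`` after the
    transient.  Negative from the RETROS corner (spiking quenches ROS),
    positive from the FETROS corner.
    """
    from .stimuli import periodic_times, poisson_fixture

    if seed is None:
        spikes = periodic_times(spike_rate_hz, duration)
    else:
        spikes = poisson_fixture(spike_rate_hz, duration, 1, seed)[0]
    ss = find_steady_state(params, budget).as_array()
    n_steps = int(round(duration / dt))
    cons = np.stack([
        np.full(n_steps, budget.baseline_cost),
        _consumption_series(budget, spikes, n_steps, dt),
    ], axis=1)
    kicks = np.zeros((n_steps, 2))
    idx = np.round(spikes / dt).astype(int)
    idx = idx[idx < n_steps]
    np.add.at(kicks[:, 1], idx, 1.0)
    y0 = np.stack([ss, ss], axis=1)
    ros = _integrate_batch(y0, params, cons, dt, kicks)
    i0 = int(round(transient / dt))
    return float(ros[i0:, 1].mean() - ros[i0:, 0].mean())
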