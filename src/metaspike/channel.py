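"""Hodgkin-Huxley neuron with a ROS-modulated A-type potassium current.

A single-compartment model with transient sodium, delayed-rectifier
potassium, leak, and an A-type potassium conductance in the
Connor-Stevens tradition (fast activation ``a``, inactivation ``hA``).
The continuous parameter ``rho`` in [0, 1] interpolates the A-type
channel between its ordinary fast-inactivating behaviour (``rho = 0``)
and the non-inactivating behaviour seen when ROS scavenging strips the
inactivation mechanism from the channel's beta subunits (``rho = 1``)::

    I_A = g_a * a**3 * hA_eff * (V - e_k),   hA_eff = (1 - rho) * hA + rho

With inactivation removed, the fast A current dominates spike
repolarisation, out-competing the slower delayed rectifier; spikes
narrow, the after-hyperpolarisation driven by the slow K current
shrinks, and inter-spike intervals shorten — firing rate increases
with ``rho`` under fixed current injection.

Units are absolute: mV, ms, pA, nS, pF (a ~200 um^2 membrane patch).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DomainError, IntegrationError

__all__ = [
    "ChannelParams",
    "HHState",
    "ClampProtocol",
    "RosCurveShift",
    "step_hh",
    "resting_state",
    "voltage_clamp",
    "current_clamp",
    "detect_spikes",
    "ros_to_rho",
    "shifted_ros_curve",
]


@dataclass(frozen=True)
class ChannelParams:
    """Conductances, reversals, and A-type kinetics of the model neuron.

    The voltage shifts on the A-type curves position its activation so
    the current engages during the action potential rather than at
    sub-threshold voltages; all kinetics can be overridden from config.
    """

    c_m: float = 2.0          #: membrane capacitance (pF)
    g_na: float = 240.0       #: nS
    g_k: float = 40.0         #: delayed-rectifier K, nS
    g_a: float = 150.0        #: A-type K, nS
    g_leak: float = 0.7       #: nS
    e_na: float = 55.0        #: mV
    e_k: float = -72.0        #: mV
    e_leak: float = -70.0     #: mV
    rho: float = 0.0          #: 0 = inactivating, 1 = non-inactivating A-type
    rho_mode: str = "gate_removal"   #: "gate_removal" | "slow_tau"
    slow_tau_factor: float = 50.0    #: tau_hA multiplier at rho = 1 (slow_tau mode)
    # A-type kinetics (Boltzmann steady states, fixed time constants) —
    # high-threshold activation so the current engages during the spike
    # rather than at sub-threshold voltages
    a_v_half: float = -30.0   #: activation midpoint (mV)
    a_slope: float = 8.0      #: activation slope (mV)
    tau_a: float = 0.6        #: activation time constant (ms)
    ha_v_half: float = -74.0  #: inactivation midpoint (mV)
    ha_slope: float = 5.0     #: inactivation slope (mV)
    tau_ha: float = 5.0       #: inactivation time constant (ms)
    n_tau_scale: float = 4.0  #: slow-down factor on the delayed-rectifier gate
    spike_threshold: float = 0.0     #: detection threshold (mV)
    spike_refractory: float = 2.0    #: detection dedup window (ms)

    def __post_init__(self):
        for name in ("c_m", "g_na", "g_k", "g_a", "g_leak"):
            if getattr(self, name) < 0:
                raise DomainError(f"ChannelParams.{name} must be >= 0")
        if not 0.0 <= self.rho <= 1.0:
            raise DomainError("rho must lie in [0, 1]")
        if self.rho_mode not in ("gate_removal", "slow_tau"):
            raise DomainError(f"unknown rho_mode {self.rho_mode!r}")


@dataclass(frozen=True)
class HHState:
    """Membrane potential and gating variables (all gates in [0, 1])."""

    v: float
    m: float
    h: float
    n: float
    a: float
    ha: float

    def as_array(self) -> np.ndarray:
        return np.array([self.v, self.m, self.h, self.n, self.a, self.ha])

    @classmethod
    def from_array(cls, y) -> "HHState":
        return cls(*map(float, y))


@dataclass(frozen=True)
class ClampProtocol:
    """A sequence of command segments for voltage or current clamp."""

    mode: str                          #: "voltage" | "current"
    segments: tuple                    #: ((duration_ms, command), ...) mV or pA
    holding: float = -70.0             #: pre-protocol command value

    def __post_init__(self):
        if self.mode not in ("voltage", "current"):
            raise DomainError(f"unknown clamp mode {self.mode!r}")
        for d, _ in self.segments:
            if d <= 0:
                raise DomainError("segment durations must be > 0")

    @property
    def duration(self) -> float:
        return float(sum(d for d, _ in self.segments))


@dataclass(frozen=True)
class RosCurveShift:
    """Additive offset of the ROS-vs-baseline curve.

    Positive shifts emulate optogenetic ROS delivery (miniSOG-like);
    negative shifts emulate alternative-oxidase overexpression
    (AOX-like), which drains electrons from the ETC.
    """

    offset: float = 0.0


# --- gating kinetics (Connor-Stevens-style rate functions) ------------------

def _exprel(x: float) -> float:
    """x / (1 - exp(-x)), stable near 0."""
    if abs(x) < 1e-6:
        return 1.0 + x / 2.0
    return x / (1.0 - math.exp(-x))


def _alpha_m(v):  # noqa: D103
    return 3.8 * _exprel((v + 29.7) / 10.0)


def _beta_m(v):
    return 15.2 * math.exp(-0.0556 * (v + 54.7))


def _alpha_h(v):
    return 0.266 * math.exp(-0.05 * (v + 48.0))


def _beta_h(v):
    return 3.8 / (1.0 + math.exp(-0.1 * (v + 18.0)))


def _alpha_n(v):
    return 0.2 * _exprel((v + 45.7) / 10.0)


def _beta_n(v):
    return 0.25 * math.exp(-0.0125 * (v + 55.7))


def _a_inf(v, p):
    return 1.0 / (1.0 + math.exp(-(v - p.a_v_half) / p.a_slope))


def _ha_inf(v, p):
    return 1.0 / (1.0 + math.exp((v - p.ha_v_half) / p.ha_slope))


def _currents(y, p: ChannelParams):
    """Ionic currents (pA, outward positive) at state vector ``y``."""
    v, m, h, n, a, ha = y
    if p.rho_mode == "gate_removal":
        ha_eff = (1.0 - p.rho) * ha + p.rho
    else:
        ha_eff = ha
    i_na = p.g_na * m ** 3 * h * (v - p.e_na)
    i_k = p.g_k * n ** 4 * (v - p.e_k)
    i_a = p.g_a * a ** 3 * ha_eff * (v - p.e_k)
    i_leak = p.g_leak * (v - p.e_leak)
    return i_na, i_k, i_a, i_leak


def _deriv(y, p: ChannelParams, i_inj: float):
    v, m, h, n, a, ha = y
    i_na, i_k, i_a, i_leak = _currents(y, p)
    dv = (i_inj - i_na - i_k - i_a - i_leak) / p.c_m
    dm = _alpha_m(v) * (1.0 - m) - _beta_m(v) * m
    dh = _alpha_h(v) * (1.0 - h) - _beta_h(v) * h
    dn = (_alpha_n(v) * (1.0 - n) - _beta_n(v) * n) / p.n_tau_scale
    da = (_a_inf(v, p) - a) / p.tau_a
    tau_ha = p.tau_ha
    if p.rho_mode == "slow_tau":
        tau_ha *= 1.0 + p.rho * (p.slow_tau_factor - 1.0)
    dha = (_ha_inf(v, p) - ha) / tau_ha
    return (dv, dm, dh, dn, da, dha)


_GATE_TOL = 1e-6


def step_hh(state: HHState, params: ChannelParams, i_inj: float,
            dt: float = 0.01) -> HHState:
    """One fixed 4th-order Runge-Kutta step of the full membrane equation."""
    y = state.as_array()
    k1 = np.array(_deriv(y, params, i_inj))
    k2 = np.array(_deriv(y + 0.5 * dt * k1, params, i_inj))
    k3 = np.array(_deriv(y + 0.5 * dt * k2, params, i_inj))
    k4 = np.array(_deriv(y + dt * k3, params, i_inj))
    out = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    if np.any(out[1:] < -_GATE_TOL) or np.any(out[1:] > 1.0 + _GATE_TOL):
        raise IntegrationError("a gating variable left [0, 1]; use a smaller dt")
    return HHState.from_array(out)


def _steady_gates(v: float, p: ChannelParams):
    m = _alpha_m(v) / (_alpha_m(v) + _beta_m(v))
    h = _alpha_h(v) / (_alpha_h(v) + _beta_h(v))
    n = _alpha_n(v) / (_alpha_n(v) + _beta_n(v))
    return m, h, n, _a_inf(v, p), _ha_inf(v, p)


def resting_state(params: ChannelParams, *, v0: float = -68.0,
                  settle_ms: float = 500.0, dt: float = 0.02) -> HHState:
    """Relax to the zero-input fixed point from a hyperpolarized start."""
    s = HHState(v0, *_steady_gates(v0, params))
    y = s.as_array()
    for _ in range(int(round(settle_ms / dt))):
        k1 = np.array(_deriv(y, params, 0.0))
        k2 = np.array(_deriv(y + 0.5 * dt * k1, params, 0.0))
        k3 = np.array(_deriv(y + 0.5 * dt * k2, params, 0.0))
        k4 = np.array(_deriv(y + dt * k3, params, 0.0))
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return HHState.from_array(y)


def _command_series(protocol: ClampProtocol, dt: float):
    vals = []
    for d, v in protocol.segments:
        vals.append(np.full(int(round(d / dt)), float(v)))
    return np.concatenate(vals) if vals else np.empty(0)


def voltage_clamp(params: ChannelParams, protocol: ClampProtocol, *,
                  dt: float = 0.01) -> pd.DataFrame:
    """Gate dynamics and per-channel currents under a voltage command.

    V follows the command exactly; within each segment the gates relax
    exponentially toward their (frozen) steady states, which the
    integrator exploits for exactness.  Returns columns
    ``time_ms, v_mv, i_na, i_k, i_a, i_leak``.
    """
    if protocol.mode != "voltage":
        raise DomainError("voltage_clamp requires a voltage protocol")
    cmd = _command_series(protocol, dt)
    vh = protocol.holding
    m, h, n, a, ha = _steady_gates(vh, params)
    rows = np.empty((cmd.size, 6))
    for i, v in enumerate(cmd):
        # exact exponential update at frozen V
        am, bm = _alpha_m(v), _beta_m(v)
        ah, bh = _alpha_h(v), _beta_h(v)
        an, bn = _alpha_n(v), _beta_n(v)
        m = am / (am + bm) + (m - am / (am + bm)) * math.exp(-dt * (am + bm))
        h = ah / (ah + bh) + (h - ah / (ah + bh)) * math.exp(-dt * (ah + bh))
        n = an / (an + bn) + (n - an / (an + bn)) * math.exp(-dt * (an + bn) / params.n_tau_scale)
        a_inf, ha_inf = _a_inf(v, params), _ha_inf(v, params)
        tau_ha = params.tau_ha
        if params.rho_mode == "slow_tau":
            tau_ha *= 1.0 + params.rho * (params.slow_tau_factor - 1.0)
        a = a_inf + (a - a_inf) * math.exp(-dt / params.tau_a)
        ha = ha_inf + (ha - ha_inf) * math.exp(-dt / tau_ha)
        i_na, i_k, i_a, i_leak = _currents((v, m, h, n, a, ha), params)
        rows[i] = ((i + 1) * dt, v, i_na, i_k, i_a, i_leak)
    return pd.DataFrame(rows, columns=["time_ms", "v_mv", "i_na", "i_k", "i_a", "i_leak"])


def detect_spikes(times: np.ndarray, v: np.ndarray, *, threshold: float = 0.0,
                  refractory: float = 2.0) -> np.ndarray:
    """Upward threshold crossings with refractory deduplication."""
    above = v >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    spikes = []
    last = -np.inf
    for i in crossings:
        if times[i] - last >= refractory:
            spikes.append(times[i])
            last = times[i]
    return np.asarray(spikes)


def current_clamp(params: ChannelParams, protocol: ClampProtocol, *,
                  dt: float = 0.01, record_every: int = 5):
    """Free-running membrane under injected current.

    Returns ``(traces, spike_times)``: traces with columns
    ``time_ms, v_mv, i_na, i_k, i_a, i_leak``, spikes as upward
    crossings of the detection threshold.
    """
    if protocol.mode != "current":
        raise DomainError("current_clamp requires a current protocol")
    cmd = _command_series(protocol, dt)
    y = resting_state(params).as_array()
    n_rec = cmd.size // record_every + 1
    rec_t = np.empty(n_rec)
    rec = np.empty((n_rec, 5))
    full_t = np.empty(cmd.size)
    full_v = np.empty(cmd.size)
    j = 0
    for i, inj in enumerate(cmd):
        k1 = np.array(_deriv(y, params, inj))
        k2 = np.array(_deriv(y + 0.5 * dt * k1, params, inj))
        k3 = np.array(_deriv(y + 0.5 * dt * k2, params, inj))
        k4 = np.array(_deriv(y + dt * k3, params, inj))
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        t = (i + 1) * dt
        full_t[i] = t
        full_v[i] = y[0]
        if i % record_every == 0:
            rec_t[j] = t
            rec[j] = (y[0], *_currents(y, params))
            j += 1
    if np.any(np.asarray(y[1:]) < -_GATE_TOL) or np.any(np.asarray(y[1:]) > 1 + _GATE_TOL):
        raise IntegrationError("a gating variable left [0, 1]; use a smaller dt")
    spikes = detect_spikes(full_t, full_v, threshold=params.spike_threshold,
                           refractory=params.spike_refractory)
    df = pd.DataFrame(rec[:j], columns=["v_mv", "i_na", "i_k", "i_a", "i_leak"])
    df.insert(0, "time_ms", rec_t[:j])
    return df, spikes


def ros_to_rho(ros, *, ros_half: float = 0.5, hill: float = 2.0):
    """Monotone saturating map from ROS level to the inactivation-removal fraction.

    A Hill function: rho(0) = 0, rho -> 1 as ROS -> infinity, midpoint
    at ``ros_half``.
    """
    ros = np.asarray(ros, dtype=float)
    if np.any(ros < 0):
        raise DomainError("ros must be >= 0")
    val = ros ** hill / (ros ** hill + ros_half ** hill)
    return float(val) if val.ndim == 0 else val


def shifted_ros_curve(curve, shift: RosCurveShift):
    """Apply an additive ROS offset to a baseline-vs-ROS curve, floored at 0.

    Accepts either the DataFrame produced by
    :func:`metaspike.mito.ros_vs_baseline_curve` (the ``ros_ss`` column
    is shifted) or a plain array of ROS values.
    """
    if isinstance(curve, pd.DataFrame):
        out = curve.copy()
        out["ros_ss"] = np.maximum(0.0, out["ros_ss"] + shift.offset)
        return out
    arr = np.asarray(curve, dtype=float)
    return np.maximum(0.0, arr + shift.offset)
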