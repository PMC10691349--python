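"""Sparse recurrent conductance-based LIF network with metabolic currents.

The wiring follows the classic sparse balanced-network recipe: 8,000
excitatory and 2,000 inhibitory leaky integrate-and-fire neurons with
exponential synaptic conductances, each neuron receiving input from a
random 2% of the network plus external Poisson drive.  On top of the
standard machinery every neuron carries a metabolic state variable
``MS`` in ``[0, ms_max]`` — a cost-tracking reservoir, full at rest —
that is debited per incoming synaptic event and per emitted spike and
recovers toward ``ms_rest`` with time constant ``tau_ms``.  MS sets a
homeostatic membrane current

    I_M(MS) = clip(im_gain * (MS - ms_neutral), -im_bound, +im_bound)

depolarising when the reservoir is full (quiet neuron, RETROS-like) and
hyperpolarising when drained (hard-driven neuron, FETROS-like).  With
the metabolic current enabled the network keeps firing after external
drive is removed — metabolic spiking recruits the recurrent synapses
into self-sustained, avalanche-structured activity; with ``im_gain = 0``
the same network falls silent.

The default size is the full 8,000/2,000 network; ``scaled_down()``
gives the 800/200 variant (weights rescaled by 1/sqrt(10), per-event
costs by 10) used for routine testing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DomainError, IntegrationError

__all__ = [
    "NetworkConfig",
    "Network",
    "NeuronRecord",
    "RasterWindow",
    "SimResult",
    "build_network",
    "ms_update",
    "i_m_from_ms",
    "simulate",
    "summarize_activity",
    "persistence_time",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Wiring, LIF, synaptic, metabolic, and drive parameters."""

    # size and wiring
    n_exc: int = 8000
    n_inh: int = 2000
    p_connect: float = 0.02
    # LIF membrane
    c_m: float = 200.0         #: pF
    g_leak: float = 10.0       #: nS (tau_m = 20 ms)
    v_rest: float = -60.0      #: mV
    v_thresh: float = -50.0    #: mV
    v_reset: float = -60.0     #: mV
    refractory: float = 5.0    #: ms
    # synapses (exponential conductances, one-step delay)
    e_exc: float = 0.0         #: mV
    e_inh: float = -80.0       #: mV
    tau_exc: float = 5.0       #: ms
    tau_inh: float = 10.0      #: ms
    w_exc: float = 6.0         #: nS per excitatory spike
    w_inh: float = 67.0        #: nS per inhibitory spike
    # external drive
    ext_rate_hz: float = 150.0  #: Poisson rate per neuron while the stimulus is on
    ext_weight: float = 6.0     #: nS per external event
    # metabolic state and current
    ms_max: float = 1.0
    ms_rest: float = 1.0       #: recovery target (full reservoir)
    ms_neutral: float = 0.5    #: MS level at which I_M crosses zero
    tau_ms: float = 300.0      #: recovery time constant (ms)
    cost_exc: float = 0.0004   #: MS debit per excitatory synaptic event
    cost_inh: float = 0.0004   #: MS debit per inhibitory synaptic event
    cost_spike: float = 0.04   #: MS debit per emitted spike
    im_gain: float = 600.0     #: pA per unit MS deviation
    im_bound: float = 150.0    #: saturation bound (pA)
    ext_counts_cost: bool = True  #: external events also debit MS
    # integration
    dt: float = 0.1            #: ms
    seed: int = 0

    def __post_init__(self):
        if self.n_exc <= 0 or self.n_inh <= 0:
            raise DomainError("n_exc and n_inh must be positive")
        if not 0.0 < self.p_connect < 1.0:
            raise DomainError("p_connect must lie in (0, 1)")
        if self.im_bound <= 0:
            raise DomainError("im_bound must be > 0")
        if self.ms_max <= 0 or self.tau_ms <= 0 or self.dt <= 0:
            raise DomainError("ms_max, tau_ms, dt must be > 0")

    @property
    def n_total(self) -> int:
        return self.n_exc + self.n_inh

    @classmethod
    def scaled_down(cls, scale: int = 10, **overrides) -> "NetworkConfig":
        """A 1/scale network for routine testing.

        Recurrent weights shrink by 1/sqrt(scale) (the in-degree falls
        by ``scale``, so this keeps synaptic fluctuations comparable
        without letting the small network self-sustain on recurrence
        alone) and per-event metabolic costs grow by ``scale`` (each
        neuron sees ``scale`` times fewer events for the same rate).
        External drive is per-neuron and is not rescaled.
        """
        base = cls()
        kwargs = dict(
            n_exc=base.n_exc // scale,
            n_inh=base.n_inh // scale,
            w_exc=base.w_exc / np.sqrt(scale),
            w_inh=base.w_inh / np.sqrt(scale),
            cost_exc=base.cost_exc * scale,
            cost_inh=base.cost_inh * scale,
        )
        kwargs.update(overrides)
        return replace(base, **kwargs)


@dataclass
class Network:
    """Built connectivity: per-source postsynaptic target lists."""

    config: NetworkConfig
    targets: list        #: targets[j] = ndarray of postsynaptic indices of neuron j

    @property
    def n(self) -> int:
        return self.config.n_total

    def in_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        for tgt in self.targets:
            np.add.at(deg, tgt, 1)
        return deg

    def adjacency(self) -> np.ndarray:
        """Dense boolean adjacency (source row, target column); small nets only."""
        adj = np.zeros((self.n, self.n), dtype=bool)
        for j, tgt in enumerate(self.targets):
            adj[j, tgt] = True
        return adj


@dataclass
class NeuronRecord:
    """Sub-sampled traces of one recorded neuron."""

    neuron_id: int
    times: np.ndarray
    ms: np.ndarray
    i_syn: np.ndarray
    i_m: np.ndarray


@dataclass
class RasterWindow:
    """Population spike counts on a 1-ms grid."""

    counts: np.ndarray
    bin_ms: float
    n_neurons: int

    @property
    def edges(self) -> np.ndarray:
        return np.arange(len(self.counts) + 1) * self.bin_ms


@dataclass
class SimResult:
    """Everything one simulation run produced."""

    config: NetworkConfig
    duration: float
    stim_off_time: float
    spike_ids: np.ndarray      #: neuron id per spike, in time order
    spike_times: np.ndarray    #: ms
    spike_ms: np.ndarray       #: MS of the spiking neuron at spike time
    window: RasterWindow
    records: list              #: NeuronRecord for the recorded subset
    cumulative_cost: np.ndarray   #: per-neuron sum of MS debits actually requested
    event_counts: np.ndarray      #: per-neuron (n_exc_events, n_inh_events, n_spikes)

    def trains(self) -> list[np.ndarray]:
        out = [np.empty(0)] * self.config.n_total
        order = np.argsort(self.spike_ids, kind="stable")
        ids = self.spike_ids[order]
        ts = self.spike_times[order]
        bounds = np.searchsorted(ids, np.arange(self.config.n_total + 1))
        for i in range(self.config.n_total):
            out[i] = np.sort(ts[bounds[i]:bounds[i + 1]])
        return out


def build_network(config: NetworkConfig, rng: np.random.Generator | None = None) -> Network:
    """Independent Bernoulli(p) directed wiring without self-connections.

    Reproducible from ``config.seed`` (connectivity uses its own spawned
    stream, so the same wiring is drawn regardless of what else consumes
    randomness).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    n = config.n_total
    targets = []
    for j in range(n):
        draw = rng.random(n) < config.p_connect
        draw[j] = False
        targets.append(np.flatnonzero(draw))
    return Network(config=config, targets=targets)


def ms_update(ms: float, events, config: NetworkConfig, dt: float | None = None) -> float:
    """One metabolic-state update: recovery minus event and spike costs.

    ``events`` is ``(n_exc_events, n_inh_events, spiked)``.  The result
    is clamped to ``[0, ms_max]``.
    """
    dt = config.dt if dt is None else dt
    n_e, n_i, spiked = events
    ms = ms + dt * (config.ms_rest - ms) / config.tau_ms
    ms -= n_e * config.cost_exc + n_i * config.cost_inh + bool(spiked) * config.cost_spike
    return float(min(config.ms_max, max(0.0, ms)))


def i_m_from_ms(ms, config: NetworkConfig):
    """Saturating metabolic current: depolarising above the neutral MS, hyperpolarising below."""
    ms_arr = np.asarray(ms, dtype=float)
    if np.any(ms_arr < 0) or np.any(ms_arr > config.ms_max):
        raise DomainError("ms must lie in [0, ms_max]")
    val = np.clip(config.im_gain * (ms_arr - config.ms_neutral),
                  -config.im_bound, config.im_bound)
    return float(val) if val.ndim == 0 else val


def simulate(config: NetworkConfig, duration: float, stim_off_time: float | None = None,
             *, network: Network | None = None, record_ids=(0,),
             record_every: int = 50) -> SimResult:
    """Run the network; external Poisson drive is on before ``stim_off_time``.

    The integration uses a fixed global step ``config.dt`` with spikes
    aligned to steps and a one-step synaptic delay.  All randomness
    (wiring, initial voltages, external drive) derives from
    ``config.seed``.
    """
    if stim_off_time is None:
        stim_off_time = duration
    if stim_off_time > duration:
        raise DomainError("stim_off_time must not exceed duration")
    cfg = config
    ss = np.random.SeedSequence(cfg.seed).spawn(3)
    rng_wire, rng_ext, rng_init = (np.random.default_rng(s) for s in ss)
    net = network if network is not None else build_network(cfg, rng_wire)
    n = cfg.n_total
    n_e = cfg.n_exc
    dt = cfg.dt

    v = rng_init.uniform(cfg.v_rest, cfg.v_thresh, size=n)
    ge = np.zeros(n)
    gi = np.zeros(n)
    ms = np.full(n, cfg.ms_rest)
    refrac_until = np.zeros(n)
    cumulative_cost = np.zeros(n)
    event_counts = np.zeros((n, 3), dtype=np.int64)

    decay_e = np.exp(-dt / cfg.tau_exc)
    decay_i = np.exp(-dt / cfg.tau_inh)
    p_ext = cfg.ext_rate_hz * dt / 1000.0
    recovery = dt / cfg.tau_ms

    n_steps = int(round(duration / dt))
    spike_ids, spike_times, spike_ms = [], [], []
    prev_spikes = np.empty(0, dtype=np.int64)

    record_ids = tuple(record_ids or ())
    rec_t, rec_vals = [], {i: [] for i in record_ids}

    n_bins = int(np.ceil(duration))
    counts_1ms = np.zeros(n_bins, dtype=np.int64)

    for i in range(n_steps):
        t = (i + 1) * dt
        # synaptic propagation (one-step delay) and event costs
        cnt_e = np.zeros(n)
        cnt_i = np.zeros(n)
        for j in prev_spikes:
            tgt = net.targets[j]
            if j < n_e:
                ge[tgt] += cfg.w_exc
                cnt_e[tgt] += 1.0
            else:
                gi[tgt] += cfg.w_inh
                cnt_i[tgt] += 1.0
        # external drive
        if t <= stim_off_time and p_ext > 0:
            ext = rng_ext.random(n) < p_ext
            ge[ext] += cfg.ext_weight
            if cfg.ext_counts_cost:
                cnt_e[ext] += 1.0
        # currents and membrane update
        i_m = np.clip(cfg.im_gain * (ms - cfg.ms_neutral), -cfg.im_bound, cfg.im_bound)
        i_syn = ge * (cfg.e_exc - v) + gi * (cfg.e_inh - v)
        active = refrac_until <= t
        dv = dt * (cfg.g_leak * (cfg.v_rest - v) + i_syn + i_m) / cfg.c_m
        v = np.where(active, v + dv, v)
        spiked = active & (v >= cfg.v_thresh)
        new_spikes = np.flatnonzero(spiked)
        v[new_spikes] = cfg.v_reset
        refrac_until[new_spikes] = t + cfg.refractory
        # metabolic state
        debit = cnt_e * cfg.cost_exc + cnt_i * cfg.cost_inh
        debit[new_spikes] += cfg.cost_spike
        cumulative_cost += debit
        event_counts[:, 0] += cnt_e.astype(np.int64)
        event_counts[:, 1] += cnt_i.astype(np.int64)
        event_counts[new_spikes, 2] += 1
        ms = np.clip(ms + recovery * (cfg.ms_rest - ms) - debit, 0.0, cfg.ms_max)
        # bookkeeping
        if new_spikes.size:
            spike_ids.append(new_spikes)
            spike_times.append(np.full(new_spikes.size, t))
            spike_ms.append(ms[new_spikes])
            b = min(n_bins - 1, int(t))
            counts_1ms[b] += new_spikes.size
        if record_ids and i % record_every == 0:
            rec_t.append(t)
            for rid in record_ids:
                rec_vals[rid].append((ms[rid], i_syn[rid], i_m[rid]))
        prev_spikes = new_spikes
        ge *= decay_e
        gi *= decay_i
        if not np.all(np.isfinite(v)):
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise IntegrationError(
                f"membrane potential of neuron {bad} became non-finite at t = {t:g} ms")

    records = []
    if record_ids:
        rt = np.asarray(rec_t)
        for rid in record_ids:
            arr = np.asarray(rec_vals[rid])
            records.append(NeuronRecord(rid, rt, arr[:, 0], arr[:, 1], arr[:, 2]))
    return SimResult(
        config=cfg, duration=duration, stim_off_time=stim_off_time,
        spike_ids=(np.concatenate(spike_ids) if spike_ids else np.empty(0, dtype=np.int64)),
        spike_times=(np.concatenate(spike_times) if spike_times else np.empty(0)),
        spike_ms=(np.concatenate(spike_ms) if spike_ms else np.empty(0)),
        window=RasterWindow(counts_1ms, 1.0, n),
        records=records, cumulative_cost=cumulative_cost, event_counts=event_counts,
    )


def persistence_time(result: SimResult) -> float:
    """Time (ms) activity outlived the stimulus: last spike minus stim-off."""
    if result.spike_times.size == 0:
        return 0.0
    return float(result.spike_times.max() - result.stim_off_time)


def summarize_activity(result: SimResult, window: tuple[float, float]) -> dict:
    """Firing-rate / ISI / CV / MS-at-spike statistics within a time window.

    Returns a dict with per-neuron ``rates_hz``, pooled ``isis_ms``,
    per-neuron ``cv_isi`` (neurons with >= 3 spikes in the window), and
    ``ms_at_spike`` samples.
    """
    t0, t1 = window
    if t1 <= t0:
        raise DomainError("window must have positive length")
    sel = (result.spike_times >= t0) & (result.spike_times < t1)
    ids = result.spike_ids[sel]
    times = result.spike_times[sel]
    n = result.config.n_total
    rates = np.bincount(ids, minlength=n) / ((t1 - t0) / 1000.0)
    isis, cvs = [], []
    order = np.argsort(ids, kind="stable")
    ids_s, times_s = ids[order], times[order]
    bounds = np.searchsorted(ids_s, np.arange(n + 1))
    for i in range(n):
        ts = np.sort(times_s[bounds[i]:bounds[i + 1]])
        if ts.size >= 2:
            d = np.diff(ts)
            isis.append(d)
            if ts.size >= 3 and d.mean() > 0:
                cvs.append(d.std() / d.mean())
    return {
        "rates_hz": rates,
        "isis_ms": np.concatenate(isis) if isis else np.empty(0),
        "cv_isi": np.asarray(cvs),
        "ms_at_spike": result.spike_ms[sel],
    }
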