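# Methods

`metaspike` implements four linked models of metabolically regulated
neuronal spiking plus the analysis machinery used to characterise their
output.  This note records the model equations, the reasoning behind
every tunable default, what the simulations do and do not emulate, and
the numerical choices.

## 1. Mitochondrial respiration and ROS (`metaspike.mito`)

### State and equations

Seven variables, all normalized: pyruvate `pyr` (capacity `pyr_max`),
NADH fraction `nadh` (`nad = 1 - nadh`), proton gradient `delta_psi`
in [0, 1], mitochondrial ATP fraction `atp_m` (`adp_m = 1 - atp_m`),
cytosolic ATP `atp_c` in [0, 1], ROS level `ros >= 0`, matrix calcium
`ca_m`.  Mass-action fluxes:

    J_sup = k_pyr * (1 - pyr / pyr_max)          pyruvate supply
    J_tca = k_tca * pyr * (1 - nadh)             TCA: pyruvate + NAD+ -> NADH
    J_etc = k_etc * nadh * (1 - delta_psi)       ETC pumping (stalls at full gradient)
    J_syn = k_atp * delta_psi * (1 - atp_m)      complex V: gradient + ADP_M -> ATP_M
    J_ant = k_ant * atp_m * (1 - atp_c)          ANT exchange with the cytosol
    J_con = b * atp_c                            consumption at demand rate b

    d(pyr)/dt   = J_sup - J_tca
    d(nadh)/dt  = J_tca - J_etc
    d(psi)/dt   = p_etc*J_etc - p_syn*J_syn - k_leak*psi
    d(atp_m)/dt = J_syn - J_ant
    d(atp_c)/dt = J_ant - J_con
    d(ros)/dt   = (ROS_inf(atp_m, psi) - ros) / tau_ros
    d(ca_m)/dt  = -ca_m / tau_ca

with the cubic ROS production law

    ROS_inf = (atp_m * psi * f_ret + (1 - atp_m) * (1 - psi) * f_fet)^3.

Electron flux (`J_etc`) and ATP flux (`J_syn`) are coupled only through
the proton gradient.  This single structural choice produces the
respiratory-state-space geometry: at zero demand the chain stalls at
complex V and `(atp_m, psi) -> (1, ~0.98)` (reverse-electron-transport
ROS, "RETROS" corner); at high demand both collapse toward
`(~0.05, ~0.17)` ("FETROS" corner).  Because the fixed-point branch
traverses the saddle of the cubic, steady-state ROS versus demand is
V-shaped with an interior minimum (near b = 0.015 at the defaults).

A spike does two things: its cost Q is spread over a kernel
(rectangular, 5 ms by default — an instantaneous ATP jump would defeat
the integrator's error control and Fig-style transients are smooth),
and the accompanying calcium influx decrements `delta_psi` by
`ca_coupling` immediately (calcium entry across the inner membrane
dissipates part of the gradient).

### Parameter defaults

Units are per-ms rates on normalized pools; physical units are out of
scope.  `k_pyr=0.02, pyr_max=2, k_tca=0.05, k_etc=0.1, k_atp=0.1,
k_ant=0.5, k_leak=0.002, p_etc=p_syn=1, f_ret=f_fet=1, tau_ros=50 ms,
ca_coupling=0.01, tau_ca=100 ms`.  These were calibrated once, before
the test suite was frozen, to satisfy three qualitative constraints
and were not adjusted afterwards: (i) the default demand grid
(0.001–0.04) spans both corners with a single interior ROS minimum;
(ii) the slowest relaxation time anywhere on the branch is a few
hundred ms, so spike transients resolve within ~1.5 s windows;
(iii) from the low-demand reference point (`RETROS_BASELINE = 0.005`)
periodic 20-Hz spiking lowers time-averaged ROS, while from the
high-demand point (`FETROS_BASELINE = 0.03`) it raises it.

### Numerics

Fixed-step classical Runge–Kutta (RK4); `step()` defaults to
dt = 0.01 ms, long simulations use 0.05–0.1 ms (the stiffest rate is
0.5/ms, so RK4 is stable far beyond that; the convergence test halves
dt and requires endpoint agreement to 1e-6).  A step that drives any
bounded pool outside [0, 1] (beyond 1e-9) raises an error instead of
clipping, so parameter pathologies surface in tests.  Fixed points are
found by LSODA integration from a standard interior initial condition
followed by a Newton polish; residual tolerance 1e-9.  `relax_ros` as
a standalone operation uses the exact exponential update.

## 2. The metabolic-accounting neuron (`metaspike.accounting`)

### Dynamics

The default backend is phenomenological (the full mitochondrial ODE can
be swapped in via `ros_backend="mito"`).  Per step of size dt:

    c       = baseline + (Q / kernel) while a spike kernel is active
    ATP    -> atp_target(c) = clip(1 - c / c_max)          (tau_atp = 15 ms)
    c_slow -> c                                            (tau_c = 50 ms)
    ROS    -> ros_min + ros_slope * |c_slow - c_bar|       (tau_ros = 50 ms)
    MS_true = ROS * (ATP - ATP_bar)
    MS     -> MS_true                                      (tau_ms = 15 ms)

A spike multiplies ROS by `(1 - ros_quench)` (calcium influx partially
collapsing the proton gradient — the same coupling as `ca_coupling` in
the ODE model, read out at the ROS level).  Gating: if not refractory
and MS > theta_ret, a *metabolic* spike; else if driven and
MS > theta_fet, a *synaptic* spike; below theta_fet nothing fires.

Three design points deserve explanation because simpler variants fail
in instructive ways:

* **The ROS target takes low-pass-filtered consumption.**  With the
  instantaneous rate, a large spike kernel momentarily lands on the
  far (FETROS) side of the V, so the ROS target jumps *up* during the
  kernel and cancels the quench in MS.  Physiologically, ROS production
  responds to sustained demand, not 5-ms transients; `tau_c` encodes
  that.
* **MS is sensed with a lag.**  With instantaneous sensing, any
  configuration settles into threshold-riding: the neuron fires exactly
  at each upward crossing, resetting to a fixed state, and the steady
  pattern is strictly periodic — silent, tonic, or continuous, never
  bursting.  (This is structural: spiking only pushes MS down, so the
  fast subsystem cannot be bistable, and the monotone relaxations
  exclude oscillatory returns.)  First-order sensing kinetics — a
  messenger between metabolic state and the spike-initiation machinery
  — let MS swing across the thresholds: several spikes fire inside the
  sensing delay, the accumulated quench overshoots, and a long silent
  recovery follows.  `tau_ms = 0` restores the instantaneous readout.
* **The refractory period (2 ms) is short relative to the
  metabolic-consequence delay** (kernel 5 ms + tau_atp 15 ms), which is
  what allows multi-spike episodes at low Q; lengthening the refractory
  period lowers the in-burst rate, and the in-burst rate is always
  1/refractory at the burst core.

### Thresholds and reference levels

`atp_bar = 0.75` is the ATP level at the ROS-minimum demand
(`c_bar = 0.015`, matching the ODE model's V minimum) given
`c_max = 0.06`.  `theta_ret = 0.04` sits between the resting MS at the
low-demand reference (0.067) and the MS at demand ≈ 0.012, so
self-initiated spiking switches off along the baseline axis exactly
where the RETROS surplus vanishes; `theta_fet = -0.1` blocks all
spiking once depletion is severe (baseline ≳ 0.028 at rest).  With
these defaults the (baseline, Q) plane over the default grids
(baseline 0.002–0.02, Q 0.003–0.3 geometric) contains all four firing
patterns, with silence filling the high-baseline edge.

### Pattern classifier

The paper-style labels are defined operationally (all cutoffs in
`PatternCriteria`): *silent* below 0.1 Hz; *continuous* at ≥ 20 Hz with
no ISI above 2× the median (sustained pauseless firing); *bursting*
when ISIs above 5× the median exist and their mean is ≥ 5× the mean of
the remaining ISIs (clearly bimodal); *tonic* otherwise.

## 3. The A-type channel neuron (`metaspike.channel`)

Single compartment, absolute units (a ~200 µm² patch: c_m = 2 pF),
currents I_Na (m³h), delayed-rectifier I_K (n⁴), leak, and A-type

    I_A = g_a * a^3 * hA_eff * (V - e_k),   hA_eff = (1 - rho)*hA + rho.

Na/K rate functions follow the Connor–Stevens formulation.  The A-type
gates use Boltzmann steady states with fixed time constants — the form
experimental transient-K currents are fit with — because the classic
Connor–Stevens A-type activation has a shallow, cube-rooted tail that
stays near 0.5 even at −85 mV: with inactivation removed it becomes a
large standing K conductance and silences the cell outright, the
opposite of the modelled biology.  The defaults place activation high
(midpoint −30 mV, tau 0.6 ms: the current engages during the spike,
not at rest) and inactivation low and slow to recover (midpoint
−74 mV, tau 5 ms), and slow the delayed rectifier four-fold
(`n_tau_scale`), so that:

* with `rho = 0`, sustained firing keeps hA depleted; repolarisation
  falls to the slow delayed rectifier, spikes broaden, the AHP deepens,
  and ISIs stretch;
* with `rho = 1`, the fast A current handles repolarisation, the
  delayed rectifier barely engages, and ISIs shorten.

At the reference 20 pA injection the defaults give 38 spikes/800 ms
(inactivating) versus 47 (non-inactivating), monotone in `rho`, with no
spontaneous firing at rest (leak reversal −70 mV, rheobase just below
20 pA).  `rho` can also act by slowing inactivation instead of removing
the gate (`rho_mode="slow_tau"`).  `ros_to_rho` is a Hill function
(midpoint 0.5, coefficient 2) mapping ROS level to the inactivation-
removal fraction; experimental ROS manipulations enter as additive
shifts of the ROS-versus-demand curve, floored at zero.

Integration: RK4, dt = 0.01 ms default (0.02 ms in routine tests;
halving dt moves spike times by < 0.02 ms).  Voltage clamp uses exact
exponential gate updates at the frozen command potential.  Spike
detection: upward 0 mV crossings with a 2-ms dedup window.

## 4. The recurrent network (`metaspike.network`)

Conductance-based leaky integrate-and-fire neurons with exponential
synapses, wired by independent Bernoulli(2%) draws without autapses.
Membrane and synaptic defaults are the published sparse balanced-
network values (tau_m 20 ms, V_rest = V_reset = −60 mV, threshold
−50 mV, refractory 5 ms, E_exc 0 / E_inh −80 mV, tau_exc 5 /
tau_inh 10 ms, w_exc 6 / w_inh 67 nS at full 8,000E/2,000I scale).
External drive: independent per-neuron Poisson events (150 Hz, 6 nS)
while the stimulus is on.

Each neuron carries a metabolic state MS in [0, 1] — a cost-tracking
reservoir, full at rest — debited per incoming synaptic event
(cost_exc/cost_inh) and per emitted spike (cost_spike), recovering
toward 1 with tau_ms = 300 ms, and driving the saturating metabolic
current

    I_M = clip(im_gain * (MS - 0.5), -150 pA, +150 pA),  im_gain = 600 pA.

The saturation bound slightly exceeds the rheobase (100 pA), so a fully
recovered neuron can reach threshold on I_M alone; the per-spike and
per-event debits then pull MS back toward the neutral point, which is
the homeostatic set point of the self-sustained state.

**Scaled-down study conditions.**  Routine testing and the acceptance
run use the 800E/200I network with recurrent weights divided by √10 and
per-event costs multiplied by 10 (`NetworkConfig.scaled_down()`).  The
weight reduction is essential, not cosmetic: compensating the smaller
in-degree by *increasing* weights produces a fluctuation-driven state
that self-sustains even without the metabolic current, which would void
the very contrast the model exists to show.  At the chosen scale the
ablated (im_gain = 0) network collapses within ~50 ms of stimulus
removal, while the intact network transitions to self-sustained
activity: externally driven at ~19 Hz with MS low (hyperpolarising
I_M limiting the rate), then self-sustained at ~10 Hz with MS near
0.6, irregular ISIs (CV ≈ 0.7), super-Poisson population-rate
fluctuations, and avalanche-structured population activity.  The mean
MS at spike times separates sharply between the two phases (≈ 0.09
driven vs ≈ 0.60 self-sustained).  The full-scale network runs with
the same code but is not exercised by the test suite; its metabolic
cost constants are defined to be consistent with the scaled-down
calibration (per-event costs scale inversely with in-degree).

Numerics: fixed global step 0.1 ms, spikes aligned to steps, one-step
synaptic delay, per-run randomness split into independent streams
(wiring / external drive / initial voltages) from the single config
seed.  MS clamping to [0, 1] is applied after the debits; the
*requested* debits are accumulated separately so energy accounting is
exact by construction.

## 5. Avalanches and power laws (`metaspike.avalanches`)

Avalanches are maximal runs of consecutive nonempty 1-ms population
bins (duration = run length, size = spike count); 1 ms is canonical
because it matches the silence criterion, other widths are accepted
but non-standard.  By this definition sizes partition the total spike
count and durations partition the nonempty bins, which the tests
assert exactly.

Tail fitting is discrete maximum likelihood: alpha maximizes
`-n log zeta(alpha, x_min) - alpha * sum(log x)` (Hurwitz zeta from
scipy), with `x_min` chosen to minimize the KS distance between the
empirical and fitted tail CDFs.  Candidate cutoffs must retain at
least 10% of the observations (and ≥ 50 of them): an unconstrained
scan will walk into a ~100-point extreme tail where *any* smooth
distribution fits, making the goodness-of-fit flag vacuous.  The fit
is flagged `plausible` when KS < 1.36/√n_tail — with these
constraints, exact power-law samples pass comfortably and
geometric (exponential-tail) controls fail across a range of rates.
Estimator calibration: recovery bias < 0.006 at 10⁵ samples for
exponents in [1.3, 2.5].

The companion sampler inverts the discrete survival function by
integer bisection on the zeta function (exact; support truncated at
2⁴⁰, which discards < 0.02% of mass even at exponent 1.3).
Size–duration scaling is the least-squares slope of mean log-size per
duration class against log-duration.

## 6. Randomness, determinism, and IO

Every stochastic operation consumes randomness only through an integer
seed; one run seed is split into per-component streams via
`SeedSequence.spawn`, so subsystem results do not depend on execution
order.  Identical config + seed reproduces primary CSV outputs byte
for byte; numeric output precision is fixed at 9 significant digits to
make that assertion meaningful.  Every writer emits a JSON sidecar
with the seed, a config hash, and the package version.  Rasters travel
as two-column ASCII (`neuron_id  time_ms`).

## 7. What the simulations do and do not show

All inputs are internally generated (Poisson trains, DC/step
protocols); there is no external data.  Passing tests therefore
demonstrate internal consistency of the models and the qualitative
phenomena they were built to exhibit — the V-shaped ROS curve, spike
quenching, threshold-gated firing-pattern diversity, the inactivation
switch's rate effect, the metabolically rescued self-sustained network
state — not quantitative agreement with any biological measurement.
Known limitations: normalized (unitless) metabolic pools; a single
pooled ATP level in the accounting neuron; no ROS species
differentiation or mitochondrial calcium buffering beyond the scalar
gradient decrement; no synaptic plasticity, conduction-delay
distributions, or topographic wiring in the network; per-neuron
mitochondrial ODE coupling at network scale is out of scope (the ODE
backend is available for single neurons); and formal model comparison
for criticality (likelihood ratios against lognormal alternatives,
shape collapse) is deliberately not implemented.
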