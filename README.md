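# metaspike

Simulators and analysis tools for **metabolically regulated neuronal
spiking** — the hypothesis that some "spontaneous" action potentials
are a homeostatic release valve: when a neuron's energy consumption is
low, its mitochondrial electron transport chain stalls, reverse-
electron-transport reactive oxygen species (RETROS) build up, and
firing a spike spends ATP, resupplies mitochondrial ADP, and quenches
the ROS.  The package is aimed at computational neuroscientists and
systems biologists who want to simulate, perturb, and analyse this
mechanism at four levels of description:

| module | model |
|---|---|
| `metaspike.mito` | mitochondrial respiration ODE with ROS: `dROS/dt = (ROS∞ − ROS)/τ_ROS`, `ROS∞(ATP_M, ΔΨ) = (ATP_M·ΔΨ·f_RET + (1−ATP_M)(1−ΔΨ)·f_FET)³` — the V-shaped ROS-vs-consumption curve and spike excursions in the (ATP, ΔΨ) respiratory state space |
| `metaspike.accounting` | a threshold neuron bookkeeping ATP and ROS; the metabolic signal `MS = ROS·(ATP − ĀTP)` gates self-initiated *metabolic* spikes (`MS > θ_RET`) and blocks all spiking under depletion (`MS < θ_FET`); (baseline cost, per-spike cost Q) maps to silent/tonic/bursting/continuous firing |
| `metaspike.channel` | Hodgkin–Huxley neuron with an A-type K⁺ current whose inactivation is removed under high ROS (`I_A = g_A·a³·h_eff·(V−E_K)`, `h_eff = (1−ρ)h_A + ρ`), reproducing the firing-rate increase of fly sleep-switch neurons |
| `metaspike.network` | 8,000E/2,000I conductance-based LIF network (2% random wiring) where a per-neuron metabolic reservoir MS drives a saturating current `I_M = clip(g_M(MS − ½))` — hyperpolarising under load, depolarising at rest — producing the transition from externally driven to self-sustained, avalanche-structured activity |
| `metaspike.avalanches` | avalanche detection on 1-ms population bins (episodes separated by ≥ 1 ms of silence) and discrete power-law tail fitting (maximum-likelihood exponent, KS-selected x_min) |

All simulations are seeded and reproduce byte-identically; there are no
external data dependencies.

## Worked example

```python
import numpy as np
from metaspike import mito
from metaspike.mito import MitoParams, EnergyBudget

params = MitoParams()
curve = mito.ros_vs_baseline_curve(params)          # 50-point demand sweep
b_min = mito.min_ros_baseline(curve)
print(f"ROS-minimizing demand rate: {b_min:.4f} ATP/ms")
print(f"ROS at minimum: {curve['ros_ss'].min():.3f}; "
      f"at the RETROS end: {curve['ros_ss'].iloc[0]:.3f}")

budget = EnergyBudget(baseline_cost=mito.RETROS_BASELINE, q=0.05)
delta = mito.spike_effect_on_ros(params, budget, spike_rate_hz=20.0,
                                 duration=2000.0, dt=0.1)
print(f"Change in mean ROS from 20-Hz spiking at the RETROS point: {delta:+.3f}")
```

prints

```
ROS-minimizing demand rate: 0.0153 ATP/ms
ROS at minimum: 0.115; at the RETROS end: 0.884
Change in mean ROS from 20-Hz spiking at the RETROS point: -0.052
```

Reading: steady-state ROS is minimal at an intermediate ATP demand
(0.0153 per ms in normalized units) and almost eightfold higher when
demand is low and the electron transport chain stalls (0.884 vs
0.115).  From that low-demand operating point, making the neuron fire
at 20 Hz *lowers* time-averaged ROS by 0.052 — spikes as a metabolic
release valve.  Running the same call at
`baseline_cost=mito.FETROS_BASELINE` gives a positive change: where
demand is already high, extra spikes make ROS worse, which is why the
accounting neuron blocks spiking below `θ_FET`.

The network-level claim in two lines:

```python
from metaspike.network import NetworkConfig, simulate, persistence_time
res = simulate(NetworkConfig.scaled_down(seed=1), duration=7500.0, stim_off_time=2000.0)
print(persistence_time(res) / 1000.0)   # -> 5.4986  (seconds active after stimulus removal)
```

With `im_gain=0` the same network falls silent within ~50 ms of
stimulus removal.

## Command line

Each model has a thin CLI under the `metaspike` umbrella, writing CSV
(9 significant digits) plus a JSON metadata sidecar recording seed,
config hash, and version:

```
metaspike mito sweep --out out/ --seed 1
metaspike account phase --out out/ --baseline-grid 0.002:0.02:10 --q-grid geom:0.003:0.3:10
metaspike channel iclamp --rho 1.0 --inj-pa 20 --out out/
metaspike net simulate --duration 7500 --stim-off 2000 --seed 1 --out out/
metaspike aval fit --raster out/spikes.txt --quantity duration --out out/
```

YAML configs (`--config`) override any model parameter; unknown keys
are rejected with the offending key path.

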