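# Methods

## Model

A single-compartment conductance-based neuron in the standard
Hodgkin–Huxley unit system (mV, ms, µF/cm², mS/cm², µA/cm²):

    C dV/dt = −I_Na − I_Kdr − I_Klt − I_Kht − I_Ka − I_L + I_app
    dx/dt  = (x∞(V) − x)/τ_x(V)          for every gate x

| current | form | gates | default density |
|---|---|---|---|
| I_Na  | g m³h (V−E_Na) | m, h (pluggable rates) | 91.66 mS/cm² (1100 nS) |
| I_Kdr | g a² (V−E_K) | a: Boltzmann V½ = 8.4 mV, k = 18.5 mV, τ_a = 3.2 ms | 20.83 (250 nS) |
| I_Klt | g w⁴z (V−E_K) | w∞ = (1+e^−(V+48)/6)^−¼; z∞ = ½(1+e^(V+71)/10)^−1 + ½ | 0 (variants: 1.667 / 16.67) |
| I_Kht | g (0.85 n² + 0.15 p)(V−E_K) | n∞ = (1+e^−(V+15)/5)^−½; p∞ = (1+e^−(V+23)/6)^−1 | 0 (variant: 12.50) |
| I_Ka  | g m_F⁴h_F (V−E_K) | m_F∞ = (1+e^−(V+53)/25.8)^−1; h_F∞ = (1+e^(V+89.6)/6.7)^−1 | 0 (variant: 10.42) |
| I_L   | g (V−E_L) | — | swept 0.1667–0.6333 mS/cm² (2.0–7.6 nS) |

Reversals: E_Na = 50, E_K = −94, E_L = −77 mV. The K-gate time constants
have the form τ = A·(Σ of two exponentials)⁻¹ + offset (e.g. τ_z =
1000/(e^(V+60)/20 + e^−(V+60)/8) + 50 ms); τ_a is voltage-independent.

**Membrane area.** The area is not an independent choice: the printed
pairing 2 nS ↔ 0.1667 mS/cm² fixes it at 1.2×10⁻⁵ cm², giving C = 12 pF,
and makes every other printed density/absolute pair (16.67 → 200 nS,
12.50 → 150 nS, 10.42 → 125 nS) consistent to < 0.5% (asserted by test).
The 120 pA stimulus is therefore 10 µA/cm².

**Sodium kinetics are a pluggable choice.** The model family only pins the
transient Na current down to "Hodgkin–Huxley type". Two rate sets are
built in: `hh1952` (the classic squid rates in the modern −65 mV resting
convention, no Q10) and `rm2003` (the fast Na current of the ventral
cochlear nucleus bushy-cell model this neuron model derives from). The
choice is decisive, not a detail — it is the largest single source of
uncertainty in the sweep:

| Na variant | phasic band (nS) | transient top (nS) | tonic top (nS) | silent points |
|---|---|---|---|---|
| rm2003 (default) | 5.6–5.8 | 5.4 | 5.2 | 9 (gL ≥ 6.0) |
| hh1952 | none | — | 7.6 (all tonic) | 0 |

`rm2003` reproduces the published firing-class edges exactly on the 0.2 nS
grid (phasic down to 5.6 nS, transient at 5.4 nS, tonic at ≤ 5.2 nS) and is
therefore the default. Two further variants were probed and rejected: a
hybrid (hh m-gate with rm2003 h-gate) fires tonically everywhere, and the
1952 rates re-anchored to this cell's −77 mV rest are silent everywhere.

**Known discrepancies under the default.** (i) The source describes one AP
across the whole 5.6–7.4 nS band; with `rm2003` the model's rheobase rises
above the 120 pA probe for gL ≥ 6.0 nS, so those points are silent rather
than phasic. No documented Na variant fires phasically across the full
band: a variant excitable enough at −61 mV (where a 7.4 nS cell sits under
120 pA) is, in every form tried, excitable enough to fire repetitively at
low leak. (ii) The 5.2 nS point is tonic (24 spikes), not transient.
(iii) Adding the 125 nS A-type current — described as nearly without
influence — shifts the tonic/phasic transition by 0.4 nS and silences
5.2–5.6 nS, because near the rheobase edge its transient outward charge
decides spike initiation. The corresponding acceptance test is left
failing deliberately rather than loosened. (iv) The AP threshold of the
`rm2003` variant sits near −56 mV, below the −43…−36 mV measured in real
cells.

**Resting state.** Gates start at steady state and V at the fixed point of
the steady-state current (scan + Brent refinement on (E_K, E_Na), most
hyperpolarized stable root, 1-s settling fallback). With all conductances
at default the cell rests at −77.05 mV.

## Protocols and numerics

Current-clamp and voltage-clamp steps are integrated with LSODA
(rtol = atol = 10⁻⁸), restarting the solver at each stimulus discontinuity
so adaptive steps never straddle an edge, then resampled to the 50 kHz
(CC) / 10 kHz (VC) acquisition grids. Halving the tolerances changes no
spike count on the sweep grid (tested). Voltage clamp is ideal (no series
resistance) by default — the model has none — with Rs as an explicit
option; with Rs > 0 the capacitive transient decays with τ = Rs·C and its
integral is used for the capacitance measurement. Boundary samples belong
to the incoming command segment so records include the instantaneous jump.

The dynamic clamp emulates the discrete hardware loop: the artificial
current I = g(V − E_rev) is sampled every 0.1 ms (the 100 µs command
interval) and held between ticks; within a tick the state advances by
fixed-step RK4 (25 µs substeps). Halving the update interval leaves spike
counts unchanged and moves spike times < 0.1 ms (tested). Injecting
(g, E_K) on top of a 2 nS cell reproduces, at every sweep grid point, the
spike count of the continuous model carrying the two-component leak
(g_L at E_L) + (g at E_K) — combined as g_L′ = g_L+g,
E_L′ = (g_L E_L + g E_K)/(g_L+g). The rescue analysis injects at
E_rev = E_L because the artificial conductance stands in for the blocked
native leak (experimentally, for the measured reversal of the
Ba²⁺-sensitive current).

The sweep uses a 500 ms, 120 pA step after 100 ms baseline (the lower end
of the experimental 500–3000 ms range; classification is
duration-insensitive beyond a few inter-spike intervals) on a 0.2 nS grid
from 2.0 to 7.6 nS — the resolution at which the boundaries are quoted.

## Measurements

- **Spikes**: upward crossings of −10 mV followed by a local maximum,
  2 ms minimum peak separation.
- **Firing class**: 0 spikes silent; 1 phasic; ≥ 2 tonic if the last spike
  falls within 1.5 median inter-spike intervals of stimulus offset, else
  transient. The 1.5 factor is a scale-free operationalization of
  "stops firing before the stimulus ends"; classification is invariant to
  2× resampling and to 0.2 mV RMS added noise (tested).
- **AP threshold**: first sample of the upstroke where dV/dt ≥
  max(2×SD of the pre-stimulus baseline dV/dt, 1 mV/ms). The upstroke is
  anchored at the last local minimum of dV/dt before the maximal rate of
  rise; without this anchor the passive charging phase (up to 10 mV/ms on
  clean traces, where the 2×SD term is zero and the floor engages) would
  be swept into the threshold search. Half-width is measured at
  (threshold+peak)/2 with linear interpolation between samples.
- **Rheobase**: bisection between a silent and a spiking amplitude to 5 pA;
  latency from stimulus onset to threshold time at the rheobase trace.
- **VI/IV**: mean over the final 100 ms of each step (window configurable);
  input resistance from the least-squares slope restricted to potentials
  negative to −60 mV (slope mV/pA = GΩ).
- **τ_m**: single-exponential least-squares fit (offset+amplitude+τ) with
  residual RMS reported; a biexponential input raises the RMS by > 100×
  (tested), flagging an inappropriate fit.
- **Sag**: steady mean (final 100 ms) minus the early minimum (first
  200 ms) of a hyperpolarizing step, the minimum taken on a 2 ms
  boxcar-smoothed copy so a clean 0.2 mV-noise floor cannot fake
  ~0.8 mV of sag (the raw minimum of 10⁴ Gaussian samples sits ≈ 3.8σ
  below the mean). Positive = sag present.
- **Capacitance**: ∫(I − I_steady) dt / ΔV over the step (pA·ms/mV = pF).
  With leak g and access resistance Rs the estimate carries a physical
  (1+Rs·g)⁻² divider bias — 0.4% at 20 MΩ for the 0.1 nS test cell, but
  ~8% for a real 4 nS cell; the function reports the uncorrected integral,
  as the measurement does.
- **P/−4**: each trace zeroed on its own pre-pulse baseline (holding
  current does not scale with the pulse), then main + 4×mean(sub); an
  ohmic cell cancels to < 10⁻⁹ of its response.
- **Activation τ**: single exponential fitted from 30% of the current rise
  onward. The a² gating makes the onset sigmoidal; fitting the whole rise
  inflates τ by ~40%, the 30%-onset convention by ~ +14% (the model's
  3.2 ms gate reads out as ≈ 3.6 ms) — an inherent bias of fitting a
  squared-gate current with a single exponential, kept because it mirrors
  the experimental procedure.
- **Difference current**: least-squares line through (control − blocked)
  IV points; g from the slope (pA/mV = nS), E_rev = −intercept/slope. The
  model's own Ba²⁺-emulation difference reverses at E_L = −77 mV (the
  lumped leak reversal), whereas generator bundles embed the measured
  Ba²⁺-sensitive component (5.9 nS at −98.6 mV) as a separate ohmic leak.
- **Nernst**: (RT/F)·ln([K]out/[K]in); 2.5/150 mM at 25 °C → −105.2 mV.
- **Junction correction**: all potentials −10 mV, idempotent via a
  metadata flag.

## Synthetic recordings

The generator emulates the study's recording conditions, not a download:
square current steps (500 ms default) and 1-s voltage steps, additive
white Gaussian recording noise (0.2 mV / 5 pA defaults — noise enters the
record, not the dynamics), and control/blocked voltage-clamp pairs whose
difference is ohmic by construction. Three archetypes are parameterized
from the published class means: leak = 1/R_i (tonic 276 MΩ → 3.6 nS,
transient 179 → 5.6 nS, phasic 125 → 8.0 nS), resting potential set to the
class mean (−62.7/−66.7/−66.8 mV) by an offset on E_L, and a 4.5 mV sag
surrogate for tonic cells — a single-exponential relaxation (τ = 60 ms,
switched on after 5 passive time constants) standing in for the
h-current signature, since the model contains no I_h. Class labels are
assigned by construction from the measured population, not by the model's
dynamics: with its resting potential raised to the measured −66.8 mV the
8 nS "phasic" archetype is phasic only just above rheobase (the bundles
probe it at 100 pA), and the transient archetype's 5.6 nS sits on the
model's phasic boundary. Depolarizing probe amplitudes are therefore
per-class (120/200/100 pA). Bundles are pure functions of (spec, protocol,
seed), and every extracted feature has a scored truth entry.

What passing recovery tests show: the measurement code is unbiased at the
stated noise levels on data whose generative model is known. What they do
not show: robustness to 1/f noise, electrode drift, seal instability, or
spontaneous synaptic events, none of which the generator emulates.

## Problem sizes

The test suite classifies 29-point sweeps for the Kdr-only model and each
added-current variant, runs the dynamic-clamp additivity check at all 28
nonzero grid points, and uses 200 fit repetitions for the Boltzmann
recovery study (median |V̂½ − 8.4| ≈ 0.2 mV, accepted at < 1.5 mV); the
acceptance script reruns the 29-point sweep and the 200-seed recovery.

## Limitations

Single compartment, no temperature dependence (all kinetics at their
source-model room-temperature forms), deterministic channels, no I_h or
inward-rectifier biophysics (emulated only as ohmic difference components
or a voltage surrogate), ideal current clamp, and no attempt to reproduce
group-level statistics of the recorded populations — the published means
enter only as generator parameters.
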