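# leakfire

How a voltage-independent background potassium ("leak") conductance, by
itself, switches a neuron between firing a single action potential (phasic),
a short terminating train (transient), or a sustained train (tonic).

Neurons of the zebra finch caudomedial nidopallium (NCM) — a songbird
auditory forebrain area analogous to supragranular auditory cortex — fire
phasically without expressing the low-threshold Kv1-type potassium currents
that produce phasic firing in auditory brainstem neurons. Instead, phasic
NCM cells carry an unusually large Ba²⁺-sensitive K⁺ leak (KCNK-family)
conductance. This package implements the conductance-based point-neuron
model of such a cell and the full electrophysiology analysis pipeline
needed to demonstrate the mechanism in silico, for computational
neuroscientists and electrophysiologists who want a tested, scriptable
version of the experiment.

## The model

A single compartment obeying

    C dV/dt = −I_Na − I_Kdr [− I_Klt − I_Kht − I_Ka] − I_L + I_app

with C = 1 µF/cm² over 1.2×10⁻⁵ cm² (12 pF), E_Na = 50 mV, E_K = −94 mV,
E_L = −77 mV. The delayed rectifier is `g_Kdr a² (V − E_K)` with Boltzmann
activation a∞ = 1/(1+exp((V½−V)/k)), V½ = 8.4 mV, k = 18.5 mV, τ_a = 3.2 ms;
transient Na is Hodgkin–Huxley m³h with a pluggable rate set (the
auditory-brainstem `rm2003` rates by default — see `docs/methods.md` for the
sensitivity analysis); optional low-threshold (w⁴z), high-threshold
(φn²+(1−φ)p, φ = 0.85) and A-type (m_F⁴h_F) K⁺ currents come from cochlear-
nucleus models. The leak is ohmic, `g_L (V − E_L)`, swept over 2.0–7.6 nS.

The analysis layer implements the measurement procedures of a patch-clamp
study: spike detection, dV/dt-criterion AP threshold, half-width, rheobase
by bisection, VI/IV construction from the final 100 ms of each step, input
resistance below −60 mV, membrane-τ and activation-τ exponential fits, sag,
capacitance from the capacitive-transient integral, P/−4 leak subtraction,
Boltzmann activation fits, difference-current (Ba²⁺-subtraction) reversal,
the K⁺ Nernst potential, and liquid-junction-potential correction. A
synthetic-recordings module generates noisy current/voltage-clamp bundles
with known ground truth so every measurement is scored against what was
put in.

## Worked example

```python
import leakfire as lf

params = lf.ncm_model_params()        # printed densities, 12 pF, 7.4 nS leak
for gl in (5.6, 5.4, 2.0):
    trace = lf.simulate_current_clamp(params.with_leak_nS(gl), lf.StepProtocol())
    spikes = lf.detect_spikes(trace)
    cls = lf.classify_firing(spikes, trace.protocol)
    print(f"gL = {gl:3.1f} nS -> {cls.count:2d} AP(s), {cls.label}")
print(f"E_K (Nernst, 2.5/150 mM, 25 C) = {lf.nernst_potential(2.5, 150.0):.1f} mV")
```

prints

    gL = 5.6 nS ->  1 AP(s), phasic
    gL = 5.4 nS ->  2 AP(s), transient
    gL = 2.0 nS -> 47 AP(s), tonic
    E_K (Nernst, 2.5/150 mM, 25 C) = -105.2 mV

i.e. lowering the leak alone, with every voltage-gated conductance held
fixed, carries the cell from one AP (phasic) through a terminating
two-spike response (transient) into sustained ~94 Hz firing (tonic). The
Nernst value is the theoretical K⁺ equilibrium potential for the recording
solutions (2.5 mM K⁺ outside, 150 mM inside at 25 °C), against which the
measured reversal of the Ba²⁺-sensitive difference current is compared.

## Analyses

Numbered drivers under `analysis/` write tables to `results/`
(bulky regenerable traces go to `scratch/`):

1. `01_leak_sweep.py` — firing class vs. leak over the 0.2 nS grid, at five
   delayed-rectifier scalings (60–140%), with the class-boundary summary.
2. `02_variant_currents.py` — the same sweep with added A-type /
   low-threshold / high-threshold K⁺ currents, and the Na-kinetics
   sensitivity table.
3. `03_dynamic_clamp_rescue.py` — control → leak-reduced → rescued-by-
   artificial-conductance, through the simulated 100 µs dynamic-clamp loop.
4. `04_feature_recovery.py` — synthetic archetype recordings scored against
   ground truth (R_i, τ_m, sag, difference conductance and reversal).

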