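"""Patch-clamp feature extraction.

Implements the measurement procedures used on current- and voltage-clamp
records: spike detection and AP waveform metrics (dV/dt threshold,
half-width), firing-pattern classification (silent / phasic / transient /
tonic), passive properties (input resistance from the VI slope below
-60 mV, membrane time constant, sag, capacitance from the capacitive-
transient integral), rheobase by bisection, P/-4 leak subtraction,
Boltzmann activation fits, difference-current reversal, the Nernst
potential, and liquid-junction-potential correction.

All fits report residual diagnostics; every function is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .protocol_engine import (
    StepProtocol,
    Trace,
    SolverOptions,
    simulate_current_clamp,
)
from .biophysics_core import MembraneParams

__all__ = [
    "SpikeTrain",
    "FiringClass",
    "PassiveFit",
    "BoltzmannFit",
    "LinearIVFit",
    "detect_spikes",
    "ap_waveform_features",
    "classify_firing",
    "rheobase_and_latency",
    "build_vi_iv",
    "input_resistance",
    "fit_membrane_tau",
    "sag_amplitude",
    "capacitance_from_transient",
    "p_over_minus4_subtract",
    "boltzmann_activation_fit",
    "activation_tau_fit",
    "difference_current_reversal",
    "nernst_potential",
    "junction_correct",
    "NotExcitableError",
]

#: Spike detector: upward crossing of this level followed by a local maximum.
SPIKE_DETECT_LEVEL_MV = -10.0
#: Minimum separation between consecutive spike peaks.
SPIKE_REFRACTORY_MS = 2.0
#: Floor on the dV/dt threshold criterion (mV/ms); engages when the baseline
#: is noiseless so that 2 x SD would be zero.
DVDT_FLOOR_MV_PER_MS = 1.0


class NotExcitableError(RuntimeError):
    """No spike at the maximum tested stimulus amplitude."""


@dataclass
class SpikeTrain:
    """Spike times at the AP peak, with per-spike waveform annotations."""

    times_ms: np.ndarray
    peaks_mV: np.ndarray
    threshold_mV: np.ndarray | None = None
    threshold_t_ms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.peaks_mV = np.asarray(self.peaks_mV, dtype=float)
        if self.times_ms.size != self.peaks_mV.size:
            raise ValueError("times and peaks must have equal length")
        if self.times_ms.size > 1:
            d = np.diff(self.times_ms)
            if np.any(d <= 0):
                raise ValueError("spike times must be strictly increasing")
            if np.any(d < SPIKE_REFRACTORY_MS):
                raise ValueError(
                    f"consecutive peaks closer than {SPIKE_REFRACTORY_MS} ms")

    def __len__(self) -> int:
        return int(self.times_ms.size)


@dataclass(frozen=True)
class FiringClass:
    """Operational firing-pattern label.

    silent: no AP during the step; phasic: exactly one AP regardless of
    timing; transient: >= 2 APs that cease well before stimulus offset;
    tonic: >= 2 APs sustained to the end of the step.
    """

    label: str
    count: int

    def __post_init__(self) -> None:
        if self.label not in ("silent", "phasic", "transient", "tonic"):
            raise ValueError(f"unknown firing class {self.label!r}")
        if (self.label == "silent") != (self.count == 0):
            raise ValueError("silent iff zero spikes")
        if (self.label == "phasic") != (self.count == 1):
            raise ValueError("phasic iff exactly one spike")
        if self.label in ("transient", "tonic") and self.count < 2:
            raise ValueError("transient/tonic require >= 2 spikes")


@dataclass
class PassiveFit:
    R_i_MOhm: float | None = None
    tau_m_ms: float | None = None
    sag_mV: float | None = None
    C_m_pF: float | None = None
    residual_rms: float | None = None


@dataclass
class BoltzmannFit:
    V_half_mV: float
    slope_k_mV: float
    G_max: float
    stderr: dict = field(default_factory=dict)
    residual_rms: float = 0.0


@dataclass
class LinearIVFit:
    g_nS: float
    E_rev_mV: float
    r_squared: float
    stderr: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Spikes and firing class
# ---------------------------------------------------------------------------

def _require_voltage(trace: Trace) -> None:
    if trace.unit != "mV":
        raise ValueError(f"expected a voltage trace, got unit {trace.unit!r}")


def detect_spikes(trace: Trace, level_mV: float = SPIKE_DETECT_LEVEL_MV,
                  min_separation_ms: float = SPIKE_REFRACTORY_MS) -> SpikeTrain:
    """Locate APs as upward crossings of ``level_mV`` followed by a local
    maximum, enforcing a minimum peak separation.

    Returns peak times and amplitudes; per-spike thresholds are filled by
    :func:`ap_waveform_features`.
    """
    _require_voltage(trace)
    v = trace.values
    t = trace.t_ms
    above = v >= level_mV
    # indices where the trace crosses the level upward
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times, peaks = [], []
    for c in crossings:
        # local maximum of the supra-level excursion
        end = c
        while end < v.size and v[end] >= level_mV:
            end += 1
        seg = slice(c, end)
        j = c + int(np.argmax(v[seg]))
        if times and t[j] - times[-1] < min_separation_ms:
            # merge with the previous peak, keeping the larger
            if v[j] > peaks[-1]:
                times[-1], peaks[-1] = t[j], v[j]
            continue
        times.append(float(t[j]))
        peaks.append(float(v[j]))
    return SpikeTrain(np.array(times), np.array(peaks))


def classify_firing(spike_train: SpikeTrain, protocol: StepProtocol,
                    tonic_isi_factor: float = 1.5) -> FiringClass:
    """Classify the response to a depolarizing step.

    >= 2 spikes are tonic when the last spike falls within
    ``tonic_isi_factor`` median inter-spike intervals of the stimulus
    offset (firing sustained to the end), transient otherwise.
    """
    n = len(spike_train)
    if n == 0:
        return FiringClass("silent", 0)
    if n == 1:
        return FiringClass("phasic", 1)
    isis = np.diff(spike_train.times_ms)
    cutoff = protocol.offset_ms - tonic_isi_factor * float(np.median(isis))
    label = "tonic" if spike_train.times_ms[-1] > cutoff else "transient"
    return FiringClass(label, n)


def ap_waveform_features(trace: Trace, spike_train: SpikeTrain,
                         dvdt_floor: float = DVDT_FLOOR_MV_PER_MS,
                         min_baseline_ms: float = 50.0) -> pd.DataFrame:
    """Per-spike threshold, peak and half-width.

    Threshold: the first sample of the upstroke where dV/dt reaches
    max(2 x SD of the pre-stimulus baseline dV/dt, ``dvdt_floor``).
    Half-width: duration at the voltage halfway between threshold and peak,
    by linear interpolation between samples.  Requires a pre-stimulus
    baseline (>= ``min_baseline_ms``) to estimate the dV/dt noise SD.
    """
    _require_voltage(trace)
    proto = trace.protocol
    if proto is None or proto.onset_ms < min_baseline_ms:
        raise ValueError(
            f"need >= {min_baseline_ms} ms pre-stimulus baseline for the dV/dt SD")
    t, v = trace.t_ms, trace.values
    dvdt = np.gradient(v, t)
    base = dvdt[t < proto.onset_ms]
    crit = max(2.0 * float(np.std(base)), dvdt_floor)

    rows = []
    thr_v = np.full(len(spike_train), np.nan)
    thr_t = np.full(len(spike_train), np.nan)
    for i, (tp, vp) in enumerate(zip(spike_train.times_ms, spike_train.peaks_mV)):
        j_peak = int(np.argmin(np.abs(t - tp)))
        j_start = 0 if i == 0 else int(np.argmin(np.abs(t - spike_train.times_ms[i - 1])))
        # anchor the upstroke at the last local minimum of dV/dt before the
        # spike's maximal rate of rise, so the subthreshold charging phase
        # (which can itself exceed the criterion on clean traces) is excluded
        j_up = j_start + int(np.argmax(dvdt[j_start:j_peak + 1]))
        j_foot = j_up
        while j_foot > j_start and dvdt[j_foot - 1] <= dvdt[j_foot]:
            j_foot -= 1
        # first supra-criterion sample of the upstroke proper
        j = j_foot
        while j < j_peak and dvdt[j] < crit:
            j += 1
        if dvdt[j] < crit:  # no supra-criterion sample: leave NaN
            rows.append({"threshold_mV": np.nan, "threshold_t_ms": np.nan,
                         "peak_mV": vp, "half_width_ms": np.nan})
            continue
        v_thr, t_thr = float(v[j]), float(t[j])
        thr_v[i], thr_t[i] = v_thr, t_thr
        v_half = 0.5 * (v_thr + vp)
        # rising crossing of v_half before the peak
        jr = j_peak
        while jr > 0 and v[jr - 1] > v_half:
            jr -= 1
        t_rise = _interp_crossing(t, v, jr - 1, v_half) if jr > 0 else t[0]
        # falling crossing after the peak
        jf = j_peak
        while jf < v.size - 1 and v[jf + 1] > v_half:
            jf += 1
        t_fall = _interp_crossing(t, v, jf, v_half) if jf < v.size - 1 else t[-1]
        rows.append({"threshold_mV": v_thr, "threshold_t_ms": t_thr,
                     "peak_mV": vp, "half_width_ms": float(t_fall - t_rise)})
    spike_train.threshold_mV = thr_v
    spike_train.threshold_t_ms = thr_t
    return pd.DataFrame(rows)


def _interp_crossing(t: np.ndarray, v: np.ndarray, j: int, level: float) -> float:
    """Linear-interpolated time where v crosses ``level`` between j and j+1."""
    v0, v1 = v[j], v[j + 1]
    if v1 == v0:
        return float(t[j])
    return float(t[j] + (level - v0) / (v1 - v0) * (t[j + 1] - t[j]))


def rheobase_and_latency(params: MembraneParams, step_ms: float = 500.0,
                         resolution_pA: float = 5.0, i_max_pA: float = 1000.0,
                         baseline_ms: float = 100.0,
                         solver: SolverOptions = SolverOptions()) -> tuple[float, float]:
    """Minimum step current eliciting an AP, and first-spike latency there.

    Bisection between a silent and a spiking amplitude down to
    ``resolution_pA``; latency is measured on the rheobase trace from
    stimulus onset to the AP threshold time (dV/dt criterion).
    Raises :class:`NotExcitableError` if ``i_max_pA`` fails to elicit a spike.
    """

    def n_spikes_at(amp: float) -> tuple[int, Trace]:
        proto = StepProtocol(baseline_ms=baseline_ms, step_ms=step_ms,
                             amplitude=amp, post_ms=50.0)
        tr = simulate_current_clamp(params, proto, solver=solver)
        return len(detect_spikes(tr)), tr

    n_hi, tr_hi = n_spikes_at(i_max_pA)
    if n_hi == 0:
        raise NotExcitableError(
            f"no spike at the maximum tested amplitude {i_max_pA} pA")
    lo, hi = 0.0, i_max_pA
    while hi - lo > resolution_pA:
        mid = 0.5 * (lo + hi)
        n_mid, tr_mid = n_spikes_at(mid)
        if n_mid > 0:
            hi, tr_hi = mid, tr_mid
        else:
            lo = mid
    st = detect_spikes(tr_hi)
    feats = ap_waveform_features(tr_hi, st)
    t_thr = feats["threshold_t_ms"].iloc[0]
    if not np.isfinite(t_thr):
        t_thr = st.times_ms[0]
    latency = float(t_thr - tr_hi.protocol.onset_ms)
    return float(hi), latency


# ---------------------------------------------------------------------------
# Passive properties
# ---------------------------------------------------------------------------

def build_vi_iv(traces: list[Trace], window_ms: float = 100.0) -> pd.DataFrame:
    """Steady-state (command, response) points from a family of step traces.

    The steady response is the mean over the final ``window_ms`` of the step;
    one point per trace.  Works for VI (current command -> voltage) and IV
    (voltage command -> current) families alike.
    """
    rows = []
    for tr in traces:
        proto = tr.protocol
        if proto is None:
            raise ValueError("every trace needs protocol annotation")
        if window_ms > proto.step_ms:
            raise ValueError(
                f"window {window_ms} ms exceeds the step duration {proto.step_ms} ms")
        sel = (tr.t_ms >= proto.offset_ms - window_ms) & (tr.t_ms < proto.offset_ms)
        level = proto.holding + proto.amplitude
        rows.append({"command": float(level),
                     "steady": float(np.mean(tr.values[sel])),
                     "unit": tr.unit})
    return pd.DataFrame(rows)


def input_resistance(vi_points: pd.DataFrame, v_max_mV: float = -60.0) -> float:
    """Input resistance (MOhm) from the slope of the VI relation.

    Uses only points with steady-state potential negative to ``v_max_mV``.
    Expects ``command`` in pA and ``steady`` in mV; the least-squares slope
    mV/pA equals GOhm, returned in MOhm.
    """
    pts = vi_points[vi_points["steady"] < v_max_mV]
    if len(pts) < 2:
        raise ValueError(
            f"need >= 2 VI points negative to {v_max_mV} mV, have {len(pts)}")
    slope = np.polyfit(pts["command"].to_numpy(), pts["steady"].to_numpy(), 1)[0]
    return float(slope * 1e3)  # GOhm -> MOhm


def fit_membrane_tau(trace: Trace, t_start_ms: float, t_end_ms: float) -> tuple[float, float]:
    """Membrane time constant from a single-exponential fit
    ``V(t) = offset + amp * exp(-(t - t0)/tau)`` over [t_start, t_end].

    Returns (tau_ms, residual RMS in mV); the RMS flags poor
    (e.g. biexponential) fits.
    """
    sel = (trace.t_ms >= t_start_ms) & (trace.t_ms <= t_end_ms)
    t = trace.t_ms[sel]
    v = trace.values[sel]
    if t.size < 5:
        raise ValueError("need >= 5 samples in the fit segment")
    t0 = t[0]
    off0 = v[-1]
    amp0 = v[0] - off0
    # crude tau init from the 1/e point
    tau0 = max((t[-1] - t0) / 3.0, 1e-3)

    def model(tt, off, amp, tau):
        return off + amp * np.exp(-(tt - t0) / tau)

    popt, _ = curve_fit(model, t, v, p0=(off0, amp0, tau0), maxfev=20000,
                        bounds=([-np.inf, -np.inf, 1e-6], np.inf))
    resid = v - model(t, *popt)
    return float(popt[2]), float(np.sqrt(np.mean(resid ** 2)))


def sag_amplitude(trace: Trace, early_window_ms: float = 200.0,
                  steady_window_ms: float = 100.0,
                  smooth_ms: float = 2.0) -> float:
    """Depolarizing sag during a hyperpolarizing step (mV, positive = present).

    Measured as (steady mean over the final ``steady_window_ms`` of the step)
    minus (early minimum within ``early_window_ms`` of onset): when the
    membrane dips below its steady level and relaxes back, the value is
    positive and equals the size of the relaxation.  The early extremum is
    taken on a boxcar-smoothed copy (``smooth_ms``) so it is not biased by
    the per-sample noise floor.
    """
    _require_voltage(trace)
    proto = trace.protocol
    if proto is None:
        raise ValueError("sag needs protocol annotation")
    if proto.amplitude >= 0:
        raise ValueError("sag is defined on hyperpolarizing steps only")
    t, v = trace.t_ms, trace.values
    if smooth_ms > 0:
        n = max(1, int(round(smooth_ms / trace.dt_ms)))
        v_s = np.convolve(v, np.ones(n) / n, mode="same")
    else:
        v_s = v
    early = (t >= proto.onset_ms) & (t < proto.onset_ms + early_window_ms)
    steady = (t >= proto.offset_ms - steady_window_ms) & (t < proto.offset_ms)
    return float(np.mean(v[steady]) - np.min(v_s[early]))


def capacitance_from_transient(trace: Trace, delta_V_mV: float,
                               window_ms: float | None = None) -> float:
    """Whole-cell capacitance (pF) from the integral of the capacitive
    transient after a voltage step.

    The steady leak level (mean of the final quarter of the step) is
    subtracted before integrating, so C_m = integral(I - I_steady) dt / dV.
    pA x ms / mV = pF.
    """
    if trace.unit != "pA":
        raise ValueError("capacitance needs a current trace")
    if delta_V_mV == 0:
        raise ValueError("delta V must be non-zero")
    proto = trace.protocol
    if proto is None:
        raise ValueError("needs protocol annotation")
    t, i = trace.t_ms, trace.values
    t_end = proto.offset_ms if window_ms is None else proto.onset_ms + window_ms
    sel = (t >= proto.onset_ms) & (t < t_end)
    if not np.any(sel):
        raise ValueError("empty integration window")
    steady_sel = (t >= proto.offset_ms - 0.25 * proto.step_ms) & (t < proto.offset_ms)
    i_steady = float(np.mean(i[steady_sel]))
    q = np.trapezoid(i[sel] - i_steady, t[sel])  # pA*ms = fC
    return float(q / delta_V_mV)  # fC/mV = pF


# ---------------------------------------------------------------------------
# Subtraction protocols and fits
# ---------------------------------------------------------------------------

def p_over_minus4_subtract(main: Trace, sub_traces: list[Trace]) -> Trace:
    """P/-4 leak subtraction: remove leak and capacitive currents using four
    quarter-amplitude inverted sub-pulses.

    Each trace is first zeroed on its own pre-pulse baseline (the holding
    current does not scale with the pulse), then the sub responses are scaled
    by the amplitude ratio (main/sub = -4) and subtracted, so a purely ohmic
    cell yields ~0 everywhere: corrected = (main - b) + 4 * mean(sub - b').
    """
    if len(sub_traces) != 4:
        raise ValueError(f"P/-4 needs exactly 4 sub-pulse traces, got {len(sub_traces)}")
    mp = main.protocol
    for s in sub_traces:
        sp = s.protocol
        if sp is None or mp is None:
            raise ValueError("all traces need protocol annotation")
        if not (np.isclose(sp.onset_ms, mp.onset_ms) and np.isclose(sp.offset_ms, mp.offset_ms)):
            raise ValueError("sub-pulse timing must match the main pulse")
        if not np.isclose(sp.amplitude, -mp.amplitude / 4.0):
            raise ValueError(
                f"sub-pulse amplitude {sp.amplitude} is not -1/4 of main {mp.amplitude}")
        if s.t_ms.size != main.t_ms.size:
            raise ValueError("sub-pulse sampling must match the main pulse")
    def zeroed(tr: Trace) -> np.ndarray:
        base = tr.values[tr.t_ms < tr.protocol.onset_ms]
        return tr.values - (float(np.mean(base)) if base.size else 0.0)

    mean_sub = np.mean([zeroed(s) for s in sub_traces], axis=0)
    corrected = zeroed(main) + 4.0 * mean_sub
    return Trace(main.t_ms, corrected, main.unit, protocol=mp,
                 meta={**main.meta, "leak_subtracted": "P/-4"})


def boltzmann_activation_fit(V_mV: np.ndarray, G: np.ndarray) -> BoltzmannFit:
    """Least-squares Boltzmann fit G = G_max / (1 + exp((V_half - V)/k)).

    Expects >= 4 (V, G) points spanning the midpoint; G is typically
    steady-state conductance I/(V - EK) normalized to its maximum.
    """
    V = np.asarray(V_mV, dtype=float)
    G = np.asarray(G, dtype=float)
    if V.size < 4:
        raise ValueError("need >= 4 (V, G) points")
    if np.allclose(G, G[0]):
        raise ValueError("degenerate activation data (all G equal)")

    def model(v, gmax, vh, k):
        return gmax / (1.0 + np.exp((vh - v) / k))

    gmax0 = float(np.max(G))
    vh0 = float(V[np.argmin(np.abs(G - 0.5 * gmax0))])
    popt, pcov = curve_fit(model, V, G, p0=(gmax0, vh0, 10.0), maxfev=20000)
    perr = np.sqrt(np.diag(pcov))
    resid = G - model(V, *popt)
    return BoltzmannFit(V_half_mV=float(popt[1]), slope_k_mV=float(popt[2]),
                        G_max=float(popt[0]),
                        stderr={"G_max": float(perr[0]), "V_half": float(perr[1]),
                                "k": float(perr[2])},
                        residual_rms=float(np.sqrt(np.mean(resid ** 2))))


def activation_tau_fit(trace: Trace, fit_span_ms: float | None = None) -> tuple[float, float]:
    """Activation time constant of an outward current: single-exponential fit
    to the rising phase after step onset.

    Returns (tau_ms, residual RMS in pA).
    """
    if trace.unit != "pA":
        raise ValueError("activation fit needs a current trace")
    proto = trace.protocol
    if proto is None:
        raise ValueError("needs protocol annotation")
    t, i = trace.t_ms, trace.values
    sel = (t >= proto.onset_ms) & (t < proto.offset_ms)
    tt, ii = t[sel], i[sel]
    # fit to the end of the rise (or a caller-set span)
    if fit_span_ms is None:
        j_end = int(np.argmax(ii)) + 1
        j_end = max(j_end, 5)
    else:
        j_end = int(np.searchsorted(tt, proto.onset_ms + fit_span_ms))
    tt, ii = tt[:j_end], ii[:j_end]
    if tt.size < 5:
        raise ValueError("rising phase too short to fit")
    # skip the sigmoidal foot produced by higher-order gating (a^2 etc.):
    # start at 30% of the rise so the single exponential sees the
    # tail-dominated part of the activation, where the squared-gate current
    # decays with the gate's own time constant (residual bias ~ +14% for a^2)
    i0, i_end = ii[0], ii[-1]
    rise = np.abs(ii - i0) >= 0.3 * abs(i_end - i0)
    if np.any(rise):
        j0 = int(np.argmax(rise))
        if tt.size - j0 >= 5:
            tt, ii = tt[j0:], ii[j0:]
    t0 = tt[0]
    iss0 = ii[-1]

    def model(x, iss, amp, tau):
        return iss + amp * np.exp(-(x - t0) / tau)

    popt, _ = curve_fit(model, tt, ii, p0=(iss0, ii[0] - iss0, (tt[-1] - t0) / 3.0),
                        maxfev=20000)
    resid = ii - model(tt, *popt)
    return float(abs(popt[2])), float(np.sqrt(np.mean(resid ** 2)))


def difference_current_reversal(control_iv: pd.DataFrame,
                                blocked_iv: pd.DataFrame) -> LinearIVFit:
    """Ohmic fit of the (control - blocked) difference current.

    Both inputs are IV tables from :func:`build_vi_iv` (command in mV,
    steady in pA) at matching potentials.  Slope pA/mV = nS;
    E_rev = -intercept/slope.
    """
    if len(control_iv) < 2 or len(control_iv) != len(blocked_iv):
        raise ValueError("need >= 2 matching IV points in both conditions")
    V = control_iv["command"].to_numpy(dtype=float)
    if not np.allclose(V, blocked_iv["command"].to_numpy(dtype=float)):
        raise ValueError("control and blocked IVs must share command potentials")
    dI = control_iv["steady"].to_numpy(dtype=float) - blocked_iv["steady"].to_numpy(dtype=float)
    A = np.vstack([V, np.ones_like(V)]).T
    (slope, intercept), res, *_ = np.linalg.lstsq(A, dI, rcond=None)
    if abs(slope) < 1e-12:
        raise ValueError("zero difference slope: reversal potential undefined")
    pred = slope * V + intercept
    ss_res = float(np.sum((dI - pred) ** 2))
    ss_tot = float(np.sum((dI - np.mean(dI)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LinearIVFit(g_nS=float(slope), E_rev_mV=float(-intercept / slope),
                       r_squared=float(min(max(r2, 0.0), 1.0)))


# Gas constant R = 8.314462618 J/(mol K), Faraday F = 96485.33212 C/mol
_R_OVER_F_mV_per_K = 8.314462618 / 96485.33212 * 1e3


def nernst_potential(K_out_mM: float, K_in_mM: float, T_celsius: float = 25.0) -> float:
    """Potassium Nernst equilibrium potential (mV): (RT/F) ln([K]out/[K]in)."""
    if K_out_mM <= 0 or K_in_mM <= 0:
        raise ValueError("concentrations must be positive")
    T = T_celsius + 273.15
    return float(_R_OVER_F_mV_per_K * T * np.log(K_out_mM / K_in_mM))


def junction_correct(trace: Trace, ljp_mV: float = 10.0) -> Trace:
    """Correct a voltage trace for the liquid junction potential.

    All potentials shift by -LJP; a metadata flag guards idempotence (a
    second correction returns the trace unchanged with a warning).
    """
    _require_voltage(trace)
    if trace.meta.get("ljp_corrected"):
        warnings.warn("trace already junction-corrected; returning unchanged",
                      stacklevel=2)
        return trace
    out = Trace(trace.t_ms, trace.values - ljp_mV, trace.unit,
                protocol=trace.protocol, stimulus=trace.stimulus,
                meta={**trace.meta, "ljp_corrected": ljp_mV})
    return out
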