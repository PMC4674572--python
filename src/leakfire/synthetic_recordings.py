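"""Synthetic current- and voltage-clamp recordings with known ground truth.

Stand-ins for raw patch-clamp data: three archetype cells (tonic, transient,
phasic) whose leak conductances are set from the published per-class input
resistance means, model-integrated protocol families with additive Gaussian
recording noise, drug-subtraction (control vs. Ba2+-blocked) voltage-clamp
pairs whose difference current is ohmic by construction, and noisy
steady-state activation datasets for Boltzmann-fit recovery.

Every bundle is a pure function of (spec, protocol, seed); the ground-truth
record carries enough to score each feature the bundle exercises.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np

from .biophysics_core import MembraneParams, find_resting_state
from .protocol_engine import (
    StepProtocol,
    Trace,
    SolverOptions,
    simulate_current_clamp,
    simulate_voltage_clamp,
)
from .ephys_features import detect_spikes

__all__ = [
    "ArchetypeSpec",
    "RecordingBundle",
    "ARCHETYPE_TABLE",
    "make_archetype",
    "generate_cc_bundle",
    "generate_vc_bundle",
    "generate_activation_points",
]

#: Published per-class means used as generator targets: input resistance
#: (MOhm), resting potential (mV, junction-corrected), sag (mV, tonic only),
#: and membrane time constant (ms).  These parameterize the generator; they
#: are population values from real cells, not reproduction claims.
ARCHETYPE_TABLE = {
    "tonic": {"R_i_MOhm": 276.1, "rmp_mV": -62.7, "sag_mV": 4.5, "tau_m_ms": 44.5,
              "depol_pA": 120.0},
    "transient": {"R_i_MOhm": 179.2, "rmp_mV": -66.7, "sag_mV": 0.0, "tau_m_ms": 22.3,
                  "depol_pA": 200.0},
    "phasic": {"R_i_MOhm": 125.0, "rmp_mV": -66.8, "sag_mV": 0.0, "tau_m_ms": 13.9,
               "depol_pA": 100.0},
}

#: Default additive white recording noise.
NOISE_SIGMA_MV = 0.2
NOISE_SIGMA_PA = 5.0
#: Time constant of the sag surrogate (single-exponential conductance
#: relaxation emulating Ih, which the model itself does not contain).
SAG_TAU_MS = 60.0


@dataclass(frozen=True)
class ArchetypeSpec:
    """Generator settings for one synthetic cell."""

    label: str
    R_i_MOhm: float
    leak_nS: float
    rmp_mV: float
    sag_mV: float = 0.0
    noise_sigma_mV: float = NOISE_SIGMA_MV
    noise_sigma_pA: float = NOISE_SIGMA_PA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in ARCHETYPE_TABLE:
            raise ValueError(f"unknown archetype {self.label!r}")
        if abs(1e3 / self.leak_nS - self.R_i_MOhm) / self.R_i_MOhm > 0.10:
            raise ValueError(
                f"R_i {self.R_i_MOhm} MOhm inconsistent with leak {self.leak_nS} nS")


@dataclass
class RecordingBundle:
    """A set of traces plus the ground truth needed to score them."""

    traces: dict[str, Trace]
    truth: dict
    spec: ArchetypeSpec

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tr in self.traces.items():
            tr.save_csv(out / f"{name}.csv")
            side = {"protocol": asdict(tr.protocol) if tr.protocol else None,
                    "unit": tr.unit, "meta": tr.meta}
            (out / f"{name}.json").write_text(json.dumps(side, indent=2))
        (out / "truth.json").write_text(json.dumps(self.truth, indent=2, default=float))


def make_archetype(label: str, seed: int = 0) -> tuple[ArchetypeSpec, MembraneParams]:
    """Archetype spec + model parameters for one firing class.

    The leak is the inverse of the published class-mean input resistance,
    rounded to the 0.1 nS the sweep reports (tonic 276 MOhm -> 3.6 nS,
    transient 179 -> 5.6 nS, phasic 125 -> 8.0 nS); all other densities stay
    at the published model values.  The resting potential is brought into the
    published range by an offset on EL, recorded in the ground truth.  Note
    the class label is assigned by construction from the measured population,
    not by the model's own dynamics (the printed transient-cell mean leak
    sits on the model's phasic boundary).
    """
    if label not in ARCHETYPE_TABLE:
        raise ValueError(f"unknown archetype {label!r}; choose from {sorted(ARCHETYPE_TABLE)}")
    row = ARCHETYPE_TABLE[label]
    leak_nS = round(1e3 / row["R_i_MOhm"], 1)
    params = MembraneParams().with_leak_nS(leak_nS)
    # shift EL until the full model rests at the published class-mean RMP
    target = row["rmp_mV"]
    el = target
    for _ in range(4):
        trial = replace(params, EL=el)
        v_rest = find_resting_state(trial).V
        el += target - v_rest
    params = replace(params, EL=el)
    spec = ArchetypeSpec(label=label, R_i_MOhm=row["R_i_MOhm"], leak_nS=leak_nS,
                         rmp_mV=target, sag_mV=row["sag_mV"], seed=seed)
    return spec, params


def _sag_surrogate(trace: Trace, sag_mV: float, delay_ms: float,
                   tau_ms: float = SAG_TAU_MS) -> np.ndarray:
    """Slow depolarizing relaxation added to hyperpolarizing steps.

    Emulates the Ih signature of tonic cells as a single-exponential
    relaxation of amplitude ``sag_mV``, switched on once the passive
    transient has settled (``delay_ms`` after onset) so the built-in
    amplitude is exactly what the early-minimum-vs-steady measurement
    recovers; the underlying model has no Ih current.
    """
    proto = trace.protocol
    t = trace.t_ms
    add = np.zeros_like(t)
    on, off = proto.onset_ms + delay_ms, proto.offset_ms
    in_step = (t >= on) & (t < off)
    add[in_step] = sag_mV * (1.0 - np.exp(-(t[in_step] - on) / tau_ms))
    after = t >= off
    plateau = sag_mV * (1.0 - np.exp(-max(off - on, 0.0) / tau_ms))
    add[after] = plateau * np.exp(-(t[after] - off) / tau_ms)
    return add


def generate_cc_bundle(spec: ArchetypeSpec, params: MembraneParams,
                       amplitudes_pA: tuple[float, ...] | None = None,
                       step_ms: float = 500.0,
                       noise_sigma_mV: float | None = None,
                       seed: int | None = None,
                       solver: SolverOptions = SolverOptions()) -> RecordingBundle:
    """Current-clamp bundle: square steps at several amplitudes with noise.

    Hyperpolarizing steps carry the archetype's sag surrogate; ground truth
    includes the noiseless spike times, the true leak-only input resistance
    (1/g_L) and the true passive time constant C/g_L.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    sigma = spec.noise_sigma_mV if noise_sigma_mV is None else noise_sigma_mV
    if amplitudes_pA is None:
        # two hyperpolarizing steps for passive properties plus one
        # depolarizing step sized per class: just-suprathreshold for the
        # narrow phasic window of the elevated-RMP archetype, stronger for
        # the repetitively firing classes
        amplitudes_pA = (-50.0, -25.0, ARCHETYPE_TABLE[spec.label]["depol_pA"])
    traces: dict[str, Trace] = {}
    truth: dict = {
        "label": spec.label,
        "leak_nS": spec.leak_nS,
        "R_i_MOhm_true": 1e3 / spec.leak_nS,
        "tau_m_ms_true": params.C_total_pF / spec.leak_nS,
        "EL_mV": params.EL,
        "sag_mV_true": {},
        "spike_times_ms": {},
    }
    for amp in amplitudes_pA:
        proto = StepProtocol(baseline_ms=100.0, step_ms=step_ms, amplitude=amp,
                             post_ms=200.0)
        clean = simulate_current_clamp(params, proto, solver=solver)
        name = f"cc_{'m' if amp < 0 else 'p'}{abs(amp):g}pA"
        truth["spike_times_ms"][name] = detect_spikes(clean).times_ms.tolist()
        v = clean.values.copy()
        sag_true = 0.0
        if amp < 0 and spec.sag_mV > 0:
            settle_ms = 5.0 * params.C_total_pF / spec.leak_nS  # 5 tau_m
            v = v + _sag_surrogate(clean, spec.sag_mV, delay_ms=settle_ms)
            sag_true = spec.sag_mV
        truth["sag_mV_true"][name] = sag_true
        if sigma > 0:
            v = v + rng.normal(0.0, sigma, size=v.shape)
        traces[name] = Trace(clean.t_ms, v, "mV", protocol=proto,
                             stimulus=clean.stimulus,
                             meta={**clean.meta, "noise_sigma_mV": sigma,
                                   "archetype": spec.label})
    return RecordingBundle(traces=traces, truth=truth, spec=spec)


def _split_leak(params: MembraneParams, g_extra_nS: float,
                E_extra_mV: float) -> tuple[MembraneParams, MembraneParams]:
    """(control, blocked) parameter pair whose leaks differ by exactly an
    ohmic component (g_extra, E_extra).

    blocked keeps the native leak; control carries native + extra combined
    into a single equivalent (g, E) pair, so control - blocked under voltage
    clamp is g_extra*(V - E_extra) exactly.
    """
    from .biophysics_core import convert_conductance

    g_extra = convert_conductance(g_extra_nS, "absolute_to_density", params.area)
    g_comb = params.gL + g_extra
    e_comb = (params.gL * params.EL + g_extra * E_extra_mV) / g_comb
    control = replace(params, gL=g_comb, EL=e_comb)
    return control, params


def generate_vc_bundle(spec: ArchetypeSpec, params: MembraneParams,
                       step_levels_mV: tuple[float, ...] = (-110.0, -90.0, -70.0),
                       holding_mV: float = -50.0,
                       include_ba_pair: bool = True,
                       ba_g_nS: float = 5.9, ba_E_mV: float = -98.6,
                       noise_sigma_pA: float | None = None,
                       seed: int | None = None,
                       solver: SolverOptions = SolverOptions()) -> RecordingBundle:
    """Voltage-clamp bundle: 1-s hyperpolarizing steps from -50 mV holding.

    With ``include_ba_pair`` every level carries a blocked-leak twin whose
    difference from control is the ohmic component (``ba_g_nS``,
    ``ba_E_mV``) — the published Ba2+-sensitive leak magnitude and reversal
    are the defaults.  Ground truth carries the true difference conductance
    and reversal.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    sigma = spec.noise_sigma_pA if noise_sigma_pA is None else noise_sigma_pA
    traces: dict[str, Trace] = {}
    truth: dict = {"label": spec.label, "holding_mV": holding_mV,
                   "levels_mV": list(step_levels_mV)}
    if include_ba_pair:
        control_p, blocked_p = _split_leak(params, ba_g_nS, ba_E_mV)
        truth["ba_g_nS_true"] = ba_g_nS
        truth["ba_E_mV_true"] = ba_E_mV
    else:
        control_p, blocked_p = params, None

    for lvl in step_levels_mV:
        proto = StepProtocol(baseline_ms=200.0, step_ms=1000.0,
                             amplitude=lvl - holding_mV, holding=holding_mV,
                             post_ms=200.0, dt_ms=0.1)  # 10 kHz VC acquisition
        for tag, p in (("control", control_p), ("blocked", blocked_p)):
            if p is None:
                continue
            clean = simulate_voltage_clamp(p, proto, solver=solver)
            i = clean.values.copy()
            if sigma > 0:
                i = i + rng.normal(0.0, sigma, size=i.shape)
            name = f"vc_{tag}_{lvl:g}mV"
            traces[name] = Trace(clean.t_ms, i, "pA", protocol=proto,
                                 stimulus=clean.stimulus,
                                 meta={**clean.meta, "condition": tag,
                                       "noise_sigma_pA": sigma,
                                       "archetype": spec.label})
    return RecordingBundle(traces=traces, truth=truth, spec=spec)


def generate_activation_points(rng: np.random.Generator,
                               V_half: float = 8.4, slope_k: float = 18.5,
                               voltages_mV: np.ndarray | None = None,
                               noise_frac: float = 0.02) -> tuple[np.ndarray, np.ndarray]:
    """Normalized steady-state activation points with multiplicative noise.

    G(V) = 1/(1 + exp((V_half - V)/k)) times (1 + N(0, noise_frac)); defaults
    are the published delayed-rectifier midpoint and slope over 8 voltages
    spanning -50 to +70 mV.
    """
    if voltages_mV is None:
        voltages_mV = np.linspace(-50.0, 70.0, 8)
    V = np.asarray(voltages_mV, dtype=float)
    G = 1.0 / (1.0 + np.exp((V_half - V) / slope_k))
    G = G * (1.0 + rng.normal(0.0, noise_frac, size=G.shape))
    return V, G
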