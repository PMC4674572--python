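"""Stimulation protocols over the point-neuron model.

Current-clamp square steps, ideal / series-resistance voltage clamp,
the leak-conductance sweep that maps firing class against background
K+ conductance, and a discrete-update (zero-order-hold) dynamic-clamp
loop emulating closed-loop conductance injection.

All simulations start from the model's resting state and use stiff-capable
adaptive integration (LSODA), split at stimulus discontinuities, then
resample onto the protocol's uniform grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .biophysics_core import (
    MembraneParams,
    NeuronState,
    GateValues,
    GATE_NAMES,
    find_resting_state,
    rhs,
    steady_state_gates,
    convert_conductance,
)

__all__ = [
    "StepProtocol",
    "Trace",
    "SweepResult",
    "OhmicConductanceSpec",
    "SolverOptions",
    "simulate_current_clamp",
    "simulate_voltage_clamp",
    "run_leak_sweep",
    "simulate_dynamic_clamp",
    "emulate_ba_subtraction",
    "DEFAULT_GL_GRID_NS",
    "VARIANT_DENSITIES",
]

#: Default leak grid (nS) for the firing-class sweep: 2.0-7.6 in 0.2 steps.
DEFAULT_GL_GRID_NS = np.round(np.arange(2.0, 7.6 + 1e-9, 0.2), 10)

#: Extra K-current densities (mS/cm^2) added by each sweep variant.
#: "klt20" is the low-threshold current at one tenth of its source-model
#: density (20 nS absolute); "klt200" the full 200 nS.
VARIANT_DENSITIES = {
    "kdr": {},
    "ka": {"gKa": 10.42},
    "klt20": {"gKlt": 1.667},
    "klt200": {"gKlt": 16.67},
    "kht": {"gKht": 12.50},
}


@dataclass(frozen=True)
class StepProtocol:
    """A square step riding on a holding level.

    Amplitude is in pA for current clamp and mV for voltage clamp; the
    holding level is a current (pA, usually 0) or the holding potential (mV).
    """

    baseline_ms: float = 100.0
    step_ms: float = 500.0
    amplitude: float = 120.0
    holding: float = 0.0
    post_ms: float = 100.0
    dt_ms: float = 0.02  # 50 kHz, the current-clamp acquisition rate

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("sampling interval must be positive")
        if self.baseline_ms < 0 or self.step_ms <= 0 or self.post_ms < 0:
            raise ValueError("durations must be non-negative (step positive)")

    @property
    def onset_ms(self) -> float:
        return self.baseline_ms

    @property
    def offset_ms(self) -> float:
        return self.baseline_ms + self.step_ms

    @property
    def total_ms(self) -> float:
        return self.baseline_ms + self.step_ms + self.post_ms

    def times(self) -> np.ndarray:
        n = int(round(self.total_ms / self.dt_ms)) + 1
        return np.arange(n) * self.dt_ms

    def stimulus(self, t: np.ndarray) -> np.ndarray:
        s = np.full_like(t, float(self.holding))
        s[(t >= self.onset_ms) & (t < self.offset_ms)] += self.amplitude
        return s


@dataclass
class Trace:
    """A uniformly sampled recording; the common currency of feature extraction."""

    t_ms: np.ndarray
    values: np.ndarray
    unit: str  # "mV" or "pA"
    protocol: StepProtocol | None = None
    stimulus: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t_ms.size < 2:
            raise ValueError("a trace needs at least two samples")
        if self.t_ms.shape != self.values.shape:
            raise ValueError("time base and values must have equal length")
        dt = np.diff(self.t_ms)
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("trace must be uniformly sampled")
        if self.unit not in ("mV", "pA"):
            raise ValueError(f"unit must be 'mV' or 'pA', got {self.unit!r}")

    @property
    def dt_ms(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0])

    def to_frame(self) -> pd.DataFrame:
        col = "V_mV" if self.unit == "mV" else "I_pA"
        df = pd.DataFrame({"t_ms": self.t_ms, col: self.values})
        if self.stimulus is not None:
            df["stim"] = self.stimulus
        return df

    def save_csv(self, path, every: int = 1) -> None:
        """Write t/value(/stim) columns as CSV, keeping every n-th sample."""
        df = self.to_frame()
        if every > 1:
            df = df.iloc[::every]
        df.to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path, protocol: StepProtocol | None = None) -> "Trace":
        df = pd.read_csv(path)
        if "V_mV" in df.columns:
            unit, col = "mV", "V_mV"
        elif "I_pA" in df.columns:
            unit, col = "pA", "I_pA"
        else:
            raise ValueError(f"{path}: no V_mV or I_pA column")
        stim = df["stim"].to_numpy() if "stim" in df.columns else None
        return cls(df["t_ms"].to_numpy(), df[col].to_numpy(), unit,
                   protocol=protocol, stimulus=stim)


@dataclass(frozen=True)
class OhmicConductanceSpec:
    """Artificial ohmic conductance injected by the dynamic-clamp loop."""

    g_nS: float
    E_rev_mV: float
    update_ms: float = 0.1  # the 100-us hardware command interval

    def __post_init__(self) -> None:
        if self.g_nS < 0:
            raise ValueError("conductance must be non-negative")
        if self.update_ms <= 0:
            raise ValueError("update interval must be positive")


@dataclass(frozen=True)
class SolverOptions:
    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-8
    max_step: float = np.inf


SweepResult = pd.DataFrame  # rows: gL_nS, vakc_scale, variant, n_spikes, firing_class


def _pA_to_density(i_pA: float, params: MembraneParams) -> float:
    """pA -> uA/cm^2 at the model's area."""
    return i_pA * 1e-6 / params.area


class SolverError(RuntimeError):
    pass


def _integrate_segments(params: MembraneParams, y0: np.ndarray,
                        breakpoints: Sequence[float],
                        currents: Sequence[float],
                        t_eval: np.ndarray,
                        solver: SolverOptions) -> np.ndarray:
    """Integrate piecewise-constant injected current, sampling at t_eval.

    breakpoints: [t0, t1, ..., tN] with len(currents) == N; the solver is
    restarted at each discontinuity so adaptive stepping never straddles one.
    Returns the full state array (n_state, len(t_eval)).
    """
    out = np.empty((y0.size, t_eval.size))
    y = np.asarray(y0, dtype=float)
    filled = 0
    for k in range(len(currents)):
        t0, t1 = breakpoints[k], breakpoints[k + 1]
        mask = (t_eval >= t0 - 1e-12) & (t_eval <= t1 + 1e-12) & (np.arange(t_eval.size) >= filled)
        seg_eval = t_eval[mask]
        sol = solve_ivp(rhs, (t0, t1), y, args=(params, currents[k]),
                        method=solver.method, rtol=solver.rtol, atol=solver.atol,
                        max_step=solver.max_step, t_eval=seg_eval if seg_eval.size else None,
                        dense_output=False)
        if not sol.success:
            raise SolverError(f"integration failed on [{t0}, {t1}] ms: {sol.message}")
        if seg_eval.size:
            out[:, filled:filled + seg_eval.size] = sol.y
            filled += seg_eval.size
        y = sol.y[:, -1] if sol.y.size else y
        if seg_eval.size and np.isclose(seg_eval[-1], t1):
            # restart exactly from the segment end
            y = out[:, filled - 1]
    if filled != t_eval.size:
        raise SolverError("resampling did not cover the full protocol grid")
    return out


def simulate_current_clamp(params: MembraneParams, protocol: StepProtocol,
                           solver: SolverOptions = SolverOptions(),
                           initial: NeuronState | None = None) -> Trace:
    """Membrane-voltage response to a square current step from rest.

    The step amplitude and holding level are in pA and are converted to
    current density through the model area.  Deterministic for fixed inputs.
    """
    state0 = initial if initial is not None else find_resting_state(params)
    t_eval = protocol.times()
    i_hold = _pA_to_density(protocol.holding, params)
    i_step = _pA_to_density(protocol.holding + protocol.amplitude, params)
    bp = [0.0, protocol.onset_ms, protocol.offset_ms, protocol.total_ms]
    cur = [i_hold, i_step, i_hold]
    if protocol.baseline_ms == 0:
        bp, cur = bp[1:], cur[1:]
    if protocol.post_ms == 0:
        bp, cur = bp[:-1], cur[:-1]
    y = _integrate_segments(params, state0.as_array(), bp, cur, t_eval, solver)
    return Trace(t_eval, y[0], "mV", protocol=protocol,
                 stimulus=protocol.stimulus(t_eval),
                 meta={"kind": "current_clamp", "gL_nS": params.gL_nS,
                       "na_kinetics": params.na_kinetics})


def _gate_rhs(t: float, g: np.ndarray, params: MembraneParams, V: float) -> np.ndarray:
    """Gate-only kinetics at a clamped potential."""
    full = np.concatenate([[V], g])
    return rhs(t, full, params, 0.0)[1:]


def simulate_voltage_clamp(params: MembraneParams, protocol: StepProtocol,
                           series_resistance_MOhm: float = 0.0,
                           solver: SolverOptions = SolverOptions()) -> Trace:
    """Clamp current during a voltage step (holding -> holding+amplitude, in mV).

    With an ideal clamp (Rs = 0) the membrane potential follows the command
    exactly and the recorded current is the ionic current alone (the
    capacitive impulse at the edge is not representable).  With Rs > 0 the
    membrane charges through the pipette and the record includes the
    capacitive transient decaying with tau = Rs * C_total.
    Output current is in pA (outward positive, amplifier convention).
    """
    t_eval = protocol.times()
    v_hold = float(protocol.holding)
    v_step = v_hold + protocol.amplitude
    area = params.area

    if series_resistance_MOhm < 0:
        raise ValueError("series resistance must be non-negative")

    if series_resistance_MOhm == 0.0:
        g0 = steady_state_gates(v_hold, params).as_array()
        segs = [(0.0, protocol.onset_ms, v_hold),
                (protocol.onset_ms, protocol.offset_ms, v_step),
                (protocol.offset_ms, protocol.total_ms, v_hold)]
        cur = np.empty(t_eval.size)
        g = g0.copy()
        filled = 0
        live = [(a, b, V) for (a, b, V) in segs if b > a]
        for k, (t0, t1, V) in enumerate(live):
            last = k == len(live) - 1
            # boundary samples belong to the NEW command segment, so the
            # recorded current includes the instantaneous jump at the step
            upper = (t_eval <= t1 + 1e-12) if last else (t_eval < t1 - 1e-12)
            mask = (t_eval >= t0 - 1e-12) & upper & (np.arange(t_eval.size) >= filled)
            seg_eval = t_eval[mask]
            sol = solve_ivp(_gate_rhs, (t0, t1), g, args=(params, V),
                            method=solver.method, rtol=solver.rtol, atol=solver.atol,
                            t_eval=seg_eval if seg_eval.size else None)
            if not sol.success:
                raise SolverError(f"voltage-clamp gate integration failed: {sol.message}")
            for j in range(seg_eval.size):
                st = NeuronState(V=V, gates=GateValues.from_array(sol.y[:, j]))
                from .biophysics_core import membrane_currents
                cur[filled + j] = membrane_currents(st, params).total() * area * 1e6  # uA/cm2 -> pA
            if seg_eval.size:
                filled += seg_eval.size
                g = sol.y[:, -1]
            elif sol.y.size:
                g = sol.y[:, -1]
        trace = Trace(t_eval, cur, "pA", protocol=protocol,
                      stimulus=np.where((t_eval >= protocol.onset_ms) & (t_eval < protocol.offset_ms),
                                        v_step, v_hold),
                      meta={"kind": "voltage_clamp", "Rs_MOhm": 0.0})
        return trace

    # Non-ideal clamp: V is a state; command drives it through Rs.
    # I_clamp = (Vcmd - V)/Rs; recorded current is I_clamp.
    rs_density = series_resistance_MOhm * 1e6 * area  # Ohm*cm^2 -> (V/A)*cm^2; work in HH units:
    # In HH units (mV, uA/cm^2): g_s (mS/cm^2) = 1/(Rs[MOhm] * area[cm^2] * 1e-3)
    g_s = 1.0 / (series_resistance_MOhm * area * 1e3)  # mS/cm^2

    def rs_rhs(t, y, vcmd):
        V = y[0]
        base = rhs(t, y, params, 0.0)
        i_clamp = g_s * (vcmd - V)  # uA/cm^2
        base[0] += i_clamp / params.Cm
        return base

    v0 = v_hold  # start clamped at holding steady state
    y = np.concatenate([[v0], steady_state_gates(v0, params).as_array()])
    segs = [(0.0, protocol.onset_ms, v_hold),
            (protocol.onset_ms, protocol.offset_ms, v_step),
            (protocol.offset_ms, protocol.total_ms, v_hold)]
    cur = np.empty(t_eval.size)
    filled = 0
    live = [(a, b, v) for (a, b, v) in segs if b > a]
    for k, (t0, t1, vcmd) in enumerate(live):
        last = k == len(live) - 1
        upper = (t_eval <= t1 + 1e-12) if last else (t_eval < t1 - 1e-12)
        mask = (t_eval >= t0 - 1e-12) & upper & (np.arange(t_eval.size) >= filled)
        seg_eval = t_eval[mask]
        sol = solve_ivp(rs_rhs, (t0, t1), y, args=(vcmd,),
                        method=solver.method, rtol=solver.rtol, atol=solver.atol,
                        t_eval=seg_eval if seg_eval.size else None)
        if not sol.success:
            raise SolverError(f"Rs voltage-clamp integration failed: {sol.message}")
        for j in range(seg_eval.size):
            cur[filled + j] = g_s * (vcmd - sol.y[0, j]) * area * 1e6  # pA
        if seg_eval.size:
            filled += seg_eval.size
        if sol.y.size:
            y = sol.y[:, -1]
    return Trace(t_eval, cur, "pA", protocol=protocol,
                 stimulus=np.where((t_eval >= protocol.onset_ms) & (t_eval < protocol.offset_ms),
                                   v_step, v_hold),
                 meta={"kind": "voltage_clamp", "Rs_MOhm": series_resistance_MOhm})


def apply_variant(params: MembraneParams, variant: str,
                  vakc_scale: float = 1.0) -> MembraneParams:
    """Parameter set for a sweep variant with the delayed rectifier scaled."""
    if variant not in VARIANT_DENSITIES:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(VARIANT_DENSITIES)}")
    extra = VARIANT_DENSITIES[variant]
    return replace(params, gKdr=params.gKdr * vakc_scale, **extra)


def run_leak_sweep(params: MembraneParams,
                   gl_grid_nS: Iterable[float] = DEFAULT_GL_GRID_NS,
                   vakc_scales: Iterable[float] = (1.0,),
                   variants: Iterable[str] = ("kdr",),
                   i_app_pA: float = 120.0,
                   step_ms: float = 500.0,
                   baseline_ms: float = 100.0,
                   solver: SolverOptions = SolverOptions()) -> SweepResult:
    """Firing class vs. background leak conductance.

    One current-clamp simulation and classification per (gL, scale, variant)
    grid point; spike counting and classification delegate to
    :mod:`leakfire.ephys_features` (single source of truth).
    """
    from .ephys_features import detect_spikes, classify_firing

    gl_grid = list(gl_grid_nS)
    if not gl_grid:
        raise ValueError("leak grid must be non-empty")
    for s in vakc_scales:
        if not (0.0 < s <= 2.0):
            raise ValueError(f"vakc scale {s} outside (0, 2]")

    rows = []
    for variant in variants:
        for scale in vakc_scales:
            base = apply_variant(params, variant, scale)
            for gl in gl_grid:
                p = base.with_leak_nS(gl)
                proto = StepProtocol(baseline_ms=baseline_ms, step_ms=step_ms,
                                     amplitude=i_app_pA, post_ms=50.0)
                try:
                    tr = simulate_current_clamp(p, proto, solver=solver)
                except SolverError as exc:
                    raise SolverError(
                        f"sweep point gL={gl} nS, scale={scale}, variant={variant}: {exc}"
                    ) from exc
                st = detect_spikes(tr)
                fc = classify_firing(st, proto)
                rows.append({"gL_nS": round(float(gl), 10), "vakc_scale": scale,
                             "variant": variant, "n_spikes": fc.count,
                             "firing_class": fc.label})
    return pd.DataFrame(rows)


def _rk4_step(y: np.ndarray, t: float, dt: float,
              params: MembraneParams, i_inj: float) -> np.ndarray:
    k1 = rhs(t, y, params, i_inj)
    k2 = rhs(t + 0.5 * dt, y + 0.5 * dt * k1, params, i_inj)
    k3 = rhs(t + 0.5 * dt, y + 0.5 * dt * k2, params, i_inj)
    k4 = rhs(t + dt, y + dt * k3, params, i_inj)
    return y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def simulate_dynamic_clamp(params: MembraneParams,
                           artificial: OhmicConductanceSpec,
                           protocol: StepProtocol,
                           substeps_per_tick: int = 4,
                           solver: SolverOptions = SolverOptions()) -> Trace:
    """Current-clamp step with an artificial ohmic conductance injected in a
    discrete closed loop.

    The injected current I = g*(V - E_rev) is recomputed only at each update
    tick and held constant in between (zero-order hold), emulating the
    hardware loop's 100-us command interval.  Between ticks the membrane is
    advanced by fixed-step RK4 (``substeps_per_tick`` steps per tick, i.e.
    25 us at the defaults, far below the fastest gate time constant); the
    loop is deterministic and its refinement behaviour is covered by tests.
    """
    if artificial.g_nS == 0.0:
        return simulate_current_clamp(params, protocol, solver=solver)
    if substeps_per_tick < 1:
        raise ValueError("substeps_per_tick must be >= 1")

    state0 = find_resting_state_with_artificial(params, artificial)
    t_eval = protocol.times()
    dt_up = artificial.update_ms
    g_density = convert_conductance(artificial.g_nS, "absolute_to_density", params.area)

    n_ticks = int(np.ceil(protocol.total_ms / dt_up - 1e-12))
    y = state0.as_array()
    # record V on the tick grid, then resample onto the protocol grid
    t_tick = np.empty(n_ticks + 1)
    v_tick = np.empty(n_ticks + 1)
    t_tick[0], v_tick[0] = 0.0, y[0]
    for k in range(n_ticks):
        t0 = k * dt_up
        t1 = min((k + 1) * dt_up, protocol.total_ms)
        i_stim = protocol.holding + (protocol.amplitude
                                     if (protocol.onset_ms <= t0 < protocol.offset_ms) else 0.0)
        i_dyn = -g_density * (y[0] - artificial.E_rev_mV)  # uA/cm^2, held for the tick
        i_tot = _pA_to_density(i_stim, params) + i_dyn
        h = (t1 - t0) / substeps_per_tick
        for s in range(substeps_per_tick):
            y = _rk4_step(y, t0 + s * h, h, params, i_tot)
        t_tick[k + 1], v_tick[k + 1] = t1, y[0]
    out_v = np.interp(t_eval, t_tick, v_tick)
    return Trace(t_eval, out_v, "mV", protocol=protocol,
                 stimulus=protocol.stimulus(t_eval),
                 meta={"kind": "dynamic_clamp", "g_art_nS": artificial.g_nS,
                       "E_art_mV": artificial.E_rev_mV, "update_ms": dt_up})


def find_resting_state_with_artificial(params: MembraneParams,
                                       artificial: OhmicConductanceSpec) -> NeuronState:
    """Rest of the native model plus a continuous version of the artificial leak.

    The discrete loop's rest is within O(update interval) of this; using it as
    the initial condition keeps the pre-stimulus baseline flat.
    """
    g_density = convert_conductance(artificial.g_nS, "absolute_to_density", params.area)
    # absorb the artificial ohmic conductance into an equivalent native leak:
    # gL' = gL + g_art, EL' = (gL*EL + g_art*E_art)/(gL + g_art)
    gl_new = params.gL + g_density
    el_new = (params.gL * params.EL + g_density * artificial.E_rev_mV) / gl_new
    el_new = min(max(el_new, params.EK + 1e-6), params.ENa - 1e-6)
    p_eq = replace(params, gL=gl_new, EL=el_new)
    return find_resting_state(p_eq)


def emulate_ba_subtraction(params: MembraneParams, blocked_fraction: float,
                           protocol: StepProtocol,
                           solver: SolverOptions = SolverOptions()) -> tuple[Trace, Trace]:
    """Control / leak-blocked voltage-clamp pair emulating Ba2+ application.

    The two runs differ only in gL (blocked = (1-fraction)*gL); their
    difference current is ohmic by construction and reverses at EL.
    """
    if not (0.0 <= blocked_fraction <= 1.0):
        raise ValueError("blocked fraction must lie in [0, 1]")
    control = simulate_voltage_clamp(params, protocol, solver=solver)
    blocked_params = replace(params, gL=params.gL * (1.0 - blocked_fraction))
    blocked = simulate_voltage_clamp(blocked_params, protocol, solver=solver)
    control.meta["condition"] = "control"
    blocked.meta["condition"] = "ba_blocked"
    return control, blocked
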