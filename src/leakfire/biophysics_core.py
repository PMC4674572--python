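"""Single-compartment conductance-based model of a songbird NCM neuron.

The membrane obeys ``Cm * dV/dt = -(I_Na + I_Kdr + I_Klt + I_Kht + I_Ka + I_L) + I_inj``
in the standard Hodgkin-Huxley unit system: V in mV, t in ms, conductance
densities in mS/cm^2, current densities in uA/cm^2, Cm in uF/cm^2.  The
delayed rectifier uses a^2 gating with Boltzmann steady-state activation
(midpoint ``V_half``, slope ``slope_k``, fixed time constant ``tau_a``); the
optional low-threshold (w^4 z), high-threshold (phi n^2 + (1-phi) p) and
A-type (mF^4 hF) potassium currents follow auditory-brainstem kinetics.
Transient sodium kinetics are pluggable (see :data:`NA_KINETICS`) because
only "Hodgkin-Huxley type" is pinned down by the source model family.

Gating variables and their currents:

==========  =====================  =========================================
gate(s)     current                density form (outward positive)
==========  =====================  =========================================
m, h        I_Na                   gNa * m^3 * h * (V - ENa)
a           I_Kdr                  gKdr * a^2 * (V - EK)
w, z        I_Klt                  gKlt * w^4 * z * (V - EK)
n, p        I_Kht                  gKht * (phi*n^2 + (1-phi)*p) * (V - EK)
mF, hF      I_Ka                   gKa * mF^4 * hF * (V - EK)
(none)      I_L                    gL * (V - EL)
==========  =====================  =========================================
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MembraneParams",
    "KineticConstants",
    "GateValues",
    "GateTaus",
    "CurrentBreakdown",
    "NeuronState",
    "GATE_NAMES",
    "NA_KINETICS",
    "steady_state_gates",
    "gate_time_constants",
    "membrane_currents",
    "state_derivative",
    "rhs",
    "convert_conductance",
    "find_resting_state",
    "ncm_model_params",
    "load_params",
    "save_params",
]

GATE_NAMES = ("m", "h", "a", "w", "z", "n", "p", "mF", "hF")

#: Membrane area (cm^2) pinning the density <-> absolute conductance scale.
#: Derived from the printed pairing 2 nS <-> 0.1667 mS/cm^2; gives a total
#: capacitance of 12 pF at 1 uF/cm^2 and makes the remaining printed
#: density/absolute pairs (16.67 -> 200 nS, 12.50 -> 150 nS, 10.42 -> 125 nS)
#: mutually consistent to <0.5%.
DEFAULT_AREA_CM2 = 1.2e-5


@dataclass(frozen=True)
class KineticConstants:
    """Fixed mixing constants of the K-current kinetics.

    phi: fraction of the high-threshold current carried by the fast n^2 gate.
    zeta: voltage-independent floor of the low-threshold inactivation gate z.
    """

    phi: float = 0.85
    zeta: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError(f"phi must lie in [0, 1], got {self.phi}")
        if not (0.0 <= self.zeta <= 1.0):
            raise ValueError(f"zeta must lie in [0, 1], got {self.zeta}")


@dataclass(frozen=True)
class MembraneParams:
    """Full parameterization of the point neuron.

    Conductances are densities in mS/cm^2; a value of zero removes the
    current.  ``na_kinetics`` selects the transient-Na rate functions
    ("hh1952" or "rm2003").
    """

    Cm: float = 1.0                 # uF/cm^2
    area: float = DEFAULT_AREA_CM2  # cm^2
    ENa: float = 50.0               # mV
    EK: float = -94.0               # mV
    EL: float = -77.0               # mV
    gNa: float = 91.66              # mS/cm^2
    gKdr: float = 20.83             # mS/cm^2
    gKlt: float = 0.0               # mS/cm^2
    gKht: float = 0.0               # mS/cm^2
    gKa: float = 0.0                # mS/cm^2
    gL: float = 0.6167              # mS/cm^2 (7.4 nS at the default area)
    V_half: float = 8.4             # mV, delayed-rectifier activation midpoint
    slope_k: float = 18.5           # mV, Boltzmann slope
    tau_a: float = 3.2              # ms, delayed-rectifier activation tau
    #: Transient-Na rate functions.  The source model family pins down only
    #: "Hodgkin-Huxley type"; the rm2003 (auditory bushy-cell) variant is the
    #: default because it reproduces the published leak-sweep firing-class
    #: boundaries (phasic down to 5.6 nS, transient at 5.4 nS) exactly on a
    #: 0.2 nS grid, whereas the classic hh1952 rates yield tonic firing at
    #: every leak level.  See docs/methods.md for the sensitivity analysis.
    na_kinetics: str = "rm2003"
    kinetics: KineticConstants = field(default_factory=KineticConstants)

    def __post_init__(self) -> None:
        if self.Cm <= 0:
            raise ValueError(f"Cm must be positive, got {self.Cm}")
        if self.area <= 0:
            raise ValueError(f"area must be positive, got {self.area}")
        for name in ("gNa", "gKdr", "gKlt", "gKht", "gKa", "gL"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (self.EK < self.EL < self.ENa):
            raise ValueError(
                f"require EK < EL < ENa, got EK={self.EK}, EL={self.EL}, ENa={self.ENa}"
            )
        if self.tau_a <= 0:
            raise ValueError("tau_a must be positive")
        if self.na_kinetics not in NA_KINETICS:
            raise ValueError(
                f"unknown na_kinetics {self.na_kinetics!r}; choose from {sorted(NA_KINETICS)}"
            )

    # -- convenience -------------------------------------------------------
    def with_leak_nS(self, gL_nS: float) -> "MembraneParams":
        """Return a copy with the leak set from an absolute conductance in nS."""
        return replace(self, gL=convert_conductance(gL_nS, "absolute_to_density", self.area))

    @property
    def gL_nS(self) -> float:
        return convert_conductance(self.gL, "density_to_absolute", self.area)

    @property
    def C_total_pF(self) -> float:
        """Whole-cell capacitance in pF (Cm uF/cm^2 x area cm^2 x 1e6)."""
        return self.Cm * self.area * 1e6

    def tau0_ms(self) -> float:
        """Passive membrane time constant Cm/gL (equivalently C_total/g_total)."""
        if self.gL <= 0:
            raise ValueError("tau0 undefined for gL = 0")
        return self.Cm / self.gL


@dataclass
class GateValues:
    m: float = 0.0
    h: float = 1.0
    a: float = 0.0
    w: float = 0.0
    z: float = 1.0
    n: float = 0.0
    p: float = 0.0
    mF: float = 0.0
    hF: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, g) for g in GATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "GateValues":
        return cls(**{g: float(v) for g, v in zip(GATE_NAMES, arr)})

    def validate(self) -> None:
        for g in GATE_NAMES:
            v = getattr(self, g)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"gate {g} = {v} outside [0, 1]")


@dataclass
class GateTaus:
    m: float
    h: float
    a: float
    w: float
    z: float
    n: float
    p: float
    mF: float
    hF: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, g) for g in GATE_NAMES], dtype=float)


@dataclass
class CurrentBreakdown:
    """Ionic current densities in uA/cm^2, outward positive."""

    I_Na: float
    I_Kdr: float
    I_Klt: float
    I_Kht: float
    I_Ka: float
    I_L: float

    def total(self) -> float:
        return self.I_Na + self.I_Kdr + self.I_Klt + self.I_Kht + self.I_Ka + self.I_L


@dataclass
class NeuronState:
    V: float
    gates: GateValues

    def as_array(self) -> np.ndarray:
        return np.concatenate([[self.V], self.gates.as_array()])

    @classmethod
    def from_array(cls, arr) -> "NeuronState":
        return cls(V=float(arr[0]), gates=GateValues.from_array(arr[1:]))


# ---------------------------------------------------------------------------
# Sodium kinetics variants
# ---------------------------------------------------------------------------

def _hh1952_na(V):
    """Classic squid-axon Na rates in the modern (rest ~ -65 mV) convention.

    Returns (m_inf, tau_m, h_inf, tau_h); no Q10 scaling.
    """
    vm = V + 40.0
    # alpha_m has a removable singularity at V = -40 mV
    am = np.where(np.abs(vm) < 1e-7, 1.0, 0.1 * vm / (1.0 - np.exp(-vm / 10.0)))
    bm = 4.0 * np.exp(-(V + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(V + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    tm = 1.0 / (am + bm)
    th = 1.0 / (ah + bh)
    return am * tm, tm, ah * th, th


def _rm2003_na(V):
    """Rothman-Manis (2003) fast transient Na kinetics (22 C form, no Q10)."""
    m_inf = (1.0 + np.exp(-(V + 38.0) / 7.0)) ** -1.0
    h_inf = (1.0 + np.exp((V + 65.0) / 6.0)) ** -1.0
    tau_m = 10.0 / (5.0 * np.exp((V + 60.0) / 18.0) + 36.0 * np.exp(-(V + 60.0) / 25.0)) + 0.04
    tau_h = 100.0 / (7.0 * np.exp((V + 60.0) / 11.0) + 10.0 * np.exp(-(V + 60.0) / 25.0)) + 0.6
    return m_inf, tau_m, h_inf, tau_h


#: Registry of pluggable transient-Na rate functions; each maps V (mV) to
#: (m_inf, tau_m, h_inf, tau_h).
NA_KINETICS = {"hh1952": _hh1952_na, "rm2003": _rm2003_na}


# ---------------------------------------------------------------------------
# Gating kinetics
# ---------------------------------------------------------------------------

def _check_voltage(V) -> None:
    if not np.all(np.isfinite(V)):
        raise ValueError(f"membrane potential must be finite, got {V}")


def steady_state_gates(V: float, params: MembraneParams) -> GateValues:
    """Voltage-dependent steady-state activation/inactivation of all gates.

    All values lie in [0, 1].  The delayed rectifier follows the Boltzmann
    a_inf = 1/(1 + exp((V_half - V)/k)) with the parameterized midpoint and
    slope; the low-threshold inactivation gate has floor z_inf >= zeta.
    """
    _check_voltage(V)
    m_inf, _, h_inf, _ = NA_KINETICS[params.na_kinetics](V)
    zeta = params.kinetics.zeta
    a = 1.0 / (1.0 + np.exp((params.V_half - V) / params.slope_k))
    w = (1.0 + np.exp(-(V + 48.0) / 6.0)) ** -0.25
    z = (1.0 - zeta) * (1.0 + np.exp((V + 71.0) / 10.0)) ** -1.0 + zeta
    n = (1.0 + np.exp(-(V + 15.0) / 5.0)) ** -0.5
    p = (1.0 + np.exp(-(V + 23.0) / 6.0)) ** -1.0
    mF = (1.0 + np.exp(-(V + 53.0) / 25.8)) ** -1.0
    hF = (1.0 + np.exp((V + 89.6) / 6.7)) ** -1.0
    return GateValues(m=float(m_inf), h=float(h_inf), a=float(a), w=float(w),
                      z=float(z), n=float(n), p=float(p), mF=float(mF), hF=float(hF))


def gate_time_constants(V: float, params: MembraneParams) -> GateTaus:
    """Voltage-dependent relaxation time constants (ms) of all gates.

    The delayed-rectifier tau is voltage independent (``params.tau_a``);
    the remaining K-gate taus are of the form A/(sum of exponentials) + offset.
    """
    _check_voltage(V)
    _, tau_m, _, tau_h = NA_KINETICS[params.na_kinetics](V)
    u = V + 60.0
    tau_w = 100.0 / (6.0 * np.exp(u / 6.0) + 16.0 * np.exp(-u / 45.0)) + 1.5
    tau_z = 1000.0 / (np.exp(u / 20.0) + np.exp(-u / 8.0)) + 50.0
    tau_n = 100.0 / (11.0 * np.exp(u / 24.0) + 21.0 * np.exp(-u / 23.0)) + 0.7
    tau_p = 100.0 / (4.0 * np.exp(u / 32.0) + 5.0 * np.exp(-u / 22.0)) + 5.0
    tau_mF = 1.0 / (0.15 * np.exp((V + 57.0) / 10.0) + 0.3 * np.exp(-(V + 57.0) / 10.0)) + 0.5
    tau_hF = 1.0 / (0.015 * np.exp((V + 87.0) / 20.0) + 0.03 * np.exp(-(V + 87.0) / 20.0)) + 10.0
    return GateTaus(m=float(tau_m), h=float(tau_h), a=float(params.tau_a),
                    w=float(tau_w), z=float(tau_z), n=float(tau_n),
                    p=float(tau_p), mF=float(tau_mF), hF=float(tau_hF))


def membrane_currents(state: NeuronState, params: MembraneParams) -> CurrentBreakdown:
    """Instantaneous ionic current densities (uA/cm^2, outward positive)."""
    V, g = state.V, state.gates
    phi = params.kinetics.phi
    return CurrentBreakdown(
        I_Na=params.gNa * g.m ** 3 * g.h * (V - params.ENa),
        I_Kdr=params.gKdr * g.a ** 2 * (V - params.EK),
        I_Klt=params.gKlt * g.w ** 4 * g.z * (V - params.EK),
        I_Kht=params.gKht * (phi * g.n ** 2 + (1.0 - phi) * g.p) * (V - params.EK),
        I_Ka=params.gKa * g.mF ** 4 * g.hF * (V - params.EK),
        I_L=params.gL * (V - params.EL),
    )


def state_derivative(state: NeuronState, params: MembraneParams,
                     I_inj: float = 0.0) -> np.ndarray:
    """Time derivative [dV/dt, dgates/dt] of the full state.

    I_inj is the injected current density (uA/cm^2, depolarizing positive);
    dV/dt = (-sum of ionic currents + I_inj)/Cm and each gate relaxes
    first-order toward its steady state.
    """
    return rhs(0.0, state.as_array(), params, I_inj)


def rhs(t: float, y: np.ndarray, params: MembraneParams, I_inj: float) -> np.ndarray:
    """ODE right-hand side over the packed state vector [V, m, h, a, w, z, n, p, mF, hF].

    Written with scalar math for speed inside adaptive solvers.
    """
    V = y[0]
    m, h, a, w, z, n, p, mF, hF = y[1:10]
    phi = params.kinetics.phi
    zeta = params.kinetics.zeta

    I_ion = (params.gNa * m * m * m * h * (V - params.ENa)
             + params.gKdr * a * a * (V - params.EK)
             + params.gKlt * w ** 4 * z * (V - params.EK)
             + params.gKht * (phi * n * n + (1.0 - phi) * p) * (V - params.EK)
             + params.gKa * mF ** 4 * hF * (V - params.EK)
             + params.gL * (V - params.EL))

    m_inf, tau_m, h_inf, tau_h = NA_KINETICS[params.na_kinetics](V)
    a_inf = 1.0 / (1.0 + math.exp((params.V_half - V) / params.slope_k))
    w_inf = (1.0 + math.exp(-(V + 48.0) / 6.0)) ** -0.25
    z_inf = (1.0 - zeta) / (1.0 + math.exp((V + 71.0) / 10.0)) + zeta
    n_inf = (1.0 + math.exp(-(V + 15.0) / 5.0)) ** -0.5
    p_inf = 1.0 / (1.0 + math.exp(-(V + 23.0) / 6.0))
    mF_inf = 1.0 / (1.0 + math.exp(-(V + 53.0) / 25.8))
    hF_inf = 1.0 / (1.0 + math.exp((V + 89.6) / 6.7))

    u = V + 60.0
    tau_w = 100.0 / (6.0 * math.exp(u / 6.0) + 16.0 * math.exp(-u / 45.0)) + 1.5
    tau_z = 1000.0 / (math.exp(u / 20.0) + math.exp(-u / 8.0)) + 50.0
    tau_n = 100.0 / (11.0 * math.exp(u / 24.0) + 21.0 * math.exp(-u / 23.0)) + 0.7
    tau_p = 100.0 / (4.0 * math.exp(u / 32.0) + 5.0 * math.exp(-u / 22.0)) + 5.0
    tau_mF = 1.0 / (0.15 * math.exp((V + 57.0) / 10.0) + 0.3 * math.exp(-(V + 57.0) / 10.0)) + 0.5
    tau_hF = 1.0 / (0.015 * math.exp((V + 87.0) / 20.0) + 0.03 * math.exp(-(V + 87.0) / 20.0)) + 10.0

    return np.array([
        (-I_ion + I_inj) / params.Cm,
        (m_inf - m) / tau_m,
        (h_inf - h) / tau_h,
        (a_inf - a) / params.tau_a,
        (w_inf - w) / tau_w,
        (z_inf - z) / tau_z,
        (n_inf - n) / tau_n,
        (p_inf - p) / tau_p,
        (mF_inf - mF) / tau_mF,
        (hF_inf - hF) / tau_hF,
    ])


# ---------------------------------------------------------------------------
# Unit conversion and resting state
# ---------------------------------------------------------------------------

def convert_conductance(value: float, direction: str, area: float = DEFAULT_AREA_CM2) -> float:
    """Convert between conductance density (mS/cm^2) and absolute conductance (nS).

    absolute [nS] = density [mS/cm^2] * area [cm^2] * 1e6.  The round trip is
    the identity.
    """
    if area <= 0:
        raise ValueError(f"area must be positive, got {area}")
    if direction == "density_to_absolute":
        return value * area * 1e6
    if direction == "absolute_to_density":
        return value / (area * 1e6)
    raise ValueError(
        f"direction must be 'density_to_absolute' or 'absolute_to_density', got {direction!r}"
    )


def find_resting_state(params: MembraneParams, tol: float = 1e-8) -> NeuronState:
    """Resting fixed point: V where the total ionic current vanishes with gates
    at steady state.

    Scans (EK, ENa) for sign changes of the steady-state current, refines each
    by Brent's method, and returns the most hyperpolarized stable root (the
    physiological rest).  Falls back to a 1-s settling integration if the
    scan finds no bracket.  Raises if no fixed point exists (e.g. all
    conductances zero).
    """

    if (params.gNa + params.gKdr + params.gKlt + params.gKht
            + params.gKa + params.gL) == 0.0:
        raise RuntimeError("no conductances: the membrane has no restoring current")

    def i_ss(V: float) -> float:
        st = NeuronState(V=V, gates=steady_state_gates(V, params))
        return membrane_currents(st, params).total()

    lo, hi = params.EK + 1e-6, params.ENa - 1e-6
    grid = np.linspace(lo, hi, 600)
    vals = np.array([i_ss(v) for v in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(i_ss, grid[i], grid[i + 1], xtol=1e-12))
    # stable roots have positive slope of I_ss (restoring outward current
    # above, inward below)
    stable = [r for r in roots
              if i_ss(r + 1e-4) - i_ss(r - 1e-4) > 0]
    candidates = stable or roots
    if not candidates:
        raise RuntimeError(
            "no resting fixed point found in (EK, ENa); the model has no restoring current"
        )
    V_rest = min(candidates)
    state = NeuronState(V=V_rest, gates=steady_state_gates(V_rest, params))
    deriv = state_derivative(state, params, 0.0)
    if np.max(np.abs(deriv)) > max(tol, 1e-6):
        # refine by settling integration for 1 s
        from scipy.integrate import solve_ivp

        sol = solve_ivp(rhs, (0.0, 1000.0), state.as_array(),
                        args=(params, 0.0), method="LSODA",
                        rtol=1e-10, atol=1e-10)
        state = NeuronState.from_array(sol.y[:, -1])
        deriv = state_derivative(state, params, 0.0)
        if np.max(np.abs(deriv)) > 1e-6:
            raise RuntimeError("resting-state search did not converge")
    if not (params.EK < state.V < params.ENa):
        raise RuntimeError(f"resting potential {state.V} outside (EK, ENa)")
    return state


# ---------------------------------------------------------------------------
# Parameter-set I/O
# ---------------------------------------------------------------------------

def ncm_model_params(**overrides) -> MembraneParams:
    """The published phasic-cell parameter set (Kdr-only, gL = 7.4 nS)."""
    return MembraneParams(**overrides) if overrides else MembraneParams()


def bundled_model_path() -> Path:
    """Path of the bundled NCM phasic-cell parameter file (JSON config)."""
    return Path(__file__).parent / "models" / "ncm_phasic.json"


def save_params(params: MembraneParams, path) -> None:
    d = asdict(params)
    d["kinetics"] = asdict(params.kinetics)
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def load_params(path) -> MembraneParams:
    """Load a MembraneParams set from a flat JSON config."""
    d = json.loads(Path(path).read_text())
    kin = d.pop("kinetics", None)
    if kin is not None:
        d["kinetics"] = KineticConstants(**kin)
    return MembraneParams(**d)
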