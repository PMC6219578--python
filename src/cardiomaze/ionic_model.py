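"""Ischemia-modified human ventricular myocyte model (TT3).

The baseline electrophysiology is the ten Tusscher-Panfilov 2006 epicardial
human ventricular cell model with reduced concentration dynamics: the
intracellular Na+ and K+ concentrations are held at their 1 Hz steady-state
values, while the full intracellular calcium subsystem (cytosol, subspace,
sarcoplasmic reticulum, RyR release gating) is retained.  The total ionic
current is

    I_ion = I_Na + I_K1 + I_to + I_Kr + I_Ks + I_CaL + I_NaCa + I_NaK
            + I_pCa + I_pK + I_bCa + I_bNa + I_KATP,

in per-capacitance units (pA/pF == uA/uF), with V in mV and t in ms.

Ischemia enters through three mechanisms:

* hypoxia -- an ATP-sensitive K+ current I_KATP with open fraction
  P_ATP = 1/(1 + ([ATP]i/k0.5)^H) (H = 2, k0.5 = 0.25 mM) and an
  extracellular-K+ factor ([K]o/[K]o,normal)^0.24, plus an ATP-dependent
  depression of the L-type Ca2+ permeability
  P_CaL,ATP = 1/(1 + (k0.5/[ATP]i)^H) with H = 2.6, k0.5 = 1.4 mM;
* hyperkalemia -- elevated [K]o entering every K+ reversal potential and
  K-conductance scaling;
* acidosis -- multiplicative down-scaling of g_Na and g_CaL.

This module is the plain-NumPy reference formulation (readable, exactly the
published rate equations).  The table-driven fast stepper in
:mod:`cardiomaze._kernel` is built from these same functions and is validated
against this module in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellState",
    "IschemiaParams",
    "KatpConstants",
    "HEALTHY_ISCHEMIA",
    "GATE_NAMES",
    "ION_NAMES",
    "p_atp",
    "p_cal_atp",
    "i_katp",
    "total_ionic_current",
    "rush_larsen_step",
    "run_single_cell",
    "StimulusTrain",
    "initial_state",
]

# ---------------------------------------------------------------------------
# Physical constants and baseline TTP06 (epicardial) parameters
# ---------------------------------------------------------------------------

R_GAS = 8314.472     # J/(kmol K)
TEMP = 310.0         # K
FARADAY = 96485.3415  # C/mol
RTF = R_GAS * TEMP / FARADAY  # mV

CM_CELL = 0.185      # uF, whole-cell capacitance (concentration updates)
V_C = 0.016404       # um^3 (scaled), cytosolic volume
V_SR = 0.001094      # SR volume
V_SS = 0.00005468    # subspace volume

KO_NORMAL = 5.4      # mmol/l, baseline extracellular K+
NAO = 140.0          # mmol/l
CAO = 2.0            # mmol/l
NAI_FIXED = 8.604    # mmol/l (1 Hz steady state; held fixed)
KI_FIXED = 136.89    # mmol/l (held fixed)

G_NA = 14.838        # nS/pF
G_K1 = 5.405
G_TO = 0.294         # epicardial
G_KR = 0.153
G_KS = 0.392         # epicardial
G_CAL = 3.98e-5      # cm^3/(uF s) in the published scaling
P_KNA = 0.03
K_NACA = 1000.0      # pA/pF
GAMMA_NACA = 0.35
KM_CA = 1.38
KM_NAI = 87.5
K_SAT = 0.1
ALPHA_NACA = 2.5
P_NAK = 2.724
KM_K = 1.0
KM_NA = 40.0
G_PK = 0.0146
G_PCA = 0.1238
K_PCA = 0.0005
G_BNA = 0.00029
G_BCA = 0.000592

# calcium subsystem
VMAX_UP = 0.006375
K_UP = 0.00025
V_REL = 0.102
K1_REL = 0.15
K2_REL = 0.045
K3_REL = 0.060
K4_REL = 0.005
MAX_SR = 2.5
MIN_SR = 1.0
EC_SR = 1.5
V_LEAK = 0.00036
V_XFER = 0.0038
BUF_C = 0.2
K_BUF_C = 0.001
BUF_SR = 10.0
K_BUF_SR = 0.3
BUF_SS = 0.4
K_BUF_SS = 0.00025

GATE_NAMES = ("m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f", "f2",
              "fcass", "rbar")
ION_NAMES = ("cai", "cass", "casr")

# state vector layout: V, 13 gates, 3 Ca concentrations
N_GATES = len(GATE_NAMES)
N_VARS = 1 + N_GATES + len(ION_NAMES)
IDX_V = 0
IDX_GATE = {g: 1 + i for i, g in enumerate(GATE_NAMES)}
IDX_ION = {c: 1 + N_GATES + i for i, c in enumerate(ION_NAMES)}

# 1 Hz steady-state initial values (epicardial)
_INIT = {
    "V": -85.23, "m": 0.00172, "h": 0.7444, "j": 0.7045,
    "xr1": 0.00621, "xr2": 0.4712, "xs": 0.0095, "r": 2.42e-8,
    "s": 0.999998, "d": 3.373e-5, "f": 0.7888, "f2": 0.9755,
    "fcass": 0.9953, "rbar": 0.9073,
    "cai": 0.000126, "cass": 0.00036, "casr": 3.64,
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class KatpConstants:
    """Constants of the ATP-sensitive potassium current and the ATP gate of
    the L-type Ca2+ current.

    ``g_katp_max`` is the effective maximal I_KATP conductance in nS/pF
    (per-capacitance units).  The source formulation prints the channel
    conductance as 195e-6/Nichols_area (nS/cm^2) with Nichols_area = 5e3,
    a scale that does not map onto per-capacitance model units without a
    membrane-density convention; the value here is the package's one-time
    conversion, fixed by requiring the documented hypoxic behaviour
    APD90 = 50 ms at [ATP]i = 3 mM (see docs/methods.md).
    """

    g_katp_max: float = 7.223  # nS/pF, calibrated (scripts/calibrate.py)
    n_exp: float = 0.24        # exponent of the [K]o factor
    h_atp: float = 2.0         # Hill coefficient of P_ATP
    k05_atp: float = 0.250     # mM, half-saturation of P_ATP
    h_cal: float = 2.6         # Hill coefficient of P_CaL,ATP
    k05_cal: float = 1.4       # mM, half-saturation of P_CaL,ATP
    k_o_normal: float = KO_NORMAL

    def __post_init__(self) -> None:
        for name in ("g_katp_max", "n_exp", "h_atp", "k05_atp", "h_cal",
                     "k05_cal", "k_o_normal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


KATP_DEFAULT = KatpConstants()


@dataclass(frozen=True)
class IschemiaParams:
    """Local disease severity of one cell (or one tissue region).

    atp_i   -- intracellular ATP, mM (healthy 6.8; acute ischemia 2-5)
    k_o     -- extracellular K+, mmol/l (healthy 5.4; hyperkalemia up to ~9)
    f_gcal  -- multiplicative scale on the L-type Ca2+ conductance (acidosis)
    f_gna   -- multiplicative scale on the fast Na+ conductance (acidosis)
    """

    atp_i: float = 6.8
    k_o: float = KO_NORMAL
    f_gcal: float = 1.0
    f_gna: float = 1.0

    def __post_init__(self) -> None:
        if self.atp_i <= 0:
            raise ValueError("atp_i must be > 0")
        if self.k_o <= 0:
            raise ValueError("k_o must be > 0")
        if not (0.0 < self.f_gcal <= 1.0):
            raise ValueError("f_gcal must lie in (0, 1]")
        if not (0.0 < self.f_gna <= 1.0):
            raise ValueError("f_gna must lie in (0, 1]")


HEALTHY_ISCHEMIA = IschemiaParams()


@dataclass
class CellState:
    """Full state of one myocyte: V (mV), 13 gating variables in [0, 1] and
    the three dynamic Ca2+ concentrations (mM)."""

    y: np.ndarray = field(default_factory=lambda: initial_state())

    @property
    def v(self) -> float:
        return float(self.y[IDX_V])

    @v.setter
    def v(self, value: float) -> None:
        self.y[IDX_V] = value

    @property
    def gates(self) -> np.ndarray:
        return self.y[1:1 + N_GATES]

    @property
    def ions(self) -> np.ndarray:
        return self.y[1 + N_GATES:]

    def copy(self) -> "CellState":
        return CellState(self.y.copy())

    def validate(self) -> None:
        if not np.all(np.isfinite(self.y)):
            raise FloatingPointError("non-finite value in cell state")
        g = self.gates
        if np.any(g < -1e-12) or np.any(g > 1 + 1e-12):
            raise ValueError("gating variable outside [0, 1]")


def initial_state() -> np.ndarray:
    """State vector at the paced (1 Hz) resting steady state."""
    y = np.empty(N_VARS)
    y[IDX_V] = _INIT["V"]
    for g in GATE_NAMES:
        y[IDX_GATE[g]] = _INIT[g]
    for c in ION_NAMES:
        y[IDX_ION[c]] = _INIT[c]
    return y


# ---------------------------------------------------------------------------
# Ischemia formulation
# ---------------------------------------------------------------------------

def p_atp(atp_i, consts: KatpConstants = KATP_DEFAULT):
    """Open fraction of the K_ATP channel: 1/(1 + ([ATP]i/k0.5)^H).

    Strictly decreasing in [ATP]i; -> 1 as [ATP]i -> 0, -> 0 as
    [ATP]i -> inf.  Raises ValueError for non-positive [ATP]i.
    """
    atp = np.asarray(atp_i, dtype=float)
    if np.any(atp <= 0):
        raise ValueError("atp_i must be strictly positive")
    out = 1.0 / (1.0 + (atp / consts.k05_atp) ** consts.h_atp)
    return out if out.ndim else float(out)


def p_cal_atp(atp_i, consts: KatpConstants = KATP_DEFAULT):
    """ATP-dependence of the L-type Ca2+ permeability:
    1/(1 + (k0.5/[ATP]i)^H), H = 2.6, k0.5 = 1.4 mM.

    Strictly increasing in [ATP]i (hypoxia depresses I_CaL).
    """
    atp = np.asarray(atp_i, dtype=float)
    if np.any(atp <= 0):
        raise ValueError("atp_i must be strictly positive")
    out = 1.0 / (1.0 + (consts.k05_cal / atp) ** consts.h_cal)
    return out if out.ndim else float(out)


def g_katp(atp_i, k_o, consts: KatpConstants = KATP_DEFAULT):
    """I_KATP conductance g = G_max * P_ATP * ([K]o/[K]o,normal)^n (nS/pF)."""
    k_o = np.asarray(k_o, dtype=float)
    if np.any(k_o <= 0):
        raise ValueError("k_o must be strictly positive")
    out = (consts.g_katp_max * np.asarray(p_atp(atp_i, consts))
           * (k_o / consts.k_o_normal) ** consts.n_exp)
    return out if out.ndim else float(out)


def i_katp(v, e_k, atp_i, k_o, consts: KatpConstants = KATP_DEFAULT):
    """ATP-sensitive K+ current g_KATP * (V - E_K), pA/pF."""
    out = np.asarray(g_katp(atp_i, k_o, consts)) * (np.asarray(v) - e_k)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Gate rate equations (steady state and time constant, per gate)
# ---------------------------------------------------------------------------
# Each function accepts scalar or ndarray V (mV) and returns (inf, tau[ms]).

def _rates_m(v):
    v = np.asarray(v, dtype=float)
    inf = 1.0 / (1.0 + np.exp((-56.86 - v) / 9.03)) ** 2
    a = 1.0 / (1.0 + np.exp((-60.0 - v) / 5.0))
    b = (0.1 / (1.0 + np.exp((v + 35.0) / 5.0))
         + 0.1 / (1.0 + np.exp((v - 50.0) / 200.0)))
    return inf, a * b


def _rates_h(v):
    v = np.asarray(v, dtype=float)
    inf = 1.0 / (1.0 + np.exp((v + 71.55) / 7.43)) ** 2
    low = v < -40.0
    a = np.where(low, 0.057 * np.exp(-(v + 80.0) / 6.8), 0.0)
    b = np.where(
        low,
        2.7 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.3485 * v),
        0.77 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1))),
    )
    return inf, 1.0 / (a + b)


def _rates_j(v):
    v = np.asarray(v, dtype=float)
    inf = 1.0 / (1.0 + np.exp((v + 71.55) / 7.43)) ** 2
    low = v < -40.0
    a = np.where(
        low,
        ((-2.5428e4 * np.exp(0.2444 * v) - 6.948e-6 * np.exp(-0.04391 * v))
         * (v + 37.78)) / (1.0 + np.exp(0.311 * (v + 79.23))),
        0.0,
    )
    b = np.where(
        low,
        0.02424 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14))),
        0.6 * np.exp(0.057 * v) / (1.0 + np.exp(-0.1 * (v + 32.0))),
    )
    return inf, 1.0 / (a + b)


def _rates_xr1(v):
    v = np.asarray(v, dtype=float)
    inf = 1.0 / (1.0 + np.exp((-26.0 - v) / 7.0))
    a = 450.0 / (1.0 + np.exp((-45.0 - v) / 10.0))
    b = 6.0 / (1.0 + np.exp((v + 30.0) / 11.5))
    return inf, a * b


def _rates_xr2(v):
    v = np.asarray(v, dtype=float)
    inf = 1.0 / (1.0 + np.exp((v + 88.0) / 24.0))
    a = 3.0 / (1.0 + np.exp((-60.0 - v) / 20.0))
    b = 1.12 / (1.0 + np.exp((v - 60.0) / 20.0))
    return inf, a * b


def _rates_xs(v):
    v = np.asarray(v, dtype=float)
    inf = 1.0 / (1.0 + np.exp((-5.0 - v) / 14.0))
    a = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - v) / 6.0))
    b = 1.0 / (1.0 + np.exp((v - 35.0) / 15.0))
    return inf, a * b + 80.0


def _rates_r(v):
    v = np.asarray(v, dtype=float)
    inf = 1.0 / (1.0 + np.exp((20.0 - v) / 6.0))
    tau = 9.5 * np.exp(-((v + 40.0) ** 2) / 1800.0) + 0.8
    return inf, tau


def _rates_s(v):  # epicardial
    v = np.asarray(v, dtype=float)
    inf = 1.0 / (1.0 + np.exp((v + 20.0) / 5.0))
    tau = (85.0 * np.exp(-((v + 45.0) ** 2) / 320.0)
           + 5.0 / (1.0 + np.exp((v - 20.0) / 5.0)) + 3.0)
    return inf, tau


def _rates_d(v):
    v = np.asarray(v, dtype=float)
    inf = 1.0 / (1.0 + np.exp((-8.0 - v) / 7.5))
    a = 1.4 / (1.0 + np.exp((-35.0 - v) / 13.0)) + 0.25
    b = 1.4 / (1.0 + np.exp((v + 5.0) / 5.0))
    g = 1.0 / (1.0 + np.exp((50.0 - v) / 20.0))
    return inf, a * b + g


def _rates_f(v):
    v = np.asarray(v, dtype=float)
    inf = 1.0 / (1.0 + np.exp((v + 20.0) / 7.0))
    tau = (1102.5 * np.exp(-((v + 27.0) ** 2) / 225.0)
           + 200.0 / (1.0 + np.exp((13.0 - v) / 10.0))
           + 180.0 / (1.0 + np.exp((v + 30.0) / 10.0)) + 20.0)
    return inf, tau


def _rates_f2(v):
    v = np.asarray(v, dtype=float)
    inf = 0.67 / (1.0 + np.exp((v + 35.0) / 7.0)) + 0.33
    tau = (562.0 * np.exp(-((v + 27.0) ** 2) / 240.0)
           + 31.0 / (1.0 + np.exp((25.0 - v) / 10.0))
           + 80.0 / (1.0 + np.exp((v + 30.0) / 10.0)))
    return inf, tau


#: voltage-dependent gates in state-vector order
VOLTAGE_GATE_RATES = {
    "m": _rates_m, "h": _rates_h, "j": _rates_j,
    "xr1": _rates_xr1, "xr2": _rates_xr2, "xs": _rates_xs,
    "r": _rates_r, "s": _rates_s,
    "d": _rates_d, "f": _rates_f, "f2": _rates_f2,
}


def _rates_fcass(cass):
    cass = np.asarray(cass, dtype=float)
    q = 1.0 / (1.0 + (cass / 0.05) ** 2)
    return 0.6 * q + 0.4, 80.0 * q + 2.0


def xk1_inf(v_minus_ek):
    """Steady-state inward-rectifier gate as a function of V - E_K (mV)."""
    w = np.asarray(v_minus_ek, dtype=float)
    a = 0.1 / (1.0 + np.exp(0.06 * (w - 200.0)))
    b = ((3.0 * np.exp(0.0002 * (w + 100.0)) + np.exp(0.1 * (w - 10.0)))
         / (1.0 + np.exp(-0.5 * w)))
    return a / (a + b)


# ---------------------------------------------------------------------------
# Voltage-dependent current factors (shared with the fast kernel's tables)
# ---------------------------------------------------------------------------

def ical_coeffs(v):
    """L-type Ca2+ GHK-like driving terms A(V), B(V) such that
    I_CaL = g_scale * d*f*f2*fCass * (A(V)*Ca_ss - B(V))."""
    v = np.asarray(v, dtype=float)
    z = 2.0 * (v - 15.0) / RTF
    pref = G_CAL * 4.0 * (v - 15.0) * FARADAY / RTF
    with np.errstate(over="ignore"):
        ez = np.exp(z)
    small = np.abs(z) < 1e-7
    denom = np.where(small, 1.0, ez - 1.0)
    # z -> 0 limit: pref/(e^z - 1) -> G_CAL * 2 * F
    a = np.where(small, 0.5 * G_CAL * FARADAY, pref * 0.25 * ez / denom)
    b = np.where(small, 2.0 * G_CAL * FARADAY * CAO, pref * CAO / denom)
    return a, b


def inaca_coeffs(v):
    """Na+/Ca2+ exchanger split I_NaCa = A(V) - B(V)*Ca_i (fixed Na_i)."""
    v = np.asarray(v, dtype=float)
    e1 = np.exp(GAMMA_NACA * v / RTF)
    e2 = np.exp((GAMMA_NACA - 1.0) * v / RTF)
    denom = ((KM_NAI ** 3 + NAO ** 3) * (KM_CA + CAO)
             * (1.0 + K_SAT * e2))
    a = K_NACA * e1 * NAI_FIXED ** 3 * CAO / denom
    b = K_NACA * e2 * NAO ** 3 * ALPHA_NACA / denom
    return a, b


def inak_vfactor(v):
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * v / RTF)
                  + 0.0353 * np.exp(-v / RTF))


def ipk_vfactor(v):
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp((25.0 - v) / 5.98))


# ---------------------------------------------------------------------------
# Total ionic current
# ---------------------------------------------------------------------------

def reversal_potentials(isch: IschemiaParams, cai):
    """(E_Na, E_K, E_Ks, E_Ca) in mV for the given extracellular K+."""
    e_na = RTF * math.log(NAO / NAI_FIXED)
    e_k = RTF * math.log(isch.k_o / KI_FIXED)
    e_ks = RTF * math.log((isch.k_o + P_KNA * NAO)
                          / (KI_FIXED + P_KNA * NAI_FIXED))
    e_ca = 0.5 * RTF * np.log(CAO / np.asarray(cai, dtype=float))
    return e_na, e_k, e_ks, e_ca


def total_ionic_current(state: CellState, isch: IschemiaParams = HEALTHY_ISCHEMIA,
                        consts: KatpConstants = KATP_DEFAULT):
    """Total membrane current I_ion (pA/pF) and its per-current breakdown.

    The breakdown dict sums to the returned total exactly (same additions,
    same order).  Raises FloatingPointError on a non-finite state.
    """
    state.validate()
    y = state.y
    v = y[IDX_V]
    g = {n: y[IDX_GATE[n]] for n in GATE_NAMES}
    cai = y[IDX_ION["cai"]]
    cass = y[IDX_ION["cass"]]

    e_na, e_k, e_ks, e_ca = reversal_potentials(isch, cai)
    sqrt_ko = math.sqrt(isch.k_o / KO_NORMAL)

    br = {}
    br["i_na"] = (G_NA * isch.f_gna * g["m"] ** 3 * g["h"] * g["j"]
                  * (v - e_na))
    br["i_k1"] = G_K1 * sqrt_ko * float(xk1_inf(v - e_k)) * (v - e_k)
    br["i_to"] = G_TO * g["r"] * g["s"] * (v - e_k)
    br["i_kr"] = G_KR * sqrt_ko * g["xr1"] * g["xr2"] * (v - e_k)
    br["i_ks"] = G_KS * g["xs"] ** 2 * (v - e_ks)
    a_cal, b_cal = ical_coeffs(v)
    br["i_cal"] = (isch.f_gcal * p_cal_atp(isch.atp_i, consts)
                   * g["d"] * g["f"] * g["f2"] * g["fcass"]
                   * (float(a_cal) * cass - float(b_cal)))
    a_nc, b_nc = inaca_coeffs(v)
    br["i_naca"] = float(a_nc) - float(b_nc) * cai
    br["i_nak"] = (P_NAK * (isch.k_o / (isch.k_o + KM_K))
                   * (NAI_FIXED / (NAI_FIXED + KM_NA)) * float(inak_vfactor(v)))
    br["i_pca"] = G_PCA * cai / (K_PCA + cai)
    br["i_pk"] = G_PK * float(ipk_vfactor(v)) * (v - e_k)
    br["i_bna"] = G_BNA * (v - e_na)
    br["i_bca"] = G_BCA * (v - float(e_ca))
    br["i_katp"] = i_katp(v, e_k, isch.atp_i, isch.k_o, consts)

    total = 0.0
    for val in br.values():
        total += val
    return total, br


# ---------------------------------------------------------------------------
# Calcium subsystem derivatives (shared by reference stepper and kernel spec)
# ---------------------------------------------------------------------------

def _calcium_fluxes(cai, cass, casr, rbar):
    kcasr = MAX_SR - (MAX_SR - MIN_SR) / (1.0 + (EC_SR / casr) ** 2)
    k1 = K1_REL / kcasr
    k2 = K2_REL * kcasr
    o_rel = k1 * cass ** 2 * rbar / (K3_REL + k1 * cass ** 2)
    i_rel = V_REL * o_rel * (casr - cass)
    i_up = VMAX_UP / (1.0 + (K_UP / cai) ** 2)
    i_leak = V_LEAK * (casr - cai)
    i_xfer = V_XFER * (cass - cai)
    return i_rel, i_up, i_leak, i_xfer, k2


# ---------------------------------------------------------------------------
# Rush-Larsen stepper (reference implementation)
# ---------------------------------------------------------------------------

def rush_larsen_step(state: CellState, isch: IschemiaParams = HEALTHY_ISCHEMIA,
                     dt: float = 0.02, *, istim: float = 0.0,
                     update_v: bool = True,
                     consts: KatpConstants = KATP_DEFAULT) -> CellState:
    """Advance one cell by ``dt`` ms.

    Gating variables follow the Rush-Larsen exponential update
    g' = g_inf + (g - g_inf) exp(-dt/tau) (exact for frozen rates); Ca2+
    concentrations use forward Euler; V uses forward Euler with the total
    ionic current (skipped when ``update_v`` is False, in which case the
    voltage is treated as externally prescribed, e.g. by the tissue solver).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    new = state.copy()
    y = new.y
    v = y[IDX_V]
    cai = y[IDX_ION["cai"]]
    cass = y[IDX_ION["cass"]]
    casr = y[IDX_ION["casr"]]

    total, br = total_ionic_current(state, isch, consts)

    # voltage-dependent gates
    for name, fn in VOLTAGE_GATE_RATES.items():
        inf, tau = fn(v)
        k = IDX_GATE[name]
        y[k] = inf + (y[k] - inf) * math.exp(-dt / float(tau))
    # Ca-subspace gate
    inf, tau = _rates_fcass(cass)
    k = IDX_GATE["fcass"]
    y[k] = float(inf) + (y[k] - float(inf)) * math.exp(-dt / float(tau))

    # RyR availability: dR/dt = -k2*Cass*R + k4*(1-R), exponential update
    i_rel, i_up, i_leak, i_xfer, k2 = _calcium_fluxes(
        cai, cass, casr, y[IDX_GATE["rbar"]])
    tau_r = 1.0 / (k2 * cass + K4_REL)
    rinf = K4_REL * tau_r
    k = IDX_GATE["rbar"]
    y[k] = rinf + (y[k] - rinf) * math.exp(-dt / tau_r)

    # concentration updates (forward Euler, buffered)
    buf_c = 1.0 / (1.0 + BUF_C * K_BUF_C / (cai + K_BUF_C) ** 2)
    buf_sr = 1.0 / (1.0 + BUF_SR * K_BUF_SR / (casr + K_BUF_SR) ** 2)
    buf_ss = 1.0 / (1.0 + BUF_SS * K_BUF_SS / (cass + K_BUF_SS) ** 2)
    ca_factor = CM_CELL / (2.0 * V_C * FARADAY)
    dcai = buf_c * ((i_leak - i_up) * V_SR / V_C + i_xfer
                    - (br["i_bca"] + br["i_pca"] - 2.0 * br["i_naca"])
                    * ca_factor)
    dcasr = buf_sr * (i_up - i_rel - i_leak)
    dcass = buf_ss * (-br["i_cal"] * CM_CELL / (2.0 * V_SS * FARADAY)
                      + i_rel * V_SR / V_SS - i_xfer * V_C / V_SS)
    y[IDX_ION["cai"]] = max(cai + dt * dcai, 1e-9)
    y[IDX_ION["casr"]] = max(casr + dt * dcasr, 1e-9)
    y[IDX_ION["cass"]] = max(cass + dt * dcass, 1e-9)

    if update_v:
        # dV/dt = -(I_ion + I_stim): a depolarizing stimulus is negative
        y[IDX_V] = v - dt * (total + istim)
    return new


# ---------------------------------------------------------------------------
# Single-cell pacing runs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusTrain:
    """Periodic suprathreshold pulse train for single-cell pacing.

    amplitude is a per-capacitance current (uA/uF); negative = depolarizing.
    """

    amplitude: float = -52.0
    duration: float = 1.0      # ms
    period: float = 1000.0     # ms
    start: float = 50.0        # ms
    n_beats: int = 5

    def current(self, t: float) -> float:
        if t < self.start:
            return 0.0
        k = int((t - self.start) // self.period)
        if k >= self.n_beats:
            return 0.0
        phase = t - self.start - k * self.period
        return self.amplitude if phase < self.duration else 0.0


def run_single_cell(isch: IschemiaParams = HEALTHY_ISCHEMIA,
                    pacing: StimulusTrain | None = None,
                    duration: float | None = None, dt: float = 0.02,
                    sample_every: float = 1.0,
                    consts: KatpConstants = KATP_DEFAULT,
                    state: CellState | None = None,
                    use_kernel: bool = True):
    """Pace a single cell and return (t_ms, V_mV) uniformly sampled arrays.

    Deterministic given its inputs.  Uses the fast table-driven kernel by
    default; ``use_kernel=False`` runs the plain reference stepper (slow,
    used for validation).  Raises FloatingPointError with the failing step
    index on numerical blow-up.
    """
    pacing = pacing or StimulusTrain()
    if duration is None:
        duration = pacing.start + pacing.n_beats * pacing.period
    if duration <= pacing.start + pacing.duration:
        raise ValueError("duration must cover at least one paced beat")

    if use_kernel:
        from . import _kernel
        return _kernel.run_single_cell_kernel(
            isch, pacing, duration, dt, sample_every, consts, state)

    st = (state or CellState()).copy()
    n_steps = int(round(duration / dt))
    stride = max(int(round(sample_every / dt)), 1)
    ts, vs = [], []
    for i in range(n_steps):
        t = i * dt
        if i % stride == 0:
            ts.append(t)
            vs.append(st.v)
        st = rush_larsen_step(st, isch, dt, istim=pacing.current(t),
                              consts=consts)
        if not math.isfinite(st.v) or abs(st.v) > 300.0:
            raise FloatingPointError(
                f"numerical blow-up at step {i} (t = {t:.2f} ms)")
    return np.asarray(ts), np.asarray(vs)


def healthy_reference(isch: IschemiaParams) -> bool:
    """True when the parameters reduce the model to the unmodified baseline
    (aside from the vanishingly small healthy-[ATP]i I_KATP)."""
    return isch == HEALTHY_ISCHEMIA
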