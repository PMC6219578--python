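"""Table-driven fast stepper for the TT3 cell model.

The voltage-dependent factors of every gate update and every current are
precomputed on a fine voltage grid (0.01 mV, nearest-neighbour lookup) from
the exact rate functions in :mod:`cardiomaze.ionic_model`, and the per-cell
update runs as a compiled numba loop.  The Rush-Larsen factor
exp(-dt/tau(V)) is tabulated per gate, so tables are cached per time step.

The kernel is validated against the plain-NumPy reference stepper in the
test suite (same trajectory to lookup-grid accuracy).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from . import ionic_model as im

V_MIN, V_MAX, DV = -120.0, 80.0, 0.01
W_MIN, W_MAX, DW = -200.0, 260.0, 0.01

_N_VGATES = len(im.VOLTAGE_GATE_RATES)  # 11, state order
ROW_INACA_A = 2 * _N_VGATES
ROW_INACA_B = ROW_INACA_A + 1
ROW_INAK = ROW_INACA_A + 2
ROW_IPK = ROW_INACA_A + 3
ROW_ICAL_A = ROW_INACA_A + 4
ROW_ICAL_B = ROW_INACA_A + 5
N_ROWS = ROW_INACA_A + 6

_TABLE_CACHE: dict[float, tuple[np.ndarray, np.ndarray]] = {}


def build_tables(dt: float) -> tuple[np.ndarray, np.ndarray]:
    """(T, TK1): voltage tables for time step ``dt`` (ms)."""
    key = round(float(dt), 9)
    hit = _TABLE_CACHE.get(key)
    if hit is not None:
        return hit
    v = np.arange(V_MIN, V_MAX + DV / 2, DV)
    T = np.empty((N_ROWS, v.size))
    for k, fn in enumerate(im.VOLTAGE_GATE_RATES.values()):
        inf, tau = fn(v)
        T[2 * k] = inf
        T[2 * k + 1] = np.exp(-dt / tau)
    T[ROW_INACA_A], T[ROW_INACA_B] = im.inaca_coeffs(v)
    T[ROW_INAK] = im.inak_vfactor(v)
    T[ROW_IPK] = im.ipk_vfactor(v)
    T[ROW_ICAL_A], T[ROW_ICAL_B] = im.ical_coeffs(v)
    w = np.arange(W_MIN, W_MAX + DW / 2, DW)
    TK1 = np.ascontiguousarray(im.xk1_inf(w))
    _TABLE_CACHE[key] = (np.ascontiguousarray(T), TK1)
    return _TABLE_CACHE[key]


def cell_params(atp, k_o, f_gcal, f_gna,
                consts: im.KatpConstants = im.KATP_DEFAULT) -> np.ndarray:
    """Per-cell constant factors, shape (8, n).

    Rows: E_K, E_Ks, g_Na_eff, p_CaL_eff, g_K1 factor, g_Kr factor,
    I_NaK factor, g_KATP_eff.
    """
    atp = np.atleast_1d(np.asarray(atp, dtype=float))
    k_o = np.broadcast_to(np.asarray(k_o, dtype=float), atp.shape)
    f_gcal = np.broadcast_to(np.asarray(f_gcal, dtype=float), atp.shape)
    f_gna = np.broadcast_to(np.asarray(f_gna, dtype=float), atp.shape)
    P = np.empty((8, atp.size))
    sqrt_ko = np.sqrt(k_o / im.KO_NORMAL)
    P[0] = im.RTF * np.log(k_o / im.KI_FIXED)
    P[1] = im.RTF * np.log((k_o + im.P_KNA * im.NAO)
                           / (im.KI_FIXED + im.P_KNA * im.NAI_FIXED))
    P[2] = im.G_NA * f_gna
    P[3] = f_gcal * im.p_cal_atp(atp, consts)
    P[4] = im.G_K1 * sqrt_ko
    P[5] = im.G_KR * sqrt_ko
    P[6] = (im.P_NAK * (k_o / (k_o + im.KM_K))
            * (im.NAI_FIXED / (im.NAI_FIXED + im.KM_NA)))
    P[7] = im.g_katp(atp, k_o, consts)
    return P


_E_NA = im.RTF * math.log(im.NAO / im.NAI_FIXED)

# constants baked into the jitted kernel at compile time
_C = (im.G_TO, im.G_KS, im.G_PCA, im.K_PCA, im.G_PK, im.G_BNA, im.G_BCA,
      im.RTF, im.CAO)


@njit(cache=True, fastmath=True)
def _react(Y, P, T, TK1, dt, istim, update_v):  # pragma: no cover - compiled
    (G_TO, G_KS, G_PCA, K_PCA, G_PK, G_BNA, G_BCA, RTF, CAO) = _C
    n = Y.shape[1]
    nv = T.shape[1]
    nw = TK1.shape[0]
    inv_dv = 1.0 / DV
    inv_dw = 1.0 / DW
    iv_cai = 1 + 13  # V + 13 gates
    iv_cass = iv_cai + 1
    iv_casr = iv_cai + 2
    i_fcass = 1 + 11
    i_rbar = 1 + 12
    for i in range(n):
        v = Y[0, i]
        idx = int((v - V_MIN) * inv_dv + 0.5)
        if idx < 0:
            idx = 0
        elif idx >= nv:
            idx = nv - 1
        ek = P[0, i]
        w = v - ek
        widx = int((w - W_MIN) * inv_dw + 0.5)
        if widx < 0:
            widx = 0
        elif widx >= nw:
            widx = nw - 1

        m = Y[1, i]; h = Y[2, i]; j = Y[3, i]
        xr1 = Y[4, i]; xr2 = Y[5, i]; xs = Y[6, i]
        r = Y[7, i]; s = Y[8, i]
        d = Y[9, i]; f = Y[10, i]; f2 = Y[11, i]
        fcass = Y[i_fcass, i]; rbar = Y[i_rbar, i]
        cai = Y[iv_cai, i]; cass = Y[iv_cass, i]; casr = Y[iv_casr, i]

        # ---- currents from the current state -------------------------
        i_na = P[2, i] * m * m * m * h * j * (v - _E_NA)
        i_k1 = P[4, i] * TK1[widx] * w
        i_to = G_TO * r * s * w
        i_kr = P[5, i] * xr1 * xr2 * w
        i_ks = G_KS * xs * xs * (v - P[1, i])
        i_cal = (P[3, i] * d * f * f2 * fcass
                 * (T[26, idx] * cass - T[27, idx]))
        i_naca = T[22, idx] - T[23, idx] * cai
        i_nak = P[6, i] * T[24, idx]
        i_pca = G_PCA * cai / (K_PCA + cai)
        i_pk = G_PK * T[25, idx] * w
        i_bna = G_BNA * (v - _E_NA)
        e_ca = 0.5 * RTF * math.log(CAO / cai)
        i_bca = G_BCA * (v - e_ca)
        i_katp = P[7, i] * w
        i_ion = (i_na + i_k1 + i_to + i_kr + i_ks + i_cal + i_naca + i_nak
                 + i_pca + i_pk + i_bna + i_bca + i_katp)

        # ---- Rush-Larsen gate updates (tabulated) --------------------
        for k in range(11):
            inf = T[2 * k, idx]
            Y[1 + k, i] = inf + (Y[1 + k, i] - inf) * T[2 * k + 1, idx]
        q = 1.0 / (1.0 + (cass / 0.05) ** 2)
        fc_inf = 0.6 * q + 0.4
        fc_tau = 80.0 * q + 2.0
        Y[i_fcass, i] = fc_inf + (fcass - fc_inf) * math.exp(-dt / fc_tau)

        # ---- calcium subsystem ---------------------------------------
        kcasr = 2.5 - 1.5 / (1.0 + (1.5 / casr) ** 2)
        k1 = 0.15 / kcasr
        k2 = 0.045 * kcasr
        o_rel = k1 * cass * cass * rbar / (0.060 + k1 * cass * cass)
        i_rel = 0.102 * o_rel * (casr - cass)
        i_up = 0.006375 / (1.0 + (0.00025 / cai) ** 2)
        i_leak = 0.00036 * (casr - cai)
        i_xfer = 0.0038 * (cass - cai)
        tau_rb = 1.0 / (k2 * cass + 0.005)
        rb_inf = 0.005 * tau_rb
        Y[i_rbar, i] = rb_inf + (rbar - rb_inf) * math.exp(-dt / tau_rb)

        buf_c = 1.0 / (1.0 + 0.2 * 0.001 / ((cai + 0.001) ** 2))
        buf_sr = 1.0 / (1.0 + 10.0 * 0.3 / ((casr + 0.3) ** 2))
        buf_ss = 1.0 / (1.0 + 0.4 * 0.00025 / ((cass + 0.00025) ** 2))
        ca_f = 0.185 / (2.0 * 0.016404 * 96485.3415)
        dcai = buf_c * ((i_leak - i_up) * 0.001094 / 0.016404 + i_xfer
                        - (i_bca + i_pca - 2.0 * i_naca) * ca_f)
        dcasr = buf_sr * (i_up - i_rel - i_leak)
        dcass = buf_ss * (-i_cal * 0.185 / (2.0 * 0.00005468 * 96485.3415)
                          + i_rel * 0.001094 / 0.00005468
                          - i_xfer * 0.016404 / 0.00005468)
        cai += dt * dcai
        casr += dt * dcasr
        cass += dt * dcass
        Y[iv_cai, i] = cai if cai > 1e-9 else 1e-9
        Y[iv_casr, i] = casr if casr > 1e-9 else 1e-9
        Y[iv_cass, i] = cass if cass > 1e-9 else 1e-9

        if update_v:
            # dV/dt = -(I_ion + I_stim); depolarizing stimulus is negative
            Y[0, i] = v - dt * (i_ion + istim[i])


def react_step(Y: np.ndarray, P: np.ndarray, dt: float,
               istim: np.ndarray, update_v: bool = True) -> None:
    """In-place reaction update of all cells in ``Y`` (shape (N_VARS, n))."""
    T, TK1 = build_tables(dt)
    _react(Y, P, T, TK1, dt, istim, update_v)


def initial_states(n: int) -> np.ndarray:
    """(N_VARS, n) array of resting steady-state cells."""
    return np.repeat(im.initial_state()[:, None], n, axis=1)


def run_single_cell_kernel(isch, pacing, duration, dt, sample_every,
                           consts, state=None):
    """Fast single-cell pacing run; see ionic_model.run_single_cell."""
    Y = (state.y.copy()[:, None] if state is not None
         else initial_states(1))
    P = cell_params(isch.atp_i, isch.k_o, isch.f_gcal, isch.f_gna, consts)
    T, TK1 = build_tables(dt)
    n_steps = int(round(duration / dt))
    stride = max(int(round(sample_every / dt)), 1)
    n_samp = (n_steps + stride - 1) // stride
    ts = np.empty(n_samp)
    vs = np.empty(n_samp)
    istim = np.zeros(1)
    k = 0
    for i in range(n_steps):
        t = i * dt
        if i % stride == 0:
            ts[k] = t
            vs[k] = Y[0, 0]
            k += 1
        istim[0] = pacing.current(t)
        _react(Y, P, T, TK1, dt, istim, True)
        vv = Y[0, 0]
        if not math.isfinite(vv) or abs(vv) > 300.0:
            raise FloatingPointError(
                f"numerical blow-up at step {i} (t = {t:.2f} ms)")
    return ts[:k], vs[:k]


# ---------------------------------------------------------------------------
# Chunked tissue integration (reaction + CSR diffusion + event extraction)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _integrate_chunk(Y, P, T, TK1, dt, n_steps, t_start,  # noqa: C901
                     site_cells, site_off, site_amp, site_t0, site_t1,
                     Ldata, Lind, Lptr, n_sub, scale,
                     last_act, peak, rest_ref, active,
                     act_cell, act_time, rep_cell, rep_time,
                     stim_end, check_quiescent, quiescent_run_ms
                     ):  # pragma: no cover - compiled
    """Integrate ``n_steps`` operator-split steps with in-loop event
    detection.  Returns (steps_done, n_act, n_rep, status, quiescent_ms)
    where status: 0 ok, 1 event-buffer full, 2 blow-up, 3 quiescent."""
    n = Y.shape[1]
    n_sites = site_off.shape[0] - 1
    istim = np.zeros(n)
    vprev = np.empty(n)
    vnew = np.empty(n)
    n_act = 0
    n_rep = 0
    qms = quiescent_run_ms
    for s in range(n_steps):
        t = t_start + s * dt
        # stimulus assembly
        for i in range(n):
            istim[i] = 0.0
        for k in range(n_sites):
            if site_t0[k] <= t < site_t1[k]:
                for q in range(site_off[k], site_off[k + 1]):
                    istim[site_cells[q]] += site_amp[k]
        for i in range(n):
            vprev[i] = Y[0, i]
        _react(Y, P, T, TK1, dt, istim, True)
        # explicit diffusion sub-steps (CSR matvec)
        for _ in range(n_sub):
            for i in range(n):
                vnew[i] = Y[0, i]
            for i in range(n):
                acc = 0.0
                for q in range(Lptr[i], Lptr[i + 1]):
                    acc += Ldata[q] * vnew[Lind[q]]
                Y[0, i] = vnew[i] + scale * acc
        t_next = t + dt
        # event extraction + maximum V
        vmax = -1e30
        for i in range(n):
            v = Y[0, i]
            if v > vmax:
                vmax = v
            if not np.isfinite(v) or abs(v) > 300.0:
                return s + 1, n_act, n_rep, 2, 0.0
            if (vprev[i] < -20.0 and v >= -20.0
                    and t_next - last_act[i] > 10.0):
                if n_act >= act_cell.shape[0]:
                    return s + 1, n_act, n_rep, 1, qms
                act_cell[n_act] = i
                act_time[n_act] = t_next
                n_act += 1
                last_act[i] = t_next
                active[i] = 1
                peak[i] = v
            elif active[i] == 1:
                if v > peak[i]:
                    peak[i] = v
                v90 = peak[i] - 0.9 * (peak[i] - rest_ref[i])
                if v <= v90 and t_next - last_act[i] > 1.0:
                    if n_rep >= rep_cell.shape[0]:
                        return s + 1, n_act, n_rep, 1, qms
                    rep_cell[n_rep] = i
                    rep_time[n_rep] = t_next
                    n_rep += 1
                    active[i] = 0
            else:
                if v < rest_ref[i]:
                    rest_ref[i] = v
        # quiescence early stop
        if check_quiescent and t_next > stim_end + 5.0:
            if vmax < -75.0:
                qms += dt
                if qms >= 20.0:
                    return s + 1, n_act, n_rep, 3, qms
            else:
                qms = 0.0
    return n_steps, n_act, n_rep, 0, qms
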