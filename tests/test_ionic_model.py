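"""Unit tests of the ischemia-modified TT3 cell model."""

import math

import numpy as np
import pytest

from cardiomaze import _kernel
from cardiomaze import ionic_model as im
from cardiomaze.activity_metrics import measure_apd90
from cardiomaze.ionic_model import (
    CellState,
    HEALTHY_ISCHEMIA,
    IschemiaParams,
    KatpConstants,
    StimulusTrain,
    i_katp,
    p_atp,
    p_cal_atp,
    run_single_cell,
    rush_larsen_step,
    total_ionic_current,
)

from conftest import apd_of

K = KatpConstants()


class TestHillFunctions:
    @pytest.mark.parametrize("atp,expected", [
        (K.k05_atp, 0.5),            # half saturation
        (2 * K.k05_atp, 0.2),        # 1/(1+2^2)
        (1e6, 0.0),
        (1e-9, 1.0),
    ])
    def test_p_atp_values(self, atp, expected):
        assert p_atp(atp) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("atp,expected", [
        (1.4, 0.5),
        (2.8, 1.0 / (1.0 + 2.0 ** -2.6)),  # ~0.858
        (1e6, 1.0),
    ])
    def test_p_cal_atp_values(self, atp, expected):
        assert p_cal_atp(atp) == pytest.approx(expected, abs=1e-6)

    def test_monotonicity(self):
        grid = np.linspace(0.5, 10.0, 40)
        assert np.all(np.diff(p_atp(grid)) < 0)
        assert np.all(np.diff(p_cal_atp(grid)) > 0)

    @pytest.mark.parametrize("fn", [p_atp, p_cal_atp])
    def test_nonpositive_atp_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(0.0)
        with pytest.raises(ValueError):
            fn(-1.0)


class TestIkatp:
    def test_zero_at_reversal(self):
        for atp, ko in [(2.0, 5.4), (6.8, 9.0)]:
            assert i_katp(-80.0, -80.0, atp, ko) == 0.0

    def test_ko_normal_factor_is_one(self):
        # at [K]o,normal the conductance is exactly G_max * P_ATP
        g = i_katp(0.0, -85.0, 3.0, im.KO_NORMAL) / 85.0
        assert g == pytest.approx(K.g_katp_max * p_atp(3.0), rel=1e-12)

    def test_magnitude_grows_with_hyperkalemia_and_hypoxia(self):
        base = i_katp(0.0, -85.0, 3.0, 5.4)
        assert i_katp(0.0, -85.0, 2.0, 5.4) > base       # more hypoxia
        assert i_katp(0.0, -85.0, 3.0, 7.0) > base       # more [K]o

    def test_printed_conductance_scale(self):
        # the printed channel-density scale: 195e-6 / 5e3 = 3.9e-8
        assert 195e-6 / 5e3 == pytest.approx(3.9e-8)


class TestTotalCurrent:
    def test_breakdown_sums_to_total(self):
        state = CellState()
        state.v = -20.0
        total, br = total_ionic_current(state, IschemiaParams(atp_i=3.0))
        assert total == pytest.approx(sum(br.values()), rel=1e-12)
        assert set(br) == {
            "i_na", "i_k1", "i_to", "i_kr", "i_ks", "i_cal", "i_naca",
            "i_nak", "i_pca", "i_pk", "i_bna", "i_bca", "i_katp"}

    def test_rest_is_near_fixed_point(self):
        # relax to rest, then |dV/dt| must be tiny
        st = CellState()
        for _ in range(50000):
            st = rush_larsen_step(st, HEALTHY_ISCHEMIA, 0.1)
        total, _ = total_ionic_current(st, HEALTHY_ISCHEMIA)
        assert abs(total) < 1e-3  # pA/pF == mV/ms

    def test_hypoxia_increases_outward_plateau_current(self):
        state = CellState()
        state.v = 0.0
        t_hyp, _ = total_ionic_current(state, IschemiaParams(atp_i=3.0))
        t_heal, _ = total_ionic_current(state, HEALTHY_ISCHEMIA)
        assert t_hyp > t_heal  # net outward larger under hypoxia

    def test_nan_state_rejected(self):
        state = CellState()
        state.v = float("nan")
        with pytest.raises(FloatingPointError):
            total_ionic_current(state, HEALTHY_ISCHEMIA)


class TestRushLarsen:
    def test_frozen_rates_match_analytic_exponential(self):
        """With V fixed, each gate must follow
        g(t) = g_inf + (g0 - g_inf) exp(-t/tau) to machine precision."""
        st = CellState()
        v = st.v
        dt = 0.5
        stepped = rush_larsen_step(st, HEALTHY_ISCHEMIA, dt, update_v=False)
        for name, fn in im.VOLTAGE_GATE_RATES.items():
            inf, tau = fn(v)
            g0 = st.y[im.IDX_GATE[name]]
            expected = float(inf) + (g0 - float(inf)) * math.exp(-dt / float(tau))
            assert stepped.y[im.IDX_GATE[name]] == pytest.approx(
                expected, rel=1e-14, abs=1e-300)

    def test_small_dt_changes_state_by_order_dt(self):
        st = CellState()
        st.v = -30.0  # away from rest so derivatives are non-trivial
        d1 = np.abs(rush_larsen_step(st, dt=1e-3).y - st.y).max()
        d2 = np.abs(rush_larsen_step(st, dt=2e-3).y - st.y).max()
        assert d2 == pytest.approx(2 * d1, rel=0.05)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            rush_larsen_step(CellState(), dt=0.0)


class TestPacedCell:
    def test_gates_stay_in_unit_interval(self, healthy_trace):
        # run a fresh short paced simulation retaining full state
        Y = _kernel.initial_states(1)
        P = _kernel.cell_params(6.8, 5.4, 1.0, 1.0)
        pacing = StimulusTrain(n_beats=2)
        lo = np.ones(im.N_GATES)
        hi = np.zeros(im.N_GATES)
        for i in range(int(2000 / 0.02)):
            _kernel.react_step(Y, P, 0.02,
                               np.array([pacing.current(i * 0.02)]))
            g = Y[1:1 + im.N_GATES, 0]
            lo = np.minimum(lo, g)
            hi = np.maximum(hi, g)
        assert lo.min() >= 0.0 and hi.max() <= 1.0

    def test_apd_monotone_in_atp(self):
        """APD90 decreases monotonically as [ATP]i decreases (5-point grid)."""
        apds = []
        for atp in (6.8, 5.5, 4.5, 3.5, 3.0):
            t, v = run_single_cell(IschemiaParams(atp_i=atp),
                                   pacing=StimulusTrain(n_beats=3),
                                   sample_every=0.5)
            apds.append(measure_apd90(t, v))
        assert all(a is not None for a in apds)
        assert all(a > b for a, b in zip(apds, apds[1:]))

    def test_kernel_matches_reference_stepper(self):
        """Table-driven kernel reproduces the plain-NumPy reference
        trajectory (one paced beat, hypoxic cell)."""
        isch = IschemiaParams(atp_i=3.0)
        pacing = StimulusTrain(start=5.0, n_beats=1)
        t_ref, v_ref = run_single_cell(isch, pacing, duration=400.0,
                                       sample_every=2.0, use_kernel=False)
        t_k, v_k = run_single_cell(isch, pacing, duration=400.0,
                                   sample_every=2.0, use_kernel=True)
        assert np.array_equal(t_ref, t_k)
        a_ref = measure_apd90(t_ref, v_ref)
        a_k = measure_apd90(t_k, v_k)
        assert a_k == pytest.approx(a_ref, abs=2.5)
        # pointwise agreement away from the upstroke (where a sub-sample
        # shift dominates); compare resting and plateau segments
        sel = (t_ref < 5.0) | ((t_ref > 30) & (t_ref < 80))
        assert np.allclose(v_ref[sel], v_k[sel], atol=2.0)

    def test_healthy_parameters_reduce_to_baseline(self, healthy_trace):
        """The ischemia machinery at healthy parameters leaves only the
        small healthy-[ATP]i K_ATP background (regression-locked APD)."""
        apd = apd_of(healthy_trace)
        assert apd == pytest.approx(227.8, abs=3.0)

    def test_duration_must_cover_a_beat(self):
        with pytest.raises(ValueError):
            run_single_cell(HEALTHY_ISCHEMIA, StimulusTrain(start=50.0),
                            duration=10.0)


class TestIschemiaParams:
    @pytest.mark.parametrize("kw", [
        {"atp_i": 0.0}, {"k_o": -1.0}, {"f_gcal": 0.0}, {"f_gna": 1.5},
    ])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            IschemiaParams(**kw)

    def test_healthy_reference(self):
        p = IschemiaParams()
        assert (p.atp_i, p.k_o, p.f_gcal, p.f_gna) == (6.8, 5.4, 1.0, 1.0)
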