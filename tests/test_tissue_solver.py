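"""Tests of the monodomain finite-volume solver."""

import numpy as np
import pytest

from cardiomaze import _kernel
from cardiomaze import tissue_solver as ts
from cardiomaze.activity_metrics import measure_cv
from cardiomaze.ionic_model import IschemiaParams, StimulusTrain, \
    run_single_cell
from cardiomaze.tissue_solver import (
    StabilityError,
    StimulusProtocol,
    Tag,
    TissueGrid,
    assemble_diffusion_operator,
)


def random_grid(rng, dims=(6, 5, 4), p_noncond=0.3) -> TissueGrid:
    g = TissueGrid.uniform(dims, spacing=100.0)
    mask = rng.random(dims) < p_noncond
    mask.ravel()[0] = False  # keep at least one conducting cell
    g.tags[mask] = int(Tag.NONCOND)
    g.sigma = 0.5 + 2.0 * rng.random(dims)
    return g


class TestDiffusionOperator:
    def test_rows_sum_to_zero_and_symmetric(self, rng):
        for _ in range(10):
            g = random_grid(rng)
            L = assemble_diffusion_operator(g)
            assert np.allclose(np.asarray(L.sum(axis=1)).ravel(), 0.0,
                               atol=1e-9)
            assert (L - L.T).nnz == 0 or \
                np.abs((L - L.T).data).max() < 1e-9

    def test_uniform_field_in_kernel(self, rng):
        g = random_grid(rng)
        L = assemble_diffusion_operator(g)
        v = np.full(L.shape[0], -37.5)
        assert np.allclose(L @ v, 0.0, atol=1e-9)

    def test_isolated_cell_row_is_zero(self):
        g = TissueGrid.uniform((3, 3, 1), spacing=100.0)
        g.tags[:] = int(Tag.NONCOND)
        g.tags[1, 1, 0] = int(Tag.HEALTHY)
        L = assemble_diffusion_operator(g)
        assert L.shape == (1, 1)
        assert L.nnz == 0

    def test_three_cell_cable_stencil(self):
        """Hand-assembled 1D stencil: centre row (1, -2, 1) * sigma/h^2."""
        g = TissueGrid.uniform((3, 1, 1), spacing=100.0, sigma=2.0)
        L = assemble_diffusion_operator(g).toarray()
        h_cm = 100e-4
        c = 2.0 / h_cm ** 2
        expected = c * np.array([[-1, 1, 0], [1, -2, 1], [0, 1, -1]])
        assert np.allclose(L, expected)

    def test_no_conducting_cells_rejected(self):
        g = TissueGrid.uniform((2, 2, 1))
        g.tags[:] = int(Tag.NONCOND)
        with pytest.raises(ValueError):
            assemble_diffusion_operator(g)


class TestStepping:
    def test_zero_sigma_equals_single_cells(self):
        """With sigma = 0 every cell evolves like an isolated cell."""
        isch = IschemiaParams(atp_i=3.0)
        g = TissueGrid.uniform((4, 1, 1), spacing=100.0, isch=isch,
                               sigma=0.0)
        prot = StimulusProtocol.plane(g, axis=0, thickness=4,
                                      amplitude=-52.0, start=2.0,
                                      duration=1.0)
        rec = ts.run(g, prot, 60.0, snapshot_every=1.0,
                     early_stop_quiescent=False)
        t_ref, v_ref = run_single_cell(
            isch, StimulusTrain(amplitude=-52.0, duration=1.0, start=2.0,
                                n_beats=1, period=1000.0),
            duration=60.0, sample_every=1.0)
        for k in range(4):
            assert np.allclose(rec.v_fields[:, k], v_ref,
                               atol=1e-6), "cell diverged from ODE trace"

    def test_charge_conserved_by_diffusion(self, rng):
        """With no reaction, the diffusion update conserves sum(V)."""
        g = random_grid(rng, dims=(8, 8, 3), p_noncond=0.2)
        L = assemble_diffusion_operator(g)
        v = -85.0 + 60.0 * rng.random(L.shape[0])
        total = v.sum()
        for _ in range(100):
            v = v + 0.01 * (L @ v) / (g.beta * g.cm)
        assert v.sum() == pytest.approx(total, rel=1e-12)

    def test_cfl_guard_raises(self):
        g = TissueGrid.uniform((10, 1, 1), spacing=10.0, sigma=20.0)
        with pytest.raises(StabilityError, match="sub-steps"):
            ts.run(g, StimulusProtocol.plane(g, axis=0), 10.0)


class TestRuns:
    def test_no_stimulus_stays_quiescent(self):
        g = TissueGrid.uniform((12, 12, 1), spacing=100.0)
        prot = StimulusProtocol(sites=[])
        rec = ts.run(g, prot, 100.0, early_stop_quiescent=False)
        assert all(not a for a in rec.activations)
        assert rec.v_fields.max() < -80.0

    def test_center_stimulus_single_target_wave(self):
        g = TissueGrid.uniform((25, 25, 1), spacing=200.0)
        prot = StimulusProtocol.point(g, (12, 12, 0), radius_cells=2.5,
                                      start=2.0, duration=2.0)
        rec = ts.run(g, prot, 400.0, early_stop_quiescent=True)
        n_acts = np.array([len(a) for a in rec.activations])
        assert np.all(n_acts == 1), "every cell activates exactly once"
        # quiescent long before 1 s after the stimulus
        assert rec.quiescent_from is not None
        assert rec.quiescent_from < 500.0
        # activation time grows with distance from the centre
        amap = np.array([a[0] for a in rec.activations])
        d = np.linalg.norm(rec.positions - rec.positions[12 * 25 + 12],
                           axis=1)
        assert np.corrcoef(d, amap)[0, 1] > 0.99

    def test_cv_scales_like_sqrt_sigma(self):
        cvs = {}
        for s in (0.925, 1.85, 3.7):
            g = TissueGrid.uniform((120, 1, 1), spacing=200.0, sigma=s)
            prot = StimulusProtocol.plane(g, axis=0, thickness=3)
            rec = ts.run(g, prot, 250.0)
            cvs[s] = measure_cv(rec, 40, 90)
        assert cvs[0.925] < cvs[1.85] < cvs[3.7]
        assert cvs[3.7] / cvs[0.925] == pytest.approx(2.0, rel=0.10)

    def test_ischemia_signs_on_cable(self):
        """Halving g_Na slows conduction; raising [K]o depolarizes rest."""
        g0 = TissueGrid.uniform((80, 1, 1), spacing=200.0)
        gna = TissueGrid.uniform((80, 1, 1), spacing=200.0,
                                 isch=IschemiaParams(f_gna=0.5))
        hyper = TissueGrid.uniform((80, 1, 1), spacing=200.0,
                                   isch=IschemiaParams(k_o=9.0))
        prot0 = StimulusProtocol.plane(g0, axis=0, thickness=3)
        cv0 = measure_cv(ts.run(g0, prot0, 200.0), 20, 60)
        cv1 = measure_cv(ts.run(gna, prot0, 200.0), 20, 60)
        assert cv1 < cv0
        rec = ts.run(hyper, StimulusProtocol(sites=[]), 50.0,
                     early_stop_quiescent=False)
        assert rec.v_fields[-1].mean() > -80.0  # depolarized vs -85 rest

    def test_cv_dt_refinement_self_consistency(self):
        """Halving dt changes the measured CV by < 1%."""
        cvs = {}
        for dt in (0.02, 0.01):
            g = TissueGrid.uniform((100, 1, 1), spacing=200.0)
            prot = StimulusProtocol.plane(g, axis=0, thickness=3)
            rec = ts.run(g, prot, 200.0, dt=dt)
            cvs[dt] = measure_cv(rec, 30, 70)
        assert cvs[0.01] == pytest.approx(cvs[0.02], rel=0.01)

    def test_invalid_inputs(self):
        g = TissueGrid.uniform((10, 1, 1))
        with pytest.raises(ValueError):
            ts.run(g, StimulusProtocol.plane(g), -5.0)
        with pytest.raises(ValueError):
            StimulusProtocol.point(g, (-8, -8, 0), radius_cells=1.0)


class TestKernelChunkEquivalence:
    def test_chunked_run_matches_plain_stepper(self):
        """The chunked integrator and the step-by-step path produce the
        same voltage field."""
        g = TissueGrid.uniform((20, 4, 1), spacing=200.0)
        prot = StimulusProtocol.plane(g, axis=0, thickness=2, start=1.0)
        rec = ts.run(g, prot, 30.0, snapshot_every=20.0,
                     early_stop_quiescent=False)
        # manual integration up to the t = 20 ms snapshot
        st = ts._TissueStepper(g, 0.02)
        index = -np.ones(g.conducting_mask().size, dtype=np.int64)
        index[g.conducting_mask().ravel()] = np.arange(st.n)
        site = prot.sites[0]
        ci = index[site.indices]
        for i in range(1000):
            t = i * 0.02
            st.istim[:] = 0.0
            if site.start <= t < site.start + site.duration:
                st.istim[ci] = site.amplitude
            st.advance()
        k = int(np.argmin(np.abs(rec.times - 20.0)))
        assert rec.times[k] == pytest.approx(20.0)
        assert np.allclose(rec.v_fields[k], st.Y[0], atol=1e-5)
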