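"""Input-function machinery: population model, IDIF, hybrid, dual-injection."""

import numpy as np
import pytest

from petki import (DynamicImage, FengParams, SampledCurve,
                   assemble_composite_if, auc_ratio, build_hybrid_if,
                   build_schedule, decompose_dual_injection, extract_idif,
                   population_if, uniform_grid)
from petki.errors import CurveError, DecompositionError, JunctionError, MaskError


class TestPopulationModel:
    def test_bolus_peaks_within_first_minute(self):
        c = population_if()
        assert c.t[np.argmax(c.v)] < 60.0
        assert np.all(c.v >= 0.0)

    def test_zero_amplitudes_give_zero_curve(self):
        c = population_if(FengParams(A1=0.0, A2=0.0, A3=0.0))
        assert np.all(c.v == 0.0)

    def test_auc_stable_under_grid_refinement(self):
        coarse = population_if(grid=uniform_grid(3600.0, 1.0))
        fine = population_if(grid=uniform_grid(3600.0, 0.1))
        assert coarse.auc() == pytest.approx(fine.auc(), rel=1e-3)


class TestExtractIdif:
    def test_uniform_image_gives_constant_curve(self):
        sched = build_schedule("P1")
        dyn = DynamicImage(np.full((70, 2, 2, 2), 7.0), sched)
        mask = np.ones((2, 2, 2), bool)
        c = extract_idif(dyn, mask)
        np.testing.assert_allclose(c.v, 7.0)

    def test_single_voxel_mask_returns_that_tac(self):
        sched = build_schedule("P1")
        vals = np.zeros((70, 2, 1, 1))
        vals[:, 0, 0, 0] = np.arange(70.0)
        vals[:, 1, 0, 0] = 99.0
        mask = np.zeros((2, 1, 1), bool)
        mask[0, 0, 0] = True
        c = extract_idif(DynamicImage(vals, sched), mask)
        mids = sched.midpoints
        # evaluated back at the midpoints through the 1-s grid; allow the
        # grid-discretization wobble of the re-interpolation
        np.testing.assert_allclose(c(mids), np.arange(70.0), atol=0.06)

    def test_closed_loop_blood_recovery(self, p1_dataset, feng_cp):
        """IDIF from the noiseless blood pool reproduces the simulating
        input function's frame averages within 0.5% of the peak once past
        the bolus upslope (the first ~4 frames carry the curvature error of
        midpoint interpolation against a sharply rising bolus)."""
        from petki.kinetics import frame_averages
        ph = p1_dataset.phantom
        idif = extract_idif(p1_dataset.image, ph.blood_mask)
        sched = p1_dataset.image.schedule
        truth = frame_averages(feng_cp, sched)
        got = idif(sched.midpoints)
        rel = np.abs(got - truth) / truth.max()
        assert rel[5:].max() < 0.005
        assert rel[1:5].max() < 0.02

    def test_empty_mask_rejected(self, p1_dataset):
        with pytest.raises(MaskError):
            extract_idif(p1_dataset.image,
                         np.zeros(p1_dataset.image.spatial_shape, bool))


class TestHybrid:
    def _curves(self, early_v, pop_fn, late_v, t1=240.0, t2=340.0, T=600.0):
        g_e = uniform_grid(t1, 1.0)
        g_a = uniform_grid(T, 1.0)
        g_l = uniform_grid(T, 1.0, t_start=t2)
        early = SampledCurve(g_e, np.full(g_e.size, early_v))
        pop = SampledCurve(g_a, pop_fn(g_a))
        late = SampledCurve(g_l, np.full(g_l.size, late_v))
        return early, late, pop

    def test_worked_junction_example(self):
        # early(t1)=10, pop=5 everywhere -> mu = 2; late(t2)=4, pop(t2)=5
        # with t2-t1=100 s -> exp(-100 gamma) = 4/10, gamma = ln(2.5)/100
        early, late, pop = self._curves(10.0, lambda t: np.full(t.size, 5.0),
                                        4.0)
        curve, spec = build_hybrid_if(early, late, pop, 240.0, 340.0)
        assert spec.mu == pytest.approx(2.0)
        assert spec.gamma == pytest.approx(np.log(2.5) / 100.0)
        # continuity is exact at both junctions
        assert curve(240.0) == pytest.approx(10.0, abs=1e-12)
        assert curve(340.0) == pytest.approx(4.0, abs=1e-12)

    def test_pure_scaling_case_gives_gamma_half_life(self):
        # late(t2)=5 with mu*pop(t2)=10 -> e^{-100 gamma}=0.5
        early, late, pop = self._curves(10.0, lambda t: np.full(t.size, 5.0),
                                        5.0)
        _, spec = build_hybrid_if(early, late, pop, 240.0, 340.0)
        assert spec.gamma == pytest.approx(np.log(2.0) / 100.0)

    def test_proportional_population_reproduces_truth_on_gap(self, feng_cp):
        """A population curve proportional to the truth is corrected exactly
        by mu (and gamma = 0)."""
        t1, t2 = 240.0, 3240.0
        truth = feng_cp
        pop = SampledCurve(truth.t, truth.v / truth.v.max())
        early = truth.restrict(0.0, t1)
        late = truth.restrict(t2, 3600.0)
        hybrid, spec = build_hybrid_if(early, late, pop, t1, t2)
        assert abs(spec.gamma) < 1e-9
        gap = (hybrid.t > t1) & (hybrid.t < t2)
        np.testing.assert_allclose(hybrid.v[gap], truth(hybrid.t[gap]),
                                   rtol=1e-9)

    def test_junction_errors(self):
        early, late, pop = self._curves(10.0, lambda t: np.full(t.size, 5.0),
                                        4.0)
        with pytest.raises(JunctionError):
            build_hybrid_if(early, late, pop, 340.0, 240.0)
        zero_late = SampledCurve(late.t, np.zeros(late.t.size))
        with pytest.raises(JunctionError):
            build_hybrid_if(early, zero_late, pop, 240.0, 340.0)


class TestDualInjectionDecomposition:
    def _window(self, fn):
        g = uniform_grid(3600.0, 1.0, t_start=3000.0)
        return SampledCurve(g, fn(g))

    def test_pure_exponential_leaves_no_bolus(self):
        c0, b = 20.0, 5e-4
        w = self._window(lambda t: c0 * np.exp(-b * t))
        early, late, fit = decompose_dual_injection(w, 3360.0)
        assert np.max(np.abs(early.v)) < 0.01 * fit.C_B0
        assert fit.b == pytest.approx(b, rel=1e-3)

    def test_recovers_known_bolus(self):
        c0, b, t0 = 20.0, 5e-4, 3360.0
        bolus = lambda tau: np.where(tau >= 0,
                                     60.0 * (tau / 30.0)
                                     * np.exp(1.0 - tau / 30.0), 0.0)
        w = self._window(lambda t: c0 * np.exp(-b * t) + bolus(t - t0))
        early, late, fit = decompose_dual_injection(w, t0)
        assert fit.b == pytest.approx(b, rel=0.05)
        rmse = np.sqrt(np.mean((early.v - bolus(early.t)) ** 2))
        assert rmse < 0.02 * bolus(np.array([30.0]))[0]

    def test_constant_tail_gives_zero_rate(self):
        w = self._window(lambda t: np.where(t < 3360.0, 5.0,
                                            5.0 + 3.0 * np.exp(
                                                -(t - 3360.0) / 40.0)))
        early, late, fit = decompose_dual_injection(w, 3360.0)
        assert fit.b == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(
            early.v, w(early.t + 3360.0) - 5.0, atol=1e-6)

    def test_needs_enough_pre_injection_data(self):
        g = uniform_grid(3600.0, 1.0, t_start=3300.0)
        w = SampledCurve(g, np.full(g.size, 5.0))
        with pytest.raises(DecompositionError):
            decompose_dual_injection(w, 3360.0)

    def test_round_trip_through_composite(self, feng_cp):
        """Assemble a two-bolus input, sample the late window, decompose:
        the injected bolus comes back (RMSE < 2% of its peak)."""
        t0 = 3360.0
        bolus = feng_cp.restrict(0.0, 240.0)
        comp = assemble_composite_if(feng_cp, bolus, t0, 1.0)
        window = comp.restrict(3000.0, 3600.0)
        early, _, fit = decompose_dual_injection(window, t0)
        assert np.sqrt(np.mean((early.v - bolus(early.t)) ** 2)) \
            < 0.02 * bolus.v.max()


class TestCompositeAssembly:
    def test_zero_dose_ratio_rejected_and_identity(self, feng_cp):
        bolus = feng_cp.restrict(0.0, 240.0)
        with pytest.raises(CurveError):
            assemble_composite_if(feng_cp, bolus, 3360.0, 0.0)
        tiny = assemble_composite_if(feng_cp, bolus, 3360.0, 1e-12)
        np.testing.assert_allclose(tiny.v, feng_cp.v, rtol=1e-9)

    def test_superposition_of_identical_bolus(self, feng_cp):
        bolus = feng_cp.restrict(0.0, 240.0)
        comp = assemble_composite_if(feng_cp, bolus, 3360.0, 1.0)
        assert comp(3361.0) == pytest.approx(feng_cp(3361.0) + feng_cp(1.0),
                                             rel=1e-9)
        assert comp(100.0) == pytest.approx(feng_cp(100.0), rel=1e-12)

    def test_auc_adds_linearly(self, feng_cp):
        bolus = feng_cp.restrict(0.0, 240.0)
        ratio = 0.7
        comp = assemble_composite_if(feng_cp, bolus, 3360.0, ratio)
        expected = feng_cp.auc() + ratio * bolus.auc(0.0, feng_cp.t_end - 3360.0)
        # the truncated bolus ends discontinuously; allow one half-cell edge
        assert comp.auc() == pytest.approx(expected, rel=1e-3)


class TestAucRatio:
    def test_identity_and_scaling(self, feng_cp):
        assert auc_ratio(feng_cp, feng_cp) == pytest.approx(1.0)
        double = SampledCurve(feng_cp.t, 2.0 * feng_cp.v)
        assert auc_ratio(double, feng_cp) == pytest.approx(2.0)

    def test_exponential_vs_unit_closed_form(self):
        t = uniform_grid(3600.0, 1.0)
        a = SampledCurve(t, np.exp(-t / 600.0))
        b = SampledCurve(t, np.ones(t.size))
        expected = 600.0 * (1.0 - np.exp(-6.0)) / 3600.0
        assert auc_ratio(a, b) == pytest.approx(expected, rel=1e-4)

    def test_zero_reference_rejected(self):
        t = uniform_grid(10.0, 1.0)
        a = SampledCurve(t, np.ones(t.size))
        z = SampledCurve(t, np.zeros(t.size))
        with pytest.raises(ZeroDivisionError):
            auc_ratio(a, z)
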