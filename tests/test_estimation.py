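"""ML updates, alternating joint fit, and the Patlak reference estimator."""

import numpy as np
import pytest

from petki import (FitConfig, NonlinearKineticModel, PatlakModel,
                   SampledCurve, TissueParams, build_schedule, fit_image,
                   make_basis, patlak_fit, solve_2tc)
from petki.errors import InsufficientDataError
from petki.estimation import (poisson_loglik, update_delay, update_k1p,
                              update_ki, update_k2p, update_linear,
                              update_vb)
from petki.kinetics import forward_model, frame_averages
from petki.protocols import DynamicImage


@pytest.fixture(scope="module")
def basis(feng_cp):
    return make_basis(feng_cp, 0.5, 0.0, build_schedule("P1"))


class TestMultiplicativeUpdates:
    def test_fixed_point_when_prediction_matches_data(self, basis):
        X = forward_model(0.05, 0.08, 0.02, basis)
        assert update_ki(0.02, X, X, basis.Bi, basis.w) \
            == pytest.approx(0.02, rel=1e-12)
        assert update_k1p(0.08, X, X, basis.Bexp, basis.w) \
            == pytest.approx(0.08, rel=1e-12)
        assert update_vb(0.05, X, X, basis.Bp, basis.w) \
            == pytest.approx(0.05, rel=1e-12)

    def test_single_update_solves_one_parameter_model(self, basis):
        """With vb = K1' = 0 the prediction is ki*Bi and one update lands on
        the weighted estimator sum(w X)/sum(w Bi) from any positive start."""
        ki_true = 0.015
        X = ki_true * basis.Bi
        closed = (basis.w * X).sum() / (basis.w * basis.Bi).sum()
        for start in (1e-4, 0.01, 5.0):
            got = update_ki(start, X, start * basis.Bi, basis.Bi, basis.w)
            assert got == pytest.approx(closed, rel=1e-12)
        assert closed == pytest.approx(ki_true, rel=1e-12)

    def test_restarts_agree_with_grid_search_mle(self, basis, rng):
        """On Poisson-noised one-parameter data, iterated updates from 200
        random starts all land on the grid-search likelihood maximum."""
        ki_true = 0.02
        scale = 50.0  # counts per kBq/mL at unit weight
        lam = ki_true * basis.Bi * scale * basis.w
        X = rng.poisson(lam) / (scale * basis.w)
        starts = np.exp(rng.uniform(np.log(1e-4), np.log(1.0), 200))
        ki = starts.copy()
        for _ in range(400):
            Xh = ki[:, None] * basis.Bi
            ki = update_ki(ki, X, Xh, basis.Bi, basis.w)
        # brute-force likelihood scan
        grid = np.linspace(0.5 * ki_true, 2.0 * ki_true, 40001)
        ll = poisson_loglik(X, grid[:, None] * basis.Bi, basis.w)
        ki_grid = grid[np.argmax(ll)]
        assert np.all(np.abs(ki - ki_grid) / ki_grid < 1e-3)

    def test_joint_updates_recover_noiseless_linear_triplet(self, basis):
        """Alternating multiplicative sweeps at the true (k2', delay)
        recover vb, K1' and Ki within 1% on noiseless data."""
        truth = (0.07, 0.12, 0.008)
        X = forward_model(*truth, basis)
        vb, k1p, ki = 0.05, 0.05, 0.01
        for _ in range(400):
            vb, k1p, ki = update_linear(vb, k1p, ki, X, basis)
        assert vb == pytest.approx(truth[0], rel=0.01)
        assert k1p == pytest.approx(truth[1], rel=0.01)
        assert ki == pytest.approx(truth[2], rel=0.01)

    def test_sweeps_never_decrease_likelihood_on_1000_voxels(self, basis,
                                                             rng):
        """MLEM monotonicity with the nonlinear parameters fixed, checked
        voxelwise on 1,000 random noisy voxels."""
        V = 1000
        vb_t = rng.uniform(0.0, 0.3, V)
        k1p_t = rng.uniform(0.0, 0.5, V)
        ki_t = rng.uniform(0.0, 0.05, V)
        Xc = (vb_t[:, None] * basis.Bp + k1p_t[:, None] * basis.Bexp
              + ki_t[:, None] * basis.Bi)
        scale = 5.0
        X = rng.poisson(np.maximum(Xc, 0.0) * scale * basis.w) \
            / (scale * basis.w)
        vb = rng.uniform(0.01, 0.5, V)
        k1p = rng.uniform(0.01, 0.5, V)
        ki = rng.uniform(0.001, 0.1, V)
        def ll():
            Xh = (vb[:, None] * basis.Bp + k1p[:, None] * basis.Bexp
                  + ki[:, None] * basis.Bi)
            return poisson_loglik(X, Xh, basis.w)
        prev = ll()
        for _ in range(25):
            vb, k1p, ki = update_linear(vb, k1p, ki, X, basis)
            cur = ll()
            assert np.all(cur >= prev - 1e-9 * np.abs(prev) - 1e-12)
            prev = cur


class TestNonlinearUpdates:
    def _make(self, feng_cp, k2p_true, delta_true=0.0):
        sched = build_schedule("P1")
        truth = (0.05, 0.2, 0.015)
        b = make_basis(feng_cp, k2p_true, delta_true, sched)
        X = forward_model(*truth, b)
        basis_for_k2p = lambda k: make_basis(feng_cp, k, delta_true, sched)
        return X, truth, basis_for_k2p, sched

    def test_k2p_converges_to_truth_on_noiseless_data(self, feng_cp):
        X, truth, basis_for, _ = self._make(feng_cp, 0.45)
        vb, k1p, ki = truth
        k2p, step = 1.0, None
        lls = []
        for _ in range(27):
            k2p, step = update_k2p(k2p, X, vb, k1p, ki, basis_for, step)
            b = basis_for(k2p)
            lls.append(poisson_loglik(X, forward_model(vb, k1p, ki, b), b.w))
        assert abs(k2p - 0.45) / 0.45 < 0.05
        assert np.all(np.diff(lls) >= -1e-9 * np.abs(lls[0]))

    def test_k2p_flat_likelihood_keeps_value(self, feng_cp):
        """With K1' = 0 the likelihood does not depend on k2'."""
        X, truth, basis_for, _ = self._make(feng_cp, 0.45)
        vb, _, ki = truth
        b0 = basis_for(0.45)
        X = forward_model(vb, 0.0, ki, b0)
        k2p, _ = update_k2p(0.7, X, vb, 0.0, ki, basis_for, 1.5)
        assert k2p == 0.7

    def test_k2p_stays_clipped_at_bound(self, feng_cp):
        X, truth, basis_for, _ = self._make(feng_cp, 0.01)
        vb, k1p, ki = truth
        k2p = 0.01
        for _ in range(3):
            k2p, _ = update_k2p(k2p, X, vb, k1p, ki, basis_for, 2.0,
                                bounds=(0.01, 3.0))
        assert k2p >= 0.01

    def test_delay_recovers_known_shift(self, feng_cp):
        sched = build_schedule("P1")
        truth = (0.05, 0.2, 0.015)
        delta_true = 8.0
        b = make_basis(feng_cp, 0.5, delta_true, sched)
        X = forward_model(*truth, b)
        basis_for = lambda d: make_basis(feng_cp, 0.5, d, sched)
        vb, k1p, ki = truth
        grid = tuple(float(d) for d in range(-10, 31))
        delay = 0.0
        for _ in range(20):
            delay = update_delay(delay, X, vb, k1p, ki, basis_for, grid)
        assert abs(delay - delta_true) <= 1.0

    def test_delay_flat_likelihood_stays_and_respects_grid(self, feng_cp):
        sched = build_schedule("P1")
        basis_for = lambda d: make_basis(feng_cp, 0.5, d, sched)
        b = basis_for(0.0)
        X = 0.01 * b.Bi  # Ki-only voxel: nearly delay-insensitive late data
        grid = (0.0, 1.0, 2.0)
        # at the grid edge the search never leaves the grid
        d = update_delay(2.0, X, 0.0, 0.0, 0.01, basis_for, grid)
        assert d in grid
        # exactly flat likelihood (all coefficients zero) keeps the value
        assert update_delay(1.0, X, 0.0, 0.0, 0.0, basis_for, grid) == 1.0


class TestFitImage:
    def test_counter_and_trace_on_small_fit(self, p1_dataset):
        ph = p1_dataset.phantom
        mask = np.zeros(ph.labels.shape, bool)
        idx = np.argwhere(ph.mask(1))[:16]
        mask[tuple(idx.T)] = True
        res = fit_image(p1_dataset.image, p1_dataset.cp_model, mask=mask)
        assert res.counters["main_iterations"] == 27
        assert res.counters["ki_updates"] == 162
        assert res.counters["k1p_updates"] == 162
        assert res.counters["vb_updates"] == 162
        trace = res.loglik_trace
        assert np.all(np.diff(trace) >= -1e-7 * np.abs(trace[0]))

    def test_flagging_of_bad_voxels(self, feng_cp):
        sched = build_schedule("P1")
        b = make_basis(feng_cp, 0.5, 0.0, sched)
        vals = np.zeros((70, 3, 1, 1))
        vals[:, 0, 0, 0] = forward_model(0.05, 0.1, 0.02, b)
        vals[:, 1, 0, 0] = 0.0            # all-zero TAC
        vals[10, 2, 0, 0] = np.nan        # corrupt frame
        cfg = FitConfig(n_main=2)
        res = fit_image(DynamicImage(vals, sched), feng_cp, cfg)
        assert res.maps.flags[0, 0, 0] == 0
        assert res.maps.flags[1, 0, 0] == 2
        assert res.maps.flags[2, 0, 0] == 1
        # all-zero voxels stay at the initialization
        assert res.maps.ki[1, 0, 0] == cfg.init_ki
        assert res.n_flagged == 2

    def test_results_summary_is_tabular(self, p1_dataset):
        ph = p1_dataset.phantom
        mask = np.zeros(ph.labels.shape, bool)
        mask[tuple(np.argwhere(ph.mask(1))[:8].T)] = True
        model = NonlinearKineticModel(p1_dataset.image, p1_dataset.cp_model,
                                      mask=mask,
                                      config=FitConfig(n_main=3))
        res = model.fit()
        df = res.summary()
        assert set(df.index) == {"Ki", "K1p", "k2p", "vb", "delay"}
        assert (df["mean"] >= 0).all()
        rep = res.report()
        assert rep["counters"]["main_iterations"] == 3


class TestPatlak:
    def test_blood_only_voxel_gives_intercept_vb(self, feng_cp):
        sched = build_schedule("P1")
        bp = frame_averages(feng_cp, sched)
        vals = np.zeros((70, 1, 1, 1))
        vals[:, 0, 0, 0] = 0.31 * bp
        res = patlak_fit(DynamicImage(vals, sched), feng_cp)
        assert res.ki[0, 0, 0] == pytest.approx(0.0, abs=1e-12)
        assert res.intercept[0, 0, 0] == pytest.approx(0.31, rel=1e-9)

    def test_analytic_toy_slope(self, feng_cp):
        """K1=0.1, k2=0.1, k3=0.05 /min: the Patlak slope after 20 min is
        within 2% of Ki = K1 k3/(k2+k3) = 1/30 /min."""
        sched = build_schedule("P1")
        p = TissueParams(0.1, 0.1, 0.05, 0.0, 0.0)
        tac = frame_averages(solve_2tc(p, feng_cp), sched)
        vals = tac.reshape(-1, 1, 1, 1)
        res = patlak_fit(DynamicImage(vals, sched), feng_cp, t_star=1200.0)
        assert res.ki[0, 0, 0] == pytest.approx(1.0 / 30.0, rel=0.02)

    def test_slope_invariant_to_joint_rescaling(self, feng_cp, p1_dataset):
        img = p1_dataset.image
        res1 = patlak_fit(img, feng_cp)
        scaled_img = DynamicImage(img.values * 3.7, img.schedule)
        scaled_cp = SampledCurve(feng_cp.t, feng_cp.v * 3.7)
        res2 = patlak_fit(scaled_img, scaled_cp)
        np.testing.assert_allclose(res2.ki, res1.ki, rtol=1e-9, atol=1e-15)

    def test_requires_frames_after_tstar(self, p1_dataset, feng_cp):
        with pytest.raises(InsufficientDataError):
            PatlakModel(p1_dataset.image, feng_cp, t_star=3550.0).fit()
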