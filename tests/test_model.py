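"""BETPL density, normalization, sampling and the grid likelihood fit."""

import numpy as np
import pytest
from scipy import integrate

from betpl.model import (FIXED_GRID, FREE_GRID, BetplGridFit, BetplParams,
                         betpl_cdf, betpl_logpdf, betpl_norm, betpl_sample,
                         fit_betpl)
from betpl.geometry import StepSample


class TestNormalization:
    def test_pure_power_law_closed_form(self):
        # mu=3/2, lim_a=1, l_max -> inf: N = (mu-1) a^(mu-1) = 1/2
        p = BetplParams(1.5, 0.0, 0.0, 1.0, 1e9)
        assert betpl_norm(p) == pytest.approx(0.5, rel=1e-4)

    def test_invalid_mu_rejected(self):
        with pytest.raises(ValueError):
            BetplParams(0.0, 0.0, 0.0, 1.0)

    def test_matches_dense_trapezoid_oracle(self, ref_params):
        N = betpl_norm(ref_params)
        l = np.linspace(ref_params.lim_a, ref_params.l_max, 1_000_000)
        f = l ** -ref_params.mu * np.exp(-ref_params.lambda1 * l
                                         - ref_params.lambda2 / l)
        assert N * np.trapezoid(f, l) == pytest.approx(1.0, abs=1e-6)

    def test_grid_norms_match_quadrature(self):
        from betpl.model import _log_norm_grid
        g = _log_norm_grid(FREE_GRID, 0.3, 600.0)
        l1, l2, mu = (FREE_GRID.lambda1_axis(), FREE_GRID.lambda2_axis(),
                      FREE_GRID.mu_axis())
        rng = np.random.default_rng(3)
        for _ in range(8):
            i, j, m = (rng.integers(l1.size), rng.integers(l2.size),
                       rng.integers(mu.size))
            logN = np.log(betpl_norm(BetplParams(mu[m], l1[i], l2[j], 0.3)))
            assert g[i, j, m] == pytest.approx(logN, abs=1e-5)


class TestDensity:
    def test_integrates_to_one(self, ref_params):
        val, _ = integrate.quad(
            lambda l: np.exp(betpl_logpdf(np.array([l]), ref_params)[0]),
            ref_params.lim_a, ref_params.l_max, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_outside_support_is_minus_inf(self, ref_params):
        lp = betpl_logpdf(np.array([0.1, 1.0, 700.0]), ref_params)
        assert lp[0] == -np.inf and lp[2] == -np.inf and np.isfinite(lp[1])

    def test_mode_matches_dense_grid(self):
        p = BetplParams(1.5, 0.01, 2.0, 0.05)
        l = np.geomspace(p.lim_a, p.l_max, 100_000)
        dense_mode = l[np.argmax(betpl_logpdf(l, p))]
        # analytic stationary point: -mu/l - lambda1 + lambda2/l^2 = 0
        coeff = [p.lambda1, p.mu, -p.lambda2]
        root = max(np.roots(coeff))
        assert dense_mode == pytest.approx(root, rel=1e-3)

    def test_zero_lambdas_reduce_to_truncated_pareto(self):
        p = BetplParams(2.0, 0.0, 0.0, 1.0, 100.0)
        l = np.array([1.0, 5.0, 50.0])
        # truncated Pareto closed form
        N = (p.mu - 1) / (p.lim_a ** (1 - p.mu) - p.l_max ** (1 - p.mu))
        assert np.allclose(betpl_logpdf(l, p), np.log(N) - p.mu * np.log(l))


class TestSampling:
    def test_support_and_determinism(self, ref_params):
        s1 = betpl_sample(ref_params, 2000, seed=5)
        s2 = betpl_sample(ref_params, 2000, seed=5)
        assert np.array_equal(s1, s2)
        assert s1.min() >= ref_params.lim_a and s1.max() <= ref_params.l_max

    def test_mean_matches_quadrature(self, ref_params):
        n = 100_000
        s = betpl_sample(ref_params, n, seed=11)
        N = betpl_norm(ref_params)
        mean, _ = integrate.quad(
            lambda l: l * N * l ** -ref_params.mu
            * np.exp(-ref_params.lambda1 * l - ref_params.lambda2 / l),
            ref_params.lim_a, ref_params.l_max, limit=200)
        var, _ = integrate.quad(
            lambda l: (l - mean) ** 2 * N * l ** -ref_params.mu
            * np.exp(-ref_params.lambda1 * l - ref_params.lambda2 / l),
            ref_params.lim_a, ref_params.l_max, limit=200)
        assert abs(s.mean() - mean) < 3.0 * np.sqrt(var / n)


class TestGridFit:
    def test_recovers_truth_within_ci(self, ref_params, ref_sample):
        fit = BetplGridFit(mode="free", lim_a=ref_params.lim_a).fit(ref_sample)
        for name, truth in (("mu", ref_params.mu),
                            ("lambda1", ref_params.lambda1),
                            ("lambda2", ref_params.lambda2)):
            lo, hi = fit.ci_[name]
            assert lo <= getattr(fit, f"{name}_") <= hi
            assert lo - 0.05 <= truth <= hi + 0.05  # generous outer guard
        assert not fit.boundary_

    def test_ml_loglik_beats_mean_estimate_on_grid(self, ref_params, ref_sample):
        # the grid argmax dominates every grid node, in particular the node
        # nearest the (off-grid) mean-likelihood estimate
        fit = BetplGridFit(mode="free", lim_a=ref_params.lim_a).fit(ref_sample)
        snap = BetplParams(
            mu=round((fit.mu_ - 1.0) / 0.01) * 0.01 + 1.0,
            lambda1=round(fit.lambda1_ / 0.002) * 0.002,
            lambda2=round(fit.lambda2_ / 0.005) * 0.005,
            lim_a=ref_params.lim_a)
        ll_snap = betpl_logpdf(ref_sample, snap).sum()
        assert fit.loglik_ >= ll_snap - 5e-3  # float32 grid resolution slack

    def test_pure_pareto_lambdas_near_zero(self):
        p = BetplParams(1.5, 0.0, 0.0, 0.3, 600.0)
        s = betpl_sample(p, 5000, seed=3)
        fit = BetplGridFit(mode="free", lim_a=0.3).fit(s)
        assert fit.lambda1_ < 0.005
        assert fit.lambda2_ < 0.05

    def test_fixed_mu_agrees_with_free(self, ref_params, ref_sample):
        free = BetplGridFit(mode="free", lim_a=ref_params.lim_a).fit(ref_sample)
        fixed = BetplGridFit(mode="fixed", lim_a=ref_params.lim_a).fit(ref_sample)
        assert free.ci_["lambda1"][0] - 0.002 <= fixed.lambda1_ <= free.ci_["lambda1"][1] + 0.002
        assert free.ci_["lambda2"][0] - 0.02 <= fixed.lambda2_ <= free.ci_["lambda2"][1] + 0.02

    def test_grid_refinement_stability(self, ref_params, ref_sample):
        from betpl.model import GridSpec
        fine = GridSpec(d_lambda1=0.001, lambda1_max=0.2, d_lambda2=0.0025,
                        lambda2_max=3.0, d_mu=0.01)
        est = BetplGridFit(mode="free", lim_a=ref_params.lim_a)
        est.fit(ref_sample)
        coarse = (est.lambda1_, est.lambda2_)
        est2 = BetplGridFit(mode="free", lim_a=ref_params.lim_a)
        est2._grid_spec = lambda: fine
        est2.fit(ref_sample)
        assert abs(est2.lambda1_ - coarse[0]) < 0.002
        assert abs(est2.lambda2_ - coarse[1]) < 0.005

    def test_sklearn_contract(self, ref_params, ref_sample):
        est = BetplGridFit(mode="fixed", lim_a=0.3)
        assert est.get_params()["mode"] == "fixed"
        est.set_params(mode="free").fit(ref_sample)
        assert hasattr(est, "mu_")
        assert est.score(ref_sample) == pytest.approx(
            np.mean(est.score_samples(ref_sample)))

    def test_fit_betpl_requires_sufficient_sample(self):
        sample = StepSample(lengths=np.array([1.0, 2.0]), lim_a=0.5, theta=0.0,
                            source_id="s")
        with pytest.raises(ValueError, match="insufficient"):
            fit_betpl(sample)


def test_fixed_grid_axes_match_spacing():
    assert FIXED_GRID.lambda1_axis()[0] == pytest.approx(0.0005)
    assert np.diff(FIXED_GRID.lambda2_axis())[0] == pytest.approx(0.0005)
    assert FREE_GRID.mu_axis()[0] == pytest.approx(1.01)
    assert FREE_GRID.mu_axis()[-1] == pytest.approx(3.0)
    assert FREE_GRID.lambda1_axis().size == 100
    assert FREE_GRID.lambda2_axis().size == 600
    assert FREE_GRID.mu_axis().size == 200
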