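"""Hierarchical wavelet-domain fit: moment estimators, MML fixed point,
shrinkage, and equivalence with probe-wise least squares."""

import numpy as np
import pytest

from tilewave import (
    DesignSpec,
    EffectRegion,
    SimulationSpec,
    back_transform,
    build_helmert,
    build_two_group,
    effect_combination,
    estimate_common_tau,
    fit_model,
    gauss_seidel_update,
    load_fit,
    orthogonalize,
    save_fit,
    simulate,
)
from tilewave.errors import ConfigurationError, DataError


def marginal_loglik(d, design, tau, sigma2):
    """Marginal log-likelihood of D ~ N(0, sigma2 (I + tau P)), P = X''X''^T."""
    q = design.q
    p2 = np.sum((design.values.T @ d) ** 2)
    t2 = d @ d
    return -0.5 * (
        d.size * np.log(sigma2) + q * np.log1p(tau) + (p2 / (1 + tau) + t2 - p2) / sigma2
    )


@pytest.fixture
def two_group_norm():
    return build_two_group(3, 3, normalize=True)


class TestCommonTau:
    def test_boundary_of_positive_part(self, two_group_norm):
        # projection energy exactly q * sigma2 sits on the truncation boundary
        d = np.sqrt(2.0) * two_group_norm.values[:, 0] + np.sqrt(0.0) * two_group_norm.values[:, 1]
        d = two_group_norm.values @ np.array([1.0, 1.0])  # ||X''^T D||^2 = 2 = q sigma2
        assert estimate_common_tau(d, two_group_norm, sigma2=1.0) == pytest.approx(0.0)

    def test_moment_value(self, two_group_norm):
        d = two_group_norm.values @ np.array([2.0, 2.0])  # projection energy 8, q=2
        assert estimate_common_tau(d, two_group_norm, sigma2=1.0) == pytest.approx(3.0)

    def test_negative_part_truncated(self, two_group_norm):
        d = two_group_norm.values @ np.array([1.0, 0.0])  # projection energy 1 < q sigma2
        assert estimate_common_tau(d, two_group_norm, sigma2=1.0) == pytest.approx(0.0)

    def test_nonpositive_sigma2_rejected(self, two_group_norm):
        with pytest.raises(DataError):
            estimate_common_tau(np.ones(6), two_group_norm, sigma2=0.0)


class TestGaussSeidel:
    def test_orthogonal_noise_fixed_point(self, two_group_norm):
        # D orthogonal to the design: sigma2 = ||D||^2 / N, tau stays 0
        d = np.array([1.0, -1.0, 0.0, 0.0, 1.0, -1.0])
        assert np.allclose(two_group_norm.values.T @ d, 0.0)
        state = gauss_seidel_update(d, two_group_norm, {"tau": 0.0, "sigma2": 1.0})
        assert state["sigma2"] == pytest.approx(d @ d / 6)
        assert state["tau"] == 0.0

    def test_strong_signal_drives_shrinkage_to_one(self, two_group_norm):
        d = two_group_norm.values @ np.array([50.0, 50.0]) + np.array(
            [0.01, -0.01, 0.02, -0.02, 0.0, 0.0]
        )
        state = {"tau": 1.0, "sigma2": 1.0}
        for _ in range(200):
            state = gauss_seidel_update(d, two_group_norm, state)
        assert state["tau"] / (1 + state["tau"]) > 0.999

    @pytest.mark.parametrize("seed", range(12))
    def test_fixed_point_maximizes_marginal_likelihood(self, seed):
        # oracle: dense 2-D grid search over (tau, sigma2)
        design = build_helmert([2, 2, 2], normalize=True)
        rng = np.random.default_rng(seed)
        d = rng.normal(size=6) + design.values @ rng.normal(scale=rng.uniform(0, 3), size=3)
        state = {"tau": 0.5, "sigma2": 1.0}
        for _ in range(2000):
            new = gauss_seidel_update(d, design, state)
            if abs(new["tau"] - state["tau"]) < 1e-13 and abs(new["sigma2"] - state["sigma2"]) < 1e-13:
                state = new
                break
            state = new
        taus = np.concatenate([[0.0], np.geomspace(1e-3, 1e3, 1200)])[:, None]
        s2s = np.geomspace(1e-3, 1e2, 1200)[None, :]
        q = design.q
        p2 = np.sum((design.values.T @ d) ** 2)
        t2 = d @ d
        ll = -0.5 * (
            d.size * np.log(s2s) + q * np.log1p(taus) + (p2 / (1 + taus) + t2 - p2) / s2s
        )
        grid_best = ll.max()
        achieved = marginal_loglik(d, design, state["tau"], state["sigma2"])
        assert achieved >= grid_best - 1e-6 * abs(grid_best)

    def test_iteration_order_insensitive(self):
        design = build_two_group(4, 4, normalize=True)
        rng = np.random.default_rng(42)
        for _ in range(20):
            d = rng.normal(size=8) + design.values @ rng.normal(scale=2.0, size=2)
            a = {"tau": 0.01, "sigma2": 5.0}
            b = {"tau": 30.0, "sigma2": 0.1}
            for _ in range(3000):
                a = gauss_seidel_update(d, design, a)
                b = gauss_seidel_update(d, design, b)
            assert a["tau"] == pytest.approx(b["tau"], rel=1e-4, abs=1e-8)
            assert a["sigma2"] == pytest.approx(b["sigma2"], rel=1e-4)


class TestFitModel:
    def test_noise_free_signal_recovered(self, two_group_norm):
        rng = np.random.default_rng(0)
        x = two_group_norm.original
        B = np.zeros((2, 256))
        B[0] = 5.0
        B[1, 60:120] = 1.5
        Y = x @ B + rng.normal(scale=1e-6, size=(6, 256))
        fit = fit_model(Y, two_group_norm, smoothing="common")
        means, _ = back_transform(fit)
        assert np.max(np.abs(means - B)) < 0.05

    def test_pure_noise_median_tau_zero(self, two_group_norm):
        # the local positive-part estimator truncates at 0 for most null
        # locations: ||X''^T D||^2 / sigma2 ~ chi^2_2, P(chi^2_2 <= 2) > 1/2
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(6, 2048))
        fit = fit_model(Y, two_group_norm, smoothing="common", pool="none")
        assert np.median(fit.tau) == pytest.approx(0.0)

    def test_pure_noise_pooled_posteriors_are_conservative(self, two_group_norm):
        # with scale-pooled hyperparameters almost no null probe reaches
        # P(effect > 0.2) > 0.95
        rng = np.random.default_rng(8)
        Y = rng.normal(scale=0.3, size=(6, 1024))
        fit = fit_model(Y, two_group_norm, smoothing="common")
        mean, var = effect_combination(fit, np.array([0.0, 2.0]))
        sd = np.sqrt(var)
        from scipy.stats import norm

        with np.errstate(divide="ignore"):
            p_above = np.where(sd > 0, 1.0 - norm.cdf((0.2 - mean) / sd), (mean > 0.2) * 1.0)
        assert np.mean(p_above > 0.95) < 0.01

    def test_zero_tau_means_full_shrinkage(self, two_group_norm):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(6, 64))
        fit = fit_model(Y, two_group_norm, smoothing="common")
        zero = fit.tau == 0.0
        assert zero.any()
        np.testing.assert_array_equal(fit.posterior_mean[:, zero], 0.0)

    @pytest.mark.parametrize("smoothing", ["common", "per_effect"])
    def test_shrinkage_never_exceeds_ols(self, smoothing, two_group_norm):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(6, 128)) + 0.3 * rng.normal(size=(6, 1))
        fit = fit_model(Y, two_group_norm, smoothing=smoothing)
        assert np.all(np.abs(fit.posterior_mean) <= np.abs(fit.b) + 1e-12)
        assert np.all(fit.posterior_var >= 0)
        assert np.all(fit.sigma2 > 0)

    def test_common_smoothing_requires_normalized_design(self):
        with pytest.raises(ConfigurationError):
            fit_model(np.zeros((4, 8)), build_two_group(2, 2), smoothing="common")

    def test_non_finite_data_rejected(self, two_group_norm):
        Y = np.zeros((6, 16))
        Y[0, 0] = np.nan
        with pytest.raises(DataError):
            fit_model(Y, two_group_norm)


class TestBackTransform:
    def test_no_shrinkage_equals_probewise_ols(self, two_group_norm):
        # orthogonal W makes wavelet-domain OLS identical to data-domain OLS
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(6, 16))
        fit = fit_model(Y, two_group_norm, smoothing="none")
        means, _ = back_transform(fit)
        ols = np.linalg.lstsq(two_group_norm.original, Y, rcond=None)[0]
        assert np.max(np.abs(means - ols)) < 1e-8

    def test_zero_data_zero_tracks(self, two_group_norm):
        fit = fit_model(np.zeros((6, 32)), two_group_norm, smoothing="common")
        means, variances = back_transform(fit)
        np.testing.assert_allclose(means, 0.0, atol=1e-12)
        assert np.all(variances >= 0)

    def test_qr_back_transform_equals_direct_ols(self):
        rng = np.random.default_rng(5)
        x = np.column_stack([np.ones(8), rng.integers(0, 2, size=(8, 2)).astype(float)])
        x[:, 2] += 0.5 * x[:, 1]  # deliberately non-orthogonal
        Y = rng.normal(size=(8, 32))
        fit = fit_model(Y, orthogonalize(x), smoothing="none")
        means, _ = back_transform(fit)
        ols = np.linalg.lstsq(x, Y, rcond=None)[0]
        assert np.max(np.abs(means - ols)) < 1e-8


def test_two_group_parameter_recovery():
    """Boxcar difference of 1.0 log2 over 128/1024 probes, sigma 0.3, 3+3 arrays:
    the mean fitted differential effect inside the region lands in [0.8, 1.1],
    outside stays near zero (20 seeded replicates)."""
    inside, outside = [], []
    for rep in range(20):
        spec = SimulationSpec(
            design=DesignSpec(kind="two_group", labels=["c1"] * 3 + ["c2"] * 3),
            T=1024,
            effect_regions=[EffectRegion(448, 576, "group_diff", 1.0)],
            noise_sd=0.3,
            seed=1000 + rep,
        )
        expr, _, truth = simulate(spec)
        fit = fit_model(expr, truth.design, smoothing="common")
        f = np.array([0.0, 2.0])  # difference of the two conditions under +/-1 coding
        mean, _ = effect_combination(fit, f)
        inside.append(mean[448:576].mean())
        outside.append(np.abs(np.concatenate([mean[:400], mean[624:]])).mean())
    assert 0.8 <= np.mean(inside) <= 1.1
    assert np.mean(outside) < 0.1


def test_fit_archive_round_trip(tmp_path, two_group_norm):
    rng = np.random.default_rng(6)
    Y = rng.normal(size=(6, 100))
    fit = fit_model(Y, two_group_norm, smoothing="common")
    save_fit(fit, tmp_path / "arch")
    loaded = load_fit(tmp_path / "arch")
    np.testing.assert_allclose(loaded.posterior_mean, fit.posterior_mean, atol=1e-12)
    np.testing.assert_allclose(loaded.sigma2, fit.sigma2, atol=1e-12)
    np.testing.assert_allclose(loaded.design.values, fit.design.values, atol=1e-12)
    m0, v0 = effect_combination(fit, np.array([0.0, 2.0]))
    m1, v1 = effect_combination(loaded, np.array([0.0, 2.0]))
    np.testing.assert_array_equal(m0, m1)
    np.testing.assert_array_equal(v0, v1)
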