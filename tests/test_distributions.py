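import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st
from scipy import integrate, stats

from vitalcentiles.distributions import (
    BCPE,
    BCT,
    CentilePoint,
    DomainError,
    FamilyParams,
    TailTruncationError,
    boxcox_z,
    cdf,
    fit_params_to_centiles,
    pdf,
    quantile,
    sample,
    zscore,
)

PARAM_GRID = [
    FamilyParams(BCPE, 100.0, 0.1, 1.0, 2.0),
    FamilyParams(BCPE, 140.0, 0.12, 0.5, 2.5),
    FamilyParams(BCPE, 120.0, 0.18, -0.8, 1.5),
    FamilyParams(BCPE, 50.0, 0.05, 0.0, 3.0),
    FamilyParams(BCT, 30.0, 0.2, 0.0, 10.0),
    FamilyParams(BCT, 30.0, 0.2, 1.0, 5.0),
    FamilyParams(BCT, 3.2, 0.06, -2.0, 12.0),
]


class TestParamsValidation:
    def test_rejects_nonpositive_mu_sigma_tau(self):
        with pytest.raises(DomainError):
            FamilyParams(BCPE, -1.0, 0.1, 1.0, 2.0)
        with pytest.raises(DomainError):
            FamilyParams(BCPE, 100.0, 0.0, 1.0, 2.0)
        with pytest.raises(DomainError):
            FamilyParams(BCT, 100.0, 0.1, 1.0, -3.0)

    def test_rejects_unknown_family(self):
        with pytest.raises(DomainError):
            FamilyParams("LMS", 100.0, 0.1, 1.0, 2.0)

    def test_centile_point_domain(self):
        with pytest.raises(DomainError):
            CentilePoint(0.0, 50.0)
        with pytest.raises(DomainError):
            CentilePoint(50.0, -1.0)


class TestBoxcoxZ:
    def test_location_maps_to_zero(self, normal_params):
        assert boxcox_z(100.0, normal_params) == pytest.approx(0.0, abs=1e-14)

    def test_linear_branch(self, normal_params):
        # ((120/100) - 1) / (1 * 0.1)
        assert boxcox_z(120.0, normal_params) == pytest.approx(2.0, rel=1e-12)

    def test_log_branch(self):
        p = FamilyParams(BCPE, 100.0, 0.1, 0.0, 2.0)
        assert boxcox_z(100.0 * np.exp(0.3), p) == pytest.approx(3.0, rel=1e-12)

    def test_rejects_nonpositive_y(self, normal_params):
        with pytest.raises(DomainError):
            boxcox_z(0.0, normal_params)
        with pytest.raises(DomainError):
            boxcox_z(-5.0, normal_params)

    @pytest.mark.parametrize("params", PARAM_GRID)
    def test_strictly_increasing(self, params):
        y = np.linspace(0.3 * params.mu, 3.0 * params.mu, 100)
        z = boxcox_z(y, params)
        assert np.all(np.diff(z) > 0)


class TestQuantile:
    def test_median_equals_mu(self):
        for params in PARAM_GRID:
            assert quantile(params, 50.0) == pytest.approx(params.mu, rel=1e-12)

    def test_normal_reduction(self, normal_params):
        # nu=1, tau=2 BCPE is exactly Normal(mu, mu*sigma)
        expect = 100.0 * (1.0 + 0.1 * stats.norm.ppf(0.975))
        got = quantile(normal_params, 97.5)
        assert got == pytest.approx(expect, abs=1e-9)
        assert got == pytest.approx(119.6, abs=5e-4)

    def test_bct_log_branch_closed_form(self, bct_params):
        expect = 30.0 * np.exp(0.2 * stats.t(10).ppf(0.75))
        assert quantile(bct_params, 75.0) == pytest.approx(expect, rel=1e-12)

    def test_rejects_out_of_range_p(self, normal_params):
        for p in (0.0, 100.0, -1.0, 101.0):
            with pytest.raises(DomainError):
                quantile(normal_params, p)

    def test_tail_truncation_breach_reported(self):
        params = FamilyParams(BCPE, 100.0, 0.5, 2.0, 2.0)
        with pytest.raises(TailTruncationError) as err:
            quantile(params, 0.01)
        assert err.value.z_breach == pytest.approx(-1.0 / (0.5 * 2.0))

    @pytest.mark.parametrize("params", PARAM_GRID)
    def test_strictly_increasing_in_p(self, params):
        p = np.linspace(1.0, 99.0, 50)
        q = quantile(params, p)
        assert np.all(np.diff(q) > 0)

    def test_bct_large_tau_matches_bcpe_tau2(self):
        # BCT -> Box-Cox normal as tau -> inf; BCPE(tau=2) is Box-Cox normal
        for mu, sigma, nu in [(100.0, 0.1, 0.5), (30.0, 0.2, -1.0)]:
            a = FamilyParams(BCT, mu, sigma, nu, 1e6)
            b = FamilyParams(BCPE, mu, sigma, nu, 2.0)
            p = np.array([1.0, 5.0, 25.0, 50.0, 75.0, 95.0, 99.0])
            np.testing.assert_allclose(quantile(a, p), quantile(b, p), rtol=1e-4)


class TestCdf:
    @pytest.mark.parametrize("params", PARAM_GRID)
    def test_round_trip(self, params):
        for p in (0.1, 1.0, 2.5, 10.0, 25.0, 50.0, 75.0, 90.0, 97.5,
                  99.0, 99.9):
            try:
                y = quantile(params, p)
            except TailTruncationError:
                continue  # documented breach of the y > 0 truncation point
            assert cdf(params, y) == pytest.approx(p / 100.0, abs=1e-9)

    def test_symmetric_kernel_at_location(self, normal_params):
        assert cdf(normal_params, 100.0) == pytest.approx(0.5, abs=1e-12)

    def test_bct_round_trip_99(self):
        params = FamilyParams(BCT, 30.0, 0.2, 1.0, 5.0)
        assert cdf(params, quantile(params, 99.0)) == pytest.approx(0.99,
                                                                    abs=1e-9)


class TestPdf:
    def test_normal_case_density(self, normal_params):
        # Normal(100, 10) density at its mean: 1 / (10 sqrt(2 pi))
        expect = 1.0 / (10.0 * np.sqrt(2.0 * np.pi))
        assert pdf(normal_params, 100.0) == pytest.approx(expect, rel=1e-9)
        assert expect == pytest.approx(0.0398942, abs=5e-8)

    @pytest.mark.parametrize("params", PARAM_GRID[:5])
    def test_integrates_to_one_renormalized(self, params):
        total, _ = integrate.quad(
            lambda y: pdf(params, y, renormalize=True),
            1e-6, params.mu * 15.0, limit=200)
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_nonnegative(self, normal_params):
        y = np.linspace(1.0, 300.0, 200)
        assert np.all(pdf(normal_params, y) >= 0)


class TestZscore:
    def test_matches_normal_deviate(self, normal_params):
        y = quantile(normal_params, 100.0 * stats.norm.cdf(2.0))
        assert zscore(normal_params, y) == pytest.approx(2.0, abs=1e-6)

    def test_zero_at_median(self):
        for params in PARAM_GRID:
            assert zscore(params, params.mu) == pytest.approx(0.0, abs=1e-9)

    def test_monotone(self, bct_params):
        y = np.linspace(10.0, 90.0, 50)
        z = zscore(bct_params, y)
        assert np.all(np.diff(z) > 0)

    def test_extreme_tail_clamped_with_warning(self):
        params = FamilyParams(BCPE, 30.0, 0.05, 0.0, 2.0)
        with pytest.warns(RuntimeWarning):
            z = zscore(params, 30.0 * np.exp(0.05 * 50.0))  # 50-SD deviate
        assert z == 8.0


class TestSample:
    def test_reproducible(self, normal_params):
        a = sample(normal_params, 1000, seed=7)
        b = sample(normal_params, 1000, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_median_converges(self, normal_params):
        # binomial CI for the sample median at n = 1e5 is well within 0.2
        y = sample(normal_params, 100_000, seed=1)
        assert np.median(y) == pytest.approx(100.0, abs=0.2)

    def test_upper_tail_quantile(self, normal_params):
        n = 100_000
        y = sample(normal_params, n, seed=2)
        q95 = quantile(normal_params, 95.0)
        # order-statistic SE of the empirical 95th percentile
        dens = pdf(normal_params, q95)
        se = np.sqrt(0.95 * 0.05 / n) / dens
        assert abs(np.percentile(y, 95.0) - q95) < 3.0 * se

    @pytest.mark.parametrize("params", PARAM_GRID[:4])
    def test_ks_distance(self, params):
        n = 100_000
        y = sample(params, n, seed=3)
        d = stats.kstest(y, lambda v: cdf(params, v)).statistic
        assert d < 1.63 / np.sqrt(n)   # 1% significance

    def test_rejects_zero_n(self, normal_params):
        with pytest.raises(DomainError):
            sample(normal_params, 0, seed=1)


class TestFitParamsToCentiles:
    def test_round_trip_four_points(self):
        truth = FamilyParams(BCPE, 140.0, 0.12, 0.5, 2.5)
        p = np.array([5.0, 25.0, 75.0, 95.0])
        pts = [(pi, quantile(truth, pi)) for pi in p]
        fit = fit_params_to_centiles(pts, family=BCPE)
        assert fit.mu == pytest.approx(truth.mu, rel=1e-6)
        assert fit.sigma == pytest.approx(truth.sigma, rel=1e-6)
        assert fit.nu == pytest.approx(truth.nu, abs=1e-6)
        assert fit.tau == pytest.approx(truth.tau, rel=1e-6)

    def test_normal_quantiles_recover_normal_case(self):
        p = np.array([5.0, 25.0, 75.0, 95.0])
        pts = [(pi, 100.0 + 10.0 * stats.norm.ppf(pi / 100.0)) for pi in p]
        fit = fit_params_to_centiles(pts, family=BCPE)
        assert fit.mu == pytest.approx(100.0, rel=1e-4)
        assert fit.sigma == pytest.approx(0.1, rel=1e-3)
        assert fit.nu == pytest.approx(1.0, abs=1e-3)
        assert fit.tau == pytest.approx(2.0, rel=1e-3)

    def test_overdetermined_identity(self):
        truth = FamilyParams(BCT, 30.0, 0.2, -0.5, 8.0)
        p = np.array([1.0, 5.0, 10.0, 25.0, 50.0, 75.0, 90.0, 95.0, 99.0])
        pts = [(pi, quantile(truth, pi)) for pi in p]
        fit = fit_params_to_centiles(pts, family=BCT)
        np.testing.assert_allclose(quantile(fit, p), quantile(truth, p),
                                   rtol=1e-6)

    def test_log_scale_round_trip(self):
        truth = FamilyParams(BCT, np.log(25.0), 0.06, -1.5, 10.0)
        p = np.array([5.0, 25.0, 75.0, 95.0])
        pts = [(pi, np.exp(quantile(truth, pi))) for pi in p]
        fit = fit_params_to_centiles(pts, family=BCT, log_scale=True)
        assert fit.mu == pytest.approx(truth.mu, rel=1e-5)
        assert np.exp(quantile(fit, 50.0)) == pytest.approx(25.0, rel=1e-5)

    def test_published_hr_row_predicts_held_out_median(self, hr_table):
        row = hr_table[hr_table["description"] == "2 to <3 years"].iloc[0]
        levels = [1, 2.5, 5, 10, 25, 75, 90, 95, 97.5, 99]   # C50 held out
        pts = [(p, float(row[f"c{p:g}".lower()])) for p in levels]
        fit = fit_params_to_centiles(pts, family=BCPE)
        assert quantile(fit, 50.0) == pytest.approx(126.0, abs=1.0)

    def test_rejects_decreasing_values(self):
        with pytest.raises(DomainError):
            fit_params_to_centiles(
                [(5.0, 110.0), (25.0, 100.0), (75.0, 120.0), (95.0, 130.0)])

    def test_rejects_too_few_points(self):
        with pytest.raises(DomainError):
            fit_params_to_centiles([(25.0, 90.0), (50.0, 100.0),
                                    (75.0, 110.0)])


@settings(max_examples=40, deadline=None)
@given(
    mu=st.floats(20.0, 200.0),
    sigma=st.floats(0.02, 0.3),
    nu=st.floats(-2.0, 2.0),
    tau=st.floats(1.2, 6.0),
    p=st.floats(0.5, 99.5),
    family=st.sampled_from([BCPE, BCT]),
)
def test_property_cdf_quantile_round_trip(mu, sigma, nu, tau, p, family):
    params = FamilyParams(family, mu, sigma, nu, tau)
    try:
        y = quantile(params, p)
    except TailTruncationError:
        assume(False)  # beyond the y > 0 truncation point: defined behavior
    assert cdf(params, y) == pytest.approx(p / 100.0, abs=1e-9)


@settings(max_examples=25, deadline=None)
@given(
    mu=st.floats(50.0, 150.0),
    sigma=st.floats(0.05, 0.2),
    nu=st.floats(-1.5, 1.5),
    y_factor=st.floats(0.7, 1.4),
)
def test_property_zscore_sign(mu, sigma, nu, y_factor):
    # values above the median have positive z-scores and vice versa
    params = FamilyParams(BCPE, mu, sigma, nu, 2.0)
    z = zscore(params, mu * y_factor)
    assert np.sign(z) == np.sign(y_factor - 1.0) or abs(z) < 1e-9
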