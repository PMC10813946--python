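"""MLE, linear Bayes estimation, bootstrap dispersion, and MSE evaluation."""

import warnings

import numpy as np
import pytest
from scipy import optimize

import cohenpois as cp
from cohenpois import (
    DesignMatrix,
    EstimationError,
    FrequencyTable,
    ModelParams,
    PriorSpec,
    SampleSummary,
    StatisticT,
    bootstrap_w,
    evaluate,
    linear_bayes,
    loglik,
    mle,
    msem_ordering_check,
    statistic_and_design,
    summarize,
)
from conftest import draw_joint_model


def numeric_mle(table: FrequencyTable) -> np.ndarray:
    """Independent oracle: direct maximisation of the log-likelihood."""
    grid = [
        (lam, phi)
        for lam in np.linspace(0.05, 6.0, 40)
        for phi in np.linspace(0.01, 0.99, 25)
    ]
    start = max(grid, key=lambda p: loglik(table, p))
    res = optimize.minimize(
        lambda p: -loglik(table, p),
        start,
        method="Nelder-Mead",
        options=dict(xatol=1e-10, fatol=1e-12, maxiter=10_000),
    )
    return res.x


class TestSummarize:
    def test_horsekick_altered_printed_summary(self, horsekick_altered):
        s = summarize(horsekick_altered)
        assert (s.n, s.n0, s.n1) == (200, 129, 45)
        assert s.sample_mean == pytest.approx(102 / 200, abs=0)

    def test_traffic_altered_summary(self, traffic_altered):
        s = summarize(traffic_altered)
        assert (s.n, s.n0, s.n1) == (45, 18, 2)
        assert s.sample_mean == pytest.approx(83 / 45, abs=1e-15)

    def test_single_zero(self):
        s = summarize(FrequencyTable.from_pairs({0: 1}))
        assert (s.n, s.n0, s.n1, s.sample_mean) == (1, 1, 0, 0.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            FrequencyTable.from_pairs({})


class TestMle:
    def test_horsekick_worked_example(self, horsekick_altered):
        est = mle(summarize(horsekick_altered))
        assert est.lambda_hat == pytest.approx(0.61695, abs=5e-6)
        assert est.phi_hat == pytest.approx(0.322187, abs=5e-6)
        assert est.warnings == []

    def test_traffic_worked_example(self, traffic_altered):
        est = mle(summarize(traffic_altered))
        assert est.lambda_hat == pytest.approx(2.101127, abs=5e-7)
        assert est.phi_hat == pytest.approx(0.8524065, abs=5e-7)

    def test_small_sample_closed_form(self):
        # {0:5, 1:3, 2:2}: lam solves lam^2 - 0.2 lam - 0.4 = 0
        est = mle(summarize(FrequencyTable.from_pairs({0: 5, 1: 3, 2: 2})))
        assert est.lambda_hat == pytest.approx((0.2 + np.sqrt(1.64)) / 2, abs=1e-12)
        assert est.phi_hat == pytest.approx(0.11845710274067045, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_solves_score_quadratic(self, seed):
        rng = np.random.default_rng(seed)
        params = ModelParams(rng.uniform(0.3, 3.0), rng.uniform(0.1, 0.9))
        s = summarize(FrequencyTable.from_observations(cp.sample(200, params, rng)))
        lam = mle(s).lambda_hat
        b = s.sample_mean - 1 + s.n0 / s.n
        c = s.sample_mean - s.n1 / s.n
        assert lam**2 - b * lam - c == pytest.approx(0.0, abs=1e-10)

    def test_matches_numeric_likelihood_maximization(self):
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 50:
            params = ModelParams(rng.uniform(0.3, 2.5), rng.uniform(0.1, 0.9))
            table = FrequencyTable.from_observations(
                cp.sample(int(rng.integers(30, 80)), params, rng)
            )
            try:
                est = mle(summarize(table))
            except EstimationError:
                continue
            if not 0.0 <= est.phi_hat <= 1.0:
                continue  # boundary solutions: grid oracle searches the interior
            oracle = numeric_mle(table)
            np.testing.assert_allclose(est.theta_hat, oracle, atol=1e-4)
            checked += 1

    def test_all_zero_sample_degenerate(self):
        with pytest.raises(EstimationError):
            mle(summarize(FrequencyTable.from_pairs({0: 10})))

    def test_no_zeros_or_ones_keeps_lambda(self):
        with pytest.raises(EstimationError) as err:
            mle(summarize(FrequencyTable.from_pairs({2: 5, 3: 5})))
        assert err.value.lambda_hat is not None and err.value.lambda_hat > 0

    def test_one_inflated_sample_warns_and_clamps(self):
        # more ones than the model can explain drives phi negative
        s = summarize(FrequencyTable.from_pairs({0: 1, 1: 8, 2: 1}))
        raw = mle(s)
        assert raw.phi_hat < 0.0
        assert any("outside" in w for w in raw.warnings)
        clamped = mle(s, clamp=True)
        assert clamped.phi_hat == 0.0
        assert any("clamped" in w for w in clamped.warnings)


class TestLoglik:
    def test_score_vanishes_at_mle(self, horsekick_altered):
        est = mle(summarize(horsekick_altered))
        lam, phi = est.theta_hat
        h = 1e-6
        d_lam = (
            loglik(horsekick_altered, (lam + h, phi))
            - loglik(horsekick_altered, (lam - h, phi))
        ) / (2 * h)
        d_phi = (
            loglik(horsekick_altered, (lam, phi + h))
            - loglik(horsekick_altered, (lam, phi - h))
        ) / (2 * h)
        assert abs(d_lam) < 1e-5 * 200 and abs(d_phi) < 1e-5 * 200

    def test_phi_free_without_zeros_or_ones(self):
        table = FrequencyTable.from_pairs({2: 4, 3: 2})
        assert loglik(table, (1.3, 0.2)) == pytest.approx(loglik(table, (1.3, 0.8)), abs=0)

    def test_increases_toward_mle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            params = ModelParams(rng.uniform(0.4, 2.0), rng.uniform(0.2, 0.8))
            table = FrequencyTable.from_observations(cp.sample(100, params, rng))
            est = mle(summarize(table))
            if not 0 < est.phi_hat < 1:
                continue
            start = est.theta_hat + np.array([0.3, -0.1])
            lls = [
                loglik(table, start + frac * (est.theta_hat - start))
                for frac in (0.0, 0.5, 1.0)
            ]
            assert lls[0] <= lls[1] <= lls[2] + 1e-12

    def test_invalid_params_give_minus_inf(self):
        table = FrequencyTable.from_pairs({0: 3, 1: 2})
        assert loglik(table, (-1.0, 0.5)) == -np.inf
        assert loglik(table, (1.0, 1.0)) == -np.inf  # ones observed, phi = 1

    def test_constant_included_for_table_only(self, horsekick_altered):
        s = summarize(horsekick_altered)
        params = (0.6, 0.3)
        from scipy.special import gammaln

        const = float(
            np.dot(gammaln(horsekick_altered.values + 1.0), horsekick_altered.counts)
        )
        assert loglik(horsekick_altered, params) == pytest.approx(
            loglik(s, params) - const, abs=1e-9
        )


class TestStatisticAndDesign:
    def test_reproduces_mle_identity(self, horsekick_altered, traffic_altered):
        for table in (horsekick_altered, traffic_altered):
            s = summarize(table)
            t, a = statistic_and_design(s)
            np.testing.assert_allclose(
                a.matrix @ t.asarray(), mle(s).theta_hat, rtol=0, atol=1e-14
            )

    def test_horsekick_components(self, horsekick_altered):
        t, a = statistic_and_design(summarize(horsekick_altered))
        assert t.t1 == pytest.approx(1.2339, abs=5e-5)
        assert t.t2 == pytest.approx(56.0605, abs=5e-4)
        np.testing.assert_allclose(np.diag(a.matrix), [0.5, 1 / 174])

    def test_traffic_design(self, traffic_altered):
        _, a = statistic_and_design(summarize(traffic_altered))
        np.testing.assert_allclose(np.diag(a.matrix), [0.5, 1 / 20])

    def test_singular_design_rejected(self):
        with pytest.raises((EstimationError, ValueError)):
            statistic_and_design(summarize(FrequencyTable.from_pairs({2: 5, 3: 5})))


class TestBootstrapW:
    def test_deterministic(self, horsekick_altered):
        w1 = bootstrap_w(horsekick_altered, n_boot=200, seed=9)
        w2 = bootstrap_w(horsekick_altered, n_boot=200, seed=9)
        np.testing.assert_array_equal(w1, w2)
        assert w1.shape == (2, 2) and w1[0, 1] == 0.0 and w1[1, 0] == 0.0
        assert np.all(np.diag(w1) >= 0)

    def test_degenerate_single_value_table(self):
        # every resample of {2: 50} lacks zeros and ones: statistic undefined
        with pytest.raises(EstimationError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                bootstrap_w(FrequencyTable.from_pairs({2: 50}), n_boot=50, seed=0)

    def test_variance_shrinks_with_sample_size(self):
        params = ModelParams(0.7, 0.7)
        rng = np.random.default_rng(31)
        w_small = bootstrap_w(
            FrequencyTable.from_observations(cp.sample(200, params, rng)),
            n_boot=800,
            seed=rng,
        )
        w_large = bootstrap_w(
            FrequencyTable.from_observations(cp.sample(800, params, rng)),
            n_boot=800,
            seed=rng,
        )
        # t1 = 2 lam_hat is sqrt(N)-consistent: 4x the data, ~4x less variance
        ratio = w_small[0, 0] / w_large[0, 0]
        assert 2.0 < ratio < 8.0

    def test_too_few_resamples_rejected(self, horsekick_altered):
        with pytest.raises(ValueError):
            bootstrap_w(horsekick_altered, n_boot=1, seed=0)


class TestLinearBayes:
    @pytest.fixture()
    def components(self, horsekick_altered):
        s = summarize(horsekick_altered)
        t, a = statistic_and_design(s)
        w = bootstrap_w(horsekick_altered, n_boot=500, seed=17)
        return s, t, a, w

    def test_prior_washout_recovers_mle(self, components):
        s, t, a, w = components
        prior = PriorSpec(mean=[5.0, 0.9], cov=1e12 * np.eye(2))
        est, _ = linear_bayes(t, a, w, prior)
        np.testing.assert_allclose(est.theta_hat, mle(s).theta_hat, atol=1e-6)

    def test_degenerate_prior_full_shrinkage(self, components):
        _, t, a, w = components
        prior = PriorSpec(mean=[0.61, 0.308], cov=1e-12 * np.eye(2))
        est, _ = linear_bayes(t, a, w, prior)
        np.testing.assert_allclose(est.theta_hat, [0.61, 0.308], atol=1e-6)

    def test_zero_w_is_exactly_mle(self, components):
        s, t, a, _ = components
        prior = PriorSpec(mean=[0.61, 0.308], cov=np.diag([0.01, 0.01]))
        est, comps = linear_bayes(t, a, np.zeros((2, 2)), prior)
        np.testing.assert_allclose(est.theta_hat, mle(s).theta_hat, rtol=0, atol=1e-15)
        np.testing.assert_allclose(comps.b_mat, a.matrix, atol=1e-15)
        np.testing.assert_allclose(comps.b_vec, 0.0, atol=1e-15)

    def test_both_algebraic_forms_agree(self, components):
        _, t, a, w = components
        prior = PriorSpec(mean=[0.61, 0.308], cov=np.diag([0.01, 0.04]))
        est, comps = linear_bayes(t, a, w, prior)
        # (A - A W M) T + A W M A^-1 E(theta)
        awm = a.matrix @ w @ comps.m
        alt = (a.matrix - awm) @ t.asarray() + awm @ a.inverse @ prior.mean
        np.testing.assert_allclose(est.theta_hat, alt, atol=1e-12)

    def test_shrinks_between_mle_and_prior_mean(self, components):
        s, t, a, w = components
        prior = PriorSpec(mean=[0.61, 0.308], cov=np.diag([0.01, 0.01]))
        est, _ = linear_bayes(t, a, w, prior)
        theta_mle = mle(s).theta_hat
        for k in range(2):
            lo, hi = sorted([theta_mle[k], prior.mean[k]])
            assert lo - 1e-12 <= est.theta_hat[k] <= hi + 1e-12

    def test_singular_inner_matrix_named(self, components):
        _, t, a, _ = components
        prior = PriorSpec(mean=[0.6, 0.3], cov=np.zeros((2, 2)))
        with pytest.raises(EstimationError, match="singular"):
            linear_bayes(t, a, np.zeros((2, 2)), prior)

    def test_unbiased_under_joint_model(self):
        # theta drawn from a two-point prior with mean (0.7, 0.7) and
        # covariance diag(0.01, 0.01); data generated given theta.
        rng = np.random.default_rng(123)
        n_reps, n = 20_000, 400
        lam, phi, n0, n1, xbar = draw_joint_model(rng, n_reps, n)
        from cohenpois.estimators import _mle_arrays

        lam_hat, phi_hat = _mle_arrays(np.full(n_reps, n), n0, n1, xbar)
        ok = np.isfinite(lam_hat) & np.isfinite(phi_hat)
        pilot = FrequencyTable.from_observations(cp.sample(n, ModelParams(0.7, 0.7), rng))
        w = bootstrap_w(pilot, n_boot=1000, seed=rng)
        # componentwise shrinkage form of B T + b for diagonal A, W, Cov
        k1 = w[0, 0] / (w[0, 0] + 4 * 0.01)
        n01 = (n0 + n1)[ok].astype(float)
        k2 = w[1, 1] / (w[1, 1] + n01**2 * 0.01)
        lb_lam = (1 - k1) * lam_hat[ok] + k1 * 0.7
        lb_phi = (1 - k2) * phi_hat[ok] + k2 * 0.7
        for v in (lb_lam, lb_phi):
            se = v.std(ddof=1) / np.sqrt(v.size)
            assert abs(v.mean() - 0.7) < 4 * se


class TestEvaluate:
    def test_exact_estimate_zero_error(self):
        r = evaluate(np.array([0.7, 0.7]), [0.7, 0.7])
        assert r.mse_avg == 0.0 and r.mse_sum == 0.0
        np.testing.assert_array_equal(r.msem, np.zeros((2, 2)))

    def test_horsekick_printed_mse(self):
        r = evaluate(np.array([0.61695, 0.322187]), [0.610, 0.308])
        assert r.mse_avg == pytest.approx(0.0001247861, abs=1e-8)
        assert r.mse_sum == pytest.approx(2 * r.mse_avg, abs=0)

    def test_replicate_list_matches_brute_force(self):
        rng = np.random.default_rng(8)
        thetas = rng.normal([0.7, 0.5], 0.1, size=(40, 2))
        truth = np.array([0.7, 0.5])
        r = evaluate(thetas, truth)
        brute = sum(np.outer(t - truth, t - truth) for t in thetas) / len(thetas)
        np.testing.assert_allclose(r.msem, brute, atol=1e-15)
        assert r.mse_sum == pytest.approx(np.trace(brute), abs=1e-15)
        eig = np.linalg.eigvalsh(r.msem)
        assert np.all(eig >= -1e-12)


class TestMsemOrdering:
    def test_zero_w_zero_gap(self):
        a = DesignMatrix(n01=20)
        prior = PriorSpec(mean=[0.7, 0.7], cov=np.diag([0.01, 0.01]))
        _, comps = linear_bayes(StatisticT(1.4, 14.0), a, np.zeros((2, 2)), prior)
        assert msem_ordering_check(a, comps.w, comps.m) == pytest.approx(0.0, abs=1e-15)

    def test_gap_always_psd_over_random_configs(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            a = DesignMatrix(n01=int(rng.integers(1, 500)))
            w = np.diag(rng.uniform(0.0, 10.0, size=2))
            root = rng.normal(size=(2, 2))
            prior = PriorSpec(mean=rng.uniform(0, 2, size=2), cov=root @ root.T + 1e-8 * np.eye(2))
            t = StatisticT(*rng.uniform(0.1, 5.0, size=2))
            _, comps = linear_bayes(t, a, w, prior)
            assert msem_ordering_check(a, comps.w, comps.m) >= -1e-10

    def test_horsekick_instance(self, horsekick_altered):
        s = summarize(horsekick_altered)
        t, a = statistic_and_design(s)
        w = bootstrap_w(horsekick_altered, n_boot=400, seed=4)
        prior = PriorSpec(mean=[0.61, 0.308], cov=np.diag([0.02, 0.005]))
        _, comps = linear_bayes(t, a, w, prior)
        assert msem_ordering_check(a, comps.w, comps.m) >= -1e-10
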