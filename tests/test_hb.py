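"""Hierarchical Bayes sampler: determinism, recovery, shrinkage, fit stats.

Chains here are short (hundreds to low thousands of iterations) to keep the
suite fast; the corresponding tolerances are wider than production use and
the deeper simulation checks live in the acceptance tests.
"""

import numpy as np
import pandas as pd
import pytest

import opendce as od
from opendce.coding import CodedMatrix
from opendce.hb import _chain_loglik


@pytest.fixture(scope="module")
def small_hb_problem(request):
    """Moderate-signal synthetic study on the 3-attribute spec: 60
    respondents, 8 tasks."""
    spec = od.StudySpec(attributes=(
        od.AttributeSpec("color", ("red", "green", "blue")),
        od.AttributeSpec("size", ("small", "large")),
        od.AttributeSpec("shape", ("round", "square", "hex")),
    ), n_tasks=8)
    cm = CodedMatrix.from_spec(spec)
    rng = np.random.default_rng(10)
    theta = np.linspace(-1.0, 1.0, cm.n_params)[None, :]
    cov = 0.16 * np.eye(cm.n_params)
    truth = od.PopulationTruth(theta=theta, cov=cov)
    _, beta = od.generate_population(truth, 60, seed=11)
    design = od.generate_design(spec, n_versions=4, seed=12)
    dataset = od.simulate_choices(beta, design, seed=13)
    X, y = cm.respondent_tensors(dataset)
    return spec, cm, truth, beta, X, y


def _fit(X, y, seed=1, **kw):
    defaults = dict(n_burn=800, n_draws=600, thin=3, seed=seed)
    defaults.update(kw)
    return od.HierarchicalBayesLogit(**defaults).fit(X, y)


class TestSamplerMechanics:
    def test_same_seed_bit_identical_posteriors(self, small_hb_problem):
        _, _, _, _, X, y = small_hb_problem
        a = _fit(X, y, seed=5)
        b = _fit(X, y, seed=5)
        np.testing.assert_array_equal(a.posterior_.beta_draws,
                                      b.posterior_.beta_draws)
        np.testing.assert_array_equal(a.posterior_.theta_draws,
                                      b.posterior_.theta_draws)
        c = _fit(X, y, seed=6)
        assert not np.array_equal(a.posterior_.beta_draws,
                                  c.posterior_.beta_draws)

    def test_acceptance_rate_near_target(self, small_hb_problem):
        _, _, _, _, X, y = small_hb_problem
        est = _fit(X, y, seed=2, n_burn=1500, n_draws=800, target_accept=0.3)
        assert abs(est.accept_rate_ - 0.3) < 0.15

    def test_covariance_draws_symmetric_positive_definite(self, small_hb_problem):
        _, _, _, _, X, y = small_hb_problem
        est = _fit(X, y, seed=3, n_burn=300, n_draws=300)
        for D in est.posterior_.cov_draws[::20]:
            np.testing.assert_allclose(D, D.T, atol=1e-12)
            assert np.linalg.eigvalsh(D).min() > 0

    def test_draw_count_honors_thinning(self, small_hb_problem):
        _, _, _, _, X, y = small_hb_problem
        est = _fit(X, y, seed=4, n_burn=200, n_draws=300, thin=5)
        assert est.posterior_.n_draws == 60

    def test_rejects_single_respondent(self, small_hb_problem):
        _, _, _, _, X, y = small_hb_problem
        with pytest.raises(ValueError, match=">= 2 respondents"):
            _fit(X[:1], y[:1])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            od.HBConfig(n_burn=0)
        with pytest.raises(ValueError):
            od.HBConfig(target_accept=1.5)


class TestRecovery:
    def test_population_mean_recovered(self, small_hb_problem):
        """Posterior mean of the population-average utilities correlates
        strongly with the generating truth."""
        _, _, truth, _, X, y = small_hb_problem
        est = _fit(X, y, seed=7, n_burn=1500, n_draws=1000)
        r = np.corrcoef(est.population_mean_, truth.theta[0])[0, 1]
        assert r > 0.9

    def test_null_data_credible_intervals_cover_zero(self):
        """Respondents choosing uniformly at random: population-mean 95%
        credible intervals cover 0 for >= 90% of parameters (averaged over
        three replicates to tame the per-interval coin flips)."""
        spec, truth, _ = od.study_preset("india")
        design = od.generate_design(spec, n_versions=5, seed=2)
        cm = od.CodedMatrix.from_spec(spec)
        X = np.stack([cm.code_levels(design.task_array(v))
                      for v in design.versions] * 30)  # 150 respondents
        coverages = []
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            y_rand = rng.integers(2, size=X.shape[:2])
            est = _fit(X, y_rand, seed=8, n_burn=2000, n_draws=2000)
            # the population mean is the intercept row of Theta (covariates
            # are centered), so its credible interval comes from Theta draws
            means = est.posterior_.theta_draws[:, 0, :]
            lo = np.quantile(means, 0.025, axis=0)
            hi = np.quantile(means, 0.975, axis=0)
            coverages.append(((lo <= 0.0) & (0.0 <= hi)).mean())
        assert np.mean(coverages) >= 0.9

    def test_individual_utilities_shrink_toward_population(self, small_hb_problem):
        """Posterior-mean individual coefficients lie between the aggregate
        estimate and the respondent's own data for most coordinates, i.e.
        their spread is smaller than the true cross-respondent spread but
        they still track individual differences."""
        _, _, truth, beta_true, X, y = small_hb_problem
        est = _fit(X, y, seed=9, n_burn=1500, n_draws=1000)
        B = est.coef_
        # tracks individuals
        r = np.corrcoef(B.ravel(), beta_true.ravel())[0, 1]
        assert r > 0.6
        # shrinkage: per-coordinate SD across respondents no larger than truth
        frac_shrunk = (B.std(axis=0) <= beta_true.std(axis=0) + 0.05).mean()
        assert frac_shrunk >= 0.8

    def test_point_utilities_zero_sum_and_shape(self, small_hb_problem):
        spec, cm, _, _, X, y = small_hb_problem
        est = _fit(X, y, seed=1, n_burn=300, n_draws=200)
        pu = od.point_utilities(est.posterior_, cm)
        sums = pu.groupby(["respondent_id", "attribute"])["utility"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 0.0, atol=1e-9)
        n_levels_total = sum(a.n_levels for a in spec.design_attributes)
        assert len(pu) == X.shape[0] * n_levels_total


class TestFitStatistics:
    def test_null_posterior_gives_exact_null_rlh(self, small_hb_problem):
        """A zero-coefficient posterior on binary tasks gives RLH = 1/2 and
        percent certainty = 0 exactly."""
        _, cm, _, _, X, y = small_hb_problem
        null = od.HBPosterior(
            theta_draws=np.zeros((1, 1, cm.n_params)),
            cov_draws=np.eye(cm.n_params)[None],
            beta_draws=np.zeros((1, X.shape[0], cm.n_params)),
            accept_rate=1.0, loglik_trace=np.zeros(1))
        fs = od.fit_statistics(null, X, y)
        assert fs.rlh == pytest.approx(0.5, abs=1e-12)
        assert fs.percent_certainty == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_predictions_approach_unity(self, small_hb_problem):
        """Huge utilities whose argmax reproduces every observed choice drive
        RLH and percent certainty toward 1."""
        _, cm, _, _, X, _ = small_hb_problem
        N, t, a, p = X.shape
        rng = np.random.default_rng(0)
        B = 100.0 * rng.standard_normal((N, p))
        u = np.einsum("ntap,np->nta", X, B)
        y_det = u.argmax(axis=2)  # choices perfectly consistent with B
        post = od.HBPosterior(
            theta_draws=np.zeros((1, 1, p)), cov_draws=np.eye(p)[None],
            beta_draws=B[None], accept_rate=1.0, loglik_trace=np.zeros(1))
        fs = od.fit_statistics(post, X, y_det)
        assert fs.rlh > 0.99
        assert fs.percent_certainty > 0.95

    def test_loglik_oracle_brute_force(self):
        """Sampler-side log-likelihood matches explicit enumeration."""
        rng = np.random.default_rng(2)
        X = rng.standard_normal((3, 4, 2, 3))
        y = rng.integers(2, size=(3, 4))
        B = rng.standard_normal((3, 3))
        expected = np.zeros(3)
        for i in range(3):
            for t in range(4):
                probs = np.exp(X[i, t] @ B[i])
                probs = probs / probs.sum()
                expected[i] += np.log(probs[y[i, t]])
        np.testing.assert_allclose(_chain_loglik(B, X, y), expected, atol=1e-9)


def test_posterior_summary_table_shape(small_hb_problem):
    spec, cm, _, _, X, y = small_hb_problem
    est = _fit(X, y, seed=1, n_burn=200, n_draws=200)
    summary = est.posterior_.summary(cm)
    assert list(summary.columns) == ["attribute", "level", "B", "SD",
                                     "ci_low", "ci_high"]
    assert (summary["ci_low"] <= summary["ci_high"]).all()
    # per-attribute zero-sum of population utilities
    sums = summary.groupby("attribute")["B"].sum()
    np.testing.assert_allclose(sums, 0.0, atol=1e-9)
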