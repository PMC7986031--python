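"""Hierarchical Bayes estimation of individual-level choice utilities.

Model
-----
Respondent i's choices follow a multinomial logit with coefficient vector
beta_i on the effects-coded design columns.  Across respondents,

    beta_i ~ MVN(Theta' z_i, D),

where z_i = (1, covariates_i) and Theta is a (1 + n_covariates) x n_params
matrix, so the population mean of the utilities can shift with respondent
covariates (age, education, ever-use of a modern method).  Priors: Theta flat,
D inverse-Wishart with ``df = n_params + prior_df_add`` and scale
``prior_cov_scale * I`` — weakly informative defaults in line with common
choice-based-conjoint practice.

Sampling alternates (a) a conjugate matrix-normal update for Theta, (b) an
inverse-Wishart update for D, and (c) one random-walk Metropolis step per
respondent for beta_i, with the proposal shaped by the current Cholesky factor
of D.  The scalar proposal step size adapts toward ``target_accept`` every 100
iterations during burn-in only, so the post-burn-in chain satisfies detailed
balance.  All randomness flows through one seeded generator: a fixed seed
gives bit-identical draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .coding import CodedMatrix, expand_utilities

__all__ = ["HBConfig", "HBPosterior", "FitStatistics", "HierarchicalBayesLogit",
           "fit_hb", "point_utilities", "fit_statistics"]


@dataclass
class HBConfig:
    """MCMC settings for the hierarchical sampler.

    Defaults (10k burn-in, 10k sampling iterations thinned by 10) suit
    production runs; simulation studies in the test suite use shorter chains.
    """

    n_burn: int = 10_000
    n_draws: int = 10_000
    thin: int = 10
    proposal_scale: float = 0.3
    target_accept: float = 0.3
    prior_cov_scale: float = 1.0
    prior_df_add: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_burn, self.n_draws, self.thin) < 1:
            raise ValueError("n_burn, n_draws and thin must all be >= 1")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must lie in (0, 1)")


@dataclass
class HBPosterior:
    """Retained MCMC draws and chain diagnostics.

    ``theta_draws`` has shape (n_ret, 1 + n_covariates, n_params);
    ``cov_draws`` (n_ret, n_params, n_params); ``beta_draws`` (n_ret,
    n_respondents, n_params).  ``loglik_trace`` records the total choice
    log-likelihood at every iteration (burn-in included).
    """

    theta_draws: np.ndarray
    cov_draws: np.ndarray
    beta_draws: np.ndarray
    accept_rate: float
    loglik_trace: np.ndarray
    labels: list[str] = field(default_factory=list)
    respondent_ids: list = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.theta_draws.shape[0]

    def beta_point(self) -> np.ndarray:
        """Posterior-mean coefficient vector per respondent, (N, p)."""
        return self.beta_draws.mean(axis=0)

    def population_mean(self) -> np.ndarray:
        """Posterior mean of the across-respondent average coefficient
        vector, length p."""
        return self.beta_draws.mean(axis=(0, 1))

    def summary(self, cm: CodedMatrix) -> pd.DataFrame:
        """Population utility table: per expanded attribute level, the
        posterior mean B of the across-respondent average utility, the
        across-respondent SD, and a 95% credible interval for B."""
        n_ret = self.beta_draws.shape[0]
        means = np.stack([
            expand_utilities(self.beta_draws[d].mean(axis=0), cm)["utility"].to_numpy()
            for d in range(n_ret)
        ])  # (n_ret, n_rows)
        sds = np.stack([
            expand_utilities(self.beta_draws[d], cm)
            .filter(like="utility").to_numpy().std(axis=1, ddof=1)
            for d in range(n_ret)
        ])
        base = expand_utilities(self.population_mean(), cm)[["attribute", "level"]]
        base["B"] = means.mean(axis=0)
        base["SD"] = sds.mean(axis=0)
        base["ci_low"] = np.quantile(means, 0.025, axis=0)
        base["ci_high"] = np.quantile(means, 0.975, axis=0)
        return base


@dataclass
class FitStatistics:
    """Root likelihood and percent certainty of a fitted model.

    RLH is the geometric mean of the predicted probability of the observed
    choices (1/a for a null model); percent certainty is 1 - LL/LL0, the
    fractional log-likelihood improvement over random choice.
    """

    rlh: float
    percent_certainty: float


def _chain_loglik(B: np.ndarray, X: np.ndarray, chosen: np.ndarray) -> np.ndarray:
    """Per-respondent choice log-likelihood for coefficient matrix B (N, p)
    against X (N, t, a, p) and chosen (N, t)."""
    u = np.einsum("ntap,np->nta", X, B)
    lse = logsumexp(u, axis=-1)
    n, t = chosen.shape
    picked = np.take_along_axis(u, chosen[:, :, None], axis=2)[:, :, 0]
    return (picked - lse).sum(axis=1)


class HierarchicalBayesLogit(BaseEstimator):
    """Hierarchical Bayes multinomial logit, sklearn-style.

    Parameters mirror :class:`HBConfig`.  ``fit`` consumes the respondent-major
    tensors produced by :meth:`opendce.coding.CodedMatrix.respondent_tensors`.

    Attributes
    ----------
    posterior_ : HBPosterior
        Retained draws of Theta, D and the individual beta_i.
    coef_ : ndarray of shape (n_respondents, n_params)
        Posterior-mean individual coefficients.
    population_mean_ : ndarray of shape (n_params,)
        Posterior mean of the across-respondent average coefficients.
    accept_rate_ : float
        Mean Metropolis acceptance rate after burn-in.
    """

    def __init__(self, n_burn: int = 10_000, n_draws: int = 10_000, thin: int = 10,
                 proposal_scale: float = 0.3, target_accept: float = 0.3,
                 prior_cov_scale: float = 1.0, prior_df_add: int = 5,
                 seed: int | None = None):
        self.n_burn = n_burn
        self.n_draws = n_draws
        self.thin = thin
        self.proposal_scale = proposal_scale
        self.target_accept = target_accept
        self.prior_cov_scale = prior_cov_scale
        self.prior_df_add = prior_df_add
        self.seed = seed

    @classmethod
    def from_config(cls, config: HBConfig) -> "HierarchicalBayesLogit":
        return cls(**config.__dict__)

    # ------------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, Z: np.ndarray | None = None,
            labels: list[str] | None = None, respondent_ids: list | None = None):
        """Run the sampler.

        Parameters
        ----------
        X : ndarray (n_respondents, n_tasks, n_alternatives, n_params)
            Effects-coded design per respondent.
        y : ndarray (n_respondents, n_tasks)
            Chosen alternative index per task.
        Z : ndarray (n_respondents, n_covariates), optional
            Respondent covariates entering the upper-model mean; an intercept
            column is prepended internally.
        """
        cfg = HBConfig(self.n_burn, self.n_draws, self.thin, self.proposal_scale,
                       self.target_accept, self.prior_cov_scale, self.prior_df_add,
                       self.seed)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 4:
            raise ValueError("X must be (n_resp, n_tasks, n_alts, n_params)")
        N, t, a, p = X.shape
        if N < 2:
            raise ValueError("hierarchical estimation needs >= 2 respondents")
        if Z is None:
            Z1 = np.ones((N, 1))
        else:
            Z = np.asarray(Z, dtype=float)
            # center covariates so the intercept row is the population mean
            Z1 = np.column_stack([np.ones(N), Z - Z.mean(axis=0)])
        k = Z1.shape[1]
        rng = np.random.default_rng(cfg.seed)

        ZtZ = Z1.T @ Z1
        ZtZ_inv = np.linalg.inv(ZtZ)
        L_zz = np.linalg.cholesky(ZtZ_inv)

        df0 = p + cfg.prior_df_add
        S0 = cfg.prior_cov_scale * np.eye(p)

        # initialize every respondent at the pooled aggregate-MNL estimate so
        # the population level starts near its posterior mode; the pooled
        # covariance also shapes the joint translation move below.  Fall back
        # to zeros/identity when the pooled fit is unavailable (separation).
        try:
            from .mnl import MultinomialLogit
            pooled = MultinomialLogit().fit(
                X.reshape(-1, a, p), y.reshape(-1))
            b0 = pooled.coef_
            L_pooled = np.linalg.cholesky(pooled.cov_)
        except Exception:
            b0 = np.zeros(p)
            L_pooled = np.eye(p)
        B = np.tile(b0, (N, 1))
        Theta = np.zeros((k, p))
        Theta[0] = b0
        D = np.eye(p)
        step = cfg.proposal_scale
        shift_step = 1.0

        ll = _chain_loglik(B, X, y)

        n_iter = cfg.n_burn + cfg.n_draws
        n_ret = cfg.n_draws // cfg.thin
        theta_draws = np.empty((n_ret, k, p))
        cov_draws = np.empty((n_ret, p, p))
        beta_draws = np.empty((n_ret, N, p))
        loglik_trace = np.empty(n_iter)
        post_accepts = 0
        post_steps = 0
        window_accepts = 0
        window_steps = 0
        shift_accepts = 0
        shift_total = 0
        ret = 0

        for it in range(n_iter):
            # --- Theta | B, D  (matrix-normal, flat prior)
            Theta_hat = ZtZ_inv @ (Z1.T @ B)
            L_D = self._chol(D)
            E = rng.standard_normal((k, p))
            Theta = Theta_hat + L_zz @ E @ L_D.T

            # --- D | B, Theta  (inverse-Wishart)
            R = B - Z1 @ Theta
            S_post = S0 + R.T @ R
            D = stats.invwishart.rvs(df=df0 + N, scale=S_post, random_state=rng)
            D = np.atleast_2d(D)
            L_D = self._chol(D)
            D_inv = np.linalg.inv(D)

            # --- beta_i | rest  (random-walk Metropolis, vectorized over i)
            mu = Z1 @ Theta
            prop = B + step * rng.standard_normal((N, p)) @ L_D.T
            ll_prop = _chain_loglik(prop, X, y)
            dev_old = B - mu
            dev_new = prop - mu
            lp_old = -0.5 * np.einsum("np,pq,nq->n", dev_old, D_inv, dev_old)
            lp_new = -0.5 * np.einsum("np,pq,nq->n", dev_new, D_inv, dev_new)
            log_ratio = (ll_prop + lp_new) - (ll + lp_old)
            accept = np.log(rng.uniform(size=N)) < log_ratio
            B[accept] = prop[accept]
            ll[accept] = ll_prop[accept]

            n_acc = int(accept.sum())
            window_accepts += n_acc
            window_steps += N

            # --- joint translation move: shift every beta_i and the
            # population intercept together.  The within-group deviations
            # (and hence the prior terms) are unchanged, so the acceptance
            # ratio is the product likelihood alone.  This breaks the slow
            # random-walk coupling of the population mean to the individual
            # updates (which is severe when D is small) without altering the
            # stationary distribution; the proposal is shaped by the pooled
            # MNL covariance, the natural scale of the population mean.
            delta = shift_step * (L_pooled @ rng.standard_normal(p))
            ll_shift = _chain_loglik(B + delta, X, y)
            if np.log(rng.uniform()) < ll_shift.sum() - ll.sum():
                B = B + delta
                Theta[0] = Theta[0] + delta
                ll = ll_shift
                shift_accepts += 1
            shift_total += 1

            loglik_trace[it] = ll.sum()

            if it < cfg.n_burn:
                if (it + 1) % 100 == 0:  # adapt during burn-in only
                    rate = window_accepts / window_steps
                    step *= 1.1 if rate > cfg.target_accept else 0.9
                    window_accepts = window_steps = 0
                    shift_rate = shift_accepts / shift_total
                    shift_step *= 1.1 if shift_rate > cfg.target_accept else 0.9
                    shift_accepts = shift_total = 0
            else:
                post_accepts += n_acc
                post_steps += N
                j = it - cfg.n_burn
                if (j + 1) % cfg.thin == 0 and ret < n_ret:
                    theta_draws[ret] = Theta
                    cov_draws[ret] = D
                    beta_draws[ret] = B
                    ret += 1

        accept_rate = post_accepts / max(post_steps, 1)
        if accept_rate < 0.01:
            raise RuntimeError(
                f"sampler diverged: post-adaptation acceptance rate "
                f"{accept_rate:.4f} < 1%; final step size {step:.3g}"
            )
        self.posterior_ = HBPosterior(
            theta_draws=theta_draws[:ret],
            cov_draws=cov_draws[:ret],
            beta_draws=beta_draws[:ret],
            accept_rate=accept_rate,
            loglik_trace=loglik_trace,
            labels=list(labels) if labels else [],
            respondent_ids=list(respondent_ids) if respondent_ids is not None
            else list(range(N)),
        )
        self.coef_ = self.posterior_.beta_point()
        self.population_mean_ = self.posterior_.population_mean()
        self.accept_rate_ = accept_rate
        self.step_size_ = step
        return self

    @staticmethod
    def _chol(D: np.ndarray) -> np.ndarray:
        """Cholesky with jitter-and-retry for numerically non-PD draws."""
        jitter = 0.0
        for _ in range(6):
            try:
                return np.linalg.cholesky(D + jitter * np.eye(len(D)))
            except np.linalg.LinAlgError:
                jitter = max(jitter * 10.0, 1e-10)
        raise np.linalg.LinAlgError("covariance draw not positive definite")


def fit_hb(X: np.ndarray, y: np.ndarray, config: HBConfig,
           Z: np.ndarray | None = None, labels: list[str] | None = None,
           respondent_ids: list | None = None) -> HBPosterior:
    """Functional wrapper over :class:`HierarchicalBayesLogit`."""
    est = HierarchicalBayesLogit.from_config(config)
    est.fit(X, y, Z=Z, labels=labels, respondent_ids=respondent_ids)
    return est.posterior_


def point_utilities(posterior: HBPosterior, cm: CodedMatrix) -> pd.DataFrame:
    """Per-respondent posterior-mean utilities, expanded to every attribute
    level (reference level = minus the sum of the others).

    Returns a tidy frame with columns ``respondent_id``, ``attribute``,
    ``level``, ``utility``.
    """
    if posterior.beta_draws.shape[0] < 1:
        raise ValueError("posterior holds no retained draws")
    B = posterior.beta_point()
    wide = expand_utilities(B, cm)
    frames = []
    for i, rid in enumerate(posterior.respondent_ids):
        f = wide[["attribute", "level"]].copy()
        col = "utility" if B.shape[0] == 1 else f"utility_{i}"
        f["utility"] = wide[col].to_numpy()
        f.insert(0, "respondent_id", rid)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def fit_statistics(posterior: HBPosterior, X: np.ndarray, y: np.ndarray,
                   max_draws: int = 200) -> FitStatistics:
    """RLH and percent certainty of a fitted posterior.

    The per-task log probability of each observed choice is averaged over (up
    to ``max_draws`` equally spaced) retained draws; RLH exponentiates the
    mean over respondent-tasks, and percent certainty compares the total
    log-likelihood with the null model LL0 = n_tasks * ln(1/a).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    N, t, a, p = X.shape
    n_ret = posterior.beta_draws.shape[0]
    idx = np.unique(np.linspace(0, n_ret - 1, min(max_draws, n_ret)).astype(int))
    ll_draws = np.stack([
        _chain_loglik(posterior.beta_draws[d], X, y) for d in idx
    ])  # (n_draws_used, N)
    total_ll = ll_draws.sum(axis=1).mean()
    n_tasks = N * t
    rlh = float(np.exp(total_ll / n_tasks))
    ll0 = n_tasks * np.log(1.0 / a)
    return FitStatistics(rlh=rlh, percent_certainty=float(1.0 - total_ll / ll0))
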