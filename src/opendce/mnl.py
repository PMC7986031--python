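"""Multinomial logit choice probabilities and aggregate (pooled) estimation.

The aggregate model treats every choice task as an independent multinomial
logit observation with a single shared coefficient vector.  It is used to
test candidate designs (do simulated random responders yield precise,
near-zero main effects?) and to screen interactions and covariates with
likelihood-ratio tests; individual-level estimation lives in
:mod:`opendce.hb`.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

__all__ = ["mnl_choice_prob", "mnl_loglik", "MultinomialLogit", "fit_aggregate_mnl",
           "lr_test", "RankDeficientError"]


class RankDeficientError(ValueError):
    """Design matrix does not identify all coded parameters."""

    def __init__(self, columns: list[str] | list[int]):
        self.columns = list(columns)
        super().__init__(f"unidentified design: collinear or constant columns {self.columns}")


def mnl_choice_prob(beta: np.ndarray, task: np.ndarray) -> np.ndarray:
    """Choice probabilities for one task.

    ``task`` is an (a, p) coded matrix of alternatives; the result is the
    softmax of the alternative utilities ``task @ beta``.  The maximum utility
    is subtracted before exponentiation, so adding any constant to all
    utilities leaves the probabilities unchanged and overflow cannot occur.
    """
    u = np.asarray(task) @ np.asarray(beta)
    u = u - u.max(axis=-1, keepdims=True)
    e = np.exp(u)
    return e / e.sum(axis=-1, keepdims=True)


def _utilities(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    return X @ beta


def mnl_loglik(beta: np.ndarray, X: np.ndarray, chosen: np.ndarray) -> float:
    """Pooled log-likelihood for stacked tasks.

    ``X`` is (T, a, p), ``chosen`` (T,) 0-based chosen-alternative indices.
    """
    u = _utilities(X, beta)
    lse = logsumexp(u, axis=-1)
    return float(np.sum(u[np.arange(len(chosen)), chosen] - lse))


def _score_hessian(beta, X, chosen):
    """Gradient and Hessian of the pooled log-likelihood."""
    T, a, p = X.shape
    u = _utilities(X, beta)
    u = u - u.max(axis=1, keepdims=True)
    e = np.exp(u)
    P = e / e.sum(axis=1, keepdims=True)  # (T, a)
    xbar = np.einsum("ta,tap->tp", P, X)
    grad = (X[np.arange(T), chosen] - xbar).sum(axis=0)
    # H = -sum_t [ sum_j p_j x_j x_j' - xbar xbar' ]
    H = -(np.einsum("ta,tap,taq->pq", P, X, X) - xbar.T @ xbar)
    return grad, H


def check_identification(X: np.ndarray, labels: list[str] | None = None,
                         tol: float = 1e-8) -> None:
    """Raise :class:`RankDeficientError` if the information matrix at beta=0
    is singular, naming the involved columns."""
    p = X.shape[-1]
    beta0 = np.zeros(p)
    _, H = _score_hessian(beta0, X, np.zeros(len(X), dtype=int))
    info = -H
    w, v = np.linalg.eigh(info)
    scale = max(w.max(), 1.0)
    bad = w < tol * scale
    if bad.any():
        null_mass = np.abs(v[:, bad]).max(axis=1)
        cols = np.nonzero(null_mass > 1e-6)[0]
        names = [labels[c] for c in cols] if labels else cols.tolist()
        raise RankDeficientError(names)


class MultinomialLogit(BaseEstimator):
    """Aggregate multinomial logit estimated by Newton's method.

    Parameters
    ----------
    tol : float
        Convergence threshold on the gradient max-norm.
    max_iter : int
        Newton iteration cap.

    Attributes
    ----------
    coef_ : ndarray of shape (n_params,)
        Maximum-likelihood estimates.
    se_ : ndarray of shape (n_params,)
        Standard errors from the inverse observed information.
    cov_ : ndarray of shape (n_params, n_params)
        Inverse observed information matrix.
    loglik_ : float
        Log-likelihood at the optimum.
    loglik_null_ : float
        Log-likelihood of the zero-coefficient (uniform choice) model.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X: np.ndarray, y: np.ndarray, labels: list[str] | None = None):
        """Fit on stacked tasks: ``X`` (n_tasks, n_alts, n_params), ``y``
        (n_tasks,) chosen alternative indices."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 3:
            raise ValueError("X must be (n_tasks, n_alternatives, n_params)")
        if len(y) != X.shape[0]:
            raise ValueError("y length must equal the number of tasks")
        check_identification(X, labels)
        T, a, p = X.shape
        beta = np.zeros(p)
        self.converged_ = False
        for it in range(1, self.max_iter + 1):
            grad, H = _score_hessian(beta, X, y)
            if np.abs(grad).max() < self.tol:
                self.converged_ = True
                self.n_iter_ = it
                break
            # small ridge keeps the step defined under near-separation
            step = np.linalg.solve(H - 1e-10 * np.eye(p), grad)
            ll_old = mnl_loglik(beta, X, y)
            t_step = 1.0
            for _ in range(30):  # backtracking line search
                cand = beta - t_step * step
                if mnl_loglik(cand, X, y) >= ll_old:
                    break
                t_step *= 0.5
            beta = beta - t_step * step
        else:
            self.n_iter_ = self.max_iter
        _, H = _score_hessian(beta, X, y)
        self.coef_ = beta
        self.cov_ = np.linalg.inv(-H)
        self.se_ = np.sqrt(np.diag(self.cov_))
        self.loglik_ = mnl_loglik(beta, X, y)
        self.loglik_null_ = T * np.log(1.0 / a)
        self.labels_ = labels
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return mnl_choice_prob(self.coef_, np.asarray(X, dtype=float))


def fit_aggregate_mnl(X: np.ndarray, y: np.ndarray,
                      labels: list[str] | None = None) -> MultinomialLogit:
    """Functional wrapper over :class:`MultinomialLogit`."""
    return MultinomialLogit().fit(X, y, labels=labels)


def lr_test(loglik_restricted: float, loglik_full: float, df: int,
            tol: float = 1e-6) -> float:
    """Likelihood-ratio p-value for nested models.

    Returns the chi-square tail probability of ``2 * (ll_full - ll_restricted)``
    on ``df`` degrees of freedom.  Used to keep an interaction or covariate
    block only when p <= 0.05.
    """
    delta = 2.0 * (loglik_full - loglik_restricted)
    if delta < -tol:
        raise ValueError(
            f"full model log-likelihood below restricted ({loglik_full} < "
            f"{loglik_restricted}); models are not nested or fit failed"
        )
    delta = max(delta, 0.0)
    return float(stats.chi2.sf(delta, df))
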