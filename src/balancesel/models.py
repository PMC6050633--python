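"""Regression of the response on a candidate balance plus covariates.

Continuous responses use ordinary least squares on

    Y = b0 + b1 * B(X+, X-) + gamma' Z

scored by the mean squared residual (1/n convention).  Dichotomous
responses use maximum-likelihood logistic regression on

    logit(Y) = b0 + b1 * B(X+, X-) + gamma' Z

scored by default with the area under the ROC curve of the full model's
fitted probabilities (Mann-Whitney form, ties counted half).  Two further
criteria are available for logistic fits: McFadden's pseudo-R^2
(1 - loglik_full / loglik_null) as an explained-variance measure, and
Tjur's discrimination coefficient (mean fitted probability among cases
minus mean among controls).

The logistic solver is a small Newton/IRLS routine written for the inner
loop of the balance search, where tens of thousands of 2-4 parameter fits
are performed; when plain maximum likelihood fails to converge (typically
quasi-complete separation on small candidate balances) the fit is retried
with a weak ridge penalty on the slopes (intercept unpenalised) so the
search always receives a finite, comparable criterion, and the result is
flagged ``converged=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import qr
from scipy.special import expit
from scipy.stats import rankdata

__all__ = [
    "FitResult",
    "CriterionSpec",
    "CRITERIA",
    "default_criterion",
    "fit_linear",
    "fit_logistic",
    "criterion_auc",
    "criterion_tjur",
    "criterion_pseudo_r2",
]


class CollinearityError(np.linalg.LinAlgError):
    """Design matrix is rank deficient."""


@dataclass(frozen=True)
class CriterionSpec:
    name: str
    direction: str  # "maximize" | "minimize"

    @property
    def sign(self) -> float:
        return 1.0 if self.direction == "maximize" else -1.0


CRITERIA: dict[str, CriterionSpec] = {
    "mse": CriterionSpec("mse", "minimize"),
    "auc": CriterionSpec("auc", "maximize"),
    "pseudo_r2": CriterionSpec("pseudo_r2", "maximize"),
    "tjur_d": CriterionSpec("tjur_d", "maximize"),
}


def default_criterion(response_type: str) -> CriterionSpec:
    """AUC for dichotomous responses, MSE for continuous ones."""
    return CRITERIA["auc" if response_type == "dichotomous" else "mse"]


@dataclass
class FitResult:
    beta0: float
    beta1: float
    gamma: np.ndarray
    criterion_name: str
    criterion_value: float
    fitted_values: np.ndarray
    converged: bool = True
    loglik: float | None = None
    loglik_null: float | None = None

    def predict(self, scores: np.ndarray, z: np.ndarray | None = None) -> np.ndarray:
        """Linear predictor at new balance scores / covariates."""
        eta = self.beta0 + self.beta1 * np.asarray(scores, dtype=float)
        if self.gamma.size:
            eta = eta + np.asarray(z, dtype=float) @ self.gamma
        return eta


def _design(scores: np.ndarray, z: np.ndarray | None) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    cols = [np.ones_like(scores), scores]
    if z is not None and np.size(z):
        z = np.asarray(z, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        cols.append(z)
        return np.column_stack(cols)
    return np.column_stack(cols)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = qr(X, pivoting=True, mode="economic")
        dependent = sorted(names[j] for j in piv[rank:])
        raise CollinearityError(
            f"design matrix is rank deficient; collinear column(s): {dependent}"
        )


def _column_names(n_cov: int) -> list[str]:
    return ["intercept", "balance"] + [f"z{i}" for i in range(n_cov)]


def criterion_auc(probabilities: np.ndarray, y: np.ndarray) -> float:
    """Area under the ROC curve in its Mann-Whitney form.

    AUC = P(score_pos > score_neg) + 0.5 * P(tie) over all positive/negative
    pairs, computed from midranks.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(y, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes to be present")
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def criterion_tjur(probabilities: np.ndarray, y: np.ndarray) -> float:
    """Tjur's discrimination coefficient, clipped to [0, 1]."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("Tjur's D requires both classes to be present")
    return float(np.clip(p[y == 1].mean() - p[y == 0].mean(), 0.0, 1.0))


def criterion_pseudo_r2(loglik_full: float, loglik_null: float) -> float:
    """McFadden's pseudo-R^2 = 1 - loglik_full / loglik_null."""
    if loglik_null == 0:
        raise ValueError("null model log-likelihood is zero; pseudo-R^2 undefined")
    return float(np.clip(1.0 - loglik_full / loglik_null, 0.0, 1.0))


def fit_linear(
    scores: np.ndarray,
    y: np.ndarray,
    z: np.ndarray | None = None,
    criterion: str = "mse",
) -> FitResult:
    """OLS fit of a continuous response on the balance and covariates."""
    if criterion != "mse":
        raise ValueError("continuous responses support only the mse criterion")
    X = _design(scores, z)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} samples for {p} parameters")
    _check_rank(X, _column_names(p - 2))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    mse = float(np.mean((y - fitted) ** 2))
    return FitResult(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        gamma=np.asarray(beta[2:], dtype=float),
        criterion_name="mse",
        criterion_value=mse,
        fitted_values=fitted,
    )


def _logistic_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log-likelihood via the numerically stable log(1 + exp(.)) form
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _newton_logistic(
    X: np.ndarray, y: np.ndarray, ridge: float, max_iter: int = 50, tol: float = 1e-9
) -> tuple[np.ndarray, bool]:
    n, p = X.shape
    penalty = np.zeros((p, p))
    if ridge > 0:
        penalty[np.arange(1, p), np.arange(1, p)] = ridge  # slopes only
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -35, 35)
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - penalty @ beta
        hess = (X * w[:, None]).T @ X + penalty
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, False
        beta = beta + step
        if not np.all(np.isfinite(beta)):
            return beta, False
        if np.max(np.abs(step)) < tol:
            return beta, True
    return beta, False


def fit_logistic(
    scores: np.ndarray,
    y: np.ndarray,
    z: np.ndarray | None = None,
    criterion: str = "auc",
    ridge_fallback: float = 1e-4,
) -> FitResult:
    """Maximum-likelihood logistic fit with a ridge fallback on separation.

    ``y`` must be 0/1 with both classes present.  ``criterion`` is one of
    auc (default), pseudo_r2 or tjur_d, evaluated on the full model's fitted
    probabilities.
    """
    if criterion not in ("auc", "pseudo_r2", "tjur_d"):
        raise ValueError(f"unsupported logistic criterion {criterion!r}")
    y = np.asarray(y, dtype=float)
    if not (np.any(y == 1) and np.any(y == 0)):
        raise ValueError("logistic fit requires both response classes")
    X = _design(scores, z)
    _check_rank(X, _column_names(X.shape[1] - 2))
    beta, converged = _newton_logistic(X, y, ridge=0.0)
    if not converged or np.max(np.abs(beta)) > 1e3:
        beta, _ = _newton_logistic(X, y, ridge=ridge_fallback)
        converged = False
    eta = np.clip(X @ beta, -35, 35)
    probs = expit(eta)
    loglik = _logistic_loglik(X @ beta, y)
    pbar = float(np.mean(y))
    loglik_null = float(
        np.sum(y) * np.log(pbar) + np.sum(1 - y) * np.log(1 - pbar)
    )
    if criterion == "auc":
        value = criterion_auc(probs, y)
    elif criterion == "tjur_d":
        value = criterion_tjur(probs, y)
    else:
        value = criterion_pseudo_r2(loglik, loglik_null)
    return FitResult(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        gamma=np.asarray(beta[2:], dtype=float),
        criterion_name=criterion,
        criterion_value=value,
        fitted_values=probs,
        converged=converged,
        loglik=loglik,
        loglik_null=loglik_null,
    )
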