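"""Poisson log-link GLM fitting for structured equations.

Each endogenous species is modelled by its own Poisson regression
(local estimation).  Fitting is iteratively reweighted least squares with
a deviance-based stopping rule; standard errors come from the inverse
Fisher information at the optimum and p-values are two-sided Wald tests.
Per-equation fit quality is summarised by the Nagelkerke pseudo-R^2, and
effect sizes by standardized coefficients on a latent linear scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

P_FLOOR = 1e-300  # probabilities are floored here before any logarithm
ETA_CLIP = 30.0


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, last_beta: np.ndarray | None = None):
        super().__init__(message)
        self.last_beta = last_beta


class RankDeficiencyError(np.linalg.LinAlgError):
    """Design matrix is not full column rank (perfect collinearity)."""


class DegenerateInputError(ValueError):
    pass


@dataclass(frozen=True)
class EquationFit:
    """One structured equation's fitted Poisson GLM."""

    response: str
    predictors: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray        # per predictor, link scale
    std_errors: np.ndarray          # per predictor
    intercept_se: float
    wald_p: np.ndarray              # per predictor, two-sided
    log_lik: float
    null_log_lik: float
    n: int
    fitted_eta: np.ndarray
    std_estimates: np.ndarray | None = field(default=None)
    std_method: str | None = field(default=None)

    @property
    def residual_df(self) -> int:
        return self.n - (len(self.predictors) + 1)

    @property
    def n_params(self) -> int:
        return len(self.predictors) + 1

    @property
    def pseudo_r2(self) -> float:
        return nagelkerke_r2(self.log_lik, self.null_log_lik, self.n)

    def p_for(self, predictor: str) -> float:
        return float(self.wald_p[self.predictors.index(predictor)])

    def coef_for(self, predictor: str) -> float:
        return float(self.coefficients[self.predictors.index(predictor)])


def _poisson_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    mu = np.exp(np.clip(eta, -ETA_CLIP, ETA_CLIP))
    return float(np.sum(y * eta - mu - gammaln(y + 1.0)))


def _irls(y: np.ndarray, X: np.ndarray, max_iter: int, tol: float):
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise RankDeficiencyError("design matrix is rank deficient")
    # standard mean-of-y start for the intercept, zeros elsewhere
    beta = np.zeros(p)
    beta[0] = np.log(max(np.mean(y), 1e-8))
    eta = X @ beta
    dev = -2.0 * _poisson_loglik(y, eta)
    for _ in range(max_iter):
        mu = np.exp(np.clip(eta, -ETA_CLIP, ETA_CLIP))
        w = mu  # Poisson: var = mu, canonical link
        z = eta + (y - mu) / mu
        WX = X * w[:, None]
        xtwx = X.T @ WX
        try:
            beta_new = np.linalg.solve(xtwx, WX.T @ z)
        except np.linalg.LinAlgError as exc:
            raise RankDeficiencyError(str(exc)) from exc
        eta_new = X @ beta_new
        dev_new = -2.0 * _poisson_loglik(y, eta_new)
        step = 1.0
        # halve the step if the deviance went up (rare, strong starts)
        while dev_new > dev + 1e-10 and step > 1e-4:
            step /= 2.0
            beta_new = beta + step * (beta_new - beta)
            eta_new = X @ beta_new
            dev_new = -2.0 * _poisson_loglik(y, eta_new)
        converged = abs(dev - dev_new) / (abs(dev_new) + 0.1) < tol
        beta, eta, dev = beta_new, eta_new, dev_new
        if converged:
            break
    else:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations", last_beta=beta
        )
    mu = np.exp(np.clip(eta, -ETA_CLIP, ETA_CLIP))
    fisher = X.T @ (X * mu[:, None])
    cov = np.linalg.inv(fisher)
    return beta, eta, cov


def fit_poisson(
    y: np.ndarray,
    X: np.ndarray,
    predictors: tuple[str, ...] | list[str],
    response: str = "y",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> EquationFit:
    """Fit a Poisson log-link GLM by IRLS.

    Parameters
    ----------
    y
        Non-negative integer counts, length n.
    X
        Predictor matrix (n, k) WITHOUT an intercept column; the intercept
        is always included.
    predictors
        Names for the k columns of X.

    Raises :class:`ConvergenceError` after ``max_iter`` non-converged
    iterations (carrying the last iterate) and
    :class:`RankDeficiencyError` for perfectly collinear designs.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n, k = X.shape
    if len(predictors) != k:
        raise ValueError(f"{len(predictors)} names for {k} columns")
    if n <= k + 1:
        raise DegenerateInputError(f"n={n} too small for {k} predictors")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts must be non-negative integers")

    design = np.column_stack([np.ones(n), X])
    beta, eta, cov = _irls(y, design, max_iter, tol)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    wald = 2.0 * stats.norm.sf(np.abs(z))
    wald = np.clip(wald, P_FLOOR, 1.0)

    log_lik = _poisson_loglik(y, eta)
    null_beta, null_eta, _ = _irls(y, np.ones((n, 1)), max_iter, tol)
    null_log_lik = _poisson_loglik(y, null_eta)

    return EquationFit(
        response=response,
        predictors=tuple(predictors),
        intercept=float(beta[0]),
        coefficients=beta[1:].copy(),
        std_errors=se[1:].copy(),
        intercept_se=float(se[0]),
        wald_p=wald[1:].copy(),
        log_lik=log_lik,
        null_log_lik=null_log_lik,
        n=n,
        fitted_eta=eta,
    )


def nagelkerke_r2(log_lik: float, null_log_lik: float, n: int) -> float:
    """Nagelkerke pseudo-R^2: likelihood-ratio R^2 rescaled to max 1.

    R^2 = [1 - exp(2(ll0 - ll)/n)] / [1 - exp(2*ll0/n)], clamped to [0, 1].
    ll must be >= ll0 up to small numerical slack.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if log_lik < null_log_lik - 1e-8:
        raise ValueError(
            f"log_lik {log_lik} below null_log_lik {null_log_lik}"
        )
    log_lik = max(log_lik, null_log_lik)
    denom = 1.0 - np.exp(2.0 * null_log_lik / n)
    if denom <= 0.0:
        raise DegenerateInputError("degenerate null likelihood (denominator <= 0)")
    r2 = (1.0 - np.exp(2.0 * (null_log_lik - log_lik) / n)) / denom
    return float(np.clip(r2, 0.0, 1.0))


def standardize_coefficients(
    fit: EquationFit,
    sd_predictors: np.ndarray,
    method: str = "latent_linear",
    y: np.ndarray | None = None,
) -> np.ndarray:
    """Standardized effect sizes: std_b = b * sd(x) / sd_latent(y).

    ``latent_linear`` (default) takes sd_latent(y) as the sd of the fitted
    linear predictor eta-hat — the spread of the response on the link
    scale implied by the model, with no added error-variance term (the
    log link has no canonical latent error variance).
    ``observation_empirical`` uses the sd of log(y + 1), an empirical
    mapping of the observed counts onto the link scale (requires ``y``).
    Within one equation every predictor shares the same denominator, so
    std_b / b is constant across unit-sd predictors.
    """
    sd_predictors = np.asarray(sd_predictors, dtype=float)
    if np.any(sd_predictors <= 0):
        raise ValueError("predictor sds must be > 0")
    if method == "latent_linear":
        sd_y = float(np.std(fit.fitted_eta, ddof=1))
    elif method == "observation_empirical":
        if y is None:
            raise ValueError("observation_empirical needs the observed counts")
        sd_y = float(np.std(np.log(np.asarray(y, dtype=float) + 1.0), ddof=1))
    else:
        raise ValueError(f"unknown standardization method {method!r}")
    if sd_y == 0.0:
        return np.zeros_like(fit.coefficients)
    return fit.coefficients * sd_predictors / sd_y


def fits_to_frame(fits: list[EquationFit]) -> pd.DataFrame:
    """Tidy coefficient table: Response, Predictor, Estimate, SE, DF, p,
    Std.Estimate — one row per path, equations in input order."""
    rows = []
    for fit in fits:
        std = fit.std_estimates
        for j, pred in enumerate(fit.predictors):
            rows.append(
                {
                    "Response": fit.response,
                    "Predictor": pred,
                    "Estimate": fit.coefficients[j],
                    "SE": fit.std_errors[j],
                    "DF": fit.residual_df,
                    "p": fit.wald_p[j],
                    "Std.Estimate": std[j] if std is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)
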