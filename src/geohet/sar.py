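"""Simultaneous autoregressive (SAR) error models and covariate selection.

The model regresses a per-unit response on covariates while letting the
residuals be spatially autoregressive:

    y = X beta + u,   u = lambda W u + eps,   eps ~ N(0, sigma^2 I),

with W the binary spatial-weights matrix.  lambda is estimated by maximizing
the profile log-likelihood

    LL(lambda) = -(n/2) (ln 2 pi sigma2(lambda) + 1) + ln |I - lambda W|,

where beta(lambda) and sigma2(lambda) are generalized-least-squares solutions
under A = I - lambda W, and the log-determinant is evaluated through the
eigenvalues of W (W symmetric here, so ln|I - lambda W| = sum ln(1 - lambda
w_k)).  lambda is searched over the feasible interval (1/w_min, 1/w_max).

A likelihood-ratio test against lambda = 0 (ordinary least squares) gives the
spatial-dependence p-value; covariate p-values are Wald z-tests from the ML
covariance.  Forward selection adds covariates greedily by smallest Wald p
and retains every visited model in which all covariates are individually
significant at the chosen alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .regionalization import SpatialWeights

__all__ = [
    "ModelSpec",
    "SARFit",
    "feasible_lambda_interval",
    "fit_sar_error",
    "forward_search",
    "evaluate_added_covariate",
]

_EDGE = 1e-6  # relative shrink of the feasible interval at its endpoints


@dataclass(frozen=True)
class ModelSpec:
    """A response plus a set of covariate names (intercept implicit)."""

    response: str
    covariates: tuple[str, ...]

    def formula(self) -> str:
        rhs = " + ".join(self.covariates) if self.covariates else "1"
        return f"{self.response} ~ {rhs}"


@dataclass
class SARFit:
    """Fitted SAR error model."""

    beta: pd.Series  # coefficients, index = ['Intercept', *covariates]
    beta_se: pd.Series
    beta_p: pd.Series  # two-sided Wald p-values
    lam: float
    sigma2: float
    loglik: float
    loglik_null: float  # profile log-likelihood at lambda = 0 (OLS)
    lr_stat: float
    lr_p: float
    fitted: np.ndarray  # trend + spatial signal, per unit
    trend: np.ndarray  # X beta
    residuals: np.ndarray  # y - fitted
    lambda_interval: tuple[float, float] = (np.nan, np.nan)


def feasible_lambda_interval(W: SpatialWeights) -> tuple[float, float]:
    """Feasible lambda range (1/w_min, 1/w_max) from the eigenvalues of W."""
    eig = np.linalg.eigvalsh(W.W)
    w_min, w_max = eig[0], eig[-1]
    if w_min >= 0 or w_max <= 0:
        raise ValueError("weights matrix has no sign-mixed eigenvalue range")
    return 1.0 / w_min, 1.0 / w_max


def _profile_terms(lam: float, y: np.ndarray, X: np.ndarray, W: np.ndarray, eig: np.ndarray):
    """GLS beta, sigma2 and profile log-likelihood at a given lambda."""
    n = y.size
    A = np.eye(n) - lam * W
    Xa, ya = A @ X, A @ y
    beta, *_ = np.linalg.lstsq(Xa, ya, rcond=None)
    resid = ya - Xa @ beta
    sigma2 = float(resid @ resid) / n
    logdet = float(np.log(1.0 - lam * eig).sum())
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet
    return beta, sigma2, ll


def fit_sar_error(
    y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    W: SpatialWeights,
    add_intercept: bool = True,
) -> SARFit:
    """Maximum-likelihood fit of the SAR error model.

    ``X`` holds the covariate columns (intercept added unless
    ``add_intercept=False``).  Requires n >= number of coefficients + 2 and a
    full-rank design.  Fitted values include the spatial signal,
    X beta + lambda W (y - X beta).
    """
    y = np.asarray(y, dtype=float)
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        names = [f"x{i}" for i in range(Xm.shape[1])]
    if add_intercept:
        Xm = np.column_stack([np.ones(len(y)), Xm])
        names = ["Intercept", *names]
    n, k = Xm.shape
    if y.size != n or n != W.n:
        raise ValueError("y, X and W dimensions do not agree")
    if n < k + 2:
        raise ValueError(f"too few units (n={n}) for {k} coefficients")
    if np.linalg.matrix_rank(Xm) < k:
        raise ValueError("singular design matrix")

    eig = np.linalg.eigvalsh(W.W)
    lo, hi = feasible_lambda_interval(W)
    span = hi - lo
    lo_s, hi_s = lo + _EDGE * span, hi - _EDGE * span

    def neg_ll(lam: float) -> float:
        return -_profile_terms(lam, y, Xm, W.W, eig)[2]

    res = optimize.minimize_scalar(neg_ll, bounds=(lo_s, hi_s), method="bounded",
                                   options={"xatol": 1e-10})
    lam = float(res.x)
    # a boundary optimum means the likelihood wants lambda outside the
    # feasible range; report it rather than fail
    if min(lam - lo_s, hi_s - lam) < 1e-6 * span:
        warnings.warn(
            f"lambda estimate {lam:.4f} at the feasible-interval boundary "
            f"({lo:.4f}, {hi:.4f})",
            stacklevel=2,
        )
    beta, sigma2, ll = _profile_terms(lam, y, Xm, W.W, eig)
    _, _, ll0 = _profile_terms(0.0, y, Xm, W.W, eig)
    if ll < ll0:  # numerical guard: the optimum can never be below lambda=0
        lam, (beta, sigma2, ll) = 0.0, _profile_terms(0.0, y, Xm, W.W, eig)
    lr_stat = 2.0 * (ll - ll0)
    lr_p = float(stats.chi2.sf(max(lr_stat, 0.0), df=1))

    A = np.eye(n) - lam * W.W
    Xa = A @ Xm
    cov = sigma2 * np.linalg.inv(Xa.T @ Xa)
    se = np.sqrt(np.diag(cov))
    zval = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(zval))

    trend = Xm @ beta
    u = y - trend
    fitted = trend + lam * (W.W @ u)
    return SARFit(
        beta=pd.Series(beta, index=names),
        beta_se=pd.Series(se, index=names),
        beta_p=pd.Series(pval, index=names),
        lam=lam,
        sigma2=sigma2,
        loglik=ll,
        loglik_null=ll0,
        lr_stat=float(max(lr_stat, 0.0)),
        lr_p=lr_p,
        fitted=fitted,
        trend=trend,
        residuals=y - fitted,
        lambda_interval=(lo, hi),
    )


def _covariate_p(fit: SARFit) -> pd.Series:
    return fit.beta_p.drop("Intercept", errors="ignore")


def forward_search(
    y: np.ndarray,
    candidates: pd.DataFrame,
    W: SpatialWeights,
    response: str = "y",
    alpha: float = 0.05,
    max_terms: int = 4,
) -> list[tuple[ModelSpec, SARFit]]:
    """Greedy forward covariate selection for the SAR error model.

    Starting from the intercept-only model, at each step the candidate with
    the smallest Wald p-value is added (up to ``max_terms`` covariates).
    Every visited model whose covariates are all individually significant at
    ``alpha`` is retained; an empty list is a valid outcome.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    selected: list[str] = []
    remaining = list(candidates.columns)
    retained: list[tuple[ModelSpec, SARFit]] = []
    while remaining and len(selected) < max_terms:
        trials = []
        for name in remaining:
            cols = selected + [name]
            try:
                fit = fit_sar_error(y, candidates[cols], W)
            except (ValueError, np.linalg.LinAlgError):
                continue
            trials.append((float(fit.beta_p[name]), name, fit))
        if not trials:
            break
        trials.sort(key=lambda t: (t[0], t[1]))
        p_new, name, fit = trials[0]
        selected.append(name)
        remaining.remove(name)
        if (_covariate_p(fit) < alpha).all():
            retained.append((ModelSpec(response, tuple(selected)), fit))
    return retained


def evaluate_added_covariate(
    base: ModelSpec,
    extra: str,
    y: np.ndarray,
    covariates: pd.DataFrame,
    W: SpatialWeights,
    alpha: float = 0.05,
) -> dict:
    """Test whether adding one covariate improves a fitted model.

    "Improves" requires the added covariate to be significant at ``alpha``
    while every base covariate stays significant.  Returns a decision record
    with both fits and the log-likelihood change.
    """
    if extra in base.covariates:
        raise ValueError(f"{extra!r} is already in the model")
    base_fit = fit_sar_error(y, covariates[list(base.covariates)], W)
    aug_cols = [*base.covariates, extra]
    aug_fit = fit_sar_error(y, covariates[aug_cols], W)
    p_extra = float(aug_fit.beta_p[extra])
    all_sig = bool((_covariate_p(aug_fit) < alpha).all())
    return {
        "base": base,
        "extra": extra,
        "improves": p_extra < alpha and all_sig,
        "p_extra": p_extra,
        "all_significant": all_sig,
        "delta_loglik": float(aug_fit.loglik - base_fit.loglik),
        "base_fit": base_fit,
        "augmented_fit": aug_fit,
    }
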