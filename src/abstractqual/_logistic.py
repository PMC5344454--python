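"""Logistic-regression helper for the supervised response stage.

Wraps statsmodels for the unpenalized fit and falls back to a small ridge
Newton solver when the likelihood does not converge (e.g. quasi-complete
separation).  The fallback is always flagged on the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

RIDGE_LAMBDA = 1e-4


@dataclass
class LogisticFit:
    coef: np.ndarray           # intercept first
    cov: np.ndarray            # coefficient covariance (Wald)
    llf: float
    aic: float
    ridged: bool
    names: list[str] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _ridge_newton(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray, float]:
    n, p = X.shape
    pen = np.full(p, lam)
    pen[0] = 0.0  # intercept unpenalized
    beta = np.zeros(p)
    for _ in range(200):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = X.T @ (y - mu) - pen * beta
        hess = (X.T * w) @ X + np.diag(pen)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta
    llf = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    cov = np.linalg.inv(hess)
    return beta, cov, llf


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    add_intercept: bool = True,
    ridge_lambda: float = RIDGE_LAMBDA,
) -> LogisticFit:
    """ML logistic fit with automatic ridge fallback on non-convergence.

    ``X`` has no intercept column unless ``add_intercept=False``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["intercept"] + list(names or [f"x{i}" for i in range(X.shape[1] - 1)])
    else:
        names = list(names or [f"x{i}" for i in range(X.shape[1])])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            ok = (
                res.mle_retvals.get("converged", False)
                and np.all(np.isfinite(res.bse))
                and np.max(np.abs(res.params)) < 30
            )
        except Exception:
            ok = False
        if ok:
            return LogisticFit(
                coef=np.asarray(res.params),
                cov=np.asarray(res.cov_params()),
                llf=float(res.llf),
                aic=float(res.aic),
                ridged=False,
                names=names,
            )

    beta, cov, llf = _ridge_newton(X, y, ridge_lambda)
    aic = 2.0 * X.shape[1] - 2.0 * llf
    return LogisticFit(coef=beta, cov=cov, llf=llf, aic=aic, ridged=True, names=names)
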