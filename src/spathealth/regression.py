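"""Global (aspatial) regression diagnostics run before spatially varying fits.

Ordinary least squares with classical inference, variance-inflation factors
for collinearity screening (alert threshold 10), and residual-moment
normality summaries.  These are the conventional pre-tests run before
calibrating a geographically weighted model: the global fit establishes
overall significance, VIF rules out serious covariance between covariates,
and the residual moments check the Gaussian error assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import SingularDesignError

__all__ = ["OLSResult", "VIFReport", "ols_fit", "vif", "residual_normality"]

VIF_ALERT = 10.0


@dataclass(frozen=True)
class OLSResult:
    coefficients: np.ndarray      # intercept first
    std_errors: np.ndarray
    p_values: np.ndarray
    r_squared: float
    adj_r_squared: float
    residuals: np.ndarray
    fitted: np.ndarray
    names: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"variable": self.names, "coefficient": self.coefficients,
                             "std_error": self.std_errors, "p": self.p_values})


@dataclass(frozen=True)
class VIFReport:
    vif: np.ndarray
    names: list[str]
    max_vif: float
    alert: bool                   # any VIF above the conventional threshold 10


def ols_fit(X: np.ndarray, y: np.ndarray, names: list[str] | None = None) -> OLSResult:
    """OLS with intercept; classical standard errors and t-test p-values."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p + 1:
        raise SingularDesignError(f"need n > p + 1 observations (n={n}, p={p})")
    design = sm.add_constant(X, has_constant="raise")
    if np.linalg.matrix_rank(design) < p + 1:
        raise SingularDesignError("design matrix is rank deficient")
    fit = sm.OLS(y, design).fit()
    if names is None:
        names = [f"x{k}" for k in range(p)]
    return OLSResult(coefficients=fit.params, std_errors=fit.bse, p_values=fit.pvalues,
                     r_squared=float(fit.rsquared), adj_r_squared=float(fit.rsquared_adj),
                     residuals=np.asarray(fit.resid), fitted=np.asarray(fit.fittedvalues),
                     names=["intercept"] + list(names))


def vif(X: np.ndarray, names: list[str] | None = None) -> VIFReport:
    """Variance-inflation factor per covariate, ``VIF_k = 1/(1 − R²_k)``.

    Each covariate is regressed (with intercept) on the others.  A perfectly
    collinear column yields an infinite VIF, flagged rather than raised.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p < 2:
        raise SingularDesignError("VIF needs at least 2 covariates")
    out = np.empty(p)
    for k in range(p):
        others = sm.add_constant(np.delete(X, k, axis=1))
        r2 = sm.OLS(X[:, k], others).fit().rsquared
        out[k] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    if names is None:
        names = [f"x{k}" for k in range(p)]
    return VIFReport(vif=out, names=list(names), max_vif=float(np.max(out)),
                     alert=bool(np.any(out > VIF_ALERT)))


def residual_normality(residuals: np.ndarray,
                       skew_limit: float = 1.0,
                       kurt_limit: float = 2.0) -> tuple[float, float, bool]:
    """Sample skewness, excess kurtosis, and a conventional normality flag.

    The flag is True when |skewness| < ``skew_limit`` and |excess kurtosis|
    < ``kurt_limit`` — a coarse screen, not a formal test.
    """
    r = np.asarray(residuals, dtype=float)
    if len(r) < 8:
        raise ValueError("need at least 8 residuals for moment summaries")
    if np.std(r) == 0:
        raise ValueError("moments undefined for constant residuals")
    skew = float(stats.skew(r))
    kurt = float(stats.kurtosis(r))          # Fisher: excess kurtosis
    return skew, kurt, abs(skew) < skew_limit and abs(kurt) < kurt_limit
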