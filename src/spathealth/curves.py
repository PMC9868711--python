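"""Coefficient-ratio effect curves between two study periods.

For a covariate whose local effect is significant in both periods, the
per-unit ratio ``β_period2 / β_period1`` plotted against baseline health
summarizes how the marginal utility of that resource changed along the
health gradient.  A continuous two-segment piecewise-linear least-squares
fit, compared against a single line by AICc, locates the breakpoint where
the regime changes; the segment slopes classify the curve as V-shaped,
inverted-V, oblique-L, or monotone/flat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import EmptyCurveError, InsufficientDataError
from .mgwr import MGWRFit

__all__ = [
    "RatioCurve",
    "PiecewiseFit",
    "build_ratio_points",
    "fit_piecewise",
    "classify_shape",
]

RATIO_DENOM_EPS = 1e-6


@dataclass(frozen=True)
class PiecewiseFit:
    breakpoint: float | None
    slopes: tuple[float, ...]            # one slope per segment
    intercepts: tuple[float, ...]
    aicc_one_segment: float
    aicc_two_segment: float
    rss: float
    n_points: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.breakpoint is None:
            return self.intercepts[0] + self.slopes[0] * x
        left = self.intercepts[0] + self.slopes[0] * x
        right = self.intercepts[1] + self.slopes[1] * x
        return np.where(x <= self.breakpoint, left, right)


@dataclass(frozen=True)
class RatioCurve:
    x: np.ndarray                        # baseline health at surviving units
    y: np.ndarray                        # coefficient ratios
    n_excluded: int
    negative_ratio_units: int            # sign changes between periods, kept but flagged
    alpha: float
    fit: PiecewiseFit | None = None
    shape: str | None = None


def build_ratio_points(fit1: MGWRFit, fit2: MGWRFit, term: int | str,
                       baseline: np.ndarray, alpha: float = 0.05,
                       denom_eps: float = RATIO_DENOM_EPS) -> RatioCurve:
    """Per-unit coefficient ratios where both periods are significant.

    ``term`` is a term index or name shared by the two fits.  Units are kept
    when the local |t| = |β/SE| passes the two-sided normal threshold for
    ``alpha`` in *both* periods and the first-period coefficient is not
    numerically zero.  Negative ratios (effects that changed sign between
    periods) are retained and counted in ``negative_ratio_units``.
    """
    from scipy import stats

    if isinstance(term, str):
        if term not in fit1.term_names or term not in fit2.term_names:
            raise KeyError(f"term {term!r} not present in both fits")
        k1 = fit1.term_names.index(term)
        k2 = fit2.term_names.index(term)
    else:
        k1 = k2 = int(term)
    b1 = fit1.coefficients[:, k1]
    b2 = fit2.coefficients[:, k2]
    if len(b1) != len(b2):
        raise ValueError("fits cover different numbers of units")
    baseline = np.asarray(baseline, dtype=float)

    crit = stats.norm.ppf(1.0 - alpha / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.abs(b1) / fit1.std_errors[:, k1]
        t2 = np.abs(b2) / fit2.std_errors[:, k2]
    keep = (t1 >= crit) & (t2 >= crit) & (np.abs(b1) > denom_eps)
    if not np.any(keep):
        raise EmptyCurveError("no units pass the two-period significance filter")
    ratio = b2[keep] / b1[keep]
    return RatioCurve(x=baseline[keep], y=ratio, n_excluded=int((~keep).sum()),
                      negative_ratio_units=int((ratio < 0).sum()), alpha=alpha)


def _linear_aicc(n: int, rss: float, k: int) -> float:
    if rss <= 0:
        return -np.inf
    if n - k - 2 <= 0:
        return np.inf
    return n * np.log(rss / n) + 2 * (k + 1) + 2 * (k + 1) * (k + 2) / (n - k - 2)


def fit_piecewise(x: np.ndarray, y: np.ndarray, max_breakpoints: int = 1,
                  quantile_window: tuple[float, float] = (0.05, 0.95)) -> PiecewiseFit:
    """Continuous 1- or 2-segment least-squares fit with AICc selection.

    The breakpoint is grid-searched over every distinct x value between the
    5th and 95th percentiles; for each candidate ``c`` the design
    ``[1, x − c, (x − c)₊]`` gives the continuous two-segment solution in
    closed form.  The two-segment model is retained only when its AICc
    beats the single line's; otherwise a single segment with no breakpoint
    is returned.

    Because the knot is profiled over the whole candidate grid, counting it
    as a single parameter underpenalizes the two-segment model and a pure
    line gets split routinely.  The knot is therefore charged three
    effective degrees of freedom (the free-knot convention of Friedman's
    MARS GCV), giving k = 6 for the two-segment model against k = 2 for the
    line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 10:
        raise InsufficientDataError(f"need at least 10 points, got {n}")
    if max_breakpoints not in (0, 1):
        raise ValueError("max_breakpoints must be 0 or 1")

    # single line
    A1 = np.column_stack([np.ones(n), x])
    coef1, *_ = np.linalg.lstsq(A1, y, rcond=None)
    rss1 = float(np.sum((y - A1 @ coef1) ** 2))
    aicc1 = _linear_aicc(n, rss1, k=2)

    # a numerically perfect line cannot be improved by a breakpoint; the
    # AICc comparison is meaningless at machine-zero residuals
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if rss1 <= 1e-20 * max(ss_tot, 1.0):
        max_breakpoints = 0

    lo, hi = np.quantile(x, quantile_window)
    candidates = np.unique(x[(x >= lo) & (x <= hi)])
    best = None
    if max_breakpoints == 1 and len(candidates) >= 1:
        for c in candidates:
            hinge = np.maximum(x - c, 0.0)
            A2 = np.column_stack([np.ones(n), x - c, hinge])
            coef2, *_ = np.linalg.lstsq(A2, y, rcond=None)
            rss2 = float(np.sum((y - A2 @ coef2) ** 2))
            if best is None or rss2 < best[0]:
                best = (rss2, float(c), coef2)
    if best is None:
        aicc2 = np.inf
    else:
        aicc2 = _linear_aicc(n, best[0], k=6)  # 1 intercept + 2 slopes + 3 dof for the free knot

    if best is not None and aicc2 < aicc1:
        rss2, c, (a, bl, db) = best
        slope_left, slope_right = float(bl), float(bl + db)
        # intercepts of the two rays in raw-x form
        int_left = float(a - bl * c)
        int_right = float(a - (bl + db) * c)
        return PiecewiseFit(breakpoint=c, slopes=(slope_left, slope_right),
                            intercepts=(int_left, int_right), aicc_one_segment=aicc1,
                            aicc_two_segment=aicc2, rss=rss2, n_points=n)
    return PiecewiseFit(breakpoint=None, slopes=(float(coef1[1]),),
                        intercepts=(float(coef1[0]),), aicc_one_segment=aicc1,
                        aicc_two_segment=aicc2, rss=rss1, n_points=n)


def classify_shape(fit: PiecewiseFit, flat_eps: float = 1e-3,
                   oblique_ratio: float = 0.25) -> str:
    """Shape label from the fitted segment slopes.

    Two segments: (−, +) → ``V``; (+, −) → ``inverted-V``; (−, −) with the
    second slope much shallower (|s₂| < ``oblique_ratio``·|s₁|) →
    ``oblique-L``; anything else two-segment → ``other``.  One segment:
    ``flat`` when |slope| < ``flat_eps``, else ``monotone``.
    """
    if fit.breakpoint is None:
        s = fit.slopes[0]
        return "flat" if abs(s) < flat_eps else "monotone"
    s1, s2 = fit.slopes
    if s1 < 0 <= s2 or (s1 < 0 and s2 > 0):
        return "V"
    if s1 > 0 > s2:
        return "inverted-V"
    if s1 < 0 and s2 < 0 and abs(s2) < oblique_ratio * abs(s1):
        return "oblique-L"
    return "other"
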