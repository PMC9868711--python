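"""Geographically weighted regression and its multiscale extension.

GWR fits a weighted least-squares regression at every observation location,
with weights decaying in distance according to a kernel:

    β(u_i, v_i) = (XᵀW_i X)⁻¹ XᵀW_i y

The Gaussian kernel ``w = exp(−0.5 (d/b)²)`` is the default; the bandwidth
``b`` is either a fixed distance or adaptive (the distance to the bw-th
nearest neighbour, so the kernel's reach follows the local point density).
Bandwidths are selected by minimizing the corrected Akaike criterion

    AICc = 2n·ln(σ̂) + n·ln(2π) + n·(n + tr(S)) / (n − 2 − tr(S))

where ``S`` is the hat matrix of the local fits and ``tr(S)`` the effective
number of parameters.

Multiscale GWR (MGWR) relaxes the single-bandwidth restriction: viewing the
model as a generalized additive model ``y = Σ_k f_k + ε`` with
``f_k = β_k(u, v)·x_k``, each additive term is calibrated with its *own*
bandwidth by backfitting — cycling through terms, refitting each on the
partial residual of the others with a freshly AICc-selected bandwidth, until
the sum-of-changes criterion

    SOC_f = Σ_k Σ_i (f̂_ik_new − f̂_ik_old)² / [n·Σ_i (Σ_k f̂_ik_new)²]

falls below tolerance.  A term whose selected bandwidth approaches the
sample size acts at the global scale (no spatial heterogeneity); small
bandwidths indicate local-scale effects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Literal

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import InvalidSpecError, SingularDesignError

__all__ = [
    "KernelSpec",
    "GWRFit",
    "MGWRFit",
    "kernel_weights",
    "gwr_fit",
    "select_bandwidth",
    "mgwr_fit",
    "soc_f",
    "report_scales",
]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and bandwidth for locally weighted fits.

    ``adaptive=True`` interprets ``bandwidth`` as a nearest-neighbour count
    (the convention when published bandwidths are unit counts); otherwise it
    is a fixed distance in coordinate units.
    """

    kind: Literal["gaussian", "bisquare"] = "gaussian"
    adaptive: bool = True
    bandwidth: float | int | None = None

    def validate(self) -> None:
        if self.kind not in ("gaussian", "bisquare"):
            raise InvalidSpecError(f"unknown kernel kind: {self.kind!r}")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise InvalidSpecError("bandwidth must be positive")


def kernel_weights(distances: np.ndarray, spec: KernelSpec,
                   n_units: int | None = None) -> np.ndarray:
    """Kernel weights for one calibration point given its distance vector.

    For an adaptive spec the local bandwidth distance is the ``bw``-th order
    statistic of ``distances`` (the calibration point itself, at distance 0,
    counts as the first).  Adaptive neighbour counts above the sample size
    are clamped to it.
    """
    spec.validate()
    if spec.bandwidth is None:
        raise InvalidSpecError("kernel spec has no bandwidth")
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise InvalidSpecError("distances must be nonnegative")
    if spec.adaptive:
        k = int(min(spec.bandwidth, len(d) if n_units is None else n_units))
        b = np.partition(d, k - 1)[k - 1]
        if b <= 0:
            b = np.min(d[d > 0]) if np.any(d > 0) else 1.0
    else:
        b = float(spec.bandwidth)
    if spec.kind == "gaussian":
        return np.exp(-0.5 * (d / b) ** 2)
    u = d / b
    w = np.where(u < 1, (1 - u ** 2) ** 2, 0.0)
    return w


def _weight_matrix(D: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Dense n×n kernel weight matrix; row i holds point i's weights."""
    if spec.adaptive:
        k = int(min(spec.bandwidth, D.shape[1]))
        b = np.partition(D, k - 1, axis=1)[:, k - 1][:, None]
        b[b <= 0] = np.min(D[D > 0]) if np.any(D > 0) else 1.0
    else:
        b = float(spec.bandwidth)
    if spec.kind == "gaussian":
        return np.exp(-0.5 * (D / b) ** 2)
    u = D / b
    return np.where(u < 1, (1 - u ** 2) ** 2, 0.0)


@dataclass(frozen=True)
class GWRFit:
    coefficients: np.ndarray      # n × (p+1), intercept first
    std_errors: np.ndarray        # n × (p+1)
    fitted: np.ndarray
    residuals: np.ndarray
    trace_S: float
    aicc: float
    r_squared: float
    adj_r_squared: float
    spec: KernelSpec


def _aicc_from(n: int, rss: float, tr_s: float) -> float:
    if n - 2.0 - tr_s <= 0 or rss <= 0:
        return math.inf
    sigma = math.sqrt(rss / n)
    return 2.0 * n * math.log(sigma) + n * math.log(2.0 * math.pi) \
        + n * (n + tr_s) / (n - 2.0 - tr_s)


def gwr_fit(X: np.ndarray, y: np.ndarray, coords: np.ndarray,
            spec: KernelSpec, add_intercept: bool = True,
            _Wmat: np.ndarray | None = None) -> GWRFit:
    """Calibrate GWR at every observation location with a single bandwidth."""
    spec.validate()
    if spec.bandwidth is None:
        raise InvalidSpecError("gwr_fit needs a bandwidth; use select_bandwidth first")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    design = np.column_stack([np.ones(n), X]) if add_intercept else X
    p = design.shape[1]
    Wmat = _Wmat if _Wmat is not None else _weight_matrix(
        cdist(coords, coords), spec)

    betas = np.empty((n, p))
    ses = np.empty((n, p))
    s_diag = np.empty(n)
    for i in range(n):
        w = Wmat[i]
        xw = design * w[:, None]
        xtx = design.T @ xw
        try:
            xtx_inv = np.linalg.inv(xtx)
        except np.linalg.LinAlgError as exc:
            raise SingularDesignError(
                f"singular local design at unit {i}; increase the bandwidth") from exc
        betas[i] = xtx_inv @ (xw.T @ y)
        # hat-matrix diagonal: row i of S is x_i (X'WX)^-1 X'W
        ci = design[i] @ xtx_inv
        s_diag[i] = float(ci @ (design[i] * w[i]))
        # local variance: (X'WX)^-1 X'W^2X (X'WX)^-1 (sigma^2 applied later)
        mid = (design * (w ** 2)[:, None]).T @ design
        ses[i] = np.sqrt(np.diag(xtx_inv @ mid @ xtx_inv))

    fitted = np.sum(design * betas, axis=1)
    resid = y - fitted
    rss = float(resid @ resid)
    tr_s = float(np.sum(s_diag))
    dof = max(n - tr_s, 1e-8)
    sigma2 = rss / dof
    ses *= math.sqrt(sigma2)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    adj = 1.0 - (1.0 - r2) * (n - 1) / dof if tss > 0 else np.nan
    return GWRFit(coefficients=betas, std_errors=ses, fitted=fitted, residuals=resid,
                  trace_S=tr_s, aicc=_aicc_from(n, rss, tr_s), r_squared=r2,
                  adj_r_squared=adj, spec=spec)


def _golden_section_int(lo: int, hi: int, f: Callable[[int], float]) -> tuple[int, dict[int, float]]:
    """Integer golden-section minimization with a final sweep of the bracket.

    Ties resolve to the smaller bandwidth.  Returns the argmin and the cache
    of evaluated points.
    """
    cache: dict[int, float] = {}

    def F(b: int) -> float:
        if b not in cache:
            cache[b] = f(b)
        return cache[b]

    phi = (math.sqrt(5.0) - 1.0) / 2.0
    a, c = lo, hi
    while c - a > 2:
        b1 = int(round(c - phi * (c - a)))
        b2 = int(round(a + phi * (c - a)))
        if b1 == b2:
            break
        if F(b1) <= F(b2):
            c = b2
        else:
            a = b1
    best = min(range(a, c + 1), key=F)
    return best, cache


def select_bandwidth(X: np.ndarray, y: np.ndarray, coords: np.ndarray,
                     spec: KernelSpec = KernelSpec(),
                     add_intercept: bool = True,
                     bracket: tuple[int, int] | None = None) -> int:
    """AICc-optimal adaptive bandwidth by golden-section search.

    Searches integer neighbour counts in ``[p+2, n]`` (or the given
    bracket).  If the AICc profile is not unimodal the search still returns
    the best point of its final bracket, with a warning when an endpoint of
    the initial bracket beats it.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p_cov = X.shape
    D = cdist(coords, coords)
    lo, hi = bracket if bracket is not None else (p_cov + 2 + (1 if add_intercept else 0), n)
    lo = max(2, lo)

    def objective(bw: int) -> float:
        s = replace(spec, bandwidth=bw)
        try:
            fit = gwr_fit(X, y, coords, s, add_intercept=add_intercept,
                          _Wmat=_weight_matrix(D, s))
        except SingularDesignError:
            return math.inf
        return fit.aicc

    best, cache = _golden_section_int(lo, hi, objective)
    for end in (lo, hi):
        if end in cache and cache[end] < cache[best] - 1e-9:
            warnings.warn("AICc profile appears non-unimodal; returning best of final bracket",
                          stacklevel=2)
    return best


# ---------------------------------------------------------------------------
# multiscale calibration


def soc_f(f_new: np.ndarray, f_old: np.ndarray) -> float:
    """Sum-of-changes convergence criterion over additive terms.

    Both arguments are n × (terms) matrices of additive-term values.
    """
    f_new = np.asarray(f_new, dtype=float)
    f_old = np.asarray(f_old, dtype=float)
    if f_new.shape != f_old.shape:
        raise InvalidSpecError("f_new and f_old must have matching shapes")
    n = f_new.shape[0]
    denom = n * float(np.sum(np.sum(f_new, axis=1) ** 2))
    if denom == 0:
        raise InvalidSpecError("degenerate fit: all additive terms are zero")
    return float(np.sum((f_new - f_old) ** 2)) / denom


def _univariate_smooth(xk: np.ndarray, e: np.ndarray, Wmat: np.ndarray,
                       want_hat: bool) -> tuple[np.ndarray, float, np.ndarray | None, np.ndarray]:
    """Local univariate WLS of partial residual ``e`` on one term column.

    Returns (beta, trace, hat matrix or None, se_denominators).  All rows of
    the smoother ``S_ij = x_i w_ij x_j / Σ_j w_ij x_j²`` follow from the
    closed-form univariate weighted least squares solution.
    """
    num = Wmat @ (xk * e)
    den = Wmat @ (xk * xk)
    beta = num / den
    trace = float(np.sum(np.diag(Wmat) * xk * xk / den))
    hat = None
    if want_hat:
        hat = (xk[:, None] * Wmat * xk[None, :]) / den[:, None]
    return beta, trace, hat, den


@dataclass(frozen=True)
class MGWRFit:
    bandwidths: np.ndarray        # per term, intercept first
    coefficients: np.ndarray      # n × (p+1) local coefficient surfaces
    std_errors: np.ndarray        # n × (p+1), from the final per-term smooths
    terms: np.ndarray             # n × (p+1) additive terms f_k
    fitted: np.ndarray
    residuals: np.ndarray
    iterations: int
    final_soc: float
    converged: bool
    aicc: float
    enp: np.ndarray               # per-term effective parameters (NaN if untracked)
    r_squared: float
    adj_r_squared: float
    soc_trace: list[float] = field(default_factory=list)
    term_names: list[str] = field(default_factory=list)
    # standardization applied internally (identity scalings if standardize=False)
    x_means: np.ndarray | None = None
    x_sds: np.ndarray | None = None
    y_mean: float = 0.0
    y_sd: float = 1.0

    def raw_coefficients(self) -> np.ndarray:
        """Back-transform local coefficients to the original data units.

        Slope surfaces scale by ``sd_y / sd_xk``; the intercept surface
        absorbs the means.
        """
        if self.x_means is None or self.x_sds is None:
            return self.coefficients.copy()
        out = np.empty_like(self.coefficients)
        slopes = self.coefficients[:, 1:] * (self.y_sd / self.x_sds)
        out[:, 1:] = slopes
        out[:, 0] = self.y_mean + self.y_sd * self.coefficients[:, 0] \
            - slopes @ self.x_means
        return out


def mgwr_fit(X: np.ndarray, y: np.ndarray, coords: np.ndarray,
             tolerance: float = 1e-5, max_iterations: int = 200,
             spec: KernelSpec = KernelSpec(),
             bandwidths: np.ndarray | None = None,
             standardize: bool = True,
             hat_matrix: bool = True,
             term_names: list[str] | None = None) -> MGWRFit:
    """Calibrate multiscale GWR by backfitting with per-term bandwidths.

    The initial additive terms come from a single-bandwidth GWR fit at the
    AICc-optimal bandwidth.  Each backfitting sweep re-selects every term's
    bandwidth on its current partial residual; passing ``bandwidths``
    disables selection and holds the given per-term values fixed (with all
    terms equal this reproduces plain GWR at that bandwidth).

    ``standardize=True`` (the default, matching common MGWR software
    practice) z-scores X and y so coefficients are in standardized units.
    ``hat_matrix=False`` skips the per-term smoother-matrix recursion that
    yields ENP_k and AICc — bandwidths, coefficients and fit quality are
    unaffected and large problems calibrate faster.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p_cov = X.shape
    if standardize:
        x_means, x_sds = X.mean(axis=0), X.std(axis=0)
        X = (X - x_means) / x_sds
        y_mean, y_sd = float(y.mean()), float(y.std())
        y = (y - y_mean) / y_sd
    else:
        x_means, x_sds = np.zeros(p_cov), np.ones(p_cov)
        y_mean, y_sd = 0.0, 1.0
    design = np.column_stack([np.ones(n), X])
    p = design.shape[1]
    if term_names is None:
        term_names = ["intercept"] + [f"x{k}" for k in range(p_cov)]

    D = cdist(coords, coords)
    wmat_cache: dict[float, np.ndarray] = {}

    def get_wmat(bw: float) -> np.ndarray:
        key = float(bw)
        if key not in wmat_cache:
            if len(wmat_cache) > 60:      # bound the kernel cache
                wmat_cache.pop(next(iter(wmat_cache)))
            wmat_cache[key] = _weight_matrix(D, replace(spec, bandwidth=bw))
        return wmat_cache[key]

    fixed = bandwidths is not None
    if fixed:
        bws = np.asarray(bandwidths, dtype=float)
        if len(bws) != p:
            raise InvalidSpecError(f"need {p} bandwidths (intercept first), got {len(bws)}")
    else:
        bws = np.empty(p)

    # --- initialization from a single-bandwidth GWR fit
    if fixed:
        init_bw = bws[0]
    else:
        init_bw = select_bandwidth(X, y, coords, spec)
        bws[:] = init_bw
    init = gwr_fit(X, y, coords, replace(spec, bandwidth=init_bw),
                   _Wmat=get_wmat(init_bw))
    betas = init.coefficients.copy()
    f = design * betas                     # n × p additive terms

    # per-term smoother matrices for ENP/AICc (A_k maps y -> f_k)
    track = hat_matrix
    A = [None] * p
    if track:
        # seed from the initial fit's local projections is not needed for
        # correctness: the recursion below converges with backfitting itself.
        A = [np.zeros((n, n)) for _ in range(p)]

    se_parts = np.empty((n, p))
    sweep_lo = 2
    converged = False
    soc_trace: list[float] = []
    it = 0
    for it in range(1, max_iterations + 1):
        f_old = f.copy()
        for k in range(p):
            e_k = y - (f.sum(axis=1) - f[:, k])
            xk = design[:, k]
            if not fixed:
                def obj(bw: int, _xk=xk, _e=e_k) -> float:
                    Wm = get_wmat(bw)
                    beta_b, tr_b, _, _ = _univariate_smooth(_xk, _e, Wm, False)
                    rss = float(np.sum((_e - _xk * beta_b) ** 2))
                    return _aicc_from(n, rss, tr_b)
                bws[k], _ = _golden_section_int(max(sweep_lo, 3), n, obj)
            Wm = get_wmat(bws[k])
            beta_k, _, S_k, den = _univariate_smooth(xk, e_k, Wm, track)
            betas[:, k] = beta_k
            f[:, k] = xk * beta_k
            se_parts[:, k] = np.sqrt((Wm ** 2 @ (xk * xk)) / den ** 2)
            if track:
                other = np.zeros((n, n))
                for j in range(p):
                    if j != k:
                        other += A[j]
                A[k] = S_k @ (np.eye(n) - other)
        soc = soc_f(f, f_old)
        soc_trace.append(soc)
        if soc <= tolerance:
            converged = True
            break

    fitted = f.sum(axis=1)
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan

    if track:
        enp = np.array([float(np.trace(Ak)) for Ak in A])
        tr_s = float(enp.sum())
        aicc = _aicc_from(n, rss, tr_s)
        dof = max(n - tr_s, 1e-8)
    else:
        enp = np.full(p, np.nan)
        aicc = np.nan
        dof = max(n - p, 1e-8)
    adj = 1.0 - (1.0 - r2) * (n - 1) / dof if tss > 0 else np.nan
    sigma2 = rss / dof
    ses = se_parts * math.sqrt(sigma2)

    if not converged:
        warnings.warn(f"backfitting did not converge in {max_iterations} iterations "
                      f"(final SOC_f {soc_trace[-1]:.3g})", stacklevel=2)
    return MGWRFit(bandwidths=bws.copy(), coefficients=betas, std_errors=ses,
                   terms=f, fitted=fitted, residuals=resid, iterations=it,
                   final_soc=soc_trace[-1] if soc_trace else np.nan,
                   converged=converged, aicc=aicc, enp=enp, r_squared=r2,
                   adj_r_squared=adj, soc_trace=soc_trace, term_names=list(term_names),
                   x_means=x_means, x_sds=x_sds, y_mean=y_mean, y_sd=y_sd)


def report_scales(bandwidths: np.ndarray, n: int, global_fraction: float = 0.95) -> list[str]:
    """Label each term's bandwidth as acting at the global or local scale.

    A bandwidth at or above ``global_fraction·n`` neighbours means the
    kernel reaches essentially the whole study area — no spatial
    heterogeneity in that term's effect.  Published bandwidths of n+1 are
    read as "≥ n".
    """
    bws = np.minimum(np.asarray(bandwidths, dtype=float), n)
    return ["global" if bw >= global_fraction * n else "local" for bw in bws]
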