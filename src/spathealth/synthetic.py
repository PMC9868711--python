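"""Seeded synthetic county panels, demographic schedules and allocations.

The real study data (county panels built from censuses and health
yearbooks) are not publicly deposited, so every downstream stage is
exercised on synthetic inputs that reproduce the statistical structure the
methods assume:

* a regular lattice of spatial units with planar coordinates;
* spatially autocorrelated covariates (simultaneous-autoregressive
  smoothing of white noise with lattice rook weights);
* spatially varying coefficient surfaces at distinct scales — constant
  (global), gradient (broad), hotspot (local) — the ground truth for
  multiscale-recovery tests;
* Gompertz–Makeham adult mortality with a separate infant component,
  yielding the exposure/death schedules life tables consume;
* population-weighted Dirichlet resource allocations whose concentration
  parameter dials inequality from extreme to perfectly per-capita equal;
* two-period coefficient sets with a planted piecewise-linear relation
  between the coefficient ratio and baseline health, for breakpoint
  recovery.

Every generator is a pure function of its spec (seed included): the same
spec replays identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.linalg import spsolve
from scipy import sparse

from .exceptions import DimensionError, InvalidSpecError
from .lifetable import AgeSchedule
from .spatial import lattice_rook_weights

__all__ = [
    "LatticeSpec",
    "SurfaceScenario",
    "MortalityScheduleSpec",
    "AllocationSpec",
    "gen_lattice",
    "gen_coefficient_surface",
    "gen_covariates",
    "gen_outcome",
    "gen_demography",
    "gen_allocation",
    "gen_two_period_panel",
    "make_multiscale_panel",
]


@dataclass(frozen=True)
class LatticeSpec:
    side_count: int
    spacing: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.side_count < 2:
            raise InvalidSpecError("side_count must be ≥ 2")
        if self.spacing <= 0:
            raise InvalidSpecError("spacing must be positive")


@dataclass(frozen=True)
class SurfaceScenario:
    """Ground-truth coefficient surface: constant, gradient or hotspot."""

    kind: Literal["constant", "gradient", "hotspot"]
    amplitude: float = 1.0
    scale_parameter: float = 1.0     # hotspot radius, or gradient span (unused: full extent)


@dataclass(frozen=True)
class MortalityScheduleSpec:
    """Gompertz–Makeham hazard ``a + b·exp(c·age)`` plus an infant rate."""

    infant_rate: float = 0.03
    makeham_a: float = 5e-4
    gompertz_b: float = 3e-5
    gompertz_c: float = 0.095
    interval_edges: Sequence[int] = field(default_factory=lambda: (0, 1, 5, 10, 15, 20, 25,
                                                                   30, 35, 40, 45, 50, 55,
                                                                   60, 65, 70, 75, 80, 85))
    population_base: int = 100_000
    seed: int = 0

    def validate(self) -> None:
        if len(self.interval_edges) == 0:
            raise InvalidSpecError("interval_edges must be non-empty")
        edges = np.asarray(self.interval_edges)
        if edges[0] != 0:
            raise InvalidSpecError("interval_edges must start at 0")
        if np.any(np.diff(edges) <= 0):
            raise InvalidSpecError("interval_edges must be strictly increasing")
        if not (0 <= self.infant_rate < 1):
            raise InvalidSpecError("infant_rate must lie in [0, 1)")
        if min(self.makeham_a, self.gompertz_b, self.gompertz_c) <= 0:
            raise InvalidSpecError("hazard parameters must be positive")


@dataclass(frozen=True)
class AllocationSpec:
    """Dirichlet allocation around population shares.

    ``concentration`` scales the Dirichlet parameters ``α_j ∝ W_j``;
    small values concentrate the resource in few units, the ∞ limit gives
    exactly population-proportional (equal per-capita) shares.
    """

    concentration: float = 1.0
    total_resource: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.concentration < 0:
            raise InvalidSpecError("concentration must be ≥ 0")
        if self.total_resource <= 0:
            raise InvalidSpecError("total_resource must be positive")


def gen_lattice(spec: LatticeSpec) -> pd.DataFrame:
    """Regular ``side × side`` grid of units (row-major), columns unit_id, u, v."""
    spec.validate()
    s = spec.side_count
    r, c = np.divmod(np.arange(s * s), s)
    return pd.DataFrame({"unit_id": [f"u{i:04d}" for i in range(s * s)],
                         "u": r * spec.spacing, "v": c * spec.spacing})


def gen_coefficient_surface(coords: np.ndarray, scenario: SurfaceScenario) -> np.ndarray:
    """Evaluate a ground-truth coefficient surface at unit coordinates.

    * constant — every unit gets ``amplitude``;
    * gradient — linear in ``u + v``, rescaled to span ``[0, amplitude]``;
    * hotspot — ``amplitude`` inside a circle of radius ``scale_parameter``
      around the domain centre, 0 outside.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) == 0:
        raise InvalidSpecError("coords must be non-empty")
    if scenario.kind == "constant":
        return np.full(len(coords), float(scenario.amplitude))
    if scenario.kind == "gradient":
        t = coords[:, 0] + coords[:, 1]
        span = t.max() - t.min()
        if span == 0:
            return np.full(len(coords), float(scenario.amplitude))
        return scenario.amplitude * (t - t.min()) / span
    if scenario.kind == "hotspot":
        centre = coords.mean(axis=0)
        r = np.hypot(*(coords - centre).T)
        return np.where(r <= scenario.scale_parameter, float(scenario.amplitude), 0.0)
    raise InvalidSpecError(f"unknown surface kind: {scenario.kind!r}")


def gen_covariates(coords: np.ndarray, n_covariates: int, spatial_rho: float,
                   seed: int = 0) -> np.ndarray:
    """Standardized covariate columns with optional spatial autocorrelation.

    ``spatial_rho = 0`` gives i.i.d. Gaussian columns; ``spatial_rho > 0``
    applies the simultaneous-autoregressive filter ``(I − ρW)⁻¹`` to white
    noise, with W the row-standardized rook weights of the implied lattice.
    Columns are z-scored afterwards.
    """
    if not (0 <= spatial_rho < 1):
        raise InvalidSpecError("spatial_rho must lie in [0, 1)")
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    rng = np.random.default_rng(seed)
    E = rng.standard_normal((n, n_covariates))
    if spatial_rho > 0:
        side = int(round(np.sqrt(n)))
        if side * side != n:
            raise InvalidSpecError("SAR smoothing requires a square lattice of units")
        W = lattice_rook_weights(side, "row").matrix
        A = (sparse.eye(n) - spatial_rho * W).tocsc()
        E = np.column_stack([spsolve(A, E[:, k]) for k in range(n_covariates)])
    E = E - E.mean(axis=0)
    E = E / E.std(axis=0)
    return E


def gen_outcome(X: np.ndarray, surfaces: np.ndarray, noise_sd: float,
                seed: int = 0) -> np.ndarray:
    """Outcome ``y_i = β_0(u_i,v_i) + Σ_k β_k(u_i,v_i)·X_ik + ε_i``.

    ``surfaces`` is n × (p+1) with the intercept surface first.
    """
    X = np.asarray(X, dtype=float)
    surfaces = np.asarray(surfaces, dtype=float)
    n, p = X.shape
    if surfaces.shape != (n, p + 1):
        raise DimensionError(f"surfaces must be {n}×{p + 1} (intercept first), "
                             f"got {surfaces.shape}")
    design = np.column_stack([np.ones(n), X])
    y = np.sum(design * surfaces, axis=1)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, n)
    return y


def gen_demography(spec: MortalityScheduleSpec, stochastic: bool = False) -> AgeSchedule:
    """Exposure/death schedule from the hazard model.

    The interval hazard is the Gompertz–Makeham hazard at the interval
    midpoint (the open terminal interval uses its start age + 5); the age-0
    interval uses ``infant_rate`` directly.  Deterministic mode (default)
    sets deaths to their expectation ``P_x·m_x`` so life-table recurrences
    can be checked exactly; stochastic mode draws binomial deaths.
    """
    spec.validate()
    edges = np.asarray(spec.interval_edges, dtype=float)
    k = len(edges)
    widths = np.append(np.diff(edges), np.nan)
    mids = np.where(np.isnan(widths), edges + 5.0, edges + widths / 2.0)
    m = spec.makeham_a + spec.gompertz_b * np.exp(spec.gompertz_c * mids)
    m[0] = spec.infant_rate
    m = np.minimum(m, 0.99)

    P = np.full(k, float(spec.population_base))
    if stochastic:
        rng = np.random.default_rng(spec.seed)
        D = rng.binomial(P.astype(int), m).astype(float)
    else:
        D = P * m
    return AgeSchedule(edges, P, D)


def gen_allocation(populations: np.ndarray, spec: AllocationSpec) -> np.ndarray:
    """Per-unit resource totals Y_j summing to ``total_resource``.

    Shares are Dirichlet with parameters ``concentration · n · W_j/ΣW``;
    the high-concentration limit returns exactly population-proportional
    shares (per-capita equality, Gini 0).
    """
    spec.validate()
    W = np.asarray(populations, dtype=float)
    if np.any(W <= 0):
        raise InvalidSpecError("populations must be positive")
    shares = W / W.sum()
    if spec.concentration >= 1e8:
        return spec.total_resource * shares
    rng = np.random.default_rng(spec.seed)
    alpha = np.maximum(spec.concentration * len(W) * shares, 1e-12)
    draw = rng.dirichlet(alpha)
    return spec.total_resource * draw


def gen_two_period_panel(breakpoint_x: float, slopes_left_right: tuple[float, float],
                         noise_sd: float = 0.05, n: int = 500, seed: int = 0,
                         baseline_range: tuple[float, float] = (55.0, 85.0),
                         ratio_at_break: float = 1.0,
                         beta1_value: float = 1.0) -> pd.DataFrame:
    """Two-period local coefficients with a planted ratio-vs-baseline law.

    Baseline health values are uniform over ``baseline_range``; the
    coefficient ratio ``β₂/β₁`` follows the continuous piecewise-linear
    form with the given breakpoint and segment slopes, plus Gaussian noise.
    Returns a frame with columns baseline, beta1, beta2, ratio_true.
    """
    sl, sr = slopes_left_right
    if not (np.isfinite(sl) and np.isfinite(sr)):
        raise InvalidSpecError("segment slopes must be finite")
    rng = np.random.default_rng(seed)
    x = rng.uniform(*baseline_range, n)
    ratio = ratio_at_break + np.where(x < breakpoint_x,
                                      sl * (x - breakpoint_x),
                                      sr * (x - breakpoint_x))
    obs = ratio + (rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0)
    beta1 = np.full(n, float(beta1_value))
    return pd.DataFrame({"baseline": x, "beta1": beta1, "beta2": obs * beta1,
                         "ratio_true": ratio})


def make_multiscale_panel(side: int = 24, noise_sd: float = 0.5, seed: int = 0,
                          spatial_rho: float = 0.0,
                          amplitudes: tuple[float, float, float, float] = (1.0, 2.0, 2.0, 2.0),
                          hotspot_radius: float | None = None,
                          ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray]:
    """Convenience bundle: lattice + 3 covariates + multiscale outcome.

    True coefficient surfaces are (intercept constant, constant, gradient,
    hotspot) — three distinct spatial scales.  Returns
    (panel frame, coords, X, true surface matrix).
    """
    lat = gen_lattice(LatticeSpec(side_count=side, seed=seed))
    coords = lat[["u", "v"]].to_numpy()
    if hotspot_radius is None:
        hotspot_radius = side / 4.0
    rng = np.random.default_rng(seed)
    X = gen_covariates(coords, 3, spatial_rho, seed=int(rng.integers(2 ** 31)))
    surfaces = np.column_stack([
        gen_coefficient_surface(coords, SurfaceScenario("constant", amplitudes[0])),
        gen_coefficient_surface(coords, SurfaceScenario("constant", amplitudes[1])),
        gen_coefficient_surface(coords, SurfaceScenario("gradient", amplitudes[2])),
        gen_coefficient_surface(coords, SurfaceScenario("hotspot", amplitudes[3],
                                                        hotspot_radius)),
    ])
    y = gen_outcome(X, surfaces, noise_sd, seed=int(rng.integers(2 ** 31)))
    panel = lat.assign(year=2000, life_expectancy=y,
                       **{f"x{k}": X[:, k] for k in range(3)})
    return panel, coords, X, surfaces
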