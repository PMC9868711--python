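"""Lorenz curves and the direct-method Gini coefficient for resource equity.

Measures how evenly a health resource (facilities, technicians, beds) is
allocated across spatial units relative to their populations.  Units are
ranked by per-capita resources; the Gini coefficient is computed both by the
direct summation formula

    G = −1 + Σ_j (W_j/W)(Y_j/Y) + 2 Σ_{j=1}^{n−1} (W_j/W)(1 − V_j)

(with ``W_j`` population, ``Y_j`` resources and ``V_j`` the cumulative
resource share) and, as an independent cross-check, by trapezoid integration
of the Lorenz curve, ``G = 1 − 2·(area under the curve)``.  The two agree
algebraically; both are exposed so either can audit the other.

The classification scale follows the conventional equity bands with 0.4 as
the equitable/inequitable alert threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidTableError, UndefinedGiniError

__all__ = [
    "AllocationTable",
    "GiniResult",
    "gini_direct",
    "gini_trapezoid",
    "classify_gini",
]

_CLASS_BANDS = [
    (0.2, "absolute average"),
    (0.3, "relatively average"),
    (0.4, "reasonable"),
    (0.5, "large gap"),
    (float("inf"), "wide gap"),
]


@dataclass(frozen=True)
class AllocationTable:
    """Per-unit populations ``W_j`` and resource quantities ``Y_j``."""

    populations: np.ndarray
    resources: np.ndarray
    unit_ids: np.ndarray | None = None

    def __init__(self, populations, resources, unit_ids=None):
        W = np.asarray(populations, dtype=float)
        Y = np.asarray(resources, dtype=float)
        if W.shape != Y.shape or W.ndim != 1:
            raise InvalidTableError("populations and resources must be equal-length 1-D arrays")
        if np.any(W <= 0):
            raise InvalidTableError("populations must be positive")
        if np.any(Y < 0):
            raise InvalidTableError("resources must be nonnegative")
        ids = np.arange(len(W)) if unit_ids is None else np.asarray(unit_ids)
        object.__setattr__(self, "populations", W)
        object.__setattr__(self, "resources", Y)
        object.__setattr__(self, "unit_ids", ids)

    def sorted_shares(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Population shares, resource shares and cumulative resource
        shares ``V_j``, sorted ascending by per-capita resources.

        Ties in per-capita resources are broken by unit id so the ordering
        (and hence the Lorenz curve) is deterministic.
        """
        if self.resources.sum() <= 0:
            raise UndefinedGiniError("all resources are zero; Gini undefined")
        per_capita = self.resources / self.populations
        order = np.lexsort((self.unit_ids, per_capita))
        p = self.populations[order] / self.populations.sum()
        y = self.resources[order] / self.resources.sum()
        return p, y, np.cumsum(y)


@dataclass(frozen=True)
class GiniResult:
    G: float
    classification: str
    equitable: bool
    lorenz_points: np.ndarray   # (n+1, 2): cumulative population vs resource share


def _lorenz_points(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    pts = np.zeros((len(p) + 1, 2))
    pts[1:, 0] = np.cumsum(p)
    pts[1:, 1] = np.cumsum(y)
    pts[-1] = (1.0, 1.0)  # clamp float drift at the endpoint
    return pts


def gini_direct(table: AllocationTable) -> GiniResult:
    """Gini coefficient by the direct summation formula."""
    p, y, V = table.sorted_shares()
    G = -1.0 + float(np.dot(p, y)) + 2.0 * float(np.dot(p[:-1], 1.0 - V[:-1]))
    G = max(G, 0.0)
    label = classify_gini(G)
    return GiniResult(G=G, classification=label, equitable=G < 0.4,
                      lorenz_points=_lorenz_points(p, y))


def gini_trapezoid(table: AllocationTable) -> float:
    """Gini coefficient by trapezoid integration of the Lorenz curve.

    Independent of :func:`gini_direct` beyond the shared sort; kept as a
    cross-check oracle.
    """
    p, y, V = table.sorted_shares()
    V0 = np.concatenate(([0.0], V[:-1]))
    area = float(np.dot(p, (V0 + V) / 2.0))
    return max(1.0 - 2.0 * area, 0.0)


def classify_gini(G: float) -> str:
    """Equity band of a Gini value; boundaries belong to the upper band."""
    if not (0.0 <= G < 1.0):
        raise ValueError(f"Gini coefficient must lie in [0, 1): got {G!r}")
    for upper, label in _CLASS_BANDS:
        if G < upper:
            return label
    raise AssertionError("unreachable")
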