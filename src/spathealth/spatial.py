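"""Spatial weights and Moran autocorrelation statistics.

Provides first-order contiguity / nearest-neighbour / distance-band weight
matrices over point coordinates, the global Moran's I statistic

    I = (n / S0) · Σ_i Σ_j w_ij (x_i − x̄)(x_j − x̄) / Σ_i (x_i − x̄)²

with permutation inference, and the local (Anselin) Moran statistic

    I_i = ((x_i − x̄) / s²) · Σ_j w_ij (x_j − x̄),   s² = Σ(x_i − x̄)²/n

with conditional-permutation pseudo p-values and HH/LL/HL/LH cluster
labelling.  When weights are row-standardized S0 = n, so the leading factor
drops out of the global statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .exceptions import InvalidSpecError, ZeroVarianceError

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "LISAResult",
    "build_weights",
    "lattice_rook_weights",
    "global_moran",
    "local_moran",
]


@dataclass(frozen=True)
class SpatialWeights:
    """Sparse spatial weight matrix with its standardization state."""

    matrix: sparse.csr_matrix           # n × n, zero diagonal
    standardization: Literal["binary", "row"]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def total_weight(self) -> float:
        return float(self.matrix.sum())

    def neighbors(self, i: int) -> np.ndarray:
        return self.matrix.indices[self.matrix.indptr[i]:self.matrix.indptr[i + 1]]

    def lag(self, x: np.ndarray) -> np.ndarray:
        """Spatial lag W·x."""
        return self.matrix @ np.asarray(x, dtype=float)

    def to_edge_frame(self) -> pd.DataFrame:
        coo = self.matrix.tocoo()
        return pd.DataFrame({"i": coo.row, "j": coo.col, "w": coo.data})


def _row_standardize(A: sparse.csr_matrix) -> sparse.csr_matrix:
    rs = np.asarray(A.sum(axis=1)).ravel()
    inv = np.divide(1.0, rs, out=np.zeros_like(rs), where=rs > 0)
    return sparse.diags(inv) @ A


def lattice_rook_weights(side: int, standardization: str = "row") -> SpatialWeights:
    """Rook contiguity on a ``side × side`` regular lattice (row-major order)."""
    n = side * side
    rows, cols = [], []
    for r in range(side):
        for c in range(side):
            i = r * side + c
            if c + 1 < side:
                rows += [i, i + 1]; cols += [i + 1, i]
            if r + 1 < side:
                j = i + side
                rows += [i, j]; cols += [j, i]
    A = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    if standardization == "row":
        A = _row_standardize(A).tocsr()
    return SpatialWeights(matrix=A, standardization=standardization)  # type: ignore[arg-type]


def build_weights(coords: np.ndarray,
                  method: Literal["rook", "knn", "distance_band"] = "rook",
                  k_or_threshold: float | int | None = None,
                  standardization: Literal["binary", "row"] = "row") -> SpatialWeights:
    """Build spatial weights from planar point coordinates.

    ``rook`` links each point to the points exactly one grid step away
    (the minimum positive inter-point distance), which reproduces rook
    contiguity on a regular lattice.  ``knn`` links to the ``k`` nearest
    neighbours and symmetrizes the graph.  ``distance_band`` links all
    pairs within the threshold distance; isolated points get empty rows.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        raise InvalidSpecError("need at least 2 units to build weights")
    if standardization not in ("binary", "row"):
        raise InvalidSpecError(f"unknown standardization: {standardization!r}")

    tree = cKDTree(coords)
    if method == "rook":
        d, _ = tree.query(coords, k=2)
        step = float(np.min(d[:, 1]))
        pairs = tree.query_pairs(step * (1 + 1e-9), output_type="ndarray")
    elif method == "knn":
        if k_or_threshold is None:
            raise InvalidSpecError("knn weights require k")
        k = int(k_or_threshold)
        if not (1 <= k < n):
            raise InvalidSpecError("k must satisfy 1 <= k < n")
        _, idx = tree.query(coords, k=k + 1)
        src = np.repeat(np.arange(n), k)
        dst = idx[:, 1:].ravel()
        pairs = np.column_stack([src, dst])
    elif method == "distance_band":
        if k_or_threshold is None:
            raise InvalidSpecError("distance_band weights require a threshold")
        pairs = tree.query_pairs(float(k_or_threshold), output_type="ndarray")
    else:
        raise InvalidSpecError(f"unknown weights method: {method!r}")

    if len(pairs) == 0:
        A = sparse.csr_matrix((n, n))
    else:
        if method == "knn":
            rows = np.concatenate([pairs[:, 0], pairs[:, 1]])  # symmetrize
            cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
        else:
            rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
            cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
        A = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        A.data[:] = 1.0  # collapse duplicate edges from symmetrization
        A.setdiag(0.0)
        A.eliminate_zeros()
    if method == "distance_band":
        rs = np.asarray(A.sum(axis=1)).ravel()
        if np.any(rs == 0):
            import warnings
            warnings.warn(f"{int((rs == 0).sum())} isolated unit(s) under distance_band; "
                          "their weight rows are empty", stacklevel=2)
    if standardization == "row":
        A = _row_standardize(A).tocsr()
    return SpatialWeights(matrix=A.tocsr(), standardization=standardization)


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected_I: float
    pseudo_p: float
    z_score: float
    n_permutations: int
    seed: int
    alternative: str


def _moran_stat(z: np.ndarray, W: SpatialWeights, szz: float) -> float:
    scale = 1.0 if W.standardization == "row" else W.n / W.total_weight
    return scale * float(z @ W.lag(z)) / szz


def global_moran(x: np.ndarray, W: SpatialWeights, n_permutations: int = 999,
                 seed: int = 0, alternative: str = "two-sided") -> MoranResult:
    """Global Moran's I with a random-relabelling permutation null."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n != W.n:
        raise InvalidSpecError("x length does not match weights")
    z = x - x.mean()
    szz = float(z @ z)
    if szz == 0:
        raise ZeroVarianceError("Moran's I undefined for constant x")
    I = _moran_stat(z, W, szz)

    rng = np.random.default_rng(seed)
    perm_I = np.empty(n_permutations)
    for b in range(n_permutations):
        perm_I[b] = _moran_stat(rng.permutation(z), W, szz)
    if alternative == "two-sided":
        extreme = np.abs(perm_I - perm_I.mean()) >= abs(I - perm_I.mean())
    elif alternative == "greater":
        extreme = perm_I >= I
    elif alternative == "less":
        extreme = perm_I <= I
    else:
        raise InvalidSpecError(f"unknown alternative: {alternative!r}")
    p = (int(extreme.sum()) + 1) / (n_permutations + 1)
    sd = perm_I.std(ddof=1)
    z_score = (I - perm_I.mean()) / sd if sd > 0 else np.nan
    return MoranResult(I=I, expected_I=-1.0 / (n - 1), pseudo_p=float(p),
                       z_score=float(z_score), n_permutations=n_permutations,
                       seed=seed, alternative=alternative)


@dataclass(frozen=True)
class LISAResult:
    I_local: np.ndarray
    quadrant: np.ndarray        # "HH", "LL", "HL", "LH", "NS"
    pseudo_p: np.ndarray
    s2: float
    alpha: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"I_local": self.I_local, "quadrant": self.quadrant,
                             "pseudo_p": self.pseudo_p})


def local_moran(x: np.ndarray, W: SpatialWeights, n_permutations: int = 999,
                seed: int = 0, alpha: float = 0.05) -> LISAResult:
    """Local Moran (LISA) with conditional permutation.

    For each unit its own value is held fixed while neighbour values are
    drawn without replacement from the remaining n−1 observations; the
    pseudo p-value is two-sided around the permutation mean.  Quadrants are
    assigned from the signs of the deviation and its spatial lag; units with
    pseudo p above ``alpha`` are labelled NS.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n != W.n:
        raise InvalidSpecError("x length does not match weights")
    z = x - x.mean()
    s2 = float(z @ z) / n
    if s2 == 0:
        raise ZeroVarianceError("local Moran undefined for constant x")

    lag = W.lag(z)
    I_loc = z / s2 * lag

    rng = np.random.default_rng(seed)
    p_vals = np.ones(n)
    A = W.matrix
    for i in range(n):
        nbrs = A.indices[A.indptr[i]:A.indptr[i + 1]]
        wts = A.data[A.indptr[i]:A.indptr[i + 1]]
        ki = len(nbrs)
        if ki == 0:
            continue
        others = np.delete(z, i)
        # sample ki neighbour values without replacement per permutation
        draw_idx = rng.random((n_permutations, n - 1)).argpartition(ki - 1, axis=1)[:, :ki]
        sim_lag = others[draw_idx] @ wts
        sim_I = z[i] / s2 * sim_lag
        extreme = np.abs(sim_I - sim_I.mean()) >= abs(I_loc[i] - sim_I.mean())
        p_vals[i] = (int(extreme.sum()) + 1) / (n_permutations + 1)

    quad = np.full(n, "NS", dtype=object)
    sig = p_vals <= alpha
    hi = z > 0
    lag_hi = lag > 0
    quad[sig & hi & lag_hi] = "HH"
    quad[sig & ~hi & ~lag_hi] = "LL"
    quad[sig & hi & ~lag_hi] = "HL"
    quad[sig & ~hi & lag_hi] = "LH"
    return LISAResult(I_local=I_loc, quadrant=quad.astype(str), pseudo_p=p_vals,
                      s2=s2, alpha=alpha, seed=seed)
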