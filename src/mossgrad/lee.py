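"""Lee's L bivariate spatial association on a lattice, with Monte Carlo
significance for the local statistic.

Lee's L blends Pearson correlation with spatial smoothing through a
weights matrix W.  With mean-deviations ``zx = x - mean(x)`` and spatial
lags ``x~_i = sum_j w_ij zx_j`` (same for y):

    L(x, y) = n / sum_i (sum_j w_ij)^2
              * sum_i x~_i y~_i / sqrt(sum zx^2) / sqrt(sum zy^2)

and the local decomposition

    L_i(x, y) = n * x~_i * y~_i / sqrt(sum zx^2) / sqrt(sum zy^2),
    L = sum_i L_i / sum_i (sum_j w_ij)^2.

With identity weights the spatial lag is the observation itself and L
collapses to the Pearson correlation of the two maps; the statistic is
symmetric in (x, y) and invariant to affine rescaling of either map.

Significance of the local values uses a Monte Carlo test in which the
paired observations (x_i, y_i) are jointly permuted across pixels: the
aspatial correlation of the two maps is preserved while the spatial
arrangement is destroyed.  A pixel is classified Positive when its
observed local value ranks in the upper 2.5% tail of its permutation
distribution (observed value included in the ranking), Negative in the
lower 2.5% tail, and not-significant otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import sparse

from .errors import UndefinedStatisticError
from .grid import LatticeGrid

__all__ = [
    "WeightsMatrix",
    "LeeResult",
    "build_weights",
    "lee_global",
    "lee_local",
    "lee_mc",
]

Scheme = Literal["rook", "queen", "identity"]

_OFFSETS = {
    "rook": [(-1, 0), (1, 0), (0, -1), (0, 1)],
    "queen": [(-1, -1), (-1, 0), (-1, 1), (0, -1),
              (0, 1), (1, -1), (1, 0), (1, 1)],
}


@dataclass
class WeightsMatrix:
    """Sparse pairwise spatial weights over land pixels."""

    w: sparse.csr_matrix
    scheme: str
    row_standardized: bool
    isolated: np.ndarray  # land-pixel indices with no neighbour

    @property
    def n(self) -> int:
        return self.w.shape[0]


def build_weights(
    grid: LatticeGrid,
    scheme: Scheme = "queen",
    row_standardize: bool = True,
) -> WeightsMatrix:
    """Contiguity weights on the lattice, restricted to land pixels.

    ``identity`` gives W = I (useful as the smoothing-free baseline);
    ``rook`` shares edges, ``queen`` edges and corners.  Rows of pixels
    with at least one neighbour are normalized to sum to 1 when
    ``row_standardize`` is set; isolated pixels keep an all-zero row and
    are reported in ``isolated``.
    """
    n = grid.n_land
    if n < 1:
        raise ValueError("grid has no land pixels")
    if scheme == "identity":
        w = sparse.identity(n, format="csr")
        return WeightsMatrix(w, scheme, False, np.empty(0, dtype=int))
    if scheme not in _OFFSETS:
        raise ValueError(f"unknown weights scheme {scheme!r}")
    lut = grid.land_index_lookup()
    rc = grid.land_rc
    rows, cols = [], []
    for dr, dc in _OFFSETS[scheme]:
        r2 = rc[:, 0] + dr
        c2 = rc[:, 1] + dc
        ok = (r2 >= 0) & (r2 < grid.n_rows) & (c2 >= 0) & (c2 < grid.n_cols)
        nb = np.full(n, -1, dtype=int)
        nb[ok] = lut[r2[ok], c2[ok]]
        valid = nb >= 0
        rows.append(np.flatnonzero(valid))
        cols.append(nb[valid])
    ri = np.concatenate(rows)
    ci = np.concatenate(cols)
    w = sparse.csr_matrix((np.ones(ri.size), (ri, ci)), shape=(n, n))
    deg = np.asarray(w.sum(axis=1)).ravel()
    isolated = np.flatnonzero(deg == 0)
    if row_standardize:
        inv = np.where(deg > 0, 1.0 / np.where(deg > 0, deg, 1.0), 0.0)
        w = sparse.diags(inv) @ w
    return WeightsMatrix(w.tocsr(), scheme, bool(row_standardize), isolated)


# ---------------------------------------------------------------------------
# statistic
# ---------------------------------------------------------------------------

def _validate(x: np.ndarray, y: np.ndarray, W: WeightsMatrix
              ) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != (W.n,) or y.shape != (W.n,):
        raise ValueError("x and y must be land-pixel vectors matching W")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("constant map: Lee's L is undefined")
    return x, y


def _locals_raw(x: np.ndarray, y: np.ndarray, W: WeightsMatrix) -> np.ndarray:
    """n * lag(zx)_i * lag(zy)_i / (||zx|| ||zy||)."""
    n = x.size
    zx = x - x.mean()
    zy = y - y.mean()
    lx = W.w @ zx
    ly = W.w @ zy
    denom = np.sqrt(np.sum(zx**2)) * np.sqrt(np.sum(zy**2))
    return n * lx * ly / denom


def _row_sum_sq(W: WeightsMatrix) -> float:
    rs = np.asarray(W.w.sum(axis=1)).ravel()
    return float(np.sum(rs**2))


def lee_global(x: np.ndarray, y: np.ndarray, W: WeightsMatrix) -> float:
    """Global Lee's L of two maps under weights W."""
    x, y = _validate(x, y, W)
    return float(_locals_raw(x, y, W).sum() / _row_sum_sq(W))


def lee_local(x: np.ndarray, y: np.ndarray, W: WeightsMatrix
              ) -> tuple[np.ndarray, np.ndarray]:
    """Local Lee's L values and their max-|L_i| rescaled version.

    ``sum(local) / sum_i (sum_j w_ij)^2`` recovers the global statistic.
    """
    x, y = _validate(x, y, W)
    local = _locals_raw(x, y, W)
    peak = np.max(np.abs(local))
    rescaled = local / peak if peak > 0 else local.copy()
    return local, rescaled


# ---------------------------------------------------------------------------
# Monte Carlo test
# ---------------------------------------------------------------------------

@dataclass
class LeeResult:
    """Lee's L with Monte Carlo classification of the local values.

    ``classification`` codes pixels +1 (Positive: observed local value in
    the top 2.5% of its permutation distribution), -1 (Negative: bottom
    2.5%) and 0 (not significant).
    """

    global_l: float
    p_global: float
    local: np.ndarray
    local_rescaled: np.ndarray
    classification: np.ndarray
    n_permutations: int
    seed: int
    alpha: float

    @property
    def labels(self) -> np.ndarray:
        out = np.full(self.classification.shape, "not-significant",
                      dtype=object)
        out[self.classification > 0] = "Positive"
        out[self.classification < 0] = "Negative"
        return out

    @property
    def fraction_significant(self) -> float:
        return float(np.mean(self.classification != 0))


def lee_mc(
    x: np.ndarray,
    y: np.ndarray,
    W: WeightsMatrix,
    n_permutations: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> LeeResult:
    """Monte Carlo test on Lee's statistic at the (1 - alpha) level.

    The null jointly permutes the paired (x_i, y_i) observations across
    pixels.  Observed values are included in their own null ranking (rank
    among n_permutations + 1), the standard conservative convention.
    """
    if n_permutations < 19:
        raise ValueError("n_permutations must be >= 19")
    x, y = _validate(x, y, W)
    n = x.size
    obs_local = _locals_raw(x, y, W)
    rss = _row_sum_sq(W)
    obs_global = float(obs_local.sum() / rss)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1EE]))
    ge_local = np.zeros(n, dtype=int)   # permuted >= observed
    le_local = np.zeros(n, dtype=int)
    ge_global = le_global = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        loc = _locals_raw(x[perm], y[perm], W)
        ge_local += loc >= obs_local
        le_local += loc <= obs_local
        g = loc.sum() / rss
        ge_global += g >= obs_global
        le_global += g <= obs_global

    m = n_permutations + 1
    tail = alpha / 2.0
    upper = (ge_local + 1) / m <= tail       # Positive
    lower = (le_local + 1) / m <= tail       # Negative
    classification = np.zeros(n, dtype=np.int8)
    classification[upper] = 1
    classification[lower & ~upper] = -1

    p_global = 2.0 * min((ge_global + 1) / m, (le_global + 1) / m)
    p_global = float(min(1.0, p_global))

    peak = np.max(np.abs(obs_local))
    rescaled = obs_local / peak if peak > 0 else obs_local.copy()
    return LeeResult(obs_global, p_global, obs_local, rescaled,
                     classification, n_permutations, int(seed), alpha)
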