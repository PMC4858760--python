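"""Multisite beta diversity: Sørensen dissimilarity partitioned into
turnover and nestedness-resultant components, with resampling and
empirical comparisons.

For a set of *n* sites with incidence matrix ``A`` (sites x species) let
``b_ij`` be the number of species present in site *i* but not *j*,
``S_i`` the richness of site *i* and ``S_T`` the pooled richness.  With
``Smin = sum_{i<j} min(b_ij, b_ji)``, ``Smax = sum_{i<j} max(b_ij, b_ji)``
and ``D = sum_i S_i - S_T``:

    beta_SIM = Smin / (D + Smin)                      (turnover)
    beta_SOR = (Smin + Smax) / (2 D + Smin + Smax)    (total)
    beta_SNE = beta_SOR - beta_SIM                    (nestedness-resultant)

beta_SIM is independent of richness differences (pure replacement);
beta_SNE captures dissimilarity produced by ordered species loss, where
poorer sites are subsets of richer ones.  For n = 2 the multisite values
reduce exactly to the pairwise Sørensen and Simpson dissimilarities.

Because the measures depend on the number of sites, distributions are
compared via repeated random subsets of equal size (default 1000 samples
of 50 sites), and group/region contrasts use a paired-by-index empirical
two-sided p-value over those samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Union

import numpy as np

from .errors import UndefinedStatisticError
from .grid import RegionMask, SpeciesGrid

__all__ = [
    "BetaPartition",
    "BetaSampleDistribution",
    "ComparisonResult",
    "pairwise_components",
    "multisite_partition",
    "beta_sample",
    "compare_distributions",
]

Component = Literal["beta_sim", "beta_sne", "beta_sor"]


def _matrix(sg: Union[SpeciesGrid, np.ndarray]) -> np.ndarray:
    occ = sg.occupancy if isinstance(sg, SpeciesGrid) else np.asarray(sg)
    return occ.astype(bool)


@dataclass(frozen=True)
class BetaPartition:
    """Multisite dissimilarity triple with its building blocks."""

    beta_sor: float
    beta_sim: float
    beta_sne: float
    n_sites: int
    sum_min: float   # Smin
    sum_max: float   # Smax
    rich_diff: float  # D = sum_i S_i - S_T


def pairwise_components(sg: Union[SpeciesGrid, np.ndarray], i: int, j: int
                        ) -> tuple[int, int, int]:
    """(shared a, b_ij, b_ji) for two sites; a + b_ij = S_i."""
    occ = _matrix(sg)
    a = int(np.sum(occ[i] & occ[j]))
    b_ij = int(np.sum(occ[i] & ~occ[j]))
    b_ji = int(np.sum(occ[j] & ~occ[i]))
    return a, b_ij, b_ji


def multisite_partition(sg: Union[SpeciesGrid, np.ndarray]) -> BetaPartition:
    """Partition multisite Sørensen dissimilarity into turnover and
    nestedness-resultant components.

    Species absent from every site are excluded from the pooled richness
    (the measure is defined on the realized pool).  Raises
    :class:`UndefinedStatisticError` for fewer than 2 sites or an
    all-empty matrix.
    """
    occ = _matrix(sg)
    n = occ.shape[0]
    if n < 2:
        raise UndefinedStatisticError("multisite dissimilarity needs >= 2 sites")
    if not occ.any():
        raise UndefinedStatisticError("all-empty incidence matrix")
    A = occ.astype(np.int64)
    shared = A @ A.T                       # a_ij
    S = A.sum(axis=1)                      # S_i
    b = S[:, None] - shared                # b_ij = S_i - a_ij
    iu = np.triu_indices(n, k=1)
    bmin = np.minimum(b, b.T)[iu].sum()
    bmax = np.maximum(b, b.T)[iu].sum()
    S_T = int(occ.any(axis=0).sum())
    D = float(S.sum() - S_T)

    denom_sim = D + bmin
    beta_sim = float(bmin / denom_sim) if denom_sim > 0 else 0.0
    denom_sor = 2.0 * D + bmin + bmax
    beta_sor = float((bmin + bmax) / denom_sor) if denom_sor > 0 else 0.0
    return BetaPartition(
        beta_sor=beta_sor,
        beta_sim=beta_sim,
        beta_sne=beta_sor - beta_sim,
        n_sites=n,
        sum_min=float(bmin),
        sum_max=float(bmax),
        rich_diff=D,
    )


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

@dataclass
class BetaSampleDistribution:
    """Empirical distribution of multisite components over random
    equal-size subsets of one region's pixels."""

    group: str
    region: str
    sites_per_sample: int
    n_samples: int
    beta_sim: np.ndarray
    beta_sne: np.ndarray
    beta_sor: np.ndarray
    seed: int

    def component(self, name: Component) -> np.ndarray:
        return getattr(self, name)


def beta_sample(
    sg: SpeciesGrid,
    mask: Optional[RegionMask] = None,
    side: str = "all",
    sites_per_sample: int = 50,
    n_samples: int = 1000,
    seed: int = 0,
    group: str = "",
) -> BetaSampleDistribution:
    """Multisite partition over repeated without-replacement draws of
    ``sites_per_sample`` pixels from one region.

    Each sample is an independent draw; deterministic given ``seed``.
    """
    if mask is None or side == "all":
        pool = np.arange(sg.occupancy.shape[0])
        region = "all"
    else:
        pool = mask.side(side)  # type: ignore[arg-type]
        region = side
    if pool.size < sites_per_sample:
        raise ValueError(
            f"region {region!r} has {pool.size} pixels, fewer than "
            f"sites_per_sample={sites_per_sample}; choose a smaller subset size"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBE7A]))
    sim = np.empty(n_samples)
    sne = np.empty(n_samples)
    sor = np.empty(n_samples)
    occ = sg.occupancy
    for k in range(n_samples):
        sites = rng.choice(pool, size=sites_per_sample, replace=False)
        part = multisite_partition(occ[sites])
        sim[k], sne[k], sor[k] = part.beta_sim, part.beta_sne, part.beta_sor
    return BetaSampleDistribution(group, region, sites_per_sample,
                                  n_samples, sim, sne, sor, int(seed))


# ---------------------------------------------------------------------------
# comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    """Empirical contrast between two resampled distributions."""

    component: Component
    side_a: str
    side_b: str
    direction: str  # '>', '<' or '='
    p: float
    n_resamples: int


def compare_distributions(
    a: BetaSampleDistribution,
    b: BetaSampleDistribution,
    component: Component,
) -> ComparisonResult:
    """Two-sided empirical p for a difference between two distributions.

    Samples are aligned by index (truncated to the shorter run); with
    ``m = #{r : a_r > b_r}`` over R pairs, ``p = 2 min(m/R, 1 - m/R)``
    floored at 1/R.  Identical distributions (every pair tied) give
    direction '=' and p = 1.  The direction reports the sign of the median
    difference.
    """
    va = a.component(component)
    vb = b.component(component)
    if va.size == 0 or vb.size == 0:
        raise UndefinedStatisticError("empty sample distribution")
    R = min(va.size, vb.size)
    va, vb = va[:R], vb[:R]
    diff = va - vb
    med = float(np.median(diff))
    direction = ">" if med > 0 else ("<" if med < 0 else "=")
    label_a = f"{a.group}:{a.region}".strip(":")
    label_b = f"{b.group}:{b.region}".strip(":")
    if np.all(diff == 0):
        return ComparisonResult(component, label_a, label_b, "=", 1.0, R)
    m = int(np.sum(diff > 0))
    p = 2.0 * min(m / R, 1.0 - m / R)
    p = float(min(1.0, max(p, 1.0 / R)))
    return ComparisonResult(component, label_a, label_b, direction, p, R)
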