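"""Synthetic gridded communities with controlled beta-diversity architecture.

The generator emulates the ingredients of a continental latitudinal-gradient
study on an equal-area lattice: climate layers with a north-south
temperature gradient plus spatial heterogeneity, a species pool whose
incidence structure is controlled by a mix parameter ``theta`` between two
archetypes, and record sampling with spatially biased collection effort.

Archetypes
----------
* **Ordered loss (nested)** — species carry one-sided cold-edge tolerance
  limits: species *k* occurs wherever mean temperature >= t_k.  Because the
  limits are ordered, every species' range is a subset of the range of the
  next more cold-tolerant species, so assemblages lose species in a fixed
  order along the gradient and any set of sites is perfectly nested
  (multisite turnover is exactly zero when occupancy is deterministic).
* **Replacement (turnover)** — species have narrow Gaussian thermal optima
  evenly spaced along the gradient, so composition is replaced from band to
  band while richness stays roughly constant.

``theta`` mixes the archetypes (1 = pure ordered loss, 0 = pure
replacement).  ``theta_north`` / ``theta_south`` optionally give the two
halves of the pool — species whose thermal positions lie in the northern
vs southern part of the climate — different architectures, which is how a
community can be nested in the north yet replacement-driven in the south.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError
from .grid import LatticeGrid, SpeciesGrid

__all__ = [
    "EnvStack",
    "SimulationConfig",
    "make_landscape",
    "simulate_pool",
    "simulate_truth",
    "sample_records",
    "effort_map",
]

# Environmental drivers emulated (mean + heterogeneity of the classical
# energy/water/history axes used in richness modelling).
LAYER_NAMES = (
    "temperature_mean",
    "temperature_sd",
    "precipitation_mean",
    "precipitation_sd",
    "altitude_sd",
    "pet_mean",
    "pet_sd",
    "distance_coast",
    "distance_refugia",
)


@dataclass
class EnvStack:
    """Named environmental layers on a shared lattice (land-pixel vectors)."""

    grid: LatticeGrid
    layers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if len(set(self.layers)) != len(self.layers):
            raise ValueError("layer names must be unique")
        for name, v in self.layers.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (self.grid.n_land,):
                raise ValueError(f"layer {name!r} is not a land-pixel vector")
            self.layers[name] = v

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def matrix(self, names: Optional[list[str]] = None) -> np.ndarray:
        """(n_land, n_layers) design matrix in the given layer order."""
        names = names if names is not None else self.names
        return np.column_stack([self.layers[n] for n in names])


@dataclass
class SimulationConfig:
    """Scenario for one synthetic community.

    theta
        Structure mix in [0, 1]: fraction of the pool built on the
        ordered-loss (nested) archetype; the rest is replacement.
    theta_north, theta_south
        Optional per-region mixes.  When set, half of the pool is anchored
        in the northern thermal domain (mixed by ``theta_north``) and half
        in the southern domain (``theta_south``); ``theta`` is ignored.
    noise
        Occupancy noise in [0, 1): maximum occupancy probability is
        ``1 - noise``, so 0 makes nested ranges deterministic.
    split_latitude
        Parallel separating the two thermal domains (degrees).
    """

    n_species: int = 60
    theta: float = 0.5
    theta_north: Optional[float] = None
    theta_south: Optional[float] = None
    noise: float = 0.05
    gradient_direction: str = "north-cold"
    split_latitude: float = 46.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("theta", "theta_north", "theta_south"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 <= self.noise < 1.0):
            raise ConfigError(f"noise must be in [0, 1), got {self.noise}")
        if self.n_species < 1:
            raise ConfigError("n_species must be >= 1")
        if self.gradient_direction not in ("north-cold", "south-cold"):
            raise ConfigError("gradient_direction must be 'north-cold' or 'south-cold'")
        if (self.theta_north is None) != (self.theta_south is None):
            raise ConfigError("theta_north and theta_south must be set together")

    @property
    def regional(self) -> bool:
        return self.theta_north is not None


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape, sigma: float = 2.0
                  ) -> np.ndarray:
    """Spatially autocorrelated standard-normal field (unit variance)."""
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def make_landscape(
    n_rows: int = 20,
    n_cols: int = 20,
    lat_range: tuple[float, float] = (40.0, 52.0),
    seed: int = 0,
    noise_scale: float = 1.0,
    pixel_size: float = 100.0,
    land_fraction: float = 1.0,
) -> EnvStack:
    """Generate an equal-area lattice with latitudinal climate gradients.

    Mean temperature decreases linearly northwards (band means are strictly
    monotone before noise); precipitation increases mildly northwards;
    potential evapotranspiration tracks temperature closely (so that
    collinearity screening has something to do); heterogeneity layers
    (SD of temperature/precipitation/PET, SD of altitude) are non-negative
    smooth fields; distance-to-coast and distance-to-refugia complete the
    classical driver set.  Deterministic given ``seed``.
    """
    if n_rows < 2 or n_cols < 2:
        raise ConfigError("n_rows and n_cols must both be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xE17]))

    if land_fraction >= 1.0:
        land = np.ones((n_rows, n_cols), dtype=bool)
    else:
        blob = _smooth_field(rng, (n_rows, n_cols), sigma=2.5)
        cut = np.quantile(blob, 1.0 - land_fraction)
        land = blob >= cut
        if land.sum() < 4:  # keep the grid usable
            land = np.ones((n_rows, n_cols), dtype=bool)

    grid = LatticeGrid.regular(n_rows, n_cols, pixel_size=pixel_size,
                               lat_range=lat_range, land_mask=land)
    lat = grid.centroid_lat
    lat_s, lat_n = lat_range

    def fld() -> np.ndarray:
        return _smooth_field(rng, (n_rows, n_cols))[land]

    # deterministic gradients + seeded smooth noise; temperature runs with
    # latitude, precipitation west-east (oceanic -> continental) so the two
    # principal climate axes are not collinear
    temp = 16.0 - 0.8 * (lat - lat_s) + 0.4 * noise_scale * fld()
    west_frac = (grid.land_rc[:, 1] + 0.5) / n_cols
    precip = 900.0 - 350.0 * west_frac + 40.0 * noise_scale * fld()
    precip = np.clip(precip, 0.0, None)
    pet = 60.0 * temp + 120.0 + 15.0 * noise_scale * fld()

    temp_sd = 0.5 + 0.4 * noise_scale * np.abs(fld())
    precip_sd = 40.0 + 30.0 * noise_scale * np.abs(fld())
    alt_sd = 100.0 + 120.0 * noise_scale * np.abs(fld())
    pet_sd = 30.0 + 20.0 * noise_scale * np.abs(fld())

    # distances from grid geometry (km)
    inside = ndimage.distance_transform_edt(np.pad(land, 1)[1:-1, 1:-1])
    dist_coast = inside[land] * pixel_size
    rc = grid.land_rc
    n_ref = max(1, min(3, grid.n_land))
    ref_pool = np.flatnonzero(lat <= np.quantile(lat, 0.25))
    if ref_pool.size == 0:
        ref_pool = np.arange(grid.n_land)
    refugia = rng.choice(ref_pool, size=min(n_ref, ref_pool.size), replace=False)
    d = np.hypot(rc[:, None, 0] - rc[refugia][None, :, 0],
                 rc[:, None, 1] - rc[refugia][None, :, 1])
    dist_refugia = d.min(axis=1) * pixel_size

    return EnvStack(grid, {
        "temperature_mean": temp,
        "temperature_sd": temp_sd,
        "precipitation_mean": precip,
        "precipitation_sd": precip_sd,
        "altitude_sd": alt_sd,
        "pet_mean": pet,
        "pet_sd": pet_sd,
        "distance_coast": dist_coast,
        "distance_refugia": dist_refugia,
    })


# ---------------------------------------------------------------------------
# species pool
# ---------------------------------------------------------------------------

def _archetype_rows(
    n_nested: int, n_turnover: int, t_lo: float, t_hi: float,
    p_lo: float, p_hi: float, max_prob: float, domain: str, start_id: int,
) -> list[dict]:
    """Build niche rows for one thermal domain [t_lo, t_hi]."""
    rows: list[dict] = []
    span = t_hi - t_lo
    # nested: cold-edge limits evenly spaced inside the domain; the species
    # with the lowest limit is the most cold-tolerant (largest range)
    for k in range(n_nested):
        frac = (k + 1) / (n_nested + 1)
        rows.append(dict(
            archetype="nested", domain=domain,
            temp_threshold=t_lo + frac * span,
            temp_opt=np.nan, temp_breadth=np.nan,
            precip_opt=np.nan, precip_breadth=np.inf,
            max_prob=max_prob, cold_rank=k,
        ))
    # replacement: narrow optima evenly spaced; breadth ties adjacent ranges
    if n_turnover:
        spacing = span / (n_turnover + 1)
        mid_p = 0.5 * (p_lo + p_hi)
        for j in range(n_turnover):
            rows.append(dict(
                archetype="turnover", domain=domain,
                temp_threshold=np.nan,
                temp_opt=t_lo + (j + 1) * spacing,
                temp_breadth=max(1.5 * spacing, 1e-6),
                precip_opt=mid_p,
                precip_breadth=max(3.0 * (p_hi - p_lo + 1e-9), 1e-6),
                max_prob=max_prob, cold_rank=-1,
            ))
    for i, r in enumerate(rows):
        r["species_id"] = f"sp{start_id + i:03d}"
    return rows


def simulate_pool(cfg: SimulationConfig, env: EnvStack) -> pd.DataFrame:
    """Build the niche table for a scenario.

    Returns one row per species with columns ``species_id, archetype,
    domain, temp_threshold, temp_opt, temp_breadth, precip_opt,
    precip_breadth, max_prob, cold_rank``.
    """
    temp = env.layers["temperature_mean"]
    precip = env.layers["precipitation_mean"]
    lat = env.grid.centroid_lat
    max_prob = 1.0 - cfg.noise
    q = lambda v, a, b: (float(np.quantile(v, a)), float(np.quantile(v, b)))

    rows: list[dict] = []
    if not cfg.regional:
        t_lo, t_hi = q(temp, 0.05, 0.95)
        p_lo, p_hi = q(precip, 0.05, 0.95)
        n_nested = int(round(cfg.theta * cfg.n_species))
        rows = _archetype_rows(n_nested, cfg.n_species - n_nested,
                               t_lo, t_hi, p_lo, p_hi, max_prob,
                               "global", 0)
    else:
        north = lat > cfg.split_latitude
        if not north.any() or north.all():
            raise ConfigError(
                "regional structure mix requires land on both sides of "
                f"latitude {cfg.split_latitude}"
            )
        n_n = cfg.n_species // 2
        n_s = cfg.n_species - n_n
        for side, n_side, theta, start in (
            ("north", n_n, cfg.theta_north, 0),
            ("south", n_s, cfg.theta_south, n_n),
        ):
            sel = north if side == "north" else ~north
            t_lo, t_hi = q(temp[sel], 0.05, 0.95)
            p_lo, p_hi = q(precip[sel], 0.05, 0.95)
            n_nested = int(round(theta * n_side))
            rows += _archetype_rows(n_nested, n_side - n_nested,
                                    t_lo, t_hi, p_lo, p_hi, max_prob,
                                    side, start)
    table = pd.DataFrame(rows)
    return table[["species_id", "archetype", "domain", "temp_threshold",
                  "temp_opt", "temp_breadth", "precip_opt",
                  "precip_breadth", "max_prob", "cold_rank"]]


def _suitability(niche: pd.Series, env: EnvStack) -> np.ndarray:
    """Per-pixel occupancy probability for one species."""
    temp = env.layers["temperature_mean"]
    precip = env.layers["precipitation_mean"]
    if niche["archetype"] == "nested":
        resp = (temp >= niche["temp_threshold"]).astype(float)
    else:
        b = niche["temp_breadth"]
        resp = (np.ones_like(temp) if not np.isfinite(b)
                else np.exp(-0.5 * ((temp - niche["temp_opt"]) / b) ** 2))
        pb = niche["precip_breadth"]
        if np.isfinite(pb):
            resp = resp * np.exp(-0.5 * ((precip - niche["precip_opt"]) / pb) ** 2)
    return niche["max_prob"] * resp


def simulate_truth(niches: pd.DataFrame, env: EnvStack, seed: int = 0
                   ) -> SpeciesGrid:
    """Draw the true presence/absence matrix: Bernoulli(suitability) per
    pixel and species, deterministic given ``seed``.  Pixels with
    suitability exactly 1 are always present, exactly 0 always absent."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7B0]))
    n_land = env.grid.n_land
    occ = np.zeros((n_land, len(niches)), dtype=bool)
    for j, (_, niche) in enumerate(niches.iterrows()):
        s = _suitability(niche, env)
        occ[:, j] = rng.random(n_land) < s
    return SpeciesGrid(env.grid, niches["species_id"].tolist(), occ,
                       meta={"seed": int(seed)})


# ---------------------------------------------------------------------------
# biased record sampling
# ---------------------------------------------------------------------------

def effort_map(grid: LatticeGrid, north_weight: float = 1.0,
               south_weight: float = 1.0, split_latitude: float = 46.0
               ) -> np.ndarray:
    """Step collection-effort surface: constant weight per region."""
    if north_weight < 0 or south_weight < 0:
        raise ConfigError("effort weights must be non-negative")
    return np.where(grid.centroid_lat > split_latitude,
                    float(north_weight), float(south_weight))


def sample_records(
    truth: SpeciesGrid,
    effort: np.ndarray,
    n_records: int,
    seed: int = 0,
    replace: bool = False,
) -> pd.DataFrame:
    """Draw occurrence records from the true presences with probability
    proportional to per-pixel collection effort.

    Records are (species, pixel-centroid x, pixel-centroid y) rows; a
    (species, pixel) pair absent from the truth can never be emitted.
    """
    effort = np.asarray(effort, dtype=float)
    if effort.shape != (truth.grid.n_land,):
        raise ValueError("effort must be a land-pixel vector")
    if (effort < 0).any() or not (effort > 0).any():
        raise ConfigError("effort must be non-negative and not all zero")
    pix, sp = np.nonzero(truth.occupancy)
    w = effort[pix]
    available = w > 0
    if not replace and n_records > int(available.sum()):
        raise ValueError(
            f"n_records={n_records} exceeds the {int(available.sum())} "
            "true presence pixels reachable with the given effort "
            "(replacement disabled)"
        )
    p = w / w.sum()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5A3]))
    idx = rng.choice(len(pix), size=int(n_records), replace=replace, p=p)
    x, y = truth.grid.centroid_xy
    return pd.DataFrame({
        "species": [truth.species_ids[j] for j in sp[idx]],
        "x": x[pix[idx]],
        "y": y[pix[idx]],
    })
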