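"""End-to-end orchestration of the synthetic latitudinal-gradient analysis.

``run_pipeline`` executes, for each configured taxon group: landscape
generation, truth simulation, biased record sampling, rasterization, the
minimum-presence filter, collinearity screening, the SDM ensemble and
stacking; then Lee's L for every group pair, the resampled beta-diversity
comparison for every group x region, and latitudinal band profiles.  All
tables, rasters, the resolved configuration and the master seed are
written to the output directory; two runs with identical configuration
and seed produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import bands as bands_mod
from . import beta as beta_mod
from . import lee as lee_mod
from . import sdm as sdm_mod
from .errors import ConfigError
from .grid import (RegionMask, RichnessMap, SpeciesGrid, filter_min_presence,
                   rasterize, richness_from_occupancy, split_regions)
from .raster import write_asc
from .synthetic import (EnvStack, SimulationConfig, effort_map,
                        make_landscape, sample_records, simulate_pool,
                        simulate_truth)

logger = logging.getLogger(__name__)

__all__ = ["GridSpec", "SamplingSpec", "BetaSpec", "LeeSpec", "BandSpec",
           "PipelineConfig", "GroupResult", "PipelineResult", "run_pipeline"]

_FLOAT_FMT = "%.10g"


@dataclass
class GridSpec:
    n_rows: int = 20
    n_cols: int = 20
    pixel_size: float = 100.0
    lat_range: tuple[float, float] = (40.0, 52.0)
    land_fraction: float = 1.0
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ConfigError("grid must be at least 2x2")
        lo, hi = self.lat_range
        if not lo < hi:
            raise ConfigError("lat_range must be (south, north) with south < north")


@dataclass
class SamplingSpec:
    # atlas-style compilations revisit pixels, so records are drawn with
    # replacement and densely relative to the number of presence pixels
    # (~90% of true presence pixels receive at least one record on the
    # default 20x20 / 60-species scenario)
    n_records: int = 24000
    effort_north: float = 1.0
    effort_south: float = 1.0
    replace: bool = True


@dataclass
class BetaSpec:
    sites_per_sample: int = 50
    n_samples: int = 1000


@dataclass
class LeeSpec:
    scheme: str = "queen"
    row_standardize: bool = True
    n_permutations: int = 999
    alpha: float = 0.05


@dataclass
class BandSpec:
    band_width: float = 100.0
    z: float = 0.25


@dataclass
class PipelineConfig:
    """Fully serializable configuration of one pipeline run."""

    grid: GridSpec = field(default_factory=GridSpec)
    groups: dict[str, SimulationConfig] = field(
        default_factory=lambda: {"community": SimulationConfig()})
    sampling: SamplingSpec = field(default_factory=SamplingSpec)
    sdm: sdm_mod.SDMConfig = field(default_factory=sdm_mod.SDMConfig)
    beta: BetaSpec = field(default_factory=BetaSpec)
    lee: LeeSpec = field(default_factory=LeeSpec)
    bands: BandSpec = field(default_factory=BandSpec)
    # candidate predictor layers offered to the SDM stage (before
    # collinearity screening): the climatic drivers of suitability.  The
    # heterogeneity and distance layers stay in the stack as richness-driver
    # covariates for the band analysis.
    sdm_candidates: tuple[str, ...] = (
        "temperature_mean", "precipitation_mean", "pet_mean")
    split_latitude: float = 46.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ConfigError("at least one group must be configured")

    # -- (de)serialization --------------------------------------------------

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        try:
            kwargs: dict = {}
            if "grid" in raw:
                g = dict(raw["grid"])
                if "lat_range" in g:
                    g["lat_range"] = tuple(g["lat_range"])
                kwargs["grid"] = GridSpec(**g)
            if "groups" in raw:
                kwargs["groups"] = {
                    name: SimulationConfig(**params)
                    for name, params in raw["groups"].items()
                }
            for key, klass in (("sampling", SamplingSpec),
                               ("beta", BetaSpec), ("lee", LeeSpec),
                               ("bands", BandSpec)):
                if key in raw:
                    kwargs[key] = klass(**raw[key])
            if "sdm" in raw:
                s = dict(raw["sdm"])
                for tup in ("techniques", "threshold_rules"):
                    if tup in s:
                        s[tup] = tuple(s[tup])
                kwargs["sdm"] = sdm_mod.SDMConfig(**s)
            if "sdm_candidates" in raw:
                kwargs["sdm_candidates"] = tuple(raw["sdm_candidates"])
            for scalar in ("split_latitude", "seed"):
                if scalar in raw:
                    kwargs[scalar] = raw[scalar]
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid pipeline configuration: {exc}") from exc


def _asdict(obj) -> dict:
    d = dataclasses.asdict(obj)

    def clean(v):
        if isinstance(v, tuple):
            return [clean(x) for x in v]
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, np.generic):
            return v.item()
        return v

    return clean(d)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class GroupResult:
    name: str
    truth: SpeciesGrid
    observed: SpeciesGrid          # rasterized records, unfiltered
    filtered: SpeciesGrid
    potential: SpeciesGrid         # consensus composition
    stacked: RichnessMap
    predictors: sdm_mod.PredictorSet
    ensembles: list[sdm_mod.EnsembleResult]
    evaluation: pd.DataFrame


@dataclass
class PipelineResult:
    config: PipelineConfig
    env: EnvStack
    regions: RegionMask
    groups: dict[str, GroupResult]
    beta_distributions: dict[tuple[str, str], beta_mod.BetaSampleDistribution]
    comparisons: pd.DataFrame
    lee: dict[tuple[str, str], lee_mod.LeeResult]
    band_profiles: dict[str, pd.DataFrame]
    band_env: pd.DataFrame
    out_dir: Optional[Path]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _run_group(name: str, idx: int, cfg: PipelineConfig, env: EnvStack
               ) -> GroupResult:
    sim = cfg.groups[name]
    seed = int(np.random.SeedSequence(
        [cfg.seed, idx, 0x6E0]).generate_state(1)[0] % (2**31))
    pool = simulate_pool(sim, env)
    truth = simulate_truth(pool, env, seed=seed)
    effort = effort_map(env.grid, cfg.sampling.effort_north,
                        cfg.sampling.effort_south, cfg.split_latitude)
    records = sample_records(truth, effort, cfg.sampling.n_records,
                             seed=seed + 1, replace=cfg.sampling.replace)
    observed = rasterize(records, env.grid)
    filtered = filter_min_presence(observed, cfg.sdm.min_presences)
    missing = [n for n in cfg.sdm_candidates if n not in env.layers]
    if missing:
        raise ConfigError(f"sdm_candidates not in the layer stack: {missing}")
    candidates = EnvStack(env.grid,
                          {n: env.layers[n] for n in cfg.sdm_candidates})
    predictors = sdm_mod.screen_predictors(candidates, cfg.sdm.r_max)
    group_sdm = dataclasses.replace(cfg.sdm, seed=seed + 2)
    ensembles = sdm_mod.fit_ensemble(filtered, env, group_sdm,
                                     predictors.retained)
    stacked = sdm_mod.stack(ensembles, env.grid)
    potential = sdm_mod.potential_species_grid(ensembles, env.grid)
    evaluation = (pd.concat([e.evaluation_table() for e in ensembles],
                            ignore_index=True)
                  if ensembles else pd.DataFrame())
    logger.info("group %s: %d/%d species retained, stacked richness "
                "range %g-%g", name, filtered.n_species, truth.n_species,
                stacked.richness.min(), stacked.richness.max())
    return GroupResult(name, truth, observed, filtered, potential, stacked,
                       predictors, ensembles, evaluation)


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> PipelineResult:
    """Run the full chain; optionally write the report bundle to ``out_dir``."""
    env = make_landscape(
        cfg.grid.n_rows, cfg.grid.n_cols, cfg.grid.lat_range,
        seed=cfg.seed, noise_scale=cfg.grid.noise_scale,
        pixel_size=cfg.grid.pixel_size,
        land_fraction=cfg.grid.land_fraction,
    )
    regions = split_regions(env.grid, cfg.split_latitude)

    groups: dict[str, GroupResult] = {}
    for idx, name in enumerate(cfg.groups):
        try:
            groups[name] = _run_group(name, idx, cfg, env)
        except Exception as exc:
            raise RuntimeError(f"stage 'sdm:{name}' failed: {exc}") from exc

    # beta distributions per group x region and comparisons
    beta_dists: dict[tuple[str, str], beta_mod.BetaSampleDistribution] = {}
    comp_rows = []
    sides = ("north", "south")
    try:
        for gi, (name, g) in enumerate(groups.items()):
            for si, side in enumerate(sides):
                beta_dists[(name, side)] = beta_mod.beta_sample(
                    g.potential, regions, side,
                    cfg.beta.sites_per_sample, cfg.beta.n_samples,
                    seed=int(np.random.SeedSequence(
                        [cfg.seed, gi, si, 0xBE]).generate_state(1)[0]
                        % (2**31)),
                    group=name,
                )
        for comp in ("beta_sim", "beta_sne"):
            for name in groups:  # north vs south within group
                res = beta_mod.compare_distributions(
                    beta_dists[(name, "north")], beta_dists[(name, "south")],
                    comp)
                comp_rows.append(dict(
                    component=comp, contrast="region", group=name,
                    a=res.side_a, b=res.side_b, direction=res.direction,
                    p=res.p, n=res.n_resamples,
                    median_a=float(np.median(
                        beta_dists[(name, "north")].component(comp))),
                    median_b=float(np.median(
                        beta_dists[(name, "south")].component(comp))),
                ))
            for (na, nb) in itertools.combinations(groups, 2):
                for side in sides:  # group pairs within region
                    res = beta_mod.compare_distributions(
                        beta_dists[(na, side)], beta_dists[(nb, side)], comp)
                    comp_rows.append(dict(
                        component=comp, contrast="group", group=side,
                        a=res.side_a, b=res.side_b, direction=res.direction,
                        p=res.p, n=res.n_resamples,
                        median_a=float(np.median(
                            beta_dists[(na, side)].component(comp))),
                        median_b=float(np.median(
                            beta_dists[(nb, side)].component(comp))),
                    ))
    except Exception as exc:
        raise RuntimeError(f"stage 'beta' failed: {exc}") from exc
    comparisons = pd.DataFrame(comp_rows)

    # Lee's L per group pair on stacked richness
    lee_results: dict[tuple[str, str], lee_mod.LeeResult] = {}
    try:
        W = lee_mod.build_weights(env.grid, cfg.lee.scheme,
                                  cfg.lee.row_standardize)
        for pi, (na, nb) in enumerate(itertools.combinations(groups, 2)):
            lee_results[(na, nb)] = lee_mod.lee_mc(
                groups[na].stacked.richness, groups[nb].stacked.richness, W,
                cfg.lee.n_permutations,
                seed=int(np.random.SeedSequence(
                    [cfg.seed, pi, 0x1E]).generate_state(1)[0] % (2**31)),
                alpha=cfg.lee.alpha,
            )
    except Exception as exc:
        raise RuntimeError(f"stage 'lee' failed: {exc}") from exc

    # band profiles
    try:
        band_profiles = {
            name: bands_mod.normalize_species_area(
                bands_mod.band_aggregate(g.stacked, cfg.bands.band_width),
                cfg.bands.z)
            for name, g in groups.items()
        }
        band_env = bands_mod.band_environment(env, cfg.bands.band_width)
    except Exception as exc:
        raise RuntimeError(f"stage 'bands' failed: {exc}") from exc

    result = PipelineResult(cfg, env, regions, groups, beta_dists,
                            comparisons, lee_results, band_profiles,
                            band_env, Path(out_dir) if out_dir else None)
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------

def _write_bundle(res: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = res.config
    cfg.to_yaml(out / "config.yaml")
    (out / "seed.json").write_text(json.dumps({"seed": cfg.seed}) + "\n")

    grid = res.env.grid
    for name, g in res.groups.items():
        write_asc(out / f"richness_{name}.asc",
                  grid.to_full(g.stacked.richness), grid.origin,
                  grid.pixel_size)
        write_asc(out / f"richness_observed_{name}.asc",
                  grid.to_full(richness_from_occupancy(g.observed).richness),
                  grid.origin, grid.pixel_size)
        g.evaluation.to_csv(out / f"evaluation_{name}.csv", index=False,
                            float_format=_FLOAT_FMT)
        res.band_profiles[name].to_csv(out / f"bands_{name}.csv",
                                       index=False, float_format=_FLOAT_FMT)
    res.band_env.to_csv(out / "bands_environment.csv", index=False,
                        float_format=_FLOAT_FMT)

    tidy = []
    for (name, side), dist in res.beta_distributions.items():
        for k in range(dist.n_samples):
            tidy.append((name, side, k, dist.beta_sim[k], dist.beta_sne[k],
                         dist.beta_sor[k]))
    pd.DataFrame(tidy, columns=["group", "region", "sample_id", "beta_sim",
                                "beta_sne", "beta_sor"]).to_csv(
        out / "beta_samples.csv", index=False, float_format=_FLOAT_FMT)
    res.comparisons.to_csv(out / "beta_comparisons.csv", index=False,
                           float_format=_FLOAT_FMT)

    lines = ["component contrast a b direction p"]
    for _, r in res.comparisons.iterrows():
        lines.append(f"{r['component']} {r['contrast']} {r['a']} {r['b']} "
                     f"{r['direction']} {r['p']:.4g}")
    for (na, nb), lr in res.lee.items():
        write_asc(out / f"lee_local_{na}_{nb}.asc",
                  grid.to_full(lr.local), grid.origin, grid.pixel_size)
        write_asc(out / f"lee_class_{na}_{nb}.asc",
                  grid.to_full(lr.classification.astype(float)),
                  grid.origin, grid.pixel_size)
        lines.append(f"lee {na}~{nb} global_L={lr.global_l:.6g} "
                     f"p={lr.p_global:.4g} "
                     f"significant_fraction={lr.fraction_significant:.4g}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
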