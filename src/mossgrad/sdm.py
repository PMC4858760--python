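"""Ensemble species distribution modelling and stacking (S-SDM).

Per species the stage runs several statistical techniques (a logistic GLM
with linear + quadratic terms, a random-forest classifier, and a
maxent-like presence/background weighted logistic model) over replicated
70/30 split samples, evaluates each replicate on the held-out 30% with AUC
and TSS, binarizes the continuous suitability maps under two threshold
rules (max-TSS and sensitivity = specificity) and takes a weighted
majority vote across all members as the species' consensus potential
distribution.  Summing consensus maps over species yields the stacked
potential richness map.

Because only presences are observed, each species is contrasted against
background pixels drawn uniformly from land pixels without a presence of
that species.  All randomness flows from one master seed through a
hierarchical scheme (species -> technique -> replicate); the 70/30 splits
are shared across techniques within a replicate so ensemble members see
the same data partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ConfigError, UndefinedStatisticError
from .grid import RichnessMap, SpeciesGrid
from .synthetic import EnvStack

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorSet",
    "Scores",
    "SDMFit",
    "EnsembleResult",
    "SDMConfig",
    "screen_predictors",
    "fit_species",
    "evaluate",
    "binarize",
    "consensus",
    "stack",
    "fit_ensemble",
    "ensemble_species",
    "potential_species_grid",
]

TECHNIQUES = ("glm", "rf", "maxent")
THRESHOLD_RULES = ("max_tss", "sens_spec_equal")


@dataclass
class SDMConfig:
    """Settings for the ensemble stage."""

    techniques: tuple[str, ...] = TECHNIQUES
    n_replicates: int = 10
    train_fraction: float = 0.7
    threshold_rules: tuple[str, ...] = THRESHOLD_RULES
    background_cap: int = 1000
    n_trees: int = 100
    weighted_consensus: bool = True
    r_max: float = 0.8
    min_presences: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.techniques) - set(TECHNIQUES)
        if unknown:
            raise ConfigError(f"unknown technique(s): {sorted(unknown)}")
        if not self.techniques:
            raise ConfigError("at least one technique is required")
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigError("train_fraction must be in (0, 1)")
        if set(self.threshold_rules) - set(THRESHOLD_RULES):
            raise ConfigError(f"unknown threshold rule in {self.threshold_rules}")


# ---------------------------------------------------------------------------
# predictor screening
# ---------------------------------------------------------------------------

@dataclass
class PredictorSet:
    """Result of greedy collinearity screening."""

    candidates: list[str]
    retained: list[str]
    correlation: pd.DataFrame
    log: list[str] = field(default_factory=list)


def screen_predictors(env: EnvStack, r_max: float = 0.8) -> PredictorSet:
    """Greedy pairwise-correlation elimination.

    Constant layers are excluded up front (their correlation is
    undefined).  While any retained pair has |r| > ``r_max``, the member
    of the worst-offending pair with the larger mean absolute correlation
    to the remaining candidates is dropped.  The final set contains no
    pair above the threshold.
    """
    names = env.names
    if len(names) < 2:
        raise ValueError("need at least 2 candidate layers")
    log: list[str] = []
    usable = []
    for n in names:
        if np.ptp(env.layers[n]) == 0:
            log.append(f"excluded constant layer {n!r}")
            logger.warning("screen_predictors: constant layer %r excluded", n)
        else:
            usable.append(n)
    X = env.matrix(usable)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 valid pixels")
    corr = pd.DataFrame(np.corrcoef(X, rowvar=False), index=usable,
                        columns=usable)
    retained = list(usable)
    while len(retained) > 1:
        sub = corr.loc[retained, retained].abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= r_max:
            break
        mean_i = sub[i].sum() / (len(retained) - 1)
        mean_j = sub[j].sum() / (len(retained) - 1)
        drop = retained[i] if mean_i >= mean_j else retained[j]
        keep = retained[j] if drop == retained[i] else retained[i]
        log.append(
            f"dropped {drop!r} (|r|={sub[i, j]:.3f} with {keep!r}; "
            f"mean |r| {max(mean_i, mean_j):.3f})"
        )
        retained.remove(drop)
    return PredictorSet(names, retained, corr, log)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scores:
    auc: float
    tss: float
    thr_max_tss: float
    thr_sens_spec: float


def evaluate(pred: np.ndarray, truth: np.ndarray) -> Scores:
    """AUC and TSS of continuous predictions against binary labels.

    TSS = sensitivity + specificity - 1, maximized over all candidate
    thresholds; the sensitivity = specificity threshold minimizes
    |sensitivity - specificity|.  Binarization uses ``pred >= threshold``.
    """
    truth = np.asarray(truth).astype(int)
    pred = np.asarray(pred, dtype=float)
    if len(np.unique(truth)) < 2:
        raise UndefinedStatisticError("test labels contain a single class")
    auc = float(roc_auc_score(truth, pred))
    # candidate thresholds are the observed scores, matching the
    # `pred >= threshold` binarization rule exactly
    cand = np.unique(pred)
    hits = pred[:, None] >= cand[None, :]
    pos = truth == 1
    sens = hits[pos].sum(axis=0) / pos.sum()
    spec = (~hits[~pos]).sum(axis=0) / (~pos).sum()
    tss = sens + spec - 1.0
    k = int(np.argmax(tss))
    k_eq = int(np.argmin(np.abs(sens - spec)))
    return Scores(auc=auc, tss=float(tss[k]), thr_max_tss=float(cand[k]),
                  thr_sens_spec=float(cand[k_eq]))


def binarize(pred: np.ndarray, threshold: float) -> np.ndarray:
    """Binary map: pixel is 1 iff prediction >= threshold."""
    out = np.asarray(pred, dtype=float) >= threshold
    if not out.any():
        logger.warning("binarize: no pixel reaches threshold %.4f", threshold)
    return out


def consensus(members: Sequence[np.ndarray],
              weights: Optional[Sequence[float]] = None) -> np.ndarray:
    """Weighted majority vote over binary member maps.

    A pixel is present iff the weighted vote fraction strictly exceeds
    0.5; exact ties resolve to absence (conservative richness).
    """
    if len(members) == 0:
        raise ValueError("consensus needs at least one member map")
    M = np.stack([np.asarray(m, dtype=bool) for m in members])
    if weights is None:
        w = np.ones(len(members))
    else:
        w = np.asarray(weights, dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if w.sum() == 0:
            w = np.ones(len(members))
    frac = (w[:, None] * M).sum(axis=0) / w.sum()
    return frac > 0.5


# ---------------------------------------------------------------------------
# per-species fitting
# ---------------------------------------------------------------------------

@dataclass
class ReplicateFit:
    replicate: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    prediction: np.ndarray       # continuous suitability on all land pixels
    scores: Scores


@dataclass
class SDMFit:
    species: str
    technique: str
    replicates: list[ReplicateFit]
    skipped: list[int] = field(default_factory=list)


def _design(X: np.ndarray, technique: str) -> np.ndarray:
    """GLM-family techniques use linear + quadratic terms."""
    if technique in ("glm", "maxent"):
        return np.hstack([X, X**2])
    return X


def _make_model(technique: str, cfg: SDMConfig, seed: int):
    if technique == "glm":
        # large C approximates the unregularized maximum-likelihood GLM
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=3000, C=1000.0),
        )
    if technique == "maxent":
        # presence/background weighted logistic: balanced class weights make
        # the background act as a sampled contrast rather than true absences
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=3000, C=1000.0,
                               class_weight="balanced"),
        )
    if technique == "rf":
        return RandomForestClassifier(
            n_estimators=cfg.n_trees, random_state=seed, n_jobs=1,
            min_samples_leaf=2,
        )
    raise ConfigError(f"unknown technique {technique!r}")


def _background(sg: SpeciesGrid, sp_idx: int, cfg: SDMConfig) -> np.ndarray:
    """Uniform random background pixels without a presence of the species."""
    absent = np.flatnonzero(~sg.occupancy[:, sp_idx])
    n_pres = int(sg.occupancy[:, sp_idx].sum())
    n_bg = min(max(n_pres, cfg.background_cap), absent.size)
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, sp_idx, 0xB6]))
    return rng.choice(absent, size=n_bg, replace=False)


def _splits(n_rows: int, y: np.ndarray, cfg: SDMConfig, sp_idx: int
            ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified 70/30 splits, shared across techniques (one per replicate)."""
    out = []
    for rep in range(cfg.n_replicates):
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, sp_idx, rep, 0x57]))
        train_mask = np.zeros(n_rows, dtype=bool)
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            n_train = int(round(cfg.train_fraction * idx.size))
            n_train = min(max(n_train, 1), idx.size - 1) if idx.size > 1 else idx.size
            train_mask[rng.choice(idx, size=n_train, replace=False)] = True
        out.append((np.flatnonzero(train_mask), np.flatnonzero(~train_mask)))
    return out


def fit_species(
    sg: SpeciesGrid,
    species: str,
    env: EnvStack,
    technique: str,
    cfg: SDMConfig,
    predictors: Optional[Sequence[str]] = None,
    background: Optional[np.ndarray] = None,
    splits: Optional[list[tuple[np.ndarray, np.ndarray]]] = None,
) -> SDMFit:
    """Replicated split-sample fits of one technique for one species.

    Returns per-replicate continuous suitability over all land pixels and
    held-out evaluation scores; replicates whose training split holds
    fewer than 2 presences are skipped and logged.
    """
    sp_idx = sg.species_ids.index(species)
    names = list(predictors) if predictors is not None else env.names
    X_all = env.matrix(names)
    if background is None:
        background = _background(sg, sp_idx, cfg)
    pres = np.flatnonzero(sg.occupancy[:, sp_idx])
    rows = np.concatenate([pres, background])
    y = np.concatenate([np.ones(pres.size, dtype=int),
                        np.zeros(background.size, dtype=int)])
    X = _design(X_all[rows], technique)
    X_land = _design(X_all, technique)
    if splits is None:
        splits = _splits(rows.size, y, cfg, sp_idx)

    tech_idx = TECHNIQUES.index(technique)
    fits: list[ReplicateFit] = []
    skipped: list[int] = []
    for rep, (tr, te) in enumerate(splits):
        if y[tr].sum() < 2 or te.size == 0 or len(np.unique(y[te])) < 2:
            skipped.append(rep)
            logger.info("fit_species(%s, %s): replicate %d skipped "
                        "(degenerate split)", species, technique, rep)
            continue
        model_seed = int(np.random.SeedSequence(
            [cfg.seed, sp_idx, tech_idx, rep, 0x4D]).generate_state(1)[0]
            % (2**31))
        model = _make_model(technique, cfg, model_seed)
        model.fit(X[tr], y[tr])
        pred_land = model.predict_proba(X_land)[:, 1]
        scores = evaluate(pred_land[rows[te]], y[te])
        fits.append(ReplicateFit(rep, tr, te, pred_land, scores))
    return SDMFit(species, technique, fits, skipped)


# ---------------------------------------------------------------------------
# ensemble + stacking
# ---------------------------------------------------------------------------

@dataclass
class EnsembleResult:
    """Per-species ensemble: member binary maps and their consensus."""

    species: str
    members: dict[tuple[str, int, str], np.ndarray]
    weights: dict[tuple[str, int, str], float]
    consensus_map: np.ndarray
    fits: dict[str, SDMFit]

    def evaluation_table(self) -> pd.DataFrame:
        rows = []
        for tech, fit in self.fits.items():
            for rf in fit.replicates:
                rows.append(dict(
                    species=self.species, technique=tech,
                    replicate=rf.replicate, auc=rf.scores.auc,
                    tss=rf.scores.tss, thr_max_tss=rf.scores.thr_max_tss,
                    thr_sens_spec=rf.scores.thr_sens_spec,
                ))
        return pd.DataFrame(rows)


def ensemble_species(
    sg: SpeciesGrid,
    species: str,
    env: EnvStack,
    cfg: SDMConfig,
    predictors: Optional[Sequence[str]] = None,
) -> EnsembleResult:
    """Fit all configured techniques for one species and build the
    threshold-consensus binary map.

    Members are (technique, replicate, threshold-rule) binary maps; the
    vote is weighted by replicate TSS (clipped at zero) unless
    ``cfg.weighted_consensus`` is off.
    """
    sp_idx = sg.species_ids.index(species)
    background = _background(sg, sp_idx, cfg)
    pres = np.flatnonzero(sg.occupancy[:, sp_idx])
    y = np.concatenate([np.ones(pres.size, dtype=int),
                        np.zeros(background.size, dtype=int)])
    splits = _splits(pres.size + background.size, y, cfg, sp_idx)

    members: dict[tuple[str, int, str], np.ndarray] = {}
    weights: dict[tuple[str, int, str], float] = {}
    fits: dict[str, SDMFit] = {}
    for tech in cfg.techniques:
        fit = fit_species(sg, species, env, tech, cfg, predictors,
                          background=background, splits=splits)
        fits[tech] = fit
        for rf in fit.replicates:
            for rule in cfg.threshold_rules:
                thr = (rf.scores.thr_max_tss if rule == "max_tss"
                       else rf.scores.thr_sens_spec)
                key = (tech, rf.replicate, rule)
                members[key] = binarize(rf.prediction, thr)
                weights[key] = (max(rf.scores.tss, 0.0)
                                if cfg.weighted_consensus else 1.0)
    if not members:
        cons = np.zeros(sg.grid.n_land, dtype=bool)
        logger.warning("ensemble_species(%s): no usable member maps", species)
    else:
        cons = consensus(list(members.values()), list(weights.values()))
    return EnsembleResult(species, members, weights, cons, fits)


def fit_ensemble(
    sg: SpeciesGrid,
    env: EnvStack,
    cfg: SDMConfig,
    predictors: Optional[Sequence[str]] = None,
) -> list[EnsembleResult]:
    """Ensemble every species of an (already presence-filtered) grid."""
    if predictors is None:
        predictors = screen_predictors(env, cfg.r_max).retained
    return [ensemble_species(sg, s, env, cfg, predictors)
            for s in sg.species_ids]


def stack(ensembles: Sequence[EnsembleResult], grid) -> RichnessMap:
    """Stacked potential richness: per-pixel sum of consensus presences."""
    if len(ensembles) == 0:
        return RichnessMap(grid, np.zeros(grid.n_land))
    total = np.sum([e.consensus_map for e in ensembles], axis=0).astype(float)
    return RichnessMap(grid, total)


def potential_species_grid(ensembles: Sequence[EnsembleResult],
                           grid) -> SpeciesGrid:
    """Potential species composition: consensus maps as an incidence matrix."""
    ids = [e.species for e in ensembles]
    occ = (np.column_stack([e.consensus_map for e in ensembles])
           if ensembles else np.zeros((grid.n_land, 0), dtype=bool))
    return SpeciesGrid(grid, ids, occ)
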