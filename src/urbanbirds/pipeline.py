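"""Orchestration of the three community hypotheses.

* H1 -- per-species presence/abundance and site-level richness/total
  abundance: all-subsets GLMM selection, conditional averaging, and the
  randomised-null relative-importance verdicts, per season.
* H2 -- community stability: per-site-year turnover scores from binary
  dissimilarities, modeled with a gaussian random-intercept GLMM through
  the same selection machinery.
* H3 -- community composition: none/low/high restaurant strata, pairwise
  PERMANOVA, dispersion tests and NMDS per season.

Everything here is plumbing over the library modules; no quantity is
computed in this layer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import community as cs
from . import ingest
from .glmm import GLMMError
from .selection import (AllSubsetsGLMM, NullCalibration, calibrate_null,
                        decide_meaningful)

DEFAULT_TERMS = ("restaurant_count", "business_count", "cropland",
                 "cultivated_vegetation", "natural_vegetation", "water",
                 "residential", "highly_developed", "soil_desert", "year_num")


@dataclass
class RunConfig:
    """Settings shared by the hypothesis runners."""

    candidate_terms: tuple = DEFAULT_TERMS
    seasons: tuple = ("winter", "spring")
    focal_species: tuple | None = None  # None: 20 most abundant + additions
    extra_species: tuple = ()
    n_most_abundant: int = 20
    delta_cutoff: float = 2.0
    null_iters: int = 100
    n_perm: int = 999
    seed: int = 0
    distance_method: str = "sorensen"


def select_focal_species(responses: pd.DataFrame, n_most_abundant: int = 20,
                         extra: tuple = ()) -> list:
    """The most abundant species by total individuals, plus named additions.

    Ties are broken alphabetically by species code.
    """
    ab_cols = [c for c in responses.columns if c.startswith("abund_")]
    totals = responses[ab_cols].sum()
    totals.index = [c[len("abund_"):] for c in ab_cols]
    ranked = sorted(totals.index, key=lambda s: (-totals[s], s))
    focal = ranked[:n_most_abundant]
    for sp in extra:
        if sp not in focal:
            if sp not in totals.index:
                warnings.warn(f"requested extra species {sp!r} not in data",
                              UserWarning, stacklevel=2)
                continue
            focal.append(sp)
    return focal


def _species_runs(frame, species, terms, cfg, season, thresholds):
    """Dredge + average + verdict for one species' presence and abundance."""
    out = {}
    for response_kind, col_prefix, family in (
            ("presence", "pres_", "binomial"),
            ("species_abundance", "abund_", "poisson")):
        col = f"{col_prefix}{species}"
        y = frame[col]
        if y.nunique() <= 1:
            warnings.warn(f"{col} has zero variance in {season}; skipped",
                          UserWarning, stacklevel=2)
            continue
        work = frame.copy()
        if family == "poisson":
            work[col] = np.round(y.to_numpy(dtype=float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            sel = AllSubsetsGLMM(work, col, terms, "site_id", family)
            res = sel.fit()
        avg = res.average(delta_cutoff=cfg.delta_cutoff)
        verdict = decide_meaningful(avg, thresholds[response_kind])
        out[response_kind] = {"selection": res, "averaged": avg,
                              "verdict": verdict}
    return out


def run_h1(frame_by_season: dict, cfg: RunConfig) -> dict:
    """Species- and site-level selection with null-calibrated verdicts.

    ``frame_by_season`` maps season -> modeling frame (scaled predictors,
    ``pres_*``/``abund_*``/richness/total_abundance columns, site_id).
    Returns a nested report dict; every stochastic element carries the
    seed it used.
    """
    terms = list(cfg.candidate_terms)
    report = {"hypothesis": "H1", "seasons": {}, "seed": cfg.seed}
    rng = np.random.default_rng(cfg.seed)
    for season in cfg.seasons:
        frame = frame_by_season[season]
        focal = (list(cfg.focal_species) if cfg.focal_species is not None
                 else select_focal_species(frame, cfg.n_most_abundant,
                                           cfg.extra_species))
        if not focal:
            raise GLMMError("empty focal species list")
        pres_cols = [f"pres_{s}" for s in focal]
        ab_cols = [f"abund_{s}" for s in focal]
        # null thresholds shared across species within a season, with the
        # randomisation parameters taken from the focal-community averages
        p_bar = float(frame[pres_cols].to_numpy().mean())
        lam_bar = float(frame[ab_cols].to_numpy().mean())
        thresholds = {}
        proto = frame.copy()
        proto["_null_y"] = 0.0
        for kind, fam, params in (
                ("presence", "binomial", {"p": p_bar}),
                ("species_abundance", "poisson", {"lambda": lam_bar}),
                ("richness", "poisson",
                 {"lambda": float(frame["richness"].mean())}),
                ("total_abundance", "poisson",
                 {"lambda": float(frame["total_abundance"].mean())})):
            sel = AllSubsetsGLMM(proto, "_null_y", terms, "site_id", fam)
            thresholds[kind] = calibrate_null(
                sel, kind, n_iter=cfg.null_iters,
                seed=int(rng.integers(2 ** 31)), params=params,
                delta_cutoff=cfg.delta_cutoff)
        season_rep = {"focal_species": focal,
                      "null_thresholds": {k: v.threshold
                                          for k, v in thresholds.items()},
                      "species": {}, "site_level": {}}
        # screening correlations between focal species and restaurants
        from scipy.stats import spearmanr
        season_rep["restaurant_correlations"] = {
            s: float(spearmanr(frame[f"abund_{s}"],
                               frame["restaurant_count"]).statistic)
            for s in focal}
        for sp in focal:
            season_rep["species"][sp] = _species_runs(
                frame, sp, terms, cfg, season, thresholds)
        for kind, col, fam in (("richness", "richness", "poisson"),
                               ("total_abundance", "total_abundance",
                                "poisson")):
            work = frame.copy()
            work[col] = np.round(work[col].to_numpy(dtype=float))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                sel = AllSubsetsGLMM(work, col, terms, "site_id", fam)
                res = sel.fit()
            avg = res.average(delta_cutoff=cfg.delta_cutoff)
            season_rep["site_level"][kind] = {
                "selection": res, "averaged": avg,
                "verdict": decide_meaningful(avg, thresholds[kind])}
        report["seasons"][season] = season_rep
    return report


def run_h2(responses: pd.DataFrame, covariates: pd.DataFrame,
           cfg: RunConfig) -> dict:
    """Community turnover vs predictors, per season.

    Builds the presence matrix per season, computes per-site-year turnover
    scores, fits the gaussian all-subsets GLMM, and calibrates the
    dissimilarity null (gaussian with the observed score mean/sd).
    """
    report = {"hypothesis": "H2", "seasons": {}, "seed": cfg.seed}
    rng = np.random.default_rng(cfg.seed + 1)
    terms = list(cfg.candidate_terms)
    for season in cfg.seasons:
        mat = cs.build_community_matrix(responses, season)
        scores = cs.site_dissimilarity_scores(mat, method=cfg.distance_method)
        frame, _ = ingest.build_modeling_frame(
            scores.assign(season=season), covariates)
        if frame["site_id"].nunique() < 2:
            raise GLMMError("all sites single-year; turnover model impossible")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            sel = AllSubsetsGLMM(frame, "dissimilarity", terms, "site_id",
                                 "gaussian")
            res = sel.fit()
            avg = res.average(delta_cutoff=cfg.delta_cutoff)
            cal = calibrate_null(sel, "dissimilarity", n_iter=cfg.null_iters,
                                 seed=int(rng.integers(2 ** 31)),
                                 delta_cutoff=cfg.delta_cutoff)
        verdict = decide_meaningful(avg, cal)
        report["seasons"][season] = {
            "n_obs": len(frame), "scores": scores, "selection": res,
            "averaged": avg, "null": cal, "verdict": verdict,
            "table": verdict[["beta", "relative_importance", "n_models",
                              "meaningful"]]}
    return report


def run_h3(responses: pd.DataFrame, covariates: pd.DataFrame,
           cfg: RunConfig) -> dict:
    """Composition by restaurant strata: PERMANOVA, dispersion, NMDS."""
    report = {"hypothesis": "H3", "seasons": {}, "seed": cfg.seed}
    cov = covariates.set_index(["site_id", "year"])
    for season in cfg.seasons:
        mat = cs.build_community_matrix(responses, season)
        rest = cov.loc[mat.index, "restaurant_count"]
        strata = cs.assign_strata(rest)
        counts = strata.value_counts().to_dict()
        by_year = (pd.DataFrame({"stratum": strata.to_numpy(),
                                 "year": mat.index.get_level_values(1)})
                   .value_counts().unstack(fill_value=0).to_dict())
        D = cs.binary_dissimilarity(mat.to_numpy(),
                                    method=cfg.distance_method,
                                    empty_pairs="zero")
        season_rep = {"strata_sizes": counts, "strata_sizes_by_year": by_year,
                      "pairwise": {}, "dispersion": {}}
        labels = strata.to_numpy()
        pairs = [("none", "low"), ("none", "high"), ("low", "high")]
        for a, b in pairs:
            ix = np.isin(labels, (a, b))
            if min(counts.get(a, 0), counts.get(b, 0)) < 2:
                warnings.warn(f"stratum pair {a}/{b} too small in {season}; "
                              "skipped", UserWarning, stacklevel=2)
                continue
            sub = D[np.ix_(ix, ix)]
            pr = cs.permanova(sub, labels[ix], n_perm=cfg.n_perm,
                              seed=cfg.seed + 2)
            dr = cs.beta_dispersion(sub, labels[ix], n_perm=cfg.n_perm,
                                    seed=cfg.seed + 3)
            season_rep["pairwise"][f"{a}_vs_{b}"] = {
                "permanova_F": pr.pseudo_F, "permanova_R2": pr.R2,
                "permanova_p": pr.p_value, "dispersion_F": dr.F,
                "dispersion_p": dr.p_value,
                "mean_dist_to_centroid": dr.group_mean_distances}
        nm = cs.nmds(D, k=2, n_starts=50, seed=cfg.seed + 4)
        season_rep["nmds"] = {"stress": nm.stress,
                              "shepard_r2": nm.shepard_r2,
                              "coordinates": nm.coordinates,
                              "converged": nm.converged}
        report["seasons"][season] = season_rep
    return report


# ----------------------------------------------------------------------
def verdict_frame(report: dict, season: str, response_kind: str) -> pd.DataFrame:
    """Collect per-species restaurant rows from an H1 report into one
    table (beta, RI, meaningful), mirroring the published summary layout."""
    rows = []
    for sp, runs in report["seasons"][season]["species"].items():
        if response_kind not in runs:
            continue
        v = runs[response_kind]["verdict"]
        r = v.loc["restaurant_count"]
        rows.append({"species": sp, "beta": r.beta,
                     "relative_importance": r.relative_importance,
                     "meaningful": bool(r.meaningful)})
    return pd.DataFrame(rows).set_index("species")


def report_to_json(report: dict, path):
    """Serialise a report (tables flattened) for provenance."""

    def conv(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, pd.DataFrame):
            return obj.to_dict(orient="index")
        if isinstance(obj, pd.Series):
            return obj.to_dict()
        if isinstance(obj, NullCalibration):
            return obj.to_dict()
        if hasattr(obj, "table") and hasattr(obj, "n_top"):  # AveragedResults
            return {"n_top": obj.n_top,
                    "table": obj.table.to_dict(orient="index")}
        if hasattr(obj, "subsets") and hasattr(obj, "weight"):
            return {"n_models": len(obj.subsets),
                    "best_terms": list(obj.subsets[0]),
                    "best_aic": float(obj.models[0].aic)}
        if isinstance(obj, dict):
            return {str(k): conv(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [conv(v) for v in obj]
        return obj

    with open(path, "w") as fh:
        json.dump(conv(report), fh, indent=1, default=str)
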