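"""Survey, business and land-cover ingestion for point-count analyses.

Turns raw inputs -- point-count detection records, geocoded business
records, and per-site land-use/land-cover (LULC) fraction tables -- into
the modeling frame consumed by the GLMM and community modules:

* detection filtering (flyovers always dropped; heard-only detections
  dropped for abundance responses),
* 1-km circular-buffer counts of businesses and restaurants around each
  survey point (restaurants defined by a configurable NAICS-style category
  code list),
* iterative merging of rank-correlated LULC categories (Spearman rho above
  a threshold, 0.7 by default), with the published Phoenix merge available
  as a preset,
* z-scoring of predictors, and
* construction of the four season responses: richness, total abundance,
  per-species presence and per-species mean abundance, under the
  "observed on at least two visits" inclusion rule.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

SEASONS = ("winter", "spring")
DETECTIONS = ("seen", "heard", "both")

#: NAICS-style category codes treated as restaurants by default:
#: full-service restaurants, limited-service restaurants and other
#: prepared-food services; drinking places (7224xx) are excluded.
DEFAULT_RESTAURANT_CODES = ("722511", "722513", "722514", "722515", "7225")

#: The published merge of the 11 raw Phoenix LULC categories into 7.
PHOENIX_LULC_MERGE = {
    "cropland": ["active_cropland", "inactive_cropland"],
    "residential": ["residential", "residential_white_roof"],
    "highly_developed": ["asphalt", "concrete_building", "urban_mixture"],
    "cultivated_vegetation": ["cultivated_vegetation"],
    "natural_vegetation": ["natural_vegetation"],
    "water": ["water"],
    "soil_desert": ["soil_desert"],
}


class IngestError(ValueError):
    """Malformed input data."""


# ----------------------------------------------------------------------
def filter_detections(records: pd.DataFrame,
                      purpose: str = "presence") -> pd.DataFrame:
    """Apply the detection filters, preserving input order.

    Flyovers are always excluded.  For ``purpose="abundance"`` heard-only
    detections are excluded too (counts based on auditory detections alone
    are unreliable); for ``purpose="presence"`` they are retained.
    """
    if purpose not in ("abundance", "presence"):
        raise IngestError(f"unknown purpose {purpose!r}")
    if len(records) == 0:
        return records.copy()
    bad = ~records["detection"].isin(DETECTIONS)
    if bad.any():
        rows = records.index[bad].tolist()[:5]
        raise IngestError(f"unknown detection label(s) at rows {rows}")
    keep = ~records["flyover"].astype(bool)
    if purpose == "abundance":
        keep &= records["detection"].isin(("seen", "both"))
    return records.loc[keep].copy()


# ----------------------------------------------------------------------
def count_in_buffer(sites: pd.DataFrame, businesses: pd.DataFrame,
                    radius_m: float = 1000.0,
                    category_filter=None) -> pd.DataFrame:
    """Businesses within ``radius_m`` of each site, per site-year.

    Both tables must carry projected coordinates in meters (``x``, ``y``).
    The buffer is a closed ball: a record at exactly ``radius_m`` counts.
    Returns a frame with columns site_id, year, count.
    """
    if radius_m <= 0:
        raise IngestError("radius must be positive")
    for df, cols, name in ((sites, ("site_id", "x", "y"), "sites"),
                           (businesses, ("year", "x", "y"), "businesses")):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise IngestError(f"{name} table missing columns {missing}")
        xy = df[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise IngestError(f"non-finite coordinates in {name} table")
    years = sorted(businesses["year"].unique()) if len(businesses) else []
    if category_filter is not None:
        cats = {str(c) for c in category_filter}
        businesses = businesses[businesses["category_code"].astype(str)
                                .isin(cats)]
    site_xy = sites[["site_id", "x", "y"]].drop_duplicates("site_id")
    out = []
    for year in years:
        sub = businesses[businesses["year"] == year]
        if len(sub):
            tree = cKDTree(sub[["x", "y"]].to_numpy(dtype=float))
            # closed-ball convention: scale radius by (1 + eps) then prune
            idx = tree.query_ball_point(
                site_xy[["x", "y"]].to_numpy(dtype=float), r=radius_m * (1 + 1e-9))
            pts = sub[["x", "y"]].to_numpy(dtype=float)
            for sid, (sx, sy), neigh in zip(site_xy["site_id"],
                                            site_xy[["x", "y"]].to_numpy(float),
                                            idx):
                if neigh:
                    d = np.hypot(pts[neigh, 0] - sx, pts[neigh, 1] - sy)
                    cnt = int((d <= radius_m * (1 + 1e-12)).sum())
                else:
                    cnt = 0
                out.append((sid, year, cnt))
        else:
            for sid in site_xy["site_id"]:
                out.append((sid, year, 0))
    return pd.DataFrame(out, columns=["site_id", "year", "count"])


# ----------------------------------------------------------------------
def merge_collinear(raw_lulc: pd.DataFrame, rho_threshold: float = 0.7,
                    preset: str | None = None,
                    id_cols=("site_id", "year")):
    """Merge rank-correlated LULC fraction columns.

    Iteratively sums the pair of category columns with the highest Spearman
    correlation until no pair exceeds ``rho_threshold``.  Total cover per
    row is conserved.  ``preset="phoenix"`` applies the published 11-to-7
    category merge instead of the data-driven procedure.

    Returns ``(merged_frame, report)`` where ``report`` lists the merges in
    the order applied.
    """
    id_cols = [c for c in id_cols if c in raw_lulc.columns]
    cats = [c for c in raw_lulc.columns if c not in id_cols]
    if preset == "phoenix":
        missing = [c for group in PHOENIX_LULC_MERGE.values() for c in group
                   if c not in cats]
        if missing:
            raise IngestError(f"phoenix preset needs raw categories {missing}")
        out = raw_lulc[id_cols].copy()
        report = []
        for merged, group in PHOENIX_LULC_MERGE.items():
            out[merged] = raw_lulc[group].sum(axis=1)
            if len(group) > 1:
                report.append({"merged": merged, "from": list(group),
                               "rho": None})
        return out, report
    if not 0 < rho_threshold < 1:
        raise IngestError("rho_threshold must be in (0, 1)")
    if len(raw_lulc) < 3:
        raise IngestError("need at least 3 rows to estimate correlations")
    work = raw_lulc[cats].copy()
    constant = [c for c in work.columns if work[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant LULC column(s) excluded from merging: "
                      f"{constant}", UserWarning, stacklevel=2)
    report = []
    while True:
        cols = [c for c in work.columns if c not in constant]
        best = None
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                rho = spearmanr(work[a], work[b]).statistic
                if np.isnan(rho):
                    continue
                if rho > rho_threshold and (best is None or rho > best[2]):
                    best = (a, b, rho)
        if best is None:
            break
        a, b, rho = best
        name = f"{a}+{b}"
        work[name] = work[a] + work[b]
        work = work.drop(columns=[a, b])
        report.append({"merged": name, "from": [a, b], "rho": float(rho)})
    out = pd.concat([raw_lulc[id_cols].reset_index(drop=True),
                     work.reset_index(drop=True)], axis=1)
    return out, report


# ----------------------------------------------------------------------
def zscore(frame: pd.DataFrame, columns=None):
    """Standardise columns to mean 0, SD 1 (SD with n-1 denominator).

    Returns ``(scaled_frame, scaling)`` where ``scaling`` maps each column
    to its ``(mean, sd)`` for back-transformation.  Zero-variance columns
    raise rather than silently producing NaN.
    """
    out = frame.copy()
    if columns is None:
        columns = [c for c in frame.columns
                   if pd.api.types.is_numeric_dtype(frame[c])]
    scaling = {}
    for c in columns:
        x = frame[c].to_numpy(dtype=float)
        mu = float(x.mean())
        sd = float(x.std(ddof=1))
        if sd <= 0 or not np.isfinite(sd):
            raise IngestError(f"column {c!r} has zero variance; cannot scale")
        out[c] = (x - mu) / sd
        scaling[c] = (mu, sd)
    return out, scaling


# ----------------------------------------------------------------------
def build_responses(records: pd.DataFrame, visits: pd.DataFrame | None = None,
                    min_obs: int = 2, presence_rule: str = "visits",
                    total_rule: str = "per_species_max") -> pd.DataFrame:
    """Season responses per site-season-year.

    * richness: number of species meeting the inclusion rule,
    * presence per species: 1 iff the species meets the inclusion rule
      (default: detected on >= ``min_obs`` distinct visits; set
      ``presence_rule="individuals"`` to count individuals instead),
    * abundance per species: mean count over all visits (zeros included),
    * total_abundance: per-species maximum count across visits, summed over
      included species (``total_rule="overall_max"`` sums a single overall
      maximum instead).

    ``records`` must already be filtered for the relevant purpose.  The
    visit universe is taken from ``visits`` (site_id, year, season,
    visit_id) when given, else inferred from the records; site-season-years
    with zero visits are excluded with a warning.

    Returns a wide frame: site_id, year, season, richness, total_abundance,
    pres_<species> and abund_<species> columns.
    """
    if presence_rule not in ("visits", "individuals"):
        raise IngestError(f"unknown presence_rule {presence_rule!r}")
    if total_rule not in ("per_species_max", "overall_max"):
        raise IngestError(f"unknown total_rule {total_rule!r}")
    key = ["site_id", "year", "season"]
    if visits is None:
        visits = records[key + ["visit_id"]].drop_duplicates()
    else:
        visits = visits[key + ["visit_id"]].drop_duplicates()
    n_visits = visits.groupby(key, sort=True)["visit_id"].nunique()
    empty = n_visits[n_visits == 0]
    if len(empty):
        warnings.warn(f"{len(empty)} site-season-years with no visits "
                      "excluded", UserWarning, stacklevel=2)
        n_visits = n_visits[n_visits > 0]
    species = sorted(records["species_code"].unique())
    # per site-season-year-species-visit totals (a species may have several
    # records on one visit, e.g. seen and heard separately)
    per_visit = (records.groupby(key + ["species_code", "visit_id"],
                                 sort=False)["count"].sum())
    grp = per_visit.groupby(key + ["species_code"])
    agg = pd.DataFrame({
        "n_visits_detected": grp.apply(lambda s: int((s > 0).sum())),
        "n_individuals": grp.sum(),
        "sum_count": grp.sum(),
        "max_count": grp.max(),
    })
    rows = []
    for ssy, nv in n_visits.items():
        site, year, season = ssy
        row = {"site_id": site, "year": year, "season": season}
        try:
            sub = agg.loc[ssy]
        except KeyError:
            sub = pd.DataFrame(columns=agg.columns)
        included = []
        total = 0.0
        overall_max = 0.0
        for sp in species:
            if sp in sub.index:
                rec = sub.loc[sp]
                if presence_rule == "visits":
                    inc = rec["n_visits_detected"] >= min_obs
                else:
                    inc = rec["n_individuals"] >= min_obs
                pres = int(bool(inc))
                abund = float(rec["sum_count"]) / nv
                mx = float(rec["max_count"])
            else:
                pres, abund, mx = 0, 0.0, 0.0
            row[f"pres_{sp}"] = pres
            row[f"abund_{sp}"] = abund
            if pres:
                included.append(sp)
                total += mx
            overall_max = max(overall_max, mx)
        row["richness"] = len(included)
        row["total_abundance"] = (total if total_rule == "per_species_max"
                                  else overall_max)
        rows.append(row)
    lead = ["site_id", "year", "season", "richness", "total_abundance"]
    out = pd.DataFrame(rows)
    return out[lead + [c for c in out.columns if c not in lead]]


# ----------------------------------------------------------------------
def build_modeling_frame(responses: pd.DataFrame, covariates: pd.DataFrame,
                         predictor_cols=None):
    """Join season responses with site-year covariates and scale predictors.

    ``covariates`` must have one row per site-year with restaurant_count,
    business_count, merged LULC fractions and year.  Predictors (including
    year, which enters as a scaled numeric covariate) are z-scored across
    the joined frame.  Returns ``(frame, scaling)``.
    """
    cov = covariates.copy()
    if predictor_cols is None:
        predictor_cols = [c for c in cov.columns
                          if c not in ("site_id", "x", "y")]
    merged = responses.merge(cov, on=["site_id", "year"], how="inner",
                             suffixes=("", "_cov"))
    if len(merged) == 0:
        raise IngestError("responses and covariates share no site-years")
    merged["year_num"] = merged["year"].astype(float)
    scale_cols = [c for c in predictor_cols if c != "year"] + ["year_num"]
    scaled, scaling = zscore(merged, scale_cols)
    return scaled, scaling
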