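"""Permutation community statistics on presence/absence matrices.

Covers the community-level analyses: binary dissimilarity (Sørensen by
default, the presence/absence form of Bray-Curtis; Jaccard optional),
multiple response permutation procedure (MRPP) with per-site-year
dissimilarity scores for the turnover model, PERMANOVA, the multivariate
homogeneity-of-dispersion test, non-metric multidimensional scaling, and
the none/low/high restaurant strata used to group sites.

Distance matrices are plain square numpy arrays (symmetric, zero
diagonal); helpers convert to ``skbio.DistanceMatrix`` where a scikit-bio
backend is used (PERMANOVA, dispersion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from skbio import DistanceMatrix as _SkbioDM
from skbio.stats.distance import permanova as _skbio_permanova
from skbio.stats.distance import permdisp as _skbio_permdisp


class CommunityError(ValueError):
    """Invalid community-analysis input."""


# ----------------------------------------------------------------------
def build_community_matrix(responses: pd.DataFrame, season: str,
                           min_total_obs: int = 2) -> pd.DataFrame:
    """Site-year x species presence matrix for one season.

    The species universe is restricted to species meeting the inclusion
    rule (presence recorded in the responses frame) in at least
    ``min_total_obs`` site-year rows... the universe the published analysis
    describes is "species observed at least twice across all point counts";
    here a species enters the universe if it was ever included (its
    presence column is 1 somewhere), which applies the same >=2-visit rule
    at the site level.  Rows are indexed by (site_id, year).
    """
    sub = responses[responses["season"] == season]
    if len(sub) == 0:
        raise CommunityError(f"no rows for season {season!r}")
    pres_cols = [c for c in sub.columns if c.startswith("pres_")]
    mat = sub.set_index(["site_id", "year"])[pres_cols]
    mat.columns = [c[len("pres_"):] for c in pres_cols]
    keep = mat.columns[mat.sum(axis=0) >= 1]
    return mat[keep].astype(int)


# ----------------------------------------------------------------------
def binary_dissimilarity(matrix, method: str = "sorensen",
                         empty_pairs: str = "error") -> np.ndarray:
    """Pairwise dissimilarity between binary community rows.

    Sørensen: ``(b + c) / (2a + b + c)`` with ``a`` shared presences and
    ``b``, ``c`` the uniques; Jaccard: ``(b + c) / (a + b + c)``.  A pair
    of empty communities has undefined dissimilarity; pass
    ``empty_pairs="zero"`` to score it 0 with a warning.
    """
    X = np.asarray(matrix, dtype=bool)
    if X.ndim != 2:
        raise CommunityError("community matrix must be 2-D")
    metric = {"sorensen": "dice", "jaccard": "jaccard"}.get(method)
    if metric is None:
        raise CommunityError(f"unknown method {method!r}")
    empty = ~X.any(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = squareform(pdist(X, metric=metric))
    if empty.sum() >= 2:
        if empty_pairs == "zero":
            warnings.warn("empty-vs-empty community pairs scored as 0",
                          UserWarning, stacklevel=2)
            ii = np.flatnonzero(empty)
            D[np.ix_(ii, ii)] = 0.0
        else:
            raise CommunityError(
                "dissimilarity undefined between empty communities "
                "(pass empty_pairs='zero' to score them 0)")
    np.fill_diagonal(D, 0.0)
    return D


def _check_square(D):
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise CommunityError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise CommunityError("distance matrix must be symmetric")
    return D


# ----------------------------------------------------------------------
@dataclass
class MRPPResult:
    delta_observed: float
    delta_expected: float
    A_statistic: float
    p_value: float
    within_group_means: dict
    n_perm: int


def mrpp(dist, groups, n_perm: int = 999, seed: int = 0,
         weight: str = "size") -> MRPPResult:
    """Multiple response permutation procedure.

    ``delta`` is the weighted mean within-group dissimilarity (weights
    ``n_g / sum n`` by default; ``weight="size_minus_1"`` uses
    ``(n_g - 1)``-proportional weights).  The p-value is the plus-one
    corrected fraction of label permutations with delta <= observed; the
    chance-corrected effect size is ``A = 1 - delta / E[delta]`` with the
    expectation taken over the permutations.  Singleton groups are
    excluded with a warning.
    """
    D = _check_square(dist)
    labels = np.asarray(groups)
    if labels.shape[0] != D.shape[0]:
        raise CommunityError("groups length mismatch")
    uniq, counts = np.unique(labels, return_counts=True)
    singles = uniq[counts < 2]
    if len(singles):
        warnings.warn(f"singleton group(s) excluded from MRPP: "
                      f"{singles.tolist()}", UserWarning, stacklevel=2)
        keep = ~np.isin(labels, singles)
        D = D[np.ix_(keep, keep)]
        labels = labels[keep]
        uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise CommunityError("MRPP needs at least two groups of size >= 2")
    n = len(labels)
    if weight == "size":
        w = counts / counts.sum()
    elif weight == "size_minus_1":
        w = (counts - 1) / (counts - 1).sum()
    else:
        raise CommunityError(f"unknown weight {weight!r}")

    codes = np.searchsorted(uniq, labels)

    def delta_for(codes_):
        d = 0.0
        means = {}
        for k, gname in enumerate(uniq):
            ix = np.flatnonzero(codes_ == k)
            sub = D[np.ix_(ix, ix)]
            m = float(sub[np.triu_indices(len(ix), 1)].mean())
            means[gname] = m
            d += w[k] * m
        return d, means

    delta_obs, within = delta_for(codes)
    rng = np.random.default_rng(seed)
    perm_deltas = np.empty(n_perm)
    for b in range(n_perm):
        perm_deltas[b] = delta_for(rng.permutation(codes))[0]
    expected = float(perm_deltas.mean())
    p = (float((perm_deltas <= delta_obs + 1e-12).sum()) + 1.0) / (n_perm + 1.0)
    A = 1.0 - delta_obs / expected if expected > 0 else 0.0
    return MRPPResult(delta_observed=float(delta_obs),
                      delta_expected=expected, A_statistic=float(A),
                      p_value=float(p), within_group_means=within,
                      n_perm=n_perm)


# ----------------------------------------------------------------------
def site_dissimilarity_scores(matrix: pd.DataFrame,
                              method: str = "sorensen") -> pd.DataFrame:
    """Per site-year turnover score: mean dissimilarity between one year's
    community and the same site's communities in the other years.

    These are the within-group dissimilarities MRPP aggregates (grouping by
    site), disaggregated back to the observation level so they can serve as
    the response of the turnover GLMM.  Higher = less stable.  Sites with a
    single year are excluded.
    """
    if not isinstance(matrix.index, pd.MultiIndex):
        raise CommunityError("matrix must be indexed by (site_id, year)")
    rows = []
    for site, sub in matrix.groupby(level=0, sort=True):
        if len(sub) < 2:
            continue
        D = binary_dissimilarity(sub.to_numpy(), method=method,
                                 empty_pairs="zero")
        years = sub.index.get_level_values(1)
        n = len(sub)
        for i in range(n):
            score = float(D[i, np.arange(n) != i].mean())
            rows.append({"site_id": site, "year": years[i],
                         "dissimilarity": score})
    if not rows:
        raise CommunityError("no site has two or more years of data")
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_perm: int


def permanova(dist, groups, n_perm: int = 999, seed: int = 0) -> PermanovaResult:
    """Permutational multivariate ANOVA (one-way) on a distance matrix.

    The pseudo-F partitions squared dissimilarities among vs within groups;
    the p-value permutes group labels (scikit-bio backend).  ``R2`` is the
    among-group share of total sum of squares.
    """
    D = _check_square(dist)
    labels = np.asarray(groups).astype(str)
    if len(np.unique(labels)) < 2:
        raise CommunityError("PERMANOVA needs at least two groups")
    if np.allclose(D, 0.0):
        # no multivariate variation at all: nothing to partition
        return PermanovaResult(pseudo_F=0.0, R2=0.0, p_value=1.0,
                               n_perm=n_perm)
    dm = _SkbioDM(D)
    res = _skbio_permanova(dm, labels, permutations=n_perm, seed=seed)
    F = float(res["test statistic"])
    n = len(labels)
    k = len(np.unique(labels))
    # F = (SSa/(k-1)) / (SSw/(n-k))  =>  R2 = SSa/SSt from F alone
    R2 = F * (k - 1) / (F * (k - 1) + (n - k))
    return PermanovaResult(pseudo_F=F, R2=float(R2),
                           p_value=float(res["p-value"]), n_perm=n_perm)


# ----------------------------------------------------------------------
@dataclass
class DispersionResult:
    F: float
    p_value: float
    group_mean_distances: dict
    n_perm: int


def beta_dispersion(dist, groups, n_perm: int = 999, seed: int = 0) -> DispersionResult:
    """Homogeneity of multivariate dispersions around group centroids.

    Observations are embedded by principal coordinates (negative-eigenvalue
    correction via the imaginary-axis convention), distances to the group
    centroid are computed, and group means are compared with a permutation
    F-test (scikit-bio ``permdisp`` with centroid test).
    """
    D = _check_square(dist)
    labels = np.asarray(groups).astype(str)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise CommunityError(
            "dispersion test needs >= 2 groups with >= 2 members each")
    dm = _SkbioDM(D)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_permdisp(dm, labels, test="centroid",
                              permutations=n_perm, seed=seed,
                              dimensions=D.shape[0] - 1,
                              warn_neg_eigval=False)
    # group mean distance to centroid, recomputed for reporting
    means = _centroid_distances(D, labels)
    return DispersionResult(F=float(res["test statistic"]),
                            p_value=float(res["p-value"]),
                            group_mean_distances=means, n_perm=n_perm)


def _centroid_distances(D, labels):
    """Mean distance to the group centroid in PCoA space (sqrt-corrected
    for negative eigenvalues: d^2 = sum_pos - sum_neg, clamped at 0)."""
    n = D.shape[0]
    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    vals, vecs = np.linalg.eigh((G + G.T) / 2)
    pos = vals > 1e-10
    neg = vals < -1e-10
    Xp = vecs[:, pos] * np.sqrt(vals[pos])
    Xn = vecs[:, neg] * np.sqrt(-vals[neg])
    means = {}
    for gname in np.unique(labels):
        ix = labels == gname
        dp = ((Xp[ix] - Xp[ix].mean(axis=0)) ** 2).sum(axis=1)
        dn = ((Xn[ix] - Xn[ix].mean(axis=0)) ** 2).sum(axis=1) if Xn.size else 0.0
        d2 = np.clip(dp - dn, 0.0, None)
        means[str(gname)] = float(np.sqrt(d2).mean())
    return means


# ----------------------------------------------------------------------
@dataclass
class NMDSResult:
    coordinates: np.ndarray
    stress: float
    shepard_r2: float
    k: int
    converged: bool


def nmds(dist, k: int = 2, n_starts: int = 50, seed: int = 0,
         max_iter: int = 300, eps: float = 1e-6) -> NMDSResult:
    """Non-metric multidimensional scaling (Kruskal stress-1).

    SMACOF majorisation with monotone (isotonic) regression, best of
    ``n_starts`` random initialisations (scikit-learn backend).  The
    non-metric fit statistic is ``shepard_r2 = 1 - stress^2``.
    """
    from sklearn.manifold import MDS
    D = _check_square(dist)
    if D.shape[0] < k + 2:
        raise CommunityError(f"need at least {k + 2} observations for k={k}")
    if np.allclose(D, 0.0):
        # all observations identical: any embedding is exact
        return NMDSResult(coordinates=np.zeros((D.shape[0], k)), stress=0.0,
                          shepard_r2=1.0, k=k, converged=True)
    model = MDS(n_components=k, metric_mds=False, metric="precomputed",
                n_init=n_starts, max_iter=max_iter, eps=eps,
                random_state=seed, init="random", normalized_stress=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        coords = model.fit_transform(D)
    stress = float(model.stress_)
    if not np.isfinite(stress):
        raise CommunityError("NMDS failed to produce a finite stress")
    return NMDSResult(coordinates=coords, stress=stress,
                      shepard_r2=float(1.0 - stress ** 2), k=k,
                      converged=bool(model.n_iter_ < max_iter))


# ----------------------------------------------------------------------
def assign_strata(restaurant_counts) -> pd.Series:
    """Restaurant strata: 0 -> none, 1-2 -> low, >2 -> high."""
    x = pd.Series(restaurant_counts)
    vals = x.to_numpy(dtype=float)
    if (vals < 0).any():
        raise CommunityError("negative restaurant counts")
    out = np.where(vals == 0, "none", np.where(vals <= 2, "low", "high"))
    return pd.Series(out, index=x.index, name="stratum")
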