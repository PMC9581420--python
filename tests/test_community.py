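"""Dissimilarity, MRPP/PERMANOVA permutation oracles, dispersion, NMDS."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from urbanbirds.community import (CommunityError, assign_strata,
                                  beta_dispersion, binary_dissimilarity,
                                  build_community_matrix, mrpp, nmds,
                                  permanova, site_dissimilarity_scores)


# ----------------------------------------------------------------------
# exact-enumeration oracles for the 6-observation, 2-group toy
def exact_mrpp_p(D, n_a=3):
    n = D.shape[0]
    deltas = []
    for combo in itertools.combinations(range(n), n_a):
        ga = list(combo)
        gb = [i for i in range(n) if i not in combo]
        da = np.mean([D[i, j] for i, j in itertools.combinations(ga, 2)])
        db = np.mean([D[i, j] for i, j in itertools.combinations(gb, 2)])
        deltas.append((len(ga) * da + len(gb) * db) / n)
    deltas = np.array(deltas)
    observed = deltas[0]  # first combination = (0, 1, 2), the true labels
    return float((deltas <= observed + 1e-12).mean())


def exact_permanova_p(D, n_a=3):
    n = D.shape[0]

    def pseudo_f(labels):
        ss_t = (D[np.triu_indices(n, 1)] ** 2).sum() / n
        ss_w = 0.0
        for gname in set(labels):
            ix = [i for i, l in enumerate(labels) if l == gname]
            sub = D[np.ix_(ix, ix)]
            ss_w += (sub[np.triu_indices(len(ix), 1)] ** 2).sum() / len(ix)
        ss_a = ss_t - ss_w
        return (ss_a / 1) / (ss_w / (n - 2))

    fs = []
    for combo in itertools.combinations(range(n), n_a):
        labels = ["a" if i in combo else "b" for i in range(n)]
        fs.append(pseudo_f(labels))
    fs = np.array(fs)
    return float((fs >= fs[0] - 1e-12).mean())


def _two_group_toy():
    rng = np.random.default_rng(5)
    X = np.vstack([rng.binomial(1, 0.85, (3, 12)),
                   rng.binomial(1, 0.25, (3, 12))])
    return binary_dissimilarity(X), np.array(["a"] * 3 + ["b"] * 3)


# ----------------------------------------------------------------------
class TestBinaryDissimilarity:
    def test_hand_values(self):
        M = np.array([[1, 1, 0, 0],
                      [1, 0, 1, 0],
                      [1, 1, 0, 0],
                      [0, 0, 1, 1]])
        D = binary_dissimilarity(M, "sorensen")
        assert D[0, 1] == pytest.approx(0.5)     # a=1, b=1, c=1 -> 2/4
        assert D[0, 2] == pytest.approx(0.0)     # identical
        assert D[0, 3] == pytest.approx(1.0)     # disjoint
        J = binary_dissimilarity(M, "jaccard")
        assert J[0, 1] == pytest.approx(2.0 / 3.0)

    def test_empty_pair_policy(self):
        M = np.array([[0, 0], [0, 0], [1, 0]])
        with pytest.raises(CommunityError):
            binary_dissimilarity(M)
        with pytest.warns(UserWarning):
            D = binary_dissimilarity(M, empty_pairs="zero")
        assert D[0, 1] == 0.0

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_valid_distance_matrix_properties(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.binomial(1, 0.5, (6, 10))
        M[:, 0] = 1  # no empty communities
        D = binary_dissimilarity(M)
        assert np.all((D >= 0) & (D <= 1))
        np.testing.assert_allclose(D, D.T)
        assert np.all(np.diag(D) == 0)


class TestMRPP:
    def test_identical_observations_give_zero_delta(self):
        M = np.tile([1, 0, 1, 0, 1], (6, 1))
        D = binary_dissimilarity(M)
        r = mrpp(D, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
        assert r.delta_observed == 0.0

    def test_permutation_p_matches_exact_enumeration(self):
        D, g = _two_group_toy()
        exact = exact_mrpp_p(D)
        r = mrpp(D, g, n_perm=10_000, seed=3)
        assert abs(r.p_value - exact) <= 0.02
        assert 0 < r.A_statistic < 1

    def test_singleton_group_excluded(self):
        D, g = _two_group_toy()
        labels = np.array(["a", "a", "a", "b", "b", "c"])
        with pytest.warns(UserWarning, match="singleton"):
            r = mrpp(D, labels, n_perm=99, seed=0)
        assert set(r.within_group_means) == {"a", "b"}

    def test_null_p_values_roughly_uniform(self):
        # structureless data, random labels: p should be ~U(0,1)
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(200):
            X = rng.binomial(1, 0.5, (12, 15))
            X[:, 0] = 1
            D = binary_dissimilarity(X)
            labels = rng.permutation(["a"] * 6 + ["b"] * 6)
            ps.append(mrpp(D, labels, n_perm=99,
                           seed=int(rng.integers(2 ** 31))).p_value)
        ps = np.asarray(ps)
        # coarse uniformity checks robust to the discrete permutation grid
        assert abs(ps.mean() - 0.5) < 0.08
        assert abs((ps <= 0.25).mean() - 0.25) < 0.1


class TestSiteScores:
    def _matrix(self, rows, site_years):
        idx = pd.MultiIndex.from_tuples(site_years,
                                        names=["site_id", "year"])
        return pd.DataFrame(rows, index=idx)

    def test_identical_years_give_zero(self):
        m = self._matrix(np.tile([1, 0, 1], (3, 1)),
                         [("A", 2000), ("A", 2005), ("A", 2010)])
        s = site_dissimilarity_scores(m)
        assert (s["dissimilarity"] == 0).all()

    def test_disjoint_two_year_site_scores_one(self):
        m = self._matrix([[1, 0], [0, 1]], [("A", 2000), ("A", 2005)])
        s = site_dissimilarity_scores(m)
        assert (s["dissimilarity"] == 1.0).all()

    def test_scores_are_row_means_of_within_site_distances(self, rng):
        rows = rng.binomial(1, 0.6, (3, 10))
        rows[:, 0] = 1
        m = self._matrix(rows, [("A", 2000), ("A", 2005), ("A", 2010)])
        D = binary_dissimilarity(rows)
        s = site_dissimilarity_scores(m).set_index("year")["dissimilarity"]
        for i, yr in enumerate([2000, 2005, 2010]):
            expected = D[i, [j for j in range(3) if j != i]].mean()
            assert s[yr] == pytest.approx(expected)

    def test_single_year_sites_excluded(self):
        m = self._matrix([[1, 0], [0, 1], [1, 1]],
                         [("A", 2000), ("A", 2005), ("B", 2000)])
        s = site_dissimilarity_scores(m)
        assert set(s["site_id"]) == {"A"}

    def test_mrpp_delta_equals_weighted_mean_of_scores(self, rng):
        """The per-observation scores disaggregate exactly what MRPP
        aggregates: delta = sum_g w_g * mean within-group distance, and the
        mean of a group's score vector recovers... the same within-group
        mean via the handshake identity."""
        rows = rng.binomial(1, 0.6, (6, 12))
        rows[:, 0] = 1
        m = self._matrix(rows, [("A", 2000), ("A", 2005), ("A", 2010),
                                ("B", 2000), ("B", 2005), ("B", 2010)])
        D = binary_dissimilarity(rows)
        scores = site_dissimilarity_scores(m)
        r = mrpp(D, ["A"] * 3 + ["B"] * 3, n_perm=9, seed=0)
        for site in ("A", "B"):
            grp = scores[scores["site_id"] == site]["dissimilarity"]
            assert grp.mean() == pytest.approx(r.within_group_means[site])
        delta = 0.5 * (scores[scores.site_id == "A"]["dissimilarity"].mean()
                       + scores[scores.site_id == "B"]["dissimilarity"].mean())
        assert delta == pytest.approx(r.delta_observed)


class TestPermanova:
    def test_p_matches_exact_enumeration(self):
        D, g = _two_group_toy()
        exact = exact_permanova_p(D)
        r = permanova(D, g, n_perm=10_000, seed=4)
        assert abs(r.p_value - exact) <= 0.02

    def test_separated_clusters_detected(self, rng):
        X = np.vstack([rng.binomial(1, 0.9, (8, 20)),
                       rng.binomial(1, 0.1, (8, 20))])
        X[:, 0] = 1
        D = binary_dissimilarity(X)
        r = permanova(D, ["a"] * 8 + ["b"] * 8, n_perm=999, seed=0)
        assert r.p_value <= 0.01
        assert 0 < r.R2 < 1

    def test_scale_invariance_of_pseudo_f(self):
        D, g = _two_group_toy()
        r1 = permanova(D, g, n_perm=99, seed=0)
        r2 = permanova(2.0 * D, g, n_perm=99, seed=0)
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F, rel=1e-10)

    def test_single_group_rejected(self):
        D, _ = _two_group_toy()
        with pytest.raises(CommunityError):
            permanova(D, ["a"] * 6, n_perm=99, seed=0)


class TestDispersion:
    def test_identical_communities_have_zero_spread(self):
        M = np.vstack([np.tile([1, 0, 1, 1], (3, 1)),
                       np.tile([0, 1, 1, 0], (3, 1))])
        D = binary_dissimilarity(M)
        r = beta_dispersion(D, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
        assert all(v == pytest.approx(0.0, abs=1e-10)
                   for v in r.group_mean_distances.values())

    def test_tight_vs_spread_cluster(self, rng):
        tight = np.tile(rng.binomial(1, 0.5, 30), (10, 1))
        flip = rng.random((10, 30)) < 0.02
        tight = np.where(flip, 1 - tight, tight)
        spread = rng.binomial(1, 0.5, (10, 30))
        M = np.vstack([tight, spread])
        M[:, 0] = 1
        D = binary_dissimilarity(M)
        r = beta_dispersion(D, ["t"] * 10 + ["s"] * 10, n_perm=999, seed=0)
        assert (r.group_mean_distances["s"]
                > r.group_mean_distances["t"])
        assert r.p_value <= 0.05

    def test_requires_two_members_per_group(self):
        D, _ = _two_group_toy()
        with pytest.raises(CommunityError):
            beta_dispersion(D, ["a"] * 5 + ["b"], n_perm=99, seed=0)


class TestNMDS:
    def test_exactly_embeddable_configuration_has_tiny_stress(self, rng):
        pts = rng.normal(size=(4, 2))
        D = squareform(pdist(pts))
        r = nmds(D, k=2, n_starts=8, seed=0)
        assert r.stress < 0.01
        assert r.shepard_r2 > 0.99

    def test_stress_nonincreasing_in_dimension(self, rng):
        X = rng.binomial(1, 0.5, (12, 20))
        X[:, 0] = 1
        D = binary_dissimilarity(X)
        s2 = nmds(D, k=2, n_starts=16, seed=0).stress
        s3 = nmds(D, k=3, n_starts=16, seed=0).stress
        assert s3 <= s2 + 1e-6

    def test_stress_invariant_to_rotation(self, rng):
        pts = rng.normal(size=(10, 2))
        D = squareform(pdist(pts))
        r = nmds(D, k=2, n_starts=4, seed=1)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        rotated = r.coordinates @ R
        d_orig = pdist(r.coordinates)
        d_rot = pdist(rotated)
        np.testing.assert_allclose(d_orig, d_rot, atol=1e-10)

    def test_too_few_observations_rejected(self):
        with pytest.raises(CommunityError):
            nmds(np.zeros((3, 3)), k=2, n_starts=2, seed=0)


class TestStrata:
    @pytest.mark.parametrize("count,expected", [
        (0, "none"), (1, "low"), (2, "low"), (3, "high"), (28, "high")])
    def test_boundaries(self, count, expected):
        assert assign_strata([count]).iloc[0] == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(CommunityError):
            assign_strata([-1])


class TestCommunityMatrix:
    def test_binary_cells_and_universe(self, small_responses):
        mat = build_community_matrix(small_responses, "winter")
        assert set(np.unique(mat.to_numpy())) <= {0, 1}
        assert (mat.sum(axis=0) >= 1).all()
        assert mat.index.names == ["site_id", "year"]

    def test_unknown_season_rejected(self, small_responses):
        with pytest.raises(CommunityError):
            build_community_matrix(small_responses, "summer")
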