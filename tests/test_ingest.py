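"""Detection filters, buffer counts, collinearity merging, responses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from urbanbirds import ingest
from urbanbirds.ingest import (IngestError, build_responses, count_in_buffer,
                               filter_detections, merge_collinear, zscore)


def _records(rows):
    return pd.DataFrame(rows, columns=["site_id", "year", "season",
                                       "visit_id", "species_code", "count",
                                       "detection", "flyover"])


class TestFilterDetections:
    def test_flyover_always_removed(self):
        rec = _records([("A", 2000, "winter", "v1", "sp1", 2, "seen", True)])
        assert len(filter_detections(rec, "presence")) == 0
        assert len(filter_detections(rec, "abundance")) == 0

    def test_heard_only_dropped_for_abundance_kept_for_presence(self):
        rec = _records([
            ("A", 2000, "winter", "v1", "sp1", 1, "seen", False),
            ("A", 2000, "winter", "v1", "sp2", 1, "heard", False),
            ("A", 2000, "winter", "v1", "sp3", 1, "both", False)])
        ab = filter_detections(rec, "abundance")
        assert set(ab["detection"]) == {"seen", "both"}
        pr = filter_detections(rec, "presence")
        assert len(pr) == 3
        # presence-filtered rows are a superset of abundance-filtered rows
        assert set(map(tuple, ab.to_numpy())) <= set(map(tuple, pr.to_numpy()))
        # input order preserved
        assert list(ab.index) == sorted(ab.index)

    def test_empty_table_passes_through(self):
        rec = _records([])
        assert len(filter_detections(rec, "abundance")) == 0

    def test_unknown_detection_label_names_row(self):
        rec = _records([("A", 2000, "winter", "v1", "sp1", 1, "glimpsed",
                         False)])
        with pytest.raises(IngestError, match="rows \\[0\\]"):
            filter_detections(rec, "presence")


class TestBufferCounts:
    def _sites(self):
        return pd.DataFrame({"site_id": ["A"], "x": [0.0], "y": [0.0]})

    def test_boundary_is_closed(self):
        biz = pd.DataFrame({"business_id": ["b1"], "year": [2000],
                            "category_code": ["722511"],
                            "x": [1000.0], "y": [0.0]})
        out = count_in_buffer(self._sites(), biz, radius_m=1000.0)
        assert out["count"].tolist() == [1]

    def test_distances_counted_exactly(self):
        biz = pd.DataFrame({"business_id": list("abc"), "year": 2000,
                            "category_code": "722511",
                            "x": [500.0, 999.0, 1001.0], "y": 0.0})
        out = count_in_buffer(self._sites(), biz, radius_m=1000.0)
        assert out["count"].tolist() == [2]

    def test_no_businesses_means_zero_counts(self):
        biz = pd.DataFrame({"business_id": ["b"], "year": [2000],
                            "category_code": ["111"],
                            "x": [10.0], "y": [10.0]})
        out = count_in_buffer(self._sites(), biz, radius_m=1000.0,
                              category_filter={"722511"})
        assert out["count"].tolist() == [0]

    def test_monotone_in_radius(self, rng):
        sites = pd.DataFrame({"site_id": ["A", "B"],
                              "x": [0.0, 5000.0], "y": [0.0, 0.0]})
        biz = pd.DataFrame({"business_id": np.arange(200), "year": 2000,
                            "category_code": "x",
                            "x": rng.uniform(-3000, 8000, 200),
                            "y": rng.uniform(-3000, 3000, 200)})
        prev = None
        for r in (200.0, 1000.0, 3000.0):
            counts = count_in_buffer(sites, biz, radius_m=r)["count"]
            if prev is not None:
                assert (counts.to_numpy() >= prev.to_numpy()).all()
            prev = counts

    def test_missing_coordinates_rejected(self):
        biz = pd.DataFrame({"business_id": ["b"], "year": [2000],
                            "category_code": ["x"], "x": [np.nan],
                            "y": [0.0]})
        with pytest.raises(IngestError, match="coordinates"):
            count_in_buffer(self._sites(), biz, 1000.0)


class TestMergeCollinear:
    def test_perfectly_correlated_pair_merges_to_sum(self, rng):
        a = rng.uniform(0, 0.5, 30)
        df = pd.DataFrame({"site_id": np.arange(30), "year": 2000,
                           "a": a, "b": 2 * a, "c": rng.uniform(0, 0.5, 30)})
        merged, report = merge_collinear(df, rho_threshold=0.7)
        assert len(report) == 1
        assert set(report[0]["from"]) == {"a", "b"}
        np.testing.assert_allclose(merged["a+b"], df["a"] + df["b"])

    def test_conserves_total_cover(self, rng):
        cats = {f"c{j}": rng.dirichlet(np.ones(5), 40)[:, j]
                for j in range(5)}
        df = pd.DataFrame({"site_id": np.arange(40), **cats})
        merged, _ = merge_collinear(df, rho_threshold=0.3)
        raw_tot = df.drop(columns="site_id").sum(axis=1)
        new_tot = merged.drop(columns="site_id").sum(axis=1)
        np.testing.assert_allclose(new_tot, raw_tot, atol=1e-12)

    def test_uncorrelated_input_unchanged(self, rng):
        df = pd.DataFrame({"site_id": np.arange(50),
                           "a": rng.normal(size=50),
                           "b": rng.normal(size=50)})
        merged, report = merge_collinear(df, rho_threshold=0.7)
        assert report == []
        assert set(merged.columns) == set(df.columns)

    def test_phoenix_preset_maps_eleven_to_seven(self, rng):
        raw = ["asphalt", "active_cropland", "inactive_cropland", "water",
               "cultivated_vegetation", "natural_vegetation",
               "concrete_building", "residential", "residential_white_roof",
               "urban_mixture", "soil_desert"]
        fracs = rng.dirichlet(np.ones(11), 20)
        df = pd.DataFrame(fracs, columns=raw)
        df.insert(0, "site_id", np.arange(20))
        merged, report = merge_collinear(df, preset="phoenix")
        cats = [c for c in merged.columns if c != "site_id"]
        assert len(cats) == 7
        assert set(cats) == {"cropland", "residential", "highly_developed",
                             "cultivated_vegetation", "natural_vegetation",
                             "water", "soil_desert"}
        np.testing.assert_allclose(
            merged["highly_developed"],
            df[["asphalt", "concrete_building", "urban_mixture"]].sum(axis=1))

    def test_constant_column_flagged_not_merged(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=20),
                           "b": np.zeros(20)})
        with pytest.warns(UserWarning, match="constant"):
            merged, _ = merge_collinear(df, rho_threshold=0.7)
        assert "b" in merged.columns


class TestZscore:
    def test_hand_values(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out, scaling = zscore(df)
        np.testing.assert_allclose(out["x"], [-1.0, 0.0, 1.0])
        assert scaling["x"] == (2.0, 1.0)

    def test_idempotent_on_standardised_column(self, rng):
        x = rng.normal(size=200)
        df = pd.DataFrame({"x": x})
        once, _ = zscore(df)
        twice, _ = zscore(once)
        np.testing.assert_allclose(once["x"], twice["x"], atol=1e-10)

    def test_constant_column_raises(self):
        with pytest.raises(IngestError, match="zero variance"):
            zscore(pd.DataFrame({"x": [1.0, 1.0, 1.0]}))

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=40,
                    unique=True))
    def test_scaled_moments(self, vals):
        out, _ = zscore(pd.DataFrame({"x": vals}))
        assert out["x"].mean() == pytest.approx(0.0, abs=1e-10)
        assert out["x"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)


class TestBuildResponses:
    def _three_visit_records(self, counts, species="sp1"):
        rows = []
        for v, c in enumerate(counts, 1):
            if c > 0:
                rows.append(("A", 2000, "winter", f"v{v}", species, c,
                             "seen", False))
        return _records(rows)

    def _visits(self, n=3):
        return pd.DataFrame({"site_id": "A", "year": 2000,
                             "season": "winter",
                             "visit_id": [f"v{i}" for i in range(1, n + 1)]})

    def test_counts_1_0_2_give_presence_mean_and_max(self):
        rec = self._three_visit_records([1, 0, 2])
        out = build_responses(rec, visits=self._visits())
        row = out.iloc[0]
        assert row["pres_sp1"] == 1
        assert row["abund_sp1"] == pytest.approx(1.0)
        assert row["total_abundance"] == pytest.approx(2.0)
        assert row["richness"] == 1

    def test_single_observation_excluded_from_richness_and_presence(self):
        rec = self._three_visit_records([0, 3, 0])
        out = build_responses(rec, visits=self._visits())
        row = out.iloc[0]
        assert row["pres_sp1"] == 0
        assert row["richness"] == 0
        assert row["abund_sp1"] == pytest.approx(1.0)  # mean still reported

    def test_individuals_rule_counts_birds_not_visits(self):
        rec = self._three_visit_records([0, 3, 0])
        out = build_responses(rec, visits=self._visits(),
                              presence_rule="individuals")
        assert out.iloc[0]["pres_sp1"] == 1

    def test_no_detections_gives_zero_richness_and_total(self):
        rec = _records([("A", 2000, "winter", "v1", "sp1", 1, "seen", False)])
        out = build_responses(rec, visits=self._visits())
        assert out.iloc[0]["richness"] == 0
        assert out.iloc[0]["total_abundance"] == 0.0

    def test_richness_invariant_to_visit_order(self, rng):
        rows = []
        for v in range(1, 4):
            for sp in ("a", "b", "c"):
                c = int(rng.integers(0, 4))
                if c:
                    rows.append(("A", 2000, "winter", f"v{v}", sp, c,
                                 "seen", False))
        rec = _records(rows)
        shuffled = rec.sample(frac=1.0, random_state=1)
        r1 = build_responses(rec, visits=self._visits())
        r2 = build_responses(shuffled, visits=self._visits())
        assert r1.iloc[0]["richness"] == r2.iloc[0]["richness"]
        assert r1.iloc[0]["total_abundance"] == r2.iloc[0]["total_abundance"]

    def test_total_abundance_bounds_any_single_species_max(self, small_study,
                                                           small_responses):
        ab_max = small_responses[[c for c in small_responses.columns
                                  if c.startswith("abund_")]].max(axis=1)
        pres_any = small_responses[[c for c in small_responses.columns
                                    if c.startswith("pres_")]].max(axis=1)
        mask = pres_any > 0
        assert (small_responses.loc[mask, "total_abundance"]
                >= ab_max[mask]).all()

    def test_site_with_zero_visits_warns(self):
        rec = self._three_visit_records([1, 1, 0])
        visits = pd.concat([self._visits(),
                            pd.DataFrame({"site_id": ["B"], "year": [2000],
                                          "season": ["winter"],
                                          "visit_id": [np.nan]})])
        with pytest.warns(UserWarning, match="no visits"):
            out = build_responses(rec, visits=visits)
        assert set(out["site_id"]) == {"A"}
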