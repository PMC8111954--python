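"""Camera/genetic group sizes, the max-merge rule, and habitat-type imputation."""

import numpy as np
import pandas as pd
import pytest

from settdens.groupsize import (
    camera_counts,
    category_means,
    cluster_group_size,
    count_genetic_individuals,
    impute_missing,
    site_category_means,
)


def cam(rows):
    return pd.DataFrame(rows, columns=["adults_simultaneous", "total_simultaneous"])


class TestCameraCounts:
    def test_componentwise_maxima(self):
        assert camera_counts(cam([(1, 1), (2, 3), (1, 2)])) == (2, 3)

    def test_single_empty_night(self):
        assert camera_counts(cam([(0, 0)])) == (0, 0)

    def test_total_below_adults_rejected(self):
        with pytest.raises(ValueError):
            camera_counts(cam([(3, 2)]))

    def test_max_count_underestimates_roster(self, rng):
        # 4 adults, nightly detection p=0.6, 14 nights: the max simultaneous
        # count misses the full roster with probability (1 - p^4)^14
        p, n_ad, nights, reps = 0.6, 4, 14, 4000
        seen = rng.uniform(size=(reps, nights, n_ad)) < p
        max_counts = seen.sum(axis=2).max(axis=1)
        assert np.all(max_counts <= n_ad)
        expected_miss = (1 - p**n_ad) ** nights
        observed_miss = np.mean(max_counts < n_ad)
        se = np.sqrt(expected_miss * (1 - expected_miss) / reps)
        assert abs(observed_miss - expected_miss) <= 4 * se


class TestGeneticCounts:
    def test_identical_genotypes_are_one_individual(self):
        assert count_genetic_individuals(["1/2;3/3", "1/2;3/3"]) == 1

    def test_one_locus_difference_splits(self):
        assert count_genetic_individuals(["1/2;3/3", "1/2;3/4"]) == 2

    def test_allele_order_within_locus_ignored(self):
        assert count_genetic_individuals(["2/1;3/4", "1/2;4/3"]) == 1

    def test_missing_loci_match_transitively(self):
        # both partial samples are compatible with the complete one
        assert count_genetic_individuals(["1/2;-;5/5", "1/2;3/3;-", "1/2;3/3;5/5"]) == 1

    def test_chained_merge_of_incompatible_pair_warns(self, caplog):
        # s1 and s2 disagree at locus 1 but both match s3 (untyped there)
        with caplog.at_level("WARNING"):
            n = count_genetic_individuals(["1/1;2/2", "3/3;2/2", "-;2/2"],
                                          max_missing_loci=1)
        assert n == 1
        assert "chaining" in caplog.text

    def test_low_quality_samples_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            n = count_genetic_individuals(["-;-;-;5/5", "1/1;2/2;3/3;5/5"],
                                          max_missing_loci=2)
        assert n == 1
        assert "excluding" in caplog.text

    def test_inconsistent_panel_rejected(self):
        with pytest.raises(ValueError, match="panel"):
            count_genetic_individuals(["1/2;3/3", "1/2"])

    def test_recovers_synthetic_individuals_with_missing_data(self, rng):
        # 3 distinct individuals, 10 samples, ~10% missing loci
        genos = [["1/1"] * 10, ["2/2"] * 10, ["1/2"] * 10]
        samples = []
        for k in range(10):
            g = list(genos[k % 3])
            for i in range(10):
                if rng.uniform() < 0.10:
                    g[i] = "-"
            samples.append(";".join(g))
        assert count_genetic_individuals(samples) == 3


class TestMerge:
    def test_genetic_raises_total(self):
        assert cluster_group_size((2, 3), 5) == (2.0, 5.0)

    def test_camera_total_kept_when_larger(self):
        assert cluster_group_size((2, 4), 3) == (2.0, 4.0)

    def test_camera_absent_leaves_adults_missing(self):
        adults, total = cluster_group_size(None, 3)
        assert np.isnan(adults) and total == 3.0

    def test_both_absent_propagates_missing(self):
        adults, total = cluster_group_size(None, None)
        assert np.isnan(adults) and np.isnan(total)


class TestSiteMeans:
    def test_single_cluster_mean(self):
        per = pd.DataFrame([{"site_id": "A", "category": "MSCR",
                             "adults": 3.0, "total": 5.0}])
        t = site_category_means(per)
        assert t.loc["A", "ad_MSCR"] == 3.0 and t.loc["A", "badger_MSCR"] == 5.0

    def test_two_cluster_mean(self):
        per = pd.DataFrame([
            {"site_id": "A", "category": "MSC", "adults": 1.0, "total": 1.0},
            {"site_id": "A", "category": "MSC", "adults": 2.0, "total": 4.0},
        ])
        t = site_category_means(per)
        assert t.loc["A", "ad_MSC"] == 1.5 and t.loc["A", "badger_MSC"] == 2.5

    def test_unsurveyed_cell_is_missing(self):
        per = pd.DataFrame([{"site_id": "A", "category": "MSC",
                             "adults": 1.0, "total": 1.0}])
        t = site_category_means(per)
        assert np.isnan(t.loc["A", "ad_SSC"])


class TestImputation:
    def _table(self):
        t = pd.DataFrame({
            "ad_SSC": [2.0, np.nan, 1.0], "badger_SSC": [3.0, np.nan, 1.0],
            "ad_MSC": [1.0, 1.0, 1.0], "badger_MSC": [1.0, 1.0, 1.0],
            "ad_MSCR": [2.0, 2.0, 2.0], "badger_MSCR": [4.0, 4.0, 4.0],
        }, index=pd.Index(["A", "B", "C"], name="site_id"))
        for c in t.columns.tolist():
            t[f"{c}_imputed"] = False
        return t

    def test_pool_mean_fills_missing(self):
        hab = {"A": "hedgerow", "B": "hedgerow", "C": "hedgerow"}
        out = impute_missing(self._table(), hab)
        assert out.loc["B", "ad_SSC"] == pytest.approx(1.5)
        assert bool(out.loc["B", "ad_SSC_imputed"])

    def test_pool_restricted_to_same_habitat(self):
        hab = {"A": "forested", "B": "hedgerow", "C": "hedgerow"}
        out = impute_missing(self._table(), hab)
        assert out.loc["B", "ad_SSC"] == pytest.approx(1.0)  # only site C pools

    def test_observed_cells_never_altered_and_idempotent(self):
        hab = {"A": "hedgerow", "B": "hedgerow", "C": "hedgerow"}
        t = self._table()
        out = impute_missing(t, hab)
        again = impute_missing(out, hab)
        pd.testing.assert_frame_equal(out, again)
        assert out.loc["A", "ad_SSC"] == 2.0

    def test_empty_pool_is_an_error(self):
        hab = {"A": "forested", "B": "hedgerow", "C": "forested"}
        t = self._table()
        t.loc["C", "ad_SSC"] = np.nan  # B hedgerow alone with a missing cell
        with pytest.raises(ValueError, match="hedgerow"):
            impute_missing(t, hab)

    def test_category_means_exclude_imputed(self):
        hab = {"A": "hedgerow", "B": "hedgerow", "C": "hedgerow"}
        out = impute_missing(self._table(), hab)
        summary = category_means(out, exclude_imputed=True)
        assert summary.loc["ad_SSC", "mean"] == pytest.approx(1.5)  # A and C only
        assert summary.loc["ad_SSC", "n_sites"] == 2


class TestRosterConvergence:
    def test_counts_bounded_by_roster_and_exact_at_full_detection(self):
        from settdens.groupsize import group_size_table
        from settdens.synthetic import SiteConfig, generate_site

        cfg = SiteConfig(area_km2=20.0, cluster_intensity=4.0,
                         camera_detect_prob=1.0, genetic_detect_prob=1.0,
                         genotype_missing_rate=0.0, seed=21)
        setts, tr, camera, genetic, truth = generate_site(cfg)
        # with certain per-night detection every roster member is seen together
        for cid, grp in camera.groupby("cluster_id"):
            roster = truth.individual_roster[cid]
            mx_ad, mx_tot = camera_counts(grp)
            n_ad = sum(1 for m in roster if m["age"] == "adult")
            assert mx_ad == n_ad and mx_tot == len(roster)
        for cid, grp in genetic.groupby("cluster_id"):
            n = count_genetic_individuals(grp)
            assert n <= len(truth.individual_roster[cid])
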