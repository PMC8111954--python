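"""Single-linkage sett clustering and occupancy classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from settdens.clustering import (
    build_clusters,
    classify_cluster,
    cluster_setts,
    occupancy_by_site,
    occupancy_proportions,
)

from conftest import make_setts


def brute_force_components(coords, threshold):
    """Independent union-find oracle over the pairwise distance graph."""
    n = len(coords)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = np.hypot(coords[i][0] - coords[j][0], coords[i][1] - coords[j][1])
            if d <= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    return [find(i) for i in range(n)]


def partitions_equal(a, b):
    return {tuple(sorted(np.flatnonzero(np.asarray(a) == lab))) for lab in set(a)} == \
           {tuple(sorted(np.flatnonzero(np.asarray(b) == lab))) for lab in set(b)}


class TestClusterSetts:
    def test_singleton(self):
        labels = cluster_setts(make_setts([(0, 0)]), 500)
        assert labels.tolist() == [0]

    def test_chaining_links_transitively(self):
        # consecutive gaps of 400 m chain into one cluster at a 500 m rule
        labels = cluster_setts(make_setts([(0, 0), (400, 0), (800, 0)]), 500)
        assert labels.nunique() == 1

    def test_above_threshold_splits(self):
        labels = cluster_setts(make_setts([(0, 0), (600, 0)]), 500)
        assert labels.nunique() == 2

    def test_matches_union_find_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 51))
            coords = rng.uniform(0, 2000, size=(n, 2))
            thr = float(rng.uniform(50, 800))
            labels = cluster_setts(make_setts([tuple(c) for c in coords]), thr)
            oracle = brute_force_components(coords, thr)
            assert partitions_equal(labels.tolist(), oracle)

    @given(st.randoms(use_true_random=False))
    def test_invariant_to_input_order(self, rnd):
        coords = [(0, 0), (300, 0), (900, 100), (2000, 2000), (2100, 2000)]
        setts = make_setts(coords)
        perm = list(range(len(coords)))
        rnd.shuffle(perm)
        shuffled = setts.iloc[perm].reset_index(drop=True)
        a = build_clusters(setts, 500)
        b = build_clusters(shuffled, 500)
        assert sorted(a["members"].map(lambda s: tuple(sorted(s.split(";"))))) == \
               sorted(b["members"].map(lambda s: tuple(sorted(s.split(";")))))

    def test_duplicate_sett_id_rejected(self):
        setts = make_setts([(0, 0), (100, 0)])
        setts.loc[1, "sett_id"] = setts.loc[0, "sett_id"]
        with pytest.raises(ValueError, match="duplicated"):
            cluster_setts(setts, 500)

    def test_empty_input(self):
        assert len(cluster_setts(make_setts([]), 500)) == 0

    def test_cluster_count_non_increasing_in_threshold(self, rng):
        coords = [tuple(c) for c in rng.uniform(0, 5000, size=(60, 2))]
        setts = make_setts(coords)
        counts = [cluster_setts(setts, t).nunique() for t in (100, 500, 900)]
        assert counts[0] >= counts[1] >= counts[2]


class TestClassify:
    def test_occupied_main_with_reproduction_dominates(self):
        members = make_setts([(0, 0), (10, 0)], sett_type=["main", "secondary"],
                             occupied=[True, False], reproduction=[True, False])
        assert classify_cluster(members) == "MSCR"

    def test_occupied_main_without_reproduction(self):
        members = make_setts([(0, 0), (10, 0)], sett_type=["main", "secondary"],
                             occupied=[True, True], reproduction=[False, False])
        assert classify_cluster(members) == "MSC"

    def test_only_secondary_with_one_occupied(self):
        members = make_setts([(0, 0), (10, 0)], sett_type=["secondary", "secondary"],
                             occupied=[True, False], reproduction=[False, False])
        assert classify_cluster(members) == "SSC"

    def test_nothing_occupied(self):
        members = make_setts([(0, 0), (10, 0)], sett_type=["main", "secondary"],
                             occupied=[False, False], reproduction=[False, False])
        assert classify_cluster(members) == "UNOCCUPIED"

    def test_unoccupied_main_blocks_ssc(self):
        # an unoccupied main sett means the cluster is not "secondary only"
        members = make_setts([(0, 0), (10, 0)], sett_type=["main", "secondary"],
                             occupied=[False, True], reproduction=[False, False])
        assert classify_cluster(members) == "UNOCCUPIED"


class TestOccupancy:
    def test_site_j_proportions(self):
        # 16 clusters: 1 SSC, 4 MSC, 1 MSCR, 10 unoccupied
        cats = ["SSC"] + ["MSC"] * 4 + ["MSCR"] + ["UNOCCUPIED"] * 10
        clusters = pd.DataFrame({"site_id": "J", "category": cats})
        p = occupancy_proportions(clusters)
        assert p.as_tuple() == (1 / 16, 4 / 16, 1 / 16)
        assert p.n_unoccupied == 10

    def test_all_unoccupied(self):
        clusters = pd.DataFrame({"site_id": "X", "category": ["UNOCCUPIED"] * 5})
        assert occupancy_proportions(clusters).as_tuple() == (0, 0, 0)

    def test_zero_clusters_is_an_error(self):
        with pytest.raises(ValueError, match="unusable"):
            occupancy_proportions(pd.DataFrame(columns=["site_id", "category"]))

    def test_by_site_counts_are_exact_ratios(self):
        clusters = pd.DataFrame({
            "site_id": ["A"] * 3 + ["B"] * 2,
            "category": ["SSC", "MSC", "UNOCCUPIED", "MSCR", "MSCR"],
        })
        out = occupancy_by_site(clusters).set_index("site_id")
        assert out.loc["A", "p_SSC"] == 1 / 3
        assert out.loc["B", "p_MSCR"] == 1.0


class TestDetectionDistance:
    def test_first_detected_flag_wins(self):
        setts = make_setts([(0, 0), (50, 0)], perp=[30.0, 5.0])
        setts["first_detected"] = [True, False]
        out = build_clusters(setts, 500)
        assert out["detection_distance_m"].iloc[0] == 30.0

    def test_fallback_to_min_distance_warns(self, caplog):
        setts = make_setts([(0, 0), (50, 0)], perp=[30.0, 5.0])
        with caplog.at_level("WARNING"):
            out = build_clusters(setts, 500)
        assert out["detection_distance_m"].iloc[0] == 5.0
        assert "first_detected" in caplog.text
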