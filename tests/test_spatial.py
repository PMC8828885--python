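"""Homotypic DBSCAN, nearest distances, group comparisons, permutation null."""

import numpy as np
import pandas as pd
import pytest

from _oracles import (
    dbscan_bruteforce,
    nearest_distances_bruteforce,
    ranksum_enumeration,
)
from sklearn.metrics import adjusted_rand_score

from tissuemux.errors import ParameterError
from tissuemux.spatial import (
    HomotypicParams,
    classify_proximity,
    compare_groups,
    homotypic_clusters,
    nearest_distances,
    permutation_null,
)


def point_cells(xy_um, sample_id="s", cell_type="t", start_id=1):
    xy = np.asarray(xy_um, dtype=float)
    return pd.DataFrame(
        {
            "cell_id": np.arange(start_id, start_id + len(xy)),
            "sample_id": sample_id,
            "centroid_x_um": xy[:, 0],
            "centroid_y_um": xy[:, 1],
            "cell_type": cell_type,
        }
    )


class TestHomotypicClusters:
    def test_eps_from_density_formula(self):
        params = HomotypicParams(min_points=5, density_per_mm2=5.0)
        # disk of radius eps holding 5 cells at 5 cells/mm^2
        assert params.resolved_eps_um == pytest.approx(
            np.sqrt(5 / (np.pi * 5)) * 1000.0
        )

    def test_planted_aggregate_and_noise(self, rng):
        angles = rng.uniform(0, 2 * np.pi, 20)
        radii = 50 * np.sqrt(rng.uniform(0, 1, 20))
        blob = np.stack([500 + radii * np.cos(angles), 500 + radii * np.sin(angles)], 1)
        isolated = np.array([[50, 50], [950, 950], [50, 950], [950, 50]])
        cells = point_cells(np.vstack([blob, isolated]))
        labels = homotypic_clusters(cells, HomotypicParams(min_points=5, eps_um=120))
        assert (labels[:20] == 1).all()
        assert (labels[20:] == 0).all()

    def test_fewer_than_min_points_all_noise(self, rng):
        cells = point_cells(rng.uniform(0, 10, size=(3, 2)))
        labels = homotypic_clusters(cells, HomotypicParams(min_points=5, eps_um=100))
        assert (labels == 0).all()

    def test_matches_textbook_dbscan_on_random_cells(self, rng):
        for _ in range(20):
            pts = rng.uniform(0, 100, size=(200, 2))
            cells = point_cells(pts)
            ours = homotypic_clusters(cells, HomotypicParams(min_points=5, eps_um=8))
            ref = dbscan_bruteforce(pts, 8.0, 5)
            assert ((ours == 0) == (ref == -1)).all()
            assert adjusted_rand_score(ref, ours) == 1.0

    def test_invariant_to_input_order(self, rng):
        pts = rng.uniform(0, 100, size=(150, 2))
        cells = point_cells(pts)
        params = HomotypicParams(min_points=5, eps_um=10)
        labels = homotypic_clusters(cells, params)
        perm = rng.permutation(len(cells))
        labels_perm = homotypic_clusters(
            cells.iloc[perm].reset_index(drop=True), params
        )
        assert ((labels_perm == 0) == (labels[perm] == 0)).all()
        assert adjusted_rand_score(labels_perm, labels[perm]) == 1.0

    def test_exactly_one_of_eps_or_density(self):
        with pytest.raises(ParameterError):
            HomotypicParams(min_points=5)
        with pytest.raises(ParameterError):
            HomotypicParams(min_points=5, eps_um=10, density_per_mm2=5)


class TestNearestDistances:
    def test_three_four_five_triangle(self):
        src = point_cells([[0, 0]], cell_type="a")
        tgt = point_cells([[3, 4], [10, 0]], cell_type="b", start_id=100)
        out = nearest_distances(src, tgt)
        assert out["nearest_distance_um"].iloc[0] == pytest.approx(5.0)
        assert out["nearest_target_id"].iloc[0] == 100

    def test_cell_in_both_sets_never_matches_itself(self):
        src = point_cells([[0, 0]], cell_type="a")
        tgt = pd.concat(
            [point_cells([[0, 0]], cell_type="b"), point_cells([[6, 8]], cell_type="b", start_id=50)],
            ignore_index=True,
        )
        out = nearest_distances(src, tgt)
        assert out["nearest_distance_um"].iloc[0] == pytest.approx(10.0)

    def test_sample_without_targets_skipped_with_warning(self, caplog):
        src = pd.concat(
            [point_cells([[0, 0]], "s1", "a"), point_cells([[1, 1]], "s2", "a")],
            ignore_index=True,
        )
        tgt = point_cells([[5, 5]], "s1", "b", start_id=10)
        with caplog.at_level("WARNING"):
            out = nearest_distances(src, tgt)
        assert set(out["sample_id"]) == {"s1"}
        assert "s2" in caplog.text

    def test_matches_brute_force_scan(self, rng):
        src_xy = rng.uniform(0, 1000, size=(300, 2))
        tgt_xy = rng.uniform(0, 1000, size=(400, 2))
        src = point_cells(src_xy, cell_type="a")
        tgt = point_cells(tgt_xy, cell_type="b", start_id=1000)
        out = nearest_distances(src, tgt)
        oracle = nearest_distances_bruteforce(
            src_xy, src["cell_id"].to_numpy(), tgt_xy, tgt["cell_id"].to_numpy()
        )
        assert len(out) == 300
        for i, (d, j) in enumerate(oracle):
            assert out["nearest_distance_um"].iloc[i] == pytest.approx(d, abs=1e-9)


class TestProximity:
    def test_strict_boundary(self):
        dist = pd.DataFrame({"nearest_distance_um": [11.9, 12.0, 12.1]})
        labels = classify_proximity(dist, 12.0)
        assert list(labels) == ["proximal", "distal", "distal"]


class TestCompareGroups:
    def _distances(self, a_values, b_values):
        rows = []
        for sid, values in (("a1", a_values), ("b1", b_values)):
            for i, v in enumerate(values):
                rows.append(
                    {
                        "cell_id": i + 1,
                        "sample_id": sid,
                        "source_type": "s",
                        "target_type": "t",
                        "nearest_distance_um": v,
                        "nearest_target_id": 0,
                    }
                )
        return pd.DataFrame(rows), {"a1": "A", "b1": "B"}

    def test_rank_sum_matches_exact_enumeration(self):
        dist, groups = self._distances([1, 2, 3], [10, 11, 12])
        results = compare_groups(dist, groups, [("s", "t")])
        r = results[0]
        w, p_exact = ranksum_enumeration(np.array([1.0, 2, 3]), np.array([10.0, 11, 12]))
        # U + n_a(n_a+1)/2 equals the rank-sum statistic
        from scipy.stats import mannwhitneyu

        u = mannwhitneyu([1, 2, 3], [10, 11, 12], alternative="two-sided").statistic
        assert u + 3 * 4 / 2 == w
        assert r.wilcoxon_p < 0.2
        assert p_exact == pytest.approx(0.1, abs=1e-12)  # most extreme of C(6,3)=20

    def test_identical_groups_p_near_one(self):
        dist, groups = self._distances([5.0, 6, 7, 8], [5.0, 6, 7, 8])
        r = compare_groups(dist, groups, [("s", "t")])[0]
        assert r.wilcoxon_p >= 0.99
        assert r.delta_median_um == 0

    def test_small_delta_never_relevant_even_when_significant(self, rng):
        a = rng.normal(20, 1, 300)
        b = rng.normal(25, 1, 300)  # 5 um shift: significant but < 8 um
        dist, groups = self._distances(a, b)
        r = compare_groups(dist, groups, [("s", "t")])[0]
        assert r.fdr_q < 0.01
        assert abs(r.delta_median_um) < 8
        assert not r.relevant

    def test_relevance_needs_both_conditions(self, rng):
        a = rng.normal(20, 3, 200)
        b = rng.normal(50, 3, 200)
        dist, groups = self._distances(a, b)
        r = compare_groups(dist, groups, [("s", "t")])[0]
        assert r.relevant and abs(r.delta_median_um) >= 8 and r.fdr_q < 0.1

    def test_unit_rescaling_preserves_p(self, rng):
        a = rng.normal(20, 5, 50)
        b = rng.normal(30, 5, 50)
        d1, groups = self._distances(a, b)
        d2, _ = self._distances(a * 2, b * 2)  # e.g. 0.5 um pixels
        p1 = compare_groups(d1, groups, [("s", "t")])[0].wilcoxon_p
        p2 = compare_groups(d2, groups, [("s", "t")])[0].wilcoxon_p
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_tiny_group_skipped(self, caplog):
        dist, groups = self._distances([1.0], [5.0, 6.0])
        with caplog.at_level("WARNING"):
            results = compare_groups(dist, groups, [("s", "t")])
        assert results == []


class TestPermutationNull:
    def _cells(self, rng, n_samples=4, planted=False):
        frames = []
        group_map = {}
        for i in range(n_samples):
            sid = f"s{i}"
            group_map[sid] = "A" if i < n_samples // 2 else "B"
            n = 40
            xy = rng.uniform(0, 1000, size=(n, 2))
            types = np.array(["src"] * 15 + ["tgt"] * 10 + ["other"] * 15, dtype=object)
            if planted and group_map[sid] == "A":
                # pull sources onto targets: huge planted effect
                xy[:15] = xy[15:25][rng.integers(0, 10, 15)] + rng.normal(0, 1, (15, 2))
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": np.arange(1, n + 1),
                        "sample_id": sid,
                        "centroid_x_um": xy[:, 0],
                        "centroid_y_um": xy[:, 1],
                        "cell_type": types,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True), group_map

    def test_extreme_observed_statistic_hits_p_floor(self, rng):
        cells, group_map = self._cells(rng, planted=True)
        result = permutation_null(cells, group_map, "src", "tgt", n_permutations=99, seed=1)
        assert result.p_two_tailed == pytest.approx(1 / 100)
        assert len(result.null_deltas) == 99

    def test_fixed_seed_reproducible(self, rng):
        cells, group_map = self._cells(rng)
        r1 = permutation_null(cells, group_map, "src", "tgt", n_permutations=50, seed=9)
        r2 = permutation_null(cells, group_map, "src", "tgt", n_permutations=50, seed=9)
        np.testing.assert_array_equal(r1.null_deltas, r2.null_deltas)
        assert r1.p_two_tailed == r2.p_two_tailed

    def test_p_in_unit_interval_and_never_zero(self, rng):
        cells, group_map = self._cells(rng)
        r = permutation_null(cells, group_map, "src", "tgt", n_permutations=20, seed=0)
        assert 0 < r.p_two_tailed <= 1

    def test_power_rises_with_planted_separation(self, rng):
        from tissuemux.synthetic import GroupEffect, TissueSpec, CellTypeSpec, generate_grouped_samples

        spec = TissueSpec(
            image_size=(1000, 1000),
            cell_types=(
                CellTypeSpec("src", count=40),
                CellTypeSpec("tgt", count=15),
                CellTypeSpec("other", count=30),
            ),
        )
        pvals = {}
        for shift in (0.0, 60.0):
            ps = []
            for rep in range(5):
                cells, gm = generate_grouped_samples(
                    spec, 4, GroupEffect("src", "tgt", shift), seed=100 + rep
                )
                ps.append(
                    permutation_null(
                        cells, gm, "src", "tgt", n_permutations=99, seed=rep
                    ).p_two_tailed
                )
            pvals[shift] = np.mean(ps)
        assert pvals[60.0] < pvals[0.0]
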