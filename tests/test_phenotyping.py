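"""Compartment assignment, overlap typing, gating and clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_stack
from _oracles import overlap_typing_bruteforce
from sklearn.metrics import adjusted_rand_score

from tissuemux.errors import ConfigurationError, ExpressionError
from tissuemux.phenotyping import (
    ClusterParams,
    GateSpec,
    OverlapRule,
    assign_compartment,
    assign_type_by_highest_overlap,
    cluster_cells,
    gate_cells,
    overlap_fractions,
)
from tissuemux.preprocess import BinaryMask
from tissuemux.segmentation import LabelImage, extract_features


def grid_label_image(rng, shape=(30, 30), n_cells=9, cell=8):
    """Non-touching square cells on a grid."""
    labels = np.zeros(shape, dtype=np.int32)
    k = 0
    for i in range(3):
        for j in range(3):
            k += 1
            labels[i * 10 + 1 : i * 10 + 1 + cell // 2, j * 10 + 1 : j * 10 + 1 + cell // 2] = k
    return LabelImage(labels, k)


def cells_frame(n, **columns):
    base = {
        "cell_id": np.arange(1, n + 1),
        "sample_id": "s",
        "compartment": pd.Series([None] * n, dtype=object),
        "cell_type": pd.Series([None] * n, dtype=object),
    }
    base.update(columns)
    return pd.DataFrame(base)


class TestAssignCompartment:
    def test_thirty_percent_boundary_is_inclusive(self):
        labels = np.zeros((2, 10), dtype=np.int32)
        labels[0, :] = 1  # 10-px cell
        mask = np.zeros((2, 10), dtype=bool)
        mask[0, :3] = True  # 3 of 10 px inside
        cells = cells_frame(1)
        out = assign_compartment(
            cells, LabelImage(labels, 1), OverlapRule("lamina", 0.30), BinaryMask(mask, "lamina")
        )
        assert out["compartment"].iloc[0] == "lamina"

    def test_cell_fully_outside_not_assigned(self):
        labels = np.zeros((4, 4), dtype=np.int32)
        labels[0, :2] = 1
        mask = np.zeros((4, 4), dtype=bool)
        mask[3, :] = True
        out = assign_compartment(
            cells_frame(1), LabelImage(labels, 1), OverlapRule("m", 0.3), BinaryMask(mask, "m")
        )
        assert out["compartment"].iloc[0] is None

    def test_half_plane_assignments_match_pixel_counting(self, rng):
        labels = grid_label_image(rng)
        mask = np.zeros(labels.pixels.shape, dtype=bool)
        mask[:, 15:] = True
        fractions = overlap_fractions(labels, BinaryMask(mask, "half"))
        out = assign_compartment(
            cells_frame(labels.n_cells),
            labels,
            OverlapRule("half", 0.5),
            BinaryMask(mask, "half"),
        )
        for i in range(labels.n_cells):
            inside = (mask & (labels.pixels == i + 1)).sum()
            area = (labels.pixels == i + 1).sum()
            assert fractions[i] == pytest.approx(inside / area)
            assert (out["compartment"].iloc[i] == "half") == (inside / area >= 0.5)


class TestHighestOverlapTyping:
    def _setup(self, rng, n_rules=4):
        labels = grid_label_image(rng)
        masks = {}
        rules = []
        minimums = [0.15, 0.15, 0.25, 0.15]
        for j in range(n_rules):
            name = f"M{j}"
            masks[name] = BinaryMask(rng.random(labels.pixels.shape) > 0.5, name)
            rules.append(OverlapRule(name, minimums[j]))
        return labels, masks, rules

    def test_eligibility_then_argmax_matches_enumeration(self, rng):
        for _ in range(20):
            labels, masks, rules = self._setup(rng)
            out = assign_type_by_highest_overlap(
                cells_frame(labels.n_cells), labels, rules, masks
            )
            fractions = np.stack(
                [overlap_fractions(labels, masks[r.mask_name]) for r in rules], axis=1
            )
            winners = overlap_typing_bruteforce(
                fractions, np.array([r.min_fraction for r in rules])
            )
            for i, w in enumerate(winners):
                expected = None if w < 0 else rules[w].mask_name
                assert out["cell_type"].iloc[i] == expected

    def test_ineligible_rule_cannot_win(self):
        # fractions {A: 0.20, B: 0.10}, minimums {0.15, 0.15} -> A
        labels = np.zeros((1, 10), dtype=np.int32)
        labels[0, :] = 1
        a = np.zeros((1, 10), bool); a[0, :2] = True
        b = np.zeros((1, 10), bool); b[0, 9] = True
        out = assign_type_by_highest_overlap(
            cells_frame(1),
            LabelImage(labels, 1),
            [OverlapRule("A", 0.15), OverlapRule("B", 0.15)],
            {"A": BinaryMask(a, "A"), "B": BinaryMask(b, "B")},
        )
        assert out["cell_type"].iloc[0] == "A"

    def test_lower_fraction_wins_when_other_ineligible(self):
        # fractions {A: 0.30, B: 0.20}, minimums {0.15, 0.25} -> A
        labels = np.zeros((1, 10), dtype=np.int32)
        labels[0, :] = 1
        a = np.zeros((1, 10), bool); a[0, :3] = True
        b = np.zeros((1, 10), bool); b[0, 3:5] = True
        out = assign_type_by_highest_overlap(
            cells_frame(1),
            LabelImage(labels, 1),
            [OverlapRule("A", 0.15), OverlapRule("B", 0.25)],
            {"A": BinaryMask(a, "A"), "B": BinaryMask(b, "B")},
        )
        assert out["cell_type"].iloc[0] == "A"

    def test_exact_tie_goes_to_first_rule(self):
        labels = np.zeros((1, 10), dtype=np.int32)
        labels[0, :] = 1
        a = np.zeros((1, 10), bool); a[0, :2] = True
        b = np.zeros((1, 10), bool); b[0, 2:4] = True
        out = assign_type_by_highest_overlap(
            cells_frame(1),
            LabelImage(labels, 1),
            [OverlapRule("B", 0.1), OverlapRule("A", 0.1)],
            {"A": BinaryMask(a, "A"), "B": BinaryMask(b, "B")},
        )
        assert out["cell_type"].iloc[0] == "B"

    def test_duplicate_rule_names_rejected(self, rng):
        labels, masks, _ = self._setup(rng)
        with pytest.raises(ConfigurationError):
            assign_type_by_highest_overlap(
                cells_frame(labels.n_cells),
                labels,
                [OverlapRule("M0", 0.1), OverlapRule("M0", 0.2)],
                masks,
            )

    def test_each_cell_gets_at_most_one_type(self, rng):
        labels, masks, rules = self._setup(rng)
        out = assign_type_by_highest_overlap(
            cells_frame(labels.n_cells), labels, rules, masks
        )
        assert out["cell_type"].map(lambda t: t is None or isinstance(t, str)).all()


class TestGating:
    def test_geq_boundary_inclusive(self):
        cells = cells_frame(3, CD4=[0.05, 0.1, 0.2])
        out = gate_cells(cells, GateSpec("CD4_T", "CD4 >= 0.1"))
        assert len(out) == 2
        assert (out["cell_type"] == "CD4_T").all()

    def test_conjunction_is_intersection_of_atoms(self):
        cells = cells_frame(4, CD8=[0.02, 0.02, 0.001, 0.5], PD1=[0.006, 0.001, 0.9, 0.01])
        both = gate_cells(cells, GateSpec("g", "CD8 >= 0.01 & PD1 >= 0.005"))
        only_cd8 = gate_cells(cells, GateSpec("a", "CD8 >= 0.01"))
        only_pd1 = gate_cells(cells, GateSpec("b", "PD1 >= 0.005"))
        assert set(both.cell_id) == set(only_cd8.cell_id) & set(only_pd1.cell_id)

    def test_parent_gate_scopes_the_subset(self):
        cells = cells_frame(4, CD4=[0.2, 0.05, 0.3, 0.2], PD1=[0.2, 0.3, 0.05, 0.16])
        cd4 = gate_cells(cells, GateSpec("CD4_T", "CD4 >= 0.1"))
        pd1 = gate_cells(cells, GateSpec("PD1_CD4_T", "PD1 >= 0.15"), parent=cd4)
        assert set(pd1.cell_id) == {1, 4}

    def test_random_expressions_match_direct_evaluation(self, rng):
        cells = cells_frame(
            50,
            A=rng.random(50),
            B=rng.random(50),
            C=rng.random(50),
        )
        for _ in range(20):
            ta, tb, tc = rng.random(3).round(2)
            expr = f"(A >= {ta} & B < {tb}) | !(C > {tc})"
            out = gate_cells(cells, GateSpec("g", expr))
            expected = (
                (cells.A >= ta) & (cells.B < tb) | ~(cells.C > tc)
            )
            assert set(out.cell_id) == set(cells.cell_id[expected])

    def test_unknown_channel_and_parse_errors(self):
        cells = cells_frame(2, CD4=[0.1, 0.2])
        with pytest.raises(ConfigurationError, match="CD8"):
            gate_cells(cells, GateSpec("g", "CD8 >= 0.1"))
        with pytest.raises(ExpressionError):
            gate_cells(cells, GateSpec("g", "CD4 >="))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        t1=st.floats(0, 1),
        t2=st.floats(0, 1),
    )
    def test_raising_threshold_never_adds_cells(self, t1, t2):
        values = np.linspace(0, 1, 21)
        cells = cells_frame(21, CD4=values)
        lo, hi = sorted([t1, t2])
        wide = gate_cells(cells, GateSpec("g", f"CD4 >= {lo}"))
        narrow = gate_cells(cells, GateSpec("g", f"CD4 >= {hi}"))
        assert set(narrow.cell_id) <= set(wide.cell_id)


class TestClustering:
    def _blob_cells(self, rng, n_per_blob=60, sd=0.01):
        means = np.eye(3)
        X = np.vstack([rng.normal(m, sd, size=(n_per_blob, 3)) for m in means])
        cells = cells_frame(3 * n_per_blob, m1=X[:, 0], m2=X[:, 1], m3=X[:, 2])
        return cells, np.repeat(np.arange(3), n_per_blob)

    def _params(self, seed=0):
        return ClusterParams(
            markers=("m1", "m2", "m3"), n_pcs=2, k_neighbours=20, resolution=0.8, seed=seed
        )

    def test_three_planted_blobs_recovered(self, rng):
        cells, truth = self._blob_cells(rng)
        labels, profile = cluster_cells(cells, self._params())
        assert adjusted_rand_score(truth, labels) >= 0.95
        assert set(labels) == {1, 2, 3}
        assert len(profile) == 3
        # profile reports mean raw intensity per cluster
        for _, row in profile.iterrows():
            sel = labels == row.cluster_id
            assert row["m1"] == pytest.approx(cells.loc[sel, "m1"].mean())

    def test_identical_cells_single_cluster(self):
        cells = cells_frame(30, m1=np.ones(30), m2=np.ones(30), m3=np.ones(30))
        labels, _ = cluster_cells(
            cells,
            ClusterParams(markers=("m1", "m2", "m3"), n_pcs=1, k_neighbours=5, resolution=1.0),
        )
        assert set(labels) == {1}

    def test_fixed_seed_reproducible(self, rng):
        cells, _ = self._blob_cells(rng)
        l1, _ = cluster_cells(cells, self._params(seed=7))
        l2, _ = cluster_cells(cells, self._params(seed=7))
        np.testing.assert_array_equal(l1, l2)

    def test_partition_invariant_to_cell_order(self, rng):
        cells, _ = self._blob_cells(rng)
        labels, _ = cluster_cells(cells, self._params(seed=7))
        perm = rng.permutation(len(cells))
        shuffled = cells.iloc[perm].reset_index(drop=True)
        labels_shuffled, _ = cluster_cells(shuffled, self._params(seed=7))
        np.testing.assert_array_equal(labels_shuffled, labels[perm])

    def test_constant_marker_dropped_with_warning(self, rng, caplog):
        cells, truth = self._blob_cells(rng)
        cells["flat"] = 1.0
        params = ClusterParams(
            markers=("m1", "m2", "m3", "flat"),
            n_pcs=2,
            k_neighbours=20,
            resolution=0.8,
            seed=0,
        )
        with caplog.at_level("WARNING"):
            labels, _ = cluster_cells(cells, params)
        assert "constant" in caplog.text
        assert adjusted_rand_score(truth, labels) >= 0.95

    def test_cluster_ids_ordered_by_descending_size(self, rng):
        means = np.eye(3)
        sizes = [80, 50, 30]
        X = np.vstack(
            [rng.normal(m, 0.01, size=(n, 3)) for m, n in zip(means, sizes)]
        )
        cells = cells_frame(sum(sizes), m1=X[:, 0], m2=X[:, 1], m3=X[:, 2])
        labels, _ = cluster_cells(cells, self._params())
        counts = np.bincount(labels)[1:]
        assert list(counts) == sorted(counts, reverse=True)


class TestEmbedding:
    def test_deterministic_shape_and_separation(self, rng):
        from tissuemux.phenotyping import embed_2d

        means = np.eye(3)[:2]
        X = np.vstack([rng.normal(m, 0.01, size=(30, 3)) for m in means])
        cells = cells_frame(60, m1=X[:, 0], m2=X[:, 1], m3=X[:, 2])
        params = ClusterParams(
            markers=("m1", "m2", "m3"), n_pcs=2, k_neighbours=10, resolution=1.0, seed=5
        )
        e1 = embed_2d(cells, params)
        e2 = embed_2d(cells, params)
        assert e1.shape == (60, 2)
        np.testing.assert_allclose(e1, e2)
        c0, c1 = e1[:30].mean(axis=0), e1[30:].mean(axis=0)
        within = np.linalg.norm(e1[:30] - c0, axis=1).mean()
        assert np.linalg.norm(c0 - c1) > within
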