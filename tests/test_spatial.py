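import math

import numpy as np
import pandas as pd
import pytest

from spatialtme.phenotyping import gate_cohort
from spatialtme.spatial import (
    build_distance_table,
    metric_correlation_matrix,
    nn_distance,
    nn_to_tumor,
    overall_nearest_radius,
    pairwise_distances,
    per_cell_nn_distances,
    summarize_patient_distances,
)
from conftest import make_cells


def brute_force_nn(src, tgt, src_ids=None, tgt_ids=None):
    """O(n^2) oracle for nearest-neighbor distances with self-exclusion."""
    out = []
    for i, a in enumerate(src):
        best = math.inf
        for j, b in enumerate(tgt):
            if src_ids is not None and src_ids[i] == tgt_ids[j]:
                continue
            best = min(best, math.hypot(a[0] - b[0], a[1] - b[1]))
        out.append(best if best < math.inf else math.nan)
    return np.array(out)


class TestPairwise:
    def test_three_four_five(self):
        d = pairwise_distances([(0, 0), (3, 4)])
        assert d[0, 1] == pytest.approx(5.0)
        assert d[1, 0] == pytest.approx(5.0)
        assert d[0, 0] == 0.0

    def test_single_point(self):
        assert pairwise_distances([(2.0, 7.0)]).shape == (1, 1)

    def test_cross_field_rejected(self):
        with pytest.raises(ValueError, match="multiple fields"):
            pairwise_distances([(0, 0), (1, 1)], field_ids=["F1", "F2"])

    def test_matches_double_loop_oracle(self, rng):
        pts = rng.uniform(0, 100, (50, 2))
        d = pairwise_distances(pts)
        for i in range(50):
            for j in range(50):
                assert d[i, j] == pytest.approx(
                    math.hypot(*(pts[i] - pts[j])), abs=1e-9)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)


class TestNNDistance:
    def test_example(self):
        d = nn_distance([(0, 0)], [(3, 4), (10, 0)])
        assert d == pytest.approx([5.0])

    def test_self_exclusion_single_cell(self):
        d = nn_distance([(1, 1)], [(1, 1)], source_ids=[7], target_ids=[7])
        assert math.isnan(d[0])

    def test_no_targets_missing(self):
        d = nn_distance([(0, 0), (1, 1)], np.empty((0, 2)))
        assert np.isnan(d).all()

    def test_matches_brute_force_with_overlap(self, rng):
        src = rng.uniform(0, 200, (80, 2))
        tgt = np.vstack([src[:30], rng.uniform(0, 200, (60, 2))])
        src_ids = np.arange(80)
        tgt_ids = np.concatenate([np.arange(30), np.arange(1000, 1060)])
        fast = nn_distance(src, tgt, src_ids, tgt_ids)
        slow = brute_force_nn(src, tgt, src_ids, tgt_ids)
        assert np.allclose(fast, slow, atol=1e-9)

    def test_translation_rotation_invariance(self, rng):
        src = rng.uniform(0, 100, (40, 2))
        tgt = rng.uniform(0, 100, (25, 2))
        base = nn_distance(src, tgt)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = nn_distance(src @ rot.T + [13.0, -5.0], tgt @ rot.T + [13.0, -5.0])
        assert np.allclose(base, moved, atol=1e-9)


class TestNNToTumor:
    def test_stromal_source_contributes(self):
        gated = gate_cohort(make_cells([
            {"cd3": True, "compartment": "stroma", "x_um": 0, "y_um": 0},
            {"ck": True, "compartment": "epithelium", "x_um": 6, "y_um": 8},
        ]))
        d = nn_to_tumor(gated, "Th")
        assert list(d["distance_um"]) == pytest.approx([10.0])

    def test_intraepithelial_source_excluded(self):
        gated = gate_cohort(make_cells([
            {"cd3": True, "compartment": "epithelium", "x_um": 0, "y_um": 0},
            {"ck": True, "compartment": "epithelium", "x_um": 6, "y_um": 8},
        ]))
        assert len(nn_to_tumor(gated, "Th")) == 0

    def test_no_tumor_field_contributes_nothing(self):
        gated = gate_cohort(make_cells([
            {"cd3": True, "compartment": "stroma"},
        ]))
        assert len(nn_to_tumor(gated, "Th")) == 0

    def test_adding_tumor_cells_never_increases(self, rng):
        rows = [{"cd3": True, "compartment": "stroma",
                 "x_um": float(x), "y_um": float(y)}
                for x, y in rng.uniform(0, 300, (30, 2))]
        tumor = [{"ck": True, "compartment": "epithelium",
                  "x_um": float(x), "y_um": float(y)}
                 for x, y in rng.uniform(0, 300, (20, 2))]
        before = nn_to_tumor(gate_cohort(make_cells(rows + tumor[:10])), "Th")
        after = nn_to_tumor(gate_cohort(make_cells(rows + tumor)), "Th")
        assert (after["distance_um"].to_numpy()
                <= before["distance_um"].to_numpy() + 1e-12).all()

    def test_between_category_self_exclusion(self):
        # a CD8 T cell is itself a T cell: T -> CD8T must not return 0
        gated = gate_cohort(make_cells([
            {"cd3": True, "cd8": True, "x_um": 0, "y_um": 0},
            {"cd3": True, "cd8": True, "x_um": 3, "y_um": 4},
        ]))
        d = per_cell_nn_distances(gated, "T", "CD8T")
        assert sorted(d["distance_um"]) == pytest.approx([5.0, 5.0])


class TestSummaries:
    def test_median_conventions(self):
        pc = pd.DataFrame({"patient_id": "P1", "field_id": "F1",
                           "cell_id": range(3), "distance_um": [1.0, 2.0, 3.0]})
        assert summarize_patient_distances(pc)["median_um"].iloc[0] == 2.0
        pc4 = pd.DataFrame({"patient_id": "P1", "field_id": "F1",
                            "cell_id": range(4), "distance_um": [1.0, 2.0, 3.0, 4.0]})
        assert summarize_patient_distances(pc4)["median_um"].iloc[0] == 2.5

    def test_pooled_convention_pinned(self):
        # pooled median (2.0) differs from median of per-field medians (2.5)
        pc = pd.DataFrame({
            "patient_id": "P1",
            "field_id": ["F1", "F1", "F1", "F2"],
            "cell_id": range(4),
            "distance_um": [1.0, 1.5, 2.0, 100.0],
        })
        pooled = summarize_patient_distances(pc)["median_um"].iloc[0]
        per_field = pc.groupby("field_id")["distance_um"].median().median()
        assert pooled == pytest.approx(1.75)
        assert pooled != pytest.approx(per_field)

    def test_overall_radius(self):
        table = pd.DataFrame({
            "patient_id": ["P1", "P2", "P3"],
            "source": "T", "target": "Tumor",
            "n_source_cells": 5, "median_um": [10.0, 20.0, 30.0],
        })
        assert overall_nearest_radius(table) == 20.0
        assert overall_nearest_radius(table.iloc[:1]) == 10.0

    def test_poisson_tumor_radius_close_to_closed_form(self, rng):
        # mean NN distance to a Poisson process of intensity lam is 1/(2 sqrt(lam))
        lam = 0.01  # per um^2
        side = 400.0
        n = rng.poisson(lam * side * side)
        tumor = rng.uniform(0, side, (n, 2))
        # sources well inside to avoid edge effects
        src = rng.uniform(100, side - 100, (4000, 2))
        d = nn_distance(src, tumor)
        assert np.mean(d) == pytest.approx(1 / (2 * math.sqrt(lam)), rel=0.05)


class TestMetricCorrelation:
    def test_unit_diagonal_and_antisymmetric_vectors(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [3.0, 2.0, 1.0]})
        for method in ("pearson", "spearman"):
            c = metric_correlation_matrix(df, method)
            assert c.loc["a", "a"] == pytest.approx(1.0)
            assert c.loc["a", "b"] == pytest.approx(-1.0)

    def test_pearson_matches_closed_form(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        c = metric_correlation_matrix(df, "pearson")
        x, y = df["a"].to_numpy(), df["c"].to_numpy()
        manual = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert c.loc["a", "c"] == pytest.approx(manual, abs=1e-12)

    def test_bad_method(self):
        with pytest.raises(ValueError):
            metric_correlation_matrix(pd.DataFrame({"a": [1, 2]}), "kendall")


def test_distance_table_on_cohort(small_gated):
    table = build_distance_table(small_gated)
    assert set(table.columns) == {"patient_id", "source", "target",
                                  "n_source_cells", "median_um"}
    assert (table["median_um"] >= 0).all()
    assert (table["n_source_cells"] >= 1).all()
    radius = overall_nearest_radius(table)
    assert np.isfinite(radius) and radius > 0
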