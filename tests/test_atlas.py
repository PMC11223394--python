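import numpy as np
import pytest

import _oracles
from methyltoo.atlas import (
    DifferentialRegionResult,
    build_atlas,
    select_top_regions,
    test_one_vs_rest,
)
from methyltoo.regions import RegionValueMatrix


def make_matrix(values, n_class=10, n_rest=50):
    values = np.asarray(values, dtype=float)
    sample_ids = [f"c{i}" for i in range(n_class)] + [f"o{i}" for i in range(n_rest)]
    labels = {f"c{i}": "Liver" for i in range(n_class)}
    labels.update({f"o{i}": "WBC" for i in range(n_rest)})
    matrix = RegionValueMatrix(
        sample_ids=sample_ids,
        region_ids=[f"r{j}" for j in range(values.shape[1])],
        values=values,
    )
    return matrix, labels


class TestOneVsRest:
    def test_planted_region_matches_textbook_welch(self, rng):
        n_class, n_rest = 10, 50
        values = np.column_stack([
            np.concatenate([rng.normal(0.1, 0.02, n_class).clip(0, 1),
                            rng.normal(0.9, 0.02, n_rest).clip(0, 1)]),
            rng.uniform(0.3, 0.7, n_class + n_rest),  # null region
        ])
        matrix, labels = make_matrix(values, n_class, n_rest)
        results = {r.region_id: r for r in test_one_vs_rest(matrix, labels, "Liver")}
        planted = results["r0"]
        t_ref, p_ref = _oracles.welch_t_test(values[:n_class, 0], values[n_class:, 0])
        assert planted.t_statistic == pytest.approx(t_ref, rel=1e-10)
        assert planted.p_value == pytest.approx(p_ref, rel=1e-8)
        assert planted.p_adjusted == pytest.approx(min(1.0, p_ref * 2), rel=1e-8)
        assert planted.p_adjusted < 0.05
        assert planted.log2fc < 0
        eps = 1e-3
        log2fc_ref = np.log2(
            (values[:n_class, 0].mean() + eps) / (values[n_class:, 0].mean() + eps)
        )
        assert planted.log2fc == pytest.approx(log2fc_ref, rel=1e-12)

    def test_identical_groups_not_significant(self):
        values = np.tile(np.array([0.5, 0.2, 0.8]), (60, 1))
        matrix, labels = make_matrix(values)
        for r in test_one_vs_rest(matrix, labels, "Liver"):
            assert r.t_statistic == 0.0
            assert r.p_adjusted == 1.0

    def test_region_missing_in_class_skipped(self, rng):
        values = rng.uniform(0.2, 0.8, size=(60, 3))
        values[:10, 1] = np.nan  # all Liver samples missing at r1
        matrix, labels = make_matrix(values)
        ids = {r.region_id for r in test_one_vs_rest(matrix, labels, "Liver")}
        assert ids == {"r0", "r2"}

    def test_absent_class_raises(self, rng):
        matrix, labels = make_matrix(rng.uniform(size=(60, 2)))
        with pytest.raises(ValueError, match="Breast"):
            test_one_vs_rest(matrix, labels, "Breast")

    def test_selection_invariant_to_sample_order(self, rng):
        values = rng.uniform(0.1, 0.9, size=(60, 40))
        values[:10, :5] -= 0.08  # mildly hypomethylated block
        matrix, labels = make_matrix(values.clip(0, 1))
        perm = rng.permutation(60)
        shuffled = RegionValueMatrix(
            sample_ids=[matrix.sample_ids[i] for i in perm],
            region_ids=matrix.region_ids,
            values=matrix.values[perm],
        )
        res_a = test_one_vs_rest(matrix, labels, "Liver")
        res_b = test_one_vs_rest(shuffled, labels, "Liver")
        sel_a = select_top_regions(res_a, top_k=10)
        sel_b = select_top_regions(res_b, top_k=10)
        assert sel_a == sel_b

    def test_bonferroni_dominance_of_selected(self, rng):
        values = rng.uniform(0.2, 0.9, size=(60, 30))
        values[:10, :8] = rng.uniform(0.0, 0.2, size=(10, 8))
        matrix, labels = make_matrix(values)
        results = test_one_vs_rest(matrix, labels, "Liver")
        n_tested = len(results)
        selected = set(select_top_regions(results, top_k=5))
        for r in results:
            if r.region_id in selected:
                assert r.p_value * n_tested < 0.05


def result(rid, log2fc, p_adj, cls="Liver"):
    return DifferentialRegionResult(rid, cls, -1.0, p_adj / 10, p_adj, log2fc)


class TestSelection:
    def test_rank_and_cut_at_top_k(self, rng):
        results = [result(f"r{j:04d}", -(0.1 + j * 0.01), 1e-4) for j in range(600)]
        rng.shuffle(results)
        selected = select_top_regions(results, top_k=500)
        assert len(selected) == 500
        expected = {f"r{j:04d}" for j in range(100, 600)}  # 500 largest |log2fc|
        assert set(selected) == expected

    def test_fewer_survivors_returned_all(self, caplog):
        results = [result(f"r{j}", -0.5, 1e-4) for j in range(12)]
        results += [result("null", -0.5, 0.9)]
        with caplog.at_level("WARNING"):
            selected = select_top_regions(results, top_k=500)
        assert len(selected) == 12
        assert any("12" in rec.message for rec in caplog.records)

    def test_positive_log2fc_excluded_even_if_significant(self):
        results = [result("neg", -0.3, 1e-4), result("pos", 0.9, 1e-9)]
        assert select_top_regions(results, top_k=10) == ["neg"]

    def test_tie_breaks_by_region_id(self):
        results = [result("b", -0.5, 1e-4), result("a", -0.5, 1e-4)]
        assert select_top_regions(results, top_k=1) == ["a"]


class TestBuildAtlas:
    def test_missing_values_removed_before_aggregating(self):
        values = np.full((60, 1), 0.5)
        values[0, 0], values[1, 0], values[2, 0] = 0.2, np.nan, 0.4
        values[3:10, 0] = np.nan
        matrix, labels = make_matrix(values)
        atlas = build_atlas(matrix, labels, {"Liver": ["r0"], "WBC": ["r0"]})
        assert atlas.row("Liver")[0] == pytest.approx((0.2 + 0.4) / 2)
        assert atlas.row("WBC")[0] == pytest.approx(0.5)

    def test_single_sample_per_class_copies_values(self, rng):
        values = rng.uniform(0.1, 0.9, size=(2, 4))
        matrix, labels = make_matrix(values, n_class=1, n_rest=1)
        atlas = build_atlas(matrix, labels, {"Liver": ["r1", "r3"], "WBC": ["r0"]})
        np.testing.assert_allclose(atlas.row("Liver"), values[0, [1, 3, 0]])

    def test_union_deduplicates_across_classes(self, rng):
        matrix, labels = make_matrix(rng.uniform(0.1, 0.9, size=(60, 10)))
        selections = {"Liver": ["r0", "r1", "r2"], "WBC": ["r2", "r3"]}
        atlas = build_atlas(matrix, labels, selections)
        assert atlas.region_ids == ["r0", "r1", "r2", "r3"]
        assert atlas.values.shape == (2, 4)

    def test_all_missing_class_region_is_build_error(self):
        values = np.full((60, 2), 0.5)
        values[:10, 0] = np.nan
        matrix, labels = make_matrix(values)
        with pytest.raises(ValueError, match=r"Liver.*r0"):
            build_atlas(matrix, labels, {"Liver": ["r0"], "WBC": ["r1"]})
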