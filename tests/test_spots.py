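import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somportray import (
    DataError,
    GeneSetCollection,
    GSZConfig,
    Portrait,
    detect_spots,
    fisher_enrichment,
    gsz_matrix,
    gsz_score,
    read_gmt,
    upregulated_overlap,
    write_gmt,
)
from somportray.portraits import group_mean_portrait
from somportray.som import SOMConfig, TrainedSOM


def _manual_som(bmu, rows=3, cols=3):
    bmu = np.asarray(bmu)
    return TrainedSOM(
        SOMConfig(grid_rows=rows, grid_cols=cols, epochs=1),
        np.zeros((rows * cols, 2)),
        {"L": (0, 2)},
        [f"g{i}" for i in range(len(bmu))],
        bmu,
    )


class TestDetectSpots:
    def test_constant_portrait_has_no_spots(self):
        som = _manual_som(np.arange(9))
        p = Portrait(np.full((3, 3), 1.0), "x", "L")
        assert detect_spots(p, som, quantile=0.9) == []

    def test_single_hot_cell_with_min_cells_one(self):
        som = _manual_som(np.arange(9))
        grid = np.zeros((3, 3))
        grid[1, 2] = 5.0
        spots = detect_spots(Portrait(grid, "x", "L"), som, quantile=0.9, min_cells=1)
        assert len(spots) == 1
        assert spots[0].cells == {(1, 2)}
        assert spots[0].member_genes == {"g5"}
        assert spots[0].peak_value == 5.0

    def test_down_polarity_mirrors_up(self):
        som = _manual_som(np.arange(9))
        grid = np.zeros((3, 3))
        grid[0, 0] = -4.0
        spots = detect_spots(Portrait(grid, "x", "L"), som, quantile=0.9,
                             min_cells=1, polarity="down")
        assert spots[0].cells == {(0, 0)} and spots[0].polarity == "down"

    def test_eight_connectivity_merges_diagonal(self):
        som = _manual_som(np.arange(9))
        grid = np.zeros((3, 3))
        grid[0, 0] = grid[1, 1] = grid[2, 2] = 9.0
        spots = detect_spots(Portrait(grid, "x", "L"), som, quantile=0.5, min_cells=3)
        assert len(spots) == 1 and spots[0].n_cells == 3

    @given(st.floats(min_value=-100, max_value=100))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_translation_invariance(self, shift):
        som = _manual_som(np.arange(9))
        rng = np.random.default_rng(0)
        grid = rng.normal(size=(3, 3))
        a = detect_spots(Portrait(grid, "x", "L"), som, quantile=0.7, min_cells=1)
        b = detect_spots(Portrait(grid + shift, "x", "L"), som, quantile=0.7, min_cells=1)
        assert {frozenset(s.cells) for s in a} == {frozenset(s.cells) for s in b}

    def test_planted_module_recovered(self, fixture_bundle):
        _, _, truth, ds, som = fixture_bundle
        port = group_mean_portrait(som, ds.layers[0], "gBRCA1")
        spots = detect_spots(port, som, quantile=0.85, min_cells=3)
        m1 = set(truth.module_genes("M1"))
        best = max(spots, key=lambda s: len(s.member_genes & m1))
        assert len(best.member_genes & m1) / len(m1) >= 0.8


def hypergeom_tail_oracle(a, n_spot, n_set, N):
    """P(overlap >= a) by direct enumeration of the hypergeometric pmf."""
    total = math.comb(N, n_spot)
    return sum(
        math.comb(n_set, i) * math.comb(N - n_set, n_spot - i)
        for i in range(a, min(n_spot, n_set) + 1)
    ) / total


class TestFisher:
    def test_perfect_overlap_hand_value(self):
        genes = {f"g{i}" for i in range(5)}
        _, p = fisher_enrichment(genes, genes, 10)
        np.testing.assert_allclose(p, 1 / 252, rtol=1e-10)

    def test_disjoint_covering_universe(self):
        spot = {f"a{i}" for i in range(5)}
        gset = {f"b{i}" for i in range(5)}
        _, p = fisher_enrichment(spot, gset, 10)
        np.testing.assert_allclose(p, 1.0)

    def test_spot_equals_universe(self):
        spot = {f"g{i}" for i in range(8)}
        _, p = fisher_enrichment(spot, {"g0", "g1"}, 8)
        np.testing.assert_allclose(p, 1.0)

    def test_empty_inputs_rejected(self):
        with pytest.raises(DataError):
            fisher_enrichment(set(), {"g0"}, 5)

    def test_matches_enumeration_for_all_small_tables(self):
        """Exhaustive check against the hypergeometric tail sum for every
        feasible (universe, spot size, set size, overlap) with N <= 20."""
        for N in range(2, 21):
            for n_spot in range(1, N + 1):
                for n_set in range(1, N + 1):
                    lo = max(0, n_spot + n_set - N)
                    for a in range(lo, min(n_spot, n_set) + 1):
                        spot = {f"g{i}" for i in range(n_spot)}
                        gset = {f"g{i}" for i in range(a)} | {
                            f"g{n_spot + i}" for i in range(n_set - a)
                        }
                        _, p = fisher_enrichment(spot, gset, N)
                        np.testing.assert_allclose(
                            p, hypergeom_tail_oracle(a, n_spot, n_set, N),
                            rtol=1e-9,
                            err_msg=f"N={N} spot={n_spot} set={n_set} a={a}",
                        )


class TestGSZ:
    def test_equal_scores_give_zero(self):
        z = gsz_score(np.full(10, 3.0), np.arange(4), GSZConfig(0.0))
        assert z == 0.0

    def test_hand_arithmetic(self):
        # scores [2,0,0,0], set {gene 0}: S=2, E=0.5, V=0.75
        z = gsz_score([2.0, 0, 0, 0], [0], GSZConfig(lambda_stabilizer=0.0))
        np.testing.assert_allclose(z, 1.5 / np.sqrt(0.75), rtol=1e-12)

    def test_full_set_with_zero_lambda_rejected(self):
        with pytest.raises(DataError):
            gsz_score([1.0, 2.0], [0, 1], GSZConfig(lambda_stabilizer=0.0))

    @given(st.floats(min_value=-50, max_value=50))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_shift_invariance(self, c):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=30)
        idx = np.arange(8)
        z1 = gsz_score(scores, idx)
        z2 = gsz_score(scores + c, idx)
        np.testing.assert_allclose(z1, z2, atol=1e-8)

    @pytest.mark.parametrize("set_size", [10, 50, 200])
    def test_null_calibration(self, set_size):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=2000)
        cfg = GSZConfig(lambda_stabilizer=0.0)
        hits = sum(
            abs(gsz_score(scores, rng.choice(2000, set_size, replace=False), cfg)) > 1.96
            for _ in range(1000)
        )
        assert 0.03 <= hits / 1000 <= 0.07


class TestGSZMatrix:
    def test_planted_module_peaks_in_target_group(self, fixture_bundle):
        _, _, truth, ds, som = fixture_bundle
        coll = GeneSetCollection({"M1_set": truth.module_genes("M1")})
        res = gsz_matrix(ds, som, coll)
        row = res.matrix.loc["M1_set"]
        assert row.idxmax() in ("L1:gBRCA1", "L2:gBRCA1")

    def test_duplicate_sets_identical_rows_adjacent(self, fixture_bundle):
        _, _, truth, ds, som = fixture_bundle
        genes = truth.module_genes("M1")
        coll = GeneSetCollection({
            "A": genes, "B": genes, "C": truth.module_genes("M2"),
        })
        res = gsz_matrix(ds, som, coll)
        np.testing.assert_allclose(res.matrix.loc["A"], res.matrix.loc["B"])
        order = res.row_order
        assert abs(order.index(0) - order.index(1)) == 1

    def test_no_overlap_set_dropped(self, fixture_bundle):
        _, _, truth, ds, som = fixture_bundle
        coll = GeneSetCollection({
            "real": truth.module_genes("M1"), "ghost": ["NOPE1", "NOPE2"],
        })
        res = gsz_matrix(ds, som, coll)
        assert res.dropped_sets == ["ghost"]
        assert list(res.matrix.index) == ["real"]


class TestOverlap:
    def test_identical_columns_overlap_equals_own_count(self):
        z = pd.DataFrame({"a": [3.0, 2.5, 1.0], "b": [3.0, 2.5, 1.0]},
                         index=["s1", "s2", "s3"])
        counts, passing = upregulated_overlap(z)
        assert counts.loc["a", "b"] == 2 == counts.loc["a", "a"]
        assert passing["a"] == {"s1", "s2"}

    def test_disjoint_passing_sets(self):
        z = pd.DataFrame({"a": [3.0, 0.0], "b": [0.0, 3.0]}, index=["s1", "s2"])
        counts, _ = upregulated_overlap(z)
        assert counts.loc["a", "b"] == 0

    def test_single_column_rejected(self):
        with pytest.raises(DataError):
            upregulated_overlap(pd.DataFrame({"a": [1.0]}))


def test_gmt_round_trip(tmp_path):
    coll = GeneSetCollection({"set1": ["g1", "g2"], "set2": ["g3"]})
    path = tmp_path / "sets.gmt"
    write_gmt(coll, path)
    back = read_gmt(path)
    assert back.sets == coll.sets
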