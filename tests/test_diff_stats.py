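import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from somportray import (
    DataError,
    ModuleSpec,
    SyntheticConfig,
    bh_fdr,
    generate_dataset,
    one_way_anova,
    pairwise_de,
    panel_heatmap,
    to_dataset,
    welch_test,
)

from conftest import make_layer_from_values


class TestWelch:
    def test_identical_groups(self):
        assert welch_test([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_hand_computed_strong_separation(self):
        x, y = [0, 0.1, -0.1], [10, 10.1, 9.9]
        t, p = welch_test(x, y)
        # closed form: se = sqrt(0.01/3 + 0.01/3), t = -10 / se
        se = np.sqrt(np.var(x, ddof=1) / 3 + np.var(y, ddof=1) / 3)
        np.testing.assert_allclose(t, -10 / se, rtol=1e-12)
        assert p < 0.001

    def test_swap_negates_t_keeps_p(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=6), rng.normal(1, 1, size=8)
        t1, p1 = welch_test(x, y)
        t2, p2 = welch_test(y, x)
        assert t1 == -t2 and p1 == p2

    def test_undersized_group_rejected(self):
        with pytest.raises(DataError):
            welch_test([1.0], [1, 2, 3])

    def test_zero_variance_both_groups(self):
        assert welch_test([2, 2, 2], [2, 2, 2]) == (0.0, 1.0)
        t, p = welch_test([3, 3, 3], [2, 2, 2])
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10_000, 10))
        y = rng.normal(size=(10_000, 10))
        _, p = stats.ttest_ind(x, y, axis=1, equal_var=False)
        rate = float(np.mean(p < 0.05))
        assert 0.045 <= rate <= 0.056


class TestBH:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1, 1, 1]), [1, 1, 1])

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=30))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_step_up_properties(self, p):
        p = np.asarray(p)
        adj = bh_fdr(p)
        order = np.argsort(p, kind="stable")
        # adjusted values are non-decreasing in the sorted-p order
        assert np.all(np.diff(adj[order]) >= -1e-12)
        # adjustment never decreases a p-value and never exceeds 1
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1 + 1e-12)


class TestPairwiseDE:
    def _planted_layer(self, seed=0, effect=1.0, n_de=200):
        cfg = SyntheticConfig(
            n_genes=2000,
            group_sizes={"L1": {"gBRCA1": 10, "noBRCA": 10}},
            modules=[ModuleSpec("M", n_de, "gBRCA1", effect)],
            module_factor_sd=0.0,   # independent planted genes for DE counting
            seed=seed,
        )
        mats, anns, truth = generate_dataset(cfg)
        return to_dataset(mats, anns).layers[0], truth

    def test_group_vs_itself_is_null(self):
        layer = make_layer_from_values(
            np.random.default_rng(0).normal(size=(50, 6)),
            groups=["noBRCA"] * 6,
        )
        res = pairwise_de(layer, "noBRCA", "noBRCA")
        np.testing.assert_allclose(res.table["logFC"], 0, atol=1e-12)
        assert res.counts_at[0.05] == 0 and res.stars == ""

    def test_planted_count_recovered_with_star(self):
        layer, _ = self._planted_layer()
        res = pairwise_de(layer, "gBRCA1", "noBRCA")
        assert 180 <= res.counts_at[0.05] <= 220
        assert res.stars == "*"
        assert len(res.top_genes) == 8
        assert set(res.top_genes["direction"]) == {"up", "down"}

    def test_logfc_sign_matches_planted_direction(self):
        layer, truth = self._planted_layer(seed=1)
        res = pairwise_de(layer, "gBRCA1", "noBRCA")
        planted = res.table["gene_id"].map(truth.module_membership.get) == "M"
        signs = np.sign(res.table.loc[planted, "logFC"])
        assert (signs > 0).mean() >= 0.95

    def test_null_fdr_control_across_seeds(self):
        ok = 0
        for seed in range(100):
            cfg = SyntheticConfig(
                n_genes=2000,
                group_sizes={"L1": {"gBRCA1": 10, "noBRCA": 10}},
                seed=seed,
            )
            mats, anns, _ = generate_dataset(cfg)
            layer = to_dataset(mats, anns).layers[0]
            res = pairwise_de(layer, "gBRCA1", "noBRCA")
            ok += res.counts_at[0.05] <= 0.05 * 2000
        assert ok >= 95

    def test_small_group_rejected(self):
        layer = make_layer_from_values(
            np.zeros((5, 3)), groups=["gBRCA1", "noBRCA", "noBRCA"]
        )
        with pytest.raises(DataError, match=">=2"):
            pairwise_de(layer, "gBRCA1", "noBRCA")


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        layer = make_layer_from_values(
            [[1.0, 1, 1, 1]], groups=["gBRCA1", "gBRCA1", "noBRCA", "noBRCA"]
        )
        res = one_way_anova(layer, "g0")
        assert res.F == 0.0 and res.p == 1.0

    def test_two_groups_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(1, 8))
        groups = ["gBRCA1"] * 4 + ["noBRCA"] * 4
        layer = make_layer_from_values(vals, groups=groups)
        res = one_way_anova(layer, "g0")
        t, _ = stats.ttest_ind(vals[0, :4], vals[0, 4:], equal_var=True)
        np.testing.assert_allclose(res.F, t**2, rtol=1e-10)

    def test_planted_gradient_detected(self):
        rng = np.random.default_rng(0)
        groups = ["gBRCA2"] * 5 + ["sBRCA2"] * 5 + ["noBRCA"] * 5
        shift = np.repeat([-1.0, 0.0, 1.0], 5)
        vals = (shift + rng.normal(0, 0.3, 15))[None, :]
        layer = make_layer_from_values(vals, groups=groups)
        res = one_way_anova(layer, "g0")
        assert res.p < 0.01
        assert res.group_means["gBRCA2"] < res.group_means["sBRCA2"] < res.group_means["noBRCA"]

    def test_needs_two_usable_groups(self):
        layer = make_layer_from_values(np.zeros((1, 3)), groups=["noBRCA"] * 3)
        with pytest.raises(DataError):
            one_way_anova(layer, "g0")


class TestPanelHeatmap:
    def _layer(self):
        rng = np.random.default_rng(7)
        groups = ["gBRCA1"] * 3 + ["sBRCA1"] * 3 + ["noBRCA"] * 4
        vals = rng.normal(size=(6, 10))
        vals[0] = vals[1]                       # identical pair
        vals[2, :3] += 3.0                      # P2 up in gBRCA1 only
        layer = make_layer_from_values(vals, groups=groups)
        layer.gene_ids = ["P0", "P1", "P2", "P3", "P4", "P5"]
        return layer

    def test_identical_rows_are_adjacent_leaves(self):
        hm = panel_heatmap(self._layer(), ["P0", "P1", "P2", "P3"])
        order = hm.row_order
        assert abs(order.index(0) - order.index(1)) == 1

    def test_rows_are_z_scored(self):
        hm = panel_heatmap(self._layer(), ["P0", "P2", "P3"])
        Z = hm.matrix.to_numpy()
        np.testing.assert_allclose(Z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=1, ddof=1), 1, rtol=1e-12)

    def test_planted_up_gene_peaks_in_target_group(self):
        hm = panel_heatmap(self._layer(), ["P2", "P3", "P4"])
        assert hm.matrix.loc["P2"].idxmax() == "gBRCA1"

    def test_missing_genes_dropped_and_too_few_rejected(self):
        hm = panel_heatmap(self._layer(), ["P0", "P2", "PARPX"])
        assert hm.dropped_genes == ["PARPX"]
        with pytest.raises(DataError, match="2 panel genes"):
            panel_heatmap(self._layer(), ["P0", "PARPX"])
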