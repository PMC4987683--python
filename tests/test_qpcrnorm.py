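"""CT normalization: stability ranking, −ΔΔCT, imputation, clustering."""

import numpy as np
import pandas as pd
import pytest

from ebclock.qpcrnorm import (
    ExpressionPanel,
    NormalizerDisagreement,
    cluster_corr,
    filter_genes,
    fold_range,
    genorm_stability,
    impute_nn,
    normalize_neg_ddct,
    normfinder_stability,
    select_normalizers,
)


def make_panel(ct: dict, groups=None) -> ExpressionPanel:
    df = pd.DataFrame(ct).T
    df.columns = [f"E{i}" for i in range(df.shape[1])]
    n = df.shape[1]
    meta = pd.DataFrame({"group": groups or ["control"] * n}, index=df.columns)
    return ExpressionPanel(ct=df, metadata=meta)


class TestGeNorm:
    def test_constant_offset_pair_has_zero_pairwise_variation(self):
        panel = make_panel({
            "a": [10.0, 11.0, 12.0, 13.0],
            "b": [12.0, 13.0, 14.0, 15.0],  # a + 2 exactly
            "c": [10.0, 14.0, 9.0, 16.0],
        })
        m = genorm_stability(panel, ["a", "b", "c"])
        # the a-b pairwise sd is 0; each of a,b still averages in the noisy c
        sd_ac = np.std(panel.ct.loc["a"] - panel.ct.loc["c"], ddof=1)
        assert m["a"] == pytest.approx(sd_ac / 2 + 0.0)

    def test_matches_brute_force_pairwise_sd(self, rng):
        ct = {f"g{i}": 10 + rng.normal(0, 1, size=6) for i in range(4)}
        panel = make_panel(ct)
        m = genorm_stability(panel, list(ct))
        for j in ct:
            sds = [np.std(np.asarray(ct[j]) - np.asarray(ct[k]), ddof=1) for k in ct if k != j]
            assert m[j] == pytest.approx(np.mean(sds))

    def test_noisiest_candidate_ranks_last(self, rng):
        base = 12 + rng.normal(0, 0.05, size=8)
        panel = make_panel({
            "s1": base + 0.1, "s2": base - 0.1,
            "loud": 12 + rng.normal(0, 3.0, size=8),
        })
        m = genorm_stability(panel, ["s1", "s2", "loud"])
        assert m.index[-1] == "loud"

    def test_gene_wise_constant_shift_invariance(self, rng):
        ct = {f"g{i}": 10 + rng.normal(0, 1, size=6) for i in range(4)}
        m0 = genorm_stability(make_panel(ct), list(ct))
        shifted = {g: np.asarray(v) + i for i, (g, v) in enumerate(ct.items())}
        m1 = genorm_stability(make_panel(shifted), list(ct))
        pd.testing.assert_series_equal(m0, m1)

    def test_too_few_candidates_rejected(self):
        panel = make_panel({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            genorm_stability(panel, ["a", "b"])


class TestNormFinder:
    def test_single_group_reduces_to_intra_variance_ranking(self, rng):
        ct = {f"g{i}": 12 + rng.normal(0, 0.2 * (i + 1), size=10) for i in range(4)}
        panel = make_panel(ct)
        s = normfinder_stability(panel, list(ct))
        vars_ = {g: np.std(np.asarray(v), ddof=1) for g, v in ct.items()}
        assert list(s.index) == sorted(vars_, key=vars_.get)

    def test_zero_variance_candidate_ranked_first_with_zero_stability(self):
        panel = make_panel({
            "flat": [10.0] * 6,
            "a": [10.0, 11.0, 9.5, 10.2, 10.8, 9.9],
            "b": [12.0, 11.0, 13.0, 12.5, 11.5, 12.2],
        })
        s = normfinder_stability(panel, ["flat", "a", "b"])
        assert s.index[0] == "flat" and s["flat"] == 0.0

    def test_matches_two_way_decomposition_oracle(self, rng):
        groups = ["g1"] * 5 + ["g2"] * 5
        ct = {f"c{i}": 12 + rng.normal(0, 1, size=10) for i in range(4)}
        panel = make_panel(ct, groups=groups)
        s = normfinder_stability(panel, list(ct))
        x = panel.ct.to_numpy()
        gmask = np.array([g == "g1" for g in groups])
        mg = np.column_stack([x[:, gmask].mean(1), x[:, ~gmask].mean(1)])
        d = mg - mg.mean(1, keepdims=True) - mg.mean(0, keepdims=True) + mg.mean()
        inter = (d**2).mean(1)
        intra = np.column_stack([x[:, gmask].var(1, ddof=1), x[:, ~gmask].var(1, ddof=1)]).mean(1)
        np.testing.assert_allclose(np.sort(np.sqrt(inter + intra)), s.to_numpy())

    def test_tiny_group_rejected(self):
        panel = make_panel({"a": [1.0] * 4, "b": [2.0] * 4, "c": [3.0] * 4},
                           groups=["x", "x", "x", "y"])
        with pytest.raises(ValueError, match="fewer than 2"):
            normfinder_stability(panel, ["a", "b", "c"])


class TestSelectNormalizers:
    def test_designed_stable_pair_selected_by_both_methods(self, rng):
        loading = rng.normal(0, 0.3, size=12)
        panel = make_panel({
            "hk1": 14 + loading + rng.normal(0, 0.05, 12),
            "hk2": 13 + loading + rng.normal(0, 0.05, 12),
            "v1": 20 + rng.normal(0, 1.5, 12),
            "v2": 22 + rng.normal(0, 2.0, 12),
        })
        assert set(select_normalizers(panel, ["hk1", "hk2", "v1", "v2"])) == {"hk1", "hk2"}

    def test_disagreement_raises_with_both_rankings(self):
        # geNorm rewards the correlated pair a,b; NormFinder's intra-variance
        # view (single group) prefers the low-variance c over b
        common = np.array([0.0, 2.0, -2.0, 1.0, -1.0, 0.5])
        panel = make_panel({
            "a": 12 + common,
            "b": 14 + common + np.array([0.02, -0.01, 0.03, -0.02, 0.01, -0.03]),
            "c": np.array([13.0, 13.05, 12.95, 13.02, 12.98, 13.0]),
        })
        with pytest.raises(NormalizerDisagreement) as exc:
            select_normalizers(panel, ["a", "b", "c"])
        assert exc.value.genorm_ranking and exc.value.normfinder_ranking

    def test_too_few_candidates_rejected(self):
        panel = make_panel({"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0]})
        with pytest.raises(ValueError):
            select_normalizers(panel, ["a", "b"])


class TestNegDdct:
    def test_hand_computed_two_gene_four_eb_table(self):
        panel = make_panel({
            "n1": [14.0, 14.0, 14.0, 14.0],
            "n2": [12.0, 12.0, 12.0, 12.0],
            "g": [20.0, 19.0, 21.0, 18.0],
        })
        norm = normalize_neg_ddct(panel, ("n1", "n2"), "control")
        # ΔCT = CT_g − 13; median ΔCT over control = 6.5; −ΔΔCT = 6.5 − ΔCT
        np.testing.assert_allclose(norm.neg_ddct.loc["g"], [-0.5, 0.5, -1.5, 1.5])

    def test_reference_median_exactly_zero(self, rng):
        ct = {"n1": 14 + rng.normal(0, 0.1, 9), "n2": 12 + rng.normal(0, 0.1, 9)}
        for i in range(5):
            ct[f"g{i}"] = 20 + rng.normal(0, 2, 9)
        norm = normalize_neg_ddct(make_panel(ct), ("n1", "n2"), "control")
        np.testing.assert_allclose(norm.neg_ddct.median(axis=1), 0.0, atol=1e-12)

    def test_one_cycle_below_reference_median_reads_plus_one(self):
        panel = make_panel({
            "n1": [14.0] * 5, "n2": [12.0] * 5,
            "g": [20.0, 20.0, 20.0, 20.0, 19.0],
        })
        norm = normalize_neg_ddct(panel, ("n1", "n2"), "control")
        assert norm.neg_ddct.loc["g"].iloc[-1] == pytest.approx(1.0)

    def test_invariant_to_per_eb_constant_ct_shift(self, rng):
        ct = {"n1": 14 + rng.normal(0, 0.1, 6), "n2": 12 + rng.normal(0, 0.1, 6),
              "g": 20 + rng.normal(0, 1, 6)}
        panel = make_panel(ct)
        shift = rng.normal(0, 1, 6)  # loading / cell-number effect
        shifted = make_panel({k: np.asarray(v) + shift for k, v in ct.items()})
        a = normalize_neg_ddct(panel, ("n1", "n2"), "control").neg_ddct
        b = normalize_neg_ddct(shifted, ("n1", "n2"), "control").neg_ddct
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_eb_missing_both_normalizers_dropped(self):
        ct = pd.DataFrame(
            {"E0": [14.0, 12.0, 20.0], "E1": [np.nan, np.nan, 21.0], "E2": [14.0, 12.0, 19.0]},
            index=["n1", "n2", "g"],
        )
        meta = pd.DataFrame({"group": ["control"] * 3}, index=ct.columns)
        norm = normalize_neg_ddct(ExpressionPanel(ct, meta), ("n1", "n2"), "control")
        assert list(norm.neg_ddct.columns) == ["E0", "E2"]


class TestImputeNN:
    def test_no_missing_is_identity(self, rng):
        m = pd.DataFrame(rng.normal(size=(4, 5)))
        pd.testing.assert_frame_equal(impute_nn(m), m)

    def test_single_missing_cell_filled_from_nearest_eb(self):
        m = pd.DataFrame(
            {"E0": [1.0, 1.0, np.nan], "E1": [1.1, 1.05, 5.0], "E2": [9.0, 9.0, -3.0]},
            index=["a", "b", "c"],
        )
        out = impute_nn(m)
        assert out.loc["c", "E0"] == 5.0  # E1 is by far the closest EB
        assert out.drop(index="c").equals(m.drop(index="c"))

    def test_all_missing_gene_rejected(self):
        m = pd.DataFrame({"E0": [1.0, np.nan], "E1": [2.0, np.nan]}, index=["a", "b"])
        with pytest.raises(ValueError, match="gene"):
            impute_nn(m)


class TestClusterCorr:
    def test_duplicated_profile_merges_first_at_zero_distance(self):
        m = pd.DataFrame(
            {"E0": [1.0, 2.0, 5.0], "E1": [2.0, 4.0, 1.0], "E2": [3.0, 6.0, 2.0]},
            index=["a", "a2", "b"],
        ).astype(float)
        m.loc["a2"] = 2 * m.loc["a"]  # perfectly correlated duplicate
        res = cluster_corr(m, axis="genes")
        first = res["linkage"][0]
        assert {int(first[0]), int(first[1])} == {0, 1} and first[2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_pair_merges_last_in_three_profile_toy(self):
        m = pd.DataFrame(
            {"E0": [0.0, 0.0, 1.0], "E1": [1.0, 1.1, 2.0], "E2": [2.0, 1.9, 3.0], "E3": [3.0, 3.0, 0.5]},
            index=["up1", "up2", "mix"],
        )
        m.loc["mix"] = -m.loc["up1"]  # d(up1, mix) = 2
        res = cluster_corr(m, axis="genes")
        assert res["linkage"][-1][2] == pytest.approx(
            (2.0 + (1 - np.corrcoef(m.loc["up2"], m.loc["mix"])[0, 1])) / 2
        )

    def test_hand_traced_average_linkage_merge_sequence(self):
        # four profiles engineered so correlations (and 1−r distances) are known:
        # a≈b (d small), c = −a (d=2), d ⟂ pattern in between
        x = np.linspace(0, 1, 6)
        m = pd.DataFrame(
            [x, x + 0.01 * np.array([0, 1, 0, -1, 0, 1]), -x, np.array([0.0, 1, 0, 1, 0, 1])],
            index=["a", "b", "c", "d"],
        )
        res = cluster_corr(m, axis="genes")
        from scipy.spatial.distance import squareform
        from scipy.cluster.hierarchy import linkage

        corr = np.corrcoef(m.to_numpy())
        expected = linkage(squareform(1 - corr, checks=False), method="average")
        np.testing.assert_allclose(res["linkage"], expected)

    def test_constant_profile_rejected(self):
        m = pd.DataFrame({"E0": [1.0, 1.0], "E1": [2.0, 1.0], "E2": [3.0, 1.0]},
                         index=["a", "flat"]).T.T
        with pytest.raises(ValueError, match="constant"):
            cluster_corr(m, axis="genes")


class TestFoldRangeAndFilters:
    def test_fold_range_values(self):
        assert fold_range([0.0, 1.0]) == pytest.approx(2.0)
        assert fold_range([-6.0, 6.0]) == pytest.approx(4096.0)
        assert fold_range([2.5, 2.5, 2.5]) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            fold_range([1.0])

    def test_filter_genes_drops_flat_and_failed(self, rng):
        m = pd.DataFrame(
            {
                "ok": rng.normal(0, 2, 10),
                "flat": rng.normal(0, 0.1, 10),
                "failed": np.where(np.arange(10) < 4, rng.normal(0, 2, 10), np.nan),
            }
        ).T
        kept = filter_genes(m)
        assert list(kept.index) == ["ok"]
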