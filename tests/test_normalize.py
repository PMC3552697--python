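import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ctnorm import (CTMatrix, WeightedMeanParams, cyclic_loess_normalize,
                    delta_ct, delta_delta_ct_fold_change, gene_sd, mean_ct0,
                    median_normalize, quantile_normalize, rank_invariant_ct0,
                    topk_ct0, weighted_mean_ct0)


def _matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return CTMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestMeanCT0:
    def test_arithmetic_and_median_odd_count(self):
        m = _matrix([[20.0], [22.0], [24.0]])
        assert mean_ct0(m, "arithmetic").values.iloc[0] == 22.0
        assert mean_ct0(m, "median").values.iloc[0] == 22.0

    def test_geometric_on_ct_scale(self):
        m = _matrix([[16.0], [25.0]])
        assert mean_ct0(m, "geometric").values.iloc[0] == pytest.approx(20.0)

    def test_missing_ignored_per_sample(self, missing_matrix):
        ct0 = mean_ct0(missing_matrix, "arithmetic")
        # s3 observes only gB (24.0) and gD (21.5)
        assert ct0.values.loc["s3"] == pytest.approx((24.0 + 21.5) / 2)

    def test_all_missing_sample_errors(self):
        data = pd.DataFrame([[np.nan, 20.0]], index=["g1"],
                            columns=["s1", "s2"])
        with pytest.raises(ValueError, match="no observed"):
            mean_ct0(CTMatrix(data), "arithmetic")


class TestGeneSd:
    def test_two_point_and_constant(self):
        m = _matrix([[10.0, 12.0], [20.0, 20.0]])
        sd = gene_sd(m)
        assert sd["g0"] == pytest.approx(np.sqrt(2))
        assert sd["g1"] == 0.0

    def test_matches_direct_formula(self, rng):
        row = rng.uniform(15, 35, size=5)
        m = _matrix(row[None, :])
        xbar = row.sum() / 5
        expected = np.sqrt(((row - xbar) ** 2).sum() / 4)
        assert gene_sd(m)["g0"] == pytest.approx(expected, abs=1e-12)

    def test_short_rows_omitted(self, missing_matrix):
        sd = gene_sd(missing_matrix)
        assert "gC" not in sd.index  # single observation: sd undefined
        assert set(sd.index) == {"gA", "gB", "gD"}


class TestTopK:
    def test_k_equals_n_genes_is_plain_mean(self, toy_matrix):
        topk = topk_ct0(toy_matrix, k=3)
        mean = mean_ct0(toy_matrix, "arithmetic")
        np.testing.assert_allclose(topk.values, mean.values)

    def test_k1_is_most_stable_gene_row(self, toy_matrix):
        sds = toy_matrix.data.std(axis=1, ddof=1)
        best = sds.idxmin()
        ct0 = topk_ct0(toy_matrix, k=1)
        np.testing.assert_allclose(ct0.values, toy_matrix.data.loc[best])
        assert ct0.params["selected_genes"] == [best]

    def test_matches_brute_force_sort_and_average(self, rng):
        # independent oracle: sort genes by sd, average the k smallest
        m = _matrix(rng.uniform(15, 35, size=(6, 5)))
        sds = m.data.std(axis=1, ddof=1)
        chosen = sds.sort_values(kind="mergesort").index[:3]
        expected = m.data.loc[chosen].mean(axis=0)
        np.testing.assert_allclose(topk_ct0(m, k=3).values, expected)

    def test_k_too_large_errors(self, toy_matrix):
        with pytest.raises(ValueError, match="exceeds"):
            topk_ct0(toy_matrix, k=10)


class TestWeightedMean:
    def test_hand_computed_two_gene_example(self, two_gene_matrix):
        # sds sqrt(2) and sqrt(0.5): weights 1/3 and 2/3 at wmp=1
        ct0 = weighted_mean_ct0(two_gene_matrix, wmp=1.0)
        assert ct0.values.loc["s1"] == pytest.approx(50.0 / 3.0, abs=1e-9)
        assert ct0.values.loc["s2"] == pytest.approx(18.0, abs=1e-9)

    def test_wmp_zero_is_arithmetic_mean(self, toy_matrix):
        np.testing.assert_array_equal(
            weighted_mean_ct0(toy_matrix, wmp=0.0).values.to_numpy(),
            mean_ct0(toy_matrix, "arithmetic").values.to_numpy())

    def test_equal_sds_give_plain_mean_for_any_wmp(self):
        # both genes have identical sd; weights must be uniform
        m = _matrix([[20.0, 21.0], [30.0, 31.0]])
        for wmp in (0.5, 1.0, 7.0, 50.0):
            np.testing.assert_array_equal(
                weighted_mean_ct0(m, wmp=wmp).values.to_numpy(),
                mean_ct0(m, "arithmetic").values.to_numpy())

    def test_large_wmp_converges_to_most_stable_gene(self, toy_matrix):
        sds = toy_matrix.data.std(axis=1, ddof=1)
        best = sds.idxmin()
        # sd ratio ~0.76 here, so the runner-up still carries ~2e-6 weight
        ct0 = weighted_mean_ct0(toy_matrix, wmp=50.0)
        np.testing.assert_allclose(ct0.values, toy_matrix.data.loc[best],
                                   atol=1e-4)

    def test_monotone_correlation_toward_stable_gene(self):
        # noise-free: shared offset scaled per gene, distinct sds
        offsets = np.array([-1.0, 0.0, 0.5, 0.5])
        sens = np.array([0.2, 0.6, 1.0, 1.5])
        mu = np.array([18.0, 22.0, 27.0, 33.0])
        m = _matrix(mu[:, None] + sens[:, None] * offsets[None, :])
        stable_row = m.data.iloc[0].to_numpy()
        corrs = []
        for wmp in (0.0, 1.0, 2.0, 4.0, 8.0, 16.0):
            ct0 = weighted_mean_ct0(m, wmp=wmp).values.to_numpy()
            corrs.append(np.corrcoef(ct0, stable_row)[0, 1])
        assert np.all(np.diff(corrs) >= -1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            WeightedMeanParams(wmp=-1.0)
        with pytest.raises(ValueError):
            WeightedMeanParams(epsilon=0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(wmp=st.floats(0.0, 30.0), seed=st.integers(0, 10_000))
    def test_ct0_is_convex_combination(self, wmp, seed):
        # for every wmp the CT0 lies within each sample's observed CT range
        rng = np.random.default_rng(seed)
        vals = rng.uniform(15, 35, size=(6, 4))
        m = _matrix(vals)
        ct0 = weighted_mean_ct0(m, wmp=wmp).values.to_numpy()
        assert np.all(ct0 >= vals.min(axis=0) - 1e-9)
        assert np.all(ct0 <= vals.max(axis=0) + 1e-9)

    def test_per_sample_renormalization_with_missing(self):
        data = pd.DataFrame([[10.0, 12.0, 11.0], [20.0, 21.0, np.nan]],
                            index=["g1", "g2"], columns=["s1", "s2", "s3"])
        ct0 = weighted_mean_ct0(CTMatrix(data), wmp=1.0)
        # s3 observes only g1: renormalized weight is 1 on g1
        assert ct0.values.loc["s3"] == pytest.approx(11.0)


class TestDeltaCT:
    def test_simple_subtraction_and_missing_preserved(self, missing_matrix):
        ct0 = mean_ct0(missing_matrix, "arithmetic")
        dct = delta_ct(missing_matrix, ct0)
        assert dct.scale == "delta_ct"
        assert np.isnan(dct.data.loc["gA", "s3"])
        assert dct.data.loc["gB", "s1"] == pytest.approx(
            25.0 - ct0.values.loc["s1"])

    def test_own_row_as_ct0_gives_zeros(self, toy_matrix):
        from ctnorm import CT0Vector
        row = toy_matrix.data.loc["gB"]
        ct0 = CT0Vector(row.copy(), method="gene:gB")
        dct = delta_ct(toy_matrix, ct0)
        np.testing.assert_allclose(dct.data.loc["gB"], 0.0)

    def test_adding_ct0_back_recovers_matrix(self, toy_matrix):
        ct0 = weighted_mean_ct0(toy_matrix, wmp=3.0)
        dct = delta_ct(toy_matrix, ct0)
        recovered = dct.data.add(ct0.values, axis=1)
        pd.testing.assert_frame_equal(recovered, toy_matrix.data)

    def test_sample_mismatch_errors(self, toy_matrix, two_gene_matrix):
        ct0 = mean_ct0(two_gene_matrix, "arithmetic")
        with pytest.raises(ValueError, match="sample ids"):
            delta_ct(toy_matrix, ct0)


class TestFoldChange:
    @pytest.mark.parametrize("ddct,fc", [(0.0, 1.0), (-1.0, 2.0), (3.0, 0.125)])
    def test_known_values(self, ddct, fc):
        exp = pd.Series([ddct], index=["g1"])
        ctrl = pd.Series([0.0], index=["g1"])
        res = delta_delta_ct_fold_change(exp, ctrl)
        assert res.delta_delta_ct[0] == ddct
        assert res.fold_change[0] == fc

    def test_log2_round_trip(self, rng):
        genes = [f"g{i}" for i in range(50)]
        exp = pd.Series(rng.normal(0, 3, 50), index=genes)
        ctrl = pd.Series(rng.normal(0, 3, 50), index=genes)
        res = delta_delta_ct_fold_change(exp, ctrl)
        np.testing.assert_allclose(-np.log2(res.fold_change),
                                   res.delta_delta_ct, rtol=1e-12)
        assert np.all(res.fold_change > 0)

    def test_unmatched_gene_errors(self):
        exp = pd.Series([1.0], index=["g1"])
        ctrl = pd.Series([1.0], index=["g2"])
        with pytest.raises(ValueError, match="unmatched"):
            delta_delta_ct_fold_change(exp, ctrl)


class TestQuantile:
    def test_three_gene_two_sample_oracle(self):
        m = _matrix(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]) + 10)
        out = quantile_normalize(m, center="mean")
        expected = np.array([[12.5, 12.5], [13.5, 13.5], [14.5, 14.5]])
        np.testing.assert_allclose(out.data.to_numpy(), expected)

    def test_single_sample_unchanged(self):
        m = _matrix([[20.0], [25.0], [30.0]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.data.to_numpy(), m.data.to_numpy())

    def test_rank_order_preserved_within_sample(self, rng):
        m = _matrix(rng.uniform(15, 35, size=(20, 6)))
        out = quantile_normalize(m)
        for s in m.sample_ids:
            orig = m.data[s].to_numpy()
            new = out.data[s].to_numpy()
            assert np.array_equal(np.argsort(orig), np.argsort(new))

    def test_missing_values_rejected(self, missing_matrix):
        with pytest.raises(ValueError, match="filter_genes"):
            quantile_normalize(missing_matrix)

    def test_tied_values_get_identical_output(self):
        m = _matrix([[20.0, 21.0], [20.0, 23.0], [26.0, 25.0]])
        out = quantile_normalize(m)
        assert out.data.loc["g0", "s0"] == out.data.loc["g1", "s0"]


class TestMedianShift:
    def test_shifts_to_median_of_medians(self):
        m = _matrix([[19.0, 21.0, 29.0],
                     [20.0, 22.0, 30.0],
                     [21.0, 23.0, 31.0]])
        out = median_normalize(m)
        meds = out.data.median(axis=0)
        np.testing.assert_allclose(meds, 22.0)
        # per-sample shifts are +2, 0, -8
        np.testing.assert_allclose(out.data["s0"] - m.data["s0"], 2.0)
        np.testing.assert_allclose(out.data["s2"] - m.data["s2"], -8.0)

    def test_identity_when_medians_agree(self):
        m = _matrix([[19.0, 18.0], [20.0, 20.0], [21.0, 22.0]])
        out = median_normalize(m)
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_within_sample_differences_preserved(self, rng):
        m = _matrix(rng.uniform(15, 35, size=(10, 4)))
        out = median_normalize(m)
        for s in m.sample_ids:
            np.testing.assert_allclose(
                np.diff(out.data[s]), np.diff(m.data[s]), rtol=1e-12)


class TestCyclicLoess:
    def test_identical_samples_unchanged(self):
        col = np.linspace(16, 34, 40)
        m = _matrix(np.column_stack([col, col]))
        out = cyclic_loess_normalize(m)
        np.testing.assert_allclose(out.data.to_numpy(), m.data.to_numpy(),
                                   rtol=1e-10)

    def test_multiplicative_offset_shrinks_mean_abs_m(self, rng):
        base = rng.uniform(16, 34, size=60)
        m = _matrix(np.column_stack([base, base * 1.2]))
        out = cyclic_loess_normalize(m, max_cycles=5, tol=1e-4)
        logs = np.log(m.data.to_numpy())
        logs_out = np.log(out.data.to_numpy())
        before = np.abs(logs[:, 0] - logs[:, 1]).mean()
        after = np.abs(logs_out[:, 0] - logs_out[:, 1]).mean()
        assert after < before

    def test_sample_order_invariance_after_convergence(self, rng):
        base = rng.uniform(16, 34, size=50)
        cols = np.column_stack([base, base * 1.1, base * 0.9])
        m = _matrix(cols)
        perm = [2, 0, 1]
        m_perm = _matrix(cols[:, perm],
                         samples=[f"s{j}" for j in perm])
        out = cyclic_loess_normalize(m, max_cycles=20, tol=1e-5)
        out_perm = cyclic_loess_normalize(m_perm, max_cycles=20, tol=1e-5)
        np.testing.assert_allclose(
            out.data[[f"s{j}" for j in perm]].to_numpy(),
            out_perm.data.to_numpy(), atol=0.02)

    def test_nonconvergence_recorded_in_provenance(self, rng):
        base = rng.uniform(16, 34, size=30)
        m = _matrix(np.column_stack([base, base * 1.5]))
        out = cyclic_loess_normalize(m, max_cycles=1, tol=1e-12)
        assert out.params["converged"] is False


class TestRankInvariant:
    def test_identical_rankings_select_all_genes(self):
        base = np.array([10.0, 15.0, 20.0, 25.0, 30.0])
        m = _matrix(np.column_stack([base, base + 0.2, base + 0.1]))
        ct0 = rank_invariant_ct0(m, rank_window=0)
        mean = mean_ct0(m, "arithmetic")
        np.testing.assert_allclose(ct0.values, mean.values)
        assert len(ct0.params["invariant_genes"]) == 5

    def test_rank_mover_excluded(self):
        # g1's rank moves from 2 to 4 in the third sample
        s1 = [10.0, 15.0, 20.0, 25.0, 30.0]
        s2 = [10.2, 15.2, 20.2, 25.2, 30.2]
        s3 = [10.1, 26.0, 20.1, 25.1, 30.1]
        m = _matrix(np.column_stack([s1, s2, s3]))
        ct0 = rank_invariant_ct0(m, rank_window=1)
        assert "g1" not in ct0.params["invariant_genes"]
        assert len(ct0.params["invariant_genes"]) == 4

    def test_huge_window_accepts_everything(self, rng):
        m = _matrix(rng.uniform(15, 35, size=(6, 3)))
        ct0 = rank_invariant_ct0(m, rank_window=10)
        assert len(ct0.params["invariant_genes"]) == 6

    def test_empty_intersection_advises_larger_window(self):
        m = _matrix([[10.0, 30.0], [20.0, 10.5], [30.0, 20.5]])
        with pytest.raises(ValueError, match="rank_window"):
            rank_invariant_ct0(m, rank_window=0)
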