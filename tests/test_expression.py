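import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copex.expression import (
    ExpressionMatrix,
    correlation_matrix,
    filter_samples_by_depth,
    log_transform,
    quantile_normalize,
    ranked_gene_list,
    upgma_dendrogram,
)


def raw(df):
    return ExpressionMatrix(values=df.astype(float), stage="raw")


def mat(arr, genes=None, samples=None, stage="raw"):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), stage=stage)


class TestDepthFilter:
    def test_removes_subthreshold_samples(self):
        e = mat([[1, 2], [3, 4]], samples=["s1", "s2"])
        out = filter_samples_by_depth(e, {"s1": 2e6, "s2": 5e5}, min_total=1e6)
        assert out.sample_ids == ["s1"]

    def test_identity_when_all_pass(self):
        e = mat([[1, 2], [3, 4]], samples=["s1", "s2"])
        out = filter_samples_by_depth(e, {"s1": 2e6, "s2": 3e6}, min_total=1e6)
        assert out.sample_ids == ["s1", "s2"]
        assert out.values.equals(e.values)

    def test_missing_total_is_an_error(self):
        e = mat([[1, 2]], samples=["s1", "s2"])
        with pytest.raises(KeyError, match="s2"):
            filter_samples_by_depth(e, {"s1": 2e6}, min_total=1e6)

    def test_removing_everything_is_an_error(self):
        e = mat([[1, 2]], samples=["s1", "s2"])
        with pytest.raises(ValueError, match="all"):
            filter_samples_by_depth(e, {"s1": 1.0, "s2": 2.0}, min_total=1e6)


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        e = mat([[1, 1], [5, 5], [3, 3]])
        out = quantile_normalize(e)
        assert np.allclose(out.values.to_numpy(), e.values.to_numpy())
        assert out.stage == "normalized"

    def test_two_distinct_columns(self):
        e = mat(np.array([[1, 4], [2, 5], [3, 6]]))
        out = quantile_normalize(e).values.to_numpy()
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        assert np.allclose(out, expected)

    def test_tie_policy_uses_mean_over_rank_span(self):
        # reference = (2, 2.5, 3.5); ties in column 1 span ranks 1-2
        e = mat(np.array([[1, 3], [1, 4], [2, 5]]))
        out = quantile_normalize(e).values.to_numpy()
        expected = np.array([[2.25, 2.0], [2.25, 2.5], [3.5, 3.5]])
        assert np.allclose(out, expected)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            quantile_normalize(mat([[1], [2]]))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_columns_become_permutations_of_each_other(self, seed):
        rng = np.random.default_rng(seed)
        e = mat(rng.gamma(2.0, 50.0, size=(12, 4)))
        out = quantile_normalize(e).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, out.shape[1]):
            # exact multiset equality of sorted columns (ties may repeat values)
            assert np.allclose(np.sort(out[:, j]), ref, atol=1e-12)


class TestLogTransform:
    def test_known_values(self):
        e = mat([[0, 4, 60]], stage="normalized")
        out = log_transform(e)
        assert np.allclose(out.values.to_numpy(), [[2, 3, 6]])
        assert out.stage == "logged"

    def test_raw_input_warns(self):
        with pytest.warns(UserWarning, match="raw"):
            log_transform(mat([[1, 2]]))

    def test_nonpositive_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            log_transform(mat([[1, 2]], stage="normalized"), pseudo_count=0)


class TestCorrelationMatrix:
    def test_diagonal_and_antiperfect(self):
        e = mat([[1, 2, 3], [6, 4, 2]], stage="logged")
        corr = correlation_matrix(e)
        arr = corr.values.to_numpy()
        assert np.allclose(np.diag(arr), 1.0)
        assert np.isclose(arr[0, 1], -1.0)

    def test_hand_computed_value(self):
        e = mat([[1, 2, 3], [1, 2, 4]], stage="logged")
        r = correlation_matrix(e).values.iloc[0, 1]
        assert np.isclose(r, 0.9819805061, atol=1e-9)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(123)
        X = rng.normal(size=(20, 10))
        corr = correlation_matrix(mat(X, stage="logged")).values.to_numpy()
        # independent two-pass Pearson computation
        mu = X.mean(axis=1, keepdims=True)
        xc = X - mu
        denom = np.sqrt((xc**2).sum(axis=1))
        oracle = (xc @ xc.T) / np.outer(denom, denom)
        assert np.abs(corr - oracle).max() < 1e-10

    def test_zero_variance_gene_reported(self):
        e = mat([[1, 1, 1], [1, 2, 3]], genes=["flat", "ok"], stage="logged")
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(e)

    def test_requires_logged_stage_and_three_samples(self):
        with pytest.raises(ValueError, match="logged"):
            correlation_matrix(mat([[1, 2, 3]], stage="raw"))
        with pytest.raises(ValueError, match="3 samples"):
            correlation_matrix(mat([[1, 2], [3, 4]], stage="logged"))


class TestRankedGeneList:
    def test_orders_by_decreasing_correlation(self, tiny_logged):
        corr = correlation_matrix(tiny_logged)
        rl = ranked_gene_list(corr, "g0")
        assert rl.target == "g0"
        assert rl.n == 4
        assert set(rl.genes) == set(corr.gene_ids) - {"g0"}
        assert all(rl.corrs[i] >= rl.corrs[i + 1] for i in range(rl.n - 1))

    def test_ties_broken_lexicographically(self):
        vals = pd.DataFrame(
            [[1.0, 0.5, 0.5], [0.5, 1.0, 0.2], [0.5, 0.2, 1.0]],
            index=["t", "b", "a"], columns=["t", "b", "a"],
        )
        from copex.expression import CorrelationMatrix

        rl = ranked_gene_list(CorrelationMatrix(vals), "t")
        assert rl.genes == ["a", "b"]

    def test_absent_target_rejected(self, tiny_logged):
        corr = correlation_matrix(tiny_logged)
        with pytest.raises(KeyError):
            ranked_gene_list(corr, "nope")


class TestUpgma:
    def test_identical_samples_merge_at_zero(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=5)
        X = np.column_stack([col, col, rng.normal(size=5)])
        tree = upgma_dendrogram(mat(X, stage="logged"))
        assert np.isclose(tree.merge_heights.min(), 0.0, atol=1e-12)

    def test_hand_computed_merge_heights(self):
        # construct samples with d(a,b)=0.1, d(a,c)=d(b,c)=0.5 via a direct
        # distance matrix is not possible through expression profiles alone,
        # so verify on scipy linkage semantics: UPGMA of that distance matrix
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        D = np.array([[0, 0.1, 0.5], [0.1, 0, 0.5], [0.5, 0.5, 0]])
        Z = linkage(squareform(D), method="average")
        assert np.allclose(Z[:, 2], [0.1, 0.5])

    def test_newick_contains_every_sample_once(self, tiny_logged):
        tree = upgma_dendrogram(tiny_logged)
        nwk = tree.to_newick()
        for s in tiny_logged.sample_ids:
            assert nwk.count(s) == 1
        assert nwk.endswith(";")

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            upgma_dendrogram(mat([[1], [2]], stage="logged"))
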