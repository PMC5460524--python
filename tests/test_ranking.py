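import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copex.expression import CorrelationMatrix
from copex.genesets import GeneSet, GeneSetCollection
from copex.ranking import (
    combined_pathway_ranking,
    inflation_diagnostic,
    internal_correlation,
    roc_auc,
)


def corr_matrix(names, arr):
    return CorrelationMatrix(pd.DataFrame(np.asarray(arr, float), index=names, columns=names))


class TestInternalCorrelation:
    def test_two_member_set_is_their_pairwise_r(self):
        c = corr_matrix(["a", "b"], [[1, 0.42], [0.42, 1]])
        assert internal_correlation(c, {"a", "b"}) == pytest.approx(0.42)

    def test_three_members_arithmetic_mean(self):
        arr = [[1, 0.6, 0.2], [0.6, 1, 0.1], [0.2, 0.1, 1]]
        c = corr_matrix(["a", "b", "c"], arr)
        assert internal_correlation(c, {"a", "b", "c"}) == pytest.approx(0.3)

    def test_perfectly_correlated_set_gives_one(self):
        c = corr_matrix(["a", "b", "c"], np.ones((3, 3)))
        assert internal_correlation(c, {"a", "b", "c"}) == pytest.approx(1.0)

    def test_fewer_than_two_members_rejected(self):
        c = corr_matrix(["a", "b"], np.eye(2))
        with pytest.raises(ValueError):
            internal_correlation(c, {"a", "zzz"})


class TestInflationDiagnostic:
    def make_inputs(self, p_by_set):
        genes = ["g1", "g2", "g3", "g4", "x1", "x2"]
        arr = np.full((6, 6), 0.1)
        arr[0, 1] = arr[1, 0] = 0.8  # P1 = {g1, g2}: high internal correlation
        arr[2, 3] = arr[3, 2] = 0.1  # P2 = {g3, g4}
        np.fill_diagonal(arr, 1.0)
        corr = corr_matrix(genes, arr)
        coll = GeneSetCollection(sets=[
            GeneSet("P1", "", frozenset({"g1", "g2"})),
            GeneSet("P2", "", frozenset({"g3", "g4"})),
        ])
        pvals = {"ora": {g: dict(p_by_set) for g in genes}}
        return pvals, coll, corr

    def test_all_p_one_gives_zero_means_and_undefined_r(self):
        pvals, coll, corr = self.make_inputs({"P1": 1.0, "P2": 1.0})
        diag = inflation_diagnostic(pvals, coll, corr)
        assert (diag.table.filter(like="mean_neglog10").to_numpy() == 0).all()
        assert diag.summary_r["ora"] is None

    def test_two_pathway_r_is_plus_or_minus_one(self):
        pvals, coll, corr = self.make_inputs({"P1": 0.01, "P2": 0.1})
        diag = inflation_diagnostic(pvals, coll, corr)
        # higher internal correlation paired with larger mean(-log10 p)
        assert diag.summary_r["ora"] == pytest.approx(1.0)

    def test_single_pathway_rejected(self):
        pvals, coll, corr = self.make_inputs({"P1": 0.5, "P2": 0.5})
        solo = GeneSetCollection(sets=[coll.sets[0]])
        with pytest.raises(ValueError):
            inflation_diagnostic(pvals, solo, corr)


class TestCombinedRanking:
    def test_primary_key_then_pscore_tiebreak(self):
        tab = combined_pathway_ranking(
            {"A": 0.01, "B": 1.0, "C": 1.0}, {"A": 0.9, "B": 0.1, "C": 0.2}
        )
        assert list(tab.index) == ["A", "B", "C"]
        assert list(tab["final_rank"]) == [1, 2, 3]

    def test_all_equal_falls_back_to_set_id(self):
        tab = combined_pathway_ranking({"B": 1.0, "A": 1.0}, {"B": 0.5, "A": 0.5})
        assert list(tab.index) == ["A", "B"]

    def test_invariant_to_input_order(self):
        a = combined_pathway_ranking({"A": 0.2, "B": 0.1}, {"A": 0.3, "B": 0.4})
        b = combined_pathway_ranking({"B": 0.1, "A": 0.2}, {"B": 0.4, "A": 0.3})
        pd.testing.assert_frame_equal(a, b)

    def test_rank_is_permutation(self):
        rng = np.random.default_rng(0)
        sids = [f"P{i}" for i in range(20)]
        tab = combined_pathway_ranking(
            {s: float(rng.uniform()) for s in sids}, {s: float(rng.uniform()) for s in sids}
        )
        assert sorted(tab["final_rank"]) == list(range(1, 21))

    def test_mismatched_pathways_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            combined_pathway_ranking({"A": 0.1}, {"B": 0.1})


def mann_whitney_auc(labels, scores, larger_is_positive=True):
    """Oracle: AUC = P(score+ > score-) + 0.5 P(score+ = score-)."""
    labels = np.asarray(labels)
    s = np.asarray(scores, float)
    if not larger_is_positive:
        s = -s
    pos, neg = s[labels == 1], s[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        roc = roc_auc([1, 1, 0, 0], [0.01, 0.02, 0.5, 0.9], "smaller-is-positive")
        assert roc.auc == 1.0

    def test_all_tied_scores_give_half(self):
        roc = roc_auc([1, 0, 1, 0], [0.3, 0.3, 0.3, 0.3])
        assert roc.auc == pytest.approx(0.5)

    def test_worked_example_larger_is_positive(self):
        roc = roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1], "larger-is-positive")
        assert roc.auc == pytest.approx(0.75)

    def test_curve_endpoints_and_monotone(self):
        rng = np.random.default_rng(1)
        roc = roc_auc(rng.integers(0, 2, 50), rng.uniform(size=50))
        assert roc.fpr[0] == 0 and roc.tpr[0] == 0
        assert roc.fpr[-1] == 1 and roc.tpr[-1] == 1
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_trapezoid_equals_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = rng.choice(np.round(rng.uniform(size=6), 2), size=n)  # force ties
        for orient, larger in (("larger-is-positive", True), ("smaller-is-positive", False)):
            got = roc_auc(labels, scores, orient).auc
            assert got == pytest.approx(mann_whitney_auc(labels, scores, larger), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.1, 0.2])
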