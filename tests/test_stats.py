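"""Fold change, Fisher's ratio and the two-stage discriminatory filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpsig import (
    extreme_separation_cohort,
    fisher_ratio,
    fold_change,
    select_discriminatory,
    snp_statistics,
)
from snpsig.stats import DiscriminatorySnpSelector


def naive_fold_change(X, case_mask):
    """Independent two-pass reference: explicit per-class mean loops."""
    out = []
    for j in range(X.shape[1]):
        c1 = [X[i, j] for i in range(len(X)) if case_mask[i]]
        c2 = [X[i, j] for i in range(len(X)) if not case_mask[i]]
        out.append(np.log2((sum(c1) / len(c1)) / (sum(c2) / len(c2))))
    return np.array(out)


def naive_fisher_ratio(X, case_mask):
    """Reference FR with explicit two-pass n-1 variances."""
    out = []
    for j in range(X.shape[1]):
        c1 = [X[i, j] for i in range(len(X)) if case_mask[i]]
        c2 = [X[i, j] for i in range(len(X)) if not case_mask[i]]
        m1, m2 = sum(c1) / len(c1), sum(c2) / len(c2)
        v1 = sum((x - m1) ** 2 for x in c1) / (len(c1) - 1)
        v2 = sum((x - m2) ** 2 for x in c2) / (len(c2) - 1)
        num = (m1 - m2) ** 2
        if v1 + v2 == 0:
            out.append(np.inf if num > 0 else 0.0)
        else:
            out.append(num / (v1 + v2))
    return np.array(out)


def _case_mask(n1, n2):
    return np.array([True] * n1 + [False] * n2)


class TestFoldChange:
    def test_perfect_separator_attains_log2_3(self):
        X = np.array([[3.0]] * 4 + [[1.0]] * 3)
        fc = fold_change(X, _case_mask(4, 3))
        np.testing.assert_allclose(fc, np.log2(3), rtol=1e-15)

    def test_equal_means_give_zero(self):
        X = np.array([[1.0], [3.0], [1.0], [3.0]])
        assert fold_change(X, _case_mask(2, 2))[0] == 0.0

    def test_doubled_mean_gives_one(self):
        X = np.array([[2.0], [2.0], [1.0], [1.0]])
        assert fold_change(X, _case_mask(2, 2))[0] == 1.0

    def test_antisymmetric_under_class_swap(self):
        rng = np.random.default_rng(0)
        X = rng.integers(1, 4, size=(12, 6)).astype(float)
        mask = _case_mask(7, 5)
        np.testing.assert_allclose(
            fold_change(X, mask), -fold_change(X, ~mask), rtol=1e-12
        )

    def test_not_invariant_under_affine_recoding(self):
        """FC depends on the absolute code scale (unlike FR)."""
        X = np.array([[3.0], [3.0], [1.0], [1.0]])
        mask = _case_mask(2, 2)
        assert fold_change(X, mask)[0] != pytest.approx(fold_change(2 * X + 1, mask)[0])


class TestFisherRatio:
    def test_hand_computed_value(self):
        # class1 codes [1,1,2], class2 [3,3,2]: FR = (4/3)^2 / (1/3 + 1/3) = 8/3
        X = np.array([[1.0], [1.0], [2.0], [3.0], [3.0], [2.0]])
        fr = fisher_ratio(X, _case_mask(3, 3))
        np.testing.assert_allclose(fr, 8.0 / 3.0, rtol=1e-14)

    def test_identical_distributions_give_zero(self):
        X = np.array([[1.0], [2.0], [1.0], [2.0]])
        assert fisher_ratio(X, _case_mask(2, 2))[0] == 0.0

    def test_zero_variance_separation_gives_sentinel(self):
        X = np.array([[3.0], [3.0], [1.0], [1.0]])
        assert np.isinf(fisher_ratio(X, _case_mask(2, 2))[0])

    def test_zero_variance_equal_means_gives_zero(self):
        X = np.array([[2.0], [2.0], [2.0], [2.0]])
        assert fisher_ratio(X, _case_mask(2, 2))[0] == 0.0

    def test_small_class_rejected(self):
        X = np.ones((3, 2))
        with pytest.raises(ValueError, match=">= 2 samples"):
            fisher_ratio(X, _case_mask(1, 2))

    def test_invariant_under_class_swap(self):
        rng = np.random.default_rng(1)
        X = rng.integers(1, 4, size=(12, 6)).astype(float)
        mask = _case_mask(7, 5)
        np.testing.assert_allclose(
            fisher_ratio(X, mask), fisher_ratio(X, ~mask), rtol=1e-12
        )

    def test_invariant_under_affine_recoding(self):
        rng = np.random.default_rng(2)
        X = rng.integers(1, 4, size=(10, 5)).astype(float)
        mask = _case_mask(6, 4)
        np.testing.assert_allclose(
            fisher_ratio(X, mask), fisher_ratio(-2.5 * X + 7, mask), rtol=1e-12
        )

    def test_monotone_in_mean_separation(self):
        """Shifting case means apart at fixed variances never lowers FR."""
        base = np.array([1.0, 2.0, 3.0, 2.0])
        prev = -1.0
        for shift in (0.0, 0.5, 1.0, 2.0):
            X = np.concatenate([base + shift, base]).reshape(-1, 1)
            fr = fisher_ratio(X, _case_mask(4, 4))[0]
            assert fr >= prev
            prev = fr


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_statistics_match_naive_reference(seed):
    """Vectorized FC/FR equal a naive two-pass oracle to 1e-12 relative."""
    rng = np.random.default_rng(seed)
    n1, n2 = rng.integers(2, 8, size=2)
    X = rng.integers(1, 4, size=(n1 + n2, 5)).astype(float)
    mask = _case_mask(n1, n2)
    np.testing.assert_allclose(
        fold_change(X, mask), naive_fold_change(X, mask), rtol=1e-12
    )
    got, ref = fisher_ratio(X, mask), naive_fisher_ratio(X, mask)
    finite = np.isfinite(ref)
    np.testing.assert_allclose(got[finite], ref[finite], rtol=1e-12)
    np.testing.assert_array_equal(got[~finite], ref[~finite])


class TestSelectDiscriminatory:
    def test_planted_separators_occupy_top_ranks(self):
        m, y, truth = extreme_separation_cohort(60, 20, 1010, 10, seed=13)
        ranked = select_discriminatory(snp_statistics(m, y), tail_fraction=0.02,
                                       fr_min=1.5)
        assert set(ranked["snp_id"][:10]) == truth.causal_snp_ids
        np.testing.assert_array_equal(ranked["rank"][:10], np.arange(1, 11))

    def test_infinite_threshold_empties_result(self):
        rng = np.random.default_rng(3)
        X = rng.integers(1, 4, size=(20, 30)).astype(float)
        stats = snp_statistics(X, _case_mask(12, 8))
        assert select_discriminatory(stats, fr_min=np.inf).empty

    def test_vacuous_filter_keeps_everything(self):
        rng = np.random.default_rng(4)
        X = rng.integers(1, 4, size=(20, 30)).astype(float)
        stats = snp_statistics(X, _case_mask(12, 8))
        ranked = select_discriminatory(stats, tail_fraction=1.0, fr_min=0.0)
        assert len(ranked) == 30
        assert sorted(ranked["rank"]) == list(range(1, 31))

    def test_ranks_are_a_permutation_and_fr_sorted(self):
        rng = np.random.default_rng(5)
        X = rng.integers(1, 4, size=(30, 100)).astype(float)
        stats = snp_statistics(X, _case_mask(18, 12))
        ranked = select_discriminatory(stats, tail_fraction=0.3, fr_min=0.0)
        fr = ranked["fisher_ratio"].to_numpy()
        assert (np.diff(fr) <= 1e-15).all()
        assert sorted(ranked["rank"]) == list(range(1, len(ranked) + 1))

    def test_no_survivors_warns_not_raises(self, caplog):
        X = np.ones((10, 5)) * np.array([1, 2, 3, 1, 2])
        stats = snp_statistics(X, _case_mask(5, 5))
        with caplog.at_level("WARNING"):
            out = select_discriminatory(stats, fr_min=100.0)
        assert out.empty and "no SNP survives" in caplog.text


def test_sklearn_selector_transform_keeps_ranked_columns():
    m, y, truth = extreme_separation_cohort(30, 10, 200, 3, seed=17)
    X = m.codes.astype(float)
    sel = DiscriminatorySnpSelector(tail_fraction=0.05, fr_min=1.5).fit(X, y.labels)
    # the three perfect columns are 0..2 by construction
    assert set(sel.ranking_[:3]) == {0, 1, 2}
    Xt = sel.transform(X)
    assert Xt.shape[1] == sel.get_support().sum()
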