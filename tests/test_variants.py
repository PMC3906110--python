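"""Variant frequency tables, screening, composite score and ROC."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from sklearn.metrics import roc_auc_score

from cystmir.simulate import simulate_variant_table
from cystmir.variants import (
    CompositeVariantScorer,
    call_variants,
    composite_score,
    roc_auc,
    screen_variants,
)


def _brute_force_auc(scores, labels):
    """Exhaustive pair enumeration: the independent AUC oracle."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    lv = np.unique(labels)
    cases = scores[labels == lv[1]]
    ctrls = scores[labels == lv[0]]
    total = 0.0
    for a in cases:
        for b in ctrls:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(cases) * len(ctrls))


class TestCallVariants:
    def _records(self):
        return pd.DataFrame(
            {
                "mirna": ["miR-A", "miR-A"],
                "variant": ["p5A>G", "p5A>G"],
                "sample": ["S1", "S3"],
                "count": [5, 2],
            }
        )

    def _totals(self):
        return pd.DataFrame(
            {"S1": [50], "S2": [50], "S3": [10]}, index=["miR-A"]
        )

    def test_frequency_is_variant_over_total(self):
        table = call_variants(self._records(), self._totals(), min_mirna_reads=20)
        assert table.loc[("miR-A", "p5A>G"), "S1"] == pytest.approx(0.10)

    def test_zero_variant_reads_is_zero_not_missing(self):
        table = call_variants(self._records(), self._totals(), min_mirna_reads=20)
        assert table.loc[("miR-A", "p5A>G"), "S2"] == 0.0

    def test_low_depth_cell_is_missing_not_zero(self):
        table = call_variants(self._records(), self._totals(), min_mirna_reads=20)
        assert np.isnan(table.loc[("miR-A", "p5A>G"), "S3"])

    def test_empty_records(self):
        table = call_variants(
            pd.DataFrame(columns=["mirna", "variant", "sample", "count"]),
            self._totals(),
        )
        assert len(table) == 0


class TestScreen:
    def test_identical_distributions_not_selected(self):
        table = pd.DataFrame(
            [[0.2] * 10],
            index=pd.MultiIndex.from_tuples([("m", "v")]),
            columns=[f"s{i}" for i in range(10)],
        )
        labels = pd.Series([0] * 5 + [1] * 5, index=table.columns)
        assert len(screen_variants(table, labels, alpha=0.1)) == 0

    def test_complete_separation_exact_p(self):
        # 5 vs 5 complete separation: exact two-sided p = 2/252 ~ 0.0079
        table = pd.DataFrame(
            [[0.1, 0.11, 0.12, 0.13, 0.14, 0.3, 0.31, 0.32, 0.33, 0.34]],
            index=pd.MultiIndex.from_tuples([("m", "v")]),
            columns=[f"s{i}" for i in range(10)],
        )
        labels = pd.Series([0] * 5 + [1] * 5, index=table.columns)
        sel = screen_variants(table, labels, alpha=0.1)
        assert len(sel) == 1
        assert sel["p_value"].iloc[0] == pytest.approx(2 / 252, rel=1e-6)
        assert sel["direction"].iloc[0] == 1

    def test_sparse_variant_skipped_with_warning(self):
        table = pd.DataFrame(
            [[0.1, np.nan, np.nan, np.nan, np.nan, 0.3, 0.31, 0.32, 0.33, 0.34]],
            index=pd.MultiIndex.from_tuples([("m", "v")]),
            columns=[f"s{i}" for i in range(10)],
        )
        labels = pd.Series([0] * 5 + [1] * 5, index=table.columns)
        with pytest.warns(UserWarning, match="skipped"):
            sel = screen_variants(table, labels, alpha=0.1)
        assert len(sel) == 0

    def test_planted_shifts_selected_unshifted_not(self):
        table, labels, shifted = simulate_variant_table(
            21, n_case=10, n_control=10, n_variants=30, n_shifted=3,
            effect_sd_multiple=3.0, obs_prob_shifted=(1.0, 1.0),
            obs_prob_null=(1.0, 1.0),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = screen_variants(table, labels, alpha=0.1)
        assert set(shifted) <= set(sel.index)
        false_rate = len(set(sel.index) - set(shifted)) / (30 - 3)
        assert false_rate < 0.3


class TestCompositeScore:
    def _table(self, values):
        return pd.DataFrame(
            values,
            index=pd.MultiIndex.from_tuples(
                [(f"m{i}", f"v{i}") for i in range(len(values))]
            ),
            columns=[f"s{j}" for j in range(len(values[0]))],
        )

    def test_all_above_median_gives_plus_v(self):
        # one sample above each of 9 variant medians -> +9
        vals = [[0.9, 0.1, 0.2, 0.3] for _ in range(9)]
        scores = composite_score(self._table(vals))
        assert scores["s0"] == 9

    def test_all_at_median_gives_zero(self):
        vals = [[0.2, 0.2, 0.2, 0.2] for _ in range(5)]
        scores = composite_score(self._table(vals))
        assert (scores == 0).all()

    def test_antisymmetry_under_comparison_flip(self):
        rng = np.random.default_rng(10)
        vals = rng.uniform(size=(6, 9))
        table = self._table(list(vals))
        # flipping above<->below is equivalent to negating frequencies
        s = composite_score(table)
        s_flip = composite_score(-table)
        assert (s + s_flip == 0).all()

    def test_random_frequencies_mean_near_zero(self):
        rng = np.random.default_rng(11)
        table = self._table(list(rng.uniform(size=(10, 200))))
        scores = composite_score(table)
        assert abs(scores.mean()) < 0.5

    def test_sample_missing_all_variants_excluded(self):
        vals = [[0.1, 0.2, np.nan], [0.3, 0.1, np.nan]]
        with pytest.warns(UserWarning, match="excluded"):
            scores = composite_score(self._table(vals))
        assert "s2" not in scores.index

    def test_empty_selection_rejected(self):
        empty = pd.DataFrame(
            index=pd.MultiIndex.from_tuples([], names=["mirna", "variant"]),
            columns=["s0", "s1"],
        )
        with pytest.raises(ValueError):
            composite_score(empty)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0

    def test_all_tied_is_half(self):
        auc, p = roc_auc([5, 5, 5, 5], [0, 0, 1, 1])
        assert auc == 0.5 and p == 1.0

    def test_matches_brute_force_enumeration(self):
        scores = np.array([3, 2, 2, 1, 2, 1, 0, 0])
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        auc, _ = roc_auc(scores, labels)
        assert auc == _brute_force_auc(scores, labels)

    def test_matches_trapezoidal_roc_integration(self):
        rng = np.random.default_rng(12)
        scores = rng.integers(-9, 10, size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]  # both classes present
        auc, _ = roc_auc(scores, labels)
        assert abs(auc - roc_auc_score(labels, scores)) < 1e-12

    def test_complement_under_score_negation(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=25)
        labels = np.array([0] * 12 + [1] * 13)
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(-scores, labels)
        assert a1 + a2 == pytest.approx(1.0)

    def test_p_matches_scipy_mannwhitney_asymptotic(self):
        rng = np.random.default_rng(14)
        scores = rng.integers(0, 6, size=20)
        labels = np.array([0] * 10 + [1] * 10)
        _, p = roc_auc(scores, labels)
        ref = stats.mannwhitneyu(
            scores[labels == 1], scores[labels == 0],
            alternative="two-sided", method="asymptotic",
        ).pvalue
        assert p == pytest.approx(ref, rel=1e-9)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.integers(-9, 9), min_size=2, max_size=12),
        st.lists(st.integers(-9, 9), min_size=2, max_size=12),
    )
    def test_pair_counting_equals_oracle_property(self, cases, ctrls):
        scores = np.array(ctrls + cases, dtype=float)
        labels = np.array([0] * len(ctrls) + [1] * len(cases))
        auc, _ = roc_auc(scores, labels)
        assert auc == _brute_force_auc(scores, labels)


class TestCompositeVariantScorer:
    def test_fit_exposes_sklearn_surface(self):
        table, labels, _ = simulate_variant_table(30)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc = CompositeVariantScorer().fit(table, labels)
        assert hasattr(sc, "selected_") and hasattr(sc, "auc_")
        clone = CompositeVariantScorer(**sc.get_params())
        assert clone.get_params() == sc.get_params()

    def test_transform_on_held_out_samples(self):
        table, labels, _ = simulate_variant_table(31, n_case=12, n_control=10)
        train = table.columns[:-4]
        test = table.columns[-4:]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc = CompositeVariantScorer().fit(table[train], labels[train])
            held_out = sc.transform(table[test])
        assert set(held_out.index) <= set(test)

    def test_label_permutation_auc_near_half(self):
        # with labels shuffled the screen-and-score pipeline has no signal:
        # mean AUC over 200 permutations ~ 0.5
        table, labels, _ = simulate_variant_table(32)
        rng = np.random.default_rng(0)
        aucs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(200):
                perm = pd.Series(
                    rng.permutation(labels.values), index=labels.index
                )
                try:
                    sc = CompositeVariantScorer().fit(table, perm)
                except ValueError:
                    continue  # no variant passed the screen: no signal either
                aucs.append(sc.auc_)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_direction_aware_mode_flips_downward_variants(self):
        rng = np.random.default_rng(15)
        base = rng.uniform(0.1, 0.3, size=(2, 12))
        base[0, 6:] += 0.5   # up in cases
        base[1, 6:] -= 0.09  # down in cases
        table = pd.DataFrame(
            base,
            index=pd.MultiIndex.from_tuples([("m0", "v0"), ("m1", "v1")]),
            columns=[f"s{i}" for i in range(12)],
        )
        labels = pd.Series([0] * 6 + [1] * 6, index=table.columns)
        literal = CompositeVariantScorer(alpha=0.2).fit(table, labels)
        aware = CompositeVariantScorer(alpha=0.2, direction_aware=True).fit(
            table, labels
        )
        assert aware.auc_ >= literal.auc_
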