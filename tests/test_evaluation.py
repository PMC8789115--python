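"""Ranking metrics, normalisation, described sets, and enrichment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gec import (
    EvaluationRecord,
    auc_pr,
    auc_roc,
    described_set,
    enrich,
    jaccard,
    max_f1_positives,
    normalize_auc_pr,
)
from oracles import (
    benjamini_hochberg,
    brute_force_average_precision,
    brute_force_max_f1_positives,
    brute_force_roc_auc,
    hypergeom_tail_by_enumeration,
)

score_sets = st.lists(
    st.tuples(st.integers(0, 8), st.integers(0, 1)),
    min_size=2, max_size=50,
).filter(lambda xs: 0 < sum(y for _, y in xs) < len(xs))


class TestAucRoc:
    def test_perfect_and_inverted_rankings(self):
        assert auc_roc([3, 2, 1], [1, 1, 0]) == 1.0
        assert auc_roc([1, 2, 3], [1, 1, 0]) == 0.0

    def test_ties_give_half_credit(self):
        assert auc_roc([5.0, 5.0], [1, 0]) == 0.5

    def test_single_class_is_na(self):
        assert math.isnan(auc_roc([1, 2], [1, 1]))
        assert math.isnan(auc_roc([1, 2], [0, 0]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(score_sets)
    def test_equals_pairwise_rank_statistic(self, items):
        scores = [s for s, _ in items]
        labels = [y for _, y in items]
        assert auc_roc(scores, labels) == pytest.approx(
            brute_force_roc_auc(scores, labels)
        )

    def test_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        for _ in range(20):
            y = rng.integers(0, 2, 30)
            if y.sum() in (0, 30):
                continue
            s = rng.integers(0, 6, 30).astype(float)
            assert auc_roc(s, y) == pytest.approx(roc_auc_score(y, s))


class TestAucPr:
    def test_hand_computed_example(self):
        assert auc_pr([3, 2, 1], [1, 0, 1]) == pytest.approx(5 / 6)

    def test_perfect_ranking(self):
        assert auc_pr([9, 8, 1], [1, 1, 0]) == 1.0

    def test_all_positive(self):
        assert auc_pr([3, 1, 2], [1, 1, 1]) == 1.0

    def test_no_positive_is_na(self):
        assert math.isnan(auc_pr([1, 2], [0, 0]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(score_sets)
    def test_equals_brute_force_threshold_sweep(self, items):
        scores = [s for s, _ in items]
        labels = [y for _, y in items]
        assert auc_pr(scores, labels) == pytest.approx(
            brute_force_average_precision(scores, labels)
        )

    def test_sklearn_cross_check(self):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(2)
        for _ in range(20):
            y = rng.integers(0, 2, 25)
            if y.sum() == 0:
                continue
            s = rng.normal(size=25)
            assert auc_pr(s, y) == pytest.approx(
                average_precision_score(y, s)
            )


class TestNormalizeAucPr:
    def test_hand_computed_example(self):
        out = normalize_auc_pr([1, 2, 3, 4, 5])
        assert out[-1] == pytest.approx(5 / 3)  # (5-3)/1.2
        assert np.median(out) == 0.0

    def test_na_propagates_and_is_excluded(self):
        out = normalize_auc_pr([1, float("nan"), 2, 3, 4, 5])
        assert math.isnan(out[1])
        clean = [v for v in out if not math.isnan(v)]
        assert clean[-1] == pytest.approx(5 / 3)

    def test_outlier_gets_the_maximal_score(self):
        out = normalize_auc_pr([0.5, 0.5, 0.5, 0.5, 0.9])
        assert np.argmax(out) == 4

    def test_shift_invariance_and_inverse_scaling(self):
        base = [0.1, 0.4, 0.2, 0.9, 0.5]
        shifted = normalize_auc_pr([v + 10 for v in base])
        np.testing.assert_allclose(shifted, normalize_auc_pr(base))
        scaled = normalize_auc_pr([3 * v for v in base])
        np.testing.assert_allclose(scaled, normalize_auc_pr(base))

    def test_degenerate_distribution_is_an_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_auc_pr([0.7, 0.7, 0.7])

    def test_too_few_values_is_an_error(self):
        with pytest.raises(ValueError, match="at least two"):
            normalize_auc_pr([0.7, float("nan")])


def make_records(norms):
    return [
        EvaluationRecord(
            pathway=f"p{i}", graphlet=0, mode="local",
            auc_roc=0.5, auc_pr=0.5, n_pos=1, n_total=2, norm_auc_pr=v,
        )
        for i, v in enumerate(norms)
    ]


class TestDescribedSet:
    def test_outlier_pathway_is_selected(self):
        recs = make_records([0.1, -0.5, 4.2, 1.0])
        assert described_set(recs) == {"p2"}

    def test_threshold_monotonicity(self):
        recs = make_records([0.1, 2.5, 4.2, 3.5])
        assert described_set(recs, threshold=2) >= described_set(recs)

    def test_na_records_never_qualify(self):
        recs = make_records([float("nan"), 5.0])
        assert described_set(recs) == {"p1"}


class TestJaccard:
    def test_examples(self):
        assert jaccard({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)
        assert jaccard({"a"}, {"a"}) == 1.0
        assert jaccard({"a"}, {"b"}) == 0.0
        assert math.isnan(jaccard(set(), set()))


class TestMaxF1Positives:
    def test_clean_split(self):
        scores = {"a": 5.0, "b": 4.0, "c": 1.0}
        labels = {"a": 1, "b": 1, "c": 0}
        assert max_f1_positives(scores, labels) == {"a", "b"}

    def test_all_positive_returns_all(self):
        scores = {"a": 3.0, "b": 1.0}
        labels = {"a": 1, "b": 1}
        assert max_f1_positives(scores, labels) == {"a", "b"}

    def test_no_positive_returns_empty(self):
        assert max_f1_positives({"a": 1.0}, {"a": 0}) == frozenset()

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(score_sets)
    def test_equals_brute_force_sweep(self, items):
        scores = {f"g{i}": float(s) for i, (s, _) in enumerate(items)}
        labels = {f"g{i}": y for i, (_, y) in enumerate(items)}
        assert max_f1_positives(scores, labels) == \
            brute_force_max_f1_positives(scores, labels)


class TestEnrich:
    def test_perfectly_concentrated_term_is_most_enriched(self):
        universe = {f"p{i}" for i in range(12)}
        selected = {"p0", "p1", "p2"}
        annotation = {
            "p0": {"hit"}, "p1": {"hit"}, "p2": {"hit"},
            "p3": {"flat"}, "p4": {"flat"}, "p5": {"flat"},
            "p6": {"flat"}, "p7": {"other"},
        }
        df = enrich(selected, annotation, universe)
        assert df.iloc[0]["term"] == "hit"
        assert bool(df.iloc[0]["enriched"])

    def test_uniform_term_is_not_enriched(self):
        universe = {f"p{i}" for i in range(10)}
        annotation = {p: {"everywhere"} for p in universe}
        df = enrich({"p0", "p1"}, annotation, universe)
        assert df.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_p_values_match_exact_enumeration(self):
        universe = {f"p{i}" for i in range(9)}
        selected = {"p0", "p1", "p2", "p3"}
        annotation = {
            "p0": {"t1"}, "p1": {"t1", "t2"}, "p4": {"t1"},
            "p5": {"t2"}, "p6": {"t2"}, "p8": {"t1"},
        }
        df = enrich(selected, annotation, universe).set_index("term")
        for term in ("t1", "t2"):
            members = {p for p, ts in annotation.items() if term in ts}
            expected = hypergeom_tail_by_enumeration(
                len(members & selected), len(universe), len(members),
                len(selected),
            )
            assert df.loc[term, "p_value"] == pytest.approx(expected)

    def test_bh_adjustment_matches_definition(self):
        universe = {f"p{i}" for i in range(20)}
        selected = {f"p{i}" for i in range(5)}
        rng = np.random.default_rng(3)
        annotation = {
            p: {f"t{j}" for j in rng.choice(6, size=2, replace=False)}
            for p in universe
        }
        df = enrich(selected, annotation, universe)
        expected = benjamini_hochberg(df["p_value"].tolist())
        np.testing.assert_allclose(df["p_adjusted"], expected)

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValueError, match="empty universe"):
            enrich(set(), {}, set())

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            enrich({"x"}, {}, {"y"})
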