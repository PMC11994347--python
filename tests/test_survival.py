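"""Survival metrics against independent oracles: brute-force pair counting
for the c-index, hand product-limit computation and lifelines for KM, hand
O−E tabulation and a permutation null for the log-rank test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fastil.survival import (
    SurvivalRecord,
    concordance_index,
    km_estimator,
    logrank_test,
    quartile_groups,
)


def rec(t, e, s, pid=""):
    return SurvivalRecord(pid or f"p{t}-{e}-{s}", float(t), int(e), float(s))


def brute_force_cindex(times, events, risks):
    """Independent all-pairs enumeration (Harrell's conventions)."""
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # i must be the observed-event subject with the shorter time
            if events[i] != 1:
                continue
            if times[i] > times[j]:
                continue
            if times[i] == times[j] and not (events[i] == 1 and events[j] == 0):
                continue
            den += 1
            if risks[i] > risks[j]:
                num += 1
            elif risks[i] == risks[j]:
                num += 0.5
    return num / den


class TestConcordance:
    def test_perfect_ranking(self):
        records = [rec(2, 1, 3.0, "a"), rec(4, 1, 2.0, "b"), rec(6, 1, 1.0, "c")]
        assert concordance_index(records) == 1.0

    def test_four_subject_hand_case(self):
        """(t,e,risk): (2,1,3.0),(3,0,1.0),(5,1,0.5),(8,1,2.0) has 4
        comparable pairs, 3 concordant -> 0.75."""
        records = [
            rec(2, 1, 3.0, "a"),
            rec(3, 0, 1.0, "b"),
            rec(5, 1, 0.5, "c"),
            rec(8, 1, 2.0, "d"),
        ]
        assert concordance_index(records) == pytest.approx(0.75)

    def test_antisymmetry_without_ties(self):
        rng = np.random.default_rng(1)
        records = [
            rec(t, e, s, f"p{i}")
            for i, (t, e, s) in enumerate(
                zip(rng.uniform(1, 10, 30), rng.integers(0, 2, 30), rng.permutation(30))
            )
        ]
        c_plus = concordance_index(records)
        c_minus = concordance_index(
            [r.with_score(-r.score) for r in records]
        )
        assert c_plus + c_minus == pytest.approx(1.0)

    def test_direction_flag_negates(self):
        records = [rec(2, 1, 1.0, "a"), rec(4, 1, 2.0, "b"), rec(6, 1, 3.0, "c")]
        assert concordance_index(records) == 0.0
        assert concordance_index(records, direction="higher_score_lower_risk") == 1.0

    @settings(derandomize=True, max_examples=100)
    @given(st.data())
    def test_matches_brute_force_on_random_cohorts(self, data):
        n = data.draw(st.integers(3, 50))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        times = rng.integers(1, 12, n).astype(float)  # many ties
        events = rng.integers(0, 2, n)
        risks = np.round(rng.uniform(0, 5, n), 1)  # some score ties
        if not events.any():
            events[0] = 1
        records = [rec(t, e, s, f"p{i}") for i, (t, e, s) in enumerate(zip(times, events, risks))]
        try:
            expected = brute_force_cindex(times, events, risks)
        except ZeroDivisionError:
            with pytest.raises(ValueError, match="comparable"):
                concordance_index(records)
            return
        assert concordance_index(records) == pytest.approx(expected, abs=1e-12)

    def test_matches_scikit_survival(self):
        """Cross-check against an independent library implementation."""
        from sksurv.metrics import concordance_index_censored

        rng = np.random.default_rng(3)
        times = rng.uniform(1, 20, 100)
        events = rng.integers(0, 2, 100).astype(bool)
        risks = rng.normal(size=100)
        events[0] = True
        records = [rec(t, e, s, f"p{i}") for i, (t, e, s) in enumerate(zip(times, events, risks))]
        ours = concordance_index(records)
        theirs = concordance_index_censored(events, times, risks)[0]
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_no_comparable_pairs_rejected(self):
        records = [rec(5, 0, 1.0, "a"), rec(7, 0, 2.0, "b")]
        with pytest.raises(ValueError, match="comparable"):
            concordance_index(records)


class TestQuartiles:
    def test_scores_one_to_eight(self):
        labels, cutoffs = quartile_groups(list(range(1, 9)))
        assert labels == ["Q1", "Q1", "Q2", "Q2", "Q3", "Q3", "Q4", "Q4"]
        assert cutoffs == pytest.approx((2.75, 4.5, 6.25))

    def test_supplied_cutoffs_applied_as_is(self):
        labels, _ = quartile_groups([1.0, 2.0, 3.0], cutoffs=(10, 20, 30))
        assert labels == ["Q1", "Q1", "Q1"]

    def test_monotone_transform_preserves_group_sizes(self):
        rng = np.random.default_rng(8)
        scores = rng.uniform(0, 100, 40)
        l1, _ = quartile_groups(scores)
        l2, _ = quartile_groups(np.exp(scores / 25.0))
        from collections import Counter

        assert Counter(l1) == Counter(l2)

    def test_right_closed_boundaries(self):
        labels, _ = quartile_groups([5.0, 10.0, 25.0], cutoffs=(5.0, 10.0, 20.0))
        assert labels == ["Q1", "Q2", "Q4"]

    def test_too_few_distinct_scores_rejected(self):
        with pytest.raises(ValueError):
            quartile_groups([1.0, 1.0, 1.0, 2.0])


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        records = [rec(t, 1, 0.0, f"p{t}") for t in (1, 2, 3, 4)]
        rows = km_estimator(records)
        assert [r[3] for r in rows] == pytest.approx([0.75, 0.5, 0.25, 0.0])

    def test_all_censored_survival_stays_one(self):
        records = [rec(t, 0, 0.0, f"p{t}") for t in (1, 2, 3)]
        assert all(r[3] == 1.0 for r in km_estimator(records))

    def test_hand_product_limit_with_censoring(self):
        """(1,event),(2,censored),(3,event): S(1)=2/3, then the final event
        with one subject at risk drops S to 0."""
        records = [rec(1, 1, 0, "a"), rec(2, 0, 0, "b"), rec(3, 1, 0, "c")]
        rows = km_estimator(records)
        assert rows[0] == (1.0, 3, 1, pytest.approx(2 / 3))
        assert rows[1] == (2.0, 2, 0, pytest.approx(2 / 3))
        assert rows[2] == (3.0, 1, 1, pytest.approx(0.0))

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(11)
        times = rng.integers(1, 15, 60).astype(float)
        events = rng.integers(0, 2, 60)
        records = [rec(t, e, 0, f"p{i}") for i, (t, e) in enumerate(zip(times, events))]
        rows = km_estimator(records)
        kmf = KaplanMeierFitter().fit(times, events)
        for t, _, _, s in rows:
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-12
            )

    def test_survival_non_increasing(self):
        rng = np.random.default_rng(12)
        records = [
            rec(t, e, 0, f"p{i}")
            for i, (t, e) in enumerate(
                zip(rng.uniform(0.1, 9, 40), rng.integers(0, 2, 40))
            )
        ]
        s = [r[3] for r in km_estimator(records)]
        assert all(a >= b for a, b in zip(s, s[1:]))


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        base = [(1, 1), (2, 0), (3, 1), (5, 1)]
        records = [rec(t, e, 0, f"a{i}") for i, (t, e) in enumerate(base)]
        records += [rec(t, e, 0, f"b{i}") for i, (t, e) in enumerate(base)]
        labels = ["A"] * 4 + ["B"] * 4
        chi2, df, p = logrank_test(records, labels)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_separated_groups_match_hand_tabulation(self):
        """Group A events at 1..10, group B at 11..20, no censoring: the
        statistic must match an explicit O−E/V tabulation over the pooled
        event times."""
        times = list(range(1, 11)) + list(range(11, 21))
        labels = ["A"] * 10 + ["B"] * 10
        records = [rec(t, 1, 0, f"p{t}") for t in times]

        # independent hand tabulation (2 groups, distinct event times)
        n_a, n_b = 10, 10
        o_minus_e = 0.0
        var = 0.0
        for t in sorted(times):
            n = n_a + n_b
            d = 1
            e_a = d * n_a / n
            if n > 1:
                var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
            if t <= 10:
                o_minus_e += 1 - e_a
                n_a -= 1
            else:
                o_minus_e += 0 - e_a
                n_b -= 1
        expected_chi2 = o_minus_e**2 / var

        chi2, df, p = logrank_test(records, labels)
        assert df == 1
        assert chi2 == pytest.approx(expected_chi2, rel=1e-9)

    def test_three_groups_df(self):
        rng = np.random.default_rng(13)
        records = [
            rec(t, e, 0, f"p{i}")
            for i, (t, e) in enumerate(
                zip(rng.uniform(1, 10, 30), rng.integers(0, 2, 30))
            )
        ]
        labels = ["A", "B", "C"] * 10
        _, df, _ = logrank_test(records, labels)
        assert df == 2

    def test_permutation_calibration(self):
        """Under random label permutations the observed statistic sits at an
        unexceptional quantile of its permutation null."""
        rng = np.random.default_rng(14)
        records = [
            rec(t, e, 0, f"p{i}")
            for i, (t, e) in enumerate(
                zip(rng.uniform(1, 10, 40), rng.integers(0, 2, 40))
            )
        ]
        labels = np.array(["A"] * 20 + ["B"] * 20)
        observed, _, _ = logrank_test(records, labels)
        null = [
            logrank_test(records, rng.permutation(labels))[0] for _ in range(200)
        ]
        quantile = np.mean([x <= observed for x in null])
        assert 0.005 < quantile <= 1.0  # observed is not an extreme outlier

    def test_single_group_rejected(self):
        records = [rec(1, 1, 0, "a"), rec(2, 1, 0, "b")]
        with pytest.raises(ValueError):
            logrank_test(records, ["A", "A"])
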