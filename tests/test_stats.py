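"""Exact tests, sample size, Mann-Whitney, and two-arm summaries."""

import itertools
import random

import pytest
from scipy.stats import hypergeom

from meshlingua import (
    ContingencyTable,
    ErrorKind,
    ErrorReport,
    SampleSizeSpec,
    fisher_exact,
    mann_whitney,
    sample_size_two_proportions,
    summarize,
    summarize_counts,
)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher by explicit enumeration of margin-preserving tables."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, col1, row1)
    p_obs = rv.pmf(a)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p_k = rv.pmf(k)
        if p_k <= p_obs * (1 + 1e-7):
            total += p_k
    return min(total, 1.0)


class TestFisher:
    def test_operator_row_rounds_to_one(self):
        # one incorrect-operator flag in each arm of ~250 queries
        assert round(fisher_exact(ContingencyTable(1, 234, 1, 256)), 1) == 1.0

    def test_row_swap_symmetry(self):
        assert fisher_exact(ContingencyTable(5, 10, 3, 20)) == pytest.approx(
            fisher_exact(ContingencyTable(3, 20, 5, 10))
        )

    def test_zero_margin_gives_one(self):
        assert fisher_exact(ContingencyTable(0, 7, 0, 11)) == pytest.approx(1.0)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(ContingencyTable(0, 0, 0, 0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)

    def test_against_enumeration_oracle(self):
        """200 random small tables versus the hypergeometric enumeration."""
        rng = random.Random(11)
        for _ in range(200):
            a, b, c, d = (rng.randint(0, 40) for _ in range(4))
            if (a + b == 0 and c + d == 0):
                continue
            got = fisher_exact(ContingencyTable(a, b, c, d))
            want = fisher_oracle(a, b, c, d)
            assert got == pytest.approx(want, rel=1e-6, abs=1e-12), (a, b, c, d)


class TestSampleSize:
    def test_study_design_value(self):
        n_obs, subjects = sample_size_two_proportions(
            SampleSizeSpec(0.25, 0.40, 0.05, 0.10, queries_per_subject=12)
        )
        assert (n_obs, subjects) == (200, 17)

    def test_monotone_in_effect_size(self):
        base = sample_size_two_proportions(SampleSizeSpec(0.25, 0.40))[0]
        wider = sample_size_two_proportions(SampleSizeSpec(0.25, 0.50))[0]
        assert wider < base

    def test_monotone_in_beta(self):
        strict = sample_size_two_proportions(SampleSizeSpec(0.25, 0.40, beta=0.05))[0]
        loose = sample_size_two_proportions(SampleSizeSpec(0.25, 0.40, beta=0.20))[0]
        assert strict > loose

    def test_subjects_cover_observations(self):
        spec = SampleSizeSpec(0.3, 0.45, queries_per_subject=7)
        n_obs, subjects = sample_size_two_proportions(spec)
        assert subjects * spec.queries_per_subject >= n_obs

    def test_equal_proportions_rejected(self):
        with pytest.raises(ValueError):
            SampleSizeSpec(0.3, 0.3)


def mw_oracle(xs, ys):
    """Exact permutation two-sided p for the Mann-Whitney U statistic."""
    pooled = list(xs) + list(ys)
    n1 = len(xs)

    def u_of(idx):
        group1 = [pooled[i] for i in idx]
        group2 = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        u = 0.0
        for x in group1:
            for y in group2:
                u += (x > y) + 0.5 * (x == y)
        return u

    u_obs = u_of(tuple(range(n1)))
    mean = n1 * (len(pooled) - n1) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(idx) - mean) >= abs(u_obs - mean) - 1e-12:
            count += 1
    return u_obs, count / total


class TestMannWhitney:
    def test_identical_samples(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_extreme_separation(self):
        u, _ = mann_whitney([1, 2, 3], [10, 11, 12])
        assert u == 0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_three_vs_three_enumeration(self):
        xs, ys = [1.2, 3.4, 5.6], [2.1, 4.3, 6.5]
        u, p = mann_whitney(xs, ys)
        u_want, p_want = mw_oracle(xs, ys)
        assert u == pytest.approx(u_want)
        assert p == pytest.approx(p_want)

    def test_matches_enumeration_up_to_six(self):
        rng = random.Random(3)
        for _ in range(25):
            n1, n2 = rng.randint(2, 6), rng.randint(2, 6)
            xs = [round(rng.uniform(0, 50), 3) for _ in range(n1)]
            ys = [round(rng.uniform(0, 50), 3) for _ in range(n2)]
            u, p = mann_whitney(xs, ys)
            u_want, p_want = mw_oracle(xs, ys)
            assert u == pytest.approx(u_want)
            assert p == pytest.approx(p_want), (xs, ys)


def report_with(**kind_counts):
    rep = ErrorReport()
    for name, v in kind_counts.items():
        rep.counts[ErrorKind(name)] = v
    return rep


class TestSummarize:
    def test_single_perfect_per_arm(self):
        s = summarize([("a", "low", ErrorReport()), ("b", "low", ErrorReport())],
                      arms=("a", "b"))
        assert s.arm_summaries["a"].perfect_pct == 100.0
        assert s.arm_summaries["b"].perfect_pct == 100.0
        assert all(v == 0 for v in s.arm_summaries["a"].error_counts.values())

    def test_unknown_arm_rejected(self):
        with pytest.raises(ValueError):
            summarize([("c", "low", ErrorReport())], arms=("a", "b"))

    def test_flag_vs_count_modes(self):
        reports = [
            ("a", "low", report_with(irrelevant_term=2)),
            ("a", "low", ErrorReport()),
            ("b", "low", report_with(irrelevant_term=1)),
            ("b", "low", ErrorReport()),
        ]
        flag = summarize(reports, arms=("a", "b"), mode="flag")
        count = summarize(reports, arms=("a", "b"), mode="count")
        k = ErrorKind.IRRELEVANT_TERM
        assert flag.arm_summaries["a"].error_counts[k] == 1
        assert count.arm_summaries["a"].error_counts[k] == 2
        # the two modes coincide exactly when no query has a type count >= 2
        assert flag.arm_summaries["b"].error_counts[k] == \
            count.arm_summaries["b"].error_counts[k]

    def test_perfect_complements_any_error(self):
        rng = random.Random(5)
        reports = []
        for arm in ("a", "b"):
            for _ in range(50):
                rep = ErrorReport()
                if rng.random() < 0.4:
                    rep.counts[rng.choice(list(ErrorKind))] = rng.randint(1, 2)
                reports.append((arm, "low", rep))
        s = summarize(reports, arms=("a", "b"))
        for arm in ("a", "b"):
            n = s.arm_summaries[arm].n_queries
            flagged_any = sum(
                1 for a, _, r in reports if a == arm and not r.perfect
            )
            assert s.arm_summaries[arm].perfect_pct == pytest.approx(
                100.0 - 100.0 * flagged_any / n
            )

    def test_difficulty_stratification(self):
        reports = [
            ("a", "low", ErrorReport()),
            ("a", "high", report_with(syntax_error=1)),
            ("b", "low", report_with(irrelevant_term=1)),
            ("b", "high", ErrorReport()),
        ]
        s = summarize(reports, arms=("a", "b"))
        assert s.by_difficulty["low"]["a"]["pct"] == 100.0
        assert s.by_difficulty["low"]["b"]["pct"] == 0.0


class TestSummarizeCounts:
    def test_from_tabulated_rows(self):
        out = summarize_counts(
            {"perfect": (89, 46), "irrelevant_term": (52, 83)},
            totals=(235, 257),
        )
        assert out["rows"]["perfect"]["french"]["pct"] == pytest.approx(37.9, abs=0.05)
        assert out["rows"]["perfect"]["english"]["pct"] == pytest.approx(17.9, abs=0.05)
        assert out["perfect_overall"]["n"] == 135
        assert out["perfect_overall"]["pct"] == pytest.approx(27.4, abs=0.05)
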