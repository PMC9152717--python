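"""Descriptives, Welch/one-sample t tests, Holm step-down, scenarios."""

import math
import statistics

import numpy as np
import pytest
from scipy import stats as sps

from wikiread.stats import (
    ComparisonResult,
    EmptyGroup,
    InsufficientSample,
    InvalidPValue,
    MissingCorpus,
    compare_chapters,
    compare_languages,
    compare_to_grade,
    descriptive_summary,
    holm_adjust,
    one_sample_t_greater,
    two_sample_t,
)
from wikiread.readability import UnsupportedMetricForLanguage


def brute_force_holm(p_values):
    """Independent step-down oracle: literal textbook procedure."""
    m = len(p_values)
    indexed = sorted(enumerate(p_values), key=lambda kv: kv[1])
    adjusted = [None] * m
    previous = 0.0
    for rank, (idx, p) in enumerate(indexed):
        value = min(1.0, max(previous, (m - rank) * p))
        adjusted[idx] = value
        previous = value
    return adjusted


def welch_oracle(x, y):
    """Textbook Welch statistic/df computed from first principles."""
    nx, ny = len(x), len(y)
    mx, my = statistics.fmean(x), statistics.fmean(y)
    vx, vy = statistics.variance(x), statistics.variance(y)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df


class TestDescriptives:
    def test_constant_sample(self):
        s = descriptive_summary([5, 5, 5], "const")
        assert s["mean"] == 5 and s["sd"] == 0 and s["n"] == 3

    def test_single_value_has_no_sd(self):
        s = descriptive_summary([55.33], "W")
        assert s["n"] == 1 and s["sd"] is None
        assert s["mean"] == s["min"] == s["max"] == 55.33

    def test_matches_hand_computation(self):
        values = [28.6, 31.2, 25.0, 40.1, 22.2, 35.5, 29.9, 30.0, 27.3, 33.8]
        s = descriptive_summary(values, "fixture")
        assert s["mean"] == pytest.approx(statistics.fmean(values))
        assert s["sd"] == pytest.approx(statistics.stdev(values))
        assert s["min"] == 22.2 and s["max"] == 40.1

    def test_empty_raises(self):
        with pytest.raises(EmptyGroup):
            descriptive_summary([], "nothing")


class TestTwoSampleT:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r = two_sample_t(x, list(x))
        assert r.t_stat == pytest.approx(0.0)
        assert r.p_raw == pytest.approx(1.0)
        assert not r.significant

    def test_location_shift_recovered(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 400)
        y = x + 3.0
        r = two_sample_t(y, x)
        assert r.diff == pytest.approx(3.0)
        assert r.ci[0] < 3.0 < r.ci[1]
        assert r.p_raw < 1e-10 and r.significant

    def test_matches_formula_oracle(self):
        x = [12.1, 9.8, 14.2, 11.5, 10.9, 13.3, 9.1, 12.7]
        y = [8.4, 10.2, 7.9, 9.5, 11.1, 8.8, 9.9, 10.6, 7.2, 9.0]
        r = two_sample_t(x, y, labels=("x", "y"))
        t_oracle, df_oracle = welch_oracle(x, y)
        assert r.t_stat == pytest.approx(t_oracle, abs=1e-10)
        assert r.df == pytest.approx(df_oracle, abs=1e-10)
        assert r.p_raw == pytest.approx(
            2 * sps.t.sf(abs(t_oracle), df_oracle), abs=1e-12)
        assert r.n1 == 8 and r.n2 == 10
        assert r.ci[0] <= r.diff <= r.ci[1]

    def test_insufficient_sample(self):
        with pytest.raises(InsufficientSample):
            two_sample_t([1.0], [2.0, 3.0])


class TestOneSampleT:
    def test_all_values_at_reference(self):
        r = one_sample_t_greater([7.0] * 12, 7.0)
        assert r.t_stat == pytest.approx(0.0)
        assert r.p_raw == pytest.approx(0.5)
        assert not r.significant

    def test_far_above_reference(self):
        rng = np.random.default_rng(6)
        r = one_sample_t_greater(rng.normal(14, 2, 100), 7.0)
        assert r.p_raw < 1e-20 and r.significant

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(8.0, 2.0, 30)
        r = one_sample_t_greater(x, 7.0)
        t_oracle = (x.mean() - 7.0) / (x.std(ddof=1) / math.sqrt(30))
        assert r.t_stat == pytest.approx(t_oracle, abs=1e-10)
        assert r.df == 29
        assert r.p_raw == pytest.approx(sps.t.sf(t_oracle, 29), abs=1e-12)

    def test_below_reference_not_significant(self):
        rng = np.random.default_rng(8)
        r = one_sample_t_greater(rng.normal(5.0, 1.0, 50), 7.0)
        assert r.p_raw > 0.99 and not r.significant


class TestHolm:
    @pytest.mark.parametrize("p, expected", [
        ([0.2], [0.2]),
        ([0.01, 0.04, 0.03], [0.03, 0.06, 0.06]),
        ([1.0, 1.0], [1.0, 1.0]),
        ([0.05, 0.01], [0.05, 0.02]),
    ])
    def test_known_cases(self, p, expected):
        assert holm_adjust(p) == pytest.approx(expected)

    def test_monotone_and_bounded(self):
        adjusted = holm_adjust([0.3, 0.001, 0.9, 0.02])
        assert all(a >= p for a, p in zip(adjusted, [0.3, 0.001, 0.9, 0.02]))
        assert all(0 <= a <= 1 for a in adjusted)

    def test_equals_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            m = int(rng.integers(1, 11))
            p = rng.uniform(0, 1, m).tolist()
            assert holm_adjust(p) == pytest.approx(brute_force_holm(p),
                                                   abs=1e-12)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(10)
        for _ in range(50):
            p = rng.uniform(0, 1, int(rng.integers(2, 9)))
            _, adjusted, _, _ = multipletests(p, method="holm")
            assert holm_adjust(p.tolist()) == pytest.approx(adjusted.tolist(),
                                                            abs=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(InvalidPValue):
            holm_adjust([0.5, 1.2])
        with pytest.raises(InvalidPValue):
            holm_adjust([-0.1])


class TestCompareLanguages:
    def test_identical_corpora_not_significant(self):
        values = list(np.linspace(20, 40, 60))
        results = compare_languages({"en": values, "de": list(values),
                                     "ru": list(values)})
        assert len(results) == 3
        assert all(r.p_adj == 1.0 and not r.significant for r in results)

    def test_planted_offsets_recovered(self):
        rng = np.random.default_rng(11)
        base = rng.normal(29, 11, 800)
        corpora = {"en": base, "de": rng.normal(21, 10, 800),
                   "ru": rng.normal(39, 13, 500)}
        results = {r.labels: r for r in compare_languages(corpora)}
        assert results[("en", "de")].ci[0] < 8 < results[("en", "de")].ci[1]
        assert results[("en", "ru")].ci[0] < -10 < results[("en", "ru")].ci[1]
        assert results[("de", "ru")].ci[0] < -18 < results[("de", "ru")].ci[1]
        assert all(r.significant for r in results.values())
        # Holm keeps the raw ordering and never shrinks p
        for r in results.values():
            assert r.p_adj >= r.p_raw

    def test_missing_language_raises(self):
        with pytest.raises(MissingCorpus):
            compare_languages({"en": [1.0, 2.0], "de": [1.0, 2.0]})


class TestCompareChapters:
    def test_inclusion_threshold_strict(self):
        rng = np.random.default_rng(12)
        all_a = rng.normal(30, 10, 500).tolist()
        chapters = {"F": rng.normal(30, 10, 26).tolist(),
                    "W": rng.normal(30, 10, 25).tolist(),
                    "U": [30.0] * 5}
        results, excluded = compare_chapters(chapters, all_a)
        assert set(results) == {"F"}
        assert excluded == ["U", "W"]

    def test_planted_deficit_detected(self):
        rng = np.random.default_rng(13)
        all_a = rng.normal(30, 10, 800).tolist()
        chapters = {"F": rng.normal(20, 10, 100).tolist()}
        results, _ = compare_chapters(chapters, all_a)
        r = results["F"]
        assert r.significant and r.diff < 0
        assert r.ci[0] < -10 < r.ci[1]


class TestCompareToGrade:
    def test_reference_chapter_at_grade(self):
        results, _ = compare_to_grade({"F": [7.0] * 40})
        assert results["F"].p_raw == pytest.approx(0.5)
        assert not results["F"].significant

    def test_planted_high_grade_significant(self):
        rng = np.random.default_rng(14)
        results, excluded = compare_to_grade(
            {"F": rng.normal(14, 2, 100).tolist(), "W": [10.0] * 4})
        assert results["F"].significant
        assert excluded == ["W"]

    def test_non_english_rejected(self):
        with pytest.raises(UnsupportedMetricForLanguage):
            compare_to_grade({"F": [8.0] * 30}, language="de")
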