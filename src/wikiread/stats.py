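"""Comparative statistics over scored, annotated corpora.

Three scenarios, all on a significance level of α = .05:

1. *Interlanguage*: pairwise two-tailed Welch t tests on the FRE scores
   of all articles (groups A and B) between the three languages, with
   Holm step-down adjustment across the family of three tests.
2. *Chapter vs. corpus*: per ICD-10 chapter, a two-tailed Welch t test
   of that chapter's FRE values against the FRE values of all group-A
   articles of the same language.  The chapter sample is part of the
   reference sample; this overlap-induced dependence is inherited from
   the study design and noted in reports.
3. *Chapter vs. recommended grade*: per English chapter, a one-sample,
   one-tailed t test of FKGL against the recommended patient-education
   grade level of 7 (H_a: mean grade > 7).

Chapters enter scenarios 2–3 only when their sample size is strictly
greater than 25.  Welch's unequal-variance statistic is used throughout
for two-sample tests, as group sizes and spreads differ widely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ALPHA",
    "MIN_CHAPTER_N",
    "RECOMMENDED_GRADE",
    "EmptyGroup",
    "InsufficientSample",
    "InvalidPValue",
    "MissingCorpus",
    "ComparisonResult",
    "descriptive_summary",
    "two_sample_t",
    "one_sample_t_greater",
    "holm_adjust",
    "compare_languages",
    "compare_chapters",
    "compare_to_grade",
]

ALPHA = 0.05
#: Chapters enter comparative analyses only with n strictly above this.
MIN_CHAPTER_N = 25
#: Recommended US grade level for patient education material.
RECOMMENDED_GRADE = 7.0


class EmptyGroup(ValueError):
    """Descriptives were requested for an empty sample."""


class InsufficientSample(ValueError):
    """A t test needs at least two observations per sample."""


class InvalidPValue(ValueError):
    """A p-value outside [0, 1] was passed to the adjustment."""


class MissingCorpus(KeyError):
    """A language required for the comparison has no scored corpus."""


@dataclass(frozen=True)
class ComparisonResult:
    """One hypothesis test, in the shape of the published comparison tables."""

    labels: tuple[str, str]
    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float | None
    sd2: float | None
    diff: float
    ci: tuple[float, float]
    t_stat: float
    df: float
    p_raw: float
    p_adj: float | None = None
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        p = self.p_adj if self.p_adj is not None else self.p_raw
        return p < self.alpha

    def with_adjusted(self, p_adj: float) -> "ComparisonResult":
        return ComparisonResult(**{**self.__dict__, "p_adj": p_adj})


def descriptive_summary(values: Sequence[float], label: str = "",
                        ) -> dict[str, float | int | str | None]:
    """n, mean, sample SD (n−1), min and max of one group.

    SD is reported as ``None`` for a single observation, matching the
    convention of the published per-chapter tables.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise EmptyGroup(f"no values for {label!r}")
    return {
        "label": label,
        "n": int(x.size),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else None,
        "min": float(x.min()),
        "max": float(x.max()),
    }


def two_sample_t(x: Sequence[float], y: Sequence[float],
                 labels: tuple[str, str] = ("1", "2"),
                 tails: str = "two") -> ComparisonResult:
    """Unpaired Welch t test with Welch–Satterthwaite df and a 95% CI
    for the mean difference."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientSample("need at least 2 observations per sample")
    alternative = {"two": "two-sided", "one": "greater"}[tails]
    res = sps.ttest_ind(x, y, equal_var=False, alternative=alternative)
    ci = res.confidence_interval(0.95)
    return ComparisonResult(
        labels=labels,
        n1=int(x.size), n2=int(y.size),
        mean1=float(x.mean()), mean2=float(y.mean()),
        sd1=float(x.std(ddof=1)), sd2=float(y.std(ddof=1)),
        diff=float(x.mean() - y.mean()),
        ci=(float(ci.low), float(ci.high)),
        t_stat=float(res.statistic), df=float(res.df),
        p_raw=float(res.pvalue),
    )


def one_sample_t_greater(x: Sequence[float], mu0: float = RECOMMENDED_GRADE,
                         label: str = "sample") -> ComparisonResult:
    """One-sample t test against a reference constant, H_a: mean > mu0."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise InsufficientSample("need at least 2 observations")
    if x.std(ddof=1) == 0.0:
        # degenerate spread: the statistic is 0 (p = .5) at the reference
        # and ±inf away from it
        mean = float(x.mean())
        t = 0.0 if mean == mu0 else math.copysign(math.inf, mean - mu0)
        p = 0.5 if mean == mu0 else (0.0 if mean > mu0 else 1.0)
        return ComparisonResult(
            labels=(label, f"mu0={mu0:g}"), n1=int(x.size), n2=0,
            mean1=mean, mean2=float(mu0), sd1=0.0, sd2=None,
            diff=mean - mu0, ci=(mean - mu0, mean - mu0),
            t_stat=t, df=float(x.size - 1), p_raw=p)
    res = sps.ttest_1samp(x, mu0, alternative="greater")
    ci = res.confidence_interval(0.95)
    return ComparisonResult(
        labels=(label, f"mu0={mu0:g}"),
        n1=int(x.size), n2=0,
        mean1=float(x.mean()), mean2=float(mu0),
        sd1=float(x.std(ddof=1)), sd2=None,
        diff=float(x.mean() - mu0),
        ci=(float(ci.low) - mu0, float(ci.high) - mu0),
        t_stat=float(res.statistic), df=float(res.df),
        p_raw=float(res.pvalue),
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment, returned in the input order.

    Ascending p_(i) is multiplied by (m − i + 1), running maxima enforce
    monotonicity, and values are capped at 1.
    """
    p = list(p_values)
    for value in p:
        if not (0.0 <= value <= 1.0) or math.isnan(value):
            raise InvalidPValue(f"p-value {value!r} outside [0, 1]")
    m = len(p)
    order = sorted(range(m), key=p.__getitem__)
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def compare_languages(fre_by_lang: Mapping[str, Sequence[float]],
                      ) -> list[ComparisonResult]:
    """Scenario 1: pairwise two-tailed Welch tests on FRE over all
    articles (groups A + B), Holm-adjusted across the family of three."""
    for lang in ("en", "de", "ru"):
        if lang not in fre_by_lang:
            raise MissingCorpus(f"no scored corpus for {lang!r}")
    pairs = (("en", "de"), ("en", "ru"), ("de", "ru"))
    results = [two_sample_t(fre_by_lang[a], fre_by_lang[b], labels=(a, b))
               for a, b in pairs]
    adjusted = holm_adjust([r.p_raw for r in results])
    return [r.with_adjusted(p) for r, p in zip(results, adjusted)]


def compare_chapters(chapter_values: Mapping[str, Sequence[float]],
                     all_group_a: Sequence[float],
                     min_n: int = MIN_CHAPTER_N,
                     ) -> tuple[dict[str, ComparisonResult], list[str]]:
    """Scenario 2: each chapter's FRE against all group-A FRE of the
    language.  Chapters with n ≤ ``min_n`` are reported excluded."""
    results: dict[str, ComparisonResult] = {}
    excluded: list[str] = []
    for chapter in sorted(chapter_values):
        values = chapter_values[chapter]
        if len(values) <= min_n:
            excluded.append(chapter)
            continue
        results[chapter] = two_sample_t(values, all_group_a,
                                        labels=(chapter, "group_A"))
    return results, excluded


def compare_to_grade(chapter_grades: Mapping[str, Sequence[float]],
                     language: str = "en",
                     mu0: float = RECOMMENDED_GRADE,
                     min_n: int = MIN_CHAPTER_N,
                     ) -> tuple[dict[str, ComparisonResult], list[str]]:
    """Scenario 3: per-chapter one-tailed FKGL test against the
    recommended grade (English only)."""
    from .readability import UnsupportedMetricForLanguage

    if language != "en":
        raise UnsupportedMetricForLanguage(
            "the recommended-grade comparison is defined for English FKGL")
    results: dict[str, ComparisonResult] = {}
    excluded: list[str] = []
    for chapter in sorted(chapter_grades):
        values = chapter_grades[chapter]
        if len(values) <= min_n:
            excluded.append(chapter)
            continue
        results[chapter] = one_sample_t_greater(values, mu0, label=chapter)
    return results, excluded
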