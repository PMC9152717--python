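"""Readability formulas with per-language dispatch and FRE difficulty bands.

Each language edition gets its published metric set:

* English — Flesch Reading Ease (FRE), Flesch–Kincaid Grade Level (FKGL),
  Gunning FOG, SMOG, Automated Readability Index (ARI), Coleman–Liau
  Index (CLI);
* German — FRE in Amstad's adaptation, and the fourth Wiener
  Sachtextformel (WSTF);
* Russian — FRE and FKGL in the Solovyev et al. adaptations.

All formulas are affine in simple text ratios (mean sentence length ASL,
mean syllables per word ASW, complex-word share, character densities).
Scores are emitted unclamped and unrounded; presentation layers round to
two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Any

from .textmetrics import TextStatistics, check_language

__all__ = [
    "UnsupportedMetricForLanguage",
    "ReadabilityScores",
    "METRICS_BY_LANGUAGE",
    "FRE_ASW_COEFFICIENT",
    "fre",
    "fkgl",
    "gunning_fog",
    "smog",
    "ari",
    "coleman_liau",
    "wstf4",
    "fre_band",
    "score_article",
    "score_text",
]


class UnsupportedMetricForLanguage(ValueError):
    """A metric was requested for a language it is not defined for."""


#: Metric sets per language; dispatch is total and exclusive.
METRICS_BY_LANGUAGE = {
    "en": ("fre", "fkgl", "fog", "smog", "ari", "cli"),
    "de": ("fre", "wstf4"),
    "ru": ("fre", "fkgl"),
}

# FRE = a - b*ASL - c*ASW, per language.
_FRE_COEFS = {
    "en": (206.835, 1.015, 84.6),
    "de": (180.0, 1.0, 58.5),
    "ru": (208.7, 2.6, 39.2),
}

#: ASW weight of each language's FRE variant (used e.g. to convert a
#: target FRE shift into an ASW shift when constructing synthetic text).
FRE_ASW_COEFFICIENT = {lang: c for lang, (_, _, c) in _FRE_COEFS.items()}

# FKGL = a*ASL + b*ASW - c, per language (English original; Russian
# adaptation).
_FKGL_COEFS = {
    "en": (0.39, 11.8, 15.59),
    "ru": (0.36, 5.76, 11.97),
}


def fre(stats: TextStatistics, lang: str) -> float:
    """Flesch Reading Ease in the language's published variant (unclamped)."""
    check_language(lang)
    a, b, c = _FRE_COEFS[lang]
    return a - b * stats.asl - c * stats.asw


def fkgl(stats: TextStatistics, lang: str) -> float:
    """Flesch–Kincaid Grade Level; defined for English and Russian only."""
    check_language(lang)
    if lang not in _FKGL_COEFS:
        raise UnsupportedMetricForLanguage(f"FKGL is not defined for {lang!r}")
    a, b, c = _FKGL_COEFS[lang]
    return a * stats.asl + b * stats.asw - c


def gunning_fog(stats: TextStatistics) -> float:
    """Gunning FOG index (English): 0.4 · (ASL + % hard words)."""
    return 0.4 * (stats.asl + stats.pct_hard_words)


def smog(stats: TextStatistics) -> float:
    """SMOG grade (English), normalized to a 30-sentence sample.

    Uses the McLaughlin constants: 3.1291 + 1.0430·sqrt(p·30/sentences),
    where p is the polysyllabic (≥3 syllables) word count.
    """
    return 3.1291 + 1.0430 * math.sqrt(stats.p_poly * 30.0 / stats.n_sentences)


def ari(stats: TextStatistics) -> float:
    """Automated Readability Index (English), character-count based."""
    return (4.71 * (stats.n_chars / stats.n_words)
            + 0.5 * (stats.n_words / stats.n_sentences) - 21.43)


def coleman_liau(stats: TextStatistics) -> float:
    """Coleman–Liau Index (English): 0.0588·L − 0.296·S − 15.8."""
    return 0.0588 * stats.l_per100 - 0.296 * stats.s_per100 - 15.8


def wstf4(stats: TextStatistics, lang: str = "de") -> float:
    """Fourth Wiener Sachtextformel (German grade level)."""
    if lang != "de":
        raise UnsupportedMetricForLanguage(f"WSTF is not defined for {lang!r}")
    return 0.2656 * stats.asl + 0.2744 * stats.ms - 1.6939


#: FRE difficulty bands: half-open intervals, lower edge inclusive, so a
#: score of exactly 30.00 is "difficult".
_BANDS = (
    (30.0, "very_difficult"),
    (50.0, "difficult"),
    (60.0, "fairly_difficult"),
    (70.0, "standard"),
    (80.0, "fairly_easy"),
    (90.0, "easy"),
)


def fre_band(score: float) -> str:
    """Map an FRE score to its difficulty label."""
    for upper, label in _BANDS:
        if score < upper:
            return label
    return "very_easy"


@dataclass(frozen=True)
class ReadabilityScores:
    """The language-appropriate metric values for one article.

    Metrics not defined for the language are ``None``.
    """

    lang: str
    fre: float
    fre_band: str
    fkgl: float | None = None
    fog: float | None = None
    smog: float | None = None
    ari: float | None = None
    cli: float | None = None
    wstf4: float | None = None

    def present_metrics(self) -> tuple[str, ...]:
        return tuple(m for m in ("fre", "fkgl", "fog", "smog", "ari", "cli",
                                 "wstf4")
                     if getattr(self, m) is not None)

    def as_dict(self) -> dict[str, Any]:
        return asdict(self)


def score_text(stats: TextStatistics, lang: str) -> ReadabilityScores:
    """Compute the full metric set for one language from text statistics."""
    check_language(lang)
    f = fre(stats, lang)
    scores: dict[str, float] = {}
    if lang == "en":
        scores = {"fkgl": fkgl(stats, "en"), "fog": gunning_fog(stats),
                  "smog": smog(stats), "ari": ari(stats),
                  "cli": coleman_liau(stats)}
    elif lang == "de":
        scores = {"wstf4": wstf4(stats)}
    else:  # ru
        scores = {"fkgl": fkgl(stats, "ru")}
    return ReadabilityScores(lang=lang, fre=f, fre_band=fre_band(f), **scores)


def score_article(article) -> ReadabilityScores:
    """Score one :class:`~wikiread.collect.ArticleRecord`.

    Raises :class:`~wikiread.textmetrics.DegenerateText` (carrying the
    article id) when the text yields no sentences or words.
    """
    from .textmetrics import compute_text_statistics

    stats = compute_text_statistics(article.text, article.language,
                                    article_id=article.key)
    return score_text(stats, article.language)
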