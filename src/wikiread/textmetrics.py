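"""Language-aware text statistics for readability scoring.

Turns raw article text (optionally wikitext) into the sentence, word,
character and syllable counts that every readability formula consumes.
Three languages are supported: English (``en``), German (``de``) and
Russian (``ru``).

Syllable estimation is heuristic.  Russian syllable structure is strictly
vocalic, so the counter is an exact vowel count.  For English and German a
vowel-group counter is used (with a silent-``e`` correction for English);
it is validated against real-word gold lists in the test suite and agrees
with dictionary syllabification on common prose vocabulary, but individual
rare words may be off by one — a known property of every automated counter
for these languages.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

__all__ = [
    "LANGUAGES",
    "DegenerateText",
    "TextStatistics",
    "strip_wiki_markup",
    "segment_sentences",
    "tokenize_words",
    "count_syllables",
    "compute_text_statistics",
    "load_abbreviations",
]

#: The three language editions the pipeline accepts, everywhere.
LANGUAGES = ("en", "de", "ru")


class DegenerateText(ValueError):
    """Raised when a text has no sentences or no words.

    Such articles cannot be scored; callers exclude them from the
    analysis and record the exclusion.
    """

    def __init__(self, message: str = "text has no sentences or words",
                 article_id: str | None = None):
        self.article_id = article_id
        if article_id is not None:
            message = f"{message} (article {article_id})"
        super().__init__(message)


def check_language(lang: str) -> str:
    if lang not in LANGUAGES:
        raise ValueError(f"unsupported language {lang!r}; expected one of {LANGUAGES}")
    return lang


# ---------------------------------------------------------------------------
# Wiki markup stripping
# ---------------------------------------------------------------------------

_COMMENT_RE = re.compile(r"<!--.*?-->", re.DOTALL)
_REF_RE = re.compile(r"<ref[^>/]*/>|<ref[^>]*>.*?</ref>", re.DOTALL | re.IGNORECASE)
_TAG_RE = re.compile(r"</?[a-zA-Z][^>]*>")
_TABLE_RE = re.compile(r"\{\|.*?\|\}", re.DOTALL)
_FILE_LINK_RE = re.compile(
    r"\[\[(?:File|Image|Datei|Bild|Файл|Изображение):[^\[\]]*(?:\[\[[^\[\]]*\]\][^\[\]]*)*\]\]",
    re.IGNORECASE,
)
_PIPED_LINK_RE = re.compile(r"\[\[[^\[\]|]*\|([^\[\]]*)\]\]")
_PLAIN_LINK_RE = re.compile(r"\[\[([^\[\]]*)\]\]")
_EXT_LINK_RE = re.compile(r"\[\w+://[^\s\]]+\s+([^\]]*)\]|\[\w+://[^\s\]]+\]")
_HEADING_RE = re.compile(r"^\s*=+\s*(.*?)\s*=+\s*$", re.MULTILINE)
_QUOTES_RE = re.compile(r"'{2,}")
_LIST_MARKER_RE = re.compile(r"^[\*#:;]+\s*", re.MULTILINE)
_MULTISPACE_RE = re.compile(r"[ \t]+")
_MULTINEWLINE_RE = re.compile(r"\n{3,}")


def _strip_templates(text: str) -> str:
    # Innermost-first removal handles nesting; bounded passes guard against
    # pathological unbalanced input (best effort, never raises).
    pattern = re.compile(r"\{\{[^{}]*\}\}")
    for _ in range(20):
        text, n = pattern.subn("", text)
        if n == 0:
            break
    return text


def strip_wiki_markup(wikitext: str) -> str:
    """Reduce wikitext to plain prose, best effort.

    Templates, reference tags, tables, file links, HTML comments/tags,
    heading markers and list markers are removed; internal links are
    replaced by their anchor text.  Markup-free text passes through
    unchanged.  Unbalanced markup never raises.
    """
    text = wikitext
    text = _COMMENT_RE.sub("", text)
    text = _REF_RE.sub("", text)
    text = _strip_templates(text)
    text = _TABLE_RE.sub("", text)
    text = _FILE_LINK_RE.sub("", text)
    text = _PIPED_LINK_RE.sub(r"\1", text)
    text = _PLAIN_LINK_RE.sub(r"\1", text)
    text = _EXT_LINK_RE.sub(r"\1", text)
    text = _HEADING_RE.sub(r"\1", text)
    text = _TAG_RE.sub("", text)
    text = _QUOTES_RE.sub("", text)
    text = _LIST_MARKER_RE.sub("", text)
    text = _MULTISPACE_RE.sub(" ", text)
    text = _MULTINEWLINE_RE.sub("\n\n", text)
    return text.strip()


# ---------------------------------------------------------------------------
# Sentence segmentation
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def load_abbreviations(lang: str) -> frozenset[str]:
    """Load the per-language abbreviation stop list (editable package data).

    Entries are matched case-insensitively against the token preceding a
    period; a match suppresses the sentence boundary.
    """
    check_language(lang)
    path = resources.files("wikiread").joinpath(f"data/abbreviations/{lang}.txt")
    entries = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            entries.add(line.rstrip("."))
    return frozenset(entries)


# A terminator is a run of . ! ? … followed by whitespace or end of text.
_TERMINATOR_RE = re.compile(r"[.!?…]+(?=\s|$)")
_LAST_WORD_RE = re.compile(r"(\S+)$")


def segment_sentences(text: str, lang: str) -> list[str]:
    """Split plain text into sentences on terminal punctuation.

    A period does not end a sentence when the preceding token is on the
    language's abbreviation list.  Whitespace-only input yields an empty
    list; the concatenation of the output equals the input modulo boundary
    whitespace.
    """
    check_language(lang)
    if not text or text.isspace():
        return []
    abbrevs = load_abbreviations(lang)
    sentences: list[str] = []
    start = 0
    for m in _TERMINATOR_RE.finditer(text):
        if m.group() == ".":
            before = _LAST_WORD_RE.search(text, start, m.start())
            if before is not None:
                token = before.group(1).lstrip("([\"'«„“‘").lower()
                if token in abbrevs:
                    continue
        sentence = text[start:m.end()].strip()
        if sentence:
            sentences.append(sentence)
        start = m.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


# ---------------------------------------------------------------------------
# Word tokenization
# ---------------------------------------------------------------------------

# Maximal runs of letters/digits with internal hyphens or apostrophes.
_WORD_RE = re.compile(r"[^\W_]+(?:['’‐-―-][^\W_]+)*")
_ALNUM_RE = re.compile(r"[^\W_]")


def tokenize_words(sentence: str, lang: str) -> list[str]:
    """Extract word tokens; pure punctuation is discarded.

    Hyphenated compounds and apostrophe forms stay single tokens.
    """
    check_language(lang)
    return _WORD_RE.findall(sentence)


# ---------------------------------------------------------------------------
# Syllable counting
# ---------------------------------------------------------------------------

_EN_VOWEL_GROUP_RE = re.compile(r"[aeiouy]+")
_DE_VOWEL_GROUP_RE = re.compile(r"[aeiouyäöü]+")
_RU_VOWEL_RE = re.compile(r"[аеёиоуыэюя]")
_HAS_LETTER_RE = re.compile(r"[^\W\d_]")


def _count_syllables_en(word: str) -> int:
    groups = _EN_VOWEL_GROUP_RE.findall(word)
    n = len(groups)
    # Final silent e ("disease", "syndrome"): only when the e stands as
    # its own vowel group ("tissue" keeps its 2), and not in a
    # consonant+le coda that carries the syllable ("muscle", "table").
    if n > 1 and word.endswith("e") and len(word) >= 2 \
            and word[-2] not in "aeiouy":
        if not (word.endswith("le") and len(word) >= 3
                and word[-3] not in "aeiouy"):
            n -= 1
    return max(1, n)


def count_syllables(word: str, lang: str) -> int:
    """Estimate the syllable count of one token; always ≥ 1.

    Russian: exact count of vowel letters.  English/German: count of
    vowel-letter groups, with English final silent ``e`` subtracted.
    Tokens with no letters (pure numbers) count as one syllable.
    """
    check_language(lang)
    w = word.lower()
    if not _HAS_LETTER_RE.search(w):
        return 1
    if lang == "ru":
        return max(1, len(_RU_VOWEL_RE.findall(w)))
    if lang == "de":
        return max(1, len(_DE_VOWEL_GROUP_RE.findall(w)))
    if "-" in w:  # compounds: syllables summed across parts
        return sum(_count_syllables_en(part) for part in w.split("-") if part)
    return _count_syllables_en(w)


# ---------------------------------------------------------------------------
# Text statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TextStatistics:
    """Counts and ratios a readability formula consumes.

    ``asl``/``asw`` are mean words per sentence and mean syllables per
    word; ``ms`` and ``pct_hard_words`` are the percentage (0–100) of
    words with ≥3 syllables (one shared complex-word definition);
    ``l_per100``/``s_per100`` are letters+digits and sentences per 100
    words; ``p_poly`` is the polysyllabic (≥3 syllables) word count.
    """

    n_sentences: int
    n_words: int
    n_chars: int
    n_syllables: int
    n_complex_words: int
    asl: float
    asw: float
    ms: float
    pct_hard_words: float
    l_per100: float
    s_per100: float
    p_poly: int

    @classmethod
    def from_counts(cls, n_sentences: int, n_words: int, n_chars: int,
                    n_syllables: int, n_complex_words: int) -> "TextStatistics":
        if n_sentences <= 0 or n_words <= 0:
            raise DegenerateText()
        ms = 100.0 * n_complex_words / n_words
        return cls(
            n_sentences=n_sentences,
            n_words=n_words,
            n_chars=n_chars,
            n_syllables=n_syllables,
            n_complex_words=n_complex_words,
            asl=n_words / n_sentences,
            asw=n_syllables / n_words,
            ms=ms,
            pct_hard_words=ms,
            l_per100=100.0 * n_chars / n_words,
            s_per100=100.0 * n_sentences / n_words,
            p_poly=n_complex_words,
        )


def compute_text_statistics(text: str, lang: str,
                            article_id: str | None = None) -> TextStatistics:
    """Compute :class:`TextStatistics` for plain text.

    Raises :class:`DegenerateText` when the text contains no sentences or
    no words, mirroring the exclusion of articles for which readability
    cannot technically be computed.
    """
    check_language(lang)
    sentences = segment_sentences(text, lang)
    n_sentences = 0
    n_words = 0
    n_chars = 0
    n_syllables = 0
    n_complex = 0
    for sentence in sentences:
        tokens = _WORD_RE.findall(sentence)
        if not tokens:
            continue  # a bare "…" fragment is not a sentence
        n_sentences += 1
        n_words += len(tokens)
        for tok in tokens:
            n_chars += len(_ALNUM_RE.findall(tok))
            s = count_syllables(tok, lang)
            n_syllables += s
            if s >= 3:
                n_complex += 1
    if n_sentences == 0 or n_words == 0:
        raise DegenerateText(article_id=article_id)
    return TextStatistics.from_counts(n_sentences, n_words, n_chars,
                                      n_syllables, n_complex)
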