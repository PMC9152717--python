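"""Cross-language linkage and ICD-10 annotation.

Articles describing the same concept in different language editions form
clusters via interlanguage links.  ICD-10 codes come from the article's
own annotation or from a structured-metadata map (emulating the Wikidata
``P4229`` property); valid codes are propagated across each cluster so an
article coded in only one edition is coded everywhere.  The "chapter" of
a code is its leading letter (A–Z), and an article whose codes span
several chapters is duplicated into one instance per chapter.  Articles
with at least one resolvable code form group A; the rest form group B.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from .collect import ArticleRecord

__all__ = [
    "InterlanguageLinkMap",
    "ICDAnnotation",
    "ManualExclusions",
    "ChapterInstance",
    "validate_icd_code",
    "normalize_icd_code",
    "merge_cross_language",
    "resolve_icd_codes",
    "propagate_codes",
    "assign_chapters",
    "split_groups",
    "group_percentage",
    "annotate_corpus",
    "load_icd_map",
]

logger = logging.getLogger(__name__)

# One uppercase Latin letter, two digits, optional "." plus 1-2 further
# digits/letters. Permissive toward metadata dialects; the manual
# exclusion list corrects residual misuse.
_ICD_CODE_RE = re.compile(r"^[A-Z][0-9]{2}(?:\.[0-9A-Z]{1,2})?$")


def normalize_icd_code(code: str) -> str:
    return code.strip().upper()


def validate_icd_code(code: str) -> bool:
    """True iff the string is a well-formed ICD-10 code."""
    return bool(_ICD_CODE_RE.match(code))


class InterlanguageLinkMap:
    """Equivalence classes over ``(language, title)`` keys.

    Built from pairwise link lines; classes are closed under symmetry and
    transitivity (union–find), with at most one title per language per
    class in well-formed data.
    """

    def __init__(self) -> None:
        self._parent: dict[str, str] = {}

    def _find(self, key: str) -> str:
        parent = self._parent.setdefault(key, key)
        if parent != key:
            root = self._find(parent)
            self._parent[key] = root
            return root
        return key

    def add_link(self, key1: str, key2: str) -> None:
        """Link two ``lang:title`` keys."""
        r1, r2 = self._find(key1), self._find(key2)
        if r1 != r2:
            self._parent[r2] = r1

    def cluster_of(self, key: str) -> frozenset[str]:
        """All keys equivalent to ``key`` (including itself)."""
        if key not in self._parent:
            return frozenset((key,))
        root = self._find(key)
        return frozenset(k for k in self._parent if self._find(k) == root)

    def clusters(self) -> list[frozenset[str]]:
        by_root: dict[str, set[str]] = {}
        for key in self._parent:
            by_root.setdefault(self._find(key), set()).add(key)
        return [frozenset(members) for members in by_root.values()]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InterlanguageLinkMap":
        """Read pairwise links, one ``lang1:title1<TAB>lang2:title2`` per line."""
        links = cls()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    logger.warning("bad link line ignored: %r", line)
                    continue
                links.add_link(parts[0], parts[1])
        return links


def load_icd_map(path: str | Path) -> dict[str, set[str]]:
    """Read the metadata code map: ``lang:title<TAB>code[,code...]`` lines."""
    mapping: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                logger.warning("bad code-map line ignored: %r", line)
                continue
            key, codes = parts
            mapping.setdefault(key, set()).update(
                c.strip() for c in codes.split(",") if c.strip())
    return mapping


class ManualExclusions:
    """Per-article code exclusions for metadata that is formally valid but
    factually wrong (e.g. an ICD-11 code pasted into the ICD-10 field)."""

    def __init__(self) -> None:
        self._excluded: set[tuple[str, str]] = set()
        self.reasons: dict[tuple[str, str], str] = {}

    def add(self, key: str, code: str, reason: str = "manual") -> None:
        pair = (key, normalize_icd_code(code))
        self._excluded.add(pair)
        self.reasons[pair] = reason

    def is_excluded(self, key: str, code: str) -> bool:
        return (key, normalize_icd_code(code)) in self._excluded

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ManualExclusions":
        """Read ``lang:title<TAB>code<TAB>reason`` lines."""
        manual = cls()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    continue
                manual.add(parts[0], parts[1],
                           parts[2] if len(parts) > 2 else "manual")
        return manual


@dataclass
class ICDAnnotation:
    """Resolved ICD-10 state of one article."""

    codes: set[str] = field(default_factory=set)
    origin: dict[str, str] = field(default_factory=dict)  # code -> direct|metadata|propagated
    dropped_invalid: set[str] = field(default_factory=set)
    dropped_manual: set[str] = field(default_factory=set)

    @property
    def group(self) -> str:
        """Group A iff any code resolved, else group B."""
        return "A" if self.codes else "B"

    @property
    def chapters(self) -> set[str]:
        """Distinct leading letters of the article's valid codes."""
        return {code[0] for code in self.codes}


def merge_cross_language(per_lang: dict[str, list[ArticleRecord]],
                         links: InterlanguageLinkMap,
                         store: dict[str, ArticleRecord],
                         ) -> tuple[dict[str, list[ArticleRecord]], int]:
    """Augment each language's set with linked counterparts.

    For every harvested article, its linked articles in the other two
    languages are added (tagged ``source_step="cross_link"``) when they
    exist in the snapshot store.  Symmetric across languages and
    idempotent.  Returns the augmented sets and the number of links whose
    target was absent from the snapshot.
    """
    by_key = {a.key: a for a in store.values()}
    merged = {lang: {a.key: a for a in articles}
              for lang, articles in per_lang.items()}
    missing = 0
    for lang, articles in per_lang.items():
        for article in articles:
            for key in links.cluster_of(article.key):
                if key == article.key:
                    continue
                other_lang = key.split(":", 1)[0]
                if other_lang not in merged or key in merged[other_lang]:
                    continue
                counterpart = by_key.get(key)
                if counterpart is None:
                    missing += 1
                    continue
                counterpart.source_step = "cross_link"
                merged[other_lang][key] = counterpart
    result = {lang: sorted(items.values(), key=lambda a: a.key)
              for lang, items in merged.items()}
    if missing:
        logger.info("cross-link merge: %d linked articles absent from "
                    "snapshot", missing)
    return result, missing


def resolve_icd_codes(article: ArticleRecord,
                      metadata_map: dict[str, set[str]],
                      manual: ManualExclusions | None = None) -> ICDAnnotation:
    """Resolve one article's codes from its own annotation plus metadata.

    Codes are normalized (uppercase, stripped); invalid codes are dropped
    with a warning, and manually excluded codes are removed with reason
    recorded.
    """
    annotation = ICDAnnotation()
    sources = [(article.icd_codes, "direct"),
               (metadata_map.get(article.key, ()), "metadata")]
    for codes, origin in sources:
        for raw in codes:
            code = normalize_icd_code(raw)
            if not validate_icd_code(code):
                annotation.dropped_invalid.add(code)
                logger.warning("invalid ICD-10 code %r on %s dropped",
                               raw, article.key)
                continue
            if manual is not None and manual.is_excluded(article.key, code):
                annotation.dropped_manual.add(code)
                continue
            annotation.codes.add(code)
            annotation.origin.setdefault(code, origin)
    return annotation


def propagate_codes(cluster: dict[str, ICDAnnotation]) -> dict[str, ICDAnnotation]:
    """Union each cluster member's code set over the whole cluster.

    Codes a member did not already carry are tagged ``propagated``.  After
    this closure no two members of a cluster differ in their code sets.
    """
    union: set[str] = set()
    for annotation in cluster.values():
        union |= annotation.codes
    for annotation in cluster.values():
        for code in union - annotation.codes:
            annotation.codes.add(code)
            annotation.origin[code] = "propagated"
    return cluster


@dataclass(frozen=True)
class ChapterInstance:
    """One (article, chapter) pair after multi-chapter duplication."""

    article_key: str
    language: str
    chapter: str


def assign_chapters(article: ArticleRecord,
                    annotation: ICDAnnotation) -> list[ChapterInstance]:
    """Duplicate a group-A article into one instance per distinct chapter.

    An article coded {O88.0, T79.0} yields exactly two instances (O and
    T); several codes sharing a letter deduplicate.  Group-B input yields
    an empty list.
    """
    return [ChapterInstance(article.key, article.language, chapter)
            for chapter in sorted(annotation.chapters)]


def group_percentage(n: int, total: int) -> float:
    """Share of ``total`` as a percentage rounded to 2 decimals."""
    if total == 0:
        return 0.0
    return round(100.0 * n / total, 2)


def split_groups(annotated: dict[str, ICDAnnotation],
                 ) -> tuple[set[str], set[str], dict[str, float | int]]:
    """Partition article keys into groups A and B with a summary.

    The summary reports n and the percentage of the total per group,
    percentages rounded to two decimals.
    """
    group_a = {key for key, ann in annotated.items() if ann.group == "A"}
    group_b = set(annotated) - group_a
    total = len(annotated)
    summary = {
        "total": total,
        "n_a": len(group_a),
        "n_b": len(group_b),
        "pct_a": group_percentage(len(group_a), total),
        "pct_b": group_percentage(len(group_b), total),
    }
    return group_a, group_b, summary


def annotate_corpus(per_lang: dict[str, list[ArticleRecord]],
                    links: InterlanguageLinkMap,
                    metadata_map: dict[str, set[str]],
                    manual: ManualExclusions | None = None,
                    ) -> dict[str, ICDAnnotation]:
    """Resolve, then propagate, codes for a merged multi-language corpus.

    Validation happens per code before propagation, so an invalid code in
    one edition never spreads to the others.  Returns annotations keyed by
    article key.
    """
    annotations = {a.key: resolve_icd_codes(a, metadata_map, manual)
                   for articles in per_lang.values() for a in articles}
    done: set[str] = set()
    for key in list(annotations):
        if key in done:
            continue
        members = {k: annotations[k] for k in links.cluster_of(key)
                   if k in annotations}
        propagate_codes(members)
        done |= set(members)
    return annotations
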