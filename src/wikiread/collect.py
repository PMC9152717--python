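"""Corpus harvesting: category-graph traversal and the 4-fold filter pipeline.

A snapshot is a plain-text file set: articles as JSON Lines, the category
graph as a node table plus directed edge list (TSV).  Harvesting starts at
the root disease concept of each language edition, walks category→category
and category→article edges (cycle-safe), and then applies four exclusion
filters in a fixed order — wildcard category names, given names,
geographic terms, stop-word titles — where the first matching filter wins.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from fnmatch import fnmatchcase
from importlib import resources
from pathlib import Path
from typing import Iterable

from .textmetrics import LANGUAGES, check_language

__all__ = [
    "ConfigError",
    "RootNotFound",
    "ArticleRecord",
    "CategoryGraph",
    "FilterConfig",
    "LoadReport",
    "FILTER_ORDER",
    "load_snapshot",
    "traverse_from_root",
    "apply_filters",
]

logger = logging.getLogger(__name__)

#: Fixed filter order; first match wins, so per-filter counts depend on
#: this order.
FILTER_ORDER = ("category_wildcard", "given_name", "geographic", "stop_word")

#: Root concept title per language edition.
DEFAULT_ROOTS = {
    "en": "Human Diseases and Disorders",
    "de": "Krankheit",
    "ru": "Заболевания человека",
}


class ConfigError(ValueError):
    """A filter configuration entry is unusable."""


class RootNotFound(KeyError):
    """The requested root category does not exist in the graph."""


@dataclass
class ArticleRecord:
    """One article in one language edition."""

    page_id: str
    title: str
    language: str
    text: str
    icd_codes: set[str] = field(default_factory=set)
    source_step: str = "graph_traversal"
    excluded_reason: str | None = None
    record_id: str | None = None
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        check_language(self.language)
        if self.record_id is None:
            self.record_id = self.key

    @property
    def key(self) -> str:
        """Cross-file join key, ``language:title``."""
        return f"{self.language}:{self.title}"


@dataclass
class _Node:
    node_type: str  # "category" | "article"
    title: str
    language: str


class CategoryGraph:
    """Typed directed graph of categories and their member articles.

    May contain cycles; traversal uses a visited set.  One graph per
    language.
    """

    def __init__(self, language: str):
        self.language = check_language(language)
        self._nodes: dict[str, _Node] = {}
        self._children: dict[str, list[str]] = {}
        self._parents: dict[str, list[str]] = {}

    def add_node(self, node_id: str, node_type: str, title: str) -> None:
        if node_type not in ("category", "article"):
            raise ValueError(f"bad node type {node_type!r}")
        self._nodes[node_id] = _Node(node_type, title, self.language)

    def add_edge(self, parent_id: str, child_id: str) -> None:
        if parent_id not in self._nodes or child_id not in self._nodes:
            raise KeyError("edge references unknown node")
        if self._nodes[parent_id].node_type != "category":
            raise ValueError(f"edge parent {parent_id!r} is not a category")
        self._children.setdefault(parent_id, []).append(child_id)
        self._parents.setdefault(child_id, []).append(parent_id)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return sum(len(c) for c in self._children.values())

    def node_type(self, node_id: str) -> str:
        return self._nodes[node_id].node_type

    def title(self, node_id: str) -> str:
        return self._nodes[node_id].title

    def children(self, node_id: str) -> list[str]:
        return self._children.get(node_id, [])

    def category_titles_of(self, node_id: str) -> set[str]:
        """Titles of the categories a node belongs to."""
        return {self._nodes[p].title for p in self._parents.get(node_id, [])
                if self._nodes[p].node_type == "category"}

    def find_category(self, title: str) -> str | None:
        for node_id, node in self._nodes.items():
            if node.node_type == "category" and node.title == title:
                return node_id
        return None


@dataclass
class LoadReport:
    """Counts and warnings collected while reading a snapshot."""

    n_articles: int = 0
    n_malformed_records: int = 0
    n_nodes: int = 0
    n_edges: int = 0
    n_dangling_edges: int = 0
    warnings: list[str] = field(default_factory=list)

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        logger.warning(message)


def load_snapshot(article_file: str | Path, nodes_file: str | Path,
                  edges_file: str | Path,
                  ) -> tuple[dict[str, CategoryGraph], dict[str, ArticleRecord],
                             LoadReport]:
    """Read a snapshot: articles (JSONL) plus graph node/edge tables (TSV).

    Returns per-language graphs, the article store indexed by record id,
    and a :class:`LoadReport`.  Malformed article records are skipped and
    counted; dangling edges are dropped with a line-numbered warning.
    """
    report = LoadReport()
    store: dict[str, ArticleRecord] = {}
    with open(article_file, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                article = ArticleRecord(
                    page_id=str(rec["page_id"]),
                    title=rec["title"],
                    language=rec["language"],
                    text=rec.get("text", ""),
                    icd_codes=set(rec.get("icd_codes", ())),
                    record_id=rec.get("id"),
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                report.n_malformed_records += 1
                report.warn(f"{article_file}:{lineno}: skipped malformed "
                            f"record ({exc})")
                continue
            store[article.record_id] = article
            report.n_articles += 1

    graphs = {lang: CategoryGraph(lang) for lang in LANGUAGES}
    node_lang: dict[str, str] = {}
    with open(nodes_file, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                report.warn(f"{nodes_file}:{lineno}: expected 4 columns")
                continue
            node_id, node_type, title, lang = parts
            try:
                graphs[lang].add_node(node_id, node_type, title)
            except (KeyError, ValueError) as exc:
                report.warn(f"{nodes_file}:{lineno}: bad node ({exc})")
                continue
            node_lang[node_id] = lang
            report.n_nodes += 1

    with open(edges_file, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                report.warn(f"{edges_file}:{lineno}: expected 2 columns")
                continue
            parent_id, child_id = parts
            lang = node_lang.get(parent_id)
            if lang is None or child_id not in graphs[lang]:
                report.n_dangling_edges += 1
                report.warn(f"{edges_file}:{lineno}: dangling edge "
                            f"{parent_id} -> {child_id}; dropped")
                continue
            graphs[lang].add_edge(parent_id, child_id)
            report.n_edges += 1

    logger.info("snapshot loaded: %d articles, %d nodes, %d edges",
                report.n_articles, report.n_nodes, report.n_edges)
    return graphs, store, report


def traverse_from_root(graph: CategoryGraph, root_title: str) -> set[str]:
    """All article node ids reachable from the root category (cycle-safe)."""
    root_id = graph.find_category(root_title)
    if root_id is None:
        raise RootNotFound(f"category {root_title!r} not in "
                           f"{graph.language} graph")
    seen: set[str] = {root_id}
    stack = [root_id]
    articles: set[str] = set()
    while stack:
        node_id = stack.pop()
        for child in graph.children(node_id):
            if child in seen:
                continue
            seen.add(child)
            if graph.node_type(child) == "article":
                articles.add(child)
            else:
                stack.append(child)
    return articles


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def _load_pattern_file(path) -> list[str]:
    patterns = []
    for lineno, line in enumerate(str(path.read_text(encoding="utf-8")).splitlines(),
                                  start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        patterns.append(line.lower())
    return patterns


@dataclass
class FilterConfig:
    """The four exclusion lists; empty lists make a filter a no-op.

    Matching is case-insensitive shell glob over titles (and, for the
    wildcard filter, over category titles).  The shipped defaults are
    small illustrative lists meant to be replaced per corpus.
    """

    category_wildcards: list[str] = field(default_factory=list)
    given_names: list[str] = field(default_factory=list)
    geo_terms: list[str] = field(default_factory=list)
    stop_words: list[str] = field(default_factory=list)
    geo_match_categories: bool = False

    def __post_init__(self) -> None:
        for attr in ("category_wildcards", "geo_terms", "stop_words"):
            cleaned = []
            for pat in getattr(self, attr):
                pat = pat.strip().lower()
                if not pat:
                    raise ConfigError(f"empty pattern in {attr}")
                cleaned.append(pat)
            setattr(self, attr, cleaned)
        self.given_names = [n.strip().lower() for n in self.given_names
                            if n.strip()]

    @classmethod
    def from_dir(cls, directory: str | Path) -> "FilterConfig":
        """Load the four lists from ``<dir>/{category_wildcards,given_names,
        geo_terms,stop_words}.txt`` (missing file = empty list)."""
        directory = Path(directory)
        lists = {}
        for name in ("category_wildcards", "given_names", "geo_terms",
                     "stop_words"):
            path = directory / f"{name}.txt"
            lists[name] = _load_pattern_file(path) if path.exists() else []
        return cls(**lists)

    @classmethod
    def default(cls) -> "FilterConfig":
        """The packaged illustrative lists."""
        base = resources.files("wikiread").joinpath("data/filters")
        return cls(**{name: _load_pattern_file(base.joinpath(f"{name}.txt"))
                      for name in ("category_wildcards", "given_names",
                                   "geo_terms", "stop_words")})


def _first_token(title: str) -> str:
    token = title.split()[0] if title.split() else ""
    return token.strip(".,;:()[]\"'«»").lower()


def _matches_any(text: str, patterns: list[str]) -> bool:
    low = text.lower()
    return any(fnmatchcase(low, pat) for pat in patterns)


def _excluding_filter(article: ArticleRecord, categories: set[str],
                      cfg: FilterConfig) -> str | None:
    # Order fixed: wildcard, given-name, geographic, stop-word.
    for cat in categories:
        if _matches_any(cat, cfg.category_wildcards):
            return "category_wildcard"
    if _first_token(article.title) in cfg.given_names:
        return "given_name"
    if _matches_any(article.title, cfg.geo_terms):
        return "geographic"
    if cfg.geo_match_categories:
        for cat in categories:
            if _matches_any(cat, cfg.geo_terms):
                return "geographic"
    if _matches_any(article.title, cfg.stop_words):
        return "stop_word"
    return None


def apply_filters(articles: Iterable[ArticleRecord],
                  categories_of: dict[str, set[str]],
                  cfg: FilterConfig,
                  ) -> tuple[list[ArticleRecord], list[ArticleRecord],
                             dict[str, int]]:
    """Apply the 4-fold exclusion pipeline.

    Returns (kept, excluded, per-filter counts).  Each excluded article is
    tagged with the FIRST matching filter's reason.  ``categories_of``
    maps article record ids to their category titles.
    """
    kept: list[ArticleRecord] = []
    excluded: list[ArticleRecord] = []
    counts = {name: 0 for name in FILTER_ORDER}
    for article in articles:
        categories = categories_of.get(article.record_id, set())
        reason = _excluding_filter(article, categories, cfg)
        if reason is None:
            kept.append(article)
        else:
            article.excluded_reason = reason
            counts[reason] += 1
            excluded.append(article)
    logger.info("filters: kept %d, excluded %s", len(kept), counts)
    return kept, excluded, counts
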