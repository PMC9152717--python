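"""Synthetic snapshot generator with controlled statistical structure.

Generates the complete plain-text file set every pipeline stage consumes
— articles (JSON Lines), category graph (node/edge TSV), interlanguage
links (TSV), metadata code map (TSV) — plus a ``manifest.json`` recording
the planted ground truth for plant-and-recover testing.

Articles are built from pseudo-words whose syllable counts are known by
construction: each syllable is a consonant–vowel unit, so the vowel-group
counters recover the construction count exactly (the final English vowel
is never a silent ``e``).  Sentence counts follow a lognormal whose scale
echoes real disease-article corpora; per-article mean sentence length
(ASL) and syllables per word (ASW) are drawn from per-language normals
chosen so the implied Flesch Reading Ease distributions match the means
and spreads reported for encyclopedia disease corpora (English ≈ 29 ± 11,
German ≈ 21 ± 10, Russian ≈ 39 ± 13).

Planted structure: a category tree per language (with a cycle), decoy
pages targeted by each of the four harvest filters, interlanguage
clusters with partial language coverage, ICD-10 codes placed in a random
subset of each coded cluster's editions (so propagation is exercised),
multi-chapter code sets, one formally-valid-but-wrong code covered by the
manual exclusion list, one malformed code, and a few empty articles.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .collect import ConfigError, DEFAULT_ROOTS
from .readability import FRE_ASW_COEFFICIENT
from .textmetrics import LANGUAGES, load_abbreviations

__all__ = [
    "LanguageProfile",
    "CorpusSpec",
    "generate_word",
    "generate_article",
    "generate_snapshot",
    "SNAPSHOT_FILES",
]

SNAPSHOT_FILES = ("articles.jsonl", "graph_nodes.tsv", "graph_edges.tsv",
                  "langlinks.tsv", "icd_map.tsv", "manual_exclusions.tsv",
                  "manifest.json")

# ---------------------------------------------------------------------------
# Corpus specification
# ---------------------------------------------------------------------------


@dataclass
class LanguageProfile:
    """Per-language generation parameters.

    ``sentences_mean``/``sentences_sd`` parameterize the lognormal
    article length (in sentences); ``asl_*``/``asw_*`` the per-article
    normal draws of mean sentence length and syllables per word;
    ``graph_coverage`` is the fraction of the language's articles
    attached to its category graph (the rest arrive via cross-links).
    """

    n_articles: int
    sentences_mean: float
    sentences_sd: float
    asl_mean: float
    asl_sd: float
    asw_mean: float
    asw_sd: float
    graph_coverage: float = 0.9


def _default_profiles() -> dict[str, LanguageProfile]:
    # ASL/ASW means are chosen so that the expected FRE per language is
    # ~28.8 (en), ~21.2 (de) and ~38.6 (ru); the SDs yield FRE spreads of
    # ~11, ~10 and ~13. Sentence scales echo the corpus means of real
    # disease articles; article counts are a ~10% desk-scale corpus.
    return {
        "en": LanguageProfile(600, 60.0, 65.0, 21.4, 4.0, 1.848, 0.121, 0.318),
        "de": LanguageProfile(590, 40.0, 55.0, 17.0, 3.0, 2.440, 0.163, 0.926),
        "ru": LanguageProfile(330, 45.0, 55.0, 16.0, 3.0, 3.280, 0.281, 0.690),
    }


def asw_mean_for_fre(lang: str, target_fre: float, asl_mean: float) -> float:
    """The ASW mean that makes the expected FRE of a language profile hit
    ``target_fre`` at a given ASL mean (FRE is affine in both)."""
    from .readability import _FRE_COEFS

    a, b, c = _FRE_COEFS[lang]
    return (a - b * asl_mean - target_fre) / c


def _default_chapter_weights() -> dict[str, float]:
    # Echoes the per-chapter share of coded disease articles (chapter Q
    # heaviest; U/W/X/Y/Z nearly empty, exercising the n>25 rule).
    return {
        "A": 2.4, "B": 2.1, "C": 4.8, "D": 6.3, "E": 9.3, "F": 7.7,
        "G": 7.3, "H": 5.4, "I": 4.1, "J": 2.6, "K": 4.5, "L": 4.3,
        "M": 5.8, "N": 3.5, "O": 1.9, "P": 1.6, "Q": 16.6, "R": 5.1,
        "S": 1.8, "T": 2.5, "U": 0.12, "W": 0.10, "X": 0.12, "Y": 0.12,
        "Z": 0.2,
    }


@dataclass
class CorpusSpec:
    """Full specification of one synthetic snapshot.

    The seed fully determines the output; re-generation is byte-identical.
    """

    languages: dict[str, LanguageProfile] = field(default_factory=_default_profiles)
    n_clusters: int = 690
    icd_fraction: float = 0.72
    multi_chapter_fraction: float = 0.08
    chapter_weights: dict[str, float] = field(default_factory=_default_chapter_weights)
    chapter_fre_offsets: dict[str, float] = field(default_factory=lambda: {"F": -10.0})
    decoys_per_filter: dict[str, int] = field(default_factory=lambda: {
        "category_wildcard": 8, "given_name": 10, "geographic": 6,
        "stop_word": 5})
    n_degenerate: dict[str, int] = field(default_factory=lambda: {
        "en": 2, "de": 2, "ru": 1})
    plant_manual_exclusion: bool = True
    plant_invalid_code: bool = True
    seed: int = 20210630

    def __post_init__(self) -> None:
        if not 0.0 <= self.icd_fraction <= 1.0:
            raise ConfigError("icd_fraction must be in [0, 1]")
        if not 0.0 <= self.multi_chapter_fraction <= 1.0:
            raise ConfigError("multi_chapter_fraction must be in [0, 1]")
        for chapter in self.chapter_fre_offsets:
            if self.chapter_weights.get(chapter, 0.0) <= 0.0:
                raise ConfigError(
                    f"FRE offset for chapter {chapter!r} but the chapter "
                    f"has no allocation weight")
        if self.n_clusters < max(p.n_articles for p in self.languages.values()):
            raise ConfigError("n_clusters must be >= the largest per-"
                              "language article count")

    def scaled(self, articles: float = 1.0, sentences: float = 1.0,
               seed: int | None = None) -> "CorpusSpec":
        """A proportionally smaller (or larger) copy of this spec."""
        languages = {
            lang: LanguageProfile(
                n_articles=max(8, round(p.n_articles * articles)),
                sentences_mean=max(4.0, p.sentences_mean * sentences),
                sentences_sd=max(1.0, p.sentences_sd * sentences),
                asl_mean=p.asl_mean, asl_sd=p.asl_sd,
                asw_mean=p.asw_mean, asw_sd=p.asw_sd,
                graph_coverage=p.graph_coverage,
            )
            for lang, p in self.languages.items()
        }
        return CorpusSpec(
            languages=languages,
            n_clusters=max(max(p.n_articles for p in languages.values()),
                           round(self.n_clusters * articles)),
            icd_fraction=self.icd_fraction,
            multi_chapter_fraction=self.multi_chapter_fraction,
            chapter_weights=dict(self.chapter_weights),
            chapter_fre_offsets=dict(self.chapter_fre_offsets),
            decoys_per_filter=dict(self.decoys_per_filter),
            n_degenerate=dict(self.n_degenerate),
            plant_manual_exclusion=self.plant_manual_exclusion,
            plant_invalid_code=self.plant_invalid_code,
            seed=self.seed if seed is None else seed,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "CorpusSpec":
        """Load a spec from JSON or YAML; keys mirror the dataclass fields."""
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if "languages" in data:
            data["languages"] = {lang: LanguageProfile(**profile)
                                 for lang, profile in data["languages"].items()}
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Pseudo-word construction
# ---------------------------------------------------------------------------

# Consonant/vowel inventories. English avoids y (ambiguous vowel) and a
# final silent e, so the vowel-group counter recovers the construction
# syllable count exactly; Russian words carry exactly one vowel letter
# per syllable.
_INVENTORY = {
    "en": ("bcdfgklmnprst", "aeiou", "aiou", "ndrlst"),
    "de": ("bdfgklmnprstwz", "aeiou", "aeiou", "ndrlst"),
    "ru": ("бвгдзклмнпрст", "аеиоу", "аеиоу", "нртлмк"),
}

_MID_POOL: dict[str, tuple[str, ...]] = {}
_FINAL_POOL: dict[str, tuple[str, ...]] = {}
for _lang, (_cons, _vowels, _final_vowels, _codas) in _INVENTORY.items():
    _MID_POOL[_lang] = tuple(c + v for c in _cons for v in _vowels)
    _FINAL_POOL[_lang] = tuple(
        [c + v for c in _cons for v in _final_vowels]
        + [c + v + k for c in _cons for v in _final_vowels for k in _codas[:3]])


def generate_word(lang: str, n_syllables: int, rand: random.Random) -> str:
    """A pseudo-word with exactly ``n_syllables`` constructed syllables."""
    if n_syllables < 1:
        raise ValueError("n_syllables must be >= 1")
    mid, final = _MID_POOL[lang], _FINAL_POOL[lang]
    parts = [rand.choice(mid) for _ in range(n_syllables - 1)]
    parts.append(rand.choice(final))
    return "".join(parts)


def _sentence_lengths(n_sentences: int, asl_target: float,
                      rand: random.Random) -> list[int]:
    """Integer words-per-sentence summing to ~n·ASL (so realized ASL is
    the target up to rounding), with balanced ±jitter."""
    total = max(n_sentences, round(n_sentences * asl_target))
    base, rem = divmod(total, n_sentences)
    lengths = [base + 1] * rem + [base] * (n_sentences - rem)
    rand.shuffle(lengths)
    for _ in range(n_sentences // 2):
        i = rand.randrange(n_sentences)
        j = rand.randrange(n_sentences)
        delta = rand.randint(0, 2)
        if lengths[i] - delta >= 1:
            lengths[i] -= delta
            lengths[j] += delta
    return lengths


def _syllable_counts(n_words: int, asw_target: float,
                     rand: random.Random) -> list[int]:
    """Discrete syllables-per-word on support 1–6 with mean equal to the
    target: a floor/ceil two-point mixture plus balanced unit swaps."""
    base = int(asw_target)
    frac = asw_target - base
    counts = [min(6, max(1, base + (1 if rand.random() < frac else 0)))
              for _ in range(n_words)]
    for _ in range(n_words // 5):
        i = rand.randrange(n_words)
        j = rand.randrange(n_words)
        if counts[i] < 6 and counts[j] > 1 and i != j:
            counts[i] += 1
            counts[j] -= 1
    return counts


def generate_article(lang: str, n_sentences: int, asl_target: float,
                     asw_target: float, rand: random.Random,
                     ) -> tuple[str, dict]:
    """Generate article text plus its construction ground truth.

    Realized ASL/ASW equal the targets up to integer rounding and the
    unbiased jitter of the discrete draws (within 5% for articles of 30+
    sentences).
    """
    abbrevs = load_abbreviations(lang)
    lengths = _sentence_lengths(n_sentences, asl_target, rand)
    total_words = sum(lengths)
    counts = _syllable_counts(total_words, asw_target, rand)
    sentences = []
    pos = 0
    for length in lengths:
        words = [generate_word(lang, counts[pos + k], rand)
                 for k in range(length)]
        pos += length
        # An accidental abbreviation before the period would merge two
        # sentences; a coda consonant keeps the syllable count intact.
        if words[-1] in abbrevs:
            words[-1] += "t"
        words[0] = words[0].capitalize()
        sentences.append(" ".join(words) + ".")
    text = " ".join(sentences)
    truth = {
        "n_sentences": n_sentences,
        "n_words": total_words,
        "n_syllables": sum(counts),
        "asl": total_words / n_sentences,
        "asw": sum(counts) / total_words,
    }
    return text, truth


def sample_fre_corpus(lang: str, profile: LanguageProfile, n_articles: int,
                      target_fre: float, rng: np.random.Generator,
                      rand: random.Random,
                      sentences_mean: float = 12.0,
                      sentences_sd: float = 7.0) -> list[float]:
    """Realized per-article FRE values for a planted language-level mean.

    Generates ``n_articles`` articles whose expected FRE equals
    ``target_fre`` (ASW mean derived from the language's FRE
    coefficients; per-article ASL/ASW spread from the profile), then
    scores each through the actual segmentation/counting/formula path.
    Used for calibration and parameter-recovery experiments.
    """
    from .readability import fre
    from .textmetrics import compute_text_statistics

    asw_mean = asw_mean_for_fre(lang, target_fre, profile.asl_mean)
    values = []
    for _ in range(n_articles):
        n_sent = _lognormal_int(rng, sentences_mean, sentences_sd, low=3)
        asl = float(np.clip(rng.normal(profile.asl_mean, profile.asl_sd),
                            5.0, 45.0))
        asw = float(np.clip(rng.normal(asw_mean, profile.asw_sd), 1.05, 5.8))
        text, _ = generate_article(lang, n_sent, asl, asw, rand)
        values.append(fre(compute_text_statistics(text, lang), lang))
    return values


# ---------------------------------------------------------------------------
# Snapshot assembly
# ---------------------------------------------------------------------------

_CLUSTER_TITLE = {"en": "Condition {i:04d}", "de": "Krankheit {i:04d}",
                  "ru": "Болезнь {i:04d}"}
_SUBCAT_TITLE = {"en": "Diseases group {k}", "de": "Krankheitsgruppe {k}",
                 "ru": "Группа болезней {k}"}
_DECOY_CATEGORY = {"en": "Diseases and disorders by country",
                   "de": "Krankheitsliste nach Land",
                   "ru": "Люди с редкими заболеваниями"}
_DECOY_TITLES = {
    "category_wildcard": {"en": "Health in country {i}",
                          "de": "Gesundheit im Land {i}",
                          "ru": "Здоровье в стране {i}"},
    "given_name": {"en": "John Testman {i}", "de": "Hans Mustermann {i}",
                   "ru": "Иван Тестов {i}"},
    "geographic": {"en": "Cholera outbreaks in Genovia {i}",
                   "de": "Seuchen in Ruritania {i}",
                   "ru": "Эпидемии в стране {i}"},
    "stop_word": {"en": "Disease Research Foundation {i}",
                  "de": "Krankheits-Gesellschaft {i}",
                  "ru": "Общество больных {i}"},
}
_N_SUBCATS = 8


def _lognormal_int(rng: np.random.Generator, mean: float, sd: float,
                   low: int = 2, high: int = 500) -> int:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return int(np.clip(round(float(rng.lognormal(mu, np.sqrt(sigma2)))),
                       low, high))


def _make_code(chapter: str, rand: random.Random) -> str:
    code = f"{chapter}{rand.randrange(100):02d}"
    if rand.random() < 0.5:
        code += f".{rand.randrange(10)}"
    return code


def generate_snapshot(spec: CorpusSpec, out_dir: str | Path) -> Path:
    """Write a complete snapshot to ``out_dir`` and return that path.

    Emits ``articles.jsonl``, ``graph_nodes.tsv``, ``graph_edges.tsv``,
    ``langlinks.tsv``, ``icd_map.tsv``, ``manual_exclusions.tsv``, a
    ``filters/`` directory (copies of the packaged default lists) and
    ``manifest.json`` with the planted ground truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    rand = random.Random(int(rng.integers(2**31)))
    langs = [lang for lang in LANGUAGES if lang in spec.languages]

    chapters = sorted(spec.chapter_weights)
    weights = np.array([spec.chapter_weights[c] for c in chapters], dtype=float)
    weights /= weights.sum()

    # --- cluster presence per language (exact per-language counts) -------
    presence: dict[str, np.ndarray] = {}
    for lang in langs:
        n = spec.languages[lang].n_articles
        chosen = rng.choice(spec.n_clusters, size=n, replace=False)
        mask = np.zeros(spec.n_clusters, dtype=bool)
        mask[chosen] = True
        presence[lang] = mask
    anywhere = np.zeros(spec.n_clusters, dtype=bool)
    for lang in langs:
        anywhere |= presence[lang]
    cluster_ids = np.flatnonzero(anywhere)

    # --- code assignment --------------------------------------------------
    n_coded = round(spec.icd_fraction * len(cluster_ids))
    coded = set(rng.choice(cluster_ids, size=n_coded, replace=False).tolist())
    n_multi = round(spec.multi_chapter_fraction * n_coded)
    multi = set(rng.choice(sorted(coded), size=n_multi, replace=False).tolist())
    cluster_codes: dict[int, list[str]] = {}
    for cid in sorted(coded):
        first = rand.choices(chapters, weights=weights)[0]
        codes = [_make_code(first, rand)]
        if cid in multi:
            second = first
            while second == first:
                second = rand.choices(chapters, weights=weights)[0]
            codes.append(_make_code(second, rand))
        if rand.random() < 0.25:  # extra code within an existing chapter
            codes.append(_make_code(codes[0][0], rand))
        cluster_codes[cid] = codes

    # --- graph attachment (coverage) -------------------------------------
    on_graph: dict[str, np.ndarray] = {}
    for lang in langs:
        profile = spec.languages[lang]
        present_ids = np.flatnonzero(presence[lang])
        k = round(profile.graph_coverage * len(present_ids))
        chosen = rng.choice(present_ids, size=k, replace=False)
        mask = np.zeros(spec.n_clusters, dtype=bool)
        mask[chosen] = True
        on_graph[lang] = mask
    reachable_any = np.zeros(spec.n_clusters, dtype=bool)
    for lang in langs:
        reachable_any |= on_graph[lang]

    # A cluster is analyzed in a language iff present there and on the
    # graph of at least one language it is present in (cross-links pull
    # the rest in).
    analyzed: dict[str, np.ndarray] = {
        lang: presence[lang] & reachable_any for lang in langs}

    # --- manual exclusion / invalid code plants ---------------------------
    manual_cluster = None
    if spec.plant_manual_exclusion and coded:
        singles = sorted(cid for cid in coded
                         if cid not in multi and reachable_any[cid])
        if singles:
            manual_cluster = singles[0]
            cluster_codes[manual_cluster] = ["C51"]  # wrong template use
    invalid_cluster = None
    if spec.plant_invalid_code:
        uncoded = sorted(cid for cid in cluster_ids.tolist()
                         if cid not in coded and reachable_any[cid])
        if uncoded:
            invalid_cluster = uncoded[0]

    # --- article records --------------------------------------------------
    articles: list[dict] = []
    node_rows: list[tuple[str, str, str, str]] = []
    edge_rows: list[tuple[str, str]] = []
    icd_map_rows: list[tuple[str, str]] = []
    manual_rows: list[tuple[str, str, str]] = []
    langlink_rows: list[tuple[str, str]] = []
    manifest_lang: dict[str, dict] = {}
    page_counter = 0

    # code placement: which editions of a coded cluster carry the codes,
    # and whether each carrying edition annotates directly or via metadata
    placement: dict[int, dict[str, str]] = {}
    for cid in sorted(coded):
        editions = [lang for lang in langs if presence[lang][cid]]
        k = rand.randint(1, len(editions))
        carriers = rand.sample(editions, k)
        placement[cid] = {lang: ("direct" if rand.random() < 0.5 else "metadata")
                          for lang in carriers}

    for lang in langs:
        profile = spec.languages[lang]
        root_id = f"{lang}:cat:root"
        node_rows.append((root_id, "category", DEFAULT_ROOTS[lang], lang))
        subcat_ids = []
        for k in range(_N_SUBCATS):
            sid = f"{lang}:cat:{k}"
            node_rows.append((sid, "category",
                              _SUBCAT_TITLE[lang].format(k=k), lang))
            edge_rows.append((root_id, sid))
            subcat_ids.append(sid)
        # planted cycle: two subcategories referencing each other
        edge_rows.append((subcat_ids[0], subcat_ids[1]))
        edge_rows.append((subcat_ids[1], subcat_ids[0]))

        present_ids = sorted(np.flatnonzero(presence[lang]).tolist())
        degenerate_keys: list[str] = []
        n_degen = spec.n_degenerate.get(lang, 0)
        degen_candidates = [cid for cid in present_ids
                            if cid not in coded and analyzed[lang][cid]]
        degen_set = set(degen_candidates[:n_degen])

        offset_coef = FRE_ASW_COEFFICIENT[lang]
        for cid in present_ids:
            page_counter += 1
            title = _CLUSTER_TITLE[lang].format(i=cid)
            key = f"{lang}:{title}"
            record_id = f"{lang}:p{page_counter}"
            asw_shift = 0.0
            for chapter in {c[0] for c in cluster_codes.get(cid, ())}:
                offset = spec.chapter_fre_offsets.get(chapter)
                if offset:
                    asw_shift += -offset / offset_coef
            if cid in degen_set:
                text, truth = "", {"degenerate": True}
                degenerate_keys.append(key)
            else:
                n_sent = _lognormal_int(rng, profile.sentences_mean,
                                        profile.sentences_sd)
                asl = float(np.clip(rng.normal(profile.asl_mean,
                                               profile.asl_sd), 5.0, 45.0))
                asw = float(np.clip(rng.normal(profile.asw_mean,
                                               profile.asw_sd) + asw_shift,
                                    1.05, 5.8))
                text, truth = generate_article(lang, n_sent, asl, asw, rand)
            direct_codes: list[str] = []
            if cid in coded and placement[cid].get(lang) == "direct":
                direct_codes = cluster_codes[cid]
            elif cid in coded and placement[cid].get(lang) == "metadata":
                icd_map_rows.append((key, ",".join(cluster_codes[cid])))
            if cid == invalid_cluster:
                direct_codes = ["0.00"]  # malformed metadata plant
            if cid == manual_cluster and lang in placement[cid]:
                manual_rows.append((key, "C51", "manual"))
            articles.append({
                "id": record_id, "page_id": page_counter, "language": lang,
                "title": title, "text": text, "icd_codes": direct_codes,
            })
            if on_graph[lang][cid]:
                node_rows.append((record_id, "article", title, lang))
                for sid in rand.sample(subcat_ids, rand.randint(1, 2)):
                    edge_rows.append((sid, record_id))

        # --- decoys (all on-graph, all excluded by exactly one filter) ---
        decoy_cat_id = f"{lang}:cat:decoy"
        node_rows.append((decoy_cat_id, "category", _DECOY_CATEGORY[lang], lang))
        edge_rows.append((root_id, decoy_cat_id))
        for filter_name, count in spec.decoys_per_filter.items():
            for i in range(count):
                page_counter += 1
                title = _DECOY_TITLES[filter_name][lang].format(i=i)
                record_id = f"{lang}:p{page_counter}"
                text, _ = generate_article(lang, 4, 8.0, 1.6
                                           if lang != "ru" else 2.4, rand)
                articles.append({
                    "id": record_id, "page_id": page_counter,
                    "language": lang, "title": title, "text": text,
                    "icd_codes": [],
                })
                node_rows.append((record_id, "article", title, lang))
                if filter_name == "category_wildcard":
                    edge_rows.append((decoy_cat_id, record_id))
                else:
                    edge_rows.append((rand.choice(subcat_ids), record_id))

        analyzed_ids = sorted(np.flatnonzero(analyzed[lang]).tolist())
        group_a_ids = [cid for cid in analyzed_ids
                       if cid in coded and cid != manual_cluster]
        chapter_counts: dict[str, int] = {}
        for cid in group_a_ids:
            for chapter in {c[0] for c in cluster_codes[cid]}:
                chapter_counts[chapter] = chapter_counts.get(chapter, 0) + 1
        manifest_lang[lang] = {
            "n_present": len(present_ids),
            "n_analyzed": len(analyzed_ids),
            "n_on_graph": int(on_graph[lang].sum()),
            "n_cross_link_only": int((analyzed[lang] & ~on_graph[lang]).sum()),
            "decoys": dict(spec.decoys_per_filter),
            "degenerate_keys": degenerate_keys,
            "group_a": len(group_a_ids),
            "group_b": len(analyzed_ids) - len(group_a_ids),
            "chapter_counts": dict(sorted(chapter_counts.items())),
        }

    # --- interlanguage links ---------------------------------------------
    for cid in sorted(cluster_ids.tolist()):
        keys = [f"{lang}:{_CLUSTER_TITLE[lang].format(i=cid)}"
                for lang in langs if presence[lang][cid]]
        for a, b in zip(keys, keys[1:]):
            langlink_rows.append((a, b))

    # --- write files -------------------------------------------------------
    with open(out_dir / "articles.jsonl", "w", encoding="utf-8") as fh:
        for record in articles:
            fh.write(json.dumps(record, ensure_ascii=False) + "\n")
    with open(out_dir / "graph_nodes.tsv", "w", encoding="utf-8") as fh:
        for row in node_rows:
            fh.write("\t".join(row) + "\n")
    with open(out_dir / "graph_edges.tsv", "w", encoding="utf-8") as fh:
        for row in edge_rows:
            fh.write("\t".join(row) + "\n")
    with open(out_dir / "langlinks.tsv", "w", encoding="utf-8") as fh:
        for row in langlink_rows:
            fh.write("\t".join(row) + "\n")
    with open(out_dir / "icd_map.tsv", "w", encoding="utf-8") as fh:
        for row in icd_map_rows:
            fh.write("\t".join(row) + "\n")
    with open(out_dir / "manual_exclusions.tsv", "w", encoding="utf-8") as fh:
        for row in manual_rows:
            fh.write("\t".join(row) + "\n")

    filters_dir = out_dir / "filters"
    filters_dir.mkdir(exist_ok=True)
    base = resources.files("wikiread").joinpath("data/filters")
    for name in ("category_wildcards", "given_names", "geo_terms",
                 "stop_words"):
        (filters_dir / f"{name}.txt").write_text(
            base.joinpath(f"{name}.txt").read_text(encoding="utf-8"),
            encoding="utf-8")

    manifest = {
        "seed": spec.seed,
        "n_clusters": int(len(cluster_ids)),
        "n_coded_clusters": int(len(coded)),
        "n_multi_chapter_clusters": int(len(multi)),
        "chapter_fre_offsets": dict(spec.chapter_fre_offsets),
        "manual_exclusion_cluster": (None if manual_cluster is None
                                     else int(manual_cluster)),
        "invalid_code_cluster": (None if invalid_cluster is None
                                 else int(invalid_cluster)),
        "per_language": manifest_lang,
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, ensure_ascii=False)
    return out_dir
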