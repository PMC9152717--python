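"""Interlanguage clustering, ICD-10 resolution/propagation, chapters, groups."""

import pytest

from wikiread.collect import ArticleRecord
from wikiread.icdlink import (
    ICDAnnotation,
    InterlanguageLinkMap,
    ManualExclusions,
    annotate_corpus,
    assign_chapters,
    group_percentage,
    merge_cross_language,
    propagate_codes,
    resolve_icd_codes,
    split_groups,
    validate_icd_code,
)


def make_article(lang, title, codes=(), **kwargs):
    return ArticleRecord(page_id="0", title=title, language=lang, text="x.",
                         icd_codes=set(codes), **kwargs)


class TestLinkMap:
    def test_transitive_closure(self):
        links = InterlanguageLinkMap()
        links.add_link("en:Cough", "de:Husten")
        links.add_link("de:Husten", "ru:Кашель")
        cluster = links.cluster_of("ru:Кашель")
        assert cluster == {"en:Cough", "de:Husten", "ru:Кашель"}

    def test_unlinked_key_is_singleton(self):
        links = InterlanguageLinkMap()
        assert links.cluster_of("en:Alone") == {"en:Alone"}

    def test_clusters_partition(self):
        links = InterlanguageLinkMap()
        links.add_link("en:A", "de:A")
        links.add_link("en:B", "ru:B")
        clusters = links.clusters()
        assert sorted(map(sorted, clusters)) == [["de:A", "en:A"],
                                                 ["en:B", "ru:B"]]


class TestMergeCrossLanguage:
    def _fixture(self):
        en = make_article("en", "Cough")
        de = make_article("de", "Husten")
        ru = make_article("ru", "Кашель")
        links = InterlanguageLinkMap()
        links.add_link("en:Cough", "de:Husten")
        links.add_link("de:Husten", "ru:Кашель")
        store = {a.record_id: a for a in (en, de, ru)}
        return en, de, ru, links, store

    def test_counterparts_added_and_tagged(self):
        en, de, ru, links, store = self._fixture()
        merged, missing = merge_cross_language(
            {"en": [en], "de": [], "ru": []}, links, store)
        assert [a.key for a in merged["de"]] == ["de:Husten"]
        assert [a.key for a in merged["ru"]] == ["ru:Кашель"]
        assert merged["de"][0].source_step == "cross_link"
        assert en.source_step == "graph_traversal"
        assert missing == 0

    def test_unlinked_article_leaves_sets_unchanged(self):
        solo = make_article("en", "Cytokine storm")
        merged, _ = merge_cross_language(
            {"en": [solo], "de": [], "ru": []}, InterlanguageLinkMap(),
            {solo.record_id: solo})
        assert len(merged["en"]) == 1 and not merged["de"] and not merged["ru"]

    def test_idempotent(self):
        en, de, ru, links, store = self._fixture()
        once, _ = merge_cross_language({"en": [en], "de": [de], "ru": []},
                                       links, store)
        twice, _ = merge_cross_language(once, links, store)
        assert {k: [a.key for a in v] for k, v in once.items()} \
            == {k: [a.key for a in v] for k, v in twice.items()}

    def test_missing_target_counted(self):
        en = make_article("en", "Cough")
        links = InterlanguageLinkMap()
        links.add_link("en:Cough", "de:Husten")  # de article not in store
        merged, missing = merge_cross_language(
            {"en": [en], "de": [], "ru": []}, links, {en.record_id: en})
        assert missing == 1 and not merged["de"]


class TestValidation:
    @pytest.mark.parametrize("code", ["T79.0", "F20", "O88.0", "Q00",
                                      "M54.5", "B99.8", "C51", "J09.X"])
    def test_valid(self, code):
        assert validate_icd_code(code)

    @pytest.mark.parametrize("code", ["0.00", "6C51", "F2", "F200", "f20",
                                      "F20.123", "", "F-20", "FF0"])
    def test_invalid(self, code):
        assert not validate_icd_code(code)


class TestResolve:
    def test_normalization(self):
        art = make_article("en", "Obstetric embolism", codes=["o88.0 "])
        ann = resolve_icd_codes(art, {})
        assert ann.codes == {"O88.0"}
        assert ann.origin["O88.0"] == "direct"

    def test_invalid_code_dropped(self):
        art = make_article("en", "Anencephaly", codes=["0.00"])
        ann = resolve_icd_codes(art, {})
        assert not ann.codes and ann.dropped_invalid == {"0.00"}
        assert ann.group == "B"

    def test_metadata_union(self):
        art = make_article("en", "Air embolism", codes=["O88.0"])
        ann = resolve_icd_codes(art, {"en:Air embolism": {"T79.0"}})
        assert ann.codes == {"O88.0", "T79.0"}
        assert ann.origin == {"O88.0": "direct", "T79.0": "metadata"}

    def test_manual_exclusion(self):
        manual = ManualExclusions()
        manual.add("de:Computerspielabhängigkeit", "C51")
        art = make_article("de", "Computerspielabhängigkeit", codes=["C51"])
        ann = resolve_icd_codes(art, {}, manual)
        assert not ann.codes and ann.dropped_manual == {"C51"}
        assert ann.group == "B"

    def test_empty_everything_is_group_b(self):
        ann = resolve_icd_codes(make_article("en", "Cough"), {})
        assert ann.group == "B" and not ann.codes


class TestPropagate:
    def test_single_edition_code_spreads(self):
        cluster = {"en:X": ICDAnnotation(codes={"F20"},
                                         origin={"F20": "direct"}),
                   "de:X": ICDAnnotation(), "ru:X": ICDAnnotation()}
        propagate_codes(cluster)
        assert all(ann.codes == {"F20"} for ann in cluster.values())
        assert cluster["de:X"].origin["F20"] == "propagated"
        assert cluster["en:X"].origin["F20"] == "direct"

    def test_union_semantics(self):
        cluster = {"en:X": ICDAnnotation(codes={"F20"}),
                   "de:X": ICDAnnotation(codes={"F20.0"})}
        propagate_codes(cluster)
        assert cluster["en:X"].codes == cluster["de:X"].codes == {"F20", "F20.0"}

    def test_all_empty_stay_group_b(self):
        cluster = {"en:X": ICDAnnotation(), "de:X": ICDAnnotation()}
        propagate_codes(cluster)
        assert all(ann.group == "B" for ann in cluster.values())

    def test_closure_property(self):
        cluster = {"en:X": ICDAnnotation(codes={"A01", "B02.1"}),
                   "de:X": ICDAnnotation(codes={"C03"}),
                   "ru:X": ICDAnnotation()}
        propagate_codes(cluster)
        sets = [frozenset(ann.codes) for ann in cluster.values()]
        assert len(set(sets)) == 1


class TestChapters:
    def test_multi_chapter_duplication(self):
        art = make_article("en", "Air embolism")
        ann = ICDAnnotation(codes={"O88.0", "T79.0"})
        instances = assign_chapters(art, ann)
        assert [i.chapter for i in instances] == ["O", "T"]
        assert all(i.article_key == "en:Air embolism" for i in instances)

    def test_same_letter_deduplicates(self):
        art = make_article("en", "Schizophrenia")
        ann = ICDAnnotation(codes={"F20", "F25.1"})
        assert [i.chapter for i in assign_chapters(art, ann)] == ["F"]

    def test_group_b_yields_nothing(self):
        assert assign_chapters(make_article("en", "Cough"),
                               ICDAnnotation()) == []


class TestGroups:
    def test_published_percentage_arithmetic(self):
        assert group_percentage(4235, 6127) == 69.12
        assert group_percentage(4625, 6024) == 76.78
        assert group_percentage(2316, 3314) == 69.89

    def test_split_partition(self):
        annotated = {"en:A": ICDAnnotation(codes={"F20"}),
                     "en:B": ICDAnnotation(),
                     "en:C": ICDAnnotation(codes={"Q00.1"})}
        group_a, group_b, summary = split_groups(annotated)
        assert group_a == {"en:A", "en:C"} and group_b == {"en:B"}
        assert summary["n_a"] + summary["n_b"] == summary["total"] == 3
        assert summary["pct_a"] == 66.67 and summary["pct_b"] == 33.33

    def test_all_annotated(self):
        annotated = {"en:A": ICDAnnotation(codes={"A00"})}
        _, group_b, summary = split_groups(annotated)
        assert not group_b and summary["pct_a"] == 100.0


class TestAnnotateCorpus:
    def test_validate_then_propagate(self):
        # the invalid code in one edition must not spread; the valid code
        # in another edition must reach every member
        en = make_article("en", "X", codes=["0.00"])
        de = make_article("de", "X", codes=["Q00.0"])
        ru = make_article("ru", "X")
        links = InterlanguageLinkMap()
        links.add_link("en:X", "de:X")
        links.add_link("de:X", "ru:X")
        annotations = annotate_corpus({"en": [en], "de": [de], "ru": [ru]},
                                      links, {})
        assert annotations["en:X"].codes == {"Q00.0"}
        assert annotations["ru:X"].codes == {"Q00.0"}
        assert annotations["en:X"].origin["Q00.0"] == "propagated"
        assert annotations["de:X"].origin["Q00.0"] == "direct"
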