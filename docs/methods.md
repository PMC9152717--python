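# Methods

This note documents the models, conventions and numerical choices behind
`wikiread`, and what the synthetic corpus does and does not establish
about real data.

## Text statistics

Every readability formula consumes counts produced by one pass over the
article text: sentences, words, letters+digits, syllables, and complex
words (≥3 syllables). Conventions:

* **Sentences** end at runs of `. ! ? …` followed by whitespace or end of
  text. A period is suppressed as a boundary when the preceding token is
  on the language's abbreviation list (plain-text config shipped as
  package data, one entry per line, editable per corpus). Colons and
  semicolons are not boundaries. Fragments without any word token (a bare
  ellipsis) do not count as sentences.
* **Words** are maximal runs of Unicode letters/digits with internal
  hyphens or apostrophes; hyphenated compounds are one word whose
  syllables sum over the parts. Pure punctuation is discarded. Tokens
  with no letters (numerals) count as one word with one syllable, and
  their digits count toward the character total — a declared convention
  chosen for determinism and language independence, not a linguistic
  claim.
* **Characters** are letters and digits only (the usual ARI/CLI
  convention).
* **Complex words** are words with ≥3 syllables. One definition serves
  both Gunning FOG's "hard words" and the WSTF's MS share; the classic
  FOG exemptions (proper nouns, familiar suffixes) are deliberately not
  applied.
* **Degenerate texts** (no sentences or no words after tokenization)
  raise `DegenerateText`; the pipeline excludes such articles from
  scoring and reports them, mirroring how corpus studies exclude articles
  whose metrics cannot technically be computed.

### Syllable estimation

Russian syllable structure is strictly vocalic, so the Russian counter is
an exact count of vowel letters (а е ё и о у ы э ю я), floored at one.
English and German use a vowel-group counter: each maximal run of vowel
letters is one syllable. English additionally drops a final silent `e`
when it forms its own vowel group and is not part of a consonant+`le`
coda (so *disease* → 2, *tissue* → 2, *table* → 2, *readability* → 5).
German has no silent-e rule; its digraphs (ie, ei, au, eu, äu) merge
automatically as single vowel groups. These heuristics are validated
against real-word gold lists in the test suite; like every automated
counter for these languages they can be off by one on individual rare
words (e.g. vowel hiatus as in *bacteria*), which is a recognised,
shared limitation of automated readability analysis rather than a defect
of one implementation.

## Harvesting and filtering

The corpus is defined as everything reachable from the root disease
concept of each language's category graph via directed
category→category/article edges (cycle-safe, unbounded depth). Four
exclusion filters run in a fixed order — wildcard category names, given
names, geographic terms, stop-word titles — and the first match wins, so
per-filter counts are order-dependent; reports state this. Matching is
case-insensitive shell glob; the given-name filter fires when the
title's first whitespace token is on the list (cheap, high precision on
person pages). The shipped lists are small and deliberately illustrative
(fictional place names); real corpora replace them. The geographic
filter matches titles by default and can optionally match category
titles too, since the intended semantics (title vs. category) are
underdetermined.

## Cross-language linkage and ICD-10 annotation

Interlanguage links induce equivalence classes (union–find) over
`language:title` keys. After per-language harvesting, each harvested
article pulls its linked counterparts in the other two languages into
those languages' sets — symmetric and idempotent.

ICD-10 codes come from the article's own annotation or a metadata map
keyed by `language:title` (the structured-metadata route). Codes are
normalized to uppercase, validated against
`^[A-Z][0-9]{2}(\.[0-9A-Z]{1,2})?$` (permissive toward metadata
dialects), and validated **per code before propagation**, so a malformed
code in one edition (e.g. `0.00`) never spreads. A manual exclusion list
(`language:title TAB code TAB reason`) removes formally valid but
factually wrong codes, such as an ICD-11 identifier pasted into the
ICD-10 field. Valid codes are then unioned across each cluster
(conflicting codes are kept, never arbitrated), with provenance recorded
per code (`direct`/`metadata`/`propagated`).

A **chapter** here is the code's leading letter A–Z, not the official
Roman-numeral chapter ranges — that is the granularity at which the
comparative tables of this analysis type are reported. An article whose
codes span k distinct letters is duplicated into k chapter instances
(one per chapter, at most once per chapter). Group A is every article
with ≥1 resolved code after propagation; group B is the rest; both stay
in the language-level analysis.

## Statistics

* **Scenario 1** (languages): three pairwise Welch t tests on FRE over
  groups A+B, two-tailed, Holm-adjusted as a family of three. Holm is
  applied only here — the only scenario described as adjusted.
* **Scenario 2** (chapters): per chapter with n > 25, a two-tailed Welch
  test of the chapter's FRE against *all* group-A FRE values of the
  language. The chapter's own members are part of the reference sample;
  this overlap-induced dependence is the literal reading of the design
  and is noted in reports rather than corrected.
* **Scenario 3** (recommended grade): per English chapter with n > 25, a
  one-sample one-tailed t test of FKGL against the constant 7 (H_a:
  mean > 7). A constant has no sample, so the "unpaired" phrasing is
  implemented as a one-sample test. Zero-variance samples get the exact
  limits (t = 0, p = .5 at the reference; ±∞ away from it).

Welch's unequal-variance statistic is used for all two-sample tests:
group sizes and SDs differ widely across chapters and languages, making
the equal-variance assumption untenable; the Welch–Satterthwaite df and
95% CIs come from scipy. Sample SDs use the n−1 denominator and are
reported absent for single observations. The Holm step-down is
implemented directly (sort ascending, multiply p(i) by m−i+1, enforce
monotonicity, cap at 1) and is cross-checked in tests against both a
brute-force oracle and statsmodels. α = .05 throughout; scores are never
clamped or rounded internally — the report layer rounds to two decimals.

## Synthetic corpus

The generator emulates the *statistical structure* of a multilingual
disease-article corpus, not its prose. Words are pseudo-words built from
consonant–vowel syllable units, so the syllable count is known by
construction and the production counters recover it exactly (the final
English vowel is never a silent `e`; Russian words carry one vowel per
syllable). Sentence counts are lognormal; per-article ASL and ASW are
normal draws.

Defaults (the generator's study conditions):

| | en | de | ru |
|---|---|---|---|
| articles | 600 | 590 | 330 |
| sentences/article (mean, SD) | 60, 65 | 40, 55 | 45, 55 |
| ASL (mean, SD) | 21.4, 4.0 | 17.0, 3.0 | 16.0, 3.0 |
| ASW (mean, SD) | 1.848, 0.121 | 2.440, 0.163 | 3.280, 0.281 |
| graph coverage | 0.318 | 0.926 | 0.690 |

Article counts are a ~10% desk-scale corpus; sentence scales and the
ASL means echo published per-article means for disease corpora, and the
ASW means are derived from the languages' FRE coefficients so that the
implied mean FRE per language is ≈28.8 (en), ≈21.2 (de) and ≈38.6 (ru)
with spreads ≈11/10/13 — the documented difficulty ordering
(Russian easiest, German hardest). Graph coverage reproduces the
observed pattern that only a minority of English articles are reachable
through their own category tree, the rest arriving via cross-links.
Further planted structure: 690 concept clusters with exact per-language
presence sampling; 72% of clusters carry an ICD-10 code, placed in a
random nonempty subset of the cluster's editions (exercising
propagation); 8% of coded clusters are multi-chapter; chapter allocation
weights echo a Q-heavy distribution with nearly-empty U/W/X/Y/Z chapters
(exercising the n > 25 rule); chapter F carries a −10 FRE-point deficit,
injected by shifting ASW by `offset/ASW-coefficient` of each language's
FRE variant; 8/10/6/5 decoy pages per language target the four filters
exactly once each; 2/2/1 empty articles exercise degenerate-text
exclusion; one cluster carries a deliberately wrong `C51` covered by the
manual exclusion list and one a malformed `0.00`.

ASW targeting uses a floor/ceil two-point mixture (support clipped to
1–6 syllables) whose mean equals the target exactly, plus balanced unit
swaps for spread — simple moment matching. Sentence lengths distribute
`round(n·ASL)` words with balanced jitter, so realized ASL matches the
target up to rounding. `manifest.json` records the planted ground truth
(per-filter decoy counts, group sizes, per-chapter counts, degenerate
keys), which the plant-and-recover tests compare against pipeline
output **exactly**.

What passing on synthetic data does not show: the wikitext stripper and
abbreviation lists face far messier real markup; pseudo-words cannot
validate syllabification of real vocabulary (the gold-list tests do
that, on a small scale); and category topology here is a shallow tree
with one planted cycle, not a real category jungle.

## Scale choices

The default test suite and the acceptance script run the full pipeline
on the default (~10%-scale) snapshot, 200 replicates of 50 articles per
language for CI-coverage of the planted interlanguage offsets (+8, −10,
−18 FRE points), 2,000 null replicates for type-I calibration, and
1,000 random p-vectors for the Holm oracle. These sizes give stable
checks (binomial SE of the coverage estimate ≈1.5 points) while keeping
a full run under a minute.

## Known limitations

* Readability formulas see only sentence/word structure — no vocabulary
  difficulty, layout, or reader modelling.
* The en/de syllable counters are heuristics; per-word errors partially
  cancel in corpus means but are not zero.
* The wikitext stripper is minimal (templates, refs, tables, links,
  headings); full dump parsing is out of scope.
* Scenario 2's chapter-vs-all overlap slightly shrinks true differences;
  with the observed chapter shares the effect is small but systematic.
* ICD-11, dagger/asterisk dual coding, and live metadata queries are out
  of scope.
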