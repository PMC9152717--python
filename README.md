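# wikiread

Automated readability analysis of disease-related encyclopedia corpora in
English, German and Russian.

Consumer-health articles are often the first thing patients read about a
condition, yet most readability studies cover a handful of pages in one
language. `wikiread` implements the full analysis pipeline for
category-organised encyclopedia snapshots at corpus scale: it harvests
disease-related articles from a category graph, links the three language
editions, buckets articles by ICD-10 chapter, scores every article with
the established readability formulas of its language, and runs the
comparative statistics. A synthetic snapshot generator with controlled
statistical structure makes every stage testable offline, without any
database downloads.

It is aimed at health-informatics researchers studying the readability of
web-based patient information, and at anyone who needs multilingual
Flesch-family metrics with reproducible, corpus-level bookkeeping.

## The measures

All formulas consume two ratios — the average sentence length ASL
(words/sentence) and the average syllables per word ASW — plus character
and complex-word densities:

| Metric | Language | Formula |
|---|---|---|
| FRE | en | 206.835 − 1.015·ASL − 84.6·ASW |
| FRE (Amstad) | de | 180 − ASL − 58.5·ASW |
| FRE (Solovyev) | ru | 208.7 − 2.6·ASL − 39.2·ASW |
| FKGL | en | 0.39·ASL + 11.8·ASW − 15.59 |
| FKGL (Solovyev) | ru | 0.36·ASL + 5.76·ASW − 11.97 |
| Gunning FOG | en | 0.4·(ASL + % words with ≥3 syllables) |
| SMOG | en | 3.1291 + 1.0430·√(p·30/sentences) |
| ARI | en | 4.71·(chars/word) + 0.5·ASL − 21.43 |
| Coleman–Liau | en | 0.0588·L − 0.296·S − 15.8 |
| 4th Wiener Sachtextformel | de | 0.2656·ASL + 0.2744·MS − 1.6939 |

FRE is higher-is-easier (a score below 30 is "very difficult"; the bands
are half-open with the lower edge inclusive); the rest are US school
grades. Each language edition gets exactly its published metric set (en:
FRE, FKGL, FOG, SMOG, ARI, CLI; de: FRE, WSTF; ru: FRE, FKGL).

The statistics layer compares (1) languages pairwise on FRE over all
articles with Welch t tests and Holm adjustment, (2) each ICD-10 chapter
against all code-annotated ("group A") articles of its language, and (3)
each English chapter's FKGL against the recommended patient-education
grade level of 7 (one-tailed). Chapters enter comparisons only with n > 25.

## Worked example

```python
from wikiread import compute_text_statistics, score_text

text = (
    "Influenza is a contagious respiratory illness caused by influenza "
    "viruses. It can cause mild to severe illness. Older people, young "
    "children, and people with certain health conditions are at higher "
    "risk of serious complications. The best way to reduce the risk of "
    "seasonal influenza is annual vaccination."
)
stats = compute_text_statistics(text, "en")
scores = score_text(stats, "en")
```

This paragraph has 4 sentences, 47 words and 84 syllables (ASL 11.75,
ASW 1.79, 21.28% words with ≥3 syllables), which yields

```
   fre: 43.71   (band: difficult)
  fkgl: 10.08
   fog: 13.21
  smog: 12.16
   ari: 9.80
   cli: 13.33
```

— i.e. despite its short sentences the vocabulary density alone puts the
paragraph in the "difficult" FRE band, and the grade-level metrics agree
that roughly a 10th–13th-grade education is needed.

## Pipeline on a synthetic corpus

```bash
wikiread generate --out snapshot/ --seed 42
wikiread run --snapshot snapshot/ --out reports/
```

`generate` writes a complete snapshot (articles as JSON Lines, category
graph, interlanguage links, ICD-10 metadata map, filter lists, and a
`manifest.json` with the planted ground truth). `run` executes harvest →
cross-link merge → ICD-10 resolution/propagation → scoring → statistics
and writes CSV/JSONL reports: per-language group splits, descriptives per
group and per chapter, the pairwise language comparison, per-chapter
comparisons, FRE-band histograms and a stage-by-stage run log.

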