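# meshlingua

Non-native English speakers query PubMed/MEDLINE at a disadvantage: the
controlled vocabulary that indexes the database — the Medical Subject
Headings (MeSH) — is English, and so is the advanced-search syntax.
`meshlingua` is a toolkit modelled on multilingual PubMed query builders:
it lets a user find MeSH descriptors and subheadings through labels and
entry-term synonyms *in their own language*, assemble Boolean queries,
and emit valid PubMed advanced-search strings. On top of the builder it
provides the evaluation machinery such tools are judged with: a grader
that classifies a candidate query's errors against librarian-validated
gold-standard queries using the MeSH hierarchy, and the statistics of a
two-arm randomized comparison (Fisher's exact test, Mann-Whitney,
two-proportion sample size, stratified summaries).

It is intended for researchers in medical information retrieval who
build or evaluate terminology-backed query tools, and for teaching the
mechanics of MeSH-based searching.

## The core ideas

**Hierarchy as the error model.** Every MeSH record carries dot-separated
*tree numbers*; record *a* is narrower than *b* iff some tree number of
*a* strictly extends one of *b* (`C10.597.751.861.479` ⊂
`C10.597.751.861`). The grader aligns candidate and gold terms by
exhaustive minimum-error assignment and reads errors off this relation:

| relation of candidate to gold | descriptor error | subheading error |
|---|---|---|
| same | — | — |
| descendant (too narrow) | over-specification | over-specification |
| ancestor (too broad) | under-specification | under-specification |
| unrelated | irrelevant term | under-specification (required one absent) |

plus *incorrect operator* (AND/OR misuse at equal term multisets) and
*syntax error* (unbalanced brackets/quotes, truncated words). A query
with zero errors is **perfect** — the primary endpoint of the trial
design the statistics module reproduces.

**Two-proportion sample size.** For arm proportions p₁, p₂ with
two-sided level α and power 1−β, the observation-level group size is

    n = ⌈ (z₁₋α/₂ + z₁₋β)² · (p₁q₁ + p₂q₂) / (p₂ − p₁)² ⌉

divided by the queries each participant contributes to give subjects per
group. For the design point 25% → 40% at α = 0.05, β = 0.1 and 12
queries per subject this gives n = 200 queries, i.e. 17 participants per
group.

## A worked example

```python
from meshlingua import (build_fixture_thesaurus, build_index, suggest,
                        parse, serialize, GOLD_QUESTIONS, grade)

th = build_fixture_thesaurus()          # packaged EN/FR vocabulary

# look up a term in French
for s in suggest(build_index(th, "fr"), "pelade", limit=2):
    print(s.ui, s.display_label)
# D000505 pelade
# D900103 pelade décalvante totale

# parse in French, emit PubMed syntax
node = parse("pelade/prévention et contrôle", th, language="fr")
print(serialize(node, th))
# "alopecia areata/prevention and control"[MeSH Terms]

# grade a flawed candidate against the gold standard for that question
rep = grade("alopecia areata", GOLD_QUESTIONS[1], th)
print(rep.perfect, {k.value: v for k, v in rep.counts.items() if v})
# False {'underspec_qualifier': 1}
```

The dropped subheading is classified as one under-specified qualifier —
the query is broader than the accepted `alopecia areata/prevention and
control`, so it retrieves noise.

Longer narrative walk-throughs live in `examples/`; the same
functionality is exposed on the command line:

```sh
meshlingua suggest --lang fr pelade
meshlingua build-query "leiomyoma" "rupture, spontaneous"
meshlingua simulate --seed 7 --out-dir out/
meshlingua grade  --gold out/gold.jsonl --submissions out/submissions.tsv
meshlingua report --gold out/gold.jsonl --submissions out/submissions.tsv --out-dir out/
```

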