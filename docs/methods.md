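# Methods

This note records the models, conventions and numerical choices behind
`meshlingua`, and what the synthetic fixtures do and do not establish.

## Thesaurus model

A thesaurus holds **descriptors** (main headings; publication types such
as *Practice Guideline* are descriptor records with
`kind=publication_type` and, by construction, no allowable qualifiers)
and **qualifiers** (subheadings), in disjoint UI namespaces. Each record
carries per-language preferred labels and entry-term synonyms, tree
numbers matching `^[A-Z][0-9]+(\.[0-9]+)*$`, and — for descriptors — an
allowable-qualifier list. English is the pivot language: the XML
interchange subset (a documented slice of the NLM `DescriptorRecordSet`
format, extended with `QualifierRecord` elements so qualifier
hierarchies are self-contained) carries English only, and further
languages are layered on from per-language TSV tables
(`ui<TAB>label<TAB>syn1|syn2…`). Loading a translation file is
idempotent and aborts atomically if any row names an unknown UI.

**Hierarchy.** Record *a* is a descendant of *b* iff *some* tree number
of *a* strictly extends (dotted prefix) some tree number of *b* —
any-prefix semantics, mirroring how PubMed explosion walks all positions
of a descriptor. Comparing a descriptor with a qualifier raises rather
than returning *unrelated*: such a call is a caller bug and should
surface early. The relation is validated to be a strict partial order;
data that would make two distinct records mutual descendants is
rejected.

**Matching normalization.** Unicode NFKD, combining marks stripped,
casefold, internal whitespace collapsed. Commas and hyphens are
literal: MeSH inverted forms ("Rupture, Spontaneous") match only with
their comma, while French diacritics never break matching ("PELADÉ" →
"pelade"). Preferred labels beat synonyms; within a language, preferred
labels must be injective per record kind.

## Autocomplete

One index entry per (record, preferred label) plus one per synonym in
the index language; records without a label in that language fall back
to the pivot label and are flagged. Match classes are ordered
exact < whole-string prefix < word-boundary prefix < substring, with
ties broken by shorter key then lexicographic key, so output is a total
order and identical input always yields identical output. Suggestions
are de-duplicated by record UI (best surface form kept, matched synonym
reported). The result limit defaults to 20. No fuzzy matching: an
autocomplete backed by a controlled vocabulary should only ever return
terms the user can actually select, and edit-distance ranking would
need usage data this package does not model.

## Query model and the PubMed dialect

Queries are finite ASTs over MeSH term nodes (descriptor + optional
qualifier + explosion flag + search tag), free-text nodes, and Boolean
nodes. AND binds tighter than OR, both left-associative; NOT is binary.
Serialization is bit-exact: `"label"[MeSH Terms]`,
`"label/qualifier"[MeSH Terms]`, `[MeSH Terms:noexp]` when explosion is
suppressed, `"label"[Publication Type]`, `text[Title/Abstract]` for free
text, uppercase operators with single spaces, and parentheses exactly
around Boolean children. `parse∘serialize` is the identity on valid
ASTs, and every emitted string passes `validate_syntax`.

Two parsing choices deserve a note:

* **Greedy longest match for bare terms.** Qualifier names legitimately
  contain operator words ("prevention **and** control"), so an unquoted
  span is resolved as the longest word sequence (slashes allowed) that
  matches a `label` or `label/qualifier` in the thesaurus; only then are
  remaining AND/OR/NOT words read as operators. Unresolvable spans
  become Title/Abstract free text, and adjacency implies AND, as PubMed
  itself interprets it.
* **Tolerant mode.** `validate_syntax` is total and reports unmatched
  brackets/quotes, wildcard-truncated words, dangling operators and the
  empty query, left to right. Tolerant parsing repairs the text
  (strip `*`, close quotes/brackets, drop dangling operators) and
  re-parses, so a query carrying both syntax and term errors can be
  graded on both — the grader counts the syntax issues *and* evaluates
  the recovered terms.

Synonym expansion replaces each unqualified term node by an OR of the
node and its pivot-language entry terms as free text; qualified terms
are left alone (a subheading restricts meaning in a way free text
cannot), and the set of MeSH-tagged terms is conserved.

## Grading procedure

The error taxonomy defines bins, not an alignment procedure; the
procedure here is declared and tested:

1. Terms are extracted from candidate and gold ASTs (free text is
   ignored — grading concerns MeSH structure).
2. An exhaustive search over injective partial assignments (term lists
   are capped at 8 per side; gold queries need 2–4 terms) minimizes
   first the total error count, then the number of unmatched terms — so
   a hierarchy-related match is preferred over leaving both sides
   unmatched at equal cost — with the lexicographically smallest
   assignment in candidate order as the final tie-break.
3. A matched pair contributes descriptor errors by hierarchy (same /
   too-narrow / too-broad / unrelated); qualifiers are examined only
   when the descriptor is not irrelevant. A missing required subheading
   is an under-specified qualifier, a spurious or narrower one an
   over-specified qualifier, and a hierarchically unrelated subheading
   counts a single under-specified qualifier: the required facet is
   effectively absent, and penalizing the spurious one too would charge
   one editorial mistake twice.
4. An unmatched gold term is one under-specified descriptor (its absence
   broadens the query); an unmatched candidate term is one irrelevant
   term. Publication types compare by identity only — the topical
   hierarchy does not apply to them.
5. When the candidate's term multiset equals a gold variant's, operator
   instances are compared (an n-ary AND/OR contributes n−1); each
   differing instance is one incorrect operator. NOT never occurs in
   gold queries, so its use surfaces as operator misuse.
6. The report is the minimum-total-error outcome over all accepted
   variants; syntax issues (from tolerant parsing) add one error each.
   A query is perfect iff every bin is zero.

Both readings of the per-arm results table are exposed: query-level
flags (`mode="flag"`, at most one unit per query per row — the
published table's semantics) and full counts (`mode="count"`), which
differ exactly when a query repeats an error type. The classifier is
deterministic, standing in for the two independent librarian passes
whose discrepancies were resolved by consensus.

## Trial statistics

* **Fisher's exact test** (two-sided) uses the minimum-likelihood
  convention — sum hypergeometric probabilities of all tables with the
  observed margins whose probability does not exceed the observed
  table's — matching R's `fisher.test`; conventions differ across
  software, so this one is declared and checked against full enumeration
  in the tests. Computation is delegated to `scipy.stats.fisher_exact`.
* **Sample size** uses the two-sided normal-approximation formula with
  binomial variance `p(1−p)/n` at the observation (query) level, ceiled,
  then divided by the queries each subject contributes (default 12) and
  ceiled again. The design point 25%→40%, α=0.05, β=0.1 yields 200
  queries ≙ 17 subjects per group; a one-sided reading would not
  reproduce that figure, which is why the two-sided reading is the
  declared one. z-quantiles come from `scipy.stats.norm.ppf` (well below
  the 1e-9 accuracy needed for a stable ceiling).
* **Mann-Whitney** uses midranks for ties; the p-value is exact (full
  enumeration) for untied samples up to 20 per group and the
  tie-corrected normal approximation otherwise, via
  `scipy.stats.mannwhitneyu`. Response-time *data* are not reproducible
  here, only the test itself.

The per-arm denominators 235 and 257 are not package measurements: they
are inferred from the published flag counts and percentages
(89/235 = 37.9%, 46/257 = 17.9%, totalling the 492 analysed queries) and
are used as inputs wherever the published table is re-aggregated.

## Synthetic fixtures: what they emulate and what they don't

The fixture thesaurus covers every descriptor and subheading named in
the twelve study questions, in English and French, with hierarchy
sufficient for every over-/under-specification path (dysgeusia below
taste disorders; overweight and obesity as siblings below a body-weight
parent; a parent and, where needed, a child for each question's leading
terms; one deliberately unrelated decoy descriptor for irrelevant-term
injection). Tree numbers are synthetic — MeSH-flavoured but invented —
and only relations the accepted query variants rely on are meaningful.
French labels beyond those fixed by the study material are likewise
invented. Fixture construction is deterministic: a given spec always
produces byte-identical serialized output.

**Error injection** inverts each taxonomy definition (ancestor /
descendant / decoy descriptor substitution; subheading drop, addition or
narrowing; one AND↔OR instance flip; bracket removal or word
truncation) and *verifies* each rewrite against the grader, rejecting
any that collides with another accepted variant (replacing *dysgeusia*
by its parent *taste disorders* would otherwise produce a different
perfect query). The applicable (question × kind) pairs — 75 of a
possible 84; the gaps are structural, e.g. there is no subheading to
drop from `sarcopenia AND aged` — are each recovered by the grader as
exactly the injected kind with count one.

**Trial simulation** samples error kinds independently per type per
query (Bernoulli), applies them through the validated mutations (a term
offers separate descriptor and qualifier slots, since the grader flags
those independently), and emits a deterministic submission TSV plus
injected-truth records. The default scenario reproduces the trial
layout: 20 + 22 participants × 12 questions, subsampled to the 235/257
analysed queries. Its injection rates are calibrated to the published
per-arm flag rates in two stages: an analytic inverse-applicability
correction, then a fixed-point refinement (four iterations against
pilot simulations of 100 participants per arm at a fixed internal seed)
that absorbs second-order losses such as two sampled kinds competing
for the same term. Calibration is deterministic and independent of the
trial seed.

What passing simulation tests shows — and what they cannot show: the
pipeline recovers the *flag-rate structure it was calibrated to* within
sampling error (seed-averaged row rates within 3 percentage points;
the perfect-row Fisher significance in ≥ 8 of 10 seeds), and ordering
of arms is stable. The independence model is a simplification: real
participants' errors are correlated across types and questions, which
is why per-difficulty mean error counts, response-time distributions,
and retrieval precision against an external corpus are *not* claimed or
tested — those require the unpublished raw queries. Perfect-query rates
emerge from the model rather than being calibrated directly, and match
the published arm rates only approximately (the independence assumption
slightly overstates the error-free fraction when real errors cluster).

## Numerical and interface conventions

* All randomness flows through explicit integer seeds
  (`random.Random`); identical inputs and seeds give byte-identical
  output files. Data files are UTF-8, LF-terminated.
* Gold standards travel as JSON lines (question id, difficulty,
  question text per language, accepted variants in the query dialect);
  submissions as TSV `participant<TAB>arm<TAB>question<TAB>query[<TAB>seconds]`.
* The assignment search refuses term lists longer than 8 per side
  rather than silently approximating.
* Live PubMed URL submission and result counts are deliberately out of
  scope; the serialized query string is the interface boundary, and a
  result-count service can be plugged in above it.
* Difficulty levels (low/medium/high ↔ 2/3/4 required terms) are
  metadata on gold standards, not a hard constructor constraint: the
  salty-taste question is deliberately a two-term query of high
  *expression* difficulty.

## Known limitations

* The fixture vocabulary is a ~70-record slice; lookup and suggestion
  performance characteristics on a full multi-language MeSH
  (≈30k descriptors × 15+ languages) are untested, though all indexing
  is dictionary-based and should scale linearly.
* The grader's operator comparison is multiset-based; it cannot
  distinguish *which* operator position was misused when term multisets
  match but several operators differ, and it does not attempt structural
  comparison when term multisets differ.
* Qualifier "allowability" is enforced for fixture integrity but not
  during parsing of user queries — a user can write a disallowed
  descriptor/subheading combination, and grading will still classify it
  by hierarchy rather than rejecting it.
* The simulator models neither learning, fatigue, nor time-on-task.
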