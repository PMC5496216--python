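"""Classify a candidate PubMed query's errors against gold-standard queries.

The taxonomy distinguishes seven classifier bins — irrelevant MeSH term,
over-/under-specification of descriptors and of qualifiers, incorrect
Boolean operator, and syntax error — with *perfect* as the eighth
category (all bins zero).  A query may accumulate several errors: two
irrelevant terms plus one under-specified qualifier count as three.

Matching procedure (the taxonomy defines the bins, not the assignment;
these rules are this package's declared procedure):

* candidate and gold term lists are aligned by exhaustive minimum-error
  bipartite search (term lists are short: gold queries need 2-4 terms);
* a gold term left unmatched counts one ``underspec_descriptor`` (its
  absence broadens the query); an unmatched candidate MeSH term counts
  one ``irrelevant_term``;
* on a matched pair, the descriptor hierarchy decides: same -> no error,
  descendant (too narrow) -> ``overspec_descriptor``, ancestor (too
  broad) -> ``underspec_descriptor``, unrelated -> ``irrelevant_term``
  (qualifiers are then not examined);
* qualifiers on a non-irrelevant pair: equal or both absent -> no error;
  missing one that gold requires -> ``underspec_qualifier``; spurious or
  narrower one -> ``overspec_qualifier``; broader one ->
  ``underspec_qualifier``; a hierarchically unrelated qualifier counts a
  single ``underspec_qualifier`` (the required subheading is effectively
  absent; the spurious one is not additionally penalized);
* publication types are compared by identity only;
* free-text nodes (synonym completion) are ignored: grading concerns the
  MeSH structure;
* when the candidate's term multiset equals a gold variant's but the
  Boolean structure differs, each differing operator instance counts one
  ``incorrect_operator``;
* each syntax issue counts one ``syntax_error``; the query is then
  repaired and re-parsed so its terms are still graded.

A query is graded against every accepted variant of the question and
keeps the minimum-total-error report.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .query import (
    BoolNode,
    FreeTextNode,
    QueryNode,
    TermNode,
    parse,
    validate_syntax,
)
from .thesaurus import IntegrityError, RecordKind, Relation, Thesaurus

MAX_TERMS_PER_SIDE = 8


class ErrorKind(str, Enum):
    IRRELEVANT_TERM = "irrelevant_term"
    OVERSPEC_DESCRIPTOR = "overspec_descriptor"
    OVERSPEC_QUALIFIER = "overspec_qualifier"
    UNDERSPEC_DESCRIPTOR = "underspec_descriptor"
    UNDERSPEC_QUALIFIER = "underspec_qualifier"
    INCORRECT_OPERATOR = "incorrect_operator"
    SYNTAX_ERROR = "syntax_error"


@dataclass
class ErrorReport:
    """Per-query error counts; perfect iff every bin is zero."""

    counts: dict[ErrorKind, int] = field(
        default_factory=lambda: {k: 0 for k in ErrorKind}
    )
    matched_variant: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def perfect(self) -> bool:
        return self.total == 0

    def flags(self) -> dict[ErrorKind, bool]:
        """Query-level view: was each error type present at least once?"""
        return {k: v > 0 for k, v in self.counts.items()}

    def as_dict(self) -> dict:
        return {
            "counts": {k.value: v for k, v in self.counts.items()},
            "matched_variant": self.matched_variant,
            "perfect": self.perfect,
            "total": self.total,
        }


@dataclass(frozen=True)
class TermMatch:
    candidate: Optional[TermNode]
    gold: Optional[TermNode]
    relation: Optional[Relation]
    errors: tuple[ErrorKind, ...]


@dataclass
class GoldStandard:
    """A study question with its accepted query variants (dialect strings)."""

    question_id: str
    difficulty: str  # "low" | "medium" | "high"
    question_text: dict[str, str]
    variants: list[str]

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError(f"question {self.question_id!r} needs >=1 accepted variant")
        if self.difficulty not in ("low", "medium", "high"):
            raise ValueError(f"unknown difficulty {self.difficulty!r}")


# ---------------------------------------------------------------------------
# pairwise classification
# ---------------------------------------------------------------------------


def classify_pair(
    candidate: TermNode, gold: TermNode, thesaurus: Thesaurus
) -> tuple[ErrorKind, ...]:
    """Errors incurred by offering ``candidate`` where gold expects ``gold``."""
    c_rec = thesaurus.descriptors.get(candidate.descriptor_ui)
    g_rec = thesaurus.descriptors.get(gold.descriptor_ui)
    if c_rec is None or g_rec is None:
        raise IntegrityError("term descriptor UI does not resolve in thesaurus")

    pub = RecordKind.PUBLICATION_TYPE
    if c_rec.kind is pub or g_rec.kind is pub:
        # publication types: identity only, no hierarchy
        if candidate.descriptor_ui != gold.descriptor_ui:
            return (ErrorKind.IRRELEVANT_TERM,)
        rel = Relation.SAME
    else:
        rel = thesaurus.relation(candidate.descriptor_ui, gold.descriptor_ui)

    errors: list[ErrorKind] = []
    if rel is Relation.DESCENDANT:
        errors.append(ErrorKind.OVERSPEC_DESCRIPTOR)
    elif rel is Relation.ANCESTOR:
        errors.append(ErrorKind.UNDERSPEC_DESCRIPTOR)
    elif rel is Relation.UNRELATED:
        return (ErrorKind.IRRELEVANT_TERM,)

    cq, gq = candidate.qualifier_ui, gold.qualifier_ui
    if cq is None and gq is None:
        pass
    elif cq is None:
        errors.append(ErrorKind.UNDERSPEC_QUALIFIER)
    elif gq is None:
        errors.append(ErrorKind.OVERSPEC_QUALIFIER)
    elif cq != gq:
        qrel = thesaurus.relation(cq, gq)
        if qrel is Relation.DESCENDANT:
            errors.append(ErrorKind.OVERSPEC_QUALIFIER)
        elif qrel is Relation.ANCESTOR:
            errors.append(ErrorKind.UNDERSPEC_QUALIFIER)
        else:
            # required subheading effectively absent; one error, not two
            errors.append(ErrorKind.UNDERSPEC_QUALIFIER)
    return tuple(errors)


# ---------------------------------------------------------------------------
# assignment search
# ---------------------------------------------------------------------------


def match_terms(
    candidate_terms: Sequence[TermNode],
    gold_terms: Sequence[TermNode],
    thesaurus: Thesaurus,
) -> list[TermMatch]:
    """Minimum-total-error assignment between candidate and gold terms.

    Exhaustive search over injective partial assignments; total errors are
    minimized first, then the number of unmatched terms (so a
    hierarchy-related match is preferred over leaving both sides
    unmatched at equal cost), then the lexicographically smallest
    assignment in candidate order.
    """
    n_c, n_g = len(candidate_terms), len(gold_terms)
    if n_c > MAX_TERMS_PER_SIDE or n_g > MAX_TERMS_PER_SIDE:
        raise ValueError(
            f"term lists too long for exhaustive matching "
            f"({n_c}x{n_g}, max {MAX_TERMS_PER_SIDE} per side)"
        )

    cost = [
        [classify_pair(c, g, thesaurus) for g in gold_terms] for c in candidate_terms
    ]
    rel = [
        [thesaurus_relation_or_none(c, g, thesaurus) for g in gold_terms]
        for c in candidate_terms
    ]

    UNMATCHED = n_g  # sentinel in assignment vectors
    best: Optional[tuple[int, int, tuple[int, ...]]] = None
    best_assign: Optional[tuple[int, ...]] = None

    def walk(i: int, used: int, errors: int, assign: tuple[int, ...]) -> None:
        nonlocal best, best_assign
        if best is not None and errors > best[0]:
            return
        if i == n_c:
            remaining = n_g - bin(used).count("1")
            total = errors + remaining  # each missing gold term: underspec
            unmatched = assign.count(UNMATCHED) + remaining
            key = (total, unmatched, assign)
            if best is None or key < best:
                best = key
                best_assign = assign
            return
        for j in range(n_g):
            if not used & (1 << j):
                walk(i + 1, used | (1 << j), errors + len(cost[i][j]), assign + (j,))
        walk(i + 1, used, errors + 1, assign + (UNMATCHED,))  # irrelevant

    walk(0, 0, 0, ())
    assert best_assign is not None

    matches: list[TermMatch] = []
    used_gold: set[int] = set()
    for i, j in enumerate(best_assign):
        if j == UNMATCHED:
            matches.append(
                TermMatch(candidate_terms[i], None, None, (ErrorKind.IRRELEVANT_TERM,))
            )
        else:
            used_gold.add(j)
            matches.append(
                TermMatch(candidate_terms[i], gold_terms[j], rel[i][j], cost[i][j])
            )
    for j in range(n_g):
        if j not in used_gold:
            matches.append(
                TermMatch(None, gold_terms[j], None, (ErrorKind.UNDERSPEC_DESCRIPTOR,))
            )
    return matches


def thesaurus_relation_or_none(
    c: TermNode, g: TermNode, thesaurus: Thesaurus
) -> Optional[Relation]:
    c_rec = thesaurus.descriptors[c.descriptor_ui]
    g_rec = thesaurus.descriptors[g.descriptor_ui]
    if RecordKind.PUBLICATION_TYPE in (c_rec.kind, g_rec.kind):
        return Relation.SAME if c.descriptor_ui == g.descriptor_ui else Relation.UNRELATED
    return thesaurus.relation(c.descriptor_ui, g.descriptor_ui)


# ---------------------------------------------------------------------------
# whole-query grading
# ---------------------------------------------------------------------------


def extract_terms(node: QueryNode) -> list[TermNode]:
    """MeSH term nodes in left-to-right order; free text is excluded."""
    if isinstance(node, TermNode):
        return [node]
    if isinstance(node, FreeTextNode):
        return []
    out: list[TermNode] = []
    for child in node.children:
        out.extend(extract_terms(child))
    return out


def operator_counts(node: QueryNode) -> Counter:
    """Operator instances: an n-ary AND/OR contributes n-1, NOT one."""
    counts: Counter = Counter()
    if isinstance(node, BoolNode):
        counts[node.operator] += 1 if node.operator == "NOT" else len(node.children) - 1
        for child in node.children:
            counts += operator_counts(child)
    return counts


def _term_key(t: TermNode) -> tuple:
    return (t.descriptor_ui, t.qualifier_ui)


def _operator_errors(candidate: QueryNode, gold: QueryNode) -> int:
    """Differing operator instances, given equal term multisets."""
    c_ops, g_ops = operator_counts(candidate), operator_counts(gold)
    diff = sum(abs(c_ops[op] - g_ops[op]) for op in ("AND", "OR", "NOT"))
    return (diff + 1) // 2  # a swap changes two counts


def grade(
    candidate_text: str,
    gold: GoldStandard,
    thesaurus: Thesaurus,
    language: str = "en",
) -> ErrorReport:
    """Grade one candidate query against every accepted variant.

    The report is the minimum-total-error outcome over the variants;
    syntax issues (if any) are counted first and the query is repaired so
    its terms still participate.
    """
    report = ErrorReport()
    if not candidate_text.strip():
        report.counts[ErrorKind.SYNTAX_ERROR] = 1
        return report

    issues = validate_syntax(candidate_text)
    n_syntax = len(issues)
    try:
        cand = parse(candidate_text, thesaurus, language, tolerant=True)
    except Exception:
        # unrecoverable text: only the syntax errors can be counted
        report.counts[ErrorKind.SYNTAX_ERROR] = max(n_syntax, 1)
        return report
    cand_terms = extract_terms(cand)

    best: Optional[tuple[int, int, Counter]] = None
    for idx, variant_text in enumerate(gold.variants):
        # gold variants are authored in the pivot language
        g_node = parse(variant_text, thesaurus, "en")
        g_terms = extract_terms(g_node)
        matches = match_terms(cand_terms, g_terms, thesaurus)
        counts: Counter = Counter()
        for m in matches:
            counts.update(m.errors)
        if Counter(map(_term_key, cand_terms)) == Counter(map(_term_key, g_terms)):
            n_op = _operator_errors(cand, g_node)
            if n_op:
                counts[ErrorKind.INCORRECT_OPERATOR] += n_op
        total = sum(counts.values())
        if best is None or (total, idx) < (best[0], best[1]):
            best = (total, idx, counts)

    _, idx, counts = best
    report.matched_variant = idx
    for kind in ErrorKind:
        report.counts[kind] = counts.get(kind, 0)
    report.counts[ErrorKind.SYNTAX_ERROR] += n_syntax
    return report


# ---------------------------------------------------------------------------
# gold-standard JSONL and submission TSV interfaces
# ---------------------------------------------------------------------------


def load_gold(path: Union[str, Path]) -> list[GoldStandard]:
    """Read gold standards from UTF-8 JSON lines."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            out.append(
                GoldStandard(
                    question_id=obj["question_id"],
                    difficulty=obj["difficulty"],
                    question_text=obj["question_text"],
                    variants=list(obj["variants"]),
                )
            )
    return out


def dump_gold(standards: Iterable[GoldStandard], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in standards:
            fh.write(
                json.dumps(
                    {
                        "question_id": gs.question_id,
                        "difficulty": gs.difficulty,
                        "question_text": gs.question_text,
                        "variants": gs.variants,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


@dataclass(frozen=True)
class Submission:
    participant_id: str
    arm: str
    question_id: str
    query_text: str
    seconds: Optional[float] = None


def load_submissions(path: Union[str, Path]) -> list[Submission]:
    """Read a submission TSV: participant, arm, question, query[, seconds]."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {lineno}: expected >=4 fields")
            seconds = float(parts[4]) if len(parts) > 4 and parts[4].strip() else None
            out.append(Submission(parts[0], parts[1], parts[2], parts[3], seconds))
    return out
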