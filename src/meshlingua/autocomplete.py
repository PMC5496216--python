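"""Language-aware incremental suggestion of MeSH terms.

Emulates the query builder's autocomplete box: a user types natural
language in their own language and gets back ranked controlled-vocabulary
records.  Ranking is deterministic: exact match beats whole-string prefix,
beats word-boundary prefix, beats substring; ties break by shorter key then
lexicographic key, so identical input always yields identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .thesaurus import PIVOT_LANGUAGE, LanguageError, Thesaurus, normalize_label

#: match classes, best first
EXACT, PREFIX, WORD_PREFIX, SUBSTRING = 0, 1, 2, 3

DEFAULT_LIMIT = 20


@dataclass(frozen=True)
class IndexEntry:
    key: str              # normalized match key
    surface: str          # display form in the index language
    ui: str
    key_kind: str         # "preferred" | "synonym"
    fallback: bool = False  # True when the label fell back to the pivot language


@dataclass
class SuggestIndex:
    language: str
    entries: list[IndexEntry]


@dataclass(frozen=True)
class Suggestion:
    ui: str
    display_label: str
    matched_key: str
    match_class: int
    rank_score: tuple[int, int, str]


def build_index(thesaurus: Thesaurus, language: str) -> SuggestIndex:
    """One entry per (record, preferred label) plus one per synonym.

    Records lacking a label in ``language`` fall back to the pivot language
    and are flagged as such, so a partially translated thesaurus stays
    fully reachable.
    """
    if language not in thesaurus.languages:
        raise LanguageError(f"language {language!r} not present in thesaurus")
    entries: list[IndexEntry] = []
    records = sorted(
        list(thesaurus.descriptors.values()) + list(thesaurus.qualifiers.values()),
        key=lambda r: r.ui,
    )
    for rec in records:
        label = rec.labels.get(language)
        fallback = label is None
        if fallback:
            label = rec.labels[PIVOT_LANGUAGE]
        entries.append(
            IndexEntry(normalize_label(label), label, rec.ui, "preferred", fallback)
        )
        for syn in rec.synonyms.get(language, []):
            entries.append(IndexEntry(normalize_label(syn), label, rec.ui, "synonym", fallback))
    return SuggestIndex(language=language, entries=entries)


def _match_class(key: str, text: str) -> Optional[int]:
    if key == text:
        return EXACT
    if key.startswith(text):
        return PREFIX
    # word-boundary prefix: text starts at an internal word boundary of key
    padded = " " + key.replace("-", " ")
    if (" " + text) in padded:
        return WORD_PREFIX
    if text in key:
        return SUBSTRING
    return None


def suggest(index: SuggestIndex, text: str, limit: int = DEFAULT_LIMIT) -> list[Suggestion]:
    """Ranked, de-duplicated suggestions for a (partial) input string.

    De-duplication keeps the best-ranked surface form per record UI; the
    matched key (possibly a synonym) is still reported.
    """
    if limit < 1:
        raise ValueError(f"limit must be >= 1, got {limit}")
    norm = normalize_label(text)
    if not norm:
        return []
    best_by_ui: dict[str, Suggestion] = {}
    for entry in index.entries:
        cls = _match_class(entry.key, norm)
        if cls is None:
            continue
        cand = Suggestion(
            ui=entry.ui,
            display_label=entry.surface,
            matched_key=entry.key,
            match_class=cls,
            rank_score=(cls, len(entry.key), entry.key),
        )
        prev = best_by_ui.get(entry.ui)
        if prev is None or cand.rank_score < prev.rank_score:
            best_by_ui[entry.ui] = cand
    ranked = sorted(best_by_ui.values(), key=lambda s: (s.rank_score, s.ui))
    return ranked[:limit]
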