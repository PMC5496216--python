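"""Multilingual MeSH-style thesaurus: records, hierarchy, and label lookup.

The thesaurus holds *descriptors* (main headings, including publication
types), and *qualifiers* (subheadings such as ``/prevention and control``).
Each record carries per-language preferred labels and entry-term synonyms,
plus one or more dot-separated *tree numbers* encoding its position in the
hierarchy: a record whose tree number strictly extends another record's tree
number (dotted-prefix relation) is narrower than it.  That prefix relation
is what PubMed's "explosion" walks, and what the grading module uses to
decide whether a query term is too broad or too narrow.

English (``"en"``) is the pivot language: every record must have an English
preferred label; other languages are layered on via translation tables.
"""

from __future__ import annotations

import re
import unicodedata
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Union

PIVOT_LANGUAGE = "en"

_TREE_NUMBER_RE = re.compile(r"^[A-Z][0-9]+(\.[0-9]+)*$")


class MeshError(Exception):
    """Base class for thesaurus-related errors."""


class MeshXmlError(MeshError):
    """Malformed XML input; the message names the offending line."""


class IntegrityError(MeshError):
    """A record violates a structural invariant (duplicate UI, bad tree number, ...)."""


class UnknownIdentifierError(MeshError, KeyError):
    """A UI does not resolve to any record."""


class LanguageError(MeshError):
    """A language code is not available in the thesaurus."""


def normalize_label(text: str) -> str:
    """Normalize a surface form for matching.

    Unicode compatibility decomposition, combining marks stripped (so French
    diacritics fold: "pelade" == "peladé" after folding), casefold, internal
    whitespace collapsed.  Commas and hyphens are kept literally — inverted
    MeSH forms like "rupture, spontaneous" match only with their comma.
    """
    decomposed = unicodedata.normalize("NFKD", text)
    stripped = "".join(ch for ch in decomposed if not unicodedata.combining(ch))
    return re.sub(r"\s+", " ", stripped.casefold()).strip()


class RecordKind(str, Enum):
    DESCRIPTOR = "descriptor"
    PUBLICATION_TYPE = "publication_type"
    QUALIFIER = "qualifier"


class Relation(str, Enum):
    """Hierarchical relation of record *a* to record *b*.

    ``DESCENDANT`` means a is narrower than b (some tree number of a strictly
    extends a tree number of b); ``ANCESTOR`` is the converse.
    """

    SAME = "same"
    DESCENDANT = "descendant"
    ANCESTOR = "ancestor"
    UNRELATED = "unrelated"


def _check_trees(ui: str, tree_numbers: Iterable[str]) -> None:
    for tn in tree_numbers:
        if not _TREE_NUMBER_RE.match(tn):
            raise IntegrityError(f"record {ui!r}: invalid tree number {tn!r}")


@dataclass
class Descriptor:
    """A MeSH main heading or publication type."""

    ui: str
    kind: RecordKind = RecordKind.DESCRIPTOR
    labels: dict[str, str] = field(default_factory=dict)
    synonyms: dict[str, list[str]] = field(default_factory=dict)
    tree_numbers: list[str] = field(default_factory=list)
    allowed_qualifiers: list[str] = field(default_factory=list)
    definition: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.ui:
            raise IntegrityError("descriptor with empty UI")
        if PIVOT_LANGUAGE not in self.labels:
            raise IntegrityError(f"record {self.ui!r} lacks a {PIVOT_LANGUAGE!r} label")
        _check_trees(self.ui, self.tree_numbers)
        if self.kind is RecordKind.PUBLICATION_TYPE and self.allowed_qualifiers:
            raise IntegrityError(
                f"publication type {self.ui!r} must not carry allowed qualifiers"
            )


@dataclass
class Qualifier:
    """A MeSH subheading, hierarchically organized like descriptors."""

    ui: str
    labels: dict[str, str] = field(default_factory=dict)
    synonyms: dict[str, list[str]] = field(default_factory=dict)
    tree_numbers: list[str] = field(default_factory=list)

    kind: RecordKind = RecordKind.QUALIFIER

    def validate(self) -> None:
        if not self.ui:
            raise IntegrityError("qualifier with empty UI")
        if PIVOT_LANGUAGE not in self.labels:
            raise IntegrityError(f"qualifier {self.ui!r} lacks a {PIVOT_LANGUAGE!r} label")
        _check_trees(self.ui, self.tree_numbers)


Record = Union[Descriptor, Qualifier]


def _tree_extends(a: str, b: str) -> bool:
    """True iff tree number ``a`` is a strict dotted extension of ``b``."""
    return a.startswith(b + ".")


@dataclass
class Thesaurus:
    """Indexed collection of descriptors and qualifiers.

    Descriptor and qualifier UI namespaces are disjoint; label lookup is
    per-language and normalized, with preferred labels taking precedence
    over synonyms.
    """

    descriptors: dict[str, Descriptor] = field(default_factory=dict)
    qualifiers: dict[str, Qualifier] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index_cache: dict = {}

    # -- construction -------------------------------------------------

    def add(self, record: Record) -> None:
        record.validate()
        table = self.qualifiers if isinstance(record, Qualifier) else self.descriptors
        other = self.descriptors if isinstance(record, Qualifier) else self.qualifiers
        if record.ui in table or record.ui in other:
            raise IntegrityError(f"duplicate UI {record.ui!r}")
        table[record.ui] = record
        self._index_cache.clear()

    def validate(self) -> None:
        """Re-check all record invariants and cross-references."""
        for rec in list(self.descriptors.values()) + list(self.qualifiers.values()):
            rec.validate()
        for d in self.descriptors.values():
            for qui in d.allowed_qualifiers:
                if qui not in self.qualifiers:
                    raise IntegrityError(
                        f"descriptor {d.ui!r}: allowed qualifier {qui!r} does not resolve"
                    )
        for lang in self.languages:
            self._label_index(lang)  # raises on duplicated preferred labels

    # -- basic queries -------------------------------------------------

    @property
    def languages(self) -> set[str]:
        langs: set[str] = set()
        for rec in list(self.descriptors.values()) + list(self.qualifiers.values()):
            langs.update(rec.labels)
            langs.update(rec.synonyms)
        return langs

    def resolve(self, ui: str) -> Record:
        rec = self.descriptors.get(ui) or self.qualifiers.get(ui)
        if rec is None:
            raise UnknownIdentifierError(ui)
        return rec

    def relation(self, ui_a: str, ui_b: str) -> Relation:
        """Hierarchical relation of ``ui_a`` relative to ``ui_b``.

        Any-prefix semantics over multiple tree numbers, mirroring MeSH
        explosion.  Comparing a descriptor with a qualifier is an error:
        the namespaces are disjoint and such a comparison is a bug in the
        caller, not an "unrelated" answer.
        """
        a, b = self.resolve(ui_a), self.resolve(ui_b)
        if isinstance(a, Qualifier) != isinstance(b, Qualifier):
            raise IntegrityError(
                f"cannot relate records of different kinds: {ui_a!r} vs {ui_b!r}"
            )
        if ui_a == ui_b:
            return Relation.SAME
        down = any(_tree_extends(ta, tb) for ta in a.tree_numbers for tb in b.tree_numbers)
        up = any(_tree_extends(tb, ta) for ta in a.tree_numbers for tb in b.tree_numbers)
        if down and up:
            raise IntegrityError(
                f"tree numbers of {ui_a!r} and {ui_b!r} violate the hierarchy partial order"
            )
        if down:
            return Relation.DESCENDANT
        if up:
            return Relation.ANCESTOR
        return Relation.UNRELATED

    # -- label lookup --------------------------------------------------

    def _label_index(self, language: str):
        cached = self._index_cache.get(language)
        if cached is not None:
            return cached
        preferred: dict[tuple[RecordKind, str], Record] = {}
        synonyms: dict[tuple[RecordKind, str], Record] = {}
        records: list[Record] = sorted(
            list(self.descriptors.values()) + list(self.qualifiers.values()),
            key=lambda r: r.ui,
        )
        for rec in records:
            label = rec.labels.get(language)
            if label is not None:
                key = (rec.kind, normalize_label(label))
                if key in preferred and preferred[key].ui != rec.ui:
                    raise IntegrityError(
                        f"preferred label {label!r} ({language}) is ambiguous between "
                        f"{preferred[key].ui!r} and {rec.ui!r}"
                    )
                preferred[key] = rec
            for syn in rec.synonyms.get(language, []):
                synonyms.setdefault((rec.kind, normalize_label(syn)), rec)
        self._index_cache[language] = (preferred, synonyms)
        return preferred, synonyms

    def lookup_label(
        self, text: str, language: str, kind: Optional[str] = None
    ) -> Optional[Record]:
        """Resolve a surface form to a record by normalized-exact match.

        ``kind`` restricts the namespace: ``"descriptor"`` (main headings
        and publication types), ``"qualifier"``, or ``None`` for both with
        descriptors preferred.  Preferred labels win over synonyms.
        """
        if language not in self.languages:
            raise LanguageError(f"language {language!r} not present in thesaurus")
        preferred, synonyms = self._label_index(language)
        norm = normalize_label(text)
        if kind == "qualifier":
            kinds = [RecordKind.QUALIFIER]
        elif kind == "descriptor":
            kinds = [RecordKind.DESCRIPTOR, RecordKind.PUBLICATION_TYPE]
        elif kind is None:
            kinds = [RecordKind.DESCRIPTOR, RecordKind.PUBLICATION_TYPE, RecordKind.QUALIFIER]
        else:
            raise ValueError(f"unknown record kind {kind!r}")
        for table in (preferred, synonyms):
            for k in kinds:
                rec = table.get((k, norm))
                if rec is not None:
                    return rec
        return None

    def parent_of(self, ui: str) -> Optional[Record]:
        """Nearest ancestor record (longest strict tree-prefix), if any."""
        rec = self.resolve(ui)
        pool = self.qualifiers if isinstance(rec, Qualifier) else self.descriptors
        best: tuple[int, str] | None = None
        for cand in pool.values():
            if cand.ui == ui:
                continue
            for tc in cand.tree_numbers:
                if any(_tree_extends(t, tc) for t in rec.tree_numbers):
                    key = (len(tc), cand.ui)
                    if best is None or key > best:
                        best = key
                        found = cand
        return found if best is not None else None

    def children_of(self, ui: str) -> list[Record]:
        """Direct and indirect descendants, sorted by UI."""
        rec = self.resolve(ui)
        pool = self.qualifiers if isinstance(rec, Qualifier) else self.descriptors
        out = [
            c
            for c in pool.values()
            if c.ui != ui and self.relation(c.ui, ui) is Relation.DESCENDANT
        ]
        return sorted(out, key=lambda r: r.ui)


# ---------------------------------------------------------------------------
# NLM DescriptorRecordSet XML subset
# ---------------------------------------------------------------------------
#
# Supported elements: DescriptorRecordSet > DescriptorRecord (attribute
# DescriptorClass, "2" marking publication types) with DescriptorUI,
# DescriptorName/String, TreeNumberList/TreeNumber, ConceptList/Concept/
# TermList/Term/String (non-preferred strings become English synonyms),
# AllowableQualifierList/AllowableQualifier/QualifierReferredTo, and an
# optional ScopeNote.  QualifierRecord elements (QualifierUI, QualifierName,
# TreeNumberList, TermList) may appear in the same file so that qualifier
# hierarchies are self-contained.  Unknown elements are ignored.  The XML
# carries English only; other languages travel in translation TSVs.


def load_mesh_xml(path: Union[str, Path]) -> Thesaurus:
    """Load a thesaurus from the documented DescriptorRecordSet XML subset."""
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        line, col = exc.position
        raise MeshXmlError(f"{path}: malformed XML at line {line}, column {col}: {exc.msg}")
    root = tree.getroot()
    th = Thesaurus()

    for qrec in root.iter("QualifierRecord"):
        ui = qrec.findtext("QualifierUI", "").strip()
        name = qrec.findtext("QualifierName/String", "").strip()
        trees = [t.text.strip() for t in qrec.findall("TreeNumberList/TreeNumber") if t.text]
        syns = [
            s.text.strip()
            for s in qrec.findall("TermList/Term/String")
            if s.text and s.text.strip() != name
        ]
        q = Qualifier(ui=ui, labels={PIVOT_LANGUAGE: name}, tree_numbers=trees)
        if syns:
            q.synonyms[PIVOT_LANGUAGE] = syns
        th.add(q)

    for rec in root.iter("DescriptorRecord"):
        ui = rec.findtext("DescriptorUI", "").strip()
        if ui in th.descriptors:
            raise IntegrityError(f"{path}: duplicate DescriptorUI {ui!r}")
        name = rec.findtext("DescriptorName/String", "").strip()
        kind = (
            RecordKind.PUBLICATION_TYPE
            if rec.get("DescriptorClass") == "2"
            else RecordKind.DESCRIPTOR
        )
        trees = [t.text.strip() for t in rec.findall("TreeNumberList/TreeNumber") if t.text]
        syns: list[str] = []
        for term in rec.findall("ConceptList/Concept/TermList/Term/String"):
            if term.text and term.text.strip() != name and term.text.strip() not in syns:
                syns.append(term.text.strip())
        allowed: list[str] = []
        for aq in rec.findall("AllowableQualifierList/AllowableQualifier"):
            qui = aq.findtext("QualifierReferredTo/QualifierUI", "").strip()
            qname = aq.findtext("QualifierReferredTo/QualifierName/String", "").strip()
            if qui:
                allowed.append(qui)
                if qui not in th.qualifiers and qname:
                    # minimal stub when the file carries no QualifierRecord
                    th.add(Qualifier(ui=qui, labels={PIVOT_LANGUAGE: qname}))
        d = Descriptor(
            ui=ui,
            kind=kind,
            labels={PIVOT_LANGUAGE: name},
            tree_numbers=trees,
            allowed_qualifiers=allowed,
        )
        if syns:
            d.synonyms[PIVOT_LANGUAGE] = syns
        note = rec.findtext("ScopeNote")
        if note and note.strip():
            d.definition[PIVOT_LANGUAGE] = note.strip()
        th.add(d)

    th.validate()
    return th


def write_mesh_xml(thesaurus: Thesaurus, path: Union[str, Path]) -> None:
    """Serialize the English layer of a thesaurus to the XML subset."""
    root = ET.Element("DescriptorRecordSet")
    for q in sorted(thesaurus.qualifiers.values(), key=lambda r: r.ui):
        el = ET.SubElement(root, "QualifierRecord")
        ET.SubElement(el, "QualifierUI").text = q.ui
        name = ET.SubElement(ET.SubElement(el, "QualifierName"), "String")
        name.text = q.labels[PIVOT_LANGUAGE]
        if q.tree_numbers:
            tl = ET.SubElement(el, "TreeNumberList")
            for tn in q.tree_numbers:
                ET.SubElement(tl, "TreeNumber").text = tn
        if q.synonyms.get(PIVOT_LANGUAGE):
            tl = ET.SubElement(el, "TermList")
            for syn in q.synonyms[PIVOT_LANGUAGE]:
                ET.SubElement(ET.SubElement(tl, "Term"), "String").text = syn
    for d in sorted(thesaurus.descriptors.values(), key=lambda r: r.ui):
        el = ET.SubElement(root, "DescriptorRecord")
        if d.kind is RecordKind.PUBLICATION_TYPE:
            el.set("DescriptorClass", "2")
        ET.SubElement(el, "DescriptorUI").text = d.ui
        name = ET.SubElement(ET.SubElement(el, "DescriptorName"), "String")
        name.text = d.labels[PIVOT_LANGUAGE]
        if d.tree_numbers:
            tl = ET.SubElement(el, "TreeNumberList")
            for tn in d.tree_numbers:
                ET.SubElement(tl, "TreeNumber").text = tn
        if d.synonyms.get(PIVOT_LANGUAGE):
            cl = ET.SubElement(
                ET.SubElement(ET.SubElement(el, "ConceptList"), "Concept"), "TermList"
            )
            for syn in [d.labels[PIVOT_LANGUAGE]] + d.synonyms[PIVOT_LANGUAGE]:
                ET.SubElement(ET.SubElement(cl, "Term"), "String").text = syn
        if d.allowed_qualifiers:
            al = ET.SubElement(el, "AllowableQualifierList")
            for qui in d.allowed_qualifiers:
                ref = ET.SubElement(
                    ET.SubElement(al, "AllowableQualifier"), "QualifierReferredTo"
                )
                ET.SubElement(ref, "QualifierUI").text = qui
                qn = ET.SubElement(ET.SubElement(ref, "QualifierName"), "String")
                qn.text = thesaurus.qualifiers[qui].labels[PIVOT_LANGUAGE]
        if d.definition.get(PIVOT_LANGUAGE):
            ET.SubElement(el, "ScopeNote").text = d.definition[PIVOT_LANGUAGE]
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="utf-8", xml_declaration=True)


# ---------------------------------------------------------------------------
# Translation tables: UTF-8 TSV ``ui<TAB>label<TAB>syn1|syn2...``, one
# language per file, applying to descriptors and qualifiers alike.
# ---------------------------------------------------------------------------


def load_translations(
    thesaurus: Thesaurus, path: Union[str, Path], language: str
) -> Thesaurus:
    """Layer one language's labels/synonyms onto an existing thesaurus.

    Idempotent: re-loading the same file changes nothing; synonyms are
    de-duplicated and a synonym equal to the preferred label is dropped.
    Rows naming unknown UIs abort with an :class:`IntegrityError` listing
    them (the thesaurus is left unmodified in that case).
    """
    path = Path(path)
    rows: list[tuple[str, str, list[str]]] = []
    bad: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                bad.append(f"line {lineno}: expected at least 2 tab-separated fields")
                continue
            ui, label = parts[0].strip(), parts[1].strip()
            syns = [s.strip() for s in parts[2].split("|") if s.strip()] if len(parts) > 2 else []
            if ui not in thesaurus.descriptors and ui not in thesaurus.qualifiers:
                bad.append(f"line {lineno}: unknown UI {ui!r}")
                continue
            rows.append((ui, label, syns))
    if bad:
        raise IntegrityError(f"{path}: " + "; ".join(bad))
    for ui, label, syns in rows:
        rec = thesaurus.resolve(ui)
        rec.labels[language] = label
        if syns:
            existing = rec.synonyms.setdefault(language, [])
            for syn in syns:
                if syn != label and syn not in existing:
                    existing.append(syn)
    thesaurus._index_cache.clear()
    thesaurus.validate()
    return thesaurus


def write_translations(
    thesaurus: Thesaurus, language: str, path: Union[str, Path]
) -> None:
    """Write one language's labels/synonyms as a translation TSV."""
    lines = []
    for rec in sorted(
        list(thesaurus.descriptors.values()) + list(thesaurus.qualifiers.values()),
        key=lambda r: r.ui,
    ):
        label = rec.labels.get(language)
        syns = rec.synonyms.get(language, [])
        if label is None and not syns:
            continue
        lines.append("\t".join([rec.ui, label or "", "|".join(syns)]).rstrip("\t"))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
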