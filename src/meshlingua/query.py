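"""Boolean query AST over MeSH terms, with a PubMed-dialect parser/serializer.

Grammar accepted by :func:`parse`:

* terms are ``label`` or ``label/qualifier-label``, resolved against the
  thesaurus in the requested language (labels may be quoted and may carry
  a bracketed search tag, as in the serialized form);
* operators ``AND``/``OR``/``NOT`` (case-insensitive); AND binds tighter
  than OR, parentheses override; adjacent terms imply AND (as PubMed does);
* labels that do not resolve become free-text nodes.

Because qualifier names such as "prevention and control" legitimately
contain the word *and*, bare (unquoted) terms are resolved by greedy
longest match against the thesaurus: the longest span of words (possibly
crossing lowercase operator words) that resolves as ``label`` or
``label/qualifier`` wins; only then are remaining operator words treated
as Boolean operators.

Serialized dialect (bit-exact): ``"label"[MeSH Terms]``, qualified terms
``"label/qualifier"[MeSH Terms]``, non-exploded ``[MeSH Terms:noexp]``,
publication types ``"label"[Publication Type]``, free text
``text[Title/Abstract]``; operators uppercase with single spaces;
children that are themselves Boolean nodes are parenthesized.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Union

from .thesaurus import IntegrityError, RecordKind, Thesaurus


class FieldTag(str, Enum):
    MESH_TERMS = "MeSH Terms"
    PUBLICATION_TYPE = "Publication Type"
    TITLE_ABSTRACT = "Title/Abstract"
    ALL_FIELDS = "All Fields"


@dataclass(frozen=True)
class TermNode:
    """A controlled-vocabulary term: descriptor plus optional subheading."""

    descriptor_ui: str
    qualifier_ui: Optional[str] = None
    explode: bool = True
    field_tag: FieldTag = FieldTag.MESH_TERMS


@dataclass(frozen=True)
class FreeTextNode:
    text: str
    field_tag: FieldTag = FieldTag.TITLE_ABSTRACT


@dataclass(frozen=True)
class BoolNode:
    operator: str  # "AND" | "OR" | "NOT"
    children: tuple["QueryNode", ...]

    def __post_init__(self) -> None:
        if self.operator not in ("AND", "OR", "NOT"):
            raise ValueError(f"unknown operator {self.operator!r}")
        if self.operator == "NOT" and len(self.children) != 2:
            raise ValueError("NOT takes exactly two children")
        if self.operator != "NOT" and len(self.children) < 2:
            raise ValueError(f"{self.operator} needs at least two children")


QueryNode = Union[TermNode, FreeTextNode, BoolNode]


class IssueKind(str, Enum):
    UNMATCHED_BRACKET = "unmatched_bracket"
    UNMATCHED_QUOTE = "unmatched_quote"
    TRUNCATED_WORD = "truncated_word"
    DANGLING_OPERATOR = "dangling_operator"
    EMPTY_QUERY = "empty_query"


@dataclass(frozen=True)
class SyntaxIssue:
    kind: IssueKind
    position: int


class QuerySyntaxError(ValueError):
    """Strict-mode parse failure; carries the list of syntax issues."""

    def __init__(self, issues: list[SyntaxIssue]):
        self.issues = issues
        super().__init__(", ".join(f"{i.kind.value}@{i.position}" for i in issues))


_OPERATORS = {"and": "AND", "or": "OR", "not": "NOT"}

_TOKEN_RE = re.compile(
    r"""(?P<ws>\s+)
      | (?P<quote>"(?P<qcontent>[^"]*)")
      | (?P<tag>\[(?P<tagname>[^\]]*)\])
      | (?P<lpar>\()
      | (?P<rpar>\))
      | (?P<slash>/)
      | (?P<word>[^\s()\[\]"/]+)
    """,
    re.X,
)


@dataclass(frozen=True)
class _Token:
    type: str
    value: str
    pos: int


def _tokenize(text: str) -> list[_Token]:
    tokens = []
    for m in _TOKEN_RE.finditer(text):
        kind = m.lastgroup
        if kind == "ws":
            continue
        if kind == "quote":
            tokens.append(_Token("quote", m.group("qcontent"), m.start()))
        elif kind == "tag":
            tokens.append(_Token("tag", m.group("tagname"), m.start()))
        else:
            tokens.append(_Token(kind, m.group(), m.start()))
    return tokens


# ---------------------------------------------------------------------------
# syntax validation (total function)
# ---------------------------------------------------------------------------


def validate_syntax(text: str) -> list[SyntaxIssue]:
    """Scan for the syntax defects of the error taxonomy.

    Returns an empty list iff the text parses under the grammar; issues are
    reported left-to-right.  Checked: unmatched round/square brackets,
    unmatched quotes, truncated (wildcard ``*``) words, dangling Boolean
    operators, and the empty query.
    """
    issues: list[SyntaxIssue] = []
    if not text.strip():
        return [SyntaxIssue(IssueKind.EMPTY_QUERY, 0)]

    # quotes: pair double quotes left to right
    quote_positions = [i for i, ch in enumerate(text) if ch == '"']
    if len(quote_positions) % 2:
        issues.append(SyntaxIssue(IssueKind.UNMATCHED_QUOTE, quote_positions[-1]))

    # brackets outside quoted spans
    in_quote = False
    stack: list[tuple[str, int]] = []
    for i, ch in enumerate(text):
        if ch == '"':
            in_quote = not in_quote
            continue
        if in_quote:
            continue
        if ch in "([":
            stack.append((ch, i))
        elif ch in ")]":
            want = "(" if ch == ")" else "["
            if stack and stack[-1][0] == want:
                stack.pop()
            else:
                issues.append(SyntaxIssue(IssueKind.UNMATCHED_BRACKET, i))
    for _, i in stack:
        issues.append(SyntaxIssue(IssueKind.UNMATCHED_BRACKET, i))

    for m in re.finditer(r"\*", text):
        issues.append(SyntaxIssue(IssueKind.TRUNCATED_WORD, m.start()))

    # dangling operators: operator at start/end, doubled, or against a paren
    tokens = _tokenize(text)
    kinds = []
    for t in tokens:
        if t.type == "word" and t.value.casefold() in _OPERATORS:
            kinds.append(("op", t.pos))
        elif t.type == "lpar":
            kinds.append(("lpar", t.pos))
        elif t.type == "rpar":
            kinds.append(("rpar", t.pos))
        elif t.type == "tag":
            continue  # tags attach to the preceding term
        else:
            kinds.append(("term", t.pos))
    for i, (k, pos) in enumerate(kinds):
        if k != "op":
            continue
        prev = kinds[i - 1][0] if i > 0 else None
        nxt = kinds[i + 1][0] if i + 1 < len(kinds) else None
        if prev in (None, "op", "lpar") or nxt in (None, "op", "rpar"):
            issues.append(SyntaxIssue(IssueKind.DANGLING_OPERATOR, pos))

    return sorted(issues, key=lambda s: (s.position, s.kind.value))


def repair(text: str) -> str:
    """Best-effort repair used by tolerant parsing.

    Strips wildcards, drops unmatched closers, closes unmatched quotes and
    brackets, and removes dangling operators, so that a query carrying both
    syntax and term errors can still be graded on its terms.
    """
    text = text.replace("*", "")
    if text.count('"') % 2:
        text = text + '"'
    # drop unmatched closers / close unmatched openers, outside quotes
    out = []
    depth = {"(": 0, "[": 0}
    in_quote = False
    for ch in text:
        if ch == '"':
            in_quote = not in_quote
            out.append(ch)
            continue
        if not in_quote:
            if ch in "([":
                depth[ch] += 1
            elif ch == ")":
                if depth["("] == 0:
                    continue
                depth["("] -= 1
            elif ch == "]":
                if depth["["] == 0:
                    continue
                depth["["] -= 1
        out.append(ch)
    text = "".join(out) + ")" * depth["("] + "]" * depth["["]

    # drop dangling operators until stable
    while True:
        dangling = [i for i in validate_syntax(text) if i.kind is IssueKind.DANGLING_OPERATOR]
        if not dangling:
            break
        pos = dangling[0].position
        m = re.match(r"\S+", text[pos:])
        text = text[:pos] + text[pos + m.end():]
    return text


# ---------------------------------------------------------------------------
# parser
# ---------------------------------------------------------------------------


_TAG_MAP = {
    "mesh terms": FieldTag.MESH_TERMS,
    "mh": FieldTag.MESH_TERMS,
    "publication type": FieldTag.PUBLICATION_TYPE,
    "pt": FieldTag.PUBLICATION_TYPE,
    "title/abstract": FieldTag.TITLE_ABSTRACT,
    "tiab": FieldTag.TITLE_ABSTRACT,
    "all fields": FieldTag.ALL_FIELDS,
    "all": FieldTag.ALL_FIELDS,
}


class _Parser:
    def __init__(self, tokens: list[_Token], thesaurus: Thesaurus, language: str):
        self.tokens = tokens
        self.i = 0
        self.th = thesaurus
        self.lang = language

    def peek(self) -> Optional[_Token]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _is_op(self, tok: Optional[_Token]) -> Optional[str]:
        if tok is not None and tok.type == "word":
            return _OPERATORS.get(tok.value.casefold())
        return None

    def parse(self) -> QueryNode:
        node = self._or()
        if self.peek() is not None:
            raise QuerySyntaxError(
                [SyntaxIssue(IssueKind.UNMATCHED_BRACKET, self.peek().pos)]
            )
        return node

    def _or(self) -> QueryNode:
        parts = [self._and()]
        while self._is_op(self.peek()) == "OR":
            self.i += 1
            parts.append(self._and())
        return parts[0] if len(parts) == 1 else BoolNode("OR", tuple(parts))

    def _and(self) -> QueryNode:
        current = self._primary()
        and_run: list[QueryNode] = [current]
        while True:
            tok = self.peek()
            op = self._is_op(tok)
            if op == "AND":
                self.i += 1
                and_run.append(self._primary())
            elif op == "NOT":
                self.i += 1
                left = and_run[0] if len(and_run) == 1 else BoolNode("AND", tuple(and_run))
                right = self._primary()
                and_run = [BoolNode("NOT", (left, right))]
            elif tok is not None and tok.type in ("word", "quote", "lpar") and op is None:
                # juxtaposition: implicit AND
                and_run.append(self._primary())
            else:
                break
        return and_run[0] if len(and_run) == 1 else BoolNode("AND", tuple(and_run))

    def _primary(self) -> QueryNode:
        tok = self.peek()
        if tok is None:
            raise QuerySyntaxError([SyntaxIssue(IssueKind.DANGLING_OPERATOR, 0)])
        if tok.type == "lpar":
            self.i += 1
            node = self._or()
            nxt = self.peek()
            if nxt is None or nxt.type != "rpar":
                raise QuerySyntaxError([SyntaxIssue(IssueKind.UNMATCHED_BRACKET, tok.pos)])
            self.i += 1
            return node
        if tok.type == "quote":
            self.i += 1
            return self._tagged_unit(tok.value)
        if tok.type == "word":
            return self._bare_term()
        raise QuerySyntaxError([SyntaxIssue(IssueKind.UNMATCHED_BRACKET, tok.pos)])

    def _consume_tag(self) -> tuple[Optional[FieldTag], bool]:
        """Optional bracketed search tag after a term; returns (tag, explode)."""
        tok = self.peek()
        if tok is None or tok.type != "tag":
            return None, True
        self.i += 1
        name = tok.value.strip()
        explode = True
        if name.casefold().endswith(":noexp"):
            explode = False
            name = name[: -len(":noexp")]
        return _TAG_MAP.get(name.strip().casefold()), explode

    def _tagged_unit(self, content: str) -> QueryNode:
        tag, explode = self._consume_tag()
        if tag in (FieldTag.TITLE_ABSTRACT, FieldTag.ALL_FIELDS):
            return FreeTextNode(content, tag)
        node = self._resolve_term(content, explode)
        if node is not None:
            return node
        return FreeTextNode(content, tag or FieldTag.TITLE_ABSTRACT)

    def _resolve_term(self, text: str, explode: bool = True) -> Optional[TermNode]:
        """Resolve ``label`` or ``label/qualifier-label``; None if unresolvable."""
        head, slash, tail = text.partition("/")
        if slash and tail.strip():
            d = self.th.lookup_label(head, self.lang, kind="descriptor")
            q = self.th.lookup_label(tail, self.lang, kind="qualifier")
            if d is not None and q is not None and d.kind is not RecordKind.PUBLICATION_TYPE:
                return TermNode(d.ui, q.ui, explode=explode)
            return None
        d = self.th.lookup_label(text, self.lang, kind="descriptor")
        if d is None:
            return None
        if d.kind is RecordKind.PUBLICATION_TYPE:
            return TermNode(d.ui, field_tag=FieldTag.PUBLICATION_TYPE)
        return TermNode(d.ui, explode=explode)

    def _bare_term(self) -> QueryNode:
        """Greedy longest-match resolution of an unquoted term.

        Spans may cross operator words (qualifier names contain "and");
        the longest resolvable span wins.  If nothing resolves, words up
        to the next operator become a free-text node.
        """
        start = self.i
        run_end = start
        while run_end < len(self.tokens) and self.tokens[run_end].type in ("word", "slash"):
            run_end += 1

        # unquoted tagged free text, e.g. ``some words[Title/Abstract]``
        if run_end < len(self.tokens) and self.tokens[run_end].type == "tag":
            span = self._span_text(start, run_end)
            self.i = run_end
            return self._tagged_unit(span)

        for end in range(run_end, start, -1):
            span = self._span_text(start, end)
            node = self._resolve_term(span)
            if node is not None:
                self.i = end
                return node

        # fallback: free text up to the next operator word
        end = start
        words = []
        while end < run_end:
            tok = self.tokens[end]
            if self._is_op(tok):
                break
            words.append("/" if tok.type == "slash" else tok.value)
            end += 1
        self.i = end
        return FreeTextNode(re.sub(r"\s*/\s*", "/", " ".join(words)))

    def _span_text(self, start: int, end: int) -> str:
        parts = []
        for tok in self.tokens[start:end]:
            parts.append("/" if tok.type == "slash" else tok.value)
        return re.sub(r"\s*/\s*", "/", " ".join(parts))


def parse(
    text: str,
    thesaurus: Thesaurus,
    language: str = "en",
    tolerant: bool = False,
) -> QueryNode:
    """Parse a query string into an AST.

    In strict mode (default) any syntax issue raises
    :class:`QuerySyntaxError` carrying the issue list.  In tolerant mode
    the text is repaired first (wildcards stripped, brackets/quotes
    closed, dangling operators dropped) so term content can still be
    extracted and graded.
    """
    issues = validate_syntax(text)
    if issues:
        if not tolerant:
            raise QuerySyntaxError(issues)
        text = repair(text)
        if not text.strip():
            raise QuerySyntaxError([SyntaxIssue(IssueKind.EMPTY_QUERY, 0)])
    return _Parser(_tokenize(text), thesaurus, language).parse()


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def serialize(node: QueryNode, thesaurus: Thesaurus) -> str:
    """Emit the PubMed dialect for an AST (see module docstring)."""
    if isinstance(node, TermNode):
        try:
            d = thesaurus.descriptors[node.descriptor_ui]
        except KeyError:
            raise IntegrityError(f"unknown descriptor UI {node.descriptor_ui!r}")
        label = d.labels["en"].lower()
        if node.qualifier_ui is not None:
            try:
                q = thesaurus.qualifiers[node.qualifier_ui]
            except KeyError:
                raise IntegrityError(f"unknown qualifier UI {node.qualifier_ui!r}")
            label = f"{label}/{q.labels['en'].lower()}"
        if d.kind is RecordKind.PUBLICATION_TYPE:
            tag = FieldTag.PUBLICATION_TYPE.value
        else:
            tag = FieldTag.MESH_TERMS.value
            if not node.explode:
                tag += ":noexp"
        return f'"{label}"[{tag}]'
    if isinstance(node, FreeTextNode):
        text = node.text
        needs_quotes = bool(re.search(r'[()\[\]"/]', text)) or any(
            w.casefold() in _OPERATORS for w in text.split()
        )
        body = f'"{text}"' if needs_quotes else text
        return f"{body}[{node.field_tag.value}]"
    parts = []
    for child in node.children:
        s = serialize(child, thesaurus)
        parts.append(f"({s})" if isinstance(child, BoolNode) else s)
    return f" {node.operator} ".join(parts)


# ---------------------------------------------------------------------------
# synonym expansion
# ---------------------------------------------------------------------------


def expand_synonyms(node: QueryNode, thesaurus: Thesaurus) -> QueryNode:
    """Complete a query with entry-term synonyms to maximize recall.

    Every *unqualified* term node whose descriptor has pivot-language
    synonyms becomes ``OR(term, synonym-free-text, ...)``; qualified terms
    are left untouched (a subheading restricts meaning in a way free text
    cannot express).  The set of MeSH-tagged terms is conserved.
    """
    if isinstance(node, TermNode):
        if node.qualifier_ui is not None:
            return node
        d = thesaurus.descriptors[node.descriptor_ui]
        syns = d.synonyms.get("en", [])
        if not syns:
            return node
        children: tuple[QueryNode, ...] = (node,) + tuple(
            FreeTextNode(s) for s in syns
        )
        return BoolNode("OR", children)
    if isinstance(node, BoolNode):
        return replace(node, children=tuple(expand_synonyms(c, thesaurus) for c in node.children))
    return node
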