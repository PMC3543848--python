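"""Ovid-dialect boolean query engine over a local corpus.

Implements the query language used by search-interface strategies for
bibliographic databases: term patterns with truncation (``*``) and wildcards
(``?`` zero-or-one character, ``#`` exactly one), quoted/unquoted phrases
(exact in-order adjacency), the boolean operators OR / AND / NOT, the
proximity operator ``adjN`` (two term patterns within N words of each other,
either order, same field), trailing field codes (``.af. .mp. .ab. .ti.
.ab,ti. .sh.``) and strategy line references (``or/1-31``).

Operator precedence, tightest first: adjN, AND, NOT, OR; parentheses
override.  Matching is case-insensitive and hyphen-insensitive: document
text is tokenized on any non-alphanumeric character, so "off-label"
tokenizes as ``["off", "label"]``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

from .corpus import Corpus, DocumentRecord

__all__ = [
    "QueryNode",
    "TermPattern",
    "Adj",
    "And",
    "Or",
    "Not",
    "FieldScope",
    "LineRef",
    "RetrievalSet",
    "Strategy",
    "StrategyLineResult",
    "ParseError",
    "EvaluationError",
    "parse_query",
    "serialize",
    "evaluate",
    "evaluate_strategy",
    "tokenize",
    "FIELD_CODES",
]

FIELD_CODES = ("af", "mp", "ab", "ti", "ab,ti", "sh")

#: searchable-field hierarchy: af ⊇ mp ⊇ ab,ti ⊇ {ab, ti}; sh is heading-only
_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase and split on any non-alphanumeric character."""
    return _TOKEN_RE.findall(text.lower())


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TermPattern:
    """A phrase of pattern tokens matched by exact in-order adjacency."""

    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("empty term pattern")


@dataclass(frozen=True)
class Adj:
    """Proximity: children within ``distance`` words (≤ distance−1 intervening)."""

    distance: int
    left: "QueryNode"
    right: "QueryNode"

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError("adj distance must be ≥ 1")
        for child in (self.left, self.right):
            if not isinstance(child, (TermPattern, Adj)):
                raise ValueError("adj operands must be term patterns or adj chains")


@dataclass(frozen=True)
class And:
    children: tuple["QueryNode", ...]


@dataclass(frozen=True)
class Or:
    children: tuple["QueryNode", ...]


@dataclass(frozen=True)
class Not:
    keep: "QueryNode"
    exclude: "QueryNode"


@dataclass(frozen=True)
class FieldScope:
    code: str
    child: "QueryNode"

    def __post_init__(self) -> None:
        if self.code not in FIELD_CODES:
            raise ValueError(f"unknown field code {self.code!r}")


@dataclass(frozen=True)
class LineRef:
    """Reference to earlier strategy lines: ``or/a-b`` is their union."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid line reference or/{self.start}-{self.end}")


QueryNode = Union[TermPattern, Adj, And, Or, Not, FieldScope, LineRef]


class ParseError(ValueError):
    def __init__(self, message: str, position: int | None = None):
        self.position = position
        suffix = f" (at position {position})" if position is not None else ""
        super().__init__(message + suffix)


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Lexer
# ---------------------------------------------------------------------------

_FIELD_LEX = re.compile(r"\.(af|mp|ab,ti|ab|ti|sh)\.")
_LINEREF_LEX = re.compile(r"or/(\d+)(?:-(\d+))?")
# '*' terminates a word token (truncation is trailing); '?'/'#' are in-word wildcards
_WORD_LEX = re.compile(r"[a-z0-9?#]+\*?|\*")
_ADJ_WORD = re.compile(r"adj(\d+)?\Z")


@dataclass(frozen=True)
class _Tok:
    kind: str  # LPAREN RPAREN FIELD WORD QUOTED OR AND NOT ADJ LINEREF
    value: object
    pos: int


def _lex(text: str) -> list[_Tok]:
    s = text.lower()
    toks: list[_Tok] = []
    i, n = 0, len(s)
    while i < n:
        ch = s[i]
        if ch.isspace() or ch == ",":
            i += 1
            continue
        if ch == "(":
            toks.append(_Tok("LPAREN", "(", i))
            i += 1
            continue
        if ch == ")":
            toks.append(_Tok("RPAREN", ")", i))
            i += 1
            continue
        if ch == '"':
            j = s.find('"', i + 1)
            if j < 0:
                raise ParseError("unterminated quote", i)
            inner = s[i + 1 : j]
            toks.append(_Tok("QUOTED", tuple(_WORD_LEX.findall(inner)), i))
            i = j + 1
            continue
        if ch == ".":
            m = _FIELD_LEX.match(s, i)
            if not m:
                raise ParseError(f"unknown field code near {s[i:i+8]!r}", i)
            toks.append(_Tok("FIELD", m.group(1), i))
            i = m.end()
            continue
        m = _LINEREF_LEX.match(s, i)
        if m and (m.end() == n or not s[m.end()].isalnum()):
            a = int(m.group(1))
            b = int(m.group(2)) if m.group(2) else a
            toks.append(_Tok("LINEREF", (a, b), i))
            i = m.end()
            continue
        m = _WORD_LEX.match(s, i)
        if m:
            word = m.group(0)
            if word == "or":
                toks.append(_Tok("OR", word, i))
            elif word == "and":
                toks.append(_Tok("AND", word, i))
            elif word == "not":
                toks.append(_Tok("NOT", word, i))
            elif _ADJ_WORD.match(word):
                dist = int(word[3:]) if len(word) > 3 else 1
                toks.append(_Tok("ADJ", dist, i))
            else:
                toks.append(_Tok("WORD", word, i))
            i = m.end()
            continue
        raise ParseError(f"unexpected character {s[i]!r}", i)
    return toks


# ---------------------------------------------------------------------------
# Parser (recursive descent; precedence OR < NOT < AND < ADJ < adjacency)
# ---------------------------------------------------------------------------


class _Parser:
    def __init__(self, toks: list[_Tok], text: str):
        self.toks = toks
        self.text = text
        self.i = 0

    def peek(self) -> Optional[_Tok]:
        return self.toks[self.i] if self.i < len(self.toks) else None

    def next(self) -> _Tok:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of query", len(self.text))
        self.i += 1
        return tok

    def expect(self, kind: str) -> _Tok:
        tok = self.peek()
        if tok is None or tok.kind != kind:
            pos = tok.pos if tok else len(self.text)
            raise ParseError(f"expected {kind}", pos)
        return self.next()

    def parse(self) -> QueryNode:
        node = self.or_expr()
        if self.peek() is not None:
            raise ParseError("trailing tokens after query", self.peek().pos)
        return node

    def or_expr(self) -> QueryNode:
        children = [self.not_expr()]
        while (tok := self.peek()) and tok.kind == "OR":
            self.next()
            children.append(self.not_expr())
        if len(children) == 1:
            return children[0]
        flat: list[QueryNode] = []
        for c in children:  # flatten so serialization round-trips structurally
            flat.extend(c.children if isinstance(c, Or) else (c,))
        return Or(tuple(flat))

    def not_expr(self) -> QueryNode:
        node = self.and_expr()
        while (tok := self.peek()) and tok.kind == "NOT":
            self.next()
            node = Not(node, self.and_expr())
        return node

    def and_expr(self) -> QueryNode:
        children = [self.adj_expr()]
        while (tok := self.peek()) and tok.kind == "AND":
            self.next()
            children.append(self.adj_expr())
        if len(children) == 1:
            return children[0]
        flat: list[QueryNode] = []
        for c in children:
            flat.extend(c.children if isinstance(c, And) else (c,))
        return And(tuple(flat))

    def adj_expr(self) -> QueryNode:
        node = self.operand()
        while (tok := self.peek()) and tok.kind == "ADJ":
            self.next()
            right = self.operand()
            for side in (node, right):
                if not isinstance(side, (TermPattern, Adj)):
                    raise ParseError("adj operands must be term-like", tok.pos)
            node = Adj(int(tok.value), node, right)
        return node

    def operand(self) -> QueryNode:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of query", len(self.text))
        if tok.kind == "LPAREN":
            self.next()
            node = self.or_expr()
            self.expect("RPAREN")
        elif tok.kind == "LINEREF":
            self.next()
            a, b = tok.value
            node = LineRef(a, b)
        elif tok.kind in ("WORD", "QUOTED"):
            node = self.phrase()
        else:
            raise ParseError(f"unexpected token {tok.value!r}", tok.pos)
        if (nxt := self.peek()) and nxt.kind == "FIELD":
            self.next()
            node = FieldScope(nxt.value, node)
        return node

    def phrase(self) -> TermPattern:
        parts: list[str] = []
        while (tok := self.peek()) and tok.kind in ("WORD", "QUOTED"):
            self.next()
            if tok.kind == "WORD":
                parts.append(tok.value)
            else:
                parts.extend(tok.value)
        if not parts:
            raise ParseError("empty phrase", self.peek().pos if self.peek() else None)
        return TermPattern(tuple(parts))


def parse_query(text: str) -> QueryNode:
    """Parse an Ovid-dialect query string into an expression tree."""
    if not text or not text.strip():
        raise ParseError("empty query")
    return _Parser(_lex(text), text).parse()


# ---------------------------------------------------------------------------
# Serialization (canonical dialect text; parse(serialize(n)) == n)
# ---------------------------------------------------------------------------

_PREC = {Or: 1, Not: 2, And: 3, Adj: 4}


def _prec(node: QueryNode) -> int:
    return _PREC.get(type(node), 5)


def serialize(node: QueryNode) -> str:
    return _serialize(node, 0)


def _serialize(node: QueryNode, parent_prec: int) -> str:
    if isinstance(node, TermPattern):
        out = " ".join(node.tokens)
    elif isinstance(node, Adj):
        out = (
            f"{_serialize(node.left, 4)} adj{node.distance} {_serialize(node.right, 5)}"
        )
    elif isinstance(node, And):
        out = " and ".join(_serialize(c, 4) for c in node.children)
    elif isinstance(node, Not):
        out = f"{_serialize(node.keep, 2)} not {_serialize(node.exclude, 3)}"
    elif isinstance(node, Or):
        out = " or ".join(_serialize(c, 2) for c in node.children)
    elif isinstance(node, LineRef):
        out = f"or/{node.start}-{node.end}"
    elif isinstance(node, FieldScope):
        inner = serialize(node.child)
        if not isinstance(node.child, TermPattern):
            inner = f"({inner})"
        return f"{inner}.{node.code}." if parent_prec <= 5 else f"({inner}.{node.code}.)"
    else:  # pragma: no cover
        raise TypeError(f"unknown node {node!r}")
    if _prec(node) < parent_prec:
        out = f"({out})"
    return out


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RetrievalSet:
    """Documents retrieved by one query (or strategy line) from one corpus."""

    query_label: str
    doc_ids: frozenset[str]

    def __len__(self) -> int:
        return len(self.doc_ids)


@lru_cache(maxsize=4096)
def _compile_token(tok: str) -> re.Pattern:
    out = []
    for ch in tok:
        if ch == "*":
            out.append("[a-z0-9]*")  # unlimited trailing truncation
        elif ch == "?":
            out.append("[a-z0-9]?")  # zero or one character
        elif ch == "#":
            out.append("[a-z0-9]")  # exactly one character
        else:
            out.append(re.escape(ch))
    return re.compile("".join(out))


class _DocView:
    """Tokenized searchable fields of one record, grouped by field code."""

    __slots__ = ("fields", "headings")

    def __init__(self, rec: DocumentRecord):
        title = tokenize(rec.title)
        abstract = tokenize(rec.abstract)
        self.headings = [tokenize(h) for h in rec.subject_headings]
        mp = [title, abstract, *self.headings]
        af = mp + [tokenize(rec.pub_type)] + [tokenize(a) for a in rec.accessions]
        self.fields: dict[str, list[list[str]]] = {
            "ti": [title],
            "ab": [abstract],
            "ab,ti": [abstract, title],
            "mp": mp,
            "af": af,
            "sh": self.headings,
        }


def _pattern_spans(tokens: Sequence[str], pattern: TermPattern) -> list[tuple[int, int]]:
    pats = [_compile_token(t) for t in pattern.tokens]
    k = len(pats)
    spans = []
    for i in range(len(tokens) - k + 1):
        if all(p.fullmatch(tokens[i + j]) for j, p in enumerate(pats)):
            spans.append((i, i + k - 1))
    return spans


def _node_spans(
    node: QueryNode, tokens: Sequence[str], in_order: bool
) -> list[tuple[int, int]]:
    if isinstance(node, TermPattern):
        return _pattern_spans(tokens, node)
    if isinstance(node, Adj):
        left = _node_spans(node.left, tokens, in_order)
        if not left:
            return []
        right = _node_spans(node.right, tokens, in_order)
        spans = set()
        for ls, le in left:
            for rs, rte in right:
                if le < rs:
                    gap = rs - le - 1
                elif rte < ls and not in_order:
                    gap = ls - rte - 1
                elif rte >= ls and le >= rs:  # overlapping occurrences
                    continue
                else:
                    continue
                if gap <= node.distance - 1:
                    spans.add((min(ls, rs), max(le, rte)))
        return sorted(spans)
    raise EvaluationError(f"cannot compute spans for {type(node).__name__}")


def _term_matches(node: QueryNode, view: _DocView, scope: str, in_order: bool) -> bool:
    if scope == "sh":
        # a heading matches only as a whole string
        for heading in view.headings:
            if any(
                (s, e) == (0, len(heading) - 1)
                for (s, e) in _node_spans(node, heading, in_order)
            ):
                return True
        return False
    return any(_node_spans(node, toks, in_order) for toks in view.fields[scope])


def evaluate(
    node: QueryNode,
    corpus: Corpus,
    context: Mapping[int, frozenset[str]] | None = None,
    *,
    label: str | None = None,
    default_scope: str = "mp",
    adj_in_order: bool = False,
) -> RetrievalSet:
    """Evaluate a query tree against a corpus; return the retrieved ids.

    ``context`` maps strategy line numbers to already-evaluated retrieval
    sets, consumed by :class:`LineRef` nodes.  A bare pattern without a field
    code searches ``default_scope`` (the interface default is the
    multi-purpose title/abstract/headings scope).
    """
    views = {rec.doc_id: _DocView(rec) for rec in corpus.records}
    ids = _evaluate_sets(node, corpus, views, context or {}, default_scope, adj_in_order)
    return RetrievalSet(query_label=label or serialize(node), doc_ids=frozenset(ids))


def _evaluate_sets(
    node: QueryNode,
    corpus: Corpus,
    views: dict[str, _DocView],
    context: Mapping[int, frozenset[str]],
    scope: str,
    in_order: bool,
) -> set[str]:
    if isinstance(node, FieldScope):
        return _evaluate_sets(node.child, corpus, views, context, node.code, in_order)
    if isinstance(node, Or):
        out: set[str] = set()
        for c in node.children:
            out |= _evaluate_sets(c, corpus, views, context, scope, in_order)
        return out
    if isinstance(node, And):
        sets = [_evaluate_sets(c, corpus, views, context, scope, in_order) for c in node.children]
        return set.intersection(*sets)
    if isinstance(node, Not):
        keep = _evaluate_sets(node.keep, corpus, views, context, scope, in_order)
        drop = _evaluate_sets(node.exclude, corpus, views, context, scope, in_order)
        return keep - drop
    if isinstance(node, LineRef):
        out = set()
        for line in range(node.start, node.end + 1):
            if line not in context:
                raise EvaluationError(f"unresolved line reference or/{node.start}-{node.end}")
            out |= context[line]
        return out
    # TermPattern / Adj: scan documents
    return {
        doc_id for doc_id, view in views.items() if _term_matches(node, view, scope, in_order)
    }


# ---------------------------------------------------------------------------
# Strategies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Strategy:
    """An ordered, numbered list of query lines; later lines may reference
    earlier ones (``or/1-31``)."""

    lines: tuple[tuple[int, str], ...]
    name: str = "strategy"

    def __post_init__(self) -> None:
        numbers = [n for n, _ in self.lines]
        if numbers != list(range(1, len(numbers) + 1)):
            raise ValueError(f"strategy line numbers must be dense from 1, got {numbers}")

    @classmethod
    def from_queries(cls, queries: Iterable[str], name: str = "strategy") -> "Strategy":
        return cls(tuple(enumerate(queries, start=1)), name=name)

    @classmethod
    def from_text(cls, text: str, name: str = "strategy") -> "Strategy":
        """Load from plain text: one numbered query per line, ``#`` comments."""
        lines: list[str] = []
        for raw in text.splitlines():
            stripped = raw.strip()
            if not stripped or stripped.startswith("#"):
                continue
            m = re.match(r"^(\d+)[.)]?\s+(.*)$", stripped)
            lines.append(m.group(2) if m else stripped)
        return cls.from_queries(lines, name=name)

    @classmethod
    def from_file(cls, path: str | Path) -> "Strategy":
        path = Path(path)
        return cls.from_text(path.read_text(encoding="utf-8"), name=path.stem)

    def to_text(self) -> str:
        return "\n".join(f"{n}  {q}" for n, q in self.lines) + "\n"


@dataclass(frozen=True)
class StrategyLineResult:
    line_number: int
    text: str
    retrieved: RetrievalSet
    cumulative: RetrievalSet


def evaluate_strategy(
    strategy: Strategy,
    corpus: Corpus,
    *,
    default_scope: str = "mp",
    adj_in_order: bool = False,
) -> list[StrategyLineResult]:
    """Evaluate every line of a strategy, resolving line references.

    Returns one result per line, carrying both the line's own retrieval set
    and the cumulative union over lines 1..k (the quantity reported in
    cumulative strategy tables).
    """
    context: dict[int, frozenset[str]] = {}
    results: list[StrategyLineResult] = []
    cumulative: frozenset[str] = frozenset()
    for number, text in strategy.lines:
        node = parse_query(text)
        _check_refs(node, number)
        rs = evaluate(
            node,
            corpus,
            context,
            label=text,
            default_scope=default_scope,
            adj_in_order=adj_in_order,
        )
        context[number] = rs.doc_ids
        cumulative = cumulative | rs.doc_ids
        results.append(
            StrategyLineResult(
                line_number=number,
                text=text,
                retrieved=rs,
                cumulative=RetrievalSet(f"1-{number}", cumulative),
            )
        )
    return results


def _check_refs(node: QueryNode, current_line: int) -> None:
    if isinstance(node, LineRef):
        if node.end >= current_line:
            raise EvaluationError(
                f"line {current_line} references line {node.end} (forward or self reference)"
            )
    elif isinstance(node, (Or, And)):
        for c in node.children:
            _check_refs(c, current_line)
    elif isinstance(node, Not):
        _check_refs(node.keep, current_line)
        _check_refs(node.exclude, current_line)
    elif isinstance(node, FieldScope):
        _check_refs(node.child, current_line)
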