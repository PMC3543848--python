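"""Independent brute-force retrieval oracle for cross-checking the engine.

Deliberately naive: character-level recursive wildcard matching (no regex),
explicit enumeration of every token window and every span pair for
proximity.  Shares only the parsed query tree with the implementation under
test, never its matching machinery.
"""

from __future__ import annotations

from hedgekit.corpus import Corpus, DocumentRecord
from hedgekit.query import Adj, And, FieldScope, LineRef, Not, Or, QueryNode, TermPattern


def naive_tokenize(text: str) -> list[str]:
    tokens, cur = [], []
    for ch in text.lower():
        if ch.isalnum() and ch.isascii():
            cur.append(ch)
        else:
            if cur:
                tokens.append("".join(cur))
            cur = []
    if cur:
        tokens.append("".join(cur))
    return tokens


def match_token(pattern: str, token: str) -> bool:
    if not pattern:
        return not token
    head, rest = pattern[0], pattern[1:]
    if head == "*":
        return any(match_token(rest, token[i:]) for i in range(len(token) + 1))
    if head == "?":
        if match_token(rest, token):
            return True
        return bool(token) and match_token(rest, token[1:])
    if head == "#":
        return bool(token) and match_token(rest, token[1:])
    return bool(token) and token[0] == head and match_token(rest, token[1:])


def phrase_spans(tokens: list[str], phrase: tuple[str, ...]) -> list[tuple[int, int]]:
    k = len(phrase)
    out = []
    for start in range(len(tokens) - k + 1):
        if all(match_token(phrase[j], tokens[start + j]) for j in range(k)):
            out.append((start, start + k - 1))
    return out


def node_spans(node: QueryNode, tokens: list[str]) -> list[tuple[int, int]]:
    if isinstance(node, TermPattern):
        return phrase_spans(tokens, node.tokens)
    if isinstance(node, Adj):
        out = set()
        for ls, le in node_spans(node.left, tokens):
            for rs, re_ in node_spans(node.right, tokens):
                if le < rs and rs - le - 1 <= node.distance - 1:
                    out.add((ls, re_))
                elif re_ < ls and ls - re_ - 1 <= node.distance - 1:
                    out.add((rs, le))
        return sorted(out)
    raise TypeError(f"span-less node {node!r}")


def field_texts(rec: DocumentRecord, scope: str) -> list[list[str]]:
    title = naive_tokenize(rec.title)
    abstract = naive_tokenize(rec.abstract)
    headings = [naive_tokenize(h) for h in rec.subject_headings]
    if scope == "ti":
        return [title]
    if scope == "ab":
        return [abstract]
    if scope == "ab,ti":
        return [abstract, title]
    if scope == "mp":
        return [title, abstract, *headings]
    if scope == "af":
        return [
            title,
            abstract,
            *headings,
            naive_tokenize(rec.pub_type),
            *[naive_tokenize(a) for a in rec.accessions],
        ]
    if scope == "sh":
        return headings
    raise ValueError(scope)


def doc_matches(node: QueryNode, rec: DocumentRecord, scope: str) -> bool:
    if isinstance(node, FieldScope):
        return doc_matches(node.child, rec, node.code)
    if isinstance(node, Or):
        return any(doc_matches(c, rec, scope) for c in node.children)
    if isinstance(node, And):
        return all(doc_matches(c, rec, scope) for c in node.children)
    if isinstance(node, Not):
        return doc_matches(node.keep, rec, scope) and not doc_matches(node.exclude, rec, scope)
    if isinstance(node, LineRef):
        raise TypeError("oracle does not resolve line references")
    for tokens in field_texts(rec, scope):
        spans = node_spans(node, tokens)
        if scope == "sh":
            if any(s == 0 and e == len(tokens) - 1 for s, e in spans):
                return True
        elif spans:
            return True
    return False


def brute_force_retrieve(node: QueryNode, corpus: Corpus, scope: str = "mp") -> frozenset[str]:
    return frozenset(r.doc_id for r in corpus.records if doc_matches(node, r, scope))
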