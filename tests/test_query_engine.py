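import re

import pytest
from hypothesis import given, settings, strategies as st

from hedgekit import datasets
from hedgekit.corpus import Corpus
from hedgekit.query import (
    Adj,
    EvaluationError,
    FieldScope,
    LineRef,
    Not,
    Or,
    ParseError,
    Strategy,
    TermPattern,
    evaluate,
    evaluate_strategy,
    parse_query,
    serialize,
)

from conftest import make_record
from _oracle import brute_force_retrieve


def ids_of(query, corpus, **kw):
    return evaluate(parse_query(query), corpus, **kw).doc_ids


class TestParse:
    def test_adj_with_field_scope(self):
        node = parse_query("(off adj2 label*).mp.")
        assert node == FieldScope(
            "mp", Adj(2, TermPattern(("off",)), TermPattern(("label*",)))
        )

    def test_bare_phrase_with_field(self):
        assert parse_query("off label*.af.") == FieldScope(
            "af", TermPattern(("off", "label*"))
        )

    def test_lineref_not_exclusion(self):
        node = parse_query("(or/1-22) not (stent* or veterinar*).af.")
        assert node == Not(
            LineRef(1, 22),
            FieldScope("af", Or((TermPattern(("stent*",)), TermPattern(("veterinar*",))))),
        )

    def test_quoted_phrase(self):
        assert parse_query('"off label drug us*".af.') == FieldScope(
            "af", TermPattern(("off", "label", "drug", "us*"))
        )

    def test_chained_adj_left_associative(self):
        node = parse_query("(drug adj2 label adj2 us*).af.")
        assert node == FieldScope(
            "af",
            Adj(2, Adj(2, TermPattern(("drug",)), TermPattern(("label",))), TermPattern(("us*",))),
        )

    def test_case_insensitive(self):
        assert parse_query("OFF Label*.AF.") == parse_query("off label*.af.")

    @pytest.mark.parametrize(
        "bad, message",
        [
            ("(off label*.af.", "expected RPAREN"),
            ("off label*.xq.", "field code"),
            ("off label*) extra", "trailing"),
            ("", "empty"),
            ('"unterminated', "quote"),
        ],
    )
    def test_errors_carry_position(self, bad, message):
        with pytest.raises(ParseError, match=message):
            parse_query(bad)

    def test_adj_operands_must_be_term_like(self):
        with pytest.raises(ParseError, match="term-like"):
            parse_query("(a or b) adj2 c")


ALL_PUBLISHED_QUERIES = sorted(
    set(datasets.top_queries_table()["query"])
    | set(datasets.sensitivity_maximizing_strategy()["query"])
    | set(datasets.precision_optimized_strategy()["query"])
)


class TestSerialize:
    @pytest.mark.parametrize("query", ALL_PUBLISHED_QUERIES)
    def test_published_queries_round_trip(self, query):
        """Every strategy line from the published tables (including the long
        NOT-refined one with typographic artifacts) reparses to the same tree."""
        node = parse_query(query)
        assert parse_query(serialize(node)) == node

    def test_single_term_fixpoint(self):
        assert serialize(parse_query("unlicense*")) == "unlicense*"


# --- grammar fuzzer for the round-trip property ---------------------------

_RESERVED = re.compile(r"(?:or|and|not|adj\d*)\*?\Z")
words = st.from_regex(r"[a-z][a-z0-9?#]{0,5}\*?", fullmatch=True).filter(
    lambda w: not _RESERVED.match(w)
)
terms = st.builds(lambda ts: TermPattern(tuple(ts)), st.lists(words, min_size=1, max_size=3))
adjs = st.recursive(
    terms,
    lambda kids: st.builds(Adj, st.integers(1, 5), kids, terms),
    max_leaves=4,
)
linerefs = st.builds(
    lambda a, d: LineRef(a, a + d), st.integers(1, 9), st.integers(0, 9)
)


def _flat(cls, children):
    kids = []
    for c in children:
        kids.extend(c.children if isinstance(c, cls) else (c,))
    return cls(tuple(kids))


query_trees = st.recursive(
    st.one_of(terms, adjs, linerefs),
    lambda sub: st.one_of(
        st.builds(lambda cs: _flat(Or, cs), st.lists(sub, min_size=2, max_size=3)),
        st.builds(lambda cs: _flat(And, cs), st.lists(sub, min_size=2, max_size=3)),
        st.builds(Not, sub, sub),
        st.builds(FieldScope, st.sampled_from(["af", "mp", "ab", "ti", "ab,ti", "sh"]), sub),
    ),
    max_leaves=8,
)
from hedgekit.query import And  # noqa: E402


@given(query_trees)
@settings(max_examples=200, derandomize=True)
def test_serialize_parse_round_trip_fuzzed(tree):
    assert parse_query(serialize(tree)) == tree


class TestEvaluate:
    def test_hyphen_insensitive_prefix_match(self, tiny_corpus):
        # "Off-label" tokenizes to ["off","label"], matched by the phrase
        assert "d1" in ids_of("off label*.af.", tiny_corpus)

    def test_wildcard_covers_spelling_variants(self, tiny_corpus):
        # licence (d4) and license (d5) both match ? as zero-or-one
        hits = ids_of("off li?en?e*.af.", tiny_corpus)
        assert {"d4", "d5"} <= hits

    def test_field_scope_restricts(self, tiny_corpus):
        rec = make_record("h", subject_headings=["off label drug use"], relevant=True)
        corpus = Corpus(records=[rec])
        assert ids_of("(off adj2 label*).mp.", corpus) == {"h"}
        assert ids_of("(off adj2 label*).ab,ti.", corpus) == frozenset()

    def test_sh_matches_whole_heading_only(self, tiny_corpus):
        assert "d1" in ids_of('"off label drug use".sh.', tiny_corpus)
        assert ids_of("off label.sh.", tiny_corpus) == frozenset()

    def test_empty_corpus(self):
        assert ids_of("off label*.af.", Corpus(records=[])) == frozenset()

    def test_adj_either_order_and_distance(self):
        rec = make_record("x", title="label of the off kind")
        corpus = Corpus(records=[rec])
        assert ids_of("(off adj4 label*).ti.", corpus) == {"x"}  # reversed, 2 between
        assert ids_of("(off adj2 label*).ti.", corpus) == frozenset()
        assert ids_of("(off adj4 label*).ti.", corpus, adj_in_order=True) == frozenset()

    def test_scope_monotonicity(self, planted):
        """Broadening the field scope never loses records: ab ⊆ ab,ti ⊆ mp ⊆ af."""
        _, corpus, _, _ = planted
        pattern = "off label*"
        chain = [
            ids_of(f"{pattern}.{code}.", corpus) for code in ("ab", "ab,ti", "mp", "af")
        ]
        for narrower, wider in zip(chain, chain[1:]):
            assert narrower <= wider

    def test_truncation_dominance(self, planted):
        _, corpus, _, _ = planted
        assert ids_of("off label.af.", corpus) <= ids_of("off label*.af.", corpus)

    def test_adj_distance_monotonic(self, tiny_corpus):
        for n in range(1, 5):
            assert ids_of(f"(off adj{n} label*).af.", tiny_corpus) <= ids_of(
                f"(off adj{n + 1} label*).af.", tiny_corpus
            )

    def test_boolean_set_algebra(self, tiny_corpus):
        a = ids_of("off label*.af.", tiny_corpus)
        b = ids_of("unlicensed.af.", tiny_corpus)
        union = ids_of("(off label*) or unlicensed.af.", tiny_corpus, default_scope="af")
        inter = ids_of("(off label*) and unlicensed.af.", tiny_corpus, default_scope="af")
        diff = ids_of("(off label*) not unlicensed.af.", tiny_corpus, default_scope="af")
        assert len(union) == len(a) + len(b) - len(inter)
        assert diff == a - b and not (diff & b)


class TestStrategy:
    def test_self_union_lineref(self, tiny_corpus):
        strat = Strategy.from_queries(["off label*.af.", "(or/1-1)"])
        results = evaluate_strategy(strat, tiny_corpus)
        assert results[1].retrieved.doc_ids == results[0].retrieved.doc_ids

    def test_cumulative_partial_sums(self, tiny_corpus):
        strat = Strategy.from_queries(
            ["stent*.af.", "veterinar*.af.", "unlicensed.af."]
        )  # pairwise disjoint on this corpus
        results = evaluate_strategy(strat, tiny_corpus)
        sizes = [len(r.retrieved.doc_ids) for r in results]
        cumulative = [len(r.cumulative.doc_ids) for r in results]
        assert cumulative == [sizes[0], sizes[0] + sizes[1], sizes[0] + sizes[1] + sizes[2]]

    def test_not_line_shrinks(self, tiny_corpus):
        strat = Strategy.from_queries(
            [
                "off label*.af.",
                "unlicense*.af.",
                "extra label.af.",
                "(or/1-3) not (stent* or veterinar*).af.",
            ]
        )
        results = evaluate_strategy(strat, tiny_corpus)
        assert results[3].retrieved.doc_ids <= results[2].cumulative.doc_ids
        assert len(results[3].retrieved.doc_ids) < len(results[2].cumulative.doc_ids)

    def test_forward_reference_rejected(self, tiny_corpus):
        strat = Strategy.from_queries(["(or/1-2)", "off label*.af."])
        with pytest.raises(EvaluationError, match="forward"):
            evaluate_strategy(strat, tiny_corpus)

    def test_strategy_file_loads_published_lines_unmodified(self, tmp_path):
        df = datasets.precision_optimized_strategy()
        text = "# precision-optimized strategy\n" + "\n".join(
            f"{line}  {q}" for line, q in zip(df["line"], df["query"])
        )
        path = tmp_path / "strategy.txt"
        path.write_text(text, encoding="utf-8")
        strat = Strategy.from_file(path)
        assert [q for _, q in strat.lines] == list(df["query"])

    def test_non_dense_numbering_rejected(self):
        with pytest.raises(ValueError, match="dense"):
            Strategy(((1, "a"), (3, "b")))


class TestOracleAgreement:
    @pytest.mark.parametrize(
        "query",
        [
            "off label*.af.",
            "(off adj2 label*).mp.",
            "off li?en?e*.af.",
            '"off label drug use".sh.',
            "(drug adj2 label adj2 us*).af.",
            "((inappropriate us* and indication) not (antibiotic* or antimicrobial)).af.",
        ],
    )
    def test_engine_equals_brute_force(self, query, tiny_corpus, planted):
        _, corpus, _, _ = planted
        node = parse_query(query)
        for c in (tiny_corpus, corpus):
            assert evaluate(node, c).doc_ids == brute_force_retrieve(node, c)
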