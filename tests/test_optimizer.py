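import itertools
import math
import random

import pytest

from hedgekit.corpus import Corpus, GoldStandard
from hedgekit.metrics import round_half_up
from hedgekit.optimizer import (
    CandidatePool,
    FrontierPoint,
    best_tradeoff,
    cumulative_or_table,
    enumerate_frontier,
    maximize_sensitivity,
    not_refinement,
)
from hedgekit.query import evaluate, parse_query
from hedgekit.synth import GeneratorConfig, QuerySpec, generate_corpus

from conftest import make_record


def _gold(n_rel, extra_internal=None):
    rel = frozenset(f"r{i}" for i in range(n_rel))
    return GoldStandard(full_set=rel, internal_set=extra_internal or rel)


def _corpus_for(gold, extra_ids):
    recs = [make_record(d, relevant=True) for d in sorted(gold.full_set)]
    recs += [make_record(d) for d in sorted(extra_ids)]
    return Corpus(records=recs)


class TestCumulativeOr:
    def test_hand_union_of_disjoint_sets(self):
        gold = _gold(20)
        q1 = ("q1", frozenset([f"r{i}" for i in range(8)] + ["x0", "x1"]))
        q2 = ("q2", frozenset([f"r{i}" for i in range(8, 12)] + ["x2"]))
        corpus = _corpus_for(gold, ["x0", "x1", "x2"])
        rows = cumulative_or_table([q1, q2], corpus, gold)
        assert [r.performance.n_relevant_retrieved for r in rows] == [8, 12]
        assert [r.performance.sensitivity_full for r in rows] == [40.0, 60.0]
        assert [r.new_relevant for r in rows] == [8, 4]

    def test_single_query_equals_its_row(self, planted):
        _, corpus, gold, _ = planted
        rs = evaluate(parse_query("off label*.af."), corpus)
        rows = cumulative_or_table([rs], corpus, gold)
        assert len(rows) == 1
        assert rows[0].performance.n_retrieved == len(rs.doc_ids)

    def test_monotone_counts(self, planted):
        _, corpus, gold, manifest = planted
        sets = [
            evaluate(parse_query(q), corpus, label=q) for q in manifest.query_counts
        ]
        rows = cumulative_or_table(sets, corpus, gold)
        rel = [r.performance.n_relevant_retrieved for r in rows]
        ret = [r.performance.n_retrieved for r in rows]
        assert rel == sorted(rel) and ret == sorted(ret)


def random_pool(rng, n_queries=8, n_docs=60, n_rel=30):
    docs = [f"d{i}" for i in range(n_docs)]
    rel = frozenset(docs[:n_rel])
    gold = GoldStandard(full_set=rel, internal_set=rel)
    queries = tuple(
        (f"q{j}", frozenset(rng.sample(docs, rng.randint(0, n_docs // 2))))
        for j in range(n_queries)
    )
    return CandidatePool(queries, gold)


def exhaustive_best_coverage(pool):
    """Brute-force subset enumeration oracle for maximal relevant coverage."""
    best = 0
    for r in range(1, len(pool.queries) + 1):
        for subset in itertools.combinations(pool.queries, r):
            union = frozenset().union(*(ids for _, ids in subset))
            best = max(best, len(union & pool.gold.full_set))
    return best


class TestMaximizeSensitivity:
    def test_dominant_query_suffices(self):
        gold = _gold(10)
        big = ("big", frozenset(gold.full_set))
        small = ("small", frozenset(list(gold.full_set)[:3]))
        order = maximize_sensitivity(CandidatePool((big, small), gold))
        assert order == ["big"]

    def test_greedy_matches_exhaustive_oracle(self):
        rng = random.Random(2024)
        for _ in range(25):
            pool = random_pool(rng)
            order = maximize_sensitivity(pool, mode="greedy")
            sets = pool.as_dict()
            covered = frozenset().union(*(sets[l] for l in order)) if order else frozenset()
            assert len(covered & pool.gold.full_set) == exhaustive_best_coverage(pool)

    def test_exhaustive_mode_agrees_with_greedy_coverage(self):
        rng = random.Random(7)
        pool = random_pool(rng, n_queries=6)
        sets = pool.as_dict()
        for mode in ("greedy", "exhaustive"):
            order = maximize_sensitivity(pool, mode=mode)
            covered = frozenset().union(*(sets[l] for l in order))
            assert len(covered & pool.gold.full_set) == exhaustive_best_coverage(pool)

    def test_exhaustive_cap_enforced(self):
        rng = random.Random(1)
        pool = random_pool(rng, n_queries=14)
        with pytest.raises(ValueError, match="capped"):
            maximize_sensitivity(pool, mode="exhaustive", exhaustive_cap=12)

    def test_dominant_planted_query_selected_first(self):
        config = GeneratorConfig(n_docs=600, seed=3)
        corpus, gold, manifest = generate_corpus(config)
        sets = [
            evaluate(parse_query(q), corpus, label=q) for q in manifest.query_counts
        ]
        pool = CandidatePool.from_retrieval_sets(sets, gold)
        order = maximize_sensitivity(pool)
        assert order[0] == "off label*.af."


class TestFrontier:
    def test_strict_domination_gives_singleton(self):
        gold = _gold(10)
        strong = ("strong", frozenset(gold.full_set))
        weak = ("weak", frozenset(list(gold.full_set)[:4]) | frozenset({"x"}))
        corpus = _corpus_for(gold, ["x"])
        frontier = enumerate_frontier(CandidatePool((strong, weak), gold))
        assert len(frontier) == 1 and frontier[0].precision == 100.0

    def test_matches_brute_force_pareto(self):
        rng = random.Random(99)
        pool = random_pool(rng, n_queries=5, n_docs=40, n_rel=18)
        frontier = enumerate_frontier(pool)
        # oracle: enumerate all subsets, filter dominated points
        pts = set()
        for r in range(1, 6):
            for subset in itertools.combinations(pool.queries, r):
                union = frozenset().union(*(ids for _, ids in subset))
                if union:
                    n_rel = len(union & pool.gold.full_set)
                    pts.add((100 * n_rel / pool.gold.n_full, 100 * n_rel / len(union)))
        expected = {
            p for p in pts
            if not any(q != p and q[0] >= p[0] and q[1] >= p[1] for q in pts)
        }
        assert {(p.sensitivity_full, p.precision) for p in frontier} == expected

    def test_pairwise_non_dominated(self):
        rng = random.Random(5)
        frontier = enumerate_frontier(random_pool(rng))
        for a in frontier:
            assert not any(b.dominates(a) for b in frontier if b is not a)

    def test_greedy_prefixes_on_or_below_frontier(self):
        rng = random.Random(11)
        pool = random_pool(rng)
        sets = pool.as_dict()
        frontier = enumerate_frontier(pool)
        order = maximize_sensitivity(pool)
        for k in range(1, len(order) + 1):
            union = frozenset().union(*(sets[l] for l in order[:k]))
            sens = 100 * len(union & pool.gold.full_set) / pool.gold.n_full
            prec = 100 * len(union & pool.gold.full_set) / len(union)
            point = FrontierPoint(frozenset(order[:k]), sens, prec)
            on = any((p.sensitivity_full, p.precision) == (sens, prec) for p in frontier)
            dominated = any(p.dominates(point) for p in frontier)
            assert on or dominated

    def test_beam_search_returns_non_dominated_points(self):
        rng = random.Random(13)
        pool = random_pool(rng, n_queries=15, n_docs=80, n_rel=40)
        frontier = enumerate_frontier(pool, budget=8, beam_width=16)
        assert frontier
        for a in frontier:
            assert not any(b.dominates(a) for b in frontier if b is not a)


class TestBestTradeoff:
    def test_distance_criterion_prefers_balanced_point(self):
        """Between the sensitivity-maximized (94.0, 69.5) and the refined
        (89.4, 87.4) operating points, minimum distance to the ideal corner
        picks the refined one (16.4 vs 31.1)."""
        a = FrontierPoint(frozenset({"a"}), 94.0, 69.5)
        b = FrontierPoint(frozenset({"b"}), 89.4, 87.4)
        assert math.hypot(100 - 94.0, 100 - 69.5) == pytest.approx(31.08, abs=0.01)
        assert math.hypot(100 - 89.4, 100 - 87.4) == pytest.approx(16.47, abs=0.01)
        assert best_tradeoff([a, b]) is b

    def test_singleton(self):
        p = FrontierPoint(frozenset({"a"}), 50.0, 50.0)
        assert best_tradeoff([p]) is p

    @pytest.mark.parametrize("criterion", ["min-distance", "max-f1", "knee"])
    def test_optimal_under_criterion_by_scan(self, criterion):
        rng = random.Random(42)
        frontier = enumerate_frontier(random_pool(rng, n_queries=7))
        chosen = best_tradeoff(frontier, criterion=criterion)
        assert chosen in frontier
        if criterion == "min-distance":
            best = min(math.hypot(100 - p.sensitivity_full, 100 - p.precision) for p in frontier)
            assert math.hypot(100 - chosen.sensitivity_full, 100 - chosen.precision) == pytest.approx(best)
        elif criterion == "max-f1":
            f1 = lambda p: 2 * p.sensitivity_full * p.precision / (p.sensitivity_full + p.precision)
            assert f1(chosen) == pytest.approx(max(f1(p) for p in frontier))


class TestNotRefinement:
    @pytest.fixture()
    def decoy_corpus(self):
        """Strategy retrieves relevant docs plus stent/veterinary decoys."""
        recs = [
            make_record(f"r{i}", title="off label use case", relevant=True)
            for i in range(40)
        ]
        recs += [
            make_record(f"s{i}", title="off label stent evaluation") for i in range(15)
        ]
        recs += [
            make_record(f"v{i}", title="off label veterinary report") for i in range(5)
        ]
        recs += [make_record("rs0", title="off label stent in humans", relevant=True)]
        corpus = Corpus(records=recs)
        return corpus, corpus.gold_standard()

    def test_decoy_exclusion_deltas_match_hand_computation(self, decoy_corpus):
        corpus, gold = decoy_corpus
        base = evaluate(parse_query("off label*.af."), corpus, label="off label*.af.")
        report = not_refinement(
            [base], corpus, gold, ["stent*", "veterinar*"], thresholds=(0.05, 0.05)
        )
        assert set(report.excluded_terms) == {"stent*", "veterinar*"}
        assert report.final_line == "(or/1-1) not (stent* or veterinar*).af."
        # 15 + 5 irrelevant decoys and 1 relevant stent record removed
        assert report.n_removed == 21
        assert report.n_removed_relevant == 1
        assert report.after.n_retrieved == 40
        assert report.delta_precision == pytest.approx(100 * 40 / 40 - 100 * 41 / 61)
        assert report.delta_sensitivity_full == pytest.approx(100 * (40 - 41) / 41)

    def test_terms_absent_from_retrieved_change_nothing(self, decoy_corpus):
        corpus, gold = decoy_corpus
        base = evaluate(parse_query("off label*.af."), corpus)
        report = not_refinement([base], corpus, gold, ["zirconium*"])
        assert report.excluded_terms == ()
        assert report.n_removed == 0
        assert report.after.n_retrieved == report.before.n_retrieved
        assert report.delta_precision == 0.0

    def test_rare_in_relevant_threshold_blocks_exclusion(self, decoy_corpus):
        corpus, gold = decoy_corpus
        base = evaluate(parse_query("off label*.af."), corpus)
        # "use" appears in every relevant record: fails the rarity threshold
        report = not_refinement([base], corpus, gold, ["use"], thresholds=(0.01, 0.05))
        assert report.excluded_terms == ()

    def test_never_increases_sensitivity_or_retrieved(self, planted):
        _, corpus, gold, manifest = planted
        sets = [evaluate(parse_query(q), corpus, label=q) for q in manifest.query_counts]
        report = not_refinement(sets, corpus, gold, ["granite*", "unlicense*"], thresholds=(0.0, 1.0))
        assert report.after.n_retrieved <= report.before.n_retrieved
        assert report.after.sensitivity_full <= report.before.sensitivity_full

    def test_published_refinement_arithmetic(self):
        """The published final-line refinement: (3650/4446) → (3635/4158)
        raises precision by 5.32 points and costs 0.37 / 0.39 sensitivity."""
        before = 100 * 3650 / 4446
        after = 100 * 3635 / 4158
        assert round_half_up(after, 2) - round_half_up(before, 2) == pytest.approx(5.32)
        assert round_half_up(100 * 3650 / 4067, 2) - round_half_up(100 * 3635 / 4067, 2) == pytest.approx(0.37)
        assert round_half_up(100 * 3650 / 3846, 2) - round_half_up(100 * 3635 / 3846, 2) == pytest.approx(0.39)
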