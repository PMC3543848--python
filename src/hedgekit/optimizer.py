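"""Construction of combined search strategies.

Three stages mirror how highly sensitive search strategies are developed in
practice: (1) OR-combine candidate queries to maximize the number of
relevant records covered (a pure union-coverage problem, so greedy selection
run to zero marginal gain attains the exhaustive optimum); (2) explore the
sensitivity/precision plane over query subsets and keep the Pareto frontier;
(3) pick the best trade-off point and optionally refine it with a NOT clause
of terms frequent among retrieved irrelevant records and rare among
retrieved relevant ones.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .corpus import Corpus, GoldStandard
from .metrics import PerformanceRow, evaluate_performance, precision, sensitivity
from .query import RetrievalSet, evaluate, parse_query

__all__ = [
    "CandidatePool",
    "CumulativeRow",
    "FrontierPoint",
    "NotRefinementReport",
    "cumulative_or_table",
    "maximize_sensitivity",
    "enumerate_frontier",
    "best_tradeoff",
    "not_refinement",
    "TRADEOFF_CRITERIA",
]

EXHAUSTIVE_CAP_DEFAULT = 12


@dataclass(frozen=True)
class CandidatePool:
    """Candidate queries with their evaluated retrieval sets."""

    queries: tuple[tuple[str, frozenset[str]], ...]
    gold: GoldStandard

    def __post_init__(self) -> None:
        labels = [lbl for lbl, _ in self.queries]
        if len(labels) != len(set(labels)):
            raise ValueError("candidate labels must be unique")

    @classmethod
    def from_retrieval_sets(
        cls, sets: Iterable[RetrievalSet], gold: GoldStandard
    ) -> "CandidatePool":
        return cls(tuple((rs.query_label, rs.doc_ids) for rs in sets), gold)

    @classmethod
    def from_queries(
        cls, queries: Iterable[str], corpus: Corpus, gold: GoldStandard, **engine_kwargs
    ) -> "CandidatePool":
        sets = [
            evaluate(parse_query(q), corpus, label=q, **engine_kwargs) for q in queries
        ]
        return cls.from_retrieval_sets(sets, gold)

    def as_dict(self) -> dict[str, frozenset[str]]:
        return dict(self.queries)


@dataclass(frozen=True)
class CumulativeRow:
    """One strategy line with cumulative performance and marginal gains."""

    performance: PerformanceRow
    new_relevant: int
    new_retrieved: int


def cumulative_or_table(
    ordered_queries: Sequence[tuple[str, frozenset[str]] | RetrievalSet],
    corpus: Corpus,
    gold: GoldStandard,
) -> list[CumulativeRow]:
    """Incrementally OR queries together; row k scores the union of 1..k."""
    if not ordered_queries:
        raise ValueError("need at least one query")
    rows: list[CumulativeRow] = []
    union: frozenset[str] = frozenset()
    rel_before = ret_before = 0
    for item in ordered_queries:
        label, ids = (
            (item.query_label, item.doc_ids) if isinstance(item, RetrievalSet) else item
        )
        union = union | ids
        perf = evaluate_performance(RetrievalSet(label, union), gold, corpus)
        rows.append(
            CumulativeRow(
                performance=perf,
                new_relevant=perf.n_relevant_retrieved - rel_before,
                new_retrieved=perf.n_retrieved - ret_before,
            )
        )
        rel_before, ret_before = perf.n_relevant_retrieved, perf.n_retrieved
    return rows


def _own_precision(ids: frozenset[str], gold: GoldStandard) -> float:
    if not ids:
        return -1.0
    return len(ids & gold.full_set) / len(ids)


def maximize_sensitivity(
    pool: CandidatePool,
    mode: str = "greedy",
    exhaustive_cap: int = EXHAUSTIVE_CAP_DEFAULT,
) -> list[str]:
    """Order queries to maximize relevant records covered by their union.

    Greedy mode repeatedly adds the query with the largest marginal
    relevant-retrieved gain (ties: higher own precision, then label order)
    and stops at zero marginal gain; because coverage is submodular and
    unconstrained, this reaches the same relevant-retrieved count as
    exhaustive subset enumeration.  Exhaustive mode enumerates all subsets
    (pool size capped) and returns the subset with maximal relevant coverage
    and, among maxima, smallest total retrieved; the returned order is the
    greedy inclusion order for cumulative reporting.
    """
    if not pool.queries:
        raise ValueError("empty candidate pool")
    if mode not in ("greedy", "exhaustive"):
        raise ValueError(f"unknown mode {mode!r}")
    relevant = pool.gold.full_set

    if mode == "exhaustive":
        if len(pool.queries) > exhaustive_cap:
            raise ValueError(
                f"exhaustive mode capped at {exhaustive_cap} queries "
                f"(pool has {len(pool.queries)}); use greedy"
            )
        best: Optional[tuple[int, int, tuple[str, ...]]] = None
        for r in range(1, len(pool.queries) + 1):
            for subset in itertools.combinations(pool.queries, r):
                union: set[str] = set()
                for _, ids in subset:
                    union |= ids
                key = (len(union & relevant), -len(union))
                if best is None or key > (best[0], best[1]):
                    best = (key[0], key[1], tuple(lbl for lbl, _ in subset))
        assert best is not None
        chosen = set(best[2])
        sub = CandidatePool(
            tuple(q for q in pool.queries if q[0] in chosen), pool.gold
        )
        return maximize_sensitivity(sub, mode="greedy")

    remaining = dict(pool.queries)
    covered: set[str] = set()
    order: list[str] = []
    while remaining:
        scored = [
            (
                len((ids & relevant) - covered),
                _own_precision(ids, pool.gold),
                label,
            )
            for label, ids in remaining.items()
        ]
        gain, _, label = max(scored, key=lambda t: (t[0], t[1], _NegStr(t[2])))
        if gain == 0:
            break
        order.append(label)
        covered |= remaining.pop(label) & relevant
    if not order:  # no query retrieves anything relevant: report the best single line
        order = [min(remaining)]
    return order


class _NegStr(str):
    """Reverses string comparison so max() breaks label ties ascending."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


@dataclass(frozen=True)
class FrontierPoint:
    """A non-dominated (sensitivity, precision) point and its query subset."""

    query_subset: frozenset[str]
    sensitivity_full: float
    precision: float

    def dominates(self, other: "FrontierPoint") -> bool:
        ge = (
            self.sensitivity_full >= other.sensitivity_full
            and self.precision >= other.precision
        )
        gt = (
            self.sensitivity_full > other.sensitivity_full
            or self.precision > other.precision
        )
        return ge and gt


def _score_subset(
    subset: Sequence[tuple[str, frozenset[str]]], gold: GoldStandard
) -> Optional[FrontierPoint]:
    union: set[str] = set()
    for _, ids in subset:
        union |= ids
    if not union:
        return None
    n_rel = len(union & gold.full_set)
    return FrontierPoint(
        query_subset=frozenset(lbl for lbl, _ in subset),
        sensitivity_full=sensitivity(n_rel, gold.n_full),
        precision=precision(n_rel, len(union)),
    )


def _pareto(points: Iterable[FrontierPoint]) -> list[FrontierPoint]:
    unique: dict[tuple[float, float], FrontierPoint] = {}
    for p in points:
        unique.setdefault((p.sensitivity_full, p.precision), p)
    frontier = [
        p
        for p in unique.values()
        if not any(q.dominates(p) for q in unique.values())
    ]
    return sorted(frontier, key=lambda p: (-p.sensitivity_full, -p.precision))


def enumerate_frontier(
    pool: CandidatePool,
    budget: int = EXHAUSTIVE_CAP_DEFAULT,
    beam_width: int = 32,
) -> list[FrontierPoint]:
    """Pareto frontier of (overall sensitivity, precision) over query subsets.

    Exhaustive over all non-empty subsets when the pool fits under
    ``budget``; otherwise a beam search seeded by the greedy sensitivity
    ordering, expanding the ``beam_width`` best partial subsets per level.
    Returned points are pairwise non-dominated, sorted by descending
    sensitivity.
    """
    if not pool.queries:
        raise ValueError("empty candidate pool")
    points: list[FrontierPoint] = []
    if len(pool.queries) <= budget:
        for r in range(1, len(pool.queries) + 1):
            for subset in itertools.combinations(pool.queries, r):
                p = _score_subset(subset, pool.gold)
                if p is not None:
                    points.append(p)
        return _pareto(points)

    # beam search: states are subsets, scored by distance to the ideal point
    by_label = pool.as_dict()
    greedy_order = maximize_sensitivity(pool, mode="greedy")
    beam: list[frozenset[str]] = [frozenset()]
    seen: set[frozenset[str]] = set(beam)
    for _ in range(len(greedy_order)):
        candidates: list[frozenset[str]] = []
        for state in beam:
            for label in by_label:
                if label in state:
                    continue
                nxt = state | {label}
                if nxt not in seen:
                    seen.add(nxt)
                    candidates.append(nxt)
        scored = []
        for state in candidates:
            p = _score_subset([(l, by_label[l]) for l in state], pool.gold)
            if p is not None:
                points.append(p)
                scored.append((_distance_to_ideal(p), state))
        scored.sort(key=lambda t: t[0])
        beam = [state for _, state in scored[:beam_width]]
        if not beam:
            break
    return _pareto(points)


def _distance_to_ideal(p: FrontierPoint) -> float:
    return math.hypot(100.0 - p.sensitivity_full, 100.0 - p.precision)


def _f1(p: FrontierPoint) -> float:
    if p.sensitivity_full + p.precision == 0:
        return 0.0
    return 2 * p.sensitivity_full * p.precision / (p.sensitivity_full + p.precision)


def _knee_scores(frontier: Sequence[FrontierPoint]) -> dict[FrontierPoint, float]:
    """Perpendicular distance from the chord joining the frontier extremes."""
    lo = min(frontier, key=lambda p: p.sensitivity_full)
    hi = max(frontier, key=lambda p: p.sensitivity_full)
    dx = hi.sensitivity_full - lo.sensitivity_full
    dy = hi.precision - lo.precision
    norm = math.hypot(dx, dy) or 1.0
    return {
        p: abs(
            dy * p.sensitivity_full
            - dx * p.precision
            + hi.sensitivity_full * lo.precision
            - hi.precision * lo.sensitivity_full
        )
        / norm
        for p in frontier
    }


TRADEOFF_CRITERIA = ("min-distance", "max-f1", "knee")


def best_tradeoff(
    frontier: Sequence[FrontierPoint], criterion: str = "min-distance"
) -> FrontierPoint:
    """Select the frontier point with the best sensitivity/precision balance.

    ``min-distance`` (default): minimal Euclidean distance to the ideal
    (100, 100) point; ``max-f1``: harmonic-mean optimum; ``knee``: maximal
    perpendicular distance from the chord between the frontier extremes.
    Ties go to the higher-sensitivity point.
    """
    if not frontier:
        raise ValueError("empty frontier")
    if criterion == "min-distance":
        return min(frontier, key=lambda p: (_distance_to_ideal(p), -p.sensitivity_full))
    if criterion == "max-f1":
        return max(frontier, key=lambda p: (_f1(p), p.sensitivity_full))
    if criterion == "knee":
        scores = _knee_scores(frontier)
        return max(frontier, key=lambda p: (scores[p], p.sensitivity_full))
    raise ValueError(f"unknown criterion {criterion!r}; choose from {TRADEOFF_CRITERIA}")


@dataclass(frozen=True)
class NotRefinementReport:
    """Effect of appending a NOT-exclusion line to a strategy."""

    excluded_terms: tuple[str, ...]
    final_line: str
    before: PerformanceRow
    after: PerformanceRow
    n_removed: int
    n_removed_relevant: int

    @property
    def delta_precision(self) -> float:
        return self.after.precision - self.before.precision

    @property
    def delta_sensitivity_full(self) -> float:
        return self.after.sensitivity_full - self.before.sensitivity_full

    @property
    def delta_sensitivity_internal(self) -> float:
        return self.after.sensitivity_internal - self.before.sensitivity_internal


def not_refinement(
    strategy_sets: Sequence[tuple[str, frozenset[str]] | RetrievalSet],
    corpus: Corpus,
    gold: GoldStandard,
    candidate_terms: Sequence[str],
    thresholds: tuple[float, float] = (0.01, 0.001),
    *,
    field_code: str = "af",
    **engine_kwargs,
) -> NotRefinementReport:
    """Refine a strategy by NOTing out decoy terms.

    A candidate term is excluded when, over the strategy's retrieved set, it
    appears in at least ``thresholds[0]`` (fraction) of the irrelevant
    retrieved records and at most ``thresholds[1]`` of the relevant retrieved
    records — frequent among false positives, rare among true positives.
    The refined strategy appends ``(or/1-k) not (t1 or t2 ...).af.``.
    """
    engine_kwargs.setdefault("default_scope", field_code)
    items = [
        (it.query_label, it.doc_ids) if isinstance(it, RetrievalSet) else it
        for it in strategy_sets
    ]
    union: frozenset[str] = frozenset().union(*(ids for _, ids in items))
    before = evaluate_performance(RetrievalSet("strategy", union), gold, corpus)

    retrieved_rel = union & gold.full_set
    retrieved_irr = union - gold.full_set
    min_irr, max_rel = thresholds
    sub = Corpus(
        records=[corpus[d] for d in union], name=f"{corpus.name}[retrieved]"
    )
    selected: list[str] = []
    removal: set[str] = set()
    for term in candidate_terms:
        hits = evaluate(parse_query(term), sub, label=term, **engine_kwargs).doc_ids
        f_irr = len(hits & retrieved_irr) / len(retrieved_irr) if retrieved_irr else 0.0
        f_rel = len(hits & retrieved_rel) / len(retrieved_rel) if retrieved_rel else 0.0
        if f_irr >= min_irr and f_rel <= max_rel:
            selected.append(term)
            removal |= hits
    refined = union - removal
    k = len(items)
    if selected:
        inner = " or ".join(selected)
        final_line = f"(or/1-{k}) not ({inner}).{field_code}."
    else:
        final_line = f"(or/1-{k})"
    after = evaluate_performance(RetrievalSet(final_line, refined), gold, corpus)
    return NotRefinementReport(
        excluded_terms=tuple(selected),
        final_line=final_line,
        before=before,
        after=after,
        n_removed=len(union) - len(refined),
        n_removed_relevant=len(retrieved_rel) - len(refined & gold.full_set),
    )
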