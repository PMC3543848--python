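"""Synthetic labelled corpora with planted retrieval structure.

The generator emulates the statistical shape of a two-database search-filter
validation study: a corpus with a configured relevance prevalence, a dual
gold standard (a fraction of relevant records is retrievable in the target
database, the rest only in the other database), a year distribution skewed
toward recent publications, vendor-style duplicate records, and — the core
mechanism — *planted query matches*: for each configured query, matching
token sequences are injected into documents so the query attains a target
within-database sensitivity and precision.

Defaults reproduce the conditions of the off-label drug-use benchmark:
prevalence 4067/6785, internal fraction 3846/4067, 90.5% of records in the
recent period, duplicate/triplicate rates 206/6785 and 2/6785, and a
dominant query at within-database sensitivity 0.819 / precision 0.881.

Text is deliberately token soup: filler tokens come from a fixed neutral
vocabulary, checked at build time never to match any planted pattern, so
every engine-measured count is attributable to the planted structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .corpus import Corpus, DocumentRecord, GoldStandard
from .query import (
    Adj,
    And,
    FieldScope,
    Or,
    QueryNode,
    TermPattern,
    parse_query,
)

__all__ = [
    "QuerySpec",
    "GeneratorConfig",
    "GeneratorManifest",
    "generate_corpus",
    "generate_retrieval_matrix",
    "FILLER_VOCABULARY",
]


class QuerySpec(BaseModel):
    """A query to plant, with its target retrieval behaviour.

    ``sensitivity`` is within-database (fraction of internal relevant
    records the query should retrieve); ``precision`` the fraction of its
    retrieved records that are relevant.
    """

    query: str
    sensitivity: float = Field(ge=0.0, le=1.0)
    precision: float = Field(gt=0.0, le=1.0)

    @field_validator("query")
    @classmethod
    def _parseable(cls, v: str) -> str:
        parse_query(v)  # raises ParseError on malformed input
        return v


#: study-condition defaults: the dominant single query at its published
#: within-database rates, plus two long-tail candidates at modest
#: (unpublished, plausible) single-query rates
DEFAULT_QUERY_SPECS = (
    QuerySpec(query="off label*.af.", sensitivity=0.819, precision=0.881),
    QuerySpec(query="unlicense*.af.", sensitivity=0.08, precision=0.25),
    QuerySpec(query="(unapprove* adj2 us*).af.", sensitivity=0.05, precision=0.30),
)


class GeneratorConfig(BaseModel):
    n_docs: int = Field(default=2000, gt=0)
    prevalence: float = Field(default=4067 / 6785, gt=0.0, lt=1.0)
    internal_fraction: float = Field(default=3846 / 4067, gt=0.0, le=1.0)
    recent_fraction: float = Field(default=0.905, ge=0.0, le=1.0)
    year_range: tuple[int, int] = (1988, 2011)
    recent_from: int = 2001
    year_distribution: Optional[dict[int, float]] = None  # overrides the two-period split
    query_specs: tuple[QuerySpec, ...] = DEFAULT_QUERY_SPECS
    duplicate_rate: float = Field(default=206 / 6785, ge=0.0, lt=0.5)
    triplicate_rate: float = Field(default=2 / 6785, ge=0.0, lt=0.5)
    mode: Literal["exact-counts", "bernoulli"] = "exact-counts"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        lo, hi = self.year_range
        if not (lo <= self.recent_from <= hi + 1):
            raise ValueError("recent_from must fall inside year_range")
        labels = [s.query for s in self.query_specs]
        if len(labels) != len(set(labels)):
            raise ValueError("query specs must have unique query strings")
        return self


# fixed neutral vocabulary for filler text; tokens are screened at build
# time against every planted pattern token and offenders are dropped
FILLER_VOCABULARY = tuple(
    f"{w}" for w in (
        "granite basalt quartz feldspar mica gypsum shale slate marble gneiss "
        "meadow tundra prairie savanna steppe fjord lagoon estuary delta atoll "
        "cumulus cirrus stratus nimbus monsoon zephyr sirocco mistral chinook "
        "copper zinc cobalt nickel tungsten vanadium yttrium hafnium tantalum "
        "violet crimson cerulean ochre umber sienna viridian magenta teal "
        "oboe viola cello timpani marimba celesta piccolo bassoon cornet "
        "quasar pulsar nebula parsec perihelion aphelion equinox solstice "
        "gable cornice lintel plinth architrave pediment balustrade parapet"
    ).split()
)


@dataclass
class GeneratorManifest:
    """Ground truth for a generated corpus.

    ``query_counts`` holds the planted per-query totals; in exact-counts
    mode (with non-interfering specs) they equal what the query engine
    recovers from the corpus.
    """

    relevant_ids: list[str]
    internal_ids: list[str]
    planted: dict[str, list[str]]  # doc_id -> planted query strings
    duplicate_clusters: list[list[str]]
    query_counts: dict[str, dict[str, int]]  # query -> retrieved / relevant_retrieved
    year_counts: dict[int, int]
    seed: int

    def to_json(self) -> str:
        payload = {
            "relevant_ids": self.relevant_ids,
            "internal_ids": self.internal_ids,
            "planted": self.planted,
            "duplicate_clusters": self.duplicate_clusters,
            "query_counts": self.query_counts,
            "year_counts": {str(k): v for k, v in sorted(self.year_counts.items())},
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Witness construction: a token sequence a given query is guaranteed to match
# ---------------------------------------------------------------------------


def _instantiate(pattern_token: str) -> str:
    out = []
    for ch in pattern_token:
        if ch == "*" or ch == "?":
            continue  # zero-width choices
        elif ch == "#":
            out.append("x")
        else:
            out.append(ch)
    return "".join(out) or "x"


def _witness_tokens(node: QueryNode) -> list[str]:
    if isinstance(node, TermPattern):
        return [_instantiate(t) for t in node.tokens]
    if isinstance(node, Adj):
        return _witness_tokens(node.left) + _witness_tokens(node.right)
    if isinstance(node, And):
        out: list[str] = []
        for c in node.children:
            out.extend(_witness_tokens(c))
        return out
    if isinstance(node, Or):
        return _witness_tokens(node.children[0])
    raise ValueError(
        f"cannot plant a witness for {type(node).__name__} queries "
        "(NOT and line references are not plantable)"
    )


def _witness_field(spec: QuerySpec) -> tuple[str, list[str]]:
    """Return (record field to inject into, witness token list)."""
    node = parse_query(spec.query)
    scope = "mp"
    if isinstance(node, FieldScope):
        scope, node = node.code, node.child
    target = {
        "af": "title",
        "mp": "title",
        "ti": "title",
        "ab": "abstract",
        "ab,ti": "abstract",
        "sh": "heading",
    }[scope]
    return target, _witness_tokens(node)


def _max_adj_distance(node: QueryNode) -> int:
    if isinstance(node, Adj):
        return max(
            node.distance, _max_adj_distance(node.left), _max_adj_distance(node.right)
        )
    if isinstance(node, (And, Or)):
        return max((_max_adj_distance(c) for c in node.children), default=1)
    if isinstance(node, FieldScope):
        return _max_adj_distance(node.child)
    return 1


def _pattern_tokens(node: QueryNode) -> set[str]:
    if isinstance(node, TermPattern):
        return set(node.tokens)
    if isinstance(node, Adj):
        return _pattern_tokens(node.left) | _pattern_tokens(node.right)
    if isinstance(node, (And, Or)):
        out: set[str] = set()
        for c in node.children:
            out |= _pattern_tokens(c)
        return out
    if isinstance(node, FieldScope):
        return _pattern_tokens(node.child)
    return set()


def _screen_vocabulary(specs: Sequence[QuerySpec]) -> list[str]:
    from .query import _compile_token  # shared pattern-token semantics

    pattern_tokens = set()
    for spec in specs:
        pattern_tokens |= _pattern_tokens(parse_query(spec.query))
    compiled = [_compile_token(t) for t in pattern_tokens]
    vocab = [w for w in FILLER_VOCABULARY if not any(p.fullmatch(w) for p in compiled)]
    if len(vocab) < 10:
        raise ValueError("query specs match nearly all filler vocabulary; cannot generate")
    return vocab


def _check_interference(specs: Sequence[QuerySpec]) -> None:
    """Exact-counts planting requires that no spec matches another's witness."""
    from .query import evaluate

    witnesses = {s.query: _witness_field(s) for s in specs}
    for spec in specs:
        target, tokens = witnesses[spec.query]
        rec = DocumentRecord(
            doc_id="probe",
            title=" ".join(tokens) if target == "title" else "",
            abstract=" ".join(tokens) if target == "abstract" else "",
            subject_headings=[" ".join(tokens)] if target == "heading" else [],
            source_dbs={"EMBASE"},
            relevant=True,
        )
        probe = Corpus(records=[rec], name="probe")
        for other in specs:
            if other.query == spec.query:
                continue
            hit = evaluate(parse_query(other.query), probe, label=other.query)
            if hit.doc_ids:
                raise ValueError(
                    f"query specs interfere: {other.query!r} matches the planted "
                    f"text of {spec.query!r}; exact-counts planting would be wrong"
                )


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------


def _year_sampler(config: GeneratorConfig, rng: np.random.Generator):
    if config.year_distribution:
        years = sorted(config.year_distribution)
        weights = np.array([config.year_distribution[y] for y in years], dtype=float)
        weights /= weights.sum()
        return lambda n: rng.choice(years, size=n, p=weights)
    lo, hi = config.year_range
    early = list(range(lo, config.recent_from))
    late = list(range(config.recent_from, hi + 1))

    def sample(n: int):
        recent = rng.random(n) < config.recent_fraction
        out = np.empty(n, dtype=int)
        out[recent] = rng.choice(late, size=int(recent.sum()))
        out[~recent] = rng.choice(early, size=int((~recent).sum()))
        return out

    return sample if early and late else (lambda n: rng.choice(list(range(lo, hi + 1)), size=n))


def _planted_counts(
    spec: QuerySpec, n_internal: int, n_irrelevant: int
) -> tuple[int, int]:
    r = round(spec.sensitivity * n_internal)
    t = round(r / spec.precision) if r else 0
    fp = t - r
    if fp > n_irrelevant:
        raise ValueError(
            f"unsatisfiable spec {spec.query!r}: needs {fp} irrelevant matches "
            f"but only {n_irrelevant} irrelevant documents exist at this prevalence"
        )
    return r, fp


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[Corpus, GoldStandard, GeneratorManifest]:
    """Generate a labelled corpus with planted query matches.

    Deterministic under ``config.seed``.  In ``exact-counts`` mode the
    planted documents are chosen by sampling without replacement so realized
    counts hit the targets exactly; in ``bernoulli`` mode each document is
    planted independently, giving binomial variation around the targets.
    """
    rng = np.random.default_rng(config.seed)
    specs = list(config.query_specs)
    vocab = _screen_vocabulary(specs)
    if config.mode == "exact-counts" and specs:
        _check_interference(specs)

    n_rel = round(config.prevalence * config.n_docs)
    n_int = round(config.internal_fraction * n_rel)
    n_irr = config.n_docs - n_rel
    if n_int == 0 or n_irr == 0:
        raise ValueError("degenerate configuration: need internal-relevant and irrelevant docs")

    ids = [f"D{i:06d}" for i in range(config.n_docs)]
    order = rng.permutation(config.n_docs)
    internal_idx = sorted(order[:n_int])
    external_idx = sorted(order[n_int:n_rel])  # relevant, other database only
    irrelevant_idx = sorted(order[n_rel:])

    years = _year_sampler(config, rng)(config.n_docs)

    # planting assignments
    planted: dict[int, list[QuerySpec]] = {}
    for spec in specs:
        if config.mode == "exact-counts":
            r, fp = _planted_counts(spec, n_int, n_irr)
            chosen_rel = rng.choice(internal_idx, size=r, replace=False)
            chosen_irr = rng.choice(irrelevant_idx, size=fp, replace=False)
        else:
            rate_irr = (
                spec.sensitivity * n_int * (1 - spec.precision)
                / (spec.precision * n_irr)
            )
            if rate_irr > 1.0:
                raise ValueError(
                    f"unsatisfiable spec {spec.query!r}: implied irrelevant match "
                    f"rate {rate_irr:.3f} exceeds 1 at this prevalence"
                )
            chosen_rel = [i for i in internal_idx if rng.random() < spec.sensitivity]
            chosen_irr = [i for i in irrelevant_idx if rng.random() < rate_irr]
        for i in [*chosen_rel, *chosen_irr]:
            planted.setdefault(int(i), []).append(spec)

    witness = {s.query: _witness_field(s) for s in specs}
    # filler gap between planted segments wide enough that no adjN pattern
    # can bridge two different witnesses in the same field
    pad = max((_max_adj_distance(parse_query(s.query)) for s in specs), default=1)
    internal_set = set(internal_idx)
    external_set = set(external_idx)

    records: list[DocumentRecord] = []
    manifest_planted: dict[str, list[str]] = {}
    for i in range(config.n_docs):
        doc_id = ids[i]
        relevant = i in internal_set or i in external_set
        if i in internal_set:
            dbs = {"EMBASE", "MEDLINE"} if rng.random() < 0.5 else {"EMBASE"}
        elif i in external_set:
            dbs = {"MEDLINE"}
        else:
            dbs = {"EMBASE"}
        title = list(rng.choice(vocab, size=4))
        abstract = list(rng.choice(vocab, size=24))
        headings = [" ".join(rng.choice(vocab, size=2))]
        for spec in planted.get(i, []):
            target, tokens = witness[spec.query]
            if target == "title":
                title += list(rng.choice(vocab, size=pad)) + tokens
            elif target == "abstract":
                abstract += list(rng.choice(vocab, size=pad)) + tokens
            else:
                headings.append(" ".join(tokens))
            manifest_planted.setdefault(doc_id, []).append(spec.query)
        records.append(
            DocumentRecord(
                doc_id=doc_id,
                accessions=[f"A{i:07d}"],
                title=" ".join(title),
                abstract=" ".join(abstract),
                subject_headings=headings,
                pub_year=int(years[i]),
                source_dbs=dbs,
                relevant=relevant,
                pub_type="article",
            )
        )

    # vendor-style duplicates: clones with their own accession and a
    # typographic title variant that normalizes identically
    n_pairs = round(config.duplicate_rate * config.n_docs)
    n_tris = round(config.triplicate_rate * config.n_docs)
    clusters: list[list[str]] = []
    if n_pairs + n_tris:
        base_idx = rng.choice(config.n_docs, size=n_pairs + n_tris, replace=False)
        for j, bi in enumerate(sorted(int(b) for b in base_idx)):
            base = records[bi]
            n_clones = 2 if j >= n_pairs else 1
            cluster = [base.doc_id]
            for k in range(n_clones):
                clone_id = f"{base.doc_id}c{k + 1}"
                clone = base.model_copy(
                    update={
                        "doc_id": clone_id,
                        "accessions": [f"A{bi:07d}x{k + 1}"],
                        "title": base.title.capitalize() + ".",
                    }
                )
                records.append(clone)
                cluster.append(clone_id)
                if base.doc_id in manifest_planted:
                    manifest_planted[clone_id] = list(manifest_planted[base.doc_id])
            clusters.append(cluster)

    corpus = Corpus(records=records, name=f"synthetic-{config.seed}")
    gold = corpus.gold_standard("EMBASE")

    query_counts: dict[str, dict[str, int]] = {}
    for spec in specs:
        hit_ids = [d for d, qs in manifest_planted.items() if spec.query in qs]
        query_counts[spec.query] = {
            "retrieved": len(hit_ids),
            "relevant_retrieved": len(set(hit_ids) & gold.full_set),
        }

    year_counts: dict[int, int] = {}
    for rec in records:
        year_counts[rec.pub_year] = year_counts.get(rec.pub_year, 0) + 1

    manifest = GeneratorManifest(
        relevant_ids=sorted(gold.full_set),
        internal_ids=sorted(gold.internal_set),
        planted={k: sorted(v) for k, v in sorted(manifest_planted.items())},
        duplicate_clusters=clusters,
        query_counts=query_counts,
        year_counts=year_counts,
        seed=config.seed,
    )
    return corpus, gold, manifest


# ---------------------------------------------------------------------------
# Matrix-only workflow
# ---------------------------------------------------------------------------


def generate_retrieval_matrix(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Binary query×document retrieval matrix with relevance labels.

    Rows are the configured queries, columns document ids; entry (q, d) says
    whether query q retrieves document d.  ``exact-counts`` mode assigns
    matches by sampling without replacement (hypergeometric margins);
    ``bernoulli`` draws each entry independently at the relevance-conditional
    rate.  The manifest reports realized row sums.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_docs
    n_rel = round(config.prevalence * n)
    n_irr = n - n_rel
    ids = [f"D{i:06d}" for i in range(n)]
    order = rng.permutation(n)
    rel_idx, irr_idx = sorted(order[:n_rel]), sorted(order[n_rel:])
    labels = pd.Series(False, index=ids, name="relevant")
    labels.iloc[rel_idx] = True

    matrix = pd.DataFrame(
        False, index=[s.query for s in config.query_specs], columns=ids
    )
    manifest: dict = {"query_counts": {}, "n_relevant": n_rel, "seed": config.seed}
    for spec in config.query_specs:
        if config.mode == "exact-counts":
            r, fp = _planted_counts(spec, n_rel, n_irr)
            hit_rel = rng.choice(rel_idx, size=r, replace=False)
            hit_irr = rng.choice(irr_idx, size=fp, replace=False)
        else:
            rate_irr = (
                spec.sensitivity * n_rel * (1 - spec.precision)
                / (spec.precision * n_irr)
            )
            if rate_irr > 1.0:
                raise ValueError(f"unsatisfiable spec {spec.query!r}")
            hit_rel = [i for i in rel_idx if rng.random() < spec.sensitivity]
            hit_irr = [i for i in irr_idx if rng.random() < rate_irr]
        cols = matrix.columns[[*map(int, hit_rel), *map(int, hit_irr)]]
        matrix.loc[spec.query, cols] = True
        manifest["query_counts"][spec.query] = {
            "retrieved": len(hit_rel) + len(hit_irr),
            "relevant_retrieved": len(hit_rel),
        }
    return matrix, labels, manifest
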