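"""Retrieval diagnostics against the dual gold standard.

Sensitivity (recall), precision (positive predictive value) and the number
needed to read (NNR = 100 / precision) for single queries or cumulative
strategy lines.  Overall sensitivity divides by the full cross-database
gold-standard set; within-database sensitivity divides by the internal
subset indexed in the target database — the numerator is the same, so
within-database sensitivity is never smaller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import pandas as pd

from .corpus import Corpus, GoldStandard
from .query import RetrievalSet

__all__ = [
    "PerformanceRow",
    "sensitivity",
    "precision",
    "nnr",
    "evaluate_performance",
    "performance_table",
    "rows_to_frame",
    "round_half_up",
]


def sensitivity(n_relevant_retrieved: int, n_relevant_total: int) -> float:
    """Percentage of the relevant set that was retrieved."""
    if n_relevant_total <= 0:
        raise ValueError("sensitivity undefined for an empty relevant set")
    if not 0 <= n_relevant_retrieved <= n_relevant_total:
        raise ValueError(
            f"need 0 ≤ retrieved ({n_relevant_retrieved}) ≤ total ({n_relevant_total})"
        )
    return 100.0 * n_relevant_retrieved / n_relevant_total


def precision(n_relevant_retrieved: int, n_retrieved: int) -> float:
    """Percentage of retrieved records that are relevant.

    Undefined (not zero) when nothing was retrieved; returns NaN so callers
    can distinguish "no retrieval" from "all retrieved records irrelevant".
    """
    if n_retrieved < 0 or n_relevant_retrieved < 0:
        raise ValueError("counts must be non-negative")
    if n_relevant_retrieved > n_retrieved:
        raise ValueError("relevant retrieved cannot exceed retrieved")
    if n_retrieved == 0:
        return math.nan
    return 100.0 * n_relevant_retrieved / n_retrieved


def nnr(precision_pct: float) -> float:
    """Number needed to read: records screened per relevant record found."""
    if math.isnan(precision_pct):
        return math.nan
    if precision_pct <= 0:
        return math.inf
    return 100.0 / precision_pct


@dataclass(frozen=True)
class PerformanceRow:
    """One line of a performance table: counts plus derived percentages."""

    label: str
    n_retrieved: int
    n_relevant_retrieved: int
    sensitivity_full: float
    sensitivity_internal: float
    precision: float
    nnr: float

    @classmethod
    def from_counts(
        cls,
        label: str,
        n_relevant_retrieved: int,
        n_retrieved: int,
        n_full: int,
        n_internal: int,
    ) -> "PerformanceRow":
        """Build a row from raw counts and the two gold-standard sizes."""
        prec = precision(n_relevant_retrieved, n_retrieved)
        return cls(
            label=label,
            n_retrieved=n_retrieved,
            n_relevant_retrieved=n_relevant_retrieved,
            sensitivity_full=sensitivity(n_relevant_retrieved, n_full),
            sensitivity_internal=sensitivity(n_relevant_retrieved, n_internal),
            precision=prec,
            nnr=nnr(prec),
        )


def evaluate_performance(
    retrieval: RetrievalSet, gold: GoldStandard, corpus: Corpus
) -> PerformanceRow:
    """Score one retrieval set against the dual gold standard.

    The retrieval set must come from this corpus, and the corpus relevance
    labels must agree with the gold standard for every labelled record it
    contains (explicit id-list gold standards may extend beyond the corpus,
    e.g. relevant records only indexed elsewhere).
    """
    unknown = retrieval.doc_ids - corpus.doc_ids
    if unknown:
        raise ValueError(f"retrieval contains ids outside the corpus: {sorted(unknown)[:5]}")
    for doc_id in gold.full_set & corpus.doc_ids:
        if not corpus[doc_id].relevant:
            raise ValueError(f"gold standard lists {doc_id} but corpus labels it irrelevant")
    n_rel_ret = len(retrieval.doc_ids & gold.full_set)
    return PerformanceRow.from_counts(
        label=retrieval.query_label,
        n_relevant_retrieved=n_rel_ret,
        n_retrieved=len(retrieval.doc_ids),
        n_full=gold.n_full,
        n_internal=gold.n_internal,
    )


def performance_table(
    retrievals: Sequence[RetrievalSet],
    corpus: Corpus,
    gold: GoldStandard,
) -> list[PerformanceRow]:
    """One row per query, sorted by overall sensitivity (desc), ties broken
    by precision (desc) then label."""
    if not retrievals:
        raise ValueError("need at least one retrieval set")
    rows = [evaluate_performance(rs, gold, corpus) for rs in retrievals]
    return sorted(
        rows,
        key=lambda r: (
            -r.sensitivity_full,
            -(r.precision if not math.isnan(r.precision) else -1.0),
            r.label,
        ),
    )


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (the rounding used in printed tables, where
    banker's rounding would disagree on ties)."""
    if math.isnan(x) or math.isinf(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


#: presentation profiles: single-query tables print 1 decimal, cumulative
#: strategy tables print 2
ROUNDING_PROFILES = {"table1": 1, "table23": 2}

_COLUMNS = [
    "label",
    "n_relevant_retrieved",
    "n_retrieved",
    "sensitivity_full",
    "sensitivity_internal",
    "precision",
    "nnr",
]


def rows_to_frame(
    rows: Iterable[PerformanceRow],
    rounding: Optional[str] = None,
    include_nnr: bool = True,
) -> pd.DataFrame:
    """Render rows as a DataFrame in the canonical column order, optionally
    rounding percentages with a presentation profile."""
    frame = pd.DataFrame(
        [
            {
                "label": r.label,
                "n_relevant_retrieved": r.n_relevant_retrieved,
                "n_retrieved": r.n_retrieved,
                "sensitivity_full": r.sensitivity_full,
                "sensitivity_internal": r.sensitivity_internal,
                "precision": r.precision,
                "nnr": r.nnr,
            }
            for r in rows
        ],
        columns=_COLUMNS,
    )
    if rounding is not None:
        nd = ROUNDING_PROFILES[rounding]
        for col in ("sensitivity_full", "sensitivity_internal", "precision"):
            frame[col] = frame[col].map(lambda v: round_half_up(v, nd))
        frame["nnr"] = frame["nnr"].map(lambda v: round_half_up(v, 1))
    if not include_nnr:
        frame = frame.drop(columns=["nnr"])
    return frame
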