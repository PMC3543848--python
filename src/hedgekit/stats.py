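"""Hypothesis tests for comparing retrieval strategies and strata.

Two paired strategies searching the same relevant records form a 2×2 paired
table (both / A-only / B-only / neither); the discordant cells drive the
McNemar test.  Independent stratum comparisons (e.g. sensitivity in two
publication periods) use Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats as sps

__all__ = ["PairedRetrievalTable", "McNemarResult", "mcnemar", "fisher_exact"]


@dataclass(frozen=True)
class PairedRetrievalTable:
    """Paired retrieval outcomes over one set of records.

    ``a``: retrieved by both strategies; ``b``: by A only; ``c``: by B only;
    ``d``: by neither.  Only the discordant counts ``b`` and ``c`` matter
    for the McNemar test.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_sets(
        cls, retrieved_a: frozenset[str] | set[str], retrieved_b: frozenset[str] | set[str],
        universe: frozenset[str] | set[str],
    ) -> "PairedRetrievalTable":
        """Cross-tabulate two retrieval sets over a reference universe
        (typically the relevant gold-standard records)."""
        ra, rb = set(retrieved_a) & set(universe), set(retrieved_b) & set(universe)
        both = len(ra & rb)
        return cls(
            a=both,
            b=len(ra) - both,
            c=len(rb) - both,
            d=len(universe) - len(ra | rb),
        )


@dataclass(frozen=True)
class McNemarResult:
    statistic: float  # chi-square statistic (NaN for the exact variant)
    p_value: float
    variant: str
    degenerate: bool = False


def mcnemar(
    table: PairedRetrievalTable, variant: str = "auto", correction: bool = False
) -> McNemarResult:
    """McNemar test for paired retrieval outcomes.

    ``exact``: two-sided binomial tail — double the smaller tail of
    Binomial(b+c, ½) at min(b, c), capped at 1.  ``chi2``: (b−c)²/(b+c)
    against χ² with 1 df; ``correction`` applies the Yates continuity
    correction (|b−c|−1)²/(b+c), which tracks the exact p closely for large
    discordance.  ``auto`` picks exact when b+c < 25.  Both discordant cells
    zero is degenerate: p = 1 by convention, flagged.
    """
    b, c = table.b, table.c
    n_disc = b + c
    if variant not in ("auto", "exact", "chi2"):
        raise ValueError(f"unknown variant {variant!r}")
    if n_disc == 0:
        return McNemarResult(statistic=0.0, p_value=1.0, variant=variant, degenerate=True)
    if variant == "auto":
        variant = "exact" if n_disc < 25 else "chi2"
    if variant == "exact":
        p = min(1.0, 2.0 * float(sps.binom.cdf(min(b, c), n_disc, 0.5)))
        return McNemarResult(statistic=float("nan"), p_value=p, variant="exact")
    diff = max(abs(b - c) - 1, 0) if correction else abs(b - c)
    stat = diff**2 / n_disc
    p = float(sps.chi2.sf(stat, df=1))
    return McNemarResult(statistic=stat, p_value=p, variant="chi2")


def fisher_exact(table: tuple[tuple[int, int], tuple[int, int]]) -> float:
    """Two-sided Fisher exact p-value for an independent 2×2 table
    (sum of hypergeometric probabilities ≤ the observed table's)."""
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("Fisher exact test requires positive margins")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
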