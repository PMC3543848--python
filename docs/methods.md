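# Methods

## Problem setting

Search-filter (hedge) development asks: given a database of bibliographic
records and a gold standard of records known to be relevant to a topic,
which boolean query — or ordered combination of queries — retrieves as many
relevant records as possible (sensitivity) without drowning the screener in
irrelevant ones (precision)? hedgekit reproduces this workflow locally: the
database is a labelled corpus, queries are Ovid-dialect strings, and
strategies are numbered query lists combined with OR/NOT.

Two gold standards are carried everywhere. The *full* set contains every
relevant record across the source databases; the *internal* set is the
subset indexed in the target database. A strategy cannot retrieve what the
database lacks, so overall sensitivity (full-set denominator) is bounded by
|internal|/|full| while within-database sensitivity (internal denominator)
can reach 100%. Both share the same numerator: the relevant records the
strategy actually retrieved.

## Query language semantics

Document text is tokenized by lowercasing and splitting on every
non-alphanumeric character; "off-label" and "off label" are identical token
sequences, which is required for truncated phrase queries to behave as
search interfaces do. Pattern tokens support `*` (any trailing characters,
including none), `?` (zero or one character — `li?en?e` covers licence,
license and licene) and `#` (exactly one character).

Semantics, by operator:

- An unnumbered phrase means exact in-order adjacency of its tokens.
- `adjN` matches when its two operands occur in the same field with at most
  N−1 intervening tokens, in either order (a flag forces in-order matching
  for stricter dialects). Chained `adj` groups parse left-associatively;
  the combined match's span anchors the next proximity test at its
  outermost matched tokens. Interface vendors do not document their exact
  span rule for chained proximity; the left-associative choice is recorded
  here, not claimed vendor-identical.
- Precedence, tightest first: `adjN`, `AND`, `NOT`, `OR`; parentheses
  override. A trailing field code scopes the preceding operand.
- Field scopes are nested by construction: `.ab.`/`.ti.` ⊂ `.ab,ti.` ⊂
  `.mp.` (title, abstract, subject headings) ⊂ `.af.` (additionally
  publication type and accession numbers). The real all-fields scope of a
  vendor interface covers fields this data model does not store (e.g.
  manufacturer names) — a documented divergence. `.sh.` matches a whole
  subject-heading string, case-insensitively, with no thesaurus explosion
  (explosion needs the vocabulary tree; narrower headings can be listed
  explicitly instead).
- `or/a-b` inside a strategy is the union of earlier lines; forward
  references are errors.

The lexer treats `)` and the truncation `*` as token terminators and skips
stray commas, so strategy lines that circulate with typographic artifacts
(missing spaces after parentheses or truncation marks, trailing commas)
load verbatim.

## Metrics and presentation

Sensitivity, precision and NNR are kept at full floating precision
internally; presentation rounds half-up (`decimal`-based, since banker's
rounding disagrees on ties) to 1 decimal for single-query tables and 2 for
cumulative strategy tables — the conventions of the published benchmark
tables, which the test suite reproduces cell-for-cell from their printed
integer counts. Precision of an empty retrieval is NaN (undefined), kept
distinct from 0% (all retrieved records irrelevant).

## Strategy optimization

Maximizing relevant coverage by OR-combination is an unconstrained
maximum-coverage problem. Greedy selection — repeatedly add the query with
the largest marginal relevant gain, ties broken by the query's own
precision then label, stop at zero gain — reaches the same covered-relevant
count as exhaustive subset enumeration, because the union of all selected
queries is reached either way; the greedy order additionally gives the
cumulative table its reporting order. Exhaustive enumeration is retained
for pools of at most 12 queries (4,096 subsets) both as an oracle and for
the retrieved-count tie-break (smallest total retrieved among coverage
maxima); enumerating all combinations of a 77-query pool (2^77) is not
meaningful, so larger pools use greedy or beam search.

The sensitivity/precision trade-off is a Pareto frontier over explored
subsets. The selection criterion is pluggable because published strategy
work rarely states one: minimal Euclidean distance to the ideal point
(100, 100) is the default, with max-F1 and the knee (maximal perpendicular
distance from the chord between frontier extremes) as alternatives; ties go
to higher sensitivity. The chosen criterion is recorded in output metadata.

NOT refinement selects exclusion terms by two thresholds over the
strategy's retrieved set: minimum frequency among retrieved *irrelevant*
records and maximum frequency among retrieved *relevant* records (defaults
1% and 0.1%). Selected terms are appended as `(or/1-k) not (t1 or t2
...).af.`; the report carries the precision gain and sensitivity cost. A
NOT clause can only shrink the retrieved set, so sensitivity never rises.

## Statistical tests

Paired strategy comparisons over one set of relevant records use the
McNemar test on the discordant counts b, c: the exact variant doubles the
smaller binomial(b+c, ½) tail and caps at 1; the chi-square variant refers
(b−c)²/(b+c) to χ²₁, with an optional Yates continuity correction
((|b−c|−1)²/(b+c)) that tracks the exact p to within 10⁻³ for large
discordance — the uncorrected statistic can differ from the exact p by up
to ~0.09 near b = c, where the capped exact p is 1. Auto mode uses the
exact variant below 25 discordant pairs. Independent stratum comparisons
use Fisher's exact test (two-sided, sum of hypergeometric probabilities not
exceeding the observed table's), delegated to scipy and cross-checked in
tests against direct enumeration.

## Synthetic corpora

The generator's defaults are the benchmark's study conditions: relevance
prevalence 4067/6785 ≈ 0.60, internal fraction 3846/4067 ≈ 0.946, 90.5% of
records in the 2001–2011 period (uniform within periods), duplicate and
triplicate rates 206/6785 and 2/6785, and a dominant query planted at
within-database sensitivity 0.819 / precision 0.881 — the benchmark's best
single query — plus two long-tail queries at 0.08/0.25 and 0.05/0.30
(single-query rates for tail queries are not published; these are chosen
once as plausible magnitudes for rare-synonym candidates).

Planting works by realizing a *witness* token sequence from the parsed
query (wildcards instantiated at their shortest expansion, proximity
operands placed adjacent) and appending it to the scoped field of selected
documents. Two modes: `exact-counts` assigns matches by sampling without
replacement so realized counts hit targets exactly (used where tests need
non-flaky equality with the manifest), and `bernoulli` draws per-document
coins (used for statistical property tests; the irrelevant-document rate is
derived from the precision target and prevalence, and unsatisfiable
targets are rejected before generation). Filler text comes from a fixed
neutral vocabulary screened at build time against every planted pattern
token, and consecutive witnesses are separated by a filler gap wider than
the largest `adjN` distance, so no accidental matches arise; in
exact-counts mode the generator additionally verifies that no configured
query matches another's witness and refuses interfering spec sets.
Relevant records outside the target database receive no planted text —
they are the retrievable-nowhere slice that separates overall from
within-database sensitivity. Duplicate clones carry their own accession and
a typographic title variant that normalizes identically, exercising the
deduplication keys.

What the generator does not emulate: natural language (text is token
soup), correlated query overlap beyond co-planting, thesaurus structure,
and indexing drift over time. Passing tests therefore demonstrate correct
mechanics — parsing, matching, counting, optimization, planting — not
performance of any strategy on real databases.

## Problem sizes and numerical choices

The test suite and acceptance script run on synthetic corpora of 400–4,000
documents and pools of up to 15 queries; the parameter-recovery check uses
n = 4,000 with a 99% binomial interval, and the optimizer-agreement check
uses 120 random pools of up to 12 queries × 100 documents against bitmask
subset enumeration. These sizes give stable statistics while keeping the
full suite under a minute. Deduplication uses union-find over shared
accessions and normalized title + year (lowercase, diacritics and
punctuation stripped, whitespace collapsed); the exact duplicate-clustering
keys of vendor databases are undocumented, so the policy is configurable.
Conflicting relevance labels within a duplicate cluster raise rather than
merge. All optimizer tie-breaks are total and deterministic (gain, own
precision, label), so runs reproduce without seeds; generator runs are
byte-identical under a fixed seed.

## Known limitations

- The all-fields scope is narrower than a live interface's; `.sh.` does not
  explode; `AND` is document-level within the scoped fields.
- Frontier beam search is heuristic beyond the exhaustive cap; returned
  points are guaranteed non-dominated among explored subsets only.
- The benchmark corpus itself is not redistributable, so full-corpus
  searches are validated on synthetic corpora; only the printed counts of
  the benchmark tables are reproduced exactly.
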