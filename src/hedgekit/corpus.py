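"""Labelled bibliographic corpora: data model, I/O, deduplication, stratification.

A corpus is a collection of :class:`DocumentRecord` objects — bibliographic
records with searchable text fields (title, abstract, subject headings), a
provenance marker (which source database(s) index the record) and a binary
relevance label.  The relevance labels induce the dual gold standard used
throughout: the *full* set of all relevant records across databases and the
*internal* subset retrievable from the target database.
"""

from __future__ import annotations

import csv
import io
import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator

__all__ = [
    "DocumentRecord",
    "GoldStandard",
    "Corpus",
    "CorpusValidationError",
    "DedupPolicy",
    "read_corpus",
    "write_corpus",
    "dedup_records",
    "stratify_by_year",
]

SourceDB = Literal["EMBASE", "MEDLINE"]

#: publication categories dropped at load time (flag-controlled, default on)
EXCLUDED_PUB_TYPES = frozenset({"book series", "video", "erratum", "correction"})

YEAR_MIN, YEAR_MAX = 1900, 2100


class CorpusValidationError(ValueError):
    """A corpus file or record set violates a structural invariant."""


class DocumentRecord(BaseModel):
    """One bibliographic record with searchable fields and a relevance label.

    ``doc_id`` is the primary identifier; accession numbers are secondary
    because one logical record can carry several accessions (database
    duplicates are clustered on them, not identified by them).
    """

    doc_id: str
    accessions: list[str] = Field(default_factory=list)
    title: str = ""
    abstract: str = ""  # may be empty: letters often lack abstracts
    subject_headings: list[str] = Field(default_factory=list)
    pub_year: Optional[int] = None
    source_dbs: set[SourceDB]
    relevant: bool
    pub_type: str = "article"

    @field_validator("doc_id")
    @classmethod
    def _nonempty_id(cls, v: str) -> str:
        if not v:
            raise ValueError("doc_id must be non-empty")
        return v

    @field_validator("source_dbs")
    @classmethod
    def _nonempty_dbs(cls, v: set[str]) -> set[str]:
        if not v:
            raise ValueError("source_dbs must be non-empty")
        return v

    @field_validator("pub_year")
    @classmethod
    def _plausible_year(cls, v: Optional[int]) -> Optional[int]:
        if v is not None and not (YEAR_MIN <= v <= YEAR_MAX):
            raise ValueError(f"pub_year {v} outside plausible range {YEAR_MIN}-{YEAR_MAX}")
        return v


@dataclass(frozen=True)
class GoldStandard:
    """Dual gold standard: full (cross-database) and internal relevant sets.

    ``internal_set`` ⊆ ``full_set``; the full set is the denominator of
    overall sensitivity, the internal set of within-database sensitivity.
    """

    full_set: frozenset[str]
    internal_set: frozenset[str]

    def __post_init__(self) -> None:
        if not self.internal_set <= self.full_set:
            raise CorpusValidationError("internal gold-standard set must be a subset of the full set")

    @property
    def n_full(self) -> int:
        return len(self.full_set)

    @property
    def n_internal(self) -> int:
        return len(self.internal_set)


@dataclass
class Corpus:
    records: list[DocumentRecord] = field(default_factory=list)
    name: str = "corpus"
    snapshot_date: str = ""

    _by_id: dict[str, DocumentRecord] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.doc_id in self._by_id:
                raise CorpusValidationError(f"duplicate doc_id {rec.doc_id!r} in corpus")
            self._by_id[rec.doc_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[DocumentRecord]:
        return iter(self.records)

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self._by_id

    def __getitem__(self, doc_id: str) -> DocumentRecord:
        return self._by_id[doc_id]

    @property
    def doc_ids(self) -> frozenset[str]:
        return frozenset(self._by_id)

    def gold_standard(self, target_db: SourceDB = "EMBASE") -> GoldStandard:
        """Derive the dual gold standard from the relevance labels.

        The internal set holds relevant records indexed in ``target_db``.
        """
        full = frozenset(r.doc_id for r in self.records if r.relevant)
        internal = frozenset(
            r.doc_id for r in self.records if r.relevant and target_db in r.source_dbs
        )
        return GoldStandard(full_set=full, internal_set=internal)

    def restrict_to_db(self, db: SourceDB) -> "Corpus":
        """Sub-corpus of records indexed in one source database."""
        return Corpus(
            records=[r for r in self.records if db in r.source_dbs],
            name=f"{self.name}[{db}]",
            snapshot_date=self.snapshot_date,
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_LIST_SEP = ";"

# minimal RIS-like tag dialect
_RIS_TAGS = {
    "TI": "title",
    "AB": "abstract",
    "KW": "subject_headings",
    "PY": "pub_year",
    "AN": "accessions",
    "DB": "source_dbs",
    "ID": "doc_id",
    "RL": "relevant",
    "PT": "pub_type",
}


def _record_from_mapping(raw: dict, lineno: int) -> DocumentRecord:
    try:
        return DocumentRecord.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError or type errors
        raise CorpusValidationError(f"line {lineno}: invalid record: {exc}") from exc


def _iter_jsonl(path: Path) -> Iterator[tuple[int, dict]]:
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                yield lineno, json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusValidationError(f"line {lineno}: malformed JSON: {exc}") from exc


def _iter_csv(path: Path) -> Iterator[tuple[int, dict]]:
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):  # header is line 1
            raw: dict = dict(row)
            for key in ("accessions", "subject_headings", "source_dbs"):
                val = raw.get(key) or ""
                raw[key] = [p.strip() for p in val.split(_LIST_SEP) if p.strip()]
            raw["source_dbs"] = set(raw["source_dbs"])
            raw["relevant"] = str(raw.get("relevant", "")).strip().lower() in {"1", "true", "yes"}
            year = str(raw.get("pub_year") or "").strip()
            raw["pub_year"] = int(year) if year else None
            yield lineno, raw


def _iter_ris(path: Path) -> Iterator[tuple[int, dict]]:
    """Minimal RIS-like tagged records separated by ``ER  -`` lines."""
    raw: dict = {}
    start_line = 1
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            m = re.match(r"^([A-Z]{2})\s{2}-\s?(.*)$", line)
            if not m:
                raise CorpusValidationError(f"line {lineno}: malformed tag line {line!r}")
            tag, value = m.group(1), m.group(2).strip()
            if tag == "ER":
                if raw:
                    yield start_line, _finalize_ris(raw)
                raw, start_line = {}, lineno + 1
                continue
            fieldname = _RIS_TAGS.get(tag)
            if fieldname is None:
                continue  # unknown tags are skipped, as RIS readers do
            if fieldname in ("subject_headings", "accessions", "source_dbs"):
                raw.setdefault(fieldname, []).append(value)
            else:
                raw[fieldname] = value
    if raw:
        yield start_line, _finalize_ris(raw)


def _finalize_ris(raw: dict) -> dict:
    out = dict(raw)
    out["source_dbs"] = set(out.get("source_dbs", []))
    out["relevant"] = str(out.get("relevant", "")).strip().lower() in {"1", "true", "yes"}
    if "pub_year" in out:
        out["pub_year"] = int(str(out["pub_year"]).split("/")[0])
    return out


_FORMATS = {"jsonl": _iter_jsonl, "csv": _iter_csv, "ris": _iter_ris}
_EXT_FORMAT = {".jsonl": "jsonl", ".json": "jsonl", ".csv": "csv", ".ris": "ris", ".txt": "ris"}


def read_corpus(
    path: str | Path,
    format: str | None = None,
    *,
    name: str | None = None,
    drop_excluded_pub_types: bool = True,
) -> Corpus:
    """Load a labelled corpus from JSONL (canonical), CSV or a RIS-like file.

    Records whose publication category is methodologically excluded (book
    series, videos, errata, corrections) are dropped when
    ``drop_excluded_pub_types`` is set (the default).  Records failing field
    validation raise :class:`CorpusValidationError` naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _EXT_FORMAT.get(path.suffix.lower())
    if fmt not in _FORMATS:
        raise ValueError(f"unknown corpus format {fmt!r} for {path}")
    records: list[DocumentRecord] = []
    seen: dict[str, int] = {}
    for lineno, raw in _FORMATS[fmt](path):
        rec = _record_from_mapping(raw, lineno)
        if drop_excluded_pub_types and rec.pub_type.strip().lower() in EXCLUDED_PUB_TYPES:
            continue
        if rec.doc_id in seen:
            raise CorpusValidationError(
                f"duplicate doc_id {rec.doc_id!r} at lines {seen[rec.doc_id]} and {lineno}"
            )
        seen[rec.doc_id] = lineno
        records.append(rec)
    return Corpus(records=records, name=name or path.stem)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as canonical JSON-lines (one record per line)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in corpus.records:
            payload = rec.model_dump()
            payload["source_dbs"] = sorted(payload["source_dbs"])
            fh.write(json.dumps(payload, ensure_ascii=False) + "\n")


def read_gold_standard(path: str | Path) -> GoldStandard:
    """Explicit gold-standard override: JSON with full_set / internal_set id lists."""
    with Path(path).open("r", encoding="utf-8") as fh:
        data = json.load(fh)
    return GoldStandard(
        full_set=frozenset(data["full_set"]),
        internal_set=frozenset(data["internal_set"]),
    )


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DedupPolicy:
    """Keys used to cluster duplicate records.

    Vendor databases cluster duplicates on shared accession numbers and on
    near-identical bibliographic fields; the exact keys are configurable
    because vendors do not document theirs.
    """

    by_accession: bool = True
    by_title_year: bool = True


_PUNCT_RE = re.compile(r"[^\w\s]", flags=re.UNICODE)
_WS_RE = re.compile(r"\s+")


def normalize_title(title: str) -> str:
    """Lowercase, strip diacritics and punctuation, collapse whitespace.

    Duplicate records often differ only typographically, so matching is done
    on this normal form.
    """
    t = unicodedata.normalize("NFKD", title)
    t = "".join(c for c in t if not unicodedata.combining(c))
    t = _PUNCT_RE.sub(" ", t.lower())
    return _WS_RE.sub(" ", t).strip()


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def dedup_records(
    corpus: Corpus, policy: DedupPolicy = DedupPolicy()
) -> tuple[Corpus, pd.DataFrame]:
    """Merge duplicate records; return the deduplicated corpus and a report.

    Records sharing any accession number, or (when enabled) sharing a
    normalized title and publication year, are clustered with union-find and
    merged into one surviving record: the union of accessions, source
    databases and subject headings, keeping the longest title/abstract.
    Conflicting relevance labels within a cluster raise — contradictory
    labels are never merged silently.

    The report has one row per member of each multi-record cluster, columns
    ``cluster_id, doc_id, accession, reason``.
    """
    uf = _UnionFind()
    reason: dict[frozenset[str], str] = {}

    if policy.by_accession:
        by_acc: dict[str, str] = {}
        for rec in corpus.records:
            for acc in rec.accessions:
                if acc in by_acc:
                    uf.union(by_acc[acc], rec.doc_id)
                    reason[frozenset((by_acc[acc], rec.doc_id))] = "shared-accession"
                else:
                    by_acc[acc] = rec.doc_id
    if policy.by_title_year:
        by_ty: dict[tuple[str, Optional[int]], str] = {}
        for rec in corpus.records:
            norm = normalize_title(rec.title)
            if not norm:
                continue
            key = (norm, rec.pub_year)
            if key in by_ty:
                uf.union(by_ty[key], rec.doc_id)
                reason[frozenset((by_ty[key], rec.doc_id))] = "title-year"
            else:
                by_ty[key] = rec.doc_id

    clusters: dict[str, list[DocumentRecord]] = {}
    for rec in corpus.records:
        clusters.setdefault(uf.find(rec.doc_id), []).append(rec)

    merged: list[DocumentRecord] = []
    rows: list[dict] = []
    cluster_id = 0
    for root in sorted(clusters, key=lambda r: corpus.records.index(corpus[r])):
        members = clusters[root]
        if len(members) == 1:
            merged.append(members[0])
            continue
        cluster_id += 1
        labels = {m.relevant for m in members}
        if len(labels) > 1:
            ids = sorted(m.doc_id for m in members)
            raise CorpusValidationError(
                f"duplicate cluster {ids} carries conflicting relevance labels"
            )
        survivor = members[0]
        merged_rec = survivor.model_copy(
            update={
                "accessions": sorted({a for m in members for a in m.accessions}),
                "source_dbs": {db for m in members for db in m.source_dbs},
                "subject_headings": sorted({h for m in members for h in m.subject_headings}),
                "title": max((m.title for m in members), key=len),
                "abstract": max((m.abstract for m in members), key=len),
            }
        )
        merged.append(merged_rec)
        for m in members:
            pair_reason = next(
                (v for k, v in reason.items() if m.doc_id in k), "clustered"
            )
            rows.append(
                {
                    "cluster_id": cluster_id,
                    "doc_id": m.doc_id,
                    "accession": _LIST_SEP.join(m.accessions),
                    "reason": pair_reason,
                }
            )

    report = pd.DataFrame(rows, columns=["cluster_id", "doc_id", "accession", "reason"])
    out = Corpus(records=merged, name=corpus.name, snapshot_date=corpus.snapshot_date)
    return out, report


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------

YearInterval = tuple[int, int]

UNASSIGNED = "unassigned"


def stratify_by_year(
    corpus: Corpus, breaks: Sequence[YearInterval]
) -> dict[YearInterval | str, Corpus]:
    """Partition a corpus by inclusive year intervals.

    Every record falls in exactly one stratum or under :data:`UNASSIGNED`
    (undated records or years outside all intervals); stratum sizes sum to
    the corpus size.  Overlapping intervals are rejected.
    """
    ivs = [(int(lo), int(hi)) for lo, hi in breaks]
    for lo, hi in ivs:
        if lo > hi:
            raise ValueError(f"invalid interval {(lo, hi)}")
    for i, a in enumerate(ivs):
        for b in ivs[i + 1 :]:
            if a[0] <= b[1] and b[0] <= a[1]:
                raise ValueError(f"overlapping intervals {a} and {b}")

    buckets: dict[YearInterval | str, list[DocumentRecord]] = {iv: [] for iv in ivs}
    buckets[UNASSIGNED] = []
    for rec in corpus.records:
        placed = False
        if rec.pub_year is not None:
            for lo, hi in ivs:
                if lo <= rec.pub_year <= hi:
                    buckets[(lo, hi)].append(rec)
                    placed = True
                    break
        if not placed:
            buckets[UNASSIGNED].append(rec)
    return {
        key: Corpus(records=recs, name=f"{corpus.name}[{key}]", snapshot_date=corpus.snapshot_date)
        for key, recs in buckets.items()
    }
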