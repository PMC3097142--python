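"""Query scoring against a loaded index and ranked hit emission.

Each query gets a scoring vector with one counter per database string;
every query k-mer found in the index increments the counter of each
string posted under it.  Counters become percent similarities via the
shared/min(unique counts) quotient, then hits are filtered, sorted
(percent descending, database order ascending on ties) and truncated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, TextIO, Union

import numpy as np

from kmerank.database import IndexView, fetch_postings
from kmerank.kmer_core import (
    Alphabet,
    KmerProfile,
    UNRESTRICTED,
    extract_unique_kmers,
    format_percent,
    similarity_percent,
)
from kmerank.sequence_io import SequenceRecord

logger = logging.getLogger(__name__)

HIT_COLUMNS = ("query_id", "subject_id", "percent", "shared", "query_unique", "subject_unique")


@dataclass(frozen=True)
class SearchParams:
    """Result filtering: depth, similarity threshold, query length guard."""

    top_n: int = 10
    min_percent: float = 90.0
    min_length: int = 0

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError(f"top_n must be >= 1, got {self.top_n}")
        if not 0.0 <= self.min_percent <= 100.0:
            raise ValueError(f"min_percent must be in [0, 100], got {self.min_percent}")


@dataclass(frozen=True)
class SearchHit:
    query_id: str
    subject_id: str
    percent: float
    shared: int
    query_unique: int
    subject_unique: int


@dataclass
class QueryResult:
    """Hits for one query; ``skipped_reason`` set when the query was not
    searched (too short, or no valid k-mers)."""

    query_id: str
    query_unique: int
    hits: List[SearchHit] = field(default_factory=list)
    skipped_reason: Optional[str] = None


def score_query(profile: KmerProfile, view: IndexView,
                cache: Optional[Dict[str, np.ndarray]] = None) -> np.ndarray:
    """Scoring vector: counts[i] = number of the query's unique k-mers
    whose posting list contains database string i.

    ``cache`` optionally memoizes posting fetches across a batch; results
    are identical with or without it.
    """
    if profile.k != view.k:
        raise ValueError(
            f"query k-mer length {profile.k} does not match index k-mer length {view.k}"
        )
    if profile.unique_count < 1:
        raise ValueError("cannot score an empty k-mer profile")
    counts = np.zeros(view.n_strings, dtype=np.uint32)
    for kmer in profile.kmers:
        if cache is not None and kmer in cache:
            postings = cache[kmer]
        else:
            postings = fetch_postings(view, kmer)
            if cache is not None and postings is not None:
                cache[kmer] = postings
        if postings is not None:
            counts[postings] += 1
    return counts


def rank_hits(scores: np.ndarray, profile: KmerProfile, view: IndexView,
              params: SearchParams, query_id: str = "query") -> List[SearchHit]:
    """Convert a scoring vector into the filtered, ordered hit list.

    Only subjects sharing at least one k-mer are candidates; subjects
    with zero valid k-mers never appear.  Percent is computed and
    compared against ``min_percent`` at full precision.
    """
    candidates = np.nonzero(scores)[0]
    hits: List[SearchHit] = []
    for i in candidates:
        s_unique = int(view.unique_per_string[i])
        if s_unique == 0:  # unreachable for nonzero score; guard anyway
            continue
        shared = int(scores[i])
        percent = similarity_percent(shared, profile.unique_count, s_unique)
        if percent >= params.min_percent:
            hits.append(
                SearchHit(
                    query_id=query_id,
                    subject_id=view.ids[i],
                    percent=percent,
                    shared=shared,
                    query_unique=profile.unique_count,
                    subject_unique=s_unique,
                )
            )
    order = {sid: j for j, sid in enumerate(view.ids)}
    hits.sort(key=lambda h: (-h.percent, order[h.subject_id]))
    return hits[: params.top_n]


def search_batch(queries: Sequence[SequenceRecord], view: IndexView,
                 params: SearchParams = SearchParams(),
                 alphabet: Alphabet = UNRESTRICTED,
                 fold_case: bool = False,
                 use_cache: bool = True) -> Iterator[QueryResult]:
    """Search queries serially, in input order.

    Queries shorter than ``params.min_length`` or with zero valid
    k-mers are skipped with a warning and yield an empty result row.
    Output is deterministic for fixed inputs.
    """
    cache: Optional[Dict[str, np.ndarray]] = {} if use_cache else None
    for rec in queries:
        sequence = rec.sequence.upper() if fold_case else rec.sequence
        if len(sequence) < params.min_length:
            logger.warning(
                "query %r skipped: length %d < min_length %d",
                rec.identifier, len(sequence), params.min_length,
            )
            yield QueryResult(rec.identifier, 0, [], skipped_reason="below min_length")
            continue
        profile = extract_unique_kmers(sequence, view.k, alphabet)
        if profile.unique_count == 0:
            logger.warning("query %r skipped: no valid %d-mers", rec.identifier, view.k)
            yield QueryResult(rec.identifier, 0, [], skipped_reason="no valid k-mers")
            continue
        scores = score_query(profile, view, cache=cache)
        hits = rank_hits(scores, profile, view, params, query_id=rec.identifier)
        yield QueryResult(rec.identifier, profile.unique_count, hits)


def write_hits_tsv(results: Iterable[QueryResult], dest: Union[str, TextIO],
                   provenance: Optional[Dict[str, object]] = None) -> None:
    """Write the tab-separated hit table.

    One row per (query, hit); queries with no hits (or skipped queries)
    emit a single row with the subject-side fields set to "-".  Header
    lines are "#"-prefixed; column order is part of the contract.
    """
    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8") as fh:
            write_hits_tsv(results, fh, provenance=provenance)
            return
    if provenance:
        for key, value in provenance.items():
            dest.write(f"# {key}={value}\n")
    dest.write("#" + "\t".join(HIT_COLUMNS) + "\n")
    for result in results:
        if not result.hits:
            dest.write(
                "\t".join([result.query_id, "-", "-", "-", str(result.query_unique), "-"]) + "\n"
            )
            continue
        for hit in result.hits:
            dest.write(
                "\t".join([
                    hit.query_id,
                    hit.subject_id,
                    format_percent(hit.percent),
                    str(hit.shared),
                    str(hit.query_unique),
                    str(hit.subject_unique),
                ]) + "\n"
            )


def read_hits_tsv(source: Union[str, TextIO]) -> List[SearchHit]:
    """Parse a hit table written by :func:`write_hits_tsv`, skipping
    "#" comment lines and no-hit placeholder rows."""
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            return read_hits_tsv(fh)
    hits: List[SearchHit] = []
    for line in source:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != len(HIT_COLUMNS):
            raise ValueError(f"malformed hit row: {line!r}")
        if parts[1] == "-":
            continue
        hits.append(
            SearchHit(
                query_id=parts[0],
                subject_id=parts[1],
                percent=float(parts[2]),
                shared=int(parts[3]),
                query_unique=int(parts[4]),
                subject_unique=int(parts[5]),
            )
        )
    return hits
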