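"""Shared fixtures and the independent brute-force search oracle.

The oracle deliberately avoids every code path of the package under
test: k-mer sets are built with a direct comprehension, similarity with
plain set intersection, ranking with an explicit sort.  Pipeline tests
compare the full disk-roundtripped search against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Set, Tuple

import pytest

from kmerank.sequence_io import SequenceRecord


def naive_kmer_set(sequence: str, k: int, allowed: Optional[Set[str]] = None) -> Set[str]:
    """Oracle k-mer extraction: direct window comprehension."""
    return {
        sequence[i:i + k]
        for i in range(len(sequence) - k + 1)
        if allowed is None or all(c in allowed for c in sequence[i:i + k])
    }


def naive_similarity(q: Set[str], s: Set[str]) -> float:
    """Oracle similarity: two-set intersection over the smaller set."""
    return 100.0 * len(q & s) / min(len(q), len(s))


@dataclass(frozen=True)
class OracleHit:
    query_id: str
    subject_id: str
    percent: float
    shared: int
    query_unique: int
    subject_unique: int


def naive_search(query: SequenceRecord, db_records: Sequence[SequenceRecord], k: int,
                 allowed: Optional[Set[str]], top_n: int,
                 min_percent: float) -> List[OracleHit]:
    """Oracle pipeline: all-pairs set intersection, filter, sort by
    percent descending then database order ascending, truncate."""
    q_set = naive_kmer_set(query.sequence, k, allowed)
    if not q_set:
        return []
    rows: List[Tuple[float, int, OracleHit]] = []
    for idx, rec in enumerate(db_records):
        s_set = naive_kmer_set(rec.sequence, k, allowed)
        if not s_set:
            continue
        shared = len(q_set & s_set)
        if shared < 1:
            continue
        percent = naive_similarity(q_set, s_set)
        if percent >= min_percent:
            rows.append((percent, idx, OracleHit(
                query.identifier, rec.identifier, percent, shared, len(q_set), len(s_set))))
    rows.sort(key=lambda r: (-r[0], r[1]))
    return [hit for _, _, hit in rows[:top_n]]


@pytest.fixture
def toy_records() -> List[SequenceRecord]:
    return [
        SequenceRecord("s0", "s0", "ACGT"),
        SequenceRecord("s1", "s1", "ACGG"),
    ]


@pytest.fixture
def toy_index(toy_records):
    from kmerank.database import build_index
    from kmerank.kmer_core import DNA

    return build_index(toy_records, 3, DNA)


@pytest.fixture
def toy_view(toy_index, tmp_path):
    from kmerank.database import read_header, write_index

    path = str(tmp_path / "toy.srdb")
    write_index(toy_index, path)
    view = read_header(path)
    yield view
    view.close()
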