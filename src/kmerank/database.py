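"""On-disk inverted k-mer index: build, serialize, load, fetch.

File layout (suffix ``.srdb``), eleven segments in fixed order; see
``docs/format.md`` for a worked hex dump:

====  =============================================  ==============
 seg  contents                                       bytes
====  =============================================  ==============
  1   F, string-ID field width                       10 (ASCII)
  2   K, k-mer length                                10 (ASCII)
  3   N, string count                                10 (ASCII)
  4   string IDs, space-padded to width F            F*N
  5   delta-encoded posting arrays, concatenated     4 * total postings
  6   all distinct k-mers, K bytes each, sorted      K*k
  7   absolute start position of each posting array  4*k
  8   element count of each posting array            4*k
  9   unique-k-mer count per string                  4*N
 10   k, distinct k-mer count                        10 (ASCII)
 11   absolute file position of segment 6            10 (ASCII)
====  =============================================  ==============

10-byte header fields are ASCII decimal, left-padded with spaces.  All
4-byte integers are unsigned little-endian.  Posting arrays store string
indices delta-encoded: first element verbatim, every later element as
the gap to its predecessor (gap >= 1).  A search-time loader reads every
segment except 5, then fetches individual posting arrays by file seek.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import BinaryIO, Dict, List, Optional, Sequence, Tuple

import numpy as np

from kmerank.kmer_core import Alphabet, UNRESTRICTED, extract_unique_kmers
from kmerank.sequence_io import SequenceRecord

logger = logging.getLogger(__name__)

HEADER_FIELD_BYTES = 10
POSTING_BYTES = 4
MAX_STRING_COUNT = 2_147_483_647
ENCODING = "latin-1"  # fixed-width byte fields require 1 byte per character


class CorruptIndexError(ValueError):
    """Index file fails a structural check; message names the segment."""


class IndexBuildError(ValueError):
    pass


def delta_encode(indices: Sequence[int]) -> np.ndarray:
    """Delta-encode a strictly ascending list of string indices.

    First element stored verbatim, subsequent elements as gaps
    (current - previous, always >= 1).
    """
    arr = np.asarray(indices, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("cannot delta-encode an empty posting list")
    if arr[0] < 0 or (arr.size > 1 and np.any(np.diff(arr) <= 0)):
        raise ValueError("posting list must be strictly ascending and non-negative")
    out = arr.copy()
    out[1:] = np.diff(arr)
    if np.any(out >= 2 ** 32):
        raise ValueError("delta value does not fit in 4 bytes unsigned")
    return out.astype(np.uint32)


def delta_decode(skips: Sequence[int]) -> np.ndarray:
    """Invert :func:`delta_encode` (cumulative sums)."""
    arr = np.asarray(skips, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("cannot delta-decode an empty offset array")
    if arr.size > 1 and np.any(arr[1:] < 1):
        raise CorruptIndexError("segment 5: zero gap inside an offset array")
    return np.cumsum(arr).astype(np.int64)


@dataclass
class DatabaseIndex:
    """In-memory inverted index over one record set at one k."""

    k: int
    ids: List[str]
    postings: Dict[str, np.ndarray]  # k-mer -> ascending string indices
    unique_per_string: np.ndarray  # int64, length N
    alphabet: Alphabet = UNRESTRICTED

    @property
    def n_strings(self) -> int:
        return len(self.ids)

    @property
    def k_total(self) -> int:
        return len(self.postings)

    @property
    def id_field_width(self) -> int:
        return max(len(i.encode(ENCODING)) for i in self.ids)

    @property
    def total_postings(self) -> int:
        return sum(len(v) for v in self.postings.values())

    def sorted_kmers(self) -> List[str]:
        return sorted(self.postings)

    def validate(self) -> None:
        n = self.n_strings
        if n < 1:
            raise IndexBuildError("index has no strings")
        if n > MAX_STRING_COUNT:
            raise IndexBuildError(f"string count {n} exceeds limit {MAX_STRING_COUNT}")
        if len(self.unique_per_string) != n:
            raise IndexBuildError("unique_per_string length != string count")
        total = 0
        for kmer, plist in self.postings.items():
            if len(kmer) != self.k:
                raise IndexBuildError(f"k-mer {kmer!r} has length != {self.k}")
            if len(plist) == 0:
                raise IndexBuildError(f"empty posting list for {kmer!r}")
            if plist[0] < 0 or plist[-1] >= n:
                raise IndexBuildError(f"posting index out of range for {kmer!r}")
            if len(plist) > 1 and np.any(np.diff(plist) <= 0):
                raise IndexBuildError(f"posting list for {kmer!r} not strictly ascending")
            total += len(plist)
        if total != int(self.unique_per_string.sum()):
            raise IndexBuildError(
                "sum of posting-list lengths != sum of per-string unique counts"
            )


def build_index(records: Sequence[SequenceRecord], k: int,
                alphabet: Alphabet = UNRESTRICTED) -> DatabaseIndex:
    """Build the inverted index: each record's distinct valid k-mers are
    posted under its 0-based file-order index.

    Records with zero valid k-mers are kept (so indices stay aligned
    with input order) and logged.  If *every* record is too short the
    index would be empty and a hard error is raised.
    """
    if not records:
        raise IndexBuildError("no records to index")
    postings: Dict[str, List[int]] = {}
    unique_counts = np.zeros(len(records), dtype=np.int64)
    for idx, rec in enumerate(records):
        profile = extract_unique_kmers(rec.sequence, k, alphabet)
        unique_counts[idx] = profile.unique_count
        if profile.unique_count == 0:
            logger.warning(
                "record %r (index %d) contributes no valid %d-mers", rec.identifier, idx, k
            )
            continue
        for kmer in profile.kmers:
            postings.setdefault(kmer, []).append(idx)
    if not postings:
        raise IndexBuildError(f"no record yields any valid {k}-mer; index would be empty")
    index = DatabaseIndex(
        k=k,
        ids=[rec.identifier for rec in records],
        postings={m: np.asarray(v, dtype=np.int64) for m, v in postings.items()},
        unique_per_string=unique_counts,
        alphabet=alphabet,
    )
    index.validate()
    return index


def expected_file_size(f: int, n: int, total_postings: int, k_len: int, k_total: int) -> int:
    """Closed-form total size of the eleven segments."""
    return (
        3 * HEADER_FIELD_BYTES
        + f * n
        + POSTING_BYTES * total_postings
        + k_len * k_total
        + POSTING_BYTES * k_total
        + POSTING_BYTES * k_total
        + POSTING_BYTES * n
        + 2 * HEADER_FIELD_BYTES
    )


def _header_field(value: int) -> bytes:
    text = str(value)
    if len(text) > HEADER_FIELD_BYTES:
        raise IndexBuildError(f"value {value} exceeds {HEADER_FIELD_BYTES} ASCII bytes")
    return text.rjust(HEADER_FIELD_BYTES).encode("ascii")


def _parse_header_field(raw: bytes, segment: str) -> int:
    try:
        return int(raw.decode("ascii").strip())
    except (UnicodeDecodeError, ValueError) as exc:
        raise CorruptIndexError(f"{segment}: unreadable ASCII integer field") from exc


def write_index(index: DatabaseIndex, path: str) -> int:
    """Serialize to the eleven-segment layout; returns bytes written."""
    index.validate()
    f_width = index.id_field_width
    n = index.n_strings
    kmers = index.sorted_kmers()
    k_total = len(kmers)

    encoded: List[bytes] = []
    positions = np.empty(k_total, dtype=np.uint32)
    counts = np.empty(k_total, dtype=np.uint32)
    seg5_start = 3 * HEADER_FIELD_BYTES + f_width * n
    cursor = seg5_start
    for j, kmer in enumerate(kmers):
        skips = delta_encode(index.postings[kmer])
        raw = skips.astype("<u4").tobytes()
        encoded.append(raw)
        positions[j] = cursor
        counts[j] = len(skips)
        cursor += len(raw)
    seg6_start = cursor

    with open(path, "wb") as fh:
        fh.write(_header_field(f_width))  # seg 1
        fh.write(_header_field(index.k))  # seg 2
        fh.write(_header_field(n))  # seg 3
        for ident in index.ids:  # seg 4
            raw_id = ident.encode(ENCODING)
            if len(raw_id) > f_width:
                raise IndexBuildError(f"identifier {ident!r} longer than field width {f_width}")
            fh.write(raw_id.ljust(f_width))
        for raw in encoded:  # seg 5
            fh.write(raw)
        for kmer in kmers:  # seg 6
            try:
                raw_kmer = kmer.encode(ENCODING)
            except UnicodeEncodeError as exc:
                raise IndexBuildError(
                    f"k-mer {kmer!r} is not latin-1 encodable; only "
                    "single-byte characters are indexable"
                ) from exc
            if len(raw_kmer) != index.k:
                raise IndexBuildError(
                    f"k-mer {kmer!r} does not encode to {index.k} bytes; "
                    "only single-byte (latin-1) characters are indexable"
                )
            fh.write(raw_kmer)
        fh.write(positions.astype("<u4").tobytes())  # seg 7
        fh.write(counts.astype("<u4").tobytes())  # seg 8
        fh.write(index.unique_per_string.astype("<u4").tobytes())  # seg 9
        fh.write(_header_field(k_total))  # seg 10
        fh.write(_header_field(seg6_start))  # seg 11
        written = fh.tell()

    expected = expected_file_size(f_width, n, index.total_postings, index.k, k_total)
    assert written == expected, f"layout bug: wrote {written}, formula says {expected}"
    return written


@dataclass
class IndexView:
    """Search-time view: every segment loaded except the posting arrays.

    ``kmer_map`` maps each k-mer to (absolute byte position, element
    count) of its on-disk posting array — fetched lazily by
    :func:`fetch_postings`.
    """

    path: str
    id_field_width: int
    k: int
    ids: List[str]
    unique_per_string: np.ndarray
    kmer_map: Dict[str, Tuple[int, int]]
    _handle: Optional[BinaryIO] = field(default=None, repr=False)

    @property
    def n_strings(self) -> int:
        return len(self.ids)

    @property
    def k_total(self) -> int:
        return len(self.kmer_map)

    def kmers(self) -> List[str]:
        return list(self.kmer_map)

    def open(self) -> "IndexView":
        if self._handle is None:
            self._handle = open(self.path, "rb")
        return self

    def close(self) -> None:
        if self._handle is not None:
            self._handle.close()
            self._handle = None

    def __enter__(self) -> "IndexView":
        return self.open()

    def __exit__(self, *exc) -> None:
        self.close()


def read_header(path: str) -> IndexView:
    """Load segments 1-4 and 6-11; never touch segment 5 bytes.

    The trailing two fields (distinct k-mer count and the absolute
    position of segment 6) locate the tail segments without scanning the
    posting arrays.
    """
    with open(path, "rb") as fh:
        fh.seek(0, io.SEEK_END)
        file_size = fh.tell()
        if file_size < 5 * HEADER_FIELD_BYTES:
            raise CorruptIndexError("file: shorter than the fixed header fields")

        fh.seek(0)
        f_width = _parse_header_field(fh.read(HEADER_FIELD_BYTES), "segment 1 (F)")
        k = _parse_header_field(fh.read(HEADER_FIELD_BYTES), "segment 2 (K)")
        n = _parse_header_field(fh.read(HEADER_FIELD_BYTES), "segment 3 (N)")
        if f_width < 1 or k < 1 or n < 1:
            raise CorruptIndexError("segments 1-3: non-positive F, K or N")

        seg4 = fh.read(f_width * n)
        if len(seg4) != f_width * n:
            raise CorruptIndexError("segment 4: truncated identifier array")
        ids = [
            seg4[i * f_width:(i + 1) * f_width].rstrip(b" ").decode(ENCODING)
            for i in range(n)
        ]

        fh.seek(file_size - 2 * HEADER_FIELD_BYTES)
        k_total = _parse_header_field(fh.read(HEADER_FIELD_BYTES), "segment 10 (k)")
        seg6_pos = _parse_header_field(fh.read(HEADER_FIELD_BYTES), "segment 11")
        if k_total < 1:
            raise CorruptIndexError("segment 10: non-positive distinct k-mer count")

        tail_size = k * k_total + 2 * POSTING_BYTES * k_total + POSTING_BYTES * n
        if seg6_pos + tail_size + 2 * HEADER_FIELD_BYTES != file_size:
            raise CorruptIndexError(
                "segment 11: stored segment-6 position inconsistent with file size"
            )
        seg5_start = 3 * HEADER_FIELD_BYTES + f_width * n
        if seg6_pos < seg5_start or (seg6_pos - seg5_start) % POSTING_BYTES:
            raise CorruptIndexError("segment 11: position not 4-byte aligned after segment 4")

        fh.seek(seg6_pos)
        seg6 = fh.read(k * k_total)
        kmers = [seg6[j * k:(j + 1) * k].decode(ENCODING) for j in range(k_total)]
        if any(kmers[j] >= kmers[j + 1] for j in range(k_total - 1)):
            raise CorruptIndexError("segment 6: k-mers not in strict ascending order")
        positions = np.frombuffer(fh.read(POSTING_BYTES * k_total), dtype="<u4")
        counts = np.frombuffer(fh.read(POSTING_BYTES * k_total), dtype="<u4")
        unique = np.frombuffer(fh.read(POSTING_BYTES * n), dtype="<u4").astype(np.int64)
        if len(positions) != k_total or len(counts) != k_total or len(unique) != n:
            raise CorruptIndexError("segments 7-9: truncated tail arrays")
        if int(counts.sum()) * POSTING_BYTES != seg6_pos - seg5_start:
            raise CorruptIndexError("segment 8: posting counts inconsistent with segment 5 span")
        if int(counts.sum()) != int(unique.sum()):
            raise CorruptIndexError("segment 9: unique counts inconsistent with posting counts")

    kmer_map = {
        kmers[j]: (int(positions[j]), int(counts[j])) for j in range(k_total)
    }
    return IndexView(
        path=path,
        id_field_width=f_width,
        k=k,
        ids=ids,
        unique_per_string=unique,
        kmer_map=kmer_map,
    )


def fetch_postings(view: IndexView, kmer: str) -> Optional[np.ndarray]:
    """Seek-and-read one posting array; ``None`` if the k-mer is absent."""
    entry = view.kmer_map.get(kmer)
    if entry is None:
        return None
    pos, count = entry
    handle = view.open()._handle
    assert handle is not None
    handle.seek(pos)
    raw = handle.read(POSTING_BYTES * count)
    if len(raw) != POSTING_BYTES * count:
        raise CorruptIndexError(f"segment 5: truncated offset array for {kmer!r}")
    return delta_decode(np.frombuffer(raw, dtype="<u4"))
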