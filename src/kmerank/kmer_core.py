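"""Unique k-mer extraction and the percent-shared-k-mer similarity statistic.

A k-mer profile is the lexically sorted set of distinct length-k windows
of a string, optionally restricted to windows composed entirely of a
user-defined alphabet.  Similarity between two strings is

    100 * |shared unique k-mers| / min(|Q k-mers|, |S k-mers|)

computed at full precision and rendered to two decimals on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Optional, Sequence, Tuple


class UndefinedSimilarityError(ValueError):
    """Raised when one of the profiles has no valid k-mers."""


@dataclass(frozen=True)
class Alphabet:
    """Character filter for k-mer windows.

    ``allowed is None`` means unrestricted: every window is valid.  When
    restricted, a window is valid only if all of its characters belong to
    ``allowed``.  No case folding is performed; callers who want it fold
    the sequence before extraction.
    """

    allowed: Optional[FrozenSet[str]] = None

    def __post_init__(self) -> None:
        if self.allowed is not None:
            if not self.allowed:
                raise ValueError("restricted alphabet must be non-empty")
            if any(len(c) != 1 for c in self.allowed):
                raise ValueError("alphabet members must be single characters")
            if "\n" in self.allowed or "\r" in self.allowed:
                raise ValueError("alphabet may not contain newline characters")

    @property
    def unrestricted(self) -> bool:
        return self.allowed is None

    def __contains__(self, char: str) -> bool:
        return self.allowed is None or char in self.allowed

    @classmethod
    def from_string(cls, spec: str) -> "Alphabet":
        """Build from a CLI-style spec: ``"all"`` (unrestricted), a named
        preset (``"dna"``, ``"protein"``), or the literal characters."""
        if spec.lower() == "all":
            return cls(None)
        if spec.lower() == "dna":
            return DNA
        if spec.lower() == "protein":
            return PROTEIN
        return cls(frozenset(spec))

    def spec_string(self) -> str:
        if self.allowed is None:
            return "all"
        return "".join(sorted(self.allowed))


DNA = Alphabet(frozenset("ACGT"))
PROTEIN = Alphabet(frozenset("ACDEFGHIKLMNPQRSTVWY"))
UNRESTRICTED = Alphabet(None)


@dataclass(frozen=True)
class KmerProfile:
    """Sorted distinct valid k-mers of one string."""

    k: int
    kmers: Tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")

    @property
    def unique_count(self) -> int:
        return len(self.kmers)

    def __contains__(self, kmer: str) -> bool:
        return kmer in set(self.kmers)


def extract_unique_kmers(sequence: str, k: int, alphabet: Alphabet = UNRESTRICTED) -> KmerProfile:
    """Extract the profile of distinct valid overlapping k-mers.

    Windows slide with stride 1; a window is kept only if every character
    is in ``alphabet``.  Strings shorter than ``k`` yield an empty
    profile (``unique_count == 0``) — downstream decides how to treat
    them.

    >>> extract_unique_kmers("AAAAAAA", 6, DNA).kmers
    ('AAAAAA',)
    >>> extract_unique_kmers("ACGTNAC", 2, DNA).kmers
    ('AC', 'CG', 'GT')
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = len(sequence)
    if n < k:
        return KmerProfile(k, ())
    if alphabet.unrestricted:
        kmers = {sequence[i:i + k] for i in range(n - k + 1)}
        return KmerProfile(k, tuple(sorted(kmers)))
    allowed = alphabet.allowed
    kmers = set()
    # Track the start of the current run of allowed characters so each
    # invalid character is inspected once, not k times.
    run_start = 0
    for pos, char in enumerate(sequence):
        if char not in allowed:
            if pos - run_start >= k:
                for i in range(run_start, pos - k + 1):
                    kmers.add(sequence[i:i + k])
            run_start = pos + 1
    if n - run_start >= k:
        for i in range(run_start, n - k + 1):
            kmers.add(sequence[i:i + k])
    return KmerProfile(k, tuple(sorted(kmers)))


def shared_kmer_count(a: KmerProfile, b: KmerProfile) -> int:
    """Count k-mers present in both profiles by linear merge of the
    sorted k-mer tuples."""
    if a.k != b.k:
        raise ValueError(f"profiles have different k: {a.k} != {b.k}")
    i = j = shared = 0
    xa, xb = a.kmers, b.kmers
    while i < len(xa) and j < len(xb):
        if xa[i] == xb[j]:
            shared += 1
            i += 1
            j += 1
        elif xa[i] < xb[j]:
            i += 1
        else:
            j += 1
    return shared


def similarity_percent(shared: int, q_unique: int, s_unique: int) -> float:
    """Percent of shared unique k-mers relative to the smaller profile.

    Raises :class:`UndefinedSimilarityError` if either count is zero.
    """
    if q_unique <= 0 or s_unique <= 0:
        raise UndefinedSimilarityError(
            f"similarity undefined for unique counts ({q_unique}, {s_unique})"
        )
    smaller = min(q_unique, s_unique)
    if not 0 <= shared <= smaller:
        raise ValueError(f"shared count {shared} outside [0, {smaller}]")
    return 100.0 * shared / smaller


def profile_similarity(a: KmerProfile, b: KmerProfile) -> float:
    """Convenience: similarity between two profiles."""
    return similarity_percent(shared_kmer_count(a, b), a.unique_count, b.unique_count)


def format_percent(value: float) -> str:
    """Render a percent value with two decimals, e.g. ``96.47``."""
    return f"{value:.2f}"


def valid_kmer_positions(sequence: str, k: int, alphabet: Alphabet) -> Sequence[int]:
    """Start positions of valid windows (diagnostics only)."""
    return [
        i for i in range(len(sequence) - k + 1)
        if all(c in alphabet for c in sequence[i:i + k])
    ]
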