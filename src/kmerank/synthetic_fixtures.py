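"""Deterministic generators for every test input the suite needs.

Random databases, periodic mutants, homopolymer expansions, and sequence
families with controlled identity — all pure functions of their seed, so
repeated calls are byte-identical and nothing has to be downloaded or
stored.  Named presets mirror the benchmark regimes (scaled down).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple, TextIO, Union

import numpy as np

from kmerank.kmer_core import Alphabet, DNA, PROTEIN, UNRESTRICTED
from kmerank.sequence_io import SequenceRecord, records_from_lines

# The two French institute address strings used in the worked text-search
# example: the short one is a suffix of the long one except for the
# postal-code spacing ("11100" vs "11 100").  At k=4, unrestricted
# alphabet, they share 96.47% of their unique 4-mers.
INSTITUTE_SHORT = (
    "Institut National de la Recherche Agronomique, "
    "Avenue des Etangs, Narbonne 11100, France"
)
INSTITUTE_LONG = (
    "Laboratoire de Biotechnologie de l'Environnement, "
    "Institut National de la Recherche Agronomique, "
    "Avenue des Etangs, Narbonne 11 100, France"
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a random-database fixture."""

    n_sequences: int
    length: int
    alphabet: Alphabet = DNA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.alphabet.unrestricted:
            raise ValueError("random generation needs a concrete alphabet")


# Scaled-down benchmark regimes; counts shrunk to desk scale, lengths,
# alphabets and k kept.
PRESETS: Dict[str, Dict[str, object]] = {
    "16s": {"spec": FixtureSpec(2000, 1350, DNA, 0), "k": 7},
    "pyro": {"spec": FixtureSpec(2000, 150, DNA, 0), "k": 6},
    "shuffle": {"spec": FixtureSpec(2000, 687, DNA, 1), "k": 7},
    "gp120": {"spec": FixtureSpec(2000, 175, PROTEIN, 0), "k": 4},
    "institutes": {"spec": None, "k": 4},  # the two worked-example strings
}


def _alphabet_chars(alphabet: Alphabet) -> List[str]:
    assert alphabet.allowed is not None
    return sorted(alphabet.allowed)


def random_sequences(spec: FixtureSpec, prefix: str = "syn") -> List[SequenceRecord]:
    """I.i.d. uniform sequences over the alphabet, ids ``syn_000000``..."""
    rng = np.random.default_rng(spec.seed)
    chars = np.array(_alphabet_chars(spec.alphabet))
    draws = rng.integers(0, len(chars), size=(spec.n_sequences, spec.length))
    return [
        SequenceRecord(
            f"{prefix}_{i:06d}", f"{prefix}_{i:06d}", "".join(chars[draws[i]])
        )
        for i in range(spec.n_sequences)
    ]


def mutate_every_mth(sequence: str, m: int, alphabet: Alphabet = DNA,
                     seed: int = 0, phase: int = 0) -> str:
    """Substitute a different alphabet character at every position
    congruent to ``phase`` modulo ``m``.

    Hamming distance to the input is exactly the number of such
    positions (ceil((len-phase)/m) for phase < len).
    """
    if m < 1:
        raise ValueError("period m must be >= 1")
    if not 0 <= phase < m:
        raise ValueError(f"phase must be in [0, {m}), got {phase}")
    chars = _alphabet_chars(alphabet)
    if len(chars) < 2:
        raise ValueError("alphabet needs >= 2 characters to substitute")
    rng = np.random.default_rng(seed)
    out = list(sequence)
    for pos in range(phase, len(sequence), m):
        alternatives = [c for c in chars if c != sequence[pos]]
        out[pos] = alternatives[int(rng.integers(0, len(alternatives)))]
    return "".join(out)


def periodic_disjoint_pair(length: int, m: int = 7, seed: int = 0,
                           phase: int = 0) -> Tuple[str, str]:
    """A sequence and an every-``m``-th-position mutant whose k-mer sets
    (k == m) are *provably* disjoint.

    For uniform random ACGT sequences, a mutant window can coincidentally
    equal a different window of the original, so the idealized
    "mismatch every m-th base => 0% similarity at k = m" claim holds
    only up to that background.  Here the original is drawn over
    {A, C, G} and every mutated position becomes T: each mutant window
    covers at least one mutated position and hence contains a T, while
    no original window does — the two k-mer sets cannot intersect, for
    any seed and any phase.
    """
    if m < 1:
        raise ValueError("period m must be >= 1")
    if not 0 <= phase < m:
        raise ValueError(f"phase must be in [0, {m}), got {phase}")
    rng = np.random.default_rng(seed)
    chars = np.array(["A", "C", "G"])
    original = "".join(chars[rng.integers(0, 3, size=length)])
    mutant = list(original)
    for pos in range(phase, length, m):
        mutant[pos] = "T"
    return original, "".join(mutant)


def expand_homopolymer(sequence: str, run_start: int, extra: int) -> str:
    """Insert ``extra`` copies of the character at ``run_start`` inside
    its run; the rest of the string is untouched."""
    if not 0 <= run_start < len(sequence):
        raise IndexError(f"run_start {run_start} out of range for length {len(sequence)}")
    if extra < 0:
        raise ValueError("extra must be >= 0")
    char = sequence[run_start]
    return sequence[:run_start] + char * extra + sequence[run_start:]


def hamming_identity(a: str, b: str) -> float:
    """Exact identity fraction for equal-length strings:
    matches / min(len) == matches / len."""
    if len(a) != len(b):
        raise ValueError("hamming identity requires equal lengths")
    matches = sum(x == y for x, y in zip(a, b))
    return matches / len(a)


def sequence_family(ancestor_length: int, n_members: int, target_identity: float,
                    alphabet: Alphabet = DNA, seed: int = 0,
                    prefix: str = "fam") -> Tuple[List[SequenceRecord], np.ndarray]:
    """A random ancestor plus diverged members at a controlled identity.

    Each member substitutes ``round((1 - target_identity) * length)``
    positions, chosen without replacement, with a different character.
    Returns (records, identity_matrix): records[0] is the ancestor and
    the matrix holds exact pairwise Hamming identities recomputed by
    direct comparison (not assumed from the target).
    """
    if not 0.0 < target_identity <= 1.0:
        raise ValueError("target_identity must be in (0, 1]")
    if n_members < 1:
        raise ValueError("need at least one member")
    rng = np.random.default_rng(seed)
    chars = _alphabet_chars(alphabet)
    ancestor = "".join(chars[i] for i in rng.integers(0, len(chars), size=ancestor_length))
    n_subs = round((1.0 - target_identity) * ancestor_length)
    sequences = [ancestor]
    for _ in range(n_members):
        positions = rng.choice(ancestor_length, size=n_subs, replace=False)
        member = list(ancestor)
        for pos in positions:
            alternatives = [c for c in chars if c != ancestor[pos]]
            member[pos] = alternatives[int(rng.integers(0, len(alternatives)))]
        sequences.append("".join(member))
    records = [
        SequenceRecord(f"{prefix}_{'anc' if i == 0 else f'm{i - 1:03d}'}",
                       f"{prefix}_{'anc' if i == 0 else f'm{i - 1:03d}'}", seq)
        for i, seq in enumerate(sequences)
    ]
    n = len(records)
    identity = np.ones((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            identity[i, j] = identity[j, i] = hamming_identity(sequences[i], sequences[j])
    return records, identity


def institute_records() -> List[SequenceRecord]:
    """The two worked-example text strings as FASTA records."""
    return [
        SequenceRecord("inst_short", "inst_short", INSTITUTE_SHORT),
        SequenceRecord("inst_long", "inst_long", INSTITUTE_LONG),
    ]


def preset_records(name: str) -> Tuple[List[SequenceRecord], int]:
    """Records and recommended k for a named preset."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    entry = PRESETS[name]
    if name == "institutes":
        return institute_records(), int(entry["k"])
    return random_sequences(entry["spec"]), int(entry["k"])  # type: ignore[arg-type]


def write_identity_tsv(records: List[SequenceRecord], identity: np.ndarray,
                       dest: Union[str, TextIO],
                       provenance: Optional[Dict[str, object]] = None) -> None:
    """Pairwise identity matrix as a (query_id, subject_id, fraction) TSV."""
    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8") as fh:
            write_identity_tsv(records, identity, fh, provenance=provenance)
            return
    if provenance:
        for key, value in provenance.items():
            dest.write(f"# {key}={value}\n")
    dest.write("#query_id\tsubject_id\tidentity_fraction\n")
    for i, qrec in enumerate(records):
        for j, srec in enumerate(records):
            if i == j:
                continue
            dest.write(f"{qrec.identifier}\t{srec.identifier}\t{identity[i, j]:.6f}\n")


__all__ = [
    "FixtureSpec",
    "PRESETS",
    "INSTITUTE_SHORT",
    "INSTITUTE_LONG",
    "random_sequences",
    "mutate_every_mth",
    "periodic_disjoint_pair",
    "expand_homopolymer",
    "hamming_identity",
    "sequence_family",
    "institute_records",
    "preset_records",
    "records_from_lines",
    "write_identity_tsv",
]
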