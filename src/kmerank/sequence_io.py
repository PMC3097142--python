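"""FASTA reading and writing with strict identifier rules.

The identifier of a record is the header substring between ">" and the
first whitespace (or end of line).  Identifiers must be unique within a
file; record order defines the 0-based string index used by the index
builder.  Sequence payloads are arbitrary text: wrapped lines are
concatenated (line endings and trailing blanks removed, interior spaces
kept — they are meaningful in text-mode databases), and no case folding
or alphabet validation happens here (that belongs to k-mer extraction).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Iterator, List, TextIO, Union


class FastaError(ValueError):
    """Malformed FASTA input (bad header, duplicate id, empty sequence...)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry.

    Attributes
    ----------
    identifier : str
        Unique token between ">" and the first space of the header.
    header : str
        Full header line text after ">" (identifier plus description).
    sequence : str
        The string payload with line breaks and internal whitespace removed.
    """

    identifier: str
    header: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.identifier or any(c.isspace() for c in self.identifier):
            raise FastaError(
                f"invalid identifier {self.identifier!r}: must be non-empty "
                "and contain no whitespace"
            )
        if not self.sequence:
            raise FastaError(f"record {self.identifier!r} has an empty sequence")


def _identifier_from_header(header: str) -> str:
    return header.split(None, 1)[0] if header.strip() else ""


def read_fasta(source: Union[str, TextIO, Iterable[str]]) -> List[SequenceRecord]:
    """Parse FASTA text into an ordered list of :class:`SequenceRecord`.

    Parameters
    ----------
    source : path, open text stream, or iterable of lines

    Raises
    ------
    FastaError
        On content before the first header, a header without an
        identifier, an empty sequence, or a duplicate identifier (the
        error names both record positions).
    """
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return read_fasta(fh)
    records: List[SequenceRecord] = []
    seen: dict[str, int] = {}
    header: str | None = None
    header_line_no = 0
    chunks: List[str] = []

    def flush() -> None:
        assert header is not None
        identifier = _identifier_from_header(header)
        if not identifier:
            raise FastaError(f"header at line {header_line_no} has no identifier")
        sequence = "".join(chunks)
        if not sequence:
            raise FastaError(
                f"record {identifier!r} (line {header_line_no}) has an empty sequence"
            )
        if identifier in seen:
            raise FastaError(
                f"duplicate identifier {identifier!r}: records "
                f"{seen[identifier]} and {len(records)}"
            )
        seen[identifier] = len(records)
        records.append(SequenceRecord(identifier, header, sequence))

    for line_no, raw in enumerate(source, start=1):
        line = raw.rstrip("\r\n")
        if line.startswith(">"):
            if header is not None:
                flush()
            header = line[1:]
            header_line_no = line_no
            chunks = []
        elif line.strip():
            if header is None:
                raise FastaError(
                    f"line {line_no} precedes the first '>' header: {line[:40]!r}"
                )
            # Keep interior spaces: they are payload characters for text-mode
            # databases (institute names).  Only line endings and trailing
            # blanks are dropped; wrapped lines are joined without separator.
            chunks.append(line.rstrip())
    if header is not None:
        flush()
    if not records:
        raise FastaError("no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], dest: Union[str, TextIO],
                width: int = 0) -> None:
    """Write records as FASTA.  ``width=0`` keeps each sequence on one line.

    Text payloads (institute names etc.) must never be wrapped, since a
    wrap point would be indistinguishable from a removed space on re-read;
    callers wrapping DNA may pass e.g. ``width=70``.
    """
    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8") as fh:
            write_fasta(records, fh, width=width)
            return
    for rec in records:
        dest.write(f">{rec.header}\n")
        if width and width > 0:
            for i in range(0, len(rec.sequence), width):
                dest.write(rec.sequence[i:i + width] + "\n")
        else:
            dest.write(rec.sequence + "\n")


def records_from_lines(lines: Iterable[str], prefix: str = "str") -> List[SequenceRecord]:
    """Convert a plain one-string-per-line listing into FASTA records.

    Used for text-mode databases (e.g. institute names): line *i* becomes
    a record with identifier ``{prefix}_{i:06d}`` and the raw line as its
    sequence.  Blank lines are skipped.
    """
    records = []
    for line in lines:
        text = line.rstrip("\r\n")
        if not text:
            continue
        records.append(
            SequenceRecord(f"{prefix}_{len(records):06d}", f"{prefix}_{len(records):06d}", text)
        )
    if not records:
        raise FastaError("no non-blank lines to convert")
    return records


def fasta_to_string(records: Iterable[SequenceRecord]) -> str:
    buf = io.StringIO()
    write_fasta(records, buf)
    return buf.getvalue()


def iter_identifiers(records: Iterable[SequenceRecord]) -> Iterator[str]:
    for rec in records:
        yield rec.identifier
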