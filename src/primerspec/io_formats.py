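"""FASTA/BED input-output and plain-text alignment rendering.

Coordinate conventions
----------------------
All coordinates inside the package are 0-based, half-open intervals.
Rendered reports use 1-based inclusive positions; minus-strand target
coordinates are printed descending (5'-most subject position first), the
conventional display for a primer annealed to the reverse strand.

Sequences are normalised on input: lowercase is uppercased, U becomes T,
and IUPAC ambiguity codes other than N are conservatively mapped to N
(they never match and never seed a search word).  Characters outside the
IUPAC nucleotide alphabet are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import BedFormatError, FastaFormatError

if TYPE_CHECKING:  # pragma: no cover
    from .realign import PrimerTargetAlignment

logger = logging.getLogger(__name__)

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")
_AMBIGUITY = set("RYSWKMBDHV")
_ALPHABET = set("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGTN string (N maps to N)."""
    return seq.translate(_RC_TABLE)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FastaFormatError(f"invalid record id: {self.id!r}")
        if not self.seq:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise FastaFormatError(
                f"record {self.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise BedFormatError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


def normalize_sequence(raw: str, context: str = "sequence") -> str:
    """Uppercase, map U->T, map non-ACGTN IUPAC ambiguity codes to N.

    Raises FastaFormatError for characters outside the IUPAC nucleotide set
    (gap characters included: an aligned FASTA is not a valid template).
    """
    seq = raw.upper().replace("U", "T")
    out = []
    n_ambig = 0
    for c in seq:
        if c in _ALPHABET:
            out.append(c)
        elif c in _AMBIGUITY:
            out.append("N")
            n_ambig += 1
        else:
            raise FastaFormatError(f"illegal character {c!r} in {context}")
    if n_ambig:
        logger.warning(
            "%d IUPAC ambiguity base(s) in %s mapped to N", n_ambig, context
        )
    return "".join(out)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into normalised SequenceRecords."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(rec.seq), context=f"record {rec.id!r}")
        if not seq:
            raise FastaFormatError(f"record {rec.id!r} has an empty sequence")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, seq=seq, description=desc))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write SequenceRecords as wrapped multi-FASTA."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_bed(path: str | Path) -> list[Interval]:
    """Read a BED3+ file of 0-based half-open intervals.

    Column 4, when present, becomes the interval label (used to carry
    "exon" / SNP-id annotations on the template).
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            label = fields[3] if len(fields) > 3 else ""
            try:
                intervals.append(Interval(fields[0], start, end, label))
            except BedFormatError as exc:
                raise BedFormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of overlapping/adjacent intervals, sorted by start."""
    ordered = sorted(intervals, key=lambda iv: (iv.seq_id, iv.start, iv.end))
    merged: list[Interval] = []
    for iv in ordered:
        if (
            merged
            and merged[-1].seq_id == iv.seq_id
            and iv.start <= merged[-1].end
        ):
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = Interval(prev.seq_id, prev.start, iv.end, prev.label)
        else:
            merged.append(iv)
    return merged


def render_alignment(aln: "PrimerTargetAlignment") -> str:
    """Dot-notation text block for one primer-target alignment.

    Two lines: the primer 5'->3' with 1-based positions, and the target
    where "." marks identity, a base letter marks a mismatch and "-" marks
    a gap.  Minus-strand target coordinates are printed descending.
    """
    ga = aln.alignment
    primer_line = ga.aligned_a
    target_chars = []
    for ca, cb in zip(ga.aligned_a, ga.aligned_b):
        if ca == "-" or cb == "-":
            target_chars.append("-")
        elif ca == cb and ca != "N":
            target_chars.append(".")
        else:
            target_chars.append(cb)
    target_line = "".join(target_chars)

    p_start, p_end = 1, len(aln.primer_seq)
    if aln.strand == "plus":
        t_start, t_end = aln.subject_window.start + 1, aln.subject_window.end
    else:
        t_start, t_end = aln.subject_window.end, aln.subject_window.start + 1

    left_w = max(len("Primer"), len("Target"))
    num_w = max(len(str(p_start)), len(str(t_start)))
    lines = [
        f"{'Primer':<{left_w}}  {p_start:>{num_w}}  {primer_line}  {p_end}",
        f"{'Target':<{left_w}}  {t_start:>{num_w}}  {target_line}  {t_end}",
    ]
    return "\n".join(lines)
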