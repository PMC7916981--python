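"""Sequence and table I/O with alphabet and coordinate normalization.

All coordinates are 0-based, half-open.  The single exception is the
seed definition on a mature miRNA, which follows the biological 1-based
inclusive convention: the seed is positions 2-7 of the mature sequence.
DNA input is silently normalized to RNA (T -> U, case folded); any other
symbol is rejected.  Only the plus strand of a supplied 3'-UTR is ever
scanned downstream: 3'-UTR targeting is strand-defined.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")

#: 1-based inclusive seed coordinates on the mature miRNA.
SEED_START, SEED_END = 2, 7


class AlphabetError(ValueError):
    """A sequence contains a symbol outside the nucleotide alphabet."""


class FastaParseError(ValueError):
    """Structurally malformed FASTA input."""


def normalize_rna(sequence: str, context: str = "sequence") -> str:
    """Uppercase, map T->U, and validate against the RNA alphabet.

    Raises :class:`AlphabetError` naming the first offending character.
    """
    seq = sequence.upper().replace("T", "U")
    for ch in seq:
        if ch not in RNA_ALPHABET:
            raise AlphabetError(
                f"invalid nucleotide {ch!r} in {context} (allowed: ACGU, "
                "with T accepted as DNA input)"
            )
    return seq


@dataclass(frozen=True)
class MiRNARecord:
    """A mature miRNA with its derived seed (positions 2-7, 1-based)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = normalize_rna(self.sequence, context=f"miRNA {self.name!r}")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 8:
            raise ValueError(
                f"miRNA {self.name!r} is {len(seq)} nt; at least 8 nt are "
                "required for a seed (positions 2-7) plus position 8"
            )

    @property
    def seed(self) -> str:
        """Seed region, mature positions 2-7 (1-based, inclusive)."""
        return self.sequence[SEED_START - 1 : SEED_END]


@dataclass(frozen=True)
class UTRRecord:
    """A candidate target 3'-UTR sequence (plus strand, 5'->3')."""

    gene: str
    sequence: str
    source_id: str = ""

    def __post_init__(self) -> None:
        seq = normalize_rna(self.sequence, context=f"UTR {self.gene!r}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicWindow:
    """An extracted sub-window of a UTR, 0-based half-open coordinates."""

    start: int
    end: int
    sequence: str
    #: flank actually obtained on each side (may be shorter than requested
    #: when the window is truncated at a UTR boundary)
    left_flank: int = 0
    right_flank: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid window [{self.start}, {self.end})")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("window sequence length does not match coordinates")


def read_fasta(path: Union[str, Path]) -> list[UTRRecord]:
    """Read UTR records from a FASTA file.

    The header token before the first whitespace becomes the gene symbol;
    the full header is kept as ``source_id``.  Sequences are normalized
    to RNA.  Empty records and headerless files raise
    :class:`FastaParseError`.
    """
    path = Path(path)
    _preflight_fasta(path)
    records: list[UTRRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FastaParseError(f"empty sequence for FASTA entry {rec.id!r} in {path}")
        records.append(UTRRecord(gene=rec.id, sequence=seq, source_id=rec.description))
    if not records:
        raise FastaParseError(f"no FASTA records found in {path}")
    return records


def _preflight_fasta(path: Path) -> None:
    """Reject sequence data before any header, reporting the line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: sequence data before any FASTA header"
                )
            return


def write_fasta(records: Iterable[UTRRecord], path: Union[str, Path], width: int = 70) -> None:
    """Write UTR records to FASTA, one wrapped entry per record."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.gene, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def read_mirna_table(path: Union[str, Path]) -> list[MiRNARecord]:
    """Read a miRNA table (TSV with columns ``name`` and ``sequence``).

    Records are returned in file order; the seed is derived from mature
    positions 2-7.  Sequences shorter than 8 nt raise ``ValueError``.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"name", "sequence"} <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: miRNA table must have 'name' and 'sequence' columns, "
                f"got {reader.fieldnames}"
            )
        return [MiRNARecord(row["name"].strip(), row["sequence"].strip()) for row in reader]


def write_mirna_table(records: Iterable[MiRNARecord], path: Union[str, Path]) -> None:
    """Write miRNA records as a two-column TSV (name, sequence)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["name", "sequence"])
        for rec in records:
            writer.writerow([rec.name, rec.sequence])


def extract_window(
    utr: UTRRecord, center_start: int, center_end: int, flank: int
) -> GenomicWindow:
    """Extract ``[center_start, center_end)`` plus up to ``flank`` nt each side.

    The window is truncated at UTR boundaries; the flank lengths actually
    obtained are recorded on the returned :class:`GenomicWindow`.
    """
    n = len(utr)
    if flank < 0:
        raise ValueError("flank must be non-negative")
    if not (0 <= center_start < center_end <= n):
        raise IndexError(
            f"site [{center_start}, {center_end}) outside UTR of length {n} "
            "(empty or out-of-bounds center)"
        )
    start = max(0, center_start - flank)
    end = min(n, center_end + flank)
    return GenomicWindow(
        start=start,
        end=end,
        sequence=utr.sequence[start:end],
        left_flank=center_start - start,
        right_flank=end - center_end,
    )
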