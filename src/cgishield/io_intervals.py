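"""Genomic intervals, FASTA/BED input and output, and sequence extraction.

All coordinates are 0-based half-open internally (BED-native); 1-based
coordinates appear only in human-readable reports. Sequences are uppercased
on read; soft-masked (lowercase) bases are kept by default or replaced with
``N`` under ``mask_mode="remove"``. ``N`` bases never match any IUPAC motif
letter and never count towards G/C in skew or density computations.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

VALID_STRANDS = {"+", "-", "."}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed input file (FASTA/BED/TSV)."""


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval; strand ``.`` means unknown."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    annotations: tuple = ()

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end <= start: {self.chrom}:{self.start}-{self.end}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N}, optionally with provenance."""

    id: str
    residues: str
    source_interval: GenomicInterval | None = None
    clipped_left: int = 0
    clipped_right: int = 0

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"empty sequence for {self.id!r}")
        bad = set(self.residues) - set("ACGTN")
        if bad:
            raise ValueError(f"invalid residues in {self.id!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclasses.dataclass
class TranscriptRecord:
    """A transcript used for CGI classification.

    ``tss``/``tes`` are the transcription start/end sites; for a ``+`` strand
    transcript the TSS is the interval start, for ``-`` the interval end.
    When the strand is unknown, TSS/TES are not meaningful and
    ``strand_known`` is False.
    """

    interval: GenomicInterval
    strand_known: bool = dataclasses.field(init=False)

    def __post_init__(self):
        self.strand_known = self.interval.strand in ("+", "-")

    @property
    def tss(self) -> int:
        if not self.strand_known:
            raise ValueError("TSS undefined for strand-unknown transcript")
        return self.interval.start if self.interval.strand == "+" else self.interval.end

    @property
    def tes(self) -> int:
        if not self.strand_known:
            raise ValueError("TES undefined for strand-unknown transcript")
        return self.interval.end if self.interval.strand == "+" else self.interval.start


def _clean_residues(raw: str, mask_mode: str) -> str:
    if mask_mode not in ("keep", "remove"):
        raise ValueError(f"mask_mode must be 'keep' or 'remove', got {mask_mode!r}")
    if mask_mode == "remove":
        raw = "".join("N" if c.islower() else c for c in raw)
    out = raw.upper()
    # degenerate IUPAC letters in genomes are treated as missing
    return "".join(c if c in "ACGTN" else "N" for c in out)


def read_fasta(path: str | Path, mask_mode: str = "keep") -> list[SequenceRecord]:
    """Read a multi-record FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased; with ``mask_mode="remove"`` soft-masked
    (lowercase) bases become ``N``. Duplicate ids raise :class:`FormatError`.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {entry.id!r}")
        seen.add(entry.id)
        records.append(SequenceRecord(entry.id, _clean_residues(str(entry.seq), mask_mode)))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6(+) into intervals; extra columns kept as annotations.

    Column 6, if present, is taken as the strand (``.`` = unknown). Records
    with ``end <= start`` raise :class:`FormatError` naming the line.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start or start < 0:
                raise FormatError(f"{path}:{lineno}: invalid interval {start}-{end}")
            strand = fields[5] if len(fields) >= 6 and fields[5] in VALID_STRANDS else "."
            intervals.append(
                GenomicInterval(chrom, start, end, strand, annotations=tuple(fields[3:]))
            )
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED; round-trips byte-identically with read_bed."""
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end), *iv.annotations]
            fh.write("\t".join(fields) + "\n")


def to_bed6(iv: GenomicInterval, name: str, score: str = "0") -> GenomicInterval:
    """Interval annotated for BED6 output so the strand column round-trips."""
    return GenomicInterval(iv.chrom, iv.start, iv.end, iv.strand,
                           annotations=(name, score, iv.strand))


def interval_name(iv: GenomicInterval, index: int | None = None) -> str:
    """BED name column if present, else a coordinate-derived id."""
    if iv.annotations and iv.annotations[0] not in ("", "."):
        return iv.annotations[0]
    suffix = f"_{index}" if index is not None else ""
    return f"{iv.chrom}:{iv.start}-{iv.end}{suffix}"


def extract_sequence(
    genome: Mapping[str, Sequence[str]],
    interval: GenomicInterval,
    flank: int = 0,
    mask_mode: str = "keep",
) -> SequenceRecord:
    """Extract ``[start-flank, end+flank)`` from a genome, clipped to bounds.

    ``genome`` is any chrom-keyed mapping whose values support ``len`` and
    slicing (a plain dict of strings, or a ``pyfaidx.Fasta``). Clipping at
    chromosome ends is silent but recorded on the returned record.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    try:
        chrom_seq = genome[interval.chrom]
    except KeyError as exc:
        raise KeyError(f"chromosome {interval.chrom!r} not in genome") from exc
    chrom_len = len(chrom_seq)
    lo = max(interval.start - flank, 0)
    hi = min(interval.end + flank, chrom_len)
    residues = _clean_residues(str(chrom_seq[lo:hi]), mask_mode)
    return SequenceRecord(
        id=interval_name(interval),
        residues=residues,
        source_interval=GenomicInterval(interval.chrom, lo, hi, interval.strand),
        clipped_left=lo - (interval.start - flank),
        clipped_right=(interval.end + flank) - hi,
    )


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share >= 1 bp (half-open arithmetic)."""
    if a.chrom != b.chrom:
        return False
    return a.start < b.end and b.start < a.end


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or abutting intervals per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlapping or abutting
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged
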