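"""File-format I/O and the domain types shared by the whole pipeline.

Every coordinate that enters the package is normalized here to 0-based
half-open intervals. BED, BedGraph and PAF are natively 0-based half-open
and pass through unchanged; RepeatMasker ``.out`` (1-based inclusive) is
shifted at the boundary. Nothing downstream of this module should ever
see a 1-based coordinate except breakpoint-junction positions, which the
junction module documents separately.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "AlignmentBlock",
    "RepeatFeature",
    "DepthTrack",
    "ReadRecord",
    "REPEAT_CLASSES",
    "FormatParseError",
    "ValidationError",
    "read_paf",
    "write_paf",
    "read_bed",
    "write_bed",
    "read_repeatmasker_out",
    "read_depth_bedgraph",
    "write_depth_bedgraph",
    "read_fasta_index",
    "read_sam_reads",
]


class FormatParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed content violates an invariant (empty interval, overlap, ...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open region ``[start, end)`` on a named sequence."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start in {self.seq_id}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValidationError(
                f"empty or inverted interval {self.seq_id}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def size(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance(self, other: "GenomicInterval") -> int | None:
        """Gap in bp between two intervals on the same sequence; 0 if they overlap
        or abut; None if on different sequences."""
        if self.seq_id != other.seq_id:
            return None
        if self.start < other.end and other.start < self.end:
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


@dataclass(frozen=True)
class AlignmentBlock:
    """One PAF record mapping a query segment onto a template (target) segment."""

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    matches: int
    block_len: int
    mapq: int

    def __post_init__(self) -> None:
        if self.query_start >= self.query_end:
            raise ValidationError(
                f"query interval empty: {self.query_id}:{self.query_start}-{self.query_end}"
            )
        if self.target_start >= self.target_end:
            raise ValidationError(
                f"target interval empty: {self.target_id}:{self.target_start}-{self.target_end}"
            )
        if self.matches > self.block_len:
            raise ValidationError(
                f"matches ({self.matches}) exceed block length ({self.block_len})"
            )
        if not 0 <= self.mapq <= 255:
            raise ValidationError(f"mapq out of range: {self.mapq}")
        if self.strand not in "+-":
            raise ValidationError(f"bad strand: {self.strand!r}")

    @property
    def target_interval(self) -> GenomicInterval:
        return GenomicInterval(self.target_id, self.target_start, self.target_end)


REPEAT_CLASSES = (
    "LINE",
    "SINE",
    "LTR",
    "DNA",
    "Simple_repeat",
    "Satellite",
    "Low_complexity",
    "Other",
)


@dataclass(frozen=True)
class RepeatFeature:
    """A RepeatMasker annotation reduced to interval + class + name."""

    interval: GenomicInterval
    repeat_class: str
    repeat_name: str

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValidationError(f"unknown repeat class {self.repeat_class!r}")


@dataclass
class DepthTrack:
    """Per-sample step function of read depth: sorted, non-overlapping steps."""

    sample_id: str
    steps: list[tuple[GenomicInterval, float]] = field(default_factory=list)

    def validate(self) -> "DepthTrack":
        prev: GenomicInterval | None = None
        for iv, depth in self.steps:
            if depth < 0:
                raise ValidationError(f"negative depth {depth} at {iv.seq_id}:{iv.start}")
            if prev is not None and prev.seq_id == iv.seq_id:
                if iv.start < prev.end:
                    raise ValidationError(
                        f"overlapping depth steps at {iv.seq_id}:{iv.start} "
                        f"(previous step ends {prev.end})"
                    )
            prev = iv
        return self


@dataclass(frozen=True)
class ReadRecord:
    """One primary read alignment summary over a region of interest."""

    read_id: str
    mapq: int
    interval: GenomicInterval
    n_alignments: int = 1
    is_supplementary: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.mapq <= 255:
            raise ValidationError(f"mapq out of range: {self.mapq}")
        if self.n_alignments < 1:
            raise ValidationError(f"n_alignments must be >= 1, got {self.n_alignments}")

    @property
    def is_multimapping(self) -> bool:
        return self.n_alignments >= 2


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------

def read_paf(path: str | os.PathLike) -> list[AlignmentBlock]:
    """Parse a PAF file into alignment blocks.

    Only the 12 mandatory columns are used; SAM-style tags beyond column 12
    are ignored. Coordinates are kept as-is (PAF is 0-based half-open).
    """
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatParseError(
                    f"{path}: line {lineno}: expected >=12 PAF fields, got {len(fields)}"
                )
            try:
                blocks.append(
                    AlignmentBlock(
                        query_id=fields[0],
                        query_len=int(fields[1]),
                        query_start=int(fields[2]),
                        query_end=int(fields[3]),
                        strand=fields[4],
                        target_id=fields[5],
                        target_len=int(fields[6]),
                        target_start=int(fields[7]),
                        target_end=int(fields[8]),
                        matches=int(fields[9]),
                        block_len=int(fields[10]),
                        mapq=int(fields[11]),
                    )
                )
            except ValueError as exc:
                if isinstance(exc, ValidationError):
                    raise ValidationError(f"{path}: line {lineno}: {exc}") from None
                raise FormatParseError(f"{path}: line {lineno}: {exc}") from None
    return blocks


def write_paf(blocks: Iterable[AlignmentBlock], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        b.query_id, b.query_len, b.query_start, b.query_end,
                        b.strand,
                        b.target_id, b.target_len, b.target_start, b.target_end,
                        b.matches, b.block_len, b.mapq,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED / BedGraph
# ---------------------------------------------------------------------------

def _is_bed_skip(line: str) -> bool:
    return (
        not line.strip()
        or line.startswith("#")
        or line.startswith("track")
        or line.startswith("browser")
    )


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read a BED3+ file; extra columns ignored, header/track lines skipped."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_bed_skip(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatParseError(
                    f"{path}: line {lineno}: expected >=3 BED columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatParseError(f"{path}: line {lineno}: {exc}") from None
            try:
                out.append(GenomicInterval(fields[0], start, end))
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | os.PathLike,
    names: Iterable[str] | None = None,
) -> None:
    names_list = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names_list is not None:
                fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{names_list[i]}\n")
            else:
                fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\n")


def read_depth_bedgraph(path: str | os.PathLike, sample_id: str) -> DepthTrack:
    """Read a 4-column BedGraph into a validated depth track."""
    steps: list[tuple[GenomicInterval, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_bed_skip(line):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise FormatParseError(
                    f"{path}: line {lineno}: expected 4 BedGraph columns, got {len(fields)}"
                )
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                depth = float(fields[3])
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
            except ValueError as exc:
                raise FormatParseError(f"{path}: line {lineno}: {exc}") from None
            steps.append((iv, depth))
    steps.sort(key=lambda sd: (sd[0].seq_id, sd[0].start))
    return DepthTrack(sample_id=sample_id, steps=steps).validate()


def write_depth_bedgraph(track: DepthTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv, depth in track.steps:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{depth:g}\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

def _repeat_class_from(field_value: str) -> str:
    prefix = field_value.split("/")[0]
    return prefix if prefix in REPEAT_CLASSES else "Other"


def read_repeatmasker_out(path: str | os.PathLike) -> list[RepeatFeature]:
    """Parse RepeatMasker ``.out``.

    The standard layout has two header lines plus a blank line; data rows are
    whitespace-delimited with the query sequence in column 5, 1-based inclusive
    begin/end in columns 6-7, the repeat name in column 10 and class/family in
    column 11. Coordinates are converted to 0-based half-open (begin-1, end).
    The class is the part of class/family before "/"; anything outside the
    closed vocabulary maps to ``Other``.
    """
    feats: list[RepeatFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            # header lines start with the literal column titles
            if stripped.startswith(("SW", "score", "bit")):
                continue
            fields = stripped.split()
            if len(fields) < 11:
                raise FormatParseError(
                    f"{path}: line {lineno}: expected >=11 RepeatMasker columns, "
                    f"got {len(fields)}"
                )
            try:
                seq_id = fields[4]
                begin = int(fields[5])
                end = int(fields[6])
            except ValueError as exc:
                raise FormatParseError(f"{path}: line {lineno}: {exc}") from None
            name = fields[9]
            klass = _repeat_class_from(fields[10])
            try:
                feats.append(
                    RepeatFeature(GenomicInterval(seq_id, begin - 1, end), klass, name)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
    return feats


# ---------------------------------------------------------------------------
# FASTA / faidx
# ---------------------------------------------------------------------------

def read_fasta_index(path: str | os.PathLike) -> dict[str, int]:
    """Sequence lengths from a faidx-style index, or by scanning a FASTA.

    A file whose first data line has >=2 tab-separated columns with an integer
    second column is treated as an index; otherwise it is read as FASTA.
    """
    path = os.fspath(path)
    with open(path) as fh:
        first = fh.readline()
    is_fai = False
    if first and not first.startswith(">"):
        parts = first.rstrip("\n").split("\t")
        if len(parts) >= 2:
            try:
                int(parts[1])
                is_fai = True
            except ValueError:
                is_fai = False
    lengths: dict[str, int] = {}
    if is_fai:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                name, length = parts[0], int(parts[1])
                if name in lengths:
                    raise ValidationError(f"{path}: duplicate sequence name {name!r}")
                if length <= 0:
                    raise ValidationError(f"{path}: non-positive length for {name!r}")
                lengths[name] = length
    else:
        for rec in SeqIO.parse(path, "fasta"):
            if rec.id in lengths:
                raise ValidationError(f"{path}: duplicate sequence name {rec.id!r}")
            if len(rec.seq) == 0:
                raise ValidationError(f"{path}: empty sequence {rec.id!r}")
            lengths[rec.id] = len(rec.seq)
    return lengths


# ---------------------------------------------------------------------------
# SAM read summaries
# ---------------------------------------------------------------------------

def read_sam_reads(path: str | os.PathLike) -> list[ReadRecord]:
    """Read alignment records from SAM text into per-read summaries.

    A read counts as multimapping when an ``NH`` tag reports more than one hit,
    or when several non-supplementary records share its name. Unmapped records
    are skipped.
    """
    raw: list[tuple[str, int, GenomicInterval, int | None, bool]] = []
    name_counts: dict[str, int] = {}
    with pysam.AlignmentFile(os.fspath(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            iv = GenomicInterval(rec.reference_name, rec.reference_start, rec.reference_end)
            nh = rec.get_tag("NH") if rec.has_tag("NH") else None
            raw.append((rec.query_name, rec.mapping_quality, iv, nh, rec.is_supplementary))
            if not rec.is_supplementary:
                name_counts[rec.query_name] = name_counts.get(rec.query_name, 0) + 1
    out: list[ReadRecord] = []
    for name, mapq, iv, nh, supp in raw:
        n_aln = nh if nh is not None else max(1, name_counts.get(name, 1))
        out.append(
            ReadRecord(
                read_id=name,
                mapq=mapq,
                interval=iv,
                n_alignments=n_aln,
                is_supplementary=supp,
            )
        )
    return out


def iter_fasta(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) pairs from a FASTA file."""
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        yield rec.id, str(rec.seq).upper()
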