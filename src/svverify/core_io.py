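"""Domain types and file I/O for SV validation.

Coordinate convention: every position in this package is 0-based,
intervals are half-open ``[start, end)``.  BED input is already 0-based
half-open; SAM/BAM 1-based positions are converted at the pysam boundary
(pysam itself reports 0-based coordinates).  Query coordinates of an
alignment segment are always expressed on the *forward orientation* of
the original read, so segments of one read share a single read axis
regardless of strand.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pysam

SV_TYPES = frozenset({"DEL", "INS", "INV"})

# CIGAR operation codes as used by pysam (BAM encoding).
_CIGAR_OPS = "MIDNSHP=X"
_QUERY_CONSUMING = frozenset("MIS=X")
_REF_CONSUMING = frozenset("MDN=X")
_CLIP_OPS = frozenset("SH")


class Label(str, Enum):
    """Validation outcome for one candidate SV."""

    HOMOZYGOUS = "HOMOZYGOUS"
    HETEROZYGOUS = "HETEROZYGOUS"
    FALSE = "FALSE"
    FILTERED_HIGH_COVERAGE = "FILTERED_HIGH_COVERAGE"
    NO_READS = "NO_READS"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


@dataclass(frozen=True)
class SVRecord:
    """One candidate structural variant from the input list.

    ``start``/``end`` are 0-based half-open on the reference.  For an
    insertion the interval is the breakpoint (``end == start + 1`` is
    permitted) and ``length`` is the inserted length; for DEL/INV the
    length defaults to ``end - start``.
    """

    id: str
    chrom: str
    start: int
    end: int
    sv_type: str
    length: int

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.sv_type in ("DEL", "INV") and not self.start < self.end:
            raise ValueError(f"{self.sv_type} requires start < end, got {self.start}..{self.end}")
        if self.length <= 0:
            raise ValueError("SV length must be positive")


@dataclass(frozen=True)
class AlignmentSegment:
    """One alignment of a read (primary or supplementary).

    ``query_start``/``query_end`` are half-open positions on the
    forward-oriented read; for reverse-strand alignments they are
    recomputed from the CIGAR clips so that all segments of a read live
    on one axis.
    """

    read_id: str
    chrom: str
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    strand: str  # "+" or "-"
    mapq: int
    cigar: tuple[tuple[str, int], ...]
    is_supplementary: bool = False

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


@dataclass
class ValidationParams:
    """Tunable thresholds of the validation pipeline (defaults as published)."""

    flank_len: int = 1000
    mapq_min: int = 20
    min_cigar_indel: int = 30
    coverage_multiplier: float = 5.0
    n_coverage_samples: int = 1000
    split_diff_threshold: int = 200
    hom_threshold: float = 0.8
    false_threshold: float = 0.1
    alt_support_fraction: float = 0.1
    inv_fwd_noise_min: float = 0.3
    inv_rev_noise_max: float = 0.2
    min_alt_sv_len: int = 50
    ins_coverage_halfwindow: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.false_threshold < self.hom_threshold <= 1):
            raise ValueError("need 0 <= false_threshold < hom_threshold <= 1")
        for name in ("flank_len", "min_cigar_indel", "split_diff_threshold",
                     "min_alt_sv_len", "ins_coverage_halfwindow"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ValidationResult:
    """Aggregated verdict for one SV."""

    sv: SVRecord
    total_reads: int
    support_reads: int
    support_rate: float
    label: Label
    corrected_length: int | None = None
    corrected_type: str | None = None
    corrected_support_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.support_reads > self.total_reads:
            raise ValueError("support_reads cannot exceed total_reads")


@dataclass
class SkippedRecord:
    """A rejected input line (unknown type etc.), reported not crashed on."""

    line_number: int
    line: str
    reason: str


# ---------------------------------------------------------------------------
# SV list readers / writers
# ---------------------------------------------------------------------------

def read_sv_bed(
    path: str | Path,
    skipped: list[SkippedRecord] | None = None,
) -> list[SVRecord]:
    """Read a BED-dialect SV list.

    Columns: chrom, start, end, type[, length][, id]; tab separated,
    0-based half-open coordinates.  Missing length defaults to
    ``end - start`` for DEL/INV; missing id is synthesized as
    ``chrom_start_type``.  Lines with an unknown SV type are collected in
    ``skipped`` (if given) instead of raising; malformed coordinates
    raise a ``ValueError`` naming the line.
    """
    records: list[SVRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: expected >= 4 columns, got {len(fields)}")
            chrom, start_s, end_s, sv_type = fields[0], fields[1], fields[2], fields[3].upper()
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if sv_type not in SV_TYPES:
                if skipped is not None:
                    skipped.append(SkippedRecord(lineno, line, f"unknown sv_type {sv_type!r}"))
                    continue
                raise ValueError(f"{path}: line {lineno}: unknown sv_type {sv_type!r}")
            length = None
            if len(fields) >= 5 and fields[4] not in ("", "."):
                try:
                    length = abs(int(fields[4]))
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: non-integer length") from exc
            if length is None:
                if sv_type == "INS":
                    raise ValueError(f"{path}: line {lineno}: INS record requires a length column")
                length = end - start
            sv_id = fields[5] if len(fields) >= 6 and fields[5] else f"{chrom}_{start}_{sv_type}"
            try:
                records.append(SVRecord(sv_id, chrom, start, end, sv_type, length))
            except ValueError as exc:
                if skipped is not None:
                    skipped.append(SkippedRecord(lineno, line, str(exc)))
                else:
                    raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return records


def read_sv_vcf(path: str | Path, skipped: list[SkippedRecord] | None = None) -> list[SVRecord]:
    """Convenience adapter: map VCF SVTYPE/SVLEN/END records into SVRecords."""
    records: list[SVRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf, start=1):
            sv_type = rec.info.get("SVTYPE")
            if sv_type not in SV_TYPES:
                if skipped is not None:
                    skipped.append(SkippedRecord(i, str(rec).strip(), f"unsupported SVTYPE {sv_type!r}"))
                continue
            start = rec.start  # pysam: 0-based
            end = rec.stop
            svlen = rec.info.get("SVLEN")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            if svlen is not None:
                length = abs(int(svlen))
            elif sv_type in ("DEL", "INV"):
                length = end - start
            else:
                if skipped is not None:
                    skipped.append(SkippedRecord(i, str(rec).strip(), "INS without SVLEN"))
                continue
            if sv_type == "INS" and end <= start:
                end = start + 1
            sv_id = rec.id or f"{rec.chrom}_{start}_{sv_type}"
            records.append(SVRecord(sv_id, rec.chrom, start, end, sv_type, length))
    return records


def write_sv_bed(records: Sequence[SVRecord], path: str | Path) -> None:
    """Write SVRecords in the same BED dialect read_sv_bed accepts."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.sv_type}\t{r.length}\t{r.id}\n")


def write_skipped_report(skipped: Sequence[SkippedRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["line_number", "reason", "line"])
        for s in skipped:
            w.writerow([s.line_number, s.reason, s.line])


# ---------------------------------------------------------------------------
# Alignment access
# ---------------------------------------------------------------------------

def _cigar_from_pysam(cigartuples) -> tuple[tuple[str, int], ...]:
    return tuple((_CIGAR_OPS[op], length) for op, length in cigartuples)


def cigar_query_length(cigar: Iterable[tuple[str, int]]) -> int:
    """Full read length implied by a CIGAR, counting S and H clips."""
    return sum(n for op, n in cigar if op in _QUERY_CONSUMING or op in _CLIP_OPS)


def cigar_reference_length(cigar: Iterable[tuple[str, int]]) -> int:
    return sum(n for op, n in cigar if op in _REF_CONSUMING)


def segment_from_aligned(read: pysam.AlignedSegment) -> AlignmentSegment:
    """Convert one pysam record, normalizing query coordinates to the
    forward orientation of the read.

    Works for both soft- and hard-clipped records: the clip lengths in
    the CIGAR reconstruct where the aligned block sits on the full read.
    """
    cigar = _cigar_from_pysam(read.cigartuples)
    full_len = cigar_query_length(cigar)
    lead = cigar[0][1] if cigar[0][0] in _CLIP_OPS else 0
    # aligned query length excludes clips
    aligned = sum(n for op, n in cigar if op in "MI=X")
    if read.is_reverse:
        strand = "-"
        query_start = full_len - lead - aligned
    else:
        strand = "+"
        query_start = lead
    return AlignmentSegment(
        read_id=read.query_name,
        chrom=read.reference_name,
        ref_start=read.reference_start,
        ref_end=read.reference_end,
        query_start=query_start,
        query_end=query_start + aligned,
        strand=strand,
        mapq=read.mapping_quality,
        cigar=cigar,
        is_supplementary=read.is_supplementary,
    )


def fetch_segments(
    bam: pysam.AlignmentFile,
    chrom: str,
    window_start: int,
    window_end: int,
) -> dict[str, list[AlignmentSegment]]:
    """All primary+supplementary alignments overlapping a window, grouped
    by read name.  Secondary and unmapped records are excluded; duplicate
    placements of the same (read, ref_start) are dropped.
    """
    if window_start >= window_end:
        raise ValueError("window_start must be < window_end")
    if chrom not in bam.references:
        import warnings

        warnings.warn(f"contig {chrom!r} not in BAM header; returning no reads")
        return {}
    groups: dict[str, list[AlignmentSegment]] = {}
    seen: set[tuple[str, str, int]] = set()
    for read in bam.fetch(chrom, max(0, window_start), window_end):
        if read.is_unmapped or read.is_secondary or read.cigartuples is None:
            continue
        key = (read.query_name, read.reference_name, read.reference_start)
        if key in seen:
            continue
        seen.add(key)
        groups.setdefault(read.query_name, []).append(segment_from_aligned(read))
    for segs in groups.values():
        segs.sort(key=lambda s: s.query_start)
    return groups


def open_bam(path: str | Path) -> pysam.AlignmentFile:
    """Open a coordinate-sorted BAM, with an actionable error if the index is missing."""
    bam = pysam.AlignmentFile(str(path))
    if not bam.has_index():
        bam.close()
        raise FileNotFoundError(
            f"{path} has no index; run `samtools index {path}` first"
        )
    return bam


# ---------------------------------------------------------------------------
# Results output
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "chrom", "start", "end", "type", "listed_length",
    "total_reads", "support_reads", "support_rate", "label", "corrected_length",
]


def write_results(results: Sequence[ValidationResult], path: str | Path) -> None:
    """Write the results TSV, one row per input SV, in input order."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(RESULT_COLUMNS)
        for r in results:
            w.writerow([
                r.sv.chrom, r.sv.start, r.sv.end, r.sv.sv_type, r.sv.length,
                r.total_reads, r.support_reads, f"{r.support_rate:.4f}",
                str(r.label),
                "" if r.corrected_length is None else r.corrected_length,
            ])
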