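"""Coverage estimation and the high-coverage SV filter (pipeline step 1).

Average coverage is estimated by sampling reference positions uniformly
over the concatenated genome (contigs weighted by length) and averaging
the alignment depth at each, then SVs in regions whose mean coverage
strictly exceeds ``coverage_multiplier`` times that average are set
aside: in such regions reads from elsewhere pile up by similarity and
per-read evidence is unreliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pysam

from .core_io import Label, SVRecord, ValidationParams, ValidationResult


@dataclass
class CoverageModel:
    average_coverage: float
    samples: list[tuple[str, int, int]] = field(default_factory=list)
    rng_seed: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def position_coverage(bam: pysam.AlignmentFile, chrom: str, pos: int) -> int:
    """Number of primary+supplementary alignments whose span contains pos."""
    n = 0
    for read in bam.fetch(chrom, pos, pos + 1):
        if read.is_unmapped or read.is_secondary:
            continue
        if read.reference_start <= pos < read.reference_end:
            n += 1
    return n


def estimate_average_coverage(
    bam: pysam.AlignmentFile,
    n_samples: int = 1000,
    rng_seed: int = 0,
) -> CoverageModel:
    """Sample ``n_samples`` positions and return their mean depth.

    Positions are drawn uniformly over the concatenated mapped genome, so
    longer contigs receive proportionally more samples.  The estimate is
    the unweighted arithmetic mean of the sampled depths.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    contigs = [(name, length) for name, length in zip(bam.references, bam.lengths) if length > 0]
    if not contigs:
        raise ValueError("BAM header lists no non-empty contigs")
    lengths = np.array([l for _, l in contigs], dtype=np.int64)
    total = int(lengths.sum())
    rng = np.random.default_rng(rng_seed)
    offsets = np.sort(rng.integers(0, total, size=n_samples))
    bounds = np.cumsum(lengths)
    samples: list[tuple[str, int, int]] = []
    for off in offsets:
        ci = int(np.searchsorted(bounds, off, side="right"))
        pos = int(off - (bounds[ci - 1] if ci else 0))
        chrom = contigs[ci][0]
        samples.append((chrom, pos, position_coverage(bam, chrom, pos)))
    avg = float(np.mean([c for _, _, c in samples]))
    if bam.mapped == 0:
        warnings.warn("BAM contains no mapped reads; average coverage is 0")
    return CoverageModel(average_coverage=avg, samples=samples, rng_seed=rng_seed)


def region_mean_coverage(
    bam: pysam.AlignmentFile, chrom: str, start: int, end: int
) -> float:
    """Mean per-base depth over [start, end) from alignment spans."""
    if start >= end:
        raise ValueError("start must be < end")
    start = max(0, start)
    if chrom not in bam.references:
        return 0.0
    total = 0
    for read in bam.fetch(chrom, start, end):
        if read.is_unmapped or read.is_secondary:
            continue
        total += min(read.reference_end, end) - max(read.reference_start, start)
    return total / (end - start)


def _sv_coverage_window(sv: SVRecord, params: ValidationParams) -> tuple[int, int]:
    if sv.sv_type == "INS":
        return sv.start - params.ins_coverage_halfwindow, sv.start + params.ins_coverage_halfwindow
    return sv.start, sv.end


def filter_high_coverage(
    svs: list[SVRecord],
    model: CoverageModel,
    bam: pysam.AlignmentFile,
    params: ValidationParams,
) -> tuple[list[SVRecord], list[ValidationResult]]:
    """Partition SVs into (kept, filtered-out results).

    An SV is filtered iff the mean coverage over its span (a ±500 bp
    window around the breakpoint for insertions) is strictly greater
    than ``coverage_multiplier * average_coverage``.
    """
    threshold = params.coverage_multiplier * model.average_coverage
    kept: list[SVRecord] = []
    filtered: list[ValidationResult] = []
    for sv in svs:
        lo, hi = _sv_coverage_window(sv, params)
        cov = region_mean_coverage(bam, sv.chrom, max(0, lo), hi)
        if cov > threshold:
            filtered.append(ValidationResult(sv, 0, 0, 0.0, Label.FILTERED_HIGH_COVERAGE))
        else:
            kept.append(sv)
    return kept, filtered
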