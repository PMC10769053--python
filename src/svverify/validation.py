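"""Genotype assignment and corrected-SV output (pipeline step 3).

The support rate — supporting reads over screened reads at the locus —
drives the call:

    rate >= 0.8          homozygous
    0.1 <= rate < 0.8    heterozygous
    rate < 0.1           false

When a listed SV is called false but more than 10% of the screened reads
agree on another SV at the locus, the mean of their implied lengths is
reported as the corrected SV.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import pysam
from pyfaidx import Fasta

from .core_io import (
    Label,
    SVRecord,
    ValidationParams,
    ValidationResult,
    fetch_segments,
)
from .coverage import CoverageModel, estimate_average_coverage, filter_high_coverage
from .support import SupportEvidence, evidence_for_read, screen_reads

logger = logging.getLogger("svverify")


def tally_support(evidences: Sequence[SupportEvidence]) -> tuple[int, int, float | None]:
    """(support_reads, total_reads, support_rate); rate is None with no reads."""
    total = len(evidences)
    support = sum(1 for e in evidences if e.supports)
    return support, total, (support / total if total else None)


def classify(support_rate: float, params: ValidationParams) -> Label:
    """Map a support rate onto a genotype label (closed lower bounds)."""
    if not 0 <= support_rate <= 1:
        raise ValueError("support_rate must be in [0, 1]")
    if support_rate >= params.hom_threshold:
        return Label.HOMOZYGOUS
    if support_rate >= params.false_threshold:
        return Label.HETEROZYGOUS
    return Label.FALSE


def corrected_sv(
    evidences: Sequence[SupportEvidence],
    sv: SVRecord,
    params: ValidationParams,
) -> tuple[int, str, float] | None:
    """If the locus supports a *different* SV, return (length, type, fraction).

    Among non-supporting reads, those implying an SV of at least
    ``min_alt_sv_len`` bp are collected; if they agree in sign and make
    up strictly more than ``alt_support_fraction`` of the screened
    reads, the rounded mean magnitude is the corrected length (DEL for
    negative evidence, INS for positive).
    """
    total = len(evidences)
    if total == 0:
        return None
    alt = [
        e.implied_length
        for e in evidences
        if not e.supports and abs(e.implied_length) >= params.min_alt_sv_len
    ]
    if not alt:
        return None
    if not (all(v > 0 for v in alt) or all(v < 0 for v in alt)):
        return None
    fraction = len(alt) / total
    if fraction <= params.alt_support_fraction:
        return None
    mean_len = int(round(sum(abs(v) for v in alt) / len(alt)))
    alt_type = "DEL" if alt[0] < 0 else "INS"
    return mean_len, alt_type, fraction


def validate_sv(
    sv: SVRecord,
    bam: pysam.AlignmentFile,
    params: ValidationParams,
    reference: Fasta | None = None,
) -> tuple[ValidationResult, list[SupportEvidence]]:
    """Screen reads at one SV locus, collect evidence, and call it."""
    window_start = max(0, sv.start - params.flank_len - 1)
    window_end = sv.end + params.flank_len + 1
    groups = fetch_segments(bam, sv.chrom, window_start, window_end)
    candidates = screen_reads(groups, sv, params)
    if not candidates:
        return ValidationResult(sv, 0, 0, 0.0, Label.NO_READS), []

    ref_segment = None
    read_seqs: dict[str, dict[tuple[int, str], str]] | None = None
    if sv.sv_type == "INV":
        if reference is None:
            raise ValueError(f"reference FASTA required to validate inversion {sv.id}")
        ref_segment = str(reference[sv.chrom][sv.start:sv.end]).upper()
        read_seqs = _collect_read_sequences(bam, sv, candidates, params)

    evidences: list[SupportEvidence] = []
    for read_id, segs in candidates.items():
        per_read_seqs = read_seqs.get(read_id) if read_seqs is not None else None
        evidences.append(
            evidence_for_read(segs, sv, params, ref_segment, per_read_seqs)
        )
    support, total, rate = tally_support(evidences)
    label = classify(rate, params)
    result = ValidationResult(sv, total, support, rate, label)
    if label is Label.FALSE:
        alt = corrected_sv(evidences, sv, params)
        if alt is not None:
            result.corrected_length, result.corrected_type, result.corrected_support_fraction = alt
    return result, evidences


def _collect_read_sequences(
    bam: pysam.AlignmentFile,
    sv: SVRecord,
    candidates: dict[str, list],
    params: ValidationParams,
) -> dict[str, dict[tuple[int, str], str]]:
    """Stored-orientation, clip-stripped sequences of candidate reads'
    segments, keyed by read then (ref_start, strand) — the inversion
    noise check needs the actual bases."""
    out: dict[str, dict[tuple[int, str], str]] = {}
    for read in bam.fetch(sv.chrom, max(0, sv.start - params.flank_len - 1), sv.end + params.flank_len + 1):
        if read.is_unmapped or read.is_secondary:
            continue
        if read.query_name not in candidates:
            continue
        seq = read.query_alignment_sequence
        if seq is None:
            continue
        strand = "-" if read.is_reverse else "+"
        out.setdefault(read.query_name, {})[(read.reference_start, strand)] = seq.upper()
    return out


def validate_all(
    svs: list[SVRecord],
    bam: pysam.AlignmentFile,
    reference: Fasta | None,
    params: ValidationParams,
    coverage_model: CoverageModel | None = None,
    collect_evidence: list[tuple[str, SupportEvidence]] | None = None,
) -> tuple[list[ValidationResult], CoverageModel]:
    """Run the full pipeline over an SV list.

    Estimates average coverage (unless a model is supplied), filters
    high-coverage loci, and validates each remaining SV.  Output order
    matches input order; a per-SV internal failure degrades to NO_READS
    with a warning rather than aborting the batch.
    """
    if coverage_model is None:
        coverage_model = estimate_average_coverage(
            bam, params.n_coverage_samples, params.rng_seed
        )
    logger.info(
        "average coverage %.2f from %d samples",
        coverage_model.average_coverage, coverage_model.n_samples,
    )
    kept, filtered = filter_high_coverage(svs, coverage_model, bam, params)
    filtered_iter = iter(filtered)
    kept_set = {id(sv) for sv in kept}
    results: list[ValidationResult] = []
    for sv in svs:
        if id(sv) not in kept_set:
            results.append(next(filtered_iter))
            continue
        try:
            result, evidences = validate_sv(sv, bam, params, reference)
        except ValueError:
            raise
        except Exception as exc:  # keep the batch alive
            warnings.warn(f"validation of {sv.id} failed ({exc}); reporting NO_READS")
            result, evidences = ValidationResult(sv, 0, 0, 0.0, Label.NO_READS), []
        results.append(result)
        if collect_evidence is not None:
            collect_evidence.extend((sv.id, e) for e in evidences)
    return results, coverage_model
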