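"""Per-read support evidence for candidate SVs (pipeline step 2).

A screened read either carries the SV inside one alignment (CIGAR
channel: large I/D operations for indels, a mismatch-dense forced
alignment for inversions) or bridges it with split alignments (split
channel: a primary plus supplementary segments).  Each read yields one
``SupportEvidence`` verdict; the fraction of supporting reads drives
the genotype call downstream.

Length agreement is judged against the tolerance

    distance_support(L) = 0.2 * L + 2000 / L

which is wide for both very short SVs (the additive term) and very long
ones (the proportional term), with its minimum of 40 bp at L = 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .core_io import AlignmentSegment, SVRecord, ValidationParams

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SupportEvidence:
    """One read's verdict at one SV.

    ``implied_length`` is signed: positive for insertion-like evidence,
    negative for deletion-like; for inversions it is the unsigned span.
    It is 0 only when the read showed no SV signal at all.
    """

    read_id: str
    supports: bool
    implied_length: int
    channel: str  # "cigar" | "split" | "none"


# ---------------------------------------------------------------------------
# Read screening
# ---------------------------------------------------------------------------

def _covers_point(segments: list[AlignmentSegment], point: int) -> bool:
    return any(s.ref_start <= point < s.ref_end for s in segments)


def screen_reads(
    read_groups: dict[str, list[AlignmentSegment]],
    sv: SVRecord,
    params: ValidationParams,
) -> dict[str, list[AlignmentSegment]]:
    """Keep reads that are informative about the SV locus.

    A read is retained iff its best segment has MAPQ >= ``mapq_min`` and
    the union of its segments' reference spans covers both flank points
    ``sv.start - flank_len`` and ``sv.end + flank_len``.  Reads that do
    not traverse the whole flanked region cannot distinguish the SV from
    an alignment artifact (common in repeats) and are dropped.  Retained
    reads form the denominator of the support rate.
    """
    left = max(0, sv.start - params.flank_len)
    right = sv.end + params.flank_len
    kept: dict[str, list[AlignmentSegment]] = {}
    for read_id, segs in read_groups.items():
        if max(s.mapq for s in segs) < params.mapq_min:
            continue
        if _covers_point(segs, left) and _covers_point(segs, right - 1):
            kept[read_id] = segs
    return kept


# ---------------------------------------------------------------------------
# Length tolerance
# ---------------------------------------------------------------------------

def distance_support(sv_length: float) -> float:
    """Accepted deviation (bp) between implied and listed SV length."""
    if sv_length <= 0:
        raise ValueError("sv_length must be positive")
    return 0.2 * sv_length + 2000.0 / sv_length


# ---------------------------------------------------------------------------
# CIGAR channel (DEL / INS)
# ---------------------------------------------------------------------------

def net_indel_in_window(
    segment: AlignmentSegment,
    window_start: int,
    window_end: int,
    min_op: int = 30,
) -> int:
    """Signed net indel length from CIGAR ops inside a reference window.

    Walks the CIGAR, adding +len for each insertion and -len for each
    deletion whose reference position (anchor position immediately left
    of the op, for insertions) lies in [window_start, window_end) and
    whose length >= ``min_op``.  Nearby fragments of one SV thus merge
    into a single net length, which is what gets compared to the listed
    SV.
    """
    ref = segment.ref_start
    net = 0
    for op, length in segment.cigar:
        if op in ("M", "=", "X"):
            ref += length
        elif op == "D" or op == "N":
            if op == "D" and length >= min_op and window_start <= ref < window_end:
                net -= length
            ref += length
        elif op == "I":
            anchor = ref - 1
            if length >= min_op and window_start <= anchor < window_end:
                net += length
        elif op in ("S", "H", "P"):
            continue
        else:
            raise ValueError(f"malformed CIGAR op {op!r}")
    return net


def _longest_segment(segments: list[AlignmentSegment]) -> AlignmentSegment:
    return max(segments, key=lambda s: s.ref_span)


def cigar_supports_indel(
    read_group: list[AlignmentSegment],
    sv: SVRecord,
    params: ValidationParams,
) -> SupportEvidence:
    """Does the read's CIGAR carry an indel matching the candidate?

    The net indel over (start - flank_len, end + flank_len) on the
    read's longest segment must have the sign of the SV type (deletion
    negative, insertion positive) and magnitude within
    ``distance_support`` of the listed length.
    """
    seg = _longest_segment(read_group)
    net = net_indel_in_window(
        seg, sv.start - params.flank_len, sv.end + params.flank_len, params.min_cigar_indel
    )
    read_id = seg.read_id
    if net == 0:
        return SupportEvidence(read_id, False, 0, "none")
    sign_ok = (net < 0) if sv.sv_type == "DEL" else (net > 0)
    ok = sign_ok and abs(abs(net) - sv.length) <= distance_support(sv.length)
    return SupportEvidence(read_id, ok, net, "cigar")


# ---------------------------------------------------------------------------
# Split channel (DEL / INS)
# ---------------------------------------------------------------------------

def split_difference(seg_a: AlignmentSegment, seg_b: AlignmentSegment) -> int | None:
    """read_distance - ref_distance for two segments of one read.

    Segments must be on the same chromosome and strand; returns None
    (not applicable) otherwise.  The caller passes them in query order.
    A positive value is insertion-like (extra read sequence between the
    anchors), a negative value deletion-like.
    """
    if seg_a.chrom != seg_b.chrom or seg_a.strand != seg_b.strand:
        return None
    if seg_a.query_start > seg_b.query_start:
        seg_a, seg_b = seg_b, seg_a
    ref_distance = seg_b.ref_start - seg_a.ref_end
    read_distance = seg_b.query_start - seg_a.query_end
    return read_distance - ref_distance


def split_supports_indel(
    read_group: list[AlignmentSegment],
    sv: SVRecord,
    params: ValidationParams,
) -> SupportEvidence:
    """Split-read test for DEL/INS.

    For a read with exactly two same-chromosome, same-strand segments:
    a gap difference > +200 bp signals an insertion, < -200 bp a
    deletion; the magnitude must agree with the listed length within
    ``distance_support``.
    """
    read_id = read_group[0].read_id
    segs = [s for s in read_group if s.chrom == sv.chrom]
    if len(segs) != 2 or segs[0].strand != segs[1].strand:
        return SupportEvidence(read_id, False, 0, "none")
    diff = split_difference(segs[0], segs[1])
    if diff is None or abs(diff) <= params.split_diff_threshold:
        return SupportEvidence(read_id, False, 0, "none")
    sign_ok = (diff < 0) if sv.sv_type == "DEL" else (diff > 0)
    ok = sign_ok and abs(abs(diff) - sv.length) <= distance_support(sv.length)
    return SupportEvidence(read_id, ok, diff, "split")


# ---------------------------------------------------------------------------
# Inversion, CIGAR (single-segment) channel
# ---------------------------------------------------------------------------

def _query_pos_at_ref(segment: AlignmentSegment, ref_target: int) -> int | None:
    """Query offset (in stored/aligned orientation, relative to the
    aligned block start) corresponding to a reference position."""
    ref = segment.ref_start
    q = 0
    for op, length in segment.cigar:
        if op in ("M", "=", "X"):
            if ref <= ref_target < ref + length:
                return q + (ref_target - ref)
            ref += length
            q += length
        elif op in ("D", "N"):
            if ref <= ref_target < ref + length:
                return q
            ref += length
        elif op == "I":
            q += length
        # clips don't advance the aligned block
    if ref_target == ref:
        return q
    return None


def read_sequence_over_region(
    segment: AlignmentSegment,
    read_seq_aligned: str,
    start: int,
    end: int,
) -> str | None:
    """Slice of the read (aligned orientation, clips removed) that the
    segment aligns across [start, end); None if not fully covered."""
    if not (segment.ref_start <= start and end <= segment.ref_end):
        return None
    q0 = _query_pos_at_ref(segment, start)
    q1 = _query_pos_at_ref(segment, end - 1)
    if q0 is None or q1 is None:
        return None
    return read_seq_aligned[q0:q1 + 1]


def inv_noise_counts(
    read_segment_seq: str,
    ref_segment_seq: str,
) -> tuple[int, int]:
    """Edit distances of the read slice against the forward reference
    segment (noise1) and its reverse complement (noise2).

    A read that truly carries the inversion is near-random against the
    forward segment but near-identical to the reverse complement.
    """
    noise1 = edlib.align(read_segment_seq, ref_segment_seq, task="distance")["editDistance"]
    noise2 = edlib.align(
        read_segment_seq, reverse_complement(ref_segment_seq), task="distance"
    )["editDistance"]
    return noise1, noise2


def cigar_supports_inv(
    noise1: int, noise2: int, inv_length: int, params: ValidationParams
) -> bool:
    """Noise criteria for a single-segment inversion read:
    noise1 / L >= 0.3 and noise2 / L <= 0.2."""
    if inv_length <= 0:
        raise ValueError("inv_length must be positive")
    return (
        noise1 / inv_length >= params.inv_fwd_noise_min
        and noise2 / inv_length <= params.inv_rev_noise_max
    )


# ---------------------------------------------------------------------------
# Inversion, split channel
# ---------------------------------------------------------------------------

def split_supports_inv(
    read_group: list[AlignmentSegment],
    sv: SVRecord,
    params: ValidationParams,
) -> SupportEvidence:
    """Split-read test for inversions.

    Three segments: require strand pattern (s, -s, s) in query order
    with the middle segment overlapping the inversion; the reference
    distance between the flanking segments must match the inversion
    length within ``distance_support``.  Two opposite-strand segments
    (reads crossing only one breakpoint of a large inversion): the
    distance between homologous segment ends across the breakpoint is
    compared instead.
    """
    read_id = read_group[0].read_id
    segs = sorted((s for s in read_group if s.chrom == sv.chrom), key=lambda s: s.query_start)
    tol = distance_support(sv.length)

    if len(segs) == 3:
        s1, s2, s3 = segs
        if s1.strand == s3.strand and s2.strand != s1.strand:
            if s2.ref_start < sv.end and s2.ref_end > sv.start:
                dist = s3.ref_start - s1.ref_end
                if abs(dist - sv.length) <= tol:
                    return SupportEvidence(read_id, True, dist, "split")
                return SupportEvidence(read_id, False, dist, "split")
        return SupportEvidence(read_id, False, 0, "none")

    if len(segs) == 2 and segs[0].strand != segs[1].strand:
        fwd = segs[0] if segs[0].strand == "+" else segs[1]
        rev = segs[1] if fwd is segs[0] else segs[0]
        mid = (sv.start + sv.end) // 2
        # A pair straddling the left breakpoint ends before the inversion
        # midpoint on the forward segment; right-breakpoint pairs start
        # after it.
        if fwd.ref_end <= mid:  # left breakpoint
            dist = abs(rev.ref_end - fwd.ref_end)
        else:  # right breakpoint
            dist = abs(rev.ref_start - fwd.ref_start)
        if abs(dist - sv.length) <= tol:
            return SupportEvidence(read_id, True, dist, "split")
        return SupportEvidence(read_id, False, dist, "split")

    return SupportEvidence(read_id, False, 0, "none")


# ---------------------------------------------------------------------------
# Dispatcher
# ---------------------------------------------------------------------------

def evidence_for_read(
    read_group: list[AlignmentSegment],
    sv: SVRecord,
    params: ValidationParams,
    reference_segment: str | None = None,
    read_sequences: dict[tuple[int, str], str] | None = None,
) -> SupportEvidence:
    """Decide whether one screened read supports the SV.

    DEL/INS: the CIGAR channel is tried first, then the split channel;
    the first supporting verdict wins.  INV: the noise (CIGAR) channel
    runs when a single segment spans the whole inversion and sequences
    are available, otherwise the split geometry is examined.  When no
    channel supports, the evidence with the largest implied length is
    returned so the corrected-SV step can still use it.

    ``reference_segment`` is the forward reference sequence over
    [sv.start, sv.end) (inversions only).  ``read_sequences`` maps
    (ref_start, strand) of a segment to its stored-orientation read
    sequence with clips removed (inversions only).
    """
    if sv.sv_type in ("DEL", "INS"):
        ev = cigar_supports_indel(read_group, sv, params)
        if ev.supports:
            return ev
        split_ev = split_supports_indel(read_group, sv, params)
        if split_ev.supports:
            return split_ev
        best = max((ev, split_ev), key=lambda e: abs(e.implied_length))
        return best

    # inversion
    spanning = [s for s in read_group if s.ref_start <= sv.start and s.ref_end >= sv.end]
    if spanning and reference_segment is not None and read_sequences is not None:
        seg = _longest_segment(spanning)
        seq = read_sequences.get((seg.ref_start, seg.strand))
        if seq is not None:
            read_slice = read_sequence_over_region(seg, seq, sv.start, sv.end)
            if read_slice:
                noise1, noise2 = inv_noise_counts(read_slice, reference_segment)
                if cigar_supports_inv(noise1, noise2, sv.length, params):
                    return SupportEvidence(seg.read_id, True, sv.length, "cigar")
    ev = split_supports_inv(read_group, sv, params)
    if ev.supports or ev.channel != "none":
        return ev
    return SupportEvidence(read_group[0].read_id, False, 0, "none")
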