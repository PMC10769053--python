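"""Per-read SV evidence: CIGAR and split channels, screening, inversions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import svverify as sv
from svverify.support import reverse_complement

DEFAULTS = sv.ValidationParams()


def seg(ref_start, cigar, *, chrom="chr1", qs=0, strand="+", mapq=60,
        read_id="r1", supplementary=False):
    """AlignmentSegment shorthand; query_end derived from the CIGAR."""
    qlen = sum(n for op, n in cigar if op in "MI=X")
    rlen = sum(n for op, n in cigar if op in "MDN=X")
    return sv.AlignmentSegment(
        read_id=read_id, chrom=chrom, ref_start=ref_start,
        ref_end=ref_start + rlen, query_start=qs, query_end=qs + qlen,
        strand=strand, mapq=mapq, cigar=tuple(cigar),
        is_supplementary=supplementary,
    )


# ---------------------------------------------------------------------------
# distance_support
# ---------------------------------------------------------------------------

class TestDistanceSupport:
    @pytest.mark.parametrize("length,expected", [(100, 40.0), (50, 50.0), (2000, 401.0)])
    def test_spot_values(self, length, expected):
        assert sv.distance_support(length) == pytest.approx(expected)

    def test_minimum_at_length_100(self):
        # 0.2*L + 2000/L has its minimum where both terms equal 20
        lengths = np.arange(50, 5000)
        values = 0.2 * lengths + 2000.0 / lengths
        assert lengths[np.argmin(values)] == 100
        assert sv.distance_support(100) == 40.0

    def test_non_positive_length_rejected(self):
        with pytest.raises(ValueError):
            sv.distance_support(0)


# ---------------------------------------------------------------------------
# net_indel_in_window
# ---------------------------------------------------------------------------

def brute_force_net_indel(segment, window_start, window_end, min_op=30):
    """Independent oracle: expand the CIGAR base by base, collecting
    indel events at their reference anchors, then sum the qualifying ones."""
    events = []
    ref = segment.ref_start
    for op, length in segment.cigar:
        if op in "M=X":
            for _ in range(length):
                ref += 1
        elif op in "DN":
            if op == "D":
                events.append((ref, -length))
            for _ in range(length):
                ref += 1
        elif op == "I":
            events.append((ref - 1, +length))
    return sum(delta for pos, delta in events
               if abs(delta) >= min_op and window_start <= pos < window_end)


class TestNetIndelInWindow:
    def test_single_deletion(self):
        s = seg(1000, [("M", 100), ("D", 500), ("M", 100)])
        assert sv.net_indel_in_window(s, 0, 10_000) == -500

    def test_nearby_insertions_merge(self):
        # two I ops in the window combine into one net SV length
        s = seg(1000, [("M", 50), ("I", 200), ("M", 30), ("I", 300), ("M", 20)])
        assert sv.net_indel_in_window(s, 0, 10_000) == 500

    def test_ops_below_floor_ignored(self):
        s = seg(1000, [("M", 100), ("D", 20), ("M", 100)])
        assert sv.net_indel_in_window(s, 0, 10_000) == 0

    def test_window_membership_by_anchor(self):
        s = seg(1000, [("M", 100), ("D", 500), ("M", 100)])
        assert sv.net_indel_in_window(s, 1100, 1101) == -500  # anchor at 1100
        assert sv.net_indel_in_window(s, 1101, 9999) == 0

    @settings(max_examples=200, deadline=None)
    @given(
        ref_start=st.integers(0, 5000),
        w=st.tuples(st.integers(0, 8000), st.integers(1, 3000)),
        ops=st.lists(
            st.tuples(st.sampled_from("MID"), st.integers(1, 400)),
            min_size=1, max_size=12,
        ),
    )
    def test_matches_brute_force_walk(self, ref_start, w, ops):
        # keep the CIGAR well-formed: must start and end with M
        cigar = [("M", 10)] + list(ops) + [("M", 10)]
        s = seg(ref_start, cigar)
        lo, hi = w[0], w[0] + w[1]
        assert sv.net_indel_in_window(s, lo, hi) == brute_force_net_indel(s, lo, hi)

    def test_malformed_cigar_raises(self):
        s = seg(0, [("M", 10)])
        s = sv.AlignmentSegment(**{**s.__dict__, "cigar": (("Z", 5),)})
        with pytest.raises(ValueError):
            sv.net_indel_in_window(s, 0, 100)


# ---------------------------------------------------------------------------
# cigar channel, DEL/INS
# ---------------------------------------------------------------------------

class TestCigarSupportsIndel:
    DEL500 = sv.SVRecord("d", "chr1", 5000, 5500, "DEL", 500)

    def _read_with_net(self, net):
        if net < 0:
            cigar = [("M", 2000), ("D", -net), ("M", 2000)]
        else:
            cigar = [("M", 2000), ("I", net), ("M", 2000)]
        return [seg(3000, cigar)]

    def test_within_tolerance_supports(self):
        # |480 - 500| = 20 <= distance_support(500) = 104
        ev = sv.cigar_supports_indel(self._read_with_net(-480), self.DEL500, DEFAULTS)
        assert ev.supports and ev.channel == "cigar" and ev.implied_length == -480

    def test_outside_tolerance_rejected(self):
        ev = sv.cigar_supports_indel(self._read_with_net(-380), self.DEL500, DEFAULTS)
        assert not ev.supports  # |380 - 500| = 120 > 104

    def test_sign_mismatch_rejected(self):
        ev = sv.cigar_supports_indel(self._read_with_net(+500), self.DEL500, DEFAULTS)
        assert not ev.supports

    def test_boundary_equality_counts_as_support(self):
        # distance_support(500) = 104 exactly; net -396 sits on the edge
        ev = sv.cigar_supports_indel(self._read_with_net(-396), self.DEL500, DEFAULTS)
        assert ev.supports


# ---------------------------------------------------------------------------
# split channel, DEL/INS
# ---------------------------------------------------------------------------

class TestSplitDifference:
    def test_deletion_like(self):
        a = seg(1000, [("M", 1000)], qs=0)
        b = seg(3500, [("M", 1000)], qs=1500)  # ref gap 1500, read gap 500
        assert sv.split_difference(a, b) == -1000

    def test_insertion_like(self):
        a = seg(1000, [("M", 1000)], qs=0)
        b = seg(2010, [("M", 1000)], qs=1310)  # ref gap 10, read gap 310
        assert sv.split_difference(a, b) == 300

    def test_small_difference_is_no_signal(self):
        a = seg(1000, [("M", 1000)], qs=0)
        b = seg(2100, [("M", 1000)], qs=1150)
        assert sv.split_difference(a, b) == 50

    def test_different_strand_not_applicable(self):
        a = seg(1000, [("M", 1000)], qs=0)
        b = seg(3000, [("M", 1000)], qs=1000, strand="-")
        assert sv.split_difference(a, b) is None


class TestSplitSupportsIndel:
    def _pair(self, ref_gap, read_gap):
        return [
            seg(1000, [("M", 1000)], qs=0),
            seg(2000 + ref_gap, [("M", 1000)], qs=1000 + read_gap),
        ]

    def test_del_supported(self):
        rec = sv.SVRecord("d", "chr1", 2000, 3000, "DEL", 1000)
        ev = sv.split_supports_indel(self._pair(1000, 0), rec, DEFAULTS)
        assert ev.supports and ev.implied_length == -1000 and ev.channel == "split"

    def test_ins_supported_within_tolerance(self):
        # distance_support(290) = 64.9; diff +300 is 10 off
        rec = sv.SVRecord("i", "chr1", 2000, 2001, "INS", 290)
        ev = sv.split_supports_indel(self._pair(0, 300), rec, DEFAULTS)
        assert ev.supports and ev.implied_length == 300

    def test_below_gate_never_supports(self):
        rec = sv.SVRecord("d", "chr1", 2000, 3000, "DEL", 1000)
        ev = sv.split_supports_indel(self._pair(150, 0), rec, DEFAULTS)
        assert not ev.supports

    @settings(max_examples=200, deadline=None)
    @given(diff=st.integers(-200, 200),
           length=st.integers(50, 5000),
           svtype=st.sampled_from(["DEL", "INS"]))
    def test_gate_property(self, diff, length, svtype):
        # |difference| <= 200 can never support, whatever the SV length
        end = 2000 + (length if svtype == "DEL" else 1)
        rec = sv.SVRecord("x", "chr1", 2000, end, svtype, length)
        pair = self._pair(-diff if diff < 0 else 0, diff if diff > 0 else 0)
        assert not sv.split_supports_indel(pair, rec, DEFAULTS).supports


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

class TestScreenReads:
    SV = sv.SVRecord("d", "chr1", 10_000, 10_500, "DEL", 500)

    def test_low_mapq_excluded(self):
        groups = {"r1": [seg(5000, [("M", 12_000)], mapq=19)]}
        assert sv.screen_reads(groups, self.SV, DEFAULTS) == {}

    def test_mapq_20_retained(self):
        groups = {"r1": [seg(5000, [("M", 12_000)], mapq=20)]}
        assert "r1" in sv.screen_reads(groups, self.SV, DEFAULTS)

    def test_read_not_spanning_right_flank_excluded(self):
        # alignment ends 200 bp past SV end; flank demands 1000
        groups = {"r1": [seg(5000, [("M", 5700)])]}
        assert sv.screen_reads(groups, self.SV, DEFAULTS) == {}

    def test_split_read_union_spans_both_flanks(self):
        groups = {"r1": [
            seg(8000, [("M", 2000)], qs=0),
            seg(10_500, [("M", 2000)], qs=2000),
        ]}
        assert "r1" in sv.screen_reads(groups, self.SV, DEFAULTS)

    @settings(max_examples=100, deadline=None)
    @given(mapq_min=st.integers(0, 60), flank=st.integers(100, 3000))
    def test_screening_monotonicity(self, mapq_min, flank):
        rng = np.random.default_rng(0)
        groups = {
            f"r{i}": [seg(int(rng.integers(0, 12_000)),
                          [("M", int(rng.integers(1000, 15_000)))],
                          mapq=int(rng.integers(0, 61)))]
            for i in range(30)
        }
        base = len(sv.screen_reads(groups, self.SV, DEFAULTS))
        stricter = sv.ValidationParams(
            mapq_min=max(DEFAULTS.mapq_min, mapq_min),
            flank_len=max(DEFAULTS.flank_len, flank))
        assert len(sv.screen_reads(groups, self.SV, stricter)) <= base


# ---------------------------------------------------------------------------
# inversions
# ---------------------------------------------------------------------------

class TestInversionNoise:
    def test_exact_inversion_has_zero_reverse_noise(self):
        rng = np.random.default_rng(1)
        ref = "".join(rng.choice(list("ACGT"), size=1000))
        read = reverse_complement(ref)
        noise1, noise2 = sv.inv_noise_counts(read, ref)
        assert noise2 == 0 and noise1 > 300

    def test_forward_read_has_zero_forward_noise(self):
        rng = np.random.default_rng(2)
        ref = "".join(rng.choice(list("ACGT"), size=800))
        noise1, _ = sv.inv_noise_counts(ref, ref)
        assert noise1 == 0

    def test_substitutions_count_as_edit_distance(self):
        rng = np.random.default_rng(3)
        ref = "".join(rng.choice(list("ACGT"), size=1000))
        read = list(reverse_complement(ref))
        for pos in (100, 300, 500, 700, 900):
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        _, noise2 = sv.inv_noise_counts("".join(read), ref)
        assert noise2 == 5

    @pytest.mark.parametrize("noise1,noise2,expected", [
        (350, 100, True),    # 0.35 >= 0.3 and 0.10 <= 0.2
        (200, 100, False),   # forward noise too low
        (400, 250, False),   # reverse noise too high
        (300, 200, True),    # both exactly at the published bounds
    ])
    def test_noise_criteria(self, noise1, noise2, expected):
        assert sv.cigar_supports_inv(noise1, noise2, 1000, DEFAULTS) is expected


class TestSplitSupportsInv:
    INV5K = sv.SVRecord("v", "chr1", 20_000, 25_000, "INV", 5000)

    def _three(self, gap, strands=("+", "-", "+")):
        return [
            seg(18_000, [("M", 2000)], qs=0, strand=strands[0]),
            seg(20_000, [("M", 5000)], qs=2000, strand=strands[1]),
            seg(20_000 + gap, [("M", 2000)], qs=7000, strand=strands[2]),
        ]

    def test_three_segment_geometry_supported(self):
        # ref gap between flanking segments 4990, tolerance 1000.4
        ev = sv.split_supports_inv(self._three(4990), self.INV5K, DEFAULTS)
        assert ev.supports and ev.implied_length == 4990

    def test_same_strand_segments_rejected(self):
        ev = sv.split_supports_inv(
            self._three(5000, strands=("+", "+", "+")), self.INV5K, DEFAULTS)
        assert not ev.supports

    def test_large_inv_left_breakpoint_pair(self):
        inv = sv.SVRecord("v", "chr1", 100_000, 150_000, "INV", 50_000)
        # forward flank ends at the left breakpoint; reverse segment walks
        # back from the right breakpoint: distance 50020, tolerance 10000.04
        pair = [
            seg(95_000, [("M", 5000)], qs=0, strand="+"),
            seg(135_020, [("M", 15_000)], qs=5000, strand="-"),
        ]
        ev = sv.split_supports_inv(pair, inv, DEFAULTS)
        assert ev.supports and ev.implied_length == 50_020

    def test_large_inv_right_breakpoint_pair(self):
        inv = sv.SVRecord("v", "chr1", 100_000, 150_000, "INV", 50_000)
        pair = [
            seg(100_000, [("M", 15_000)], qs=0, strand="-"),
            seg(150_000, [("M", 5000)], qs=15_000, strand="+"),
        ]
        ev = sv.split_supports_inv(pair, inv, DEFAULTS)
        assert ev.supports and ev.implied_length == 50_000

    def test_distance_outside_tolerance_rejected(self):
        ev = sv.split_supports_inv(self._three(7000), self.INV5K, DEFAULTS)
        assert not ev.supports


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

class TestEvidenceForRead:
    def test_single_segment_read_uses_cigar_channel(self):
        rec = sv.SVRecord("d", "chr1", 5000, 5100, "DEL", 100)
        read = [seg(3000, [("M", 2050), ("D", 100), ("M", 2050)])]
        ev = sv.evidence_for_read(read, rec, DEFAULTS)
        assert ev.supports and ev.channel == "cigar"

    def test_two_segment_read_uses_split_channel(self):
        rec = sv.SVRecord("d", "chr1", 5000, 10_000, "DEL", 5000)
        read = [
            seg(3000, [("M", 2000)], qs=0),
            seg(10_000, [("M", 2000)], qs=2000),
        ]
        ev = sv.evidence_for_read(read, rec, DEFAULTS)
        assert ev.supports and ev.channel == "split"

    def test_no_signal_returns_none_channel(self):
        rec = sv.SVRecord("d", "chr1", 5000, 5500, "DEL", 500)
        ev = sv.evidence_for_read([seg(3000, [("M", 5000)])], rec, DEFAULTS)
        assert not ev.supports and ev.channel == "none" and ev.implied_length == 0

    def test_strand_invariance(self, tmp_path):
        # the same simulated reads, re-rendered, keep their verdicts
        # regardless of which strand each alignment is stored on; checked
        # here on a hand pair: forward vs reverse representation
        rec = sv.SVRecord("d", "chr1", 5000, 5500, "DEL", 500)
        fwd = [seg(3000, [("M", 2000), ("D", 500), ("M", 2000)], strand="+")]
        rev = [seg(3000, [("M", 2000), ("D", 500), ("M", 2000)], strand="-")]
        assert (sv.evidence_for_read(fwd, rec, DEFAULTS).supports
                == sv.evidence_for_read(rev, rec, DEFAULTS).supports is True)
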