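"""Synthetic fixtures: reference, implanted SVs, and ground-truth alignments.

The generator emulates the validation setting end to end without any
external dataset: a random reference with tandem-repeat blocks, a diploid
donor carrying homozygous and heterozygous DEL/INS/INV, and noisy long
reads emitted directly as ground-truth SAM records computed from each
read's known haplotype origin (no aligner involved, so tests are
hermetic and fully deterministic per seed).

Alignment rendering models what a long-read aligner produces:

* indels shorter than ``split_sv_threshold`` appear as I/D CIGAR
  operations inside one alignment;
* longer indels split the read into a primary plus supplementary
  segment pair on the same strand;
* inversions shorter than ``inv_split_threshold`` are forced through as
  a mismatch-dense match block (what an aligner does when the inverted
  segment is too short to seed its own alignment), longer ones become a
  three-segment split with an opposite-strand middle segment;
* sequencing errors are a per-base mixture of mismatches and 1-3 bp
  indels, kept below the 30 bp evidence floor so they perturb but never
  mimic an SV.

A "Fig-2 style" fragmentation mode optionally splits each deletion's D
operation into two nearby D operations (with a short anchored match
between them) to exercise the evidence-merging logic downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .core_io import SVRecord, write_sv_bed

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FALSE_SV_MULTIPLIERS = (0.1, 0.2, 0.3, 0.4, 2, 3, 4, 5)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=n)]).decode()


@dataclass
class SimConfig:
    """Study conditions for the synthetic fixture.

    Defaults model a desk-scale version of a long-read validation run:
    a 200 kb genome with 30% tandem-repeat content, 20 homozygous plus
    20 heterozygous SVs spread over DEL/INS/INV, and 30x noise-free
    20 kb reads.  ``error_rate`` covers the published long-read regime
    (roughly 5-20% per base) when enabled.
    """

    genome_length: int = 200_000
    repeat_fraction: float = 0.3
    repeat_unit_len: int = 25
    # (sv_type, zygosity) -> count; 20 HOM + 20 HET by default
    sv_counts: dict[tuple[str, str], int] = field(default_factory=lambda: {
        ("DEL", "HOM"): 7, ("INS", "HOM"): 7, ("INV", "HOM"): 6,
        ("DEL", "HET"): 7, ("INS", "HET"): 7, ("INV", "HET"): 6,
    })
    sv_length_range: tuple[int, int] = (200, 1100)
    read_length_mean: int = 20_000
    depth: float = 30.0
    error_rate: float = 0.0
    fragment_indels: bool = False
    split_sv_threshold: int = 700
    inv_split_threshold: int = 800
    min_segment_len: int = 100
    edge_margin: int = 12_000
    min_sv_gap: int = 1500
    chrom: str = "chr1"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.error_rate <= 0.25:
            raise ValueError("error_rate must be in [0, 0.25]")
        if self.sv_length_range[0] < 50:
            raise ValueError("SV lengths must be >= 50")


@dataclass(frozen=True)
class TruthRecord:
    sv: SVRecord
    zygosity: str  # "HOM" | "HET"
    provenance: str = "implanted"  # or "false_multiplier"
    multiplier: float | None = None

    def __post_init__(self) -> None:
        if self.provenance == "false_multiplier" and self.multiplier is None:
            raise ValueError("false records must carry their multiplier")


@dataclass(frozen=True)
class Block:
    """One colinear piece of a donor haplotype.

    kind "M": forward copy of reference [ref_start, ref_end);
    kind "I": inserted sequence anchored at ref_start (== ref_end);
    kind "V": reverse complement of reference [ref_start, ref_end).
    Deletions are implicit gaps between consecutive blocks.
    """

    kind: str
    ref_start: int
    ref_end: int
    seq: str
    hap_start: int
    hap_end: int


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

def generate_reference(config: SimConfig) -> tuple[str, list[tuple[int, int]]]:
    """Random reference with tandem-repeat blocks.

    Returns the sequence and the repeat intervals (0-based half-open);
    repeat intervals total round(repeat_fraction * genome_length) bp.
    """
    if config.genome_length < 10_000:
        raise ValueError("genome_length must be >= 10 kb")
    rng = np.random.default_rng(config.rng_seed)
    g = config.genome_length
    target = int(round(config.repeat_fraction * g))
    block_lens: list[int] = []
    remaining = target
    while remaining > 0:
        bl = int(min(remaining, rng.integers(500, 1501)))
        block_lens.append(bl)
        remaining -= bl
    n_gaps = len(block_lens) + 1
    background = g - target
    # split the background into n_gaps parts via sorted uniform cuts
    if n_gaps > 1:
        cuts = np.sort(rng.integers(0, background + 1, size=n_gaps - 1))
        gap_lens = np.diff(np.concatenate(([0], cuts, [background])))
    else:
        gap_lens = np.array([background])
    parts: list[str] = []
    repeats: list[tuple[int, int]] = []
    pos = 0
    for i, gap in enumerate(gap_lens):
        parts.append(_random_seq(rng, int(gap)))
        pos += int(gap)
        if i < len(block_lens):
            bl = block_lens[i]
            unit = _random_seq(rng, config.repeat_unit_len)
            tiled = (unit * (bl // len(unit) + 1))[:bl]
            parts.append(tiled)
            repeats.append((pos, pos + bl))
            pos += bl
    return "".join(parts), repeats


def write_fasta(seq: str, path: str | Path, name: str = "chr1") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i:i + 80] + "\n")


# ---------------------------------------------------------------------------
# SV implantation
# ---------------------------------------------------------------------------

def _draw_sv_plan(config: SimConfig, rng: np.random.Generator) -> list[tuple[str, str, int]]:
    plan = [
        (sv_type, zyg)
        for (sv_type, zyg), n in sorted(config.sv_counts.items())
        for _ in range(n)
    ]
    rng.shuffle(plan)
    lo, hi = config.sv_length_range
    return [(t, z, int(rng.integers(lo, hi + 1))) for t, z in plan]


def implant_svs(
    reference: str, config: SimConfig
) -> tuple[list[list[Block]], list[TruthRecord]]:
    """Place non-overlapping SVs and build the two donor haplotypes.

    HOM SVs are applied to both haplotypes, HET to one (chosen at
    random).  Consecutive SVs are separated by at least
    ``2 * max(length_i, length_{i+1}) + min_sv_gap`` so that even a
    length-corrupted (up to 5x) candidate record's flanked evidence
    window contains only its own locus.  Raises if the genome cannot
    hold the requested SVs with those gaps.
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    plan = _draw_sv_plan(config, rng)
    g = len(reference)
    spans = [length if t != "INS" else 1 for t, _, length in plan]
    lengths = [length for _, _, length in plan]
    n = len(plan)
    gaps = [
        2 * max(lengths[i], lengths[i + 1]) + config.min_sv_gap
        for i in range(n - 1)
    ]
    base = sum(spans) + 2 * config.edge_margin + sum(gaps)
    if base > g:
        raise ValueError(
            f"cannot pack {n} SVs into {g} bp; use fewer/shorter SVs or a longer genome"
        )
    slack = g - base
    extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    truth: list[TruthRecord] = []
    pos = config.edge_margin + int(extra[0])
    events: list[tuple[int, int, str, int, str]] = []  # start, end, type, length, zyg
    for i, ((sv_type, zyg, length), span) in enumerate(zip(plan, spans)):
        start = pos
        end = start + (length if sv_type != "INS" else 1)
        sv = SVRecord(f"truth_{i:03d}_{sv_type}", config.chrom, start, end, sv_type, length)
        truth.append(TruthRecord(sv, zyg))
        events.append((start, end, sv_type, length, zyg))
        if i < n - 1:
            pos = start + span + gaps[i] + int(extra[i + 1])

    het_hap = {i: int(rng.integers(0, 2)) for i, t in enumerate(truth) if t.zygosity == "HET"}
    ins_seqs = {
        i: _random_seq(rng, t.sv.length) for i, t in enumerate(truth) if t.sv.sv_type == "INS"
    }

    haplotypes: list[list[Block]] = []
    for hap_idx in range(2):
        blocks: list[Block] = []
        hap_pos = 0
        ref_pos = 0

        def add(kind: str, rs: int, re_: int, seq: str) -> None:
            nonlocal hap_pos
            if kind == "M" and not seq:
                return
            blocks.append(Block(kind, rs, re_, seq, hap_pos, hap_pos + len(seq)))
            hap_pos += len(seq)

        for i, (start, end, sv_type, length, zyg) in enumerate(events):
            if zyg == "HET" and het_hap[i] != hap_idx:
                continue  # this haplotype keeps the reference allele here
            add("M", ref_pos, start, reference[ref_pos:start])
            if sv_type == "DEL":
                ref_pos = end
            elif sv_type == "INS":
                add("I", start, start, ins_seqs[i])
                ref_pos = start
            else:  # INV
                add("V", start, end, _revcomp(reference[start:end]))
                ref_pos = end
        add("M", ref_pos, g, reference[ref_pos:g])
        haplotypes.append(blocks)
    return haplotypes, truth


# ---------------------------------------------------------------------------
# Read simulation -> ground-truth SAM
# ---------------------------------------------------------------------------

def _add_op(ops: list[list], op: str, n: int) -> None:
    if n <= 0:
        return
    if ops and ops[-1][0] == op:
        ops[-1][1] += n
    else:
        ops.append([op, n])


def _noisy_match(
    chunk: str, rng: np.random.Generator, error_rate: float
) -> tuple[list[list], str]:
    """Apply per-base sequencing errors to one match stretch.

    Returns CIGAR ops (M/I/D) and the mutated read bases.  Mismatches
    keep the op structure; insertion errors add 1-3 read bases (I op);
    deletion errors drop 1-3 read bases (D op).  Events are kept in the
    interior of the stretch so segments never start or end on an indel.
    """
    m = len(chunk)
    if error_rate <= 0 or m < 4:
        return [["M", m]], chunk
    k = int(rng.binomial(m, error_rate))
    if k == 0:
        return [["M", m]], chunk
    positions = np.sort(rng.choice(np.arange(1, m - 1), size=min(k, m - 2), replace=False))
    kinds = rng.choice(3, size=len(positions), p=[0.6, 0.2, 0.2])  # mis, ins, del
    ops: list[list] = []
    out: list[str] = []
    cur = 0
    for p, kind in zip(positions, kinds):
        p = int(p)
        if p < cur:
            continue
        _add_op(ops, "M", p - cur)
        out.append(chunk[cur:p])
        cur = p
        if kind == 0:  # mismatch
            orig = chunk[p]
            alt = "ACGT"[(("ACGT".find(orig) if orig in "ACGT" else 0) + 1 + int(rng.integers(0, 3))) % 4]
            out.append(alt)
            _add_op(ops, "M", 1)
            cur = p + 1
        elif kind == 1:  # insertion error
            ins_len = int(rng.integers(1, 4))
            out.append(chunk[p])
            _add_op(ops, "M", 1)
            out.append(_random_seq(rng, ins_len))
            _add_op(ops, "I", ins_len)
            cur = p + 1
        else:  # deletion error
            d = int(min(rng.integers(1, 4), m - 1 - p))
            if d <= 0:
                continue
            _add_op(ops, "D", d)
            cur = p + d
    _add_op(ops, "M", m - cur)
    out.append(chunk[cur:])
    return ops, "".join(out)


@dataclass
class _Segment:
    ref_start: int
    strand: str
    ops: list[list]
    query_start: int
    query_end: int

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.ops if op in "MD")


def _fragment_last_deletion(ops: list[list], gap: int, anchor: int = 10) -> bool:
    """Rewrite ... M(a) D(gap) as ... M(a-anchor) D(g1) M(anchor) D(g2):
    the deletion shows up as two CIGAR fragments whose lengths sum to the
    true deletion, with a short flank-borrowed match between them."""
    if gap < 60 or not ops or ops[-1][0] != "M" or ops[-1][1] <= anchor + 1:
        return False
    g1, g2 = gap // 2, gap - gap // 2
    ops[-1][1] -= anchor
    ops.append(["D", g1])
    ops.append(["M", anchor])
    ops.append(["D", g2])
    return True


def _render_read(
    blocks: list[list[Block]],
    a: int,
    b: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[str, list[_Segment]]:
    """Project haplotype interval [a, b) into a read sequence plus its
    ground-truth alignment segments (query coordinates on the read)."""
    segments: list[_Segment] = []
    cur: _Segment | None = None
    seq_parts: list[str] = []
    q = 0

    def close() -> None:
        nonlocal cur
        if cur is not None:
            cur.query_end = q
            # trim trailing deletion ops (cannot end a segment on D)
            while cur.ops and cur.ops[-1][0] == "D":
                cur.ops.pop()
            if sum(n for op, n in cur.ops if op == "M") >= config.min_segment_len:
                segments.append(cur)
            cur = None

    def open_segment(ref_s: int, strand: str) -> _Segment:
        nonlocal cur
        cur = _Segment(ref_s, strand, [], q, q)
        return cur

    def add_match_piece(ref_s: int, ref_e: int, chunk: str, sv_gap_before: bool) -> None:
        """Forward match piece with gap/continuation logic."""
        nonlocal cur, q
        if cur is not None and cur.strand == "+":
            gap = ref_s - cur.ref_end
            if gap < 0 or gap >= config.split_sv_threshold:
                close()
            elif gap > 0:
                if not (config.fragment_indels and _fragment_last_deletion(cur.ops, gap)):
                    _add_op(cur.ops, "D", gap)
        elif cur is not None:
            close()
        if cur is None:
            open_segment(ref_s, "+")
        ops, mutated = _noisy_match(chunk, rng, config.error_rate)
        for op, n in ops:
            _add_op(cur.ops, op, n)
        seq_parts.append(mutated)
        q += len(mutated)

    for block in blocks:
        if block.hap_end <= a or block.hap_start >= b:
            continue
        u = max(a, block.hap_start) - block.hap_start
        v = min(b, block.hap_end) - block.hap_start
        chunk = block.seq[u:v]
        if block.kind == "M":
            add_match_piece(block.ref_start + u, block.ref_start + v, chunk, False)
        elif block.kind == "I":
            total = len(block.seq)
            if total < config.split_sv_threshold and u == 0 and v == total and cur is not None:
                _add_op(cur.ops, "I", total)
                seq_parts.append(chunk)
                q += total
            else:
                # large or truncated insertion: bases stay unaligned (clipped)
                close()
                seq_parts.append(chunk)
                q += len(chunk)
        else:  # inversion block
            inv_len = block.ref_end - block.ref_start
            if inv_len < config.inv_split_threshold:
                # forced-through alignment: colinear M with mismatching bases
                add_match_piece(block.ref_start + u, block.ref_start + v, chunk, False)
            else:
                close()
                seg = open_segment(block.ref_end - v, "-")
                ops, mutated = _noisy_match(chunk, rng, config.error_rate)
                seg.ops = [list(o) for o in ops]
                seq_parts.append(mutated)
                q += len(mutated)
                close()
    close()
    return "".join(seq_parts), segments


def _cigar_str(ops: list[list]) -> str:
    return "".join(f"{n}{op}" for op, n in ops)


def simulate_alignments(
    haplotypes: list[list[Block]],
    config: SimConfig,
    reference_len: int | None = None,
) -> str:
    """Draw reads from the donor haplotypes and emit ground-truth SAM.

    Each read's primary record carries the full (soft-clipped) sequence;
    supplementary records are hard-clipped, and all records of a read
    cross-reference each other through SA tags.  Output is valid,
    coordinate-sortable SAM.
    """
    if reference_len is None:
        reference_len = max(b.ref_end for hap in haplotypes for b in hap)
    rng = np.random.default_rng(config.rng_seed + 2)
    rows: list[tuple[int, str]] = []
    mean = config.read_length_mean
    for hap_idx, blocks in enumerate(haplotypes):
        hap_len = blocks[-1].hap_end
        # read starts may fall before the contig (the read is truncated),
        # which keeps expected coverage uniform across the whole genome
        n_reads = int(round(config.depth / 2 * (hap_len + mean - 1) / mean))
        for ri in range(n_reads):
            rl = int(np.clip(rng.normal(mean, 0.1 * mean), 0.5 * mean, 1.5 * mean))
            start0 = int(rng.integers(-(mean - 1), hap_len))
            a, b = max(0, start0), min(hap_len, start0 + rl)
            if b - a < 2 * config.min_segment_len:
                continue
            seq, segments = _render_read(blocks, a, b, config, rng)
            if not segments:
                continue
            name = f"sim_h{hap_idx}_{ri:06d}"
            rows.extend(_sam_records(name, seq, segments, config.chrom))
    rows.sort(key=lambda r: r[0])
    header = (
        "@HD\tVN:1.6\tSO:coordinate\n"
        f"@SQ\tSN:{config.chrom}\tLN:{reference_len}\n"
        "@PG\tID:svverify-sim\tPN:svverify-sim\n"
    )
    return header + "".join(text for _, text in rows)


def _sam_records(
    name: str, seq: str, segments: list[_Segment], chrom: str
) -> list[tuple[int, str]]:
    L = len(seq)
    primary = max(range(len(segments)), key=lambda i: segments[i].query_end - segments[i].query_start)

    def stored(seg: _Segment, clip_op: str) -> tuple[str, str]:
        """(cigar, seq) in stored orientation for one segment."""
        qs, qe = seg.query_start, seg.query_end
        if seg.strand == "+":
            lead, trail = qs, L - qe
            ops = seg.ops
            body = seq[qs:qe]
        else:
            lead, trail = L - qe, qs
            ops = list(reversed(seg.ops))
            body = _revcomp(seq[qs:qe])
        cig = (f"{lead}{clip_op}" if lead else "") + _cigar_str(ops) + (f"{trail}{clip_op}" if trail else "")
        if clip_op == "S":
            out_seq = _revcomp(seq) if seg.strand == "-" else seq
        else:
            out_seq = body
        return cig, out_seq

    sa_parts = []
    for seg in segments:
        cig, _ = stored(seg, "S")
        sa_parts.append(f"{chrom},{seg.ref_start + 1},{seg.strand},{cig},60,0")

    out: list[tuple[int, str]] = []
    for i, seg in enumerate(segments):
        is_primary = i == primary
        flag = (0 if is_primary else 2048) | (16 if seg.strand == "-" else 0)
        cig, sseq = stored(seg, "S" if is_primary else "H")
        fields = [
            name, str(flag), chrom, str(seg.ref_start + 1), "60", cig,
            "*", "0", "0", sseq, "*",
        ]
        if len(segments) > 1:
            others = ";".join(sa_parts[j] for j in range(len(segments)) if j != i)
            fields.append(f"SA:Z:{others};")
        out.append((seg.ref_start, "\t".join(fields) + "\n"))
    return out


# ---------------------------------------------------------------------------
# False-SV list
# ---------------------------------------------------------------------------

def make_false_svs(
    truth: list[TruthRecord],
    rng_seed: int,
    multipliers: tuple[float, ...] = FALSE_SV_MULTIPLIERS,
) -> list[TruthRecord]:
    """Length-corrupted copies of true SVs, one per DEL/INS truth record.

    Each record keeps its locus midpoint but has its length multiplied
    by a factor drawn uniformly from ``multipliers``; every multiplier
    in the published set yields a relative length error of at least 50%
    (the minimum, 60%, occurs at m = 0.4).  Inversions are skipped: the
    published false-list experiment covers deletions and insertions.
    """
    if not truth:
        raise ValueError("truth list is empty")
    rng = np.random.default_rng(rng_seed)
    out: list[TruthRecord] = []
    for t in truth:
        if t.sv.sv_type not in ("DEL", "INS"):
            continue
        m = float(multipliers[int(rng.integers(0, len(multipliers)))])
        new_len = max(1, int(round(t.sv.length * m)))
        if t.sv.sv_type == "INS":
            start, end = t.sv.start, t.sv.end
        else:
            mid = (t.sv.start + t.sv.end) // 2
            start = max(1, mid - new_len // 2)
            end = start + new_len
        sv = SVRecord(f"false_{t.sv.id}", t.sv.chrom, start, end, t.sv.sv_type, new_len)
        out.append(TruthRecord(sv, t.zygosity, "false_multiplier", m))
    return out


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

def sam_to_sorted_bam(sam_path: str | Path, bam_path: str | Path) -> None:
    pysam.sort("-o", str(bam_path), str(sam_path))
    pysam.index(str(bam_path))


def write_truth_tsv(truth: list[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\ttype\tlength\tid\tzygosity\tprovenance\tmultiplier\n")
        for t in truth:
            mult = "" if t.multiplier is None else t.multiplier
            fh.write(
                f"{t.sv.chrom}\t{t.sv.start}\t{t.sv.end}\t{t.sv.sv_type}\t{t.sv.length}"
                f"\t{t.sv.id}\t{t.zygosity}\t{t.provenance}\t{mult}\n"
            )


def simulate_bundle(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the full fixture set: FASTA, sorted+indexed BAM (plus the
    SAM it came from), truth BED/TSV, repeat BED, and the false-SV BED."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference, repeats = generate_reference(config)
    haplotypes, truth = implant_svs(reference, config)
    sam_text = simulate_alignments(haplotypes, config, reference_len=len(reference))
    false_list = make_false_svs(truth, config.rng_seed + 3)

    paths = {
        "fasta": out / "reference.fa",
        "sam": out / "reads.sam",
        "bam": out / "reads.bam",
        "truth_bed": out / "truth.bed",
        "truth_tsv": out / "truth.tsv",
        "repeat_bed": out / "repeats.bed",
        "false_bed": out / "false_svs.bed",
    }
    write_fasta(reference, paths["fasta"], config.chrom)
    try:
        import pyfaidx

        pyfaidx.Faidx(str(paths["fasta"]))
    except Exception:
        pass
    paths["sam"].write_text(sam_text)
    sam_to_sorted_bam(paths["sam"], paths["bam"])
    write_sv_bed([t.sv for t in truth], paths["truth_bed"])
    write_truth_tsv(truth, paths["truth_tsv"])
    with open(paths["repeat_bed"], "w") as fh:
        for s, e in repeats:
            fh.write(f"{config.chrom}\t{s}\t{e}\trepeat\n")
    write_sv_bed([t.sv for t in false_list], paths["false_bed"])
    write_truth_tsv(false_list, out / "false_svs.tsv")
    return paths
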