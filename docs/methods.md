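# Methods

## The validation model

`svverify` treats SV validation as a per-read classification followed by a
support-fraction genotype call. The underlying assumptions are:

* A read that genuinely traverses an SV locus must span the whole flanked
  region `(start − flank_len, end + flank_len)`; reads that stop inside it
  (frequent in tandem repeats, where partial alignments are misplaced) are
  uninformative and are excluded from both numerator and denominator.
* A true SV of length `L` leaves one of two alignment footprints: a set of
  nearby insertion/deletion CIGAR operations whose *net* signed length is
  ≈ `±L`, or a split alignment whose reference/read gap difference is
  ≈ `±L`. Inversions leave either a mismatch-dense forced alignment whose
  bases match the reverse complement of the reference segment, or an
  opposite-strand split geometry.
* Alignment noise perturbs the implied length roughly proportionally for
  large SVs and by a roughly constant amount for small ones, which is what
  the acceptance tolerance `distance_support(L) = 0.2·L + 2000/L`
  encodes (minimum 40 bp at `L = 100`).

Merging CIGAR operations into a net is what makes the method robust in
repeat regions, where one SV is frequently shattered into several nearby
operations; the sign convention (insertions positive, deletions negative,
and the sign must match the candidate's type) prevents an insertion cluster
from validating a deletion.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `flank_len` | 1000 bp | span required on each side of the SV |
| `mapq_min` | 20 | minimum best-segment mapping quality |
| `min_cigar_indel` | 30 bp | smallest CIGAR op counted as SV evidence |
| `coverage_multiplier` | 5 | high-coverage filter threshold (× average) |
| `n_coverage_samples` | 1000 | positions sampled for the coverage estimate |
| `split_diff_threshold` | 200 bp | split-read gap difference gate |
| `hom_threshold` / `false_threshold` | 0.8 / 0.1 | support-rate genotype boundaries |
| `alt_support_fraction` | 0.1 | corrected-SV minimum read fraction |
| `inv_fwd_noise_min` / `inv_rev_noise_max` | 0.3 / 0.2 | inversion noise criteria |
| `min_alt_sv_len` | 50 bp | smallest corrected SV reported |

All are overridable; the defaults are the published operating point of the
method. Support-rate boundaries use closed lower bounds (rate 0.8 is
homozygous, rate 0.1 heterozygous).

## Design choices where the procedure was open

* **Coordinates.** Everything internal is 0-based half-open; BED input is
  taken as 0-based half-open, SAM positions are converted at the pysam
  boundary. Query coordinates of all segments of a read are normalized to
  the forward orientation of the read (reconstructed from soft/hard clips),
  so split-read arithmetic lives on one axis.
* **Coverage statistic.** "Coverage of a region" for the 5× filter is the
  mean per-base depth over the SV span (a ±500 bp breakpoint window for
  insertions), robust to single-base spikes; the comparison is strictly
  greater. Coverage positions are sampled uniformly over the concatenated
  genome, contigs weighted by length; all primary and supplementary reads
  count, with no MAPQ filter at this stage.
* **Inversion noise metric.** `noise1`/`noise2` are edit distances
  (unit-cost mismatch/indel, computed with edlib) between the read segment
  projected onto `[start, end)` and the forward / reverse-complement
  reference segment. The comparison sequence is the reverse *complement*:
  a genomic inversion is the reverse complement, and a plain reversal would
  never match real inversion-carrying reads.
* **Channel precedence.** The CIGAR channel is tried before the split
  channel; the first supporting verdict wins. Non-supporting reads keep the
  largest-magnitude implied length they showed, which is what the
  corrected-SV step averages.
* **Three-segment inversions.** The compared distance is
  `ref_start(third segment) − ref_end(first segment)` with the middle
  segment required to be opposite-strand and to overlap the inversion.
  Two-segment (single-breakpoint) crossings compare homologous segment
  ends across the breakpoint. The two-segment geometry cannot pass the
  flank-spanning screen for inversions longer than any read — such loci
  come out `NO_READS` — so it matters for mid-size inversions that an
  aligner renders as a single breakpoint crossing; it is exercised directly
  in unit tests.
* **Zero candidate reads** is reported as `NO_READS`, not `FALSE`: absence
  of spanning reads carries no evidence either way.
* **Corrected SV.** The alternative cluster must agree in sign; its count
  is taken over the same screened-read denominator as `support_rate`, and
  the corrected type (DEL/INS) is reported alongside the mean length.

## The synthetic-data generator

The simulator emulates the study conditions the method targets: a 200 kb
single-contig reference with 30% tandem-repeat content (500–1500 bp blocks
of a 25 bp unit), a diploid donor with 20 homozygous and 20 heterozygous
SVs (7 DEL / 7 INS / 6 INV per zygosity, lengths uniform in 200–1100 bp),
and 20 kb ± 10% reads at 30× total depth. Reads are emitted directly as
ground-truth SAM computed from each read's haplotype origin rather than
through an aligner, which makes every test hermetic and bit-reproducible
per seed.

Its aligner model: DEL/INS shorter than 700 bp appear as CIGAR I/D ops,
longer ones as same-strand primary+supplementary pairs; inversions shorter
than 800 bp are forced through as mismatch-dense matches, longer ones as
`+/−/+` three-segment splits. Sequencing errors are a per-base mixture
(60% mismatch, 20% 1–3 bp insertion, 20% 1–3 bp deletion) spanning the
published long-read error regime when enabled; error indels stay below the
30 bp evidence floor by construction. A fragmentation mode renders each
deletion as two D operations (summing to the true length) separated by a
short borrowed-anchor match, to exercise the evidence-merging logic.

Packing places consecutive SVs at least `2·max(L_i, L_{i+1}) + 1500` bp
apart so that even a 5×-length-corrupted candidate's flanked window
contains only its own locus, and true SV lengths start at 200 bp — below
~150 bp the published tolerance `0.2L + 2000/L` is wide enough that a
0.1×-corrupted copy of the SV would still be accepted, which is a real
property of the formula, not of the implementation. The false-SV list
multiplies each true DEL/INS length by a factor drawn from
{0.1, 0.2, 0.3, 0.4, 2, 3, 4, 5} (minimum relative error 60%, at 0.4),
keeping the locus midpoint fixed; inversions are excluded from the false
list, matching the scope of the experiment it models.

What the simulator does **not** model: platform-specific error spectra and
homopolymer artifacts, mapping ambiguity (every record carries MAPQ 60;
MAPQ screening is tested with hand-built fixtures), chimeric/supplementary
mapping errors, duplications/translocations, and nested or adjacent complex
SVs. Passing tests therefore demonstrate the correctness of the decision
logic under controlled alignment footprints, not end-to-end accuracy on
real sequencing data.

## Numerical and degenerate-input choices

* Tolerance comparisons are inclusive (`≤`), as printed in the decision
  rules.
* `distance_support` is undefined for non-positive lengths and raises.
* An empty BAM yields average coverage 0 with a warning; the 5× filter then
  removes nothing and loci come out `NO_READS`.
* Duplicate placements of the same read at the same position are dropped;
  secondary alignments are excluded, supplementaries retained.
* Corrected lengths are rounded to the nearest integer; mean of identical
  implied lengths is exact on noise-free data.
* Per-SV internal failures degrade to `NO_READS` with a warning instead of
  aborting a batch.

## Problem sizes and expected behaviour

The default test and acceptance runs use the 200 kb / 40-SV / 30× genome
(seconds per run). On noise-free data the pipeline recovers 100% of
zygosities, rejects 100% of the false list, and returns corrected lengths
exactly. At 5× depth with 10% per-base error, zygosity accuracy averages
≈ 88% over seeds (typically 80–95%): heterozygous loci are then covered by
only ~3–4 spanning reads, and binomial sampling of the two haplotypes
occasionally pushes the support rate across the 0.1/0.8 boundaries — the
expected trade of recall for precision at low coverage. The genome-wide
coverage estimator is exact on uniform fixtures and within ~5% of the
configured depth on simulated runs (reads truncated at contig ends keep
expected coverage uniform).
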