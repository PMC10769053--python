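"""Shared fixtures: tiny hand-written SAM files and full synthetic runs."""

from __future__ import annotations

from pathlib import Path

import pysam
import pytest
from pyfaidx import Fasta

import svverify as sv


def make_sam(records: list[dict], contigs: dict[str, int] | None = None) -> str:
    """Render hand-specified alignment records as sorted SAM text.

    Each record dict: name, chrom, pos (0-based), cigar, and optionally
    flag (default 0), mapq (default 60), seq (default '*'), tags (list
    of raw tag strings).
    """
    contigs = contigs or {"chr1": 100_000}
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for name, length in contigs.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    rows = []
    for r in records:
        fields = [
            r["name"], str(r.get("flag", 0)), r["chrom"], str(r["pos"] + 1),
            str(r.get("mapq", 60)), r["cigar"], "*", "0", "0",
            r.get("seq", "*"), "*",
        ]
        fields.extend(r.get("tags", []))
        rows.append((r["chrom"], r["pos"], "\t".join(fields)))
    rows.sort(key=lambda x: (x[0], x[1]))
    lines.extend(text for _, _, text in rows)
    return "\n".join(lines) + "\n"


def sam_to_bam(sam_text: str, directory: Path, stem: str = "reads") -> Path:
    sam_path = directory / f"{stem}.sam"
    bam_path = directory / f"{stem}.bam"
    sam_path.write_text(sam_text)
    pysam.sort("-o", str(bam_path), str(sam_path))
    pysam.index(str(bam_path))
    return bam_path


def uniform_coverage_bam(directory: Path, depth: int = 30, length: int = 2000) -> Path:
    """Every position of the contig covered by exactly ``depth`` reads."""
    records = [
        {"name": f"u{i}", "chrom": "chr1", "pos": 0, "cigar": f"{length}M"}
        for i in range(depth)
    ]
    return sam_to_bam(make_sam(records, {"chr1": length}), directory, "uniform")


class SimRun:
    """A simulated bundle plus its validation results."""

    def __init__(self, tmpdir: Path, config: sv.SimConfig):
        self.config = config
        self.paths = sv.simulate_bundle(config, tmpdir)
        self.truth = sv.read_sv_bed(self.paths["truth_bed"])
        self.false_svs = sv.read_sv_bed(self.paths["false_bed"])
        self.zygosity = {}
        for line in Path(self.paths["truth_tsv"]).read_text().splitlines()[1:]:
            f = line.split("\t")
            self.zygosity[f[5]] = f[6]
        self.params = sv.ValidationParams(rng_seed=config.rng_seed)
        with sv.open_bam(self.paths["bam"]) as bam:
            ref = Fasta(str(self.paths["fasta"]))
            self.results, self.coverage_model = sv.validate_all(
                self.truth, bam, ref, self.params
            )
            self.false_results, _ = sv.validate_all(
                self.false_svs, bam, ref, self.params,
                coverage_model=self.coverage_model,
            )

    def expected_label(self, sv_id: str) -> str:
        return "HOMOZYGOUS" if self.zygosity[sv_id] == "HOM" else "HETEROZYGOUS"

    def zygosity_accuracy(self) -> float:
        ok = sum(1 for r in self.results if str(r.label) == self.expected_label(r.sv.id))
        return ok / len(self.results)

    def true_length_of_false(self, false_id: str) -> int:
        by_id = {t.id: t for t in self.truth}
        return by_id[false_id.removeprefix("false_")].length


@pytest.fixture(scope="session")
def noise_free_run(tmp_path_factory) -> SimRun:
    """200 kb genome, 30% repeats, 20 HOM + 20 HET SVs, 30x noise-free reads."""
    return SimRun(tmp_path_factory.mktemp("nf"), sv.SimConfig(rng_seed=1))


@pytest.fixture(scope="session")
def noisy_run(tmp_path_factory) -> SimRun:
    """Same genome conditions at 10% per-base error and 5x depth."""
    return SimRun(
        tmp_path_factory.mktemp("noisy"),
        sv.SimConfig(rng_seed=1, depth=5.0, error_rate=0.10),
    )


@pytest.fixture(scope="session")
def fragmented_run(tmp_path_factory) -> SimRun:
    """Noise-free run with deletions rendered as split CIGAR fragments."""
    return SimRun(
        tmp_path_factory.mktemp("frag"),
        sv.SimConfig(rng_seed=1, fragment_indels=True),
    )
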