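"""Scoring a validation run against a truth set.

A truth SV counts as found when validation labeled it homozygous or
heterozygous; an entry of the false-SV list counts as correctly
rejected when it was labeled false.  Recall is found-true over total
true; precision is found-true over everything called true (found truth
plus false-list records that slipped through); F1 is their harmonic
mean.  Reports can be stratified by repeat-region membership.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .core_io import Label, SVRecord, ValidationResult

TRUE_LABELS = (Label.HOMOZYGOUS, Label.HETEROZYGOUS)


@dataclass
class MetricReport:
    true_positives: int
    false_positives: int
    false_negatives: int
    strata: dict[str, "MetricReport"] = field(default_factory=dict)

    @property
    def recall(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else 0.0

    @property
    def precision(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def to_dict(self) -> dict:
        d = {
            "true_positives": self.true_positives,
            "false_positives": self.false_positives,
            "false_negatives": self.false_negatives,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
        }
        if self.strata:
            d["strata"] = {k: v.to_dict() for k, v in self.strata.items()}
        return d


def match_sv(
    call: SVRecord,
    truth: SVRecord,
    tolerance_bp: int = 1000,
    length_ratio_min: float = 0.5,
) -> bool:
    """Do two SV records describe the same event?

    Same type, start positions within ``tolerance_bp``, and length ratio
    (smaller over larger) at least ``length_ratio_min``.
    """
    if call.sv_type != truth.sv_type or call.chrom != truth.chrom:
        return False
    if abs(call.start - truth.start) > tolerance_bp:
        return False
    lo, hi = sorted((call.length, truth.length))
    return hi > 0 and lo / hi >= length_ratio_min


def match_calls(
    calls: list[SVRecord],
    truth: list[SVRecord],
    tolerance_bp: int = 1000,
    length_ratio_min: float = 0.5,
) -> dict[int, int]:
    """Greedy one-to-one assignment call-index -> truth-index, nearest
    breakpoint first."""
    pairs = [
        (abs(c.start - t.start), ci, ti)
        for ci, c in enumerate(calls)
        for ti, t in enumerate(truth)
        if match_sv(c, t, tolerance_bp, length_ratio_min)
    ]
    pairs.sort()
    assigned: dict[int, int] = {}
    used_truth: set[int] = set()
    for _, ci, ti in pairs:
        if ci in assigned or ti in used_truth:
            continue
        assigned[ci] = ti
        used_truth.add(ti)
    return assigned


def _in_any(sv: SVRecord, intervals: list[tuple[int, int]]) -> bool:
    return any(s < sv.end and sv.start < e for s, e in intervals)


def _counts(
    validated_true: list[ValidationResult],
    validated_false: list[ValidationResult],
) -> tuple[int, int, int]:
    tp = sum(1 for r in validated_true if r.label in TRUE_LABELS)
    fn = len(validated_true) - tp
    fp = sum(1 for r in validated_false if r.label in TRUE_LABELS)
    return tp, fp, fn


def score_run(
    validated_true: list[ValidationResult],
    validated_false: list[ValidationResult],
    repeat_regions: list[tuple[int, int]] | None = None,
) -> MetricReport:
    """Score a run: ``validated_true`` are the validation results on the
    truth SV list, ``validated_false`` on the false-SV list.  NO_READS
    and FILTERED_HIGH_COVERAGE count as not found."""
    if not validated_true:
        raise ValueError("truth result list is empty")
    tp, fp, fn = _counts(validated_true, validated_false)
    report = MetricReport(tp, fp, fn)
    if repeat_regions is not None:
        for name, pred in (
            ("repeat", lambda r: _in_any(r.sv, repeat_regions)),
            ("normal", lambda r: not _in_any(r.sv, repeat_regions)),
        ):
            t = [r for r in validated_true if pred(r)]
            f = [r for r in validated_false if pred(r)]
            report.strata[name] = MetricReport(*_counts(t, f))
    return report


def write_metrics_json(report: MetricReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
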