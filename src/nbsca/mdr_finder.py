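"""Minimally deleted region (MDR) identification.

Among the patients carrying a loss on an arm, every maximal contiguous
deleted interval is an MDR candidate; the MDR is the shortest candidate
(ties broken by smallest start, then sample id).  Recurrence counts the
affected samples whose deleted footprint fully contains the MDR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .core_io import ArmMap, GeneAnnotation, parse_arm_label
from .sca_calling import ArmCallSet, HOMOZYGOUS_DELETION, LOSS

Interval = tuple[int, int]


@dataclass(frozen=True)
class MDRResult:
    arm: str
    start: int
    end: int
    defining_sample: str
    recurrence_count: int
    affected_total: int
    gene_count: Optional[int] = None
    protein_coding_count: Optional[int] = None

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    def to_dict(self) -> dict:
        return {
            "arm": self.arm, "start": self.start, "end": self.end,
            "length_bp": self.length_bp, "defining_sample": self.defining_sample,
            "recurrence_count": self.recurrence_count,
            "affected_total": self.affected_total,
            "gene_count": self.gene_count,
            "protein_coding_count": self.protein_coding_count,
        }


def merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Union of intervals as maximal disjoint intervals (abutting merge)."""
    merged: list[Interval] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def collect_arm_loss_footprints(
    call_sets: Sequence[ArmCallSet],
    arm: str,
    arm_map: ArmMap,
) -> dict[str, list[Interval]]:
    """Per-sample deleted intervals on an arm, clipped to the arm extent.

    Only samples with a loss-class call on the arm contribute; their
    provenance segments are clipped to the arm and unioned into maximal
    disjoint intervals.
    """
    _, arm_start, arm_end = arm_map.arm_interval(arm)
    footprints: dict[str, list[Interval]] = {}
    for call_set in call_sets:
        segments = [
            seg
            for cls in (LOSS, HOMOZYGOUS_DELETION)
            for seg in call_set.calls.get((arm, cls), [])
        ]
        has_loss = any((arm, cls) in call_set.calls for cls in (LOSS, HOMOZYGOUS_DELETION))
        if has_loss and not segments:
            raise ValueError(
                f"sample {call_set.sample_id}: loss call on {arm} without provenance"
            )
        clipped = [
            (max(seg.start, arm_start), min(seg.end, arm_end))
            for seg in segments
            if max(seg.start, arm_start) < min(seg.end, arm_end)
        ]
        if clipped:
            footprints[call_set.sample_id] = merge_intervals(clipped)
    return footprints


def find_mdr(footprints: Mapping[str, Sequence[Interval]], arm: str = "") -> MDRResult:
    """Locate the MDR among per-sample deleted footprints.

    The MDR is the shortest maximal contiguous deleted interval of any
    sample; recurrence is the number of samples with an interval that
    fully contains it (the defining sample included).
    """
    candidates = [
        (end - start, start, sample, (start, end))
        for sample, intervals in footprints.items()
        for start, end in intervals
    ]
    if not candidates:
        raise ValueError("no affected samples: cannot define an MDR")
    _, _, defining_sample, (mdr_start, mdr_end) = min(candidates)
    recurrence = sum(
        1
        for intervals in footprints.values()
        if any(s <= mdr_start and e >= mdr_end for s, e in intervals)
    )
    return MDRResult(
        arm=arm,
        start=mdr_start,
        end=mdr_end,
        defining_sample=defining_sample,
        recurrence_count=recurrence,
        affected_total=len(footprints),
    )


def count_genes_in_region(
    chromosome: str,
    start: int,
    end: int,
    genes: Sequence[GeneAnnotation],
) -> tuple[int, int, list[GeneAnnotation]]:
    """Genes overlapping [start, end) by >= 1 bp, with the protein-coding subset."""
    hits = sorted(
        (
            g for g in genes
            if g.chromosome == chromosome and max(g.start, start) < min(g.end, end)
        ),
        key=lambda g: (g.start, g.end, g.gene_id),
    )
    n_coding = sum(1 for g in hits if g.biotype == "protein_coding")
    return len(hits), n_coding, hits


def annotate_mdr(
    mdr: MDRResult, genes: Sequence[GeneAnnotation], arm_map: ArmMap
) -> MDRResult:
    chrom, _ = parse_arm_label(mdr.arm)
    n, n_coding, _ = count_genes_in_region(chrom, mdr.start, mdr.end, genes)
    return MDRResult(
        arm=mdr.arm, start=mdr.start, end=mdr.end,
        defining_sample=mdr.defining_sample,
        recurrence_count=mdr.recurrence_count,
        affected_total=mdr.affected_total,
        gene_count=n, protein_coding_count=n_coding,
    )


def write_mdr_report(
    mdr: MDRResult,
    footprints: Mapping[str, Sequence[Interval]],
    arm_map: ArmMap,
    json_path: str | Path,
    bed_path: str | Path,
) -> None:
    """JSON summary plus a BED of per-sample footprints and the MDR."""
    with open(json_path, "w") as handle:
        json.dump(mdr.to_dict(), handle, indent=2, sort_keys=True)
        handle.write("\n")
    chrom, _ = parse_arm_label(mdr.arm)
    with open(bed_path, "w") as handle:
        for sample in sorted(footprints):
            for start, end in footprints[sample]:
                handle.write(f"{chrom}\t{start}\t{end}\t{sample}\n")
        handle.write(f"{chrom}\t{mdr.start}\t{mdr.end}\tMDR\n")


__all__ = [
    "MDRResult", "annotate_mdr", "collect_arm_loss_footprints",
    "count_genes_in_region", "find_mdr", "merge_intervals", "write_mdr_report",
]
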