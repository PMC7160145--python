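"""Arm-level segmental chromosomal aberration (SCA) calling.

Segments are classified from their mean log2 ratio, merged per
chromosome and class into contiguous footprints, filtered by the
minimum-size rule (aberrations must exceed 3 Mb by default) and by the
whole-chromosome exclusion, and finally assigned to every chromosome
arm they overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core_io import ArmMap, SegmentRecord

GAIN = "gain"
LOSS = "loss"
AMPLIFICATION = "amplification"
HOMOZYGOUS_DELETION = "homozygous_deletion"
NEUTRAL = "neutral"

#: aberration class -> the weaker class it subsumes at the arm level
_SUBSUMES = {AMPLIFICATION: GAIN, HOMOZYGOUS_DELETION: LOSS}
_GAIN_CLASSES = (GAIN, AMPLIFICATION)
_LOSS_CLASSES = (LOSS, HOMOZYGOUS_DELETION)


@dataclass(frozen=True)
class CallThresholds:
    """Log2-ratio thresholds and footprint filters for SCA calling.

    Defaults follow the conventional array-CGH settings: gains at +0.2,
    losses at -0.3, amplifications at +2, homozygous deletions at -2;
    a segmental aberration must span more than ``min_segment_bp``
    (3 Mb) and must not cover essentially the whole chromosome.
    """

    gain_log2: float = 0.2
    loss_log2: float = -0.3
    amplification_log2: float = 2.0
    homozygous_deletion_log2: float = -2.0
    min_segment_bp: int = 3_000_000
    whole_chromosome_fraction: float = 0.95
    merge_gap_bp: int = 0

    def __post_init__(self) -> None:
        if not (self.loss_log2 < 0 < self.gain_log2):
            raise ValueError("need loss_log2 < 0 < gain_log2")
        if self.homozygous_deletion_log2 > self.loss_log2:
            raise ValueError("homozygous_deletion_log2 must be <= loss_log2")
        if self.amplification_log2 < self.gain_log2:
            raise ValueError("amplification_log2 must be >= gain_log2")
        if self.min_segment_bp <= 0:
            raise ValueError("min_segment_bp must be positive")
        if not (0 < self.whole_chromosome_fraction <= 1):
            raise ValueError("whole_chromosome_fraction must be in (0, 1]")
        if self.merge_gap_bp < 0:
            raise ValueError("merge_gap_bp must be >= 0")


def classify_segment(log2_ratio: float, thresholds: CallThresholds = CallThresholds()) -> str:
    """Classify a mean segment log2 ratio into one of the five classes.

    Threshold boundaries are inclusive toward the aberrant class: a
    ratio of exactly +0.2 is a gain.
    """
    if not math.isfinite(log2_ratio):
        raise ValueError(f"non-finite log2 ratio: {log2_ratio!r}")
    if log2_ratio >= thresholds.amplification_log2:
        return AMPLIFICATION
    if log2_ratio <= thresholds.homozygous_deletion_log2:
        return HOMOZYGOUS_DELETION
    if log2_ratio >= thresholds.gain_log2:
        return GAIN
    if log2_ratio <= thresholds.loss_log2:
        return LOSS
    return NEUTRAL


@dataclass
class ArmCallSet:
    """Per-sample arm-level SCA calls with contributing segments."""

    sample_id: str
    calls: dict[tuple[str, str], list[SegmentRecord]] = field(default_factory=dict)

    def labels(self) -> set[tuple[str, str]]:
        return set(self.calls)

    def has_call(self, arm: str, aberration_class: str) -> bool:
        """True if the sample carries the SCA, honouring subsumption.

        A query for ``loss`` matches a homozygous deletion on the same
        arm, and a query for ``gain`` matches an amplification: the
        stronger class implies the weaker binary trait.
        """
        if (arm, aberration_class) in self.calls:
            return True
        if aberration_class == LOSS:
            return (arm, HOMOZYGOUS_DELETION) in self.calls
        if aberration_class == GAIN:
            return (arm, AMPLIFICATION) in self.calls
        return False


def _merge_footprints(
    segments: Sequence[SegmentRecord], merge_gap: int
) -> list[tuple[int, int, list[SegmentRecord]]]:
    """Merge overlapping/abutting same-class segments (gap <= merge_gap)."""
    footprints: list[tuple[int, int, list[SegmentRecord]]] = []
    for seg in sorted(segments, key=lambda s: (s.start, s.end)):
        if footprints and seg.start <= footprints[-1][1] + merge_gap:
            start, end, members = footprints[-1]
            footprints[-1] = (start, max(end, seg.end), members + [seg])
        else:
            footprints.append((seg.start, seg.end, [seg]))
    return footprints


def call_arm_scas(
    segments: Iterable[SegmentRecord],
    arm_map: ArmMap,
    thresholds: CallThresholds = CallThresholds(),
    precalled: bool = False,
) -> ArmCallSet:
    """Call arm-level SCAs for one sample.

    Pipeline: classify each segment; merge same-class segments per
    chromosome into footprints; drop footprints not longer than
    ``min_segment_bp``; drop footprints covering at least
    ``whole_chromosome_fraction`` of their chromosome (whole-chromosome
    aberrations are not segmental); assign survivors to every arm they
    overlap by at least one base.

    With ``precalled=True`` the segments are taken to be aberrant
    footprints already (as with deposited aberration calls) and are
    classified by the sign of the log2 ratio only.
    """
    segments = list(segments)
    if not segments:
        return ArmCallSet(sample_id="")
    sample_ids = {seg.sample_id for seg in segments}
    if len(sample_ids) > 1:
        raise ValueError(f"segments from multiple samples: {sorted(sample_ids)}")
    sample_id = segments[0].sample_id

    by_group: dict[tuple[str, str], list[SegmentRecord]] = {}
    for seg in segments:
        if seg.chromosome not in arm_map:
            raise ValueError(
                f"sample {sample_id}: chromosome {seg.chromosome} absent from arm map"
            )
        if precalled:
            if seg.log2_ratio > 0:
                cls = GAIN
            elif seg.log2_ratio < 0:
                cls = LOSS
            else:
                continue
        else:
            cls = classify_segment(seg.log2_ratio, thresholds)
            if cls == NEUTRAL:
                continue
        by_group.setdefault((seg.chromosome, cls), []).append(seg)

    call_set = ArmCallSet(sample_id=sample_id)
    for (chrom, cls), members in sorted(by_group.items()):
        chrom_length = arm_map[chrom].length
        for start, end, contributing in _merge_footprints(members, thresholds.merge_gap_bp):
            length = end - start
            if length <= thresholds.min_segment_bp:
                continue
            if length >= thresholds.whole_chromosome_fraction * chrom_length:
                continue
            for arm_label in arm_map.arms_overlapping(chrom, start, end):
                call_set.calls.setdefault((arm_label, cls), []).extend(contributing)

    # subsumption: keep one gain-class and one loss-class call per arm
    for strong, weak in _SUBSUMES.items():
        for (arm, cls) in [key for key in call_set.calls if key[1] == strong]:
            weak_key = (arm, weak)
            if weak_key in call_set.calls:
                call_set.calls[(arm, strong)].extend(call_set.calls.pop(weak_key))
    call_set.calls = dict(sorted(call_set.calls.items()))
    return call_set


def call_cohort(
    segments: Iterable[SegmentRecord],
    arm_map: ArmMap,
    thresholds: CallThresholds = CallThresholds(),
    precalled: bool = False,
) -> list[ArmCallSet]:
    """Group segments by sample and call SCAs per sample (input order kept)."""
    by_sample: dict[str, list[SegmentRecord]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    return [
        call_arm_scas(sample_segments, arm_map, thresholds, precalled)
        for sample_segments in by_sample.values()
    ]


def sca_label(arm: str, aberration_class: str) -> str:
    return f"{arm}_{aberration_class}"


def cohort_sca_matrix(
    call_sets: Sequence[ArmCallSet],
    sca_list: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Binary sample x SCA matrix (1 = call present, subsumption-aware)."""
    sample_ids = [cs.sample_id for cs in call_sets]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_ids in cohort")
    data = {
        sca_label(arm, cls): [int(cs.has_call(arm, cls)) for cs in call_sets]
        for arm, cls in sca_list
    }
    return pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id"), dtype=int)


def write_sca_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_sca_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


__all__ = [
    "AMPLIFICATION", "ArmCallSet", "CallThresholds", "GAIN",
    "HOMOZYGOUS_DELETION", "LOSS", "NEUTRAL", "call_arm_scas", "call_cohort",
    "classify_segment", "cohort_sca_matrix", "read_sca_matrix", "sca_label",
    "write_sca_matrix",
]
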