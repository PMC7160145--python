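"""Readers, writers and the shared data model.

All genomic coordinates are held internally as 0-based half-open
intervals.  SEG input is declared 1-based inclusive (the convention of
DNAcopy-style ``.seg`` output) and converted on read; BED input is
passed through unchanged.  Chromosome names are normalised to the
``chr``-prefixed form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

STAGES = ("1", "2", "3", "4", "4S")
UNKNOWN = "unknown"


class ParseError(ValueError):
    """A malformed row in an input file; the message names the line."""


def normalize_chromosome(name: str) -> str:
    name = name.strip()
    if not name:
        raise ValueError("empty chromosome name")
    return name if name.startswith("chr") else f"chr{name}"


# ---------------------------------------------------------------------------
# segments

@dataclass(frozen=True)
class SegmentRecord:
    """One segmented copy-number interval for one sample.

    ``start``/``end`` are 0-based half-open base-pair coordinates;
    ``log2_ratio`` is the mean log2 tumour/reference ratio of the
    segment.
    """

    sample_id: str
    chromosome: str
    start: int
    end: int
    log2_ratio: float
    n_probes: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} for {self.sample_id}")
        if self.end <= self.start:
            raise ValueError(
                f"end ({self.end}) must exceed start ({self.start}) "
                f"for {self.sample_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


SEG_COLUMNS = ("sample", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean")


def read_segments(path: str | Path, dialect: str = "seg") -> list[SegmentRecord]:
    """Read segments from a SEG or BED3+2 file.

    SEG rows carry 1-based inclusive coordinates and are converted to
    the internal 0-based half-open convention; BED rows are already
    half-open.
    """
    if dialect not in ("seg", "bed"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'seg' or 'bed'")
    records: list[SegmentRecord] = []
    with open(path) as handle:
        lines = handle.read().splitlines()
    start_line = 1 if dialect == "seg" else 0  # SEG has a header row
    for lineno, line in enumerate(lines, start=1):
        if lineno == 1 and dialect == "seg":
            continue
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        try:
            if dialect == "seg":
                sample, chrom, start, end, n_mark, log2 = fields[:6]
                record = SegmentRecord(
                    sample_id=sample,
                    chromosome=normalize_chromosome(chrom),
                    start=int(start) - 1,
                    end=int(end),
                    log2_ratio=float(log2),
                    n_probes=int(n_mark) if n_mark not in ("", "NA") else None,
                )
            else:
                chrom, start, end, sample, log2 = fields[:5]
                record = SegmentRecord(
                    sample_id=sample,
                    chromosome=normalize_chromosome(chrom),
                    start=int(start),
                    end=int(end),
                    log2_ratio=float(log2),
                )
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}, line {lineno}: {exc}") from exc
        records.append(record)
    return records


def write_segments(records: Iterable[SegmentRecord], path: str | Path) -> None:
    """Write segments in the SEG dialect (1-based inclusive coordinates)."""
    with open(path, "w") as handle:
        handle.write("\t".join(SEG_COLUMNS) + "\n")
        for rec in records:
            n_mark = "" if rec.n_probes is None else str(rec.n_probes)
            handle.write(
                f"{rec.sample_id}\t{rec.chromosome}\t{rec.start + 1}\t"
                f"{rec.end}\t{n_mark}\t{rec.log2_ratio!r}\n"
            )


# ---------------------------------------------------------------------------
# clinical table

@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient clinical annotation.

    Times are in years.  Missing survival information is encoded as
    ``None`` (never as a zero-time event); unknown stage or MYCN status
    is the explicit category ``"unknown"``.
    """

    sample_id: str
    age_at_diagnosis: float
    inss_stage: str = UNKNOWN
    mycn_amplified: str = UNKNOWN  # amplified / non_amplified / unknown
    os_time: Optional[float] = None
    os_event: Optional[int] = None
    efs_time: Optional[float] = None
    efs_event: Optional[int] = None

    def __post_init__(self) -> None:
        if self.age_at_diagnosis < 0:
            raise ValueError(f"negative age for {self.sample_id}")
        for name in ("os_time", "efs_time"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"negative {name} for {self.sample_id}")
        for name in ("os_event", "efs_event"):
            value = getattr(self, name)
            if value is not None and value not in (0, 1):
                raise ValueError(f"{name} must be 0/1 for {self.sample_id}")
        if self.inss_stage not in STAGES + (UNKNOWN,):
            raise ValueError(f"bad INSS stage {self.inss_stage!r}")
        if self.mycn_amplified not in ("amplified", "non_amplified", UNKNOWN):
            raise ValueError(f"bad MYCN status {self.mycn_amplified!r}")


CLINICAL_COLUMNS = (
    "sample_id", "age_years", "inss_stage", "mycn",
    "os_time_years", "os_event", "efs_time_years", "efs_event",
)

_MYCN_ALIASES = {
    "amplified": "amplified", "amp": "amplified", "1": "amplified",
    "non_amplified": "non_amplified", "non-amplified": "non_amplified",
    "normal": "non_amplified", "0": "non_amplified",
}


def _opt_float(text: str) -> Optional[float]:
    text = text.strip()
    return None if text in ("", "NA", "na", ".") else float(text)


def _opt_event(text: str) -> Optional[int]:
    text = text.strip()
    return None if text in ("", "NA", "na", ".") else int(text)


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read the tab-delimited clinical table (one row per sample)."""
    records: list[ClinicalRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        lines = handle.read().splitlines()
    if not lines:
        return records
    header = lines[0].split("\t")
    idx = {name: header.index(name) for name in CLINICAL_COLUMNS if name in header}
    missing = [c for c in ("sample_id", "age_years") if c not in idx]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")

        def get(column: str, default: str = "") -> str:
            pos = idx.get(column)
            return fields[pos] if pos is not None and pos < len(fields) else default

        try:
            sample = get("sample_id").strip()
            stage = get("inss_stage").strip().upper() or UNKNOWN
            if stage not in STAGES:
                stage = UNKNOWN
            mycn = _MYCN_ALIASES.get(get("mycn").strip().lower(), UNKNOWN)
            record = ClinicalRecord(
                sample_id=sample,
                age_at_diagnosis=float(get("age_years")),
                inss_stage=stage,
                mycn_amplified=mycn,
                os_time=_opt_float(get("os_time_years")),
                os_event=_opt_event(get("os_event")),
                efs_time=_opt_float(get("efs_time_years")),
                efs_event=_opt_event(get("efs_event")),
            )
        except ValueError as exc:
            raise ParseError(f"{path}, line {lineno}: {exc}") from exc
        if record.sample_id in seen:
            raise ParseError(
                f"{path}, line {lineno}: duplicated sample_id {record.sample_id!r}"
            )
        seen.add(record.sample_id)
        records.append(record)
    return records


def write_clinical(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    def fmt(value) -> str:
        return "" if value is None else repr(value) if isinstance(value, float) else str(value)

    with open(path, "w") as handle:
        handle.write("\t".join(CLINICAL_COLUMNS) + "\n")
        for rec in records:
            handle.write("\t".join([
                rec.sample_id,
                repr(rec.age_at_diagnosis),
                "" if rec.inss_stage == UNKNOWN else rec.inss_stage,
                "" if rec.mycn_amplified == UNKNOWN else rec.mycn_amplified,
                fmt(rec.os_time), fmt(rec.os_event),
                fmt(rec.efs_time), fmt(rec.efs_event),
            ]) + "\n")


# ---------------------------------------------------------------------------
# chromosome arms

@dataclass(frozen=True)
class ChromosomeArms:
    """p/q arm extents of one chromosome, 0-based half-open."""

    chromosome: str
    p_start: int
    p_end: int
    q_start: int
    q_end: int
    length: int

    def __post_init__(self) -> None:
        if self.p_end > self.q_start:
            raise ValueError(f"{self.chromosome}: p arm overlaps q arm")
        if not (0 <= self.p_start <= self.p_end <= self.length):
            raise ValueError(f"{self.chromosome}: p arm outside chromosome")
        if not (0 <= self.q_start <= self.q_end <= self.length):
            raise ValueError(f"{self.chromosome}: q arm outside chromosome")

    def arm_interval(self, arm: str) -> tuple[int, int]:
        if arm == "p":
            return self.p_start, self.p_end
        if arm == "q":
            return self.q_start, self.q_end
        raise ValueError(f"arm must be 'p' or 'q', got {arm!r}")


@dataclass
class ArmMap:
    """Arm extents per chromosome, keyed by normalised chromosome name."""

    chromosomes: dict[str, ChromosomeArms] = field(default_factory=dict)

    def __contains__(self, chromosome: str) -> bool:
        return normalize_chromosome(chromosome) in self.chromosomes

    def __getitem__(self, chromosome: str) -> ChromosomeArms:
        return self.chromosomes[normalize_chromosome(chromosome)]

    def arm_interval(self, arm_label: str) -> tuple[str, int, int]:
        """Resolve an arm label such as ``"19p"`` to (chrom, start, end)."""
        chrom, arm = parse_arm_label(arm_label)
        start, end = self[chrom].arm_interval(arm)
        return chrom, start, end

    def arms_overlapping(self, chromosome: str, start: int, end: int) -> list[str]:
        """Arm labels overlapping [start, end) by at least one base."""
        arms = self[chromosome]
        short = arms.chromosome.removeprefix("chr")
        labels = []
        for arm in ("p", "q"):
            a0, a1 = arms.arm_interval(arm)
            if max(start, a0) < min(end, a1):
                labels.append(f"{short}{arm}")
        return labels


def parse_arm_label(label: str) -> tuple[str, str]:
    """Split ``"19p"`` or ``"chr19p"`` into (``"chr19"``, ``"p"``)."""
    label = label.strip()
    if not label or label[-1] not in "pq":
        raise ValueError(f"bad arm label {label!r}")
    return normalize_chromosome(label[:-1]), label[-1]


def load_arm_map(path: str | Path) -> ArmMap:
    """Build an :class:`ArmMap` from a UCSC ``cytoBand.txt``-style file.

    The p arm is the union of bands whose name starts with ``p`` and the
    q arm the union of ``q`` bands (acrocentric chromosomes without
    annotated p bands get a zero-length p arm).  Any gap between the two
    unions is assigned to neither arm.
    """
    bands: dict[str, dict[str, list[tuple[int, int]]]] = {}
    lengths: dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                chrom = normalize_chromosome(fields[0])
                start, end = int(fields[1]), int(fields[2])
                band = fields[3]
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from exc
            lengths[chrom] = max(lengths.get(chrom, 0), end)
            if band[:1] in ("p", "q"):
                bands.setdefault(chrom, {}).setdefault(band[0], []).append((start, end))
    arm_map = ArmMap()
    for chrom, by_arm in bands.items():
        length = lengths[chrom]
        p = by_arm.get("p", [])
        q = by_arm.get("q", [])
        p_start = min((s for s, _ in p), default=0)
        p_end = max((e for _, e in p), default=0)
        q_start = min((s for s, _ in q), default=length)
        q_end = max((e for _, e in q), default=length)
        if not p:  # zero-length p arm placed before the q union
            p_start = p_end = q_start
        if not q:
            q_start = q_end = length
        arm_map.chromosomes[chrom] = ChromosomeArms(
            chromosome=chrom, p_start=p_start, p_end=p_end,
            q_start=q_start, q_end=q_end, length=length,
        )
    return arm_map


def bundled_cytoband_path() -> Path:
    """Path of the bundled reduced hg19 arm-definition file.

    The file is a cytoBand-dialect table holding one euchromatic band
    and one centromeric (acen) band per arm for the chromosomes this
    package analyses by default (1, 2, 11, 17, 19), with hg19 arm
    boundaries.  It defines arm extents only and is not a full
    cytogenetic ideogram.
    """
    return Path(str(resources.files("nbsca").joinpath("data/cytoband_hg19_arms.txt")))


# ---------------------------------------------------------------------------
# gene annotation

@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chromosome: str
    start: int
    end: int
    biotype: str = "other"  # protein_coding / other

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")


def read_genes(path: str | Path) -> list[GeneAnnotation]:
    """Read a BED6(+1) gene annotation; column 7, when present, is the biotype."""
    genes: list[GeneAnnotation] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                biotype = fields[6] if len(fields) > 6 else "other"
                genes.append(GeneAnnotation(
                    gene_id=fields[3],
                    chromosome=normalize_chromosome(fields[0]),
                    start=int(fields[1]),
                    end=int(fields[2]),
                    biotype="protein_coding" if biotype == "protein_coding" else "other",
                ))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from exc
    return genes


__all__ = [
    "ArmMap", "ChromosomeArms", "ClinicalRecord", "GeneAnnotation",
    "ParseError", "SegmentRecord", "bundled_cytoband_path", "load_arm_map",
    "normalize_chromosome", "parse_arm_label", "read_clinical", "read_genes",
    "read_segments", "write_clinical", "write_segments",
]
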