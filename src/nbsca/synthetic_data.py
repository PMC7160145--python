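"""Synthetic neuroblastoma cohort generator.

Emulates the statistical structure the pipeline assumes so that every
stage is testable without external downloads: an age mixture with an
infant fraction below the 18-month eligibility floor, age-dependent
19p-loss prevalence that steps up at a planted threshold, per-carrier
deletion segments on 19p that all contain a fixed core interval (one
designated carrier receives exactly the core, planting a known MDR),
co-occurring or mutually exclusive arm-level SCAs, MYCN amplification
and INSS stage, and exponential survival times with multiplicative
hazards and uniform censoring.

All randomness flows through one ``numpy`` generator seeded from
``SimulationParams.seed``; the draw order is fixed (ages, 19p flags,
19p breakpoints, other SCAs in listed order, MYCN, stage, survival,
filler segments), so a fixed seed reproduces the cohort exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core_io import (
    ArmMap, ClinicalRecord, SegmentRecord, bundled_cytoband_path, load_arm_map,
    write_clinical, write_segments,
)
from .mdr_finder import MDRResult

INDEPENDENT = "independent"
EXCLUSIVE = "exclusive"
CO_OCCURRING = "co_occurring"


def default_arm_map() -> ArmMap:
    """Arm map from the bundled reduced hg19 arm definitions."""
    return load_arm_map(bundled_cytoband_path())


@dataclass(frozen=True)
class OtherSca:
    """A recurrent SCA other than the target 19p loss.

    ``relation`` controls the joint distribution with 19p loss:
    ``independent`` draws the flag for every sample, ``exclusive`` only
    for non-carriers and ``co_occurring`` only for carriers.
    Prevalences are conditional on the age stratum (below / above the
    planted threshold).
    """

    arm: str
    aberration: str  # gain / loss
    prevalence_young: float
    prevalence_old: float
    relation: str = INDEPENDENT

    def __post_init__(self) -> None:
        if self.relation not in (INDEPENDENT, EXCLUSIVE, CO_OCCURRING):
            raise ValueError(f"bad relation {self.relation!r}")
        for p in (self.prevalence_young, self.prevalence_old):
            if not 0 <= p <= 1:
                raise ValueError("prevalence must lie in [0, 1]")


@dataclass(frozen=True)
class SurvivalParams:
    """Exponential survival with multiplicative hazards, uniform censoring.

    Baseline hazards are per year for a patient with no 19p loss, no
    MYCN amplification and stage other than 4.
    """

    os_baseline_hazard: float = 0.22
    efs_baseline_hazard: float = 0.30
    hr_loss_os: float = 1.6
    hr_loss_efs: float = 1.2
    hr_mycn: float = 1.6
    hr_stage4: float = 1.8
    censor_min_years: float = 6.0
    censor_max_years: float = 14.0


_DEFAULT_OTHER_SCAS = (
    OtherSca("1q", "gain", 0.15, 0.35, EXCLUSIVE),
    OtherSca("1p", "loss", 0.40, 0.20, INDEPENDENT),
    OtherSca("2p", "gain", 0.35, 0.15, INDEPENDENT),
)


@dataclass(frozen=True)
class SimulationParams:
    """Cohort-generation settings.

    The defaults mirror the discovery-style cohort: 556 tumours, about
    10% of patients older than the 6-year threshold, 19p-loss
    prevalence 10% below and 20% above it, and a planted 4098-kb core
    deletion on 19p.  ``validation_like`` raises the prevalences to
    19%/35% at the validation sample size.
    """

    n_samples: int = 556
    cohort_name: str = "cohort"
    seed: int = 0
    # age mixture (fractions; the remainder falls in (1.5, threshold])
    frac_infant: float = 0.10
    frac_old: float = 0.085
    threshold_years: float = 6.0
    age_max_years: float = 18.0
    # 19p loss
    p_loss_young: float = 0.10
    p_loss_old: float = 0.20
    core_start: int = 1_000_000
    core_end: int = 5_098_000
    loss_log2_mean: float = -0.5
    loss_log2_sd: float = 0.05
    other_scas: tuple[OtherSca, ...] = _DEFAULT_OTHER_SCAS
    mna_prevalence: float = 0.30
    stage4_prevalence: float = 0.60
    survival: SurvivalParams = field(default_factory=SurvivalParams)

    def __post_init__(self) -> None:
        for name in ("frac_infant", "frac_old", "p_loss_young", "p_loss_old",
                     "mna_prevalence", "stage4_prevalence"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_infant + self.frac_old > 1:
            raise ValueError("age-mixture fractions exceed 1")
        if self.core_end <= self.core_start:
            raise ValueError("core interval must be non-empty")

    @classmethod
    def discovery_like(cls, seed: int = 0, **overrides) -> "SimulationParams":
        return cls(cohort_name="discovery", seed=seed, **overrides)

    @classmethod
    def validation_like(cls, seed: int = 0, **overrides) -> "SimulationParams":
        defaults = dict(
            n_samples=208, cohort_name="validation", frac_infant=0.15,
            frac_old=0.135, p_loss_young=0.19, p_loss_old=0.35,
        )
        defaults.update(overrides)
        return cls(seed=seed, **defaults)


@dataclass
class CohortData:
    """A generated cohort: segments, clinical records and latent truth."""

    name: str
    segments: list[SegmentRecord]
    clinical: list[ClinicalRecord]
    truth: pd.DataFrame

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_segments(self.segments, directory / f"{self.name}.seg")
        write_clinical(self.clinical, directory / f"{self.name}.clinical.tsv")
        self.truth.to_csv(directory / f"{self.name}.truth.tsv", sep="\t", index=False)


def sample_ages_and_loss(
    params: SimulationParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ages and 19p-loss flags only (the generator's first stages).

    Exposed separately so large simulation studies (threshold recovery,
    null calibration) can skip segment generation.
    """
    n = params.n_samples
    frac_young = 1.0 - params.frac_infant - params.frac_old
    stratum = rng.choice(3, size=n, p=[params.frac_infant, frac_young, params.frac_old])
    u = rng.random(n)
    ages = np.empty(n)
    ages[stratum == 0] = 1.5 * u[stratum == 0]
    ages[stratum == 1] = 1.5 + (params.threshold_years - 1.5) * u[stratum == 1]
    ages[stratum == 2] = params.threshold_years + (
        params.age_max_years - params.threshold_years
    ) * u[stratum == 2]
    p_loss = np.where(ages > params.threshold_years, params.p_loss_old, params.p_loss_young)
    loss = rng.random(n) < p_loss
    return ages, loss


def generate_cohort(
    params: SimulationParams, arm_map: Optional[ArmMap] = None
) -> CohortData:
    """Generate one cohort; a fixed seed yields identical output."""
    arm_map = arm_map or default_arm_map()
    _, p19_start, p19_end = arm_map.arm_interval("19p")
    _, q19_start, q19_end = arm_map.arm_interval("19q")
    if not (p19_start <= params.core_start < params.core_end <= p19_end):
        raise ValueError("planted core interval does not fit inside 19p")

    rng = np.random.default_rng(params.seed)
    n = params.n_samples
    sample_ids = [f"{params.cohort_name}_{i:04d}" for i in range(n)]

    ages, loss = sample_ages_and_loss(params, rng)

    # 19p deletion breakpoints: every carrier's segment contains the core.
    # One designated carrier gets exactly the core interval, planting a
    # known MDR; carriers above the age threshold are preferred so the
    # planted MDR survives restriction to the older stratum.
    carrier_idx = np.flatnonzero(loss)
    seg_start = np.full(n, -1, dtype=np.int64)
    seg_end = np.full(n, -1, dtype=np.int64)
    if carrier_idx.size:
        seg_start[carrier_idx] = rng.integers(p19_start, params.core_start + 1,
                                              size=carrier_idx.size)
        seg_end[carrier_idx] = rng.integers(params.core_end, p19_end + 1,
                                            size=carrier_idx.size)
        old_carriers = carrier_idx[ages[carrier_idx] > params.threshold_years]
        designated = old_carriers[0] if old_carriers.size else carrier_idx[0]
        seg_start[designated], seg_end[designated] = params.core_start, params.core_end
    loss_log2 = rng.normal(params.loss_log2_mean, params.loss_log2_sd, size=n)

    # other SCAs, in listed order
    old = ages > params.threshold_years
    other_flags: dict[str, np.ndarray] = {}
    other_geom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for sca in params.other_scas:
        prevalence = np.where(old, sca.prevalence_old, sca.prevalence_young)
        draw = rng.random(n) < prevalence
        if sca.relation == EXCLUSIVE:
            flags = draw & ~loss
        elif sca.relation == CO_OCCURRING:
            flags = draw & loss
        else:
            flags = draw
        _, arm_start, arm_end = arm_map.arm_interval(sca.arm)
        arm_len = arm_end - arm_start
        lengths = rng.integers(5_000_000, max(5_000_001, int(0.6 * arm_len)), size=n)
        starts = arm_start + (rng.random(n) * (arm_len - lengths)).astype(np.int64)
        sign = 1.0 if sca.aberration == "gain" else -1.0
        log2 = rng.normal(sign * 0.5, 0.05, size=n)
        label = f"{sca.arm}_{sca.aberration}"
        other_flags[label] = flags
        other_geom[label] = (starts, starts + lengths, log2)

    mna = rng.random(n) < params.mna_prevalence
    stage4 = rng.random(n) < params.stage4_prevalence
    other_stage = rng.choice(["1", "2", "3", "4S"], size=n)

    sp = params.survival
    hazard_os = sp.os_baseline_hazard * (
        sp.hr_loss_os ** loss * sp.hr_mycn ** mna * sp.hr_stage4 ** stage4
    )
    hazard_efs = sp.efs_baseline_hazard * (
        sp.hr_loss_efs ** loss * sp.hr_mycn ** mna * sp.hr_stage4 ** stage4
    )
    t_os = rng.exponential(1.0 / hazard_os)
    t_efs = rng.exponential(1.0 / hazard_efs)
    censor = rng.uniform(sp.censor_min_years, sp.censor_max_years, size=n)
    os_time = np.minimum(t_os, censor)
    os_event = (t_os <= censor).astype(int)
    efs_time = np.minimum(t_efs, censor)
    efs_event = (t_efs <= censor).astype(int)

    # diploid filler on 19q so neutral classification is exercised
    filler_log2 = rng.normal(0.0, 0.03, size=n)

    segments: list[SegmentRecord] = []
    clinical: list[ClinicalRecord] = []
    _, p2_start, _ = arm_map.arm_interval("2p")
    for i, sid in enumerate(sample_ids):
        if loss[i]:
            segments.append(SegmentRecord(
                sid, "chr19", int(seg_start[i]), int(seg_end[i]),
                float(loss_log2[i]),
            ))
        for label, flags in other_flags.items():
            if flags[i]:
                starts, ends, log2 = other_geom[label]
                chrom = f"chr{label.split('_')[0][:-1]}"
                segments.append(SegmentRecord(
                    sid, chrom, int(starts[i]), int(ends[i]), float(log2[i]),
                ))
        if mna[i]:
            # focal MYCN amplicon (~1 Mb, below the segmental-size filter)
            segments.append(SegmentRecord(
                sid, "chr2", p2_start + 15_900_000, p2_start + 16_900_000, 2.5,
            ))
        segments.append(SegmentRecord(
            sid, "chr19", q19_start, q19_end, float(filler_log2[i]),
        ))
        clinical.append(ClinicalRecord(
            sample_id=sid,
            age_at_diagnosis=float(ages[i]),
            inss_stage="4" if stage4[i] else str(other_stage[i]),
            mycn_amplified="amplified" if mna[i] else "non_amplified",
            os_time=float(os_time[i]), os_event=int(os_event[i]),
            efs_time=float(efs_time[i]), efs_event=int(efs_event[i]),
        ))

    truth = pd.DataFrame({
        "sample_id": sample_ids,
        "age_years": ages,
        "loss_19p": loss.astype(int),
        "seg_start": seg_start,
        "seg_end": seg_end,
        "mycn_amplified": mna.astype(int),
        "stage4": stage4.astype(int),
        "latent_os_time": t_os,
        "latent_efs_time": t_efs,
        **{label: flags.astype(int) for label, flags in other_flags.items()},
    })
    return CohortData(
        name=params.cohort_name, segments=segments, clinical=clinical, truth=truth
    )


def generate_null_cohort(
    params: SimulationParams, arm_map: Optional[ArmMap] = None
) -> CohortData:
    """As :func:`generate_cohort` with age-constant 19p-loss prevalence."""
    return generate_cohort(
        dataclasses.replace(params, p_loss_old=params.p_loss_young), arm_map
    )


def known_mdr(cohort: CohortData, params: SimulationParams) -> MDRResult:
    """The MDR the generator planted, recomputed from the latent truth.

    The expected interval is the shortest planted deletion; recurrence
    recounts, from the recorded breakpoints, the carriers whose segment
    contains it.  Serves as the oracle for ``mdr_finder.find_mdr``.
    """
    carriers = cohort.truth[cohort.truth["loss_19p"] == 1]
    if carriers.empty:
        raise ValueError("cohort has no 19p-loss carriers")
    lengths = carriers["seg_end"] - carriers["seg_start"]
    order = sorted(
        zip(lengths, carriers["seg_start"], carriers["sample_id"],
            carriers["seg_end"])
    )
    _, start, defining_sample, end = order[0]
    contains = (carriers["seg_start"] <= start) & (carriers["seg_end"] >= end)
    return MDRResult(
        arm="19p",
        start=int(start),
        end=int(end),
        defining_sample=str(defining_sample),
        recurrence_count=int(contains.sum()),
        affected_total=len(carriers),
    )


__all__ = [
    "CO_OCCURRING", "CohortData", "EXCLUSIVE", "INDEPENDENT", "OtherSca",
    "SimulationParams", "SurvivalParams", "default_arm_map", "generate_cohort",
    "generate_null_cohort", "known_mdr", "sample_ages_and_loss",
]
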