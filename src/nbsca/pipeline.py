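"""End-to-end orchestration of the analysis stages.

Order mirrors the analysis design: SCA calling, the age-cut-off scan,
then — restricted to the stratum older than the discovered (or fixed)
cut-off — MDR identification, co-occurrence testing and survival
stratification.  All reports land under one output directory and rerun
byte-identically for identical inputs and configuration.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, age_scan, cooccurrence, mdr_finder, sca_calling, survival
from .core_io import (
    ArmMap, ClinicalRecord, load_arm_map, bundled_cytoband_path, read_clinical,
    read_genes, read_segments,
)

logger = logging.getLogger(__name__)

DEFAULT_SCA_LIST = (
    ("19p", "loss"), ("1q", "gain"), ("1p", "loss"), ("2p", "gain"),
    ("11q", "loss"), ("17q", "gain"),
)


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def parse_sca(text: str) -> tuple[str, str]:
    """Parse an SCA spec such as ``19p:loss`` into (arm, class)."""
    arm, _, cls = text.partition(":")
    if not arm or not cls:
        raise ValueError(f"bad SCA spec {text!r}; expected e.g. '19p:loss'")
    return arm, cls


@dataclass
class CohortInput:
    name: str
    segments_path: str
    clinical_path: str
    dialect: str = "seg"
    precalled: bool = False


@dataclass
class PipelineConfig:
    cohorts: list[CohortInput]
    output_dir: str
    cytoband_path: Optional[str] = None
    genes_path: Optional[str] = None
    thresholds: sca_calling.CallThresholds = field(
        default_factory=sca_calling.CallThresholds
    )
    sca_list: Sequence[tuple[str, str]] = DEFAULT_SCA_LIST
    target_sca: tuple[str, str] = ("19p", "loss")
    cutoffs: Sequence[float] = age_scan.DEFAULT_CUTOFFS
    alpha: float = 0.05
    bonferroni_m: Optional[int] = None
    min_age_years: float = age_scan.DEFAULT_MIN_AGE_YEARS
    fixed_cutoff: Optional[float] = None
    endpoint: str = "os"
    eval_time_years: float = 5.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        cohorts = [CohortInput(**entry) for entry in raw.pop("cohorts")]
        if "thresholds" in raw:
            raw["thresholds"] = sca_calling.CallThresholds(**raw["thresholds"])
        for key in ("sca_list",):
            if key in raw:
                raw[key] = [parse_sca(item) for item in raw[key]]
        if "target_sca" in raw:
            raw["target_sca"] = parse_sca(raw["target_sca"])
        return cls(cohorts=cohorts, **raw)

    def validate(self) -> None:
        if not self.cohorts:
            raise ValueError("at least one cohort is required")
        for cohort in self.cohorts:
            for path in (cohort.segments_path, cohort.clinical_path):
                if not Path(path).exists():
                    raise FileNotFoundError(f"input file not found: {path}")
        if self.cytoband_path and not Path(self.cytoband_path).exists():
            raise FileNotFoundError(f"cytoband file not found: {self.cytoband_path}")
        if self.genes_path and not Path(self.genes_path).exists():
            raise FileNotFoundError(f"gene annotation not found: {self.genes_path}")


@dataclass
class CohortState:
    name: str
    clinical: list[ClinicalRecord]
    call_sets: list
    matrix: "object"  # pandas DataFrame


def _load_cohort(
    cohort: CohortInput, arm_map: ArmMap, config: PipelineConfig
) -> CohortState:
    segments = read_segments(cohort.segments_path, dialect=cohort.dialect)
    clinical = read_clinical(cohort.clinical_path)
    call_sets = sca_calling.call_cohort(
        segments, arm_map, config.thresholds, precalled=cohort.precalled
    )
    known = {rec.sample_id for rec in clinical}
    call_sets = [cs for cs in call_sets if cs.sample_id in known]
    by_sample = {cs.sample_id: cs for cs in call_sets}
    # every clinical sample gets a row, including samples without segments
    full = [
        by_sample.get(rec.sample_id, sca_calling.ArmCallSet(rec.sample_id))
        for rec in clinical
    ]
    matrix = sca_calling.cohort_sca_matrix(full, list(config.sca_list))
    return CohortState(cohort.name, clinical, full, matrix)


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the machine-readable summary."""
    try:
        config.validate()
    except (ValueError, FileNotFoundError) as exc:
        raise StageError("config", str(exc)) from exc

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    arm_map = load_arm_map(config.cytoband_path or bundled_cytoband_path())
    target_label = sca_calling.sca_label(*config.target_sca)

    # --- SCA calling -------------------------------------------------------
    try:
        states = [_load_cohort(c, arm_map, config) for c in config.cohorts]
        for state in states:
            sca_calling.write_sca_matrix(
                state.matrix, out / f"{state.name}.sca_matrix.tsv"
            )
    except (OSError, ValueError, KeyError) as exc:
        raise StageError("sca_calling", str(exc)) from exc

    # --- age scan ----------------------------------------------------------
    try:
        cohorts = []
        for state in states:
            ages = np.array([rec.age_at_diagnosis for rec in state.clinical])
            flags = state.matrix[target_label].to_numpy(dtype=bool)
            cohorts.append(age_scan.AgeScaCohort(state.name, ages, flags))
        scan = age_scan.run_age_scan(
            cohorts, cutoffs=config.cutoffs, alpha=config.alpha,
            m=config.bonferroni_m, min_age_years=config.min_age_years,
        )
        scan.write(out / "age_scan.tsv", out / "age_scan.json")
    except ValueError as exc:
        raise StageError("age_scan", str(exc)) from exc

    cutoff = config.fixed_cutoff
    if cutoff is None:
        cutoff = scan.lowest_significant_cutoff
    if cutoff is None:
        raise StageError(
            "age_scan",
            "no significant age cut-off found and no fixed cut-off configured",
        )

    # --- older stratum, pooled across cohorts ------------------------------
    older_ids: set[str] = set()
    for state in states:
        older_ids |= {
            rec.sample_id for rec in state.clinical if rec.age_at_diagnosis > cutoff
        }
    pooled_calls = [cs for s in states for cs in s.call_sets if cs.sample_id in older_ids]
    pooled_clinical = [
        rec for s in states for rec in s.clinical if rec.sample_id in older_ids
    ]
    pooled_matrix = pd.concat([s.matrix for s in states]).loc[
        [rec.sample_id for rec in pooled_clinical]
    ]

    # --- MDR ---------------------------------------------------------------
    try:
        footprints = mdr_finder.collect_arm_loss_footprints(
            pooled_calls, config.target_sca[0], arm_map
        )
        mdr = mdr_finder.find_mdr(footprints, arm=config.target_sca[0])
        if config.genes_path:
            mdr = mdr_finder.annotate_mdr(mdr, read_genes(config.genes_path), arm_map)
        mdr_finder.write_mdr_report(
            mdr, footprints, arm_map, out / "mdr.json", out / "mdr_footprints.bed"
        )
    except (OSError, ValueError) as exc:
        raise StageError("mdr_finder", str(exc)) from exc

    # --- co-occurrence -----------------------------------------------------
    try:
        pairs = [
            (target_label, sca_calling.sca_label(arm, cls))
            for arm, cls in config.sca_list
            if (arm, cls) != tuple(config.target_sca)
        ]
        pair_report = cooccurrence.pairwise_report(
            pooled_matrix, pairs, alpha=config.alpha
        )
        cooccurrence.write_pairwise_report(pair_report, out / "cooccurrence.tsv")
        full_clinical = [rec for s in states for rec in s.clinical]
        full_matrix = pd.concat([s.matrix for s in states])
        prevalence = cooccurrence.stratum_prevalence(full_matrix, full_clinical, cutoff)
        prevalence.to_csv(out / "stratum_prevalence.tsv", sep="\t", index=False)
    except (ValueError, KeyError) as exc:
        raise StageError("cooccurrence", str(exc)) from exc

    # --- survival ----------------------------------------------------------
    try:
        loss_flags = {
            sid: bool(v)
            for sid, v in pooled_matrix[target_label].items()
        }
        frame, n_dropped = survival.prepare_survival_frame(
            pooled_clinical, loss_flags, endpoint=config.endpoint
        )
        groups, chi2, p = survival.stratified_survival(
            frame, group_col="sca_loss", eval_time=config.eval_time_years
        )
        cox = survival.cox_ph(
            frame, covariates=["sca_loss", "mycn", "stage4"]
        )
        survival.write_survival_report(
            groups, chi2, p, cox, out / "survival.json",
            eval_time=config.eval_time_years,
        )
    except (ValueError, KeyError) as exc:
        raise StageError("survival", str(exc)) from exc

    summary = {
        "version": __version__,
        "python": platform.python_version(),
        "cohorts": {
            s.name: {
                "n_samples": len(s.clinical),
                "target_prevalence": float(s.matrix[target_label].mean()),
            }
            for s in states
        },
        "age_scan": scan.summary(),
        "analysis_cutoff_years": cutoff,
        "older_stratum_n": len(pooled_clinical),
        "mdr": mdr.to_dict(),
        "survival": {
            "endpoint": config.endpoint,
            "n_dropped": n_dropped,
            "logrank_p": p,
        },
    }
    with open(out / "run_summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return summary


__all__ = [
    "CohortInput", "DEFAULT_SCA_LIST", "PipelineConfig", "StageError",
    "parse_sca", "run_all",
]
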