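"""End-to-end pipeline: map -> cohort -> profiles -> 3x PheWAS -> intersection -> report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import cohort as coh
from . import phewas as phw
from . import reporting as rep
from .cohort import AgeBinning, ConfigError, DataError, DEFAULT_AGE_BINS
from .phecodes import UNMAPPED, load_phecode_map

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in its message."""


@dataclass
class RunConfig:
    """Paths, thresholds and switches for one pipeline run.

    The configuration is serialized verbatim into the output directory so
    every run is reproducible from its artifacts.
    """

    patients: str = ""
    events: str = ""
    phecode_map: str = ""
    out_dir: str = "multiphewas_out"
    case_icd9_set: tuple[str, ...] = tuple(sorted(coh.ASD_ICD9_CODES))
    min_case_occasions: int = 3
    min_comorbid_occasions: int = 3
    min_span_days: int = 366
    min_age: int = 0
    max_age: int = 18
    alpha: float = 0.01
    or_cutoff: float = 1.5
    bonferroni_mode: str = "per_bin"
    occasion_scope: str = "overall"
    exclusion_mode: str = "per_bin"
    denominator_mode: str = "span_overlap"
    age_bins: tuple[tuple[str, int, int], ...] = DEFAULT_AGE_BINS.bins
    seed: int = 0

    @property
    def binning(self) -> AgeBinning:
        return AgeBinning(tuple(tuple(b) for b in self.age_bins))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "age_bins" in raw:
            raw["age_bins"] = tuple(tuple(b) for b in raw["age_bins"])
        if "case_icd9_set" in raw:
            raw["case_icd9_set"] = tuple(raw["case_icd9_set"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        d = asdict(self)
        d["age_bins"] = [list(b) for b in self.age_bins]
        d["case_icd9_set"] = list(self.case_icd9_set)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (DataError, ConfigError, OSError, KeyError, ValueError) as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    return wrap


def run_pipeline(
    config: RunConfig,
    patients: pd.DataFrame | None = None,
    events: pd.DataFrame | None = None,
    phecode_map=None,
) -> dict:
    """Execute all stages and write result tables plus a run summary.

    Inputs may be passed in memory (``patients``/``events``/
    ``phecode_map``) or read from the paths in ``config``.  Returns a
    dict with the three contrast result frames, the intersection, the
    sorted result table, the cutoff sweep and the run-summary counts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    bins = config.binning

    if phecode_map is None:
        phecode_map = _stage("phecode_map")(load_phecode_map, config.phecode_map)
    if patients is None:
        patients = _stage("load_patients")(pd.read_csv, config.patients, dtype={"patient_id": str})
    if events is None:
        events = _stage("load_events")(pd.read_csv, config.events, dtype={"patient_id": str, "icd9": str})
    if len(events) == 0:
        raise PipelineError("stage 'cohort' failed: events table is empty")

    assignment = _stage("cohort")(
        coh.assign_cohorts,
        patients, events,
        case_icd9_set=set(config.case_icd9_set),
        min_case_occasions=config.min_case_occasions,
        min_span_days=config.min_span_days,
        min_age=config.min_age,
        max_age=config.max_age,
        phecode_map=phecode_map,
    )
    counts = assignment.counts()
    included = assignment.table[assignment.table["status"].isin(["case", "control"])]
    cohort_df = included.merge(patients[["patient_id", "sex"]], on="patient_id")
    ev_inc = events[events["patient_id"].isin(included["patient_id"])]
    pat_inc = patients[patients["patient_id"].isin(included["patient_id"])]

    profile = _stage("profiles")(
        coh.build_profiles,
        ev_inc, pat_inc, phecode_map, bins,
        min_comorbid_occasions=config.min_comorbid_occasions,
        occasion_scope=config.occasion_scope,
    )
    denominators = _stage("denominators")(
        coh.bin_population, pat_inc, ev_inc, bins, assignment, config.denominator_mode
    )

    suppress = {
        phecode_map.map_to_phecode(c) for c in config.case_icd9_set
    } - {UNMAPPED}
    results = {}
    for spec in (phw.CASE_F_VS_CASE_M, phw.CASE_F_VS_CTRL_F, phw.CTRL_F_VS_CTRL_M):
        results[spec.name] = _stage(f"phewas:{spec.name}")(
            phw.run_phewas,
            profile, denominators, cohort_df, spec, bins,
            alpha=config.alpha,
            or_cutoff=config.or_cutoff,
            bonferroni_mode=config.bonferroni_mode,
            n_vocabulary=len(phecode_map.phecodes) or None,
            suppress_phecodes=suppress,
        )
        results[spec.name].to_csv(out / f"phewas_{spec.name}.csv", index=False)

    ir = _stage("intersection")(
        phw.intersect,
        results["case_F_vs_case_M"],
        results["case_F_vs_ctrl_F"],
        results["ctrl_F_vs_ctrl_M"],
        bins=bins,
        exclusion_mode=config.exclusion_mode,
    )
    table = _stage("report")(rep.make_result_table, ir, phecode_map, bins)
    table.to_csv(out / "intersection_table.csv", index=False)
    rep.export_heatmap(
        table, out / "heatmap_matrix.csv", out / "heatmap.png", bins
    )
    sweep = _stage("sweep")(
        phw.cutoff_sweep,
        results["case_F_vs_case_M"],
        results["case_F_vs_ctrl_F"],
        results["ctrl_F_vs_ctrl_M"],
        bins=bins,
        exclusion_mode=config.exclusion_mode,
    )
    sweep.to_csv(out / "cutoff_sweep.csv")

    per_bin, n_distinct = rep.summarize_by_bin(table, bins)
    summary = {
        "n_patients": int(len(patients)),
        "cohort": counts,
        "unmapped_events_dropped": profile.n_unmapped_events,
        "tests_per_contrast": {k: int(len(v)) for k, v in results.items()},
        "significant_per_contrast": {
            k: int(v["significant"].sum()) if len(v) else 0 for k, v in results.items()
        },
        "retained_per_bin": per_bin,
        "retained_distinct_phecodes": n_distinct,
        "config": str(out / "run_config.yaml"),
    }
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    funnel = counts["status"]
    log.info(
        "cohort funnel: %d patients -> %d cases / %d controls / %d excluded",
        len(patients), funnel.get("case", 0), funnel.get("control", 0),
        funnel.get("excluded", 0),
    )
    return {
        "assignment": assignment,
        "profile": profile,
        "denominators": denominators,
        "results": results,
        "intersection": ir,
        "table": table,
        "sweep": sweep,
        "summary": summary,
    }
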