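"""Cohort construction and per-age-bin phenotype profiles.

Cases are children (0-18 completed years at first qualifying code) who
received an ASD ICD-9-CM code on at least three distinct service dates,
whose record spans more than 12 months, and who carry at least one
phenotype besides ASD.  Controls never received any ASD code and satisfy
the same span and age criteria.  Patients with one or two ASD code
occasions are neither cases nor controls and are excluded, as are
patients with missing sex or birth date.

Comorbid phenotypes are retained only when coded on at least three
distinct service dates — repeated coding makes the diagnosis proxy
specific, filtering out rule-out or testing codes.  Presence is recorded
per age bin (0-2, 3-5, 6-11, 12-18 completed years by default); a patient
can contribute to several bins as their record progresses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phecodes import UNMAPPED, PhecodeMap, normalize_icd9, normalize_series

__all__ = [
    "ASD_ICD9_CODES",
    "AgeBinning",
    "DEFAULT_AGE_BINS",
    "CohortAssignment",
    "PhenotypeProfile",
    "assign_cohorts",
    "build_profiles",
    "bin_population",
    "completed_years",
    "DataError",
    "ConfigError",
]

log = logging.getLogger(__name__)

#: ICD-9-CM codes defining the ASD case phenotype.
ASD_ICD9_CODES = frozenset(
    {"299.00", "299.01", "299.80", "299.81", "299.90", "299.91"}
)


class DataError(ValueError):
    """Raised for input records violating data invariants."""


class ConfigError(ValueError):
    """Raised for invalid threshold or binning configuration."""


@dataclass(frozen=True)
class AgeBinning:
    """Ordered, contiguous age bins in completed years, inclusive bounds."""

    bins: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if not self.bins:
            raise ConfigError("age binning must contain at least one bin")
        prev_hi = None
        for label, lo, hi in self.bins:
            if lo > hi:
                raise ConfigError(f"bin {label!r} has min_age > max_age")
            if prev_hi is not None and lo != prev_hi + 1:
                raise ConfigError("age bins must be ascending and contiguous")
            prev_hi = hi
        if self.bins[0][1] != 0 or self.bins[-1][2] != 18:
            raise ConfigError("age bins must cover 0-18 completed years")

    @property
    def labels(self) -> list[str]:
        return [b[0] for b in self.bins]

    @property
    def min_age(self) -> int:
        return self.bins[0][1]

    @property
    def max_age(self) -> int:
        return self.bins[-1][2]

    def interval(self, label: str) -> tuple[int, int]:
        for lab, lo, hi in self.bins:
            if lab == label:
                return lo, hi
        raise ConfigError(f"unknown age bin label {label!r}")

    def assign(self, age_years: pd.Series) -> pd.Series:
        """Bin label for each completed-years age (NaN outside range)."""
        edges = [self.bins[0][1] - 0.5] + [hi + 0.5 for _, _, hi in self.bins]
        return pd.cut(age_years, bins=edges, labels=self.labels)

    def overlapping(self, age_lo: int, age_hi: int) -> list[str]:
        """Labels of bins whose window intersects [age_lo, age_hi]."""
        return [lab for lab, lo, hi in self.bins if age_lo <= hi and age_hi >= lo]


DEFAULT_AGE_BINS = AgeBinning(
    (("0-2", 0, 2), ("3-5", 3, 5), ("6-11", 6, 11), ("12-18", 12, 18))
)


def completed_years(birth: pd.Series, when: pd.Series) -> pd.Series:
    """Age in completed years at ``when`` for birth dates ``birth``."""
    b, w = pd.to_datetime(birth), pd.to_datetime(when)
    before_anniv = (w.dt.month < b.dt.month.values) | (
        (w.dt.month == b.dt.month.values) & (w.dt.day < b.dt.day.values)
    )
    return w.dt.year - b.dt.year.values - before_anniv.astype(int)


def _normalize_events(events: pd.DataFrame) -> pd.DataFrame:
    ev = events.copy()
    ev["icd9"] = normalize_series(ev["icd9"])
    ev["service_date"] = pd.to_datetime(ev["service_date"])
    return ev


def _check_patients(patients: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split patients into usable and demographics-missing."""
    if patients["patient_id"].duplicated().any():
        raise DataError("duplicate patient_id in demographics table")
    sex_ok = patients["sex"].isin(["F", "M"])
    birth_ok = pd.to_datetime(patients["birth_date"], errors="coerce").notna()
    good = patients[sex_ok & birth_ok].copy()
    bad = patients[~(sex_ok & birth_ok)].copy()
    if len(bad):
        log.info("excluding %d patients with missing sex or birth date", len(bad))
    good["birth_date"] = pd.to_datetime(good["birth_date"])
    return good, bad


@dataclass
class CohortAssignment:
    """Per-patient status (case / control / excluded) with exclusion reason."""

    table: pd.DataFrame = field(repr=False)  # patient_id, status, reason

    @property
    def cases(self) -> pd.Index:
        return self.table.loc[self.table["status"] == "case", "patient_id"]

    @property
    def controls(self) -> pd.Index:
        return self.table.loc[self.table["status"] == "control", "patient_id"]

    def counts(self) -> dict:
        by_status = self.table["status"].value_counts().to_dict()
        by_reason = (
            self.table.loc[self.table["status"] == "excluded", "reason"]
            .value_counts()
            .to_dict()
        )
        return {"status": by_status, "exclusion_reasons": by_reason}


def assign_cohorts(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    case_icd9_set: frozenset[str] | set[str] = ASD_ICD9_CODES,
    min_case_occasions: int = 3,
    min_span_days: int = 366,
    min_age: int = 0,
    max_age: int = 18,
    phecode_map: PhecodeMap | None = None,
) -> CohortAssignment:
    """Apply the case/control inclusion and exclusion criteria.

    A patient is a *case* iff (a) a case-set code appears on at least
    ``min_case_occasions`` distinct service dates, (b) the record span
    (last minus first event date, any code) is at least ``min_span_days``,
    (c) age at the first qualifying code is within [min_age, max_age], and
    (d) at least one phenotype besides the case-defining one is present
    (mapped phecode when ``phecode_map`` is given, otherwise any non-case
    ICD-9 code).  A *control* never carries a case-set code and satisfies
    the span criterion with age at first event in range.  Everyone else is
    *excluded* with a reason tag; in particular patients with 1 to
    ``min_case_occasions - 1`` case-code occasions are neither cases nor
    controls.
    """
    if not case_icd9_set:
        raise ConfigError("case_icd9_set must be non-empty")
    if min_span_days < 0:
        raise ConfigError("min_span_days must be non-negative")
    if len(patients) == 0:
        warnings.warn("empty patient set: empty cohort assignment", stacklevel=2)
        return CohortAssignment(
            pd.DataFrame(columns=["patient_id", "status", "reason"])
        )

    case_codes = {normalize_icd9(c) for c in case_icd9_set}
    good, bad = _check_patients(patients)
    ev = _normalize_events(events)
    unknown = ~ev["patient_id"].isin(patients["patient_id"])
    if unknown.any():
        raise DataError(
            f"{int(unknown.sum())} events reference unknown patient_id "
            f"(e.g. {ev.loc[unknown, 'patient_id'].iloc[0]!r})"
        )
    ev = ev[ev["patient_id"].isin(good["patient_id"])]

    span = ev.groupby("patient_id")["service_date"].agg(["min", "max"])
    span_days = (span["max"] - span["min"]).dt.days

    is_case_code = ev["icd9"].isin(case_codes)
    case_ev = ev[is_case_code]
    case_occ = case_ev.groupby("patient_id")["service_date"].nunique()
    first_case = case_ev.groupby("patient_id")["service_date"].min()

    gi = good.set_index("patient_id")
    age_first_case = completed_years(
        gi.loc[first_case.index, "birth_date"].reset_index(drop=True),
        first_case.reset_index(drop=True),
    )
    age_first_case.index = first_case.index
    first_any = span["min"]
    age_first_any = completed_years(
        gi.loc[first_any.index, "birth_date"].reset_index(drop=True),
        first_any.reset_index(drop=True),
    )
    age_first_any.index = first_any.index

    if phecode_map is not None:
        case_phecodes = {
            phecode_map.map_to_phecode(c) for c in case_codes
        } - {UNMAPPED}
        phe = phecode_map.map_series(ev["icd9"])
        comorbid = ev[(phe != UNMAPPED) & ~phe.isin(case_phecodes)]
    else:
        comorbid = ev[~is_case_code]
    has_comorbid = set(comorbid["patient_id"].unique())

    tab = patients[["patient_id"]].copy()
    tab["known"] = tab["patient_id"].isin(gi.index)
    tab = tab.merge(span_days.rename("span"), left_on="patient_id", right_index=True, how="left")
    tab = tab.merge(case_occ.rename("n_occ"), left_on="patient_id", right_index=True, how="left")
    tab = tab.merge(age_first_case.rename("age_case"), left_on="patient_id", right_index=True, how="left")
    tab = tab.merge(age_first_any.rename("age_any"), left_on="patient_id", right_index=True, how="left")
    tab["n_occ"] = tab["n_occ"].fillna(0).astype(int)
    tab["comorbid"] = tab["patient_id"].isin(has_comorbid)

    span_ok = tab["span"] >= min_span_days
    case_age_ok = tab["age_case"].between(min_age, max_age)
    any_age_ok = tab["age_any"].between(min_age, max_age)
    enough_occ = tab["n_occ"] >= min_case_occasions
    some_occ = tab["n_occ"] > 0

    conditions = [
        ~tab["known"],
        tab["span"].isna(),
        enough_occ & ~span_ok,
        enough_occ & ~case_age_ok,
        enough_occ & ~tab["comorbid"],
        enough_occ,
        some_occ,
        ~span_ok,
        ~any_age_ok,
    ]
    statuses = np.select(
        conditions,
        ["excluded"] * 5 + ["case", "excluded", "excluded", "excluded"],
        default="control",
    )
    reasons = np.select(
        conditions,
        [
            "missing_demographics",
            "no_records",
            "short_record_span",
            "age_out_of_range",
            "no_comorbid_phenotype",
            "",
            "subthreshold_case_codes",
            "short_record_span",
            "age_out_of_range",
        ],
        default="",
    )
    out = pd.DataFrame(
        {"patient_id": tab["patient_id"], "status": statuses, "reason": reasons}
    )
    assert len(out) == len(patients)
    return CohortAssignment(out)


@dataclass
class PhenotypeProfile:
    """(patient, phecode, age bin) presence triples after occasion filters.

    ``triples`` columns: patient_id, phecode, age_bin, n_occasions (distinct
    service dates within the bin), n_occasions_total (across bins).
    """

    triples: pd.DataFrame = field(repr=False)
    occasion_scope: str = "overall"
    n_unmapped_events: int = 0


def build_profiles(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    phecode_map: PhecodeMap,
    bins: AgeBinning = DEFAULT_AGE_BINS,
    min_comorbid_occasions: int = 3,
    occasion_scope: str = "overall",
) -> PhenotypeProfile:
    """Roll events up to phecodes and build per-age-bin presence triples.

    Occasions are distinct service dates per (patient, phecode).  With
    ``occasion_scope="overall"`` (default) a phecode is retained for a
    patient when its total distinct-date count reaches the threshold, and
    a triple is emitted for every bin holding at least one occurrence;
    with ``"per_bin"`` the threshold applies within each bin separately.
    """
    if occasion_scope not in ("overall", "per_bin"):
        raise ConfigError(f"unknown occasion_scope {occasion_scope!r}")
    if min_comorbid_occasions < 1:
        raise ConfigError("min_comorbid_occasions must be >= 1")
    good, _ = _check_patients(patients)
    ev = _normalize_events(events)
    ev = ev.merge(good[["patient_id", "birth_date"]], on="patient_id", how="inner")
    early = ev["service_date"] < ev["birth_date"]
    if early.any():
        bad = ev[early].iloc[0]
        raise DataError(
            f"event before birth date: patient {bad['patient_id']!r}, "
            f"code {bad['icd9']} on {bad['service_date'].date()}"
        )
    ev["age"] = completed_years(ev["birth_date"], ev["service_date"])
    ev["phecode"] = phecode_map.map_series(ev["icd9"])
    n_unmapped = int((ev["phecode"] == UNMAPPED).sum())
    if n_unmapped:
        log.info("profiles: dropping %d events with unmapped ICD-9 codes", n_unmapped)
    ev = ev[ev["phecode"] != UNMAPPED]
    ev["age_bin"] = bins.assign(ev["age"])
    ev = ev.dropna(subset=["age_bin"])

    occ = ev.drop_duplicates(subset=["patient_id", "phecode", "service_date"])
    total = occ.groupby(["patient_id", "phecode"], observed=True).size()
    per_bin = (
        ev.drop_duplicates(subset=["patient_id", "phecode", "age_bin", "service_date"])
        .groupby(["patient_id", "phecode", "age_bin"], observed=True)
        .size()
        .rename("n_occasions")
        .reset_index()
    )
    per_bin = per_bin.merge(
        total.rename("n_occasions_total").reset_index(), on=["patient_id", "phecode"]
    )
    if occasion_scope == "overall":
        keep = per_bin["n_occasions_total"] >= min_comorbid_occasions
    else:
        keep = per_bin["n_occasions"] >= min_comorbid_occasions
    triples = per_bin[keep].reset_index(drop=True)
    triples["age_bin"] = triples["age_bin"].astype(str)
    return PhenotypeProfile(triples, occasion_scope, n_unmapped)


def bin_population(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    bins: AgeBinning = DEFAULT_AGE_BINS,
    assignment: CohortAssignment | None = None,
    mode: str = "span_overlap",
) -> pd.DataFrame:
    """Per-bin denominators: patient counts by cohort status and sex.

    With ``mode="span_overlap"`` (default) a patient counts toward a bin
    when their record span — first to last event, in completed years —
    overlaps the bin's age window; ``mode="all"`` counts every cohort
    member in every bin.  Returns a frame with columns age_bin, status,
    sex, n.
    """
    if mode not in ("span_overlap", "all"):
        raise ConfigError(f"unknown denominator mode {mode!r}")
    good, _ = _check_patients(patients)
    ev = _normalize_events(events)
    ev = ev.merge(good[["patient_id", "birth_date"]], on="patient_id", how="inner")
    ev["age"] = completed_years(ev["birth_date"], ev["service_date"])
    ages = ev.groupby("patient_id")["age"].agg(["min", "max"])

    pat = good[["patient_id", "sex"]].merge(ages, on="patient_id", how="left")
    if assignment is not None:
        pat = pat.merge(assignment.table[["patient_id", "status"]], on="patient_id")
        pat = pat[pat["status"].isin(["case", "control"])]
    else:
        pat = pat.assign(status="all")

    rows = []
    for lab, lo, hi in bins.bins:
        if mode == "all":
            sub = pat
        else:
            sub = pat[(pat["min"] <= hi) & (pat["max"] >= lo)]
        counts = sub.groupby(["status", "sex"]).size()
        for (status, sex), n in counts.items():
            rows.append((lab, status, sex, int(n)))
    return pd.DataFrame(rows, columns=["age_bin", "status", "sex", "n"])
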