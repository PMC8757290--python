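"""Synthetic longitudinal claims generator with ground-truth manifest.

Emulates the statistical structure the intersection analysis assumes:

* a sex-imbalanced case population (default 4:1 male:female among ASD
  cases) over four groups (case/control x F/M),
* per-phecode, per-age-bin carrier prevalences, with planted effects
  specified as odds multipliers so every contrast's true odds ratio is
  known analytically,
* carriers coded on >= 3 distinct service dates versus sub-threshold
  noise codes on 1-2 dates,
* record spans that straddle the 12-month inclusion rule, plus case
  patients with only 1-2 ASD code occasions (excluded by design).

Two planted-effect kinds matter for the intersection: ``asd_female``
multiplies carrier odds in females with ASD only (the signal the
pipeline should retain), while ``female_general`` multiplies odds in all
females, with or without ASD.  A phecode planted with *both* kinds is
significant in all three contrasts and must be removed specifically by
the control-comparison exclusion step.

Implementation notes.  Birth dates are pinned to January 1 and event
dates expressed as (completed-years age, day-of-year <= 364), so an
event's completed-years age is exact by construction.  Each occasion
index draws its day within a disjoint 50-day slot, which guarantees
distinct service dates without rejection sampling.  The ground-truth
manifest is rebuilt from the emitted tables by direct counting — a
deliberately plain implementation, independent of the cohort module.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import AgeBinning, ConfigError, DEFAULT_AGE_BINS

__all__ = [
    "PlantedEffect",
    "GeneratorConfig",
    "SyntheticDataset",
    "GroundTruthManifest",
    "generate",
    "write_dataset",
    "verify_manifest",
]

log = logging.getLogger(__name__)

GROUPS = ("case_F", "case_M", "control_F", "control_M")

ASD_CODES = ("299.00", "299.01", "299.80", "299.81", "299.90", "299.91")


@dataclass(frozen=True)
class PlantedEffect:
    """Odds multiplier for one phecode in selected age bins.

    ``kind`` is ``"asd_female"`` (odds multiplied in females with ASD
    only) or ``"female_general"`` (odds multiplied in all females).
    ``bins`` is a tuple of bin labels, or None for every bin.
    """

    phecode: str
    odds_ratio: float
    kind: str = "asd_female"
    bins: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ConfigError("planted odds_ratio must be > 0")
        if self.kind not in ("asd_female", "female_general"):
            raise ConfigError(f"unknown planted-effect kind {self.kind!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic claims generator."""

    seed: int
    n_patients: int = 8000
    case_prevalence: float = 0.25
    male_fraction_of_cases: float = 0.8
    female_fraction_of_controls: float = 0.5
    n_phecodes: int = 100
    n_categories: int = 5
    baseline_prevalence: float = 0.05
    planted_effects: tuple[PlantedEffect, ...] = ()
    carrier_occasions: tuple[int, int] = (3, 5)
    noise_rate: float = 0.02
    short_span_fraction: float = 0.05
    subthreshold_case_fraction: float = 0.05
    min_window_years: int = 2
    max_window_years: int = 4
    age_bins: AgeBinning = DEFAULT_AGE_BINS

    def __post_init__(self) -> None:
        for name in ("case_prevalence", "male_fraction_of_cases",
                     "female_fraction_of_controls", "baseline_prevalence",
                     "noise_rate", "short_span_fraction",
                     "subthreshold_case_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_patients < 1 or self.n_phecodes < 1:
            raise ConfigError("n_patients and n_phecodes must be >= 1")
        lo, hi = self.carrier_occasions
        if not (3 <= lo <= hi <= 7):
            raise ConfigError("carrier_occasions must satisfy 3 <= lo <= hi <= 7")
        vocab = set(self.phecodes)
        for eff in self.planted_effects:
            if eff.phecode not in vocab:
                raise ConfigError(f"planted phecode {eff.phecode!r} not in vocabulary")
            for lab in eff.bins or ():
                self.age_bins.interval(lab)

    @property
    def phecodes(self) -> list[str]:
        return [str(300 + j) for j in range(self.n_phecodes)]

    def map_frame(self) -> pd.DataFrame:
        """ICD-9 -> phecode mapping table; two ICD-9 codes per phecode."""
        rows = []
        for j, code in enumerate(self.phecodes):
            for suffix in ("0", "1"):
                rows.append(
                    (f"{code}.{suffix}", code, f"Synthetic phenotype {code}",
                     f"category{j % self.n_categories}")
                )
        for icd in ASD_CODES:
            rows.append((icd, "299", "Autism spectrum disorder", "mental disorders"))
        return pd.DataFrame(rows, columns=["icd9", "phecode", "phenotype", "category"])

    def odds_multipliers(self) -> np.ndarray:
        """(n_bins, n_groups, n_phecodes) array of planted odds multipliers."""
        labels = self.age_bins.labels
        code_ix = {c: j for j, c in enumerate(self.phecodes)}
        m = np.ones((len(labels), len(GROUPS), self.n_phecodes))
        for eff in self.planted_effects:
            bins = eff.bins if eff.bins is not None else tuple(labels)
            j = code_ix[eff.phecode]
            targets = ["case_F"] if eff.kind == "asd_female" else ["case_F", "control_F"]
            for lab in bins:
                b = labels.index(lab)
                for g in targets:
                    m[b, GROUPS.index(g), j] *= eff.odds_ratio
        return m

    def expected_sets(self) -> dict:
        """Analytically expected significant/retained sets per bin.

        A phecode is expected significant in a contrast when its planted
        odds multiplier ratio between the two groups exceeds 1.
        """
        m = self.odds_multipliers()
        labels = self.age_bins.labels
        g = {name: GROUPS.index(name) for name in GROUPS}
        out = {}
        for b, lab in enumerate(labels):
            ratio_a = m[b, g["case_F"]] / m[b, g["case_M"]]
            ratio_b = m[b, g["case_F"]] / m[b, g["control_F"]]
            ratio_e = m[b, g["control_F"]] / m[b, g["control_M"]]
            sig_a = {self.phecodes[j] for j in np.flatnonzero(ratio_a > 1)}
            sig_b = {self.phecodes[j] for j in np.flatnonzero(ratio_b > 1)}
            sig_e = {self.phecodes[j] for j in np.flatnonzero(ratio_e > 1)}
            out[lab] = {
                "sig_case_F_vs_case_M": sorted(sig_a),
                "sig_case_F_vs_ctrl_F": sorted(sig_b),
                "sig_ctrl_F_vs_ctrl_M": sorted(sig_e),
                "retained": sorted((sig_a & sig_b) - sig_e),
                "removed_by_exclusion": sorted((sig_a & sig_b) & sig_e),
            }
        return out


@dataclass
class GroundTruthManifest:
    """Ground truth rebuilt from the emitted tables by direct counting."""

    statuses: pd.DataFrame = field(repr=False)       # patient_id, status, sex, group
    triples_overall: pd.DataFrame = field(repr=False)
    triples_per_bin: pd.DataFrame = field(repr=False)
    denominators: pd.DataFrame = field(repr=False)   # age_bin, status, sex, n
    carrier_counts: pd.DataFrame = field(repr=False) # age_bin, group, phecode, n_carriers, n_at_risk
    expected: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "statuses": self.statuses.to_dict(orient="list"),
            "triples_overall": self.triples_overall.to_dict(orient="list"),
            "triples_per_bin": self.triples_per_bin.to_dict(orient="list"),
            "denominators": self.denominators.to_dict(orient="list"),
            "carrier_counts": self.carrier_counts.to_dict(orient="list"),
            "expected": self.expected,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    patients: pd.DataFrame = field(repr=False)
    events: pd.DataFrame = field(repr=False)
    phecode_map: pd.DataFrame = field(repr=False)
    manifest: GroundTruthManifest = field(repr=False, default=None)


def _ranges(k: np.ndarray) -> np.ndarray:
    """Concatenated [0..k_i) ranges, vectorized."""
    if k.size == 0:
        return np.array([], dtype=int)
    ends = np.cumsum(k)
    return np.arange(int(ends[-1])) - np.repeat(ends - k, k)


def _dates_from_parts(birth_year: np.ndarray, age: np.ndarray, day: np.ndarray) -> np.ndarray:
    """Service date = Jan 1 of (birth_year + age) plus day-of-year offset."""
    years = (birth_year + age).astype("int64")
    jan1 = (years - 1970).astype("datetime64[Y]").astype("datetime64[D]")
    return jan1 + day.astype("timedelta64[D]")


def generate(config: GeneratorConfig, with_manifest: bool = True) -> SyntheticDataset:
    """Draw patients, diagnosis events and the mapping table.

    Deterministic for a fixed config (single seeded generator, fixed draw
    order).  Returns the dataset with its ground-truth manifest attached;
    ``with_manifest=False`` skips the (relatively costly) direct recount
    and leaves only statuses/denominators implicit in ``carrier_counts``
    and the analytically expected sets.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    bins = config.age_bins
    labels = bins.labels

    # --- group assignment with exact arm sizes
    n_cases = int(round(n * config.case_prevalence))
    n_case_f = int(round(n_cases * (1.0 - config.male_fraction_of_cases)))
    n_ctrl = n - n_cases
    n_ctrl_f = int(round(n_ctrl * config.female_fraction_of_controls))
    group = np.concatenate([
        np.full(n_case_f, 0), np.full(n_cases - n_case_f, 1),
        np.full(n_ctrl_f, 2), np.full(n_ctrl - n_ctrl_f, 3),
    ])
    rng.shuffle(group)
    is_case = group < 2
    sex = np.where((group == 0) | (group == 2), "F", "M")

    patient_id = np.array([f"P{i:06d}" for i in range(n)])
    birth_year = rng.integers(1996, 2004, size=n)

    # --- observation windows in whole completed-years ages
    short = rng.random(n) < config.short_span_fraction
    start = rng.integers(0, 19 - config.min_window_years, size=n)
    length = rng.integers(config.min_window_years, config.max_window_years + 1, size=n)
    end = np.minimum(start + length, 18)
    start = np.where(short, rng.integers(0, 19, size=n), start)
    end = np.where(short, start, end)

    ev_pid, ev_age, ev_day, ev_icd = [], [], [], []

    def emit(pids, ages, days, codes):
        ev_pid.append(pids)
        ev_age.append(ages)
        ev_day.append(days)
        ev_icd.append(codes)

    # --- anchor wellness visits pin the record span to the window
    emit(np.arange(n), start, rng.integers(0, 51, size=n), np.full(n, "V70.0"))
    emit(np.arange(n), end, rng.integers(300, 365, size=n), np.full(n, "V70.0"))

    # --- ASD diagnosis occasions for cases (1-2 for sub-threshold probes)
    case_ix = np.flatnonzero(is_case)
    probe = rng.random(case_ix.size) < config.subthreshold_case_fraction
    k_asd = np.where(probe, rng.integers(1, 3, case_ix.size),
                     rng.integers(3, 7, case_ix.size))
    rep = np.repeat(case_ix, k_asd)
    occ = _ranges(k_asd)
    span_years = end[rep] - start[rep] + 1
    asd_age = start[rep] + rng.integers(0, 10**9, rep.size) % span_years
    asd_day = occ * 50 + rng.integers(0, 50, rep.size)
    emit(rep, asd_age, asd_day,
         np.array(ASD_CODES)[rng.integers(0, len(ASD_CODES), rep.size)])

    # --- per-bin carrier draws with planted odds multipliers
    o0 = config.baseline_prevalence / (1.0 - config.baseline_prevalence)
    mult = config.odds_multipliers()
    prev = mult * o0 / (1.0 + mult * o0)  # (n_bins, n_groups, n_phecodes)
    codes = np.array(config.phecodes)
    icd_variants = np.array(
        [f"{c}.{s}" for c in config.phecodes for s in ("0", "1")]
    )
    carrier_any = np.zeros((n, config.n_phecodes), dtype=bool)
    carrier_counts_rows = []
    k_lo, k_hi = config.carrier_occasions

    for b, (lab, lo, hi) in enumerate(bins.bins):
        at_risk = np.flatnonzero((start <= hi) & (end >= lo))
        if at_risk.size == 0:
            continue
        p_rows = prev[b][group[at_risk]]  # (n_at_risk, n_phecodes)
        hit = rng.random(p_rows.shape) < p_rows
        pi, ci = np.nonzero(hit)
        pat = at_risk[pi]
        carrier_any[pat, ci] = True
        for g in range(len(GROUPS)):
            g_at_risk = group[at_risk] == g
            n_at = int(g_at_risk.sum())
            by_code = np.bincount(ci[g_at_risk[pi]], minlength=config.n_phecodes)
            for j in range(config.n_phecodes):
                carrier_counts_rows.append(
                    (lab, GROUPS[g], codes[j], int(by_code[j]), n_at)
                )
        # occasion dates within the bin window clipped to the patient window
        k = rng.integers(k_lo, k_hi + 1, size=pat.size)
        rep_p = np.repeat(pat, k)
        rep_c = np.repeat(ci, k)
        occ = _ranges(k)
        y_lo = np.maximum(start[rep_p], lo)
        y_hi = np.minimum(end[rep_p], hi)
        age = y_lo + rng.integers(0, 10**9, rep_p.size) % (y_hi - y_lo + 1)
        day = occ * 50 + rng.integers(0, 50, rep_p.size)
        variant = rng.integers(0, 2, rep_p.size)
        emit(rep_p, age, day, icd_variants[rep_c * 2 + variant])

    # --- sub-threshold noise: 1-2 dates, only on never-carrier pairs
    noise = (rng.random((n, config.n_phecodes)) < config.noise_rate) & ~carrier_any
    pi, ci = np.nonzero(noise)
    if pi.size:
        k = rng.integers(1, 3, size=pi.size)
        rep_p = np.repeat(pi, k)
        rep_c = np.repeat(ci, k)
        occ = _ranges(k)
        span_years = end[rep_p] - start[rep_p] + 1
        age = start[rep_p] + rng.integers(0, 10**9, rep_p.size) % span_years
        day = occ * 50 + rng.integers(0, 50, rep_p.size)
        variant = rng.integers(0, 2, rep_p.size)
        emit(rep_p, age, day, icd_variants[rep_c * 2 + variant])

    pid_ix = np.concatenate(ev_pid)
    age = np.concatenate(ev_age)
    day = np.concatenate(ev_day)
    icd = np.concatenate(ev_icd)
    dates = _dates_from_parts(birth_year[pid_ix], age, day)
    order = rng.permutation(pid_ix.size)
    events = pd.DataFrame(
        {
            "patient_id": patient_id[pid_ix[order]],
            "icd9": icd[order],
            "service_date": dates[order],
        }
    )
    patients = pd.DataFrame(
        {
            "patient_id": patient_id,
            "sex": sex,
            "birth_date": _dates_from_parts(birth_year, np.zeros(n, int), np.zeros(n, int)),
        }
    )
    carrier_counts = pd.DataFrame(
        carrier_counts_rows,
        columns=["age_bin", "group", "phecode", "n_carriers", "n_at_risk"],
    )
    ds = SyntheticDataset(config, patients, events, config.map_frame())
    if with_manifest:
        ds.manifest = build_manifest(ds, carrier_counts)
    else:
        ds.manifest = GroundTruthManifest(
            statuses=pd.DataFrame(), triples_overall=pd.DataFrame(),
            triples_per_bin=pd.DataFrame(), denominators=pd.DataFrame(),
            carrier_counts=carrier_counts, expected=config.expected_sets(),
        )
    return ds


def build_manifest(
    ds: SyntheticDataset, carrier_counts: pd.DataFrame | None = None
) -> GroundTruthManifest:
    """Rebuild the ground truth from the emitted tables by direct counting.

    Plain pandas throughout, sharing no code with the cohort module, so
    that pipeline outputs can be checked against an independent count.
    """
    cfg = ds.config
    lookup = dict(zip(ds.phecode_map["icd9"], ds.phecode_map["phecode"]))
    ev = ds.events.merge(
        ds.patients[["patient_id", "birth_date"]], on="patient_id"
    )
    sd, bd = ev["service_date"], ev["birth_date"]
    before = (sd.dt.month < bd.dt.month.values) | (
        (sd.dt.month == bd.dt.month.values) & (sd.dt.day < bd.dt.day.values)
    )
    ev["age"] = sd.dt.year - bd.dt.year.values - before.astype(int)
    ev["phecode"] = ev["icd9"].map(lookup)

    # cohort statuses
    asd = ev[ev["icd9"].isin(ASD_CODES)]
    n_asd = asd.groupby("patient_id")["service_date"].nunique()
    first_asd_age = asd.groupby("patient_id")["age"].min()
    span = ev.groupby("patient_id")["service_date"].agg(["min", "max"])
    span_days = (span["max"] - span["min"]).dt.days
    first_age = ev.groupby("patient_id")["age"].min()
    comorbid = ev[ev["phecode"].notna() & (ev["phecode"] != "299")]
    has_comorbid = set(comorbid["patient_id"])

    statuses = ds.patients[["patient_id", "sex"]].copy()
    t = (
        statuses.merge(n_asd.rename("n_asd"), on="patient_id", how="left")
        .merge(span_days.rename("span"), on="patient_id", how="left")
        .merge(first_asd_age.rename("asd_age"), on="patient_id", how="left")
        .merge(first_age.rename("first_age"), on="patient_id", how="left")
    )
    t["n_asd"] = t["n_asd"].fillna(0)
    t["span"] = t["span"].fillna(-1)
    t["comorbid"] = t["patient_id"].isin(has_comorbid)
    full_case = (
        (t["n_asd"] >= 3) & (t["span"] >= 366)
        & t["asd_age"].between(0, 18) & t["comorbid"]
    )
    clean_ctrl = (
        (t["n_asd"] == 0) & (t["span"] >= 366) & t["first_age"].between(0, 18)
    )
    statuses["status"] = np.select(
        [full_case, clean_ctrl], ["case", "control"], default="excluded"
    )
    statuses["group"] = np.where(
        statuses["status"] == "excluded",
        "excluded",
        np.where(statuses["status"] == "case", "case_", "control_")
        + statuses["sex"],
    )

    # presence triples under both occasion scopes
    phe = ev.dropna(subset=["phecode"])
    phe = phe[(phe["age"] >= 0) & (phe["age"] <= 18)].copy()
    edges = [cfg.age_bins.bins[0][1] - 0.5] + [h + 0.5 for _, _, h in cfg.age_bins.bins]
    phe["age_bin"] = pd.cut(phe["age"], bins=edges, labels=cfg.age_bins.labels)
    occ = phe.drop_duplicates(["patient_id", "phecode", "service_date"])
    total = occ.groupby(["patient_id", "phecode"])["service_date"].nunique()
    per_bin = (
        phe.drop_duplicates(["patient_id", "phecode", "age_bin", "service_date"])
        .groupby(["patient_id", "phecode", "age_bin"], observed=True)["service_date"]
        .nunique()
        .rename("n_occ")
        .reset_index()
    )
    per_bin = per_bin.merge(
        total.rename("n_total").reset_index(), on=["patient_id", "phecode"]
    )
    per_bin["age_bin"] = per_bin["age_bin"].astype(str)
    t_overall = per_bin[per_bin["n_total"] >= 3][
        ["patient_id", "phecode", "age_bin"]
    ].reset_index(drop=True)
    t_per_bin = per_bin[per_bin["n_occ"] >= 3][
        ["patient_id", "phecode", "age_bin"]
    ].reset_index(drop=True)

    # per-bin denominators by record-span overlap among cases/controls
    ages = ev.groupby("patient_id")["age"].agg(["min", "max"])
    pat = statuses.merge(ages, on="patient_id")
    pat = pat[pat["status"].isin(["case", "control"])]
    den = []
    for lab, lo, hi in cfg.age_bins.bins:
        sub = pat[(pat["min"] <= hi) & (pat["max"] >= lo)]
        for (st, sx), cnt in sub.groupby(["status", "sex"]).size().items():
            den.append((lab, st, sx, int(cnt)))
    denominators = pd.DataFrame(den, columns=["age_bin", "status", "sex", "n"])

    if carrier_counts is None:
        carrier_counts = pd.DataFrame(
            columns=["age_bin", "group", "phecode", "n_carriers", "n_at_risk"]
        )
    return GroundTruthManifest(
        statuses=statuses,
        triples_overall=t_overall,
        triples_per_bin=t_per_bin,
        denominators=denominators,
        carrier_counts=carrier_counts,
        expected=cfg.expected_sets(),
    )


def verify_manifest(ds: SyntheticDataset) -> dict:
    """Recount the ground truth from the emitted tables and diff it.

    Returns ``{"n_mismatches": int, "mismatches": [description, ...]}``;
    any tampering with the event file shows up as a mismatch.
    """
    fresh = build_manifest(ds, ds.manifest.carrier_counts)
    report = {"n_mismatches": 0, "mismatches": []}

    def compare(name, left: pd.DataFrame, right: pd.DataFrame, keys):
        l = set(map(tuple, left[keys].itertuples(index=False)))
        r = set(map(tuple, right[keys].itertuples(index=False)))
        for item in sorted(l ^ r):
            report["mismatches"].append(f"{name}: {item}")

    compare("status", fresh.statuses, ds.manifest.statuses,
            ["patient_id", "status"])
    compare("triple_overall", fresh.triples_overall, ds.manifest.triples_overall,
            ["patient_id", "phecode", "age_bin"])
    compare("triple_per_bin", fresh.triples_per_bin, ds.manifest.triples_per_bin,
            ["patient_id", "phecode", "age_bin"])
    compare("denominator", fresh.denominators, ds.manifest.denominators,
            ["age_bin", "status", "sex", "n"])
    report["n_mismatches"] = len(report["mismatches"])
    return report


def write_dataset(ds: SyntheticDataset, out_dir) -> dict:
    """Write patients/events/map CSVs and the manifest JSON; return paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": out / "patients.csv",
        "events": out / "events.csv",
        "map": out / "phecode_map.csv",
        "manifest": out / "manifest.json",
    }
    pat = ds.patients.copy()
    pat["birth_date"] = pat["birth_date"].dt.strftime("%Y-%m-%d")
    pat.to_csv(paths["patients"], index=False)
    ev = ds.events.copy()
    ev["service_date"] = ev["service_date"].astype("datetime64[s]").dt.strftime("%Y-%m-%d")
    ev.to_csv(paths["events"], index=False)
    ds.phecode_map.to_csv(paths["map"], index=False)
    ds.manifest.to_json(paths["manifest"])
    return {k: str(v) for k, v in paths.items()}
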