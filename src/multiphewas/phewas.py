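"""Age-stratified PheWAS contrasts and the multi-PheWAS intersection.

The method runs three phenome-wide case/control contrasts per age bin —

* ``case_F_vs_case_M``   females with ASD vs males with ASD,
* ``case_F_vs_ctrl_F``   females with ASD vs females without ASD,
* ``ctrl_F_vs_ctrl_M``   females vs males in the general (non-ASD) population,

each testing every phecode with a Fisher exact test on the 2x2 table of
carriers/non-carriers by group.  A phecode is *retained* in a bin when it
is significant (Bonferroni-corrected p < alpha, OR above the effect-size
cutoff) in both of the first two contrasts and not significant in the
third: phenotypes that are simply more common in females regardless of
ASD are thereby excluded, leaving phenotypes enriched specifically in
females with ASD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import AgeBinning, ConfigError, DEFAULT_AGE_BINS, PhenotypeProfile
from .exact import bonferroni_threshold, fisher_exact

__all__ = [
    "ComparisonSpec",
    "CASE_F_VS_CASE_M",
    "CASE_F_VS_CTRL_F",
    "CTRL_F_VS_CTRL_M",
    "IntersectionResult",
    "run_phewas",
    "intersect",
    "cutoff_sweep",
    "AlignmentError",
]

log = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "comparison", "age_bin", "phecode", "a", "b", "c", "d",
    "odds_ratio", "ci_low", "ci_high", "p", "n_tests", "p_threshold",
    "significant", "protective",
]


class AlignmentError(ValueError):
    """Raised when PheWAS result sets disagree on their age bins."""


@dataclass(frozen=True)
class ComparisonSpec:
    """One contrast: group selectors are (cohort status, sex) pairs."""

    name: str
    group1: tuple[str, str]
    group2: tuple[str, str]

    def __post_init__(self) -> None:
        if self.group1 == self.group2:
            raise ConfigError(f"contrast {self.name!r}: groups must be disjoint")


CASE_F_VS_CASE_M = ComparisonSpec("case_F_vs_case_M", ("case", "F"), ("case", "M"))
CASE_F_VS_CTRL_F = ComparisonSpec("case_F_vs_ctrl_F", ("case", "F"), ("control", "F"))
CTRL_F_VS_CTRL_M = ComparisonSpec("ctrl_F_vs_ctrl_M", ("control", "F"), ("control", "M"))


def _or_passes(odds_ratio: float, ci_low: float, cutoff: float) -> bool:
    # infinite estimates pass only on the strength of their lower CI bound
    if np.isnan(odds_ratio):
        return False
    if np.isinf(odds_ratio):
        return ci_low > 1.0
    return odds_ratio > cutoff


def _or_protective(odds_ratio: float, ci_high: float, cutoff: float) -> bool:
    if np.isnan(odds_ratio):
        return False
    if odds_ratio == 0.0:
        return ci_high < 1.0
    return odds_ratio < 1.0 / cutoff


def run_phewas(
    profile: PhenotypeProfile,
    denominators: pd.DataFrame,
    cohort: pd.DataFrame,
    spec: ComparisonSpec,
    bins: AgeBinning = DEFAULT_AGE_BINS,
    alpha: float = 0.01,
    or_cutoff: float = 1.5,
    bonferroni_mode: str = "per_bin",
    n_vocabulary: int | None = None,
    suppress_phecodes: frozenset[str] | set[str] = frozenset(),
    or_kind: str = "conditional",
) -> pd.DataFrame:
    """Run one phenome-wide contrast across all age bins.

    Parameters
    ----------
    profile
        Presence triples from :func:`multiphewas.cohort.build_profiles`.
    denominators
        Per-bin patient counts by status and sex from
        :func:`multiphewas.cohort.bin_population`.
    cohort
        Frame with columns patient_id, status, sex for cohort members.
    spec
        The contrast to run.
    bonferroni_mode
        ``"per_bin"`` divides alpha by the number of phecodes actually
        tested within the bin; ``"global"`` divides by ``n_vocabulary``.
    suppress_phecodes
        Phecodes derived from the case-defining ICD-9 codes; they are
        significant by construction and are removed from every contrast.

    Returns
    -------
    DataFrame
        One row per (phecode with at least one carrier, age bin) with the
        2x2 counts, exact-test results, the Bonferroni threshold used and
        the significance flag (p < threshold and OR above cutoff, with
        infinite ORs admitted only when the lower CI bound exceeds 1).
    """
    if bonferroni_mode not in ("per_bin", "global"):
        raise ConfigError(f"unknown bonferroni_mode {bonferroni_mode!r}")
    if bonferroni_mode == "global" and not n_vocabulary:
        raise ConfigError("global bonferroni_mode requires n_vocabulary")

    members = {}
    for tag, (status, sex) in (("g1", spec.group1), ("g2", spec.group2)):
        sel = cohort[(cohort["status"] == status) & (cohort["sex"] == sex)]
        members[tag] = pd.Index(sel["patient_id"].unique())
    if len(members["g1"].intersection(members["g2"])):
        raise ConfigError(f"contrast {spec.name!r}: groups overlap")

    den = denominators.set_index(["age_bin", "status", "sex"])["n"]
    triples = profile.triples[~profile.triples["phecode"].isin(suppress_phecodes)]
    tag = pd.Series("", index=cohort.index)
    for name, (status, sex) in (("g1", spec.group1), ("g2", spec.group2)):
        tag[(cohort["status"] == status) & (cohort["sex"] == sex)] = name
    grp_of = dict(zip(cohort["patient_id"], tag))
    t = triples.assign(_grp=triples["patient_id"].map(grp_of))
    t = t[t["_grp"].isin(["g1", "g2"])]
    # triples are unique per (patient, phecode, bin), so size == carrier count
    carriers = (
        t.groupby(["age_bin", "_grp", "phecode"], observed=True)
        .size()
        .unstack("_grp", fill_value=0)
    )
    rows = []
    for lab in bins.labels:
        n1 = int(den.get((lab, *spec.group1), 0))
        n2 = int(den.get((lab, *spec.group2), 0))
        if n1 == 0 or n2 == 0:
            warnings.warn(
                f"contrast {spec.name}, bin {lab}: empty group, tests skipped",
                stacklevel=2,
            )
            continue
        if lab in carriers.index.get_level_values(0):
            sub = carriers.loc[lab]
            carr1 = sub["g1"] if "g1" in sub.columns else pd.Series(0, index=sub.index)
            carr2 = sub["g2"] if "g2" in sub.columns else pd.Series(0, index=sub.index)
        else:
            carr1 = carr2 = pd.Series(dtype=int)
        tested = sorted(set(carr1.index) | set(carr2.index))
        if not tested:
            continue
        n_tests = len(tested) if bonferroni_mode == "per_bin" else int(n_vocabulary)
        thr = bonferroni_threshold(alpha, n_tests)
        for code in tested:
            a = int(carr1.get(code, 0))
            c = int(carr2.get(code, 0))
            b, d = n1 - a, n2 - c
            if b < 0 or d < 0:
                raise ValueError(
                    f"carrier count exceeds denominator for {code} in bin {lab}"
                )
            res = fisher_exact(a, b, c, d, or_kind=or_kind)
            sig = res.p_value < thr and _or_passes(res.odds_ratio, res.ci_low, or_cutoff)
            prot = res.p_value < thr and _or_protective(res.odds_ratio, res.ci_high, or_cutoff)
            rows.append(
                (spec.name, lab, code, a, b, c, d,
                 res.odds_ratio, res.ci_low, res.ci_high, res.p_value,
                 n_tests, thr, sig, prot)
            )
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    log.info(
        "contrast %s: %d tests, %d significant",
        spec.name, len(out), int(out["significant"].sum()) if len(out) else 0,
    )
    return out


@dataclass
class IntersectionResult:
    """Per-bin retained phecodes with both target contrasts' estimates.

    ``table`` columns: age_bin, phecode, then the female-vs-male OR, CI
    and p (``*_fvsm``) and the ASD-vs-non-ASD equivalents
    (``*_asdvsnon``).
    """

    table: pd.DataFrame = field(repr=False)
    bins: tuple[str, ...] = ()

    def retained(self, age_bin: str) -> set[str]:
        t = self.table
        return set(t.loc[t["age_bin"] == age_bin, "phecode"])

    def retained_by_bin(self) -> dict[str, set[str]]:
        return {b: self.retained(b) for b in self.bins}


def _sig_sets(results: pd.DataFrame, or_cutoff: float | None = None) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    if len(results) == 0:
        return out
    if or_cutoff is None:
        sig = results[results["significant"]]
    else:
        passes = results.apply(
            lambda r: r["p"] < r["p_threshold"]
            and _or_passes(r["odds_ratio"], r["ci_low"], or_cutoff),
            axis=1,
        )
        sig = results[passes]
    for lab, grp in sig.groupby("age_bin"):
        out[lab] = set(grp["phecode"])
    return out


def _check_alignment(res_a, res_b, res_exclusion) -> None:
    bins_a = set(res_a["age_bin"].unique()) if len(res_a) else set()
    bins_b = set(res_b["age_bin"].unique()) if len(res_b) else set()
    if bins_a != bins_b:
        raise AlignmentError(
            f"target contrasts tested different age bins: {sorted(bins_a)} vs {sorted(bins_b)}"
        )
    if len(res_exclusion):
        bins_e = set(res_exclusion["age_bin"].unique())
        if not bins_e <= bins_a:
            raise AlignmentError(
                f"exclusion contrast covers unknown age bins: {sorted(bins_e - bins_a)}"
            )


def intersect(
    res_a: pd.DataFrame,
    res_b: pd.DataFrame,
    res_exclusion: pd.DataFrame,
    bins: AgeBinning = DEFAULT_AGE_BINS,
    exclusion_mode: str = "per_bin",
    or_cutoff: float | None = None,
) -> IntersectionResult:
    """Intersect the two target contrasts and remove the exclusion set.

    Per age bin, retained = {significant in A} ∩ {significant in B}
    \\ {significant in the exclusion contrast}.  With
    ``exclusion_mode="global"`` a phecode significant in the exclusion
    contrast in *any* bin is removed from every bin.  When ``or_cutoff``
    is given, significance is re-derived from the stored p-values and
    thresholds with that OR cutoff instead of the stored flags.
    """
    if exclusion_mode not in ("per_bin", "global"):
        raise ConfigError(f"unknown exclusion_mode {exclusion_mode!r}")
    _check_alignment(res_a, res_b, res_exclusion)
    sig_a = _sig_sets(res_a, or_cutoff)
    sig_b = _sig_sets(res_b, or_cutoff)
    sig_e = _sig_sets(res_exclusion, or_cutoff)
    global_excl = set().union(*sig_e.values()) if sig_e else set()

    idx_a = res_a.set_index(["age_bin", "phecode"]) if len(res_a) else None
    idx_b = res_b.set_index(["age_bin", "phecode"]) if len(res_b) else None
    rows = []
    labels = [b for b in bins.labels if b in sig_a or b in sig_b]
    for lab in labels:
        excl = global_excl if exclusion_mode == "global" else sig_e.get(lab, set())
        kept = (sig_a.get(lab, set()) & sig_b.get(lab, set())) - excl
        # invariants of the intersection-minus-exclusion construction
        assert kept <= sig_a.get(lab, set()) and kept <= sig_b.get(lab, set())
        assert not kept & (sig_e.get(lab, set()) if exclusion_mode == "per_bin" else global_excl)
        for code in sorted(kept):
            ra = idx_a.loc[(lab, code)]
            rb = idx_b.loc[(lab, code)]
            rows.append(
                (lab, code,
                 ra["odds_ratio"], ra["ci_low"], ra["ci_high"], ra["p"],
                 rb["odds_ratio"], rb["ci_low"], rb["ci_high"], rb["p"])
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "age_bin", "phecode",
            "or_fvsm", "ci_low_fvsm", "ci_high_fvsm", "p_fvsm",
            "or_asdvsnon", "ci_low_asdvsnon", "ci_high_asdvsnon", "p_asdvsnon",
        ],
    )
    return IntersectionResult(table, tuple(bins.labels))


def cutoff_sweep(
    res_a: pd.DataFrame,
    res_b: pd.DataFrame,
    res_exclusion: pd.DataFrame,
    cutoffs=tuple(round(1.1 + 0.1 * i, 1) for i in range(10)),
    bins: AgeBinning = DEFAULT_AGE_BINS,
    exclusion_mode: str = "per_bin",
) -> pd.DataFrame:
    """Retained-set sizes as the OR cutoff varies (tests are not re-run).

    Returns a frame indexed by cutoff with one column per age bin plus
    ``distinct_total``, the number of distinct phecodes retained across
    bins.  Counts are monotone non-increasing in the cutoff.
    """
    cutoffs = list(cutoffs)
    if not cutoffs:
        raise ConfigError("cutoff list must be non-empty")
    rows = []
    for cut in cutoffs:
        ir = intersect(
            res_a, res_b, res_exclusion,
            bins=bins, exclusion_mode=exclusion_mode, or_cutoff=cut,
        )
        per_bin = {lab: len(ir.retained(lab)) for lab in bins.labels}
        per_bin["distinct_total"] = ir.table["phecode"].nunique() if len(ir.table) else 0
        rows.append({"cutoff": cut, **per_bin})
    return pd.DataFrame(rows).set_index("cutoff")
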