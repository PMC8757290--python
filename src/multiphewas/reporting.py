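"""Result tables, summary set arithmetic and heatmap export.

The analysis reports, per age bin, the phenotypes retained by the
intersection with both contrasts' odds ratios and 95% CIs, sorted within
each bin by the female-vs-male OR in decreasing order.  Two reference
result tables — the published claims-cohort table and the pediatric
hospital validation table, transcribed to CSV — ship with the package so
the set-arithmetic summaries can be exercised without access to any
proprietary data.
"""

from __future__ import annotations

import logging
import re
from importlib import resources

import numpy as np
import pandas as pd

from .cohort import AgeBinning, ConfigError, DEFAULT_AGE_BINS
from .exact import fisher_exact
from .phecodes import PhecodeMap
from .phewas import IntersectionResult

__all__ = [
    "load_reference_table",
    "make_result_table",
    "format_result_table",
    "summarize_by_bin",
    "cross_age_sets",
    "cross_dataset_sets",
    "export_heatmap",
    "recompute_from_counts",
]

log = logging.getLogger(__name__)

_FIXTURES = {
    "claims": "claims_reference_results.csv",
    "hospital": "hospital_reference_results.csv",
}


def load_reference_table(which: str = "claims") -> pd.DataFrame:
    """Load one of the shipped reference result tables.

    ``which`` is ``"claims"`` (the 27-phenotype claims-cohort table) or
    ``"hospital"`` (the 7-phenotype pediatric-hospital validation table).
    """
    if which not in _FIXTURES:
        raise ConfigError(f"unknown reference table {which!r}")
    with resources.files("multiphewas.data").joinpath(_FIXTURES[which]).open() as fh:
        return pd.read_csv(fh)


def _name_column(table: pd.DataFrame) -> str:
    for col in ("phenotype", "phecode"):
        if col in table.columns:
            return col
    raise ConfigError("result table needs a 'phenotype' or 'phecode' column")


def sort_result_table(
    table: pd.DataFrame, bins: AgeBinning = DEFAULT_AGE_BINS
) -> pd.DataFrame:
    """Order rows: age bins ascending, then female-vs-male OR descending."""
    order = {lab: i for i, lab in enumerate(bins.labels)}
    name = _name_column(table)
    out = table.copy()
    out["_bin_order"] = out["age_bin"].map(order)
    out = out.sort_values(
        ["_bin_order", "or_fvsm", name], ascending=[True, False, True]
    ).drop(columns="_bin_order")
    return out.reset_index(drop=True)


def make_result_table(
    ir: IntersectionResult,
    phecode_map: PhecodeMap,
    bins: AgeBinning = DEFAULT_AGE_BINS,
) -> pd.DataFrame:
    """One row per (age bin, retained phecode) with names and categories.

    Phecodes absent from the map get category "unknown" with a warning.
    """
    t = ir.table.copy()
    t["phenotype"] = t["phecode"].map(phecode_map.phenotype_name)
    t["category"] = t["phecode"].map(phecode_map.category)
    unknown = t["category"] == "unknown"
    if unknown.any():
        log.warning(
            "%d retained phecodes missing from the map (category 'unknown')",
            int(unknown.sum()),
        )
    cols = ["age_bin", "phecode", "phenotype", "category",
            "or_fvsm", "ci_low_fvsm", "ci_high_fvsm",
            "or_asdvsnon", "ci_low_asdvsnon", "ci_high_asdvsnon"]
    return sort_result_table(t[cols], bins)


def format_result_table(table: pd.DataFrame) -> pd.DataFrame:
    """Human-readable rendering: ORs at 3 decimals, CIs as "low-high"."""
    def fmt(x):
        return "inf" if np.isinf(x) else f"{x:.3f}".rstrip("0").rstrip(".")

    out = table.copy()
    for side in ("fvsm", "asdvsnon"):
        if f"or_{side}" not in out.columns:
            continue
        out[f"or_{side}"] = out[f"or_{side}"].map(fmt)
        out[f"ci_{side}"] = (
            out[f"ci_low_{side}"].map(fmt) + "-" + out[f"ci_high_{side}"].map(fmt)
        )
        out = out.drop(columns=[f"ci_low_{side}", f"ci_high_{side}"])
    return out


def summarize_by_bin(
    table: pd.DataFrame, bins: AgeBinning = DEFAULT_AGE_BINS
) -> tuple[dict[str, int], int]:
    """Per-bin row counts and the number of distinct phenotype codes."""
    name = _name_column(table)
    counts = {lab: int((table["age_bin"] == lab).sum()) for lab in bins.labels}
    return counts, int(table[name].nunique())


def cross_age_sets(
    table: pd.DataFrame, bin_labels: list[str] | None = None,
    bins: AgeBinning = DEFAULT_AGE_BINS,
) -> dict:
    """Set comparisons of retained phenotypes across age bins.

    Returns the phenotypes present in *all* of ``bin_labels`` (default:
    every bin in the table), those present in more than one bin, and per
    bin the phenotypes recurring in at least one other bin.
    """
    name = _name_column(table)
    present = {lab: set(g[name]) for lab, g in table.groupby("age_bin")}
    if bin_labels is None:
        bin_labels = [lab for lab in bins.labels if lab in present]
    for lab in bin_labels:
        if lab not in bins.labels:
            raise ConfigError(f"unknown age bin label {lab!r}")
    sets = [present.get(lab, set()) for lab in bin_labels]
    shared_all = set.intersection(*sets) if sets else set()
    recurring = {
        lab: {p for p in codes if any(p in other for l2, other in present.items() if l2 != lab)}
        for lab, codes in present.items()
    }
    in_multiple = set().union(*recurring.values()) if recurring else set()
    return {
        "shared_all": shared_all,
        "in_multiple": in_multiple,
        "recurring_by_bin": recurring,
    }


def _normalize_name(name: str) -> str:
    return re.sub(r"\s+", " ", str(name)).strip().casefold()


def cross_dataset_sets(
    table_primary: pd.DataFrame, table_validation: pd.DataFrame
) -> tuple[set[str], set[str], set[str]]:
    """Phenotype-name overlap between two result tables.

    Matching is case-insensitive exact string match after whitespace
    normalization, across all age bins.  Returns (shared,
    validation-only, primary-only) — three disjoint sets partitioning the
    union of names.
    """
    p = {_normalize_name(n) for n in table_primary[_name_column(table_primary)]}
    v = {_normalize_name(n) for n in table_validation[_name_column(table_validation)]}
    return p & v, v - p, p - v


def heatmap_matrix(
    table: pd.DataFrame, bins: AgeBinning = DEFAULT_AGE_BINS
) -> pd.DataFrame:
    """Phenotype x age-bin matrix of female-vs-male ORs.

    Rows are grouped so phenotypes of one category occupy consecutive
    rows; columns are the age bins in ascending order; absent cells are
    blank (NaN).
    """
    name = _name_column(table)
    if len(table) == 0:
        return pd.DataFrame()
    cat = table.get("category", pd.Series("unknown", index=table.index))
    t = table.assign(_cat=cat)
    mat = t.pivot_table(index=["_cat", name], columns="age_bin",
                        values="or_fvsm", aggfunc="first")
    cols = [lab for lab in bins.labels if lab in mat.columns]
    # category blocks ordered by their strongest OR, phenotypes likewise,
    # keeping each category's phenotypes in consecutive rows
    strength = mat.max(axis=1)
    cat_rank = strength.groupby(level="_cat").max().rank(ascending=False, method="first")
    order = sorted(
        mat.index,
        key=lambda ix: (cat_rank[ix[0]], -strength[ix], ix[1]),
    )
    return mat.loc[order, cols]


def export_heatmap(
    table: pd.DataFrame,
    matrix_path,
    figure_path=None,
    bins: AgeBinning = DEFAULT_AGE_BINS,
):
    """Write the heatmap matrix CSV and optionally render the figure."""
    mat = heatmap_matrix(table, bins)
    if mat.empty:
        log.warning("empty result set: writing empty heatmap matrix, no figure")
        pd.DataFrame().to_csv(matrix_path)
        return mat
    flat = mat.reset_index().rename(columns={"_cat": "category"})
    flat.to_csv(matrix_path, index=False)
    if figure_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(6, max(2.0, 0.3 * len(mat) + 1.5)), constrained_layout=True
        )
        data = np.log10(mat.to_numpy(dtype=float))
        im = ax.imshow(data, aspect="auto", cmap="viridis")
        ax.set_xticks(range(mat.shape[1]), mat.columns)
        ax.set_yticks(
            range(mat.shape[0]),
            [f"{p}  [{c}]" for c, p in mat.index],
            fontsize=7,
        )
        ax.set_xlabel("age group (years)")
        fig.colorbar(im, ax=ax, label="log10 OR (female vs male, ASD)")
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return mat


def recompute_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Exact-test results for a table of raw 2x2 counts.

    ``counts`` needs columns a, b, c, d (carriers / non-carriers in each
    group) and is returned with odds_ratio, ci_low, ci_high and p columns
    appended, for direct comparison against printed OR/CI values.
    """
    out = counts.copy()
    res = [fisher_exact(int(r.a), int(r.b), int(r.c), int(r.d))
           for r in counts.itertuples()]
    out["odds_ratio"] = [r.odds_ratio for r in res]
    out["ci_low"] = [r.ci_low for r in res]
    out["ci_high"] = [r.ci_high for r in res]
    out["p"] = [r.p_value for r in res]
    return out
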