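"""PheWAS contrasts, intersection-minus-exclusion, cutoff sweep."""

import numpy as np
import pandas as pd
import pytest

from multiphewas.cohort import ConfigError, PhenotypeProfile
from multiphewas.phewas import (
    AlignmentError,
    CASE_F_VS_CASE_M,
    ComparisonSpec,
    RESULT_COLUMNS,
    _or_passes,
    cutoff_sweep,
    intersect,
    run_phewas,
)


def _profile(triples):
    df = pd.DataFrame(triples, columns=["patient_id", "phecode", "age_bin"])
    df["n_occasions"] = 3
    df["n_occasions_total"] = 3
    return PhenotypeProfile(df)


def _denominators(rows):
    return pd.DataFrame(rows, columns=["age_bin", "status", "sex", "n"])


def _cohort(n_f=50, n_m=50):
    ids = [f"f{i}" for i in range(n_f)] + [f"m{i}" for i in range(n_m)]
    return pd.DataFrame(
        {
            "patient_id": ids,
            "status": "case",
            "sex": ["F"] * n_f + ["M"] * n_m,
        }
    )


def _result_rows(rows):
    """rows: (comparison, bin, phecode, or, ci_low, p, thr, significant)."""
    out = []
    for comp, lab, code, orr, ci_low, p, thr, sig in rows:
        out.append((comp, lab, code, 1, 1, 1, 1, orr, ci_low, orr * 10, p,
                    10, thr, sig, False))
    return pd.DataFrame(out, columns=RESULT_COLUMNS)


def test_identical_proportions_not_significant():
    triples = [(f"f{i}", "500", "0-2") for i in range(10)] + [
        (f"m{i}", "500", "0-2") for i in range(10)
    ]
    den = _denominators([("0-2", "case", "F", 50), ("0-2", "case", "M", 50),
                         ("3-5", "case", "F", 50), ("3-5", "case", "M", 50),
                         ("6-11", "case", "F", 50), ("6-11", "case", "M", 50),
                         ("12-18", "case", "F", 50), ("12-18", "case", "M", 50)])
    res = run_phewas(_profile(triples), den, _cohort(), CASE_F_VS_CASE_M)
    row = res.iloc[0]
    assert row["a"] == 10 and row["c"] == 10
    assert row["odds_ratio"] == pytest.approx(1.0, abs=1e-9)
    assert not row["significant"]
    # the flag is recomputable from the stored fields
    assert row["significant"] == (
        row["p"] < row["p_threshold"]
        and _or_passes(row["odds_ratio"], row["ci_low"], 1.5)
    )


def test_case_defining_phecode_suppressed():
    triples = [(f"f{i}", "299", "0-2") for i in range(10)]
    den = _denominators([("0-2", "case", "F", 50), ("0-2", "case", "M", 50)])
    with pytest.warns(UserWarning):  # other bins have empty groups
        res = run_phewas(_profile(triples), den, _cohort(), CASE_F_VS_CASE_M,
                         suppress_phecodes={"299"})
    assert len(res) == 0


def test_overlapping_groups_rejected():
    with pytest.raises(ConfigError):
        ComparisonSpec("bad", ("case", "F"), ("case", "F"))


def test_infinite_or_needs_informative_lower_bound():
    assert _or_passes(np.inf, 1.2, 1.5)
    assert not _or_passes(np.inf, 0.8, 1.5)
    assert _or_passes(3.0, 0.5, 1.5)
    assert not _or_passes(np.nan, 0.5, 1.5)


def test_intersection_set_algebra():
    thr = 1e-4
    a = _result_rows([
        ("A", "0-2", "x", 3.0, 2.0, 1e-9, thr, True),
        ("A", "0-2", "y", 3.0, 2.0, 1e-9, thr, True),
    ])
    b = _result_rows([
        ("B", "0-2", "y", 4.0, 2.5, 1e-9, thr, True),
        ("B", "0-2", "z", 4.0, 2.5, 1e-9, thr, True),
        ("B", "0-2", "x", 1.1, 0.9, 0.5, thr, False),
    ])
    empty = a.iloc[0:0]
    ir = intersect(a, b, empty)
    assert ir.retained("0-2") == {"y"}

    b2 = _result_rows([
        ("B", "0-2", "x", 4.0, 2.5, 1e-9, thr, True),
        ("B", "0-2", "y", 4.0, 2.5, 1e-9, thr, True),
    ])
    excl = _result_rows([("E", "0-2", "y", 2.0, 1.5, 1e-9, thr, True)])
    ir = intersect(a, b2, excl)
    assert ir.retained("0-2") == {"x"}
    # retained rows carry both contrasts' estimates
    row = ir.table.iloc[0]
    assert row["or_fvsm"] == 3.0 and row["or_asdvsnon"] == 4.0


def test_strict_threshold_boundary():
    """p equal to the Bonferroni threshold is not significant."""
    thr = 1e-4
    a = _result_rows([("A", "0-2", "x", 3.0, 2.0, 1e-4, thr, False)])
    b = _result_rows([("B", "0-2", "x", 3.0, 2.0, 1e-9, thr, True)])
    ir = intersect(a, b, a.iloc[0:0], or_cutoff=1.5)
    assert ir.retained("0-2") == set()


def test_bin_misalignment_is_error():
    thr = 1e-4
    a = _result_rows([("A", "0-2", "x", 3.0, 2.0, 1e-9, thr, True)])
    b = _result_rows([("B", "3-5", "x", 3.0, 2.0, 1e-9, thr, True)])
    with pytest.raises(AlignmentError):
        intersect(a, b, a.iloc[0:0])


def test_global_exclusion_mode():
    thr = 1e-4
    a = _result_rows([
        ("A", "0-2", "x", 3.0, 2.0, 1e-9, thr, True),
        ("A", "3-5", "x", 3.0, 2.0, 1e-9, thr, True),
    ])
    b = _result_rows([
        ("B", "0-2", "x", 3.0, 2.0, 1e-9, thr, True),
        ("B", "3-5", "x", 3.0, 2.0, 1e-9, thr, True),
    ])
    excl = _result_rows([("E", "3-5", "x", 2.0, 1.5, 1e-9, thr, True)])
    per_bin = intersect(a, b, excl, exclusion_mode="per_bin")
    assert per_bin.retained("0-2") == {"x"} and per_bin.retained("3-5") == set()
    glob = intersect(a, b, excl, exclusion_mode="global")
    assert glob.retained("0-2") == set() and glob.retained("3-5") == set()


class TestCutoffSweep:
    def results(self):
        thr = 1e-4
        ors = {"x": 1.3, "y": 1.7, "z": 2.5}
        a = _result_rows([
            ("A", "0-2", code, orr, orr - 0.2, 1e-9, thr, orr > 1.5)
            for code, orr in ors.items()
        ])
        b = _result_rows([
            ("B", "0-2", code, orr + 0.1, orr - 0.1, 1e-9, thr, orr + 0.1 > 1.5)
            for code, orr in ors.items()
        ])
        return a, b, a.iloc[0:0]

    def test_single_point_equals_intersect(self):
        a, b, e = self.results()
        sweep = cutoff_sweep(a, b, e, cutoffs=[1.5])
        ir = intersect(a, b, e)  # stored flags used or_cutoff 1.5
        assert sweep.loc[1.5, "0-2"] == len(ir.retained("0-2"))

    def test_counts_at_planted_ors(self):
        a, b, e = self.results()
        sweep = cutoff_sweep(a, b, e, cutoffs=[1.1, 1.5, 2.0])
        assert sweep["0-2"].tolist() == [3, 2, 1]
        assert sweep["distinct_total"].tolist() == [3, 2, 1]

    def test_monotone_non_increasing(self):
        a, b, e = self.results()
        sweep = cutoff_sweep(a, b, e)
        for col in sweep.columns:
            assert (np.diff(sweep[col].to_numpy()) <= 0).all()

    def test_empty_cutoffs_rejected(self):
        a, b, e = self.results()
        with pytest.raises(ConfigError):
            cutoff_sweep(a, b, e, cutoffs=[])


def test_end_to_end_retains_planted_sets(small_ds, small_map):
    """On the shared planted cohort the retained set equals the ground truth."""
    import tempfile

    from multiphewas.pipeline import RunConfig, run_pipeline

    with tempfile.TemporaryDirectory() as d:
        out = run_pipeline(RunConfig(out_dir=d), patients=small_ds.patients,
                           events=small_ds.events, phecode_map=small_map)
    retained = out["intersection"].retained_by_bin()
    expected = small_ds.manifest.expected
    for lab, codes in retained.items():
        assert codes == set(expected[lab]["retained"])
    # the doubly-planted probe was significant everywhere yet excluded
    excl = out["results"]["ctrl_F_vs_ctrl_M"]
    assert excl[excl["phecode"] == "311"]["significant"].any()
    assert all("311" not in codes for codes in retained.values())
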