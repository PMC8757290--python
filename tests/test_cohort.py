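"""Inclusion criteria, age binning, profiles and denominators."""

import warnings

import pandas as pd
import pytest

from multiphewas.cohort import (
    AgeBinning,
    ConfigError,
    DEFAULT_AGE_BINS,
    DataError,
    assign_cohorts,
    bin_population,
    build_profiles,
    completed_years,
)
from multiphewas.phecodes import PhecodeMap


def _patients(rows):
    return pd.DataFrame(rows, columns=["patient_id", "sex", "birth_date"])


def _events(rows):
    return pd.DataFrame(rows, columns=["patient_id", "icd9", "service_date"])


TINY_MAP = PhecodeMap(
    pd.DataFrame(
        {
            "icd9": ["299.00", "345.40", "564.00"],
            "phecode": ["299", "345.1", "564"],
            "phenotype": ["Autism", "Partial epilepsy", "Constipation"],
            "category": ["mental disorders", "neurological", "digestive"],
        }
    )
)


class TestAgeBinning:
    def test_default_bins(self):
        assert DEFAULT_AGE_BINS.labels == ["0-2", "3-5", "6-11", "12-18"]
        assert DEFAULT_AGE_BINS.interval("6-11") == (6, 11)

    @pytest.mark.parametrize(
        "bins",
        [
            (("a", 0, 5), ("b", 5, 18)),   # overlap
            (("a", 0, 5), ("b", 7, 18)),   # gap
            (("a", 1, 5), ("b", 6, 18)),   # not starting at 0
            (("a", 0, 5), ("b", 6, 17)),   # not reaching 18
        ],
    )
    def test_invalid_binnings(self, bins):
        with pytest.raises(ConfigError):
            AgeBinning(bins)

    def test_overlap_rule(self):
        assert DEFAULT_AGE_BINS.overlapping(1, 4) == ["0-2", "3-5"]
        assert DEFAULT_AGE_BINS.overlapping(0, 18) == DEFAULT_AGE_BINS.labels


def test_completed_years_around_birthday():
    birth = pd.Series(pd.to_datetime(["2000-06-15"] * 3))
    when = pd.Series(pd.to_datetime(["2003-06-14", "2003-06-15", "2003-06-16"]))
    assert completed_years(birth, when).tolist() == [2, 3, 3]


class TestAssignCohorts:
    def base(self):
        patients = _patients(
            [
                ("p1", "F", "2000-01-01"),  # 2 occasions -> excluded
                ("p2", "M", "2000-01-01"),  # 3 events on one date -> excluded
                ("p3", "F", "2000-01-01"),  # proper case
                ("p4", "M", "2000-01-01"),  # control
                ("p5", "F", "2000-01-01"),  # case codes but span < 366d
                ("p6", "M", "2000-01-01"),  # case without any comorbidity
                ("p7", None, "2000-01-01"),  # missing sex
            ]
        )
        events = _events(
            [
                ("p1", "299.00", "2003-01-01"),
                ("p1", "299.00", "2004-06-01"),
                ("p1", "564.00", "2005-01-01"),
                ("p2", "299.00", "2003-05-05"),
                ("p2", "299.01", "2003-05-05"),
                ("p2", "29980", "2003-05-05"),
                ("p2", "564.00", "2005-01-01"),
                ("p3", "299.00", "2003-01-01"),
                ("p3", "299.00", "2003-06-01"),
                ("p3", "299.00", "2004-02-01"),
                ("p3", "345.40", "2004-03-01"),
                ("p4", "564.00", "2003-01-01"),
                ("p4", "564.00", "2004-06-01"),
                ("p5", "299.00", "2003-01-01"),
                ("p5", "299.00", "2003-03-01"),
                ("p5", "299.00", "2003-06-01"),
                ("p5", "564.00", "2003-08-01"),
                ("p6", "299.00", "2003-01-01"),
                ("p6", "299.00", "2003-06-01"),
                ("p6", "299.00", "2004-02-01"),
            ]
        )
        return patients, events

    def test_statuses_and_reasons(self):
        patients, events = self.base()
        asg = assign_cohorts(patients, events, phecode_map=TINY_MAP)
        t = asg.table.set_index("patient_id")
        assert t.loc["p1", "status"] == "excluded"
        assert t.loc["p1", "reason"] == "subthreshold_case_codes"
        assert t.loc["p2", "status"] == "excluded"  # one distinct date only
        assert t.loc["p3", "status"] == "case"
        assert t.loc["p4", "status"] == "control"
        assert t.loc["p5", "reason"] == "short_record_span"
        assert t.loc["p6", "reason"] == "no_comorbid_phenotype"
        assert t.loc["p7", "reason"] == "missing_demographics"

    def test_partition(self):
        patients, events = self.base()
        asg = assign_cohorts(patients, events, phecode_map=TINY_MAP)
        counts = asg.table["status"].value_counts()
        assert counts.sum() == len(patients)

    def test_no_control_carries_case_code(self):
        patients, events = self.base()
        asg = assign_cohorts(patients, events, phecode_map=TINY_MAP)
        ctrl_events = events[events["patient_id"].isin(asg.controls)]
        assert not ctrl_events["icd9"].str.startswith("299").any()

    def test_empty_patients_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            asg = assign_cohorts(_patients([]), _events([]))
        assert len(asg.table) == 0

    def test_config_and_data_errors(self):
        patients, events = self.base()
        with pytest.raises(ConfigError):
            assign_cohorts(patients, events, min_span_days=-1)
        with pytest.raises(ConfigError):
            assign_cohorts(patients, events, case_icd9_set=set())
        bad = pd.concat(
            [events, _events([("ghost", "564.00", "2003-01-01")])]
        )
        with pytest.raises(DataError, match="ghost"):
            assign_cohorts(patients, bad)


class TestBuildProfiles:
    def profile_inputs(self):
        patients = _patients([("p1", "F", "2000-01-01")])
        # distinct dates at completed ages 4, 4, 7
        events = _events(
            [
                ("p1", "345.40", "2004-03-01"),
                ("p1", "345.40", "2004-09-01"),
                ("p1", "345.40", "2007-03-01"),
            ]
        )
        return patients, events

    def test_overall_scope_places_in_both_bins(self):
        patients, events = self.profile_inputs()
        prof = build_profiles(events, patients, TINY_MAP, occasion_scope="overall")
        got = set(zip(prof.triples["phecode"], prof.triples["age_bin"]))
        assert got == {("345.1", "3-5"), ("345.1", "6-11")}

    def test_per_bin_scope_filters_both(self):
        patients, events = self.profile_inputs()
        prof = build_profiles(events, patients, TINY_MAP, occasion_scope="per_bin")
        assert len(prof.triples) == 0

    def test_event_before_birth_is_data_error(self):
        patients = _patients([("p1", "F", "2000-06-01")])
        events = _events([("p1", "345.40", "2000-01-01")])
        with pytest.raises(DataError, match="p1"):
            build_profiles(events, patients, TINY_MAP)

    def test_monotone_in_threshold_and_scope(self, small_ds, small_map):
        inc = small_ds.manifest.statuses
        inc = inc[inc["status"].isin(["case", "control"])]
        pats = small_ds.patients[small_ds.patients["patient_id"].isin(inc["patient_id"])]
        evs = small_ds.events[small_ds.events["patient_id"].isin(inc["patient_id"])]
        def triple_set(**kw):
            prof = build_profiles(evs, pats, small_map, **kw)
            return set(map(tuple, prof.triples[["patient_id", "phecode", "age_bin"]].itertuples(index=False)))
        t3 = triple_set(min_comorbid_occasions=3)
        t4 = triple_set(min_comorbid_occasions=4)
        per_bin = triple_set(occasion_scope="per_bin")
        assert t4 <= t3
        assert per_bin <= t3

    def test_profiles_match_independent_manifest(self, small_ds, small_map):
        """Cohort-module counting agrees with the generator's direct recount."""
        inc = small_ds.manifest.statuses
        inc = inc[inc["status"].isin(["case", "control"])]
        pats = small_ds.patients[small_ds.patients["patient_id"].isin(inc["patient_id"])]
        evs = small_ds.events[small_ds.events["patient_id"].isin(inc["patient_id"])]
        for scope, truth in (
            ("overall", small_ds.manifest.triples_overall),
            ("per_bin", small_ds.manifest.triples_per_bin),
        ):
            prof = build_profiles(evs, pats, small_map, occasion_scope=scope)
            got = set(map(tuple, prof.triples[["patient_id", "phecode", "age_bin"]].itertuples(index=False)))
            truth = truth[truth["patient_id"].isin(inc["patient_id"])]
            truth = truth[truth["phecode"] != "299"]
            want = set(map(tuple, truth.itertuples(index=False)))
            got = {t for t in got if t[1] != "299"}
            assert got == want


class TestBinPopulation:
    def test_overlap_rule(self):
        patients = _patients([("p1", "F", "2000-01-01"), ("p2", "M", "2000-01-01")])
        events = _events(
            [
                ("p1", "564.00", "2001-06-01"),  # ages 1..4
                ("p1", "564.00", "2004-06-01"),
                ("p2", "564.00", "2000-06-01"),  # ages 0..18
                ("p2", "564.00", "2018-06-01"),
            ]
        )
        den = bin_population(patients, events)
        p1_bins = set(den[(den["sex"] == "F") & (den["n"] > 0)]["age_bin"])
        assert p1_bins == {"0-2", "3-5"}
        p2_bins = set(den[(den["sex"] == "M") & (den["n"] > 0)]["age_bin"])
        assert p2_bins == {"0-2", "3-5", "6-11", "12-18"}

    def test_all_mode_counts_everyone_everywhere(self):
        patients = _patients([("p1", "F", "2000-01-01")])
        events = _events([("p1", "564.00", "2001-06-01")])
        den = bin_population(patients, events, mode="all")
        assert (den["n"] == 1).all() and len(den) == 4

    def test_matches_manifest_denominators(self, small_ds, small_map):
        asg = assign_cohorts(small_ds.patients, small_ds.events,
                             phecode_map=small_map)
        den = bin_population(small_ds.patients, small_ds.events,
                             assignment=asg)
        want = small_ds.manifest.denominators
        merged = den.merge(want, on=["age_bin", "status", "sex"],
                           suffixes=("", "_want"), how="outer")
        assert (merged["n"] == merged["n_want"]).all()


def test_assignment_matches_generator_manifest(small_ds, small_map):
    """Cohort rules recover the generator's independently counted statuses."""
    asg = assign_cohorts(small_ds.patients, small_ds.events,
                         phecode_map=small_map)
    got = asg.table.set_index("patient_id")["status"]
    want = small_ds.manifest.statuses.set_index("patient_id")["status"]
    assert (got.sort_index() == want.sort_index()).all()
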