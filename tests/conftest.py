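import pandas as pd
import pytest
from hypothesis import settings

from multiphewas.phecodes import PhecodeMap
from multiphewas.synth import GeneratorConfig, PlantedEffect, generate

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def map_file(tmp_path_factory):
    """50 ICD-9 codes over 20 phecodes in 5 categories."""
    rows = []
    for j in range(20):
        code = f"{400 + j}"
        for s in range(3 if j < 10 else 2):  # 10*3 + 10*2 = 50 icd9 rows
            rows.append(
                {
                    "icd9": f"{code}.{s}",
                    "phecode": code,
                    "phenotype": f"Phenotype {code}",
                    "category": f"cat{j % 5}",
                }
            )
    path = tmp_path_factory.mktemp("map") / "phecode_map.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def small_ds():
    """Small planted synthetic cohort shared across tests.

    Phecode 310 is ASD-female enriched (OR 3); 311 carries both a general
    female bias and an ASD-female bias, so it is significant in all three
    contrasts and must be removed by the exclusion step.
    """
    cfg = GeneratorConfig(
        seed=11,
        n_patients=16000,
        case_prevalence=0.5,
        male_fraction_of_cases=0.5,
        n_phecodes=25,
        planted_effects=(
            PlantedEffect("310", 3.0, kind="asd_female"),
            PlantedEffect("311", 3.0, kind="asd_female"),
            PlantedEffect("311", 3.0, kind="female_general"),
        ),
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def small_map(small_ds):
    return PhecodeMap(small_ds.phecode_map)


@pytest.fixture(scope="session")
def claims_table():
    from multiphewas.reporting import load_reference_table

    return load_reference_table("claims")


@pytest.fixture(scope="session")
def hospital_table():
    from multiphewas.reporting import load_reference_table

    return load_reference_table("hospital")
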