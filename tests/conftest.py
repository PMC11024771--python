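import numpy as np
import pandas as pd
import pytest

from famh2.registry import REGISTRY_COLUMNS
from famh2.simulate import GeneratorConfig, simulate_registry


def make_child(child_id, sex="male", birth_year=1990, birth_date=None,
               mother_id="M1", father_id="F1",
               mgm="GM1", mgf="GF1", pgm="GM2", pgf="GF2",
               maternal_age=28, paternal_age=31, gest=40,
               swedish=1, diagnosis=0):
    return {
        "child_id": child_id, "sex": sex, "birth_year": birth_year,
        "birth_date": birth_date or f"{birth_year}-100",
        "mother_id": mother_id, "father_id": father_id,
        "maternal_grandmother_id": mgm, "maternal_grandfather_id": mgf,
        "paternal_grandmother_id": pgm, "paternal_grandfather_id": pgf,
        "maternal_age": maternal_age, "paternal_age": paternal_age,
        "gestational_age_weeks": gest, "parents_swedish": swedish,
        "diagnosis": diagnosis,
    }


def make_registry(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=REGISTRY_COLUMNS)
    df["parents_swedish"] = df["parents_swedish"].astype(bool)
    return df


@pytest.fixture(scope="session")
def small_registry():
    """~2000-couple synthetic registry with default (study-like) settings."""
    return simulate_registry(GeneratorConfig(n_couples=2000, seed=11))


@pytest.fixture(scope="session")
def small_cohort(small_registry):
    from famh2.registry import apply_cohort_filters
    cohort, _ = apply_cohort_filters(small_registry)
    return cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
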