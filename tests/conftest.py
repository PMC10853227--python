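import pandas as pd
import pytest

from deltasurv.cohort import PairedFeatureTable
from deltasurv.synthetic import CohortSpec, PhantomSpec, generate_cohort, generate_dynamic_phantom


@pytest.fixture(scope="session")
def planted_cohort():
    """Default-conditions cohort: 18 patients, planted delta effect beta=1.5."""
    return generate_cohort(CohortSpec(seed=42))


@pytest.fixture(scope="session")
def null_cohort():
    """No prognostic signal anywhere (beta=0)."""
    return generate_cohort(CohortSpec(effect_size_beta=0.0, seed=43))


@pytest.fixture(scope="session")
def phantom():
    """Low-noise dynamic phantom with a visible lesion (contrast 2.0)."""
    return generate_dynamic_phantom(PhantomSpec(), seed=0)


@pytest.fixture()
def tiny_paired():
    """Hand-sized paired table for formula-level checks."""
    ids = pd.Index(["P0", "P1", "P2"], name="patient_id")
    pet0 = pd.DataFrame({"rad_a": [1.5, 2.0, 4.0], "conv_TBR_max": [2.0, 3.0, 1.0]}, index=ids)
    pet1 = pd.DataFrame({"rad_a": [2.0, 2.0, 2.0], "conv_TBR_max": [2.5, 3.0, 2.0]}, index=ids)
    t0 = pd.Series([2.0, 3.0, 2.5], index=ids)
    t1 = pd.Series([6.0, 11.0, 4.5], index=ids)
    return PairedFeatureTable(pet0, pet1, t0, t1)


def survival_frame(times, events, ids=None):
    ids = ids if ids is not None else [f"P{i:03d}" for i in range(len(times))]
    return pd.DataFrame({"pfs_months": times, "event": events},
                        index=pd.Index(ids, name="patient_id"))


@pytest.fixture(scope="session")
def outcome_maker():
    return survival_frame
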