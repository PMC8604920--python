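import numpy as np
import pytest

from wpnet.cohort_builder import GroupingTable, PatientProfile
from wpnet.synthetic_claims import SyntheticCohortSpec, generate_claims


def make_profile(pid, diagnoses, label=0, age_norm=0.5, gender=0, smoking=0):
    return PatientProfile(
        patient_id=pid,
        age=50.0,
        age_norm=age_norm,
        gender=gender,
        smoking=smoking,
        grouped_diagnoses=frozenset(diagnoses),
        label=label,
    )


@pytest.fixture(scope="session")
def grouping():
    return GroupingTable.default()


@pytest.fixture(scope="session")
def toy_profiles():
    """Three patients over two diseases: P1~{D1,D2}, P2~{D1,D2}, P4~{D2}."""
    return [
        make_profile("P1", {"D1", "D2"}),
        make_profile("P2", {"D1", "D2"}),
        make_profile("P4", {"D2"}),
    ]


@pytest.fixture(scope="session")
def small_table():
    """A small planted cohort used by several module tests."""
    spec = SyntheticCohortSpec(n_cases=40, n_controls=40, seed=11)
    return generate_claims(spec)


def random_symmetric_adjacency(rng, n, weighted=False, p=0.4):
    """Random symmetric nonnegative zero-diagonal adjacency."""
    a = (rng.random((n, n)) < p).astype(float)
    if weighted:
        a *= rng.integers(1, 5, size=(n, n)).astype(float)
    a = np.triu(a, 1)
    return a + a.T
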