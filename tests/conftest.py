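import datetime as dt

import pytest

from disdrift.data_model import ChunkedDataset, Mode, PatientRecord
from disdrift.synthetic import CohortConfig, generate_high_granularity


@pytest.fixture
def tiny_high() -> ChunkedDataset:
    """Two chunks, four patients, hand-built event lists."""
    records = (
        PatientRecord("p1", "A", events=("a", "a", "b"), outcome="deceased"),
        PatientRecord("p2", "A", events=("b", "c"), outcome="not_deceased"),
        PatientRecord("p3", "B", events=("a", "c", "c"), outcome="deceased"),
        PatientRecord("p4", "B", events=("b",), outcome="not_deceased"),
    )
    return ChunkedDataset(
        mode=Mode.HIGH,
        chunks=("A", "B"),
        records=records,
        outcome_categories=("deceased", "not_deceased"),
    )


@pytest.fixture
def tiny_low() -> ChunkedDataset:
    records = (
        PatientRecord(
            "p1",
            "A",
            attributes={"age": 70.0, "sex": "female"},
            outcome="deceased",
            admission_date=dt.date(2020, 1, 5),
        ),
        PatientRecord(
            "p2",
            "A",
            attributes={"age": 40.0, "sex": "male"},
            outcome="not_deceased",
            admission_date=dt.date(2020, 2, 1),
        ),
        PatientRecord(
            "p3",
            "B",
            attributes={"age": 55.0, "sex": "male"},
            outcome="not_deceased",
            admission_date=dt.date(2020, 4, 2),
        ),
    )
    return ChunkedDataset(
        mode=Mode.LOW,
        chunks=("A", "B"),
        records=records,
        outcome_categories=("deceased", "not_deceased"),
    )


@pytest.fixture(scope="session")
def small_cohort() -> ChunkedDataset:
    """A seeded 3-chunk null cohort shared by read-only tests."""
    cfg = CohortConfig(
        n_patients_per_chunk=150, n_chunks=3, vocabulary_size=25, seed=11
    )
    return generate_high_granularity(cfg)
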