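import numpy as np
import pytest

from fairdx.metrics import ScoredSet
from fairdx.subgroups import (
    CategoricalBinning,
    GroupingSpec,
    NumericBinning,
    SampleRecord,
)


@pytest.fixture
def midrc_age_spec():
    return GroupingSpec(
        name="age",
        binnings={
            "age": NumericBinning(thresholds=(75,), labels=("<75 yrs", ">=75 yrs"))
        },
    )


@pytest.fixture
def areds_age_spec():
    return GroupingSpec(
        name="age",
        binnings={
            "age": NumericBinning(
                thresholds=(65, 75), labels=("<65 yrs", "65-75 yrs", ">=75 yrs")
            )
        },
    )


@pytest.fixture
def sex_spec():
    return GroupingSpec(name="sex", binnings={"sex": CategoricalBinning()})


def make_records(rows):
    """rows: (sample_id, patient_id, label, attributes)."""
    return [
        SampleRecord(sample_id=s, patient_id=p, label=y, attributes=dict(a))
        for s, p, y, a in rows
    ]


@pytest.fixture
def cohort_records():
    """Six samples covering a 2 (age) × 2 (sex) design with one empty cell
    when sex is collapsed to 3 pseudo-levels in specific tests."""
    return make_records(
        [
            ("s1", "p1", 1, {"age": 45, "sex": "Male"}),
            ("s2", "p1", 0, {"age": 45, "sex": "Male"}),
            ("s3", "p2", 1, {"age": 74, "sex": "Female"}),
            ("s4", "p3", 0, {"age": 75, "sex": "Female"}),
            ("s5", "p4", 1, {"age": 80, "sex": "Male"}),
            ("s6", "p5", 0, {"age": 62, "sex": "Female"}),
        ]
    )


@pytest.fixture
def eight_sample_batch():
    """Two groups, fixed scores; group B clearly worse-ranked than A."""
    return ScoredSet(
        scores=np.array([0.9, 0.8, 0.3, 0.2, 0.7, 0.6, 0.4, 0.1]),
        labels=np.array([1, 1, 1, 1, 0, 0, 0, 0]),
        groups=np.array(["A", "A", "B", "B", "A", "B", "A", "B"], dtype=object),
    )


def random_scored_set(rng, n, n_groups=3, ties=False):
    scores = rng.normal(size=n)
    if ties:
        scores = np.round(scores, 1)  # force tie mass
    labels = rng.integers(0, 2, size=n)
    # ensure both classes
    labels[0], labels[1] = 0, 1
    groups = rng.choice([f"g{i}" for i in range(n_groups)], size=n)
    return ScoredSet(scores=scores, labels=labels, groups=groups.astype(object))
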