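import random

import pytest
from hypothesis import HealthCheck, settings

from ereckit.acuity import AcuityDialect, parse_acuity
from ereckit.classification import PersonRecord, classify_all
from ereckit.datasets import worked_example_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: chart lines used when tests build random records
CHART = ["6/6", "6/9", "6/12", "6/18", "6/24", "6/36", "6/60", "3/60", "CF", "HM"]


def acuity(text, dialect=AcuityDialect.METRIC_6):
    return parse_acuity(text, dialect) if text is not None else None


def random_person(rng: random.Random, person_id: str) -> PersonRecord:
    """A random acuity battery with arbitrary presence/absence patterns."""

    def maybe_line(p_present=0.85):
        return rng.choice(CHART) if rng.random() < p_present else None

    return PersonRecord(
        person_id=person_id,
        wears_distance_correction=rng.random() < 0.5,
        ucva_left=acuity(maybe_line(0.95)),
        ucva_right=acuity(maybe_line(0.95)),
        cva_left=acuity(maybe_line(0.7)),
        cva_right=acuity(maybe_line(0.7)),
        pinhole_left=acuity(maybe_line(0.7)),
        pinhole_right=acuity(maybe_line(0.7)),
        bcva_left=acuity(maybe_line(0.3)),
        bcva_right=acuity(maybe_line(0.3)),
        weight=rng.choice([0.5, 1.0, 2.0]),
    )


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_cohort()


@pytest.fixture(scope="session")
def worked_example_classified(worked_example):
    cats = classify_all(worked_example)
    return [(p, c) for p, (_, c) in zip(worked_example, cats)]
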