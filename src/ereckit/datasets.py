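"""Bundled demonstration data.

``worked_example_cohort`` builds the canonical 100-person teaching cohort
for the coverage indicators: 50 people with unmet need, 50 wearers of
distance correction of whom 20 can see 6/12 uncorrected (no need), 5 have
corrected acuity below 6/12 that pinhole-over-correction restores
(under-met need), and 25 reach 6/12 with their own correction (met need).
At the 6/12 need and outcome thresholds it yields eREC 31.25%, REC 37.5%
and a relative quality gap of 16.7%.

``PUBLISHED_COVERAGE`` holds eREC/REC pairs reported by population-based
surveys (Pakistan 2008, South Africa 2016, Australia 2017 by Indigenous
status), useful for recomputing the quality gap from published figures.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .acuity import AcuityDialect, parse_acuity
from .classification import PersonRecord, Sex
from .survey_io import ColumnMapping, write_cohort

__all__ = [
    "PUBLISHED_COVERAGE",
    "packaged_worked_example_path",
    "worked_example_cohort",
    "worked_example_mapping",
    "write_worked_example",
]

#: (survey, subgroup) -> (eREC %, REC %) as published.
PUBLISHED_COVERAGE = {
    ("pakistan_2008", "national"): (15.1, 22.7),
    ("south_africa_2016", "subnational"): (51.4, 54.3),
    ("australia_2017", "non_indigenous"): (93.5, 98.7),
    ("australia_2017", "indigenous"): (82.2, 94.0),
}


def _person(i, wears, ucva, cva=None, pinhole=None, **kw):
    def acuity(text):
        return parse_acuity(text, AcuityDialect.METRIC_6) if text else None

    # deterministic, non-random demographics: cycle ages and sexes
    return PersonRecord(
        person_id=f"wx{i:03d}",
        wears_distance_correction=wears,
        ucva_left=acuity(ucva[0]),
        ucva_right=acuity(ucva[1]),
        cva_left=acuity(cva[0]) if cva else None,
        cva_right=acuity(cva[1]) if cva else None,
        pinhole_left=acuity(pinhole[0]) if pinhole else None,
        pinhole_right=acuity(pinhole[1]) if pinhole else None,
        age_years=20 + (i * 7) % 60,
        sex=Sex.FEMALE if i % 2 == 0 else Sex.MALE,
        strata={"residence": "urban" if i % 3 else "rural"},
        weight=1.0,
        cluster_id=f"c{i % 10:02d}",
        **kw,
    )


def worked_example_cohort() -> list[PersonRecord]:
    """The 100-person demonstration cohort (deterministic, no RNG)."""
    people = []
    i = 0
    # 50 with unmet need: no correction, impaired UCVA, pinhole restores 6/12+
    unmet_lines = ["6/18", "6/24", "6/36", "6/60", "3/60"]
    pinhole_lines = ["6/6", "6/9", "6/12"]
    for k in range(50):
        u = unmet_lines[k % len(unmet_lines)]
        p = pinhole_lines[k % len(pinhole_lines)]
        people.append(_person(i, False, (u, u), pinhole=(p, p)))
        i += 1
    # 20 wearers with no need: UCVA 6/12 or better without correction
    for k in range(20):
        u = ["6/6", "6/9", "6/12"][k % 3]
        people.append(_person(i, True, (u, u), cva=("6/6", "6/6")))
        i += 1
    # 5 wearers with under-met need: CVA < 6/12, pinhole over correction 6/12+
    for k in range(5):
        people.append(
            _person(i, True, ("6/60", "6/36"), cva=("6/18", "6/24"),
                    pinhole=("6/9", "6/12"))
        )
        i += 1
    # 25 wearers with met need: CVA 6/12 or better
    met_cva = ["6/6", "6/9", "6/12"]
    for k in range(25):
        c = met_cva[k % 3]
        people.append(_person(i, True, ("6/24", "6/36"), cva=(c, c)))
        i += 1
    return people


def worked_example_mapping() -> ColumnMapping:
    from .survey_io import DEFAULT_COLUMNS

    return ColumnMapping(strata={"residence": "residence"}, **DEFAULT_COLUMNS)


def write_worked_example(path: str | Path) -> None:
    """Write the demonstration cohort as a survey CSV."""
    write_cohort(worked_example_cohort(), path)


def packaged_worked_example_path() -> Path:
    """Path of the CSV copy shipped inside the package."""
    return Path(resources.files("ereckit") / "data" / "worked_example.csv")
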