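"""Person-level classification of refractive-error need.

Each survey participant is assigned exactly one need category from their
visual-acuity battery, following the standard flow:

* better-eye uncorrected acuity (UCVA) meets the need threshold → no need;
* otherwise, participants **without** distance correction are unmet need
  when pinhole (or best-corrected) acuity reaches the need threshold, and
  other vision impairment when it does not;
* participants **with** distance correction are met need when their
  corrected acuity (CVA) reaches the outcome threshold; failing that,
  under-met need when pinhole over the correction (or a new refraction)
  reaches the need threshold, and other vision impairment otherwise.

A missing deciding measurement always yields INDETERMINATE — a
first-class excluded category that is reported, never imputed or
silently dropped.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

from .acuity import AcuityThreshold, AcuityValue, better_eye, meets_threshold

__all__ = [
    "NeedCategory",
    "PersonRecord",
    "Sex",
    "classify",
    "classify_all",
]

log = logging.getLogger(__name__)


class NeedCategory(str, Enum):
    NO_NEED = "NO_NEED"
    MET = "MET"
    UNDER_MET = "UNDER_MET"
    UNMET = "UNMET"
    OTHER_VI = "OTHER_VI"
    INDETERMINATE = "INDETERMINATE"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"
    OTHER = "other"
    UNKNOWN = "unknown"


class CorrectionType(str, Enum):
    SPECTACLES = "spectacles"
    CONTACT_LENSES = "contact_lenses"
    BOTH = "both"
    UNKNOWN = "unknown"


@dataclass
class PersonRecord:
    """One survey participant.

    Corrected acuities (``cva_*``) carry meaning only for wearers of
    distance correction; pinhole acuities are through a pinhole occluder
    alone for non-wearers and over the habitual correction for wearers.
    """

    person_id: str
    wears_distance_correction: bool
    ucva_left: Optional[AcuityValue] = None
    ucva_right: Optional[AcuityValue] = None
    cva_left: Optional[AcuityValue] = None
    cva_right: Optional[AcuityValue] = None
    pinhole_left: Optional[AcuityValue] = None
    pinhole_right: Optional[AcuityValue] = None
    bcva_left: Optional[AcuityValue] = None
    bcva_right: Optional[AcuityValue] = None
    correction_type: CorrectionType = CorrectionType.UNKNOWN
    age_years: Optional[int] = None
    sex: Sex = Sex.UNKNOWN
    strata: Mapping[str, str] = field(default_factory=dict)
    weight: float = 1.0
    cluster_id: Optional[str] = None

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError(
                f"person {self.person_id!r}: weight must be positive, got {self.weight}"
            )
        if self.age_years is not None and self.age_years < 0:
            raise ValueError(f"person {self.person_id!r}: negative age")

    def validation_warnings(self) -> list[str]:
        """Non-fatal data-quality issues (the record still classifies)."""
        warnings = []
        if not self.wears_distance_correction and (
            self.cva_left is not None or self.cva_right is not None
        ):
            warnings.append(
                f"person {self.person_id!r}: corrected acuity recorded for a "
                "non-wearer of distance correction"
            )
        u = better_eye(self.ucva_left, self.ucva_right)
        c = better_eye(self.cva_left, self.cva_right)
        if (
            self.wears_distance_correction
            and u is not None
            and c is not None
            and c.logmar > u.logmar + 1e-9
        ):
            warnings.append(
                f"person {self.person_id!r}: corrected acuity worse than "
                "uncorrected acuity"
            )
        return warnings


def _improvement_acuity(person: PersonRecord) -> Optional[AcuityValue]:
    # Best-corrected acuity (new refraction) decides when measured; the
    # pinhole result is the fallback surveys more commonly have.
    b = better_eye(person.bcva_left, person.bcva_right)
    if b is not None:
        return b
    return better_eye(person.pinhole_left, person.pinhole_right)


def classify(
    person: PersonRecord,
    need: AcuityThreshold | None = None,
    outcome: AcuityThreshold | None = None,
) -> NeedCategory:
    """Assign the need category for one participant.

    ``need`` is the impairment threshold (default 6/12 better eye) that
    defines whether refractive correction is needed at all and whether the
    impairment is refractive (pinhole-improvable); ``outcome`` (default
    also 6/12) is the "good visual outcome" line a wearer's corrected
    acuity must reach for met need.

    Contradictory measurements (e.g. CVA worse than UCVA) are classified
    strictly by the thresholds; non-compliance with owned correction is
    not detectable from a survey battery and gets no special handling.
    """
    if need is None:
        need = AcuityThreshold.default()
    if outcome is None:
        outcome = AcuityThreshold.default()

    u = better_eye(person.ucva_left, person.ucva_right)
    if u is None:
        return NeedCategory.INDETERMINATE
    if meets_threshold(u, need):
        # Includes wearers who can see the need line without correction.
        return NeedCategory.NO_NEED

    improvement = _improvement_acuity(person)

    if not person.wears_distance_correction:
        if improvement is None:
            return NeedCategory.INDETERMINATE
        if meets_threshold(improvement, need):
            return NeedCategory.UNMET
        return NeedCategory.OTHER_VI

    c = better_eye(person.cva_left, person.cva_right)
    if c is None:
        return NeedCategory.INDETERMINATE
    if meets_threshold(c, outcome):
        return NeedCategory.MET
    if improvement is None:
        return NeedCategory.INDETERMINATE
    if meets_threshold(improvement, need):
        return NeedCategory.UNDER_MET
    return NeedCategory.OTHER_VI


def classify_all(
    records: Iterable[PersonRecord],
    need: AcuityThreshold | None = None,
    outcome: AcuityThreshold | None = None,
) -> list[tuple[str, NeedCategory]]:
    """Classify every record, preserving order.

    Per-record validation failures become INDETERMINATE with a logged
    reason rather than aborting the run.
    """
    out: list[tuple[str, NeedCategory]] = []
    for person in records:
        try:
            category = classify(person, need, outcome)
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("person %r failed classification: %s", person.person_id, exc)
            category = NeedCategory.INDETERMINATE
        out.append((person.person_id, category))

    counts = Counter(category for _, category in out)
    n = len(out)
    indeterminate_fraction = counts[NeedCategory.INDETERMINATE] / n if n else 0.0
    log.info(
        "classified %d records: %s; indeterminate fraction %.3f",
        n,
        {k.value: v for k, v in sorted(counts.items(), key=lambda kv: kv[0].value)},
        indeterminate_fraction,
    )
    return out
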