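"""Visual-acuity values, parsing, and threshold predicates.

Distance visual acuity in population surveys is recorded as a chart line:
a Snellen fraction (``6/12`` on a 6-metre chart, ``20/40`` on a 20-foot
chart), a decimal logMAR value, or a low-vision category when no chart
line can be read (counting fingers, hand movements, perception of light,
no perception of light).  All comparisons here happen on the logMAR scale
(log10 of the minimum angle of resolution; 0.0 is 6/6, larger is worse),
so phrases such as "worse than 6/12" and "6/12 or better" become exact,
mutually exclusive predicates.

Low-vision categories are mapped to fixed ordinal sentinels strictly worse
than any measurable Snellen line; only their order matters for need
classification, never their magnitude.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from enum import Enum
from typing import Optional

__all__ = [
    "AcuityDialect",
    "AcuityKind",
    "AcuityParseError",
    "AcuityThreshold",
    "AcuityValue",
    "LOGMAR_TOLERANCE",
    "LOW_VISION_LOGMAR",
    "ThresholdRole",
    "better_eye",
    "meets_threshold",
    "parse_acuity",
    "to_metric_snellen",
]

#: Absolute tolerance for logMAR comparisons.  Survey acuities are
#: categorical chart lines, so exact-line equality must compare equal
#: despite floating-point rounding of log10.
LOGMAR_TOLERANCE = 1e-6

#: Ordinal logMAR sentinels for low-vision categories, strictly worse than
#: every measurable chart line and strictly increasing in severity.
LOW_VISION_LOGMAR = {"CF": 2.0, "HM": 2.3, "PL": 2.6, "NPL": 3.0}

_LOW_VISION_ALIASES = {
    "CF": "CF",
    "COUNTING FINGERS": "CF",
    "HM": "HM",
    "HAND MOVEMENTS": "HM",
    "HAND MOTION": "HM",
    "PL": "PL",
    "LP": "PL",
    "NPL": "NPL",
    "NLP": "NPL",
}

_SNELLEN_RE = re.compile(r"^(\d+(?:\.\d+)?)\s*/\s*(\d+(?:\.\d+)?)$")


class AcuityKind(str, Enum):
    SNELLEN = "snellen"
    LOGMAR = "logmar"
    LOW_VISION_CATEGORY = "low_vision_category"


class AcuityDialect(str, Enum):
    """Input notation for acuity columns."""

    METRIC_6 = "metric_6"  # 6-metre Snellen fractions, e.g. 6/12
    IMPERIAL_20 = "imperial_20"  # 20-foot Snellen fractions, e.g. 20/40
    LOGMAR = "logmar"  # decimal logMAR, e.g. 0.3


class ThresholdRole(str, Enum):
    NEED = "need"
    OUTCOME = "outcome"


class AcuityParseError(ValueError):
    """Raised when an acuity string cannot be interpreted."""

    def __init__(self, token: str, context: str = ""):
        self.token = token
        self.context = context
        where = f" ({context})" if context else ""
        super().__init__(f"unparseable acuity {token!r}{where}")


@dataclass(frozen=True)
class AcuityValue:
    """One visual-acuity measurement on the ordinal logMAR scale."""

    notation: str
    logmar: float
    kind: AcuityKind

    def __post_init__(self):
        if not math.isfinite(self.logmar):
            raise ValueError(f"non-finite logMAR for {self.notation!r}")

    def is_better_or_equal(self, other: "AcuityValue") -> bool:
        return self.logmar <= other.logmar + LOGMAR_TOLERANCE

    def __str__(self) -> str:
        return self.notation


@dataclass(frozen=True)
class AcuityThreshold:
    """A need or outcome threshold; the conventional default is 6/12."""

    value: AcuityValue
    role: ThresholdRole

    @classmethod
    def default(cls, role: ThresholdRole = ThresholdRole.NEED) -> "AcuityThreshold":
        return cls(parse_acuity("6/12", AcuityDialect.METRIC_6), role)

    @classmethod
    def from_text(
        cls,
        text: str,
        role: ThresholdRole = ThresholdRole.NEED,
        dialect: AcuityDialect = AcuityDialect.METRIC_6,
    ) -> "AcuityThreshold":
        return cls(parse_acuity(text, dialect), role)

    def __str__(self) -> str:
        return self.value.notation


def parse_acuity(
    text: str,
    dialect: AcuityDialect | str = AcuityDialect.METRIC_6,
    context: str = "",
) -> AcuityValue:
    """Parse one acuity string in the given dialect.

    Snellen fractions map to ``logmar = log10(denominator / numerator)``;
    the logMAR dialect passes the value through; low-vision categories
    (CF/HM/PL/NPL and common synonyms) map to fixed sentinels in every
    dialect.

    Raises
    ------
    AcuityParseError
        If the text is empty or not interpretable in the dialect.
    """
    dialect = AcuityDialect(dialect)
    token = text.strip()
    if not token:
        raise AcuityParseError(text, context)

    cat = _LOW_VISION_ALIASES.get(token.upper())
    if cat is not None:
        return AcuityValue(cat, LOW_VISION_LOGMAR[cat], AcuityKind.LOW_VISION_CATEGORY)

    if dialect is AcuityDialect.LOGMAR:
        try:
            value = float(token)
        except ValueError:
            raise AcuityParseError(token, context) from None
        if not math.isfinite(value):
            raise AcuityParseError(token, context)
        return AcuityValue(token, value, AcuityKind.LOGMAR)

    m = _SNELLEN_RE.match(token)
    if m is None:
        raise AcuityParseError(token, context)
    num, den = float(m.group(1)), float(m.group(2))
    if num <= 0 or den <= 0:
        raise AcuityParseError(token, context)
    return AcuityValue(token, math.log10(den / num), AcuityKind.SNELLEN)


def to_metric_snellen(va: AcuityValue) -> str:
    """Canonical 6-metre notation for reports.

    Snellen fractions already on the 6-metre chart are preserved exactly;
    other notations are converted by ratio equivalence (20/40 ≡ 6/12).
    Low-vision categories keep their category label.
    """
    if va.kind is AcuityKind.LOW_VISION_CATEGORY:
        return va.notation
    if va.kind is AcuityKind.SNELLEN and va.notation.strip().startswith("6/"):
        return va.notation.strip()
    denominator = 6.0 * 10.0**va.logmar
    if abs(denominator - round(denominator)) < 1e-6:
        return f"6/{round(denominator):d}"
    return f"6/{denominator:.1f}"


def meets_threshold(va: AcuityValue, threshold: AcuityThreshold) -> bool:
    """True iff ``va`` is the threshold line or better.

    "Worse than" the threshold is the exact negation, so every acuity
    falls on exactly one side.
    """
    return va.logmar <= threshold.value.logmar + LOGMAR_TOLERANCE


def better_eye(
    left: Optional[AcuityValue], right: Optional[AcuityValue]
) -> Optional[AcuityValue]:
    """The better (smaller-logMAR) of two per-eye acuities.

    A missing eye falls back to the other; both missing propagates as
    missing (never as worst), so missingness surfaces downstream as an
    indeterminate classification rather than inflating unmet need.
    """
    if left is None:
        return right
    if right is None:
        return left
    return left if left.logmar <= right.logmar else right
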