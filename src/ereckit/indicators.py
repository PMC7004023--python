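"""Coverage indicators: eREC, REC and the relative quality gap.

With met need *a* (vision-impairing refractive error corrected to the
outcome threshold by the person's own correction), under-met need *b*
(correction owned but the outcome threshold not reached, although
pinhole/refraction would reach the need threshold) and unmet need *c*
(uncorrected refractive error):

    eREC (%) = a / (a + b + c) × 100
    REC  (%) = (a + b) / (a + b + c) × 100
    Relative Quality Gap (%) = (1 − eREC / REC) × 100

No-need, other-vision-impairment and indeterminate participants are
excluded from both numerator and denominator but always reported.  All
arithmetic runs on unrounded proportions; rounding happens only at report
serialisation.

Weighted mode uses survey-weight sums in numerator and denominator (a
ratio estimator for a domain proportion).  Uncertainty comes from a
Wilson score interval on the unweighted proportion, or a seeded percentile
bootstrap over clusters (or persons when unclustered) when weights or a
cluster design are in play.
"""

from __future__ import annotations

import itertools
import logging
import warnings as _warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .acuity import AcuityThreshold, ThresholdRole
from .classification import NeedCategory, PersonRecord, classify_all

__all__ = [
    "CoverageEstimate",
    "Indicator",
    "NeedSummary",
    "Report",
    "ThresholdReport",
    "confidence_interval",
    "erec",
    "multi_threshold_report",
    "quality_gap",
    "quality_gap_from_percentages",
    "rec",
    "standardise",
    "stratified_estimates",
    "tabulate_need",
]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD_PAIR = ("6/12", "6/12")


class Indicator(str, Enum):
    EREC = "eREC"
    REC = "REC"
    QUALITY_GAP = "quality_gap"


class EstimationMode(str, Enum):
    COUNTS = "counts"
    WEIGHTED = "weighted"


@dataclass(frozen=True)
class NeedSummary:
    """Category tallies for one stratum at one threshold pair.

    ``met_a + under_met_b + unmet_c`` (counts or weights, per mode) is the
    denominator of both eREC and REC: the population with vision-impairing
    refractive error.
    """

    met_a: int
    under_met_b: int
    unmet_c: int
    no_need: int
    other_vi: int
    indeterminate: int
    met_a_weight: float
    under_met_b_weight: float
    unmet_c_weight: float
    no_need_weight: float
    other_vi_weight: float
    indeterminate_weight: float
    thresholds: tuple[str, str] = DEFAULT_THRESHOLD_PAIR
    stratum: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        counts = (
            self.met_a, self.under_met_b, self.unmet_c,
            self.no_need, self.other_vi, self.indeterminate,
        )
        weights = (
            self.met_a_weight, self.under_met_b_weight, self.unmet_c_weight,
            self.no_need_weight, self.other_vi_weight, self.indeterminate_weight,
        )
        if any(c < 0 for c in counts) or any(w < 0 for w in weights):
            raise ValueError("category counts and weighted totals must be >= 0")

    @property
    def n(self) -> int:
        return (
            self.met_a + self.under_met_b + self.unmet_c
            + self.no_need + self.other_vi + self.indeterminate
        )

    def need_denominator(self, mode: EstimationMode | str = EstimationMode.COUNTS) -> float:
        mode = EstimationMode(mode)
        if mode is EstimationMode.COUNTS:
            return self.met_a + self.under_met_b + self.unmet_c
        return self.met_a_weight + self.under_met_b_weight + self.unmet_c_weight

    def numerator(
        self,
        indicator: Indicator | str,
        mode: EstimationMode | str = EstimationMode.COUNTS,
    ) -> float:
        indicator = Indicator(indicator)
        mode = EstimationMode(mode)
        if indicator is Indicator.EREC:
            return self.met_a if mode is EstimationMode.COUNTS else self.met_a_weight
        if indicator is Indicator.REC:
            if mode is EstimationMode.COUNTS:
                return self.met_a + self.under_met_b
            return self.met_a_weight + self.under_met_b_weight
        raise ValueError("quality_gap has no direct numerator; derive it from eREC and REC")


@dataclass(frozen=True)
class CoverageEstimate:
    """One indicator value with its provenance.

    ``value_pct`` is None (with ``defined`` False) when the need
    denominator — or, for the quality gap, REC — is zero; an undefined
    estimate still carries its counts and is never a silent NaN.
    """

    indicator: Indicator
    value_pct: Optional[float]
    numerator: float
    denominator: float
    ci_low_pct: Optional[float] = None
    ci_high_pct: Optional[float] = None
    ci_method: Optional[str] = None
    stratum: Mapping[str, str] = field(default_factory=dict)
    thresholds: tuple[str, str] = DEFAULT_THRESHOLD_PAIR
    standardised: bool = False
    defined: bool = True

    def __post_init__(self):
        if self.defined:
            if self.value_pct is None or not (0.0 <= self.value_pct <= 100.0):
                raise ValueError(f"indicator percentage out of [0, 100]: {self.value_pct}")


def tabulate_need(
    classified: Sequence[tuple[PersonRecord, NeedCategory]],
    thresholds: tuple[str, str] = DEFAULT_THRESHOLD_PAIR,
    stratum: Mapping[str, str] | None = None,
) -> NeedSummary:
    """Tally categories (counts and weight sums) for one threshold pair.

    All classifications passed in one call must come from the same
    threshold pair; pass them per pair.
    """
    counts = {cat: 0 for cat in NeedCategory}
    weights = {cat: 0.0 for cat in NeedCategory}
    for person, category in classified:
        counts[category] += 1
        weights[category] += person.weight
    return NeedSummary(
        met_a=counts[NeedCategory.MET],
        under_met_b=counts[NeedCategory.UNDER_MET],
        unmet_c=counts[NeedCategory.UNMET],
        no_need=counts[NeedCategory.NO_NEED],
        other_vi=counts[NeedCategory.OTHER_VI],
        indeterminate=counts[NeedCategory.INDETERMINATE],
        met_a_weight=weights[NeedCategory.MET],
        under_met_b_weight=weights[NeedCategory.UNDER_MET],
        unmet_c_weight=weights[NeedCategory.UNMET],
        no_need_weight=weights[NeedCategory.NO_NEED],
        other_vi_weight=weights[NeedCategory.OTHER_VI],
        indeterminate_weight=weights[NeedCategory.INDETERMINATE],
        thresholds=thresholds,
        stratum=dict(stratum or {}),
    )


def _ratio_estimate(
    summary: NeedSummary,
    indicator: Indicator,
    mode: EstimationMode,
) -> CoverageEstimate:
    denominator = summary.need_denominator(mode)
    if denominator <= 0:
        log.warning(
            "zero need denominator for %s in stratum %r; estimate undefined",
            indicator.value, dict(summary.stratum),
        )
        return CoverageEstimate(
            indicator=indicator,
            value_pct=None,
            numerator=0.0,
            denominator=0.0,
            stratum=summary.stratum,
            thresholds=summary.thresholds,
            defined=False,
        )
    numerator = summary.numerator(indicator, mode)
    return CoverageEstimate(
        indicator=indicator,
        value_pct=100.0 * numerator / denominator,
        numerator=float(numerator),
        denominator=float(denominator),
        stratum=summary.stratum,
        thresholds=summary.thresholds,
    )


def erec(
    summary: NeedSummary, mode: EstimationMode | str = EstimationMode.COUNTS
) -> CoverageEstimate:
    """Effective refractive error coverage: 100·a/(a+b+c)."""
    return _ratio_estimate(summary, Indicator.EREC, EstimationMode(mode))


def rec(
    summary: NeedSummary, mode: EstimationMode | str = EstimationMode.COUNTS
) -> CoverageEstimate:
    """Refractive error coverage (access regardless of outcome): 100·(a+b)/(a+b+c)."""
    return _ratio_estimate(summary, Indicator.REC, EstimationMode(mode))


def quality_gap(
    erec_est: CoverageEstimate, rec_est: CoverageEstimate
) -> CoverageEstimate:
    """Relative quality gap 100·(1 − eREC/REC) on unrounded values.

    The share of refractive error coverage that is under-met: zero when
    every owned correction achieves the outcome threshold.
    """
    if erec_est.stratum != rec_est.stratum or erec_est.thresholds != rec_est.thresholds:
        raise ValueError("quality gap requires eREC and REC from the same stratum and thresholds")
    if (
        not erec_est.defined
        or not rec_est.defined
        or rec_est.value_pct is None
        or rec_est.value_pct <= 0
    ):
        log.warning("quality gap undefined (REC is zero or undefined)")
        return CoverageEstimate(
            indicator=Indicator.QUALITY_GAP,
            value_pct=None,
            numerator=0.0,
            denominator=0.0,
            stratum=erec_est.stratum,
            thresholds=erec_est.thresholds,
            defined=False,
        )
    value = 100.0 * (1.0 - erec_est.value_pct / rec_est.value_pct)
    return CoverageEstimate(
        indicator=Indicator.QUALITY_GAP,
        value_pct=value,
        numerator=rec_est.value_pct - erec_est.value_pct,
        denominator=rec_est.value_pct,
        stratum=erec_est.stratum,
        thresholds=erec_est.thresholds,
    )


def quality_gap_from_percentages(erec_pct: float, rec_pct: float) -> float:
    """Quality gap from already-computed coverage percentages.

    Useful for recomputing the gap from published survey reports that
    print eREC and REC but not the gap itself.
    """
    if rec_pct <= 0:
        raise ValueError("REC must be positive to define a quality gap")
    return 100.0 * (1.0 - erec_pct / rec_pct)


def confidence_interval(
    summary: NeedSummary,
    indicator: Indicator | str = Indicator.EREC,
    method: str = "wilson",
    level: float = 0.95,
    reps: int = 1000,
    seed: int = 0,
    classified: Sequence[tuple[PersonRecord, NeedCategory]] | None = None,
    mode: EstimationMode | str = EstimationMode.COUNTS,
) -> tuple[float, float]:
    """Confidence interval for eREC or REC, as percentages.

    ``wilson`` is the closed-form score interval on the unweighted
    proportion.  ``cluster_bootstrap`` resamples clusters (persons when no
    cluster ids are present) with replacement and takes percentile bounds
    of the weighted estimate; it needs the person-level ``classified``
    sequence and is reproducible from ``seed``.
    """
    indicator = Indicator(indicator)
    if indicator is Indicator.QUALITY_GAP:
        raise ValueError("confidence intervals are provided for eREC and REC only")
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    denominator = summary.need_denominator(EstimationMode.COUNTS)
    if denominator <= 0:
        raise ValueError("zero need denominator: no interval")

    if method == "wilson":
        count = summary.numerator(indicator, EstimationMode.COUNTS)
        low, high = proportion_confint(count, int(denominator), alpha=1 - level, method="wilson")
        return 100.0 * float(low), 100.0 * float(high)

    if method == "cluster_bootstrap":
        if classified is None:
            raise ValueError("cluster_bootstrap requires the classified person-level data")
        if reps < 100:
            _warnings.warn(f"bootstrap with reps={reps} < 100 is unstable", stacklevel=2)
        return _cluster_bootstrap_ci(
            classified, indicator, level, reps, seed, EstimationMode(mode), summary.thresholds
        )

    raise ValueError(f"unknown CI method {method!r}")


def _cluster_bootstrap_ci(
    classified: Sequence[tuple[PersonRecord, NeedCategory]],
    indicator: Indicator,
    level: float,
    reps: int,
    seed: int,
    mode: EstimationMode,
    thresholds: tuple[str, str],
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    clusters: dict[str, list[tuple[PersonRecord, NeedCategory]]] = {}
    for i, item in enumerate(classified):
        person, _ = item
        key = person.cluster_id if person.cluster_id is not None else f"__person_{i}"
        clusters.setdefault(key, []).append(item)
    keys = sorted(clusters)
    n_clusters = len(keys)
    values = []
    for _ in range(reps):
        pick = rng.integers(0, n_clusters, size=n_clusters)
        resample = [item for k in pick for item in clusters[keys[k]]]
        summary = tabulate_need(resample, thresholds=thresholds)
        est = _ratio_estimate(summary, indicator, mode)
        if est.defined:
            values.append(est.value_pct)
    if not values:
        raise ValueError("all bootstrap resamples had zero need denominator")
    alpha = 1.0 - level
    low, high = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(low), float(high)


def _with_ci(
    est: CoverageEstimate,
    summary: NeedSummary,
    classified: Sequence[tuple[PersonRecord, NeedCategory]],
    ci_method: Optional[str],
    level: float,
    reps: int,
    seed: int,
    mode: EstimationMode,
) -> CoverageEstimate:
    if ci_method is None or not est.defined or est.indicator is Indicator.QUALITY_GAP:
        return est
    low, high = confidence_interval(
        summary, est.indicator, ci_method, level, reps, seed, classified=classified, mode=mode
    )
    return replace(est, ci_low_pct=low, ci_high_pct=high, ci_method=ci_method)


def _group_by_strata(
    classified: Sequence[tuple[PersonRecord, NeedCategory]],
    by: Sequence[str],
) -> dict[tuple[str, ...], list[tuple[PersonRecord, NeedCategory]]]:
    known = {lab for person, _ in classified for lab in person.strata} | {"sex"}
    for label in by:
        if label not in known:
            raise KeyError(
                f"unknown stratum label {label!r}; available: {sorted(known) or 'none'}"
            )
    groups: dict[tuple[str, ...], list[tuple[PersonRecord, NeedCategory]]] = {
        (): list(classified)
    }
    if by:
        for item in classified:
            person, _ = item
            key = tuple(_stratum_value(person, label) for label in by)
            groups.setdefault(key, []).append(item)
    return groups


def _stratum_value(person: PersonRecord, label: str) -> str:
    # "sex" is a first-class demographic field; other labels live in strata
    if label in person.strata:
        return str(person.strata[label])
    if label == "sex":
        return person.sex.value
    return ""


def _stratum_label(key: tuple[str, ...], by: Sequence[str]) -> dict[str, str]:
    if key == ():
        return {"overall": "overall"} if by else {}
    return dict(zip(by, key))


def stratum_summaries(
    classified: Sequence[tuple[PersonRecord, NeedCategory]],
    by: Sequence[str] = (),
    thresholds: tuple[str, str] = DEFAULT_THRESHOLD_PAIR,
) -> list[NeedSummary]:
    """Category tallies overall and per stratum combination."""
    groups = _group_by_strata(classified, by)
    return [
        tabulate_need(groups[key], thresholds=thresholds, stratum=_stratum_label(key, by))
        for key in sorted(groups)
    ]


def stratified_estimates(
    classified: Sequence[tuple[PersonRecord, NeedCategory]],
    by: Sequence[str] = (),
    mode: EstimationMode | str = EstimationMode.COUNTS,
    thresholds: tuple[str, str] = DEFAULT_THRESHOLD_PAIR,
    ci_method: Optional[str] = "wilson",
    level: float = 0.95,
    reps: int = 1000,
    seed: int = 0,
) -> list[CoverageEstimate]:
    """eREC, REC and quality gap overall and per stratum combination.

    Strata with zero need denominator yield flagged undefined estimates
    rather than disappearing from the output.
    """
    mode = EstimationMode(mode)
    groups = _group_by_strata(classified, by)

    out: list[CoverageEstimate] = []
    for key in sorted(groups):
        stratum = _stratum_label(key, by)
        subset = groups[key]
        summary = tabulate_need(subset, thresholds=thresholds, stratum=stratum)
        e = _with_ci(erec(summary, mode), summary, subset, ci_method, level, reps, seed, mode)
        r = _with_ci(rec(summary, mode), summary, subset, ci_method, level, reps, seed, mode)
        out.extend([e, r, quality_gap(e, r)])
    return out


def standardise(
    stratum_estimates: Sequence[CoverageEstimate],
    reference: Mapping[tuple[str, ...] | str, float],
) -> CoverageEstimate:
    """Direct standardisation to a reference population.

    Weights each stratum estimate by the reference population share of
    that stratum: ``Σ share_s · value_s``.  Shares must cover every
    stratum and sum to one; a zero-denominator stratum cannot be
    standardised — re-estimate with coarser strata.
    """
    ests = [e for e in stratum_estimates if e.stratum and "overall" not in e.stratum]
    if not ests:
        raise ValueError("no stratum-level estimates to standardise")
    indicators = {e.indicator for e in ests}
    if len(indicators) != 1:
        raise ValueError("standardise one indicator at a time")
    thresholds = {e.thresholds for e in ests}
    if len(thresholds) != 1:
        raise ValueError("standardise within one threshold pair")

    shares = {}
    for key, share in reference.items():
        shares[(key,) if isinstance(key, str) else tuple(key)] = float(share)
    total = sum(shares.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"reference population shares sum to {total}, expected 1")

    value = 0.0
    for est in ests:
        key = tuple(est.stratum.values())
        if key not in shares:
            raise KeyError(f"stratum {key} missing from reference population table")
        if not est.defined:
            raise ValueError(
                f"stratum {key} has zero need denominator; use coarser strata "
                "before standardising"
            )
        value += shares[key] * est.value_pct
    return CoverageEstimate(
        indicator=ests[0].indicator,
        value_pct=value,
        numerator=value,
        denominator=100.0,
        thresholds=ests[0].thresholds,
        stratum={"standardised": "reference"},
        standardised=True,
    )


@dataclass
class ThresholdReport:
    """All indicators at one (need, outcome) threshold pair."""

    thresholds: tuple[str, str]
    summary: NeedSummary
    estimates: list[CoverageEstimate]
    stratum_summaries: list[NeedSummary] = field(default_factory=list)


@dataclass
class Report:
    """Full multi-threshold report plus reproducibility metadata."""

    entries: list[ThresholdReport]
    metadata: dict


def multi_threshold_report(
    records: Sequence[PersonRecord],
    need_thresholds: Sequence[str] = ("6/12",),
    outcome_thresholds: Sequence[str] = ("6/12",),
    by: Sequence[str] = (),
    mode: EstimationMode | str = EstimationMode.COUNTS,
    ci_method: Optional[str] = "wilson",
    level: float = 0.95,
    reps: int = 1000,
    seed: int = 0,
    metadata: Mapping[str, object] | None = None,
) -> Report:
    """Indicators at every requested threshold pair.

    The 6/12-need, 6/12-outcome pair is the convention for international
    comparison and is appended automatically when not requested.
    """
    if not need_thresholds or not outcome_thresholds:
        raise ValueError("threshold lists must be non-empty")
    pairs = list(dict.fromkeys(itertools.product(need_thresholds, outcome_thresholds)))
    if DEFAULT_THRESHOLD_PAIR not in pairs:
        log.info("appending the standard 6/12 need and outcome thresholds for comparability")
        pairs.append(DEFAULT_THRESHOLD_PAIR)

    mode = EstimationMode(mode)
    entries = []
    for need_text, outcome_text in pairs:
        need = AcuityThreshold.from_text(need_text, ThresholdRole.NEED)
        outcome = AcuityThreshold.from_text(outcome_text, ThresholdRole.OUTCOME)
        categories = classify_all(records, need, outcome)  # order-preserving
        classified = [(person, cat) for person, (_, cat) in zip(records, categories)]
        summary = tabulate_need(classified, thresholds=(need_text, outcome_text))
        estimates = stratified_estimates(
            classified,
            by=by,
            mode=mode,
            thresholds=(need_text, outcome_text),
            ci_method=ci_method,
            level=level,
            reps=reps,
            seed=seed,
        )
        entries.append(
            ThresholdReport(
                thresholds=(need_text, outcome_text),
                summary=summary,
                estimates=estimates,
                stratum_summaries=stratum_summaries(
                    classified, by=by, thresholds=(need_text, outcome_text)
                ),
            )
        )
    meta = {
        "threshold_pairs": [list(p) for p in pairs],
        "mode": mode.value,
        "ci_method": ci_method,
        "ci_level": level,
        "bootstrap_reps": reps,
        "seed": seed,
        "n_records": len(records),
    }
    meta.update(dict(metadata or {}))
    return Report(entries=entries, metadata=meta)
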