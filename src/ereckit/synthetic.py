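"""Synthetic survey cohorts with known true refractive-error coverage.

No public individual-level dataset accompanies the coverage indicators
implemented here, so every pipeline stage is exercised against generated
cohorts whose true need category is known per person.  The generative
model draws, independently per person:

* vision-impairing refractive error (probability ``re_prevalence``,
  optionally per age band);
* non-refractive ("other") vision impairment, independent of refractive
  status (``other_vi_prevalence``) — it caps pinhole acuity below the
  need threshold, so these people are classified OTHER_VI;
* possession of distance correction, only among those with refractive
  error (``uptake``);
* a good visual outcome with that correction (``quality``), only among
  owners.

Acuities are then emitted as chart lines consistent with the latent
state, so the classification flowchart must reproduce the latent category
exactly whenever no measurement is missing.  Under independence the
population eREC among those in need is ``uptake × quality`` and REC is
``uptake`` — closed forms used by the parameter-recovery tests.

Because ``quality`` is already conditional on possession, conditioning is
the correlation knob; no separate dependence parameter is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .acuity import AcuityDialect, AcuityThreshold, ThresholdRole, parse_acuity
from .classification import NeedCategory, PersonRecord, Sex, classify_all
from .indicators import confidence_interval, erec, tabulate_need

__all__ = [
    "CHART_LINES",
    "GeneratorConfig",
    "TruthRecord",
    "generate_population",
    "recovery_experiment",
    "true_erec",
    "true_rec",
]

#: Standard distance chart lines, best to worst, used for emitted acuities.
CHART_LINES = ["6/6", "6/9", "6/12", "6/18", "6/24", "6/36", "6/60", "3/60", "CF", "HM"]

# Severity mix of better-eye presenting lines among the vision impaired,
# skewed towards mild impairment as in most population surveys.
_IMPAIRED_SEVERITY = np.array([0.30, 0.25, 0.18, 0.15, 0.07, 0.03, 0.02])


class GeneratorConfig(BaseModel):
    """Parameters of the synthetic survey population."""

    n: int = Field(default=10_000, ge=0)
    seed: int = 0
    re_prevalence: Union[float, dict[str, float]] = 0.3
    uptake: float = Field(default=0.5, ge=0.0, le=1.0)
    quality: float = Field(default=0.8, ge=0.0, le=1.0)
    other_vi_prevalence: float = Field(default=0.05, ge=0.0, le=1.0)
    missing_pinhole_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    age_band_edges: list[int] = Field(default=[15, 30, 45, 60, 80])
    age_band_shares: Optional[list[float]] = None
    sex_ratio: float = Field(default=0.5, ge=0.0, le=1.0)  # share female
    line_jitter_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    need_threshold: str = "6/12"
    outcome_threshold: str = "6/12"
    n_clusters: int = Field(default=0, ge=0)  # 0 = unclustered

    @model_validator(mode="after")
    def _check(self):
        if isinstance(self.re_prevalence, dict):
            for band, p in self.re_prevalence.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"re_prevalence[{band!r}] outside [0, 1]")
            expected = set(self._band_labels())
            if set(self.re_prevalence) != expected:
                raise ValueError(
                    f"per-band re_prevalence keys {sorted(self.re_prevalence)} "
                    f"must match age bands {sorted(expected)}"
                )
        elif not 0.0 <= self.re_prevalence <= 1.0:
            raise ValueError("re_prevalence outside [0, 1]")
        if len(self.age_band_edges) < 2 or any(
            hi <= lo for lo, hi in zip(self.age_band_edges, self.age_band_edges[1:])
        ):
            raise ValueError("age_band_edges must be strictly increasing, length >= 2")
        if self.age_band_shares is not None:
            if len(self.age_band_shares) != len(self.age_band_edges) - 1:
                raise ValueError("age_band_shares length must be number of bands")
            if abs(sum(self.age_band_shares) - 1.0) > 1e-9:
                raise ValueError("age_band_shares must sum to 1")
        return self

    def _band_labels(self) -> list[str]:
        edges = self.age_band_edges
        return [f"{lo}-{hi - 1}" for lo, hi in zip(edges, edges[1:])]


@dataclass(frozen=True)
class TruthRecord:
    """Latent state and the need category it implies."""

    person_id: str
    true_category: NeedCategory
    has_re: bool
    has_other_vi: bool
    has_correction: bool
    correction_good: bool


def true_erec(config: GeneratorConfig) -> float:
    """Population eREC among those in need: uptake × quality."""
    return config.uptake * config.quality


def true_rec(config: GeneratorConfig) -> float:
    """Population REC among those in need: uptake (access regardless of outcome)."""
    return config.uptake


def _true_category(
    has_re: bool, has_other_vi: bool, has_correction: bool, correction_good: bool
) -> NeedCategory:
    if has_other_vi:
        return NeedCategory.OTHER_VI
    if not has_re:
        return NeedCategory.NO_NEED
    if not has_correction:
        return NeedCategory.UNMET
    return NeedCategory.MET if correction_good else NeedCategory.UNDER_MET


def _draw_line(rng: np.random.Generator, indices: np.ndarray, probs: np.ndarray) -> int:
    return int(rng.choice(indices, p=probs))


def generate_population(
    config: GeneratorConfig,
) -> tuple[list[PersonRecord], list[TruthRecord]]:
    """Generate one cohort; fully reproducible from ``config.seed``.

    Per-eye acuities are emitted around the drawn better-eye line (the
    fellow eye is the same line or one worse), consistent with the latent
    category, so classification at the configured thresholds recovers the
    truth for every person with no missing measurements.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    need_idx = CHART_LINES.index(config.need_threshold)
    outcome_idx = CHART_LINES.index(config.outcome_threshold)

    meets_need = np.arange(0, need_idx + 1)
    worse_than_need = np.arange(need_idx + 1, len(CHART_LINES))
    meets_outcome = np.arange(0, outcome_idx + 1)
    worse_than_outcome = np.arange(outcome_idx + 1, len(CHART_LINES))

    sev = _IMPAIRED_SEVERITY[: len(worse_than_need)].copy()
    sev /= sev.sum()

    edges = np.asarray(config.age_band_edges)
    n_bands = len(edges) - 1
    band_shares = (
        np.asarray(config.age_band_shares)
        if config.age_band_shares is not None
        else np.full(n_bands, 1.0 / n_bands)
    )
    band_labels = config._band_labels()
    if isinstance(config.re_prevalence, dict):
        p_re_by_band = np.array([config.re_prevalence[b] for b in band_labels])
    else:
        p_re_by_band = np.full(n_bands, float(config.re_prevalence))

    # Pre-draw vectorised latent state.
    band = rng.choice(n_bands, size=n, p=band_shares) if n else np.empty(0, dtype=int)
    age = (
        edges[band] + rng.integers(0, edges[band + 1] - edges[band], size=n)
        if n
        else np.empty(0, dtype=int)
    )
    female = rng.random(n) < config.sex_ratio
    has_re = rng.random(n) < p_re_by_band[band] if n else np.empty(0, dtype=bool)
    has_other_vi = rng.random(n) < config.other_vi_prevalence
    has_correction = has_re & (rng.random(n) < config.uptake)
    correction_good = has_correction & (rng.random(n) < config.quality)
    pinhole_missing = rng.random(n) < config.missing_pinhole_rate
    cluster = (
        rng.integers(0, config.n_clusters, size=n) if config.n_clusters else None
    )

    def jitter(idx: int, allowed: np.ndarray) -> int:
        # one-line jitter that stays on the same side of the threshold
        if config.line_jitter_prob and rng.random() < config.line_jitter_prob:
            step = -1 if rng.random() < 0.5 else 1
            if idx + step in allowed:
                return idx + step
        return idx

    def eyes(idx: int) -> tuple[str, str]:
        # fellow eye same or one line worse; the better eye drives classification
        fellow = min(idx + int(rng.random() < 0.4), len(CHART_LINES) - 1)
        if rng.random() < 0.5:
            return CHART_LINES[idx], CHART_LINES[fellow]
        return CHART_LINES[fellow], CHART_LINES[idx]

    records: list[PersonRecord] = []
    truths: list[TruthRecord] = []
    for i in range(n):
        category = _true_category(
            bool(has_re[i]), bool(has_other_vi[i]),
            bool(has_correction[i]), bool(correction_good[i]),
        )
        ucva = cva = pinhole = (None, None)
        impaired = bool(has_re[i]) or bool(has_other_vi[i])
        if not impaired:
            ucva_idx = jitter(_draw_line(rng, meets_need, None), meets_need)
            ucva = eyes(ucva_idx)
        else:
            ucva_idx = jitter(worse_than_need[_draw_line(rng, np.arange(len(sev)), sev)],
                              worse_than_need)
            ucva = eyes(ucva_idx)
            if has_other_vi[i]:
                # pinhole (over correction for owners) stays below the need line
                ph_idx = min(ucva_idx, worse_than_need[-1])
                if not pinhole_missing[i]:
                    pinhole = eyes(ph_idx)
                if has_correction[i]:
                    cva = eyes(ucva_idx)
            elif has_correction[i]:
                if correction_good[i]:
                    # CVA at/better than the outcome line; pinhole not required
                    cva = eyes(jitter(_draw_line(rng, meets_outcome, None), meets_outcome))
                else:
                    cva = eyes(jitter(
                        worse_than_outcome[
                            _draw_line(
                                rng,
                                np.arange(len(worse_than_outcome)),
                                None,
                            )
                        ],
                        worse_than_outcome,
                    ))
                    if not pinhole_missing[i]:
                        pinhole = eyes(jitter(_draw_line(rng, meets_need, None), meets_need))
            else:
                if not pinhole_missing[i]:
                    pinhole = eyes(jitter(_draw_line(rng, meets_need, None), meets_need))

        def acuity(text: Optional[str]):
            return parse_acuity(text, AcuityDialect.METRIC_6) if text else None

        pid = f"p{i:06d}"
        records.append(
            PersonRecord(
                person_id=pid,
                wears_distance_correction=bool(has_correction[i]),
                ucva_left=acuity(ucva[0]),
                ucva_right=acuity(ucva[1]),
                cva_left=acuity(cva[0]),
                cva_right=acuity(cva[1]),
                pinhole_left=acuity(pinhole[0]),
                pinhole_right=acuity(pinhole[1]),
                age_years=int(age[i]),
                sex=Sex.FEMALE if female[i] else Sex.MALE,
                strata={
                    "age_band": band_labels[band[i]],
                    "sex": "female" if female[i] else "male",
                },
                weight=1.0,
                cluster_id=f"c{cluster[i]:04d}" if cluster is not None else None,
            )
        )
        truths.append(
            TruthRecord(
                person_id=pid,
                true_category=category,
                has_re=bool(has_re[i]),
                has_other_vi=bool(has_other_vi[i]),
                has_correction=bool(has_correction[i]),
                correction_good=bool(correction_good[i]),
            )
        )
    return records, truths


def recovery_experiment(
    config: GeneratorConfig,
    n_seeds: int = 50,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Repeated generate → classify → estimate runs against the truth.

    Returns one row per seed with the estimated eREC (as a fraction), the
    generative truth, the absolute error, Wilson confidence bounds and
    whether they cover the truth.  Seeds are derived reproducibly from
    ``config.seed``.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    truth = true_erec(config)
    need = AcuityThreshold.from_text(config.need_threshold, ThresholdRole.NEED)
    outcome = AcuityThreshold.from_text(config.outcome_threshold, ThresholdRole.OUTCOME)

    rows = []
    for seed in seeds:
        cohort_config = config.model_copy(update={"seed": int(seed)})
        records, _ = generate_population(cohort_config)
        classified_ids = classify_all(records, need, outcome)
        classified = [(p, cat) for p, (_, cat) in zip(records, classified_ids)]
        summary = tabulate_need(
            classified, thresholds=(config.need_threshold, config.outcome_threshold)
        )
        est = erec(summary)
        low, high = confidence_interval(summary, "eREC", "wilson", ci_level)
        est_frac = est.value_pct / 100.0 if est.defined else np.nan
        rows.append(
            {
                "seed": int(seed),
                "erec_hat": est_frac,
                "erec_true": truth,
                "abs_error": abs(est_frac - truth),
                "ci_low": low / 100.0,
                "ci_high": high / 100.0,
                "covered": bool(low / 100.0 <= truth <= high / 100.0),
            }
        )
    return pd.DataFrame(rows)
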