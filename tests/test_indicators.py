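"""Coverage indicator arithmetic, uncertainty and aggregation."""

import math
import random
from dataclasses import replace

import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import acuity, random_person
from ereckit.classification import NeedCategory, PersonRecord
from ereckit.datasets import PUBLISHED_COVERAGE
from ereckit.indicators import (
    CoverageEstimate,
    Indicator,
    NeedSummary,
    confidence_interval,
    erec,
    multi_threshold_report,
    quality_gap,
    quality_gap_from_percentages,
    rec,
    standardise,
    stratified_estimates,
    tabulate_need,
)


def summary(a=0, b=0, c=0, no_need=0, other_vi=0, indeterminate=0, wa=None, wb=None, wc=None):
    return NeedSummary(
        met_a=a, under_met_b=b, unmet_c=c,
        no_need=no_need, other_vi=other_vi, indeterminate=indeterminate,
        met_a_weight=wa if wa is not None else float(a),
        under_met_b_weight=wb if wb is not None else float(b),
        unmet_c_weight=wc if wc is not None else float(c),
        no_need_weight=float(no_need),
        other_vi_weight=float(other_vi),
        indeterminate_weight=float(indeterminate),
    )


class TestPointEstimates:
    def test_worked_example_values(self):
        s = summary(a=25, b=5, c=50, no_need=20)
        e, r = erec(s), rec(s)
        assert e.value_pct == pytest.approx(31.25)
        assert r.value_pct == pytest.approx(37.5)
        g = quality_gap(e, r)
        assert g.value_pct == pytest.approx(100 * (1 - 31.25 / 37.5))
        assert round(g.value_pct, 1) == 16.7

    @pytest.mark.parametrize(
        "a, b, c, expected_erec, expected_rec",
        [(10, 0, 0, 100.0, 100.0), (0, 5, 5, 0.0, 50.0), (3, 1, 0, 75.0, 100.0),
         (0, 0, 10, 0.0, 0.0)],
    )
    def test_boundary_compositions(self, a, b, c, expected_erec, expected_rec):
        s = summary(a=a, b=b, c=c)
        assert erec(s).value_pct == pytest.approx(expected_erec)
        assert rec(s).value_pct == pytest.approx(expected_rec)

    def test_zero_denominator_is_flagged_not_nan(self):
        s = summary(no_need=10)
        e = erec(s)
        assert not e.defined and e.value_pct is None

    def test_quality_gap_zero_when_no_under_met(self):
        s = summary(a=10, c=5)
        g = quality_gap(erec(s), rec(s))
        assert g.value_pct == pytest.approx(0.0)

    def test_quality_gap_undefined_when_rec_zero(self):
        s = summary(c=10)
        g = quality_gap(erec(s), rec(s))
        assert not g.defined

    def test_weighted_mode_uses_weight_sums(self):
        s = summary(a=2, b=1, c=1, wa=20.0, wb=5.0, wc=15.0)
        assert erec(s, "weighted").value_pct == pytest.approx(100 * 20 / 40)
        assert erec(s, "counts").value_pct == pytest.approx(50.0)


def test_published_survey_quality_gaps_recompute():
    """Gaps recomputed from published eREC/REC pairs at one-decimal rounding."""
    expected = {
        ("pakistan_2008", "national"): 33.5,
        ("south_africa_2016", "subnational"): 5.3,
        ("australia_2017", "non_indigenous"): 5.3,
    }
    for key, gap in expected.items():
        e_pct, r_pct = PUBLISHED_COVERAGE[key]
        assert round(quality_gap_from_percentages(e_pct, r_pct), 1) == gap


def test_tabulate_need_counts_and_weights(worked_example_classified):
    s = tabulate_need(worked_example_classified)
    assert (s.met_a, s.under_met_b, s.unmet_c, s.no_need) == (25, 5, 50, 20)
    assert s.other_vi == 0 and s.indeterminate == 0
    assert s.need_denominator() == 80
    assert s.need_denominator("weighted") == pytest.approx(80.0)


def test_weight_two_equals_two_identical_unit_weights():
    p1 = PersonRecord(person_id="a", wears_distance_correction=False,
                      ucva_left=acuity("6/60"), pinhole_left=acuity("6/6"), weight=2.0)
    p2 = replace(p1, person_id="b", weight=1.0)
    p3 = replace(p1, person_id="c", weight=1.0)
    s_dup = tabulate_need([(p1, NeedCategory.UNMET)])
    s_two = tabulate_need([(p2, NeedCategory.UNMET), (p3, NeedCategory.UNMET)])
    assert s_dup.unmet_c_weight == s_two.unmet_c_weight


class TestConfidenceIntervals:
    def test_wilson_matches_closed_form(self):
        # score interval for 25 successes of 80, z = 1.95996...
        low, high = confidence_interval(summary(a=25, b=5, c=50), "eREC", "wilson", 0.95)
        assert low == pytest.approx(22.1504041129, abs=1e-6)
        assert high == pytest.approx(42.0677757447, abs=1e-6)

    def test_wilson_lower_bound_zero_at_zero_successes(self):
        low, _ = confidence_interval(summary(a=0, b=30, c=50), "eREC", "wilson", 0.95)
        assert low == 0.0

    def test_bootstrap_deterministic_under_seed(self):
        rng = random.Random(11)
        records = [random_person(rng, f"r{i}") for i in range(150)]
        for i, p in enumerate(records):
            p.cluster_id = f"c{i % 10}"
        from ereckit.classification import classify

        classified = [(p, classify(p)) for p in records]
        s = tabulate_need(classified)
        kwargs = dict(level=0.95, reps=200, classified=classified)
        ci1 = confidence_interval(s, "eREC", "cluster_bootstrap", seed=5, **kwargs)
        ci2 = confidence_interval(s, "eREC", "cluster_bootstrap", seed=5, **kwargs)
        ci3 = confidence_interval(s, "eREC", "cluster_bootstrap", seed=6, **kwargs)
        assert ci1 == ci2
        assert ci1 != ci3
        assert ci1[0] <= ci1[1]

    def test_bad_level_rejected(self):
        with pytest.raises(ValueError):
            confidence_interval(summary(a=5, c=5), "eREC", "wilson", 1.5)

    def test_low_reps_warns(self):
        rng = random.Random(3)
        records = [random_person(rng, f"r{i}") for i in range(60)]
        from ereckit.classification import classify

        classified = [(p, classify(p)) for p in records]
        s = tabulate_need(classified)
        with pytest.warns(UserWarning):
            confidence_interval(s, "eREC", "cluster_bootstrap", reps=50,
                                classified=classified)


class TestStratification:
    def _records(self):
        out = []
        # identical composition in both strata: 2 met, 1 under-met, 2 unmet each
        for stratum in ("urban", "rural"):
            for i in range(2):
                out.append(PersonRecord(
                    person_id=f"{stratum}m{i}", wears_distance_correction=True,
                    ucva_left=acuity("6/24"), cva_left=acuity("6/9"),
                    strata={"residence": stratum}))
            out.append(PersonRecord(
                person_id=f"{stratum}b", wears_distance_correction=True,
                ucva_left=acuity("6/24"), cva_left=acuity("6/18"),
                pinhole_left=acuity("6/9"), strata={"residence": stratum}))
            for i in range(2):
                out.append(PersonRecord(
                    person_id=f"{stratum}c{i}", wears_distance_correction=False,
                    ucva_left=acuity("6/60"), pinhole_left=acuity("6/6"),
                    strata={"residence": stratum}))
        return out

    def _classified(self, records):
        from ereckit.classification import classify

        return [(p, classify(p)) for p in records]

    def test_homogeneous_strata_equal_overall(self):
        classified = self._classified(self._records())
        ests = stratified_estimates(classified, by=["residence"], ci_method=None)
        erecs = {tuple(e.stratum.items()): e.value_pct
                 for e in ests if e.indicator is Indicator.EREC}
        values = set(round(v, 9) for v in erecs.values())
        assert len(values) == 1  # both strata and overall agree

    def test_overall_is_denominator_weighted_mean_of_strata(self):
        records = self._records()
        # make rural all-unmet so strata differ
        for p in records:
            if p.strata["residence"] == "rural" and p.wears_distance_correction:
                p.wears_distance_correction = False
                p.cva_left = None
                p.pinhole_left = acuity("6/6")
        classified = self._classified(records)
        ests = stratified_estimates(classified, by=["residence"], ci_method=None)
        by_stratum = {
            e.stratum.get("residence", e.stratum.get("overall")): e
            for e in ests if e.indicator is Indicator.EREC
        }
        overall = by_stratum["overall"]
        pooled = sum(
            e.value_pct * e.denominator for k, e in by_stratum.items() if k != "overall"
        ) / sum(e.denominator for k, e in by_stratum.items() if k != "overall")
        assert overall.value_pct == pytest.approx(pooled)

    def test_all_no_need_stratum_flagged(self):
        records = self._records()
        for p in records:
            if p.strata["residence"] == "rural":
                p.ucva_left = acuity("6/6")
        ests = stratified_estimates(self._classified(records), by=["residence"],
                                    ci_method=None)
        rural = [e for e in ests
                 if e.stratum.get("residence") == "rural" and e.indicator is Indicator.EREC]
        assert rural and not rural[0].defined

    def test_unknown_label_lists_available(self):
        classified = self._classified(self._records())
        with pytest.raises(KeyError, match="residence"):
            stratified_estimates(classified, by=["province"], ci_method=None)


class TestStandardise:
    def _stratum_estimates(self, values):
        return [
            CoverageEstimate(indicator=Indicator.EREC, value_pct=v, numerator=v,
                             denominator=100.0, stratum={"age_band": band})
            for band, v in values.items()
        ]

    def test_known_mixture(self):
        ests = self._stratum_estimates({"young": 0.0, "old": 100.0})
        out = standardise(ests, {"young": 0.25, "old": 0.75})
        assert out.value_pct == pytest.approx(75.0)
        assert out.standardised

    def test_self_standardisation_identity(self, worked_example_classified):
        # reference equal to the sample's own need distribution -> crude value
        ests = stratified_estimates(worked_example_classified, by=["residence"],
                                    ci_method=None)
        per = [e for e in ests
               if e.indicator is Indicator.EREC and "residence" in e.stratum]
        overall = [e for e in ests
                   if e.indicator is Indicator.EREC and "overall" in e.stratum][0]
        total = sum(e.denominator for e in per)
        reference = {e.stratum["residence"]: e.denominator / total for e in per}
        out = standardise(per, reference)
        assert out.value_pct == pytest.approx(overall.value_pct)

    def test_order_invariance(self):
        ests = self._stratum_estimates({"a": 10.0, "b": 60.0, "c": 90.0})
        ref = {"a": 0.2, "b": 0.3, "c": 0.5}
        assert standardise(ests, ref).value_pct == pytest.approx(
            standardise(list(reversed(ests)), ref).value_pct
        )

    def test_shares_must_sum_to_one(self):
        ests = self._stratum_estimates({"a": 10.0, "b": 60.0})
        with pytest.raises(ValueError, match="sum"):
            standardise(ests, {"a": 0.5, "b": 0.6})

    def test_missing_stratum_in_reference(self):
        ests = self._stratum_estimates({"a": 10.0, "b": 60.0})
        with pytest.raises(KeyError):
            standardise(ests, {"a": 1.0})


class TestMultiThresholdReport:
    def test_standard_pair_always_appended(self, worked_example):
        report = multi_threshold_report(worked_example, ["6/18"], ["6/18"],
                                        ci_method=None)
        pairs = [entry.thresholds for entry in report.entries]
        assert ("6/18", "6/18") in pairs and ("6/12", "6/12") in pairs

    def test_single_entry_when_standard_requested(self, worked_example):
        report = multi_threshold_report(worked_example, ["6/12"], ["6/12"],
                                        ci_method=None)
        assert len(report.entries) == 1

    def test_fixture_erec_at_standard_pair(self, worked_example):
        report = multi_threshold_report(worked_example, ["6/12"], ["6/12"],
                                        ci_method=None)
        e = [x for x in report.entries[0].estimates if x.indicator is Indicator.EREC][0]
        assert e.value_pct == pytest.approx(31.25)

    def test_empty_threshold_list_rejected(self, worked_example):
        with pytest.raises(ValueError):
            multi_threshold_report(worked_example, [], ["6/12"])


# ---------------------------------------------------------------------------
# invariants

counts = st.integers(min_value=0, max_value=10_000)


@given(a=counts, b=counts, c=counts)
def test_erec_never_exceeds_rec(a, b, c):
    if a + b + c == 0:
        return
    s = summary(a=a, b=b, c=c)
    e, r = erec(s), rec(s)
    assert e.value_pct <= r.value_pct + 1e-9
    g = quality_gap(e, r)
    if r.value_pct > 0:
        assert -1e-9 <= g.value_pct <= 100 + 1e-9
        assert (abs(g.value_pct) < 1e-9) == (b == 0)


@given(a=counts, b=counts, c=counts, extra=st.integers(min_value=0, max_value=500))
def test_excluded_categories_do_not_move_estimates(a, b, c, extra):
    if a + b + c == 0:
        return
    base = summary(a=a, b=b, c=c)
    padded = summary(a=a, b=b, c=c, no_need=extra, other_vi=extra, indeterminate=extra)
    assert erec(base).value_pct == pytest.approx(erec(padded).value_pct)
    assert rec(base).value_pct == pytest.approx(rec(padded).value_pct)


@given(a=counts, b=counts, c=counts,
       scale=st.floats(min_value=0.01, max_value=100, allow_nan=False))
def test_weight_rescaling_leaves_weighted_estimates_unchanged(a, b, c, scale):
    if a + b + c == 0:
        return
    base = summary(a=a, b=b, c=c)
    scaled = summary(a=a, b=b, c=c, wa=a * scale, wb=b * scale, wc=c * scale)
    assert erec(base, "weighted").value_pct == pytest.approx(
        erec(scaled, "weighted").value_pct
    )
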