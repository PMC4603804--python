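"""Closed-form sample size calculations: worked values, properties, errors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import dsampsize as dz
from dsampsize.exceptions import FeasibilityError, InvalidInputError

CLIP_PRIOR = dz.PriorStudy(events=502, se_d1=0.09, d1=1.01, censoring=0.07)


def design_sig(sided, power=0.9, delta=0.25, cens=0.0, alpha=0.05):
    return dz.DesignSpec(alpha=alpha, sidedness=sided, power=power,
                         margin=delta, censoring=cens)


def design_ci(w=0.2, cens=0.0, alpha=0.05):
    return dz.DesignSpec(alpha=alpha, halfwidth=w, censoring=cens)


class TestLambda:
    def test_study_based_lambda_from_liver_cancer_study(self):
        lam = dz.lambda_from_study(CLIP_PRIOR)
        assert lam.value == pytest.approx(4.0662, abs=1e-10)
        assert round(lam.value, 1) == 4.1
        assert lam.source == "study"

    def test_study_based_lambda_simple_arithmetic(self):
        lam = dz.lambda_from_study(dz.PriorStudy(events=1000, se_d1=0.1))
        assert lam.value == pytest.approx(10.0)

    @pytest.mark.parametrize("events,se", [(502, 0.0), (502, -0.1), (0, 0.09)])
    def test_degenerate_prior_rejected(self, events, se):
        with pytest.raises(InvalidInputError):
            dz.PriorStudy(events=events, se_d1=se)

    @pytest.mark.parametrize(
        "d,cens,expected",
        [(1.3, 0.10, 4.62), (1.1, 0.10, 4.08), (1.5, 0.10, 5.24)],
    )
    def test_model_based_lambda_published_values(self, d, cens, expected):
        assert round(dz.lambda_from_model(d, cens).value, 2) == expected

    def test_model_based_lambda_zero_d_reduces_to_intercept(self):
        with pytest.warns(UserWarning):  # d below the fitted region
            assert dz.lambda_from_model(0.0, 0.0).value == pytest.approx(2.66)

    def test_model_based_lambda_rejects_negative_d(self):
        with pytest.raises(InvalidInputError):
            dz.lambda_from_model(-0.5, 0.1)

    def test_model_based_lambda_warns_outside_fitted_region(self):
        with pytest.warns(UserWarning):
            dz.lambda_from_model(3.8, 0.1)

    @given(d=st.floats(0.1, 3.5))
    def test_uncensored_lambda_closed_form(self, d):
        assert dz.lambda_from_model(d, 0.0).value == pytest.approx(
            2.66 + 1.26 * d**1.9
        )

    def test_lambda_increasing_in_d_at_moderate_censoring(self):
        # at heavier censoring the (d*cens)^1.3 term dominates for very small
        # d, so monotonicity only holds from a censoring-dependent floor
        for cens, d_lo in ((0.0, 0.1), (0.1, 0.1), (0.3, 0.1), (0.5, 0.2)):
            grid = np.linspace(d_lo, 3.5, 200)
            values = [dz.lambda_from_model(d, cens).value for d in grid]
            assert np.all(np.diff(values) > 0)


class TestQuantiles:
    @pytest.mark.parametrize(
        "alpha,sided,power,expected",
        [
            (0.05, "one-sided", 0.90, 2.9264),
            (0.05, "two-sided", 0.50, 1.9600),
            (0.05, "two-sided", 0.90, 3.2415),
        ],
    )
    def test_zz_against_normal_quantiles(self, alpha, sided, power, expected):
        assert dz.zz_quantile(alpha, sided, power) == pytest.approx(expected, abs=5e-5)

    def test_zz_matches_scipy_composition(self):
        assert dz.zz_quantile(0.10, 1, 0.8) == pytest.approx(
            stats.norm.ppf(0.90) + stats.norm.ppf(0.8)
        )

    @pytest.mark.parametrize("alpha,power", [(0.0, 0.9), (1.0, 0.9), (0.05, 1.0)])
    def test_out_of_range_probabilities_rejected(self, alpha, power):
        with pytest.raises(InvalidInputError):
            dz.zz_quantile(alpha, 2, power)


class TestEventCalculations:
    """The eleven worked event counts of the liver-cancer (CLIP) example."""

    def test_significance_with_study_lambda(self):
        lam = dz.lambda_from_study(CLIP_PRIOR)
        assert dz.events_significance(lam, design_sig("one-sided")).events == 558
        assert dz.events_significance(lam, design_sig("two-sided")).events == 684

    def test_ci_with_study_lambda(self):
        lam = dz.lambda_from_study(CLIP_PRIOR)
        assert dz.events_ci(lam, design_ci()).events == 391

    def test_significance_with_model_lambda(self):
        lam = dz.lambda_from_model(1.3, 0.10)
        assert dz.events_significance(lam, design_sig("one-sided")).events == 633
        assert dz.events_significance(lam, design_sig("two-sided")).events == 777

    @pytest.mark.parametrize(
        "d,cens,events,patients",
        [(1.3, 0.10, 444, 494), (1.1, 0.10, 392, 436),
         (1.5, 0.10, 504, 560), (1.5, 0.30, 461, 659)],
    )
    def test_ci_with_model_lambda_over_plausible_range(self, d, cens, events, patients):
        res = dz.events_ci(dz.lambda_from_model(d, cens), design_ci(cens=cens))
        assert res.events == events
        assert res.patients == patients

    def test_unit_ratio_gives_one_event(self):
        lam = dz.LambdaEstimate(value=1.0, source="study")
        zz = dz.zz_quantile(0.05, 1, 0.9)
        res = dz.events_significance(
            lam, dz.DesignSpec(alpha=0.05, sidedness=1, power=0.9, margin=zz)
        )
        assert res.events == 1

    def test_displayed_lambda_would_mislead(self):
        # rounding lambda_s to the displayed 4.1 changes the answer: full
        # precision is required internally
        rounded = dz.LambdaEstimate(value=4.1, source="study")
        assert dz.events_significance(rounded, design_sig("one-sided")).events == 562

    def test_margin_required_and_positive(self):
        lam = dz.lambda_from_model(1.3, 0.1)
        with pytest.raises(InvalidInputError):
            dz.events_significance(lam, design_ci())
        with pytest.raises(InvalidInputError):
            dz.DesignSpec(alpha=0.05, sidedness=1, power=0.9, margin=-0.25)


class TestPriorBasedCalculations:
    def test_reduces_to_fixed_target_when_prior_se_negligible(self):
        # same lambda value with sigma1 ~ 0: (A) ~ (B) and (C) ~ (D)
        prior = dz.PriorStudy(events=4_066_200_000_000, se_d1=1e-6)
        lam = dz.lambda_from_study(prior)
        res_a = dz.events_with_prior(prior, design_sig("one-sided"), "significance")
        res_b = dz.events_significance(lam, design_sig("one-sided"))
        assert res_a.raw_events == pytest.approx(res_b.raw_events, rel=1e-9)
        assert res_a.events == res_b.events
        res_c = dz.events_with_prior(prior, design_ci(), "ci")
        res_d = dz.events_ci(lam, design_ci())
        assert res_c.raw_events == pytest.approx(res_d.raw_events, rel=1e-9)
        assert res_c.events == res_d.events

    def test_direct_arithmetic(self):
        # delta must exceed se_d1 * zz = 0.263, so use 0.30 for a feasible case
        zz = dz.zz_quantile(0.05, 1, 0.9)
        expected = math.ceil(4.0662 / ((0.30 / zz) ** 2 - 0.09**2))
        res = dz.events_with_prior(
            CLIP_PRIOR, design_sig("one-sided", delta=0.30), "significance"
        )
        assert res.events == expected
        assert res.min_margin == pytest.approx(0.09 * zz)

    def test_margin_below_prior_uncertainty_is_infeasible(self):
        # the non-inferiority margin of the fixed-target worked example (0.25)
        # sits below the prior's own uncertainty floor 0.09 * zz = 0.263
        with pytest.raises(FeasibilityError):
            dz.events_with_prior(CLIP_PRIOR, design_sig("one-sided"), "significance")

    def test_infeasible_margin_raises_with_bound(self):
        zz = dz.zz_quantile(0.05, 1, 0.9)
        with pytest.raises(FeasibilityError) as exc:
            dz.events_with_prior(
                CLIP_PRIOR, design_sig("one-sided", delta=0.09 * zz), "significance"
            )
        assert exc.value.minimum == pytest.approx(0.09 * zz)


class TestEquivalencesAndMonotonicity:
    @given(
        lam=st.floats(0.5, 20.0),
        w=st.floats(0.05, 1.0),
        alpha=st.floats(0.01, 0.2),
    )
    @settings(max_examples=50, deadline=None)
    def test_ci_equals_two_sided_significance_at_half_power(self, lam, w, alpha):
        """A CI design is a two-sided significance design with 50% power."""
        lam_est = dz.LambdaEstimate(value=lam, source="study")
        ci = dz.events_ci(lam_est, dz.DesignSpec(alpha=alpha, halfwidth=w))
        sig = dz.events_significance(
            lam_est,
            dz.DesignSpec(alpha=alpha, sidedness=2, power=0.5, margin=w),
        )
        assert ci.raw_events == pytest.approx(sig.raw_events, rel=1e-12)
        assert ci.events == sig.events

    def test_events_strictly_decreasing_in_margin_and_width(self):
        lam = dz.lambda_from_model(1.3, 0.1)
        deltas = np.linspace(0.05, 1.0, 40)
        sig_raw = [
            dz.events_significance(lam, design_sig(2, delta=d)).raw_events
            for d in deltas
        ]
        ci_raw = [dz.events_ci(lam, design_ci(w=w)).raw_events for w in deltas]
        assert np.all(np.diff(sig_raw) < 0)
        assert np.all(np.diff(ci_raw) < 0)

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_raw_events_linear_in_lambda(self, scale):
        base = dz.LambdaEstimate(value=4.0, source="study")
        scaled = dz.LambdaEstimate(value=4.0 * scale, source="study")
        r1 = dz.events_significance(base, design_sig(1)).raw_events
        r2 = dz.events_significance(scaled, design_sig(1)).raw_events
        assert r2 == pytest.approx(scale * r1, rel=1e-12)

    def test_quadrupled_margin_quarters_raw_events(self):
        lam = dz.lambda_from_model(1.6, 0.2)
        r1 = dz.events_significance(lam, design_sig(2, delta=0.2)).raw_events
        r2 = dz.events_significance(lam, design_sig(2, delta=0.4)).raw_events
        assert r1 == pytest.approx(4 * r2, rel=1e-12)


class TestComposite:
    def test_published_composite_maximum(self):
        design = dz.DesignSpec(alpha=0.05, sidedness=2, power=0.9, censoring=0.10)
        res = dz.composite_events(0.25, 0.20, design)
        assert res.peak_d == pytest.approx(1.25)
        assert round(res.lambda_peak.value, 2) == 4.47
        assert res.events == 753

    def test_composite_dominates_profile(self):
        design = dz.DesignSpec(alpha=0.05, sidedness=2, power=0.9, censoring=0.10)
        res = dz.composite_events(0.25, 0.20, design)
        assert (res.profile["events_composite"] <= res.events).all()
        assert (
            res.profile["events_composite"]
            == res.profile[["events_absolute", "events_relative"]].min(axis=1)
        ).all()

    def test_p_near_one_collapses_to_absolute_curve_at_small_d(self):
        design = dz.DesignSpec(alpha=0.05, sidedness=2, power=0.9)
        res = dz.composite_events(0.25, 0.999, design)
        assert res.peak_d == pytest.approx(0.25 / 0.999)
        low_d = res.profile[res.profile["d"] < res.peak_d]
        assert (low_d["events_composite"] == low_d["events_absolute"]).all()

    def test_invalid_p_rejected(self):
        design = dz.DesignSpec(alpha=0.05, sidedness=2, power=0.9)
        for p in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(InvalidInputError):
                dz.composite_events(0.25, p, design)


class TestAchievedMargin:
    def test_published_achieved_precision(self):
        # sized for the composite peak, the same study at D=2 detects 0.32
        assert round(dz.achieved_margin(753, 2.0, 0.10, 0.05, 2, 0.9), 2) == 0.32

    def test_round_trip_never_loses_precision(self):
        for d, cens, delta in [(1.3, 0.1, 0.25), (2.0, 0.3, 0.4), (0.8, 0.0, 0.15)]:
            lam = dz.lambda_from_model(d, cens)
            design = dz.DesignSpec(alpha=0.05, sidedness=2, power=0.9,
                                   margin=delta, censoring=cens)
            events = dz.events_significance(lam, design).events
            assert dz.achieved_margin(events, d, cens, 0.05, 2, 0.9) <= delta

    def test_margin_shrinks_monotonically_with_events(self):
        margins = [dz.achieved_margin(e, 1.5, 0.1) for e in (50, 200, 1000, 10000)]
        assert np.all(np.diff(margins) < 0)

    def test_zero_events_rejected(self):
        with pytest.raises(InvalidInputError):
            dz.achieved_margin(0, 1.5, 0.1)


class TestPatients:
    @pytest.mark.parametrize(
        "events,cens,expected",
        [(392, 0.10, 436), (504, 0.10, 560), (461, 0.30, 659), (100, 0.0, 100)],
    )
    def test_patient_counts(self, events, cens, expected):
        assert dz.patients_from_events(events, cens) == expected

    def test_full_censoring_rejected(self):
        with pytest.raises(InvalidInputError):
            dz.patients_from_events(100, 1.0)

    @given(events=st.integers(1, 10000), cens=st.floats(0.0, 0.95))
    @settings(max_examples=50, deadline=None)
    def test_patients_at_least_events(self, events, cens):
        assert dz.patients_from_events(events, cens) >= events
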