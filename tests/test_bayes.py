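"""Half-normal Bayes factors, scale rules, robustness, sample-size projection."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from tonetrain import bayes


class TestBayesFactor:
    def test_symmetric_null_case_has_closed_form(self):
        # beta=0, se=1, x=1: marginal ratio N(0;0,sqrt(2))/N(0;0,1) = 1/sqrt(2)
        assert bayes.bf_halfnormal(0.0, 1.0, 1.0) == pytest.approx(1 / math.sqrt(2), abs=1e-10)

    @pytest.mark.parametrize(
        "beta,se,x,expected",
        [(0.13, 0.228, 1.71, 0.219), (-0.225, 0.168, 1.076, 0.067)],
    )
    def test_reference_contrasts(self, beta, se, x, expected):
        assert bayes.bf_halfnormal(beta, se, x) == pytest.approx(expected, abs=0.01)

    def test_h1_collapsing_onto_null_gives_unit_evidence(self):
        for beta, se in [(0.3, 0.2), (-1.0, 0.5), (0.0, 1.0)]:
            assert bayes.bf_halfnormal(beta, se, 1e-8) == pytest.approx(1.0, abs=1e-3)

    def test_diffuse_prior_penalised_at_zero_estimate(self):
        xs = np.linspace(0.05, 5, 60)
        bs = [bayes.bf_halfnormal(0.0, 0.3, x) for x in xs]
        assert np.all(np.diff(bs) < 0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        beta=st.floats(-3, 3),
        se=st.floats(0.05, 2.0),
        x=st.floats(0.05, 5.0),
    )
    def test_closed_form_agrees_with_quadrature(self, beta, se, x):
        # keep |z| moderate so the quadrature route itself stays representable
        assume(abs(beta) < 6 * se)
        closed = bayes.bf_halfnormal(beta, se, x, method="closed_form")
        quad = bayes.bf_halfnormal(beta, se, x, method="quad")
        assert closed == pytest.approx(quad, abs=1e-6, rel=1e-6)

    @pytest.mark.parametrize("beta,se,x", [(0.1, 0.0, 1.0), (0.1, 0.2, 0.0), (0.1, -1, 1)])
    def test_invalid_inputs_rejected(self, beta, se, x):
        with pytest.raises(ValueError):
            bayes.bf_halfnormal(beta, se, x)


class TestConclusionCategory:
    @pytest.mark.parametrize(
        "B,expected",
        [
            (0.219, "substantial_null"),
            (0.5, "ambiguous"),
            (4.0, "substantial_H1"),
            (1 / 3, "ambiguous"),  # boundaries are ambiguous
            (3.0, "ambiguous"),
        ],
    )
    def test_thresholds(self, B, expected):
        assert bayes.conclusion_category(B) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            bayes.conclusion_category(0.0)


class TestRobustnessRegion:
    def test_null_region_lower_endpoint(self):
        rr = bayes.robustness_region(0.13, 0.228, 1.71)
        assert rr.category == "substantial_null"
        assert rr.lo == pytest.approx(1.11, abs=0.05)
        assert math.isinf(rr.hi)

    def test_ambiguous_region_touches_zero(self):
        rr = bayes.robustness_region(0.006, 0.127, 0.171)
        assert rr.category == "ambiguous"
        assert rr.lo == 0.0
        assert rr.hi == pytest.approx(0.354, abs=0.05)

    @pytest.mark.parametrize("beta,se,x", [(0.13, 0.228, 1.71), (-0.2, 0.15, 1.0)])
    def test_null_regions_always_extend_to_infinity(self, beta, se, x):
        rr = bayes.robustness_region(beta, se, x)
        if rr.category == "substantial_null":
            assert math.isinf(rr.hi)

    def test_category_flips_just_outside_finite_endpoints(self):
        rr = bayes.robustness_region(0.13, 0.228, 1.71)
        inside = bayes.conclusion_category(bayes.bf_halfnormal(0.13, 0.228, rr.lo + 0.01))
        outside = bayes.conclusion_category(bayes.bf_halfnormal(0.13, 0.228, rr.lo - 0.02))
        assert inside == rr.category
        assert outside != rr.category


class TestScaleRules:
    def test_main_effect_is_grand_mean_minus_baseline(self):
        h1 = bayes.scale_main_effect(1.0986, 0.0)
        assert h1.scale == pytest.approx(1.0986)
        assert h1.derivation_case == "main_effect"
        # picture-naming pinyin: grand mean −0.213 over baseline logit(1/72)
        assert bayes.scale_main_effect(-0.213, -4.263).scale == pytest.approx(4.05)

    def test_degenerate_main_effect_rejected(self):
        with pytest.raises(ValueError):
            bayes.scale_main_effect(0.0, 0.0)

    @pytest.mark.parametrize("t_bar", [0.31, 0.395])
    def test_session_interaction_scale(self, t_bar):
        assert bayes.scale_session_interaction(t_bar).scale == t_bar
        with pytest.raises(ValueError):
            bayes.scale_session_interaction(0.0)

    @pytest.mark.parametrize("a_bar", [0.171, 0.129])
    def test_aptitude_interaction_scale(self, a_bar):
        assert bayes.scale_aptitude_interaction(a_bar).scale == a_bar
        with pytest.raises(ValueError):
            bayes.scale_aptitude_interaction(0.0)

    def test_threeway_scale_is_half_the_headroom(self):
        assert bayes.scale_threeway(1.0, 0.2).scale == pytest.approx(0.4)
        with pytest.raises(ValueError):
            bayes.scale_threeway(0.5, 0.5)

    def test_max_aptitude_effect(self):
        assert bayes.max_aptitude_effect(4.263, -1.099, 5.0) == pytest.approx(1.0724)
        with pytest.raises(ValueError):
            bayes.max_aptitude_effect(4.263, 4.263, 5.0)
        with pytest.raises(ValueError):
            bayes.max_aptitude_effect(4.263, -1.099, 0.0)

    @pytest.mark.parametrize(
        "kind,expected",
        [("two_afc", 0.0), ("four_way_tone", -1.099), ("pinyin_minimal", -4.263),
         ("three_oddity", -0.693)],
    )
    def test_chance_logodds(self, kind, expected):
        assert bayes.chance_logodds(kind) == pytest.approx(expected, abs=5e-4)

    def test_unknown_task_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown task kind"):
            bayes.chance_logodds("seven_afc")


class TestSampleSizeProjection:
    def test_already_satisfied_returns_n0(self):
        proj = bayes.required_sample_size(0.13, 0.228, 1.71, n0=60)
        assert proj.n_required == 60 and proj.attainable

    def test_search_matches_exhaustive_scan(self):
        beta, se, x, n0 = 0.05, 0.2, 0.5, 30
        proj = bayes.required_sample_size(beta, se, x, n0=n0)
        brute = next(
            n for n in range(n0, 5001)
            if bayes.bf_halfnormal(beta, se * math.sqrt(n0 / n), x) <= 1 / 3
        )
        assert proj.n_required == brute

    def test_non_attainable_reported(self):
        # large positive estimate in the predicted direction: evidence for the
        # null never accumulates as n grows
        proj = bayes.required_sample_size(1.0, 0.3, 1.0, n0=20, n_max=5000)
        assert not proj.attainable and proj.n_required is None
        assert proj.b_limit > 1 / 3


def test_evaluate_contrast_bundles_consistent_fields():
    out = bayes.evaluate_contrast(0.13, 0.228, 1.71)
    assert out.category == bayes.conclusion_category(out.B)
    assert out.robustness.lo <= 1.71 <= (out.robustness.hi if math.isfinite(out.robustness.hi) else np.inf)
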