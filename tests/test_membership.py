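"""Neutrosophic membership functions: closed-form values, bounds, monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neutrodent.membership import (
    AgeGroup,
    AuxEvidence,
    MembershipParams,
    NeutrosophicTriple,
    age_adjusted_params,
    age_group_of,
    falsehood_membership,
    indeterminacy_membership,
    neutrosophize_image,
    truth_membership,
)

unit = st.floats(0.0, 1.0)


class TestTruthMembership:
    def test_at_healthy_intensity_sigmoid_is_half(self, printed_params):
        # alpha_t * 0.5 = 0.225 with zero clinical/genetic evidence
        assert truth_membership(0.75, 0.0, 0.0, printed_params) == pytest.approx(0.225)

    def test_saturated_evidence_reaches_one(self, printed_params):
        # sigmoid -> 1 plus full clinical and genetic evidence: 0.45+0.35+0.20
        p = MembershipParams(dark_lesions=False, mu_healthy=0.0, sigma_pathological=1e-4)
        assert truth_membership(1.0, 1.0, 1.0, p) == pytest.approx(1.0, abs=1e-9)

    def test_vanishes_with_no_evidence_and_low_sigmoid(self):
        p = MembershipParams(dark_lesions=False, mu_healthy=1.0, sigma_pathological=1e-4)
        assert truth_membership(0.0, 0.0, 0.0, p) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_each_argument_printed_form(self, printed_params):
        xs = np.linspace(0.0, 1.0, 21)
        t_int = [truth_membership(x, 0.3, 0.3, printed_params) for x in xs]
        t_cli = [truth_membership(0.5, x, 0.3, printed_params) for x in xs]
        t_gen = [truth_membership(0.5, 0.3, x, printed_params) for x in xs]
        for series in (t_int, t_cli, t_gen):
            assert np.all(np.diff(series) >= -1e-12)

    def test_dark_lesion_convention_reverses_intensity_direction(self):
        p = MembershipParams(dark_lesions=True)
        xs = np.linspace(0.0, 1.0, 21)
        series = [truth_membership(x, 0.0, 0.0, p) for x in xs]
        assert np.all(np.diff(series) <= 1e-12)

    def test_rejects_non_finite(self, printed_params):
        with pytest.raises(ValueError):
            truth_membership(np.nan, 0.0, 0.0, printed_params)


class TestIndeterminacyMembership:
    def test_peak_at_transition_intensity(self, printed_params):
        assert indeterminacy_membership(0.5, 0.0, 0.0, printed_params) == pytest.approx(0.40)

    def test_far_from_transition_only_uncertainty_terms(self):
        p = MembershipParams(mu_transition=0.5, sigma_developmental=1e-3)
        assert indeterminacy_membership(1.0, 1.0, 1.0, p) == pytest.approx(0.60)
        assert indeterminacy_membership(1.0, 0.0, 0.0, p) == pytest.approx(0.0, abs=1e-9)

    def test_maximized_exactly_at_mu_transition(self, printed_params):
        xs = np.linspace(0.0, 1.0, 101)
        vals = [indeterminacy_membership(x, 0.2, 0.2, printed_params) for x in xs]
        assert xs[int(np.argmax(vals))] == pytest.approx(printed_params.mu_transition)


class TestFalsehoodMembership:
    @pytest.mark.parametrize(
        "t,i,h,expected",
        [(1.0, 0.0, 0.0, 0.0), (0.0, 0.0, 1.0, 1.0), (0.0, 1.0, 0.0, 0.5)],
    )
    def test_closed_form_corners(self, printed_params, t, i, h, expected):
        assert falsehood_membership(t, i, h, printed_params) == pytest.approx(expected)

    def test_monotone_non_increasing_in_truth(self, printed_params):
        ts = np.linspace(0.0, 1.0, 21)
        vals = [falsehood_membership(t, 0.3, 0.5, printed_params) for t in ts]
        assert np.all(np.diff(vals) <= 1e-12)

    def test_rejects_out_of_range(self, printed_params):
        with pytest.raises(ValueError):
            falsehood_membership(1.5, 0.0, 0.0, printed_params)


class TestNeutrosophizeImage:
    def test_constant_image_default_aux(self, printed_params):
        nmap = neutrosophize_image(np.full((6, 6), 0.75), p=printed_params)
        assert np.allclose(nmap.t_grid, 0.225)

    def test_degenerate_single_pixel(self, printed_params):
        nmap = neutrosophize_image(np.array([[0.4]]), p=printed_params)
        assert nmap.height == nmap.width == 1
        assert 0.0 <= nmap.t_grid[0, 0] <= 1.0

    def test_matches_scalar_loop_oracle(self, rng, printed_params):
        img = rng.uniform(0.0, 1.0, size=(5, 5))
        aux = AuxEvidence(
            clinical_map=rng.uniform(0, 1, (5, 5)),
            genetic_map=rng.uniform(0, 1, (5, 5)),
            examiner_map=rng.uniform(0, 1, (5, 5)),
            development_map=rng.uniform(0, 1, (5, 5)),
            healthy_map=rng.uniform(0, 1, (5, 5)),
        )
        nmap = neutrosophize_image(img, aux, printed_params)
        for r in range(5):
            for c in range(5):
                t = truth_membership(
                    img[r, c], aux.clinical_map[r, c], aux.genetic_map[r, c], printed_params
                )
                i = indeterminacy_membership(
                    img[r, c], aux.examiner_map[r, c], aux.development_map[r, c], printed_params
                )
                f = falsehood_membership(t, i, aux.healthy_map[r, c], printed_params)
                assert nmap.t_grid[r, c] == pytest.approx(t)
                assert nmap.i_grid[r, c] == pytest.approx(i)
                assert nmap.f_grid[r, c] == pytest.approx(f)

    def test_neutrosophic_bound_on_random_images(self, printed_params):
        for seed in range(10):
            img = np.random.default_rng(seed).uniform(0, 1, (16, 16))
            nmap = neutrosophize_image(img, p=printed_params)
            total = nmap.t_grid + nmap.i_grid + nmap.f_grid
            assert total.max() <= 3.0 + 1e-12

    def test_dimension_mismatch_raises(self, printed_params):
        with pytest.raises(ValueError):
            neutrosophize_image(
                np.zeros((4, 4)), AuxEvidence(clinical_map=np.zeros((3, 3))), printed_params
            )


class TestAgeAdjustment:
    @pytest.mark.parametrize(
        "group,field,expected",
        [
            (AgeGroup.EARLY_CHILDHOOD, "alpha_t", 0.5175),
            (AgeGroup.SCHOOL_AGE, "beta_t", 0.385),
            (AgeGroup.ADOLESCENCE, "gamma_t", 0.176),
        ],
    )
    def test_single_field_modifier(self, printed_params, group, field, expected):
        adjusted = age_adjusted_params(printed_params, group)
        assert getattr(adjusted, field) == pytest.approx(expected)
        untouched = {"alpha_t", "beta_t", "gamma_t"} - {field}
        for name in untouched:
            assert getattr(adjusted, name) == getattr(printed_params, name)

    def test_double_application_is_detectable(self, printed_params):
        once = age_adjusted_params(printed_params, AgeGroup.EARLY_CHILDHOOD)
        twice = age_adjusted_params(once, AgeGroup.EARLY_CHILDHOOD)
        assert twice.alpha_t != pytest.approx(once.alpha_t)

    @pytest.mark.parametrize(
        "age,group",
        [
            (3, AgeGroup.EARLY_CHILDHOOD),
            (6, AgeGroup.EARLY_CHILDHOOD),
            (6.5, AgeGroup.SCHOOL_AGE),
            (12, AgeGroup.SCHOOL_AGE),
            (12.5, AgeGroup.ADOLESCENCE),
            (17, AgeGroup.ADOLESCENCE),
        ],
    )
    def test_age_boundaries(self, age, group):
        assert age_group_of(age) is group

    def test_age_outside_range_raises(self):
        with pytest.raises(ValueError):
            age_group_of(2.5)


class TestInvariants:
    @settings(derandomize=True, max_examples=60)
    @given(intensity=unit, clinical=unit, genetic=unit, exam=unit, dev=unit, h=unit)
    def test_memberships_always_in_unit_interval(
        self, intensity, clinical, genetic, exam, dev, h
    ):
        params = MembershipParams(dark_lesions=False)
        t = truth_membership(intensity, clinical, genetic, params)
        i = indeterminacy_membership(intensity, exam, dev, params)
        f = falsehood_membership(t, i, h, params)
        for v in (t, i, f):
            assert 0.0 <= v <= 1.0
        assert t + i + f <= 3.0
        NeutrosophicTriple(t, i, f)  # no invariant violation

    def test_params_validation(self):
        with pytest.raises(ValueError):
            MembershipParams(sigma_pathological=0.0)
        with pytest.raises(ValueError):
            MembershipParams(alpha_t=-0.1)
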