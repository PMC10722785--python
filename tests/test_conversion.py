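"""The VSL/VOLY/VOQ conversion algebra against published values and oracles."""

import dataclasses
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lifevalues import (CountryParams, Measure, MoneyRange, annuity_factor,
                        convert, implied_annuity, implied_ratio,
                        invert_annuity, rescaled_annuity, voq_vsl_diagnostic)
from lifevalues.conversion import ConversionConventionWarning


def annuity_by_summation(r: float, n: int) -> float:
    """Independent oracle: year-by-year discounted sum over an integer horizon."""
    return sum((1.0 + r) ** (-t) for t in range(1, n + 1))


class TestAnnuityFactor:
    def test_matches_published_uk_ratio(self):
        # the VSL:VOLY ratio implied by the published UK pairs
        assert annuity_factor(0.015, 41.1) == pytest.approx(30.5128, abs=5e-4)

    @pytest.mark.parametrize("r", [0.0, 0.001, 0.015, 0.03, 0.07, 0.15])
    @pytest.mark.parametrize("n", [1, 5, 41, 80])
    def test_closed_form_equals_discounted_sum(self, r, n):
        assert annuity_factor(r, n) == pytest.approx(
            annuity_by_summation(r, n), rel=1e-9)

    def test_continuous_at_zero_rate(self):
        assert annuity_factor(0.0, 37.5) == 37.5
        assert annuity_factor(1e-12, 37.5) == pytest.approx(37.5, rel=1e-9)

    def test_small_horizon_limit(self):
        assert annuity_factor(0.03, 1e-9) == pytest.approx(0.0, abs=1e-8)

    @given(r=st.floats(0.0, 0.2), n=st.floats(0.1, 100.0))
    @settings(deadline=None, max_examples=200)
    def test_bounded_by_horizon(self, r, n):
        a = annuity_factor(r, n)
        assert 0 < a <= n + 1e-12

    @pytest.mark.parametrize("r, n", [(-0.01, 10), (0.02, 0), (0.02, -3)])
    def test_domain_errors(self, r, n):
        with pytest.raises(ValueError):
            annuity_factor(r, n)

    @given(r=st.floats(0.001, 0.2), n=st.floats(0.5, 80.0))
    @settings(deadline=None, max_examples=100)
    def test_inversion_round_trips(self, r, n):
        assert invert_annuity(annuity_factor(r, n), r) == pytest.approx(n, rel=1e-9)


@pytest.fixture(scope="module")
def uk(params):
    return params["UK"]


class TestConvertAgainstPublishedUK:
    """Spot checks against the published UK table (±2 currency units)."""

    def test_vpf_to_voly_and_voq(self, uk):
        t = convert(MoneyRange.point(2064189), Measure.VSL, uk)
        assert t.voly.lower == pytest.approx(67650, abs=2)
        assert t.voq.lower == pytest.approx(73535, abs=2)
        assert t.vsl.lower == 2064189  # source slot echoes the input

    def test_statistical_life_year_to_vsl(self, uk):
        t = convert(MoneyRange.point(60000), Measure.VOLY, uk)
        assert t.vsl.lower == pytest.approx(1830770, abs=2)
        assert t.voq.lower == pytest.approx(65220, abs=2)

    def test_nice_threshold_to_voly_and_vsl(self, uk):
        t = convert(MoneyRange(20000, 30000), Measure.VOQ, uk)
        assert t.voly.lower == pytest.approx(18399, abs=2)
        assert t.vsl.lower == pytest.approx(663351, abs=2)

    def test_highly_specialised_threshold_voly(self, uk):
        t = convert(MoneyRange(100000, 300000), Measure.VOQ, uk)
        assert t.voly.lower == pytest.approx(91996, abs=2)

    def test_air_pollution_voly_to_voq(self, uk):
        t = convert(MoneyRange.point(23435), Measure.VOLY, uk)
        assert t.voq.lower == pytest.approx(25474, abs=2)

    def test_netherlands_transport_spot_check(self, params):
        t = convert(MoneyRange.point(1500000), Measure.VSL, params["NL"])
        assert t.voly.lower == pytest.approx(48553, abs=2)
        assert t.voq.lower == pytest.approx(52777, abs=2)


class TestConvertProperties:
    def test_voq_equals_voly_at_unit_ratio(self, uk):
        p = dataclasses.replace(uk, rho=1.0, rho_reciprocal=None)
        for measure, value in [(Measure.VSL, 2064189), (Measure.VOLY, 60000),
                               (Measure.VOQ, 20000)]:
            t = convert(MoneyRange.point(value), measure, p)
            assert t.voq == t.voly

    @given(value=st.floats(1000, 5e8))
    @settings(deadline=None, max_examples=150)
    def test_round_trip_vsl_voly(self, uk, value):
        t = convert(MoneyRange.point(value), Measure.VSL, uk)
        back = convert(t.raw_voly, Measure.VOLY, uk)
        assert abs(back.vsl.lower - round(value)) <= 1

    @given(value=st.floats(1000, 5e8), bump=st.floats(1.001, 4.0))
    @settings(deadline=None, max_examples=150)
    def test_outputs_strictly_increase_with_input(self, uk, value, bump):
        t1 = convert(MoneyRange.point(value), Measure.VSL, uk)
        t2 = convert(MoneyRange.point(value * bump), Measure.VSL, uk)
        assert t2.raw_voly.lower > t1.raw_voly.lower
        assert t2.raw_voq.lower > t1.raw_voq.lower

    @pytest.mark.parametrize("measure", [Measure.VSL, Measure.VOLY])
    def test_voq_non_increasing_in_rho(self, uk, measure):
        voqs = []
        for rho in (0.85, 0.91996, 0.95, 1.0):
            p = dataclasses.replace(uk, rho=rho, rho_reciprocal=None)
            voqs.append(convert(MoneyRange.point(100000), measure, p).voq.lower)
        assert voqs == sorted(voqs, reverse=True)

    def test_rejects_nonpositive_value(self, uk):
        with pytest.raises(ValueError):
            convert(MoneyRange(0.0, 0.0), Measure.VOQ, uk)


class TestQalySourceChain:
    """The published QALY→VSL convention and its consistent alternative."""

    def test_published_convention_warns(self, uk):
        with pytest.warns(ConversionConventionWarning):
            convert(MoneyRange.point(20000), Measure.VOQ, uk)

    def test_strict_mode_uses_consistent_chain(self, uk):
        t = convert(MoneyRange.point(20000), Measure.VOQ, uk, strict=True)
        expected = 20000 * uk.rho * uk.annuity
        assert t.raw_vsl.lower == pytest.approx(expected, rel=1e-12)

    def test_diagnostic_reports_candidates_and_ratio(self, uk):
        d = voq_vsl_diagnostic(20000.0, uk)
        assert d["published"] / d["consistent"] == pytest.approx(
            1.0 / uk.rho**2, rel=1e-12)
        assert d["ratio"] == pytest.approx(d["expected_ratio"], rel=1e-12)


class TestParameterRecovery:
    def test_ratio_from_published_uk_pairs(self):
        est = implied_ratio([(20000, 18399), (100000, 91996), (50000, 45998)])
        assert est.value == pytest.approx(0.91996, abs=1e-4)

    def test_ratio_identity_pair(self):
        assert implied_ratio([(12345, 12345)]).value == 1.0

    def test_ratio_recovered_through_rounding(self):
        rho = 0.87
        pairs = [(v, round(v * rho)) for v in (20000, 35000, 50000, 80000, 120000)]
        est = implied_ratio(pairs)
        assert est.value == pytest.approx(rho, abs=10 * 0.5 / 20000)

    def test_annuity_from_published_uk_pairs(self):
        est = implied_annuity([(2064189, 67650), (1830770, 60000), (715068, 23435)])
        assert est.value == pytest.approx(30.513, abs=1e-3)

    def test_annuity_from_published_au_pair(self):
        assert implied_annuity([(3725676, 213000)]).value == pytest.approx(
            17.491, abs=1e-3)

    def test_annuity_exact_for_constructed_pairs(self):
        a = 23.75
        est = implied_annuity([(a * v, v) for v in (1000.0, 2000.0, 4000.0)])
        assert est.value == pytest.approx(a, rel=1e-12)
        assert est.max_abs_deviation == pytest.approx(0.0, abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            implied_ratio([])


class TestRescaledAnnuity:
    def test_known_inputs_rebuild_closed_form(self, params):
        uk = params["UK"]
        assert rescaled_annuity(uk, 30.0) == pytest.approx(
            annuity_factor(0.015, 51.1), rel=1e-12)

    def test_baseline_age_is_identity(self, params):
        for code, p in params.items():
            assert rescaled_annuity(p, 40.0) == pytest.approx(p.annuity, rel=1e-12)

    def test_derived_factor_rescales_monotonically(self, params):
        nl = params["NL"]
        factors = [rescaled_annuity(nl, age) for age in (20, 30, 40, 50, 60)]
        assert factors == sorted(factors, reverse=True)  # younger -> longer horizon

    def test_age_beyond_life_expectancy_rejected(self, params):
        with pytest.raises(ValueError):
            rescaled_annuity(params["UK"], 82.0)


def test_country_params_rejects_bad_domains():
    with pytest.raises(Exception):
        CountryParams(country="ZZ", rho=1.5, annuity_override=30.0)
    with pytest.raises(Exception):
        CountryParams(country="ZZ", rho=0.9)  # no annuity and no (r, LE, age)
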