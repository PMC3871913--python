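"""Floquet multipliers, extinction threshold, permanence certificates."""

import math

import numpy as np
import pytest

from pulseprey import (
    OrbitExistenceError,
    analytic_multipliers,
    classify_regime,
    extinction_threshold,
    numeric_monodromy,
    panda_free_solution,
    permanence_conditions,
)
from conftest import random_parameters


class TestPandaFreeSolution:
    def test_canonical_orbits_exist(self, p0):
        o1, o2 = panda_free_solution(p0)
        assert o1.x0plus > 0 and o2.x0plus > 0
        assert o1.phase == pytest.approx(p0.l * p0.T)
        assert o2.phase == 0.0

    def test_failure_names_the_prey(self, p0):
        bad = p0.replace(alpha=0.7, T=0.3)  # ln(0.3) + 0.3 < 0
        with pytest.raises(OrbitExistenceError, match="bamboo1"):
            panda_free_solution(bad)

    def test_unpulsed_orbits_are_equilibria(self, p0):
        o1, o2 = panda_free_solution(p0.replace(alpha=0.0, beta=0.0))
        assert o1.x0plus == pytest.approx(p0.a10 / p0.a11)
        assert o2.x0plus == pytest.approx(p0.a20 / p0.a22)


class TestAnalyticMultipliers:
    def test_predator_multiplier_canonical(self, p0):
        # exponent: -0.3 + 0.2*(ln0.6+1) + 0.25*(ln0.5+1.2) = -0.075452
        _, _, lam3 = analytic_multipliers(p0)
        assert lam3 == pytest.approx(math.exp(-0.0754519), rel=1e-6)
        assert lam3 < 1.0

    def test_predator_multiplier_longer_period(self, p0):
        _, _, lam3 = analytic_multipliers(p0.replace(T=2.0))
        assert lam3 == pytest.approx(1.13264, rel=1e-5)
        assert lam3 > 1.0

    def test_unpulsed_limit_constant_coefficients(self, p0):
        lam1, lam2, lam3 = analytic_multipliers(p0.replace(alpha=0.0, beta=0.0))
        assert lam1 == pytest.approx(math.exp(-1.0), rel=1e-12)
        assert lam2 == pytest.approx(math.exp(-1.2), rel=1e-12)
        assert lam3 == pytest.approx(math.exp(0.2), rel=1e-12)

    def test_prey_multipliers_below_one_whenever_orbits_exist(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = random_parameters(rng)
            lam1, lam2, _ = analytic_multipliers(p)
            assert 0.0 < lam1 < 1.0 and 0.0 < lam2 < 1.0

    def test_monotone_in_conversion_and_mortality(self, p0):
        # lambda3 increases with either conversion gain, decreases with mortality
        for field, sign in (("a31", +1), ("a32", +1), ("a30", -1)):
            grid = np.linspace(0.05, 0.5, 8)
            lams = [analytic_multipliers(p0.replace(**{field: v}))[2] for v in grid]
            assert np.all(sign * np.diff(lams) > 0)


class TestNumericMonodromy:
    def test_agrees_with_analytic_lambda3(self, p0):
        rep = numeric_monodromy(p0)
        assert rep.rel_error_lambda3 < 1e-6
        assert rep.spectral_radius == pytest.approx(rep.lambda3, rel=1e-6)
        assert np.all(rep.eigenvalue_moduli < 1.0)

    def test_unpulsed_limit_closed_form(self, p0):
        rep = numeric_monodromy(p0.replace(alpha=0.0, beta=0.0))
        expected = np.sort([math.exp(0.2), math.exp(-1.0), math.exp(-1.2)])[::-1]
        assert np.allclose(rep.eigenvalue_moduli, expected, rtol=1e-8)

    def test_predator_row_decouples(self, p0):
        rep = numeric_monodromy(p0)
        assert abs(rep.monodromy[2, 0]) < 1e-12
        assert abs(rep.monodromy[2, 1]) < 1e-12

    def test_resolves_prey_multiplier_form(self, p0):
        # the monodromy diagonal matches e^{-aT}/(1-theta), not the
        # alternative printed simplification e^{-aT}
        rep = numeric_monodromy(p0)
        assert rep.monodromy[0, 0] == pytest.approx(rep.lambda1, rel=1e-8)
        assert rep.monodromy[1, 1] == pytest.approx(rep.lambda2, rel=1e-8)
        assert not rep.printed_form_matches

    def test_random_sets_oracle_agreement(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            p = random_parameters(rng)
            rep = numeric_monodromy(p)
            assert rep.rel_error_lambda3 < 1e-6


class TestExtinctionThreshold:
    def test_canonical_value(self, p0):
        thr = extinction_threshold(p0)
        assert thr.defined
        assert thr.value == pytest.approx(1.37726, rel=1e-5)

    def test_multiplier_is_one_at_threshold(self, p0):
        thr = extinction_threshold(p0)
        _, _, lam3 = analytic_multipliers(p0.replace(T=thr.value))
        assert abs(lam3 - 1.0) < 1e-9

    def test_sign_consistency_around_threshold(self, p0):
        thr = extinction_threshold(p0)
        for T in np.linspace(0.8 * thr.value, 1.2 * thr.value, 9):
            if abs(T - thr.value) < 1e-12:
                continue
            _, _, lam3 = analytic_multipliers(p0.replace(T=float(T)))
            assert math.copysign(1, lam3 - 1.0) == math.copysign(1, T - thr.value)

    def test_not_defined_when_mortality_dominates(self, p0):
        # huge a30: denominator positive, predator can never invade
        thr = extinction_threshold(p0.replace(a30=10.0))
        assert not thr.defined
        for T in (0.6, 1.0, 5.0):  # orbits exist at these periods
            _, _, lam3 = analytic_multipliers(p0.replace(a30=10.0, T=T))
            assert lam3 < 1.0


class TestPermanenceConditions:
    def test_full_condition_value(self, p0):
        rep = permanence_conditions(p0.replace(T=2.0))
        assert rep.stability_exponent == pytest.approx(0.124548, abs=1e-6)

    def test_subsystem1_condition_fails_canonical(self, p0):
        rep = permanence_conditions(p0)
        # -0.3 + 0.2*(ln0.6+1) = -0.202166
        assert rep.cond_sub1 == pytest.approx(-0.202166, abs=1e-6)
        assert rep.cond_sub1 < 0.0

    def test_side_conditions_fail_for_canonical_bound(self, p0):
        # M = 2.5 * D/a30 = 8.208; a10 - a13*M = 1 - 1.64 < 0: no certificate
        rep = permanence_conditions(p0)
        assert rep.M_used == pytest.approx(8.2083, rel=1e-4)
        for T in (0.5, 1.0, 2.0, 5.0):
            r = permanence_conditions(p0.replace(T=T))
            assert r.side_alpha < 0.0


class TestClassifyRegime:
    def test_canonical_extinction_regime(self, p0):
        assert classify_regime(p0).label == "panda_free_stable"

    def test_longer_period_uncertified(self, p0):
        # predator invades at T=2 but the M side conditions fail
        assert classify_regime(p0.replace(T=2.0)).label == "unstable_uncertified"

    def test_no_orbit_label(self, p0):
        rep = classify_regime(p0.replace(alpha=0.7, T=0.3))
        assert rep.label == "no_bamboo_orbit"
        assert not rep.exists1

    def test_label_consistent_with_condition_signs(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            p = random_parameters(rng, require_orbits=False)
            rep = classify_regime(p)
            if rep.label == "no_bamboo_orbit":
                assert not (rep.exists1 and rep.exists2)
            elif rep.label == "panda_free_stable":
                assert rep.stability_exponent < 0
            elif rep.label == "permanent_certified":
                assert rep.stability_exponent > 0
                assert rep.side_alpha > 0 and rep.side_beta > 0
            elif rep.label == "subsystem1_permanent":
                assert rep.cond_sub1 > 0
            elif rep.label == "subsystem2_permanent":
                assert rep.cond_sub2 > 0
            else:
                assert rep.label == "unstable_uncertified"
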