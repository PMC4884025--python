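import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from btbiodyn.model_core import (
    BiodynamicParameters,
    GompertzParams,
    YieldCoefficients,
    biomass_at,
    cry_at,
    dpa_at,
    gompertz_value,
    phb_at,
    simulate,
)


def scalar_gompertz(t, a, mu, tc):
    """Independent scalar oracle: closed form via the math module."""
    try:
        return a * math.exp(-math.exp(-mu * (t - tc)))
    except OverflowError:
        return 0.0


def random_params(rng, n):
    for _ in range(n):
        yield GompertzParams(
            asymptote=float(rng.uniform(0.01, 20.0)),
            rate=float(rng.uniform(0.05, 3.0)),
            critical_time=float(rng.uniform(-5.0, 25.0)),
        )


def random_biodynamic(rng):
    return BiodynamicParameters(
        biomass=GompertzParams(rng.uniform(1, 15), rng.uniform(0.2, 2), rng.uniform(2, 8)),
        phb=GompertzParams(rng.uniform(0.1, 2), rng.uniform(0.2, 2), rng.uniform(5, 10)),
        dpa=GompertzParams(rng.uniform(0.05, 0.3), rng.uniform(0.2, 1), rng.uniform(10, 16)),
        cry=GompertzParams(rng.uniform(0.05, 1), rng.uniform(0.1, 1), rng.uniform(10, 17)),
        yields=YieldCoefficients(rng.uniform(0.005, 0.05), rng.uniform(0.1, 2), rng.uniform(0.1, 6)),
    )


class TestGompertz:
    def test_value_at_critical_time_is_asymptote_over_e(self, rng):
        """The inflection-point identity holds to machine precision."""
        for p in random_params(rng, 1000):
            assert gompertz_value(p.critical_time, p) == pytest.approx(
                p.asymptote / math.e, rel=1e-12
            )

    def test_monotone_non_decreasing(self, rng):
        for p in random_params(rng, 200):
            t1, t2 = sorted(rng.uniform(-50, 50, size=2))
            assert gompertz_value(t1, p) <= gompertz_value(t2, p) + 1e-15

    @settings(derandomize=True, max_examples=200)
    @given(
        asymptote=st.floats(0.0, 50.0),
        rate=st.floats(0.01, 5.0),
        tc=st.floats(-30.0, 30.0),
        t1=st.floats(-100.0, 100.0),
        t2=st.floats(-100.0, 100.0),
    )
    def test_monotone_and_bounded_property(self, asymptote, rate, tc, t1, t2):
        p = GompertzParams(asymptote, rate, tc)
        lo, hi = sorted((t1, t2))
        v_lo, v_hi = gompertz_value(lo, p), gompertz_value(hi, p)
        assert 0.0 <= v_lo <= v_hi <= asymptote

    def test_limits(self):
        p = GompertzParams(5.58, 0.78, 4.54)
        assert gompertz_value(-1e6, p) == 0.0
        assert gompertz_value(1e6, p) == pytest.approx(5.58, rel=1e-12)

    def test_f1_cry_sigmoid_at_its_critical_time(self, f1):
        # published F1 Cry triple (0.19 g/L, 0.20 1/h, 14.88 h)
        assert gompertz_value(14.88, f1.cry) == pytest.approx(0.19 / math.e, rel=1e-12)
        assert gompertz_value(14.88, f1.cry) == pytest.approx(0.0699, abs=1e-4)

    def test_scalar_oracle_agreement(self):
        p = GompertzParams(5.58, 0.78, 4.54)
        assert gompertz_value(10.0, p) == pytest.approx(5.501658086334491, rel=1e-12)
        assert gompertz_value(10.0, p) == pytest.approx(scalar_gompertz(10, 5.58, 0.78, 4.54))

    def test_rejects_non_finite_time(self):
        p = GompertzParams(1.0, 1.0, 0.0)
        for bad in (math.nan, math.inf, -math.inf):
            with pytest.raises(ValueError):
                gompertz_value(bad, p)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            GompertzParams(-1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            GompertzParams(1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            GompertzParams(1.0, 1.0, math.inf)


class TestCompoundCurves:
    def test_dpa_cry_are_plain_sigmoids(self, f1, rng):
        for t in rng.uniform(0, 25, size=20):
            assert dpa_at(t, f1) == gompertz_value(t, f1.dpa)
            assert cry_at(t, f1) == gompertz_value(t, f1.cry)

    def test_dpa_asymptote_f1(self, f1):
        assert dpa_at(1e6, f1) == pytest.approx(0.17, rel=1e-12)

    def test_cry_asymptote_f4(self, presets):
        assert cry_at(1e6, presets["F4"]) == pytest.approx(0.78, rel=1e-12)

    def test_dpa_at_time_zero_underflows_to_zero(self, f1):
        # inner exponent exp(0.66*14.12) ≈ 1.1e4 drives the curve to exactly 0
        assert dpa_at(0.0, f1) == scalar_gompertz(0, 0.17, 0.66, 14.12) == 0.0

    def test_biomass_two_term_equation_f1(self, f1):
        # late-culture death exceeds growth: the unclamped value goes negative
        expected = scalar_gompertz(20, 5.58, 0.78, 4.54) - scalar_gompertz(20, 0.17, 0.66, 14.12) / 0.025
        assert biomass_at(20.0, f1) == pytest.approx(expected, rel=1e-12)
        assert biomass_at(20.0, f1) == pytest.approx(-1.0812, abs=1e-3)
        assert biomass_at(20.0, f1, clamp=True) == 0.0

    def test_biomass_at_critical_time_f1(self, f1):
        expected = 5.58 / math.e - scalar_gompertz(4.54, 0.17, 0.66, 14.12) / 0.025
        assert biomass_at(4.54, f1) == pytest.approx(expected, rel=1e-12)

    def test_phb_three_term_equation_f3(self, presets):
        f3 = presets["F3"]
        expected = (
            scalar_gompertz(11, 1.16, 0.95, 8.39)
            - scalar_gompertz(11, 0.16, 0.59, 15.77) / 0.21
            - scalar_gompertz(11, 0.53, 0.40, 14.96) / 4.92
        )
        assert phb_at(11.0, f3) == pytest.approx(expected, rel=1e-12)

    def test_phb_algebraic_limit_f1(self, f1):
        expected = 0.61 - 0.17 / 1.02 - 0.19 / 0.19
        assert phb_at(1e6, f1) == pytest.approx(expected, rel=1e-10)

    def test_pure_gompertz_when_no_sporulation(self, f1):
        # a zero DPA asymptote removes the death term entirely
        import dataclasses

        p = dataclasses.replace(f1, dpa=GompertzParams(0.0, 0.66, 14.12))
        for t in (0.0, 5.0, 20.0):
            assert biomass_at(t, p) == gompertz_value(t, p.biomass)

    def test_conservation_identities(self, rng):
        """With clamp off the production terms are recovered exactly."""
        for _ in range(50):
            p = random_biodynamic(rng)
            t = np.sort(rng.uniform(0, 25, size=8))
            growth = gompertz_value(t, p.biomass)
            lhs = biomass_at(t, p) + dpa_at(t, p) / p.yields.dpa_from_biomass
            np.testing.assert_allclose(lhs, growth, rtol=1e-12, atol=1e-15)
            production = gompertz_value(t, p.phb)
            lhs = (
                phb_at(t, p)
                + dpa_at(t, p) / p.yields.dpa_from_phb
                + cry_at(t, p) / p.yields.cry_from_phb
            )
            np.testing.assert_allclose(lhs, production, rtol=1e-12, atol=1e-15)

    def test_biomass_monotone_in_dpa_yield(self, f1, rng):
        import dataclasses

        higher = dataclasses.replace(
            f1, yields=dataclasses.replace(f1.yields, dpa_from_biomass=0.05)
        )
        for t in rng.uniform(0, 25, size=20):
            assert biomass_at(t, higher) >= biomass_at(t, f1)


class TestSimulate:
    def test_matches_pointwise_evaluation(self, rng):
        for _ in range(20):
            p = random_biodynamic(rng)
            t = np.sort(rng.uniform(0, 25, size=11))
            traj = simulate(p, t)
            np.testing.assert_allclose(traj.biomass, [biomass_at(ti, p) for ti in t], rtol=1e-12)
            np.testing.assert_allclose(traj.phb, [phb_at(ti, p) for ti in t], rtol=1e-12)
            np.testing.assert_allclose(traj.dpa, [dpa_at(ti, p) for ti in t], rtol=1e-12)
            np.testing.assert_allclose(traj.cry, [cry_at(ti, p) for ti in t], rtol=1e-12)

    def test_single_point_consistent_with_biomass_at(self, f1):
        traj = simulate(f1, [4.54])
        assert traj.biomass[0] == pytest.approx(biomass_at(4.54, f1), rel=1e-12)

    def test_f1_default_grid_has_11_points(self, f1):
        traj = simulate(f1, np.arange(0, 21, 2.0))
        assert traj.times.size == 11

    def test_zero_asymptotes_give_zero_trajectory(self):
        p = BiodynamicParameters(
            biomass=GompertzParams(0.0, 1.0, 5.0),
            phb=GompertzParams(0.0, 1.0, 8.0),
            dpa=GompertzParams(0.0, 1.0, 14.0),
            cry=GompertzParams(0.0, 1.0, 15.0),
            yields=YieldCoefficients(0.02, 1.0, 1.0),
        )
        traj = simulate(p, np.arange(0, 21, 2.0))
        for name in ("biomass", "phb", "dpa", "cry"):
            np.testing.assert_array_equal(traj.compound(name), 0.0)

    def test_clamp_flags_negative_biomass(self, f1):
        traj = simulate(f1, np.arange(0, 21, 2.0), clamp=True)
        assert traj.clamped["biomass"].any()
        assert np.all(traj.biomass >= 0)
        assert np.all(traj.biomass[traj.clamped["biomass"]] == 0.0)

    def test_dpa_cry_bounded_by_asymptote(self, f1):
        traj = simulate(f1, np.arange(0, 21, 2.0))
        assert np.all(traj.dpa >= 0) and np.all(traj.dpa <= f1.dpa.asymptote)
        assert np.all(traj.cry >= 0) and np.all(traj.cry <= f1.cry.asymptote)

    @pytest.mark.parametrize("bad", [[], [3.0, 2.0], [1.0, 1.0]])
    def test_rejects_bad_grids(self, f1, bad):
        with pytest.raises(ValueError):
            simulate(f1, bad)
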