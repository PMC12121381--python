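"""Unit tests for the FvCB leaf model and its Arrhenius kinetics."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import thermleaf as tl
from thermleaf.errors import ParameterRangeError, UnitMismatchError
from thermleaf.fvcb import assimilation_arrays, classify_limitation

R = 8.314


class TestArrhenius:
    @pytest.mark.parametrize(
        "c, dha, t, expected",
        [
            # WT V_cmax constants at 25°C: exp(27.68 - 57960/(8.314*298.15))
            (27.68, 57.96, 25.0, 73.5451),
            # WT Γ* constants at 25°C
            (15.6, 34.8, 25.0, 4.76385),
            # zero activation energy is temperature-independent
            (3.0, 0.0, 10.0, math.exp(3.0)),
            (3.0, 0.0, 40.0, math.exp(3.0)),
        ],
    )
    def test_known_values(self, c, dha, t, expected):
        param = tl.ArrheniusParam(c, dha)
        assert tl.arrhenius_value(param, t) == pytest.approx(expected, rel=1e-4)

    @given(
        c=st.floats(-5, 40),
        dha=st.floats(0.1, 200),
        t1=st.floats(-40, 50),
        dt=st.floats(0.1, 9),
    )
    def test_strictly_increasing_in_temperature(self, c, dha, t1, dt):
        param = tl.ArrheniusParam(c, dha)
        assert tl.arrhenius_value(param, t1 + dt) > tl.arrhenius_value(param, t1)

    @given(c=st.floats(-30, 30), dha=st.floats(0, 200), t=st.floats(-40, 55))
    def test_strictly_positive(self, c, dha, t):
        assert tl.arrhenius_value(tl.ArrheniusParam(c, dha), t) > 0

    def test_vectorized_matches_scalar(self):
        param = tl.ArrheniusParam(21.6, 41.76)
        grid = np.linspace(0, 45, 7)
        vec = tl.arrhenius_value(param, grid)
        assert vec == pytest.approx([tl.arrhenius_value(param, t) for t in grid])

    def test_rejects_nonfinite_and_absurd_temperature(self):
        param = tl.ArrheniusParam(27.68, 57.96)
        with pytest.raises(ValueError):
            tl.arrhenius_value(param, float("nan"))
        with pytest.raises(ValueError):
            tl.arrhenius_value(param, 80.0)

    def test_overflow_names_the_parameter(self):
        with pytest.raises(ParameterRangeError, match="c=800"):
            tl.arrhenius_value(tl.ArrheniusParam(800.0, 0.0), 25.0)

    def test_negative_activation_energy_rejected(self):
        with pytest.raises(ValueError):
            tl.ArrheniusParam(10.0, -1.0)


class TestLeafEnvironment:
    def test_operating_co2_partial_pressure(self, env25):
        # 410 µmol/mol × 0.7 × 101.325 kPa → 29.08 Pa
        assert env25.co2_pa == pytest.approx(29.0803, abs=1e-3)

    @pytest.mark.parametrize(
        "kwargs", [{"ca": -1}, {"ci_ratio": 0.0}, {"ci_ratio": 1.2},
                   {"o2": -2.0}, {"pressure": 0.0}]
    )
    def test_invalid_environment_rejected(self, kwargs):
        with pytest.raises(ValueError):
            tl.LeafEnvironment(**kwargs)


class TestLimitedRates:
    def test_rubisco_limited_at_25C(self, wt, env25):
        # frozen from a direct hand evaluation of the rate equation with the
        # default constants (V_cmax 73.545, Γ* 4.7639 Pa, K_C 41.145 Pa,
        # K_O 28.057 kPa, R_l 1.0055, C 29.080 Pa, O 21.27 kPa)
        assert tl.rubisco_limited_rate(wt, env25) == pytest.approx(16.6282, abs=1e-3)

    def test_rubp_limited_at_25C(self, wt, env25):
        assert tl.rubp_limited_rate(wt, env25) == pytest.approx(17.2537, abs=1e-3)

    def test_compensation_point_returns_minus_rl(self, wt):
        # pick ca so the operating CO2 equals Γ* at 25°C exactly
        gamma = wt.gamma_star.value(25.0)
        env = tl.LeafEnvironment(ca=gamma / 0.101325, ci_ratio=1.0)
        rl = wt.rl.value(25.0)
        assert env.co2_pa == pytest.approx(gamma, rel=1e-12)
        assert tl.rubisco_limited_rate(wt, env) == pytest.approx(-rl, rel=1e-9)
        assert tl.rubp_limited_rate(wt, env) == pytest.approx(-rl, rel=1e-9)
        assert tl.net_assimilation(wt, env).a_n == pytest.approx(-rl, rel=1e-9)

    def test_saturating_co2_asymptotes(self, wt):
        env = tl.LeafEnvironment(ca=1e7, ci_ratio=1.0)  # C ≈ 10⁶ Pa
        vmax = wt.vcmax.value(25.0)
        jmax = wt.jmax.value(25.0)
        rl = wt.rl.value(25.0)
        a_c = tl.rubisco_limited_rate(wt, env)
        assert a_c == pytest.approx(vmax - rl, rel=1e-3)
        assert a_c < vmax - rl  # approached from below
        assert tl.rubp_limited_rate(wt, env) == pytest.approx(jmax / 4 - rl, rel=1e-3)
        # at huge C the rubisco limb exceeds the electron-transport ceiling
        assert tl.net_assimilation(wt, env).limitation is tl.Limitation.RUBP

    def test_unit_mismatch_detected(self, wt, env25):
        bad = wt.with_overrides(
            {"gamma_star": tl.ArrheniusParam(15.6, 34.8, "kPa")}
        )
        with pytest.raises(UnitMismatchError, match="gamma_star"):
            tl.rubisco_limited_rate(bad, env25)


class TestNetAssimilation:
    def test_minimum_and_label_at_25C(self, wt, env25):
        res = tl.net_assimilation(wt, env25)
        assert res.a_n == min(res.a_c, res.a_j)
        assert res.a_n == pytest.approx(16.6282, abs=1e-3)
        assert res.limitation is tl.Limitation.RUBISCO
        assert res.evaluated_params["vcmax"] == pytest.approx(73.545, abs=1e-2)

    def test_colimited_tie_band(self):
        assert classify_limitation(10.0, 10.0) is tl.Limitation.COLIMITED
        assert classify_limitation(10.0, 10.0 + 5e-7) is tl.Limitation.COLIMITED
        assert classify_limitation(10.0, 10.1) is tl.Limitation.RUBISCO
        assert classify_limitation(10.1, 10.0) is tl.Limitation.RUBP

    @given(
        t=st.floats(5, 45),
        ca=st.floats(100, 1500),
        ci=st.floats(0.4, 1.0),
    )
    def test_an_never_exceeds_either_limb(self, wt, t, ca, ci):
        env = tl.LeafEnvironment(t_leaf=t, ca=ca, ci_ratio=ci)
        res = tl.net_assimilation(wt, env)
        assert res.a_n <= res.a_c and res.a_n <= res.a_j

    def test_below_compensation_rates_are_negative_not_clamped(self, wt):
        env = tl.LeafEnvironment(t_leaf=25.0, ca=40.0, ci_ratio=0.7)  # C < Γ*
        res = tl.net_assimilation(wt, env)
        assert res.a_n < 0

    def test_unit_system_invariance(self, wt, env25):
        """Tracking CO2 in mole fraction instead of Pa changes nothing.

        Independent second route: express C, Γ* and K_C in µmol mol⁻¹ (and
        O, K_O in mmol mol⁻¹) at the stated pressure and evaluate the same
        rate equations.
        """
        p = wt.evaluate(env25.t_leaf)
        to_ppm = 1.0 / (env25.pressure * 1e-3)  # Pa → µmol/mol
        c_ppm = env25.ca * env25.ci_ratio
        gamma = p["gamma_star"] * to_ppm
        kc = p["kc"] * to_ppm
        o_mmol = env25.o2 / env25.pressure * 1e3
        ko = p["ko"] / env25.pressure * 1e3
        a_c_ppm = (c_ppm - gamma) * p["vcmax"] / (c_ppm + kc * (1 + o_mmol / ko)) - p["rl"]
        a_j_ppm = (c_ppm - gamma) * p["jmax"] / (4 * c_ppm + 8 * gamma) - p["rl"]
        res = tl.net_assimilation(wt, env25)
        assert res.a_c == pytest.approx(a_c_ppm, rel=1e-12)
        assert res.a_j == pytest.approx(a_j_ppm, rel=1e-12)

    def test_vectorized_assimilation_matches_scalar(self, wt, env25):
        grid = np.linspace(12, 44, 9)
        a_n, a_c, a_j = assimilation_arrays(wt, env25, grid)
        for i, t in enumerate(grid):
            res = tl.net_assimilation(wt, env25.at(t))
            assert a_n[i] == pytest.approx(res.a_n, rel=1e-12)
            assert a_c[i] == pytest.approx(res.a_c, rel=1e-12)
            assert a_j[i] == pytest.approx(res.a_j, rel=1e-12)


def test_parameter_set_requires_all_roles_finite():
    wt = tl.wt_parameters()
    assert set(wt.evaluate(25.0)) == set(tl.ParameterSet.ROLES)
    with pytest.raises(ParameterRangeError):
        wt.with_overrides({"vcmax": tl.ArrheniusParam(720.0, 0.0)})
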