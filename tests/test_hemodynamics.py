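import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pulsebp.errors import CalibrationError, InvalidInputError
from pulsebp.hemodynamics import (
    MMHG_TO_PA,
    ArterialState,
    BPEstimate,
    RegressionCoeffs,
    StiffnessParams,
    beta_calibrate,
    map_p_beta,
    mk_pressure,
    mk_pwv,
    pulse_pressure,
    pwv_from_ptt,
    regression_fit,
    regression_predict,
    track_sbp_dbp,
    youngs_modulus,
)


def make_state(**kw):
    defaults = dict(dd=2.5e-3, h=3e-4, delta_d=1.5e-4)
    defaults.update(kw)
    return ArterialState(**defaults)


class TestTypes:
    def test_ds_is_dd_plus_delta(self):
        s = make_state()
        assert s.ds == pytest.approx(s.dd + s.delta_d)

    def test_d_defaults_to_dd(self):
        assert make_state().d == make_state().dd

    @pytest.mark.parametrize("kw", [dict(dd=0), dict(h=-1e-4), dict(delta_d=-1e-5)])
    def test_invalid_geometry(self, kw):
        with pytest.raises(InvalidInputError):
            make_state(**kw)

    @pytest.mark.parametrize("kw", [dict(e0=0), dict(beta=-1), dict(k=0), dict(k=1.2)])
    def test_invalid_stiffness(self, kw):
        defaults = dict(e0=1e5, xi=0.016, beta=5.0)
        defaults.update(kw)
        with pytest.raises(InvalidInputError):
            StiffnessParams(**defaults)

    def test_bp_estimate_ordering_enforced(self):
        with pytest.raises(InvalidInputError):
            BPEstimate(sbp=100, dbp=110, map=105, pp=0, method="p_beta")

    def test_regression_coeffs_must_be_finite(self):
        with pytest.raises(InvalidInputError):
            RegressionCoeffs(k1=float("nan"), k2=0.0)


class TestPwvFromPtt:
    def test_direct_division(self):
        assert pwv_from_ptt(0.02, 0.004) == pytest.approx(5.0)

    def test_identity(self):
        assert pwv_from_ptt(1.0, 1.0) == pytest.approx(1.0)

    def test_zero_ptt_errors(self):
        with pytest.raises(InvalidInputError):
            pwv_from_ptt(0.02, 0.0)

    def test_zero_distance_errors(self):
        with pytest.raises(InvalidInputError):
            pwv_from_ptt(0.0, 0.004)


class TestMkPwv:
    def test_terms_cancel(self):
        s = make_state()
        e = s.rho_blood * s.d / s.h
        assert mk_pwv(s, e) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # sqrt(500000 * 0.0003 / (0.0025 * 1060))
        s = ArterialState(dd=2.5e-3, h=3e-4, rho_blood=1060.0)
        expected = math.sqrt(500e3 * 3e-4 / (2.5e-3 * 1060.0))
        assert mk_pwv(s, 500e3) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(7.525, abs=2e-3)

    def test_sqrt2_scaling(self):
        s = make_state()
        assert mk_pwv(s, 2e5) == pytest.approx(math.sqrt(2) * mk_pwv(s, 1e5))

    def test_nonpositive_modulus(self):
        with pytest.raises(InvalidInputError):
            mk_pwv(make_state(), 0.0)


class TestYoungsModulus:
    def test_zero_pressure(self):
        p = StiffnessParams(e0=1e5, xi=0.016, beta=5.0)
        assert youngs_modulus(p, 0.0) == pytest.approx(1e5)

    def test_zero_xi(self):
        p = StiffnessParams(e0=1e5, xi=0.0, beta=5.0)
        assert youngs_modulus(p, 150.0) == pytest.approx(1e5)

    def test_hand_arithmetic(self):
        p = StiffnessParams(e0=100e3, xi=0.016, beta=5.0)
        assert youngs_modulus(p, 100.0) == pytest.approx(100e3 * math.e**1.6)
        assert youngs_modulus(p, 100.0) == pytest.approx(495.3e3, rel=1e-3)

    def test_strictly_increasing(self):
        p = StiffnessParams(e0=1e5, xi=0.016, beta=5.0)
        pressures = np.linspace(40, 200, 20)
        vals = [youngs_modulus(p, x) for x in pressures]
        assert np.all(np.diff(vals) > 0)


class TestMkPressure:
    @pytest.mark.parametrize("pressure", np.linspace(60, 180, 13).tolist())
    def test_exact_inverse(self, pressure):
        s = make_state()
        p = StiffnessParams(e0=1.2e5, xi=0.0172, beta=5.0)
        pwv = mk_pwv(s, youngs_modulus(p, pressure))
        assert mk_pressure(s, p, pwv) == pytest.approx(pressure, rel=1e-9)

    def test_log_of_one(self):
        s = make_state()
        p = StiffnessParams(e0=1e5, xi=0.016, beta=5.0)
        pwv = math.sqrt(s.h * p.e0 / (s.rho_blood * s.d))
        assert mk_pressure(s, p, pwv) == pytest.approx(0.0, abs=1e-12)

    def test_consistency_with_mk_pwv_example(self):
        s = ArterialState(dd=2.5e-3, h=3e-4, rho_blood=1060.0)
        p = StiffnessParams(e0=1e5, xi=0.016, beta=5.0)
        pwv = mk_pwv(s, 500e3)
        pressure = mk_pressure(s, p, pwv)
        assert youngs_modulus(p, pressure) == pytest.approx(500e3, rel=1e-9)

    def test_invalid_inputs(self):
        s = make_state()
        p = StiffnessParams(e0=1e5, xi=0.016, beta=5.0)
        with pytest.raises(InvalidInputError):
            mk_pressure(s, p, 0.0)
        with pytest.raises(InvalidInputError):
            mk_pressure(s, StiffnessParams(e0=1e5, xi=0.0, beta=5.0), 5.0)


class TestRegression:
    def test_exact_fit(self):
        ptts = np.exp(np.linspace(-6.2, -5.0, 10))
        pairs = [(p, -50.0 * math.log(p)) for p in ptts]
        coeffs = regression_fit(pairs)
        assert coeffs.k1 == pytest.approx(-50.0, abs=1e-9)
        assert coeffs.k2 == pytest.approx(0.0, abs=1e-9)

    def test_two_points_zero_residual(self):
        pairs = [(0.003, 120.0), (0.004, 100.0)]
        coeffs = regression_fit(pairs)
        for ptt, bp in pairs:
            assert regression_predict(coeffs, ptt) == pytest.approx(bp, abs=1e-9)

    def test_noisy_recovery_within_3_se(self):
        rng = np.random.default_rng(17)
        k1_true, k2_true, sigma, n = -45.0, -120.0, 3.0, 100
        ptt = np.exp(rng.uniform(-6.3, -5.2, n))
        x = np.log(ptt)
        bp = k1_true * x + k2_true + rng.normal(0, sigma, n)
        coeffs = regression_fit(list(zip(ptt, bp)))
        # standard errors from the OLS sampling distribution
        sxx = float(np.sum((x - x.mean()) ** 2))
        se_k1 = sigma / math.sqrt(sxx)
        se_k2 = sigma * math.sqrt(1.0 / n + x.mean() ** 2 / sxx)
        assert abs(coeffs.k1 - k1_true) < 3 * se_k1
        assert abs(coeffs.k2 - k2_true) < 3 * se_k2

    def test_unbiased_monte_carlo(self):
        # 1000 replicates: mean estimate within MC error of the truth
        rng = np.random.default_rng(5)
        k1_true, k2_true, sigma, n = -40.0, -90.0, 2.0, 30
        x = np.log(np.exp(rng.uniform(-6.3, -5.2, n)))
        k1s = np.empty(1000)
        for r in range(1000):
            bp = k1_true * x + k2_true + rng.normal(0, sigma, n)
            k1s[r], _ = np.polyfit(x, bp, 1)
        se_mean = np.std(k1s, ddof=1) / math.sqrt(1000)
        assert abs(np.mean(k1s) - k1_true) < 4 * se_mean

    def test_too_few_pairs(self):
        with pytest.raises(CalibrationError):
            regression_fit([(0.003, 120.0)])

    def test_duplicate_ptt(self):
        with pytest.raises(CalibrationError):
            regression_fit([(0.003, 120.0), (0.003, 100.0)])

    def test_predict_at_unit_ptt(self):
        assert regression_predict(RegressionCoeffs(-50, 80), 1.0) == pytest.approx(80)

    def test_predict_log_value(self):
        coeffs = RegressionCoeffs(-50.0, 0.0)
        assert regression_predict(coeffs, math.exp(-2)) == pytest.approx(100.0)

    def test_predict_nonpositive_ptt(self):
        with pytest.raises(InvalidInputError):
            regression_predict(RegressionCoeffs(-50, 0), 0.0)


class TestPulsePressure:
    def test_zero_excursion(self):
        assert pulse_pressure(make_state(delta_d=0.0), 5.0) == 0.0

    def test_hand_arithmetic(self):
        # 1060 * 25 * (2*0.05 + 0.05^2) = 2716.25 Pa = 20.374 mmHg
        s = ArterialState(dd=2.0e-3, h=3e-4, delta_d=1.0e-4)
        assert pulse_pressure(s, 5.0) == pytest.approx(2716.25 / MMHG_TO_PA, rel=1e-12)
        assert pulse_pressure(s, 5.0) == pytest.approx(20.374, abs=1e-3)

    def test_algebraic_identity_returns_density(self):
        # 2x + x^2 = 1 at x = sqrt(2) - 1, so Pa output equals rho
        x = math.sqrt(2) - 1
        s = ArterialState(dd=2.0e-3, h=3e-4, delta_d=x * 2.0e-3)
        assert pulse_pressure(s, 1.0) * MMHG_TO_PA == pytest.approx(s.rho_blood, rel=1e-12)

    def test_invalid_pwv(self):
        with pytest.raises(InvalidInputError):
            pulse_pressure(make_state(), -1.0)


class TestMapPBeta:
    def params(self, beta=4.0):
        return StiffnessParams(e0=1e5, xi=0.016, beta=beta)

    def test_zero_pwv(self):
        assert map_p_beta(make_state(), self.params(), 0.0) == 0.0

    def test_hand_arithmetic(self):
        # 2*1060*25/4 = 13250 Pa = 99.38 mmHg
        s = make_state(delta_d=0.0)
        assert map_p_beta(s, self.params(4.0), 5.0) == pytest.approx(
            13250.0 / MMHG_TO_PA, rel=1e-12)
        assert map_p_beta(s, self.params(4.0), 5.0) == pytest.approx(99.38, abs=5e-3)

    def test_doubling_beta_halves_output(self):
        s = make_state()
        assert map_p_beta(s, self.params(8.0), 5.0) == pytest.approx(
            map_p_beta(s, self.params(4.0), 5.0) / 2.0)


class TestBetaCalibrate:
    def test_round_trip_exact(self):
        s = make_state()
        beta = beta_calibrate(s, 5.0, 99.0)
        p = StiffnessParams(e0=1e5, xi=0.016, beta=beta)
        assert map_p_beta(s, p, 5.0) == pytest.approx(99.0, rel=1e-12)

    def test_inverse_of_map_example(self):
        s = make_state(delta_d=0.0)
        assert beta_calibrate(s, 5.0, 13250.0 / MMHG_TO_PA) == pytest.approx(4.0, rel=1e-12)

    def test_strictly_decreasing_in_map_ref(self):
        s = make_state()
        maps = np.linspace(70, 120, 10)
        betas = [beta_calibrate(s, 5.0, m) for m in maps]
        assert np.all(np.diff(betas) < 0)

    def test_invalid_inputs(self):
        with pytest.raises(CalibrationError):
            beta_calibrate(make_state(), 0.0, 100.0)
        with pytest.raises(CalibrationError):
            beta_calibrate(make_state(), 5.0, -10.0)


class TestTrackSbpDbp:
    def test_hand_arithmetic(self):
        est = track_sbp_dbp(100.0, pp=30.0, k=0.76)
        assert est.dbp == pytest.approx(76.0)
        assert est.sbp == pytest.approx(118.24)
        assert est.map == pytest.approx(100.0)
        assert est.pp == pytest.approx(30.0)

    def test_degenerate_k(self):
        est = track_sbp_dbp(100.0, k=1.0)
        assert est.dbp == est.sbp == est.map == pytest.approx(100.0)

    def test_ratio_identity(self):
        for m in (60.0, 95.0, 140.0):
            assert track_sbp_dbp(m, k=0.76).dbp / m == pytest.approx(0.76)

    def test_pp_variant(self):
        est = track_sbp_dbp(100.0, pp=50.0, k=0.76, tracking_variant="pp")
        assert est.sbp == pytest.approx(100.0 + 0.24 * 50.0)

    def test_invalid_k(self):
        with pytest.raises(InvalidInputError):
            track_sbp_dbp(100.0, k=0.0)
        with pytest.raises(InvalidInputError):
            track_sbp_dbp(100.0, k=1.5)


# ---- property tests ------------------------------------------------------

pwv_st = st.floats(min_value=0.5, max_value=20.0)
rho_st = st.floats(min_value=900.0, max_value=1200.0)


@given(map_mmhg=st.floats(min_value=1.0, max_value=300.0),
       k=st.floats(min_value=1e-3, max_value=1.0))
def test_tracking_always_ordered(map_mmhg, k):
    est = track_sbp_dbp(map_mmhg, k=k)
    assert est.sbp >= est.map >= est.dbp


@given(pwv=pwv_st, rho=rho_st,
       ratio=st.floats(min_value=1e-4, max_value=0.099))
def test_pulse_pressure_positive_and_rho_linear(pwv, rho, ratio):
    s1 = ArterialState(dd=2.5e-3, h=3e-4, delta_d=ratio * 2.5e-3, rho_blood=rho)
    s2 = ArterialState(dd=2.5e-3, h=3e-4, delta_d=ratio * 2.5e-3, rho_blood=2 * rho)
    p1 = pulse_pressure(s1, pwv)
    assert p1 > 0
    assert pulse_pressure(s2, pwv) == pytest.approx(2 * p1, rel=1e-12)
    assert pulse_pressure(s1, pwv * 1.1) > p1  # strictly increasing in pwv


@given(pwv=pwv_st, beta=st.floats(min_value=0.5, max_value=20.0))
def test_map_p_beta_increasing_in_pwv(pwv, beta):
    s = ArterialState(dd=2.5e-3, h=3e-4)
    p = StiffnessParams(e0=1e5, xi=0.016, beta=beta)
    assert map_p_beta(s, p, pwv * 1.01) > map_p_beta(s, p, pwv)


@given(pwv=pwv_st, map_ref=st.floats(min_value=40.0, max_value=200.0))
def test_beta_round_trip_property(pwv, map_ref):
    s = ArterialState(dd=2.5e-3, h=3e-4)
    beta = beta_calibrate(s, pwv, map_ref)
    p = StiffnessParams(e0=1e5, xi=0.016, beta=beta)
    assert map_p_beta(s, p, pwv) == pytest.approx(map_ref, rel=1e-12)


@given(pressure=st.floats(min_value=40.0, max_value=220.0),
       e0=st.floats(min_value=1e4, max_value=1e6),
       xi=st.floats(min_value=0.005, max_value=0.03))
def test_mk_inverse_property(pressure, e0, xi):
    s = ArterialState(dd=2.5e-3, h=3e-4)
    p = StiffnessParams(e0=e0, xi=xi, beta=5.0)
    pwv = mk_pwv(s, youngs_modulus(p, pressure))
    assert mk_pressure(s, p, pwv) == pytest.approx(pressure, rel=1e-9)
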