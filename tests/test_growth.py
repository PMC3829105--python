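"""Chemostat analytics: calibration, rates, Pirt, washout, balances."""

import numpy as np
import pytest

from fluxrecon.growth import (
    CalibrationModel,
    ChemostatRecord,
    RatesResult,
    calibrate_od_to_dcw,
    corrected_dcw,
    element_balance,
    fit_pirt,
    fit_washout,
    steady_state_rates,
)


# -- calibration -------------------------------------------------------

def test_calibration_exact_line():
    cal = calibrate_od_to_dcw([(1.0, 0.35), (2.0, 0.70)])
    assert cal.slope == pytest.approx(0.35, abs=1e-12)
    assert cal.r_squared == pytest.approx(1.0, abs=1e-12)


def test_calibration_through_origin():
    cal = calibrate_od_to_dcw([(0.0, 0.0), (1.0, 0.42)])
    assert cal.slope == pytest.approx(0.42, abs=1e-12)


def test_calibration_noisy_recovery():
    rng = np.random.default_rng(1)
    od = rng.uniform(0.2, 3.0, size=50)
    cx = 0.35 * od + rng.normal(0, 0.01, size=50)
    cal = calibrate_od_to_dcw(list(zip(od, cx)))
    # analytic through-origin OLS standard error
    se = 0.01 / np.sqrt(np.sum(od**2))
    assert abs(cal.slope - 0.35) < 1.96 * se * 2  # generous 2x guard band
    assert cal.r_squared > 0.99


def test_calibration_degenerate_inputs():
    with pytest.raises(ValueError):
        calibrate_od_to_dcw([(1.0, 0.35), (1.0, 0.36)])


# -- dry weight correction ---------------------------------------------

def test_corrected_dcw_od_route():
    cal = CalibrationModel(slope=0.35)
    rec = ChemostatRecord(D=0.2, OD600=2.0)
    assert corrected_dcw(rec, cal) == pytest.approx(0.70, abs=1e-12)


def test_corrected_dcw_direct_route():
    cal = CalibrationModel()
    rec = ChemostatRecord(D=0.2, Cx_raw=1.156)
    assert corrected_dcw(rec, cal) == pytest.approx((1.156 - 0.356) * 0.35 / 0.399,
                                                    abs=1e-9)
    assert corrected_dcw(rec, cal) == pytest.approx(0.7018, abs=1e-4)


def test_corrected_dcw_mean_of_both_routes():
    cal = CalibrationModel()
    rec = ChemostatRecord(D=0.2, OD600=2.0, Cx_raw=1.156)
    expected = 0.5 * (0.70 + (1.156 - 0.356) * 0.35 / 0.399)
    assert corrected_dcw(rec, cal) == pytest.approx(expected, abs=1e-9)


def test_corrected_dcw_below_blank_raises():
    with pytest.raises(ValueError):
        corrected_dcw(ChemostatRecord(D=0.2, Cx_raw=0.3), CalibrationModel())


# -- steady-state rates ------------------------------------------------

def test_rates_arithmetic():
    cal = CalibrationModel(slope=0.35)
    rec = ChemostatRecord(D=0.2, OD600=2.0, Cglc_feed=10.0, Cglc_residual=0.0)
    rates = steady_state_rates(rec, cal)
    assert rates.Rglc == pytest.approx(0.36032, abs=1e-5)
    assert rates.qs == pytest.approx(0.5148, abs=1e-4)
    assert rates.Yxs == pytest.approx(0.3885, abs=1e-4)
    assert rates.Rx == pytest.approx(0.14, abs=1e-9)


def test_rates_identity_yxs_equals_d_over_qs():
    cal = CalibrationModel()
    for D, od in [(0.05, 0.9), (0.2, 2.0), (0.4, 2.2)]:
        rec = ChemostatRecord(D=D, OD600=od)
        rates = steady_state_rates(rec, cal)
        assert rates.Yxs == pytest.approx(D / rates.qs, rel=1e-12)
        assert min(rates.Rx, rates.Rglc, rates.qs, rates.Yxs) >= 0


def test_rates_no_consumption_raises():
    rec = ChemostatRecord(D=0.2, OD600=2.0, Cglc_feed=10.0, Cglc_residual=10.0)
    with pytest.raises(ValueError):
        steady_state_rates(rec, CalibrationModel())


def test_rates_zero_offgas_gives_zero_co2():
    rec = ChemostatRecord(D=0.2, OD600=2.0, co2_offgas_fraction=0.0)
    assert steady_state_rates(rec, CalibrationModel()).Rco2 == 0.0


def test_residual_above_feed_rejected():
    with pytest.raises(ValueError):
        ChemostatRecord(D=0.2, OD600=2.0, Cglc_feed=5.0, Cglc_residual=6.0)


# -- Pirt --------------------------------------------------------------

def _pirt_points(yxs_max, ms, ds):
    return [(d, d / yxs_max + ms) for d in ds]


def test_pirt_exact_small():
    params = fit_pirt(_pirt_points(0.4, 0.05, [0.1, 0.2, 0.4]))
    assert params.Yxs_max == pytest.approx(0.4, abs=1e-12)
    assert params.ms == pytest.approx(0.05, abs=1e-12)


def test_pirt_exact_study_values():
    ds = np.arange(0.05, 0.51, 0.05)
    params = fit_pirt(_pirt_points(0.397, 0.037, ds))
    assert params.Yxs_max == pytest.approx(0.397, abs=1e-9)
    assert params.ms == pytest.approx(0.037, abs=1e-9)
    assert params.r_squared == pytest.approx(1.0, abs=1e-12)


def test_pirt_estimator_unbiased_over_replicates():
    rng = np.random.default_rng(42)
    ds = np.arange(0.05, 0.51, 0.05)
    estimates = []
    for _ in range(200):
        qs = np.array([d / 0.397 + 0.037 for d in ds]) + rng.normal(0, 0.02, len(ds))
        estimates.append(fit_pirt(list(zip(ds, qs))).Yxs_max)
    estimates = np.asarray(estimates)
    se_mean = estimates.std(ddof=1) / np.sqrt(len(estimates))
    assert abs(estimates.mean() - 0.397) < max(2 * se_mean, 0.005)


def test_pirt_negative_slope_raises():
    with pytest.raises(ValueError):
        fit_pirt([(0.1, 0.5), (0.2, 0.4), (0.3, 0.3)])


def test_pirt_too_few_points():
    with pytest.raises(ValueError):
        fit_pirt([(0.1, 0.3), (0.2, 0.55)])


# -- washout -----------------------------------------------------------

def test_washout_exact():
    series = [(t, np.exp(-0.61 * t)) for t in (0.0, 1.0, 2.0, 3.0)]
    params = fit_washout(series, D=1.2)
    assert params.mu_max == pytest.approx(0.59, abs=1e-12)


def test_washout_constant_series_gives_mu_equal_d():
    series = [(t, 0.5) for t in (0.0, 1.0, 2.0)]
    assert fit_washout(series, D=0.3).mu_max == pytest.approx(0.3, abs=1e-12)


def test_washout_slope_plus_d_invariant():
    rng = np.random.default_rng(7)
    t = np.linspace(0, 3, 10)
    cx = 0.7 * np.exp((0.59 - 1.2) * t) * np.exp(rng.normal(0, 0.02, len(t)))
    params = fit_washout(list(zip(t, cx)), D=1.2)
    slope = params.mu_max - 1.2
    # analytic OLS SE of the slope under sigma=0.02 noise on ln Cx
    se = 0.02 / np.sqrt(np.sum((t - t.mean()) ** 2))
    assert abs(params.mu_max - 0.59) < 3 * se
    assert slope < 0


def test_washout_nonpositive_density_raises():
    with pytest.raises(ValueError):
        fit_washout([(0.0, 1.0), (1.0, 0.0), (2.0, 0.1)], D=1.2)


# -- element balance ---------------------------------------------------

def test_carbon_balance_worked_example():
    # 12 Cmmol/L/h of glucose carbon in, 5.7 Cmmol/L/h CO2 carbon out
    rates = RatesResult(
        Rx=0.144,
        Rglc=2.0 * 180.16 / 1000.0,       # 2 mmol glucose = 12 Cmmol
        Rco2=5.7 * 44.009 / 1000.0,
        qs=0.5, Yxs=0.4, Cx=0.7,
    )
    rec = ChemostatRecord(D=0.2, OD600=2.0, co2_offgas_fraction=0.001)
    carbon, nitrogen = element_balance([(rec, rates)])
    assert carbon == pytest.approx(6.3 * 12.011 / 144.0, rel=1e-3)
    assert nitrogen is None


def test_carbon_balance_zero_when_all_carbon_leaves():
    rglc = 2.0 * 180.16 / 1000.0
    rates = RatesResult(Rx=0.144, Rglc=rglc, Rco2=12.0 * 44.009 / 1000.0,
                        qs=0.5, Yxs=0.4, Cx=0.7)
    rec = ChemostatRecord(D=0.2, OD600=2.0, co2_offgas_fraction=0.001)
    carbon, _ = element_balance([(rec, rates)])
    assert carbon == pytest.approx(0.0, abs=1e-9)


def test_nitrogen_balance():
    rates = RatesResult(Rx=0.14, Rglc=0.36, Rco2=0.0, qs=0.5, Yxs=0.39, Cx=0.7)
    rec = ChemostatRecord(D=0.2, OD600=2.0, NH4_feed=0.15, NH4_residual=0.05)
    _, nitrogen = element_balance([(rec, rates)])
    assert nitrogen == pytest.approx(0.1 / 0.7, rel=1e-9)


def test_element_balance_zero_rx_raises():
    rates = RatesResult(Rx=0.0, Rglc=0.36, Rco2=0.1, qs=0.5, Yxs=0.0, Cx=0.7)
    rec = ChemostatRecord(D=0.2, OD600=2.0)
    with pytest.raises(ValueError):
        element_balance([(rec, rates)])
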