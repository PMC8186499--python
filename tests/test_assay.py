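"""Fluorometric assay: standard curves, initial rates, blank correction."""

import numpy as np
import pytest

from hydroscreen.assay import (
    AssayError,
    StandardCurve,
    average_concentrations,
    blank_correct,
    estimate_initial_rate,
    fit_standard_curve,
    plate_activity,
)
from hydroscreen.simulate import generate_plate


class TestStandardCurve:
    def test_exact_line(self):
        curve = fit_standard_curve([(0, 100), (1, 300), (2, 500)])
        assert curve.slope == pytest.approx(200.0)
        assert curve.intercept == pytest.approx(100.0)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.linear_range == (0.0, 2.0)

    def test_flat_fluorescence_rejected(self):
        with pytest.raises(AssayError, match="slope"):
            fit_standard_curve([(0, 100), (1, 100), (2, 100)])

    def test_too_few_concentrations(self):
        with pytest.raises(AssayError, match="3 distinct"):
            fit_standard_curve([(0, 100), (1, 300)])

    def test_noisy_line_matches_ols_closed_form(self, rng):
        conc = np.array([0.0, 2.0, 5.0, 10.0, 25.0, 50.0])
        fluor = 40.0 + 180.0 * conc + rng.normal(0, 2.0, size=6)
        curve = fit_standard_curve(zip(conc, fluor), r2_threshold=0.95)
        # closed-form OLS oracle on the same points
        xm, ym = conc.mean(), fluor.mean()
        slope = np.sum((conc - xm) * (fluor - ym)) / np.sum((conc - xm) ** 2)
        assert curve.slope == pytest.approx(slope, rel=1e-12)

    def test_linear_range_truncated_on_saturation(self):
        # quenching above 10 µM: fluorescence falls off the line
        pts = [(0, 100), (1, 300), (2, 500), (5, 1100), (10, 2100), (50, 4000)]
        curve = fit_standard_curve(pts)
        assert curve.linear_range == (0.0, 10.0)
        assert curve.slope == pytest.approx(200.0)


class TestInitialRate:
    CURVE = StandardCurve("active", slope=200.0, intercept=100.0, r_squared=1.0,
                          linear_range=(0.0, 50.0))

    def test_unit_arithmetic(self):
        # 10 AU/min over a 200 AU per µM curve: 10/200*60*0.17617 mg·L⁻¹·h⁻¹
        t = np.arange(0, 125, 5)
        est = estimate_initial_rate(t, 100 + 10.0 * t, self.CURVE, dilution=1.0)
        assert est.rate == pytest.approx(0.52851, abs=1e-5)
        assert not est.qc_flags

    def test_dilution_scales_rate(self):
        t = np.arange(0, 125, 5)
        est = estimate_initial_rate(t, 100 + 10.0 * t, self.CURVE, dilution=0.01)
        assert est.rate == pytest.approx(52.851, abs=1e-3)

    def test_saturating_curve_recovers_initial_slope(self):
        # linear at 8 AU/min with end-of-run saturation (plateau from 110 min)
        t = np.arange(0, 125, 5.0)
        y = np.where(t <= 110, 100 + 8.0 * t, 100 + 8.0 * 110)
        est = estimate_initial_rate(t, y, self.CURVE, dilution=1.0)
        oracle = 8.0 / 200.0 * 60 * 0.17617  # slope of the pre-plateau segment
        assert est.rate == pytest.approx(oracle, rel=0.05)

    def test_stricter_threshold_shortens_window_on_early_plateau(self):
        # plateau from 60 min: a tighter r² cut excludes more of the bend
        # and converges on the constructed slope
        t = np.arange(0, 125, 5.0)
        y = np.where(t <= 60, 100 + 8.0 * t, 100 + 8.0 * 60)
        oracle = 8.0 / 200.0 * 60 * 0.17617
        loose = estimate_initial_rate(t, y, self.CURVE, 1.0, r2_threshold=0.98)
        strict = estimate_initial_rate(t, y, self.CURVE, 1.0, r2_threshold=0.999)
        assert strict.window_points < loose.window_points
        assert abs(strict.rate - oracle) < abs(loose.rate - oracle)
        assert strict.rate == pytest.approx(oracle, rel=1e-9)

    def test_flagged_when_no_linear_window(self, rng):
        t = np.arange(0, 125, 5.0)
        y = rng.normal(0, 100, size=len(t))  # pure noise, no kinetics
        est = estimate_initial_rate(t, y, self.CURVE, dilution=1.0)
        assert "nonlinear" in est.qc_flags

    def test_intercept_invariance(self):
        t = np.arange(0, 125, 5)
        a = estimate_initial_rate(t, 100 + 7.0 * t, self.CURVE, 1.0)
        b = estimate_initial_rate(t, 5000 + 7.0 * t, self.CURVE, 1.0)
        assert a.rate == pytest.approx(b.rate, rel=1e-12)


class TestCorrections:
    @pytest.mark.parametrize(
        "sample,blank,expected,flagged",
        [(10.0, 0.0, 10.0, False), (10.0, 12.0, 0.0, True), (70.4, 3.5, 66.9, False)],
    )
    def test_blank_correct(self, sample, blank, expected, flagged):
        net, flags = blank_correct(sample, blank)
        assert net == pytest.approx(expected)
        assert ("high_blank" in flags) == flagged

    @pytest.mark.parametrize(
        "high,low,mean,flag",
        [(10.0, 10.0, 10.0, False), (10.0, 6.0, 8.0, True), (0.0, 0.0, 0.0, False)],
    )
    def test_average_concentrations(self, high, low, mean, flag):
        m, f = average_concentrations(high, low)
        assert m == pytest.approx(mean)
        assert f is flag


class TestRoundTrip:
    @pytest.mark.parametrize("rate", [0.1, 1.0, 10.0, 100.0])
    @pytest.mark.parametrize("dilution", [0.005, 0.01, 1.0])
    def test_noiseless_plate_recovers_rate(self, rate, dilution):
        plate, _ = generate_plate(rate, dilution=dilution, noise_sd=0.0, seed=0)
        est, _, flags = plate_activity(plate, "MUF-cellobioside")
        assert est == pytest.approx(rate, rel=1e-9)

    def test_blank_wells_fit_zero_slope(self):
        plate, _ = generate_plate(5.0, dilution=0.01, noise_sd=0.0, seed=0)
        curve = StandardCurve("heat_inactivated", 200.0, 50.0, 1.0, (0, 50))
        for well in plate.by_role("blank"):
            est = estimate_initial_rate(well.times, well.fluorescence, curve, well.dilution)
            assert est.rate == pytest.approx(0.0, abs=1e-12)

    def test_estimator_sd_matches_ols_closed_form(self, rng):
        # Gaussian read noise: empirical sd of the fitted slope tracks the
        # OLS slope standard error sigma / sqrt(sum (t - tbar)^2)
        t = np.arange(0, 125, 5.0)
        sigma, slope = 5.0, 10.0
        curve = StandardCurve("active", 200.0, 0.0, 1.0, (0, 50))
        rates = [
            estimate_initial_rate(t, slope * t + rng.normal(0, sigma, len(t)), curve, 1.0).rate
            for _ in range(500)
        ]
        factor = 60 * 0.17617 / 200.0  # AU/min → mg·L⁻¹·h⁻¹
        expected_sd = sigma / np.sqrt(np.sum((t - t.mean()) ** 2)) * factor
        assert np.std(rates, ddof=1) == pytest.approx(expected_sd, rel=0.10)
        assert np.mean(rates) == pytest.approx(slope * factor, rel=0.01)
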