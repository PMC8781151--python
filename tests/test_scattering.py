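"""Debye/Guinier fitting and aggregation-onset detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from silksol.scattering import (
    DebyeFitResult,
    ScatteringCurve,
    aggregation_onset,
    background_subtract,
    debye_intensity,
    fit_debye,
    guinier_fit,
    power_law_exponent,
    q_from_angle,
)


class TestQFromAngle:
    @pytest.mark.parametrize(
        "two_theta, wavelength, expected",
        [
            (0.0, 0.154, 0.0),
            (180.0 - 1e-9, 1.0, 4.0 * math.pi),
            (2.0, 0.154, 1.42419),  # Cu K-alpha at 2 degrees
        ],
    )
    def test_values(self, two_theta, wavelength, expected):
        assert q_from_angle(two_theta, wavelength) == pytest.approx(expected, abs=1e-4)

    def test_rejects_bad_wavelength(self):
        with pytest.raises(ValueError):
            q_from_angle(2.0, 0.0)


class TestDebyeIntensity:
    def test_zero_q_limit(self):
        assert debye_intensity(0.0, 3.0, 12.0) == pytest.approx(3.0)

    def test_x_equals_one(self):
        # 2 I0 e^-1 at q rg = 1
        value = debye_intensity(1.0 / 12.0, 5.0, 12.0)
        assert value == pytest.approx(2.0 * 5.0 * math.exp(-1.0), rel=1e-10)

    def test_high_q_asymptote(self):
        # I q^2 -> 2 I0 / rg^2 in the power-law regime
        rg, I0 = 12.0, 1.0
        q = 20.0 / rg  # x = 400
        assert debye_intensity(q, I0, rg) * q**2 == pytest.approx(
            2.0 * I0 / rg**2, rel=1e-2
        )

    @given(st.floats(1e-3, 50.0))
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_normalised(self, qrg):
        value = debye_intensity(qrg / 7.0, 1.0, 7.0)
        assert 0.0 < value < 1.0

    def test_strictly_decreasing(self):
        q = np.linspace(0.0, 3.0, 500)
        i = debye_intensity(q, 1.0, 9.0)
        assert np.all(np.diff(i) < 0)

    def test_guinier_consistency_at_low_q(self):
        # |D(q)/I0 - (1 - x/3)| <= 0.01 for q rg <= 0.3
        rg = 10.0
        q = np.linspace(1e-4, 0.3 / rg, 50)
        x = q**2 * rg**2
        assert np.max(np.abs(debye_intensity(q, 1.0, rg) - (1.0 - x / 3.0))) <= 0.01


class TestGuinierFit:
    def test_recovers_debye_coil(self, debye_curve):
        _, rg = guinier_fit(debye_curve)
        assert rg == pytest.approx(12.5, rel=0.02)

    def test_exactly_linear_log_intensity(self):
        q = np.linspace(0.01, 0.1, 30)
        curve = ScatteringCurve(q, 4.0 * np.exp(-48.0 * q**2))
        I0, rg = guinier_fit(curve)
        assert rg == pytest.approx(12.0, rel=1e-6)
        assert I0 == pytest.approx(4.0, rel=1e-6)

    def test_flat_curve_has_no_guinier_regime(self):
        q = np.linspace(0.01, 0.1, 30)
        with pytest.raises(ValueError, match="Guinier"):
            guinier_fit(ScatteringCurve(q, np.full_like(q, 2.0)))

    def test_nonpositive_intensity_rejected(self):
        q = np.linspace(0.01, 0.1, 30)
        i = 4.0 * np.exp(-48.0 * q**2)
        i[5] = -1.0
        with pytest.raises(ValueError, match="onpositive"):
            guinier_fit(ScatteringCurve(q, i))


class TestFitDebye:
    def test_noiseless_self_consistency(self, debye_curve):
        res = fit_debye(debye_curve)
        assert res.converged
        assert res.rg == pytest.approx(12.5, rel=1e-6)
        assert res.I0 == pytest.approx(3.0, rel=1e-6)

    @pytest.mark.parametrize("rg", [2.0, 8.0, 17.0, 30.0])
    def test_noiseless_recovery_across_sizes(self, rg):
        q = np.linspace(0.01, 2.0, 300)
        curve = ScatteringCurve(q, debye_intensity(q, 2.0, rg))
        assert fit_debye(curve).rg == pytest.approx(rg, rel=1e-6)

    def test_agrees_with_guinier(self, debye_curve):
        _, rg_g = guinier_fit(debye_curve)
        assert fit_debye(debye_curve).rg == pytest.approx(rg_g, rel=0.03)

    def test_noisy_recovery(self, q_grid):
        rng = np.random.default_rng(20)
        clean = debye_intensity(q_grid, 3.0, 12.5)
        noisy = clean * (1.0 + rng.normal(0.0, 0.05, q_grid.shape))
        curve = ScatteringCurve(q_grid, noisy, 0.05 * clean)
        assert fit_debye(curve).rg == pytest.approx(12.5, rel=0.05)

    def test_aggregated_curve_breaks_single_chain_fit(self, q_grid):
        single = debye_intensity(q_grid, 1.0, 12.5)
        aggregate = 100.0 * debye_intensity(q_grid, 1.0, 90.0)
        curve = ScatteringCurve(q_grid, single + aggregate)
        res = fit_debye(curve)
        assert (not res.converged) or res.rg > 3.0 * 12.5

    def test_too_few_points_rejected(self):
        q = np.linspace(0.01, 0.05, 5)
        with pytest.raises(ValueError):
            fit_debye(ScatteringCurve(q, debye_intensity(q, 1.0, 10.0)))


class TestPowerLawExponent:
    def test_exact_q_minus_two(self):
        q = np.linspace(0.5, 2.0, 40)
        curve = ScatteringCurve(q, 3.0 * q**-2.0)
        assert power_law_exponent(curve, (0.5, 2.0)) == pytest.approx(-2.0, abs=1e-10)

    def test_debye_tail_is_q_minus_two(self):
        rg = 12.5
        q = np.linspace(5.0 / rg, 20.0 / rg, 60)
        curve = ScatteringCurve(q, debye_intensity(q, 1.0, rg))
        assert -2.1 < power_law_exponent(curve, (q[0], q[-1])) < -1.9

    def test_constant_curve(self):
        q = np.linspace(0.5, 2.0, 40)
        curve = ScatteringCurve(q, np.full_like(q, 7.0))
        assert power_law_exponent(curve, (0.5, 2.0)) == pytest.approx(0.0, abs=1e-12)


class TestBackgroundSubtract:
    def test_self_subtraction_is_zero(self, debye_curve):
        out = background_subtract(debye_curve, debye_curve, scale=1.0)
        assert np.allclose(out.intensity, 0.0)

    def test_zero_scale_is_identity(self, debye_curve):
        out = background_subtract(debye_curve, debye_curve, scale=0.0)
        assert np.array_equal(out.intensity, debye_curve.intensity)

    def test_interpolated_background(self):
        sample = ScatteringCurve(np.array([0.2, 0.3, 0.4]), np.array([5.0, 5.0, 5.0]))
        background = ScatteringCurve(
            np.array([0.1, 0.5]), np.array([1.0, 2.0])
        )  # linear: 1 + 2.5 (q - 0.1)
        out = background_subtract(sample, background)
        assert out.intensity == pytest.approx([5 - 1.25, 5 - 1.5, 5 - 1.75])

    def test_disjoint_ranges_rejected(self):
        a = ScatteringCurve(np.array([0.1, 0.2, 0.3, 0.4]), np.ones(4))
        b = ScatteringCurve(np.array([1.0, 1.1, 1.2, 1.3]), np.ones(4))
        with pytest.raises(ValueError):
            background_subtract(a, b)

    def test_sigma_in_quadrature(self):
        q = np.array([0.1, 0.2, 0.3, 0.4])
        a = ScatteringCurve(q, np.ones(4), np.full(4, 3.0))
        b = ScatteringCurve(q, np.ones(4), np.full(4, 4.0))
        out = background_subtract(a, b)
        assert out.sigma == pytest.approx(np.full(4, 5.0))


def _ok(rg):
    return DebyeFitResult(I0=1.0, rg=rg, residual_norm=0.0, converged=True)


def _failed():
    return DebyeFitResult(I0=1.0, rg=float("nan"), residual_norm=1.0, converged=False)


class TestAggregationOnset:
    def test_flat_series_has_no_onset(self):
        series = [(t, _ok(12.0)) for t in (25, 35, 45, 55, 65)]
        assert aggregation_onset(series) is None

    def test_jump_then_failure(self):
        series = [(25, _ok(12)), (35, _ok(12.2)), (45, _ok(11.8)), (55, _ok(12.1)),
                  (60, _ok(12.0)), (65, _ok(25.0)), (70, _ok(60.0)), (75, _failed())]
        assert aggregation_onset(series) == 65

    def test_failure_alone_triggers(self):
        series = [(25, _ok(12)), (35, _ok(12)), (45, _ok(12)), (55, _failed())]
        assert aggregation_onset(series) == 55

    def test_early_failure_rejected(self):
        series = [(25, _failed()), (35, _ok(12)), (45, _ok(12)), (55, _ok(12))]
        with pytest.raises(ValueError):
            aggregation_onset(series)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            aggregation_onset([(25, _ok(12)), (35, _ok(12)), (45, _ok(12))])

    def test_unsorted_series_rejected(self):
        series = [(25, _ok(12)), (45, _ok(12)), (35, _ok(12)), (55, _ok(12))]
        with pytest.raises(ValueError):
            aggregation_onset(series)
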