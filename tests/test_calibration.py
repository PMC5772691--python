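import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxiquant.calibration import (
    CalibrationCurve,
    CalibrationPoint,
    assess_loq,
    back_calculate,
    fit_calibration,
)
from toxiquant.errors import (
    InsufficientCalibrationError,
    InvalidInputError,
    OutOfRangeError,
)


def wls_oracle(xs, ys, w):
    """Independent closed-form weighted normal equations for the quadratic."""
    X = np.column_stack([np.square(xs), xs, np.ones_like(xs)])
    W = np.diag(w)
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ ys)
    return beta  # (a, b, c)


class TestFitCalibration:
    def test_exact_three_point_interpolation(self):
        a, b, c = 1e-4, 0.2, 0.01
        xs = np.array([1.0, 50.0, 400.0])
        pts = [CalibrationPoint(x, a * x**2 + b * x + c) for x in xs]
        curve = fit_calibration(pts)
        assert curve.a == pytest.approx(a, abs=1e-10)
        assert curve.b == pytest.approx(b, abs=1e-10)
        assert curve.c == pytest.approx(c, abs=1e-10)

    def test_noisy_seven_levels_against_oracle(self, rng):
        a, b, c = 2e-6, 1.4e-3, 5e-4
        xs = np.geomspace(1.5, 731, 7)
        truth = a * xs**2 + b * xs + c
        ys = truth * rng.lognormal(0, 0.03, size=7)
        curve = fit_calibration([CalibrationPoint(x, y) for x, y in zip(xs, ys)])
        oracle = wls_oracle(xs, ys, 1.0 / xs)
        assert curve.a == pytest.approx(oracle[0], rel=1e-8)
        assert curve.b == pytest.approx(oracle[1], rel=1e-8)
        assert curve.c == pytest.approx(oracle[2], rel=1e-8, abs=1e-12)
        # coefficients near the generator's
        assert curve.b == pytest.approx(b, rel=0.05)

    @pytest.mark.parametrize("weighting", ["1/x", "1/x^2", "none"])
    def test_oracle_equivalence_random_sets(self, weighting, rng):
        for _ in range(25):
            n = int(rng.integers(4, 11))
            xs = np.sort(rng.uniform(0.5, 900.0, size=n))
            ys = np.abs(rng.uniform(0.001, 2.0, size=n))
            w = {"1/x": 1 / xs, "1/x^2": 1 / xs**2, "none": np.ones_like(xs)}[weighting]
            curve = fit_calibration(
                [CalibrationPoint(x, y) for x, y in zip(xs, ys)], weighting=weighting
            )
            oracle = wls_oracle(xs, ys, w)
            scale = max(abs(oracle).max(), 1e-12)
            assert np.allclose(curve.coefficients, oracle, rtol=1e-6, atol=1e-6 * scale)

    def test_unweighted_equals_polyfit(self, rng):
        xs = np.geomspace(2.0, 500.0, 7)
        ys = 0.003 * xs + rng.normal(0, 0.01, 7) ** 2
        curve = fit_calibration(
            [CalibrationPoint(x, y) for x, y in zip(xs, ys)], weighting="none"
        )
        ref = np.polyfit(xs, ys, 2)
        assert np.allclose(curve.coefficients, ref, rtol=1e-6, atol=1e-10)

    def test_flat_responses_degenerate(self):
        pts = [CalibrationPoint(x, 0.5) for x in (1.0, 10.0, 100.0)]
        curve = fit_calibration(pts)
        assert curve.a == pytest.approx(0.0, abs=1e-12)
        assert curve.b == pytest.approx(0.0, abs=1e-12)
        assert not curve.monotone_on_range

    def test_too_few_levels(self):
        pts = [CalibrationPoint(1.0, 0.1), CalibrationPoint(10.0, 1.0)]
        with pytest.raises(InsufficientCalibrationError):
            fit_calibration(pts)

    def test_duplicate_levels_do_not_count_twice(self):
        pts = [CalibrationPoint(x, x) for x in (1.0, 1.0, 10.0, 10.0)]
        with pytest.raises(InsufficientCalibrationError):
            fit_calibration(pts)

    def test_origin_excluded(self):
        with pytest.raises(InvalidInputError):
            CalibrationPoint(0.0, 0.0)

    def test_weighted_r_squared_definition(self, rng):
        xs = np.geomspace(1.5, 731, 7)
        ys = 0.002 * xs * rng.lognormal(0, 0.05, 7)
        curve = fit_calibration([CalibrationPoint(x, y) for x, y in zip(xs, ys)])
        w = 1.0 / xs
        yhat = curve.predict(xs)
        sse = np.sum(w * (ys - yhat) ** 2)
        ybar = np.sum(w * ys) / np.sum(w)
        sst = np.sum(w * (ys - ybar) ** 2)
        assert curve.r_squared == pytest.approx(1 - sse / sst, rel=1e-12)

    def test_mean_r_squared_anchor(self):
        """Seven-level fits at 3% noise keep the weighted R² above 0.995."""
        rng = np.random.default_rng(777)
        xs = np.geomspace(1.5, 731, 7)
        truth = -3e-7 * xs**2 + 1.4e-3 * xs
        r2 = []
        for _ in range(200):
            ys = truth * rng.lognormal(0, 0.03, 7)
            r2.append(
                fit_calibration([CalibrationPoint(x, y) for x, y in zip(xs, ys)]).r_squared
            )
        assert np.mean(r2) >= 0.995


curve_strategy = st.builds(
    lambda a, b, c, high: CalibrationCurve(
        a=a, b=b, c=c, weighting="1/x", low=high / 500.0, high=high,
        r_squared=1.0, r_squared_unweighted=1.0, loq=high / 500.0,
    ),
    a=st.floats(min_value=-1e-7, max_value=1e-5),
    b=st.floats(min_value=1e-4, max_value=0.1),
    c=st.floats(min_value=-0.01, max_value=0.01),
    high=st.floats(min_value=100.0, max_value=1500.0),
)


class TestBackCalculate:
    @settings(max_examples=300)
    @given(curve=curve_strategy, frac=st.floats(min_value=0.0, max_value=1.0))
    def test_inverse_identity_on_range(self, curve, frac):
        x0 = curve.low + frac * (curve.high - curve.low)
        if 2 * curve.a * curve.high + curve.b <= 0:
            return  # non-monotone draw, out of contract
        response = curve.predict(x0)
        if response < 0:
            return  # negative-intercept draw below the detectable region
        x = back_calculate(curve, response)
        assert x == pytest.approx(x0, rel=1e-9, abs=1e-9)

    def test_linear_curve_matches_bisection(self):
        curve = CalibrationCurve(
            a=0.0, b=0.002, c=0.001, weighting="1/x", low=1.5, high=731.0,
            r_squared=1.0, r_squared_unweighted=1.0, loq=1.5,
        )
        response = 0.002 * 123.4 + 0.001
        lo, hi = 0.0, 1.2 * curve.high
        for _ in range(100):  # bisection oracle on the monotone branch
            mid = 0.5 * (lo + hi)
            if curve.predict(mid) < response:
                lo = mid
            else:
                hi = mid
        assert back_calculate(curve, response) == pytest.approx(0.5 * (lo + hi), rel=1e-9)
        assert back_calculate(curve, response) == pytest.approx(123.4, rel=1e-9)

    def test_response_below_curve_minimum_errors(self):
        curve = CalibrationCurve(
            a=1e-5, b=0.01, c=0.5, weighting="1/x", low=1.0, high=100.0,
            r_squared=1.0, r_squared_unweighted=1.0, loq=1.0,
        )
        with pytest.raises(OutOfRangeError) as err:
            back_calculate(curve, 0.1)  # below intercept, no root in [0, 120]
        assert err.value.response == 0.1

    def test_response_above_ceiling_errors(self):
        curve = CalibrationCurve(
            a=0.0, b=0.001, c=0.0, weighting="1/x", low=1.5, high=731.0,
            r_squared=1.0, r_squared_unweighted=1.0, loq=1.5,
        )
        with pytest.raises(OutOfRangeError):
            back_calculate(curve, 0.001 * 2000.0)

    def test_below_range_returned_not_raised(self):
        curve = CalibrationCurve(
            a=0.0, b=0.002, c=0.0, weighting="1/x", low=1.5, high=731.0,
            r_squared=1.0, r_squared_unweighted=1.0, loq=1.5,
        )
        assert back_calculate(curve, 0.002 * 0.8) == pytest.approx(0.8, rel=1e-9)

    def test_root_selection_on_calibrated_branch(self):
        # saturating curve: two positive roots for responses near the vertex
        curve = CalibrationCurve(
            a=-1e-6, b=0.004, c=0.0, weighting="1/x", low=1.5, high=731.0,
            r_squared=1.0, r_squared_unweighted=1.0, loq=1.5,
        )
        x0 = 500.0
        x = back_calculate(curve, curve.predict(x0))
        assert x == pytest.approx(x0, rel=1e-9)


class TestAssessLoq:
    def test_accepted(self):
        d = assess_loq(1.5, peak_height=150.0, baseline_noise_sd=10.0)
        assert d.signal_to_noise == pytest.approx(15.0)
        assert d.accepted and d.loq == 1.5

    def test_rejected(self):
        d = assess_loq(1.5, peak_height=80.0, baseline_noise_sd=10.0)
        assert d.signal_to_noise == pytest.approx(8.0)
        assert not d.accepted and d.loq is None

    def test_boundary_is_accepted(self):
        assert assess_loq(2.7, 100.0, 10.0).accepted

    def test_invalid_noise(self):
        with pytest.raises(InvalidInputError):
            assess_loq(1.5, 100.0, 0.0)
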