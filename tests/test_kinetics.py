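import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxiquant.errors import InsufficientDataError, InvalidInputError
from toxiquant.kinetics import (
    ConcentrationTimeSeries,
    TimePoint,
    biphasic_summary,
    fit_phase,
    two_point_half_life,
)
from toxiquant.quantify import Censoring


def exponential_series(
    days, c0=100.0, half_life=10.0, loq=0.01, matrix="blood", censor_below_loq=True
):
    points = []
    for d in days:
        c = c0 * 2.0 ** (-d / half_life)
        cens = (
            Censoring.QUANTIFIED
            if (c >= loq or not censor_below_loq)
            else Censoring.BELOW_LOQ_DETECTED
        )
        if not censor_below_loq and c < loq:
            cens = Censoring.QUANTIFIED
        points.append(TimePoint(day=float(d), concentration=c, censoring=cens))
    return ConcentrationTimeSeries(
        matrix=matrix, analyte="coumatetralyl", points=points, loq=loq
    )


class TestTwoPointHalfLife:
    def test_worked_case_values(self):
        t = two_point_half_life((6.0, 9.8), (11.0, 1.5))
        assert t == pytest.approx(1.8465, abs=1e-4)
        assert round(t, 1) == 1.8

    def test_exact_halving(self):
        assert two_point_half_life((0.0, 10.0), (5.0, 5.0)) == pytest.approx(5.0)

    def test_equal_concentrations_rejected(self):
        with pytest.raises(InvalidInputError):
            two_point_half_life((0.0, 10.0), (5.0, 10.0))

    def test_increasing_concentration_rejected(self):
        with pytest.raises(InvalidInputError):
            two_point_half_life((0.0, 5.0), (5.0, 10.0))

    def test_day_order_enforced(self):
        with pytest.raises(InvalidInputError):
            two_point_half_life((5.0, 10.0), (5.0, 5.0))


class TestFitPhase:
    def test_exact_exponential_recovered(self):
        series = exponential_series([6, 7, 11, 18, 22], half_life=7.3)
        fit = fit_phase(series, (6, 22))
        assert fit.half_life == pytest.approx(7.3, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0)
        assert not fit.is_lower_bound

    @settings(max_examples=50)
    @given(
        half_life=st.floats(min_value=0.5, max_value=200.0),
        c0=st.floats(min_value=1.0, max_value=1e4),
    )
    def test_exact_recovery_property(self, half_life, c0):
        series = exponential_series([1, 2, 5, 9], c0=c0, half_life=half_life)
        fit = fit_phase(series, (1, 9))
        assert fit.half_life == pytest.approx(half_life, rel=1e-10)

    def test_two_point_window_matches_two_point_formula(self):
        series = exponential_series([6, 11], c0=9.8 * 2.0 ** (6 / 1.846), half_life=1.846)
        fit = fit_phase(series, (6, 11))
        p1, p2 = [(p.day, p.concentration) for p in series.points]
        assert fit.half_life == pytest.approx(two_point_half_life(p1, p2), rel=1e-12)

    def test_time_shift_invariance(self):
        days = [6, 7, 11, 18]
        s1 = exponential_series(days, half_life=4.0)
        s2 = ConcentrationTimeSeries(
            matrix="blood",
            analyte="coumatetralyl",
            points=[
                TimePoint(p.day + 100.0, p.concentration, p.censoring) for p in s1.points
            ],
            loq=s1.loq,
        )
        f1 = fit_phase(s1, (6, 18))
        f2 = fit_phase(s2, (106, 118))
        assert f1.half_life == pytest.approx(f2.half_life, rel=1e-12)

    def test_scale_invariance(self):
        s1 = exponential_series([6, 7, 11, 18], half_life=4.0)
        for k in (0.5, 7.0, 1e3):
            s2 = ConcentrationTimeSeries(
                matrix="blood",
                analyte="coumatetralyl",
                points=[
                    TimePoint(p.day, k * p.concentration, p.censoring) for p in s1.points
                ],
                loq=s1.loq,
            )
            assert fit_phase(s2, (6, 18)).half_life == pytest.approx(
                fit_phase(s1, (6, 18)).half_life, rel=1e-12
            )

    def test_censored_points_excluded_from_fit(self):
        points = [
            TimePoint(6.0, 100.0),
            TimePoint(7.0, 80.0),
            TimePoint(11.0, 40.0),
            TimePoint(18.0, 0.5, Censoring.BELOW_LOQ_DETECTED),
        ]
        series = ConcentrationTimeSeries("blood", "coumatetralyl", points, loq=1.5)
        fit = fit_phase(series, (6, 18))
        assert fit.n_points == 3
        assert fit.censored_excluded == 1
        assert fit.is_lower_bound  # censored point inside the window

    def test_trailing_censored_sets_lower_bound(self):
        points = [
            TimePoint(64.0, 50.0),
            TimePoint(93.0, 30.0),
            TimePoint(121.0, 20.0),
            TimePoint(204.0, 2.1),
            TimePoint(422.0, 1.0, Censoring.BELOW_LOQ_DETECTED),
        ]
        series = ConcentrationTimeSeries("faeces", "coumatetralyl", points, loq=1.5)
        fit = fit_phase(series, (64, 204))
        assert fit.is_lower_bound

    def test_large_sampling_gap_sets_lower_bound(self):
        series = exponential_series([64, 93, 121, 204, 422], half_life=81.0)
        fit = fit_phase(series, (64, 422))
        assert fit.is_lower_bound  # 204 -> 422 gap >> 2x median spacing

    def test_dense_regular_sampling_no_lower_bound(self):
        series = exponential_series([10, 20, 30, 40, 50], half_life=20.0)
        assert not fit_phase(series, (10, 50)).is_lower_bound

    def test_adding_trailing_censored_never_unsets_flag(self):
        base_days = [64, 93, 121, 204, 422]
        s1 = exponential_series(base_days, half_life=81.0, c0=100.0, loq=0.01)
        f1 = fit_phase(s1, (64, 422))
        points = list(s1.points) + [
            TimePoint(470.0, 0.005, Censoring.BELOW_LOQ_DETECTED)
        ]
        s2 = ConcentrationTimeSeries("blood", "coumatetralyl", points, loq=0.01)
        f2 = fit_phase(s2, (64, 422))
        assert f2.is_lower_bound >= f1.is_lower_bound

    def test_insufficient_data(self):
        series = exponential_series([6, 7, 11], half_life=2.0)
        with pytest.raises(InsufficientDataError):
            fit_phase(series, (100, 200))

    def test_non_decaying_flagged_not_negative(self):
        points = [TimePoint(6.0, 10.0), TimePoint(11.0, 20.0)]
        series = ConcentrationTimeSeries("blood", "coumatetralyl", points, loq=1.0)
        fit = fit_phase(series, (6, 11))
        assert fit.non_decaying
        assert fit.half_life is None


class TestSeriesValidation:
    def test_days_must_increase(self):
        with pytest.raises(InvalidInputError):
            ConcentrationTimeSeries(
                "blood",
                "coumatetralyl",
                [TimePoint(6.0, 10.0), TimePoint(6.0, 9.0)],
                loq=1.0,
            )

    def test_quantified_below_loq_rejected(self):
        with pytest.raises(InvalidInputError):
            ConcentrationTimeSeries(
                "blood", "coumatetralyl", [TimePoint(6.0, 0.5)], loq=1.0
            )


class TestBiphasicSummary:
    def _case_series(self):
        points = [
            TimePoint(6.0, 9.8),
            TimePoint(7.0, 7.0),
            TimePoint(11.0, 1.5),
            TimePoint(18.0, 0.9, Censoring.BELOW_LOQ_DETECTED),
            TimePoint(32.0, 5.0),  # recirculation peak, outside both windows
            TimePoint(39.0, 4.0),
            TimePoint(50.0, 2.5),
            TimePoint(64.0, 1.6),
            TimePoint(93.0, 1.2, Censoring.BELOW_LOQ_DETECTED),
            TimePoint(204.0, 0.0, Censoring.NOT_DETECTED),
        ]
        return ConcentrationTimeSeries("blood", "coumatetralyl", points, loq=1.5)

    def test_last_days_reported(self):
        summary = biphasic_summary(self._case_series(), [(6, 11)])
        assert summary.last_quantified_day == 64.0
        assert summary.last_detected_day == 93.0

    def test_excluded_points_counted(self):
        summary = biphasic_summary(self._case_series(), [(6, 11), (45, 70)])
        assert summary.excluded_days == [32.0, 39.0]

    def test_single_window_covering_all(self):
        series = exponential_series([6, 7, 11, 18], half_life=3.0)
        summary = biphasic_summary(series, [(1, 20)])
        assert len(summary.fits) == 1
        assert summary.excluded_days == []

    def test_overlapping_windows_rejected(self):
        with pytest.raises(InvalidInputError):
            biphasic_summary(self._case_series(), [(6, 11), (10, 20)])

    def test_bump_exclusion_bookkeeping(self, rng):
        from toxiquant.synthgen import PkProfile, generate_case_profile

        profile = PkProfile(
            a_alpha=97.8968, a_beta=0.0921, t_half_alpha=1.8, t_half_beta=81.0,
            faeces_scale=1300.0, bump=(32.0, 5.0, 1.5), aliquot_rsd=0.0,
        )
        case = generate_case_profile(profile, n_aliquots=3)
        summary = biphasic_summary(case["faeces"], [(6.0, 11.0), (64.0, 422.0)])
        in_gap = [
            p.day
            for p in case["faeces"].points
            if 11.0 < p.day < 64.0 and p.quantified
        ]
        not_in_windows = [d for d in summary.excluded_days if 11.0 < d < 64.0]
        assert not_in_windows == in_gap


class TestParameterRecovery:
    def test_case_schedule_monte_carlo(self):
        """Both phases recovered within 15% in >=90% of seeded faecal runs."""
        from toxiquant.synthgen import PkProfile, generate_case_profile

        rng = np.random.default_rng(2024)
        profile = PkProfile(
            a_alpha=97.8968, a_beta=0.0921, t_half_alpha=1.8, t_half_beta=81.0,
            faeces_scale=1300.0, bump=(32.0, 5.0, 1.5), aliquot_rsd=0.25,
        )
        ok_alpha = ok_beta = 0
        n = 500
        for _ in range(n):
            case = generate_case_profile(profile, n_aliquots=6, rng=rng)
            faeces = case["faeces"]
            fa = fit_phase(faeces, (6.0, 11.0))
            fb = fit_phase(faeces, (64.0, 422.0))
            if fa.half_life and abs(fa.half_life - 1.8) / 1.8 <= 0.15:
                ok_alpha += 1
            if fb.half_life and abs(fb.half_life - 81.0) / 81.0 <= 0.15:
                ok_beta += 1
        assert ok_alpha / n >= 0.90
        assert ok_beta / n >= 0.90
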