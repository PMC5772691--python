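"""Multiphasic elimination half-lives from serial concentrations.

Each phase is a log-linear (mono-exponential) segment fitted by ordinary
least squares of ln(concentration) on day over the quantified points in a
user-chosen window; censored points are excluded from the regression but
still drive the lower-bound flag on the estimate. Windows are supplied by
the analyst — no automatic breakpoint detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InsufficientDataError, InvalidInputError
from .quantify import Censoring

__all__ = [
    "TimePoint",
    "ConcentrationTimeSeries",
    "PhaseFit",
    "BiphasicSummary",
    "two_point_half_life",
    "fit_phase",
    "biphasic_summary",
]

LN2 = math.log(2.0)

# a sampling gap larger than this multiple of the median in-window spacing
# marks the terminal estimate as a lower bound
GAP_FACTOR = 2.0


@dataclass(frozen=True)
class TimePoint:
    day: float
    concentration: float
    censoring: Censoring = Censoring.QUANTIFIED
    n_aliquots: int = 1
    aliquot_rsd: float | None = None

    @property
    def quantified(self) -> bool:
        return self.censoring == Censoring.QUANTIFIED

    @property
    def detected(self) -> bool:
        return self.censoring in (
            Censoring.QUANTIFIED,
            Censoring.BELOW_LOQ_DETECTED,
            Censoring.ABOVE_RANGE,
        )


@dataclass
class ConcentrationTimeSeries:
    """Serial concentrations for one analyte in one matrix."""

    matrix: str
    analyte: str
    points: list[TimePoint]
    loq: float
    aliquots: dict[float, np.ndarray] | None = None  # raw parallels per day

    def __post_init__(self) -> None:
        days = [p.day for p in self.points]
        if any(d2 <= d1 for d1, d2 in zip(days, days[1:])):
            raise InvalidInputError("sampling days must be strictly increasing")
        bad = [p.day for p in self.points if p.quantified and p.concentration < self.loq]
        if bad:
            raise InvalidInputError(
                f"points flagged quantified but below LOQ {self.loq}: days {bad}"
            )

    @property
    def days(self) -> list[float]:
        return [p.day for p in self.points]

    def last_quantified_day(self) -> float | None:
        days = [p.day for p in self.points if p.quantified]
        return max(days) if days else None

    def last_detected_day(self) -> float | None:
        days = [p.day for p in self.points if p.detected]
        return max(days) if days else None


@dataclass
class PhaseFit:
    """A log-linear elimination phase over one time window."""

    window: tuple[float, float]
    n_points: int
    lam: float | None  # elimination rate constant, 1/day
    half_life: float | None  # ln2 / lam, days
    r_squared: float
    is_lower_bound: bool
    censored_excluded: int
    non_decaying: bool = False

    def to_dict(self) -> dict:
        return {
            "window": list(self.window),
            "n_points": self.n_points,
            "lambda_per_day": self.lam,
            "half_life_days": self.half_life,
            "r_squared": self.r_squared,
            "is_lower_bound": self.is_lower_bound,
            "censored_excluded": self.censored_excluded,
            "non_decaying": self.non_decaying,
        }


def two_point_half_life(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Half-life from two (day, concentration) points assuming exponential decay.

    t½ = (t₂ − t₁)·ln 2 / ln(C₁/C₂). Non-decaying pairs raise rather than
    returning a negative or infinite half-life.
    """
    (t1, c1), (t2, c2) = p1, p2
    if t2 <= t1:
        raise InvalidInputError(f"day order violated: {t2} <= {t1}")
    if c1 <= 0 or c2 <= 0:
        raise InvalidInputError("both concentrations must be > 0")
    if c2 >= c1:
        raise InvalidInputError(
            f"concentration does not decay ({c1} -> {c2}); no half-life"
        )
    return (t2 - t1) * LN2 / math.log(c1 / c2)


def _window_points(
    series: ConcentrationTimeSeries, window: tuple[float, float]
) -> tuple[list[TimePoint], list[TimePoint]]:
    lo, hi = window
    if hi <= lo:
        raise InvalidInputError(f"window must satisfy start < end, got {window}")
    inside = [p for p in series.points if lo <= p.day <= hi]
    quantified = [p for p in inside if p.quantified]
    censored = [p for p in inside if not p.quantified]
    return quantified, censored


def _lower_bound_flag(
    series: ConcentrationTimeSeries,
    window: tuple[float, float],
    used: Sequence[TimePoint],
    censored_in_window: Sequence[TimePoint],
) -> bool:
    """Lower-bound policy for the 'at least' phrasing on terminal phases.

    Set when (a) the window contains censored-below-LOQ points, (b) the
    first sample after the window is censored (the decline ran into the
    LOQ), or (c) consecutive quantified points in the window are separated
    by a gap larger than twice the median in-window spacing — the true
    decline between sparse late samples is then unresolved.
    """
    if any(p.censoring == Censoring.BELOW_LOQ_DETECTED for p in censored_in_window):
        return True
    after = [p for p in series.points if p.day > window[1]]
    if after and after[0].censoring in (
        Censoring.BELOW_LOQ_DETECTED,
        Censoring.NOT_DETECTED,
    ):
        return True
    if len(used) >= 3:
        days = np.array([p.day for p in used])
        gaps = np.diff(days)
        if gaps.size >= 2 and float(gaps.max()) > GAP_FACTOR * float(np.median(gaps)):
            return True
    return False


def fit_phase(
    series: ConcentrationTimeSeries, window: tuple[float, float]
) -> PhaseFit:
    """OLS of ln(concentration) on day over quantified points in ``window``.

    λ is the negated slope and t½ = ln2/λ. A non-positive λ yields a flagged
    non-decaying result with the half-life unset instead of a negative value.

    Raises
    ------
    InsufficientDataError
        With fewer than 2 quantified points in the window.
    """
    used, censored = _window_points(series, window)
    if len(used) < 2:
        raise InsufficientDataError(
            f"window {window}: need >= 2 quantified points, found {len(used)}"
        )
    days = np.array([p.day for p in used], dtype=float)
    logc = np.log([p.concentration for p in used])
    slope, intercept = np.polyfit(days, logc, 1)
    resid = logc - (slope * days + intercept)
    sst = float(np.sum((logc - logc.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0

    lam = -float(slope)
    non_decaying = lam <= 0
    return PhaseFit(
        window=(float(window[0]), float(window[1])),
        n_points=len(used),
        lam=None if non_decaying else lam,
        half_life=None if non_decaying else LN2 / lam,
        r_squared=r2,
        is_lower_bound=_lower_bound_flag(series, window, used, censored),
        censored_excluded=len(censored),
        non_decaying=non_decaying,
    )


@dataclass
class BiphasicSummary:
    """Ordered phase fits plus bookkeeping of what fell outside every window."""

    matrix: str
    analyte: str
    fits: list[PhaseFit]
    excluded_days: list[float]  # quantified points not used by any window
    last_quantified_day: float | None
    last_detected_day: float | None

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix,
            "analyte": self.analyte,
            "phases": [f.to_dict() for f in self.fits],
            "excluded_days": self.excluded_days,
            "last_quantified_day": self.last_quantified_day,
            "last_detected_day": self.last_detected_day,
        }


def biphasic_summary(
    series: ConcentrationTimeSeries, windows: Sequence[tuple[float, float]]
) -> BiphasicSummary:
    """Fit each window and report points excluded from all of them.

    Windows must be non-overlapping and increasing; the points between them
    (e.g. an enterohepatic-recirculation peak) are listed, not silently lost.
    """
    if not windows:
        raise InvalidInputError("at least one phase window is required")
    wins = [tuple(map(float, w)) for w in windows]
    for (a1, b1), (a2, b2) in zip(wins, wins[1:]):
        if a2 <= b1:
            raise InvalidInputError(
                f"windows must be non-overlapping and increasing: {(a1, b1)} vs {(a2, b2)}"
            )
    fits = [fit_phase(series, w) for w in wins]
    excluded = [
        p.day
        for p in series.points
        if p.quantified and not any(lo <= p.day <= hi for lo, hi in wins)
    ]
    return BiphasicSummary(
        matrix=series.matrix,
        analyte=series.analyte,
        fits=fits,
        excluded_days=excluded,
        last_quantified_day=series.last_quantified_day(),
        last_detected_day=series.last_detected_day(),
    )
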