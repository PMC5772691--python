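"""Weighted second-order calibration: fitting, inversion and LOQ policy.

The quantification model is a quadratic response curve y = a·x² + b·x + c
fitted by weighted least squares with 1/x weights (origin excluded), which
is appropriate for the constant-CV noise of peak-height ratios over a wide
concentration range. Back-calculation inverts the fitted curve on the
monotone branch containing the calibration range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    InsufficientCalibrationError,
    InvalidInputError,
    OutOfRangeError,
)

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "LoqDecision",
    "fit_calibration",
    "back_calculate",
    "assess_loq",
    "WEIGHTING_SCHEMES",
]

WEIGHTING_SCHEMES = ("1/x", "1/x^2", "none")

# extrapolation ceiling above the top calibrator within which roots are accepted
RANGE_CEILING = 1.2


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibrator observation: nominal concentration and response ratio."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if self.x <= 0:
            raise InvalidInputError(f"calibrator concentration must be > 0, got {self.x}")
        if self.y < 0:
            raise InvalidInputError(f"response ratio must be >= 0, got {self.y}")


@dataclass
class CalibrationCurve:
    """Fitted quadratic y = a·x² + b·x + c with its quality metadata."""

    a: float
    b: float
    c: float
    weighting: str
    low: float
    high: float
    r_squared: float
    r_squared_unweighted: float
    loq: float | None = None
    analyte: str | None = None
    monotone_on_range: bool = True
    n_points: int = 0

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    def predict(self, x: float | np.ndarray) -> float | np.ndarray:
        return self.a * np.square(x) + self.b * np.asarray(x) + self.c

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "weighting": self.weighting,
            "low": self.low,
            "high": self.high,
            "r_squared": self.r_squared,
            "r_squared_unweighted": self.r_squared_unweighted,
            "loq": self.loq,
            "monotone_on_range": self.monotone_on_range,
            "n_points": self.n_points,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(**d)


@dataclass(frozen=True)
class LoqDecision:
    loq: float | None
    signal_to_noise: float
    accepted: bool


def _weights(xs: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "1/x":
        return 1.0 / xs
    if weighting in ("1/x^2", "1/x2", "1/x²"):
        return 1.0 / xs**2
    if weighting == "none":
        return np.ones_like(xs)
    raise InvalidInputError(
        f"unknown weighting scheme {weighting!r}; expected one of {WEIGHTING_SCHEMES}"
    )


def _r_squared(y: np.ndarray, yhat: np.ndarray, w: np.ndarray) -> float:
    """1 - SSE/SST on the weighted scale, with the weighted mean in SST."""
    sse = float(np.sum(w * (y - yhat) ** 2))
    ybar = float(np.sum(w * y) / np.sum(w))
    sst = float(np.sum(w * (y - ybar) ** 2))
    if sst == 0.0:
        return float("nan")
    return 1.0 - sse / sst


def fit_calibration(
    points: Iterable[CalibrationPoint] | Sequence[tuple[float, float]],
    weighting: str = "1/x",
    loq: float | None = None,
    analyte: str | None = None,
) -> CalibrationCurve:
    """Fit y = a·x² + b·x + c by weighted least squares.

    Minimizes Σ wᵢ(yᵢ − a·xᵢ² − b·xᵢ − c)² with wᵢ given by ``weighting``
    (default 1/x). The design is solved on a concentration scale normalized
    by the top calibrator so that exact data are recovered to near machine
    precision over wide (three-decade) ranges.

    A curve that is not strictly increasing on [low, high] is returned with
    ``monotone_on_range`` False (quantification on the monotone sub-branch
    is still permitted), not rejected.

    Raises
    ------
    InsufficientCalibrationError
        With fewer than 3 distinct concentration levels.
    """
    pts = [p if isinstance(p, CalibrationPoint) else CalibrationPoint(*p) for p in points]
    xs = np.array([p.x for p in pts], dtype=float)
    ys = np.array([p.y for p in pts], dtype=float)
    if len(np.unique(xs)) < 3:
        raise InsufficientCalibrationError(
            f"need >= 3 distinct calibration levels, got {len(np.unique(xs))}"
        )
    w = _weights(xs, weighting)

    # scale x to condition the quadratic design
    x_scale = float(xs.max())
    t = xs / x_scale
    design = np.column_stack([t**2, t, np.ones_like(t)])
    sw = np.sqrt(w)
    coef_t, *_ = np.linalg.lstsq(design * sw[:, None], ys * sw, rcond=None)
    a = coef_t[0] / x_scale**2
    b = coef_t[1] / x_scale
    c = coef_t[2]

    yhat = a * xs**2 + b * xs + c
    low, high = float(xs.min()), float(xs.max())
    # quadratic derivative is linear: positivity at both endpoints suffices
    monotone = bool(2 * a * low + b > 0 and 2 * a * high + b > 0)
    return CalibrationCurve(
        a=float(a),
        b=float(b),
        c=float(c),
        weighting=weighting,
        low=low,
        high=high,
        r_squared=_r_squared(ys, yhat, w),
        r_squared_unweighted=_r_squared(ys, yhat, np.ones_like(w)),
        loq=loq if loq is not None else low,
        analyte=analyte,
        monotone_on_range=monotone,
        n_points=len(pts),
    )


def _newton_polish(curve: CalibrationCurve, x: float, response: float) -> float:
    """One or two Newton steps to clean up the closed-form root."""
    for _ in range(2):
        deriv = 2 * curve.a * x + curve.b
        if deriv == 0:
            break
        x -= (curve.predict(x) - response) / deriv
    return x


def back_calculate(curve: CalibrationCurve, response: float) -> float:
    """Invert the calibration curve: find x with curve.predict(x) = response.

    Root selection policy: real roots in [0, 1.2·high] are candidates; when
    both quadratic roots qualify, the one on the monotone branch containing
    the calibration range wins. Results below the lowest calibrator are
    returned as-is — censoring against the LOQ is the caller's concern.

    Raises
    ------
    OutOfRangeError
        If no real root exists or no root lies in [0, 1.2·high]; the
        offending response is attached to the exception.
    """
    if response < 0:
        raise InvalidInputError(f"response must be >= 0, got {response}")
    a, b, c = curve.a, curve.b, curve.c
    ceiling = RANGE_CEILING * curve.high
    tol = 1e-9 * max(1.0, ceiling)

    if a == 0.0 or abs(a) * ceiling**2 < 1e-14 * max(abs(b) * ceiling, abs(c), 1e-300):
        # effectively linear
        if b == 0.0:
            raise OutOfRangeError("degenerate flat curve cannot be inverted", response)
        roots = [(response - c) / b]
    else:
        disc = b * b - 4 * a * (c - response)
        if disc < 0:
            raise OutOfRangeError(
                f"response {response} has no real solution on the curve", response
            )
        sq = math.sqrt(disc)
        # numerically stable quadratic roots
        q = -0.5 * (b + math.copysign(sq, b)) if b != 0 else 0.5 * sq
        if q != 0:
            roots = [q / a, (c - response) / q]
        else:
            roots = [sq / (2 * a), -sq / (2 * a)]

    candidates = [r for r in roots if -tol <= r <= ceiling + tol]
    if not candidates:
        raise OutOfRangeError(
            f"response {response} maps outside [0, {ceiling:.6g}] "
            f"(roots: {sorted(set(roots))})",
            response,
        )
    if len(candidates) > 1 and a != 0.0:
        vertex = -b / (2 * a)
        mid = 0.5 * (curve.low + curve.high)
        range_side = 1.0 if mid >= vertex else -1.0
        on_branch = [r for r in candidates if (r - vertex) * range_side >= 0]
        if on_branch:
            candidates = on_branch
        # tie-break: nearest to the calibration range
        candidates.sort(key=lambda r: abs(r - mid))
    x = max(0.0, _newton_polish(curve, candidates[0], response))
    return x


def assess_loq(
    lowest_calibrator: float,
    peak_height: float,
    baseline_noise_sd: float,
    min_signal_to_noise: float = 10.0,
) -> LoqDecision:
    """LOQ policy: accept the lowest calibrator if its S/N is at least 10.

    S/N is peak height divided by the standard deviation of a peak-free
    baseline segment.
    """
    if baseline_noise_sd <= 0:
        raise InvalidInputError(
            f"baseline noise SD must be > 0, got {baseline_noise_sd}"
        )
    sn = peak_height / baseline_noise_sd
    accepted = sn >= min_signal_to_noise
    return LoqDecision(
        loq=lowest_calibrator if accepted else None,
        signal_to_noise=sn,
        accepted=accepted,
    )
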