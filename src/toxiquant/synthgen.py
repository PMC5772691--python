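"""Seeded synthetic data: calibration/QC peak tables, matrix-effect
experiments and case-like biphasic concentration-time profiles.

This module replaces the instrument and the subject. Response noise is
multiplicative lognormal with a fixed CV — exactly the heteroscedastic
regime that motivates 1/x calibration weighting — and every stochastic
operation takes an explicit :class:`numpy.random.Generator`; there is no
global random state anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InvalidInputError
from .kinetics import ConcentrationTimeSeries, TimePoint
from .panel import AnalytePanel
from .quantify import Censoring, PeakRecord, PeakTable

__all__ = [
    "ResponseModel",
    "PkProfile",
    "simulate_response",
    "generate_calibration_set",
    "generate_qc_set",
    "generate_matrix_experiment",
    "generate_case_profile",
    "DEFAULT_SCHEDULE",
    "default_models",
]

# the 16-day case sampling schedule, days post-ingestion
DEFAULT_SCHEDULE: tuple[float, ...] = (
    6, 7, 11, 18, 22, 24, 32, 39, 50, 64, 93, 121, 204, 422, 470, 513,
)

SET_SCALES = {"neat": "none", "post_spike": "m", "pre_spike": "mr", "routine": "mr"}

DEFAULT_IS_HEIGHT = 1.0e5


@dataclass(frozen=True)
class ResponseModel:
    """Generative counterpart of the quadratic quantification model.

    Mean response ratio at concentration x is s·(a2·x² + a1·x + a0) where s
    depends on the spiking set: 1 for neat standard, m (matrix effect) for
    post-extraction spikes, m·r (with extraction recovery r) for
    pre-extraction spikes and routine samples.
    """

    a1: float
    a2: float = 0.0
    a0: float = 0.0
    noise_cv: float = 0.0
    matrix_effect: float = 1.0  # m
    recovery: float = 1.0  # r
    qualifier_ratio: float = 0.40  # mean qualifier/quantifier height ratio

    def __post_init__(self) -> None:
        if self.a1 <= 0:
            raise InvalidInputError(f"slope a1 must be > 0, got {self.a1}")
        if self.noise_cv < 0:
            raise InvalidInputError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if not 0 < self.matrix_effect <= 1.2:
            raise InvalidInputError(
                f"matrix_effect must be in (0, 1.2], got {self.matrix_effect}"
            )
        if not 0 < self.recovery <= 1:
            raise InvalidInputError(f"recovery must be in (0, 1], got {self.recovery}")
        if self.qualifier_ratio <= 0:
            raise InvalidInputError("qualifier_ratio must be > 0")

    def check_increasing(self, low: float, high: float) -> None:
        """The quadratic derivative is linear — endpoint checks suffice."""
        if 2 * self.a2 * low + self.a1 <= 0 or 2 * self.a2 * high + self.a1 <= 0:
            raise InvalidInputError(
                f"response model is not strictly increasing on [{low}, {high}]"
            )

    def mean_response(self, conc: float) -> float:
        return self.a2 * conc**2 + self.a1 * conc + self.a0


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit mean and the requested CV."""
    sigma2 = math.log1p(cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=sigma, size=size)


def simulate_response(
    conc: float,
    model: ResponseModel,
    set_kind: str = "neat",
    rng: np.random.Generator | None = None,
) -> float:
    """One response ratio draw for a sample at ``conc``.

    ``set_kind`` selects the deterministic scale (see :class:`ResponseModel`);
    noise is multiplicative lognormal with CV ``model.noise_cv``, so a
    positive mean response always yields a strictly positive draw.
    """
    if conc < 0:
        raise InvalidInputError(f"concentration must be >= 0, got {conc}")
    if set_kind not in SET_SCALES:
        raise InvalidInputError(
            f"unknown set kind {set_kind!r}; expected one of {sorted(SET_SCALES)}"
        )
    scale = 1.0
    if SET_SCALES[set_kind] == "m":
        scale = model.matrix_effect
    elif SET_SCALES[set_kind] == "mr":
        scale = model.matrix_effect * model.recovery
    mean = scale * model.mean_response(conc)
    if model.noise_cv > 0:
        if rng is None:
            raise InvalidInputError("noisy simulation requires an rng")
        mean *= float(_lognormal_factor(rng, model.noise_cv))
    return mean


def default_models(
    panel: AnalytePanel,
    noise_cv: float = 0.0,
    matrix_effect: float = 1.0,
    recovery: float = 1.0,
    curvature_rel: float = -2e-4,
) -> dict[str, ResponseModel]:
    """One mildly curved response model per panel analyte.

    The slope is scaled to each analyte's range so top-of-range response
    ratios are O(1); ``curvature_rel`` bends the curve by a few percent of
    the linear term at the top calibrator (negative = detector saturation).
    """
    models = {}
    for analyte in panel.analytes:
        high = analyte.calibration_range_ng[1]
        a1 = 1.0 / high
        models[analyte.name] = ResponseModel(
            a1=a1,
            a2=curvature_rel * a1 / high,
            a0=0.0,
            noise_cv=noise_cv,
            matrix_effect=matrix_effect,
            recovery=recovery,
        )
    return models


def _emit_records(
    model: ResponseModel,
    analyte: str,
    conc: float,
    set_kind: str,
    rng: np.random.Generator | None,
    sample_id: str,
    role: str,
    matrix: str,
    is_height: float,
    nominal_conc: float | None,
) -> list[PeakRecord]:
    """Quantifier + qualifier record pair for one injection."""
    ratio = simulate_response(conc, model, set_kind, rng)
    qual_ratio = ratio * model.qualifier_ratio
    if model.noise_cv > 0 and rng is not None:
        qual_ratio *= float(_lognormal_factor(rng, model.noise_cv))
    common = dict(
        sample_id=sample_id,
        analyte=analyte,
        matrix=matrix,
        role=role,
        nominal_conc=nominal_conc,
        is_height=is_height,
    )
    return [
        PeakRecord(transition_role="quantifier", peak_height=ratio * is_height, **common),
        PeakRecord(transition_role="qualifier", peak_height=qual_ratio * is_height, **common),
    ]


def calibration_levels(low: float, high: float, n_levels: int) -> np.ndarray:
    """Geometric level spacing over [low, high], endpoints included."""
    if n_levels < 3:
        raise InvalidInputError(f"need >= 3 calibration levels, got {n_levels}")
    return np.geomspace(low, high, n_levels)


def generate_calibration_set(
    panel: AnalytePanel,
    models: Mapping[str, ResponseModel],
    n_levels: int = 7,
    replicates: int = 1,
    rng: np.random.Generator | None = None,
    matrix: str = "blood",
    set_kind: str = "neat",
    is_height: float = DEFAULT_IS_HEIGHT,
) -> PeakTable:
    """Calibrator peak table: geometric levels over each analyte's range."""
    if replicates < 1:
        raise InvalidInputError(f"replicates must be >= 1, got {replicates}")
    table = PeakTable()
    for analyte in panel.analytes:
        model = models[analyte.name]
        low, high = analyte.calibration_range_ng
        model.check_increasing(low, high)
        for i, level in enumerate(calibration_levels(low, high, n_levels)):
            for rep in range(replicates):
                table.extend(
                    _emit_records(
                        model,
                        analyte.name,
                        float(level),
                        set_kind,
                        rng,
                        sample_id=f"cal-L{i + 1}-r{rep + 1}",
                        role="calibrator",
                        matrix=matrix,
                        is_height=is_height,
                        nominal_conc=float(level),
                    )
                )
    return table


def generate_qc_set(
    panel: AnalytePanel,
    models: Mapping[str, ResponseModel],
    levels: Mapping[str, Sequence[float]] | None = None,
    n_replicates: int = 6,
    n_days: int = 1,
    between_day_cv: float = 0.0,
    rng: np.random.Generator | None = None,
    matrix: str = "blood",
    set_kind: str = "routine",
    is_height: float = DEFAULT_IS_HEIGHT,
) -> PeakTable:
    """QC replicates at 3 levels (default: 3×LOQ, mid-range, 80% of top).

    ``n_days`` > 1 adds a shared lognormal day factor with CV
    ``between_day_cv`` to every replicate of a day, for between-day
    precision experiments; the day index is stored in the ``day`` field.
    """
    if n_replicates < 1 or n_days < 1:
        raise InvalidInputError("n_replicates and n_days must be >= 1")
    if between_day_cv > 0 and rng is None:
        raise InvalidInputError("between-day variation requires an rng")
    table = PeakTable()
    for analyte in panel.analytes:
        model = models[analyte.name]
        low, high = analyte.calibration_range_ng
        if levels is None:
            qc_levels: Sequence[float] = (3 * low, math.sqrt(low * high), 0.8 * high)
        else:
            qc_levels = levels[analyte.name]
        for day in range(1, n_days + 1):
            day_factor = (
                float(_lognormal_factor(rng, between_day_cv))
                if between_day_cv > 0
                else 1.0
            )
            for li, level in enumerate(qc_levels):
                for rep in range(n_replicates):
                    day_model = ResponseModel(
                        a1=model.a1 * day_factor,
                        a2=model.a2 * day_factor,
                        a0=model.a0 * day_factor,
                        noise_cv=model.noise_cv,
                        matrix_effect=model.matrix_effect,
                        recovery=model.recovery,
                        qualifier_ratio=model.qualifier_ratio,
                    )
                    recs = _emit_records(
                        day_model,
                        analyte.name,
                        float(level),
                        set_kind,
                        rng,
                        sample_id=f"qc-L{li + 1}-d{day}-r{rep + 1}",
                        role="qc",
                        matrix=matrix,
                        is_height=is_height,
                        nominal_conc=float(level),
                    )
                    recs = [
                        PeakRecord(
                            **{
                                **{c: getattr(r, c) for c in PeakTable.COLUMNS},
                                "day": float(day),
                            }
                        )
                        for r in recs
                    ]
                    table.extend(recs)
    return table


def generate_matrix_experiment(
    panel: AnalytePanel,
    models: Mapping[str, ResponseModel],
    n_lots: int = 5,
    levels: int | Mapping[str, Sequence[float]] = 2,
    lot_cv: float = 0.0,
    rng: np.random.Generator | None = None,
    matrix: str = "blood",
    is_height: float = DEFAULT_IS_HEIGHT,
) -> dict[str, PeakTable]:
    """Three-set post-extraction-spiking experiment over ``n_lots`` blank lots.

    Returns peak tables keyed ``neat`` (set A), ``post_spike`` (set B) and
    ``pre_spike`` (set C). A per-lot multiplicative effect (CV ``lot_cv``) is
    drawn once per lot and shared between that lot's post- and pre-spiked
    samples, so ME/RE estimators see realistically paired lots; neat
    standards carry no lot effect.
    """
    if n_lots < 2:
        raise InvalidInputError(f"need >= 2 lots, got {n_lots}")
    if lot_cv > 0 and rng is None:
        raise InvalidInputError("lot effects require an rng")
    sets = {"neat": PeakTable(), "post_spike": PeakTable(), "pre_spike": PeakTable()}
    roles = {"neat": "setA", "post_spike": "setB", "pre_spike": "setC"}
    for analyte in panel.analytes:
        model = models[analyte.name]
        low, high = analyte.calibration_range_ng
        if isinstance(levels, int):
            if levels == 2:
                concs: Sequence[float] = (3 * low, 0.5 * high)
            else:
                concs = tuple(calibration_levels(3 * low, 0.5 * high, max(levels, 3)))[
                    :levels
                ]
        else:
            concs = levels[analyte.name]
        lot_factors = (
            _lognormal_factor(rng, lot_cv, size=n_lots) if lot_cv > 0 else np.ones(n_lots)
        )
        for lot in range(n_lots):
            for li, conc in enumerate(concs):
                for set_kind, table in sets.items():
                    recs = _emit_records(
                        model,
                        analyte.name,
                        float(conc),
                        set_kind,
                        rng,
                        sample_id=f"{roles[set_kind]}-lot{lot + 1}-L{li + 1}",
                        role=roles[set_kind],
                        matrix=matrix,
                        is_height=is_height,
                        nominal_conc=float(conc),
                    )
                    if set_kind != "neat":
                        factor = float(lot_factors[lot])
                        recs = [
                            PeakRecord(
                                **{
                                    **{c: getattr(r, c) for c in PeakTable.COLUMNS},
                                    "peak_height": r.peak_height * factor,
                                }
                            )
                            for r in recs
                        ]
                    table.extend(recs)
    return sets


@dataclass(frozen=True)
class PkProfile:
    """Two-exponential elimination profile with an optional faecal bump.

    Blood follows C(t) = A_α·2^(−t/t½α) + A_β·2^(−t/t½β); faeces scale the
    same curve by ``faeces_scale`` times an optional Gaussian bump
    (center, width, relative height) standing in for enterohepatic
    recirculation. Aliquot scatter is lognormal with CV ``aliquot_rsd``.
    """

    a_alpha: float
    a_beta: float
    t_half_alpha: float
    t_half_beta: float
    faeces_scale: float = 10.0
    bump: tuple[float, float, float] | None = None
    aliquot_rsd: float = 0.25
    loq: float = 1.5

    def __post_init__(self) -> None:
        if self.a_alpha < 0 or self.a_beta < 0:
            raise InvalidInputError("amplitudes must be >= 0")
        if self.t_half_alpha <= 0 or self.t_half_beta <= 0:
            raise InvalidInputError("half-lives must be > 0")
        if self.t_half_alpha >= self.t_half_beta:
            raise InvalidInputError(
                f"alpha half-life ({self.t_half_alpha}) must be shorter than "
                f"beta half-life ({self.t_half_beta})"
            )
        if self.aliquot_rsd < 0 or self.loq <= 0 or self.faeces_scale <= 0:
            raise InvalidInputError("aliquot_rsd >= 0, loq > 0, faeces_scale > 0 required")

    def blood_conc(self, t: float) -> float:
        return self.a_alpha * 2.0 ** (-t / self.t_half_alpha) + self.a_beta * 2.0 ** (
            -t / self.t_half_beta
        )

    def faeces_conc(self, t: float) -> float:
        value = self.faeces_scale * self.blood_conc(t)
        if self.bump is not None:
            center, width, height = self.bump
            value *= 1.0 + height * math.exp(-0.5 * ((t - center) / width) ** 2)
        return value


def _censor(value: float, loq: float) -> Censoring:
    if value >= loq:
        return Censoring.QUANTIFIED
    return Censoring.BELOW_LOQ_DETECTED if value > 0 else Censoring.NOT_DETECTED


def generate_case_profile(
    profile: PkProfile,
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
    n_aliquots: int | tuple[int, int] = (3, 6),
    rng: np.random.Generator | None = None,
    analyte: str = "coumatetralyl",
) -> dict[str, ConcentrationTimeSeries]:
    """Blood and faeces series over ``schedule`` with raw faecal aliquots.

    Blood is one measurement per day; faeces carry 3-6 parallel aliquots
    (uniform draw within the bounds, or a fixed count) whose values scatter
    lognormally around the true curve with CV ``aliquot_rsd``. Points below
    the LOQ are emitted flagged censored, never dropped; a faecal point's
    concentration is the mean of its quantified aliquots.
    """
    days = [float(d) for d in schedule]
    if any(d <= 0 for d in days):
        raise InvalidInputError("schedule days must be > 0")
    if any(d2 <= d1 for d1, d2 in zip(days, days[1:])):
        raise InvalidInputError("schedule must be strictly increasing")
    noisy = profile.aliquot_rsd > 0
    if noisy and rng is None:
        raise InvalidInputError("noisy profiles require an rng")

    blood_points = []
    for day in days:
        value = profile.blood_conc(day)
        if noisy:
            value *= float(_lognormal_factor(rng, profile.aliquot_rsd))
        blood_points.append(
            TimePoint(day=day, concentration=value, censoring=_censor(value, profile.loq))
        )

    faeces_points = []
    raw: dict[float, np.ndarray] = {}
    for day in days:
        if isinstance(n_aliquots, int):
            n = n_aliquots
        else:
            lo, hi = n_aliquots
            n = int(rng.integers(lo, hi + 1)) if rng is not None else lo
        truth = profile.faeces_conc(day)
        values = truth * (
            _lognormal_factor(rng, profile.aliquot_rsd, size=n) if noisy else np.ones(n)
        )
        raw[day] = values
        quantified = values[values >= profile.loq]
        if quantified.size:
            mean = float(quantified.mean())
            rsd = (
                100.0 * float(quantified.std(ddof=1)) / mean
                if quantified.size >= 2 and mean > 0
                else None
            )
            faeces_points.append(
                TimePoint(
                    day=day,
                    concentration=mean,
                    censoring=Censoring.QUANTIFIED,
                    n_aliquots=int(n),
                    aliquot_rsd=rsd,
                )
            )
        else:
            mean = float(values.mean())
            faeces_points.append(
                TimePoint(
                    day=day,
                    concentration=mean,
                    censoring=_censor(mean, profile.loq),
                    n_aliquots=int(n),
                )
            )

    return {
        "blood": ConcentrationTimeSeries(
            matrix="blood", analyte=analyte, points=blood_points, loq=profile.loq
        ),
        "faeces": ConcentrationTimeSeries(
            matrix="faeces",
            analyte=analyte,
            points=faeces_points,
            loq=profile.loq,
            aliquots=raw,
        ),
    }
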