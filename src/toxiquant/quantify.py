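"""Peak tables to concentrations: response ratios, ion-ratio QC, censoring.

Censoring is explicit. A detected-but-below-LOQ signal ("trace amounts") is
a first-class state distinct from not-detected, and responses above the
calibrated range are flagged rather than extrapolated.
"""

from __future__ import annotations

import enum
import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, back_calculate
from .errors import (
    InternalStandardError,
    InvalidInputError,
    MalformedSampleError,
    OutOfRangeError,
)

__all__ = [
    "Censoring",
    "PeakRecord",
    "PeakTable",
    "SampleResult",
    "response_ratio",
    "ion_ratio_check",
    "quantify_sample",
    "aggregate_aliquots",
    "batch_expected_ion_ratio",
    "DEFAULT_ION_RATIO_TOLERANCE",
]

DEFAULT_ION_RATIO_TOLERANCE = 0.30


class Censoring(str, enum.Enum):
    """Quantification outcome, ordered by informativeness for aggregation."""

    QUANTIFIED = "quantified"
    ABOVE_RANGE = "above_range"
    BELOW_LOQ_DETECTED = "below_loq_detected"
    NOT_DETECTED = "not_detected"


# higher = more informative when all aliquots are censored
_CENSOR_RANK = {
    Censoring.NOT_DETECTED: 0,
    Censoring.BELOW_LOQ_DETECTED: 1,
    Censoring.ABOVE_RANGE: 2,
    Censoring.QUANTIFIED: 3,
}


@dataclass(frozen=True)
class PeakRecord:
    """One MRM measurement: a transition's peak height plus the IS height."""

    sample_id: str
    analyte: str
    transition_role: str  # quantifier | qualifier
    peak_height: float
    is_height: float
    matrix: str = "blood"  # blood | faeces
    role: str = "unknown"  # calibrator | qc | unknown | setA | setB | setC
    nominal_conc: float | None = None
    day: float | None = None
    aliquot_index: int | None = None

    def __post_init__(self) -> None:
        if self.peak_height < 0 or self.is_height < 0:
            raise InvalidInputError(
                f"peak heights must be >= 0 (sample {self.sample_id}, "
                f"analyte {self.analyte})"
            )
        if self.role in ("calibrator", "qc") and self.nominal_conc is None:
            raise InvalidInputError(
                f"{self.role} record for sample {self.sample_id} lacks nominal_conc"
            )


class PeakTable:
    """An ordered collection of :class:`PeakRecord` with frame conversion."""

    COLUMNS = [
        "sample_id",
        "analyte",
        "transition_role",
        "peak_height",
        "is_height",
        "matrix",
        "role",
        "nominal_conc",
        "day",
        "aliquot_index",
    ]

    def __init__(self, records: Iterable[PeakRecord] = ()):
        self.records: list[PeakRecord] = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def extend(self, records: Iterable[PeakRecord]) -> None:
        self.records.extend(records)

    def filter(self, **kwargs) -> "PeakTable":
        out = self.records
        for key, value in kwargs.items():
            out = [r for r in out if getattr(r, key) == value]
        return PeakTable(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{c: getattr(r, c) for c in self.COLUMNS} for r in self.records],
            columns=self.COLUMNS,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PeakTable":
        records = []
        for _, row in frame.iterrows():
            kwargs = {c: row[c] for c in cls.COLUMNS if c in frame.columns}
            for opt in ("nominal_conc", "day"):
                if opt in kwargs and pd.isna(kwargs[opt]):
                    kwargs[opt] = None
            if "aliquot_index" in kwargs:
                ai = kwargs["aliquot_index"]
                kwargs["aliquot_index"] = None if pd.isna(ai) else int(ai)
            records.append(PeakRecord(**kwargs))
        return cls(records)


@dataclass
class SampleResult:
    """Back-calculated concentration for one sample (or aggregated specimen)."""

    sample_id: str
    analyte: str
    concentration: float | None
    censoring: Censoring
    matrix: str = "blood"
    ion_ratio_ok: bool | None = None
    n_aliquots: int = 1
    aliquot_rsd: float | None = None
    n_censored_aliquots: int = 0
    day: float | None = None
    nominal_conc: float | None = None


def response_ratio(record: PeakRecord) -> float:
    """Analyte peak height over internal-standard peak height.

    A zero IS height means the injection or extraction failed; the sample is
    rejected loudly rather than producing a bogus ratio.
    """
    if record.is_height <= 0:
        raise InternalStandardError(
            f"internal standard height is {record.is_height} for sample "
            f"{record.sample_id} ({record.analyte}); sample rejected"
        )
    return record.peak_height / record.is_height


def ion_ratio_check(
    quant_height: float,
    qual_height: float,
    expected_ratio: float,
    tolerance: float = DEFAULT_ION_RATIO_TOLERANCE,
) -> bool:
    """Identity confirmation: qualifier/quantifier ratio within ±tolerance·expected."""
    if expected_ratio <= 0:
        raise InvalidInputError(f"expected ion ratio must be > 0, got {expected_ratio}")
    if quant_height <= 0:
        raise InvalidInputError("quantifier height must be > 0 for an ion-ratio check")
    observed = qual_height / quant_height
    return abs(observed - expected_ratio) <= tolerance * expected_ratio


def batch_expected_ion_ratio(records: Iterable[PeakRecord]) -> float:
    """Expected qualifier/quantifier ratio from a batch's calibrator records."""
    by_sample: dict[tuple, dict[str, float]] = {}
    for r in records:
        if r.role != "calibrator":
            continue
        key = (r.sample_id, r.analyte)
        by_sample.setdefault(key, {})[r.transition_role] = r.peak_height
    ratios = [
        d["qualifier"] / d["quantifier"]
        for d in by_sample.values()
        if d.get("quantifier", 0) > 0 and "qualifier" in d
    ]
    if not ratios:
        raise InvalidInputError("no calibrator quantifier/qualifier pairs in batch")
    return float(np.mean(ratios))


def quantify_sample(
    curve: CalibrationCurve,
    records: Sequence[PeakRecord],
    expected_ion_ratio: float | None = None,
    ion_ratio_tolerance: float = DEFAULT_ION_RATIO_TOLERANCE,
) -> SampleResult:
    """Quantify one sample from its quantifier (and optional qualifier) records.

    Censoring policy:

    * quantifier height 0 -> ``not_detected``
    * back-calculated concentration < LOQ -> ``below_loq_detected``
    * concentration above the top calibrator (or response above the
      quantifiable ceiling) -> ``above_range``
    * otherwise -> ``quantified``
    """
    quant = [r for r in records if r.transition_role == "quantifier"]
    if not quant:
        ids = sorted({r.sample_id for r in records}) or ["<empty>"]
        raise MalformedSampleError(f"no quantifier record for sample(s) {ids}")
    if len(quant) > 1:
        raise MalformedSampleError(
            f"multiple quantifier records for sample {quant[0].sample_id}"
        )
    rec = quant[0]
    quals = [r for r in records if r.transition_role == "qualifier"]

    ion_ok: bool | None = None
    if quals and expected_ion_ratio is not None and rec.peak_height > 0:
        ion_ok = ion_ratio_check(
            rec.peak_height, quals[0].peak_height, expected_ion_ratio, ion_ratio_tolerance
        )

    base = dict(
        sample_id=rec.sample_id,
        analyte=rec.analyte,
        matrix=rec.matrix,
        ion_ratio_ok=ion_ok,
        day=rec.day,
        nominal_conc=rec.nominal_conc,
    )

    if rec.peak_height == 0:
        return SampleResult(concentration=0.0, censoring=Censoring.NOT_DETECTED, **base)

    ratio = response_ratio(rec)
    try:
        conc = back_calculate(curve, ratio)
    except OutOfRangeError:
        if ratio > curve.predict(curve.high):
            return SampleResult(
                concentration=None, censoring=Censoring.ABOVE_RANGE, **base
            )
        raise

    loq = curve.loq if curve.loq is not None else curve.low
    if conc > curve.high:
        censoring = Censoring.ABOVE_RANGE
    elif conc >= loq:
        censoring = Censoring.QUANTIFIED
    else:
        censoring = Censoring.BELOW_LOQ_DETECTED
    return SampleResult(concentration=conc, censoring=censoring, **base)


def aggregate_aliquots(
    results: Sequence[SampleResult],
    substitute_half_loq: bool = False,
    loq: float | None = None,
) -> SampleResult:
    """Aggregate 2+ aliquot results for one specimen into a mean and RSD.

    Censored aliquots are counted and excluded from the mean (optionally
    substituted by LOQ/2 when ``substitute_half_loq``). When every aliquot is
    censored, the aggregate inherits the most informative censoring state.
    RSD is the sample (n-1) standard deviation over the mean, in percent.
    """
    if not results:
        raise InvalidInputError("no aliquot results to aggregate")
    keys = {(r.sample_id.rsplit("/", 1)[0], r.analyte, r.matrix) for r in results}
    if len({(a, m) for _, a, m in keys}) > 1:
        raise InvalidInputError(f"aliquots mix analytes/matrices: {sorted(keys)}")

    first = results[0]
    quantified = [r for r in results if r.censoring == Censoring.QUANTIFIED]
    values = [r.concentration for r in quantified]
    if substitute_half_loq:
        if loq is None:
            raise InvalidInputError("substitute_half_loq requires an explicit loq")
        values = values + [
            loq / 2.0 for r in results if r.censoring == Censoring.BELOW_LOQ_DETECTED
        ]
    n_censored = len(results) - len(quantified)

    base = dict(
        sample_id=first.sample_id.rsplit("/", 1)[0],
        analyte=first.analyte,
        matrix=first.matrix,
        n_aliquots=len(results),
        n_censored_aliquots=n_censored,
        day=first.day,
        nominal_conc=first.nominal_conc,
    )

    if not values:
        worst = max(results, key=lambda r: _CENSOR_RANK[r.censoring])
        return SampleResult(
            concentration=worst.concentration, censoring=worst.censoring, **base
        )

    mean = float(np.mean(values))
    rsd = None
    if len(values) >= 2 and mean != 0:
        rsd = 100.0 * statistics.stdev(values) / mean
    return SampleResult(
        concentration=mean,
        censoring=Censoring.QUANTIFIED,
        aliquot_rsd=rsd,
        **base,
    )
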