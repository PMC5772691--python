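"""Bioanalytical validation battery: precision, bias, matrix effect, recovery.

Matrix effect and extraction recovery follow the three-set post-extraction
spiking design: set A is neat standard, set B is blank extract spiked after
extraction, set C is matrix spiked before extraction. ME% = 100·mean(B)/mean(A)
(below 100 means ion suppression), RE% = 100·mean(C)/mean(B), and process
efficiency is their product over 100.

Between-day precision is reported as ANOVA intermediate precision from a
one-way variance decomposition; the naive RSD over all observations is kept
alongside for comparison because the simpler reading of "between-day (n=6)"
cannot be ruled out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "within_day_precision",
    "between_day_precision",
    "IntermediatePrecision",
    "bias",
    "matrix_effect",
    "extraction_recovery",
    "ValidationEntry",
    "validation_report",
    "DEFAULT_PRECISION_LIMIT",
    "DEFAULT_BIAS_LIMIT",
]

DEFAULT_PRECISION_LIMIT = 20.0
DEFAULT_BIAS_LIMIT = 20.0


def _as_array(values: Iterable[float], name: str, min_n: int = 1) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.size < min_n:
        raise InvalidInputError(f"{name}: need >= {min_n} values, got {arr.size}")
    return arr


def within_day_precision(replicates: Iterable[float]) -> float:
    """Within-day RSD%: 100 · sample SD / mean over same-day replicates."""
    arr = _as_array(replicates, "within_day_precision", min_n=2)
    mean = arr.mean()
    if mean == 0:
        raise InvalidInputError("RSD undefined: replicate mean is zero")
    return 100.0 * arr.std(ddof=1) / mean


@dataclass(frozen=True)
class IntermediatePrecision:
    """One-way ANOVA decomposition of a multi-day precision experiment."""

    rsd: float  # intermediate precision RSD%
    naive_rsd: float  # RSD% over all observations pooled
    within_sd: float
    between_sd: float
    grand_mean: float
    n_days: int
    n_total: int


def between_day_precision(day_groups: Sequence[Iterable[float]]) -> IntermediatePrecision:
    """Between-day (intermediate) precision from >= 2 days of replicates.

    Uses the one-way random-effects decomposition:
    s_total² = MS_within + max(0, (MS_between − MS_within)/n₀) with
    n₀ = (N − Σnᵢ²/N)/(k−1) for unbalanced designs. With one replicate per
    day MS_within is taken as 0 and the estimate reduces to the RSD of the
    day values.
    """
    groups = [_as_array(g, "between_day_precision day group", min_n=1) for g in day_groups]
    k = len(groups)
    if k < 2:
        raise InsufficientDataError(f"need >= 2 days, got {k}")
    ns = np.array([g.size for g in groups], dtype=float)
    all_values = np.concatenate(groups)
    n_total = int(ns.sum())
    grand = all_values.mean()
    if grand == 0:
        raise InvalidInputError("RSD undefined: grand mean is zero")

    means = np.array([g.mean() for g in groups])
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ms_between = ss_between / (k - 1)
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
    df_within = n_total - k
    ms_within = ss_within / df_within if df_within > 0 else 0.0

    n0 = (n_total - float(np.sum(ns**2)) / n_total) / (k - 1)
    s2_between = max(0.0, (ms_between - ms_within) / n0) if n0 > 0 else 0.0
    s2_total = ms_within + s2_between

    naive = (
        100.0 * all_values.std(ddof=1) / grand if n_total >= 2 else float("nan")
    )
    return IntermediatePrecision(
        rsd=100.0 * float(np.sqrt(s2_total)) / grand,
        naive_rsd=naive,
        within_sd=float(np.sqrt(ms_within)),
        between_sd=float(np.sqrt(s2_between)),
        grand_mean=float(grand),
        n_days=k,
        n_total=n_total,
    )


def bias(measured: Iterable[float], nominal: float) -> float:
    """Bias%: 100 · (mean(measured) − nominal) / nominal."""
    if nominal <= 0:
        raise InvalidInputError(f"nominal concentration must be > 0, got {nominal}")
    arr = _as_array(measured, "bias", min_n=1)
    return 100.0 * (arr.mean() - nominal) / nominal


def _set_ratio(numer: Iterable[float], denom: Iterable[float], what: str) -> float:
    num = _as_array(numer, what, min_n=2)
    den = _as_array(denom, what, min_n=2)
    if den.mean() == 0:
        raise InvalidInputError(f"{what}: reference set mean is zero")
    return 100.0 * num.mean() / den.mean()


def matrix_effect(set_a: Iterable[float], set_b: Iterable[float]) -> float:
    """ME% = 100 · mean(post-extraction spiked B) / mean(neat A), one level.

    Below 100 indicates ion suppression, above 100 enhancement.
    """
    return _set_ratio(set_b, set_a, "matrix_effect")


def extraction_recovery(set_b: Iterable[float], set_c: Iterable[float]) -> float:
    """RE% = 100 · mean(pre-extraction spiked C) / mean(post-spiked B), one level."""
    return _set_ratio(set_c, set_b, "extraction_recovery")


def matrix_effect_per_lot(
    set_a: Iterable[float], set_b: Iterable[float]
) -> float:
    """Mean of per-lot B/A ratios (alternative to the set-mean formulation)."""
    a = _as_array(set_a, "matrix_effect_per_lot", min_n=2)
    b = _as_array(set_b, "matrix_effect_per_lot", min_n=2)
    if a.size != b.size:
        raise InvalidInputError("per-lot ME needs paired sets of equal size")
    if np.any(a == 0):
        raise InvalidInputError("per-lot ME undefined: zero neat response")
    return 100.0 * float(np.mean(b / a))


@dataclass
class ValidationEntry:
    """Raw inputs for one analyte × level cell of the validation report."""

    analyte: str
    level: float  # nominal concentration
    matrix: str = "blood"
    within_day: Sequence[float] | None = None
    day_groups: Sequence[Sequence[float]] | None = None
    measured_for_bias: Sequence[float] | None = None
    set_a: Sequence[float] | None = None
    set_b: Sequence[float] | None = None
    set_c: Sequence[float] | None = None


def validation_report(
    entries: Iterable[ValidationEntry],
    precision_limit: float = DEFAULT_PRECISION_LIMIT,
    bias_limit: float = DEFAULT_BIAS_LIMIT,
) -> pd.DataFrame:
    """Assemble the per-analyte/per-level validation table.

    Missing inputs yield NaN metric cells (explicit missing-metric markers).
    ``accepted`` is True only when within-day RSD, between-day RSD and |bias|
    are all present and within their limits; it is False when any of the
    three is missing.
    """
    if precision_limit <= 0 or bias_limit <= 0:
        raise InvalidInputError("acceptance limits must be > 0")
    rows = []
    for e in entries:
        row: dict = {
            "analyte": e.analyte,
            "matrix": e.matrix,
            "level": e.level,
            "within_day_rsd": np.nan,
            "between_day_rsd": np.nan,
            "between_day_rsd_naive": np.nan,
            "bias": np.nan,
            "me_percent": np.nan,
            "re_percent": np.nan,
            "process_efficiency": np.nan,
            "n_within": 0,
            "n_days": 0,
        }
        if e.within_day is not None:
            row["within_day_rsd"] = within_day_precision(e.within_day)
            row["n_within"] = len(e.within_day)
        if e.day_groups is not None:
            ip = between_day_precision(e.day_groups)
            row["between_day_rsd"] = ip.rsd
            row["between_day_rsd_naive"] = ip.naive_rsd
            row["n_days"] = ip.n_days
        measured = e.measured_for_bias
        if measured is None and e.within_day is not None:
            measured = e.within_day
        if measured is not None:
            row["bias"] = bias(measured, e.level)
        if e.set_a is not None and e.set_b is not None:
            row["me_percent"] = matrix_effect(e.set_a, e.set_b)
        if e.set_b is not None and e.set_c is not None:
            row["re_percent"] = extraction_recovery(e.set_b, e.set_c)
        if e.set_a is not None and e.set_b is not None and e.set_c is not None:
            row["process_efficiency"] = row["me_percent"] * row["re_percent"] / 100.0
        core = (row["within_day_rsd"], row["between_day_rsd"], row["bias"])
        row["accepted"] = bool(
            not any(np.isnan(v) for v in core)
            and row["within_day_rsd"] <= precision_limit
            and row["between_day_rsd"] <= precision_limit
            and abs(row["bias"]) <= bias_limit
        )
        rows.append(row)
    return pd.DataFrame(rows)
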