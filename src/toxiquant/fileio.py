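"""CSV/JSON/YAML interfaces and the end-to-end pipeline orchestration.

Everything on disk is plain text: peak tables and concentration series as
CSV with fixed documented headers, calibration curves as JSON, validation
and calibration reports as CSV, and the PK report as JSON. Scenario and run
configuration are YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import calibration as cal
from . import kinetics as kin
from . import synthgen as gen
from . import validate as val
from .errors import ParseError, ToxiquantError
from .panel import AnalytePanel, default_panel, load_panel
from .quantify import (
    Censoring,
    PeakRecord,
    PeakTable,
    SampleResult,
    batch_expected_ion_ratio,
    quantify_sample,
)

__all__ = [
    "read_peak_table",
    "write_peak_table",
    "read_series",
    "write_series",
    "write_curves",
    "read_curves",
    "RunConfig",
    "run_pipeline",
]

SCHEMA_VERSION = "1"

PEAK_TABLE_REQUIRED = ["sample_id", "analyte", "transition_role", "peak_height", "is_height"]

SERIES_COLUMNS = [
    "matrix",
    "analyte",
    "day",
    "concentration",
    "unit",
    "censoring",
    "n_aliquots",
    "aliquot_rsd",
    "loq",
]


def read_peak_table(path: str | Path, panel: AnalytePanel | None = None) -> PeakTable:
    """Read and validate a peak-table CSV.

    Required columns: sample_id, analyte, transition_role, peak_height,
    is_height; optional: matrix, role, nominal_conc, day, aliquot_index.
    Errors carry the 1-based data row number; when a panel is given, analyte
    names are checked against it.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in PEAK_TABLE_REQUIRED if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    valid_names = set(panel.analyte_names) if panel is not None else None
    records = []
    for i, row in frame.iterrows():
        rowno = int(i) + 1
        try:
            if valid_names is not None and row["analyte"] not in valid_names:
                raise ParseError(
                    f"unknown analyte {row['analyte']!r}; panel defines "
                    f"{sorted(valid_names)}"
                )
            kwargs: dict[str, Any] = {
                "sample_id": str(row["sample_id"]),
                "analyte": str(row["analyte"]),
                "transition_role": str(row["transition_role"]),
                "peak_height": float(row["peak_height"]),
                "is_height": float(row["is_height"]),
            }
            for opt, conv in (
                ("matrix", str),
                ("role", str),
                ("nominal_conc", float),
                ("day", float),
                ("aliquot_index", int),
            ):
                if opt in frame.columns and not pd.isna(row[opt]):
                    kwargs[opt] = conv(row[opt])
            records.append(PeakRecord(**kwargs))
        except (ToxiquantError, ValueError) as exc:
            raise ParseError(f"{path}, data row {rowno}: {exc}") from exc
    return PeakTable(records)


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def write_series(series: kin.ConcentrationTimeSeries, path: str | Path, unit: str | None = None) -> None:
    if unit is None:
        unit = "ng/mL" if series.matrix == "blood" else "ng/g"
    rows = [
        {
            "matrix": series.matrix,
            "analyte": series.analyte,
            "day": p.day,
            "concentration": p.concentration,
            "unit": unit,
            "censoring": p.censoring.value,
            "n_aliquots": p.n_aliquots,
            "aliquot_rsd": p.aliquot_rsd,
            "loq": series.loq,
        }
        for p in series.points
    ]
    pd.DataFrame(rows, columns=SERIES_COLUMNS).to_csv(path, index=False)


def read_series(path: str | Path) -> list[kin.ConcentrationTimeSeries]:
    """Read a series CSV; returns one series per (matrix, analyte) group."""
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in SERIES_COLUMNS if c not in frame.columns and c != "aliquot_rsd"]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    out = []
    for (matrix, analyte), grp in frame.groupby(["matrix", "analyte"], sort=False):
        grp = grp.sort_values("day")
        points = [
            kin.TimePoint(
                day=float(r["day"]),
                concentration=float(r["concentration"]),
                censoring=Censoring(r["censoring"]),
                n_aliquots=int(r["n_aliquots"]),
                aliquot_rsd=None if pd.isna(r.get("aliquot_rsd")) else float(r["aliquot_rsd"]),
            )
            for _, r in grp.iterrows()
        ]
        try:
            out.append(
                kin.ConcentrationTimeSeries(
                    matrix=str(matrix),
                    analyte=str(analyte),
                    points=points,
                    loq=float(grp["loq"].iloc[0]),
                )
            )
        except ToxiquantError as exc:
            raise ParseError(f"{path}: series ({matrix}, {analyte}): {exc}") from exc
    return out


def write_curves(curves: Sequence[cal.CalibrationCurve], path: str | Path) -> None:
    payload = {"schema_version": SCHEMA_VERSION, "curves": [c.to_dict() for c in curves]}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_curves(path: str | Path) -> list[cal.CalibrationCurve]:
    payload = json.loads(Path(path).read_text())
    return [cal.CalibrationCurve.from_dict(d) for d in payload["curves"]]


def calibration_report_frame(curves: Sequence[cal.CalibrationCurve]) -> pd.DataFrame:
    return pd.DataFrame([c.to_dict() for c in curves])


class RunConfig(BaseModel):
    """Configuration of a full synthetic-demo pipeline run."""

    seed: int = 1
    panel_path: str | None = None
    out_dir: str = "toxiquant-out"
    weighting: str = "1/x"
    ion_ratio_tolerance: float = Field(default=0.30, gt=0)
    precision_limit: float = Field(default=20.0, gt=0)
    bias_limit: float = Field(default=20.0, gt=0)
    noise_cv: float = Field(default=0.03, ge=0)
    matrix_effect: float = Field(default=0.90, gt=0)
    recovery: float = Field(default=0.70, gt=0)
    lot_cv: float = Field(default=0.05, ge=0)
    between_day_cv: float = Field(default=0.05, ge=0)
    n_levels: int = Field(default=7, ge=3)
    qc_replicates: int = Field(default=6, ge=2)
    qc_days: int = Field(default=6, ge=2)
    n_lots: int = Field(default=5, ge=2)
    aliquot_rsd: float = Field(default=0.25, ge=0)
    n_aliquots: int = Field(default=6, ge=1)
    windows: list[tuple[float, float]] = Field(default=[(6.0, 11.0), (64.0, 422.0)])
    profile: dict[str, Any] | None = None

    @field_validator("windows")
    @classmethod
    def _check_windows(cls, windows):
        for lo, hi in windows:
            if hi <= lo:
                raise ValueError(f"window {lo}:{hi} must have start < end")
        return windows

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)


# Case-like profile anchored so blood decays 9.8 -> 1.5 ng/mL between days
# 6 and 11 with half-lives 1.8/81 d; the faecal scale keeps the terminal
# window quantifiable and is otherwise arbitrary.
DEFAULT_PROFILE_KWARGS = dict(
    a_alpha=97.8968,
    a_beta=0.0921,
    t_half_alpha=1.8,
    t_half_beta=81.0,
    faeces_scale=1300.0,
    bump=(32.0, 5.0, 1.5),
    aliquot_rsd=0.25,
    loq=1.5,
)


def default_profile(**overrides) -> gen.PkProfile:
    return gen.PkProfile(**{**DEFAULT_PROFILE_KWARGS, **overrides})


def _fit_curves(
    panel: AnalytePanel, cal_table: PeakTable, weighting: str
) -> dict[str, cal.CalibrationCurve]:
    curves = {}
    for analyte in panel.analytes:
        recs = cal_table.filter(analyte=analyte.name, transition_role="quantifier")
        points = [
            cal.CalibrationPoint(r.nominal_conc, r.peak_height / r.is_height)
            for r in recs
        ]
        curves[analyte.name] = cal.fit_calibration(
            points, weighting=weighting, loq=analyte.loq, analyte=analyte.name
        )
    return curves


def _quantified_concs(
    table: PeakTable,
    curves: dict[str, cal.CalibrationCurve],
    analyte: str,
    level: float | None = None,
    day: float | None = None,
    ion_ratio: float | None = None,
    tolerance: float = 0.30,
) -> list[SampleResult]:
    recs = table.filter(analyte=analyte)
    if level is not None:
        recs = PeakTable([r for r in recs if r.nominal_conc == level])
    if day is not None:
        recs = recs.filter(day=day)
    by_sample: dict[str, list[PeakRecord]] = {}
    for r in recs:
        by_sample.setdefault(r.sample_id, []).append(r)
    return [
        quantify_sample(curves[analyte], sample_recs, ion_ratio, tolerance)
        for _, sample_recs in sorted(by_sample.items())
    ]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Simulate, calibrate, quantify, validate and fit kinetics end to end.

    All artifacts are computed in memory first and written only on success,
    so a failing run leaves no partial results directory. Returns the paths
    of the four reports keyed by artifact name.
    """
    rng = np.random.default_rng(config.seed)
    panel = load_panel(config.panel_path) if config.panel_path else default_panel()
    models = gen.default_models(
        panel,
        noise_cv=config.noise_cv,
        matrix_effect=config.matrix_effect,
        recovery=config.recovery,
    )

    # calibrators are matrix-matched (pre-extraction spiked), like the samples
    cal_table = gen.generate_calibration_set(
        panel, models, n_levels=config.n_levels, rng=rng, set_kind="routine"
    )
    curves = _fit_curves(panel, cal_table, config.weighting)

    within_table = gen.generate_qc_set(
        panel, models, n_replicates=config.qc_replicates, n_days=1, rng=rng
    )
    between_table = gen.generate_qc_set(
        panel,
        models,
        n_replicates=config.qc_replicates,
        n_days=config.qc_days,
        between_day_cv=config.between_day_cv,
        rng=rng,
    )
    matrix_sets = gen.generate_matrix_experiment(
        panel, models, n_lots=config.n_lots, lot_cv=config.lot_cv, rng=rng
    )

    entries = []
    for analyte in panel.analytes:
        low, high = analyte.calibration_range_ng
        qc_levels = (3 * low, float(np.sqrt(low * high)), 0.8 * high)
        me_levels = (3 * low, 0.5 * high)
        ion_ratio = batch_expected_ion_ratio(cal_table.filter(analyte=analyte.name))
        for level in qc_levels:
            within = [
                r.concentration
                for r in _quantified_concs(
                    within_table, curves, analyte.name, level, ion_ratio=ion_ratio,
                    tolerance=config.ion_ratio_tolerance,
                )
                if r.censoring == Censoring.QUANTIFIED
            ]
            day_groups = []
            for day in range(1, config.qc_days + 1):
                grp = [
                    r.concentration
                    for r in _quantified_concs(
                        between_table, curves, analyte.name, level, day=float(day)
                    )
                    if r.censoring == Censoring.QUANTIFIED
                ]
                if grp:
                    day_groups.append(grp)
            sets = {}
            if level in me_levels:
                for key in ("neat", "post_spike", "pre_spike"):
                    recs = matrix_sets[key].filter(
                        analyte=analyte.name, transition_role="quantifier"
                    )
                    sets[key] = [
                        r.peak_height / r.is_height
                        for r in recs
                        if r.nominal_conc == level
                    ]
            entries.append(
                val.ValidationEntry(
                    analyte=analyte.name,
                    level=level,
                    within_day=within or None,
                    day_groups=day_groups if len(day_groups) >= 2 else None,
                    set_a=sets.get("neat") or None,
                    set_b=sets.get("post_spike") or None,
                    set_c=sets.get("pre_spike") or None,
                )
            )
        # ME/RE-only rows for the low matrix-experiment level not among QCs
        # are covered above because 3*low is shared between designs.
    report = val.validation_report(
        entries, precision_limit=config.precision_limit, bias_limit=config.bias_limit
    )

    profile = default_profile(**(config.profile or {}))
    case = gen.generate_case_profile(
        profile, n_aliquots=config.n_aliquots, rng=rng
    )
    pk: dict[str, Any] = {}
    for matrix, series in case.items():
        summaries = []
        for window in config.windows:
            try:
                summaries.append(kin.fit_phase(series, window).to_dict())
            except ToxiquantError as exc:
                summaries.append({"window": list(window), "error": str(exc)})
        pk[matrix] = {
            "phases": summaries,
            "last_quantified_day": series.last_quantified_day(),
            "last_detected_day": series.last_detected_day(),
            "loq": series.loq,
        }

    results_rows = []
    for matrix, series in case.items():
        unit = "ng/mL" if matrix == "blood" else "ng/g"
        for p in series.points:
            results_rows.append(
                {
                    "matrix": matrix,
                    "analyte": series.analyte,
                    "day": p.day,
                    "concentration": p.concentration,
                    "unit": unit,
                    "censoring": p.censoring.value,
                    "n_aliquots": p.n_aliquots,
                    "aliquot_rsd": p.aliquot_rsd,
                    "loq": series.loq,
                }
            )
    results_frame = pd.DataFrame(results_rows, columns=SERIES_COLUMNS)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "calibration_report": out_dir / "calibration_report.csv",
        "results": out_dir / "results.csv",
        "validation_report": out_dir / "validation_report.csv",
        "pk_report": out_dir / "pk_report.json",
    }
    calibration_report_frame(list(curves.values())).to_csv(
        paths["calibration_report"], index=False
    )
    results_frame.to_csv(paths["results"], index=False)
    report.to_csv(paths["validation_report"], index=False)
    pk_payload = {
        "schema_version": SCHEMA_VERSION,
        "config": config.model_dump(),
        "kinetics": pk,
    }
    paths["pk_report"].write_text(json.dumps(pk_payload, indent=2) + "\n")
    return paths
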