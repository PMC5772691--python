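# toxiquant

Targeted UHPLC–MS/MS quantification of six anticoagulant rodenticides
(coumatetralyl, bromadiolone, difenacoum, flocoumafen, brodifacoum,
difethialone) in blood and faeces, as a tested, reusable pipeline:

- **panel** — analyte panel domain model (MRM transitions, molar masses,
  dual ng/µM calibration ranges), config loading, unit conversion.
- **synthgen** — seeded synthetic data replacing the instrument and the
  subject: calibration/QC peak tables, Matuszewski-style three-set matrix
  experiments, biphasic case-like concentration–time profiles with faecal
  aliquot scatter.
- **calibration** — weighted quadratic calibration (`y = a·x² + b·x + c`,
  1/x weights, origin excluded), weighted/unweighted R², monotonicity
  checks, back-calculation with explicit root-selection policy, LOQ
  (lowest calibrator, S/N ≥ 10).
- **quantify** — response ratios against the internal standard, ion-ratio
  identity QC, explicit censoring states (`quantified`,
  `below_loq_detected`, `not_detected`, `above_range`), faecal
  multi-aliquot aggregation (mean, RSD).
- **validate** — within-/between-day precision (ANOVA intermediate
  precision), bias, matrix effect (ME% = 100·B̄/Ā), extraction recovery
  (RE% = 100·C̄/B̄), process efficiency, ±20% acceptance flags.
- **kinetics** — multiphasic elimination: two-point half-life, windowed
  log-linear phase fits with censoring awareness and a lower-bound
  ("at least") flag, biphasic summaries with last-detectable-day reporting.
- **fileio / cli** — plain-text CSV/JSON/YAML formats and the `toxiquant`
  command-line interface.

## CLI

```sh
toxiquant simulate --seed 1 --out scratch/inputs      # synthetic peak tables + series
toxiquant calibrate scratch/inputs/calibrators.csv --out scratch/curves.json
toxiquant quantify scratch/inputs/qc.csv --curves scratch/curves.json --out scratch/qc_results.csv
toxiquant kinetics scratch/inputs/series_faeces.csv --window 6:11 --window 64:422 --out scratch/pk.json
toxiquant run --seed 1 --out scratch/demo             # full end-to-end demo
```

`toxiquant run` writes four artifacts: `calibration_report.csv`,
`results.csv`, `validation_report.csv` and `pk_report.json`. Runs are
deterministic given the seed. A scenario YAML (see
`src/toxiquant/scenarios/demo.yaml` for every key) can be passed via
`--config`.

## Panel configuration

The bundled panel lives at `src/toxiquant/panels/rodenticides6.yaml`.
Schema (YAML or JSON):

```yaml
name: <panel name>
internal_standard:
  name: <str>
  working_concentration_mg_per_l: <float>
  retention_time_min: <float>
  transitions: [{precursor_mz, product_mz, role, cone_voltage, collision_energy}, ...]
analytes:
  - name: <str>
    molecular_formula: <str>
    molar_mass: <g/mol>
    retention_time_min: <float>
    calibration_range_ng: [low, high]    # ng/mL blood = ng/g dry faeces
    calibration_range_um: [low, high]    # must agree via molar_mass (±1 %)
    transitions: [...]                   # exactly one role: quantifier
```

ng/mL (blood) and ng/g (lyophilized faeces) share one numeric scale; no
density correction is applied. µM↔mass conversion is
`ng = µM × molar_mass`.

## Peak table CSV

One row per (sample, analyte, transition). Required columns:
`sample_id, analyte, transition_role, peak_height, is_height`; optional:
`matrix, role, nominal_conc, day, aliquot_index`. Concentration series CSVs
carry `matrix, analyte, day, concentration, unit, censoring, n_aliquots,
aliquot_rsd, loq`.

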