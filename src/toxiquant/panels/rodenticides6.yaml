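# Six-compound anticoagulant rodenticide panel.
#
# Molar masses are average molecular weights computed from the molecular
# formula with standard atomic weights (C 12.011, H 1.008, O 15.999,
# Br 79.904, F 18.998, S 32.06). Calibration ranges are given dually:
# mass concentration (ng/mL blood or ng/g dry faeces — same numeric scale)
# and µM; the pair must agree through the molar mass after endpoint rounding.
# The first transition of each analyte is the quantifier, the second the
# qualifier used for ion-ratio confirmation.
name: rodenticides6
internal_standard:
  name: warfarin-d5
  working_concentration_mg_per_l: 0.078
  retention_time_min: 1.62
  transitions:
    - {precursor_mz: 314.2, product_mz: 163.1, role: quantifier, cone_voltage: 24, collision_energy: 14}
    - {precursor_mz: 314.2, product_mz: 256.0, role: qualifier, cone_voltage: 24, collision_energy: 22}
analytes:
  - name: coumatetralyl
    molecular_formula: C19H16O3
    molar_mass: 292.33
    retention_time_min: 1.86
    calibration_range_ng: [1.5, 731]
    calibration_range_um: [0.0050, 2.5]
    transitions:
      - {precursor_mz: 239.1, product_mz: 107.1, role: quantifier, cone_voltage: 40, collision_energy: 32}
      - {precursor_mz: 239.1, product_mz: 91.0, role: qualifier, cone_voltage: 30, collision_energy: 28}
  - name: bromadiolone
    molecular_formula: C30H23BrO4
    molar_mass: 527.41
    retention_time_min: 2.73
    calibration_range_ng: [2.6, 1319]
    calibration_range_um: [0.0050, 2.5]
    transitions:
      - {precursor_mz: 511.1, product_mz: 251.2, role: quantifier, cone_voltage: 26, collision_energy: 24}
      - {precursor_mz: 511.1, product_mz: 173.0, role: qualifier, cone_voltage: 26, collision_energy: 42}
  - name: difenacoum
    molecular_formula: C31H24O3
    molar_mass: 444.53
    retention_time_min: 2.83
    calibration_range_ng: [2.2, 1111]
    calibration_range_um: [0.0050, 2.5]
    transitions:
      - {precursor_mz: 445.3, product_mz: 179.1, role: quantifier, cone_voltage: 30, collision_energy: 32}
      - {precursor_mz: 445.3, product_mz: 257.2, role: qualifier, cone_voltage: 30, collision_energy: 22}
  - name: flocoumafen
    molecular_formula: C33H25F3O4
    molar_mass: 542.55
    retention_time_min: 3.17
    calibration_range_ng: [2.7, 1356]
    calibration_range_um: [0.0050, 2.5]
    transitions:
      - {precursor_mz: 543.2, product_mz: 159.1, role: quantifier, cone_voltage: 28, collision_energy: 42}
      - {precursor_mz: 543.2, product_mz: 335.2, role: qualifier, cone_voltage: 28, collision_energy: 24}
  - name: brodifacoum
    molecular_formula: C31H23BrO3
    molar_mass: 523.43
    retention_time_min: 3.27
    calibration_range_ng: [2.6, 1309]
    calibration_range_um: [0.0050, 2.5]
    transitions:
      - {precursor_mz: 525.2, product_mz: 337.1, role: quantifier, cone_voltage: 34, collision_energy: 34}
      - {precursor_mz: 525.2, product_mz: 178.2, role: qualifier, cone_voltage: 55, collision_energy: 55}
  - name: difethialone
    molecular_formula: C31H23BrO2S
    molar_mass: 539.49
    retention_time_min: 3.33
    calibration_range_ng: [2.7, 1349]
    calibration_range_um: [0.0050, 2.5]
    transitions:
      - {precursor_mz: 539.1, product_mz: 178.1, role: quantifier, cone_voltage: 36, collision_energy: 32}
      - {precursor_mz: 539.1, product_mz: 335.1, role: qualifier, cone_voltage: 36, collision_energy: 22}
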