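{
  "_comment": "31P chemical shifts (ppm relative to PC = 0) and assignment tolerances for phospholipid classes in the CUBO solvent system. SYNTHETIC, user-editable placeholder values: the packaged numbers are plausible relative positions used by the synthetic-data generator and tests; replace them with measured shifts for real samples.",
  "PC": [0.0, 0.12],
  "SM": [-0.40, 0.12],
  "LPC": [0.50, 0.12],
  "PE": [0.85, 0.12],
  "PI": [-0.95, 0.12],
  "PS": [1.50, 0.12],
  "PG": [1.20, 0.12]
}
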