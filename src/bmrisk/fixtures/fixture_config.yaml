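# Synthetic survey-emulation fixture: generated data, not study records.
analytes:
  CYA:
    tdi_ng_per_kg_day: 2500.0
    lod_ng_per_ml: 100.0
    loq_ng_per_ml: 310.0
  MEL:
    tdi_ng_per_kg_day: 3150.0
    lod_ng_per_ml: 90.0
    loq_ng_per_ml: 270.0
censoring_rule: exclude
generator:
  seed: 20250825
  n_samples: 100
  group_sizes: [20, 15, 15]
  calibrated_concentration_location:
    CYA: 137.7704893621409
    MEL: 109.20913954844944
  sd_param:
    CYA: 38.0
    MEL: 26.0
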