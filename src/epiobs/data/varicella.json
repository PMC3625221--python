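{
  "name": "varicella",
  "observable": {"R1": 3.24, "R2": 3.24, "alpha": 1.0},
  "R_a": 6.47,
  "g": 1.0,
  "theta": 0.5,
  "R0_printed": 6.47,
  "m_assumed": 0.7,
  "vaccine": {"VE_S": 0.5, "VE_I": 0.8, "VE_P": 0.5},
  "provenance": {
    "source": "published parameter table for four directly transmitted viral diseases",
    "ve_p_assumed": true,
    "notes": "Recomposed R0 = R1 + alpha*R2 = 6.48 vs printed 6.47 (2-dp rounding); derived quantities use the recomposed value. The slope of R0 in the pre-symptomatic share is a rounding artifact here (R_pre + R2 vs R_a differ only in the last printed digit)."
  }
}
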