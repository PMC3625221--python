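{
  "name": "hiv",
  "observable": {"R1": 3.67, "R2": 0.0, "alpha": 0.8},
  "R_a": 6.12,
  "g": 0.6666666666666666,
  "theta": 1.0,
  "R0_printed": 3.67,
  "m_assumed": 0.5,
  "vaccine": {"VE_S": 0.4, "VE_I": 0.6, "VE_P": 0.6},
  "provenance": {
    "source": "published parameter table for four directly transmitted viral diseases",
    "g_printed": 0.67,
    "vaccine_hypothetical": true,
    "notes": "All secondary transmission occurs before the onset of AIDS (R2 = 0, theta = 1). g is stored as the exact fraction 2/3; the printed 0.67 is its 2-dp rounding. No licensed HIV vaccine exists; the vaccine effect parameters are hypothetical."
  }
}
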