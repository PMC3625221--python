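{
  "name": "smallpox",
  "observable": {"R1": 0.69, "R2": 6.18, "alpha": 1.0},
  "R_a": 1.37,
  "g": 1.0,
  "theta": 0.1,
  "R0_printed": 6.87,
  "m_assumed": 0.5,
  "vaccine": {"VE_S": 0.95, "VE_I": 0.8, "VE_P": 0.87},
  "provenance": {
    "source": "published parameter table for four directly transmitted viral diseases",
    "notes": "Very few asymptomatic transmissions (theta = 0.10); alpha = 1 so the fully asymptomatic reproduction number R_a carries no weight in the baseline R0 and is exercised only by the pre-symptomatic-share sweep."
  }
}
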