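{
  "name": "influenza",
  "observable": {"R1": 0.6, "R2": 1.2, "alpha": 0.75},
  "R_a": 0.96,
  "g": 0.6,
  "theta": 0.4,
  "R0_printed": 1.5,
  "m_assumed": 0.5,
  "vaccine": {"VE_S": 0.41, "VE_I": 0.15, "VE_P": 0.67},
  "provenance": {
    "source": "published parameter table for four directly transmitted viral diseases",
    "notes": "Vaccine efficacies quantified from challenge and community-based influenza studies; the intermediate case between smallpox and HIV for the asymptomatic transmission share."
  }
}
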