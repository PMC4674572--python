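{
  "Cm": 1.0,
  "area": 1.2e-05,
  "ENa": 50.0,
  "EK": -94.0,
  "EL": -77.0,
  "gNa": 91.66,
  "gKdr": 20.83,
  "gKlt": 0.0,
  "gKht": 0.0,
  "gKa": 0.0,
  "gL": 0.6167,
  "V_half": 8.4,
  "slope_k": 18.5,
  "tau_a": 3.2,
  "na_kinetics": "rm2003",
  "kinetics": {
    "phi": 0.85,
    "zeta": 0.5
  }
}
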