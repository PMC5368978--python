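{
  "P-GSH": {
    "tau_unreacted": 6.0,
    "tau_reacted": 225.0,
    "linear_limit": 10.0,
    "saturation_conc": 20.0,
    "analyte": "GSH"
  },
  "P-HP": {
    "tau_unreacted": 5.5,
    "tau_reacted": 146.0,
    "linear_limit": 50.0,
    "saturation_conc": 100.0,
    "analyte": "H2O2"
  },
  "P-HA": {
    "tau_unreacted": 4.3,
    "tau_reacted": 90.5,
    "linear_limit": 40.0,
    "saturation_conc": 80.0,
    "analyte": "HOCl"
  }
}
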