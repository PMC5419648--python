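{
  "name": "standard",
  "parameters": {
    "clm": {"mean": 0.225, "sd": 0.113, "setting": "Bayesian"},
    "fr": {"mean": 0.727, "sd": 0.471, "setting": "Bayesian"},
    "vd": {"mean": 0.273, "sd": 0.082, "setting": "Bayesian"}
  },
  "assay_error_coeffs": [0.0766, 0.0006, 0.0064]
}
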