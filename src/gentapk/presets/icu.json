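{
  "name": "icu",
  "parameters": {
    "clm": {"mean": 0.277, "sd": 0.138, "setting": "Bayesian"},
    "fr": {"mean": 0.899, "sd": 0.417, "setting": "Bayesian"},
    "vd": {"mean": 0.335, "sd": 0.104, "setting": "Bayesian"}
  },
  "assay_error_coeffs": [0.0766, 0.0006, 0.0064]
}
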