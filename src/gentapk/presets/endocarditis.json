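{
  "name": "endocarditis",
  "parameters": {
    "clm": {"mean": 0.277, "sd": 0.0, "setting": "Fixed"},
    "fr": {"mean": 0.698, "sd": 0.358, "setting": "Bayesian"},
    "vd": {"mean": 0.312, "sd": 0.076, "setting": "Bayesian"}
  },
  "assay_error_coeffs": [0.0766, 0.0006, 0.0064]
}
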