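{
  "usyk": {
    "law": "fung_usyk",
    "species": "canine",
    "coefficients": {
      "C": 0.88,
      "b_ff": 8.0,
      "b_ss": 6.0,
      "b_nn": 3.0,
      "b_fs": 12.0,
      "b_fn": 3.0,
      "b_ns": 3.0
    }
  },
  "whow": {
    "law": "holzapfel_ogden",
    "species": "swine",
    "coefficients": {
      "a": 0.24,
      "b": 10.81,
      "a_ff": 20.04,
      "b_ff": 14.2,
      "a_ss": 3.72,
      "b_ss": 5.16,
      "a_fs": 0.41,
      "b_fs": 11.3
    }
  },
  "whog": {
    "law": "holzapfel_ogden",
    "species": "human",
    "coefficients": {
      "a": 0.4,
      "b": 6.55,
      "a_ff": 3.05,
      "b_ff": 29.05,
      "a_ss": 1.25,
      "b_ss": 36.65,
      "a_fs": 0.15,
      "b_fs": 6.28
    }
  }
}
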