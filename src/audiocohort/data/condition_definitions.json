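{
  "parkinsons": {"prefixes": ["332.0", "332.1"]},
  "diabetes": {"prefixes": ["250"]},
  "arthritis": {"ranges": [[360, 379]]},
  "vision_impairment": {"ranges": [[710, 739]]}
}
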