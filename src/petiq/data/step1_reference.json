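{
  "description": "SYNTHETIC reference value for the step-1 SUVmax tie-break: mean lesion SUVmax of the PET/CT comparison reconstruction.",
  "petct_suvmax_mean": 20.0
}
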