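{
  "chlamy1": ["R_GPI", "R_IDHP", "R_NIR", "R_PYK", "R_PDH", "R_ASL"],
  "asl_nir_only": ["R_ASL", "R_NIR"]
}
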