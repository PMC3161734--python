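# Model configuration of the packaged core network.
# Buffered (external) species: the two night-time carbon sources, the three
# nitrogen sources, CO2, and the five target amino acids.
external:
  - G6P
  - Ac
  - NO3e
  - NO2e
  - NH4
  - CO2
  - Gly
  - Ala
  - Asn
  - Lys
  - Arg
carbon_sources:
  - G6P
  - Ac
targets:
  - Gly
  - Ala
  - Asn
  - Lys
  - Arg
# Reactions whose enzymes are entirely encoded by (UG)7-bearing mRNAs and
# hence under circadian translational control of CHLAMY1 (six enzymes).
regulated_reactions:
  - R_GPI
  - R_IDHP
  - R_NIR
  - R_PYK
  - R_PDH
  - R_ASL
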