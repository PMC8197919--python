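# Candidate-gene panel derived from the genes with retained variants in the
# two study cohorts, keyed by functional category. The full literature-curated
# panel used for discovery is study-specific; any panel document with the same
# structure (category -> gene list) can be supplied in its place.
super_enhancer_essential: [TBXT, ATP6V1B2]
notochord: [GDF3, COL2A1]
mesoderm_commitment:
  [ATP8B2, TCF7L1, EPB41L5, NFE2L2, BMPR2, RARB, SRF, EXT1, JAK2, PAX6,
   EXT2, SOX21, WDHD1, ACACA, PRKACA, FOXA2]
swi_snf: [SMARCA2, SMARCB1]
pi3k_akt_mtor: [PDK1, DEPTOR, AKT1, TSC2]
sonic_hedgehog: [LRP2, HHIP, PTCH1, SUFU]
driver: [LYST]
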