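# Guide presets: TCR-targeting spacers used with the packaged amplicons.
# Each entry names its nuclease profile preset; the DN and TRAC guides do
# not occur in the packaged amplicon sequences (locate_target returns no
# site for them there) and are provided for completeness.
CRAFT_crRNA:
  spacer: GCCCTATCCTGGGTCCACTCG
  profile: AsCas12a
TRBC_sgRNA:
  spacer: GGAGAATGACGAGTGGACCC
  profile: SpCas9
DN_TRBC_crRNA:
  spacer: GGTGTGGGAGATCTCTGCTTC
  profile: AsCas12a
TRAC_crRNA:
  spacer: CACATGCAAAGTCAGATTTGT
  profile: AsCas12a
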