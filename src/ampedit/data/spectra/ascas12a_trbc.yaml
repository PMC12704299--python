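# Editing-outcome spectrum of the AsCas12a / CRAFT-crRNA arm at the TRBC
# consensus amplicon. Category values are fractions of all reads; mmej is
# the MMEJ-repaired subset of deletion_on_position. The four categories sum
# to 0.999 as printed (rounding residue); the loader renormalizes.
name: ascas12a_trbc
categories:
  wt: 0.046
  insertion: 0.001
  deletion_on_position: 0.906
  deletion_off_position: 0.046
mmej: 0.110
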