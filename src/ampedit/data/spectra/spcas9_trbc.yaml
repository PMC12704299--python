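# Editing-outcome spectrum of the SpCas9 / TRBC-sgRNA arm at the TRBC
# consensus amplicon. MMEJ repair is absent from this arm.
name: spcas9_trbc
categories:
  wt: 0.354
  insertion: 0.040
  deletion_on_position: 0.447
  deletion_off_position: 0.159
mmej: 0.0
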