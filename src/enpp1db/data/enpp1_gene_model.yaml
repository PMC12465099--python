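# ENPP1 transcript/protein coordinate system and domain architecture.
# Domain residue ranges follow the published ENPP1 architecture; the two
# linker regions are pinned by curated domain assignments of Trp190 and
# Leu611. Residues 98-103 (between the transmembrane segment and SMB1) are
# an unnamed intervening region.
transcript_accession: NM_006208.3
protein_accession: NP_006199.2
protein_length: 925
cds_length: 2778   # 925 codons + stop
domains:
  - {name: Cytoplasmic domain, start: 1, end: 76}
  - {name: Transmembrane region, start: 77, end: 97}
  - {name: SMB 1, start: 104, end: 144}
  - {name: SMB 2, start: 145, end: 188}
  - {name: Linker 1, start: 189, end: 190}
  - {name: Phosphodiesterase, start: 191, end: 591}
  - {name: Linker 2, start: 592, end: 653}
  - {name: Nuclease, start: 654, end: 925}
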