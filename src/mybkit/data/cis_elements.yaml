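# Bundled cis-regulatory element dictionary (element name -> IUPAC consensus).
# Consensus strings follow the common PlantCARE-style one-line motifs for the
# elements reported in pepper MYB promoters; the file is editable, matching is
# exact IUPAC (both strands).
elements:
  TATA-box: TATAAA
  CAAT-box: CCAAT
  ABRE: ACGTGGC
  G-box: CACGTG
  GATA-motif: AAGATAAGATT
  MRE: AACCTAA
  RY-element: CATGCATG
  AE-box: AGAAACAA
  AACA-motif: AACAAAC
  GCN4-motif: TGAGTCA
  BoxII: CCACGTGG
  LTRE: CCGAAA
  TC-rich: ATTTTCTTCA
  MBS: CAACTG
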