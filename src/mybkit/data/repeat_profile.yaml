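# Bundled MYB repeat profile: synthetic seed alignments (constructed for this
# repository, anchor geometry per the canonical plant R2/R3 repeat), anchor
# rules, and the detection score threshold calibrated on synthetic data.
version: 1
score_threshold: 10.0
max_linker: 25
repeats:
  R2:
    length: 52
    anchors:
    - column: 5
      residues:
      - W
    - column: 26
      residues:
      - W
      spacing:
      - 20
      - 21
    - column: 47
      residues:
      - W
      spacing:
      - 20
      - 21
    seed_alignment:
    - LKKGAWTAEEDRLLVEYVQKHGEGNRWLPKKAGLQRCGKSCRLRSNYWRPGN
    - LKKGAWTTEEDDLLVEYYQKHGEGHRWLPKKAGLQRCGKSCRLRSNYWCPGN
    - EKKPAWTAEEDRLLVEYLQKHGEGNRWLPKKAGLQRCGKSCRLRSNQWRPGN
    - LKKGEWTAEEDRLLVEYVTKHGEGNRWNPSKDGLQRCGHSCRLRSMYWRPGN
    - LKKTAWTAEEGRLLVEDPCKHKEGNRWLTKKAGLQRCGKSCQLLSNNWRPGN
    - LVKGAWTAEEDQLLVEKVQGHGEGNRWLMLKAGKVRCGSSHRLRSNGWRSGN
    - CKKCAWTAEEDRQLVEYVQYAGMENRWLPKDAGLQRCGVSCRLRSNYWRPGN
    - LKKGAWTAERIRTLVEYVQKHSEISRWLPKKAGLQREGKTNRLRPNYWRPGS
    - LKKAAWTMERDRLLVEYVQKHGEGNRWLQKKAGLQRCNKSCRLRSMYWRPPN
    - LIKGRWTAEEVRLLEEYVQKHLEGNRWLPKHAGLQLCGESCRLRSNYWRPGN
  R3:
    length: 52
    anchors:
    - column: 5
      residues:
      - F
      - W
    - column: 24
      residues:
      - W
      spacing:
      - 19
      - 19
    - column: 43
      residues:
      - W
      spacing:
      - 19
      - 19
    seed_alignment:
    - LKKGAFTAEEDRLLVEYVQKHGEGWRNLPKKAGLQRCGKSCRLWSNYLRPGN
    - LQKGAFTAYEDRTLVEYVQKHGEGWRYHPKKAGLQREAKSCSLWSNHLRPGE
    - LKKGIFTVEEDRCLVEYVQKHGEGWRNLPKKAGLCRCGKSCRLWPNYNRPGM
    - LHKGAFYSNEDRLLVEYVQKHGEGWRNLPKPACLQREGLSCRLWSNYLRPGN
    - LCVGAFTNEEDRLLVEIVAKRGNGWRNLPKKAHLQRCGDSCRLWENYLRPGV
    - LYKGAFHAEEDRLLVQQVQKNGEGWRNKPKVAGLQRCGKECRLWYNYLRPVN
    - LKKGAFTAEEGRLLVENGQKHSEGWRNLCKKSGLQRCGKSCRLWSNYLNPGN
    - LGKGAFTAEESRLLVEYIQKHGIGWRNLPKKAGLQRCGADCRVWSNYLRAGN
    - LKKGAFTSEECRLLHEHISKHGEGWRNLSKKAGLQRCGKPDRLWRCYLRPGN
    - LKQGAFTAEEDRLKVEYVQKHGEGWRNLPKKAGLAYRGKGCRLWSNYLRPRD
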