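# Curated reference V-domain consensus sequences used as numbering profiles.
#
# The sequences are human germline-style consensus V-domains (VH3-type heavy,
# Vkappa1-type light) curated for this package: each is exactly one residue
# per scheme position with no insertion codes (Kabat heavy 1..113, Kabat
# light 1..107), so the reference maps onto itself trivially and every
# query position is transferred across a pairwise alignment to the profile.
#
# region splits are 1-based inclusive residue-index spans of the reference
# sequence.  Kabat spans coincide with Kabat numbers because the references
# carry no insertions.  IMGT spans follow the IMGT unique-numbering region
# layout (FR1 1-26, CDR1 27-38, FR2 39-55, CDR2 56-65, FR3 66-104,
# CDR3 105-117, FR4 118-128) with the conserved Cys23/Trp41/Cys104/Trp118
# landmarks falling on their canonical slots.
heavy:
  sequence: >-
    EVQLVESGGGLVQPGGSLRLSCAASGFTFSSYAMSWVRQAPGKGLEWVSAISGSGGSTYYADSVKRFTISRDNSKNTLYLQMNSLRAEDYYCARDRGGYFDYWGQGTLVTVSS
  kabat:
    regions:
      FR1: [1, 30]
      CDR1: [31, 35]
      FR2: [36, 49]
      CDR2: [50, 65]
      FR3: [66, 94]
      CDR3: [95, 102]
      FR4: [103, 113]
    anchors:          # canonical Kabat insertion anchors per region
      CDR1: 35        # 35a, 35b
      CDR2: 52        # 52a-52c
      FR3: 82         # 82a-82c
      CDR3: 100       # 100a-100k
  imgt:
    regions:          # reference residue-index spans per IMGT region
      FR1: [1, 25]
      CDR1: [26, 33]
      FR2: [34, 50]
      CDR2: [51, 58]
      FR3: [59, 92]
      CDR3: [93, 102]
      FR4: [103, 113]
light:
  sequence: >-
    DIQMTQSPSSLSASVGDRVTITCRASQSVSSAVAWYQQKPGKAPKLLIYSASSLYSGVPSRFSGSGSGTDFTLTISSLQPEDFATYYCQQYNSLPWTFGQGTKVEIK
  kabat:
    regions:
      FR1: [1, 23]
      CDR1: [24, 34]
      FR2: [35, 49]
      CDR2: [50, 56]
      FR3: [57, 88]
      CDR3: [89, 97]
      FR4: [98, 107]
    anchors:
      CDR1: 27        # 27a-27f
      CDR3: 95        # 95a-95f
      FR4: 106        # 106a
  imgt:
    regions:
      FR1: [1, 26]
      CDR1: [27, 32]
      FR2: [33, 49]
      CDR2: [50, 52]
      FR3: [53, 88]
      CDR3: [89, 97]
      FR4: [98, 107]
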