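# Default 32-channel 10-20 montage used for laterality normalisation.
# The vendor's exact electrode sheet is not enumerated in the source text,
# so this standard 32-channel layout is a documented, editable assumption.
channels:
  - Fp1
  - Fp2
  - AF3
  - AF4
  - F7
  - F3
  - Fz
  - F4
  - F8
  - FC5
  - FC1
  - FC2
  - FC6
  - T7
  - C3
  - Cz
  - C4
  - T8
  - CP5
  - CP1
  - CP2
  - CP6
  - P7
  - P3
  - Pz
  - P4
  - P8
  - PO7
  - PO3
  - PO4
  - PO8
  - Oz
homologous_pairs:
  - [Fp1, Fp2]
  - [AF3, AF4]
  - [F7, F8]
  - [F3, F4]
  - [FC5, FC6]
  - [FC1, FC2]
  - [T7, T8]
  - [C3, C4]
  - [CP5, CP6]
  - [CP1, CP2]
  - [P7, P8]
  - [P3, P4]
  - [PO7, PO8]
  - [PO3, PO4]
midline:
  - Fz
  - Cz
  - Pz
  - Oz
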