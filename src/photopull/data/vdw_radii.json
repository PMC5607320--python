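{
  "comment": "Heavy-atom van der Waals radii (Angstrom) by element, Tsai-style set used for the enlarged-overlap native-contact criterion. Override via native_contact_map(vdw_table=...).",
  "C": 1.76,
  "N": 1.64,
  "O": 1.46,
  "S": 1.77,
  "SE": 1.90,
  "P": 1.80
}
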