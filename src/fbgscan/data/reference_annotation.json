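{
  "reference_id": "FBG-C-syn",
  "loop5": [110, 139],
  "loop6": [143, 151],
  "loop7": [155, 170],
  "loop10_anchor": 224,
  "triad_positions": [157, 160, 162],
  "triad_residues": ["D", "I", "N"],
  "ridge_motif": "KTRYKLK",
  "ridge_slots": [124, 126, 128, 130, 147, 164, 168],
  "buffer_positions": [107, 108, 109, 140, 141, 142, 152, 153, 154, 171, 172, 173],
  "comment": "Synthetic tenascin-C FBG scaffold. Domain-local 1-based coordinates. Anchors follow the published residue numbering (KTRYKLK loop-5 motif, D157/I160/N162 loop-7 triad, RRKRA tail at 224-228, truncation point 223). Loop extents are a design calibration: they are not printed anywhere and are chosen to be consistent with every printed anchor."
}
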