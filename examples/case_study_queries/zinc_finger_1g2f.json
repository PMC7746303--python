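{
  "comment": "Simplified His2/Cys2 zinc-finger query (three of the four coordinating residues; the structurally variable second cysteine is deliberately omitted, which sharply lowers the false-negative rate). Requires 1g2f.cif in this directory.",
  "reference": {"path": "1g2f.cif", "format": "mmcif", "structure_id": "1g2f"},
  "selectors": [
    {"chain": "F", "seq": 207, "numbering": "auth"},
    {"chain": "F", "seq": 225, "numbering": "auth"},
    {"chain": "F", "seq": 229, "numbering": "auth"}
  ],
  "exchanges": {}
}
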