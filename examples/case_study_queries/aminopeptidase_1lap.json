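{
  "comment": "Five zinc-coordinating residues of bovine lens leucine aminopeptidase; a rigid 5-residue motif, pruned to 4 spanning-tree edges at search time. Requires 1lap.cif in this directory.",
  "reference": {"path": "1lap.cif", "format": "mmcif", "structure_id": "1lap", "assembly": "1"},
  "selectors": [
    {"chain": "A", "seq": 250, "numbering": "auth"},
    {"chain": "A", "seq": 255, "numbering": "auth"},
    {"chain": "A", "seq": 273, "numbering": "auth"},
    {"chain": "A", "seq": 332, "numbering": "auth"},
    {"chain": "A", "seq": 334, "numbering": "auth"}
  ],
  "exchanges": {}
}
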