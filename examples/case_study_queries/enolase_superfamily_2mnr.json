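{
  "comment": "Enolase-superfamily active site with position-specific exchanges: Lys/His at the first and last positions, Glu/Asp/Asn at the fourth. Requires 2mnr.cif in this directory.",
  "reference": {"path": "2mnr.cif", "format": "mmcif", "structure_id": "2mnr"},
  "selectors": [
    {"chain": "A", "seq": 164, "numbering": "auth"},
    {"chain": "A", "seq": 195, "numbering": "auth"},
    {"chain": "A", "seq": 221, "numbering": "auth"},
    {"chain": "A", "seq": 247, "numbering": "auth"},
    {"chain": "A", "seq": 297, "numbering": "auth"}
  ],
  "exchanges": {"0": ["H"], "3": ["D", "N"], "4": ["K"]}
}
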