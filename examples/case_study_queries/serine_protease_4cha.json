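{
  "comment": "His-Asp-Ser catalytic triad of alpha-chymotrypsin. Download 4cha.cif into this directory first (e.g. from files.rcsb.org), then: strucmotif search --index <IDX> --query serine_protease_4cha.json --rmsd-cutoff 1.0 --out triad",
  "reference": {"path": "4cha.cif", "format": "mmcif", "structure_id": "4cha"},
  "selectors": [
    {"chain": "B", "seq": 57, "numbering": "auth"},
    {"chain": "B", "seq": 102, "numbering": "auth"},
    {"chain": "C", "seq": 195, "numbering": "auth"}
  ],
  "exchanges": {}
}
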