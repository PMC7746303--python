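# Examples

Numbered scripts are self-contained and offline — each generates its own
synthetic input, runs one capability and prints what the numbers mean:

| script | capability |
| --- | --- |
| `01_build_and_inspect_index.py` | index construction and the descriptor-bin census |
| `02_search_planted_motif.py` | end-to-end motif search with RMSD-scored hits |
| `03_exchanges_and_tolerance.py` | position-specific exchanges and the bin tolerance |
| `04_assemblies_and_interchain_motifs.py` | biological-assembly expansion, inter-copy pairs |

Run with `python examples/<script>.py`.

## Case-study queries

`case_study_queries/` holds ready-made query files for well-known motifs
(serine-protease catalytic triad, leucine-aminopeptidase zinc site,
His2/Cys2 zinc finger, enolase-superfamily site with exchanges). They
reference real PDB entries, so you must download the named mmCIF file into
that directory first and build an index over whatever corpus you want to
search; nothing in the test suite depends on them.

Nucleotide motifs (e.g. guanine tetrads in G-quadruplexes) are authored the
same way: selectors pointing at nucleotides resolve to lower-case type
tokens (a/c/g/t/u) with C4′/C1′ as the representative atoms, and assembly
expansion makes tetrads that span strand copies searchable.
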