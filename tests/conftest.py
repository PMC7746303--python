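"""Shared fixtures: hand-written mmCIF snippets and synthetic corpora."""

import numpy as np
import pytest

from strucmotif.structures import Structure
from strucmotif.synthetic import make_benchmark_corpus, make_triad_motif

# A minimal, hand-written two-residue mmCIF (Ala then Gly) — written by hand
# so the parser is exercised on a file our own writer did not produce.
TWO_RESIDUE_CIF = """\
data_mini
_entry.id mini
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM 1 N N  . ALA A 1 1 ? 1.458 0.000 0.000 1.00 0.00 11 X 1
ATOM 2 C CA . ALA A 1 1 ? 0.000 0.000 0.000 1.00 0.00 11 X 1
ATOM 3 C C  . ALA A 1 1 ? -0.551 1.420 0.000 1.00 0.00 11 X 1
ATOM 4 O O  . ALA A 1 1 ? -1.752 1.620 0.210 1.00 0.00 11 X 1
ATOM 5 C CB . ALA A 1 1 ? -0.540 -0.785 -1.200 1.00 0.00 11 X 1
ATOM 6 N N  . GLY A 1 2 ? 0.280 2.400 -0.180 1.00 0.00 12 X 1
ATOM 7 C CA . GLY A 1 2 ? -0.130 3.790 -0.250 1.00 0.00 12 X 1
ATOM 8 C C  . GLY A 1 2 ? 0.940 4.710 0.330 1.00 0.00 12 X 1
ATOM 9 O O  . GLY A 1 2 ? 2.120 4.390 0.270 1.00 0.00 12 X 1
"""

# One RNA guanosine plus one water and one ion — the latter two must be
# stripped; the nucleotide's representatives are C4' and C1'.
NUCLEOTIDE_CIF = """\
data_rna
_entry.id rna
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM   1 P "P"   . G   A 1 1 ? 0.000 0.000 0.000 1.00 0.00 1 A 1
ATOM   2 C "C5'" . G   A 1 1 ? 1.200 1.100 0.400 1.00 0.00 1 A 1
ATOM   3 C "C4'" . G   A 1 1 ? 2.400 0.800 1.250 1.00 0.00 1 A 1
ATOM   4 O "O4'" . G   A 1 1 ? 3.100 -0.350 0.760 1.00 0.00 1 A 1
ATOM   5 C "C3'" . G   A 1 1 ? 3.450 1.900 1.300 1.00 0.00 1 A 1
ATOM   6 C "C2'" . G   A 1 1 ? 4.700 1.200 0.820 1.00 0.00 1 A 1
ATOM   7 C "C1'" . G   A 1 1 ? 4.450 -0.250 1.120 1.00 0.00 1 A 1
ATOM   8 N N9    . G   A 1 1 ? 5.100 -1.150 0.200 1.00 0.00 1 A 1
ATOM   9 C C8    . G   A 1 1 ? 4.900 -2.500 0.150 1.00 0.00 1 A 1
HETATM 10 O O    . HOH B 2 . ? 8.000 8.000 8.000 1.00 0.00 101 A 1
HETATM 11 Z ZN   . ZN  C 3 . ? 9.000 9.000 9.000 1.00 0.00 102 A 1
"""


@pytest.fixture(scope="session")
def triad():
    return make_triad_motif()


@pytest.fixture()
def triad_reference(triad):
    """The synthetic triad packaged as a reference structure for queries."""
    return Structure("triadref", triad)


@pytest.fixture()
def two_residue_path(tmp_path):
    path = tmp_path / "mini.cif"
    path.write_text(TWO_RESIDUE_CIF)
    return path


@pytest.fixture()
def nucleotide_path(tmp_path):
    path = tmp_path / "rna.cif"
    path.write_text(NUCLEOTIDE_CIF)
    return path


@pytest.fixture(scope="session")
def small_planted_corpus():
    """10 random chains, 3 carrying one noiseless planted triad each."""
    structures, truth = make_benchmark_corpus(
        10, 3, sigma=0.0, seed=7, residues_range=(40, 80)
    )
    return structures, truth


def truth_assignments(truth_df):
    """Truth table -> {structure_id: (locator strings ordered by role)}."""
    out = {}
    for sid, group in truth_df.groupby("structure_id"):
        group = group.sort_values("role")
        out[sid] = tuple(
            f"{r.chain}_{r.operator}-{r.seq_id}" for r in group.itertuples()
        )
    return out
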