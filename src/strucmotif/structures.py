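"""Structure model: parsing, cleaning, assembly expansion and representative points.

A parsed :class:`Structure` is a flat, ordered collection of polymer residues.
Each residue carries its full (hydrogen-free) atom set plus two representative
points that all pair descriptors are computed from: for amino acids the
backbone representative is Cα and the sidechain representative Cβ (virtually
reconstructed for glycine); for nucleotides they are C4′ and C1′ respectively.

Residues are addressed by a :class:`ResidueLocator` — label_asym_id, the
biological-assembly operator id ("1" for the identity / asymmetric unit), and
the 1-based label_seq_id — rendered as e.g. ``"A_1-87"``.

Parsing is delegated to :mod:`gemmi`; this module owns the cleaning rules
(drop hydrogens, keep first alternate locations, drop waters/ions/ligands and
unmappable components) and the conversion to the package's residue model.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np

from .errors import (
    DegenerateGeometryError,
    EmptyStructureError,
    ParseError,
    SelectorError,
    UnknownAssemblyError,
)

__all__ = [
    "ResidueLocator",
    "Residue",
    "Structure",
    "LoadReport",
    "Selector",
    "load_structure",
    "read_raw",
    "expand_assembly",
    "list_assemblies",
    "reconstruct_gly_cb",
    "select_residues",
    "write_mmcif",
    "AMINO_ONE_LETTER",
    "NUCLEOTIDE_TOKENS",
    "DEFAULT_MODIFIED_MAP",
]

# ---------------------------------------------------------------------------
# residue-type tokens
# ---------------------------------------------------------------------------

#: Three-letter component id -> one-letter token for the 20 standard amino acids.
AMINO_ONE_LETTER: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Component id -> lower-case token for standard (deoxy)ribonucleotides.
#: Lower case keeps adenosine ("a") distinct from alanine ("A").
NUCLEOTIDE_TOKENS: dict[str, str] = {
    "A": "a", "C": "c", "G": "g", "U": "u", "T": "t",
    "DA": "a", "DC": "c", "DG": "g", "DT": "t", "DU": "u",
}

#: Common modified components mapped to their parent token. Components absent
#: from this table (and from the standard tables) are excluded from indexing
#: and counted in the load report.
DEFAULT_MODIFIED_MAP: dict[str, str] = {
    "MSE": "M",   # selenomethionine
    "SEP": "S",   # phosphoserine
    "TPO": "T",   # phosphothreonine
    "PTR": "Y",   # phosphotyrosine
    "CSO": "C",   # S-hydroxycysteine
    "CME": "C",   # S,S-(2-hydroxyethyl)thiocysteine
    "HYP": "P",   # 4-hydroxyproline
    "MLY": "K",   # N-dimethyl-lysine
    "M3L": "K",   # N-trimethyl-lysine
    "KCX": "K",   # carboxylysine
    "PSU": "u",   # pseudouridine
    "1MA": "a",   # 1-methyladenosine
    "5MC": "c",   # 5-methylcytidine
    "OMG": "g",   # O2'-methylguanosine
    "7MG": "g",   # 7-methylguanosine
}

_AMINO_KIND = "amino-acid"
_NUCLEOTIDE_KIND = "nucleotide"

# Ideal L-alanine fragment (CCD ideal coordinates) used to reconstruct a
# virtual Cβ for glycine by least-squares superposition onto N/Cα/C.
_IDEAL_ALA = {
    "N": np.array([-0.966, 0.493, 1.500]),
    "CA": np.array([0.257, 0.418, 0.692]),
    "C": np.array([-0.094, 0.017, -0.716]),
    "CB": np.array([1.204, -0.620, 1.296]),
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class ResidueLocator:
    """Address of one residue inside an assembly-expanded structure.

    Ordering is lexicographic on (chain_id, operator_id, seq_id); the rendered
    form is ``"<chain>_<operator>-<seq>"``.
    """

    chain_id: str
    operator_id: str
    seq_id: int

    def __post_init__(self):
        if self.seq_id < 1:
            raise ValueError(f"seq_id must be >= 1, got {self.seq_id}")

    def render(self) -> str:
        return f"{self.chain_id}_{self.operator_id}-{self.seq_id}"

    def __str__(self) -> str:  # pragma: no cover - convenience alias
        return self.render()

    @classmethod
    def parse(cls, text: str) -> "ResidueLocator":
        """Inverse of :meth:`render` (``"A_1-87"`` -> locator)."""
        try:
            chain_op, seq = text.rsplit("-", 1)
            chain, op = chain_op.split("_", 1)
            return cls(chain, op, int(seq))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"cannot parse residue locator {text!r}") from exc


@dataclass
class Residue:
    """One polymer residue with its atoms and representative points."""

    locator: ResidueLocator
    code: str
    polymer_kind: str  # "amino-acid" | "nucleotide"
    atoms: dict[str, np.ndarray]
    backbone_rep: np.ndarray
    sidechain_rep: np.ndarray
    # author numbering, kept only so selectors written in author numbering can
    # be translated; never part of the locator.
    auth_chain_id: str = ""
    auth_seq_id: int | None = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Residue):
            return NotImplemented
        return (
            self.locator == other.locator
            and self.code == other.code
            and self.polymer_kind == other.polymer_kind
            and set(self.atoms) == set(other.atoms)
            and all(np.array_equal(self.atoms[k], other.atoms[k]) for k in self.atoms)
            and np.array_equal(self.backbone_rep, other.backbone_rep)
            and np.array_equal(self.sidechain_rep, other.sidechain_rep)
        )


@dataclass
class LoadReport:
    """Bookkeeping of what the cleaning rules removed."""

    kept: int = 0
    removed_nonpolymer: int = 0
    removed_unmapped: int = 0
    removed_missing_atoms: int = 0
    removed_duplicate_locator: int = 0
    unmapped_components: list[str] = field(default_factory=list)


class Structure:
    """An assembly-expanded, polymer-only structure."""

    def __init__(
        self,
        structure_id: str,
        residues: Sequence[Residue],
        assembly_id: str = "asymmetric-unit",
        load_report: LoadReport | None = None,
    ):
        self.structure_id = structure_id
        self.residues = list(residues)
        self.assembly_id = assembly_id
        self.load_report = load_report or LoadReport(kept=len(self.residues))
        self._by_locator: dict[ResidueLocator, Residue] = {}
        for res in self.residues:
            if res.locator in self._by_locator:
                raise ValueError(f"duplicate residue locator {res.locator.render()}")
            self._by_locator[res.locator] = res

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def get(self, locator: ResidueLocator) -> Residue | None:
        return self._by_locator.get(locator)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<Structure {self.structure_id} assembly={self.assembly_id} "
            f"residues={len(self.residues)}>"
        )


@dataclass(frozen=True)
class Selector:
    """A residue selector in either label or author numbering.

    ``numbering="label"`` matches (label_asym_id, operator, label_seq_id);
    ``numbering="auth"`` matches (auth_asym_id, operator, auth_seq_id) and is
    translated to label numbering on resolution.
    """

    chain_id: str
    seq_id: int
    operator_id: str = "1"
    numbering: str = "label"

    def __post_init__(self):
        if self.numbering not in ("label", "auth"):
            raise ValueError(f"numbering must be 'label' or 'auth', got {self.numbering!r}")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _kabsch_transform(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) with R @ moving_i + t ≈ fixed_i."""
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    h = (moving - mc).T @ (fixed - fc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = fc - rot @ mc
    return rot, trans


def reconstruct_gly_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Virtual Cβ position for glycine.

    Superposes the N/Cα/C fragment of an ideal L-alanine onto the given
    backbone coordinates (least squares) and transplants the alanine Cβ.
    Equivariant under rigid motion of the inputs by construction.
    """
    n = np.asarray(n, dtype=float)
    ca = np.asarray(ca, dtype=float)
    c = np.asarray(c, dtype=float)
    v1 = n - ca
    v2 = c - ca
    if np.linalg.norm(np.cross(v1, v2)) < 1e-6:
        raise DegenerateGeometryError("backbone N/CA/C are (nearly) collinear")
    template = np.stack([_IDEAL_ALA["N"], _IDEAL_ALA["CA"], _IDEAL_ALA["C"]])
    target = np.stack([n, ca, c])
    rot, trans = _kabsch_transform(template, target)
    return rot @ _IDEAL_ALA["CB"] + trans


# ---------------------------------------------------------------------------
# parsing / cleaning
# ---------------------------------------------------------------------------

def _map_component(name: str, modified_map: Mapping[str, str]) -> tuple[str, str] | None:
    """Component id -> (token, polymer_kind), or None when not indexable."""
    name = name.strip().upper()
    if name in AMINO_ONE_LETTER:
        return AMINO_ONE_LETTER[name], _AMINO_KIND
    if name in NUCLEOTIDE_TOKENS:
        return NUCLEOTIDE_TOKENS[name], _NUCLEOTIDE_KIND
    if name in modified_map:
        token = modified_map[name]
        kind = _AMINO_KIND if token.isupper() else _NUCLEOTIDE_KIND
        return token, kind
    return None


def read_raw(source, fmt: str = "mmcif") -> gemmi.Structure:
    """Parse a structure file (optionally gzipped) into a raw gemmi model.

    Hydrogens are removed and only the first alternate location of each atom
    is kept; no other cleaning happens here.
    """
    fmt = fmt.lower()
    if fmt not in ("mmcif", "pdb"):
        raise ValueError(f"unsupported format {fmt!r}")
    try:
        if hasattr(source, "read"):
            data = source.read()
            if isinstance(data, str):
                data = data.encode()
            if data[:2] == b"\x1f\x8b":
                data = gzip.decompress(data)
            name = getattr(source, "name", "stream")
            if fmt == "mmcif":
                doc = gemmi.cif.read_string(data.decode())
                st = gemmi.make_structure_from_block(doc.sole_block())
            else:
                st = gemmi.read_pdb_string(data.decode())
            if not st.name or st.name == "":
                st.name = os.path.splitext(os.path.basename(str(name)))[0]
        else:
            path = os.fspath(source)
            if not os.path.exists(path):
                raise ParseError(f"no such file: {path}")
            if fmt == "mmcif":
                st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
            else:
                st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"cannot parse {fmt} input: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError("file contains no model")
    st.remove_hydrogens()
    st.remove_alternative_conformations()  # keeps the first-listed location
    if fmt == "pdb":
        st.setup_entities()
        st.assign_label_seq_id()
    return st


def _convert_residue(
    res: gemmi.Residue,
    chain: gemmi.Chain,
    modified_map: Mapping[str, str],
    report: LoadReport,
) -> Residue | None:
    """Convert one gemmi residue; None when the cleaning rules exclude it."""
    if res.is_water():
        report.removed_nonpolymer += 1
        return None
    mapped = _map_component(res.name, modified_map)
    if mapped is None:
        # unmappable component: ion, ligand, or unknown modification
        if len(res) <= 1:
            report.removed_nonpolymer += 1
        else:
            report.removed_unmapped += 1
            report.unmapped_components.append(res.name)
        return None
    token, kind = mapped
    label_seq = res.label_seq if res.label_seq is not None else res.seqid.num
    if label_seq is None or label_seq < 1:
        report.removed_missing_atoms += 1
        return None
    atoms: dict[str, np.ndarray] = {}
    for atom in res:
        if atom.name in atoms:
            continue  # one coordinate per atom name
        atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
    if kind == _AMINO_KIND:
        if "CA" not in atoms:
            report.removed_missing_atoms += 1
            return None
        backbone = atoms["CA"]
        if "CB" in atoms:
            sidechain = atoms["CB"]
        elif {"N", "C"} <= atoms.keys():
            try:
                sidechain = reconstruct_gly_cb(atoms["N"], atoms["CA"], atoms["C"])
            except DegenerateGeometryError:
                report.removed_missing_atoms += 1
                return None
        else:
            report.removed_missing_atoms += 1
            return None
    else:
        if "C4'" not in atoms or "C1'" not in atoms:
            report.removed_missing_atoms += 1
            return None
        backbone = atoms["C4'"]
        sidechain = atoms["C1'"]
    chain_id = res.subchain if res.subchain else chain.name
    locator = ResidueLocator(chain_id, "1", int(label_seq))
    return Residue(
        locator=locator,
        code=token,
        polymer_kind=kind,
        atoms=atoms,
        backbone_rep=backbone,
        sidechain_rep=sidechain,
        auth_chain_id=chain.name,
        auth_seq_id=res.seqid.num,
    )


def _convert_model(
    st: gemmi.Structure, modified_map: Mapping[str, str]
) -> tuple[list[Residue], LoadReport]:
    report = LoadReport()
    residues: list[Residue] = []
    seen: set[ResidueLocator] = set()
    model = st[0]
    for chain in model:
        for res in chain:
            converted = _convert_residue(res, chain, modified_map, report)
            if converted is None:
                continue
            if converted.locator in seen:
                report.removed_duplicate_locator += 1
                continue
            seen.add(converted.locator)
            residues.append(converted)
            report.kept += 1
    return residues, report


def list_assemblies(raw: gemmi.Structure) -> list[str]:
    """Names of the biological assemblies defined in a raw structure."""
    return [asm.name for asm in raw.assemblies]


def _apply_transform(coords: np.ndarray, tr: gemmi.Transform) -> np.ndarray:
    mat = np.array(tr.mat.tolist())
    vec = np.array(tr.vec.tolist())
    return coords @ mat.T + vec


def expand_assembly(
    raw: gemmi.Structure,
    assembly_id: str | None,
    modified_map: Mapping[str, str] | None = None,
    structure_id: str | None = None,
) -> Structure:
    """Expand a biological assembly of a raw (parsed, uncleaned) structure.

    ``assembly_id=None`` (or ``"asymmetric-unit"``) keeps the deposited
    coordinates; every residue then carries the identity operator ``"1"``.
    Otherwise each generated chain copy carries the operator id from the
    file's assembly definition.
    """
    modified_map = DEFAULT_MODIFIED_MAP if modified_map is None else modified_map
    sid = structure_id or raw.name.lower()
    base_residues, report = _convert_model(raw, modified_map)

    if assembly_id is None or assembly_id == "asymmetric-unit":
        if not base_residues:
            raise EmptyStructureError(f"{sid}: no polymer residues after cleaning")
        return Structure(sid, base_residues, "asymmetric-unit", report)

    assembly = None
    for asm in raw.assemblies:
        if asm.name == str(assembly_id):
            assembly = asm
            break
    if assembly is None:
        raise UnknownAssemblyError(str(assembly_id), list_assemblies(raw))

    by_chain: dict[str, list[Residue]] = {}
    auth_to_label: dict[str, set[str]] = {}
    for res in base_residues:
        by_chain.setdefault(res.locator.chain_id, []).append(res)
        auth_to_label.setdefault(res.auth_chain_id, set()).add(res.locator.chain_id)

    expanded: list[Residue] = []
    fallback_op = 0
    for gen in assembly.generators:
        chain_ids: list[str] = []
        if len(gen.subchains) > 0:
            chain_ids = [c for c in gen.subchains if c in by_chain]
        else:
            for auth in gen.chains:
                chain_ids.extend(sorted(auth_to_label.get(auth, ())))
        for op in gen.operators:
            fallback_op += 1
            op_id = op.name if op.name else str(fallback_op)
            for chain_id in chain_ids:
                for res in by_chain[chain_id]:
                    names = list(res.atoms)
                    coords = np.stack([res.atoms[n] for n in names])
                    moved = _apply_transform(coords, op.transform)
                    atoms = {n: moved[i] for i, n in enumerate(names)}
                    reps = _apply_transform(
                        np.stack([res.backbone_rep, res.sidechain_rep]), op.transform
                    )
                    expanded.append(
                        Residue(
                            locator=ResidueLocator(chain_id, op_id, res.locator.seq_id),
                            code=res.code,
                            polymer_kind=res.polymer_kind,
                            atoms=atoms,
                            backbone_rep=reps[0],
                            sidechain_rep=reps[1],
                            auth_chain_id=res.auth_chain_id,
                            auth_seq_id=res.auth_seq_id,
                        )
                    )
    if not expanded:
        raise EmptyStructureError(
            f"{sid}: assembly {assembly_id!r} generated no polymer residues"
        )
    return Structure(sid, expanded, str(assembly_id), report)


def load_structure(
    source,
    fmt: str = "mmcif",
    assembly: str | None = None,
    structure_id: str | None = None,
    modified_map: Mapping[str, str] | None = None,
) -> Structure:
    """Parse, clean and (optionally) assembly-expand a structure file.

    Parameters
    ----------
    source
        File path or readable byte/text stream; gzip is detected.
    fmt
        ``"mmcif"`` or ``"pdb"``.
    assembly
        Assembly name to expand (e.g. ``"1"``); ``None`` keeps the
        asymmetric unit with identity operators.
    structure_id
        Override for the entry identifier; defaults to the file's entry id.
    modified_map
        Mapping of modified-component ids to parent tokens; defaults to
        :data:`DEFAULT_MODIFIED_MAP`.
    """
    raw = read_raw(source, fmt)
    return expand_assembly(raw, assembly, modified_map, structure_id)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def _as_selector(sel) -> Selector:
    if isinstance(sel, Selector):
        return sel
    if isinstance(sel, (tuple, list)):
        if len(sel) == 3:
            chain, op, seq = sel
            return Selector(str(chain), int(seq), str(op))
        raise SelectorError(f"selector tuple must be (chain, operator, seq): {sel!r}")
    raise SelectorError(f"cannot interpret selector {sel!r}")


def select_residues(structure: Structure, selectors: Iterable) -> list[Residue]:
    """Resolve selectors (label or author numbering) to residues, in order."""
    out: list[Residue] = []
    for raw_sel in selectors:
        sel = _as_selector(raw_sel)
        if sel.numbering == "label":
            loc = ResidueLocator(sel.chain_id, sel.operator_id, sel.seq_id)
            res = structure.get(loc)
            if res is None:
                raise SelectorError(
                    f"no residue {loc.render()} in {structure.structure_id}"
                )
        else:
            matches = [
                r
                for r in structure.residues
                if r.auth_chain_id == sel.chain_id
                and r.auth_seq_id == sel.seq_id
                and r.locator.operator_id == sel.operator_id
            ]
            if not matches:
                raise SelectorError(
                    f"no residue with auth chain {sel.chain_id!r}, auth seq "
                    f"{sel.seq_id}, operator {sel.operator_id!r} in "
                    f"{structure.structure_id}"
                )
            res = matches[0]
        out.append(res)
    return out


# ---------------------------------------------------------------------------
# minimal mmCIF writer (fixtures / synthetic corpora)
# ---------------------------------------------------------------------------

_TOKEN_TO_COMP = {v: k for k, v in AMINO_ONE_LETTER.items()}
_TOKEN_TO_COMP.update({"a": "A", "c": "C", "g": "G", "u": "U", "t": "DT"})

_ELEMENT_GUESS = {"N": "N", "O": "O", "S": "S", "P": "P"}


def _guess_element(atom_name: str) -> str:
    return _ELEMENT_GUESS.get(atom_name[0], "C")


def write_mmcif(
    structure: Structure,
    path,
    assemblies: Mapping[str, Sequence[tuple[str, np.ndarray, np.ndarray]]] | None = None,
) -> None:
    """Write a minimal mmCIF sufficient to round-trip the model.

    Only the asymmetric-unit residues (operator "1") are written as atom_site
    records; ``assemblies`` optionally maps an assembly name to a list of
    ``(operator_id, rotation 3x3, translation 3)`` applied to all chains,
    emitted as pdbx_struct_assembly/oper_list categories.
    """
    doc = gemmi.cif.Document()
    block = doc.add_new_block(structure.structure_id)
    block.set_pair("_entry.id", structure.structure_id)

    if assemblies:
        chain_ids = sorted({r.locator.chain_id for r in structure.residues})
        asm_rows: list[list[str]] = []
        gen_rows: list[list[str]] = []
        oper_rows: list[list[str]] = []
        seen_ops: set[str] = set()
        for asm_name, ops in assemblies.items():
            asm_rows.append([str(asm_name), "?", "?", "?", "?"])
            expr = ",".join(op_id for op_id, _, _ in ops)
            gen_rows.append([str(asm_name), expr, ",".join(chain_ids)])
            for op_id, rot, vec in ops:
                if op_id in seen_ops:
                    continue
                seen_ops.add(op_id)
                rot = np.asarray(rot, dtype=float)
                vec = np.asarray(vec, dtype=float)
                kind = (
                    "identity operation"
                    if np.allclose(rot, np.eye(3)) and np.allclose(vec, 0)
                    else "crystal symmetry operation"
                )
                row = [str(op_id), gemmi.cif.quote(kind)]
                for i in range(3):
                    row += [f"{rot[i, j]:.10g}" for j in range(3)]
                    row.append(f"{vec[i]:.10g}")
                oper_rows.append(row)
        # loop handles invalidate when the block grows: fill each before the next
        loop = block.init_loop(
            "_pdbx_struct_assembly.",
            ["id", "details", "method_details", "oligomeric_details", "oligomeric_count"],
        )
        for row in asm_rows:
            loop.add_row(row)
        loop = block.init_loop(
            "_pdbx_struct_assembly_gen.", ["assembly_id", "oper_expression", "asym_id_list"]
        )
        for row in gen_rows:
            loop.add_row(row)
        oper_tags = ["id", "type"]
        for i in (1, 2, 3):
            oper_tags += [f"matrix[{i}][{j}]" for j in (1, 2, 3)]
            oper_tags.append(f"vector[{i}]")
        loop = block.init_loop("_pdbx_struct_oper_list.", oper_tags)
        for row in oper_rows:
            loop.add_row(row)

    loop = block.init_loop(
        "_atom_site.",
        [
            "group_PDB", "id", "type_symbol", "label_atom_id", "label_alt_id",
            "label_comp_id", "label_asym_id", "label_entity_id", "label_seq_id",
            "pdbx_PDB_ins_code", "Cartn_x", "Cartn_y", "Cartn_z", "occupancy",
            "B_iso_or_equiv", "auth_seq_id", "auth_asym_id", "pdbx_PDB_model_num",
        ],
    )
    serial = 0
    for res in structure.residues:
        if res.locator.operator_id != "1":
            continue
        comp = _TOKEN_TO_COMP.get(res.code, "UNK")
        for name in res.atoms:
            serial += 1
            xyz = res.atoms[name]
            loop.add_row(
                [
                    "ATOM",
                    str(serial),
                    _guess_element(name),
                    gemmi.cif.quote(name),
                    ".",
                    comp,
                    res.locator.chain_id,
                    "1",
                    str(res.locator.seq_id),
                    "?",
                    f"{xyz[0]:.3f}",
                    f"{xyz[1]:.3f}",
                    f"{xyz[2]:.3f}",
                    "1.00",
                    "0.00",
                    str(res.auth_seq_id if res.auth_seq_id is not None else res.locator.seq_id),
                    res.auth_chain_id or res.locator.chain_id,
                    "1",
                ]
            )
    doc.write_file(os.fspath(path))
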