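"""File-system-backed word-level inverted index and residue coordinate store.

The index maps a packed descriptor key (a "word") to the structures
("documents") containing a residue pair with that descriptor and to the exact
positions of those pairs. Each descriptor bin is one file under a two-level
fan-out directory; payloads are a compact binary framing with interned
chain/operator tokens and flat integer arrays, so a lookup touches exactly
the files of the bins it needs.

The coordinate store keeps one file per structure with a per-residue offset
table, so scoring can fetch the handful of candidate residues of a large
structure without reading its siblings. Stored coordinates are rounded to
0.1 Å, which has negligible effect on motif RMSDs while keeping records
small.

Builds are atomic: everything is written to a temporary sibling directory
and published by a single rename. Incremental updates rewrite only the bins
touched by the new structures and are bin-for-bin equivalent to a fresh
build over the union corpus.
"""

from __future__ import annotations

import hashlib
import json
import os
import shutil
import struct
import tempfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .descriptors import (
    DescriptorKey,
    Occurrence,
    PairEnumerationReport,
    decode_key,
    encode_key,
    enumerate_pairs,
)
from .errors import (
    DuplicateStructureError,
    IndexIntegrityError,
    MissingResidueError,
    StrucmotifError,
)
from .structures import Residue, ResidueLocator, Structure, reconstruct_gly_cb

__all__ = [
    "IndexManifest",
    "InvertedIndex",
    "CoordinateStore",
    "build_index",
    "update_index",
    "lookup",
    "index_stats",
    "fetch_residues",
]

SCHEMA_VERSION = 1
_BIN_MAGIC = b"SMB1"
_COORD_MAGIC = b"SMC1"
_OCC_STRUCT = struct.Struct("<HHIHHIB")  # c1,o1,s1,c2,o2,s2,swapped


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

@dataclass
class IndexManifest:
    """Summary of an on-disk index."""

    indexed_ids: dict[str, str] = field(default_factory=dict)  # id -> ISO timestamp
    total_pairs: int = 0
    bin_count: int = 0
    schema_version: int = SCHEMA_VERSION
    checksum: str = ""

    def to_json(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "indexed_ids": self.indexed_ids,
            "total_pairs": self.total_pairs,
            "bin_count": self.bin_count,
            "checksum": self.checksum,
        }

    @classmethod
    def from_json(cls, data: dict) -> "IndexManifest":
        return cls(
            indexed_ids=dict(data["indexed_ids"]),
            total_pairs=int(data["total_pairs"]),
            bin_count=int(data["bin_count"]),
            schema_version=int(data["schema_version"]),
            checksum=data.get("checksum", ""),
        )


# ---------------------------------------------------------------------------
# bin payload codec
# ---------------------------------------------------------------------------

def _encode_postings(postings: Mapping[str, Sequence[Occurrence]]) -> bytes:
    """Serialize a bin's postings with interned chain/operator tokens."""
    tokens: list[str] = []
    token_idx: dict[str, int] = {}

    def intern(tok: str) -> int:
        if tok not in token_idx:
            token_idx[tok] = len(tokens)
            tokens.append(tok)
        return token_idx[tok]

    body = bytearray()
    sids = sorted(postings)
    for sid in sids:
        occs = sorted(set(postings[sid]))
        sid_b = sid.encode()
        body += struct.pack("<H", len(sid_b)) + sid_b
        body += struct.pack("<I", len(occs))
        for occ in occs:
            body += _OCC_STRUCT.pack(
                intern(occ.first.chain_id),
                intern(occ.first.operator_id),
                occ.first.seq_id,
                intern(occ.second.chain_id),
                intern(occ.second.operator_id),
                occ.second.seq_id,
                1 if occ.swapped else 0,
            )
    head = bytearray(_BIN_MAGIC)
    head += struct.pack("<I", len(tokens))
    for tok in tokens:
        tb = tok.encode()
        head += struct.pack("<B", len(tb)) + tb
    head += struct.pack("<I", len(sids))
    return bytes(head) + bytes(body)


def _decode_postings(blob: bytes, origin: str) -> dict[str, list[Occurrence]]:
    try:
        if blob[:4] != _BIN_MAGIC:
            raise ValueError("bad magic")
        off = 4
        (n_tokens,) = struct.unpack_from("<I", blob, off)
        off += 4
        tokens: list[str] = []
        for _ in range(n_tokens):
            (ln,) = struct.unpack_from("<B", blob, off)
            off += 1
            tokens.append(blob[off : off + ln].decode())
            off += ln
        (n_structs,) = struct.unpack_from("<I", blob, off)
        off += 4
        out: dict[str, list[Occurrence]] = {}
        for _ in range(n_structs):
            (sid_len,) = struct.unpack_from("<H", blob, off)
            off += 2
            sid = blob[off : off + sid_len].decode()
            off += sid_len
            (n_occ,) = struct.unpack_from("<I", blob, off)
            off += 4
            occs = []
            for _ in range(n_occ):
                c1, o1, s1, c2, o2, s2, sw = _OCC_STRUCT.unpack_from(blob, off)
                off += _OCC_STRUCT.size
                occs.append(
                    Occurrence(
                        ResidueLocator(tokens[c1], tokens[o1], s1),
                        ResidueLocator(tokens[c2], tokens[o2], s2),
                        bool(sw),
                    )
                )
            out[sid] = occs
        if off != len(blob):
            raise ValueError("trailing bytes")
        return out
    except (ValueError, struct.error, IndexError, UnicodeDecodeError) as exc:
        raise IndexIntegrityError(f"corrupt index bin file {origin}: {exc}") from exc


# ---------------------------------------------------------------------------
# coordinate store
# ---------------------------------------------------------------------------

def _encode_residue_record(res: Residue) -> bytes:
    body = bytearray()
    code_b = res.code.encode()
    body += struct.pack("<B", len(code_b)) + code_b
    body += struct.pack("<B", 0 if res.polymer_kind == "amino-acid" else 1)
    names = sorted(res.atoms)
    body += struct.pack("<H", len(names))
    for name in names:
        nb = name.encode()
        xyz = np.rint(np.asarray(res.atoms[name], dtype=float) * 10.0).astype(np.int32)
        body += struct.pack("<B", len(nb)) + nb
        body += struct.pack("<iii", int(xyz[0]), int(xyz[1]), int(xyz[2]))
    return bytes(body)


def _decode_residue_record(blob: bytes, locator: ResidueLocator) -> Residue:
    off = 0
    (cl,) = struct.unpack_from("<B", blob, off)
    off += 1
    code = blob[off : off + cl].decode()
    off += cl
    (kind_flag,) = struct.unpack_from("<B", blob, off)
    off += 1
    kind = "amino-acid" if kind_flag == 0 else "nucleotide"
    (n_atoms,) = struct.unpack_from("<H", blob, off)
    off += 2
    atoms: dict[str, np.ndarray] = {}
    for _ in range(n_atoms):
        (nl,) = struct.unpack_from("<B", blob, off)
        off += 1
        name = blob[off : off + nl].decode()
        off += nl
        x, y, z = struct.unpack_from("<iii", blob, off)
        off += 12
        atoms[name] = np.array([x, y, z], dtype=float) / 10.0
    if kind == "amino-acid":
        backbone = atoms["CA"]
        sidechain = atoms["CB"] if "CB" in atoms else reconstruct_gly_cb(
            atoms["N"], atoms["CA"], atoms["C"]
        )
    else:
        backbone = atoms["C4'"]
        sidechain = atoms["C1'"]
    return Residue(
        locator=locator,
        code=code,
        polymer_kind=kind,
        atoms=atoms,
        backbone_rep=backbone,
        sidechain_rep=sidechain,
    )


class CoordinateStore:
    """Per-structure residue records addressable without reading siblings.

    ``records_read`` counts individual residue records deserialized, so tests
    can verify that fetching a few residues of a large structure does not
    scan the whole file.
    """

    def __init__(self, root: str | os.PathLike):
        self.root = os.fspath(root)
        self._offset_cache: dict[str, dict[str, tuple[int, int]]] = {}
        self.records_read = 0

    def _path(self, structure_id: str) -> str:
        return os.path.join(self.root, f"{structure_id}.bin")

    def write_structure(self, structure: Structure) -> None:
        os.makedirs(self.root, exist_ok=True)
        records: list[tuple[str, bytes]] = []
        for res in structure.residues:
            records.append((res.locator.render(), _encode_residue_record(res)))
        index_entries = bytearray()
        data = bytearray()
        for key, blob in records:
            kb = key.encode()
            index_entries += struct.pack("<H", len(kb)) + kb
            index_entries += struct.pack("<QI", len(data), len(blob))
            data += blob
        head = bytearray(_COORD_MAGIC)
        head += struct.pack("<I", len(records))
        head += struct.pack("<Q", len(index_entries))
        with open(self._path(structure.structure_id), "wb") as fh:
            fh.write(bytes(head) + bytes(index_entries) + bytes(data))
        self._offset_cache.pop(structure.structure_id, None)

    def _load_offsets(self, structure_id: str) -> dict[str, tuple[int, int]]:
        if structure_id in self._offset_cache:
            return self._offset_cache[structure_id]
        path = self._path(structure_id)
        if not os.path.exists(path):
            raise MissingResidueError(f"structure {structure_id!r} not in coordinate store")
        with open(path, "rb") as fh:
            head = fh.read(16)
            if head[:4] != _COORD_MAGIC:
                raise IndexIntegrityError(f"corrupt coordinate file {path}")
            (n_records,) = struct.unpack_from("<I", head, 4)
            (idx_len,) = struct.unpack_from("<Q", head, 8)
            idx_blob = fh.read(idx_len)
        offsets: dict[str, tuple[int, int]] = {}
        off = 0
        data_start = 16 + idx_len
        for _ in range(n_records):
            (kl,) = struct.unpack_from("<H", idx_blob, off)
            off += 2
            key = idx_blob[off : off + kl].decode()
            off += kl
            rec_off, rec_len = struct.unpack_from("<QI", idx_blob, off)
            off += 12
            offsets[key] = (data_start + rec_off, rec_len)
        self._offset_cache[structure_id] = offsets
        return offsets

    def fetch_residues(
        self, structure_id: str, locators: Sequence[ResidueLocator]
    ) -> list[Residue]:
        """Fetch exactly the requested residues at stored (0.1 Å) precision."""
        if not locators:
            return []
        offsets = self._load_offsets(structure_id)
        out: list[Residue] = []
        with open(self._path(structure_id), "rb") as fh:
            for loc in locators:
                entry = offsets.get(loc.render())
                if entry is None:
                    raise MissingResidueError(
                        f"residue {loc.render()} not stored for {structure_id!r}"
                    )
                fh.seek(entry[0])
                blob = fh.read(entry[1])
                self.records_read += 1
                out.append(_decode_residue_record(blob, loc))
        return out

    def structure_ids(self) -> list[str]:
        if not os.path.isdir(self.root):
            return []
        return sorted(
            os.path.splitext(f)[0] for f in os.listdir(self.root) if f.endswith(".bin")
        )


# ---------------------------------------------------------------------------
# inverted index
# ---------------------------------------------------------------------------

def _bin_relpath(packed: int) -> str:
    return os.path.join("bins", f"{packed % 256:02x}", f"{packed}.bin")


def _write_tree(
    destination: str,
    bins: Mapping[int, Mapping[str, Sequence[Occurrence]]],
    structures: Iterable[Structure],
    manifest: IndexManifest,
) -> None:
    for packed in sorted(bins):
        rel = _bin_relpath(packed)
        path = os.path.join(destination, rel)
        os.makedirs(os.path.dirname(path), exist_ok=True)
        with open(path, "wb") as fh:
            fh.write(_encode_postings(bins[packed]))
    store = CoordinateStore(os.path.join(destination, "coords"))
    for st in structures:
        store.write_structure(st)
    _write_manifest(destination, manifest)


def _write_manifest(destination: str, manifest: IndexManifest) -> None:
    manifest.checksum = _tree_checksum(destination)
    tmp = os.path.join(destination, "manifest.json.tmp")
    with open(tmp, "w") as fh:
        json.dump(manifest.to_json(), fh, indent=1, sort_keys=True)
    os.replace(tmp, os.path.join(destination, "manifest.json"))


def _tree_checksum(destination: str) -> str:
    """Checksum over bin file names and sizes; detects partial writes."""
    h = hashlib.sha256()
    bins_root = os.path.join(destination, "bins")
    if os.path.isdir(bins_root):
        for sub in sorted(os.listdir(bins_root)):
            subdir = os.path.join(bins_root, sub)
            for name in sorted(os.listdir(subdir)):
                size = os.path.getsize(os.path.join(subdir, name))
                h.update(f"{sub}/{name}:{size};".encode())
    return h.hexdigest()


def _collect_bins(
    structures: Sequence[Structure],
) -> tuple[dict[int, dict[str, list[Occurrence]]], int]:
    bins: dict[int, dict[str, list[Occurrence]]] = {}
    total = 0
    for st in structures:
        for key, occ in enumerate_pairs(st):
            bins.setdefault(encode_key(key), {}).setdefault(st.structure_id, []).append(occ)
            total += 1
    return bins, total


class InvertedIndex:
    """Handle to an on-disk inverted index (bins + coordinate store + manifest)."""

    def __init__(self, root: str | os.PathLike):
        self.root = os.fspath(root)
        manifest_path = os.path.join(self.root, "manifest.json")
        if not os.path.exists(manifest_path):
            raise IndexIntegrityError(f"no manifest at {manifest_path}")
        with open(manifest_path) as fh:
            self.manifest = IndexManifest.from_json(json.load(fh))
        if self.manifest.schema_version != SCHEMA_VERSION:
            raise IndexIntegrityError(
                f"unsupported index schema {self.manifest.schema_version}"
            )
        self.store = CoordinateStore(os.path.join(self.root, "coords"))

    # -- construction -------------------------------------------------------

    @classmethod
    def build(
        cls, structures: Iterable[Structure], destination: str | os.PathLike
    ) -> "InvertedIndex":
        """Build a fresh index; writes to a temp sibling and publishes by rename."""
        destination = os.fspath(destination)
        structures = list(structures)
        ids = [st.structure_id for st in structures]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateStructureError(f"duplicate structure ids: {dupes}")
        if os.path.exists(destination) and os.listdir(destination):
            raise StrucmotifError(f"destination {destination} exists and is not empty")
        bins, total = _collect_bins(structures)
        now = datetime.now(timezone.utc).isoformat(timespec="seconds")
        manifest = IndexManifest(
            indexed_ids={sid: now for sid in sorted(ids)},
            total_pairs=total,
            bin_count=len(bins),
        )
        parent = os.path.dirname(os.path.abspath(destination)) or "."
        os.makedirs(parent, exist_ok=True)
        tmpdir = tempfile.mkdtemp(prefix=".index-build-", dir=parent)
        try:
            _write_tree(tmpdir, bins, structures, manifest)
            if os.path.exists(destination):
                os.rmdir(destination)
            os.replace(tmpdir, destination)
        except Exception:
            shutil.rmtree(tmpdir, ignore_errors=True)
            raise
        return cls(destination)

    def update(self, structures: Iterable[Structure], replace: bool = False) -> IndexManifest:
        """Incrementally add structures; equivalent to a fresh union build."""
        structures = list(structures)
        ids = [st.structure_id for st in structures]
        if len(set(ids)) != len(ids):
            raise DuplicateStructureError("duplicate structure ids within the update batch")
        colliding = [sid for sid in ids if sid in self.manifest.indexed_ids]
        if colliding and not replace:
            raise DuplicateStructureError(
                f"already indexed (pass replace=True to overwrite): {sorted(colliding)}"
            )
        if colliding:
            self._remove_structures(colliding)
        new_bins, total_added = _collect_bins(structures)
        for packed, postings in sorted(new_bins.items()):
            path = os.path.join(self.root, _bin_relpath(packed))
            merged: dict[str, list[Occurrence]]
            if os.path.exists(path):
                with open(path, "rb") as fh:
                    merged = _decode_postings(fh.read(), path)
            else:
                merged = {}
                os.makedirs(os.path.dirname(path), exist_ok=True)
            for sid, occs in postings.items():
                merged.setdefault(sid, []).extend(occs)
            tmp = path + ".tmp"
            with open(tmp, "wb") as fh:
                fh.write(_encode_postings(merged))
            os.replace(tmp, path)
        store = CoordinateStore(os.path.join(self.root, "coords"))
        for st in structures:
            store.write_structure(st)
        now = datetime.now(timezone.utc).isoformat(timespec="seconds")
        for sid in ids:
            self.manifest.indexed_ids[sid] = now
        self.manifest.total_pairs += total_added
        self.manifest.bin_count = self._count_bins()
        _write_manifest(self.root, self.manifest)
        return self.manifest

    def _remove_structures(self, ids: Sequence[str]) -> None:
        """Drop all postings and coordinates of the given structure ids."""
        drop = set(ids)
        removed_pairs = 0
        for packed in list(self.iter_bin_keys()):
            path = os.path.join(self.root, _bin_relpath(packed))
            with open(path, "rb") as fh:
                postings = _decode_postings(fh.read(), path)
            touched = drop & postings.keys()
            if not touched:
                continue
            for sid in touched:
                removed_pairs += len(postings.pop(sid))
            if postings:
                tmp = path + ".tmp"
                with open(tmp, "wb") as fh:
                    fh.write(_encode_postings(postings))
                os.replace(tmp, path)
            else:
                os.remove(path)
        for sid in drop:
            coord = os.path.join(self.root, "coords", f"{sid}.bin")
            if os.path.exists(coord):
                os.remove(coord)
            self.manifest.indexed_ids.pop(sid, None)
        self.manifest.total_pairs -= removed_pairs

    # -- queries ------------------------------------------------------------

    def lookup(self, key: DescriptorKey) -> dict[str, list[Occurrence]]:
        """Postings of one bin; empty mapping for an absent bin."""
        path = os.path.join(self.root, _bin_relpath(encode_key(key)))
        if not os.path.exists(path):
            return {}
        with open(path, "rb") as fh:
            return _decode_postings(fh.read(), path)

    def iter_bin_keys(self) -> Iterator[int]:
        bins_root = os.path.join(self.root, "bins")
        if not os.path.isdir(bins_root):
            return
        for sub in sorted(os.listdir(bins_root)):
            subdir = os.path.join(bins_root, sub)
            for name in sorted(os.listdir(subdir)):
                if name.endswith(".bin"):
                    yield int(name[:-4])

    def _count_bins(self) -> int:
        return sum(1 for _ in self.iter_bin_keys())

    def stats(self, top_n: int | None = None) -> pd.DataFrame:
        """Per-bin statistics, mirroring the shape of an index census table.

        Columns: descriptor, structures, occurrences; sorted descending by
        structure count, ties by occurrence count then descriptor key.
        """
        rows = []
        for packed in self.iter_bin_keys():
            path = os.path.join(self.root, _bin_relpath(packed))
            with open(path, "rb") as fh:
                postings = _decode_postings(fh.read(), path)
            rows.append(
                (
                    decode_key(packed).render(),
                    len(postings),
                    sum(len(v) for v in postings.values()),
                    packed,
                )
            )
        rows.sort(key=lambda r: (-r[1], -r[2], r[3]))
        df = pd.DataFrame(
            [(r[0], r[1], r[2]) for r in rows],
            columns=["descriptor", "structures", "occurrences"],
        )
        if top_n is not None:
            df = df.head(top_n).reset_index(drop=True)
        return df


# ---------------------------------------------------------------------------
# module-level operation surface
# ---------------------------------------------------------------------------

def build_index(
    structures: Iterable[Structure], destination: str | os.PathLike
) -> IndexManifest:
    return InvertedIndex.build(structures, destination).manifest


def update_index(
    index: InvertedIndex, structures: Iterable[Structure], replace: bool = False
) -> IndexManifest:
    return index.update(structures, replace=replace)


def lookup(index: InvertedIndex, key: DescriptorKey) -> dict[str, list[Occurrence]]:
    return index.lookup(key)


def index_stats(index: InvertedIndex, top_n: int | None = None) -> pd.DataFrame:
    return index.stats(top_n)


def fetch_residues(
    store: CoordinateStore, structure_id: str, locators: Sequence[ResidueLocator]
) -> list[Residue]:
    return store.fetch_residues(structure_id, locators)
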