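"""Rotation-invariant residue-pair descriptors and their binned integer keys.

A residue pair is summarised by three rigid-motion-invariant measurements
(Cα/Cβ geometry for amino acids, C4′/C1′ for nucleotides):

* ``d_b`` — distance between the two backbone representatives,
* ``d_s`` — distance between the two sidechain representatives,
* ``theta`` — angle between the two backbone→sidechain vectors.

Distances are binned at 1 Å, the angle at 20°; together with the two residue
type tokens (sorted lexicographically so the descriptor is order-free) this
gives a :class:`DescriptorKey`, bijectively packable into a single integer.
The rendered form is ``"<pair>-<db>-<ds>-<theta>"``, e.g. ``"HS-8-7-5"`` for
a histidine/serine pair with d_b in [8,9) Å, d_s in [7,8) Å and θ in
[100°,120°).

Pairs with d_b at or beyond 20 Å are not indexed; lookups consult a
(2t+1)³ neighborhood of bins at tolerance t so occurrences adjacent to a bin
border are not lost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, InvalidKeyError, OutOfRangeError
from .structures import AMINO_ONE_LETTER, NUCLEOTIDE_TOKENS, Residue, ResidueLocator, Structure

__all__ = [
    "PairGeometry",
    "DescriptorKey",
    "Occurrence",
    "TOKENS",
    "pair_geometry",
    "bin_descriptor",
    "encode_key",
    "decode_key",
    "neighbor_keys",
    "enumerate_pairs",
    "PairEnumerationReport",
    "DB_BINS",
    "DS_BINS",
    "THETA_BINS",
    "DISTANCE_CUTOFF",
]

#: All residue-type tokens, sorted; amino acids (upper case) sort before
#: nucleotides (lower case).
TOKENS: tuple[str, ...] = tuple(
    sorted(set(AMINO_ONE_LETTER.values()) | set(NUCLEOTIDE_TOKENS.values()))
)
_TOKEN_SET = frozenset(TOKENS)

#: Lexicographically ordered list of all sorted token pairs.
TYPE_PAIRS: tuple[str, ...] = tuple(
    TOKENS[i] + TOKENS[j]
    for i in range(len(TOKENS))
    for j in range(i, len(TOKENS))
)
_PAIR_INDEX: dict[str, int] = {p: i for i, p in enumerate(TYPE_PAIRS)}

DB_BINS = 20       # d_b in [0, 20) Å at 1 Å width
DS_BINS = 32       # d_s in [0, 32) Å at 1 Å width
THETA_BINS = 9     # theta in [0°, 180°] at 20° width; 180° clamps into bin 8
DISTANCE_CUTOFF = 20.0

_BIN_SPAN = DB_BINS * DS_BINS * THETA_BINS


@dataclass(frozen=True)
class PairGeometry:
    """The (d_b, d_s, theta) measurement of one residue pair."""

    d_b: float
    d_s: float
    theta: float  # degrees, in [0, 180]

    def __post_init__(self):
        if self.d_b < 0 or self.d_s < 0:
            raise ValueError("distances must be non-negative")
        if not (0.0 <= self.theta <= 180.0):
            raise ValueError(f"theta must be in [0, 180], got {self.theta}")


@dataclass(frozen=True, order=True)
class DescriptorKey:
    """Binned, type-tagged residue-pair descriptor."""

    type_pair: str
    db_bin: int
    ds_bin: int
    theta_bin: int

    def __post_init__(self):
        if self.type_pair not in _PAIR_INDEX:
            raise InvalidKeyError(f"unknown type pair {self.type_pair!r}")
        if not (0 <= self.db_bin < DB_BINS):
            raise InvalidKeyError(f"db_bin out of range: {self.db_bin}")
        if not (0 <= self.ds_bin < DS_BINS):
            raise InvalidKeyError(f"ds_bin out of range: {self.ds_bin}")
        if not (0 <= self.theta_bin < THETA_BINS):
            raise InvalidKeyError(f"theta_bin out of range: {self.theta_bin}")

    def render(self) -> str:
        return f"{self.type_pair}-{self.db_bin}-{self.ds_bin}-{self.theta_bin}"

    def __str__(self) -> str:  # pragma: no cover
        return self.render()

    @classmethod
    def parse(cls, text: str) -> "DescriptorKey":
        parts = text.split("-")
        if len(parts) != 4:
            raise InvalidKeyError(f"cannot parse descriptor key {text!r}")
        return cls(parts[0], int(parts[1]), int(parts[2]), int(parts[3]))


@dataclass(frozen=True, order=True)
class Occurrence:
    """Canonically ordered residue pair (first < second under locator order).

    ``swapped`` records the token orientation relative to the descriptor's
    sorted type pair: when False, ``first`` carries the lexicographically
    smaller token of the pair; when True it carries the larger one. It is
    ignored for ordering/equality so an occurrence remains the plain ordered
    locator pair.
    """

    first: ResidueLocator
    second: ResidueLocator
    swapped: bool = field(default=False, compare=False)

    def __post_init__(self):
        if not (self.first < self.second):
            raise ValueError("occurrence locators must satisfy first < second")


def pair_geometry(r1: Residue, r2: Residue) -> PairGeometry:
    """Measure (d_b, d_s, theta) for a residue pair.

    Invariant under rigid motion applied to both residues and symmetric in
    its arguments.
    """
    v1 = r1.sidechain_rep - r1.backbone_rep
    v2 = r2.sidechain_rep - r2.backbone_rep
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise DegenerateGeometryError(
            f"zero-length representative vector on {r1.locator.render()} or "
            f"{r2.locator.render()}"
        )
    d_b = float(np.linalg.norm(r1.backbone_rep - r2.backbone_rep))
    d_s = float(np.linalg.norm(r1.sidechain_rep - r2.sidechain_rep))
    cos_t = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    theta = math.degrees(math.acos(cos_t))
    return PairGeometry(d_b, d_s, theta)


def bin_descriptor(code1: str, code2: str, g: PairGeometry) -> DescriptorKey:
    """Bin a pair geometry into its descriptor key.

    Bins are left-closed/right-open floors (1 Å distances, 20° angles);
    θ = 180° clamps into the last bin. Raises :class:`OutOfRangeError` for
    pairs outside the indexable range (d_b ≥ 20 Å or d_s ≥ 32 Å).
    """
    if code1 not in _TOKEN_SET or code2 not in _TOKEN_SET:
        raise InvalidKeyError(f"unknown residue token in ({code1!r}, {code2!r})")
    if g.d_b >= DISTANCE_CUTOFF:
        raise OutOfRangeError(f"d_b = {g.d_b:.2f} Å beyond the {DISTANCE_CUTOFF:.0f} Å cutoff")
    ds_bin = int(g.d_s)  # floor for non-negative values
    if ds_bin >= DS_BINS:
        raise OutOfRangeError(f"d_s = {g.d_s:.2f} Å beyond the {DS_BINS} Å sidechain ceiling")
    db_bin = int(g.d_b)
    theta_bin = min(int(g.theta / 20.0), THETA_BINS - 1)
    pair = code1 + code2 if code1 <= code2 else code2 + code1
    return DescriptorKey(pair, db_bin, ds_bin, theta_bin)


def encode_key(key: DescriptorKey) -> int:
    """Pack a descriptor key into one integer.

    The encoding is strictly monotone in (type_pair, db_bin, ds_bin,
    theta_bin) lexicographic order and bijective over valid keys.
    """
    return (
        _PAIR_INDEX[key.type_pair] * _BIN_SPAN
        + key.db_bin * DS_BINS * THETA_BINS
        + key.ds_bin * THETA_BINS
        + key.theta_bin
    )


def decode_key(packed: int) -> DescriptorKey:
    """Inverse of :func:`encode_key`."""
    if not isinstance(packed, (int, np.integer)) or packed < 0:
        raise InvalidKeyError(f"not a packed descriptor key: {packed!r}")
    pair_idx, rest = divmod(int(packed), _BIN_SPAN)
    if pair_idx >= len(TYPE_PAIRS):
        raise InvalidKeyError(f"packed key {packed} out of range")
    db_bin, rest = divmod(rest, DS_BINS * THETA_BINS)
    ds_bin, theta_bin = divmod(rest, THETA_BINS)
    return DescriptorKey(TYPE_PAIRS[pair_idx], db_bin, ds_bin, theta_bin)


def neighbor_keys(key: DescriptorKey, tolerance: int) -> set[DescriptorKey]:
    """All keys whose three geometric bins each differ by at most `tolerance`.

    The type pair is unchanged; ranges are clamped, so away from range
    boundaries the set has (2t+1)³ elements.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    t = tolerance
    out: set[DescriptorKey] = set()
    for db in range(max(0, key.db_bin - t), min(DB_BINS - 1, key.db_bin + t) + 1):
        for ds in range(max(0, key.ds_bin - t), min(DS_BINS - 1, key.ds_bin + t) + 1):
            for th in range(max(0, key.theta_bin - t), min(THETA_BINS - 1, key.theta_bin + t) + 1):
                out.add(DescriptorKey(key.type_pair, db, ds, th))
    return out


@dataclass
class PairEnumerationReport:
    """Counts of pairs skipped while enumerating a structure."""

    yielded: int = 0
    skipped_out_of_range: int = 0
    skipped_degenerate: int = 0


def enumerate_pairs(
    structure: Structure,
    cutoff: float = DISTANCE_CUTOFF,
    report: PairEnumerationReport | None = None,
) -> Iterator[tuple[DescriptorKey, Occurrence]]:
    """Yield (key, occurrence) for every unordered residue pair with d_b < cutoff.

    Pairs are found with a k-d tree on the backbone representatives and
    include intra- and inter-chain pairs across all assembly copies.
    Degenerate and out-of-range pairs are skipped and counted in ``report``.
    """
    residues = structure.residues
    n = len(residues)
    if n < 2:
        return
    rep = report if report is not None else PairEnumerationReport()

    back = np.stack([r.backbone_rep for r in residues])
    side = np.stack([r.sidechain_rep for r in residues])
    vecs = side - back
    norms = np.linalg.norm(vecs, axis=1)

    tree = cKDTree(back)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return
    # canonical orientation by locator order, then globally sorted output
    order = np.array(
        [0 if residues[i].locator < residues[j].locator else 1 for i, j in pairs]
    )
    ii = np.where(order == 0, pairs[:, 0], pairs[:, 1])
    jj = np.where(order == 0, pairs[:, 1], pairs[:, 0])

    d_b = np.linalg.norm(back[ii] - back[jj], axis=1)
    d_s = np.linalg.norm(side[ii] - side[jj], axis=1)
    dots = np.einsum("ij,ij->i", vecs[ii], vecs[jj])
    denom = norms[ii] * norms[jj]

    entries = []
    for k in range(len(ii)):
        i, j = int(ii[k]), int(jj[k])
        if d_b[k] >= cutoff:
            # query_pairs uses <=; the index is strict
            rep.skipped_out_of_range += 1
            continue
        if denom[k] < 1e-9:
            rep.skipped_degenerate += 1
            continue
        cos_t = min(1.0, max(-1.0, dots[k] / denom[k]))
        theta = math.degrees(math.acos(cos_t))
        ds_bin = int(d_s[k])
        if ds_bin >= DS_BINS:
            rep.skipped_out_of_range += 1
            continue
        c1, c2 = residues[i].code, residues[j].code
        pair = c1 + c2 if c1 <= c2 else c2 + c1
        key = DescriptorKey(pair, int(d_b[k]), ds_bin, min(int(theta / 20.0), THETA_BINS - 1))
        swapped = c1 != c2 and c1 != pair[0]
        entries.append((key, Occurrence(residues[i].locator, residues[j].locator, swapped)))
    entries.sort()
    rep.yielded += len(entries)
    yield from entries
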