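"""Atom correspondences and quaternion-based least-squares RMSD scoring.

Hits are scored by superposing the candidate residues onto the query
residues. Because the search already established which residue fills which
query role, the atom correspondence is simply the intersection of atom names
per residue pair (restricted by the selected atom mode); no attempt is made
to resolve chemically ambiguous atom labels (e.g. the two ring branches of a
tyrosine). The optimal rigid superposition is found with the quaternion
characteristic-polynomial formulation, which always yields a proper rotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError
from .structures import Residue, ResidueLocator

__all__ = [
    "AtomPairing",
    "RigidTransform",
    "Hit",
    "ATOM_MODES",
    "atom_correspondence",
    "superpose_rmsd",
    "score_candidates",
    "hits_to_dataframe",
]

logger = logging.getLogger(__name__)

ATOM_MODES = ("all", "sidechain", "representatives")

#: Backbone atom names excluded in sidechain mode. For nucleotides the
#: sugar-phosphate moiety counts as backbone; C1' is kept with the base since
#: it is the sidechain representative.
_BACKBONE_AA = frozenset({"N", "CA", "C", "O", "OXT"})
_BACKBONE_NT = frozenset(
    {"P", "OP1", "OP2", "OP3", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'"}
)


@dataclass
class AtomPairing:
    """Paired coordinates (same length, same order) with their atom names."""

    query: np.ndarray  # (n, 3)
    hit: np.ndarray    # (n, 3)
    names: list[str]

    def __len__(self) -> int:
        return len(self.names)

    @classmethod
    def concatenate(cls, fragments: Sequence["AtomPairing"]) -> "AtomPairing":
        frags = [f for f in fragments if len(f)]
        if not frags:
            return cls(np.empty((0, 3)), np.empty((0, 3)), [])
        return cls(
            np.concatenate([f.query for f in frags]),
            np.concatenate([f.hit for f in frags]),
            [n for f in frags for n in f.names],
        )


@dataclass
class RigidTransform:
    """Proper rigid transform x -> R @ x + t (maps hit coordinates onto the query)."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class Hit:
    """A scored motif match."""

    structure_id: str
    assignment: dict[int, ResidueLocator]
    rmsd: float
    transform: RigidTransform
    atom_count: int
    atom_mode: str

    def rendered_assignment(self) -> str:
        return ",".join(self.assignment[r].render() for r in sorted(self.assignment))

    def sort_key(self):
        return (self.rmsd, self.structure_id, self.rendered_assignment())


def _backbone_names(kind: str) -> frozenset[str]:
    return _BACKBONE_AA if kind == "amino-acid" else _BACKBONE_NT


def atom_correspondence(
    query_residue: Residue, hit_residue: Residue, mode: str = "sidechain"
) -> AtomPairing:
    """Pair atoms of a query/hit residue pair.

    ``all`` pairs every atom name present in both residues (hydrogens are
    already absent from the model); ``sidechain`` restricts to non-backbone
    names; ``representatives`` pairs exactly the backbone and sidechain
    representative points. When residue types differ (an exchange match) only
    the shared names pair, per plain name intersection.
    """
    if mode not in ATOM_MODES:
        raise ValueError(f"unknown atom mode {mode!r}; choose from {ATOM_MODES}")
    if mode == "representatives":
        return AtomPairing(
            np.stack([query_residue.backbone_rep, query_residue.sidechain_rep]),
            np.stack([hit_residue.backbone_rep, hit_residue.sidechain_rep]),
            ["<backbone_rep>", "<sidechain_rep>"],
        )
    shared = sorted(set(query_residue.atoms) & set(hit_residue.atoms))
    if mode == "sidechain":
        excluded = _backbone_names(query_residue.polymer_kind) | _backbone_names(
            hit_residue.polymer_kind
        )
        shared = [n for n in shared if n not in excluded]
    if not shared:
        return AtomPairing(np.empty((0, 3)), np.empty((0, 3)), [])
    return AtomPairing(
        np.stack([query_residue.atoms[n] for n in shared]),
        np.stack([hit_residue.atoms[n] for n in shared]),
        list(shared),
    )


def superpose_rmsd(pairing: AtomPairing) -> tuple[float, RigidTransform]:
    """Globally optimal rigid-superposition RMSD via the quaternion method.

    Builds the 4x4 quaternion key matrix from the cross-covariance of the
    centered coordinate sets; the largest eigenvalue gives the minimal
    residual and its eigenvector the optimal proper rotation (hit -> query).
    """
    n = len(pairing)
    if n < 3:
        raise DegenerateGeometryError(f"need at least 3 atom pairs, got {n}")
    a = np.asarray(pairing.query, dtype=float)  # target
    b = np.asarray(pairing.hit, dtype=float)    # moving
    ac = a.mean(axis=0)
    bc = b.mean(axis=0)
    am = a - ac
    bm = b - bc
    # both sets collinear -> rotation about the common axis is unconstrained
    if np.linalg.svd(am, compute_uv=False)[1] < 1e-9 and (
        np.linalg.svd(bm, compute_uv=False)[1] < 1e-9
    ):
        raise DegenerateGeometryError("all atom pairs are collinear")

    s = bm.T @ am  # cross-covariance, moving vs target
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(key)
    lam = eigvals[-1]
    q = eigvecs[:, -1]  # unit quaternion (w, x, y, z) rotating moving onto target
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    del lam  # the eigenvalue also encodes the residual, but evaluating the
    # deviation of the realized superposition is numerically stabler when the
    # optimum is (near) zero, where the eigenvalue route loses ~half the digits
    translation = ac - rot @ bc
    moved = bm @ rot.T
    rmsd = float(np.sqrt(((moved - am) ** 2).sum() / n))
    return rmsd, RigidTransform(rot, translation)


def score_candidates(
    candidates,
    query,
    store,
    atom_mode: str = "sidechain",
    rmsd_cutoff: float | None = None,
) -> list[Hit]:
    """Score assembled candidates against the query by superposition RMSD.

    ``query`` provides the reference residues and allowed tokens per role
    (``query.residues`` with ``.role``, ``.residue``, ``.tokens``); ``store``
    is the coordinate store the candidate residues are fetched from. Hits
    above ``rmsd_cutoff`` are dropped; the result is sorted ascending by RMSD
    with a deterministic tie-break (structure id, then assignment).
    """
    hits: list[Hit] = []
    roles = sorted(q.role for q in query.residues)
    by_role = {q.role: q for q in query.residues}
    for cand in candidates:
        amap = dict(cand.assignment)
        locators = [amap[r] for r in roles]
        try:
            residues = store.fetch_residues(cand.structure_id, locators)
        except Exception as exc:  # missing residues: skip this candidate
            logger.warning(
                "skipping candidate in %s (%s): %s",
                cand.structure_id,
                ",".join(l.render() for l in locators),
                exc,
            )
            continue
        compatible = all(
            res.code in by_role[r].tokens for r, res in zip(roles, residues)
        )
        if not compatible:
            continue
        fragments = [
            atom_correspondence(by_role[r].residue, res, atom_mode)
            for r, res in zip(roles, residues)
        ]
        if any(len(f) == 0 for f in fragments):
            logger.warning(
                "empty atom correspondence for candidate in %s; skipped",
                cand.structure_id,
            )
            continue
        pairing = AtomPairing.concatenate(fragments)
        try:
            rmsd, transform = superpose_rmsd(pairing)
        except DegenerateGeometryError as exc:
            logger.warning("degenerate candidate in %s: %s", cand.structure_id, exc)
            continue
        if rmsd_cutoff is not None and rmsd > rmsd_cutoff:
            continue
        hits.append(
            Hit(
                structure_id=cand.structure_id,
                assignment=amap,
                rmsd=rmsd,
                transform=transform,
                atom_count=len(pairing),
                atom_mode=atom_mode,
            )
        )
    hits.sort(key=Hit.sort_key)
    return hits


def hits_to_dataframe(hits: Sequence[Hit]):
    """Tabular hit list: id, assignment, rmsd (3 decimals), atom count/mode,
    and the 12 components of the hit->query transform."""
    import pandas as pd

    rows = []
    for h in hits:
        row = {
            "structure_id": h.structure_id,
            "assignment": h.rendered_assignment(),
            "rmsd": round(h.rmsd, 3),
            "atom_count": h.atom_count,
            "atom_mode": h.atom_mode,
        }
        for i in range(3):
            for j in range(3):
                row[f"r{i+1}{j+1}"] = h.transform.rotation[i, j]
            row[f"t{i+1}"] = h.transform.translation[i]
        rows.append(row)
    columns = ["structure_id", "assignment", "rmsd", "atom_count", "atom_mode"] + [
        f"r{i+1}{j+1}" for i in range(3) for j in range(3)
    ] + ["t1", "t2", "t3"]
    return pd.DataFrame(rows, columns=columns)
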