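"""Exhaustive (index-free) reference search.

Enumerates every injective role→residue assignment directly from structure
objects and keeps those whose every admissible query pair falls within the
bin tolerance of the query geometry. It deliberately shares no retrieval or
assembly machinery with the inverted-index path — geometry and bin arithmetic
are recomputed inline from first principles — so it can serve as an
independent reference when validating the indexed search, in the spirit of
comparing against an exhaustive search tool. It is exact but quadratic per
structure and has no place in production searching.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Sequence

import numpy as np

from .structures import Residue, ResidueLocator, Structure

__all__ = ["exhaustive_candidates", "exhaustive_corpus_candidates"]

_DB_CUTOFF = 20.0
_DS_CEILING = 32.0
_THETA_LAST_BIN = 8


def _bins(r1: Residue, r2: Residue) -> tuple[int, int, int] | None:
    """Floor bins of a residue pair, or None when not indexable."""
    d_b = float(np.linalg.norm(r1.backbone_rep - r2.backbone_rep))
    if d_b >= _DB_CUTOFF:
        return None
    d_s = float(np.linalg.norm(r1.sidechain_rep - r2.sidechain_rep))
    if d_s >= _DS_CEILING:
        return None
    v1 = r1.sidechain_rep - r1.backbone_rep
    v2 = r2.sidechain_rep - r2.backbone_rep
    n1 = float(np.linalg.norm(v1))
    n2 = float(np.linalg.norm(v2))
    if n1 < 1e-9 or n2 < 1e-9:
        return None
    cos_t = min(1.0, max(-1.0, float(np.dot(v1, v2)) / (n1 * n2)))
    theta = math.degrees(math.acos(cos_t))
    return (int(d_b), int(d_s), min(int(theta / 20.0), _THETA_LAST_BIN))


def exhaustive_candidates(
    structure: Structure, query, tolerance: int = 1, edges=None
) -> list[tuple[int, ...]]:
    """All accepted assignments in one structure, as residue indices per role.

    ``query`` needs ``.residues`` (with ``.role``, ``.tokens``, ``.residue``)
    and ``.edges`` (with ``.role_a``, ``.role_b``); i.e. a
    :class:`~strucmotif.search.MotifQuery`. ``edges`` selects which query
    pairs are enforced (defaults to all admissible pairs; pass a pruned edge
    list to mirror a pruned search). Returns sorted tuples of indices into
    ``structure.residues`` ordered by role.
    """
    roles = sorted(q.role for q in query.residues)
    by_role = {q.role: q for q in query.residues}
    # reference bins per enforced edge
    edge_bins = {}
    for edge in (query.edges if edges is None else edges):
        ref = _bins(by_role[edge.role_a].residue, by_role[edge.role_b].residue)
        if ref is None:
            continue
        edge_bins[(edge.role_a, edge.role_b)] = ref

    # candidate residues per role by token
    residues = structure.residues
    per_role: dict[int, list[int]] = {}
    for role in roles:
        allowed = set(by_role[role].tokens)
        per_role[role] = [i for i, r in enumerate(residues) if r.code in allowed]
        if not per_role[role]:
            return []

    accepted: list[tuple[int, ...]] = []
    for combo in itertools.product(*(per_role[r] for r in roles)):
        if len(set(combo)) != len(combo):
            continue
        picked = dict(zip(roles, combo))
        ok = True
        for (ra, rb), ref in edge_bins.items():
            got = _bins(residues[picked[ra]], residues[picked[rb]])
            if got is None or any(abs(g - q) > tolerance for g, q in zip(got, ref)):
                ok = False
                break
        if ok:
            accepted.append(combo)
    accepted.sort()
    return accepted


def exhaustive_corpus_candidates(
    structures: Iterable[Structure], query, tolerance: int = 1, edges=None
) -> dict[str, list[tuple[str, ...]]]:
    """Accepted assignments per structure, rendered as locator strings."""
    out: dict[str, list[tuple[str, ...]]] = {}
    for st in structures:
        combos = exhaustive_candidates(st, query, tolerance, edges)
        if combos:
            out[st.structure_id] = [
                tuple(st.residues[i].locator.render() for i in combo)
                for combo in combos
            ]
    return out
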