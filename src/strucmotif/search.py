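"""Motif queries: fragmentation, index retrieval and candidate assembly.

A motif query is a small set of residue *roles* taken from a reference
structure, each with one or more allowed residue types (position-specific
exchanges). The query graph is fragmented into residue pairs; for motifs of
four or more residues the n(n−1)/2 pairs are pruned to the n−1 edges of a
minimum spanning tree (Kruskal, weighted by the reference backbone distance),
since the pairwise constraints are transitive and fewer index lookups mean
fewer reads and fewer chances to lose borderline hits.

For each retained edge, all descriptor keys within the bin tolerance are
retrieved from the inverted index; a structure is rejected outright when any
edge has no postings for it. Surviving structures are searched for injective
role→residue assignments in which every edge is witnessed by a retrieved
occurrence with compatible residue types — a subgraph-matching step done by
depth-first backtracking over the query edges. Candidates are then scored by
superposition RMSD using only the residues actually assigned; geometric
distortion in pairs dropped by the MST pruning surfaces there and is removed
by the RMSD cutoff.
"""

from __future__ import annotations

import itertools
import json
import time
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx

from .descriptors import (
    DescriptorKey,
    PairGeometry,
    bin_descriptor,
    neighbor_keys,
    pair_geometry,
)
from .errors import MotifTooExtendedError, OutOfRangeError, QueryError
from .index import InvertedIndex
from .scoring import Hit, score_candidates
from .structures import Residue, ResidueLocator, Structure, select_residues

__all__ = [
    "QueryResidue",
    "QueryEdge",
    "MotifQuery",
    "Candidate",
    "SearchParameters",
    "SearchReport",
    "SearchResult",
    "define_query",
    "fragment_query",
    "assemble_candidates",
    "run_search",
]


@dataclass(frozen=True)
class QueryResidue:
    """One motif role: a reference residue plus its allowed residue tokens."""

    role: int
    locator: ResidueLocator
    tokens: tuple[str, ...]
    residue: Residue


@dataclass(frozen=True)
class QueryEdge:
    """An admissible residue pair of the query with its reference geometry."""

    role_a: int
    role_b: int
    geometry: PairGeometry

    def __post_init__(self):
        if not self.role_a < self.role_b:
            raise ValueError("edge roles must satisfy role_a < role_b")


@dataclass
class MotifQuery:
    """A fully specified motif query."""

    reference_id: str
    residues: list[QueryResidue]
    edges: list[QueryEdge]  # all admissible pairs, before pruning

    @property
    def n(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Candidate:
    """An injective role -> locator assignment within one structure."""

    structure_id: str
    assignment: tuple[tuple[int, ResidueLocator], ...]  # sorted by role

    def as_dict(self) -> dict[int, ResidueLocator]:
        return dict(self.assignment)


@dataclass(frozen=True)
class SearchParameters:
    """Search-time knobs.

    tolerance: how many neighboring bins per geometric measure are consulted
    (default 1, i.e. three bins per measure); rmsd_cutoff in Å (None keeps
    all hits); atom_mode selects the atoms scored; max_hits truncates the
    sorted hit list.
    """

    tolerance: int = 1
    rmsd_cutoff: float | None = None
    atom_mode: str = "sidechain"
    max_hits: int | None = None

    def __post_init__(self):
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")
        if self.rmsd_cutoff is not None and self.rmsd_cutoff <= 0:
            raise ValueError("rmsd_cutoff must be positive when set")


@dataclass
class SearchReport:
    """What the search touched and rejected."""

    structures_indexed: int = 0
    structures_with_postings: int = 0
    structures_rejected: int = 0
    candidates: int = 0
    hits: int = 0
    bins_read: int = 0
    elapsed_s: float = 0.0


@dataclass
class SearchResult:
    hits: list[Hit]
    report: SearchReport


# ---------------------------------------------------------------------------
# query definition and pruning
# ---------------------------------------------------------------------------

def define_query(
    reference: Structure,
    selectors: Sequence,
    exchanges: Mapping[int, Sequence[str]] | None = None,
) -> MotifQuery:
    """Build a motif query from reference residues and optional exchanges.

    ``exchanges`` maps a role index (position in ``selectors``) to extra
    allowed residue tokens at that position. All admissible pair geometries
    (backbone distance below the indexing cutoff) are computed here; if the
    admissible-pair graph does not connect every role the motif is too
    extended to be represented by indexable residue pairs.
    """
    residues = select_residues(reference, selectors)
    n = len(residues)
    if n < 2:
        raise QueryError(f"a motif query needs at least 2 residues, got {n}")
    exchanges = {int(k): v for k, v in (exchanges or {}).items()}
    unknown = sorted(set(exchanges) - set(range(n)))
    if unknown:
        raise QueryError(f"exchange roles out of range: {unknown}")

    query_residues: list[QueryResidue] = []
    for role, res in enumerate(residues):
        tokens = [res.code]
        for extra in exchanges.get(role, ()):  # preserve author order, dedup
            if extra not in tokens:
                tokens.append(extra)
        query_residues.append(
            QueryResidue(role, res.locator, tuple(tokens), res)
        )

    edges: list[QueryEdge] = []
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for a, b in itertools.combinations(range(n), 2):
        geom = pair_geometry(residues[a], residues[b])
        try:
            # binnability check under every allowed token combination
            for ta, tb in itertools.product(
                query_residues[a].tokens, query_residues[b].tokens
            ):
                bin_descriptor(ta, tb, geom)
        except OutOfRangeError:
            continue
        edges.append(QueryEdge(a, b, geom))
        graph.add_edge(a, b)
    if not nx.is_connected(graph):
        parts = [sorted(c) for c in nx.connected_components(graph)]
        raise MotifTooExtendedError(
            "query roles cannot all be joined by residue pairs within the "
            f"distance cutoff; disconnected groups: {parts}"
        )
    return MotifQuery(reference.structure_id, query_residues, edges)


def fragment_query(query: MotifQuery) -> list[QueryEdge]:
    """Select the edges actually used for index retrieval.

    Motifs of 2 or 3 residues keep all admissible pairs; larger motifs are
    pruned to the minimum spanning tree of the admissible-pair graph
    (Kruskal), weighted by the reference backbone distance with a
    deterministic lexicographic tie-break on the role-index pair.
    """
    if query.n <= 3:
        return list(query.edges)
    ordered = sorted(query.edges, key=lambda e: (e.geometry.d_b, e.role_a, e.role_b))
    parent = list(range(query.n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    mst: list[QueryEdge] = []
    for edge in ordered:
        ra, rb = find(edge.role_a), find(edge.role_b)
        if ra != rb:
            parent[ra] = rb
            mst.append(edge)
        if len(mst) == query.n - 1:
            break
    mst.sort(key=lambda e: (e.role_a, e.role_b))
    return mst


# ---------------------------------------------------------------------------
# retrieval and assembly
# ---------------------------------------------------------------------------

def _edge_key_plan(
    query: MotifQuery, edge: QueryEdge, tolerance: int
) -> dict[DescriptorKey, list[tuple[str, str]]]:
    """Map each lookup key of an edge to the token combos that produced it."""
    tokens_a = query.residues[edge.role_a].tokens
    tokens_b = query.residues[edge.role_b].tokens
    plan: dict[DescriptorKey, list[tuple[str, str]]] = {}
    for ta, tb in itertools.product(tokens_a, tokens_b):
        base = bin_descriptor(ta, tb, edge.geometry)
        for key in neighbor_keys(base, tolerance):
            combos = plan.setdefault(key, [])
            if (ta, tb) not in combos:
                combos.append((ta, tb))
    return plan


def assemble_candidates(
    index: InvertedIndex,
    edges: Sequence[QueryEdge],
    query: MotifQuery,
    params: SearchParameters = SearchParameters(),
    report: SearchReport | None = None,
) -> list[Candidate]:
    """All injective role assignments witnessed by retrieved occurrences.

    Structures missing postings for any edge are rejected before any
    per-structure work; the remaining structures are searched by depth-first
    backtracking over the query edges (ordered so each edge extends an
    already-anchored role when possible).
    """
    if not edges:
        raise QueryError("no query edges to search with")
    rep = report if report is not None else SearchReport()
    rep.structures_indexed = len(index.manifest.indexed_ids)

    key_cache: dict[DescriptorKey, dict] = {}

    # per edge: structure_id -> oriented (loc_for_role_a, loc_for_role_b) pairs
    edge_occurrences: list[dict[str, set[tuple[ResidueLocator, ResidueLocator]]]] = []
    for edge in edges:
        plan = _edge_key_plan(query, edge, params.tolerance)
        per_structure: dict[str, set[tuple[ResidueLocator, ResidueLocator]]] = {}
        for key, combos in plan.items():
            if key not in key_cache:
                key_cache[key] = index.lookup(key)
                rep.bins_read += 1
            postings = key_cache[key]
            t_small, t_large = key.type_pair[0], key.type_pair[1]
            for sid, occs in postings.items():
                bucket = per_structure.setdefault(sid, set())
                for occ in occs:
                    t_first = t_large if occ.swapped else t_small
                    t_second = t_small if occ.swapped else t_large
                    for ta, tb in combos:
                        if t_first == ta and t_second == tb:
                            bucket.add((occ.first, occ.second))
                        if t_first == tb and t_second == ta:
                            bucket.add((occ.second, occ.first))
        edge_occurrences.append(per_structure)

    survivors = set(edge_occurrences[0])
    for per_structure in edge_occurrences[1:]:
        survivors &= per_structure.keys()
    rep.structures_with_postings = len(survivors)
    rep.structures_rejected = rep.structures_indexed - len(survivors)

    # order edges so that after the first, each edge touches an assigned role
    edge_order = _connected_edge_order(edges)

    candidates: list[Candidate] = []
    for sid in sorted(survivors):
        tables = [edge_occurrences[i][sid] for i in edge_order]
        ordered_edges = [edges[i] for i in edge_order]
        found: list[dict[int, ResidueLocator]] = []
        _backtrack(ordered_edges, tables, 0, {}, set(), found)
        for assignment in found:
            candidates.append(
                Candidate(sid, tuple(sorted(assignment.items())))
            )
    # deterministic, duplicate-free output
    candidates = sorted(set(candidates), key=lambda c: (c.structure_id, c.assignment))
    rep.candidates = len(candidates)
    return candidates


def _connected_edge_order(edges: Sequence[QueryEdge]) -> list[int]:
    remaining = set(range(len(edges)))
    order: list[int] = []
    anchored: set[int] = set()
    while remaining:
        pick = None
        for i in sorted(remaining):
            if not order or edges[i].role_a in anchored or edges[i].role_b in anchored:
                pick = i
                break
        if pick is None:  # disconnected edge set; start a new component
            pick = min(remaining)
        order.append(pick)
        anchored.update((edges[pick].role_a, edges[pick].role_b))
        remaining.remove(pick)
    return order


def _backtrack(
    edges: Sequence[QueryEdge],
    tables: Sequence[set[tuple[ResidueLocator, ResidueLocator]]],
    depth: int,
    assignment: dict[int, ResidueLocator],
    used: set[ResidueLocator],
    found: list[dict[int, ResidueLocator]],
) -> None:
    if depth == len(edges):
        found.append(dict(assignment))
        return
    edge = edges[depth]
    table = tables[depth]
    a_loc = assignment.get(edge.role_a)
    b_loc = assignment.get(edge.role_b)
    if a_loc is not None and b_loc is not None:
        if (a_loc, b_loc) in table:
            _backtrack(edges, tables, depth + 1, assignment, used, found)
        return
    for la, lb in sorted(table):
        if a_loc is not None and la != a_loc:
            continue
        if b_loc is not None and lb != b_loc:
            continue
        if la == lb:
            continue
        new_roles = []
        if a_loc is None:
            if la in used:
                continue
            assignment[edge.role_a] = la
            used.add(la)
            new_roles.append((edge.role_a, la))
        if b_loc is None:
            if lb in used:  # injectivity: no residue fills two roles
                for role, loc in new_roles:
                    del assignment[role]
                    used.discard(loc)
                continue
            assignment[edge.role_b] = lb
            used.add(lb)
            new_roles.append((edge.role_b, lb))
        _backtrack(edges, tables, depth + 1, assignment, used, found)
        for role, loc in new_roles:
            del assignment[role]
            used.discard(loc)


# ---------------------------------------------------------------------------
# end-to-end search
# ---------------------------------------------------------------------------

def run_search(
    index: InvertedIndex,
    query: MotifQuery,
    params: SearchParameters = SearchParameters(),
    store=None,
) -> SearchResult:
    """Fragment, retrieve, assemble and score a motif query end to end.

    Only the residues of assembled candidates are fetched from the
    coordinate store (``store`` defaults to the index's own).
    """
    t0 = time.perf_counter()
    store = store if store is not None else index.store
    report = SearchReport()
    edges = fragment_query(query)
    candidates = assemble_candidates(index, edges, query, params, report)
    hits = score_candidates(
        candidates,
        query,
        store,
        atom_mode=params.atom_mode,
        rmsd_cutoff=params.rmsd_cutoff,
    )
    if params.max_hits is not None:
        hits = hits[: params.max_hits]
    report.hits = len(hits)
    report.elapsed_s = time.perf_counter() - t0
    return SearchResult(hits, report)


# ---------------------------------------------------------------------------
# query (de)serialization — JSON schema used by the CLI and examples
# ---------------------------------------------------------------------------

def query_spec_to_json(
    reference_path: str,
    fmt: str,
    assembly: str | None,
    selectors: Sequence[Mapping],
    exchanges: Mapping[int, Sequence[str]] | None = None,
) -> dict:
    """Build the JSON document describing a query (see docs/methods.md)."""
    return {
        "reference": {"path": reference_path, "format": fmt, "assembly": assembly},
        "selectors": [dict(s) for s in selectors],
        "exchanges": {str(k): list(v) for k, v in (exchanges or {}).items()},
    }


def load_query_file(path: str) -> tuple[dict, dict]:
    """Read a query JSON file; returns (reference spec, parsed fields)."""
    with open(path) as fh:
        doc = json.load(fh)
    for field_name in ("reference", "selectors"):
        if field_name not in doc:
            raise QueryError(f"query file missing {field_name!r}")
    return doc["reference"], {
        "selectors": doc["selectors"],
        "exchanges": {int(k): v for k, v in doc.get("exchanges", {}).items()},
    }
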