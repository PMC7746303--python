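"""Query definition, MST pruning, candidate assembly and end-to-end search."""

import itertools

import numpy as np
import pytest

from strucmotif.errors import MotifTooExtendedError, QueryError
from strucmotif.exhaustive import exhaustive_candidates
from strucmotif.index import InvertedIndex
from strucmotif.scoring import Hit
from strucmotif.search import (
    SearchParameters,
    assemble_candidates,
    define_query,
    fragment_query,
    run_search,
)
from strucmotif.structures import ResidueLocator, Structure
from strucmotif.synthetic import (
    PlantSpec,
    generate_structure,
    make_benchmark_corpus,
    make_triad_motif,
    plant_motif,
)

from conftest import truth_assignments


def _label_selectors(n):
    return [("A", "1", i + 1) for i in range(n)]


def _quad_reference():
    """A 4-residue query reference carved from a random chain."""
    chain = generate_structure(30, seed=21, structure_id="quadref")
    picks = [chain.residues[i] for i in (2, 5, 9, 14)]
    # compact enough that all pairs are admissible?  not necessarily; the
    # define_query contract only needs a connected admissible graph
    return Structure("quadref", picks, "asymmetric-unit"), [
        ("A", "1", r.locator.seq_id) for r in picks
    ]


class TestDefineQuery:
    def test_triad_query_has_three_admissible_pairs(self, triad_reference):
        query = define_query(triad_reference, _label_selectors(3))
        assert query.n == 3
        assert len(query.edges) == 3
        assert [q.tokens for q in query.residues] == [("H",), ("D",), ("S",)]

    def test_exchanges_extend_tokens(self, triad_reference):
        query = define_query(
            triad_reference,
            _label_selectors(3),
            exchanges={0: ["K"], 2: ["T", "S"]},
        )
        assert query.residues[0].tokens == ("H", "K")
        assert query.residues[1].tokens == ("D",)
        assert query.residues[2].tokens == ("S", "T")

    def test_single_residue_rejected(self, triad_reference):
        with pytest.raises(QueryError):
            define_query(triad_reference, [("A", "1", 1)])

    def test_too_extended_motif_rejected(self):
        a = generate_structure(1, seed=1, structure_id="far").residues[0]
        b_src = generate_structure(1, seed=2, structure_id="farb").residues[0]
        shifted = {n: xyz + np.array([30.0, 0, 0]) for n, xyz in b_src.atoms.items()}
        from strucmotif.structures import Residue

        b = Residue(
            locator=ResidueLocator("A", "1", 2),
            code=b_src.code,
            polymer_kind="amino-acid",
            atoms=shifted,
            backbone_rep=b_src.backbone_rep + np.array([30.0, 0, 0]),
            sidechain_rep=b_src.sidechain_rep + np.array([30.0, 0, 0]),
        )
        ref = Structure("far2", [a, b])
        with pytest.raises(MotifTooExtendedError):
            define_query(ref, _label_selectors(2))


class TestFragmentQuery:
    def test_pair_query_keeps_single_edge(self, triad_reference):
        two = Structure("duo", triad_reference.residues[:2])
        query = define_query(two, _label_selectors(2))
        assert len(fragment_query(query)) == 1

    def test_triad_keeps_all_three_edges(self, triad_reference):
        query = define_query(triad_reference, _label_selectors(3))
        assert len(fragment_query(query)) == 3

    def test_four_or_more_pruned_to_spanning_tree(self):
        ref, selectors = _quad_reference()
        query = define_query(ref, selectors)
        edges = fragment_query(query)
        assert len(edges) == query.n - 1
        covered = {e.role_a for e in edges} | {e.role_b for e in edges}
        assert covered == set(range(query.n))

    def test_pruning_deterministic(self):
        ref, selectors = _quad_reference()
        query = define_query(ref, selectors)
        first = [(e.role_a, e.role_b) for e in fragment_query(query)]
        second = [(e.role_a, e.role_b) for e in fragment_query(query)]
        assert first == second


def _build_indexed_corpus(tmp_path, structures, name="idx"):
    return InvertedIndex.build(structures, tmp_path / name)


class TestAssembly:
    def test_planted_triad_recovered_exactly(self, tmp_path, triad_reference):
        host = generate_structure(60, seed=30, structure_id="host")
        locs = [ResidueLocator("A", "1", p) for p in (10, 25, 40)]
        rng = np.random.default_rng(3)
        from strucmotif.synthetic import random_rigid_transform

        rot, trans = random_rigid_transform(rng)
        planted, truth = plant_motif(
            host, PlantSpec(make_triad_motif(), rot, trans, 0.0, locs), seed=1
        )
        decoys = [
            generate_structure(50, seed=31 + i, structure_id=f"d{i}") for i in range(3)
        ]
        idx = _build_indexed_corpus(tmp_path, [planted] + decoys)
        query = define_query(triad_reference, _label_selectors(3))
        candidates = assemble_candidates(
            idx, fragment_query(query), query, SearchParameters(tolerance=1)
        )
        planted_assignment = tuple(sorted(truth.items()))
        matching = [c for c in candidates if c.structure_id == "host"]
        assert any(c.assignment == planted_assignment for c in matching)

    def test_structure_without_edge_postings_rejected_early(
        self, tmp_path, triad_reference
    ):
        # decoys only; none contains His and Ser in the query arrangement
        all_ala = generate_structure(40, seed=33, structure_id="bland")
        for r in all_ala.residues:
            r.code = "A"
        idx = _build_indexed_corpus(tmp_path, [all_ala])
        query = define_query(triad_reference, _label_selectors(3))
        from strucmotif.search import SearchReport

        report = SearchReport()
        candidates = assemble_candidates(
            idx, fragment_query(query), query, SearchParameters(tolerance=1), report
        )
        assert candidates == []
        assert report.structures_rejected == 1
        assert report.structures_with_postings == 0

    def test_injectivity_no_residue_fills_two_roles(self, tmp_path):
        # two-role query where both roles allow the same token and geometry;
        # a single residue may not satisfy both roles at once
        chain = generate_structure(10, seed=35, structure_id="inj")
        for r in chain.residues:
            r.code = "C"
        ref = Structure("injref", chain.residues[:2])
        idx = _build_indexed_corpus(tmp_path, [chain])
        query = define_query(ref, _label_selectors(2))
        candidates = assemble_candidates(
            idx, fragment_query(query), query, SearchParameters(tolerance=2)
        )
        for cand in candidates:
            locs = [loc for _, loc in cand.assignment]
            assert len(set(locs)) == len(locs)


class TestOracleEquivalence:
    @pytest.mark.parametrize("tolerance", [0, 1, 2])
    def test_candidates_match_brute_force(self, tmp_path, triad_reference, tolerance):
        structures, _ = make_benchmark_corpus(
            8, 3, sigma=0.1, seed=40, residues_range=(30, 60)
        )
        idx = _build_indexed_corpus(tmp_path, structures, name=f"t{tolerance}")
        query = define_query(triad_reference, _label_selectors(3))
        edges = fragment_query(query)
        candidates = assemble_candidates(
            idx, edges, query, SearchParameters(tolerance=tolerance)
        )
        got = {
            (c.structure_id, tuple(loc.render() for _, loc in c.assignment))
            for c in candidates
        }
        expected = set()
        for st in structures:
            for combo in exhaustive_candidates(st, query, tolerance, edges):
                expected.add(
                    (
                        st.structure_id,
                        tuple(st.residues[i].locator.render() for i in combo),
                    )
                )
        assert got == expected

    def test_rejection_soundness(self, tmp_path, triad_reference):
        # structures rejected by the index path contain no brute-force hit
        structures, _ = make_benchmark_corpus(
            6, 2, sigma=0.0, seed=41, residues_range=(30, 60)
        )
        idx = _build_indexed_corpus(tmp_path, structures)
        query = define_query(triad_reference, _label_selectors(3))
        edges = fragment_query(query)
        candidates = assemble_candidates(
            idx, edges, query, SearchParameters(tolerance=1)
        )
        accepted_ids = {c.structure_id for c in candidates}
        for st in structures:
            if st.structure_id not in accepted_ids:
                assert exhaustive_candidates(st, query, 1, edges) == []


class TestMonotonicityAndMstSafety:
    def test_hit_set_grows_with_tolerance(self, tmp_path, triad_reference):
        structures, _ = make_benchmark_corpus(
            8, 4, sigma=0.2, seed=42, residues_range=(30, 60)
        )
        idx = _build_indexed_corpus(tmp_path, structures)
        query = define_query(triad_reference, _label_selectors(3))
        edges = fragment_query(query)
        sets = []
        for tol in (0, 1, 2):
            cands = assemble_candidates(
                idx, edges, query, SearchParameters(tolerance=tol)
            )
            sets.append({(c.structure_id, c.assignment) for c in cands})
        assert sets[0] <= sets[1] <= sets[2]

    def test_mst_pruning_only_relaxes_constraints(self, tmp_path):
        ref, selectors = _quad_reference()
        query = define_query(ref, selectors)
        structures, _ = make_benchmark_corpus(
            6, 0, sigma=0.0, seed=43, residues_range=(40, 70)
        )
        # plant the quad itself into two hosts so hits exist
        rng = np.random.default_rng(5)
        from strucmotif.synthetic import random_rigid_transform

        motif = ref.residues
        planted = []
        for i, st in enumerate(structures[:2]):
            positions = sorted(rng.choice(len(st.residues), 4, replace=False) + 1)
            locs = [ResidueLocator("A", "1", int(p)) for p in positions]
            rot, trans = random_rigid_transform(rng)
            new_st, _ = plant_motif(st, PlantSpec(motif, rot, trans, 0.0, locs), seed=i)
            planted.append(new_st)
        corpus = planted + structures[2:]
        idx = _build_indexed_corpus(tmp_path, corpus)
        full = assemble_candidates(
            idx, query.edges, query, SearchParameters(tolerance=1)
        )
        mst = assemble_candidates(
            idx, fragment_query(query), query, SearchParameters(tolerance=1)
        )
        full_set = {(c.structure_id, c.assignment) for c in full}
        mst_set = {(c.structure_id, c.assignment) for c in mst}
        assert full_set <= mst_set
        assert len(full_set) >= 2  # the planted instances were found at all


class TestRunSearch:
    def test_self_search_recovers_query_at_rounding_bound(self, tmp_path, triad_reference):
        idx = _build_indexed_corpus(tmp_path, [triad_reference])
        query = define_query(triad_reference, _label_selectors(3))
        result = run_search(idx, query, SearchParameters(tolerance=1))
        assert result.hits
        top = result.hits[0]
        assert top.structure_id == "triadref"
        assert top.rmsd <= 0.12  # bounded by the 0.1 Å stored precision
        assert {loc.render() for loc in top.assignment.values()} == {
            "A_1-1",
            "A_1-2",
            "A_1-3",
        }

    def test_planted_corpus_full_recall_and_ordering(self, tmp_path, triad_reference, small_planted_corpus):
        structures, truth = small_planted_corpus
        idx = _build_indexed_corpus(tmp_path, structures)
        query = define_query(triad_reference, _label_selectors(3))
        result = run_search(
            idx, query, SearchParameters(tolerance=1, rmsd_cutoff=1.0)
        )
        found = {
            (h.structure_id, tuple(h.assignment[r].render() for r in sorted(h.assignment)))
            for h in result.hits
        }
        for sid, locs in truth_assignments(truth).items():
            assert (sid, locs) in found
        rmsds = [h.rmsd for h in result.hits]
        assert rmsds == sorted(rmsds)

    def test_max_hits_truncates_sorted_list(self, tmp_path, triad_reference, small_planted_corpus):
        structures, _ = small_planted_corpus
        idx = _build_indexed_corpus(tmp_path, structures)
        query = define_query(triad_reference, _label_selectors(3))
        full = run_search(idx, query, SearchParameters(tolerance=1, rmsd_cutoff=1.0))
        capped = run_search(
            idx, query, SearchParameters(tolerance=1, rmsd_cutoff=1.0, max_hits=2)
        )
        assert len(capped.hits) == min(2, len(full.hits))
        assert [h.sort_key() for h in capped.hits] == [
            h.sort_key() for h in full.hits[: len(capped.hits)]
        ]
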