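"""Pair geometry, binning, key encoding and pair enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from strucmotif.descriptors import (
    DB_BINS,
    DS_BINS,
    THETA_BINS,
    TYPE_PAIRS,
    DescriptorKey,
    Occurrence,
    PairEnumerationReport,
    PairGeometry,
    bin_descriptor,
    decode_key,
    encode_key,
    enumerate_pairs,
    neighbor_keys,
    pair_geometry,
)
from strucmotif.errors import (
    DegenerateGeometryError,
    InvalidKeyError,
    OutOfRangeError,
)
from strucmotif.structures import Residue, ResidueLocator, Structure
from strucmotif.synthetic import generate_structure


def _point_residue(code, backbone, sidechain, seq=1, chain="A"):
    backbone = np.asarray(backbone, dtype=float)
    sidechain = np.asarray(sidechain, dtype=float)
    return Residue(
        locator=ResidueLocator(chain, "1", seq),
        code=code,
        polymer_kind="amino-acid",
        atoms={"CA": backbone, "CB": sidechain},
        backbone_rep=backbone,
        sidechain_rep=sidechain,
    )


class TestPairGeometry:
    def test_parallel_vectors_give_zero_angle(self):
        r1 = _point_residue("A", [0, 0, 0], [0, 0, 1])
        r2 = _point_residue("C", [5, 0, 0], [5, 0, 1], seq=2)
        g = pair_geometry(r1, r2)
        assert g.theta == pytest.approx(0.0, abs=1e-9)
        assert g.d_b == pytest.approx(5.0)
        assert g.d_s == pytest.approx(5.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            r1 = _point_residue("A", rng.normal(size=3), rng.normal(size=3))
            r2 = _point_residue("W", rng.normal(size=3), rng.normal(size=3), seq=2)
            g1 = pair_geometry(r1, r2)
            g2 = pair_geometry(r2, r1)
            assert g1 == g2

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        for i in range(20):
            b1, s1 = rng.normal(size=3), rng.normal(size=3)
            b2, s2 = rng.normal(size=3) + 4, rng.normal(size=3) + 4
            rot = Rotation.random(random_state=i).as_matrix()
            t = rng.uniform(-30, 30, 3)
            g0 = pair_geometry(
                _point_residue("A", b1, s1), _point_residue("C", b2, s2, seq=2)
            )
            g1 = pair_geometry(
                _point_residue("A", rot @ b1 + t, rot @ s1 + t),
                _point_residue("C", rot @ b2 + t, rot @ s2 + t, seq=2),
            )
            assert abs(g0.d_b - g1.d_b) < 1e-9
            assert abs(g0.d_s - g1.d_s) < 1e-9
            assert abs(g0.theta - g1.theta) < 1e-7

    def test_zero_length_vector_rejected(self):
        r1 = _point_residue("A", [0, 0, 0], [0, 0, 0])
        r2 = _point_residue("C", [5, 0, 0], [5, 0, 1], seq=2)
        with pytest.raises(DegenerateGeometryError):
            pair_geometry(r1, r2)


class TestBinning:
    def test_worked_example_his_ser(self):
        # a His/Ser pair at 8.4 Å backbone, 7.2 Å sidechain, 105 deg renders
        # as the serine-protease pair descriptor HS-8-7-5
        g = PairGeometry(8.4, 7.2, 105.0)
        assert bin_descriptor("S", "H", g).render() == "HS-8-7-5"
        assert bin_descriptor("H", "S", g).render() == "HS-8-7-5"

    def test_theta_180_clamps_to_last_bin(self):
        key = bin_descriptor("A", "A", PairGeometry(5.0, 5.0, 180.0))
        assert key.theta_bin == THETA_BINS - 1

    def test_bin_edges_floor(self):
        assert bin_descriptor("A", "A", PairGeometry(7.999, 6.0, 99.9)).db_bin == 7
        assert bin_descriptor("A", "A", PairGeometry(8.0, 6.0, 100.0)).db_bin == 8
        assert bin_descriptor("A", "A", PairGeometry(8.0, 6.0, 100.0)).theta_bin == 5

    def test_out_of_range_signals(self):
        with pytest.raises(OutOfRangeError):
            bin_descriptor("A", "A", PairGeometry(20.0, 5.0, 10.0))
        with pytest.raises(OutOfRangeError):
            bin_descriptor("A", "A", PairGeometry(19.0, 32.0, 10.0))

    @given(
        code1=st.sampled_from("ACDGHKLSWY" + "acgtu"),
        code2=st.sampled_from("ACDGHKLSWY" + "acgtu"),
        d_b=st.floats(0.0, 19.99),
        d_s=st.floats(0.0, 31.99),
        theta=st.floats(0.0, 180.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_symmetry_property(self, code1, code2, d_b, d_s, theta):
        g = PairGeometry(d_b, d_s, theta)
        assert bin_descriptor(code1, code2, g) == bin_descriptor(code2, code1, g)

    def test_type_pair_always_sorted(self):
        g = PairGeometry(3.0, 3.0, 30.0)
        for c1, c2 in [("C", "A"), ("S", "H"), ("a", "A"), ("u", "g")]:
            key = bin_descriptor(c1, c2, g)
            assert key.type_pair == "".join(sorted((c1, c2)))


class TestKeyCodec:
    def test_exhaustive_round_trip_one_type_pair(self):
        for db, ds, th in itertools.product(
            range(DB_BINS), range(DS_BINS), range(THETA_BINS)
        ):
            key = DescriptorKey("HS", db, ds, th)
            assert decode_key(encode_key(key)) == key

    def test_injective_across_type_pairs(self):
        keys = [
            DescriptorKey(tp, db, 3, 4)
            for tp in TYPE_PAIRS[:50]
            for db in range(0, DB_BINS, 5)
        ]
        packed = [encode_key(k) for k in keys]
        assert len(set(packed)) == len(packed)

    def test_encoding_monotone_in_lexicographic_order(self):
        # brute-force enumeration over a slice of the full key space
        keys = [
            DescriptorKey(tp, db, ds, th)
            for tp in TYPE_PAIRS[::20]
            for db in range(0, DB_BINS, 3)
            for ds in range(0, DS_BINS, 5)
            for th in range(THETA_BINS)
        ]
        ordered = sorted(keys, key=lambda k: (k.type_pair, k.db_bin, k.ds_bin, k.theta_bin))
        packed = [encode_key(k) for k in ordered]
        assert packed == sorted(packed)

    def test_decode_rejects_out_of_range(self):
        with pytest.raises(InvalidKeyError):
            decode_key(len(TYPE_PAIRS) * DB_BINS * DS_BINS * THETA_BINS + 7)
        with pytest.raises(InvalidKeyError):
            decode_key(-1)


class TestNeighborhood:
    def test_tolerance_zero_is_identity(self):
        key = DescriptorKey("HS", 8, 7, 5)
        assert neighbor_keys(key, 0) == {key}

    def test_interior_tolerance_one_gives_27(self):
        key = DescriptorKey("HS", 8, 7, 5)
        neigh = neighbor_keys(key, 1)
        assert len(neigh) == 27
        for k in neigh:
            assert k.type_pair == "HS"
            assert abs(k.db_bin - 8) <= 1
            assert abs(k.ds_bin - 7) <= 1
            assert abs(k.theta_bin - 5) <= 1

    def test_clamped_at_range_boundary(self):
        key = DescriptorKey("AA", 0, 7, 5)
        assert len(neighbor_keys(key, 1)) == 2 * 3 * 3
        corner = DescriptorKey("AA", 0, 0, 0)
        assert len(neighbor_keys(corner, 1)) == 8

    @given(
        db1=st.integers(0, DB_BINS - 1),
        ds1=st.integers(0, DS_BINS - 1),
        th1=st.integers(0, THETA_BINS - 1),
        delta=st.tuples(
            st.integers(-1, 1), st.integers(-1, 1), st.integers(-1, 1)
        ),
    )
    @settings(max_examples=200, derandomize=True)
    def test_adjacent_bins_mutually_visible(self, db1, ds1, th1, delta):
        # geometries in the same or adjacent bin on every measure are in each
        # other's tolerance-1 neighborhood: no hit lost to a single bin border
        db2 = db1 + delta[0]
        ds2 = ds1 + delta[1]
        th2 = th1 + delta[2]
        if not (0 <= db2 < DB_BINS and 0 <= ds2 < DS_BINS and 0 <= th2 < THETA_BINS):
            return
        k1 = DescriptorKey("AC", db1, ds1, th1)
        k2 = DescriptorKey("AC", db2, ds2, th2)
        assert k2 in neighbor_keys(k1, 1)
        assert k1 in neighbor_keys(k2, 1)


class TestEnumeratePairs:
    def test_two_residue_structure_within_cutoff(self):
        r1 = _point_residue("A", [0, 0, 0], [0, 0, 1.5], seq=1)
        r2 = _point_residue("C", [5, 0, 0], [5, 0, 1.5], seq=2)
        st_ = Structure("x", [r1, r2])
        pairs = list(enumerate_pairs(st_))
        assert len(pairs) == 1
        key, occ = pairs[0]
        assert occ.first == r1.locator and occ.second == r2.locator

    def test_cutoff_excludes_distant_pair(self):
        r1 = _point_residue("A", [0, 0, 0], [0, 0, 1.5], seq=1)
        r2 = _point_residue("C", [25, 0, 0], [25, 0, 1.5], seq=2)
        assert list(enumerate_pairs(Structure("x", [r1, r2]))) == []

    def test_matches_brute_force_double_loop(self):
        struct = generate_structure(30, seed=9, structure_id="bf")
        fast = sorted(enumerate_pairs(struct))
        brute = []
        residues = struct.residues
        for i in range(len(residues)):
            for j in range(i + 1, len(residues)):
                d_b = np.linalg.norm(
                    residues[i].backbone_rep - residues[j].backbone_rep
                )
                if d_b >= 20.0:
                    continue
                g = pair_geometry(residues[i], residues[j])
                key = bin_descriptor(residues[i].code, residues[j].code, g)
                first, second = sorted(
                    (residues[i], residues[j]), key=lambda r: r.locator
                )
                swapped = (
                    first.code != second.code and first.code != key.type_pair[0]
                )
                brute.append((key, Occurrence(first.locator, second.locator, swapped)))
        brute.sort()
        assert [(k, o.first, o.second, o.swapped) for k, o in fast] == [
            (k, o.first, o.second, o.swapped) for k, o in brute
        ]

    def test_invariant_under_rigid_motion(self):
        struct = generate_structure(40, seed=5, structure_id="rot")
        rot = Rotation.random(random_state=8).as_matrix()
        t = np.array([12.0, -7.0, 30.0])
        moved = []
        for r in struct.residues:
            atoms = {n: rot @ xyz + t for n, xyz in r.atoms.items()}
            moved.append(
                Residue(
                    locator=r.locator,
                    code=r.code,
                    polymer_kind=r.polymer_kind,
                    atoms=atoms,
                    backbone_rep=rot @ r.backbone_rep + t,
                    sidechain_rep=rot @ r.sidechain_rep + t,
                )
            )
        moved_struct = Structure("rot", moved)
        orig = [(k, o.first, o.second) for k, o in enumerate_pairs(struct)]
        rotated = [(k, o.first, o.second) for k, o in enumerate_pairs(moved_struct)]
        assert orig == rotated

    def test_degenerate_pairs_skipped_and_counted(self):
        r1 = _point_residue("A", [0, 0, 0], [0, 0, 0])  # zero-length vector
        r2 = _point_residue("C", [5, 0, 0], [5, 0, 1.5], seq=2)
        report = PairEnumerationReport()
        out = list(enumerate_pairs(Structure("x", [r1, r2]), report=report))
        assert out == []
        assert report.skipped_degenerate == 1
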