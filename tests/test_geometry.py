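import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from gpcrswitch.geometry import (
    RING_ATOMS,
    DegenerateGeometryError,
    NoChi1Error,
    chi1_series,
    dihedral,
    distance_series,
    ring_atom_indices,
    ring_centroid_distance_series,
)
from gpcrswitch.synthetic_data import RotamerFeature, embed_features

from conftest import make_structure


def oracle_dihedral(p1, p2, p3, p4):
    """Independent projection/cross-product construction of the torsion."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    axis = p3 - p2
    axis = axis / np.linalg.norm(axis)
    v1 = (p1 - p2) - np.dot(p1 - p2, axis) * axis  # reject onto plane ⊥ axis
    v2 = (p4 - p3) - np.dot(p4 - p3, axis) * axis
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    ang = math.degrees(math.acos(np.clip(cosang, -1, 1)))
    if np.dot(np.cross(v1, v2), axis) < 0:
        ang = -ang
    return ang % 360.0


class TestDihedral:
    def test_cis_zero(self):
        assert dihedral((1, 0, 0), (0, 0, 0), (0, 0, 1), (1, 0, 1)) == pytest.approx(0.0)

    def test_anti_180(self):
        assert dihedral((1, 0, 0), (0, 0, 0), (0, 0, 1), (-1, 0, 1)) == pytest.approx(180.0)

    def test_90_against_cross_product_oracle(self):
        pts = ((1, 0, 0), (0, 0, 0), (0, 0, 1), (0, 1, 1))
        assert dihedral(*pts) == pytest.approx(90.0)
        assert dihedral(*pts) == pytest.approx(oracle_dihedral(*pts))

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_oracle_on_random_points(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3)) * 3
        try:
            expected = oracle_dihedral(*pts)
            got = dihedral(*pts)
        except (DegenerateGeometryError, ZeroDivisionError):
            return
        assert got == pytest.approx(expected, abs=1e-6)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3)) * 5
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(size=3) * 10
        moved = pts @ rot.T + shift
        a = dihedral(*pts)
        b = dihedral(*moved)
        diff = abs(a - b) % 360.0
        assert min(diff, 360.0 - diff) < 1e-6

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_reversal_invariance(self, seed):
        # a torsion angle does not change when the atom order is reversed
        rng = np.random.default_rng(seed)
        p = rng.normal(size=(4, 3)) * 5
        fwd = dihedral(p[0], p[1], p[2], p[3])
        rev = dihedral(p[3], p[2], p[1], p[0])
        diff = abs(fwd - rev) % 360.0
        assert min(diff, 360.0 - diff) < 1e-6

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_mirror_antisymmetry(self, seed):
        # an improper transformation (reflection) negates the torsion
        rng = np.random.default_rng(seed)
        p = rng.normal(size=(4, 3)) * 5
        mirrored = p * np.array([1.0, 1.0, -1.0])
        fwd = dihedral(*p)
        neg = dihedral(*mirrored)
        assert (fwd + neg) % 360.0 == pytest.approx(0.0, abs=1e-6) or (
            fwd + neg
        ) % 360.0 == pytest.approx(360.0, abs=1e-6)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateGeometryError, match="coincide"):
            dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))

    def test_collinear_points_rejected(self):
        with pytest.raises(DegenerateGeometryError, match="collinear"):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (2, 1, 0))

    def test_range_is_0_360(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 4
            try:
                a = dihedral(*pts)
            except DegenerateGeometryError:
                continue
            assert 0.0 <= a < 360.0


class TestChi1Series:
    def test_nerf_embedded_values_recovered(self):
        target = np.array([180.0, 280.0])
        s = embed_features(
            [RotamerFeature(residue_id=5, residue_name="PHE", series=target)]
        )
        got = chi1_series(s, 5)
        assert np.allclose(got.angles, target, atol=1e-6)
        assert got.atom_names == ("N", "CA", "CB", "CG")

    def test_glycine_has_no_chi1(self):
        s = make_structure(
            [(1, "N", "N", "GLY", 3), (2, "CA", "C", "GLY", 3)],
            np.zeros((1, 2, 3)),
        )
        with pytest.raises(NoChi1Error, match="3"):
            chi1_series(s, 3)

    def test_missing_cg_named_in_error(self):
        s = make_structure(
            [(1, "N", "N", "SER", 8), (2, "CA", "C", "SER", 8), (3, "CB", "C", "SER", 8)],
            np.zeros((1, 3, 3)),
        )
        with pytest.raises(NoChi1Error, match="CG"):
            chi1_series(s, 8)

    def test_unknown_residue(self):
        s = make_structure([(1, "CA", "C", "GLY", 1)], np.zeros((1, 1, 3)))
        with pytest.raises(KeyError):
            chi1_series(s, 99)


class TestDistanceSeries:
    def test_3_4_5(self):
        s = make_structure(
            [(1, "CA", "C", "GLY", 1), (2, "CA", "C", "GLY", 2)],
            [[[0, 0, 0], [3, 4, 0]]],
        )
        d = distance_series(s, (1, "CA"), (2, "CA"))
        assert d.values[0] == pytest.approx(5.0)

    def test_constant_driven_distance(self):
        coords = np.zeros((7, 2, 3))
        coords[:, 1, 0] = 4.2
        s = make_structure(
            [(1, "CZ", "C", "ARG", 1), (2, "CG", "C", "ASP", 2)], coords
        )
        d = distance_series(s, (1, "CZ"), (2, "CG"))
        assert np.allclose(d.values, 4.2)

    def test_symmetric_in_endpoints(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(5, 2, 3)) * 4
        s = make_structure(
            [(1, "CA", "C", "GLY", 1), (2, "CA", "C", "GLY", 2)], coords
        )
        ab = distance_series(s, (1, "CA"), (2, "CA")).values
        ba = distance_series(s, (2, "CA"), (1, "CA")).values
        assert np.array_equal(ab, ba)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(11)
        coords = rng.normal(size=(20, 3, 3)) * 5
        s = make_structure(
            [(1, "CA", "C", "GLY", 1), (2, "CA", "C", "GLY", 2), (3, "CA", "C", "GLY", 3)],
            coords,
        )
        d12 = distance_series(s, (1, "CA"), (2, "CA")).values
        d23 = distance_series(s, (2, "CA"), (3, "CA")).values
        d13 = distance_series(s, (1, "CA"), (3, "CA")).values
        assert np.all(d13 <= d12 + d23 + 1e-12)

    def test_missing_atom_names_residue(self):
        s = make_structure([(1, "CA", "C", "GLY", 1)], np.zeros((1, 1, 3)))
        with pytest.raises(KeyError, match="CZ"):
            distance_series(s, (1, "CA"), (1, "CZ"))


class TestRingCentroid:
    def _hexagon(self, z=0.0, radius=1.4):
        return [
            [radius * math.cos(k * math.pi / 3), radius * math.sin(k * math.pi / 3), z]
            for k in range(6)
        ]

    def test_hexagon_centroid_to_axial_atom(self):
        atoms = [(i + 1, n, "C", "PHE", 1) for i, n in enumerate(RING_ATOMS["PHE"])]
        atoms.append((7, "NA", "NA", "SOD", 2))
        coords = [self._hexagon() + [[0, 0, 2.0]]]
        s = make_structure(atoms, coords)
        d = ring_centroid_distance_series(s, ring_atom_indices(s, 1), (2, "NA"))
        assert d.values[0] == pytest.approx(2.0)

    def test_single_atom_ring_reduces_to_distance(self):
        s = make_structure(
            [(1, "CA", "C", "GLY", 1), (2, "CA", "C", "GLY", 2)],
            [[[0, 0, 0], [3, 4, 0]]],
        )
        d = ring_centroid_distance_series(s, [0], (2, "CA"))
        assert d.values[0] == pytest.approx(5.0)

    def test_two_parallel_hexagons(self):
        atoms = [(i + 1, n, "C", "PHE", 1) for i, n in enumerate(RING_ATOMS["PHE"])]
        atoms += [(i + 7, n, "C", "PHE", 2) for i, n in enumerate(RING_ATOMS["PHE"])]
        coords = [self._hexagon(0.0) + self._hexagon(3.5)]
        s = make_structure(atoms, coords)
        d = ring_centroid_distance_series(
            s, ring_atom_indices(s, 1), ring_atom_indices(s, 2)
        )
        assert d.values[0] == pytest.approx(3.5)

    def test_empty_ring_rejected(self):
        s = make_structure([(1, "CA", "C", "GLY", 1)], np.zeros((1, 1, 3)))
        with pytest.raises(ValueError, match="empty"):
            ring_centroid_distance_series(s, [], (1, "CA"))
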