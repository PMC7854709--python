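"""Geometry container, XYZ round-trips, and minimized-RMSD behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from qm7xtools.structures import (
    IncomparableStructuresError,
    Structure,
    XYZFormatError,
    min_rmsd,
    raw_rmsd,
    read_xyz,
    write_xyz,
)

CH4 = Structure(
    [6, 1, 1, 1, 1],
    np.array([
        [0.0, 0.0, 0.0],
        [0.6291, 0.6291, 0.6291],
        [-0.6291, -0.6291, 0.6291],
        [-0.6291, 0.6291, -0.6291],
        [0.6291, -0.6291, -0.6291],
    ]),
    label="methane",
)

# four-atom asymmetric geometry used throughout the RMSD tests
ASYM4 = Structure(
    [6, 7, 8, 16],
    np.array([
        [0.0, 0.0, 0.0],
        [1.4, 0.1, -0.2],
        [-0.3, 1.5, 0.4],
        [0.8, -0.9, 1.3],
    ]),
)


def random_rigid_motion(rng):
    rot = Rotation.random(rng=rng)
    shift = rng.uniform(-10, 10, size=3)
    return rot, shift


class TestStructure:
    def test_shape_and_finite_validation(self):
        with pytest.raises(ValueError):
            Structure([6, 1], np.zeros((3, 3)))
        with pytest.raises(ValueError):
            Structure([6], [[np.nan, 0, 0]])
        with pytest.raises(ValueError):
            Structure([0], [[0, 0, 0]])

    def test_masses_and_symbols(self):
        assert CH4.symbols == ["C", "H", "H", "H", "H"]
        assert CH4.masses[0] == pytest.approx(12.011)


class TestXYZ:
    def test_read_single_frame(self, tmp_path):
        p = tmp_path / "ch4.xyz"
        p.write_text(
            "5\nmethane\n"
            "C 0.0 0.0 0.0\nH 0.6291 0.6291 0.6291\nH -0.6291 -0.6291 0.6291\n"
            "H -0.6291 0.6291 -0.6291\nH 0.6291 -0.6291 -0.6291\n"
        )
        (s,) = read_xyz(p)
        assert s.n_atoms == 5
        assert s.atomic_numbers.tolist() == [6, 1, 1, 1, 1]
        assert s.label == "methane"

    def test_count_mismatch_names_line(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("3\ncomment\nC 0 0 0\nH 1 0 0\n")
        with pytest.raises(XYZFormatError, match="line 1"):
            read_xyz(p)

    def test_unknown_element_and_bad_coordinate(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("1\n\nXx 0 0 0\n")
        with pytest.raises(XYZFormatError, match="unknown element"):
            read_xyz(p)
        p.write_text("1\n\nC zero 0 0\n")
        with pytest.raises(XYZFormatError, match="line 3"):
            read_xyz(p)

    def test_round_trip_coordinates(self, tmp_path, rng):
        frames = [
            Structure(
                rng.integers(1, 18, size=n),
                rng.uniform(-5, 5, size=(n, 3)),
                label=f"frame-{i}",
            )
            for i, n in enumerate([1, 4, 7])
        ]
        p = tmp_path / "traj.xyz"
        write_xyz(frames, p)
        back = read_xyz(p)
        assert len(back) == 3
        for a, b in zip(frames, back):
            assert a.label == b.label
            assert np.array_equal(a.atomic_numbers, b.atomic_numbers)
            np.testing.assert_allclose(a.positions, b.positions, atol=1e-6)

    def test_many_frames_and_empty(self, tmp_path):
        frames = [CH4.copy() for _ in range(100)]
        p = tmp_path / "many.xyz"
        write_xyz(frames, p)
        assert len(read_xyz(p)) == 100
        write_xyz([], p)
        assert p.read_text() == ""
        assert read_xyz(p) == []


class TestMinRMSD:
    def test_identity_is_zero(self):
        assert min_rmsd(ASYM4, ASYM4) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_of_one_input(self):
        rot = Rotation.from_euler("z", 90, degrees=True)
        moved = Structure(
            ASYM4.atomic_numbers, rot.apply(ASYM4.positions) + np.array([5.0, 5.0, 5.0])
        )
        assert min_rmsd(ASYM4, moved) == pytest.approx(0.0, abs=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_invariant_under_common_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        b = Structure(ASYM4.atomic_numbers, ASYM4.positions + rng.normal(scale=0.5, size=(4, 3)))
        base = min_rmsd(ASYM4, b)
        rot, shift = random_rigid_motion(rng)
        a2 = Structure(ASYM4.atomic_numbers, rot.apply(ASYM4.positions) + shift)
        b2 = Structure(b.atomic_numbers, rot.apply(b.positions) + shift)
        assert min_rmsd(a2, b2) == pytest.approx(base, abs=1e-8)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_optimality_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        b = Structure(ASYM4.atomic_numbers, ASYM4.positions + rng.normal(scale=0.8, size=(4, 3)))
        assert min_rmsd(ASYM4, b) <= raw_rmsd(ASYM4, b) + 1e-12
        assert min_rmsd(ASYM4, b) == pytest.approx(min_rmsd(b, ASYM4), abs=1e-12)

    def test_against_rotation_grid_oracle(self):
        b = ASYM4.copy()
        b.positions[2] += np.array([1.0, 0.0, 0.0])  # one atom moved 1 A
        expected = rotation_grid_rmsd_oracle(ASYM4.positions, b.positions)
        assert min_rmsd(ASYM4, b) == pytest.approx(expected, abs=1e-3)

    def test_enantiomers_keep_nonzero_rmsd(self):
        mirrored = Structure(ASYM4.atomic_numbers, ASYM4.positions * np.array([-1.0, 1.0, 1.0]))
        # proper rotations only: the mirror image of a chiral arrangement
        # cannot be superimposed
        assert min_rmsd(ASYM4, mirrored) > 0.1

    def test_incomparable_structures(self):
        other = Structure([6, 7, 8], np.eye(3))
        with pytest.raises(IncomparableStructuresError):
            min_rmsd(ASYM4, other)
        permuted = Structure([7, 6, 8, 16], ASYM4.positions)
        with pytest.raises(IncomparableStructuresError):
            min_rmsd(ASYM4, permuted)

    def test_heavy_only_ignores_hydrogens(self):
        a = CH4.copy()
        b = CH4.copy()
        b.positions[1] += 0.5  # move one H
        assert min_rmsd(a, b, heavy_only=True) == pytest.approx(0.0, abs=1e-9)
        assert min_rmsd(a, b) > 0.1


def rotation_grid_rmsd_oracle(pa, pb, coarse_deg=6.0):
    """Brute-force minimum RMSD over rotations: Euler grid + local refinement."""
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    n = len(pa)

    def rmsd_of(euler):
        r = Rotation.from_euler("zyz", euler)
        return np.sqrt(np.mean(np.sum((pa - r.apply(pb)) ** 2, axis=1)))

    grid = np.deg2rad(np.arange(0.0, 360.0, coarse_deg))
    half = np.deg2rad(np.arange(0.0, 180.0 + coarse_deg, coarse_deg))
    best, best_euler = np.inf, None
    angles = np.array(np.meshgrid(grid, half, grid)).reshape(3, -1).T
    rots = Rotation.from_euler("zyz", angles)
    rotated = np.einsum("rij,aj->rai", rots.as_matrix(), pb)
    vals = np.sqrt(np.mean(np.sum((pa[None] - rotated) ** 2, axis=2), axis=1))
    k = int(np.argmin(vals))
    best, best_euler = vals[k], angles[k]
    res = minimize(rmsd_of, best_euler, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14})
    return min(best, float(res.fun))
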