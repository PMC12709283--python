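"""Water triplet-angle distribution and tetrahedral-fraction pipeline."""

import numpy as np
import pytest

from conftest import brute_force_triplet_angles, random_rotation
from pdzkit import synth, tetra
from pdzkit.io import AtomRecord, EmptyInputError, ResidueRecord, StructureModel
from pdzkit.tetra import (HydrationShell, TETRAHEDRAL_ANGLE, fraction_in_window,
                          histogram_angles, select_hydration_waters,
                          site_tetrahedrality, tetrahedral_fraction,
                          triplet_angles, water_oxygen_coords)


def waters_at(coords, box=None, extra_chains=None):
    chains = dict(extra_chains or {})
    chains["W"] = [ResidueRecord("W", i + 1, "HOH", [AtomRecord("O", "O", c)])
                   for i, c in enumerate(np.atleast_2d(np.asarray(coords, float)))]
    return StructureModel(0, chains, box=None if box is None else np.asarray(box, float))


class TestShellSelection:
    def test_cutoff_arithmetic(self):
        frame = waters_at([[3.0, 0, 0], [4.2, 0, 0], [4.3, 0, 0]])
        shell = select_hydration_waters(frame, np.zeros(3), r_hyd=4.25)
        assert list(shell.water_indices) == [0, 1]

    def test_empty_shell_is_valid(self):
        frame = waters_at([[10.0, 0, 0], [12.0, 0, 0], [14, 0, 0], [16, 0, 0], [18, 0, 0]])
        shell = select_hydration_waters(frame, np.zeros(3))
        assert shell.water_indices.size == 0
        assert triplet_angles(frame, shell).size == 0

    def test_overlapping_probe_shells_union(self):
        frame = waters_at([[0, 0, 2], [0, 0, -2], [3.0, 0, 0]])
        probes = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        shell = select_hydration_waters(frame, probes)
        assert list(shell.water_indices) == [0, 1, 2]

    def test_no_waters_raises(self):
        frame = StructureModel(0, {"P": [ResidueRecord(
            "P", 1, "PRB", [AtomRecord("C", "C", np.zeros(3))])]})
        with pytest.raises(EmptyInputError):
            select_hydration_waters(frame, np.zeros(3))

    def test_virtual_sites_ignored(self):
        res = ResidueRecord("W", 1, "TIP4", [
            AtomRecord("O", "O", np.zeros(3)),
            AtomRecord("MW", "O", np.array([0.1, 0, 0])),  # 4-site extra point
        ])
        frame = StructureModel(0, {"W": [res]})
        assert water_oxygen_coords(frame).shape == (1, 3)


class TestTripletAngles:
    def test_right_angle_pair(self):
        frame = waters_at([[0, 0, 0], [2.8, 0, 0], [0, 2.8, 0]])
        shell = HydrationShell(0, np.array([0]))
        assert triplet_angles(frame, shell) == pytest.approx([90.0])

    def test_ideal_tetrahedron_six_angles(self):
        d = 2.75 / np.sqrt(3)
        verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) * d
        frame = waters_at(np.vstack([[0, 0, 0], verts]))
        shell = HydrationShell(0, np.array([0]))
        angles = triplet_angles(frame, shell)
        assert angles.shape == (6,)
        assert np.allclose(angles, TETRAHEDRAL_ANGLE)

    def test_collinear_gives_180(self):
        frame = waters_at([[-2.8, 0, 0], [0, 0, 0], [2.8, 0, 0]])
        shell = HydrationShell(0, np.array([1]))
        assert triplet_angles(frame, shell) == pytest.approx([180.0])

    def test_neighbors_beyond_cutoff_excluded(self):
        frame = waters_at([[0, 0, 0], [2.8, 0, 0], [0, 3.5, 0]])
        shell = HydrationShell(0, np.array([0]))
        assert triplet_angles(frame, shell, r_nb=3.4).size == 0

    def test_nonpositive_cutoff_rejected(self):
        frame = waters_at([[0, 0, 0], [2.8, 0, 0], [0, 2.8, 0]])
        with pytest.raises(ValueError):
            triplet_angles(frame, HydrationShell(0, np.array([0])), r_nb=0.0)

    def test_minimum_image_across_boundary(self):
        """Two neighbours visible only through the periodic boundary."""
        box = [10.0, 10.0, 10.0]
        frame = waters_at([[0.5, 5, 5], [9.5, 5, 5], [0.5, 5, 8.0]], box=box)
        # centre at x=0.5; neighbour at 9.5 is 1.0 away through the boundary
        shell = HydrationShell(0, np.array([0]))
        angles = triplet_angles(frame, shell, r_nb=3.4)
        assert angles.shape == (1,)
        assert angles[0] == pytest.approx(90.0)

    def test_matches_brute_force_small_gas(self):
        for seed in range(5):
            frame = synth.gen_waters("ideal_gas", n=150, seed=seed)[0]
            shell = HydrationShell(0, np.arange(150))
            got = np.sort(triplet_angles(frame, shell))
            want = np.sort(brute_force_triplet_angles(frame, np.arange(150)))
            assert got.shape == want.shape
            assert np.allclose(got, want, atol=1e-8)


class TestFractions:
    def test_histogram_window_must_align(self):
        hist = histogram_angles(np.array([109.0]), n_bins=7)  # ~25.7° bins
        with pytest.raises(ValueError, match="align"):
            tetrahedral_fraction(hist)

    def test_ideal_tetrahedral_fraction_is_one(self):
        hist = histogram_angles(np.full(60, TETRAHEDRAL_ANGLE))
        assert tetrahedral_fraction(hist) == 1.0

    def test_collinear_fraction_is_zero(self):
        hist = histogram_angles(np.full(10, 180.0))
        assert tetrahedral_fraction(hist) == 0.0

    def test_histogram_route_equals_direct_count(self, rng):
        angles = rng.uniform(0.0, 180.0, size=5000)
        hist = histogram_angles(angles)
        assert tetrahedral_fraction(hist) == pytest.approx(fraction_in_window(angles))

    def test_pooling_equals_weighted_average(self, rng):
        parts = [rng.uniform(0, 180, size=n) for n in (100, 400, 50)]
        pooled = fraction_in_window(np.concatenate(parts))
        weighted = sum(fraction_in_window(p) * p.size for p in parts) / sum(p.size for p in parts)
        assert pooled == pytest.approx(weighted)


class TestSiteTetrahedrality:
    def _site(self):
        return [("P", 1, "C")]

    def test_identical_replicas_zero_sd(self):
        frames = synth.gen_waters("tetra_lattice", n=100, jitter=0.05, seed=4)
        res = site_tetrahedrality([frames, frames, frames], self._site())
        assert res.sd == 0.0
        assert res.mean == pytest.approx(res.per_replica[0])

    def test_single_replica(self):
        frames = synth.gen_waters("tetra_lattice", n=100, jitter=0.05, seed=4)
        res = site_tetrahedrality([frames], self._site())
        assert res.mean == pytest.approx(res.fraction) and res.sd == 0.0

    def test_planted_order_parameter_ordering(self):
        """Replicas with higher planted order (lower jitter) score higher."""
        fracs = []
        for jitter in (0.05, 0.25, 0.6):
            frames = synth.gen_waters("tetra_lattice", n=216, jitter=jitter,
                                      seed=11, n_frames=2)
            fracs.append(site_tetrahedrality([frames], self._site()).fraction)
        assert fracs[0] > fracs[1] > fracs[2]

    def test_rigid_motion_invariance_full_pipeline(self, rng):
        frames = synth.gen_waters("tetra_lattice", n=120, jitter=0.1, seed=2)
        res = site_tetrahedrality([frames], self._site())
        moved = [f.transformed(random_rotation(rng), rng.normal(scale=30.0, size=3))
                 for f in frames]
        res2 = site_tetrahedrality([moved], self._site())
        assert res2.fraction == pytest.approx(res.fraction, abs=1e-12)
        assert res2.n_triplets == res.n_triplets


class TestProbeResolution:
    def test_parent_heavy_replaces_hydrogen(self):
        model = synth.gen_toy_complex(planted_positions={0}, seed=0)
        coords = tetra.resolve_probes(model, [("A", 3, "H")], "parent_heavy")
        n_coords = model.chain("A")[2].atom("N").coords
        assert np.allclose(coords[0], n_coords)

    def test_residue_heavy_collects_all_heavy_atoms(self):
        model = synth.gen_toy_complex(planted_positions={0}, seed=0)
        coords = tetra.resolve_probes(model, [("A", 3, "N")], "residue_heavy")
        n_heavy = sum(a.is_heavy for a in model.chain("A")[2].atoms)
        assert coords.shape == (n_heavy, 3)

    def test_hydrogen_mode_keeps_hydrogen(self):
        model = synth.gen_toy_complex(planted_positions={0}, seed=0)
        coords = tetra.resolve_probes(model, [("A", 3, "H")], "hydrogen")
        assert np.allclose(coords[0], model.chain("A")[2].atom("H").coords)
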