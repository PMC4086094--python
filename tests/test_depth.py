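"""Depth engine: solvation, bulk filtering, nearest-water distances.

Every geometric operation is checked against an exhaustive brute-force
oracle; the layered-cluster fixtures give construction-guaranteed burial
orderings.
"""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from tspred.depth import (
    ResidueDepthProfile,
    SolvationParams,
    WaterSet,
    atom_depths,
    filter_bulk,
    residue_depth,
    solvate,
    write_depth_tsv,
)
from tspred.errors import ConfigurationError, SolvationError
from tspred.fixtures import make_layered_cluster

from .conftest import random_toy_structure, single_atom_structure


def brute_force_bulk(positions, radius, min_neighbors):
    """Reference fixed point: recount neighbours from scratch each round."""
    pos = np.asarray(positions, float).reshape(-1, 3)
    while len(pos):
        d = cdist(pos, pos)
        counts = (d <= radius).sum(axis=1) - 1
        keep = counts >= min_neighbors
        if keep.all():
            break
        pos = pos[keep]
    return pos


class TestSolvate:
    def test_clash_postcondition_single_atom(self, fast_solvation):
        s = single_atom_structure()
        w = solvate(s, fast_solvation, cycle=0)
        dists = np.linalg.norm(w.positions, axis=1)
        assert len(w) > 0
        assert dists.min() >= fast_solvation.clash_cutoff

    def test_deterministic_per_seed_and_cycle(self, fast_solvation):
        s = single_atom_structure()
        w1 = solvate(s, fast_solvation, cycle=3)
        w2 = solvate(s, fast_solvation, cycle=3)
        np.testing.assert_array_equal(w1.positions, w2.positions)
        w3 = solvate(s, fast_solvation, cycle=4)
        assert w3.positions.shape != w1.positions.shape or not np.allclose(
            w3.positions, w1.positions
        )

    def test_clash_filter_equals_brute_force_on_candidate_lattice(self):
        s = random_toy_structure(np.random.default_rng(5), 8)
        p = SolvationParams(n_cycles=1, padding=6.0, seed=11)
        # same lattice with a clash cutoff below any achievable distance
        # yields the unfiltered candidate set
        p_all = SolvationParams(n_cycles=1, padding=6.0, seed=11, clash_cutoff=1e-9)
        candidates = solvate(s, p_all, cycle=0).positions
        atoms = s.heavy_atom_coords()
        keep = cdist(candidates, atoms).min(axis=1) >= p.clash_cutoff
        expected = candidates[keep]
        got = solvate(s, p, cycle=0).positions
        np.testing.assert_allclose(np.sort(got, axis=0), np.sort(expected, axis=0))


class TestFilterBulk:
    def test_isolated_water_removed(self):
        p = SolvationParams(min_neighbors=1)
        w = filter_bulk(WaterSet(positions=np.array([[50.0, 50.0, 50.0]])), p)
        assert len(w) == 0

    def test_dense_slab_is_fixed_point(self):
        p = SolvationParams(water_spacing=2.8, neighbor_radius=4.2, min_neighbors=2)
        g = np.arange(5) * 2.8
        slab = np.stack(np.meshgrid(g, g, g, indexing="ij"), -1).reshape(-1, 3)
        w = filter_bulk(WaterSet(positions=slab), p)
        assert len(w) == len(slab)

    def test_chain_removal_cascades(self):
        # end water has 1 neighbour -> removed; middle then drops to 1 -> removed...
        p = SolvationParams(neighbor_radius=3.0, min_neighbors=2)
        chain = np.array([[0.0, 0, 0], [2.5, 0, 0], [5.0, 0, 0]])
        w = filter_bulk(WaterSet(positions=chain), p)
        expected = brute_force_bulk(chain, 3.0, 2)
        assert len(w) == len(expected) == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_fixed_point(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 12, size=(rng.integers(5, 60), 3))
        p = SolvationParams(neighbor_radius=3.5, min_neighbors=3)
        got = filter_bulk(WaterSet(positions=pts), p).positions
        expected = brute_force_bulk(pts, 3.5, 3)
        np.testing.assert_allclose(np.sort(got, axis=0), np.sort(expected, axis=0))


class TestAtomDepths:
    def test_nearest_of_two_waters(self):
        s = single_atom_structure()
        w = WaterSet(positions=np.array([[3.0, 0, 0], [0, 4.0, 0]]))
        assert atom_depths(s, w)[0] == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        s = random_toy_structure(rng, int(rng.integers(2, 25)))
        waters = WaterSet(positions=rng.uniform(-10, 10, size=(40, 3)))
        got = atom_depths(s, waters)
        expected = cdist(s.heavy_atom_coords(), waters.positions).min(axis=1)
        np.testing.assert_allclose(got, expected)

    def test_empty_water_set_raises(self):
        with pytest.raises(SolvationError):
            atom_depths(single_atom_structure(), WaterSet(positions=np.empty((0, 3))))


class TestResidueDepth:
    def test_single_residue_equals_mean_of_atom_depths(self, fast_solvation):
        s = single_atom_structure()
        p = SolvationParams(n_cycles=1, padding=7.0, seed=7)
        prof = residue_depth(s, p)
        w = filter_bulk(solvate(s, p, 0), p)
        expected = atom_depths(s, w).mean()
        assert prof.mean_depth[s.residues[0].key] == pytest.approx(expected)

    def test_exposed_atom_depth_within_lattice_bound(self, fast_solvation):
        s = single_atom_structure()
        prof = residue_depth(s, fast_solvation)
        d = prof.mean_depth[s.residues[0].key]
        lo = fast_solvation.clash_cutoff
        hi = fast_solvation.clash_cutoff + fast_solvation.water_spacing * np.sqrt(3)
        assert lo <= d <= hi

    def test_layered_cluster_burial_ordering(self, small_cluster):
        s, labels = small_cluster
        prof = residue_depth(s, SolvationParams(n_cycles=2, padding=8.0, seed=2))
        d = np.array([prof.mean_depth[r.key] for r in s.residues])
        lab = np.array(labels)
        shell_means = [d[lab == k].mean() for k in range(3)]
        assert shell_means[0] > shell_means[1] > shell_means[2]

    def test_surface_floor(self, small_cluster):
        s, _ = small_cluster
        p = SolvationParams(n_cycles=1, padding=8.0, seed=9)
        prof = residue_depth(s, p)
        assert min(prof.mean_depth.values()) >= p.clash_cutoff

    def test_bit_identical_for_identical_seed(self, small_cluster):
        s, _ = small_cluster
        p = SolvationParams(n_cycles=2, padding=8.0, seed=42)
        p1 = residue_depth(s, p)
        p2 = residue_depth(s, p)
        assert p1.mean_depth == p2.mean_depth
        assert p1.sd_depth == p2.sd_depth

    def test_exposed_residue_sd_below_lattice_spacing(self):
        s = single_atom_structure()
        p = SolvationParams(n_cycles=8, padding=7.0, seed=5)
        prof = residue_depth(s, p)
        assert prof.sd_depth[s.residues[0].key] <= p.water_spacing

    def test_monotone_burial_adding_outer_shell(self):
        """Surrounding a cluster with another shell pushes bulk water out.

        Both structures are solvated from the same candidate lattice so
        the comparison is exact: the larger structure can only remove
        more waters, hence no atom's depth may decrease.
        """
        inner2, _ = make_layered_cluster(2, atoms_per_shell=40, shell_gap=3.0, seed=1)
        inner3, _ = make_layered_cluster(3, atoms_per_shell=40, shell_gap=3.0, seed=1)
        # same seed: first two shells of the 3-shell cluster are identical
        n_common = len(inner2.residues)
        np.testing.assert_allclose(
            inner2.heavy_atom_coords(),
            inner3.heavy_atom_coords()[:n_common],
        )
        p = SolvationParams(n_cycles=1, padding=8.0, seed=13)
        p_lattice = SolvationParams(n_cycles=1, padding=8.0, seed=13, clash_cutoff=1e-9)
        candidates = solvate(inner3, p_lattice, cycle=0).positions
        waters = {}
        for name, s in (("small", inner2), ("large", inner3)):
            keep = cdist(candidates, s.heavy_atom_coords()).min(axis=1) >= p.clash_cutoff
            waters[name] = filter_bulk(WaterSet(positions=candidates[keep]), p)
        d_small = atom_depths(inner2, waters["small"])
        d_large = atom_depths(inner3, waters["large"])[:n_common]
        assert np.all(d_large >= d_small - 1e-9)

    def test_side_chain_only_falls_back_for_ca_only_residues(self):
        s = single_atom_structure()
        p = SolvationParams(n_cycles=1, side_chain_only=True, padding=7.0)
        prof = residue_depth(s, p)  # CA-only residue: falls back to all atoms
        assert prof.n_atoms[s.residues[0].key] == 1

    def test_degenerate_params_rejected(self):
        with pytest.raises(ConfigurationError):
            SolvationParams(water_spacing=-1.0)
        with pytest.raises(ConfigurationError):
            SolvationParams(n_cycles=0)


def test_depth_tsv_has_one_row_per_residue(small_cluster, fast_solvation):
    s, _ = small_cluster
    prof = residue_depth(s, fast_solvation)
    lines = write_depth_tsv(prof).strip().split("\n")
    assert len(lines) == len(s.residues) + 1
    assert lines[0].split("\t") == ["chain", "resnum", "resname", "mean_depth", "sd_depth", "n_atoms"]
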