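"""Residue depth: distance to the nearest bulk water.

The structure is immersed in a cubic lattice of candidate water positions
with a random rigid rotation and offset per cycle. Waters clashing with
protein atoms are removed, then waters that are not part of the bulk
solvent (too few water neighbours, e.g. trapped in cavities or grooves)
are iteratively pruned to a fixed point. The depth of an atom is its
Euclidean distance to the closest surviving bulk water; residue depth is
the average over the residue's atoms, and depths are averaged over
several independent solvation cycles to remove lattice artefacts.

Deep residues are buried; surface residues sit one water-contact distance
(~2.6 A) from bulk solvent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import ConfigurationError, SolvationError
from .structio import ResidueKey, Structure

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass(frozen=True)
class SolvationParams:
    """Parameters of the lattice-solvation depth protocol.

    water_spacing
        Lattice constant of the candidate water grid, in Angstrom. 2.8 A
        approximates the molecular spacing of bulk water.
    clash_cutoff
        Minimum allowed water to protein-heavy-atom distance (A).
    neighbor_radius
        Radius defining a water's water-neighbourhood (A).
    min_neighbors
        A water must retain at least this many water neighbours to count
        as bulk solvent; waters below are pruned iteratively.
    n_cycles
        Number of independent solvations averaged per structure.
    seed
        Base seed; every cycle derives its own stream from (seed, cycle).
    padding
        Margin of solvent beyond the protein bounding box (A).
    side_chain_only
        Aggregate residue depth over side-chain atoms only instead of all
        atoms (glycine falls back to all atoms).
    """

    water_spacing: float = 2.8
    clash_cutoff: float = 2.6
    neighbor_radius: float = 4.2
    min_neighbors: int = 2
    n_cycles: int = 25
    seed: int = 1
    padding: float = 10.0
    side_chain_only: bool = False

    def __post_init__(self) -> None:
        for name in ("water_spacing", "clash_cutoff", "neighbor_radius", "padding"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.min_neighbors < 1:
            raise ConfigurationError("min_neighbors must be >= 1")
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles must be >= 1")


@dataclass
class WaterSet:
    """Candidate solvent positions surviving the clash (and bulk) filters."""

    positions: np.ndarray  # (n, 3), Angstrom
    cycle_id: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class ResidueDepthProfile:
    """Per-residue mean/sd depth (A) across solvation cycles."""

    mean_depth: dict[ResidueKey, float] = field(default_factory=dict)
    sd_depth: dict[ResidueKey, float] = field(default_factory=dict)
    n_atoms: dict[ResidueKey, int] = field(default_factory=dict)

    def keys(self) -> list[ResidueKey]:
        return list(self.mean_depth)

    def __getitem__(self, key: ResidueKey) -> float:
        return self.mean_depth[key]


def _cycle_rng(p: SolvationParams, cycle: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([p.seed, cycle]))


def _protein_coords(s: Structure) -> np.ndarray:
    coords = s.heavy_atom_coords()
    if coords.size == 0:
        raise ConfigurationError("structure has no heavy atoms")
    return coords


def solvate(s: Structure, p: SolvationParams, cycle: int = 0) -> WaterSet:
    """Generate clash-filtered candidate waters for one solvation cycle.

    The cubic lattice fills the protein bounding box plus ``padding`` and
    carries a per-cycle random rigid rotation and sub-cell offset, so
    repeated cycles sample different discretisations of the solvent.
    Deterministic given (seed, cycle).
    """
    coords = _protein_coords(s)
    rng = _cycle_rng(p, cycle)
    rot = Rotation.random(random_state=rng).as_matrix()
    offset = rng.uniform(0.0, p.water_spacing, size=3)

    center = coords.mean(axis=0)
    local = (coords - center) @ rot  # protein in lattice frame
    lo = local.min(axis=0) - p.padding
    hi = local.max(axis=0) + p.padding

    axes = [
        np.arange(lo[k] + offset[k] % p.water_spacing, hi[k] + 1e-9, p.water_spacing)
        for k in range(3)
    ]
    if any(len(ax) == 0 for ax in axes):
        raise ConfigurationError("solvation box is empty; increase padding")
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    waters = grid @ rot.T + center

    tree = cKDTree(coords)
    dmin, _ = tree.query(waters, k=1)
    return WaterSet(positions=waters[dmin >= p.clash_cutoff], cycle_id=cycle)


def filter_bulk(w: WaterSet, p: SolvationParams) -> WaterSet:
    """Prune non-bulk waters to a fixed point.

    A water needs at least ``min_neighbors`` other waters within
    ``neighbor_radius`` to stay. Removal can cascade (a pruned water may
    strand its neighbours), so the pass repeats until no water is removed.
    """
    pos = w.positions
    while len(pos) > 0:
        tree = cKDTree(pos)
        n_neighbors = np.array([len(ix) - 1 for ix in tree.query_ball_point(pos, p.neighbor_radius)])
        keep = n_neighbors >= p.min_neighbors
        if keep.all():
            break
        pos = pos[keep]
    return WaterSet(positions=pos, cycle_id=w.cycle_id)


def atom_depths(s: Structure, w: WaterSet) -> np.ndarray:
    """Distance of each protein heavy atom to its nearest water (A).

    Atom order matches ``Structure.heavy_atom_coords``. Equals exhaustive
    nearest-neighbour search; a k-d tree only accelerates it.
    """
    if len(w) == 0:
        raise SolvationError(
            "no bulk waters; increase padding or lower min_neighbors"
        )
    coords = _protein_coords(s)
    d, _ = cKDTree(w.positions).query(coords, k=1)
    return d


def _residue_atom_slices(s: Structure, p: SolvationParams) -> list[tuple[ResidueKey, np.ndarray]]:
    """Heavy-atom index ranges per residue, honouring side_chain_only."""
    out = []
    idx = 0
    for res in s.residues:
        heavy = [a for a in res.atoms if not a.is_hydrogen]
        indices = np.arange(idx, idx + len(heavy))
        idx += len(heavy)
        if not heavy:
            continue
        if p.side_chain_only:
            side = [i for i, a in zip(indices, heavy) if a.name not in BACKBONE_ATOMS]
            if side:  # glycine has no side-chain heavy atoms
                indices = np.array(side)
        out.append((res.key, indices))
    return out


def residue_depth(s: Structure, p: SolvationParams | None = None) -> ResidueDepthProfile:
    """Mean residue depth over ``n_cycles`` independent solvations.

    Per cycle, residue depth is the mean over the residue's (heavy) atom
    depths; the profile reports the across-cycle mean and standard
    deviation. Bit-identical for identical seeds.
    """
    p = p or SolvationParams()
    slices = _residue_atom_slices(s, p)
    per_cycle = np.empty((p.n_cycles, len(slices)))
    for cycle in range(p.n_cycles):
        waters = filter_bulk(solvate(s, p, cycle), p)
        depths = atom_depths(s, waters)
        per_cycle[cycle] = [depths[ix].mean() for _, ix in slices]

    profile = ResidueDepthProfile()
    means = per_cycle.mean(axis=0)
    sds = per_cycle.std(axis=0, ddof=0)
    for (key, ix), m, sd in zip(slices, means, sds):
        profile.mean_depth[key] = float(m)
        profile.sd_depth[key] = float(sd)
        profile.n_atoms[key] = int(len(ix))
    return profile


def write_depth_tsv(profile: ResidueDepthProfile) -> str:
    """Depth profile as TSV: chain, resnum, resname, mean_depth, sd_depth, n_atoms."""
    lines = ["chain\tresnum\tresname\tmean_depth\tsd_depth\tn_atoms"]
    for key in profile.keys():
        lines.append(
            f"{key.chain_id}\t{key.seq_num}{key.insertion_code}\t{key.res_name}\t"
            f"{profile.mean_depth[key]:.3f}\t{profile.sd_depth[key]:.3f}\t{profile.n_atoms[key]}"
        )
    return "\n".join(lines) + "\n"


def write_depth_pdb(s: Structure, profile: ResidueDepthProfile) -> str:
    """PDB text with mean residue depth in the B-factor column."""
    from .structio import write_structure

    return write_structure(s, bfactors=profile.mean_depth)
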