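"""Synthetic structures and sequences with known burial structure.

These generators exist so the depth engine and the prediction rules can
be exercised end to end without downloading any real structure: an ideal
alpha-helix Calpha trace (for the 100 deg/residue periodicity), layered
spherical atom clusters (an oracle for burial ordering — inner shells
must come out deeper), and designed sequences with hydrophobic cores at
chosen positions.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import InputError
from .structio import ONE_TO_THREE, Atom, Residue, ResidueKey, Structure

HELIX_RISE = 1.5  # A per residue
HELIX_TWIST = 100.0  # deg per residue
HELIX_RADIUS = 2.3  # A, Calpha helix radius giving ~3.8 A Ca-Ca


def make_ideal_helix(n_res: int, residue: str = "ALA", chain_id: str = "A") -> Structure:
    """Calpha trace of a canonical alpha helix.

    Rise 1.5 A and twist 100 deg per residue on a 2.3 A radius, which
    yields the canonical ~3.8 A consecutive Calpha-Calpha distance.
    """
    if n_res < 1:
        raise InputError("n_res must be >= 1")
    if residue not in ONE_TO_THREE.values():
        raise InputError(f"unknown residue type {residue!r}")
    residues = []
    for i in range(n_res):
        ang = math.radians(i * HELIX_TWIST)
        coord = np.array(
            [HELIX_RADIUS * math.cos(ang), HELIX_RADIUS * math.sin(ang), i * HELIX_RISE]
        )
        residues.append(
            Residue(
                key=ResidueKey(chain_id=chain_id, seq_num=i + 1, res_name=residue),
                atoms=[Atom(element="C", name="CA", coord=coord)],
            )
        )
    return Structure(residues=residues, source_id=f"helix{n_res}")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral construction)."""
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_layered_cluster(
    n_shells: int,
    atoms_per_shell: int = 40,
    shell_gap: float = 3.5,
    residue: str = "VAL",
    seed: int = 0,
) -> tuple[Structure, list[int]]:
    """Concentric spherical shells of single-atom residues.

    Returns (structure, shell_labels) with label 0 = innermost shell, one
    label per residue. Shell k sits at radius (k+1) * shell_gap after a
    seeded random rotation per shell, so depth must decrease from inner
    to outer shells — a construction-guaranteed burial ordering.
    """
    if n_shells < 2:
        raise InputError("n_shells must be >= 2")
    if atoms_per_shell < 1 or n_shells * atoms_per_shell < 2:
        raise InputError("cluster must contain at least 2 atoms")
    if shell_gap <= 0:
        raise InputError("shell_gap must be positive")
    rng = np.random.default_rng(seed)
    residues = []
    labels = []
    num = 1
    for shell in range(n_shells):
        radius = (shell + 1) * shell_gap
        pts = _fibonacci_sphere(atoms_per_shell) * radius
        # random rotation decorrelates shells
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        for p in pts @ rot.T:
            residues.append(
                Residue(
                    key=ResidueKey(chain_id="A", seq_num=num, res_name=residue),
                    atoms=[Atom(element="C", name="CA", coord=p)],
                )
            )
            labels.append(shell)
            num += 1
    return Structure(residues=residues, source_id=f"cluster{n_shells}x{atoms_per_shell}"), labels


def make_core_sequence(
    length: int,
    core_positions: set[int],
    core_residue: str = "V",
    background_residue: str = "G",
) -> str:
    """Background homopolymer with a hydrophobic residue at chosen 0-based positions."""
    if length < 1:
        raise InputError("length must be >= 1")
    for aa in (core_residue, background_residue):
        if aa not in ONE_TO_THREE:
            raise InputError(f"unknown residue letter {aa!r}")
    bad = [i for i in core_positions if not 0 <= i < length]
    if bad:
        raise InputError(f"core positions out of range: {sorted(bad)}")
    return "".join(
        core_residue if i in core_positions else background_residue for i in range(length)
    )
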