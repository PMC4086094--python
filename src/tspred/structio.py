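"""Structure and sequence I/O.

Reads protein structures from PDB-format text (via gemmi), resolves
alternate conformers, selects chains, expands REMARK 350 biological
assemblies, and extracts one-letter sequences from the resolved residues.

Only the first model of an entry is used. Waters and non-polymer ligands
are dropped on read; modified amino acids recorded as HETATM (e.g. MSE)
are kept and flagged as hetero so sequence extraction can map them to 'X'.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from Bio import SeqIO

from .errors import FormatError, SelectionError

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_WATER_NAMES = {"HOH", "DOD", "WAT", "H2O"}


@dataclass
class Atom:
    """A heavy or hydrogen atom with Cartesian coordinates in Angstrom."""

    element: str
    name: str
    coord: np.ndarray
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise FormatError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not self.element:
            raise FormatError(f"atom {self.name!r}: empty element symbol")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass(frozen=True)
class ResidueKey:
    """Author-numbered residue identity: (chain, number, insertion code)."""

    chain_id: str
    seq_num: int
    insertion_code: str = ""
    res_name: str = "UNK"

    @property
    def is_standard(self) -> bool:
        return self.res_name in THREE_TO_ONE

    def __str__(self) -> str:
        return f"{self.chain_id}/{self.res_name}{self.seq_num}{self.insertion_code}"


@dataclass
class Residue:
    key: ResidueKey
    atoms: list[Atom] = field(default_factory=list)

    @property
    def is_hetero(self) -> bool:
        return any(a.is_hetero for a in self.atoms)


@dataclass
class Structure:
    """Protein atoms grouped by residue, in file order.

    ``assembly_applied`` records whether REMARK 350 symmetry copies have
    been generated; ``source_id`` is free-text provenance (a PDB code or
    file name).
    """

    residues: list[Residue] = field(default_factory=list)
    assembly_applied: bool = False
    source_id: str = ""

    def __post_init__(self) -> None:
        seen: set[ResidueKey] = set()
        for res in self.residues:
            if res.key in seen:
                raise FormatError(f"duplicate residue key {res.key}")
            seen.add(res.key)
            names = [a.name for a in res.atoms]
            if len(names) != len(set(names)):
                raise FormatError(f"residue {res.key}: duplicate atom name")

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def chains(self) -> list[str]:
        out: list[str] = []
        for res in self.residues:
            if res.key.chain_id not in out:
                out.append(res.key.chain_id)
        return out

    def chain_residues(self, chain_id: str) -> list[Residue]:
        sel = [r for r in self.residues if r.key.chain_id == chain_id]
        if not sel:
            raise SelectionError(
                f"chain {chain_id!r} not in structure (available: {', '.join(self.chains())})"
            )
        return sel

    def heavy_atom_coords(self) -> np.ndarray:
        """(n, 3) coordinates of all non-hydrogen atoms, residue order."""
        pts = [a.coord for r in self.residues for a in r.atoms if not a.is_hydrogen]
        if not pts:
            return np.empty((0, 3))
        return np.vstack(pts)


def _resolve_altlocs(atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    # max occupancy wins; ties broken by file order
    best: dict[str, gemmi.Atom] = {}
    for at in atoms:
        prev = best.get(at.name)
        if prev is None or at.occ > prev.occ:
            best[at.name] = at
    order: list[str] = []
    for at in atoms:
        if at.name not in order:
            order.append(at.name)
    return [best[name] for name in order]


def _is_polymer_residue(res: gemmi.Residue) -> bool:
    if res.name in _WATER_NAMES:
        return False
    if res.het_flag == "A":
        return True
    info = gemmi.find_tabulated_residue(res.name)
    return bool(info is not None and info.is_amino_acid())


def read_structure(
    pdb_text: str,
    chains: list[str] | None = None,
    source_id: str = "",
) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    First model only; waters and non-polymer heteroatoms are dropped;
    alternate locations are resolved to the highest-occupancy conformer
    (ties: first encountered). ``chains``, when given, restricts the
    result to those chain identifiers.

    Raises :class:`FormatError` on unparseable input and
    :class:`SelectionError` if a requested chain is absent.
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB text: {exc}") from exc
    if len(st) == 0:
        raise FormatError("PDB text contains no model")

    residues: list[Residue] = []
    model = st[0]
    for chain in model:
        for res in chain:
            if not _is_polymer_residue(res):
                continue
            key = ResidueKey(
                chain_id=chain.name,
                seq_num=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                res_name=res.name,
            )
            atoms = [
                Atom(
                    element=at.element.name,
                    name=at.name,
                    coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=at.occ,
                    is_hetero=(res.het_flag == "H"),
                )
                for at in _resolve_altlocs(list(res))
            ]
            if atoms:
                residues.append(Residue(key=key, atoms=atoms))
    if not residues:
        raise FormatError("no protein ATOM records found")

    if chains is not None:
        present = {r.key.chain_id for r in residues}
        missing = [c for c in chains if c not in present]
        if missing:
            raise SelectionError(
                f"chain(s) {', '.join(missing)} not present (available: {', '.join(sorted(present))})"
            )
        residues = [r for r in residues if r.key.chain_id in chains]

    return Structure(residues=residues, source_id=source_id or st.name or "")


def parse_assembly_transforms(pdb_text: str) -> list[tuple[list[str], np.ndarray, np.ndarray]]:
    """Extract REMARK 350 BIOMT operators from PDB text.

    Returns a list of (chain_ids, 3x3 rotation, translation) for the first
    biomolecule. Empty list when no BIOMT records are present.
    """
    if "BIOMT" not in pdb_text:
        return []
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse REMARK 350 records: {exc}") from exc
    if not st.assemblies:
        raise FormatError("BIOMT keyword present but no parseable REMARK 350 assembly")
    ops: list[tuple[list[str], np.ndarray, np.ndarray]] = []
    assembly = st.assemblies[0]
    for gen in assembly.generators:
        chain_ids = list(gen.chains)
        for op in gen.operators:
            tr = op.transform
            mat = np.array(tr.mat.tolist(), dtype=float)
            vec = np.array(tr.vec.tolist(), dtype=float)
            if not (np.all(np.isfinite(mat)) and np.all(np.isfinite(vec))):
                raise FormatError("malformed BIOMT matrix (non-finite entries)")
            ops.append((chain_ids, mat, vec))
    return ops


def apply_biological_assembly(s: Structure, pdb_text: str) -> Structure:
    """Expand a structure to its biological unit using REMARK 350 BIOMT.

    Each non-identity operator produces a copy of the affected chains with
    a distinct chain identifier (``A`` -> ``A2``, ``A3``...); author residue
    numbering is preserved in every copy. Without BIOMT records the input
    is returned unchanged (identity assembly).
    """
    ops = parse_assembly_transforms(pdb_text)
    if not ops:
        return s

    # group operators per affected chain set, keeping file order
    residues: list[Residue] = []
    copy_counter: dict[str, int] = {}
    for chain_ids, mat, vec in ops:
        targets = [r for r in s.residues if r.key.chain_id in chain_ids]
        if not targets:
            continue
        for cid in dict.fromkeys(r.key.chain_id for r in targets):
            copy_counter[cid] = copy_counter.get(cid, 0) + 1
        for res in targets:
            n = copy_counter[res.key.chain_id]
            new_cid = res.key.chain_id if n == 1 else f"{res.key.chain_id}{n}"
            residues.append(
                Residue(
                    key=replace(res.key, chain_id=new_cid),
                    atoms=[
                        Atom(
                            element=a.element,
                            name=a.name,
                            coord=mat @ a.coord + vec,
                            occupancy=a.occupancy,
                            is_hetero=a.is_hetero,
                        )
                        for a in res.atoms
                    ],
                )
            )
    if not residues:
        return s
    return Structure(residues=residues, assembly_applied=True, source_id=s.source_id)


def extract_sequence(s: Structure, chain: str) -> str:
    """One-letter sequence of a chain in author-number order.

    Nonstandard residues (including hetero amino acids such as MSE) map
    to ``'X'``.
    """
    out = []
    for res in s.chain_residues(chain):
        if res.key.is_standard and not res.is_hetero:
            out.append(THREE_TO_ONE[res.key.res_name])
        else:
            out.append("X")
    return "".join(out)


def write_structure(s: Structure, bfactors: dict[ResidueKey, float] | None = None) -> str:
    """Serialize a Structure to PDB-format text.

    ``bfactors`` optionally places a per-residue value (e.g. mean depth)
    in the B-factor column of every atom of that residue.
    """
    st = gemmi.Structure()
    st.name = s.source_id or "TSPR"
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    for res in s.residues:
        cid = res.key.chain_id
        if cid not in chain_map:
            chain_map[cid] = gemmi.Chain(cid)
        gres = gemmi.Residue()
        gres.name = res.key.res_name
        gres.seqid = gemmi.SeqId(res.key.seq_num, res.key.insertion_code or " ")
        gres.het_flag = "H" if res.is_hetero else "A"
        for a in res.atoms:
            gat = gemmi.Atom()
            gat.name = a.name
            gat.element = gemmi.Element(a.element)
            gat.pos = gemmi.Position(*a.coord)
            gat.occ = a.occupancy
            if bfactors is not None:
                gat.b_iso = float(bfactors.get(res.key, 0.0))
            gres.add_atom(gat)
        chain_map[cid].add_residue(gres)
    for chain in chain_map.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def read_fasta(text_or_path: str) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) pairs.

    Accepts either FASTA text or a path to a FASTA file. Each record is
    predicted independently downstream.
    """
    if not text_or_path.strip():
        raise FormatError("no FASTA records found")
    if text_or_path.lstrip().startswith(">") or "\n" in text_or_path:
        handle = io.StringIO(text_or_path)
    else:
        handle = open(text_or_path)
    try:
        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]
    finally:
        handle.close()
    if not records:
        raise FormatError("no FASTA records found")
    return records
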