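"""Structures, trajectories, selections, and atom typing.

Lightweight containers for protein structures (chains -> residues -> atoms)
and coordinate trajectories, plus the two primitives the analysis stages
share: atom selection by chain/residue range and identification of
carbonaceous (CHn) groups, the wrapping currency of dehydron analysis.

PDB reading is delegated to Biopython; the containers here are plain
NumPy-backed records so that geometric code stays vectorised and free of
parser details.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Trajectory",
    "StructureError",
    "SelectionError",
    "read_pdb",
    "read_trajectory",
    "write_pdb",
    "select",
    "carbonaceous_groups",
    "carbonaceous_flags",
]

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# single-bond covalent radii, Å (Cordero et al. consensus values)
COVALENT_RADIUS = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "SE": 1.20, "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39,
    "FE": 1.32, "ZN": 1.22, "CU": 1.32, "MG": 1.41, "CA": 1.76, "NA": 1.66,
}
BOND_TOLERANCE = 0.4  # Å added to the radius sum when inferring bonds


class StructureError(ValueError):
    """Malformed or empty structure input."""


class SelectionError(KeyError):
    """Selection referenced a chain or residue absent from the structure."""


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # 3-vector, Å
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise StructureError(f"atom {self.serial}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)
        if not self.element:
            raise StructureError(f"atom {self.serial}: element could not be inferred")


@dataclass(frozen=True)
class Residue:
    chain_id: str
    resseq: int
    icode: str
    resname: str

    @property
    def is_standard(self) -> bool:
        return self.resname in STANDARD_AA

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.resseq, self.icode)

    def __str__(self) -> str:  # e.g. "A/CYS111"
        return f"{self.chain_id}/{self.resname}{self.resseq}{self.icode}"


class Structure:
    """Ordered protein residues with their atoms; waters kept separate.

    Atom data is stored in flat parallel arrays (``coords`` is (n_atoms, 3))
    with ``atom_residue_index`` mapping each atom to its residue, so that
    distance queries vectorise cleanly.
    """

    def __init__(self, residues, atoms, atom_residue_index, waters=()):
        self.residues: list[Residue] = list(residues)
        self.atoms: list[Atom] = list(atoms)
        self.atom_residue_index = np.asarray(atom_residue_index, dtype=int)
        self.waters: list[Atom] = list(waters)
        if len(self.atoms) != len(self.atom_residue_index):
            raise StructureError("atom_residue_index length must match atoms")
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise StructureError("duplicate (chain, resseq, icode) residue keys")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise StructureError("duplicate atom serials")
        self._coords = np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)
        self._res_index = {k: i for i, k in enumerate(keys)}

    # -- access -----------------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        return self._coords

    @coords.setter
    def coords(self, value):
        value = np.asarray(value, dtype=float)
        if value.shape != self._coords.shape:
            raise StructureError("coordinate array shape mismatch")
        self._coords = value

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def water_coords(self) -> np.ndarray:
        if not self.waters:
            return np.zeros((0, 3))
        return np.array([w.coords for w in self.waters], dtype=float)

    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    @property
    def atom_names(self) -> np.ndarray:
        return np.array([a.name for a in self.atoms])

    def residue_index(self, chain_id: str, resseq: int, icode: str = "") -> int:
        try:
            return self._res_index[(chain_id, resseq, icode)]
        except KeyError:
            raise SelectionError(f"residue {chain_id}/{resseq}{icode} not in structure") from None

    def atoms_of_residue(self, ri: int) -> np.ndarray:
        """Atom indices belonging to residue ``ri``."""
        return np.nonzero(self.atom_residue_index == ri)[0]

    def find_atom(self, ri: int, name: str) -> int | None:
        for ai in self.atoms_of_residue(ri):
            if self.atoms[ai].name == name:
                return int(ai)
        return None

    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    def with_coords(self, coords: np.ndarray) -> "Structure":
        s = Structure(self.residues, self.atoms, self.atom_residue_index, self.waters)
        s.coords = np.asarray(coords, dtype=float)
        return s

    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if r.chain_id not in out:
                out.append(r.chain_id)
        return out


@dataclass
class Trajectory:
    """Frames over a fixed topology; times in ns, strictly increasing."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3), Å
    times: np.ndarray   # (n_frames,), ns

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructureError("frames must be (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise StructureError(
                f"frame atom count {self.frames.shape[1]} != topology {self.topology.n_atoms}"
            )
        if len(self.times) != len(self.frames):
            raise StructureError("times length must match frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise StructureError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


# -- element inference ----------------------------------------------------

def _element_from_atom(bio_atom) -> str:
    el = (bio_atom.element or "").strip().upper()
    if el:
        return el
    name = bio_atom.get_name().strip()
    # PDB convention: columns 13-14 hold the element for standard names
    core = name.lstrip("0123456789")
    if core[:2].upper() in COVALENT_RADIUS and len(core) > 1 and core[:2].upper() not in ("CA",):
        return core[:2].upper()
    return core[:1].upper()


def _pick_altloc(bio_atoms):
    """Highest occupancy wins; ties resolved toward altloc 'A' (then lexical)."""
    return max(bio_atoms, key=lambda a: (a.get_occupancy() or 0.0,
                                         -ord((a.get_altloc() or "A")[0])))


def read_pdb(path, keep_waters: bool = False) -> Structure:
    """Parse a PDB file into a :class:`Structure` (first model only).

    Alternate locations are collapsed to the highest-occupancy conformer;
    HOH records go to ``waters`` (oxygens only) when ``keep_waters``.
    Hydrogens are retained if present.
    """
    parser = PDBParser(QUIET=True)
    try:
        model = parser.get_structure("s", str(path))[0]
    except (OSError, KeyError) as e:
        raise StructureError(f"cannot read PDB file {path!r}: {e}") from e

    residues, atoms, res_idx, waters = [], [], [], []
    serial = 0
    for chain in model:
        for res in chain:
            hetflag, resseq, icode = res.get_id()
            resname = res.get_resname().strip()
            if resname == "HOH":
                if keep_waters:
                    for a in res:
                        if _element_from_atom(a) == "O":
                            serial += 1
                            waters.append(Atom(serial, a.get_name().strip(), "O",
                                               np.array(a.get_coord(), dtype=float)))
                continue
            r = Residue(chain.id, int(resseq), (icode or "").strip(), resname)
            ri = len(residues)
            residues.append(r)
            for a in res:
                if a.is_disordered():
                    a = _pick_altloc(a.disordered_get_list())
                serial += 1
                atoms.append(Atom(serial, a.get_name().strip(),
                                  _element_from_atom(a),
                                  np.array(a.get_coord(), dtype=float),
                                  (a.get_altloc() or "").strip(),
                                  float(a.get_occupancy() or 1.0)))
                res_idx.append(ri)
    # drop residues that ended up with no atoms (shouldn't happen, but safe)
    if not atoms:
        raise StructureError(f"no protein atoms found in {path!r}")
    return Structure(residues, atoms, res_idx, waters)


def write_pdb(structure: Structure, path) -> None:
    """Write a single-model PDB (ATOM records, waters as HETATM HOH)."""
    with open(path, "w") as fh:
        fh.write(_pdb_model_text(structure, structure.coords))
        fh.write("END\n")


def _pdb_model_text(structure: Structure, coords: np.ndarray) -> str:
    lines = []
    serial = 0
    for ai, atom in enumerate(structure.atoms):
        res = structure.residues[structure.atom_residue_index[ai]]
        serial += 1
        x, y, z = coords[ai]
        name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
        lines.append(
            f"ATOM  {serial:5d} {name:<4s}{'':1s}{res.resname:>3s} "
            f"{res.chain_id[:1]:1s}{res.resseq:4d}{res.icode[:1] or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
            f"          {atom.element:>2s}\n"
        )
    for w in structure.waters:
        serial += 1
        x, y, z = w.coords
        lines.append(
            f"HETATM{serial:5d}  O   HOH W{serial % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f" O\n"
        )
    return "".join(lines)


def write_trajectory_pdb(traj: Trajectory, path) -> None:
    """Write a multi-model PDB with one MODEL per frame."""
    with open(path, "w") as fh:
        for fi in range(traj.n_frames):
            fh.write(f"MODEL     {fi + 1:4d}\n")
            fh.write(_pdb_model_text(traj.topology, traj.frames[fi]))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_trajectory(path, topology: Structure, stride_ns: float = 0.002,
                    times=None) -> Trajectory:
    """Read a trajectory from a multi-model PDB or a plain coordinate table.

    A coordinate table is whitespace- or comma-separated with one frame per
    row (3 * n_atoms columns) or a flat (n_frames*n_atoms, 3) block. Times
    are synthesized as ``frame * stride_ns`` unless given.
    """
    path = Path(path)
    text_head = path.open().read(4096)
    if "MODEL" in text_head or "ATOM" in text_head:
        frames = _read_multimodel_frames(path)
    else:
        raw = np.loadtxt(path, delimiter="," if "," in text_head else None)
        raw = np.atleast_2d(raw)
        if raw.shape[1] == 3:
            if raw.shape[0] % topology.n_atoms:
                raise StructureError("coordinate block length is not a multiple of atom count")
            frames = raw.reshape(-1, topology.n_atoms, 3)
        else:
            frames = raw.reshape(raw.shape[0], -1, 3)
    if frames.shape[1] != topology.n_atoms:
        raise StructureError(
            f"trajectory atom count {frames.shape[1]} != topology {topology.n_atoms}"
        )
    if times is None:
        times = np.arange(len(frames)) * stride_ns
    return Trajectory(topology, frames, times)


def _read_multimodel_frames(path) -> np.ndarray:
    frames, current = [], []
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec in ("ATOM  ", "HETATM"):
                if line[17:20].strip() == "HOH":
                    continue
                current.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            elif rec == "ENDMDL":
                frames.append(current)
                current = []
    if current:
        frames.append(current)
    if not frames:
        raise StructureError(f"no coordinate frames found in {path!r}")
    counts = {len(f) for f in frames}
    if len(counts) != 1:
        raise StructureError("models have differing atom counts")
    return np.asarray(frames, dtype=float)


# -- selection ------------------------------------------------------------

def select(structure: Structure, chain_id: str, res_range: tuple[int, int],
           atom_names=None) -> np.ndarray:
    """Atom indices in ``chain_id`` with resseq in the inclusive range.

    ``atom_names`` optionally restricts to a set of PDB atom names
    (e.g. ``{"CA"}``). An empty result is legal; an unknown chain is not.
    """
    lo, hi = res_range
    if lo > hi:
        raise ValueError(f"res_range endpoints out of order: {lo} > {hi}")
    if chain_id not in structure.chain_ids():
        raise SelectionError(f"chain {chain_id!r} not present")
    if atom_names is not None:
        atom_names = set(atom_names)
    out = []
    for ai in range(structure.n_atoms):
        res = structure.residues[structure.atom_residue_index[ai]]
        if res.chain_id != chain_id or not (lo <= res.resseq <= hi):
            continue
        if atom_names is not None and structure.atoms[ai].name not in atom_names:
            continue
        out.append(ai)
    return np.asarray(out, dtype=int)


# -- atom typing ----------------------------------------------------------

def infer_bonds(structure: Structure) -> list[tuple[int, int]]:
    """Covalent bonds inferred by distance: d < r_i + r_j + 0.4 Å.

    PDB files carry CONECT records only for heteroatoms, so distance-based
    inference is the standard route for protein atoms.
    """
    coords = structure.coords
    elements = structure.elements
    radii = np.array([COVALENT_RADIUS.get(e, 0.77) for e in elements])
    tree = cKDTree(coords)
    max_cut = 2 * radii.max() + BOND_TOLERANCE
    bonds = []
    for i, j in tree.query_pairs(max_cut):
        if np.linalg.norm(coords[i] - coords[j]) < radii[i] + radii[j] + BOND_TOLERANCE:
            bonds.append((min(i, j), max(i, j)))
    return bonds


def carbonaceous_flags(structure: Structure) -> np.ndarray:
    """Boolean per atom: True for carbons bonded to no N, O, or S.

    Such carbons head CHn groups — the nonpolar units that "wrap" (desolvate)
    a backbone hydrogen bond. Hydrogens are never separate groups.
    """
    elements = structure.elements
    flags = elements == "C"
    for i, j in infer_bonds(structure):
        if elements[i] == "C" and elements[j] in ("N", "O", "S"):
            flags[i] = False
        if elements[j] == "C" and elements[i] in ("N", "O", "S"):
            flags[j] = False
    return flags


def carbonaceous_groups(structure: Structure) -> np.ndarray:
    """Coordinates of carbonaceous-group centers, one per qualifying carbon."""
    return structure.coords[carbonaceous_flags(structure)]
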