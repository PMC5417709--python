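"""Local frustration analysis of residue contacts.

A contact's native pairwise energy is compared against the distribution of
energies obtained by mutating the two residue identities (decoys). The
Z-score of that comparison partitions contacts into three classes:

    minimally frustrated   Z >= 0.78   native clearly better than decoys
    neutral                -1 <= Z < 0.78
    highly frustrated      Z < -1      most decoys would be more favourable

The energy model is a pluggable 20x20 contact potential; the shipped
default is a hydropathy-derived statistical table (hydrophobic pairs
favourable), a stand-in of the Miyazawa–Jernigan family. Classifications
under different potentials will differ contact-by-contact; it is the
decoy/Z-score procedure, not any particular potential, that this module
implements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import Residue, Structure

__all__ = [
    "AMINO_ACIDS",
    "ContactPotential",
    "Contact",
    "default_potential",
    "build_contact_map",
    "native_energy",
    "decoy_distribution",
    "classify",
    "z_score",
    "water_mediated",
    "frustration_histogram",
    "frustration_report",
    "MINIMALLY_Z",
    "HIGHLY_Z",
]

log = logging.getLogger(__name__)

AMINO_ACIDS = ("ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY",
               "HIS", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER",
               "THR", "TRP", "TYR", "VAL")

MINIMALLY_Z = 0.78   # Z at or above -> minimally frustrated
HIGHLY_Z = -1.0      # Z strictly below -> highly frustrated

# Kyte-Doolittle hydropathy, used to build the default contact table
_KD = {"ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
       "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
       "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
       "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5}


class EnergyError(KeyError):
    """Residue type absent from the contact potential."""


class DegenerateDecoysError(ValueError):
    """Decoy distribution has zero spread but the native energy differs."""


@dataclass(frozen=True)
class ContactPotential:
    """Symmetric 20x20 pairwise residue-type energies (lower = favourable)."""

    energies: pd.DataFrame
    name: str = "custom"

    def __post_init__(self):
        e = self.energies.reindex(index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS))
        if e.isna().any().any():
            raise ValueError("potential must cover all 20 standard residues")
        if not np.allclose(e.values, e.values.T):
            raise ValueError("contact potential must be symmetric")
        if not np.all(np.isfinite(e.values)):
            raise ValueError("contact potential entries must be finite")
        object.__setattr__(self, "energies", e.astype(float))

    def energy(self, resname_i: str, resname_j: str) -> float:
        try:
            return float(self.energies.at[resname_i, resname_j])
        except KeyError:
            raise EnergyError(
                f"non-standard residue pair ({resname_i}, {resname_j})") from None

    @property
    def matrix(self) -> np.ndarray:
        return self.energies.values

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "ContactPotential":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, name=name or str(path))

    def to_tsv(self, path) -> None:
        self.energies.to_csv(path, sep="\t")


def default_potential(scale: float = 0.2) -> ContactPotential:
    """Hydropathy-derived contact table: e_ij = -scale * (h_i + h_j) / 2.

    Hydrophobic pairs score favourable (negative), polar/charged pairs
    unfavourable — the dominant trend of knowledge-based contact potentials.
    """
    h = np.array([_KD[a] for a in AMINO_ACIDS])
    e = -scale * (h[:, None] + h[None, :]) / 2.0
    df = pd.DataFrame(e, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS))
    return ContactPotential(df, name="hydropathy-contact")


@dataclass
class Contact:
    res_i: Residue
    res_j: Residue
    distance: float
    native_energy: float | None = None
    decoy_mean: float | None = None
    decoy_sd: float | None = None
    z: float | None = None
    frustration_class: str | None = None
    water_mediated: bool = False


def build_contact_map(structure: Structure, cutoff: float = 5.0) -> list[Contact]:
    """Contacts at minimum heavy-atom distance <= cutoff.

    Intra-chain pairs need sequence separation >= 2; inter-chain pairs are
    always eligible.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    heavy = np.nonzero(structure.heavy_mask())[0]
    coords = structure.coords[heavy]
    res_of = structure.atom_residue_index[heavy]
    tree = cKDTree(coords)
    best: dict[tuple[int, int], float] = {}
    for a, b in tree.query_pairs(cutoff):
        ri, rj = int(res_of[a]), int(res_of[b])
        if ri == rj:
            continue
        key = (min(ri, rj), max(ri, rj))
        d = float(np.linalg.norm(coords[a] - coords[b]))
        if d < best.get(key, np.inf):
            best[key] = d
    contacts = []
    for (ri, rj), d in sorted(best.items()):
        res_a, res_b = structure.residues[ri], structure.residues[rj]
        if (res_a.chain_id == res_b.chain_id
                and abs(res_a.resseq - res_b.resseq) < 2):
            continue
        contacts.append(Contact(res_a, res_b, d))
    return contacts


def native_energy(potential: ContactPotential, contact: Contact) -> float:
    return potential.energy(contact.res_i.resname, contact.res_j.resname)


def decoy_distribution(potential: ContactPotential, contact: Contact,
                       mode: str = "exhaustive", n_decoys: int = 10000,
                       seed: int | None = None) -> tuple[float, float]:
    """Mean and SD of decoy energies for a contact.

    Decoys mutate both residue identities jointly. "exhaustive" enumerates
    all 400 ordered identity pairs; "sampled" draws ``n_decoys`` uniform
    pairs (reproducible under ``seed``). SD is the population form.
    """
    m = potential.matrix
    if mode == "exhaustive":
        vals = m.ravel()
    elif mode == "sampled":
        if n_decoys < 2:
            raise ValueError("sampled mode requires n_decoys >= 2")
        if seed is None:
            raise ValueError("sampled mode requires a seed")
        rng = np.random.default_rng(seed)
        ii = rng.integers(0, 20, size=n_decoys)
        jj = rng.integers(0, 20, size=n_decoys)
        vals = m[ii, jj]
    else:
        raise ValueError(f"unknown decoy mode {mode!r}")
    return float(vals.mean()), float(vals.std())


def z_score(native: float, decoy_mean: float, decoy_sd: float) -> float:
    """Z = (decoy_mean - native) / decoy_sd; positive when the native pair
    is more favourable (lower energy) than the typical decoy."""
    if decoy_sd <= 0:
        if np.isclose(native, decoy_mean):
            return 0.0
        raise DegenerateDecoysError(
            "decoy distribution has zero spread but native energy differs")
    return (decoy_mean - native) / decoy_sd


def classify(z: float) -> str:
    """Three-way partition of the Z line; boundaries as printed
    (0.78 inclusive to minimally; -1 itself neutral)."""
    if not np.isfinite(z):
        raise ValueError(f"non-finite z-score {z!r}")
    if z >= MINIMALLY_Z:
        return "minimally"
    if z < HIGHLY_Z:
        return "highly"
    return "neutral"


def water_mediated(structure: Structure, contact: Contact,
                   w_cutoff: float = 3.5) -> bool:
    """True iff some water oxygen bridges the pair: within ``w_cutoff`` of a
    heavy atom of each residue."""
    wc = structure.water_coords
    if len(wc) == 0:
        return False
    heavy = structure.heavy_mask()

    def res_heavy_coords(res):
        ri = structure.residue_index(*res.key)
        idx = [ai for ai in structure.atoms_of_residue(ri) if heavy[ai]]
        return structure.coords[idx]

    ci = res_heavy_coords(contact.res_i)
    cj = res_heavy_coords(contact.res_j)
    for w in wc:
        if (np.linalg.norm(ci - w, axis=1).min() <= w_cutoff
                and np.linalg.norm(cj - w, axis=1).min() <= w_cutoff):
            return True
    return False


def frustration_report(structure: Structure,
                       potential: ContactPotential | None = None,
                       cutoff: float = 5.0, decoy_mode: str = "exhaustive",
                       n_decoys: int = 10000, seed: int | None = None,
                       w_cutoff: float = 3.5) -> list[Contact]:
    """Classify every contact of the structure; deterministic given
    (potential, seed)."""
    if potential is None:
        potential = default_potential()
    contacts = build_contact_map(structure, cutoff)
    for k, c in enumerate(contacts):
        c.native_energy = native_energy(potential, c)
        c.decoy_mean, c.decoy_sd = decoy_distribution(
            potential, c, mode=decoy_mode, n_decoys=n_decoys,
            seed=None if seed is None else seed + k)
        try:
            c.z = z_score(c.native_energy, c.decoy_mean, c.decoy_sd)
            c.frustration_class = classify(c.z)
        except DegenerateDecoysError:
            log.warning("degenerate decoy distribution for %s-%s; forcing neutral",
                        c.res_i, c.res_j)
            c.z = 0.0
            c.frustration_class = "neutral"
        c.water_mediated = water_mediated(structure, c, w_cutoff)
    return contacts


def contacts_to_tsv(contacts: list[Contact]) -> str:
    cols = ("chain_i", "res_i", "chain_j", "res_j", "distance", "native_E",
            "decoy_mean", "decoy_sd", "z", "class", "water_mediated")
    lines = ["\t".join(cols)]
    for c in contacts:
        lines.append("\t".join(map(str, (
            c.res_i.chain_id, c.res_i.resseq, c.res_j.chain_id, c.res_j.resseq,
            f"{c.distance:.3f}", f"{c.native_energy:.4f}",
            f"{c.decoy_mean:.4f}", f"{c.decoy_sd:.4f}", f"{c.z:.4f}",
            c.frustration_class, int(c.water_mediated)))))
    return "\n".join(lines) + "\n"


def frustration_histogram(structure: Structure, contacts: list[Contact],
                          sphere: float = 5.0) -> pd.DataFrame:
    """Per-residue fractions of contact classes within a sphere.

    A contact is attributed to a residue when the midpoint of its two
    closest heavy atoms lies within ``sphere`` of the residue's Calpha.
    Residues with no contacts in their sphere are omitted; each returned
    row's three fractions sum to 1.
    """
    mids, classes = [], []
    heavy = structure.heavy_mask()
    for c in contacts:
        if c.frustration_class is None:
            raise ValueError("contacts must be classified first")
        ri = structure.residue_index(*c.res_i.key)
        rj = structure.residue_index(*c.res_j.key)
        ci = structure.coords[[a for a in structure.atoms_of_residue(ri) if heavy[a]]]
        cj = structure.coords[[a for a in structure.atoms_of_residue(rj) if heavy[a]]]
        d = np.linalg.norm(ci[:, None, :] - cj[None, :, :], axis=2)
        a, b = np.unravel_index(np.argmin(d), d.shape)
        mids.append((ci[a] + cj[b]) / 2.0)
        classes.append(c.frustration_class)
    mids = np.asarray(mids).reshape(-1, 3)
    rows = []
    for ri, res in enumerate(structure.residues):
        ca = structure.find_atom(ri, "CA")
        if ca is None:
            continue
        if len(mids) == 0:
            continue
        within = np.linalg.norm(mids - structure.coords[ca], axis=1) <= sphere
        n = int(within.sum())
        if n == 0:
            continue
        cls = [classes[k] for k in np.nonzero(within)[0]]
        rows.append({
            "chain_id": res.chain_id, "resseq": res.resseq,
            "fraction_highly": cls.count("highly") / n,
            "fraction_neutral": cls.count("neutral") / n,
            "fraction_minimally": cls.count("minimally") / n,
            "n_contacts": n,
        })
    return pd.DataFrame(rows)
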