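"""Dehydron detection: backbone H-bonds, wrapping numbers, statistical flagging.

A dehydron is a solvent-exposed intramolecular backbone hydrogen bond — a
bond poorly "wrapped" by nonpolar CHn groups and therefore vulnerable to
water attack. Wrapping is quantified by rho, the count of carbonaceous
groups inside a desolvation domain (two spheres centred on the donor and
acceptor Calpha atoms). A bond is flagged when its rho falls at or below
the structure mean minus one standard deviation of the rho distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .structure_io import Residue, Structure, carbonaceous_groups, select

__all__ = [
    "HBondCriteria",
    "BackboneHBond",
    "DehydronReport",
    "detect_backbone_hbonds",
    "wrapping_number",
    "flag_dehydrons",
    "dehydron_report",
    "calibrate_radius",
    "DEFAULT_RADIUS",
]

log = logging.getLogger(__name__)

DEFAULT_RADIUS = 6.5  # Å, desolvation-sphere radius about each Calpha


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric backbone H-bond definition.

    max_no_distance: N···O cutoff, Å.
    min_nho_angle: N–H···O angle lower bound, degrees (used when the amide
        hydrogen is present).
    min_cno_angle: C=O···N angle fallback, degrees (hydrogen-free structures).
    min_separation: minimum |i - j| in sequence within a chain; excludes the
        trivial i,i+1 backbone contacts.
    """

    max_no_distance: float = 3.5
    min_nho_angle: float = 120.0
    min_cno_angle: float = 90.0
    min_separation: int = 2


@dataclass
class BackboneHBond:
    donor: Residue
    acceptor: Residue
    donor_N: int      # atom index of donor amide N
    acceptor_O: int   # atom index of acceptor carbonyl O
    no_distance: float
    rho: int | None = None
    is_dehydron: bool = False

    def __post_init__(self):
        if self.donor.key == self.acceptor.key:
            raise ValueError("H-bond donor and acceptor must differ")


@dataclass
class DehydronReport:
    hbonds: list[BackboneHBond]
    rho_mean: float
    rho_sd: float

    @property
    def threshold(self) -> float:
        return self.rho_mean - self.rho_sd

    @property
    def dehydrons(self) -> list[BackboneHBond]:
        return [hb for hb in self.hbonds if hb.is_dehydron]

    def to_tsv(self) -> str:
        cols = ("donor_chain", "donor_resseq", "donor_resname",
                "acceptor_chain", "acceptor_resseq", "acceptor_resname",
                "rho", "is_dehydron")
        lines = ["\t".join(cols)]
        for hb in self.hbonds:
            lines.append("\t".join(map(str, (
                hb.donor.chain_id, hb.donor.resseq, hb.donor.resname,
                hb.acceptor.chain_id, hb.acceptor.resseq, hb.acceptor.resname,
                hb.rho, int(hb.is_dehydron)))))
        lines.append(f"# rho_mean\t{self.rho_mean:.6g}")
        lines.append(f"# rho_sd\t{self.rho_sd:.6g}")
        lines.append(f"# threshold\t{self.threshold:.6g}")
        return "\n".join(lines) + "\n"


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b, degrees."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_backbone_hbonds(structure: Structure,
                           criteria: HBondCriteria = HBondCriteria()
                           ) -> list[BackboneHBond]:
    """Inventory backbone amide-N -> carbonyl-O hydrogen bonds.

    Each donor is paired with at most its nearest qualifying acceptor
    (smallest N···O distance). Prolines cannot donate (no amide hydrogen).
    Residues missing backbone atoms are skipped with a warning.
    """
    coords = structure.coords
    donors, acceptors = [], []
    for ri, res in enumerate(structure.residues):
        n = structure.find_atom(ri, "N")
        ca = structure.find_atom(ri, "CA")
        c = structure.find_atom(ri, "C")
        o = structure.find_atom(ri, "O")
        if n is None or ca is None or c is None or o is None:
            if res.is_standard:
                log.warning("residue %s missing backbone atoms; skipped", res)
            continue
        h = structure.find_atom(ri, "H")
        if h is None:
            h = structure.find_atom(ri, "HN")
        if res.resname != "PRO":
            donors.append((ri, n, h))
        acceptors.append((ri, c, o))

    bonds: list[BackboneHBond] = []
    for ri, n_idx, h_idx in donors:
        res_i = structure.residues[ri]
        best = None
        for rj, c_idx, o_idx in acceptors:
            if ri == rj:
                continue
            res_j = structure.residues[rj]
            if (res_i.chain_id == res_j.chain_id
                    and abs(res_i.resseq - res_j.resseq) < criteria.min_separation):
                continue
            d = float(np.linalg.norm(coords[n_idx] - coords[o_idx]))
            if d > criteria.max_no_distance:
                continue
            if h_idx is not None:
                ang = _angle(coords[n_idx], coords[h_idx], coords[o_idx])
                if ang < criteria.min_nho_angle:
                    continue
            else:
                ang = _angle(coords[c_idx], coords[o_idx], coords[n_idx])
                if ang < criteria.min_cno_angle:
                    continue
            if best is None or d < best[0]:
                best = (d, rj, o_idx)
        if best is not None:
            d, rj, o_idx = best
            bonds.append(BackboneHBond(res_i, structure.residues[rj],
                                       n_idx, o_idx, d))
    return bonds


def wrapping_number(structure: Structure, hbond: BackboneHBond,
                    radius: float = DEFAULT_RADIUS,
                    groups: np.ndarray | None = None) -> int:
    """Count carbonaceous groups inside the two-sphere desolvation domain.

    The domain is the union of two spheres of ``radius`` centred on the
    donor and acceptor Calpha atoms; a group inside both spheres counts
    once, and groups of the donor/acceptor residues themselves count.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    di = structure.residue_index(*hbond.donor.key)
    ai = structure.residue_index(*hbond.acceptor.key)
    d_ca = structure.find_atom(di, "CA")
    a_ca = structure.find_atom(ai, "CA")
    if d_ca is None or a_ca is None:
        raise ValueError(f"H-bond {hbond.donor}->{hbond.acceptor}: missing Calpha")
    if groups is None:
        groups = carbonaceous_groups(structure)
    if len(groups) == 0:
        return 0
    d1 = np.linalg.norm(groups - structure.coords[d_ca], axis=1)
    d2 = np.linalg.norm(groups - structure.coords[a_ca], axis=1)
    return int(np.count_nonzero((d1 <= radius) | (d2 <= radius)))


def flag_dehydrons(hbonds: list[BackboneHBond],
                   sd_mode: str = "population") -> DehydronReport:
    """Flag bonds with rho at or below <rho> - 1 SD (boundary inclusive).

    ``sd_mode`` selects the denominator of the root-mean-squared deviation:
    "population" (n, default) or "sample" (n-1).
    """
    if not hbonds:
        raise ValueError("cannot build a dehydron report from zero H-bonds")
    if any(hb.rho is None for hb in hbonds):
        raise ValueError("all H-bonds must carry a wrapping number")
    rhos = np.array([hb.rho for hb in hbonds], dtype=float)
    mean = float(rhos.mean())
    ddof = 0 if sd_mode == "population" else 1
    sd = float(rhos.std(ddof=ddof)) if len(rhos) > ddof else 0.0
    thr = mean - sd
    flagged = [replace(hb, is_dehydron=bool(hb.rho <= thr)) for hb in hbonds]
    return DehydronReport(flagged, mean, sd)


def dehydron_report(structure: Structure, radius: float = DEFAULT_RADIUS,
                    criteria: HBondCriteria = HBondCriteria(),
                    sd_mode: str = "population") -> DehydronReport:
    """Full dehydron analysis: detect bonds, wrap, flag. Deterministic."""
    bonds = detect_backbone_hbonds(structure, criteria)
    if not bonds:
        raise ValueError("no backbone hydrogen bonds detected")
    groups = carbonaceous_groups(structure)
    for hb in bonds:
        hb.rho = wrapping_number(structure, hb, radius, groups=groups)
    return flag_dehydrons(bonds, sd_mode=sd_mode)


def calibrate_radius(structure: Structure, donor_key, acceptor_key,
                     target_rho: int, target_mean: float,
                     radii=np.arange(6.0, 7.01, 0.1),
                     criteria: HBondCriteria = HBondCriteria()) -> dict:
    """Sweep the desolvation radius and score against a reference bond.

    For each radius, runs the full report and records the wrapping number of
    the (donor_key, acceptor_key) bond and the mean rho. Returns the sweep
    table plus the radius minimising |rho - target_rho| + |mean - target_mean|.
    Keys are (chain_id, resseq, icode) triples.
    """
    rows = []
    for r in np.asarray(radii, dtype=float):
        rep = dehydron_report(structure, radius=float(r), criteria=criteria)
        bond = next((hb for hb in rep.hbonds
                     if hb.donor.key == tuple(donor_key)
                     and hb.acceptor.key == tuple(acceptor_key)), None)
        rows.append({
            "radius": float(r),
            "bond_rho": None if bond is None else bond.rho,
            "bond_flagged": None if bond is None else bond.is_dehydron,
            "rho_mean": rep.rho_mean,
        })
    scored = [row for row in rows if row["bond_rho"] is not None]
    best = min(scored, key=lambda row: abs(row["bond_rho"] - target_rho)
               + abs(row["rho_mean"] - target_mean), default=None)
    return {"sweep": rows, "best": best,
            "target_rho": target_rho, "target_mean": target_mean}
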