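"""Synthetic structure and trajectory generators with emitted ground truth.

Every fixture the analysis stages need is generated here, deterministically
under a seed, together with the quantity it plants (H-bond lists, wrapping
counts, analytic fluctuations, mode shapes), so each stage can be tested
against a known answer without external structure downloads.

The restrained Gaussian-network generator is a desk-scale statistical
surrogate for restrained explicit-solvent MD of a two-chain dimer. Its
"restraint" protocol emulates an oligomer contact on one loop: the loop is
pinned to its reference position AND its native cross-chain couplings are
removed (the oligomer interface displaces them). Pinning alone can only
lower variances in a harmonic network — the partner-loop disorder increase
seen in restrained simulations is a contact-replacement effect, and that is
what this generator models. Absolute magnitudes are not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Atom, Residue, Structure, Trajectory

__all__ = [
    "GNMSpec",
    "build_ideal_helix",
    "build_dehydron_helix",
    "build_wrapping_fixture",
    "sod1_like_dimer_spec",
    "sample_gnm_trajectory",
    "plant_collective_mode",
    "add_bridging_water",
]


class FixtureError(ValueError):
    """Requested fixture geometry is infeasible."""


# ---------------------------------------------------------------------------
# backbone construction (NeRF internal-coordinate placement)

_B_NCA, _B_CAC, _B_CN, _B_CO, _B_NH, _B_CACB = 1.458, 1.525, 1.329, 1.231, 1.010, 1.530
_A_CNCA, _A_NCAC, _A_CACN, _A_CACO = 121.7, 111.2, 116.2, 120.5
_HELIX_PHI, _HELIX_PSI = -57.0, -47.0


def _place(a, b, c, bond, angle, torsion):
    """Next-atom placement from three reference positions (NeRF)."""
    angle, torsion = np.radians(angle), np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(angle),
                  bond * np.sin(angle) * np.cos(torsion),
                  bond * np.sin(angle) * np.sin(torsion)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_backbone(n: int, phi: float, psi: float, omega: float = 180.0,
                    sequence: str | None = None, chain_id: str = "A",
                    start_resseq: int = 1):
    """Backbone (N, CA, C, O, H, CB) coordinates for a repeating (phi, psi)."""
    seq = sequence or "A" * n
    one2three = {"A": "ALA", "G": "GLY"}
    pos = {}  # (resseq, name) -> coords
    # seed triad for residue 1
    pos[(0, "N")] = np.array([0.0, 0.0, 0.0])
    pos[(0, "CA")] = np.array([_B_NCA, 0.0, 0.0])
    ang = np.radians(180.0 - _A_NCAC)
    pos[(0, "C")] = pos[(0, "CA")] + _B_CAC * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(n):
        if i > 0:
            pos[(i, "N")] = _place(pos[(i - 1, "N")], pos[(i - 1, "CA")],
                                   pos[(i - 1, "C")], _B_CN, _A_CACN, psi)
            pos[(i, "CA")] = _place(pos[(i - 1, "CA")], pos[(i - 1, "C")],
                                    pos[(i, "N")], _B_NCA, _A_CNCA, omega)
            pos[(i, "C")] = _place(pos[(i - 1, "C")], pos[(i, "N")],
                                   pos[(i, "CA")], _B_CAC, _A_NCAC, phi)
    for i in range(n):
        # carbonyl O: anti to the next amide N across the peptide plane
        nxt = pos.get((i + 1, "N"))
        if nxt is None:
            nxt = _place(pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")],
                         _B_CN, _A_CACN, psi)
        pos[(i, "O")] = _place(nxt, pos[(i, "CA")], pos[(i, "C")], _B_CO, _A_CACO,
                               180.0)
        # amide H: in-plane, opposite the bisector of the two N neighbours
        if i > 0:
            u1 = pos[(i - 1, "C")] - pos[(i, "N")]
            u2 = pos[(i, "CA")] - pos[(i, "N")]
            u = u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2)
            pos[(i, "H")] = pos[(i, "N")] - _B_NH * u / np.linalg.norm(u)
        if seq[i] != "G":
            pos[(i, "CB")] = _place(pos[(i, "N")], pos[(i, "C")], pos[(i, "CA")],
                                    _B_CACB, 110.1, 122.6)

    residues, atoms, res_idx = [], [], []
    serial = 0
    for i in range(n):
        residues.append(Residue(chain_id, start_resseq + i, "",
                                one2three.get(seq[i], "ALA")))
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"),
                              ("H", "H"), ("CB", "C")):
            if (i, name) not in pos:
                continue
            serial += 1
            atoms.append(Atom(serial, name, element, pos[(i, name)]))
            res_idx.append(i)
    return Structure(residues, atoms, res_idx)


def build_ideal_helix(n: int, sequence: str | None = None,
                      chain_id: str = "A"):
    """Ideal alpha-helix with its ground-truth i -> i-4 backbone H-bonds.

    Returns ``(structure, bonds)`` where bonds are (donor_resseq,
    acceptor_resseq) pairs for donors i in [5, n]; the helical geometry
    (phi = -57, psi = -47) satisfies standard H-bond criteria by
    construction.
    """
    if n < 5:
        raise FixtureError("an alpha-helix fixture needs n >= 5 residues")
    s = _build_backbone(n, _HELIX_PHI, _HELIX_PSI, sequence=sequence,
                        chain_id=chain_id)
    bonds = [(i, i - 4) for i in range(5, n + 1)]
    return s, bonds


def build_dehydron_helix(n: int = 30, stripped_donor: int | None = None):
    """Helix whose wrapping is uniform except around one deliberately
    under-wrapped bond.

    Poly-alanine side chains (CB groups) provide dense uniform wrapping;
    when ``stripped_donor`` is given, residues [donor-4, donor] are built
    as glycine, removing the CHn groups around that bond's desolvation
    domain. Returns ``(structure, bonds, stripped_bond)``.
    """
    seq = ["A"] * n
    stripped = None
    if stripped_donor is not None:
        if not 5 <= stripped_donor <= n:
            raise FixtureError("stripped donor outside helix bond range")
        for r in range(stripped_donor - 4, stripped_donor + 1):
            seq[r - 1] = "G"
        stripped = (stripped_donor, stripped_donor - 4)
    s, bonds = build_ideal_helix(n, sequence="".join(seq))
    return s, bonds, stripped


def build_wrapping_fixture(n_inside: int, n_outside: int,
                           radius: float = 6.5, seed: int = 0):
    """Minimal H-bonded pair with an exact planted wrapping count.

    Two glycine-like residues form one backbone H-bond (their own backbone
    contributes zero carbonaceous groups); ``n_inside`` lone carbon probes
    are placed inside the two-sphere desolvation domain (>= 0.5 Å from its
    boundary) and ``n_outside`` outside it, all >= 2.5 Å from any other
    atom so none acquires a bond to N/O/S. Returns ``(structure, hbond
    residue keys)``; wrapping_number at ``radius`` equals ``n_inside``.
    """
    if n_inside < 0 or n_outside < 0:
        raise FixtureError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    # donor residue backbone (resseq 1) and acceptor (resseq 5), aligned so
    # that donor N-H points at the acceptor O at 2.95 Å.
    donor = {
        "N": np.array([0.0, 0.0, 0.0]),
        "H": np.array([0.0, 0.0, 1.01]),
        "CA": np.array([1.32, 0.0, -0.60]),
        "C": np.array([2.40, 1.05, -0.60]),
        "O": np.array([2.40, 2.28, -0.60]),
    }
    acceptor = {
        "O": np.array([0.0, 0.0, 2.95]),
        "C": np.array([0.0, 0.0, 4.18]),
        "CA": np.array([1.25, 0.0, 4.95]),
        "N": np.array([1.25, 0.0, 6.41]),
    }
    residues = [Residue("A", 1, "", "GLY"), Residue("A", 5, "", "GLY")]
    atoms, res_idx = [], []
    serial = 0
    for name in ("N", "CA", "C", "O", "H"):
        serial += 1
        atoms.append(Atom(serial, name, name[0], donor[name]))
        res_idx.append(0)
    for name in ("N", "CA", "C", "O"):
        serial += 1
        atoms.append(Atom(serial, name, name[0], acceptor[name]))
        res_idx.append(1)

    centers = np.stack([donor["CA"], acceptor["CA"]])
    occupied = [a.coords for a in atoms]

    def far_enough(p):
        return all(np.linalg.norm(p - q) >= 2.5 for q in occupied)

    def sample_inside():
        for _ in range(20000):
            c = centers[rng.integers(2)]
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            p = c + v * (rng.random() ** (1 / 3)) * (radius - 0.5)
            if far_enough(p):
                return p
        raise FixtureError("cannot pack requested inside groups")

    def sample_outside():
        for _ in range(20000):
            c = centers[rng.integers(2)]
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            p = c + v * (radius + 0.5 + rng.random() * 3.0)
            if (np.linalg.norm(p - centers[0]) > radius + 0.5
                    and np.linalg.norm(p - centers[1]) > radius + 0.5
                    and far_enough(p)):
                return p
        raise FixtureError("cannot place outside groups")

    probes = [sample_inside() for _ in range(n_inside)]
    probes += [sample_outside() for _ in range(n_outside)]
    for k, p in enumerate(probes):
        occupied.append(p)
        residues.append(Residue("P", 100 + k, "", "CHX"))
        serial += 1
        atoms.append(Atom(serial, "C1", "C", p))
        res_idx.append(len(residues) - 1)

    return Structure(residues, atoms, res_idx), (("A", 1, ""), ("A", 5, ""))


# ---------------------------------------------------------------------------
# Gaussian-network trajectories

@dataclass
class GNMSpec:
    """Two-chain Gaussian-network specification (Calpha level).

    The dimer mimics SOD1 labelling: chains A and F, an "electrostatic
    loop" block EL (residues 121-142) and a "zinc-binding loop" block ZL
    (residues 50-83) per chain, with explicit EL(A)-EL(F) coupling springs.
    Fluctuation variance scales with ``temperature_scale`` (Å²) and
    inversely with spring stiffness.
    """

    n_residues: int = 153            # per chain
    chains: tuple[str, str] = ("A", "F")
    cutoff: float = 7.0              # Å, native-contact spring range
    gamma: float = 1.0               # native spring constant
    el_range: tuple[int, int] = (121, 142)
    zl_range: tuple[int, int] = (50, 83)
    coupling_edges: tuple = ()       # extra ((chain,res),(chain,res),k) springs
    restrained: tuple = ()           # residue (chain, resseq) pairs to pin
    restraint_k: float = 100.0
    restraint_replaces_contacts: bool = True
    temperature_scale: float = 1.0   # Å²
    disulfide: tuple | None = (("A", 57), ("A", 146))  # extra spring; None = reduced
    disulfide_k: float = 5.0
    seed: int = 0


def sod1_like_dimer_spec(**overrides) -> GNMSpec:
    """Dimer spec with EL(A)<->EL(F) coupling springs planted, so that the
    partner electrostatic loop is natively stabilised across the interface."""
    el_lo, el_hi = overrides.pop("el_range", (121, 142))
    edges = tuple((("A", r), ("F", el_lo + el_hi - r), 1.0)
                  for r in range(el_lo, el_hi + 1))
    return GNMSpec(el_range=(el_lo, el_hi), coupling_edges=edges, **overrides)


def _dimer_topology(spec: GNMSpec) -> Structure:
    """Calpha trace: each chain a compact coarse helix, chains side by side."""
    n = spec.n_residues
    rise, rad = 0.8, 5.0
    dtheta = np.sqrt(3.8 ** 2 - rise ** 2) / rad
    residues, atoms, res_idx = [], [], []
    serial = 0
    for c, chain in enumerate(spec.chains):
        shift = np.array([13.0 * c, 0.0, 0.0])
        for i in range(n):
            th = i * dtheta + (np.pi if c else 0.0)
            p = np.array([rad * np.cos(th), rad * np.sin(th), rise * i]) + shift
            residues.append(Residue(chain, i + 1, "", "GLY"))
            serial += 1
            atoms.append(Atom(serial, "CA", "C", p))
            res_idx.append(len(residues) - 1)
    return Structure(residues, atoms, res_idx)


def _kirchhoff(spec: GNMSpec, structure: Structure) -> np.ndarray:
    coords = structure.coords
    nn = len(coords)
    K = np.zeros((nn, nn))

    def add_spring(i, j, k):
        K[i, i] += k
        K[j, j] += k
        K[i, j] -= k
        K[j, i] -= k

    tree = cKDTree(coords)
    for i, j in tree.query_pairs(spec.cutoff):
        add_spring(i, j, spec.gamma)

    def idx(chain, resseq):
        return structure.residue_index(chain, resseq, "")

    for (a, b, k) in spec.coupling_edges:
        add_spring(idx(*a), idx(*b), k)
    if spec.disulfide is not None:
        add_spring(idx(*spec.disulfide[0]), idx(*spec.disulfide[1]),
                   spec.disulfide_k)

    restrained = {idx(*r) for r in spec.restrained}
    if restrained and spec.restraint_replaces_contacts:
        # the oligomer contact displaces the pinned loop's cross-chain
        # couplings; remove springs from restrained residues to the other chain
        for i in restrained:
            chain_i = structure.residues[i].chain_id
            for j in range(nn):
                if j == i or K[i, j] == 0.0:
                    continue
                if structure.residues[j].chain_id != chain_i:
                    k = -K[i, j]
                    add_spring(i, j, -k)
    for i in restrained:
        K[i, i] += spec.restraint_k
    return K


def gnm_analytic_rmsf(spec: GNMSpec, structure: Structure | None = None,
                      tol: float = 1e-8) -> np.ndarray:
    """Analytic per-residue RMSF: sqrt(3 * T * pinv(K)_ii), Å."""
    structure = structure or _dimer_topology(spec)
    K = _kirchhoff(spec, structure)
    w, V = np.linalg.eigh(K)
    nz = w > tol * w.max()
    if not nz.any():
        raise ValueError("stiffness matrix singular beyond rigid modes")
    diag = ((V[:, nz] ** 2) / w[nz]).sum(axis=1)
    return np.sqrt(3.0 * spec.temperature_scale * diag)


def sample_gnm_trajectory(spec: GNMSpec, n_frames: int,
                          dt_ns: float = 0.002, tol: float = 1e-8):
    """Draw frames from the network's Gaussian ensemble.

    Each Cartesian component of the displacement field is an independent
    draw from N(0, T * pinv(K)). Returns ``(trajectory, analytic_rmsf)``
    with the analytic per-residue fluctuation for oracle tests;
    byte-reproducible under ``spec.seed``.
    """
    structure = _dimer_topology(spec)
    K = _kirchhoff(spec, structure)
    w, V = np.linalg.eigh(K)
    nz = w > tol * w.max()
    if not nz.any():
        raise ValueError("stiffness matrix singular beyond rigid modes")
    Vnz, amp = V[:, nz], np.sqrt(spec.temperature_scale / w[nz])
    rng = np.random.default_rng(spec.seed)
    nn, nm = K.shape[0], int(nz.sum())
    frames = np.empty((n_frames, nn, 3))
    ref = structure.coords
    for d in range(3):
        z = rng.standard_normal((n_frames, nm))
        frames[:, :, d] = ref[:, d] + (z * amp) @ Vnz.T
    times = np.arange(n_frames) * dt_ns
    diag = ((Vnz ** 2) / w[nz]).sum(axis=1)
    analytic = np.sqrt(3.0 * spec.temperature_scale * diag)
    return Trajectory(structure, frames, times), analytic


def plant_collective_mode(base: Trajectory, mode_shape: np.ndarray,
                          amplitude_series: np.ndarray) -> Trajectory:
    """Displace each frame by amplitude[f] * mode_shape (per-atom 3-vectors)."""
    shape = np.asarray(mode_shape, dtype=float)
    amps = np.asarray(amplitude_series, dtype=float)
    if shape.shape != (base.n_atoms, 3):
        raise FixtureError(f"mode shape {shape.shape} does not match "
                           f"topology ({base.n_atoms}, 3)")
    if amps.shape != (base.n_frames,):
        raise FixtureError("amplitude series length must equal frame count")
    frames = base.frames + amps[:, None, None] * shape[None, :, :]
    return Trajectory(base.topology, frames, base.times.copy())


def breathing_mode_shape(topology: Structure, sel_A, sel_B,
                         axis: int = 0, antisymmetric: bool = True) -> np.ndarray:
    """Unit-norm per-atom mode: block A moves along ``axis``, block B moves
    opposite (antisymmetric, the breathing signature) or parallel.

    Antisymmetric shapes carry no net translation, so superposition leaves
    them intact — use these for planted-mode recovery fixtures.
    """
    shape = np.zeros((topology.n_atoms, 3))
    shape[np.asarray(sel_A, dtype=int), axis] = 1.0
    shape[np.asarray(sel_B, dtype=int), axis] = -1.0 if antisymmetric else 1.0
    n = np.linalg.norm(shape)
    if n == 0:
        raise FixtureError("empty selections give a zero mode shape")
    return shape / n


def add_bridging_water(structure: Structure, res_key_i, res_key_j,
                       d: float = 2.8) -> Structure:
    """Place one water oxygen within ``d`` of a heavy atom of each residue.

    The water sits on the segment between the residues' two closest heavy
    atoms; if that gap exceeds 2d the placement is infeasible.
    """
    heavy = structure.heavy_mask()

    def heavy_coords(key):
        key = tuple(key) if len(key) == 3 else (key[0], key[1], "")
        ri = structure.residue_index(*key)
        return structure.coords[[a for a in structure.atoms_of_residue(ri)
                                 if heavy[a]]]

    ci, cj = heavy_coords(res_key_i), heavy_coords(res_key_j)
    dist = np.linalg.norm(ci[:, None, :] - cj[None, :, :], axis=2)
    a, b = np.unravel_index(np.argmin(dist), dist.shape)
    gap = dist[a, b]
    if gap > 2 * d:
        raise FixtureError(
            f"closest heavy atoms are {gap:.2f} Å apart; no point lies "
            f"within {d} Å of both residues")
    mid = (ci[a] + cj[b]) / 2.0
    serial = max([at.serial for at in structure.atoms]
                 + [w.serial for w in structure.waters], default=0) + 1
    waters = list(structure.waters) + [Atom(serial, "O", "O", mid)]
    return Structure(structure.residues, structure.atoms,
                     structure.atom_residue_index, waters)
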