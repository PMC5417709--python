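"""Trajectory analytics: superposition, RMSF, distance series, PCA modes.

Implements the analyses used to characterise restrained-dimer dynamics:
least-squares superposition onto an iteratively refined mean structure,
per-residue root-mean-square fluctuations over the full run or a
sub-window, residue-pair distance time series with a two-window
change-point scan, principal component analysis of the coordinate
covariance, and a coupling score quantifying whether two regions move
together within one collective mode (the "breathing" signature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import SelectionError, Structure, Trajectory

__all__ = [
    "FluctuationProfile",
    "DistanceSeries",
    "CollectiveMode",
    "superpose",
    "rmsf",
    "distance_series",
    "detect_transitions",
    "pca_modes",
    "mode_coupling",
]


@dataclass
class FluctuationProfile:
    selection: np.ndarray          # Calpha atom indices
    window: tuple[int, int]        # frame interval [lo, hi)
    rmsf: np.ndarray               # per-selected-atom, Å
    residue_labels: list[str]


@dataclass
class DistanceSeries:
    pair: tuple[str, str]
    mode: str                      # "min" (min heavy-atom) or "ca"
    values: np.ndarray             # Å
    times: np.ndarray              # ns


@dataclass
class CollectiveMode:
    eigenvector: np.ndarray        # (n_sel_atoms, 3), unit norm
    eigenvalue: float              # Å²
    rank: int
    atom_indices: np.ndarray


@dataclass
class ChangePoint:
    frame: int
    time: float
    before_mean: float
    after_mean: float


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t mapping P onto Q (least squares)."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, qc - R @ pc


def superpose(traj: Trajectory, fit_selection: np.ndarray,
              max_iter: int = 20, tol: float = 1e-8) -> Trajectory:
    """Fit every frame onto the iteratively refined mean of the selection.

    Each iteration fits all frames to the current selection-mean structure,
    then recomputes the mean; stops when the mean moves less than ``tol``
    (RMS, Å). The whole frame is transformed; only ``fit_selection`` drives
    the fit, so e.g. fitting on chain A leaves chain B free to fluctuate.
    """
    sel = np.asarray(fit_selection, dtype=int)
    if sel.size < 3:
        raise ValueError("fit selection needs at least 3 atoms")
    ref = traj.frames[0][sel]
    if np.linalg.matrix_rank(ref - ref.mean(axis=0)) < 2:
        raise ValueError("degenerate (collinear) fit selection")
    frames = traj.frames.copy()
    mean = frames[:, sel].mean(axis=0)
    for _ in range(max_iter):
        for f in range(frames.shape[0]):
            R, t = _kabsch(frames[f][sel], mean)
            frames[f] = frames[f] @ R.T + t
        new_mean = frames[:, sel].mean(axis=0)
        if np.sqrt(np.mean((new_mean - mean) ** 2)) < tol:
            mean = new_mean
            break
        mean = new_mean
    return Trajectory(traj.topology, frames, traj.times.copy())


def _ca_indices(structure: Structure, selection: np.ndarray | None) -> np.ndarray:
    names = structure.atom_names
    ca = np.nonzero(names == "CA")[0]
    if selection is None:
        return ca
    return np.intersect1d(ca, np.asarray(selection, dtype=int))


def rmsf(traj: Trajectory, selection: np.ndarray | None = None,
         window: tuple[int, int] | None = None) -> FluctuationProfile:
    """Per-residue Calpha RMSF over a frame window.

    RMSF_i = sqrt(<|r_i - <r_i>_window|^2>_window); the window's own mean
    is the reference, so a sub-window profile reflects fluctuation within
    that period only.
    """
    ca = _ca_indices(traj.topology, selection)
    if ca.size == 0:
        raise SelectionError("selection contains no Calpha atoms")
    lo, hi = window if window is not None else (0, traj.n_frames)
    if not (0 <= lo < hi <= traj.n_frames) or hi - lo < 2:
        raise ValueError(f"window [{lo}, {hi}) invalid for {traj.n_frames} frames")
    X = traj.frames[lo:hi][:, ca, :]
    dev = X - X.mean(axis=0)
    vals = np.sqrt(np.mean(np.sum(dev ** 2, axis=2), axis=0))
    labels = [str(traj.topology.residues[traj.topology.atom_residue_index[a]])
              for a in ca]
    return FluctuationProfile(ca, (lo, hi), vals, labels)


def distance_series(traj: Trajectory, res_key_i, res_key_j,
                    mode: str = "min") -> DistanceSeries:
    """Per-frame distance between two residues.

    ``mode='min'`` is the minimum heavy-atom distance; ``mode='ca'`` is
    the Calpha–Calpha distance. Residue keys are (chain, resseq[, icode]).
    """
    top = traj.topology
    ri = top.residue_index(*_norm_key(res_key_i))
    rj = top.residue_index(*_norm_key(res_key_j))
    if mode == "ca":
        ai, aj = top.find_atom(ri, "CA"), top.find_atom(rj, "CA")
        if ai is None or aj is None:
            raise SelectionError("Calpha missing for distance pair")
        vals = np.linalg.norm(traj.frames[:, ai] - traj.frames[:, aj], axis=1)
    elif mode == "min":
        heavy = top.heavy_mask()
        ia = [a for a in top.atoms_of_residue(ri) if heavy[a]]
        ja = [a for a in top.atoms_of_residue(rj) if heavy[a]]
        diff = traj.frames[:, ia, None, :] - traj.frames[:, None, ja, :]
        vals = np.sqrt((diff ** 2).sum(axis=3)).min(axis=(1, 2))
    else:
        raise ValueError(f"unknown distance mode {mode!r}")
    pair = (str(top.residues[ri]), str(top.residues[rj]))
    return DistanceSeries(pair, mode, vals, traj.times.copy())


def _norm_key(key):
    key = tuple(key)
    return key if len(key) == 3 else (key[0], key[1], "")


def detect_transitions(series: DistanceSeries, min_shift: float = 2.0,
                       min_dwell: int = 50) -> list[ChangePoint]:
    """Two-window mean-shift scan for abrupt distance changes.

    At each frame f, compares the mean over the leading ``min_dwell``
    frames against the trailing ``min_dwell`` frames; a change point is
    reported at the local maximum of |shift| within each excursion above
    ``min_shift``. Greedy left-to-right; deterministic.
    """
    v = np.asarray(series.values, dtype=float)
    n = len(v)
    if n < 2 * min_dwell:
        raise ValueError("series shorter than 2 x min_dwell")
    csum = np.concatenate([[0.0], np.cumsum(v)])

    def wmean(a, b):  # mean of v[a:b]
        return (csum[b] - csum[a]) / (b - a)

    shifts = np.zeros(n)
    for f in range(min_dwell, n - min_dwell + 1):
        shifts[f] = wmean(f, f + min_dwell) - wmean(f - min_dwell, f)
    out: list[ChangePoint] = []
    f = min_dwell
    while f <= n - min_dwell:
        if abs(shifts[f]) > min_shift:
            # extend the excursion and take the strongest frame in it
            g = f
            while g <= n - min_dwell and abs(shifts[g]) > min_shift:
                g += 1
            best = max(range(f, g), key=lambda k: abs(shifts[k]))
            out.append(ChangePoint(best, float(series.times[best]),
                                   wmean(best - min_dwell, best),
                                   wmean(best, best + min_dwell)))
            f = g + min_dwell  # dwell before another transition can start
        else:
            f += 1
    return out


def pca_modes(traj: Trajectory, selection: np.ndarray | None = None,
              n_modes: int = 5) -> list[CollectiveMode]:
    """Principal components of the Calpha coordinate covariance.

    Frames must be pre-superposed. Eigenvectors are unit-norm per-atom
    3-vector fields, sorted by decreasing eigenvalue (Å²); rank-deficient
    covariances simply yield trailing zero eigenvalues.
    """
    if traj.n_frames < 3:
        raise ValueError("PCA requires at least 3 frames")
    ca = _ca_indices(traj.topology, selection)
    X = traj.frames[:, ca, :].reshape(traj.n_frames, -1)
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / Xc.shape[0]
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    modes = []
    for rank, k in enumerate(order[:n_modes], start=1):
        vec = V[:, k].reshape(-1, 3)
        modes.append(CollectiveMode(vec, float(max(w[k], 0.0)), rank, ca))
    return modes


def mode_coupling(mode: CollectiveMode, sel_A: np.ndarray,
                  sel_B: np.ndarray) -> float:
    """Cosine similarity of a mode's mean displacement over two regions.

    Selections are atom indices (must appear in the mode's atom set, be
    disjoint and non-empty). |coupling| near 1 means the two regions move
    along a common axis within this mode — the breathing-motion signature.
    """
    sel_A = np.asarray(sel_A, dtype=int)
    sel_B = np.asarray(sel_B, dtype=int)
    if sel_A.size == 0 or sel_B.size == 0:
        raise ValueError("selections must be non-empty")
    if np.intersect1d(sel_A, sel_B).size:
        raise ValueError("selections must be disjoint")
    pos = {a: i for i, a in enumerate(mode.atom_indices)}
    try:
        va = mode.eigenvector[[pos[a] for a in sel_A]].mean(axis=0)
        vb = mode.eigenvector[[pos[b] for b in sel_B]].mean(axis=0)
    except KeyError as e:
        raise SelectionError(f"atom {e} not in mode's atom set") from None
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("zero mean displacement in a selection; coupling undefined")
    return float(np.dot(va, vb) / (na * nb))
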