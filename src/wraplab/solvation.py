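"""Solvation free-energy bookkeeping for bound-water-mediated interactions.

Combines an externally supplied enthalpy (e.g. from a QM computation on a
residue/water cluster) with a per-bound-water entropic penalty, converts
the total to thermal-energy (kT) units, and evaluates whether the
stabilisation clears the macromolecular-crowding significance threshold.

Conventions: the entropic correction enters with positive sign — each
immobilised water costs +T*dS against a favourable (negative) enthalpy.
kT is the per-molecule thermal energy expressed in molar units,
k_B = 0.0019872 kcal/(mol K), so 1 kT ~ 0.592 kcal/mol at 298 K.
"""

from __future__ import annotations

from dataclasses import dataclass

K_B_KCAL = 0.0019872  # kcal mol^-1 K^-1
DEFAULT_TDS_PER_WATER = 7.5  # kcal/mol entropic cost per bound water at 298 K
DEFAULT_CROWDING_THRESHOLD_KT = 3.0  # conformers must gain > ~3-4 kT to matter

__all__ = [
    "SolvationEstimate",
    "solvation_free_energy",
    "to_kT",
    "from_kT",
    "crowding_significant",
    "K_B_KCAL",
    "DEFAULT_TDS_PER_WATER",
]


@dataclass(frozen=True)
class SolvationEstimate:
    delta_H: float          # kcal/mol
    n_waters: int
    T: float                # K
    TdS_per_water: float    # kcal/mol
    delta_G: float          # kcal/mol
    kT_units: float

    @property
    def crowding_significant(self) -> bool:
        return crowding_significant(abs(self.kT_units))


def solvation_free_energy(delta_H: float, n_waters: int, T: float = 298.0,
                          TdS_per_water: float = DEFAULT_TDS_PER_WATER
                          ) -> SolvationEstimate:
    """dG = dH + n_waters * TdS_per_water, with the kT conversion attached."""
    if T <= 0:
        raise ValueError(f"non-physical temperature {T} K")
    if n_waters < 0:
        raise ValueError("n_waters must be non-negative")
    dG = delta_H + n_waters * TdS_per_water
    return SolvationEstimate(delta_H, int(n_waters), float(T),
                             float(TdS_per_water), dG, to_kT(dG, T))


def to_kT(delta_G: float, T: float = 298.0) -> float:
    """Convert kcal/mol to kT units at temperature T; linear, sign-preserving."""
    if T <= 0:
        raise ValueError(f"non-physical temperature {T} K")
    return delta_G / (K_B_KCAL * T)


def from_kT(kt: float, T: float = 298.0) -> float:
    """Inverse of :func:`to_kT`."""
    if T <= 0:
        raise ValueError(f"non-physical temperature {T} K")
    return kt * K_B_KCAL * T


def crowding_significant(kT_magnitude: float,
                         threshold: float = DEFAULT_CROWDING_THRESHOLD_KT) -> bool:
    """True iff the stabilisation magnitude strictly exceeds the threshold
    (default 3 kT; the crowding literature quotes "greater than about 3-4 kT")."""
    if kT_magnitude < 0:
        raise ValueError("kT_magnitude must be non-negative")
    return kT_magnitude > threshold
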