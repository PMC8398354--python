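"""Approximate per-atom van der Waals surface areas (VSA).

Each atom is a sphere of vdW radius R; for every bonded neighbour the
spherical cap cut off by the neighbour's sphere — placed at an idealised
bond length d, clamped to [|R_i − R_j|, R_i + R_j] — is subtracted:

    A_i = 4πR_i² − Σ_j 2πR_i · h_ij,
    h_ij = R_i − (d² + R_i² − R_j²) / (2d).

Implicit hydrogens are treated as pseudo-neighbours of their heavy atom and
their own residual sphere area is folded back into it, so the reported
per-heavy-atom areas sum to the full molecular surface. Bondi vdW radii and
Cordero covalent radii (ideal bond length = sum of covalent radii) are used
throughout; descriptor identities hold for any consistent radii set.
"""

from __future__ import annotations

import math

from .chem import MoleculeGraph

# Bondi van der Waals radii, Å.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Ne": 1.54, "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75, "Ar": 1.88,
    "As": 1.85, "Se": 1.90, "Br": 1.85, "Kr": 2.02, "I": 1.98, "Xe": 2.16,
}

# Cordero covalent radii, Å (single-bond values; C is sp3).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Ne": 0.58, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Ar": 1.06,
    "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16, "I": 1.39, "Xe": 1.40,
}


class MissingRadiusError(ValueError):
    """Raised for elements with no tabulated vdW/covalent radius."""


def sphere_area(symbol: str) -> float:
    """Full sphere area 4πR² for an element's vdW radius."""
    return 4.0 * math.pi * _vdw(symbol) ** 2


def cap_area(r_center: float, r_neighbour: float, d: float) -> float:
    """Area of the cap cut from the center sphere by a neighbour at d.

    d is clamped to [|R_i − R_j|, R_i + R_j]; at the lower clamp the cap is
    the full sphere (engulfed) if the neighbour is larger, zero otherwise.
    """
    d = min(max(d, abs(r_center - r_neighbour)), r_center + r_neighbour)
    if d == 0.0:  # coincident spheres of equal radius
        return 2.0 * math.pi * r_center ** 2
    h = r_center - (d * d + r_center * r_center - r_neighbour * r_neighbour) / (2.0 * d)
    h = min(max(h, 0.0), 2.0 * r_center)
    return 2.0 * math.pi * r_center * h


def atom_vsa(mol: MoleculeGraph) -> list[float]:
    """Per-heavy-atom approximate vdW surface areas, Å².

    Implicit-hydrogen surface is folded into the bonded heavy atom. Every
    entry is ≥ 0.

    Raises
    ------
    MissingRadiusError
        If an element has no tabulated radius.
    """
    symbols = [a[0] for a in mol.atoms]
    n_hs = [a[3] for a in mol.atoms]
    areas = [4.0 * math.pi * _vdw(s) ** 2 for s in symbols]

    for i, j, _order, _arom in mol.bonds:
        d = _ideal_length(symbols[i], symbols[j])
        areas[i] -= cap_area(_vdw(symbols[i]), _vdw(symbols[j]), d)
        areas[j] -= cap_area(_vdw(symbols[j]), _vdw(symbols[i]), d)

    r_h = _vdw("H")
    for i, sym in enumerate(symbols):
        if n_hs[i] == 0:
            continue
        d = _ideal_length(sym, "H")
        areas[i] -= n_hs[i] * cap_area(_vdw(sym), r_h, d)
        h_residual = 4.0 * math.pi * r_h ** 2 - cap_area(r_h, _vdw(sym), d)
        areas[i] += n_hs[i] * max(h_residual, 0.0)

    return [max(a, 0.0) for a in areas]


def total_vsa(mol: MoleculeGraph) -> float:
    return sum(atom_vsa(mol))


def _vdw(symbol: str) -> float:
    try:
        return VDW_RADII[symbol]
    except KeyError:
        raise MissingRadiusError(
            f"no van der Waals radius tabulated for element {symbol!r}") from None


def _ideal_length(a: str, b: str) -> float:
    try:
        return COVALENT_RADII[a] + COVALENT_RADII[b]
    except KeyError as exc:
        missing = a if a not in COVALENT_RADII else b
        raise MissingRadiusError(
            f"no covalent radius tabulated for element {missing!r}") from exc
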