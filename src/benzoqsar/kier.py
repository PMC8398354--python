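"""Kier molecular flexibility index.

KierFlex = KierA1 · KierA2 / A for A heavy atoms, built from the
α-modified kappa shape indices

    KierA1 = (A + α)(A + α − 1)² / (P1 + α)²
    KierA2 = (A + α − 1)(A + α − 2)² / (P2 + α)²

where P1 is the bond count, P2 the number of distinct two-bond paths and
α = Σ_i (r_i / r_Csp3 − 1) over heavy atoms with hybridisation-dependent
covalent radii (sp3 carbon is the reference; aromatic atoms count as sp2).
"""

from __future__ import annotations

import warnings

from rdkit.Chem import HybridizationType

from .chem import MoleculeGraph

R_CSP3 = 0.77

# Covalent radii (Å) by (element, hybridisation bucket); Kier's table.
KIER_RADII: dict[tuple[str, str], float] = {
    ("C", "sp3"): 0.77, ("C", "sp2"): 0.67, ("C", "sp"): 0.60,
    ("N", "sp3"): 0.74, ("N", "sp2"): 0.62, ("N", "sp"): 0.55,
    ("O", "sp3"): 0.74, ("O", "sp2"): 0.62,
    ("F", "sp3"): 0.72,
    ("Cl", "sp3"): 0.99,
    ("Br", "sp3"): 1.14,
    ("I", "sp3"): 1.33,
    ("S", "sp3"): 1.04, ("S", "sp2"): 0.94,
    ("P", "sp3"): 1.10, ("P", "sp2"): 1.00,
}

_BUCKETS = {
    HybridizationType.SP: "sp",
    HybridizationType.SP2: "sp2",
    HybridizationType.SP3: "sp3",
}


def hall_kier_alpha(mol: MoleculeGraph) -> float:
    """α = Σ_i (r_i / r_Csp3 − 1) over heavy atoms."""
    alpha = 0.0
    for atom in mol.rdmol.GetAtoms():
        sym = atom.GetSymbol()
        bucket = "sp2" if atom.GetIsAromatic() else \
            _BUCKETS.get(atom.GetHybridization(), "sp3")
        r = KIER_RADII.get((sym, bucket)) or KIER_RADII.get((sym, "sp3"))
        if r is None:
            # fall back to treating the atom as sp3 carbon (α contribution 0)
            r = R_CSP3
        alpha += r / R_CSP3 - 1.0
    return alpha


def path_counts(mol: MoleculeGraph) -> tuple[int, int]:
    """(P1, P2): bond count and number of distinct two-bond paths."""
    p1 = mol.num_bonds
    degrees = [a[4] for a in mol.atoms]
    p2 = sum(d * (d - 1) // 2 for d in degrees)
    return p1, p2


def kier_flex(mol: MoleculeGraph) -> float:
    """Kier molecular flexibility index; 0 with a warning when degenerate.

    The index is undefined for fewer than 3 heavy atoms or graphs without a
    two-bond path.
    """
    a = mol.num_atoms
    p1, p2 = path_counts(mol)
    if a < 3 or p2 == 0:
        warnings.warn(
            f"Kier flexibility undefined for degenerate molecule "
            f"(A={a}, P2={p2}); returning 0", stacklevel=2)
        return 0.0
    alpha = hall_kier_alpha(mol)
    kier_a1 = (a + alpha) * (a + alpha - 1.0) ** 2 / (p1 + alpha) ** 2
    kier_a2 = (a + alpha - 1.0) * (a + alpha - 2.0) ** 2 / (p2 + alpha) ** 2
    return kier_a1 * kier_a2 / a
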