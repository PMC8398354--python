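"""Hückel π-electron systems and Coulson bond orders.

The descriptor ``h_log_pbo`` sums log(1 + p_uv) over all bonds, where p_uv
is the π bond order. Bond orders come from simple Hückel theory: each
maximal conjugated subsystem gets a topological Hamiltonian with Coulomb
terms α + h·β on heteroatoms and resonance terms k·β on bonds (α = 0,
β = 1 in our units, orbitals filled from the most bonding eigenvalue down),
and p_uv = Σ_k n_k c_uk c_vk over occupied orbitals. An isolated double
bond is just the two-site system and gets p = 1; bonds outside any π system
have p = 0.

Conjugated-subsystem membership: atoms in double/triple bonds, plus
lone-pair donors (N, O, S, P, halogens with formal charge ≤ 0) adjacent to
such atoms; every bond between two member atoms is a π edge. Donors
contribute 2 electrons, multiply-bonded atoms 1. A triple bond additionally
carries a second, orthogonal two-centre π bond with p = 1.

Open-shell counts are handled by filling degenerate frontier orbitals
fractionally (and logging a warning). Cumulated systems (allenes) are
treated as a single planar system — a known approximation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem import MoleculeGraph

logger = logging.getLogger(__name__)

# Coulomb corrections h by (element, electrons contributed). Streitwieser-type
# values; C is the α reference. Large h (electronegative 2e donors) pushes the
# lone pair down in energy and keeps its delocalised bond order small.
HUCKEL_H: dict[tuple[str, int], float] = {
    ("C", 1): 0.0,
    ("C", 2): 0.0,      # carbanion-like donors, rare here
    ("N", 1): 0.5,      # pyridine-type
    ("N", 2): 1.5,      # pyrrole/amine-type
    ("O", 1): 1.0,      # carbonyl
    ("O", 2): 2.0,      # ether/hydroxyl/furan-type
    ("S", 1): 0.5,
    ("S", 2): 1.3,      # thiophene-type
    ("P", 1): 0.2,
    ("P", 2): 0.8,
    ("F", 2): 3.0,
    ("Cl", 2): 2.0,
    ("Br", 2): 1.5,
    ("I", 2): 1.2,
}

# Resonance factors k by unordered element pair (C–C is the β reference).
HUCKEL_K: dict[frozenset, float] = {
    frozenset({"C"}): 1.0,
    frozenset({"C", "N"}): 0.9,
    frozenset({"C", "O"}): 0.9,
    frozenset({"C", "S"}): 0.7,
    frozenset({"C", "P"}): 0.7,
    frozenset({"N"}): 0.85,
    frozenset({"N", "O"}): 0.8,
    frozenset({"N", "S"}): 0.7,
    frozenset({"O"}): 0.7,
    frozenset({"S"}): 0.6,
    frozenset({"C", "F"}): 0.5,
    frozenset({"C", "Cl"}): 0.45,
    frozenset({"C", "Br"}): 0.4,
    frozenset({"C", "I"}): 0.35,
}
HUCKEL_K_DEFAULT = 0.6

_DONOR_ELEMENTS = {"N", "O", "S", "P", "F", "Cl", "Br", "I"}
DEGENERACY_TOL = 1e-9


@dataclass
class PiSystem:
    """π bond orders for one molecule.

    ``bond_orders`` maps sorted heavy-atom index pairs to p_uv ∈ [0, 1];
    pairs absent from the map have p = 0. ``extra_pi_bonds`` lists the
    orthogonal second π bonds of triple bonds (each p = 1).
    """

    atoms: frozenset[int]
    n_electrons: int
    bond_orders: dict[tuple[int, int], float] = field(default_factory=dict)
    extra_pi_bonds: list[tuple[int, int]] = field(default_factory=list)


def pi_bond_orders(mol: MoleculeGraph) -> PiSystem:
    """Compute Coulson π bond orders for every conjugated subsystem."""
    rdmol = mol.rdmol
    kek = Chem.Mol(rdmol)
    Chem.Kekulize(kek, clearAromaticFlags=True)

    multiple: set[int] = set()            # atoms in double/triple bonds
    extra: list[tuple[int, int]] = []
    for b in kek.GetBonds():
        order = int(b.GetBondTypeAsDouble())
        if order >= 2:
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            multiple.update((i, j))
            if order == 3:
                extra.append((min(i, j), max(i, j)))

    donors: set[int] = set()
    for a in kek.GetAtoms():
        idx = a.GetIdx()
        if idx in multiple:
            continue
        if a.GetSymbol() in _DONOR_ELEMENTS and a.GetFormalCharge() <= 0:
            if any(n.GetIdx() in multiple for n in a.GetNeighbors()):
                donors.add(idx)
    members = multiple | donors

    edges = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
             for b in kek.GetBonds()
             if b.GetBeginAtomIdx() in members and b.GetEndAtomIdx() in members]

    # donors bridging two multiple-bond neighbourhoods may sit adjacent to
    # other donors; their mutual bonds are π edges already by membership.
    orders: dict[tuple[int, int], float] = {}
    total_e = 0
    for comp in _connected_components(members, edges):
        comp_edges = [e for e in edges if e[0] in comp and e[1] in comp]
        n_e = sum(2 if i in donors else 1 for i in comp)
        total_e += n_e
        orders.update(_solve_huckel(kek, sorted(comp), comp_edges, n_e))

    return PiSystem(atoms=frozenset(members), n_electrons=total_e,
                    bond_orders=orders, extra_pi_bonds=extra)


def h_log_pbo(mol: MoleculeGraph, log_base: float = math.e) -> float:
    """Sum of log(1 + π bond order) over all bonds.

    The logarithm base defaults to natural log; config-switchable since the
    field convention is not universal.
    """
    system = pi_bond_orders(mol)
    total = sum(math.log1p(p) for p in system.bond_orders.values())
    total += math.log(2.0) * len(system.extra_pi_bonds)
    if log_base != math.e:
        total /= math.log(log_base)
    return total


def _connected_components(nodes: set[int],
                          edges: list[tuple[int, int]]) -> list[set[int]]:
    adj: dict[int, set[int]] = {n: set() for n in nodes}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    seen: set[int] = set()
    comps = []
    for n in nodes:
        if n in seen:
            continue
        stack, comp = [n], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def _solve_huckel(kek: Chem.Mol, atoms: list[int],
                  edges: list[tuple[int, int]],
                  n_electrons: int) -> dict[tuple[int, int], float]:
    """Diagonalise one conjugated subsystem and return its bond orders."""
    pos = {a: i for i, a in enumerate(atoms)}
    n = len(atoms)
    H = np.zeros((n, n))
    for a in atoms:
        atom = kek.GetAtomWithIdx(a)
        n_e = 2 if _is_two_electron(kek, a) else 1
        key = (atom.GetSymbol(), n_e)
        if key not in HUCKEL_H:
            key = (atom.GetSymbol(), 1) if (atom.GetSymbol(), 1) in HUCKEL_H \
                else ("C", 1)
            logger.warning("no Hückel Coulomb parameter for %s(%de); "
                           "using %s", atom.GetSymbol(), n_e, key)
        H[pos[a], pos[a]] = HUCKEL_H[key]
    for i, j in edges:
        pair = frozenset({kek.GetAtomWithIdx(i).GetSymbol(),
                          kek.GetAtomWithIdx(j).GetSymbol()})
        k = HUCKEL_K.get(pair, HUCKEL_K_DEFAULT)
        H[pos[i], pos[j]] = H[pos[j], pos[i]] = k

    evals, evecs = np.linalg.eigh(H)
    # E = α + λβ with β < 0: bonding orbitals have the largest λ.
    order = np.argsort(evals)[::-1]
    occ = _occupations(evals[order], n_electrons)
    c = evecs[:, order]
    result: dict[tuple[int, int], float] = {}
    for i, j in edges:
        p = float(np.sum(occ * c[pos[i], :] * c[pos[j], :]))
        result[(min(i, j), max(i, j))] = min(1.0, max(0.0, p))
    return result


def _occupations(evals_desc: np.ndarray, n_electrons: int) -> np.ndarray:
    """Aufbau filling with fractional occupation of degenerate frontiers."""
    occ = np.zeros(len(evals_desc))
    remaining = float(n_electrons)
    i = 0
    while remaining > 0 and i < len(evals_desc):
        j = i
        while (j + 1 < len(evals_desc)
               and abs(evals_desc[j + 1] - evals_desc[i]) < DEGENERACY_TOL):
            j += 1
        size = j - i + 1
        capacity = 2.0 * size
        if remaining >= capacity:
            occ[i:j + 1] = 2.0
        else:
            occ[i:j + 1] = remaining / size
            if size > 1:
                logger.warning("open-shell π count (%d e); degenerate "
                               "frontier orbitals filled fractionally",
                               n_electrons)
        remaining -= capacity
        i = j + 1
    return occ


def _is_two_electron(kek: Chem.Mol, idx: int) -> bool:
    """Donor atoms (no multiple bond of their own) contribute 2 electrons."""
    atom = kek.GetAtomWithIdx(idx)
    for b in atom.GetBonds():
        if int(b.GetBondTypeAsDouble()) >= 2:
            return False
    return True
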