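"""Partial charges and pharmacophore atom flags.

Charges are Gasteiger–Marsili PEOE (partial equalisation of orbital
electronegativities, damping halved each cycle), run for 8 iterations;
implicit-hydrogen charges are folded into their heavy atom so that the
per-heavy-atom charges sum to the molecule's total formal charge.

"Polar atom" (for the vsa_pol descriptor) means simultaneously hydrogen-bond
donor and acceptor — e.g. a hydroxyl oxygen or primary amine nitrogen.
Donor: N/O bearing at least one hydrogen. Acceptor: N/O with an available
lone pair, which excludes positively charged atoms, pyrrole-type aromatic
nitrogens and amide nitrogens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from rdkit.Chem import rdPartialCharges

from .chem import MoleculeGraph

PEOE_ITERATIONS = 8


class ChargeParameterError(ValueError):
    """Raised when an element lacks electronegativity parameters."""


def peoe_charges(mol: MoleculeGraph,
                 n_iterations: int = PEOE_ITERATIONS) -> list[float]:
    """Per-heavy-atom PEOE charges (implicit hydrogens folded in)."""
    rdmol = mol.rdmol
    try:
        rdPartialCharges.ComputeGasteigerCharges(
            rdmol, nIter=n_iterations, throwOnParamFailure=True)
    except Exception as exc:  # RDKit raises a ValueError subclass
        raise ChargeParameterError(
            f"PEOE electronegativity parameters missing: {exc}") from exc
    charges = []
    for atom in rdmol.GetAtoms():
        q = atom.GetDoubleProp("_GasteigerCharge")
        q += atom.GetDoubleProp("_GasteigerHCharge")
        if math.isnan(q) or math.isinf(q):
            raise ChargeParameterError(
                f"PEOE charge undefined for atom {atom.GetIdx()} "
                f"({atom.GetSymbol()})")
        charges.append(q)
    return charges


@dataclass(frozen=True)
class AtomFlags:
    donor: bool
    acceptor: bool

    @property
    def polar(self) -> bool:
        return self.donor and self.acceptor


def hbond_flags(mol: MoleculeGraph) -> list[AtomFlags]:
    """Donor/acceptor flags per heavy atom."""
    flags = []
    for atom in mol.rdmol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in ("N", "O"):
            flags.append(AtomFlags(False, False))
            continue
        donor = atom.GetTotalNumHs() > 0
        acceptor = atom.GetFormalCharge() <= 0
        if sym == "N" and acceptor:
            if atom.GetIsAromatic() and (atom.GetTotalNumHs() > 0
                                         or atom.GetDegree() >= 3):
                acceptor = False        # pyrrole-type: lone pair in the ring
            elif atom.GetDegree() >= 4:
                acceptor = False
            elif _is_amide_nitrogen(atom):
                acceptor = False
        flags.append(AtomFlags(donor, acceptor))
    return flags


def _is_amide_nitrogen(atom) -> bool:
    for nbr in atom.GetNeighbors():
        if nbr.GetSymbol() != "C":
            continue
        for bond in nbr.GetBonds():
            other = bond.GetOtherAtom(nbr)
            if (other.GetSymbol() in ("O", "S")
                    and bond.GetBondTypeAsDouble() == 2.0):
                return True
    return False
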