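"""The five 2D descriptors of the benzodiazepine activity model.

* ``h_log_pbo``   — Σ log(1 + π bond order) over all bonds (Hückel theory);
* ``kier_flex``   — Kier molecular flexibility index KierA1·KierA2/A;
* ``q_vsa_hyd``   — VSA (Å²) of hydrophobic atoms, |PEOE charge| ≤ 0.2;
* ``slogp_vsa7``  — VSA (Å²) of atoms whose Wildman–Crippen logP
                    contribution falls in (0.25, 0.30] (bin 7 of the
                    SlogP_VSA family in the original descriptor numbering);
* ``vsa_pol``     — VSA (Å²) of polar atoms (both H-bond donor and
                    acceptor).

The full SlogP_VSA bin family is exposed so the conservation identity
Σ bins = total VSA can be asserted; likewise the hydrophobic/polar charge
partition is exact by construction.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors
from sklearn.base import BaseEstimator, TransformerMixin

from .charges import hbond_flags, peoe_charges
from .chem import MoleculeGraph, parse_smiles
from .huckel import h_log_pbo
from .kier import kier_flex
from .surface import atom_vsa

#: Upper bin edges of the Wildman–Crippen contribution bins (original SlogP_VSA numbering:
#: bin k collects contributions in (edge[k-1], edge[k]], bin 0 is
#: (−inf, −0.4], the last bin is open above).
SLOGP_BIN_EDGES = (-0.4, -0.2, 0.0, 0.1, 0.15, 0.20, 0.25, 0.30, 0.40)
SLOGP_VSA7_BIN = 7          # contributions in (0.25, 0.30]
HYDROPHOBIC_CHARGE_THRESHOLD = 0.2

DESCRIPTOR_NAMES = ("h_log_pbo", "kier_flex", "q_vsa_hyd",
                    "slogp_vsa7", "vsa_pol")


@dataclass(frozen=True)
class DescriptorVector:
    """The five model descriptors for one molecule."""

    h_log_pbo: float
    kier_flex: float
    q_vsa_hyd: float
    slogp_vsa7: float
    vsa_pol: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])


def crippen_contribs(mol: MoleculeGraph) -> list[float]:
    """Per-heavy-atom Wildman–Crippen logP contributions.

    Computed on the explicit-hydrogen molecule with each hydrogen's
    contribution folded into its heavy atom, so the values sum to the
    molecular Crippen logP. Atoms matching no pattern receive the published
    wildcard contribution (RDKit's convention) and are logged by RDKit.
    """
    mh = Chem.AddHs(mol.rdmol)
    contribs = rdMolDescriptors._CalcCrippenContribs(mh)
    folded = [0.0] * mol.num_atoms
    for atom in mh.GetAtoms():
        value = contribs[atom.GetIdx()][0]
        if atom.GetAtomicNum() == 1:
            folded[atom.GetNeighbors()[0].GetIdx()] += value
        else:
            folded[atom.GetIdx()] += value
    return folded


def slogp_vsa_bins(mol: MoleculeGraph) -> list[float]:
    """VSA partitioned by Crippen-contribution bins; sums to total VSA."""
    vsa = atom_vsa(mol)
    contribs = crippen_contribs(mol)
    bins = [0.0] * (len(SLOGP_BIN_EDGES) + 1)
    for area, logp in zip(vsa, contribs):
        bins[_bin_index(logp)] += area
    return bins


def _bin_index(value: float) -> int:
    for k, edge in enumerate(SLOGP_BIN_EDGES):
        if value <= edge:
            return k
    return len(SLOGP_BIN_EDGES)


def compute_descriptors(mol: MoleculeGraph | str,
                        log_base: float = math.e,
                        charge_iterations: int = 8,
                        hyd_threshold: float = HYDROPHOBIC_CHARGE_THRESHOLD,
                        ) -> DescriptorVector:
    """Compute the five model descriptors for one molecule.

    String input is parsed and memoised by canonical SMILES (descriptors
    are pure functions of the graph and the parameters).
    """
    if isinstance(mol, str):
        return _cached_descriptors(mol, log_base, charge_iterations,
                                   hyd_threshold)
    return _descriptors_from_graph(mol, log_base, charge_iterations,
                                   hyd_threshold)


@functools.lru_cache(maxsize=8192)
def _cached_descriptors(smiles: str, log_base: float, charge_iterations: int,
                        hyd_threshold: float) -> DescriptorVector:
    return _descriptors_from_graph(parse_smiles(smiles), log_base,
                                   charge_iterations, hyd_threshold)


def _descriptors_from_graph(mol: MoleculeGraph, log_base: float,
                            charge_iterations: int,
                            hyd_threshold: float) -> DescriptorVector:
    vsa = atom_vsa(mol)
    charges = peoe_charges(mol, n_iterations=charge_iterations)
    flags = hbond_flags(mol)
    q_vsa_hyd = sum(a for a, q in zip(vsa, charges) if abs(q) <= hyd_threshold)
    vsa_pol = sum(a for a, f in zip(vsa, flags) if f.polar)
    return DescriptorVector(
        h_log_pbo=h_log_pbo(mol, log_base=log_base),
        kier_flex=kier_flex(mol),
        q_vsa_hyd=q_vsa_hyd,
        slogp_vsa7=slogp_vsa_bins(mol)[SLOGP_VSA7_BIN],
        vsa_pol=vsa_pol,
    )


class DescriptorCalculator(TransformerMixin, BaseEstimator):
    """Sklearn transformer: SMILES (or parsed graphs) → descriptor matrix.

    Parameters
    ----------
    log_base : float
        Base of the logarithm in ``h_log_pbo`` (default: natural log).
    charge_iterations : int
        PEOE iteration count for the hydrophobic/polar charge partition.
    hyd_threshold : float
        |q| cutoff below which an atom counts as hydrophobic.
    as_frame : bool
        Return a pandas DataFrame with named columns instead of an ndarray.
    """

    def __init__(self, log_base: float = math.e, charge_iterations: int = 8,
                 hyd_threshold: float = HYDROPHOBIC_CHARGE_THRESHOLD,
                 as_frame: bool = True):
        self.log_base = log_base
        self.charge_iterations = charge_iterations
        self.hyd_threshold = hyd_threshold
        self.as_frame = as_frame

    def fit(self, X, y=None):
        self.feature_names_in_ = None
        self.n_features_out_ = len(DESCRIPTOR_NAMES)
        return self

    def transform(self, X):
        rows = [compute_descriptors(
            mol, log_base=self.log_base,
            charge_iterations=self.charge_iterations,
            hyd_threshold=self.hyd_threshold).as_array() for mol in X]
        matrix = np.vstack(rows) if rows else np.empty((0, 5))
        if self.as_frame:
            return pd.DataFrame(matrix, columns=list(DESCRIPTOR_NAMES))
        return matrix

    def get_feature_names_out(self, input_features=None):
        return np.asarray(DESCRIPTOR_NAMES, dtype=object)

    def provenance(self) -> dict:
        """Parameter block written next to featurisation outputs."""
        return {
            "descriptors": list(DESCRIPTOR_NAMES),
            "log_base": "e" if self.log_base == math.e else self.log_base,
            "charge_model": "Gasteiger-Marsili PEOE",
            "charge_iterations": self.charge_iterations,
            "hydrophobic_charge_threshold": self.hyd_threshold,
            "slogp_vsa7_bin": "(0.25, 0.30]",
            "slogp_bin_edges": list(SLOGP_BIN_EDGES),
            "vsa_radii": "Bondi vdW + Cordero covalent bond lengths",
        }
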