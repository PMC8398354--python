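"""Molecular graphs, SMILES ingestion, fingerprints and Tanimoto similarity.

All structure handling is 2D: stereochemistry is discarded on parsing, only
the largest covalent fragment is kept (designer-benzodiazepine SMILES may
carry counter-ions), and implicit hydrogens never appear as graph nodes.
"""

from __future__ import annotations

import csv
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, DataStructs
from rdkit import RDLogger

logger = logging.getLogger(__name__)

# RDKit is chatty about sanitisation on stderr; errors are re-raised as
# ValueError with context instead.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

#: Path-fingerprint defaults: hashed linear paths up to 7 bonds, 2048 bits.
FP_MAX_PATH = 7
FP_N_BITS = 2048


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be turned into a sanitised graph."""


@dataclass(frozen=True)
class MoleculeGraph:
    """Sanitised 2D molecular graph (heavy atoms only).

    ``atoms`` holds ``(symbol, formal_charge, is_aromatic, n_implicit_h,
    degree)`` per heavy atom; ``bonds`` holds ``(i, j, order, is_aromatic)``
    with ``order`` in {1, 2, 3} (the Kekulé order for aromatic bonds).
    ``rdmol`` is the backing RDKit molecule used by descriptor code.
    """

    atoms: tuple[tuple[str, int, bool, int, int], ...]
    bonds: tuple[tuple[int, int, int, bool], ...]
    rdmol: Chem.Mol = field(compare=False, repr=False)

    @property
    def num_atoms(self) -> int:
        return len(self.atoms)

    @property
    def num_bonds(self) -> int:
        return len(self.bonds)

    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(self.rdmol)


@dataclass
class MoleculeRecord:
    """One molecule: identifier, canonical SMILES, optional activity.

    ``activity`` is log 1/c, the log of the reciprocal molar IC50 for
    displacing [3H]-diazepam; higher means more potent.
    """

    id: str
    smiles: str
    activity: float | None = None

    @classmethod
    def from_smiles(cls, id: str, smiles: str,
                    activity: float | None = None) -> "MoleculeRecord":
        graph = parse_smiles(smiles)
        return cls(id=id, smiles=graph.canonical_smiles(), activity=activity)


def parse_smiles(smiles: str) -> MoleculeGraph:
    """Parse a SMILES string into a sanitised :class:`MoleculeGraph`.

    Aromaticity is perceived with RDKit's default model, implicit hydrogens
    are assigned, the largest covalent fragment is retained and
    stereochemistry is removed (only 2D descriptors are computed downstream).

    Raises
    ------
    SmilesParseError
        If the string is empty, unparseable, or yields an empty molecule.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        # Re-parse without sanitisation to locate the offending token.
        probe = Chem.MolFromSmiles(smiles, sanitize=False)
        if probe is None:
            pos = _first_bad_token(smiles)
            raise SmilesParseError(
                f"unparseable SMILES {smiles!r} (near position {pos})")
        raise SmilesParseError(
            f"SMILES {smiles!r} parsed but failed sanitisation "
            "(valence or aromaticity error)")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumAtoms())
        logger.info("kept largest fragment of %r (%d fragments)",
                    smiles, len(frags))
    if mol.GetNumAtoms() == 0:
        raise SmilesParseError(f"SMILES {smiles!r} yields an empty molecule")
    Chem.RemoveStereochemistry(mol)
    return _graph_from_rdmol(mol)


def _first_bad_token(smiles: str) -> int:
    """Longest parseable prefix heuristic for error reporting."""
    for i in range(1, len(smiles) + 1):
        if Chem.MolFromSmiles(smiles[:i], sanitize=False) is None:
            return i - 1
    return len(smiles) - 1


def _graph_from_rdmol(mol: Chem.Mol) -> MoleculeGraph:
    atoms = tuple(
        (a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic(),
         a.GetTotalNumHs(), a.GetDegree())
        for a in mol.GetAtoms())
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
         int(kek.GetBondBetweenAtoms(
             b.GetBeginAtomIdx(), b.GetEndAtomIdx()).GetBondTypeAsDouble()),
         b.GetIsAromatic())
        for b in mol.GetBonds())
    return MoleculeGraph(atoms=atoms, bonds=bonds, rdmol=mol)


# ---------------------------------------------------------------------------
# Fingerprints and Tanimoto similarity
# ---------------------------------------------------------------------------

def fingerprint(mol: MoleculeGraph, max_path: int = FP_MAX_PATH,
                n_bits: int = FP_N_BITS):
    """Hashed linear-path fingerprint (paths up to ``max_path`` bonds).

    Deterministic for a fixed molecule regardless of input atom order, since
    it is computed from the canonicalised graph. Molecules with no bonds
    (single heavy atoms) have no paths to hash; they get one stable bit
    derived from the canonical SMILES so every molecule sets at least one.
    """
    fp = Chem.RDKFingerprint(mol.rdmol, maxPath=max_path, fpSize=n_bits)
    if fp.GetNumOnBits() == 0 and mol.num_atoms >= 1:
        fp.SetBit(zlib.crc32(mol.canonical_smiles().encode()) % n_bits)
    return fp


def tanimoto(a, b) -> float:
    """Tanimoto coefficient |a∩b| / |a∪b| between two bit vectors.

    Both empty is defined as 0 (and logged), so fully featureless inputs do
    not silently count as identical.
    """
    if a.GetNumBits() != b.GetNumBits():
        raise ValueError("fingerprints have different lengths "
                         f"({a.GetNumBits()} vs {b.GetNumBits()})")
    if a.GetNumOnBits() == 0 and b.GetNumOnBits() == 0:
        logger.warning("Tanimoto of two empty fingerprints defined as 0")
        return 0.0
    return float(DataStructs.TanimotoSimilarity(a, b))


def average_tc(target, pool: Sequence) -> float:
    """Mean Tanimoto similarity of ``target`` against a fingerprint pool.

    Self-similarity is excluded: pool entries with a bit set identical to the
    target's are dropped (once each occurrence).
    """
    if not pool:
        raise ValueError("empty fingerprint pool")
    others = [fp for fp in pool if fp != target]
    if not others:
        # pool consisted only of copies of the target
        return 1.0
    if target.GetNumOnBits() == 0:
        return float(sum(tanimoto(target, fp) for fp in others) / len(others))
    sims = DataStructs.BulkTanimotoSimilarity(target, others)
    return float(sum(sims) / len(sims))


# ---------------------------------------------------------------------------
# File ingestion: SMILES lists, CSV, SDF
# ---------------------------------------------------------------------------

def read_smiles_file(path: str | Path) -> list[MoleculeRecord]:
    """One molecule per line: ``SMILES`` or ``SMILES<ws>id``."""
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smiles = parts[0]
        mol_id = parts[1] if len(parts) > 1 else f"mol{lineno}"
        records.append(MoleculeRecord.from_smiles(mol_id, smiles))
    return records


def read_csv(path: str | Path) -> list[MoleculeRecord]:
    """CSV with columns ``id,smiles[,activity]`` (header required)."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        fields = {f.lower(): f for f in reader.fieldnames or []}
        if "smiles" not in fields:
            raise ValueError(f"{path}: no 'smiles' column")
        for i, row in enumerate(reader, 1):
            act = row.get(fields["activity"]) if "activity" in fields else None
            records.append(MoleculeRecord.from_smiles(
                id=row.get(fields.get("id", ""), "") or f"mol{i}",
                smiles=row[fields["smiles"]],
                activity=float(act) if act not in (None, "") else None))
    return records


def read_sdf(path: str | Path) -> list[MoleculeRecord]:
    """SDF file; the title line is used as the id when present."""
    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier, 1):
        if mol is None:
            logger.warning("%s: record %d failed to parse, skipped", path, i)
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        records.append(MoleculeRecord.from_smiles(
            name or f"mol{i}", Chem.MolToSmiles(mol)))
    return records


def read_records(path: str | Path) -> list[MoleculeRecord]:
    """Dispatch on extension: .csv, .sdf, else SMILES lines."""
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return read_csv(path)
    if suffix == ".sdf":
        return read_sdf(path)
    return read_smiles_file(path)


def write_records_csv(records: Iterable[MoleculeRecord],
                      path: str | Path) -> None:
    """Canonical-SMILES CSV echo (columns id,smiles,activity)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "activity"])
        for rec in records:
            writer.writerow([rec.id, rec.smiles,
                             "" if rec.activity is None else repr(rec.activity)])
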