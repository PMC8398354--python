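"""Molecular graph parsing, fingerprints and Tanimoto similarity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem
from rdkit.DataStructs import ExplicitBitVect

from benzoqsar import (MoleculeRecord, SmilesParseError, average_tc,
                       fingerprint, parse_smiles, tanimoto)
from benzoqsar.chem import (read_csv, read_records, read_sdf,
                            read_smiles_file, write_records_csv)


def bitvect(bits, size=16) -> ExplicitBitVect:
    fp = ExplicitBitVect(size)
    for b in bits:
        fp.SetBit(b)
    return fp


class TestParseSmiles:
    @pytest.mark.parametrize("smiles, n_atoms, n_bonds", [
        ("CC", 2, 1),                                        # ethane
        ("c1ccccc1", 6, 6),                                  # benzene
        ("CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21", 20, 22),     # diazepam
    ])
    def test_atom_and_bond_counts(self, smiles, n_atoms, n_bonds):
        mol = parse_smiles(smiles)
        assert mol.num_atoms == n_atoms
        assert mol.num_bonds == n_bonds

    def test_benzene_is_aromatic(self):
        mol = parse_smiles("c1ccccc1")
        assert all(a[2] for a in mol.atoms)
        assert all(b[3] for b in mol.bonds)

    def test_aromatic_bonds_join_aromatic_atoms(self, library_dataset):
        for rec in library_dataset.records[:20]:
            mol = parse_smiles(rec.smiles)
            for i, j, _order, arom in mol.bonds:
                if arom:
                    assert mol.atoms[i][2] and mol.atoms[j][2]

    @pytest.mark.parametrize("bad", ["", "   ", "C1CC", "not_a_smiles(("])
    def test_rejects_invalid_input(self, bad):
        with pytest.raises(SmilesParseError):
            parse_smiles(bad)

    def test_keeps_largest_fragment(self):
        mol = parse_smiles("CCO.[Cl-]")
        assert mol.num_atoms == 3
        assert mol.canonical_smiles() == "CCO"

    def test_stereochemistry_discarded(self):
        mol = parse_smiles("C[C@H](N)C(=O)O")
        assert "@" not in mol.canonical_smiles()

    def test_idempotent_on_own_canonical_output(self):
        first = parse_smiles("OC(=O)c1ccccc1N")
        again = parse_smiles(first.canonical_smiles())
        assert again.canonical_smiles() == first.canonical_smiles()

    def test_bond_indices_valid_no_self_bonds(self):
        mol = parse_smiles("CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21")
        seen = set()
        for i, j, _o, _a in mol.bonds:
            assert 0 <= i < mol.num_atoms and 0 <= j < mol.num_atoms
            assert i != j
            key = (min(i, j), max(i, j))
            assert key not in seen
            seen.add(key)


class TestFingerprint:
    DIAZEPAM = "CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21"

    def test_invariant_to_atom_reordering(self):
        ref = fingerprint(parse_smiles(self.DIAZEPAM))
        rd = Chem.MolFromSmiles(self.DIAZEPAM)
        for variant in Chem.MolToRandomSmilesVect(rd, 5, randomSeed=7):
            assert fingerprint(parse_smiles(variant)) == ref

    def test_distinct_molecules_differ(self):
        assert fingerprint(parse_smiles("CC")) != \
            fingerprint(parse_smiles("c1ccccc1"))

    def test_any_molecule_sets_at_least_one_bit(self, library_dataset):
        for fp in library_dataset.fingerprints:
            assert fp.GetNumOnBits() >= 1
        assert fingerprint(parse_smiles("C")).GetNumOnBits() >= 1


class TestTanimoto:
    def test_identity_is_one(self):
        fp = fingerprint(parse_smiles("CCO"))
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint_is_zero(self):
        assert tanimoto(bitvect({1, 2}), bitvect({5, 6})) == 0.0

    def test_enumerated_example(self):
        # {1,2,3} vs {2,3,4}: 2 common bits, 4 in the union
        assert tanimoto(bitvect({1, 2, 3}), bitvect({2, 3, 4})) == 0.5

    def test_both_empty_defined_as_zero(self):
        assert tanimoto(bitvect(set()), bitvect(set())) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            tanimoto(bitvect({1}, size=16), bitvect({1}, size=32))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(a=st.sets(st.integers(0, 63)), b=st.sets(st.integers(0, 63)))
    def test_matches_set_oracle_and_is_symmetric(self, a, b):
        fa, fb = bitvect(a, 64), bitvect(b, 64)
        expected = len(a & b) / len(a | b) if a | b else 0.0
        assert tanimoto(fa, fb) == pytest.approx(expected, abs=1e-12)
        assert tanimoto(fa, fb) == tanimoto(fb, fa)
        assert 0.0 <= tanimoto(fa, fb) <= 1.0
        assert (tanimoto(fa, fb) == 1.0) == (a == b and bool(a))


class TestAverageTc:
    def test_pool_of_copies_gives_one(self):
        fp = fingerprint(parse_smiles("CCO"))
        assert average_tc(fp, [fp, fp, fp]) == 1.0

    def test_all_disjoint_gives_zero(self):
        assert average_tc(bitvect({0, 1}),
                          [bitvect({4, 5}), bitvect({8, 9})]) == 0.0

    def test_arithmetic_mean(self):
        target = bitvect({0, 1, 2, 3})
        sim_02 = bitvect({0, 9})          # 1 common / 5 union = 0.2
        sim_06 = bitvect({0, 1, 2, 4})    # 3 common / 5 union = 0.6
        assert average_tc(target, [sim_02, sim_06]) == pytest.approx(0.4)

    def test_self_excluded_from_pool(self):
        target = bitvect({0, 1})
        other = bitvect({0, 2})   # similarity 1/3
        assert average_tc(target, [target, other]) == pytest.approx(1 / 3)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            average_tc(bitvect({1}), [])


class TestIO:
    RECORDS = [MoleculeRecord("a", "CCO", 6.5),
               MoleculeRecord("b", "c1ccccc1", None)]

    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "mols.csv"
        write_records_csv(self.RECORDS, path)
        back = read_csv(path)
        assert [(r.id, r.smiles, r.activity) for r in back] == \
            [("a", "CCO", 6.5), ("b", "c1ccccc1", None)]

    def test_smiles_file_with_ids(self, tmp_path):
        path = tmp_path / "mols.smi"
        path.write_text("CCO alcohol\nc1ccccc1\n# comment\n")
        back = read_smiles_file(path)
        assert [r.id for r in back] == ["alcohol", "mol2"]

    def test_sdf_title_used_as_id(self, tmp_path):
        path = tmp_path / "mols.sdf"
        writer = Chem.SDWriter(str(path))
        mol = Chem.MolFromSmiles("CCO")
        mol.SetProp("_Name", "ethanol")
        writer.write(mol)
        writer.close()
        back = read_sdf(path)
        assert back[0].id == "ethanol" and back[0].smiles == "CCO"

    def test_dispatch_by_extension(self, tmp_path):
        path = tmp_path / "mols.csv"
        write_records_csv(self.RECORDS, path)
        assert len(read_records(path)) == 2
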