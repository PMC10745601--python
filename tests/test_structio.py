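"""Structure, ligand, profile and manifest I/O."""

import numpy as np
import pytest

from heterodta import structio
from heterodta.structio import (
    EmptyStructureError,
    LigandParseError,
    ManifestError,
    ProfileKind,
    ProfileParseError,
)

import conftest as fx


class TestProteinReading:
    def test_three_residue_fixture(self, pdb_agv):
        s = structio.read_protein_structure(pdb_agv)
        assert s.sequence == "AGV"
        assert len(s) == 3
        assert s.n_skipped == 0
        assert s.chain_ids == ["A"]
        np.testing.assert_allclose(s.ca_coords[1], [3.8, 0.0, 0.0])

    def test_water_records_ignored(self, pdb_agv):
        s = structio.read_protein_structure(pdb_agv)
        assert all(r.three_letter_code != "HOH" for r in s.residues)

    def test_missing_ca_skipped_and_counted(self, tmp_path):
        p = tmp_path / "gap.pdb"
        p.write_text(fx.PDB_MISSING_CA)
        s = structio.read_protein_structure(p)
        assert s.sequence == "AV"
        assert s.n_skipped == 1

    def test_nonstandard_residue_maps_to_x(self, tmp_path):
        p = tmp_path / "mse.pdb"
        p.write_text(fx.PDB_MSE)
        s = structio.read_protein_structure(p)
        assert s.sequence == "AXV"

    def test_empty_structure_raises(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(EmptyStructureError):
            structio.read_protein_structure(p)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(structio.StructIOError):
            structio.read_protein_structure(tmp_path / "nope.pdb")

    def test_deterministic(self, pdb_agv):
        a = structio.read_protein_structure(pdb_agv)
        b = structio.read_protein_structure(pdb_agv)
        assert a.sequence == b.sequence
        np.testing.assert_array_equal(a.ca_coords, b.ca_coords)


class TestPocketMatching:
    def test_subset_mask_and_coordinates(self, tmp_path):
        protein_p = tmp_path / "p.pdb"
        protein_p.write_text(fx.PDB_AGV)
        pocket_p = tmp_path / "pk.pdb"
        # pocket = residues 2..3 of the protein
        pocket_p.write_text(
            "\n".join(fx.PDB_AGV.splitlines()[2:4]) + "\nEND\n"
        )
        protein = structio.read_protein_structure(protein_p)
        pocket = structio.read_protein_structure(pocket_p)
        mask = structio.pocket_mask(protein, pocket)
        np.testing.assert_array_equal(mask, [False, True, True])
        # coordinate cross-check: every pocket CA matches a protein CA exactly
        for row in pocket.ca_coords:
            assert any(np.array_equal(row, pr) for pr in protein.ca_coords)

    def test_disjoint_pocket_raises(self, pdb_agv, tmp_path):
        other = tmp_path / "other.pdb"
        other.write_text(
            "ATOM      1  CA  ALA B  99      50.000  50.000  50.000  1.00  0.00           C\nEND\n"
        )
        protein = structio.read_protein_structure(pdb_agv)
        pocket = structio.read_protein_structure(other)
        with pytest.raises(structio.StructIOError):
            structio.pocket_mask(protein, pocket)


class TestLigandReading:
    def test_sdf_ethanol(self, sdf_ethanol):
        mol = structio.read_ligand(sdf_ethanol)
        assert len(mol.atoms) == 9
        assert len(mol.bonds) == 8
        assert mol.elements[:3] == ["C", "C", "O"]
        assert mol.coords.shape == (9, 3)

    def test_mol2_matches_sdf(self, sdf_ethanol, mol2_ethanol):
        sdf = structio.read_ligand(sdf_ethanol)
        mol2 = structio.read_ligand(mol2_ethanol)
        assert sorted(sdf.elements) == sorted(mol2.elements)
        assert len(sdf.bonds) == len(mol2.bonds)
        assert {(i, j) for i, j, _ in sdf.bonds} == {(i, j) for i, j, _ in mol2.bonds}

    def test_sdf_matches_rdkit_oracle(self, sdf_ethanol):
        rdkit_chem = pytest.importorskip("rdkit.Chem")
        ref = rdkit_chem.MolFromMolFile(str(sdf_ethanol), removeHs=False, sanitize=False)
        mol = structio.read_ligand(sdf_ethanol)
        assert ref.GetNumAtoms() == len(mol.atoms)
        assert ref.GetNumBonds() == len(mol.bonds)
        ref_elements = [a.GetSymbol() for a in ref.GetAtoms()]
        assert ref_elements == mol.elements

    def test_truncated_atom_block_raises(self, tmp_path):
        lines = fx.SDF_ETHANOL.splitlines()
        bad = "\n".join(lines[:3] + ["  5  0  0  0  0  0  0  0  0  0999 V2000"] + lines[4:8])
        p = tmp_path / "bad.sdf"
        p.write_text(bad + "\n")
        with pytest.raises(LigandParseError, match="declares 5 atoms"):
            structio.read_ligand(p)

    def test_format_override(self, tmp_path):
        p = tmp_path / "ethanol.dat"
        p.write_text(fx.SDF_ETHANOL)
        mol = structio.read_ligand(p, fmt="sdf")
        assert len(mol.atoms) == 9


class TestProfiles:
    def test_pssm_identity_read(self, tmp_path):
        p = tmp_path / "prof.pssm"
        p.write_text(fx.PSSM_FIXTURE)
        prof = structio.parse_profile(p, ProfileKind.PSSM)
        assert prof.matrix.shape == (2, 20)
        assert prof.matrix[0, 0] == -2.0
        assert prof.matrix[1, 11] == 5.0  # K column for the K row

    def test_hhm_conversion(self, tmp_path):
        p = tmp_path / "prof.hhm"
        p.write_text(fx.HHM_FIXTURE)
        prof = structio.parse_profile(p, "HMM")
        assert prof.matrix.shape == (3, 20)
        # code 1000 -> 2**(-1) = 0.5; code 0 -> 1.0; '*' -> 0.0
        assert prof.matrix[0, 0] == pytest.approx(0.5)
        assert prof.matrix[0, 1] == pytest.approx(0.25)
        np.testing.assert_array_equal(prof.matrix[1], np.zeros(20))
        assert prof.matrix[2, 0] == pytest.approx(1.0)

    def test_wrong_column_count_raises(self, tmp_path):
        p = tmp_path / "bad.pssm"
        p.write_text("    1 M    -1  -2  -3\n")
        with pytest.raises(ProfileParseError):
            structio.parse_profile(p, "PSSM")

    def test_attach_profile_length_check(self, tmp_path, pdb_agv):
        p = tmp_path / "prof.pssm"
        p.write_text(fx.PSSM_FIXTURE)
        prof = structio.parse_profile(p, "PSSM")
        protein = structio.read_protein_structure(pdb_agv)  # 3 residues
        with pytest.raises(ProfileParseError):
            structio.attach_profile(prof, protein)


class TestManifestsAndPredictions:
    def test_manifest_round_trip(self, tmp_path):
        path = tmp_path / "manifest.csv"
        path.write_text(
            "complex_id,protein_path,pocket_path,ligand_path,affinity\n"
            "c1,p1.pdb,k1.pdb,l1.sdf,5.25\n"
            "c2,p2.pdb,k2.pdb,l2.sdf,7.5\n"
        )
        entries = structio.read_manifest(path)
        assert [e.complex_id for e in entries] == ["c1", "c2"]
        assert entries[0].affinity == 5.25

    def test_empty_manifest(self, tmp_path):
        path = tmp_path / "manifest.csv"
        path.write_text("complex_id,protein_path,pocket_path,ligand_path,affinity\n")
        assert structio.read_manifest(path) == []

    def test_missing_column(self, tmp_path):
        path = tmp_path / "manifest.csv"
        path.write_text("complex_id,protein_path,affinity\nc1,p,5\n")
        with pytest.raises(ManifestError, match="missing"):
            structio.read_manifest(path)

    def test_bad_affinity_cites_row(self, tmp_path):
        path = tmp_path / "manifest.csv"
        path.write_text(
            "complex_id,protein_path,pocket_path,ligand_path,affinity\n"
            "c1,p,k,l,5\nc2,p,k,l,abc\n"
        )
        with pytest.raises(ManifestError, match="row 3"):
            structio.read_manifest(path)

    def test_prediction_round_trip(self, tmp_path):
        path = tmp_path / "preds.csv"
        records = [("c1", 5.123456, 4.98765), ("c2", 7.0, 7.25)]
        structio.write_predictions(records, path)
        back = structio.read_predictions(path)
        for (cid, yt, yp), (cid2, yt2, yp2) in zip(records, back):
            assert cid == cid2
            assert yt == pytest.approx(yt2, abs=1e-6)
            assert yp == pytest.approx(yp2, abs=1e-6)

    def test_empty_predictions_header_only(self, tmp_path):
        path = tmp_path / "preds.csv"
        structio.write_predictions([], path)
        assert path.read_text().strip() == "complex_id,y_true,y_pred"

    def test_nonfinite_prediction_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            structio.write_predictions([("c1", float("nan"), 1.0)], tmp_path / "x.csv")
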