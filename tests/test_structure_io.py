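"""Structure parsing, altloc policy, atom selection and the annotation table."""

import gemmi
import pytest

import tsrkit as tk
from tsrkit.structure_io import CofactorAnnotation, MoleculeSelection, Provenance

from conftest import GLY_ATOMS, TRP_ATOMS, build_pdb


class TestReadStructure:
    def test_three_atom_backbone(self):
        text = build_pdb([("ALA", 1, GLY_ATOMS[:3])])
        model = tk.read_structure(text)
        residues = model.chains["A"]
        assert len(residues) == 1
        assert [a.atom_name for a in residues[0].atoms] == ["N", "CA", "C"]

    def test_toy_protein_contract(self):
        model = tk.read_structure(tk.make_toy_protein(5))
        residues = model.chains["A"]
        assert len(residues) == 5
        assert all(any(a.atom_name == "CA" for a in r.atoms) for r in residues)

    def test_altloc_highest_occupancy_wins(self):
        text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.40  0.00           C\n"
            "END\n"
        )
        model = tk.read_structure(text)
        atoms = model.chains["A"][0].atoms
        assert len(atoms) == 1
        assert atoms[0].altloc == "A"
        assert atoms[0].occupancy == pytest.approx(0.60)

    def test_altloc_tie_goes_to_first_code(self):
        text = (
            "ATOM      1  CA BALA A   1       1.000   0.000   0.000  0.50  0.00           C\n"
            "ATOM      2  CA AALA A   1       0.000   0.000   0.000  0.50  0.00           C\n"
            "END\n"
        )
        model = tk.read_structure(text)
        assert model.chains["A"][0].atoms[0].altloc == "A"

    def test_malformed_coordinate_line_names_line_number(self):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  ALA A   2       xx.xxx   0.000   0.000  1.00  0.00           C\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            tk.read_structure(text)

    def test_empty_model_errors(self):
        with pytest.raises(ValueError, match="empty"):
            tk.read_structure("END\n")

    def test_mmcif_matches_pdb(self):
        pdb_text = tk.make_toy_cofactor()
        st = gemmi.read_pdb_string(pdb_text)
        st.setup_entities()
        cif_text = st.make_mmcif_document().as_string()
        from_pdb = tk.read_structure(pdb_text)
        from_cif = tk.read_structure(cif_text, format="mmcif")
        names_pdb = [a.atom_name for a in from_pdb.chains["A"][0].atoms]
        cif_chain = next(iter(from_cif.chains.values()))
        assert [a.atom_name for a in cif_chain[0].atoms] == names_pdb

    def test_roundtrip_through_selection_writer(self, toy_cofactor_sel):
        text = tk.selection_to_pdb(toy_cofactor_sel)
        reread = tk.read_structure(text)
        atoms = reread.chains["A"][0].atoms
        assert [a.atom_name for a in atoms] == [
            a.atom_name for a in toy_cofactor_sel.atoms
        ]
        for a, b in zip(atoms, toy_cofactor_sel.atoms):
            assert a.coords == pytest.approx(b.coords, abs=1e-3)


class TestSelections:
    def test_calpha_from_helix(self):
        model = tk.read_structure(tk.make_toy_protein(5))
        sel = tk.select_calpha(model, "A")
        assert len(sel) == 5
        assert sel.mode == "CA"
        assert [a.res_seq for a in sel.atoms] == [1, 2, 3, 4, 5]

    def test_calpha_skips_residue_without_ca(self, caplog):
        residues = [("ALA", i, [("CA", "C", (float(i), 0.0, 0.0))]) for i in range(1, 5)]
        residues.append(("GLY", 5, [("N", "N", (5.0, 0.0, 0.0))]))
        model = tk.read_structure(build_pdb(residues))
        with caplog.at_level("WARNING"):
            sel = tk.select_calpha(model, "A")
        assert len(sel) == 4
        assert "no CA" in caplog.text

    def test_calpha_missing_chain_errors(self):
        model = tk.read_structure(tk.make_toy_protein(3))
        with pytest.raises(KeyError, match="chain 'B'"):
            tk.select_calpha(model, "B")

    def test_cofactor_selection_by_annotation(self):
        model = tk.read_structure(tk.make_toy_cofactor())
        ann = CofactorAnnotation("TOY", "P700_A", "A", 901, "CLA")
        sel = tk.select_cofactor(model, ann)
        assert sel.mode == "COFACTOR"
        assert len(sel) == 25
        assert sel.provenance.role == "P700_A"

    def test_cofactor_annotation_mismatch_names_row(self):
        model = tk.read_structure(tk.make_toy_cofactor())
        bad_seq = CofactorAnnotation("TOY", "A_0A", "A", 999, "CLA")
        with pytest.raises(ValueError, match="A_0A"):
            tk.select_cofactor(model, bad_seq)
        bad_name = CofactorAnnotation("TOY", "A_0A", "A", 901, "PQN")
        with pytest.raises(ValueError, match="found CLA"):
            tk.select_cofactor(model, bad_name)

    def test_tryptophan_heavy_atom_inventory(self, trp_model):
        sel = tk.select_residue(trp_model, "A", 7)
        assert len(sel) == 14
        assert {a.atom_name for a in sel.atoms} == {n for n, _, _ in TRP_ATOMS}

    def test_glycine_heavy_atom_inventory(self):
        model = tk.read_structure(build_pdb([("GLY", 3, GLY_ATOMS)]))
        assert len(tk.select_residue(model, "A", 3)) == 4

    def test_residue_selection_rejects_hetero(self):
        model = tk.read_structure(tk.make_toy_cofactor())
        with pytest.raises(ValueError, match="select_cofactor"):
            tk.select_residue(model, "A", 901)

    def test_residue_absent(self, trp_model):
        with pytest.raises(ValueError, match="absent"):
            tk.select_residue(trp_model, "A", 99)

    def test_hydrogens_excluded_from_residue_selection(self):
        atoms = GLY_ATOMS + [("H", "H", (2.0, 0.5, 0.0)), ("HA2", "", (0.3, 0.9, 0.2))]
        model = tk.read_structure(build_pdb([("GLY", 1, atoms)]))
        assert len(tk.select_residue(model, "A", 1)) == 4


class TestFilterAtoms:
    def test_phytol_tail_preset_removes_fifteen(self, toy_cofactor_tail_sel):
        filtered = tk.filter_atoms(toy_cofactor_tail_sel, tk.PHYTOL_TAIL)
        assert len(toy_cofactor_tail_sel) - len(filtered) == 15
        assert not {a.atom_name for a in filtered.atoms} & tk.PHYTOL_TAIL

    def test_empty_exclusion_is_identity(self, toy_cofactor_sel):
        same = tk.filter_atoms(toy_cofactor_sel, set())
        assert [a.atom_name for a in same.atoms] == [
            a.atom_name for a in toy_cofactor_sel.atoms
        ]

    def test_excluding_everything_errors(self, toy_cofactor_sel):
        names = {a.atom_name for a in toy_cofactor_sel.atoms}
        with pytest.raises(ValueError, match="every atom"):
            tk.filter_atoms(toy_cofactor_sel, names)

    def test_idempotent(self, toy_cofactor_tail_sel):
        once = tk.filter_atoms(toy_cofactor_tail_sel, tk.PHYTOL_TAIL)
        twice = tk.filter_atoms(once, tk.PHYTOL_TAIL)
        assert [a.atom_name for a in once.atoms] == [a.atom_name for a in twice.atoms]


class TestAnnotationTable:
    def test_nine_entries_times_eight_roles(self):
        rows = tk.load_cofactor_annotations()
        assert len(rows) == 72
        entries = {r.pdb_id for r in rows}
        assert entries == {
            "1JB0", "5OY0", "6HQB", "6JO6", "6KMW", "6KMX", "6PNJ", "7COY", "5ZJI"
        }
        for entry in entries:
            roles = {r.role for r in rows if r.pdb_id == entry}
            assert roles == {
                "P700_A", "P700_B", "A_-1A", "A_-1B", "A_0A", "A_0B", "A_CA", "A_CB"
            }

    def test_reference_rows(self):
        rows = {(r.pdb_id, r.role): r for r in tk.load_cofactor_annotations()}
        p700a = rows[("1JB0", "P700_A")]
        assert (p700a.chain, p700a.res_seq, p700a.res_name) == ("A", 1011, "CLA")
        assert p700a.axial_res == "H680"
        a0a = rows[("5OY0", "A_0A")]
        assert (a0a.chain, a0a.res_seq, a0a.res_name) == ("A", 1013, "CLA")
        assert a0a.axial_res == "M684"

    def test_selection_mode_invariants_enforced(self):
        atom = tk.AtomRecord(1, "CB", "C", "ALA", 1, "A", (0.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="non-CA"):
            MoleculeSelection([atom], Provenance("T", "A", "1"), "CA")
        h = tk.AtomRecord(2, "HA", "H", "ALA", 1, "A", (1.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="hydrogens"):
            MoleculeSelection([h], Provenance("T", "A", "1"), "AA")
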