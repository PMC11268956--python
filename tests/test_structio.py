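"""Structure model, PDB round-trips, loop masks and covalent bonds."""

import numpy as np
import pytest

from loopforge.fixtures import ChainRecipe, build_chain, make_loop_task
from loopforge.structio import (
    LoopSpec,
    PDBParseError,
    derive_covalent_bonds,
    loop_mask,
    parse_pdb,
    write_pdb,
)

ALA_PDB = """ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000  -0.800   1.200  1.00  0.00           C
END
"""


class TestParsePDB:
    def test_single_residue_counts(self):
        s = parse_pdb(ALA_PDB)
        assert len(s.chains) == 1
        assert len(s.chains["A"]) == 1
        assert s.n_atoms == 5
        assert [a.name for a in s.chains["A"][0].atoms] == ["N", "CA", "C", "O", "CB"]

    def test_water_skipped(self):
        text = ALA_PDB.replace("END\n", "") + (
            "HETATM    6  O   HOH A   2       9.000   9.000   9.000  1.00  0.00           O\n"
        )
        s = parse_pdb(text)
        assert s.n_atoms == 5
        assert all(res.name != "HOH" for res in s.residues())

    def test_backbone_flags_and_residue_refs(self):
        s = parse_pdb(ALA_PDB)
        atoms = list(s.atoms())
        assert [a.is_backbone for a in atoms] == [True, True, True, True, False]
        assert all(a.residue_ref == 0 for a in atoms)

    def test_malformed_coordinate_reports_line(self):
        bad = ALA_PDB.replace("1.458", "1.4x8")
        with pytest.raises(PDBParseError, match="line 2"):
            parse_pdb(bad)

    def test_altloc_keeps_highest_occupancy(self):
        text = (
            "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.40  0.00           N\n"
            "ATOM      2  N  BALA A   1       5.000   0.000   0.000  0.60  0.00           N\n"
            "ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C\n"
        )
        s = parse_pdb(text)
        n = s.chains["A"][0].atom("N")
        assert np.allclose(n.coords, [5.0, 0.0, 0.0])


class TestWritePDB:
    def test_fixed_columns(self):
        s = parse_pdb(ALA_PDB)
        s.chains["A"][0].atoms[0].coords = np.array([1.0, 2.0, 3.0])
        line = next(l for l in write_pdb(s).splitlines() if l.startswith("ATOM"))
        assert line[30:54] == "   1.000   2.000   3.000"

    def test_roundtrip_preserves_structure(self, loop_task_raw):
        structure, _, _ = loop_task_raw
        again = parse_pdb(write_pdb(structure))
        assert again.n_atoms == structure.n_atoms
        assert [a.name for a in again.atoms()] == [a.name for a in structure.atoms()]
        assert np.abs(again.atom_coords() - structure.atom_coords()).max() < 1e-3
        # second round trip is exact: 3-decimal quantisation is idempotent
        third = parse_pdb(write_pdb(again))
        assert np.array_equal(third.atom_coords(), again.atom_coords())

    def test_empty_structure_has_no_atom_lines(self):
        from loopforge.structio import ProteinStructure

        out = write_pdb(ProteinStructure(title="empty"))
        assert not any(l.startswith("ATOM") for l in out.splitlines())

    def test_huge_coordinates_rejected(self):
        s = parse_pdb(ALA_PDB)
        s.chains["A"][0].atoms[0].coords = np.array([1e4, 0.0, 0.0])
        with pytest.raises(ValueError, match="10000"):
            write_pdb(s)


class TestLoopMask:
    def test_mask_counts_selected_residues(self, loop_task_raw):
        structure, spec, _ = loop_task_raw
        mask = loop_mask(structure, spec)
        expected = sum(len(r.atoms) for r in spec.loop_residues(structure))
        assert mask.sum() == expected
        assert len(mask) == structure.n_atoms

    def test_single_residue_loop(self):
        structure = build_chain(ChainRecipe(segments=[("helix", 5)], seed=0))
        spec = LoopSpec(chain_id="A", start=2, end=2)
        mask = loop_mask(structure, spec)
        assert mask.sum() == len(structure.chains["A"][2].atoms)
        # mask and complement partition the atom set
        assert mask.sum() + (~mask).sum() == structure.n_atoms

    def test_missing_chain_is_key_error(self, loop_task_raw):
        structure, _, _ = loop_task_raw
        with pytest.raises(KeyError):
            loop_mask(structure, LoopSpec(chain_id="Z", start=2, end=3))


class TestLoopSpec:
    def test_anchors_and_length(self):
        spec = LoopSpec(chain_id="A", start=8, end=13)
        assert spec.length == 6
        assert spec.anchors == (7, 14)

    def test_end_before_start_rejected(self):
        with pytest.raises(ValueError):
            LoopSpec(chain_id="A", start=5, end=4)

    def test_terminal_loop_rejected(self, loop_task_raw):
        structure, _, _ = loop_task_raw
        with pytest.raises(ValueError, match="anchor"):
            LoopSpec(chain_id="A", start=0, end=4).validate(structure)


class TestCovalentBonds:
    def test_single_ala_has_four_bonds(self):
        bonds = derive_covalent_bonds(parse_pdb(ALA_PDB))
        assert len(bonds) == 4

    def test_consecutive_residues_one_peptide_bond(self):
        structure = build_chain(ChainRecipe(segments=[("helix", 2)], seed=0))
        bonds = derive_covalent_bonds(structure)
        names = [a.name for a in structure.atoms()]
        inter = [
            (a, b)
            for a, b in bonds
            if list(structure.atoms())[a].residue_ref != list(structure.atoms())[b].residue_ref
        ]
        assert len(inter) == 1
        a, b = inter[0]
        assert {names[a], names[b]} == {"C", "N"}

    def test_helix_bond_count_formula(self):
        n = 12
        structure = build_chain(ChainRecipe(segments=[("helix", n)], seed=0))
        bonds = derive_covalent_bonds(structure)
        assert len(bonds) == 4 * n + (n - 1)

    def test_bond_graph_symmetric_no_self_loops(self, loop_task_raw):
        structure, _, _ = loop_task_raw
        bonds = derive_covalent_bonds(structure)
        assert all(a != b for a, b in bonds)
        assert len(set(bonds)) == len(bonds)
        assert all(a < b for a, b in bonds)  # canonical undirected form
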