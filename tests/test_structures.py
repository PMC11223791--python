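import numpy as np
import pytest

from ppiddg.structures import (
    CANONICAL_AA,
    ChainResolutionError,
    DegenerateMutationError,
    EmptyStructureError,
    MissingResidueError,
    MutationFormatError,
    ONE_TO_THREE,
    PDBParseError,
    PHARMACOPHORE_TABLE,
    PharmacophoreClass,
    ResidueKey,
    WildTypeMismatchError,
    build_mutant,
    classify_pharmacophore,
    parse_mutation,
    read_structure,
    write_structure,
)


class TestReadStructure:
    def test_parses_chains_and_residues(self, toy_structure):
        assert toy_structure.chains == {"A", "B"}
        assert len(toy_structure.residues()) == 4

    def test_water_excluded_from_index_but_kept_in_atoms(self, toy_structure):
        names = {a.residue_name for a in toy_structure.atoms}
        assert "HOH" in names
        assert all(key.residue_seq != 201 for key in toy_structure.residues())

    def test_round_trip_preserves_atom_table(self, toy_pdb_text):
        s1 = read_structure(toy_pdb_text)
        s2 = read_structure(write_structure(s1))
        assert len(s1.atoms) == len(s2.atoms)
        for a1, a2 in zip(s1.atoms, s2.atoms):
            assert (a1.name, a1.residue_name, a1.chain_id, a1.residue_seq) == \
                   (a2.name, a2.residue_name, a2.chain_id, a2.residue_seq)
            np.testing.assert_allclose(a1.coords, a2.coords, atol=5e-4)

    def test_no_atom_records_is_an_error(self):
        with pytest.raises(EmptyStructureError):
            read_structure("HEADER    NOTHING\nEND\n")

    def test_malformed_line_error_names_line_number(self):
        text = "ATOM      1  CA  ALA A   1      bad coords here\n"
        with pytest.raises(PDBParseError, match="line 1"):
            read_structure(text)

    def test_altloc_keeps_highest_occupancy(self):
        text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 20.00           C\n"
            "ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.60 20.00           C\n"
        )
        s = read_structure(text)
        assert len(s.atoms) == 1
        assert s.atoms[0].coords[0] == pytest.approx(1.0)

    def test_altloc_tie_keeps_first_in_file(self):
        text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.50 20.00           C\n"
            "ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.50 20.00           C\n"
        )
        s = read_structure(text)
        assert s.atoms[0].coords[0] == pytest.approx(0.0)

    def test_agrees_with_gemmi_reader(self, toy_pdb_text, tmp_path):
        gemmi = pytest.importorskip("gemmi")
        path = tmp_path / "toy.pdb"
        path.write_text(toy_pdb_text)
        ref = gemmi.read_structure(str(path))
        ref_atoms = [
            (atom.name, res.name, chain.name, res.seqid.num, *atom.pos.tolist())
            for model in ref for chain in model
            for res in chain for atom in res
        ]
        ours = read_structure(toy_pdb_text)
        assert len(ref_atoms) == len(ours.atoms)
        # gemmi regroups waters, so compare as order-independent atom sets
        ref_set = sorted((n, r, c, s, round(x, 3), round(y, 3), round(z, 3))
                         for n, r, c, s, x, y, z in ref_atoms)
        our_set = sorted((a.name, a.residue_name, a.chain_id, a.residue_seq,
                          round(a.coords[0], 3), round(a.coords[1], 3),
                          round(a.coords[2], 3)) for a in ours.atoms)
        assert ref_set == our_set


class TestParseMutation:
    def test_single_with_default_chain(self):
        (spec,) = parse_mutation("L45G", default_chain="A")
        assert (spec.chain_id, spec.wt_aa, spec.position, spec.mut_aa) == ("A", "L", 45, "G")

    def test_multi_with_chain_prefixes(self):
        specs = parse_mutation("I D46A; I R48K")
        assert [(s.chain_id, s.wt_aa, s.position, s.mut_aa) for s in specs] == [
            ("I", "D", 46, "A"), ("I", "R", 48, "K")]

    def test_identity_substitution_rejected(self):
        with pytest.raises(DegenerateMutationError):
            parse_mutation("L45L", default_chain="A")

    def test_noncanonical_letter_rejected(self):
        with pytest.raises(MutationFormatError):
            parse_mutation("B45G", default_chain="A")

    def test_missing_chain_without_default(self):
        with pytest.raises(ChainResolutionError):
            parse_mutation("L45G")

    def test_insertion_code_position(self):
        (spec,) = parse_mutation("L45AG", default_chain="H")
        assert (spec.position, spec.insertion_code, spec.mut_aa) == (45, "A", "G")


class TestPharmacophores:
    @pytest.mark.parametrize("res,atom,expected", [
        ("LEU", "CD1", {PharmacophoreClass.HYDROPHOBIC}),
        ("CYS", "SG", {PharmacophoreClass.SULPHUR}),
        ("ASP", "OD1", {PharmacophoreClass.NEGATIVE, PharmacophoreClass.ACCEPTOR}),
        ("LYS", "NZ", {PharmacophoreClass.POSITIVE, PharmacophoreClass.DONOR}),
        ("PHE", "CZ", {PharmacophoreClass.AROMATIC, PharmacophoreClass.HYDROPHOBIC}),
    ])
    def test_table_lookups(self, res, atom, expected, toy_structure):
        from dataclasses import replace
        probe = replace(toy_structure.atoms[0], residue_name=res, name=atom)
        assert set(classify_pharmacophore(probe)) == expected

    def test_unknown_atom_classified_neutral(self, toy_structure, caplog):
        from dataclasses import replace
        probe = replace(toy_structure.atoms[0], residue_name="LEU", name="XX9")
        with caplog.at_level("WARNING"):
            assert classify_pharmacophore(probe) == {PharmacophoreClass.NEUTRAL}
        assert caplog.records

    def test_table_total_over_canonical_residues(self):
        residues = {res for res, _ in PHARMACOPHORE_TABLE}
        assert residues == set(ONE_TO_THREE.values())
        for res in residues:
            atoms = {a for r, a in PHARMACOPHORE_TABLE if r == res}
            assert {"N", "CA", "C", "O"} <= atoms
            for atom in atoms:
                assert PHARMACOPHORE_TABLE[(res, atom)]


class TestBuildMutant:
    def test_renames_and_strips_side_chain(self, toy_structure):
        (spec,) = parse_mutation("L45G", default_chain="A")
        mut = build_mutant(toy_structure, spec)
        key = ResidueKey("A", 45)
        names = {a.name for a in mut.residue_atoms(key)}
        assert mut.residue_name(key) == "GLY"
        assert names == {"N", "CA", "C", "O"}
        assert mut.naive_mutant

    def test_untouched_atoms_bitwise_identical(self, toy_structure):
        (spec,) = parse_mutation("L45G", default_chain="A")
        mut = build_mutant(toy_structure, spec)
        originals = {(a.chain_id, a.residue_seq, a.name): a.coords
                     for a in toy_structure.atoms}
        for atom in mut.atoms:
            if atom.residue_key != ResidueKey("A", 45):
                assert np.array_equal(
                    atom.coords, originals[(atom.chain_id, atom.residue_seq, atom.name)])

    def test_mutation_round_trip_restores_backbone(self, toy_structure):
        (fwd,) = parse_mutation("A46G", default_chain="A")
        back = build_mutant(build_mutant(toy_structure, fwd), fwd.reversed())
        key = ResidueKey("A", 46)
        orig = {a.name: a.coords for a in toy_structure.residue_atoms(key)}
        for atom in back.residue_atoms(key):
            assert np.array_equal(atom.coords, orig[atom.name])

    def test_wild_type_mismatch(self, toy_structure):
        (spec,) = parse_mutation("K45G", default_chain="A")
        with pytest.raises(WildTypeMismatchError):
            build_mutant(toy_structure, spec)

    def test_missing_position(self, toy_structure):
        (spec,) = parse_mutation("L999G", default_chain="A")
        with pytest.raises(MissingResidueError):
            build_mutant(toy_structure, spec)


def test_canonical_alphabet_has_twenty_letters():
    assert len(CANONICAL_AA) == 20
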