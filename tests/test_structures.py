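import numpy as np
import pytest

from bumphole.geometry import bond_angle, dihedral
from bumphole.structures import (
    Atom,
    FormatError,
    InterfaceSpec,
    MutationError,
    Mutation,
    Structure,
    apply_mutations,
    extract_design_region,
    make_synthetic_bundle,
    make_synthetic_interface,
    parse_mutation,
    read_structure,
    write_structure,
)

SINGLE_ATOM_PDB = (
    "ATOM      1  CA  ALA A  12      11.100  -2.200   3.300  1.00  0.00           C\n"
    "END\n"
)


class TestReadWrite:
    def test_single_atom_identity_parse(self):
        s = read_structure(SINGLE_ATOM_PDB)
        assert len(s) == 1
        a = s.atoms[0]
        assert (a.chain_id, a.residue_number, a.name, a.residue_name) == ("A", 12, "CA", "ALA")
        np.testing.assert_allclose(a.coord, [11.1, -2.2, 3.3])

    def test_fixture_roundtrip_preserves_all_fields(self, two_helix_bundle):
        text = write_structure(two_helix_bundle)
        back = read_structure(text)
        assert len(back) == len(two_helix_bundle)
        for a, b in zip(two_helix_bundle.atoms, back.atoms):
            assert (a.name, a.residue_number, a.residue_name, a.chain_id) == (
                b.name, b.residue_number, b.residue_name, b.chain_id
            )
            np.testing.assert_allclose(np.round(a.coord, 3), b.coord, atol=1e-9)

    def test_write_read_write_is_byte_idempotent(self, two_helix_bundle):
        t1 = write_structure(two_helix_bundle)
        t2 = write_structure(read_structure(t1))
        t3 = write_structure(read_structure(t2))
        assert t2 == t3

    def test_hetatm_waters_hydrogens_dropped(self):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  H   ALA A   1       1.000   0.000   0.000  1.00  0.00           H\n"
            "HETATM    3  O   HOH A 101       2.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        s = read_structure(text)
        assert [a.name for a in s.atoms] == ["CA"]

    def test_unparsable_record_reports_line(self):
        bad = SINGLE_ATOM_PDB.replace("11.100", "xx.xxx")
        with pytest.raises(FormatError, match="line 1"):
            read_structure(bad)

    def test_empty_selection_errors(self):
        with pytest.raises(FormatError):
            read_structure("HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\nEND\n")

    def test_coordinate_overflow_errors(self):
        s = Structure(
            atoms=[
                Atom("CA", "C", np.array([1e5, 0.0, 0.0]), 1, "ALA", "A")
            ]
        )
        with pytest.raises(FormatError):
            write_structure(s)


class TestMutations:
    def test_parse_mutation_roundtrip(self):
        m = parse_mutation("L126A")
        assert m == Mutation(wt="L", position=126, mut="A")

    @pytest.mark.parametrize("token", ["L126", "126A", "LxA", ""])
    def test_malformed_tokens_rejected(self, token):
        with pytest.raises(MutationError):
            parse_mutation(token)

    def test_threading_updates_names_and_strips_sidechains(self, two_helix_bundle):
        muts = [parse_mutation("A5I"), parse_mutation("A6W"), parse_mutation("A8I")]
        out = apply_mutations(two_helix_bundle, "A", muts)
        assert out.residue_name("A", 5) == "ILE"
        assert out.residue_name("A", 6) == "TRP"
        assert out.residue_name("A", 8) == "ILE"
        # side chains (CB for ALA) removed at mutated positions only
        assert not any(
            a.name == "CB" for a in out.residue("A", 5)
        )
        assert any(a.name == "CB" for a in out.residue("A", 7))

    def test_empty_mutation_list_is_identity(self, two_helix_bundle):
        out = apply_mutations(two_helix_bundle, "A", [])
        assert len(out) == len(two_helix_bundle)
        np.testing.assert_array_equal(out.coords(), two_helix_bundle.coords())

    def test_backbone_never_moves(self, two_helix_bundle):
        muts = [parse_mutation("A5L"), parse_mutation("A9W")]
        out = apply_mutations(two_helix_bundle, "A", muts)
        for a in out.atoms:
            if a.is_backbone:
                orig = two_helix_bundle.get_atom(a.chain_id, a.residue_number, a.name)
                np.testing.assert_array_equal(a.coord, orig.coord)

    def test_wildtype_mismatch_names_position(self, two_helix_bundle):
        with pytest.raises(MutationError, match="5"):
            apply_mutations(two_helix_bundle, "A", [parse_mutation("L5V")])

    def test_unknown_position_errors(self, two_helix_bundle):
        with pytest.raises(MutationError, match="99"):
            apply_mutations(two_helix_bundle, "A", [parse_mutation("A99V")])


class TestDesignRegion:
    def test_site_count_is_positions_times_two(self, two_helix_bundle):
        spec = InterfaceSpec("A", "B", (5, 6, 8, 9))
        region = extract_design_region(two_helix_bundle, spec)
        assert len(region.design_sites) == 8

    def test_zero_cutoff_keeps_only_design_backbones(self, two_helix_bundle):
        spec = InterfaceSpec("A", "B", (5, 8), environment_cutoff=0.0)
        region = extract_design_region(two_helix_bundle, spec)
        keys = {(a.chain_id, a.residue_number) for a in region.template_atoms}
        assert keys == {("A", 5), ("A", 8), ("B", 5), ("B", 8)}
        assert all(a.is_backbone for a in region.template_atoms)

    @pytest.mark.parametrize("cutoff", [3.0, 6.0, 8.0])
    def test_template_matches_brute_force_distance_scan(self, two_helix_bundle, cutoff):
        spec = InterfaceSpec("A", "B", (5, 8), environment_cutoff=cutoff)
        region = extract_design_region(two_helix_bundle, spec)
        design = {("A", 5), ("A", 8), ("B", 5), ("B", 8)}
        probes = [
            two_helix_bundle.get_atom(c, p, nm).coord
            for (c, p) in design
            for nm in ("CA", "CB")
        ]
        expected = set()
        for a in two_helix_bundle.atoms:
            key = (a.chain_id, a.residue_number)
            if key in design:
                if a.is_backbone:
                    expected.add((key, a.name))
                continue
            if min(np.linalg.norm(np.array(p) - a.coord) for p in probes) <= cutoff:
                expected.add((key, a.name))
        got = {((a.chain_id, a.residue_number), a.name) for a in region.template_atoms}
        assert got == expected


class TestSyntheticBundle:
    def test_single_helix_geometry(self):
        s = make_synthetic_bundle(n_helices=1, residues_per_helix=8)
        ca = [a.coord for a in s.atoms if a.name == "CA"]
        assert len(ca) == 8
        d = [np.linalg.norm(ca[i + 1] - ca[i]) for i in range(7)]
        assert all(abs(x - 3.8) < 0.1 for x in d)

    def test_atom_count_poly_ala(self):
        s = make_synthetic_bundle(n_helices=2, residues_per_helix=12)
        assert len(s) == 120  # 5 heavy atoms per ALA residue

    def test_axis_spacing_controls_interhelix_distance(self):
        # facing CA atoms approach (spacing - 2 * helix radius); the CA helix
        # radius of an ideal alpha helix is ~2.3 A
        s = make_synthetic_bundle(n_helices=2, residues_per_helix=12, inter_axis_spacing=10.0)
        ca_a = np.array([a.coord for a in s.atoms if a.name == "CA" and a.chain_id == "A"])
        ca_b = np.array([a.coord for a in s.atoms if a.name == "CA" and a.chain_id == "B"])
        dmin = min(np.linalg.norm(a - b) for a in ca_a for b in ca_b)
        assert 10.0 - 2 * 2.3 - 1.0 < dmin < 10.0 + 1.0

    def test_same_seed_reproduces_coordinates(self):
        s1 = make_synthetic_bundle(2, 10, 10.0, seed=7, jitter_sd=0.05)
        s2 = make_synthetic_bundle(2, 10, 10.0, seed=7, jitter_sd=0.05)
        np.testing.assert_array_equal(s1.coords(), s2.coords())

    def test_nonphysical_spacing_rejected(self):
        with pytest.raises(Exception):
            make_synthetic_bundle(2, 10, 3.0)

    def test_ideal_bond_lengths(self):
        s = make_synthetic_bundle(1, 8)
        for pos in s.residue_numbers("A"):
            n = s.get_atom("A", pos, "N").coord
            ca = s.get_atom("A", pos, "CA").coord
            c = s.get_atom("A", pos, "C").coord
            assert abs(np.linalg.norm(ca - n) - 1.458) < 0.05
            assert abs(np.linalg.norm(c - ca) - 1.525) < 0.05

    def test_interface_fixture_is_c2_symmetric(self):
        s, spec = make_synthetic_interface()
        c2 = np.diag([-1.0, -1.0, 1.0])
        for a in s.atoms:
            if a.chain_id == "A":
                b = s.get_atom("B", a.residue_number, a.name)
                np.testing.assert_allclose(c2 @ a.coord, b.coord, atol=1e-9)
        assert len(spec.design_positions) == 4
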