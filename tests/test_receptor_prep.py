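"""Receptor preparation: stripping, plane fits, oxy-heme, mutations, boxes."""

import numpy as np
import pytest

from cypscreen.errors import MutationError, ReceptorError
from cypscreen.receptor_prep import (
    Atom,
    HemeModel,
    MutationSpec,
    ReceptorModel,
    apply_point_mutations,
    build_oxyheme,
    compute_search_box,
    load_receptor,
    write_pdb,
)
from cypscreen.residue_templates import RESIDUE_HEAVY_ATOMS, build_backbone, build_sidechain
from cypscreen.synthetic_fixtures import (
    ResiduePlacement,
    ToyPocketConfig,
    generate_toy_pocket,
)

from conftest import make_pose


@pytest.fixture
def toy_pdb(tmp_path):
    """Toy-pocket PDB with an extra water and a chain-B atom appended."""
    pocket, _ = generate_toy_pocket(
        ToyPocketConfig(
            seed=2,
            residues=(ResiduePlacement("ASP", 8.0, (0.8, 0.0, 0.6), res_seq=301),),
        )
    )
    path = tmp_path / "pocket.pdb"
    write_pdb(pocket, path)
    lines = path.read_text().splitlines()
    extra = [
        "HETATM  998  O   HOH A 700      20.000  20.000  20.000  1.00  0.00           O",
        "ATOM    999  CA  GLY B   1      30.000  30.000  30.000  1.00  0.00           C",
    ]
    path.write_text("\n".join(lines[:-1] + extra + ["END"]) + "\n")
    return path


class TestLoadReceptor:
    def test_waters_and_other_chains_are_stripped(self, toy_pdb):
        model = load_receptor(toy_pdb, chain="A")
        assert not any(a.res_name == "HOH" for a in model.atoms)
        assert all(a.chain == "A" for a in model.atoms)
        assert model.heme is not None

    def test_requesting_chain_b_keeps_only_chain_b(self, toy_pdb):
        with pytest.warns(UserWarning, match="no HEM"):
            model = load_receptor(toy_pdb, chain="B")
        assert len(model.atoms) == 1
        assert model.heme is None

    def test_missing_chain_errors(self, toy_pdb):
        with pytest.raises(ReceptorError, match="chain 'C'"):
            load_receptor(toy_pdb, chain="C")

    def test_loading_is_idempotent(self, toy_pdb, tmp_path):
        first = load_receptor(toy_pdb, chain="A")
        rewritten = tmp_path / "again.pdb"
        write_pdb(first, rewritten)
        second = load_receptor(rewritten, chain="A")
        assert len(first.atoms) == len(second.atoms)
        np.testing.assert_allclose(first.coords(), second.coords(), atol=1e-3)


class TestHemePlane:
    def test_square_pyrrole_nitrogens_give_construction_normal(self):
        fe = np.array([1.0, -2.0, 3.0])
        atoms = [Atom("FE", "FE", fe, "HEM", 501, "A", het=True)]
        for name, (dx, dy) in zip(("NA", "NB", "NC", "ND"), ((2, 0), (0, 2), (-2, 0), (0, -2))):
            atoms.append(Atom("N", name, fe + np.array([dx, dy, 0.0]), "HEM", 501, "A", True))
        heme = HemeModel.from_atoms(atoms)
        assert abs(abs(heme.plane_normal[2]) - 1.0) < 1e-6
        assert np.linalg.norm(heme.plane_normal) == pytest.approx(1.0, abs=1e-12)


class TestOxyHeme:
    def test_default_distance_is_measured_back(self, toy_pdb):
        model = build_oxyheme(load_receptor(toy_pdb))
        assert model.heme.fe_o_distance == pytest.approx(1.97, abs=1e-9)
        measured = np.linalg.norm(model.heme.axial_oxygen - model.heme.fe_position)
        assert measured == pytest.approx(1.97, abs=1e-9)

    def test_distance_parameter_passthrough(self, toy_pdb):
        model = build_oxyheme(load_receptor(toy_pdb), distance=2.5)
        assert model.heme.fe_o_distance == pytest.approx(2.5, abs=1e-9)

    def test_oxygen_opposite_axial_cysteine(self, toy_pdb):
        model = build_oxyheme(load_receptor(toy_pdb))
        sg = next(a for a in model.atoms if a.res_name == "CYS" and a.name == "SG")
        fe = model.heme.fe_position
        assert np.dot(model.heme.axial_oxygen - fe, sg.pos - fe) < 0

    def test_oxygen_equidistant_from_pyrrole_nitrogens(self, toy_pdb):
        model = build_oxyheme(load_receptor(toy_pdb))
        d = np.linalg.norm(model.heme.pyrrole_n - model.heme.axial_oxygen, axis=1)
        assert d.max() - d.min() < 1e-6

    def test_idempotent(self, toy_pdb):
        once = build_oxyheme(load_receptor(toy_pdb))
        twice = build_oxyheme(once)
        assert twice is once

    def test_missing_heme_errors(self):
        model = ReceptorModel(atoms=[Atom("C", "CA", np.zeros(3), "GLY", 1, "A")])
        with pytest.raises(ReceptorError, match="no heme"):
            build_oxyheme(model)


def _residue_model(res_name, res_seq=122):
    coords = build_backbone()
    if res_name not in ("GLY", "ALA"):
        coords.update(build_sidechain(res_name, coords))
    atoms = [
        Atom(name[0], name, coords[name].copy(), res_name, res_seq, "A")
        for name in RESIDUE_HEAVY_ATOMS[res_name]
    ]
    return ReceptorModel(atoms=atoms)


class TestMutations:
    def test_ala_to_ser_grows_og_at_ideal_distance(self):
        model = _residue_model("ALA")
        mutated = apply_point_mutations(model, MutationSpec((("A", 122, "ALA", "SER"),)))
        by_name = {a.name: a for a in mutated.atoms}
        assert by_name["OG"].res_name == "SER"
        d = np.linalg.norm(by_name["CB"].pos - by_name["OG"].pos)
        assert d == pytest.approx(1.41, abs=0.05)

    def test_identity_mutation_is_bitwise_noop(self):
        model = _residue_model("PHE", res_seq=120)
        mutated = apply_point_mutations(model, MutationSpec((("A", 120, "PHE", "PHE"),)))
        assert [a.name for a in mutated.atoms] == [a.name for a in model.atoms]
        np.testing.assert_array_equal(mutated.coords(), model.coords())

    def test_phe_to_ile_heavy_atom_count(self):
        model = _residue_model("PHE", res_seq=120)
        assert len(model.atoms) == 11
        mutated = apply_point_mutations(model, MutationSpec((("A", 120, "PHE", "ILE"),)))
        assert len(mutated.atoms) == 8
        assert {a.name for a in mutated.atoms} == {"N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"}

    def test_wild_type_mismatch_names_both_codes(self):
        model = _residue_model("ALA")
        with pytest.raises(MutationError, match="expected PHE, found ALA"):
            apply_point_mutations(model, MutationSpec((("A", 122, "PHE", "ILE"),)))

    def test_reverse_mutation_restores_name_and_topology(self):
        model = _residue_model("PHE", res_seq=120)
        spec_fwd = MutationSpec((("A", 120, "PHE", "ILE"),))
        spec_back = MutationSpec((("A", 120, "ILE", "PHE"),))
        roundtrip = apply_point_mutations(apply_point_mutations(model, spec_fwd), spec_back)
        assert len(roundtrip.atoms) == len(model.atoms)
        assert all(a.res_name == "PHE" for a in roundtrip.atoms)
        backbone = lambda m: np.array(  # noqa: E731
            [a.pos for a in m.atoms if a.name in ("N", "CA", "C", "O", "CB")]
        )
        np.testing.assert_allclose(backbone(roundtrip), backbone(model), atol=1e-12)

    def test_parse_one_letter_spec(self):
        spec = MutationSpec.parse(["F120I", "A122S"])
        assert spec.mutations == (("A", 120, "PHE", "ILE"), ("A", 122, "ALA", "SER"))


class TestSearchBox:
    def test_buffer_grows_each_extent_by_twice_buffer(self):
        pose = make_pose(
            [[0, 0, 0], [10, 8, 6]], ["C", "C"]
        )
        box = compute_search_box([pose], buffer=8.0)
        assert box.extents == pytest.approx((26.0, 24.0, 22.0))
        assert box.center == pytest.approx((5.0, 4.0, 3.0))

    def test_zero_buffer_equals_raw_bbox(self):
        pose = make_pose([[0, 0, 0], [10, 8, 6]], ["C", "C"])
        box = compute_search_box([pose], buffer=0.0)
        assert box.extents == pytest.approx((10.0, 8.0, 6.0))

    def test_box_contains_every_atom_of_all_reference_ligands(self):
        rng = np.random.default_rng(3)
        poses = [
            make_pose(rng.uniform(-12, 12, size=(8, 3)), ["C"] * 8, name=f"p{i}")
            for i in range(2)
        ]
        box = compute_search_box(poses, buffer=8.0)
        for pose in poses:
            for xyz in pose.coords():
                assert box.contains(xyz)

    def test_empty_ligand_list_errors(self):
        with pytest.raises(ValueError, match="at least one"):
            compute_search_box([], buffer=8.0)
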