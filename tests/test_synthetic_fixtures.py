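"""Toy-pocket generator: determinism, placement accuracy, ground-truth
consistency with the profiler (the module's reason to exist)."""

import numpy as np
import pytest

from cypscreen.errors import PlacementError
from cypscreen.inhibition_classifier import call_pose_inhibition
from cypscreen.interaction_profiler import profile_pose
from cypscreen.receptor_prep import build_oxyheme
from cypscreen.synthetic_fixtures import (
    ProbePlacement,
    ResiduePlacement,
    ToyPocketConfig,
    generate_probe_pose,
    generate_toy_pocket,
    standard_truth_cases,
    write_pocket_pdb,
)


class TestPocketGeneration:
    def test_same_seed_gives_byte_identical_pdb(self, tmp_path):
        cfg = ToyPocketConfig(
            seed=8,
            residues=(ResiduePlacement("GLU", 9.0, (0.6, 0.4, 0.7), res_seq=216),),
            decoy_atoms=5,
        )
        paths = []
        for i in range(2):
            pocket, _ = generate_toy_pocket(cfg)
            path = tmp_path / f"pocket{i}.pdb"
            write_pocket_pdb(pocket, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_asp_anchor_group_lands_at_requested_distance(self):
        pocket, _ = generate_toy_pocket(
            ToyPocketConfig(
                seed=1,
                residues=(ResiduePlacement("ASP", 9.0, (0.7, 0.1, 0.7), res_seq=301),),
            )
        )
        carboxylate = np.array(
            [a.pos for a in pocket.atoms if a.res_seq == 301 and a.name in ("OD1", "OD2")]
        )
        centroid = carboxylate.mean(axis=0)
        assert np.linalg.norm(centroid - pocket.heme.fe_position) == pytest.approx(
            9.0, abs=0.3
        )

    def test_porphyrin_only_config(self):
        pocket, _ = generate_toy_pocket(
            ToyPocketConfig(seed=0, residues=(), axial_cys=False)
        )
        assert pocket.heme is not None
        assert all(a.res_name == "HEM" for a in pocket.atoms)

    def test_overlapping_residues_raise(self):
        cfg = ToyPocketConfig(
            seed=0,
            residues=(
                ResiduePlacement("ASP", 8.0, (0.8, 0.0, 0.6), res_seq=301),
                ResiduePlacement("GLU", 8.0, (0.8, 0.0, 0.6), res_seq=216),
            ),
        )
        with pytest.raises(PlacementError, match="overlap"):
            generate_toy_pocket(cfg)

    def test_residue_inside_porphyrin_rejected(self):
        with pytest.raises(ValueError, match="inside the porphyrin"):
            ToyPocketConfig(residues=(ResiduePlacement("ASP", 1.0, (0, 0, 1)),))


class TestProbePlacement:
    def test_methylamine_over_iron_is_proximal_coordinating(self, bare_pocket):
        receptor, scaffold = bare_pocket
        pose, truth = generate_probe_pose(
            receptor,
            ProbePlacement("CN", "fe_axial", 3.0, anchor_atom=1),
            scaffold,
        )
        assert truth.proximity == "proximal"
        assert truth.contact_types == frozenset({"heme_coordination"})
        assert truth.call == "proximal_inhibitory"
        n_pos = pose.coords()[1]
        assert np.linalg.norm(n_pos - receptor.heme.fe_position) == pytest.approx(3.0)

    def test_probe_at_thirty_angstrom_is_plain_distal(self, bare_pocket):
        receptor, scaffold = bare_pocket
        pose, truth = generate_probe_pose(
            receptor,
            ProbePlacement("CC", "absolute", 30.0, direction=(0.2, 0.9, 0.4)),
            scaffold,
        )
        assert truth.proximity == "distal"
        assert truth.contact_types == frozenset()
        assert truth.call == "none"

    def test_placement_straddling_proximal_boundary_rejected(self, bare_pocket):
        receptor, scaffold = bare_pocket
        with pytest.raises(PlacementError):
            generate_probe_pose(
                receptor,
                ProbePlacement("CC", "absolute", 6.05, direction=(0.0, 0.0, 1.0)),
                scaffold,
            )

    def test_ring_stack_requires_a_phe(self, bare_pocket):
        receptor, scaffold = bare_pocket
        with pytest.raises(PlacementError, match="PHE"):
            generate_probe_pose(
                receptor,
                ProbePlacement("c1ccccc1", "ring_stack", 3.8, residue_seq=120),
                scaffold,
            )


class TestGroundTruthConsistency:
    def test_profiler_reproduces_generator_truth(self):
        """profile_pose must recover proximity, contact types and pose call
        for every generated (pocket, pose, truth) triple."""
        cases = standard_truth_cases(25, seed=3)
        kinds = {c.kind for c in cases}
        assert len(kinds) == 5  # all scenario families represented
        for case in cases:
            receptor = build_oxyheme(case.pocket)
            profile = profile_pose(case.pose, receptor)
            assert profile.proximity == case.truth.proximity, case.kind
            assert (
                frozenset(c.type for c in profile.contacts) == case.truth.contact_types
            ), case.kind
            assert call_pose_inhibition(profile).call == case.truth.call, case.kind

    def test_cases_are_deterministic_under_seed(self):
        a = standard_truth_cases(10, seed=19)
        b = standard_truth_cases(10, seed=19)
        for ca, cb in zip(a, b):
            assert ca.kind == cb.kind
            np.testing.assert_array_equal(ca.pose.coords(), cb.pose.coords())
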