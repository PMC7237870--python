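"""Interaction profiler: worked geometries, exhaustive oracle, invariances.

The brute-force oracle re-applies the published distance/angle rules with
plain Python loops over every atom pair, independently of the vectorized
detection code, and must agree exactly on small pockets.
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cypscreen.interaction_profiler import (
    ProfilerParams,
    detect_interactions,
    ligand_atom_types,
    min_heme_distance,
    profile_pose,
    _receptor_typed_atoms,
)
from cypscreen.receptor_prep import build_oxyheme
from cypscreen.synthetic_fixtures import (
    ProbePlacement,
    generate_probe_pose,
    standard_truth_cases,
)
from cypscreen._geometry import fit_plane

from conftest import make_pose


# ------------------------------------------------------------ brute-force oracle

def brute_force_contacts(pose, receptor, params):
    """All-pairs reimplementation of the contact rules (loops, no dedup tricks)."""
    lt = ligand_atom_types(pose.mol)
    lig = pose.coords()
    donors, acceptors, cations, anions, hydrophobic, rings = _receptor_typed_atoms(receptor)

    def dist(a, b):
        return float(np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b))))

    def angle_ge_90(a, d, b):
        v1 = np.asarray(a) - np.asarray(d)
        v2 = np.asarray(b) - np.asarray(d)
        return float(np.dot(v1, v2)) <= 1e-9 * np.linalg.norm(v1) * np.linalg.norm(v2)

    found = set()
    for li in lt.donors:
        for ra in acceptors:
            if dist(lig[li], ra.pos) <= params.hbond_da_max:
                ante = lt.antecedent.get(li)
                if ante is None or angle_ge_90(lig[ante], lig[li], ra.pos):
                    found.add(("hbond", li, f"{ra.res_name} {ra.res_seq}", ra.name))
    for rd, ante in donors:
        for li in lt.acceptors:
            if dist(lig[li], rd.pos) <= params.hbond_da_max:
                if ante is None or angle_ge_90(ante.pos, rd.pos, lig[li]):
                    found.add(("hbond", li, f"{rd.res_name} {rd.res_seq}", rd.name))
    for li in lt.cations:
        for ra in anions:
            if dist(lig[li], ra.pos) <= params.ionic_max:
                found.add(("ionic", li, f"{ra.res_name} {ra.res_seq}", ra.name))
    for li in lt.anions:
        for ra in cations:
            if dist(lig[li], ra.pos) <= params.ionic_max:
                found.add(("ionic", li, f"{ra.res_name} {ra.res_seq}", ra.name))
    for ring in lt.rings:
        lc, _, _ = fit_plane(lig[list(ring)])
        for res_name, seq, ring_atoms in rings:
            rc, _, _ = fit_plane(np.array([a.pos for a in ring_atoms]))
            if dist(lc, rc) <= params.pistack_centroid_max:
                found.add(("pi_stack", ring[0], f"{res_name} {seq}", "ring"))
    for li in lt.hydrophobic:
        residues = {}
        for ra in hydrophobic:
            d = dist(lig[li], ra.pos)
            rid = f"{ra.res_name} {ra.res_seq}"
            if d <= params.hydrophobic_cc_max and d < residues.get(rid, np.inf):
                residues[rid] = d
        for rid in residues:
            found.add(("hydrophobic", li, rid))
    if receptor.heme is not None:
        for li in lt.coordinating:
            if dist(lig[li], receptor.heme.fe_position) <= params.heme_coordination_max:
                found.add(("heme_coordination", li, "HEM", "FE"))
    return found


def _contact_keys(contacts):
    keys = set()
    for c in contacts:
        if c.type == "hydrophobic":
            keys.add((c.type, c.ligand_atom, c.residue))
        else:
            keys.add((c.type, c.ligand_atom, c.residue, c.rec_atom))
    return keys


# ------------------------------------------------------------------- geometry

class TestMinHemeDistance:
    def test_single_atom_at_five_angstrom(self, bare_pocket):
        receptor, _ = bare_pocket
        pose = make_pose([[0.0, 0.0, 5.0]], ["C"])
        d, idx = min_heme_distance(pose, receptor.heme)
        assert d == pytest.approx(5.0, abs=1e-12)
        assert idx == 0

    @pytest.mark.parametrize("z, expected", [(5.9, "proximal"), (6.0, "distal")])
    def test_six_angstrom_boundary_is_strict(self, bare_pocket, z, expected):
        receptor, _ = bare_pocket
        pose = make_pose([[0.0, 0.0, z]], ["C"])
        assert profile_pose(pose, receptor).proximity == expected

    def test_matches_exhaustive_minimum_on_random_pose(self, bare_pocket):
        receptor, _ = bare_pocket
        rng = np.random.default_rng(9)
        coords = rng.uniform(-15, 15, size=(20, 3))
        pose = make_pose(coords, ["C"] * 20)
        d, idx = min_heme_distance(pose, receptor.heme)
        fe = receptor.heme.fe_position
        brute = min(
            (float(np.linalg.norm(c - fe)), i) for i, c in enumerate(coords)
        )
        assert d == pytest.approx(brute[0], abs=1e-12)
        assert idx == brute[1]


class TestContacts:
    def test_protonated_amine_near_carboxylate_gives_ionic(self, anchored_pocket):
        receptor, scaffold = anchored_pocket
        od1 = next(a for a in receptor.atoms if a.res_seq == 301 and a.name == "OD1")
        outward = od1.pos / np.linalg.norm(od1.pos)
        n_pos = od1.pos + 3.0 * outward
        pose = make_pose([n_pos, n_pos + 1.47 * outward], ["N", "C"], bonds=[(0, 1)])
        contacts = detect_interactions(pose, receptor)
        ionic = [c for c in contacts if c.type == "ionic"]
        assert len(ionic) >= 1
        assert all(c.residue == "ASP 301" for c in ionic)

    def test_parallel_benzene_stack_on_phe(self, anchored_pocket):
        receptor, scaffold = anchored_pocket
        pose, truth = generate_probe_pose(
            receptor,
            ProbePlacement("c1ccccc1", mode="ring_stack", distance=3.8, residue_seq=120),
            scaffold,
        )
        stacks = [c for c in detect_interactions(pose, receptor) if c.type == "pi_stack"]
        assert len(stacks) == 1
        assert stacks[0].annotation == "parallel"
        assert stacks[0].distance == pytest.approx(3.8, abs=0.05)
        assert stacks[0].residue == "PHE 120"

    def test_donor_acceptor_beyond_cutoff_gives_no_hbond(self, anchored_pocket):
        receptor, _ = anchored_pocket
        od1 = next(a for a in receptor.atoms if a.res_seq == 301 and a.name == "OD1")
        lateral = np.array([0.0, 1.0, 0.0])  # away from the residue's own backbone
        o_pos = od1.pos + 6.0 * lateral
        pose = make_pose([o_pos, o_pos + 1.4 * lateral], ["O", "C"], bonds=[(0, 1)])
        contacts = detect_interactions(pose, receptor)
        assert not [c for c in contacts if c.type == "hbond"]

    def test_quinidine_like_amine_bridges_both_anchors(self):
        # two anchoring carboxylates ~5 Å apart, amine midway, far from heme
        from cypscreen.synthetic_fixtures import (
            ResiduePlacement,
            ToyPocketConfig,
            generate_toy_pocket,
        )

        d1 = np.array([np.sin(np.deg2rad(18)), 0.0, np.cos(np.deg2rad(18))])
        d2 = np.array([-np.sin(np.deg2rad(18)), 0.0, np.cos(np.deg2rad(18))])
        pocket, _ = generate_toy_pocket(
            ToyPocketConfig(
                seed=4,
                residues=(
                    ResiduePlacement("ASP", 8.0, tuple(d1), res_seq=301),
                    ResiduePlacement("GLU", 8.0, tuple(d2), res_seq=216),
                ),
            )
        )
        receptor = build_oxyheme(pocket)
        anchors = {}
        for seq, names in ((301, ("OD1", "OD2")), (216, ("OE1", "OE2"))):
            pts = [a.pos for a in receptor.atoms if a.res_seq == seq and a.name in names]
            anchors[seq] = np.mean(pts, axis=0)
        n_pos = (anchors[301] + anchors[216]) / 2
        pose = make_pose(
            [n_pos, n_pos + np.array([0.0, 1.47, 0.0])], ["N", "C"], bonds=[(0, 1)]
        )
        profile = profile_pose(pose, receptor)
        assert profile.proximity == "distal"
        ionic_residues = {c.residue for c in profile.contacts if c.type == "ionic"}
        assert ionic_residues == {"ASP 301", "GLU 216"}

    def test_remote_pose_has_no_contacts(self, anchored_pocket):
        receptor, _ = anchored_pocket
        pose = make_pose([[0.0, -20.0, -8.0], [0.0, -21.5, -8.0]], ["C", "C"], bonds=[(0, 1)])
        profile = profile_pose(pose, receptor)
        assert profile.proximity == "distal"
        assert profile.contacts == []


class TestProperties:
    def test_rigid_motion_invariance(self, anchored_pocket):
        receptor, scaffold = anchored_pocket
        pose, _ = generate_probe_pose(
            receptor,
            ProbePlacement("CN", mode="fe_axial", distance=3.2, anchor_atom=1, seed=2),
            scaffold,
        )
        base = profile_pose(pose, receptor)
        rot = Rotation.random(random_state=12).as_matrix()
        t = np.array([11.0, -4.0, 2.5])
        moved = profile_pose(pose.transformed(rot, t), receptor.transformed(rot, t))
        assert moved.proximity == base.proximity
        assert moved.min_heme_fe_distance == pytest.approx(
            base.min_heme_fe_distance, abs=1e-9
        )
        assert len(moved.contacts) == len(base.contacts)
        for a, b in zip(base.contacts, moved.contacts):
            assert (a.type, a.ligand_atom, a.residue, a.rec_atom) == (
                b.type, b.ligand_atom, b.residue, b.rec_atom,
            )
            assert b.distance == pytest.approx(a.distance, abs=1e-9)

    def test_reported_distances_match_recomputed_pairwise(self, anchored_pocket):
        receptor, scaffold = anchored_pocket
        pose, _ = generate_probe_pose(
            receptor,
            ProbePlacement("CN", "residue_anchor", 3.0, anchor_atom=1, residue_seq=301),
            scaffold,
        )
        rec_atoms = {}
        for a in receptor.atoms:
            rec_atoms[(f"{a.res_name} {a.res_seq}", a.name)] = a.pos
        for c in detect_interactions(pose, receptor):
            if c.type in ("pi_stack",):
                continue
            if c.residue == "HEM" and c.rec_atom == "FE":
                target = receptor.heme.fe_position
            else:
                target = rec_atoms[(c.residue, c.rec_atom)]
            d = float(np.linalg.norm(pose.coords()[c.ligand_atom] - target))
            assert c.distance == pytest.approx(d, abs=1e-9)

    def test_oracle_equivalence_on_small_pockets(self):
        params = ProfilerParams()
        cases = standard_truth_cases(15, seed=23)
        assert all(len(c.pocket.atoms) <= 200 for c in cases)
        for case in cases:
            receptor = build_oxyheme(case.pocket)
            got = _contact_keys(detect_interactions(case.pose, receptor, params))
            expected = set()
            for key in brute_force_contacts(case.pose, receptor, params):
                if key[0] == "hydrophobic":
                    expected.add(key)
                else:
                    expected.add(key)
            assert got == expected, case.kind

    def test_shrinking_cutoffs_never_adds_contacts(self, anchored_pocket):
        receptor, scaffold = anchored_pocket
        pose, _ = generate_probe_pose(
            receptor,
            ProbePlacement("CN", "residue_anchor", 3.0, anchor_atom=1, residue_seq=301),
            scaffold,
        )
        base = _contact_keys(detect_interactions(pose, receptor, ProfilerParams()))
        for factor in (0.9, 0.7, 0.5):
            tight = ProfilerParams(
                hbond_da_max=3.5 * factor,
                ionic_max=4.0 * factor,
                pistack_centroid_max=5.5 * factor,
                hydrophobic_cc_max=4.0 * factor,
                heme_coordination_max=4.0 * factor,
            )
            tightened = _contact_keys(detect_interactions(pose, receptor, tight))
            assert tightened <= base


class TestParams:
    def test_cutoffs_must_be_positive(self):
        with pytest.raises(ValueError):
            ProfilerParams(ionic_max=-1.0)

    def test_proximal_must_exceed_coordination(self):
        with pytest.raises(ValueError):
            ProfilerParams(proximal_cutoff=3.0, heme_coordination_max=4.0)
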