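"""Contact enumeration, filtering, collapsing, and centroid geometry."""

import numpy as np
import pytest
from scipy.stats import ortho_group

from contactsar.contacts import (
    ContactError,
    collapse_equivalents,
    contact_set_from_frame,
    contact_set_to_frame,
    enumerate_candidates,
    filter_contacts,
    ring_centroid_distance,
)
from contactsar.structure import AtomRecord, RingAnnotation, Topology, Trajectory, annotate_groups
from conftest import random_pocket


def brute_force_pairs(traj, topo, cutoff, stride=1):
    """Exhaustive all-pairs all-frames oracle for candidate enumeration."""
    hits = set()
    for frame in traj.coordinates[::stride]:
        for a in topo.atoms:
            if not (a.is_ligand and a.is_heavy):
                continue
            for b in topo.atoms:
                if b.is_ligand or not b.is_heavy:
                    continue
                d = np.linalg.norm(frame[a.atom_index] - frame[b.atom_index])
                if d <= cutoff:
                    hits.add((a.atom_index, b.atom_index))
    return sorted(hits, key=lambda p: (p[1], p[0]))


def _two_atom_system(distance):
    atoms = [
        AtomRecord(0, "O1", "O", "LIG", 1, "L", True),
        AtomRecord(1, "N", "N", "ALA", 2, "A", False),
    ]
    coords = np.array([[[0.0, 0.0, 0.0], [distance, 0.0, 0.0]]])
    return Topology(atoms=atoms), Trajectory(coordinates=coords)


class TestEnumerate:
    @pytest.mark.parametrize("d,included", [(3.9, True), (4.0, True), (4.1, False)])
    def test_threshold_with_tie_rule(self, d, included):
        topo, traj = _two_atom_system(d)
        pairs = enumerate_candidates(traj, topo, candidate_cutoff=4.0)
        assert ((0, 1) in pairs) is included

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        topo, traj = random_pocket(rng, int(rng.integers(10, 31)))
        stride = int(rng.integers(1, 3))
        got = enumerate_candidates(traj, topo, candidate_cutoff=4.0, stride=stride)
        assert got == brute_force_pairs(traj, topo, 4.0, stride=stride)

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(99)
        topo, traj = random_pocket(rng, 20)
        tight = set(enumerate_candidates(traj, topo, candidate_cutoff=4.0))
        loose = set(enumerate_candidates(traj, topo, candidate_cutoff=4.5))
        assert tight <= loose

    def test_hydrogens_never_appear(self):
        rng = np.random.default_rng(7)
        topo, traj = random_pocket(rng, 25)
        for li, ri in enumerate_candidates(traj, topo, candidate_cutoff=8.0):
            assert topo.atoms[li].is_heavy and topo.atoms[ri].is_heavy


class TestFilter:
    def test_element_rule(self):
        rng = np.random.default_rng(5)
        topo, traj = random_pocket(rng, 24)
        pairs = enumerate_candidates(traj, topo, candidate_cutoff=6.0)
        kept, _ = filter_contacts(pairs, topo)
        for li, ri in kept:
            assert topo.atoms[li].element in {"N", "O", "S"}
            assert topo.atoms[ri].element in {"N", "O", "S"}
        removed = set(pairs) - set(kept)
        assert all(
            topo.atoms[li].element not in {"N", "O", "S"}
            or topo.atoms[ri].element not in {"N", "O", "S"}
            for li, ri in removed
        )

    def test_ring_candidate_by_centroid(self, default_dataset):
        topo = default_dataset.topology
        traj = default_dataset.trajectories[("lig1", "rep1")]
        pairs = enumerate_candidates(traj, topo)
        _, rings = filter_contacts(pairs, topo, traj, ring_candidate_cutoff=6.0)
        labels = {(lr.residue_label, rr.residue_label) for lr, rr in rings}
        assert labels == {("LIG1", "TYR961")}
        # an impossible cutoff removes them
        _, none = filter_contacts(pairs, topo, traj, ring_candidate_cutoff=0.5)
        assert none == []


def _carboxylate_arg_topology():
    """Ligand carboxylate (O1, O2 / C1) + amide O3 facing ARG929 and GLU465."""
    atoms = [
        AtomRecord(0, "C1", "C", "LIG", 1, "L", True),
        AtomRecord(1, "O1", "O", "LIG", 1, "L", True),
        AtomRecord(2, "O2", "O", "LIG", 1, "L", True),
        AtomRecord(3, "O3", "O", "LIG", 1, "L", True),  # amide oxygen
        AtomRecord(4, "N4", "N", "LIG", 1, "L", True),  # backbone-like N
        AtomRecord(5, "NE", "N", "ARG", 929, "A", False),
        AtomRecord(6, "NH1", "N", "ARG", 929, "A", False),
        AtomRecord(7, "NH2", "N", "ARG", 929, "A", False),
        AtomRecord(8, "CZ", "C", "ARG", 929, "A", False),
        AtomRecord(9, "OE1", "O", "GLU", 465, "A", False),
    ]
    topo = Topology(atoms=atoms)
    return annotate_groups(
        topo, ligand_carboxylates=[{"oxygens": ["O1", "O2"], "carbon": "C1"}]
    )


class TestCollapse:
    def test_salt_bridge_single_contact(self):
        """Carboxylate oxygens x guanidinium nitrogens -> one C_COOH<->CZ contact."""
        topo = _carboxylate_arg_topology()
        pairs = [(1, 6), (1, 7), (2, 5)]  # O1-NH1, O1-NH2, O2-NE
        cs = collapse_equivalents(pairs, topo)
        assert len(cs) == 1
        (c,) = cs.contacts
        assert c.contact_id == "C_COOH-ARG929:CZ"
        assert c.contact_type == "salt_bridge"
        assert c.ligand_selector == 0 and c.residue_selector == 8
        assert set(cs.audit) == set(pairs)
        assert set(cs.audit.values()) == {"C_COOH-ARG929:CZ"}

    def test_guanidinium_only(self):
        """Amide O x ARG NH1/NH2 -> one O<->CZ contact."""
        topo = _carboxylate_arg_topology()
        cs = collapse_equivalents([(3, 6), (3, 7)], topo)
        (c,) = cs.contacts
        assert c.contact_id == "O3-ARG929:CZ"
        assert c.contact_type == "collapsed_guanidinium"
        assert c.residue_selector == 8

    def test_carboxylate_only(self):
        """Both carboxylate oxygens x GLU OE1 -> one C_COOH<->OE1 contact."""
        topo = _carboxylate_arg_topology()
        cs = collapse_equivalents([(1, 9), (2, 9)], topo)
        (c,) = cs.contacts
        assert c.contact_id == "C_COOH-GLU465:OE1"
        assert c.contact_type == "collapsed_carboxylate"
        assert c.ligand_selector == 0 and c.residue_selector == 9

    def test_untouched_pair_stays_atomic(self):
        topo = _carboxylate_arg_topology()
        cs = collapse_equivalents([(4, 9)], topo)
        (c,) = cs.contacts
        assert c.contact_type == "hbond"
        assert c.contact_id == "N4-GLU465:OE1"

    def test_never_increases_count_and_audit_is_total(self):
        topo = _carboxylate_arg_topology()
        pairs = [(1, 6), (1, 7), (2, 5), (3, 6), (3, 7), (4, 9), (1, 9), (2, 9)]
        cs = collapse_equivalents(pairs, topo)
        assert len(cs) <= len(pairs)
        assert set(cs.audit) == set(pairs)
        assert set(cs.audit.values()) == {c.contact_id for c in cs}

    def test_missing_guanidinium_annotation_is_error(self):
        topo = Topology(
            atoms=[
                AtomRecord(0, "O1", "O", "LIG", 1, "L", True),
                AtomRecord(1, "NH1", "N", "ARG", 929, "A", False),
            ]
        )  # no annotation pass
        with pytest.raises(ContactError, match="NH1.*ARG929"):
            collapse_equivalents([(0, 1)], topo)

    def test_serialization_round_trip_and_determinism(self):
        topo = _carboxylate_arg_topology()
        pairs = [(1, 6), (2, 5), (3, 7), (4, 9)]
        cs1 = collapse_equivalents(pairs, topo)
        cs2 = collapse_equivalents(list(pairs), topo)
        csv1 = contact_set_to_frame(cs1).to_csv(index=False)
        csv2 = contact_set_to_frame(cs2).to_csv(index=False)
        assert csv1 == csv2
        back = contact_set_from_frame(contact_set_to_frame(cs1), topo)
        assert [c.contact_id for c in back] == [c.contact_id for c in cs1]
        assert [c.ligand_selector for c in back] == [c.ligand_selector for c in cs1]


class TestRingCentroid:
    def test_identical_rings_zero(self):
        coords = np.random.default_rng(0).normal(size=(6, 3))
        assert ring_centroid_distance(coords, range(6), range(6)) == 0.0

    def test_rigid_translation(self):
        rng = np.random.default_rng(1)
        ring = rng.normal(size=(6, 3))
        coords = np.vstack([ring, ring + [0.0, 0.0, 5.0]])
        assert ring_centroid_distance(coords, range(6), range(6, 12)) == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_mean_of_vertices(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(12, 3))
        expected = np.linalg.norm(coords[:6].mean(axis=0) - coords[6:].mean(axis=0))
        assert ring_centroid_distance(coords, range(6), range(6, 12)) == pytest.approx(expected)

    def test_empty_ring_rejected(self):
        with pytest.raises(ContactError):
            ring_centroid_distance(np.zeros((3, 3)), [], [0])


class TestRigidMotionInvariance:
    @pytest.mark.parametrize("seed", range(5))
    def test_enumeration_invariant_under_rotation_translation(self, seed):
        rng = np.random.default_rng(seed)
        topo, traj = random_pocket(rng, 18)
        R = ortho_group.rvs(3, random_state=seed)
        t = rng.uniform(-30, 30, size=3)
        moved = Trajectory(coordinates=traj.coordinates @ R.T + t)
        assert enumerate_candidates(traj, topo, 4.0) == enumerate_candidates(moved, topo, 4.0)
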