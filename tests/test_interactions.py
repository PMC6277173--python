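"""Geometric H-bond / stacking detection and occurrence statistics."""

import numpy as np
import pytest

from cdrloop import (
    Atom,
    AtomId,
    Ensemble,
    Frame,
    HBondCriterion,
    HBondTriplet,
    MissingHydrogensError,
    StackingCriterion,
    detect_hbond,
    detect_stacking,
    enumerate_triplets,
    hbond_occurrence,
    make_hbond_fixture,
    make_interaction_ensemble,
    make_ring_pair_fixture,
    resolve_selection,
    stacking_occurrence,
)
from oracles import naive_hbond, naive_stacking, random_rigid_motion


@pytest.mark.parametrize(
    "d_ha, angle, expected",
    [
        (0.20, 180.0, True),
        (0.25, 180.0, False),  # distance boundary: strict <
        (0.20, 135.0, False),  # angle boundary: strict >
        (0.24, 136.0, True),
        (0.30, 180.0, False),
    ],
)
def test_hbond_criterion_boundaries_are_strict(d_ha, angle, expected):
    topology, frame, triplet = make_hbond_fixture(d_ha, angle)
    assert detect_hbond(frame, topology, triplet) is expected


@pytest.mark.parametrize(
    "distance, tilt, expected",
    [
        (0.35, 0.0, True),
        (0.50, 30.0, True),  # both boundaries inclusive
        (0.51, 0.0, False),
        (0.35, 31.0, False),
        (0.80, 0.0, False),
    ],
)
def test_stacking_criterion_boundaries_are_inclusive(distance, tilt, expected):
    topology, frame, group_a, group_b = make_ring_pair_fixture(distance, tilt)
    assert detect_stacking(frame, topology, group_a, group_b) is expected


def test_missing_hydrogen_raises_explicit_error():
    topology, frame, triplet = make_hbond_fixture(0.2, 180.0)
    stripped = [a for a in topology if a.element != "H"]
    frame_stripped = Frame(frame.coordinates[[0, 2]])
    with pytest.raises(MissingHydrogensError):
        detect_hbond(frame_stripped, stripped, triplet)


def test_detections_match_naive_oracle_on_random_frames():
    rng = np.random.default_rng(42)
    topology, _, triplet = make_hbond_fixture(0.2, 180.0)
    ring_top, _, group_a, group_b = make_ring_pair_fixture(0.35, 0.0)
    crit_h = HBondCriterion()
    crit_s = StackingCriterion()
    idx_a = np.arange(0, 6)
    idx_b = np.arange(6, 12)
    agree_h = agree_s = 0
    for _ in range(50):
        triad = rng.uniform(-0.3, 0.3, size=(3, 3))
        frame = Frame(triad)
        got = detect_hbond(frame, topology, triplet, crit_h)
        want = naive_hbond(triad, 0, 1, 2, crit_h.max_ha_distance,
                           crit_h.min_dha_angle)
        assert got == want
        agree_h += 1
        rings = np.concatenate([
            0.14 * _unit_ring(rng), 0.14 * _unit_ring(rng) + rng.uniform(-0.6, 0.6, 3)
        ])
        frame_s = Frame(rings)
        got_s = detect_stacking(frame_s, ring_top, group_a, group_b, crit_s)
        want_s = naive_stacking(rings, idx_a, idx_b, crit_s.max_centroid_distance,
                                crit_s.max_plane_angle)
        assert got_s == want_s
        agree_s += 1
    assert agree_h == agree_s == 50


def _unit_ring(rng):
    angles = np.radians(np.arange(0, 360, 60))
    ring = np.column_stack([np.cos(angles), np.sin(angles), np.zeros(6)])
    rot, _ = random_rigid_motion(rng)
    return ring @ rot.T


class TestOccurrence:
    def test_generator_controlled_hbond_fraction(self):
        ensemble, triplet, _, truth = make_interaction_ensemble(
            hbond_fraction=0.4, n_frames=100, seed=3
        )
        table = hbond_occurrence([ensemble], [triplet])
        assert table.loc[0, "fraction"] == pytest.approx(0.40)
        assert table.loc[0, "n_hits"] == 40
        assert truth.interaction_flags["synthetic:hbond"].sum() == 40

    def test_generator_controlled_stacking_fraction(self):
        ensemble, _, pair, _ = make_interaction_ensemble(
            stacking_fraction=0.2, n_frames=100, seed=3
        )
        table = stacking_occurrence([ensemble], [pair])
        assert table.loc[0, "fraction"] == pytest.approx(0.20)
        assert table.loc[0, "percent"] == pytest.approx(20.0)

    def test_zero_distance_criterion_gives_zero_occurrence(self):
        ensemble, triplet, _, _ = make_interaction_ensemble(n_frames=20, seed=1)
        table = hbond_occurrence([ensemble], [triplet],
                                 HBondCriterion(max_ha_distance=0.0))
        assert (table["fraction"] == 0.0).all()

    def test_single_satisfied_frame_gives_one(self):
        topology, frame, triplet = make_hbond_fixture(0.2, 180.0)
        ens = Ensemble(label="one", topology=topology, frames=[frame])
        table = hbond_occurrence([ens], [triplet])
        assert table.loc[0, "fraction"] == 1.0

    def test_never_stacked_pair_gives_zero(self):
        topology, frame, group_a, group_b = make_ring_pair_fixture(0.8, 0.0)
        ens = Ensemble(label="far", topology=topology, frames=[frame] * 5)
        table = stacking_occurrence([ens], [(group_a, group_b)])
        assert table.loc[0, "fraction"] == 0.0
        assert table.loc[0, "status"] == "ok"

    def test_mutated_residue_reported_na_not_zero(self):
        ensemble, triplet, pair, _ = make_interaction_ensemble(n_frames=10, seed=5)
        # a "Y27A-like" variant: drop the acceptor's residue entirely
        keep = [i for i, a in enumerate(ensemble.topology)
                if a.residue_number != 31]
        mutant = Ensemble(
            label="mutant",
            topology=[ensemble.topology[i] for i in keep],
            frames=[Frame(f.coordinates[keep], model_index=f.model_index)
                    for f in ensemble.frames],
        )
        table = hbond_occurrence([ensemble, mutant], [triplet])
        by_label = table.set_index("ensemble")
        assert by_label.loc["synthetic", "status"] == "ok"
        assert by_label.loc["mutant", "status"] == "na"
        assert np.isnan(by_label.loc["mutant", "fraction"])

    def test_occurrence_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(8)
        ensemble, triplet, pair, _ = make_interaction_ensemble(
            n_frames=40, seed=7, rigid_jitter=False
        )
        moved_frames = []
        for frame in ensemble.frames:
            rot, trans = random_rigid_motion(rng)
            moved_frames.append(Frame(frame.coordinates @ rot.T + trans,
                                      model_index=frame.model_index))
        moved = Ensemble(label=ensemble.label, topology=ensemble.topology,
                         frames=moved_frames)
        base_h = hbond_occurrence([ensemble], [triplet]).loc[0, "fraction"]
        base_s = stacking_occurrence([ensemble], [pair]).loc[0, "fraction"]
        assert hbond_occurrence([moved], [triplet]).loc[0, "fraction"] == base_h
        assert stacking_occurrence([moved], [pair]).loc[0, "fraction"] == base_s

    def test_tightening_criterion_never_increases_occurrence(self):
        ensemble, triplet, pair, _ = make_interaction_ensemble(
            hbond_fraction=0.5, stacking_fraction=0.5, n_frames=60, seed=9
        )
        loose_h = hbond_occurrence([ensemble], [triplet],
                                   HBondCriterion(0.30, 120.0)).loc[0, "fraction"]
        tight_h = hbond_occurrence([ensemble], [triplet],
                                   HBondCriterion(0.22, 150.0)).loc[0, "fraction"]
        assert tight_h <= loose_h
        loose_s = stacking_occurrence([ensemble], [pair],
                                      StackingCriterion(0.6, 45.0)).loc[0, "fraction"]
        tight_s = stacking_occurrence([ensemble], [pair],
                                      StackingCriterion(0.4, 15.0)).loc[0, "fraction"]
        assert tight_s <= loose_s


class TestEnumerateTriplets:
    def _arg_topology(self, with_hydrogens=True):
        atoms = [
            Atom("H", 94, "", "ARG", "N", "N"),
            Atom("H", 94, "", "ARG", "CA", "C"),
            Atom("H", 94, "", "ARG", "C", "C"),
            Atom("H", 94, "", "ARG", "O", "O"),
            Atom("H", 94, "", "ARG", "NE", "N"),
            Atom("H", 94, "", "ARG", "NH1", "N"),
            Atom("H", 94, "", "ARG", "NH2", "N"),
            Atom("H", 31, "", "ASP", "OD1", "O"),
            Atom("H", 31, "", "ASP", "OD2", "O"),
        ]
        if with_hydrogens:
            atoms += [
                Atom("H", 94, "", "ARG", "HE", "H"),
                Atom("H", 94, "", "ARG", "HH11", "H"),
                Atom("H", 94, "", "ARG", "HH12", "H"),
                Atom("H", 94, "", "ARG", "HH21", "H"),
                Atom("H", 94, "", "ARG", "H", "H"),
            ]
        return atoms

    def test_arginine_sidechain_donors_enumerated(self):
        top = self._arg_topology()
        focus = resolve_selection("resi 94", top)
        triplets = enumerate_triplets(top, focus)
        donor_h = {(t.donor.atom_name, t.hydrogen.atom_name) for t in triplets}
        assert ("NE", "HE") in donor_h
        assert ("NH1", "HH11") in donor_h
        assert ("NH1", "HH12") in donor_h
        assert ("NH2", "HH21") in donor_h
        assert ("N", "H") in donor_h
        # NH2 only carries HH21 here, so no HH22 triplet may appear
        assert ("NH2", "HH22") not in donor_h
        acceptors = {t.acceptor.atom_name for t in triplets}
        assert acceptors == {"OD1", "OD2"}

    def test_alanine_focus_yields_backbone_only_donors(self):
        top = [
            Atom("H", 95, "", "ALA", "N", "N"),
            Atom("H", 95, "", "ALA", "H", "H"),
            Atom("H", 95, "", "ALA", "CA", "C"),
            Atom("H", 95, "", "ALA", "CB", "C"),
            Atom("H", 95, "", "ALA", "O", "O"),
            Atom("H", 31, "", "ASP", "OD1", "O"),
        ]
        focus = resolve_selection("resi 95", top)
        triplets = enumerate_triplets(top, focus)
        assert {t.donor.atom_name for t in triplets} == {"N"}

    def test_topology_without_hydrogens_warns_and_returns_empty(self):
        top = self._arg_topology(with_hydrogens=False)
        focus = resolve_selection("resi 94", top)
        with pytest.warns(UserWarning, match="no hydrogens"):
            assert enumerate_triplets(top, focus) == []


def test_criterion_validation():
    with pytest.raises(ValueError):
        HBondCriterion(min_dha_angle=190.0)
    with pytest.raises(ValueError):
        StackingCriterion(max_plane_angle=95.0)
    with pytest.raises(ValueError):
        HBondTriplet(AtomId("H", 94, "", "NE"), AtomId("H", 94, "", "NE"),
                     AtomId("H", 31, "", "OD1"))
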