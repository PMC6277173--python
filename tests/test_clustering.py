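"""RMSD matrix construction and greedy neighbour-count clustering."""

import numpy as np
import pytest

from cdrloop import (
    Ensemble,
    Frame,
    FrameKey,
    RmsdMatrix,
    TemplateMixtureSpec,
    TopologyError,
    build_rmsd_matrix,
    export_cms,
    filter_clusters,
    greedy_neighbor_cluster,
    occupancy_report,
    occupancy_tidy,
    read_multimodel,
    sample_mixture_ensembles,
)
from oracles import brute_force_greedy_cluster, random_rigid_motion


def _matrix_from(values, labels=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    labels = labels if labels is not None else ["e"] * n
    keys = []
    counts = {}
    for label in labels:
        keys.append(FrameKey(label, counts.get(label, 0)))
        counts[label] = counts.get(label, 0) + 1
    return RmsdMatrix(keys=keys, values=values, fit_expression="fit",
                      rmsd_expression="rmsd", ensemble_frame_counts=counts)


class TestBuildRmsdMatrix:
    def test_identical_frames_give_zero_matrix(self, loop_system):
        frames = [Frame(loop_system.base_frame.coordinates.copy(), model_index=i)
                  for i in range(3)]
        ens = Ensemble(label="z", topology=loop_system.topology, frames=frames)
        matrix = build_rmsd_matrix([ens], loop_system.fit_expression,
                                   loop_system.loop_expression)
        np.testing.assert_allclose(matrix.values, 0.0, atol=1e-9)

    def test_rigidly_moved_frame_at_zero_distance(self, loop_system, rng):
        coords = loop_system.base_frame.coordinates
        rot, trans = random_rigid_motion(rng)
        frames = [Frame(coords.copy(), model_index=0),
                  Frame(coords @ rot.T + trans, model_index=1)]
        ens = Ensemble(label="r", topology=loop_system.topology, frames=frames)
        matrix = build_rmsd_matrix([ens], loop_system.fit_expression,
                                   loop_system.loop_expression)
        assert matrix.values[0, 1] < 1e-10

    def test_uniform_loop_offset_measured_exactly(self, loop_system):
        coords = loop_system.base_frame.coordinates
        shifted = coords.copy()
        shifted[loop_system.loop_indices] += np.array([0.0, 0.3, 0.0])
        ens = Ensemble(label="u", topology=loop_system.topology,
                       frames=[Frame(coords), Frame(shifted, model_index=1)])
        matrix = build_rmsd_matrix([ens], loop_system.fit_expression,
                                   loop_system.loop_expression)
        assert matrix.values[0, 1] == pytest.approx(0.3, abs=1e-9)

    def test_cross_ensemble_selection_mismatch_names_atom(self, loop_system):
        other_topology = list(loop_system.topology)
        # rename one loop atom on the second ensemble
        target = loop_system.loop_indices[0]
        atom = other_topology[target]
        other_topology[target] = type(atom)(
            atom.chain_id, atom.residue_number, atom.insertion_code,
            "GLY", atom.atom_name, atom.element,
        )
        ens_a = Ensemble(label="a", topology=loop_system.topology,
                         frames=[loop_system.base_frame])
        ens_b = Ensemble(label="b", topology=other_topology,
                         frames=[Frame(loop_system.base_frame.coordinates.copy())])
        with pytest.raises(TopologyError, match="selected atom"):
            build_rmsd_matrix([ens_a, ens_b], loop_system.fit_expression,
                              loop_system.loop_expression)

    def test_stride_keeps_original_frame_indices(self, loop_system):
        frames = [Frame(loop_system.base_frame.coordinates + 0.001 * i,
                        model_index=i) for i in range(6)]
        ens = Ensemble(label="s", topology=loop_system.topology, frames=frames)
        matrix = build_rmsd_matrix([ens], loop_system.fit_expression,
                                   loop_system.loop_expression, stride=2)
        assert [k.frame_index for k in matrix.keys] == [0, 2, 4]


class TestGreedyClustering:
    def test_handcrafted_three_group_matrix(self):
        big = 1.0
        values = np.full((6, 6), big)
        np.fill_diagonal(values, 0.0)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            values[i, j] = values[j, i] = 0.1
        values[3, 4] = values[4, 3] = 0.15
        values[5, :5] = values[:5, 5] = 2.0
        clusters = greedy_neighbor_cluster(_matrix_from(values), cutoff=0.2)
        members = [sorted(k.frame_index for k in c.members) for c in clusters]
        assert members == [[0, 1, 2], [3, 4], [5]]
        assert [c.cms.frame_index for c in clusters] == [0, 3, 5]

    def test_tiny_cutoff_gives_singletons(self, rng):
        values = np.abs(rng.normal(0.5, 0.1, (5, 5)))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 0.0)
        clusters = greedy_neighbor_cluster(_matrix_from(values), cutoff=1e-12)
        assert len(clusters) == 5
        assert all(c.size == 1 for c in clusters)

    def test_huge_cutoff_gives_single_cluster(self, rng):
        values = np.abs(rng.normal(0.5, 0.1, (7, 7)))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 0.0)
        clusters = greedy_neighbor_cluster(_matrix_from(values), cutoff=10.0)
        assert len(clusters) == 1
        assert clusters[0].cms.frame_index == 0  # tie broken by lowest index
        assert clusters[0].overall_fraction == 1.0

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(314)
        for trial in range(200):
            n = int(rng.integers(2, 13))
            raw = np.abs(rng.normal(0.25, 0.12, (n, n)))
            values = (raw + raw.T) / 2
            np.fill_diagonal(values, 0.0)
            cutoff = float(rng.uniform(0.05, 0.5))
            clusters = greedy_neighbor_cluster(_matrix_from(values), cutoff)
            oracle = brute_force_greedy_cluster(values, cutoff)
            got = [(c.cms.frame_index,
                    sorted(k.frame_index for k in c.members)) for c in clusters]
            assert got == oracle, f"trial {trial} diverged"
            # partition + ordering invariants
            all_members = sorted(i for _, m in got for i in m)
            assert all_members == list(range(n))
            sizes = [len(m) for _, m in got]
            assert sizes == sorted(sizes, reverse=True)

    def test_increasing_cutoff_never_increases_cluster_count(self, rng):
        raw = np.abs(rng.normal(0.3, 0.15, (15, 15)))
        values = (raw + raw.T) / 2
        np.fill_diagonal(values, 0.0)
        matrix = _matrix_from(values)
        counts = [len(greedy_neighbor_cluster(matrix, c))
                  for c in (0.05, 0.15, 0.3, 0.5, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_asymmetric_matrix_rejected(self):
        values = np.array([[0.0, 0.1], [0.3, 0.0]])
        with pytest.raises(ValueError):
            _matrix_from(values)


class TestFilterAndReport:
    def _clusters(self, fractions, labels=("e",)):
        values = np.zeros((0, 0))
        clusters = []
        total = 100
        from cdrloop import Cluster

        for i, frac in enumerate(fractions, start=1):
            members = [FrameKey(labels[0], j) for j in range(int(frac * total))]
            clusters.append(Cluster(
                cluster_id=i, cms=members[0] if members else FrameKey(labels[0], 0),
                members=members, overall_fraction=frac,
                per_ensemble_fraction={label: frac for label in labels},
            ))
        return clusters

    def test_threshold_keeps_all_when_above(self):
        clusters = self._clusters([0.5, 0.3, 0.15, 0.05])
        assert len(filter_clusters(clusters, 0.02)) == 4

    def test_exactly_two_percent_kept_inclusively(self):
        clusters = self._clusters([0.98, 0.02])
        kept = filter_clusters(clusters, 0.02)
        assert [c.cluster_id for c in kept] == [1, 2]
        strict = filter_clusters(clusters, 0.02, inclusive=False)
        assert [c.cluster_id for c in strict] == [1]

    def test_threshold_one_keeps_only_a_total_cluster(self):
        assert filter_clusters(self._clusters([0.6, 0.4]), 1.0) == []
        assert len(filter_clusters(self._clusters([1.0]), 1.0)) == 1

    def test_occupancy_rows_sum_to_one(self, loop_system, templates):
        spec = TemplateMixtureSpec(
            topology=loop_system.topology, templates=templates,
            loop_indices=loop_system.loop_indices,
            mixture_weights={"A": np.array([0.7, 0.3, 0.0]),
                             "B": np.array([0.2, 0.8, 0.0])},
            noise_sigma=0.02, n_frames=60, seed=21,
        )
        ensembles, _ = sample_mixture_ensembles(spec)
        matrix = build_rmsd_matrix(ensembles, loop_system.fit_expression,
                                   loop_system.loop_expression)
        clusters = greedy_neighbor_cluster(matrix)
        kept = filter_clusters(clusters, 0.02)
        report = occupancy_report(kept)
        np.testing.assert_allclose(report.sum(axis=1), 1.0, atol=1e-12)
        tidy = occupancy_tidy(kept)
        assert set(tidy.columns) == {"ensemble", "cluster_id", "n_frames", "fraction"}

    def test_ensemble_absent_from_cluster_reports_zero(self, loop_system, templates):
        spec = TemplateMixtureSpec(
            topology=loop_system.topology, templates=templates[:2],
            loop_indices=loop_system.loop_indices,
            mixture_weights={"only1": np.array([1.0, 0.0]),
                             "only2": np.array([0.0, 1.0])},
            noise_sigma=0.01, n_frames=20, seed=4,
        )
        ensembles, _ = sample_mixture_ensembles(spec)
        matrix = build_rmsd_matrix(ensembles, loop_system.fit_expression,
                                   loop_system.loop_expression)
        kept = filter_clusters(greedy_neighbor_cluster(matrix), 0.02)
        report = occupancy_report(kept)
        assert len(kept) == 2
        assert (report.drop(columns="other") == 0.0).sum().sum() == 2


class TestExportCms:
    def test_cms_files_round_trip(self, tmp_path, loop_system, templates):
        spec = TemplateMixtureSpec(
            topology=loop_system.topology, templates=templates,
            loop_indices=loop_system.loop_indices,
            mixture_weights={"A": np.array([0.4, 0.3, 0.3])},
            noise_sigma=0.02, n_frames=30, seed=13,
        )
        ensembles, _ = sample_mixture_ensembles(spec)
        matrix = build_rmsd_matrix(ensembles, loop_system.fit_expression,
                                   loop_system.loop_expression)
        kept = filter_clusters(greedy_neighbor_cluster(matrix), 0.02)
        paths = export_cms(kept, ensembles, tmp_path)
        assert len(paths) == len(kept) == 3
        for cluster, path in zip(kept, paths):
            again = read_multimodel(path)
            assert again.n_frames == 1
            source = ensembles[0].frames[cluster.cms.frame_index]
            np.testing.assert_allclose(again.frames[0].coordinates,
                                       source.coordinates, atol=1e-4)

    def test_empty_cluster_list_warns(self, tmp_path, loop_system):
        ens = Ensemble(label="x", topology=loop_system.topology,
                       frames=[loop_system.base_frame])
        with pytest.warns(UserWarning, match="no clusters"):
            assert export_cms([], [ens], tmp_path) == []
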