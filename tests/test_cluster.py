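import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from pocketsig.cluster import (
    ConformationClusterer,
    assign_external_frames,
    compute_medoids,
    conformation_fractions,
    fit_conformation_model,
    hierarchical_cluster,
    similarity_from_rmsd,
    spectral_conformations,
)
from pocketsig.distance import DistanceWeights, component_matrices, combine_components
from pocketsig.featurize import FeatureLayout, FeatureTable
from pocketsig.synthetic import sample_ensembles

from conftest import REFERENCE_W


def all_partitions_into(n_items: int, n_blocks: int):
    """Every assignment of n items to exactly n_blocks unlabeled blocks."""
    for labels in itertools.product(range(n_blocks), repeat=n_items):
        # canonical form: block ids appear in order of first occurrence
        seen = {}
        canon = []
        for lab in labels:
            seen.setdefault(lab, len(seen))
            canon.append(seen[lab])
        if tuple(canon) != labels or len(seen) != n_blocks:
            continue
        yield np.array(labels)


def planted_points(rng, centers, n_per, noise):
    pts, labels = [], []
    for g, c in enumerate(centers, start=1):
        pts.append(c + rng.normal(0, noise, (n_per, len(c))))
        labels += [g] * n_per
    X = np.vstack(pts)
    D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    return D, np.array(labels)


class TestHierarchical:
    def test_every_frame_own_cluster_at_h_equals_n(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(7, 2))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        hc = hierarchical_cluster(D, h=7)
        assert sorted(hc.labels) == list(range(1, 8))

    def test_separated_blocks_recovered(self):
        D = np.ones((6, 6))
        D[:3, :3] = 0.0
        D[3:, 3:] = 0.0
        hc = hierarchical_cluster(D, h=2)
        assert len(set(hc.labels[:3])) == 1 and len(set(hc.labels[3:])) == 1
        assert hc.labels[0] != hc.labels[3]

    def test_matches_exhaustive_minimax_partition(self):
        # 12 frames from 3 planted centers: complete linkage at h=3 should
        # find the same partition as brute force over all 3-partitions
        # minimizing the maximum within-cluster distance
        rng = np.random.default_rng(5)
        D, truth = planted_points(rng, [(0, 0), (10, 0), (0, 10)], 4, noise=0.5)
        hc = hierarchical_cluster(D, h=3)
        best, best_cost = None, np.inf
        for labels in all_partitions_into(12, 3):
            cost = 0.0
            for g in range(3):
                idx = np.flatnonzero(labels == g)
                if idx.size > 1:
                    cost = max(cost, D[np.ix_(idx, idx)].max())
            if cost < best_cost:
                best, best_cost = labels, cost
        assert adjusted_rand_score(hc.labels, best) == 1.0

    def test_h_out_of_range_rejected(self):
        D = np.zeros((4, 4))
        with pytest.raises(ValueError):
            hierarchical_cluster(D, h=1)
        with pytest.raises(ValueError):
            hierarchical_cluster(D, h=5)


class TestMedoids:
    def test_singleton_cluster(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        med = compute_medoids(D, np.array([1, 2]))
        assert list(med) == [0, 1]

    def test_middle_of_path_is_medoid(self):
        # collinear points at distances {0, 1, 2}: the middle one wins
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
        assert compute_medoids(D, np.array([1, 1, 1]))[0] == 1

    def test_matches_brute_force_argmin(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 3))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        med = compute_medoids(D, np.ones(20, dtype=int))[0]
        sums = [D[i].sum() for i in range(20)]
        assert med == int(np.argmin(sums))


class TestSimilarity:
    def test_kernel_at_zero_is_one(self):
        S = similarity_from_rmsd(np.zeros((3, 3)), delta=2.0)
        assert np.allclose(S, 1.0)

    def test_gaussian_value(self):
        # delta=2 (the selected bandwidth), D=2 -> exp(-0.5)
        D = np.array([[0.0, 2.0], [2.0, 0.0]])
        S = similarity_from_rmsd(D, delta=2.0)
        assert S[0, 1] == pytest.approx(np.exp(-0.5), abs=1e-9)

    def test_monotone_decreasing_in_distance(self):
        D = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 2.0], [3.0, 2.0, 0.0]])
        S = similarity_from_rmsd(D, delta=1.5)
        assert S[0, 1] > S[1, 2] > S[0, 2]

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            similarity_from_rmsd(np.zeros((2, 2)), delta=0.0)


class TestSpectral:
    def test_perfect_blocks_recovered(self):
        S = np.full((9, 9), 1e-6)
        for g in range(3):
            S[3 * g : 3 * g + 3, 3 * g : 3 * g + 3] = 1.0
        labels = spectral_conformations(S, c=3)
        assert adjusted_rand_score(labels, [1, 1, 1, 2, 2, 2, 3, 3, 3]) == 1.0

    def test_c_equals_h_minus_one_merges_one_pair(self):
        rng = np.random.default_rng(3)
        D = np.abs(rng.normal(2, 0.5, (6, 6)))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        D[0, 1] = D[1, 0] = 0.01  # one clearly closest pair
        labels = spectral_conformations(similarity_from_rmsd(D, 1.0), c=5)
        counts = np.bincount(labels)[1:]
        assert sorted(counts) == [1, 1, 1, 1, 2]

    def test_matches_exhaustive_similarity_partition(self):
        # 8 medoids from 3 planted groups: compare against brute force over
        # all 3-partitions maximizing the within-group similarity sum
        rng = np.random.default_rng(7)
        truth = np.array([0, 0, 0, 1, 1, 1, 2, 2])
        D = np.abs(truth[:, None] - truth[None]) * 3.0 + rng.uniform(0, 0.3, (8, 8))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        S = similarity_from_rmsd(D, delta=1.0)
        labels = spectral_conformations(S, c=3)
        best, best_score = None, -np.inf
        for part in all_partitions_into(8, 3):
            score = sum(
                S[np.ix_(np.flatnonzero(part == g), np.flatnonzero(part == g))].sum()
                for g in range(3)
            )
            if score > best_score:
                best, best_score = part, score
        assert adjusted_rand_score(labels, best) == 1.0

    def test_c_out_of_range_rejected(self):
        S = np.eye(4)
        with pytest.raises(ValueError):
            spectral_conformations(S, c=4)


class TestConformationModel:
    def test_h_equals_c_is_bijection(self, separable_data):
        table = separable_data["table"].for_ligands(["L1"])
        model = fit_conformation_model(table, h=4, delta=2.0, c=3, weights=REFERENCE_W)
        assert model.cluster_to_conf.size == 4

    def test_planted_conformations_recovered(self, separable_data, fitted_model):
        ari = adjusted_rand_score(separable_data["labels"], fitted_model.frame_labels)
        assert ari == 1.0

    def test_frame_labels_compose_cluster_mapping(self, fitted_model):
        cl = fitted_model.clusterer
        assert np.array_equal(
            cl.labels_, cl.cluster_to_conf_[cl.hierarchical_.labels - 1]
        )

    def test_deterministic_refit(self, separable_data, fitted_model):
        refit = fit_conformation_model(
            separable_data["table"], h=12, delta=2.0, c=3, weights=REFERENCE_W
        )
        assert np.array_equal(refit.frame_labels, fitted_model.frame_labels)

    def test_permutation_equivariance(self, separable_data):
        table = separable_data["table"]
        rng = np.random.default_rng(0)
        idx = rng.permutation(table.n_frames)
        permuted = FeatureTable(table.values[idx], table.layout, table.ligand_ids[idx])
        m0 = fit_conformation_model(table, h=12, delta=2.0, c=3, weights=REFERENCE_W)
        m1 = fit_conformation_model(permuted, h=12, delta=2.0, c=3, weights=REFERENCE_W)
        assert adjusted_rand_score(m0.frame_labels[idx], m1.frame_labels) == 1.0

    def test_sklearn_param_interface(self):
        cl = ConformationClusterer(h=10, c=4)
        assert cl.get_params()["h"] == 10
        cl.set_params(h=12, delta=1.5)
        assert cl.h == 12 and cl.delta == 1.5
        with pytest.raises(ValueError):
            cl.set_params(bogus=1)


class TestFractions:
    def test_counting(self):
        fr = conformation_fractions(np.array([1, 1, 2, 3]), ["A"] * 4, c=3)
        assert list(fr.loc["A"]) == [0.5, 0.25, 0.25]

    def test_unit_vector_when_single_conformation(self):
        fr = conformation_fractions(np.array([2, 2, 2]), ["A"] * 3, c=3)
        assert list(fr.loc["A"]) == [0.0, 1.0, 0.0]

    def test_rows_sum_to_one_on_random_labelings(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(1, 5, 60)
        lids = rng.choice(["A", "B", "C"], 60)
        fr = conformation_fractions(labels, lids, c=4)
        assert np.allclose(fr.sum(axis=1), 1.0, atol=1e-12)

    def test_pooling_replicates(self):
        # replicate runs of one ligand pool before normalization
        labels = np.array([1, 1, 2, 2])
        fr = conformation_fractions(labels, ["A", "A", "A", "A"], c=2)
        assert list(fr.loc["A"]) == [0.5, 0.5]

    def test_zero_frame_ligand_rejected(self):
        with pytest.raises(ValueError, match="zero frames"):
            conformation_fractions(np.array([1]), ["A"], c=2, ligand_order=["A", "B"])


class TestExternalAssignment:
    def test_frame_identical_to_medoid(self, separable_data, fitted_model):
        cl = fitted_model.clusterer
        table = separable_data["table"]
        medoid_frame = cl.hierarchical_.medoid_frames[0]
        one = FeatureTable(table.values[[medoid_frame]], table.layout, ["new"])
        assert cl.predict(one)[0] == cl.labels_[medoid_frame]

    def test_tie_goes_to_lowest_conformation(self):
        # two medoids in different conformations, a frame exactly between them
        layout = FeatureLayout(1, 1, 1)
        cl = ConformationClusterer(h=2, delta=1.0, c=2, weights=(0.25, 0.25, 0.5))
        cl.layout_ = layout
        cl.cluster_to_conf_ = np.array([2, 1])
        med = np.array([[0.0, 1.0, 1.0], [0.0, 3.0, 3.0]])
        cl.medoid_features_ = med
        cl.medoid_theta_, cl.medoid_ca_, cl.medoid_hb_ = med[:, :1], med[:, 1:2], med[:, 2:]
        cl.labels_ = np.array([2, 1])
        frame = FeatureTable(np.array([[0.0, 2.0, 2.0]]), layout, ["x"])
        assert cl.predict(frame)[0] == 1

    def test_held_out_frames_recover_ground_truth(self, separable_data):
        table = separable_data["table"]
        labels = separable_data["labels"]
        train = table.for_ligands(["L1", "L2", "L3", "L4", "L5"])
        model = fit_conformation_model(train, h=10, delta=2.0, c=3, weights=REFERENCE_W)
        held = table.for_ligands(["L6"])
        held_truth = labels[np.asarray(table.ligand_ids) == "L6"]
        assigned = assign_external_frames(model, held)
        # map model conformations onto planted ids via the training frames
        train_truth = labels[np.isin(np.asarray(table.ligand_ids), train.ligands)]
        mapping = {}
        for conf in range(1, 4):
            members = model.frame_labels == conf
            mapping[conf] = np.bincount(train_truth[members]).argmax()
        agreement = np.mean([mapping[a] == t for a, t in zip(assigned, held_truth)])
        assert agreement >= 0.95

    def test_weight_mismatch_rejected(self, fitted_model, separable_data):
        with pytest.raises(ValueError, match="weights"):
            assign_external_frames(
                fitted_model, separable_data["table"], weights=DistanceWeights(0.1, 0.1, 0.8)
            )


def test_precomputed_distance_matrix_matches_internal(separable_data):
    table = separable_data["table"].for_ligands(["L1", "L2"])
    d_th, d_ca, d_hb = component_matrices(table.theta, table.ca, table.hb)
    D = combine_components(d_th, d_ca, d_hb, REFERENCE_W)
    a = ConformationClusterer(h=8, delta=2.0, c=3, weights=(0.25, 0.25, 0.5)).fit(table)
    b = ConformationClusterer(h=8, delta=2.0, c=3, weights=(0.25, 0.25, 0.5)).fit(
        table, distance_matrix=D
    )
    assert np.array_equal(a.labels_, b.labels_)
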