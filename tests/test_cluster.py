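"""Embedding, clustering diagnostics and odor-composition statistics."""

import numpy as np
import pytest

from odorvs.cluster import (
    ClusterAssignment,
    ahc_cluster,
    elbow_curve,
    embed_2d,
    functional_group_profile,
    kmeans_cluster,
    odor_note_composition,
    silhouette,
)
from odorvs.labels import LabelMatrix


def _blobs(rng, centers=((0, 0), (30, 0), (0, 30)), n_per=20, dim=5):
    pts = []
    for cx, cy in centers:
        center = np.zeros(dim)
        center[0], center[1] = cx, cy
        pts.append(center + rng.normal(0, 1.0, (n_per, dim)))
    return np.vstack(pts)


class TestEmbedding:
    def test_pca_recovers_rank_two_structure(self, rng):
        basis = rng.normal(0, 1, (2, 6))
        coords = rng.normal(0, 3, (40, 2))
        x = coords @ basis
        emb = embed_2d(x, "pca")
        # rank-2 data reconstructs exactly from 2 components
        from sklearn.decomposition import PCA

        pca = PCA(2).fit(x)
        np.testing.assert_allclose(
            pca.inverse_transform(pca.transform(x)), x, atol=1e-8)
        assert emb.coordinates.shape == (40, 2)

    @pytest.mark.parametrize("method", ["pca", "tsne", "umap", "mds"])
    def test_separated_blobs_stay_separated(self, method, rng):
        x = _blobs(rng)
        emb = embed_2d(x, method, seed=0)
        truth = ClusterAssignment(
            "kmeans", 3, np.repeat([1, 2, 3], 20))
        assert silhouette(emb, truth) > 0.5

    def test_umap_deterministic_under_fixed_seed(self, rng):
        x = _blobs(rng)
        a = embed_2d(x, "umap", seed=4).coordinates
        b = embed_2d(x, "umap", seed=4).coordinates
        np.testing.assert_array_equal(a, b)

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError):
            embed_2d(rng.normal(0, 1, (10, 3)), "sammon")


class TestClustering:
    def test_k_equals_n_gives_singletons(self, rng):
        x = rng.normal(0, 1, (8, 2))
        res = kmeans_cluster(x, 8, seed=0)
        assert res.k == 8
        assert len(np.unique(res.labels)) == 8
        assert res.inertia == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("algorithm", ["kmeans", "ahc"])
    def test_two_far_pairs_recovered(self, algorithm):
        x = np.array([[0.0, 0], [0.1, 0], [50, 50], [50.1, 50]])
        res = (kmeans_cluster(x, 2, 0) if algorithm == "kmeans"
               else ahc_cluster(x, 2))
        assert res.labels[0] == res.labels[1]
        assert res.labels[2] == res.labels[3]
        assert res.labels[0] != res.labels[2]

    def test_ward_merge_heights_non_decreasing(self, rng):
        res = ahc_cluster(rng.normal(0, 1, (30, 2)), 3)
        heights = res.merge_heights
        assert (np.diff(heights) >= -1e-12).all()

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_cluster(rng.normal(0, 1, (4, 2)), 5)

    def test_labels_canonicalized_by_size(self, rng):
        x = np.vstack([rng.normal(0, 0.5, (30, 2)),
                       rng.normal(20, 0.5, (10, 2))])
        res = kmeans_cluster(x, 2, seed=0)
        assert (res.labels == 1).sum() >= (res.labels == 2).sum()


class TestElbowAndSilhouette:
    def test_inertia_non_increasing(self, rng):
        x = rng.normal(0, 1, (40, 2))
        curve = elbow_curve(x, range(1, 8))
        assert (np.diff(curve["inertia"]) <= 1e-9).all()

    def test_knee_at_three_blobs(self, rng):
        x = _blobs(rng, dim=2)
        curve = elbow_curve(x, range(1, 7)).set_index("k")["inertia"]
        drops = -np.diff(curve.values) / curve.values[:-1]
        # successive relative drops collapse once k reaches 3
        assert drops[1] > 0.8 and drops[2] < 0.5

    def test_two_tight_pairs_score_near_one(self):
        x = np.array([[0.0, 0], [0.05, 0], [80, 80], [80.05, 80]])
        res = kmeans_cluster(x, 2, 0)
        assert silhouette(x, res) > 0.9

    def test_random_points_score_near_zero(self, rng):
        x = rng.uniform(0, 1, (200, 2))
        res = kmeans_cluster(x, 2, 0)
        assert abs(silhouette(x, res)) < 0.5

    def test_single_cluster_rejected(self, rng):
        x = rng.normal(0, 1, (10, 2))
        with pytest.raises(ValueError):
            silhouette(x, kmeans_cluster(x, 1, 0))


class TestComposition:
    def test_worked_percentages(self):
        """201 of 500 note occurrences inside a 1151-molecule cluster."""
        from odorvs.experiments import composition_worked_example

        out = composition_worked_example()
        assert out["pct_on_green"] == pytest.approx(40.2, abs=1e-9)
        assert out["pct_om_green"] == pytest.approx(17.46, abs=0.01)

    def test_single_cluster_captures_everything(self, small_dataset):
        _, labels, _, _ = small_dataset
        assign = ClusterAssignment(
            "kmeans", 1, np.ones(labels.n_molecules, dtype=int))
        table = odor_note_composition(assign, labels).table
        assert (table["pct_on"] == 100.0).all()

    def test_occurrences_conserved_across_clusters(self, small_dataset, rng):
        _, labels, _, _ = small_dataset
        raw = rng.integers(1, 4, labels.n_molecules)
        assign = ClusterAssignment("kmeans", 3, raw)
        table = odor_note_composition(assign, labels).table
        sums = table.groupby("note")["occurrences_in_cluster"].sum()
        for j, note in enumerate(labels.notes):
            assert sums[note] == labels.class_counts[j]


class TestFunctionalGroups:
    SMILES = ["CCOC(C)=O", "CCOC(CC)=O", "c1ccccc1O", "Cc1ccccc1O", "CCO"]

    def test_ester_cluster_scores_full_fraction(self):
        assign = ClusterAssignment("kmeans", 2, np.array([1, 1, 2, 2, 2]))
        prof = functional_group_profile(self.SMILES, assign, min_fraction=0.05)
        assert prof.loc["fr_ester", "cluster_1"] == 100.0
        assert prof.loc["fr_ester", "cluster_2"] == 0.0

    def test_hand_enumerated_fragment_counts(self):
        assign = ClusterAssignment("kmeans", 2, np.array([1, 1, 2, 2, 2]))
        prof = functional_group_profile(self.SMILES, assign, min_fraction=0.05)
        # cluster 2 = {phenol, cresol, ethanol}: 2 of 3 are phenols,
        # all three carry a hydroxyl somewhere
        assert prof.loc["fr_phenol", "cluster_2"] == pytest.approx(200 / 3)
        assert prof.loc["fr_Al_OH", "cluster_2"] == pytest.approx(100 / 3)

    def test_low_prevalence_groups_filtered(self):
        assign = ClusterAssignment("kmeans", 1, np.ones(5, dtype=int))
        prof = functional_group_profile(self.SMILES, assign, min_fraction=0.05)
        assert (prof.to_numpy().max(axis=1) >= 5.0).all()

    def test_invalid_smiles_reported(self):
        assign = ClusterAssignment("kmeans", 1, np.ones(2, dtype=int))
        with pytest.raises(ValueError, match="xyz"):
            functional_group_profile(["CCO", "xyz"], assign)
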