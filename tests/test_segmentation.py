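import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from msiflux import msi, segmentation, synthetic


def lipid_subimage(dataset):
    norm, _ = msi.tic_normalize(dataset.image)
    return norm, msi.select_lipid_features(norm, dataset.features)


class TestClusterPixels:
    def test_noiseless_phenotypes_recovered_perfectly(self, sim_clean):
        _, lipids = lipid_subimage(sim_clean)
        cmap = segmentation.cluster_pixels(lipids, 3, seed=0)
        assert adjusted_rand_score(sim_clean.truth.pixel_labels, cmap.pixel_cluster) == 1.0

    def test_noisy_four_phenotype_ari(self):
        ds = synthetic.simulate_dataset(
            width=40, height=40, n_types=4, seed=21, noise_sd=0.05
        )
        _, lipids = lipid_subimage(ds)
        cmap = segmentation.cluster_pixels(lipids, 4, seed=0)
        assert adjusted_rand_score(ds.truth.pixel_labels, cmap.pixel_cluster) >= 0.9

    def test_deterministic_for_fixed_seed(self, sim):
        _, lipids = lipid_subimage(sim)
        a = segmentation.cluster_pixels(lipids, 3, seed=4)
        b = segmentation.cluster_pixels(lipids, 3, seed=4)
        np.testing.assert_array_equal(a.pixel_cluster, b.pixel_cluster)

    def test_pixel_permutation_changes_nothing(self, sim_clean):
        _, lipids = lipid_subimage(sim_clean)
        cmap = segmentation.cluster_pixels(lipids, 3, seed=4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(lipids.n_pixels)
        shuffled = msi.SpectralImage(
            coords=lipids.coords[perm],
            mz=lipids.mz,
            intensities=lipids.intensities[perm],
            normalized=True,
            feature_names=lipids.feature_names,
        )
        cmap_perm = segmentation.cluster_pixels(shuffled, 3, seed=4)
        np.testing.assert_array_equal(cmap_perm.pixel_cluster, cmap.pixel_cluster[perm])

    def test_partition_covers_all_pixels(self, sim):
        _, lipids = lipid_subimage(sim)
        cmap = segmentation.cluster_pixels(lipids, 3, seed=0)
        assert cmap.pixel_cluster.shape == (lipids.n_pixels,)
        assert set(np.unique(cmap.pixel_cluster)) == {0, 1, 2}

    def test_more_clusters_than_pixels_rejected(self, toy_image):
        norm, _ = msi.tic_normalize(toy_image)
        with pytest.raises(ValueError):
            segmentation.cluster_pixels(norm, 5, seed=0)


class TestAnnotateClusters:
    def make_image(self, intensities):
        n = len(intensities)
        coords = np.column_stack([np.zeros(n, dtype=int), np.arange(n)])
        return msi.SpectralImage(
            coords=coords,
            mz=np.array([100.0, 200.0]),
            intensities=np.asarray(intensities, dtype=float),
            feature_names=["marker_a", "marker_b"],
        )

    markers = {"A": ["marker_a"], "B": ["marker_b"]}

    def test_one_hot_markers_label_clusters(self):
        img = self.make_image([[10, 0], [9, 0], [0, 8], [0, 7]])
        cmap = segmentation.ClusterMap(pixel_cluster=[0, 0, 1, 1])
        out = segmentation.annotate_clusters(cmap, img, self.markers)
        assert out.annotation == {0: "A", 1: "B"}
        assert out.margins[0] > 0

    def test_swapped_markers_swap_labels(self):
        img = self.make_image([[0, 10], [0, 9], [8, 0], [7, 0]])
        cmap = segmentation.ClusterMap(pixel_cluster=[0, 0, 1, 1])
        out = segmentation.annotate_clusters(cmap, img, self.markers)
        assert out.annotation == {0: "B", 1: "A"}

    def test_all_zero_markers_leave_cluster_unlabeled(self):
        img = self.make_image([[0, 0], [0, 0], [5, 0], [4, 0]])
        cmap = segmentation.ClusterMap(pixel_cluster=[0, 0, 1, 1])
        out = segmentation.annotate_clusters(cmap, img, self.markers)
        assert 0 in out.unlabeled and out.annotation[1] == "A"

    def test_missing_marker_feature_rejected(self):
        img = self.make_image([[1, 1]])
        cmap = segmentation.ClusterMap(pixel_cluster=[0])
        with pytest.raises(ValueError, match="nope"):
            segmentation.annotate_clusters(cmap, img, {"A": ["nope"]})


class TestDifferentialFeatures:
    def make_case(self, inside, outside):
        values = np.concatenate([inside, outside])
        n = values.shape[0]
        img = msi.SpectralImage(
            coords=np.column_stack([np.zeros(n, dtype=int), np.arange(n)]),
            mz=np.array([500.0]),
            intensities=values[:, None],
            feature_names=["f"],
        )
        cmap = segmentation.ClusterMap(
            pixel_cluster=np.r_[np.zeros(len(inside), int), np.ones(len(outside), int)]
        )
        return img, cmap

    def test_tenfold_feature_gives_log2fc_of_ten(self):
        rng = np.random.default_rng(0)
        img, cmap = self.make_case(
            10.0 + rng.normal(0, 0.01, 30), 1.0 + rng.normal(0, 0.01, 30)
        )
        row = segmentation.differential_features(img, cmap, 0).iloc[0]
        assert row["log2fc"] == pytest.approx(np.log2(10), abs=0.01)
        assert row["pvalue"] < 1e-6 and row["qvalue"] <= row["pvalue"] * 1.01

    def test_identical_distributions_are_null(self):
        img, cmap = self.make_case(np.full(20, 2.0), np.full(20, 2.0))
        row = segmentation.differential_features(img, cmap, 0).iloc[0]
        assert row["log2fc"] == pytest.approx(0.0, abs=1e-9)
        assert row["pvalue"] > 0.9

    def test_zero_outside_stays_finite_via_pseudocount(self):
        img, cmap = self.make_case(np.full(5, 3.0), np.zeros(5))
        row = segmentation.differential_features(img, cmap, 0).iloc[0]
        assert np.isfinite(row["log2fc"]) and row["log2fc"] > 20

    def test_singleton_cluster_rejected(self):
        img, cmap = self.make_case(np.array([1.0]), np.full(5, 2.0))
        with pytest.raises(ValueError):
            segmentation.differential_features(img, cmap, 0)


class TestTransferLabels:
    def make_reference(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        lipids = np.repeat([[10.0, 1.0], [1.0, 10.0]], n // 2, axis=0)
        lipids = lipids + rng.normal(0, 0.05, lipids.shape)
        met = np.where(lipids[:, 0] > lipids[:, 1], 0.8, 0.2)[:, None]
        intensities = np.clip(np.column_stack([met, lipids]), 0, None)
        coords = np.column_stack([np.zeros(n, dtype=int), np.arange(n)])
        return msi.SpectralImage(
            coords=coords,
            mz=np.array([150.0, 700.0, 800.0]),
            intensities=intensities,
            feature_names=["met", "lip_a", "lip_b"],
        )

    def make_query(self, reference):
        return msi.SpectralImage(
            coords=reference.coords,
            mz=reference.mz[1:],
            intensities=reference.intensities[:, 1:],
            feature_names=reference.feature_names[1:],
        )

    def test_identity_query_recovers_reference_channels(self):
        ref = self.make_reference()
        imputed, mz, names = segmentation.transfer_labels(ref, self.make_query(ref))
        assert names == ["met"] and mz[0] == 150.0
        np.testing.assert_allclose(imputed[:, 0], ref.intensities[:, 0], atol=1e-6)

    def test_constant_metabolite_field_imputed_exactly(self):
        ref = self.make_reference()
        ref.intensities[:, 0] = 0.42
        imputed, _, _ = segmentation.transfer_labels(ref, self.make_query(ref))
        np.testing.assert_allclose(imputed[:, 0], 0.42, atol=1e-12)

    def test_never_extrapolates_beyond_reference_range(self):
        ref = self.make_reference()
        rng = np.random.default_rng(1)
        query = self.make_query(ref)
        query.intensities = query.intensities * rng.uniform(0.5, 2.0, query.intensities.shape)
        imputed, _, _ = segmentation.transfer_labels(ref, query)
        assert imputed.min() >= ref.intensities[:, 0].min() - 1e-12
        assert imputed.max() <= ref.intensities[:, 0].max() + 1e-12

    def test_two_phenotype_means_within_five_percent_of_truth(self):
        ref = self.make_reference(n=200, seed=3)
        query = self.make_query(self.make_reference(n=200, seed=4))
        imputed, _, _ = segmentation.transfer_labels(ref, query)
        high = query.intensities[:, 0] > query.intensities[:, 1]
        assert imputed[high, 0].mean() == pytest.approx(0.8, rel=0.05)
        assert imputed[~high, 0].mean() == pytest.approx(0.2, rel=0.05)

    def test_disjoint_feature_sets_rejected(self):
        ref = self.make_reference()
        query = self.make_query(ref)
        query.mz = query.mz + 1000.0
        with pytest.raises(ValueError):
            segmentation.transfer_labels(ref, query)
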