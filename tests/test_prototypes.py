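"""Supervised k-means prototype selection: Lloyd behaviour and contracts."""

import numpy as np
import pytest

from dissimspace.data import LabeledImage
from dissimspace.prototypes import (PrototypeSet, kmeans, select_prototypes,
                                    vectorize_for_clustering)


class TestVectorize:
    def test_length_and_constant_image(self):
        img = LabeledImage(np.full((32, 32), 0.6), 0)
        vec = vectorize_for_clustering(img, side=32)
        assert vec.shape == (1024,)
        np.testing.assert_allclose(vec, 0.6)

    def test_identical_images_identical_vectors(self, rng):
        px = rng.random((40, 40))
        v1 = vectorize_for_clustering(LabeledImage(px, 0), 16)
        v2 = vectorize_for_clustering(LabeledImage(px.copy(), 1), 16)
        np.testing.assert_array_equal(v1, v2)


class TestKmeans:
    def test_k_equals_n_gives_zero_objective(self, rng):
        pts = rng.random((6, 3))
        _, result = kmeans(pts, k=6, seed=0)
        assert result.objective == pytest.approx(0.0, abs=1e-12)

    def test_k_one_gives_mean(self, rng):
        pts = rng.normal(size=(40, 4))
        cents, _ = kmeans(pts, k=1, seed=0)
        np.testing.assert_allclose(cents[0], pts.mean(axis=0), atol=1e-9)

    def test_two_blob_recovery(self):
        rng = np.random.default_rng(7)
        blob_a = rng.normal([0, 0], 0.1, size=(50, 2))
        blob_b = rng.normal([10, 10], 0.1, size=(50, 2))
        cents, _ = kmeans(np.vstack([blob_a, blob_b]), k=2, seed=1)
        cents = cents[np.argsort(cents[:, 0])]
        assert np.linalg.norm(cents[0] - blob_a.mean(axis=0)) < 0.1
        assert np.linalg.norm(cents[1] - blob_b.mean(axis=0)) < 0.1

    def test_objective_trace_non_increasing(self, rng):
        pts = rng.normal(size=(120, 5))
        for seed in range(5):
            _, result = kmeans(pts, k=7, seed=seed)
            trace = np.array(result.objective_trace)
            assert np.all(np.diff(trace) <= 1e-8 * np.maximum(1.0, trace[:-1]))

    def test_matches_sklearn_objective_on_easy_data(self):
        # independent cross-check: same objective on well-separated blobs
        from sklearn.cluster import KMeans
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(c, 0.05, size=(30, 2))
                         for c in ([0, 0], [5, 0], [0, 5])])
        _, ours = kmeans(pts, k=3, seed=0)
        ref = KMeans(n_clusters=3, n_init=10, random_state=0).fit(pts)
        assert ours.objective == pytest.approx(float(ref.inertia_), rel=1e-6)

    def test_k_exceeding_distinct_points_rejected(self):
        pts = np.zeros((5, 2))
        with pytest.raises(ValueError):
            kmeans(pts, k=2, seed=0)

    def test_deterministic(self, rng):
        pts = rng.normal(size=(30, 3))
        c1, _ = kmeans(pts, k=4, seed=5)
        c2, _ = kmeans(pts, k=4, seed=5)
        np.testing.assert_array_equal(c1, c2)


class TestSelectPrototypes:
    def test_k_equals_kc_times_c(self, small_dataset):
        protos = select_prototypes(small_dataset, kc=3, seed=0, side=16)
        assert protos.k == 3 * 2
        counts = np.bincount(protos.class_tags)
        assert list(counts) == [3, 3]

    def test_kc_one_gives_class_means(self, small_dataset):
        protos = select_prototypes(small_dataset, kc=1, seed=0, side=16)
        for label in (0, 1):
            members = np.stack([vectorize_for_clustering(im, 16)
                                for im in small_dataset if im.label == label])
            np.testing.assert_allclose(protos.centroids[label],
                                       members.mean(axis=0), atol=1e-9)

    def test_prototype_count_arithmetic(self, small_dataset):
        # per-class counts multiply out to k = kc * c
        protos = select_prototypes(small_dataset, kc=5, seed=0, side=16)
        assert protos.k == 10

    def test_undersized_class_rejected_by_name(self, small_dataset):
        with pytest.raises(ValueError, match="class 0"):
            select_prototypes(small_dataset, kc=100, seed=0)

    def test_fixed_seed_identical_set(self, small_dataset):
        p1 = select_prototypes(small_dataset, kc=2, seed=4, side=16)
        p2 = select_prototypes(small_dataset, kc=2, seed=4, side=16)
        np.testing.assert_array_equal(p1.centroids, p2.centroids)

    def test_round_trip_persistence(self, tmp_path, small_dataset):
        protos = select_prototypes(small_dataset, kc=2, seed=0, side=16)
        path = str(tmp_path / "protos.csv")
        protos.save(path)
        again = PrototypeSet.load(path)
        np.testing.assert_allclose(again.centroids, protos.centroids)
        assert again.kc == 2 and again.side == 16

    def test_as_images_reshapes_centroids(self, small_dataset):
        protos = select_prototypes(small_dataset, kc=2, seed=0, side=16)
        imgs = protos.as_images(out_size=20)
        assert len(imgs) == protos.k
        assert imgs[0].pixels.shape == (20, 20)
        assert imgs[0].label == int(protos.class_tags[0])
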