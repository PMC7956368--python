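"""Supervised k-means prototype selection.

"Supervised" means k-means is run independently inside each class: with c
classes and kc centroids per class the dissimilarity space has dimension
k = kc * c.  Clustering operates on a vector-space rendering of the images
(downsampled grayscale pixels by default); each centroid is tagged with its
source class and can be reshaped back into a (synthetic) prototype image
for scoring against real samples.

The k-means itself is Lloyd's algorithm with k-means++ seeding (centroids
drawn from the data with probability proportional to squared distance from
those already chosen), squared-Euclidean assignments, convergence when the
assignment is stable or after 300 iterations, and farthest-point re-seeding
of empty clusters.  The within-cluster objective is recorded per iteration
and checked non-increasing on every run.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from dissimspace.data import LabeledImage

DEFAULT_SIDE = 32
MAX_ITER = 300
#: the prototype-count grid explored per class
KC_GRID = (15, 30, 45, 60)


@dataclass
class PrototypeSet:
    """k = kc * c centroids, tagged with their source class."""

    centroids: np.ndarray       # (k, dim)
    class_tags: np.ndarray      # (k,)
    kc: int
    side: int = DEFAULT_SIDE
    seed: int = 0
    representation: str = "original"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("non-finite centroid")
        if len(self.centroids) != len(self.class_tags):
            raise ValueError("centroid/tag length mismatch")

    @property
    def k(self) -> int:
        return len(self.centroids)

    @property
    def c(self) -> int:
        return len(np.unique(self.class_tags))

    def as_images(self, out_size: int | None = None) -> list[LabeledImage]:
        """Render each centroid back into a square (synthetic) image."""
        images = []
        for vec, tag in zip(self.centroids, self.class_tags):
            img = LabeledImage(vec.reshape(self.side, self.side), int(tag))
            if out_size is not None and out_size != self.side:
                img = img.resized(out_size)
            images.append(img)
        return images

    def save(self, csv_path: str) -> None:
        """One centroid per row; class tag in the last column; JSON sidecar."""
        arr = np.column_stack([self.centroids, self.class_tags])
        np.savetxt(csv_path, arr, delimiter=",")
        meta = {"kc": self.kc, "c": int(self.c), "side": self.side,
                "seed": self.seed, "representation": self.representation}
        with open(os.path.splitext(csv_path)[0] + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, csv_path: str) -> "PrototypeSet":
        arr = np.loadtxt(csv_path, delimiter=",", ndmin=2)
        with open(os.path.splitext(csv_path)[0] + ".json") as fh:
            meta = json.load(fh)
        return cls(arr[:, :-1], arr[:, -1].astype(int), kc=meta["kc"],
                   side=meta["side"], seed=meta["seed"],
                   representation=meta["representation"])


@dataclass
class ClusterAssignment:
    """Point-to-centroid assignment with the per-iteration objective trace."""

    assignment: np.ndarray
    objective: float
    objective_trace: list[float] = field(default_factory=list)


def vectorize_for_clustering(image: LabeledImage, side: int = DEFAULT_SIDE) -> np.ndarray:
    """Flattened grayscale pixels of the image resized to side x side,
    affinely scaled to [0, 1] over the dataset's nominal range."""
    px = image.resized(side).pixels
    return px.ravel().astype(np.float64)


def _squared_distances(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # ||x - c||^2 = ||x||^2 - 2 x.c + ||c||^2
    d2 = (
        (points ** 2).sum(axis=1)[:, None]
        - 2.0 * points @ centroids.T
        + (centroids ** 2).sum(axis=1)[None, :]
    )
    return np.maximum(d2, 0.0)


def _kmeanspp_seed(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = len(points)
    centroids = np.empty((k, points.shape[1]))
    centroids[0] = points[rng.integers(n)]
    d2 = _squared_distances(points, centroids[:1]).ravel()
    for i in range(1, k):
        total = d2.sum()
        if total <= 0:
            # all remaining mass at chosen centroids: pick uniformly
            centroids[i] = points[rng.integers(n)]
        else:
            centroids[i] = points[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, _squared_distances(points, centroids[i:i + 1]).ravel())
    return centroids


def kmeans(points: np.ndarray, k: int, seed: int
           ) -> tuple[np.ndarray, ClusterAssignment]:
    """Lloyd's algorithm with k-means++ seeding.

    Returns (centroids (k, dim), assignment).  Raises if k exceeds the
    number of distinct points.  The within-cluster squared-Euclidean
    objective is asserted non-increasing across iterations.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2:
        raise ValueError("points must be 2D (n, dim)")
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = len(np.unique(points, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds {n_distinct} distinct points")
    rng = np.random.default_rng(seed)
    centroids = _kmeanspp_seed(points, k, rng)
    prev_assign = None
    trace: list[float] = []
    for _ in range(MAX_ITER):
        d2 = _squared_distances(points, centroids)
        assign = d2.argmin(axis=1)
        # empty-cluster repair: re-seed from the point farthest from its centroid
        for empty in set(range(k)) - set(assign.tolist()):
            farthest = d2[np.arange(len(points)), assign].argmax()
            centroids[empty] = points[farthest]
            d2[:, empty] = _squared_distances(points, centroids[empty:empty + 1]).ravel()
            assign = d2.argmin(axis=1)
        obj = float(d2[np.arange(len(points)), assign].sum())
        if trace and obj > trace[-1] + 1e-8 * max(1.0, trace[-1]):
            raise AssertionError("k-means objective increased")
        trace.append(obj)
        if prev_assign is not None and np.array_equal(assign, prev_assign):
            break
        prev_assign = assign
        for j in range(k):
            mask = assign == j
            if mask.any():
                centroids[j] = points[mask].mean(axis=0)
    result = ClusterAssignment(prev_assign if prev_assign is not None else assign,
                               trace[-1], trace)
    return centroids, result


def select_prototypes(dataset: list[LabeledImage], kc: int, seed: int,
                      side: int = DEFAULT_SIDE,
                      representation: str = "original") -> PrototypeSet:
    """Per-class k-means: kc centroids within each class, concatenated.

    The resulting set has k = kc * c centroids defining the axes of the
    dissimilarity space.
    """
    if kc < 1:
        raise ValueError("kc must be >= 1")
    by_class: dict[int, list[np.ndarray]] = {}
    for im in dataset:
        by_class.setdefault(im.label, []).append(vectorize_for_clustering(im, side))
    seeds = np.random.SeedSequence([seed, 17]).generate_state(len(by_class))
    all_centroids, tags = [], []
    for pos, label in enumerate(sorted(by_class)):
        pts = np.stack(by_class[label])
        if len(pts) < kc:
            raise ValueError(
                f"class {label} has {len(pts)} samples, fewer than kc={kc}")
        cents, _ = kmeans(pts, kc, int(seeds[pos] % (2 ** 31)))
        all_centroids.append(cents)
        tags.extend([label] * kc)
    return PrototypeSet(np.vstack(all_centroids), np.array(tags, dtype=int),
                        kc=kc, side=side, seed=seed, representation=representation)
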