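"""HASC relational descriptors: covariance (COV) and entropy/mutual-information (EMI).

Heterogeneous Auto-Similarities of Characteristics describe an image by the
pairwise relations among d low-level feature maps computed at every pixel.
Two d x d matrices are built over the whole image:

* COV -- the sample covariance of the d maps, capturing linear dependencies;
* EMI -- per-map (plug-in, histogram-binned) entropies on the diagonal and
  pairwise mutual information off the diagonal, capturing arbitrary
  dependencies.  MI(A, A) reduces to the entropy of A, which is why one
  matrix holds both quantities.

The descriptor is the concatenation of the vectorized EMI and COV matrices
(length 2 d^2 = 72 at the default d = 6).  Alternatively the six feature
maps can be tiled into a single mosaic image ("HASC image") and fed to a
CNN in place of the original image.

All entropies/MI are in nats.  Probabilities come from equal-width
histograms over [min, max] of each map; empty bins contribute zero
(0 log 0 := 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from dissimspace.data import LabeledImage

#: number of low-level feature maps (d)
DEFAULT_DEPTH = 6
#: histogram bins used by the EMI estimator
DEFAULT_BINS = 28
#: output side of the tiled HASC image
DEFAULT_HASC_SIDE = 224


@dataclass
class FeatureStack:
    """w x h x d stack of low-level feature maps over one image."""

    values: np.ndarray  # (h, w, d)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("FeatureStack must be h x w x d")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    @property
    def depth(self) -> int:
        return self.values.shape[2]

    def map(self, i: int) -> np.ndarray:
        return self.values[:, :, i]


@dataclass
class JointHistogram:
    """B x B normalized 2D histogram plus the bin edges that produced it."""

    probabilities: np.ndarray
    bin_edges_a: np.ndarray
    bin_edges_b: np.ndarray

    def __post_init__(self) -> None:
        total = float(self.probabilities.sum())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total}, not 1")
        if np.any(self.probabilities < 0):
            raise ValueError("negative probability mass")


@dataclass
class RelationalMatrix:
    """d x d symmetric relation matrix; kind is 'EMI' or 'COV'."""

    entries: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        e = self.entries
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError("relational matrix must be square")
        if np.max(np.abs(e - e.T)) > 1e-9:
            raise ValueError("relational matrix must be symmetric")
        if self.kind not in ("EMI", "COV"):
            raise ValueError(f"unknown kind {self.kind!r}")


@dataclass
class HascDescriptor:
    """Concatenation of vectorized EMI and COV (length 2 d^2)."""

    vector: np.ndarray


def low_level_features(image: LabeledImage, depth: int = DEFAULT_DEPTH) -> FeatureStack:
    """Compute the low-level feature maps z^i at every pixel.

    The default stack (d = 6): intensity, |d/dx|, |d/dy|, |d2/dx2|, |d2/dy2|,
    and gradient magnitude.  Derivatives are central differences, so a
    constant image yields identically-zero derivative maps.
    """
    if depth != DEFAULT_DEPTH:
        raise ValueError("only the default 6-map stack is provided")
    px = image.pixels
    if min(px.shape) < 3:
        raise ValueError("image too small for derivative maps (min dim >= 3)")
    dy, dx = np.gradient(px)
    dyy = np.gradient(dy, axis=0)
    dxx = np.gradient(dx, axis=1)
    grad_mag = np.hypot(dx, dy)
    stack = np.stack(
        [px, np.abs(dx), np.abs(dy), np.abs(dxx), np.abs(dyy), grad_mag], axis=2
    )
    return FeatureStack(stack)


def _edges(v: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        # degenerate support: everything lands in the first bin
        hi = lo + 1.0
    return np.linspace(lo, hi, bins + 1)


def joint_histogram(a: np.ndarray, b: np.ndarray, bins: int) -> JointHistogram:
    """Joint 2D normalized histogram of paired realizations of A and B."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("a and b must have the same length")
    if a.size < 1:
        raise ValueError("empty input")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    edges_a, edges_b = _edges(a, bins), _edges(b, bins)
    counts, _, _ = np.histogram2d(a, b, bins=[edges_a, edges_b])
    return JointHistogram(counts / a.size, edges_a, edges_b)


def _entropy_of_probs(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def entropy(a: np.ndarray, bins: int = DEFAULT_BINS) -> float:
    """Plug-in entropy (nats) of the binned marginal of a."""
    a = np.asarray(a, dtype=np.float64).ravel()
    if a.size < 1:
        raise ValueError("empty input")
    counts, _ = np.histogram(a, bins=_edges(a, bins))
    return _entropy_of_probs(counts / a.size)


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = DEFAULT_BINS) -> float:
    """Plug-in mutual information (nats) from the joint 2D histogram.

    Computed as sum_ij p_ij log(p_ij / (p_i p_j)), the table form of the
    sample-mean estimator; clipped at zero against floating-point round-off.
    """
    jh = joint_histogram(a, b, bins)
    p = jh.probabilities
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    mask = p > 0
    ratio = p[mask] / (np.outer(pa, pb)[mask])
    return max(float((p[mask] * np.log(ratio)).sum()), 0.0)


def emi_matrix(stack: FeatureStack, bins: int = DEFAULT_BINS) -> RelationalMatrix:
    """EMI: entropies on the diagonal, pairwise MI off it."""
    d = stack.depth
    if d == 0:
        raise ValueError("empty feature stack")
    flat = [stack.map(i).ravel() for i in range(d)]
    out = np.zeros((d, d))
    for i in range(d):
        out[i, i] = entropy(flat[i], bins)
        for j in range(i + 1, d):
            out[i, j] = out[j, i] = mutual_information(flat[i], flat[j], bins)
    return RelationalMatrix(out, "EMI")


def cov_matrix(stack: FeatureStack) -> RelationalMatrix:
    """Sample covariance (denominator n-1) of the d maps over pixels."""
    d = stack.depth
    obs = stack.values.reshape(-1, d)
    if obs.shape[0] < 2:
        raise ValueError("need at least 2 pixels for a covariance")
    cov = np.cov(obs, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    return RelationalMatrix((cov + cov.T) / 2.0, "COV")


def hasc_descriptor(image: LabeledImage, bins: int = DEFAULT_BINS) -> HascDescriptor:
    """Vectorized EMI followed by vectorized COV: length 2 d^2 (72 at d = 6)."""
    stack = low_level_features(image)
    emi = emi_matrix(stack, bins)
    cov = cov_matrix(stack)
    return HascDescriptor(np.concatenate([emi.entries.ravel(), cov.entries.ravel()]))


def hasc_image(image: LabeledImage, out_size: int = DEFAULT_HASC_SIDE) -> LabeledImage:
    """Tile the 6 feature maps as a 3-row x 2-column mosaic, then resize.

    Mosaic rows hold maps (1,2), (3,4), (5,6); the 3h x 2w mosaic is
    bilinearly resized to out_size x out_size.  The label is preserved.
    """
    if out_size < 1:
        raise ValueError("out_size must be >= 1")
    stack = low_level_features(image)
    rows = [
        np.hstack([stack.map(2 * r), stack.map(2 * r + 1)]) for r in range(3)
    ]
    mosaic = np.vstack(rows)
    out = _sk_resize(mosaic, (out_size, out_size), order=1, mode="reflect",
                     anti_aliasing=False, preserve_range=True)
    return LabeledImage(out, image.label, image.id)


def hasc_mosaic(image: LabeledImage) -> np.ndarray:
    """The raw 3h x 2w mosaic before resizing (exposed for inspection)."""
    stack = low_level_features(image)
    return np.vstack(
        [np.hstack([stack.map(2 * r), stack.map(2 * r + 1)]) for r in range(3)]
    )
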