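"""Pair sampling and Siamese training with binary cross-entropy.

The twin network is trained on image pairs labeled 1 when the two images
share a class and 0 otherwise, so the sigmoid head learns P(same class).
Optimization is ADAM at the published settings (learning rate 1e-4,
gradient decay 0.9, squared-gradient decay 0.99, 3000 iterations, no stop
criterion); a fresh pair batch is drawn at every iteration.  Runs are
deterministic given the seed in :class:`TrainOptions`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from dissimspace import nn
from dissimspace.data import LabeledImage
from dissimspace.siamese import (ArchitectureSpec, DissimilarityModel,
                                 build_model, subtract_block)


@dataclass
class PairBatch:
    """Aligned image pairs with same-class indicator labels."""

    first: np.ndarray   # (N, H, W)
    second: np.ndarray  # (N, H, W)
    labels: np.ndarray  # (N,) in {0, 1}; 1 = same class

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise ValueError("empty pair batch")
        if not (len(self.first) == len(self.second) == len(self.labels)):
            raise ValueError("misaligned pair batch")


@dataclass
class TrainOptions:
    """ADAM training options; defaults are the published full-scale values."""

    learning_rate: float = 1e-4
    gradient_decay: float = 0.9
    squared_gradient_decay: float = 0.99
    iterations: int = 3000
    batch_size: int = 32
    seed: int = 0
    augment: bool = False

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def _group_by_class(dataset: list[LabeledImage]) -> dict[int, list[int]]:
    groups: dict[int, list[int]] = {}
    for i, im in enumerate(dataset):
        groups.setdefault(im.label, []).append(i)
    return groups


def augment_image(pixels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random axis reflections and a random upscale by a factor in [1, 2]
    followed by a center crop back to the original size.  Off by default."""
    out = pixels
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[::-1, :]
    factor = rng.uniform(1.0, 2.0)
    h, w = out.shape
    nh, nw = int(round(h * factor)), int(round(w * factor))
    big = _sk_resize(out, (nh, nw), order=1, mode="reflect",
                     anti_aliasing=False, preserve_range=True)
    top, left = (nh - h) // 2, (nw - w) // 2
    return big[top:top + h, left:left + w]


def sample_pairs(dataset: list[LabeledImage], n: int, seed: int,
                 image_size: int | None = None,
                 _stack: np.ndarray | None = None,
                 augment: bool = False) -> PairBatch:
    """Draw n pairs, balanced 50/50 same/different-class in expectation.

    Classes are drawn uniformly, then samples uniformly within class;
    deterministic given the seed.  A single-class dataset is rejected
    because no different-class pair exists.
    """
    groups = _group_by_class(dataset)
    classes = sorted(groups)
    if len(classes) < 2:
        raise ValueError("pair sampling needs at least 2 classes")
    rng = np.random.default_rng(seed)
    if _stack is None:
        imgs = ([im.resized(image_size).pixels for im in dataset]
                if image_size else [im.pixels for im in dataset])
        _stack = np.stack(imgs)
    first, second, labels = [], [], []
    for _ in range(n):
        same = rng.random() < 0.5
        if same:
            cls = classes[rng.integers(len(classes))]
            idx = groups[cls]
            i, j = idx[rng.integers(len(idx))], idx[rng.integers(len(idx))]
        else:
            a, b = rng.choice(len(classes), size=2, replace=False)
            i = groups[classes[a]][rng.integers(len(groups[classes[a]]))]
            j = groups[classes[b]][rng.integers(len(groups[classes[b]]))]
        xi, xj = _stack[i], _stack[j]
        if augment:
            xi, xj = augment_image(xi, rng), augment_image(xj, rng)
        first.append(xi)
        second.append(xj)
        labels.append(1.0 if same else 0.0)
    return PairBatch(np.stack(first), np.stack(second), np.array(labels))


def bce_loss(score, label) -> float:
    """Binary cross-entropy of a (0,1) score against a {0,1} label;
    scores are clipped 1e-12 away from the boundaries."""
    s = np.clip(np.asarray(score, dtype=np.float64), 1e-12, 1 - 1e-12)
    y = np.asarray(label, dtype=np.float64)
    return float(np.mean(-(y * np.log(s) + (1 - y) * np.log(1 - s))))


def _train_step(model: DissimilarityModel, optimizer: nn.Adam,
                batch: PairBatch, rng: np.random.Generator) -> float:
    model.zero_grads()
    f1, caches1 = model.embed(batch.first, train=True, rng=rng)
    f2, caches2 = model.embed(batch.second, train=True, rng=rng)
    y = subtract_block(f1, f2)
    z, head_cache = model.head.forward(y)
    scores = nn.sigmoid(z[:, 0])
    loss = bce_loss(scores, batch.labels)
    n = len(batch.labels)
    dz = ((scores - batch.labels) / n)[:, None]
    dy = model.head.backward(dz, head_cache)
    d_f1 = dy * np.sign(f1 - f2)
    model.twin.backward(d_f1, caches1)
    model.twin.backward(-d_f1, caches2)
    optimizer.step(model.parameters())
    return loss


def train_snn(arch: ArchitectureSpec, dataset: list[LabeledImage],
              options: TrainOptions | None = None) -> DissimilarityModel:
    """Train a pair scorer on a labeled image set.

    Images are resized to the architecture's input layer; a fresh balanced
    pair batch is drawn each iteration.  The per-iteration BCE trace is
    stored on the returned model (``model.loss_trace``).
    """
    options = options or TrainOptions()
    model = build_model(arch, seed=options.seed)
    optimizer = nn.Adam(options.learning_rate, options.gradient_decay,
                        options.squared_gradient_decay)
    stack = np.stack([im.resized(arch.input_size).pixels for im in dataset])
    rng = np.random.default_rng(np.random.SeedSequence([options.seed, 1]).generate_state(1)[0])
    pair_rng_root = np.random.SeedSequence([options.seed, 2])
    pair_seeds = pair_rng_root.generate_state(options.iterations)
    for it in range(options.iterations):
        batch = sample_pairs(dataset, options.batch_size,
                             int(pair_seeds[it] % (2 ** 31)),
                             _stack=stack, augment=options.augment)
        loss = _train_step(model, optimizer, batch, rng)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss at iteration {it}: {loss}")
        model.loss_trace.append(loss)
    return model
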