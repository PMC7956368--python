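"""Synthetic labeled image sets with controllable class separability.

Each class is defined by a band-structured sinusoidal texture -- a harmonic
stack at a class-specific fundamental frequency and orientation, amplitude
modulated along the orthogonal axis -- which mimics the harmonic/band
structure of audio spectrograms while staying fully parametric.  Per-image
random phases and envelopes provide within-class variation; i.i.d. Gaussian
pixel noise is added on top.  At ``separation = 0`` the texture vanishes and
all class-conditional distributions coincide, so any downstream classifier
can do no better than chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dissimspace.data import LabeledImage

_N_HARMONICS = 3


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic dataset generator.

    separation is the amplitude of the class texture relative to unit
    dynamic range (0 = classes indistinguishable); noise_sd the standard
    deviation of the additive Gaussian pixel noise.
    """

    classes: int = 3
    per_class: int = 40
    side: int = 64
    separation: float = 2.0
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classes < 2:
            raise ValueError("need at least 2 classes")
        if self.per_class < 1:
            raise ValueError("per_class must be >= 1")
        if self.side < 16:
            raise ValueError("side must be >= 16")
        if self.separation < 0 or self.noise_sd < 0:
            raise ValueError("separation and noise_sd must be >= 0")


def _class_texture(cfg: GeneratorConfig, label: int, rng: np.random.Generator) -> np.ndarray:
    """One draw of the band texture for a class: harmonic stack at the class
    fundamental, tilted by the class orientation, with a slow envelope."""
    side = cfg.side
    yy, xx = np.mgrid[0:side, 0:side] / side
    # class-specific fundamental (cycles per image) and orientation
    f0 = 2.0 + 3.0 * label
    theta = label * np.pi / 8.0
    u = np.cos(theta) * yy + np.sin(theta) * xx
    v = -np.sin(theta) * yy + np.cos(theta) * xx
    tex = np.zeros((side, side))
    for h in range(1, _N_HARMONICS + 1):
        phase = rng.uniform(0, 2 * np.pi)
        tex += (1.0 / h) * np.sin(2 * np.pi * f0 * h * u + phase)
    # slow amplitude modulation along the orthogonal axis (a "time" envelope)
    env_phase = rng.uniform(0, 2 * np.pi)
    env = 0.5 + 0.5 * np.sin(2 * np.pi * rng.uniform(0.5, 1.5) * v + env_phase)
    return tex * env


def make_dataset(config: GeneratorConfig) -> list[LabeledImage]:
    """Generate ``classes * per_class`` labeled images, deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    images: list[LabeledImage] = []
    for label in range(config.classes):
        for j in range(config.per_class):
            tex = _class_texture(config, label, rng)
            noise = rng.normal(0.0, config.noise_sd, size=tex.shape) if config.noise_sd > 0 else 0.0
            pixels = 0.5 + 0.25 * config.separation * tex + noise
            images.append(LabeledImage(pixels, label, id=f"class_{label}/img_{j}.png"))
    return images


def make_split(
    dataset: list[LabeledImage], train_fraction: float, seed: int
) -> tuple[list[LabeledImage], list[LabeledImage]]:
    """Stratified, disjoint train/test split; deterministic per seed."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[int]] = {}
    for i, im in enumerate(dataset):
        by_class.setdefault(im.label, []).append(i)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in sorted(by_class):
        idx = np.array(by_class[label])
        if len(idx) < 2:
            raise ValueError(f"class {label} has fewer than 2 samples; cannot split")
        perm = rng.permutation(len(idx))
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    return [dataset[i] for i in sorted(train_idx)], [dataset[i] for i in sorted(test_idx)]
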