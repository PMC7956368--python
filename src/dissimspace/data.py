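"""The atomic sample type and image-folder I/O.

Images are grayscale 2D float arrays in [0, 1].  RGB files are converted to
grayscale on load; the Siamese input layer is single-channel.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize


@dataclass
class LabeledImage:
    """A 2D intensity grid plus its class label."""

    pixels: np.ndarray
    label: int
    id: str = field(default="")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D grid, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def resized(self, side: int) -> "LabeledImage":
        """Bilinear resize to side x side, label preserved."""
        if side < 1:
            raise ValueError("side must be >= 1")
        if self.pixels.shape == (side, side):
            return LabeledImage(self.pixels.copy(), self.label, self.id)
        out = _sk_resize(self.pixels, (side, side), order=1, mode="reflect",
                         anti_aliasing=False, preserve_range=True)
        return LabeledImage(out, self.label, self.id)


def load_image_folder(path: str) -> list[LabeledImage]:
    """Read a ``class_<i>/img_<j>.png``-style labeled folder tree.

    Every immediate subdirectory is one class; files inside it are PNG/JPEG
    images converted to grayscale and scaled to [0, 1].  Classes are numbered
    by sorted subdirectory name.
    """
    classes = sorted(
        d for d in os.listdir(path) if os.path.isdir(os.path.join(path, d))
    )
    if not classes:
        raise ValueError(f"no class subdirectories under {path!r}")
    images: list[LabeledImage] = []
    for label, cls in enumerate(classes):
        cdir = os.path.join(path, cls)
        for fname in sorted(os.listdir(cdir)):
            if not fname.lower().endswith((".png", ".jpg", ".jpeg")):
                continue
            with Image.open(os.path.join(cdir, fname)) as im:
                arr = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
            images.append(LabeledImage(arr, label, id=f"{cls}/{fname}"))
    if not images:
        raise ValueError(f"no images found under {path!r}")
    return images


def save_image_folder(images: list[LabeledImage], path: str) -> None:
    """Write images as 8-bit PNG into ``class_<label>/img_<j>.png``."""
    counters: dict[int, int] = {}
    for img in images:
        cdir = os.path.join(path, f"class_{img.label}")
        os.makedirs(cdir, exist_ok=True)
        j = counters.get(img.label, 0)
        counters[img.label] = j + 1
        lo, hi = float(img.pixels.min()), float(img.pixels.max())
        scale = (img.pixels - lo) / (hi - lo) if hi > lo else np.zeros_like(img.pixels)
        Image.fromarray((scale * 255).round().astype(np.uint8)).save(
            os.path.join(cdir, f"img_{j}.png")
        )


def labels_of(images: list[LabeledImage]) -> np.ndarray:
    return np.array([im.label for im in images], dtype=np.intp)


def class_count(images: list[LabeledImage]) -> int:
    return len({im.label for im in images})
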