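"""Projection into the dissimilarity space.

An image x becomes the vector F(x) = [d(x, p_1), ..., d(x, p_k)] of its
learned pair scores against the k prototypes; the design matrix stacks one
such row per sample.  Projection is batched over prototypes for
throughput, with output independent of batch size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dissimspace.data import LabeledImage, labels_of
from dissimspace.prototypes import PrototypeSet
from dissimspace.siamese import DissimilarityModel

DEFAULT_BATCH = 64


@dataclass
class DissimilarityVector:
    """Pair scores of one image against every prototype, in (0, 1)."""

    values: np.ndarray
    prototype_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.prototype_ids):
            raise ValueError("values/ids length mismatch")
        if np.any(self.values <= 0) or np.any(self.values >= 1):
            raise ValueError("pair scores must lie strictly in (0, 1)")


def _prototype_stack(prototypes: PrototypeSet, model: DissimilarityModel) -> np.ndarray:
    return np.stack(
        [im.pixels for im in prototypes.as_images(out_size=model.input_size)]
    )


def prototype_ids(prototypes: PrototypeSet) -> list[str]:
    counters: dict[int, int] = {}
    ids = []
    for tag in prototypes.class_tags:
        j = counters.get(int(tag), 0)
        counters[int(tag)] = j + 1
        ids.append(f"c{int(tag)}_p{j}")
    return ids


def project(x: LabeledImage, prototypes: PrototypeSet,
            model: DissimilarityModel,
            batch_size: int = DEFAULT_BATCH) -> DissimilarityVector:
    """F(x): the image's pair score against each prototype, in order."""
    px = x.resized(model.input_size).pixels
    proto_stack = _prototype_stack(prototypes, model)
    values = np.empty(len(proto_stack))
    for start in range(0, len(proto_stack), batch_size):
        chunk = proto_stack[start:start + batch_size]
        xs = np.broadcast_to(px, (len(chunk),) + px.shape)
        values[start:start + len(chunk)] = model.score_batch(xs, chunk)
    return DissimilarityVector(values, prototype_ids(prototypes))


def build_design_matrix(dataset: list[LabeledImage], prototypes: PrototypeSet,
                        model: DissimilarityModel,
                        batch_size: int = DEFAULT_BATCH
                        ) -> tuple[np.ndarray, np.ndarray]:
    """(n x k design matrix, aligned label vector).

    Row i is the projection of sample i; scoring is batched over the
    (sample, prototype) grid but the contract is batch-size independence.
    """
    if not dataset:
        raise ValueError("empty dataset")
    proto_stack = _prototype_stack(prototypes, model)
    k = len(proto_stack)
    sample_stack = np.stack(
        [im.resized(model.input_size).pixels for im in dataset])
    n = len(sample_stack)
    design = np.empty((n, k))
    # flatten the n x k pair grid and score it in fixed-size batches
    flat_x = np.repeat(np.arange(n), k)
    flat_p = np.tile(np.arange(k), n)
    out = np.empty(n * k)
    for start in range(0, n * k, batch_size):
        sl = slice(start, min(start + batch_size, n * k))
        out[sl] = model.score_batch(sample_stack[flat_x[sl]],
                                    proto_stack[flat_p[sl]])
    design[:] = out.reshape(n, k)
    return design, labels_of(dataset)


def save_design_matrix(path: str, design: np.ndarray, labels: np.ndarray,
                       prototypes: PrototypeSet) -> None:
    df = pd.DataFrame(design, columns=prototype_ids(prototypes))
    df["label"] = labels
    df.to_csv(path, index=False)


def load_design_matrix(path: str) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df.drop(columns=["label"]).to_numpy(), df["label"].to_numpy()
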