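"""The eight Siamese backbone topologies and the pair-scoring model.

Each backbone is an ordered stack of valid (unpadded) convolutions, max
pools, activations, and a final fully connected layer producing an
embedding of 4096 (2048 for Network 2) features.  Two weight-sharing
branches embed a pair of images; the subtract block Y = |F1 - F2| makes
the score symmetric; a 1-unit dense head plus sigmoid maps Y to a score
in (0, 1), trained so that larger values indicate the two images belong
to the same class.  The learned score is *not* a metric: it satisfies
neither the identity property nor the triangle inequality, only symmetry
and continuity.

Strides are part of the topology definitions here: all convolutions are
stride 1 except Network 3's first (stride 4) and Network 5's second
(stride 4) and third (stride 2); pool stride equals pool size.  Network 5's
third convolution is published with a 26 -> 9 spatial transition that no
integer stride reproduces under valid convolution; stride 2 (26 -> 11) is
used and the resulting shapes are tracked as computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from dissimspace import nn
from dissimspace.data import LabeledImage

DEFAULT_INPUT_SIZE = 224
DEFAULT_LEAKY_SLOPE = 0.01  # published value a=1 degenerates to identity
DEFAULT_DROPOUT = 0.5

_KINDS = {"input", "conv", "grouped_conv", "relu", "leaky_relu",
          "max_pool", "dropout", "fully_connected"}


@dataclass
class LayerSpec:
    kind: str
    filter_size: int = 0
    num_filters: int = 0
    stride: int = 1
    groups: int = 1
    out_units: int = 0
    rate: float = DEFAULT_DROPOUT  # dropout only

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.stride < 1 or self.groups < 1:
            raise ValueError("stride and groups must be >= 1")
        if self.kind == "grouped_conv" and self.num_filters % self.groups:
            raise ValueError("grouped conv needs num_filters divisible by groups")


@dataclass
class ArchitectureSpec:
    id: int
    layers: list[LayerSpec]
    embedding_dim: int = 4096

    def __post_init__(self) -> None:
        if not self.layers or self.layers[0].kind != "input":
            raise ValueError("first layer must be the input layer")
        if self.layers[-1].kind != "fully_connected":
            raise ValueError("last layer must be fully connected")
        if self.layers[-1].out_units != self.embedding_dim:
            raise ValueError("final FC must emit embedding_dim units")

    @property
    def input_size(self) -> int:
        return self.layers[0].filter_size

    def to_json(self) -> str:
        return json.dumps({"id": self.id, "embedding_dim": self.embedding_dim,
                           "layers": [asdict(l) for l in self.layers]}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        d = json.loads(text)
        return cls(d["id"], [LayerSpec(**l) for l in d["layers"]], d["embedding_dim"])


def _inp(size: int = DEFAULT_INPUT_SIZE) -> LayerSpec:
    return LayerSpec("input", filter_size=size)


def _conv(f: int, n: int, stride: int = 1) -> LayerSpec:
    return LayerSpec("conv", filter_size=f, num_filters=n, stride=stride)


def _gconv(f: int, n: int, groups: int = 2) -> LayerSpec:
    return LayerSpec("grouped_conv", filter_size=f, num_filters=n, groups=groups)


def _pool(size: int) -> LayerSpec:
    return LayerSpec("max_pool", filter_size=size, stride=size)


def _relu() -> LayerSpec:
    return LayerSpec("relu")


def _lrelu() -> LayerSpec:
    return LayerSpec("leaky_relu")


def _drop(rate: float = DEFAULT_DROPOUT) -> LayerSpec:
    return LayerSpec("dropout", rate=rate)


def _fc(units: int) -> LayerSpec:
    return LayerSpec("fully_connected", out_units=units)


def catalog() -> list[ArchitectureSpec]:
    """The eight backbone topologies, in publication order."""
    return [
        ArchitectureSpec(1, [
            _inp(), _conv(10, 64), _relu(), _pool(2), _conv(7, 128), _relu(),
            _pool(2), _conv(4, 128), _relu(), _pool(2), _conv(5, 64), _relu(),
            _fc(4096)]),
        ArchitectureSpec(2, [
            _inp(), _conv(5, 64), _lrelu(), _conv(5, 64), _lrelu(), _pool(2),
            _conv(3, 128), _lrelu(), _conv(3, 128), _lrelu(), _pool(2),
            _conv(4, 128), _lrelu(), _pool(2), _conv(5, 64), _lrelu(),
            _fc(2048)], embedding_dim=2048),
        ArchitectureSpec(3, [
            _inp(), _conv(7, 128, stride=4), _pool(2), _conv(5, 256), _relu(),
            _conv(5, 128), _pool(2), _conv(3, 64), _relu(), _pool(2),
            _fc(4096)]),
        ArchitectureSpec(4, [
            _inp(), _conv(7, 128), _pool(4), _relu(), _conv(5, 256), _relu(),
            _conv(3, 64), _pool(2), _conv(3, 128), _relu(), _conv(5, 64),
            _fc(4096)]),
        ArchitectureSpec(5, [
            _inp(), _conv(10, 64), _pool(2), _relu(), _conv(7, 128, stride=4),
            _relu(), _conv(5, 128, stride=2), _relu(), _conv(4, 64), _relu(),
            _fc(4096)]),
        ArchitectureSpec(6, [
            _inp(), _conv(7, 64), _pool(2), _relu(), _conv(3, 128), _pool(2),
            _relu(), _conv(1, 64), _relu(), _conv(3, 128), _relu(), _pool(2),
            _conv(1, 128), _relu(), _conv(4, 64), _pool(2), _relu(),
            _fc(4096)]),
        ArchitectureSpec(7, [
            _inp(), _drop(), _conv(7, 64), _pool(2), _conv(5, 128), _pool(2),
            _conv(5, 64), _pool(2), _conv(3, 256), _pool(2), _conv(3, 256),
            _fc(4096)]),
        ArchitectureSpec(8, [
            _inp(), _conv(10, 32), _pool(2), _relu(), _gconv(7, 64),
            _conv(5, 128), _pool(2), _relu(), _gconv(3, 256),
            _fc(4096)]),
    ]


def get_architecture(arch_id: int) -> ArchitectureSpec:
    for spec in catalog():
        if spec.id == arch_id:
            return spec
    raise ValueError(f"no architecture with id {arch_id}")


def infer_shapes(arch: ArchitectureSpec,
                 input_size: int | None = None) -> list[tuple[int, ...]]:
    """Activation shape after every layer: (h, w, c), or (units,) for FC.

    Valid-convolution rule: out = floor((in - filter)/stride) + 1; pooling
    uses the same rule with stride = pool size.
    """
    size = input_size if input_size is not None else arch.input_size
    shapes: list[tuple[int, ...]] = []
    h = w = size
    c = 1
    for layer in arch.layers:
        if layer.kind == "input":
            h = w = size
            c = 1
        elif layer.kind in ("conv", "grouped_conv"):
            h = (h - layer.filter_size) // layer.stride + 1
            w = (w - layer.filter_size) // layer.stride + 1
            c = layer.num_filters
        elif layer.kind == "max_pool":
            h = (h - layer.filter_size) // layer.stride + 1
            w = (w - layer.filter_size) // layer.stride + 1
        elif layer.kind == "fully_connected":
            shapes.append((layer.out_units,))
            continue
        if h < 1 or w < 1:
            raise ValueError(
                f"architecture {arch.id}: non-positive activation after {layer.kind}")
        shapes.append((h, w, c))
    return shapes


def count_parameters(layer: LayerSpec, in_channels: int,
                     in_shape: tuple[int, ...] | None = None) -> int:
    """Learnable parameter count of one layer given its resolved input.

    conv: f^2 * (c_in/groups) * n + n;  FC: flat_in * out + out;
    activations, pooling, dropout: 0.
    """
    if layer.kind in ("conv", "grouped_conv"):
        if in_channels % layer.groups:
            raise ValueError("in_channels must divide into groups")
        f = layer.filter_size
        return f * f * (in_channels // layer.groups) * layer.num_filters + layer.num_filters
    if layer.kind == "fully_connected":
        if in_shape is None:
            raise ValueError("FC parameter count needs the resolved input shape")
        flat = int(np.prod(in_shape))
        return flat * layer.out_units + layer.out_units
    return 0


def total_parameters(arch: ArchitectureSpec, input_size: int | None = None) -> int:
    shapes = infer_shapes(arch, input_size)
    total = 0
    for i, layer in enumerate(arch.layers):
        prev = shapes[i - 1] if i > 0 else shapes[0]
        cin = prev[2] if len(prev) == 3 else 1
        total += count_parameters(layer, cin, prev)
    return total


def leaky_relu(x, a: float = DEFAULT_LEAKY_SLOPE):
    """x for x >= 0, a*x otherwise; a = 0 reduces to plain ReLU."""
    x = np.asarray(x, dtype=np.float64)
    out = np.where(x >= 0, x, a * x)
    return float(out) if out.ndim == 0 else out


def subtract_block(f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
    """Y = |F1 - F2|: the symmetric combination of the two embeddings."""
    f1 = np.asarray(f1, dtype=np.float64)
    f2 = np.asarray(f2, dtype=np.float64)
    if f1.shape != f2.shape:
        raise ValueError("embeddings must have equal shapes")
    return np.abs(f1 - f2)


def scale_architecture(arch: ArchitectureSpec, input_size: int,
                       width_factor: float = 0.25,
                       embedding_dim: int = 64) -> ArchitectureSpec:
    """Shrink a backbone to a smaller input and narrower channels.

    Keeps the layer pattern of the parent topology; convolutions that no
    longer fit the shrunken activations are dropped, as are pools that
    would collapse the activation below 2 pixels.  Used for CPU-scale
    training runs on small synthetic images.
    """
    new_layers: list[LayerSpec] = [_inp(input_size)]
    h = input_size
    for layer in arch.layers[1:]:
        if layer.kind in ("conv", "grouped_conv"):
            out = (h - layer.filter_size) // layer.stride + 1
            if out < 1:
                continue
            n = max(4, int(round(layer.num_filters * width_factor)))
            groups = layer.groups if n % layer.groups == 0 else 1
            new_layers.append(LayerSpec(layer.kind, filter_size=layer.filter_size,
                                        num_filters=n, stride=layer.stride,
                                        groups=groups))
            h = out
        elif layer.kind == "max_pool":
            out = h // layer.filter_size
            if out < 2:
                continue
            new_layers.append(_pool(layer.filter_size))
            h = out
        elif layer.kind == "fully_connected":
            new_layers.append(_fc(embedding_dim))
        else:
            new_layers.append(LayerSpec(layer.kind, rate=layer.rate))
    return ArchitectureSpec(arch.id, new_layers, embedding_dim)


@dataclass
class DissimilarityModel:
    """A trained twin-network pair scorer: two shared-weight branches,
    the subtract block, and a dense-sigmoid head."""

    architecture: ArchitectureSpec
    twin: nn.Sequential
    head: nn.Dense
    input_size: int
    leaky_slope: float = DEFAULT_LEAKY_SLOPE
    loss_trace: list = field(default_factory=list)

    def embed(self, batch: np.ndarray, train: bool = False,
              rng: np.random.Generator | None = None):
        """batch: (N, H, W) grayscale -> (embeddings (N, E), caches)."""
        x = np.asarray(batch, dtype=np.float64)[:, None, :, :]
        if x.shape[2] != self.input_size or x.shape[3] != self.input_size:
            raise ValueError(
                f"model expects {self.input_size}x{self.input_size} images, "
                f"got {x.shape[2]}x{x.shape[3]}")
        return self.twin.forward(x, train=train, rng=rng)

    def score_batch(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        """Pair scores in (0, 1) for aligned batches of images."""
        f1, _ = self.embed(xs)
        f2, _ = self.embed(ys)
        z, _ = self.head.forward(subtract_block(f1, f2))
        return nn.sigmoid(z[:, 0])

    def parameters(self):
        yield from self.twin.parameters()
        for name in self.head.params:
            yield ("head", name), self.head.params[name], self.head.grads[name]

    def zero_grads(self) -> None:
        self.twin.zero_grads()
        self.head.zero_grads()

    def save(self, path: str) -> None:
        arrays = {}
        for (li, name), param, _ in self.parameters():
            arrays[f"{li}:{name}"] = param
        np.savez(path, **arrays)

    def load_weights(self, path: str) -> None:
        with np.load(path) as data:
            for (li, name), param, _ in self.parameters():
                param[...] = data[f"{li}:{name}"]


def build_model(arch: ArchitectureSpec, seed: int = 0,
                leaky_slope: float = DEFAULT_LEAKY_SLOPE) -> DissimilarityModel:
    """Instantiate the twin network + scoring head for a topology.

    Weights are narrow-Gaussian initialized (sigma = 0.01) from the seed;
    both branches share the same layer objects, hence the same weights.
    """
    rng = np.random.default_rng(seed)
    shapes = infer_shapes(arch)
    layers: list[nn.Layer] = []
    cin = 1
    for i, spec_layer in enumerate(arch.layers):
        if spec_layer.kind == "input":
            continue
        if spec_layer.kind in ("conv", "grouped_conv"):
            layers.append(nn.Conv2D(cin, spec_layer.num_filters,
                                    spec_layer.filter_size, spec_layer.stride,
                                    spec_layer.groups, rng=rng))
            cin = spec_layer.num_filters
        elif spec_layer.kind == "max_pool":
            layers.append(nn.MaxPool2D(spec_layer.filter_size))
        elif spec_layer.kind == "relu":
            layers.append(nn.ReLU())
        elif spec_layer.kind == "leaky_relu":
            layers.append(nn.LeakyReLU(leaky_slope))
        elif spec_layer.kind == "dropout":
            layers.append(nn.Dropout(spec_layer.rate))
        elif spec_layer.kind == "fully_connected":
            flat = int(np.prod(shapes[i - 1]))
            layers.append(nn.Dense(flat, spec_layer.out_units, rng=rng))
    head = nn.Dense(arch.embedding_dim, 1, rng=rng)
    return DissimilarityModel(arch, nn.Sequential(layers), head,
                              input_size=arch.input_size, leaky_slope=leaky_slope)


def score_pair(model: DissimilarityModel, x: LabeledImage, y: LabeledImage) -> float:
    """Dissimilarity-model score for one image pair; symmetric, in (0, 1)."""
    return float(model.score_batch(x.pixels[None], y.pixels[None])[0])
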