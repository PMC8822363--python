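"""Bridge between images/networks and the RSA pipeline.

Covers four concerns: (1) deterministic image preprocessing — foreground
is scaled onto a square gray canvas, resized, and channel-normalized;
(2) layerwise feature extraction into the pipeline's activation
containers, flattening convolutional maps; (3) hierarchy-aware top-1
scoring, where a prediction counts as correct if it names the target
class or any of its hyponyms in an is-a taxonomy; (4) a fine-tuning
driver that freezes all parameters up to a named boundary layer and
trains the rest with SGD + momentum.

The network object used throughout is :class:`TinyConvNet`, a minimal
pure-numpy convolutional network (im2col convolutions, 2x2 max pooling,
dense heads) with enough of a training loop to exercise the freezing and
extraction contracts on synthetic images.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datasets import ActivationSet, MultiLayerActivationSet

# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

IMAGENET_MEANS = (0.485, 0.456, 0.406)
IMAGENET_STDS = (0.229, 0.224, 0.225)


@dataclass(frozen=True)
class PreprocessConfig:
    """Canvas geometry and normalization constants for input images.

    The normalization constants default to the canonical per-channel
    natural-image statistics but are plain config data: pass per-image or
    other dataset statistics if those are wanted instead.
    """

    canvas: int = 224
    background: int = 128
    margin: float = 0.05
    means: tuple[float, float, float] = IMAGENET_MEANS
    stds: tuple[float, float, float] = IMAGENET_STDS

    def __post_init__(self) -> None:
        if self.canvas < 32:
            raise ValueError("canvas side must be at least 32 pixels")
        if len(self.means) != 3 or len(self.stds) != 3:
            raise ValueError("normalization vectors must have length 3")
        if not 0 <= self.margin < 0.5:
            raise ValueError("margin must lie in [0, 0.5)")


def _to_pil(image):
    from PIL import Image

    if isinstance(image, (str, Path)):
        try:
            return Image.open(image).convert("RGBA")
        except Exception as exc:
            raise ValueError(f"cannot read image file {image}: {exc}") from exc
    if isinstance(image, np.ndarray):
        if image.ndim == 2:
            image = np.stack([image] * 3, axis=-1)
        return Image.fromarray(image.astype(np.uint8)).convert("RGBA")
    return image.convert("RGBA")


def preprocess_image(image, config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Scale the foreground onto a gray canvas and channel-normalize.

    Foreground is taken from the alpha channel when informative, else
    from a background-color mask.  The foreground bounding box is scaled
    (aspect ratio preserved) to fit the canvas minus the margin, pasted
    centered, and the result normalized per channel.  Returns a float
    array of shape (3, canvas, canvas).  An all-background image maps to
    the constant normalized gray value.
    """
    from PIL import Image

    pil = _to_pil(image)
    if pil.size[0] == 0 or pil.size[1] == 0:
        raise ValueError("image has zero size")
    arr = np.array(pil)
    alpha = arr[:, :, 3]
    if alpha.min() < 255:
        mask = alpha > 0
    else:
        rgb = arr[:, :, :3].astype(int)
        mask = np.any(np.abs(rgb - config.background) > 8, axis=2)

    bg = (config.background,) * 3
    canvas_im = Image.new("RGB", (config.canvas, config.canvas), bg)
    if mask.any():
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        top, bottom = rows[0], rows[-1] + 1
        left, right = cols[0], cols[-1] + 1
        crop = Image.fromarray(arr[top:bottom, left:right])
        w, h = crop.size
        target = config.canvas * (1.0 - 2 * config.margin)
        scale = min(target / w, target / h)
        new_w = max(1, round(w * scale))
        new_h = max(1, round(h * scale))
        crop = crop.resize((new_w, new_h), Image.LANCZOS)
        off = ((config.canvas - new_w) // 2, (config.canvas - new_h) // 2)
        canvas_im.paste(crop, off, crop)

    out = np.asarray(canvas_im, dtype=float) / 255.0
    means = np.array(config.means)[None, None, :]
    stds = np.array(config.stds)[None, None, :]
    out = (out - means) / stds
    return out.transpose(2, 0, 1)


# --------------------------------------------------------------------------
# minimal numpy convolutional network
# --------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (n, c, oh, ow, k, k)
    oh, ow = win.shape[2], win.shape[3]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, oh * ow)
    return cols, oh, ow


def _col2im(dcols, x_shape, k, stride, pad, oh, ow):
    n, c, h, w = x_shape
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    dcols = dcols.reshape(n, c, k, k, oh, ow)
    for a in range(k):
        for b in range(k):
            dx[:, :, a : a + stride * oh : stride, b : b + stride * ow : stride] += (
                dcols[:, :, a, b]
            )
    return dx[:, :, pad : pad + h, pad : pad + w]


class _Layer:
    params: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(_Layer):
    def __init__(self, in_ch, out_ch, k=3, stride=1, pad=1, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * k * k
        self.k, self.stride, self.pad = k, stride, pad
        self.params = {
            "W": rng.standard_normal((out_ch, in_ch, k, k)) * np.sqrt(2.0 / fan_in),
            "b": np.zeros(out_ch),
        }

    def forward(self, x):
        self._x_shape = x.shape
        cols, oh, ow = _im2col(x, self.k, self.stride, self.pad)
        self._cols, self._oh, self._ow = cols, oh, ow
        w = self.params["W"].reshape(self.params["W"].shape[0], -1)
        out = np.einsum("of,nfl->nol", w, cols) + self.params["b"][None, :, None]
        return out.reshape(x.shape[0], -1, oh, ow)

    def backward(self, dout):
        n, oc, oh, ow = dout.shape
        dflat = dout.reshape(n, oc, oh * ow)
        w = self.params["W"].reshape(oc, -1)
        self.grads["W"] = np.einsum("nol,nfl->of", dflat, self._cols).reshape(
            self.params["W"].shape
        )
        self.grads["b"] = dflat.sum(axis=(0, 2))
        dcols = np.einsum("of,nol->nfl", w, dflat)
        return _col2im(
            dcols, self._x_shape, self.k, self.stride, self.pad, self._oh, self._ow
        )


class ReLU(_Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2D(_Layer):
    """2x2 max pooling with stride 2; spatial dims must be even."""

    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2D requires even spatial dimensions")
        self._x_shape = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        return out

    def backward(self, dout):
        n, c, h, w = self._x_shape
        d = self._mask * dout[:, :, :, None, :, None]
        # split ties evenly so gradient mass is conserved
        d = d / self._mask.sum(axis=(3, 5), keepdims=True)
        return d.reshape(n, c, h, w)


class Flatten(_Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(_Layer):
    def __init__(self, n_in, n_out, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params = {
            "W": rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in),
            "b": np.zeros(n_out),
        }

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class TinyConvNet:
    """Small named-layer convolutional network in plain numpy.

    Layers are an ordered list of (name, layer); any layer's output can
    be captured by name for feature extraction, and parameters up to a
    named boundary can be frozen during training.
    """

    def __init__(self, named_layers: list[tuple[str, _Layer]]):
        self.layers = named_layers

    @classmethod
    def create(
        cls, input_shape=(3, 32, 32), n_classes=2, widths=(8, 16), fc_width=32, seed=0
    ) -> "TinyConvNet":
        rng = np.random.default_rng(seed)
        c, h, w = input_shape
        layers: list[tuple[str, _Layer]] = []
        in_ch = c
        for i, out_ch in enumerate(widths, start=1):
            layers.append((f"conv{i}", Conv2D(in_ch, out_ch, rng=rng)))
            layers.append((f"relu{i}", ReLU()))
            layers.append((f"pool{i}", MaxPool2D()))
            in_ch = out_ch
            h //= 2
            w //= 2
        layers.append(("flatten", Flatten()))
        layers.append(("fc1", Dense(in_ch * h * w, fc_width, rng=rng)))
        layers.append((f"relu_fc1", ReLU()))
        layers.append(("fc2", Dense(fc_width, n_classes, rng=rng)))
        return cls(layers)

    @property
    def layer_names(self) -> list[str]:
        return [name for name, _ in self.layers]

    def forward(
        self, x: np.ndarray, capture: Sequence[str] = ()
    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        captured = {}
        out = x
        for name, layer in self.layers:
            out = layer.forward(out)
            if name in capture:
                captured[name] = out.reshape(out.shape[0], -1).copy()
        return out, captured

    def backward(self, dout: np.ndarray) -> None:
        for _, layer in reversed(self.layers):
            dout = layer.backward(dout)

    def predict(self, x: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(x)
        return logits.argmax(axis=1)

    def parameter_checksum(self, upto: str | None = None) -> str:
        """SHA-256 over the byte content of parameters (optionally up to
        and including the named layer) — used to verify freezing."""
        h = hashlib.sha256()
        for name, layer in self.layers:
            for key in sorted(layer.params):
                h.update(np.ascontiguousarray(layer.params[key]).tobytes())
            if name == upto:
                break
        return h.hexdigest()


# --------------------------------------------------------------------------
# feature extraction
# --------------------------------------------------------------------------

def extract_features(
    network: TinyConvNet,
    images: Sequence[np.ndarray],
    layer_names: Sequence[str],
    metadata: pd.DataFrame,
    batch_size: int = 32,
) -> MultiLayerActivationSet:
    """Layerwise flattened activations for a list of preprocessed images.

    ``images`` are channels-first arrays as produced by
    :func:`preprocess_image`; one row per stimulus, in input order.
    """
    unknown = set(layer_names) - set(network.layer_names)
    if unknown:
        raise KeyError(
            f"unknown layer(s) {sorted(unknown)}; available: {network.layer_names}"
        )
    x = np.stack([np.asarray(im, dtype=float) for im in images])
    chunks: dict[str, list[np.ndarray]] = {name: [] for name in layer_names}
    for start in range(0, len(x), batch_size):
        _, captured = network.forward(x[start : start + batch_size], capture=layer_names)
        for name in layer_names:
            chunks[name].append(captured[name])
    layers = {
        name: ActivationSet(np.vstack(chunks[name]), metadata) for name in layer_names
    }
    return MultiLayerActivationSet(layers)


# --------------------------------------------------------------------------
# hierarchy-aware scoring
# --------------------------------------------------------------------------

@dataclass
class TaxonomyGraph:
    """Is-a taxonomy (edges child -> parent) with an output-index mapping."""

    graph: nx.DiGraph
    index_to_class: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("taxonomy contains a cycle")

    @classmethod
    def from_tsv(
        cls, path: str | Path, index_to_class: Mapping[int, str] | None = None
    ) -> "TaxonomyGraph":
        """Edge list TSV with columns ``child`` and ``parent``."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"child", "parent"} <= set(df.columns):
            raise ValueError("taxonomy TSV needs columns child, parent")
        g = nx.DiGraph()
        g.add_edges_from(df[["child", "parent"]].itertuples(index=False))
        return cls(g, dict(index_to_class or {}))

    def hyponyms(self, cls_id: str) -> set[str]:
        """All descendants (more specific classes) of ``cls_id``."""
        if cls_id not in self.graph:
            return set()
        return nx.ancestors(self.graph, cls_id)  # child->parent edges


def top1_accuracy_hierarchy(
    predicted_indices: Sequence[int],
    targets: Sequence[str],
    taxonomy: TaxonomyGraph,
) -> float:
    """Top-1 accuracy where any hyponym of the target counts as correct."""
    predicted_indices = list(predicted_indices)
    targets = list(targets)
    if len(predicted_indices) != len(targets):
        raise ValueError("predictions and targets differ in length")
    known = set(taxonomy.graph.nodes)
    correct = []
    for idx, target in zip(predicted_indices, targets):
        if idx not in taxonomy.index_to_class:
            raise KeyError(f"prediction index {idx} has no class mapping")
        if target not in known:
            raise KeyError(f"target class {target!r} absent from taxonomy")
        pred = taxonomy.index_to_class[idx]
        correct.append(pred == target or pred in taxonomy.hyponyms(target))
    return float(np.mean(correct))


# --------------------------------------------------------------------------
# fine-tuning driver
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FinetuneConfig:
    """SGD settings for training a network above a frozen boundary layer."""

    freeze_boundary: str | None = None
    learning_rate: float = 0.001
    momentum: float = 0.7
    epochs: int = 5
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning rate must be nonnegative")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")


def _softmax_xent_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    z = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    n = len(y)
    loss = float(-np.log(p[np.arange(n), y] + 1e-12).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def finetune(
    network: TinyConvNet,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: FinetuneConfig = FinetuneConfig(),
) -> tuple[TinyConvNet, list[float]]:
    """Train the network past the freeze boundary; return it and the
    per-epoch validation accuracy trace.

    Parameters of layers at or before ``freeze_boundary`` are left
    bit-for-bit unchanged; the rest are updated by SGD with momentum.
    """
    train_x, train_y = train_set
    val_x, val_y = val_set
    train_x = np.asarray(train_x, dtype=float)
    val_x = np.asarray(val_x, dtype=float)
    train_y = np.asarray(train_y, dtype=int)
    val_y = np.asarray(val_y, dtype=int)
    if len(train_x) == 0:
        raise ValueError("empty training set")
    names = network.layer_names
    if config.freeze_boundary is not None and config.freeze_boundary not in names:
        raise ValueError(
            f"freeze boundary {config.freeze_boundary!r} not a layer; "
            f"available: {names}"
        )
    frozen: set[str] = set()
    if config.freeze_boundary is not None:
        for name in names:
            frozen.add(name)
            if name == config.freeze_boundary:
                break

    velocity = {
        name: {k: np.zeros_like(v) for k, v in layer.params.items()}
        for name, layer in network.layers
    }
    rng = np.random.default_rng(config.seed)
    trace: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(len(train_x))
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            logits, _ = network.forward(train_x[batch])
            _, dlogits = _softmax_xent_grad(logits, train_y[batch])
            network.backward(dlogits)
            for name, layer in network.layers:
                if name in frozen or not layer.params:
                    continue
                for key, param in layer.params.items():
                    v = velocity[name][key]
                    v *= config.momentum
                    v -= config.learning_rate * layer.grads[key]
                    param += v
        trace.append(float(np.mean(network.predict(val_x) == val_y)))
    return network, trace
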