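"""Synthetic stimuli, activations, choices and outcomes with planted truth.

The activation model is a latent-variable stand-in for a layered network
responding to the same objects rendered at several levels of abstraction
(photo, drawing, sketch).  Each object has a shared latent ``z_o`` (its
depiction-invariant identity) and one idiosyncratic latent ``u_{o,d}``
per depiction; a layer with shared-fraction ``alpha`` responds to

    alpha * z_o + sqrt(1 - alpha**2) * u_{o,d}

passed through one random linear map per layer (shared across depictions,
mirroring shared network weights) plus isotropic Gaussian noise.  Because
the idiosyncratic latents are independent across depictions, ``alpha``
alone controls how similar a layer's representational geometry is across
depictions: the expected cross-depiction RDM correlation increases from 0
(alpha = 0) to 1 (alpha = 1, no noise).  A manmade/natural class
direction of strength ``class_signal`` is added in latent space, to the
shared latent by default, so decodability transfers across depictions
exactly when the class code rides on the shared latent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import ActivationSet, MultiLayerActivationSet
from .stats import PairedOutcomeTable
from .behavior import TripletDataset

DEFAULT_LAYERS = {
    "layer1": 128,
    "layer2": 128,
    "layer3": 128,
    "layer4": 128,
    "layer5": 128,
}
DEFAULT_SHARED_FRACTION = (0.3, 0.6, 0.9, 0.6, 0.3)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-latent activation model.

    The stimulus-design constants default to the study design emulated
    here: 42 objects (21 manmade, 21 natural), each rendered as a photo,
    a drawing and a sketch.  ``shared_fraction`` is the per-layer weight
    alpha of the object's shared latent; its default rises then falls
    across five layers, planting the intermediate-layer peak in
    cross-depiction similarity.
    """

    n_objects: int = 42
    n_manmade: int = 21
    depictions: tuple[str, ...] = ("photo", "drawing", "sketch")
    layers: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_LAYERS))
    shared_fraction: tuple[float, ...] = DEFAULT_SHARED_FRACTION
    latent_dim: int = 12
    noise_sd: float = 0.1
    class_signal: float = 1.0
    class_in: str = "shared"  # "shared" or "idiosyncratic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_manmade > self.n_objects:
            raise ValueError("n_manmade cannot exceed n_objects")
        if self.n_objects < 2 or self.latent_dim < 2:
            raise ValueError("n_objects and latent_dim must be at least 2")
        if len(self.depictions) < 1:
            raise ValueError("need at least one depiction type")
        if len(self.shared_fraction) != len(self.layers):
            raise ValueError(
                "shared_fraction must give one alpha per layer "
                f"({len(self.shared_fraction)} != {len(self.layers)})"
            )
        for alpha in self.shared_fraction:
            if not 0.0 <= alpha <= 1.0:
                raise ValueError(f"shared fraction {alpha} outside [0, 1]")
        for name, dim in self.layers.items():
            if dim < 2:
                raise ValueError(f"layer {name!r} dimensionality must be >= 2")
        if self.noise_sd < 0 or self.class_signal < 0:
            raise ValueError("noise_sd and class_signal must be nonnegative")
        if self.class_in not in ("shared", "idiosyncratic"):
            raise ValueError("class_in must be 'shared' or 'idiosyncratic'")

    @property
    def object_ids(self) -> list[str]:
        width = len(str(self.n_objects))
        return [f"obj{i + 1:0{width}d}" for i in range(self.n_objects)]

    @property
    def superordinates(self) -> list[str]:
        return ["manmade"] * self.n_manmade + ["natural"] * (
            self.n_objects - self.n_manmade
        )

    def metadata(self) -> pd.DataFrame:
        rows = [
            {"object_id": o, "depiction": d, "superordinate": s}
            for o, s in zip(self.object_ids, self.superordinates)
            for d in self.depictions
        ]
        return pd.DataFrame(rows)


@dataclass
class GroundTruthSimilarity:
    """Planted symmetric similarity matrix with unit diagonal."""

    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("similarity shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("similarity diagonal must be 1")


def _draw_latents(config: SyntheticConfig, rng: np.random.Generator):
    """Shared and idiosyncratic latents with the class direction injected."""
    z = rng.standard_normal((config.n_objects, config.latent_dim))
    u = rng.standard_normal(
        (config.n_objects, len(config.depictions), config.latent_dim)
    )
    signs = np.where(np.array(config.superordinates) == "manmade", 1.0, -1.0)
    if config.class_in == "shared":
        direction = rng.standard_normal(config.latent_dim)
        direction /= np.linalg.norm(direction)
        z = z + config.class_signal * signs[:, None] * direction[None, :]
    else:
        # mutually orthogonal class directions, one per depiction, so the
        # class code cannot transfer across depictions by construction
        n_dep = len(config.depictions)
        if config.latent_dim < n_dep:
            raise ValueError(
                "idiosyncratic class code needs latent_dim >= number of depictions"
            )
        q, _ = np.linalg.qr(rng.standard_normal((config.latent_dim, n_dep)))
        for d in range(n_dep):
            u[:, d, :] += config.class_signal * signs[:, None] * q[:, d][None, :]
    return z, u


def generate_activations(config: SyntheticConfig) -> MultiLayerActivationSet:
    """Layerwise activations under the planted shared-latent model.

    Deterministic given ``config.seed``; row order is object-major
    (object 1 photo, object 1 drawing, ..., object n sketch) and is
    identical across layers.
    """
    rng = np.random.default_rng(config.seed)
    z, u = _draw_latents(config, rng)
    meta = config.metadata()
    n_dep = len(config.depictions)
    layers: dict[str, ActivationSet] = {}
    for (name, n_features), alpha in zip(config.layers.items(), config.shared_fraction):
        w = rng.standard_normal((config.latent_dim, n_features)) / np.sqrt(
            config.latent_dim
        )
        latent = alpha * z[:, None, :] + np.sqrt(1.0 - alpha**2) * u
        rows = latent.reshape(config.n_objects * n_dep, config.latent_dim) @ w
        rows = rows + config.noise_sd * rng.standard_normal(rows.shape)
        layers[name] = ActivationSet(rows, meta)
    return MultiLayerActivationSet(layers)


def planted_similarity(config: SyntheticConfig) -> GroundTruthSimilarity:
    """Object-by-object similarity implied by the shared latents.

    Pearson correlation of the shared latents ``z_o`` — the
    depiction-invariant part of the planted representation — rescaled
    from [-1, 1] to [0, 1] so it can serve as a choice-model similarity.
    """
    rng = np.random.default_rng(config.seed)
    z, _ = _draw_latents(config, rng)
    r = np.corrcoef(z)
    sim = (r + 1.0) / 2.0
    np.fill_diagonal(sim, 1.0)
    return GroundTruthSimilarity(config.object_ids, sim)


# --------------------------------------------------------------------------
# triplet choice simulator
# --------------------------------------------------------------------------

def generate_triplet_trials(
    similarity: GroundTruthSimilarity,
    mode: str = "exhaustive",
    n_trials: int | None = None,
    choice_model: str = "deterministic",
    temperature: float = 0.1,
    seed: int = 0,
) -> TripletDataset:
    """Simulate odd-one-out choices from a known similarity matrix.

    ``mode='exhaustive'`` enumerates every unordered triple once;
    ``mode='sampled'`` draws ``n_trials`` random triples with replacement.
    The deterministic choice model picks the object whose summed
    similarity to the other two is smallest (ties broken uniformly under
    the seed); the softmax model samples each object with probability
    proportional to ``exp(-(summed similarity)/temperature)``.
    """
    labels = list(similarity.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 objects for triplet trials")
    if choice_model not in ("deterministic", "softmax"):
        raise ValueError(f"unknown choice model {choice_model!r}")
    rng = np.random.default_rng(seed)
    sim = similarity.values

    if mode == "exhaustive":
        triples = list(combinations(range(n), 3))
    elif mode == "sampled":
        if not n_trials or n_trials < 1:
            raise ValueError("sampled mode requires a positive n_trials")
        triples = [
            tuple(rng.choice(n, size=3, replace=False)) for _ in range(n_trials)
        ]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rows = []
    for i, j, k in triples:
        idx = np.array([i, j, k])
        # odd-one-out score: similarity of each member to the other two
        scores = np.array(
            [sim[i, j] + sim[i, k], sim[j, i] + sim[j, k], sim[k, i] + sim[k, j]]
        )
        if choice_model == "deterministic":
            minima = np.flatnonzero(np.isclose(scores, scores.min()))
            chosen = idx[rng.choice(minima)]
        else:
            logits = -scores / temperature
            p = np.exp(logits - logits.max())
            p /= p.sum()
            chosen = idx[rng.choice(3, p=p)]
        rows.append(
            {
                "object_a": labels[i],
                "object_b": labels[j],
                "object_c": labels[k],
                "chosen": labels[chosen],
            }
        )
    return TripletDataset(pd.DataFrame(rows))


# --------------------------------------------------------------------------
# paired binary outcomes
# --------------------------------------------------------------------------

def generate_paired_outcomes(
    n_items: int,
    p_a: float,
    p_b: float,
    concordance: float | str = "independent",
    seed: int = 0,
) -> PairedOutcomeTable:
    """Paired correct/incorrect outcomes with stated marginals and dependence.

    ``concordance`` is the probability that the two conditions agree on
    an item (both correct or both incorrect); the strings
    ``'independent'`` and ``'maximal'`` select the corresponding joint
    distributions.  An infeasible concordance raises an error stating the
    feasible range implied by the marginals.
    """
    if not (0 <= p_a <= 1 and 0 <= p_b <= 1):
        raise ValueError("marginal probabilities must lie in [0, 1]")
    a_min = max(0.0, p_a + p_b - 1.0)
    a_max = min(p_a, p_b)
    if concordance == "independent":
        p11 = p_a * p_b
    elif concordance == "maximal":
        p11 = a_max
    else:
        g = float(concordance)
        g_min = 1.0 - p_a - p_b + 2.0 * a_min
        g_max = 1.0 - p_a - p_b + 2.0 * a_max
        if not g_min - 1e-12 <= g <= g_max + 1e-12:
            raise ValueError(
                f"concordance {g} infeasible for marginals p_a={p_a}, "
                f"p_b={p_b}; feasible range is [{g_min:.4f}, {g_max:.4f}]"
            )
        p11 = (g - 1.0 + p_a + p_b) / 2.0
    p10 = p_a - p11
    p01 = p_b - p11
    p00 = 1.0 - p11 - p10 - p01
    probs = np.clip([p11, p10, p01, p00], 0.0, 1.0)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    cells = rng.choice(4, size=n_items, p=probs)
    a = np.isin(cells, (0, 1)).astype(int)
    b = np.isin(cells, (0, 2)).astype(int)
    return PairedOutcomeTable(a, b)


# --------------------------------------------------------------------------
# synthetic images: textured fill vs. contour rendering of one polygon
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageConfig:
    """Settings for the synthetic photo-like / drawing-like image pairs."""

    n_objects: int = 8
    canvas: int = 64
    background: int = 128
    n_vertices: int = 7
    line_width: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_objects < 2:
            raise ValueError("need at least 2 objects")
        if self.canvas < 16:
            raise ValueError("canvas too small to render polygons")


@dataclass
class SyntheticImageSet:
    """Per object, a filled textured variant and a contour-only variant."""

    images: dict[str, dict[str, np.ndarray]]  # object_id -> variant -> HxWx3 uint8
    vertices: dict[str, np.ndarray]
    metadata: pd.DataFrame
    config: ImageConfig

    def image_list(self) -> tuple[list[np.ndarray], list[str]]:
        """Flat image list plus ``object:variant`` labels, metadata order."""
        ims, labels = [], []
        for _, row in self.metadata.iterrows():
            ims.append(self.images[row["object_id"]][row["depiction"]])
            labels.append(f"{row['object_id']}:{row['depiction']}")
        return ims, labels

    def save(self, directory: str | Path) -> None:
        from PIL import Image

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for obj, variants in self.images.items():
            for variant, arr in variants.items():
                Image.fromarray(arr).save(directory / f"{obj}_{variant}.png")
        self.metadata.to_csv(directory / "metadata.csv", index=False)


def _random_polygon(
    rng: np.random.Generator, canvas: int, n_vertices: int
) -> np.ndarray:
    """Star-convex polygon: sorted angles with jittered radii."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(0.25, 0.45, n_vertices) * canvas
    cx = cy = canvas / 2
    xs = cx + radii * np.cos(angles)
    ys = cy + radii * np.sin(angles)
    return np.column_stack([xs, ys])


def generate_images(config: ImageConfig = ImageConfig()) -> SyntheticImageSet:
    """Render each object as a textured filled shape and as its contour.

    The two variants of one object share their polygon vertices exactly;
    the filled ("photo-like") variant carries per-pixel texture noise
    inside the shape, the contour ("drawing-like") variant only a thin
    outline on the same gray background.  Deterministic given the seed.
    """
    from PIL import Image, ImageDraw

    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_objects))
    images: dict[str, dict[str, np.ndarray]] = {}
    vertices: dict[str, np.ndarray] = {}
    meta_rows = []
    bg = config.background
    half = (config.n_objects + 1) // 2
    for i in range(config.n_objects):
        obj = f"img{i + 1:0{width}d}"
        poly = _random_polygon(rng, config.canvas, config.n_vertices)
        pts = [tuple(p) for p in poly]

        base = int(rng.integers(30, 100)) if i % 2 else int(rng.integers(160, 230))
        fill_im = Image.new("RGB", (config.canvas, config.canvas), (bg,) * 3)
        ImageDraw.Draw(fill_im).polygon(pts, fill=(base,) * 3)
        fill = np.array(fill_im).astype(int)
        mask = np.any(fill != bg, axis=2)
        texture = rng.integers(-25, 26, size=(config.canvas, config.canvas, 1))
        fill = np.where(mask[:, :, None], np.clip(fill + texture, 0, 255), fill)

        contour_im = Image.new("RGB", (config.canvas, config.canvas), (bg,) * 3)
        ImageDraw.Draw(contour_im).line(
            pts + [pts[0]], fill=(0, 0, 0), width=config.line_width
        )
        images[obj] = {
            "textured": fill.astype(np.uint8),
            "contour": np.array(contour_im),
        }
        vertices[obj] = poly
        sup = "manmade" if i < half else "natural"
        for variant in ("textured", "contour"):
            meta_rows.append(
                {"object_id": obj, "depiction": variant, "superordinate": sup}
            )
    return SyntheticImageSet(
        images, vertices, pd.DataFrame(meta_rows), config
    )
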