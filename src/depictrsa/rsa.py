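"""Comparison of representational geometries across depiction types and layers.

The core quantity is the Spearman rank correlation between the
lower-triangular parts of two label-aligned RDMs.  Computed per layer for
each depiction pair (photo-drawing, photo-sketch, drawing-sketch) this
yields a cross-depiction similarity profile over layers; super-RDMs are
embedded in the plane with metric multidimensional scaling for
visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.manifold import smacof

from .datasets import ActivationSet, MultiLayerActivationSet
from .rdm import RDM, compute_rdm, lower_triangle


def depiction_rdms(acts: ActivationSet) -> dict[str, RDM]:
    """Per-depiction RDMs for one layer, labeled by object id.

    Rows are ordered by object id within each depiction so the RDMs are
    label-aligned across depictions by construction.
    """
    out = {}
    for dep in acts.depictions:
        sub = acts.subset_depiction(dep)
        out[dep] = compute_rdm(sub.data, list(sub.metadata["object_id"]))
    return out


def rdm_spearman(a: RDM, b: RDM) -> float:
    """Spearman rank correlation of two RDMs' lower triangles.

    ``b`` is aligned to ``a``'s label order first; a label mismatch is an
    error (alignment is always by label, never by position).  Ties get
    average ranks.
    """
    b = b.align_to(a.labels)
    va = lower_triangle(a).values
    vb = lower_triangle(b).values
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("an RDM lower triangle is constant; Spearman undefined")
    rho, _ = sps.spearmanr(va, vb)
    return float(rho)


@dataclass
class CrossDepictionProfile:
    """Spearman rho per (layer, depiction pair), in configured layer order."""

    layer_names: list[str]
    pairs: list[tuple[str, str]]
    rho: pd.DataFrame  # index = layer, columns = "dep1-dep2"

    def to_tidy(self) -> pd.DataFrame:
        tidy = self.rho.reset_index(names="layer").melt(
            id_vars="layer", var_name="pair", value_name="rho"
        )
        return tidy

    def argmax_layer(self, pair: str | tuple[str, str]) -> str:
        if isinstance(pair, tuple):
            pair = f"{pair[0]}-{pair[1]}"
        return str(self.rho[pair].idxmax())


def cross_depiction_profile(multi: MultiLayerActivationSet) -> CrossDepictionProfile:
    """All pairwise cross-depiction RDM correlations, per layer."""
    meta = multi.metadata
    depictions = list(dict.fromkeys(meta["depiction"]))
    pairs = list(combinations(depictions, 2))
    records = {}
    for layer in multi.layer_names:
        rdms = depiction_rdms(multi[layer])
        records[layer] = {
            f"{d1}-{d2}": rdm_spearman(rdms[d1], rdms[d2]) for d1, d2 in pairs
        }
    rho = pd.DataFrame.from_dict(records, orient="index").loc[multi.layer_names]
    rho.index.name = "layer"
    return CrossDepictionProfile(multi.layer_names, pairs, rho)


@dataclass
class MDSEmbedding:
    """2-D (or k-D) metric MDS solution for one RDM."""

    labels: list[str]
    coords: np.ndarray
    stress: float

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"dim{i + 1}" for i in range(self.coords.shape[1])]
        df = pd.DataFrame(self.coords, columns=cols)
        df.insert(0, "label", self.labels)
        return df


def mds_embed(
    rdm: RDM,
    dims: int = 2,
    seed: int = 0,
    n_restarts: int = 8,
    max_iter: int = 500,
) -> MDSEmbedding:
    """Metric MDS (raw stress) of an RDM, best of ``n_restarts`` inits.

    The embedding is only identified up to rotation/reflection/translation;
    compare recovered pairwise distances, not raw coordinates.
    """
    if not np.all(np.isfinite(rdm.values)):
        raise ValueError("RDM contains non-finite distances")
    # one run seeded by classical scaling (exact when the distances are
    # Euclidean-realizable in `dims`), plus random restarts
    candidates = []
    init = _classical_scaling(rdm.values, dims)
    for kwargs in (
        {"init": init, "n_init": 1},
        {"n_init": n_restarts, "random_state": int(seed)},
    ):
        coords, stress = smacof(
            rdm.values,
            metric=True,
            n_components=dims,
            max_iter=max_iter,
            eps=1e-12,
            normalized_stress=False,
            **kwargs,
        )
        candidates.append((stress, coords))
    stress, coords = min(candidates, key=lambda c: c[0])
    return MDSEmbedding(list(rdm.labels), coords, float(stress))


def _classical_scaling(d: np.ndarray, dims: int) -> np.ndarray:
    """Torgerson classical scaling of a distance matrix."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:dims]
    return v[:, idx] * np.sqrt(np.clip(w[idx], 0, None))


def embedding_distances(emb: MDSEmbedding) -> np.ndarray:
    """Pairwise Euclidean distances of the embedded points (square matrix)."""
    diff = emb.coords[:, None, :] - emb.coords[None, :, :]
    return np.sqrt((diff**2).sum(-1))
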