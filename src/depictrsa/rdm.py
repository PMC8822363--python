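"""Representational dissimilarity matrices (RDMs).

Dissimilarity between two stimuli is the correlation distance
``d(i, j) = 1 - Pearson r`` between their activation (or pixel) patterns,
so entries lie in [0, 2] with a zero diagonal.  All downstream comparisons
operate on the strictly-lower-triangular entries, extracted row-major
(row 1 col 0; row 2 cols 0,1; ...), never on the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import ActivationSet

_SYMMETRY_TOL = 1e-8


@dataclass
class RDM:
    """Labeled symmetric dissimilarity matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("RDM contains non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=_SYMMETRY_TOL):
            raise ValueError("RDM is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=_SYMMETRY_TOL):
            raise ValueError("RDM diagonal is not zero")
        # exact symmetry / zero diagonal after the tolerance check
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def align_to(self, labels: Sequence[str]) -> "RDM":
        """Reorder rows/columns to the given label order."""
        missing = set(labels) - set(self.labels)
        extra = set(self.labels) - set(labels)
        if missing or extra:
            raise ValueError(
                f"label mismatch: missing={sorted(missing)} extra={sorted(extra)}"
            )
        idx = [self.labels.index(l) for l in labels]
        return RDM(list(labels), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RDM":
        df = pd.read_csv(path, index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy())


@dataclass
class RDMVector:
    """Strict lower triangle of an RDM plus the label order that produced it."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.values) != n * (n - 1) // 2:
            raise ValueError("vector length does not match n(n-1)/2 for labels")


def compute_rdm(acts: ActivationSet | np.ndarray, labels: Sequence[str] | None = None) -> RDM:
    """Correlation-distance RDM (1 - Pearson r) over the rows of ``acts``.

    Raises if any row has zero variance (its correlation is undefined);
    the error names the offending stimulus rather than dropping it, so
    label alignment across depictions can never silently break.
    """
    if isinstance(acts, ActivationSet):
        data = acts.data
        if labels is None:
            labels = acts.stimulus_labels
    else:
        data = np.asarray(acts, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(data.shape[0])]
    if data.shape[0] < 3:
        raise ValueError("need at least 3 stimuli to build an RDM")
    sd = data.std(axis=1)
    if np.any(sd == 0):
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(
            f"zero-variance activation pattern(s) {bad}: correlation distance undefined"
        )
    r = np.corrcoef(data)
    values = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(values, 0.0)
    return RDM(list(labels), values)


def pixel_rdm(images: Sequence[np.ndarray], labels: Sequence[str] | None = None) -> RDM:
    """RDM over flattened (preprocessed) pixel arrays.

    All images must share one shape; each is flattened to a vector and
    the correlation-distance RDM is computed over those vectors.
    """
    arrays = [np.asarray(im, dtype=float) for im in images]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"images have mismatched shapes: {sorted(map(str, shapes))}")
    flat = np.stack([a.ravel() for a in arrays])
    if labels is None:
        labels = [f"image_{i}" for i in range(len(arrays))]
    return compute_rdm(flat, labels)


def super_rdm(multi, layer: str) -> RDM:
    """One RDM over all objects x all depiction types for one layer.

    Rows are grouped by depiction block (configured depiction order,
    objects sorted within block) and labeled ``object_id:depiction``;
    restricting the result to one depiction's block reproduces that
    depiction's own RDM exactly.
    """
    acts = multi[layer]
    depictions = acts.depictions
    if len(depictions) < 2:
        raise ValueError("super RDM needs at least two depiction types")
    blocks = [acts.subset_depiction(d) for d in depictions]
    data = np.vstack([b.data for b in blocks])
    labels = [l for b in blocks for l in b.stimulus_labels]
    return compute_rdm(data, labels)


def lower_triangle(rdm: RDM) -> RDMVector:
    """Strictly-below-diagonal entries, row-major by increasing row."""
    i, j = np.tril_indices(rdm.n, k=-1)
    return RDMVector(list(rdm.labels), rdm.values[i, j])


def squareform_from_lower(vec: RDMVector) -> RDM:
    """Rebuild the full symmetric RDM from a lower-triangle vector."""
    n = len(vec.labels)
    values = np.zeros((n, n))
    i, j = np.tril_indices(n, k=-1)
    values[i, j] = vec.values
    values[j, i] = vec.values
    return RDM(list(vec.labels), values)
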