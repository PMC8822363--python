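"""Containers for stimulus metadata and layerwise activation patterns.

An :class:`ActivationSet` holds one layer's stimuli x features matrix
together with an aligned metadata table (one row per stimulus: object
identity, depiction type, superordinate class).  A
:class:`MultiLayerActivationSet` is an ordered mapping of layer name to
ActivationSet sharing a single metadata table, mirroring how activation
patterns are extracted from several layers of one network for one stimulus
set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

METADATA_COLUMNS = ("object_id", "depiction", "superordinate")
SUPERORDINATES = ("manmade", "natural")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check a stimulus metadata table and return it with a clean index.

    Requires columns ``object_id``, ``depiction``, ``superordinate``;
    (object_id, depiction) pairs must be unique and every object must
    appear once per depiction type present in the table.
    """
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    meta = meta.reset_index(drop=True)
    dup = meta.duplicated(subset=["object_id", "depiction"])
    if dup.any():
        pairs = meta.loc[dup, ["object_id", "depiction"]].values.tolist()
        raise ValueError(f"duplicate (object_id, depiction) pairs: {pairs}")
    bad = set(meta["superordinate"]) - set(SUPERORDINATES)
    if bad:
        raise ValueError(f"unknown superordinate classes: {sorted(bad)}")
    counts = meta.groupby("object_id")["depiction"].nunique()
    n_dep = meta["depiction"].nunique()
    incomplete = counts[counts != n_dep]
    if len(incomplete):
        raise ValueError(
            "objects missing depictions: "
            f"{sorted(incomplete.index.tolist())}"
        )
    return meta


@dataclass
class ActivationSet:
    """One layer's stimuli x features activation matrix with metadata.

    Rows of ``data`` align one-to-one with rows of ``metadata``.
    """

    data: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("activation data must be 2-D (stimuli x features)")
        self.metadata = validate_metadata(self.metadata)
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError(
                f"metadata rows ({len(self.metadata)}) != activation rows "
                f"({self.data.shape[0]})"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("activation matrix contains non-finite entries")

    @property
    def n_stimuli(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def stimulus_labels(self) -> list[str]:
        """``object_id:depiction`` label per row."""
        return [
            f"{o}:{d}"
            for o, d in zip(self.metadata["object_id"], self.metadata["depiction"])
        ]

    def subset_depiction(self, depiction: str) -> "ActivationSet":
        """Rows of one depiction type, ordered by object_id."""
        mask = self.metadata["depiction"] == depiction
        if not mask.any():
            raise KeyError(f"no rows with depiction {depiction!r}")
        meta = self.metadata[mask]
        order = np.argsort(meta["object_id"].to_numpy(), kind="stable")
        idx = meta.index.to_numpy()[order]
        return ActivationSet(self.data[idx], self.metadata.iloc[idx])

    @property
    def depictions(self) -> list[str]:
        return list(dict.fromkeys(self.metadata["depiction"]))


@dataclass
class MultiLayerActivationSet:
    """Ordered layer name -> ActivationSet, all sharing one metadata table."""

    layers: dict[str, ActivationSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        metas = [a.metadata for a in self.layers.values()]
        for m in metas[1:]:
            if not m[list(METADATA_COLUMNS)].equals(metas[0][list(METADATA_COLUMNS)]):
                raise ValueError("layers disagree on stimulus metadata / row order")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def metadata(self) -> pd.DataFrame:
        if not self.layers:
            raise ValueError("empty MultiLayerActivationSet")
        return next(iter(self.layers.values())).metadata

    def __getitem__(self, layer: str) -> ActivationSet:
        return self.layers[layer]

    def __iter__(self) -> Iterator[str]:
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    # -- serialization: npz array container + sidecar metadata CSV ---------

    def save(self, path: str | Path) -> None:
        """Write ``<path>.npz`` (one array per layer) and ``<path>.meta.csv``."""
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            **{name: acts.data for name, acts in self.layers.items()},
        )
        self.metadata[list(METADATA_COLUMNS)].to_csv(
            path.with_suffix(".meta.csv"), index=False
        )

    @classmethod
    def load(cls, path: str | Path) -> "MultiLayerActivationSet":
        path = Path(path)
        meta = pd.read_csv(path.with_suffix(".meta.csv"), dtype=str)
        with np.load(path.with_suffix(".npz")) as npz:
            layers = {
                name: ActivationSet(npz[name], meta) for name in npz.files
            }
        return cls(layers)
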