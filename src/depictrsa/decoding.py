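"""Leave-N-out linear-SVM decoding of superordinate category.

Each iteration draws N test stimuli uniformly without replacement, trains
a linear support vector machine (cost fixed, default 1, no feature
scaling) on the remaining patterns, and scores accuracy on the held-out
sample; the mean and standard error over iterations summarize the layer.
Cross-domain decoding trains on one depiction type and tests the same
held-out *object ids* in another depiction, so object identity never
leaks between training and test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .datasets import ActivationSet


@dataclass(frozen=True)
class DecodeConfig:
    """Cross-validation settings for the SVM decoding analyses."""

    n_test: int = 6
    n_iter: int = 1000
    cost: float = 1.0
    seed: int = 0
    scale_features: bool = False
    max_redraws: int = 1000

    def __post_init__(self) -> None:
        if self.n_test < 1 or self.n_iter < 1:
            raise ValueError("n_test and n_iter must be positive")
        if self.cost <= 0:
            raise ValueError("SVM cost must be positive")

    def with_seed(self, seed: int) -> "DecodeConfig":
        return replace(self, seed=seed)


@dataclass
class DecodingResult:
    """Mean accuracy, its standard error, and the per-iteration accuracies."""

    mean_accuracy: float
    standard_error: float
    per_iteration: np.ndarray
    config: DecodeConfig
    n_redraws: int = 0

    def summary(self) -> str:
        return (
            f"decoding accuracy {self.mean_accuracy:.3f} "
            f"+/- {self.standard_error:.3f} SE "
            f"({self.config.n_iter} iterations, n_test={self.config.n_test})"
        )


def _as_matrix_and_labels(
    acts: ActivationSet | np.ndarray, labels: Sequence | None
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(acts, ActivationSet):
        data = acts.data
        if labels is None:
            labels = acts.metadata["superordinate"].to_numpy()
    else:
        data = np.asarray(acts, dtype=float)
    if labels is None:
        raise ValueError("labels required for a bare activation matrix")
    labels = np.asarray(labels)
    if len(labels) != data.shape[0]:
        raise ValueError("labels do not match number of stimuli")
    return data, labels


def _fit_and_score(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    test_y: np.ndarray,
    cfg: DecodeConfig,
) -> float:
    if cfg.scale_features:
        mu = train_x.mean(axis=0)
        sd = train_x.std(axis=0)
        sd[sd == 0] = 1.0
        train_x = (train_x - mu) / sd
        test_x = (test_x - mu) / sd
    clf = SVC(kernel="linear", C=cfg.cost)
    clf.fit(train_x, train_y)
    return float(np.mean(clf.predict(test_x) == test_y))


def _draw_split(
    rng: np.random.Generator, n: int, labels: np.ndarray, cfg: DecodeConfig
) -> tuple[np.ndarray, np.ndarray, int]:
    """Draw a test index set whose complement still contains both classes.

    A draw leaving the training fold single-class is rejected and redrawn
    (the count of redraws is reported); a single-class *test* fold is
    allowed and scored as-is, since accuracy stays well-defined.
    """
    redraws = 0
    while True:
        test_idx = rng.choice(n, size=cfg.n_test, replace=False)
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        if len(np.unique(labels[train_mask])) >= 2:
            return test_idx, np.flatnonzero(train_mask), redraws
        redraws += 1
        if redraws > cfg.max_redraws:
            raise RuntimeError(
                "could not draw a training fold containing both classes"
            )


def cv_decode(
    acts: ActivationSet | np.ndarray,
    labels: Sequence | None = None,
    config: DecodeConfig = DecodeConfig(),
) -> DecodingResult:
    """Leave-N-out cross-validated decoding within one stimulus set."""
    data, labels = _as_matrix_and_labels(acts, labels)
    n = data.shape[0]
    if config.n_test >= n:
        raise ValueError("n_test must be smaller than the number of stimuli")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(config.seed)
    accs = np.empty(config.n_iter)
    total_redraws = 0
    for it in range(config.n_iter):
        test_idx, train_idx, redraws = _draw_split(rng, n, labels, config)
        total_redraws += redraws
        accs[it] = _fit_and_score(
            data[train_idx], labels[train_idx], data[test_idx], labels[test_idx], config
        )
    se = float(accs.std(ddof=1) / np.sqrt(config.n_iter)) if config.n_iter > 1 else 0.0
    return DecodingResult(float(accs.mean()), se, accs, config, total_redraws)


def cross_decode(
    train_acts: ActivationSet,
    test_acts: ActivationSet,
    labels: Sequence | None = None,
    config: DecodeConfig = DecodeConfig(),
) -> DecodingResult:
    """Cross-domain decoding: train on one depiction, test on another.

    Per iteration the held-out *object ids* are removed from the training
    depiction and scored in the testing depiction, so the same objects are
    never seen in both roles.  ``cross_decode(A, A)`` reproduces
    ``cv_decode(A)`` exactly under the same seed.
    """
    train_ids = list(train_acts.metadata["object_id"])
    test_ids = list(test_acts.metadata["object_id"])
    if set(train_ids) != set(test_ids):
        raise ValueError(
            "train and test sets must share object ids; difference: "
            f"{sorted(set(train_ids) ^ set(test_ids))}"
        )
    # align test rows to the training object order
    test_pos = {o: k for k, o in enumerate(test_ids)}
    order = np.array([test_pos[o] for o in train_ids])
    test_data = test_acts.data[order]
    train_data = train_acts.data

    if labels is None:
        labels = train_acts.metadata["superordinate"].to_numpy()
    labels = np.asarray(labels)
    n = train_data.shape[0]
    if config.n_test >= n:
        raise ValueError("n_test must be smaller than the number of objects")
    rng = np.random.default_rng(config.seed)
    accs = np.empty(config.n_iter)
    total_redraws = 0
    for it in range(config.n_iter):
        test_idx, train_idx, redraws = _draw_split(rng, n, labels, config)
        total_redraws += redraws
        accs[it] = _fit_and_score(
            train_data[train_idx],
            labels[train_idx],
            test_data[test_idx],
            labels[test_idx],
            config,
        )
    se = float(accs.std(ddof=1) / np.sqrt(config.n_iter)) if config.n_iter > 1 else 0.0
    return DecodingResult(float(accs.mean()), se, accs, config, total_redraws)
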