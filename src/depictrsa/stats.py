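"""Randomization inference for RDM correlations, decoding and accuracies.

All permutation tests share one p-value convention: with ``n_perm`` null
draws, ``p = (1 + #{null >= observed}) / (1 + n_perm)``.  The add-one
count keeps the test valid (the observed statistic is counted as one
realization of the null) and makes p strictly positive, with minimum
``1/(n_perm + 1)``.

RDM nulls always permute object labels, i.e. rows and columns jointly,
never individual cells: a label permutation preserves the geometry of the
dissimilarity matrix while breaking its correspondence with the reference
RDM, which is exactly the exchangeability the Mantel test requires.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.weightstats import ttost_paired

from .rdm import RDM, lower_triangle

__all__ = [
    "PermutationResult",
    "PairedOutcomeTable",
    "one_sided_p",
    "mantel_test",
    "rdm_correlation_difference_test",
    "correlation_pair_difference_test",
    "across_layer_variation_test",
    "sign_permutation_test",
    "mcnemar_test",
    "tost_equivalence",
    "independent_t_test",
    "bh_fdr",
    "decoding_permutation_null",
]


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null sample, and the one-sided p."""

    observed: float
    null_sample: np.ndarray
    p: float
    n_perm: int
    seed: int
    name: str = ""
    family: str = ""

    def to_record(self) -> dict:
        return {
            "name": self.name,
            "family": self.family,
            "statistic": float(self.observed),
            "p": float(self.p),
            "n_perm": int(self.n_perm),
            "seed": int(self.seed),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_record(), indent=2))


@dataclass
class PairedOutcomeTable:
    """Per-item binary outcomes under two conditions (e.g. two networks)."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=int)
        self.b = np.asarray(self.b, dtype=int)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("outcomes must be two equal-length 1-D vectors")
        for v in (self.a, self.b):
            if not np.isin(v, (0, 1)).all():
                raise ValueError("outcomes must be binary (0/1)")

    @property
    def discordant(self) -> tuple[int, int]:
        """(#{a correct, b incorrect}, #{a incorrect, b correct})."""
        b10 = int(np.sum((self.a == 1) & (self.b == 0)))
        b01 = int(np.sum((self.a == 0) & (self.b == 1)))
        return b10, b01


def one_sided_p(null_sample: Sequence[float], observed: float) -> float:
    """Add-one one-sided p: fraction of null values reaching the observed."""
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size == 0:
        raise ValueError("empty null sample")
    return float((1 + np.sum(null_sample >= observed)) / (1 + null_sample.size))


# --------------------------------------------------------------------------
# vectorized Spearman over permuted lower triangles
# --------------------------------------------------------------------------

def _ranks(x: np.ndarray, axis: int = -1) -> np.ndarray:
    return sps.rankdata(x, axis=axis)


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between matching rows of two (k, m) arrays."""
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    num = np.sum(a * b, axis=-1)
    den = np.sqrt(np.sum(a * a, axis=-1) * np.sum(b * b, axis=-1))
    return num / den


def _spearman_vec(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman rho between rows (broadcast over leading axes)."""
    return _rowwise_pearson(_ranks(a), _ranks(b))


def _permuted_lower(values: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Lower-triangle vectors of values[p][:, p] for each permutation p."""
    n = values.shape[0]
    i, j = np.tril_indices(n, k=-1)
    return values[perms[:, i], perms[:, j]]


def _draw_perms(rng: np.random.Generator, n: int, n_perm: int) -> np.ndarray:
    return np.stack([rng.permutation(n) for _ in range(n_perm)])


def _aligned_values(a: RDM, b: RDM) -> tuple[np.ndarray, np.ndarray]:
    b = b.align_to(a.labels)
    return a.values, b.values


# --------------------------------------------------------------------------
# RDM permutation tests
# --------------------------------------------------------------------------

def mantel_test(a: RDM, b: RDM, n_perm: int = 1000, seed: int = 0) -> PermutationResult:
    """Mantel test for the Spearman correlation between two RDMs.

    The null shuffles object labels of ``b`` (rows and columns jointly)
    and recomputes the lower-triangle Spearman correlation with ``a``.
    """
    if a.n < 4:
        raise ValueError("Mantel test needs at least 4 objects")
    av, bv = _aligned_values(a, b)
    i, j = np.tril_indices(a.n, k=-1)
    a_vec = av[i, j]
    b_vec = bv[i, j]
    observed = float(_spearman_vec(a_vec, b_vec))
    rng = np.random.default_rng(seed)
    perms = _draw_perms(rng, a.n, n_perm)
    null = _spearman_vec(a_vec[None, :], _permuted_lower(bv, perms))
    p = one_sided_p(null, observed)
    return PermutationResult(observed, null, p, n_perm, seed, name="mantel")


def mantel_exact(a: RDM, b: RDM) -> tuple[float, float]:
    """Exhaustive Mantel p over all n! label permutations (tiny n only).

    Returns (observed rho, exact p) with the same reach-or-exceed counting
    rule, including the identity permutation in the reference set.
    """
    from itertools import permutations as iperm

    if a.n > 7:
        raise ValueError("exhaustive enumeration is limited to n <= 7")
    av, bv = _aligned_values(a, b)
    i, j = np.tril_indices(a.n, k=-1)
    a_vec = av[i, j]
    observed = float(_spearman_vec(a_vec, bv[i, j]))
    perms = np.array(list(iperm(range(a.n))))
    null = _spearman_vec(a_vec[None, :], _permuted_lower(bv, perms))
    p = float(np.mean(null >= observed - 1e-12))
    return observed, p


def rdm_correlation_difference_test(
    shared: RDM, x: RDM, y: RDM, n_perm: int = 1000, seed: int = 0
) -> PermutationResult:
    """Test rho(shared, x) > rho(shared, y) by permuting the shared RDM.

    The null permutes object labels of ``shared``, recomputes both
    correlations under the same permutation, and takes their difference.
    """
    xv = x.align_to(shared.labels)
    yv = y.align_to(shared.labels)
    i, j = np.tril_indices(shared.n, k=-1)
    x_vec, y_vec = xv.values[i, j], yv.values[i, j]
    s_vec = shared.values[i, j]
    observed = float(_spearman_vec(s_vec, x_vec) - _spearman_vec(s_vec, y_vec))
    rng = np.random.default_rng(seed)
    perms = _draw_perms(rng, shared.n, n_perm)
    s_perm = _permuted_lower(shared.values, perms)
    null = _spearman_vec(s_perm, x_vec[None, :]) - _spearman_vec(s_perm, y_vec[None, :])
    p = one_sided_p(null, observed)
    return PermutationResult(observed, null, p, n_perm, seed, name="rdm_corr_diff")


def correlation_pair_difference_test(
    a1: RDM, b1: RDM, a2: RDM, b2: RDM, n_perm: int = 1000, seed: int = 0
) -> PermutationResult:
    """Test rho(a1, b1) > rho(a2, b2) for two independent RDM pairs.

    Used to compare the same depiction-pair correlation between two runs
    (e.g. two networks).  The null applies one object-label permutation
    per draw to the second member of each correlation (same permutation
    for both, as the object set is shared) and recomputes the difference.
    """
    labels = a1.labels
    mats = [a1.values]
    for r in (b1, a2, b2):
        mats.append(r.align_to(labels).values)
    a1v, b1v, a2v, b2v = mats
    n = len(labels)
    i, j = np.tril_indices(n, k=-1)
    vecs = [m[i, j] for m in (a1v, b1v, a2v, b2v)]
    observed = float(
        _spearman_vec(vecs[0], vecs[1]) - _spearman_vec(vecs[2], vecs[3])
    )
    rng = np.random.default_rng(seed)
    perms = _draw_perms(rng, n, n_perm)
    b1p = _permuted_lower(b1v, perms)
    b2p = _permuted_lower(b2v, perms)
    null = _spearman_vec(vecs[0][None, :], b1p) - _spearman_vec(vecs[2][None, :], b2p)
    p = one_sided_p(null, observed)
    return PermutationResult(observed, null, p, n_perm, seed, name="pair_corr_diff")


def across_layer_variation_test(
    rdm_pairs: Sequence[tuple[RDM, RDM]], n_perm: int = 1000, seed: int = 0
) -> PermutationResult:
    """Test whether one depiction-pair's RDM correlation varies across layers.

    ``rdm_pairs`` holds, per layer, the two per-depiction RDMs whose
    correlation forms that layer's point of the profile.  The statistic is
    the sum of squared deviations of the per-layer correlations from their
    mean.  The null draws one object-label permutation per depiction —
    the same permutation across layers, independent between the two
    depictions — and recomputes the statistic.
    """
    if len(rdm_pairs) < 2:
        raise ValueError("need at least 2 layers")
    labels = rdm_pairs[0][0].labels
    n = len(labels)
    i, j = np.tril_indices(n, k=-1)
    a_mats = [p[0].align_to(labels).values for p in rdm_pairs]
    b_mats = [p[1].align_to(labels).values for p in rdm_pairs]
    rhos = np.array(
        [float(_spearman_vec(a[i, j], b[i, j])) for a, b in zip(a_mats, b_mats)]
    )
    observed = float(np.sum((rhos - rhos.mean()) ** 2))
    rng = np.random.default_rng(seed)
    perms_a = _draw_perms(rng, n, n_perm)
    perms_b = _draw_perms(rng, n, n_perm)
    null_rhos = np.empty((n_perm, len(rdm_pairs)))
    for l, (a, b) in enumerate(zip(a_mats, b_mats)):
        null_rhos[:, l] = _spearman_vec(
            _permuted_lower(a, perms_a), _permuted_lower(b, perms_b)
        )
    null = np.sum((null_rhos - null_rhos.mean(axis=1, keepdims=True)) ** 2, axis=1)
    p = one_sided_p(null, observed)
    return PermutationResult(observed, null, p, n_perm, seed, name="layer_variation")


# --------------------------------------------------------------------------
# accuracy-level tests
# --------------------------------------------------------------------------

def sign_permutation_test(
    per_object_acc: Sequence[float],
    cnn_acc: float,
    n_perm: int = 1000,
    seed: int = 0,
    flip: str = "accuracies",
) -> PermutationResult:
    """Sign-permutation test comparing mean per-object human accuracy to a CNN.

    observed = mean(human per-object accuracies) - cnn_acc.  The null
    flips the sign of each object's accuracy independently with
    probability 1/2 before averaging and subtracting ``cnn_acc``
    (``flip='accuracies'``, the literal construction).  With
    ``flip='differences'`` the signs of the per-object human-minus-CNN
    differences are flipped instead — the conventional paired variant.
    """
    acc = np.asarray(per_object_acc, dtype=float)
    if acc.size == 0:
        raise ValueError("empty accuracy vector")
    if flip not in ("accuracies", "differences"):
        raise ValueError(f"unknown flip mode {flip!r}")
    observed = float(acc.mean() - cnn_acc)
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, acc.size))
    if flip == "accuracies":
        null = (signs * acc).mean(axis=1) - cnn_acc
    else:
        null = (signs * (acc - cnn_acc)).mean(axis=1)
    p = one_sided_p(null, observed)
    return PermutationResult(observed, null, p, n_perm, seed, name="sign_permutation")


def mcnemar_test(
    outcomes: PairedOutcomeTable, correction: bool = False
) -> tuple[float, float]:
    """McNemar test of homogeneity on the discordant pair counts.

    chi2 = (b - c)^2 / (b + c) on the discordant counts, without
    continuity correction by default; p from chi-square with 1 df.
    """
    b, c = outcomes.discordant
    if b + c == 0:
        raise ValueError("no discordant pairs: McNemar test undefined")
    if correction:
        chi2 = (abs(b - c) - 1) ** 2 / (b + c) if abs(b - c) > 1 else 0.0
    else:
        chi2 = (b - c) ** 2 / (b + c)
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), p


def tost_equivalence(
    x: Sequence[float],
    y: Sequence[float],
    bounds: tuple[float, float],
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Two one-sided tests for equivalence of paired means within bounds.

    Returns ``(p, decision)`` where p is the larger of the two one-sided
    paired-t p-values and the decision is ``p < alpha``.  With zero
    variance of the differences the t statistics degenerate: p is 0 when
    the mean difference lies strictly inside the bounds and 1 otherwise.
    """
    low, high = bounds
    if not low < high:
        raise ValueError("equivalence bounds must satisfy low < high")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    if np.std(d, ddof=1) == 0:
        p = 0.0 if low < d.mean() < high else 1.0
        return p, p < alpha
    p, _, _ = ttost_paired(x, y, low, high)
    p = float(p)
    return p, p < alpha


def independent_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Two-sided independent two-sample t-test with pooled variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    df = len(x) + len(y) - 2
    res = sps.ttest_ind(x, y, equal_var=True)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # zero pooled variance
        if np.isclose(x.mean(), y.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = np.sign(x.mean() - y.mean()) * np.inf, 0.0
    return t, p, df


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)) or not np.all(np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(pvals, method="fdr_bh")
    return adjusted


def decoding_permutation_null(
    acts,
    labels: Sequence,
    decode_config,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation null for a cross-validated decoding accuracy.

    observed = mean cv_decode accuracy with the true labels; the null
    repeats the full cross-validated analysis with the labels randomly
    shuffled over stimuli.
    """
    from .decoding import cv_decode

    labels = np.asarray(labels)
    observed = float(cv_decode(acts, labels, decode_config).mean_accuracy)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        shuffled = labels[rng.permutation(len(labels))]
        cfg = decode_config.with_seed(int(rng.integers(2**31)))
        null[k] = cv_decode(acts, shuffled, cfg).mean_accuracy
    p = one_sided_p(null, observed)
    return PermutationResult(observed, null, p, n_perm, seed, name="decoding_null")
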