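"""Pairwise similarity from triplet odd-one-out choices, and label scoring.

In a triplet trial three objects are shown and the least-similar one is
chosen.  The similarity of a pair (x, y) is the probability the pair
"survives together": the fraction of trials containing both x and y in
which the third object was chosen as the odd-one-out.  This estimate is
context-free in the sense that it marginalizes over the identity of the
third object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .rdm import RDM

TRIAL_COLUMNS = ("object_a", "object_b", "object_c", "chosen")


@dataclass
class TripletDataset:
    """Trials of three distinct object ids plus the chosen odd-one-out."""

    trials: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(TRIAL_COLUMNS) - set(self.trials.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        t = self.trials
        trip = t[["object_a", "object_b", "object_c"]].to_numpy()
        if any(len(set(row)) != 3 for row in trip):
            raise ValueError("each trial must contain three distinct object ids")
        in_triplet = (trip == t["chosen"].to_numpy()[:, None]).any(axis=1)
        if not in_triplet.all():
            bad = t.index[~in_triplet].tolist()
            raise ValueError(f"chosen id not part of its triplet in trials {bad}")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def object_ids(self) -> list:
        trip = self.trials[["object_a", "object_b", "object_c"]].to_numpy()
        return sorted(set(trip.ravel()))

    def to_csv(self, path: str | Path) -> None:
        self.trials[list(TRIAL_COLUMNS)].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TripletDataset":
        return cls(pd.read_csv(path, dtype=str))


@dataclass
class PairwiseChoiceSimilarity:
    """P(pair kept together) per object pair, with co-occurrence counts.

    ``sim[i, j]`` is NaN for pairs that never co-occurred in a trial;
    such pairs are explicitly *undefined*, never silently zero.
    """

    labels: list
    sim: np.ndarray
    counts: np.ndarray

    @property
    def undefined_pairs(self) -> list[tuple]:
        i, j = np.tril_indices(len(self.labels), k=-1)
        mask = self.counts[i, j] == 0
        return [(self.labels[a], self.labels[b]) for a, b in zip(i[mask], j[mask])]

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame(self.sim, index=self.labels, columns=self.labels).to_csv(path)
        pd.DataFrame(self.counts, index=self.labels, columns=self.labels).to_csv(
            path.with_suffix(".counts.csv")
        )


def triplet_similarity(trials: TripletDataset) -> PairwiseChoiceSimilarity:
    """Estimate pairwise similarity from odd-one-out choices.

    sim(x, y) = #{trials containing x and y with the third object chosen}
              / #{trials containing x and y}.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    labels = trials.object_ids
    index = {o: k for k, o in enumerate(labels)}
    n = len(labels)
    together = np.zeros((n, n))
    counts = np.zeros((n, n))
    trip = trials.trials[["object_a", "object_b", "object_c"]].to_numpy()
    chosen = trials.trials["chosen"].to_numpy()
    for (a, b, c), ch in zip(trip, chosen):
        ia, ib, ic = index[a], index[b], index[c]
        for x, y in ((ia, ib), (ia, ic), (ib, ic)):
            counts[x, y] += 1
            counts[y, x] += 1
        survivors = [k for k in (ia, ib, ic) if k != index[ch]]
        x, y = survivors
        together[x, y] += 1
        together[y, x] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(counts > 0, together / np.maximum(counts, 1), np.nan)
    np.fill_diagonal(sim, 1.0)
    return PairwiseChoiceSimilarity(labels, sim, counts)


def choice_similarity_to_rdm(similarity: PairwiseChoiceSimilarity) -> RDM:
    """Behavioral RDM with d(x, y) = 1 - P(pair kept together)."""
    undefined = similarity.undefined_pairs
    if undefined:
        raise ValueError(
            f"{len(undefined)} object pair(s) never co-occurred and are "
            f"undefined: {undefined[:10]}"
        )
    values = 1.0 - similarity.sim
    np.fill_diagonal(values, 0.0)
    return RDM([str(l) for l in similarity.labels], values)


def label_accuracy(
    responses: pd.DataFrame,
    answer_key: dict[str, str],
    synonyms: dict[str, Sequence[str]] | None = None,
) -> tuple[pd.Series, float]:
    """Score free-text labels against an answer key with synonym sets.

    ``responses`` has columns ``object_id`` and ``response``; a response
    is correct when it matches the key label or any synonym for that
    object, case-insensitively after stripping whitespace.  Returns
    per-object accuracy (fraction of correct responses) and the mean over
    objects.
    """
    required = {"object_id", "response"}
    if not required <= set(responses.columns):
        raise ValueError(f"responses must have columns {sorted(required)}")
    synonyms = synonyms or {}
    unknown = set(responses["object_id"]) - set(answer_key)
    if unknown:
        raise KeyError(f"objects missing from answer key: {sorted(unknown)}")

    def norm(s: str) -> str:
        return str(s).strip().lower()

    accepted = {
        obj: {norm(answer_key[obj]), *map(norm, synonyms.get(obj, ()))}
        for obj in answer_key
    }
    correct = [
        norm(resp) in accepted[obj]
        for obj, resp in zip(responses["object_id"], responses["response"])
    ]
    scored = responses.assign(correct=correct)
    per_object = scored.groupby("object_id")["correct"].mean()
    return per_object, float(per_object.mean())


def load_synonyms(path: str | Path) -> dict[str, list[str]]:
    """Read a synonym key TSV with columns object_id, synonym."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"object_id", "synonym"} <= set(df.columns):
        raise ValueError("synonym TSV needs columns object_id, synonym")
    return {o: g["synonym"].tolist() for o, g in df.groupby("object_id")}
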