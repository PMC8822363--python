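"""Config-driven orchestration of the full analysis graph.

``run_experiment1`` executes, on synthetic (or file-supplied) activations:
per-layer per-depiction RDMs -> cross-depiction Spearman profile ->
Mantel and across-layer variation tests -> super-RDM MDS embeddings ->
intra- and cross-depiction SVM decoding -> triplet-choice simulation and
behavioral-RDM fit; results are written as tidy CSVs, JSON test records
and PNG figures, all reproducible from one global seed.

Seeding: stage k uses ``numpy.random.SeedSequence(global_seed,
spawn_key=(k,))`` with a fixed stage -> k table, so stages are
reproducible independently of one another.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import rsa, stats
from .datasets import MultiLayerActivationSet
from .decoding import DecodeConfig, cross_decode, cv_decode
from .rdm import RDM, super_rdm
from .synthetic import (
    GroundTruthSimilarity,
    SyntheticConfig,
    generate_activations,
    generate_triplet_trials,
    planted_similarity,
)

STAGE_KEYS = {
    "synthetic": 0,
    "mantel": 1,
    "layer_variation": 2,
    "mds": 3,
    "decoding": 4,
    "behavior": 5,
    "comparison": 6,
}


def stage_seed(global_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(global_seed, spawn_key=(STAGE_KEYS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class AnalysisConfig:
    """Everything one experiment run needs, serializable to/from YAML."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    activations_path: str | None = None  # load instead of simulate if set
    n_perm: int = 1000
    decode: DecodeConfig = field(default_factory=DecodeConfig)
    cross_pairs: tuple[tuple[str, str], ...] = (
        ("photo", "drawing"),
        ("photo", "sketch"),
        ("drawing", "sketch"),
    )
    mds_layers: tuple[str, ...] = ()  # empty = all layers
    triplet_mode: str = "exhaustive"
    triplet_n_trials: int | None = None
    families: Mapping[str, Sequence[str]] = field(default_factory=dict)
    make_figures: bool = True
    out_dir: str = "results"
    seed: int = 0

    def validate(self) -> None:
        deps = self.synthetic.depictions
        if len(deps) < 2:
            raise ValueError(
                "at least two depiction types are required for cross-depiction "
                f"analysis; configured: {list(deps)}"
            )
        for a, b in self.cross_pairs:
            for d in (a, b):
                if d not in deps:
                    raise ValueError(
                        f"cross pair ({a}, {b}) references unknown depiction {d!r}"
                    )
        if self.activations_path and not Path(self.activations_path).with_suffix(
            ".npz"
        ).exists():
            raise FileNotFoundError(self.activations_path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", {})
        if "depictions" in syn:
            syn["depictions"] = tuple(syn["depictions"])
        if "shared_fraction" in syn:
            syn["shared_fraction"] = tuple(syn["shared_fraction"])
        dec = raw.pop("decode", {})
        if "cross_pairs" in raw:
            raw["cross_pairs"] = tuple(tuple(p) for p in raw["cross_pairs"])
        if "mds_layers" in raw:
            raw["mds_layers"] = tuple(raw["mds_layers"])
        return cls(
            synthetic=SyntheticConfig(**syn), decode=DecodeConfig(**dec), **raw
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"]["layers"] = dict(self.synthetic.layers)
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ExperimentReport:
    """In-memory results of one run (also written to ``out_dir``)."""

    config: AnalysisConfig
    profile: rsa.CrossDepictionProfile
    rdms: dict[str, dict[str, RDM]]  # layer -> depiction -> RDM
    tests: list[dict]
    decoding: pd.DataFrame
    behavior_fit: pd.DataFrame | None
    out_dir: Path


def _write_test_records(records: list[dict], out_dir: Path) -> None:
    (out_dir / "tests.json").write_text(json.dumps(records, indent=2))
    pd.DataFrame(records).to_csv(out_dir / "tests.csv", index=False)


def _apply_fdr(records: list[dict], families: Mapping[str, Sequence[str]]) -> None:
    """BH-adjust p-values within each configured family, in place.

    Tests whose name is not claimed by any family form a residual family
    per test-name prefix.
    """
    claimed: dict[str, str] = {}
    for fam, names in families.items():
        for name in names:
            claimed[name] = fam
    for rec in records:
        rec["family"] = claimed.get(rec["name"], rec["name"].split("/")[0])
    for fam in sorted({r["family"] for r in records}):
        members = [r for r in records if r["family"] == fam]
        adjusted = stats.bh_fdr([r["p"] for r in members])
        for rec, q in zip(members, adjusted):
            rec["p_fdr"] = float(q)


def run_experiment1(config: AnalysisConfig) -> ExperimentReport:
    """Execute the full analysis graph for one configuration."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # stage: activations --------------------------------------------------
    try:
        if config.activations_path:
            multi = MultiLayerActivationSet.load(config.activations_path)
        else:
            multi = generate_activations(config.synthetic)
    except Exception as exc:
        raise RuntimeError(f"stage 'activations' failed: {exc}") from exc

    records: list[dict] = []

    # stage: RDMs and cross-depiction profile ------------------------------
    try:
        rdms = {layer: rsa.depiction_rdms(multi[layer]) for layer in multi.layer_names}
        profile = rsa.cross_depiction_profile(multi)
        profile.to_tidy().to_csv(out_dir / "profile.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'rdm/profile' failed: {exc}") from exc

    # stage: Mantel tests per layer and pair -------------------------------
    try:
        seed0 = stage_seed(config.seed, "mantel")
        k = 0
        for layer in multi.layer_names:
            for d1, d2 in combinations(multi[multi.layer_names[0]].depictions, 2):
                res = stats.mantel_test(
                    rdms[layer][d1], rdms[layer][d2], config.n_perm, seed0 + k
                )
                res.name = f"mantel/{layer}/{d1}-{d2}"
                records.append(res.to_record())
                k += 1
    except Exception as exc:
        raise RuntimeError(f"stage 'mantel' failed: {exc}") from exc

    # stage: across-layer variation per pair --------------------------------
    try:
        seed0 = stage_seed(config.seed, "layer_variation")
        for k, (d1, d2) in enumerate(
            combinations(multi[multi.layer_names[0]].depictions, 2)
        ):
            pairs = [(rdms[l][d1], rdms[l][d2]) for l in multi.layer_names]
            res = stats.across_layer_variation_test(pairs, config.n_perm, seed0 + k)
            res.name = f"layer_variation/{d1}-{d2}"
            records.append(res.to_record())
    except Exception as exc:
        raise RuntimeError(f"stage 'layer_variation' failed: {exc}") from exc

    # stage: super-RDM MDS --------------------------------------------------
    try:
        seed0 = stage_seed(config.seed, "mds")
        mds_layers = config.mds_layers or tuple(multi.layer_names)
        embeddings = {}
        for k, layer in enumerate(mds_layers):
            srdm = super_rdm(multi, layer)
            emb = rsa.mds_embed(srdm, dims=2, seed=seed0 + k)
            embeddings[layer] = emb
            emb.to_dataframe().to_csv(out_dir / f"mds_{layer}.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'mds' failed: {exc}") from exc

    # stage: decoding -------------------------------------------------------
    try:
        seed0 = stage_seed(config.seed, "decoding")
        rows = []
        k = 0
        for layer in multi.layer_names:
            acts = multi[layer]
            for dep in acts.depictions:
                sub = acts.subset_depiction(dep)
                res = cv_decode(sub, None, config.decode.with_seed(seed0 + k))
                rows.append(
                    {
                        "layer": layer,
                        "analysis": "intra",
                        "train": dep,
                        "test": dep,
                        "mean_accuracy": res.mean_accuracy,
                        "standard_error": res.standard_error,
                    }
                )
                k += 1
            for train_dep, test_dep in config.cross_pairs:
                res = cross_decode(
                    acts.subset_depiction(train_dep),
                    acts.subset_depiction(test_dep),
                    None,
                    config.decode.with_seed(seed0 + k),
                )
                rows.append(
                    {
                        "layer": layer,
                        "analysis": "cross",
                        "train": train_dep,
                        "test": test_dep,
                        "mean_accuracy": res.mean_accuracy,
                        "standard_error": res.standard_error,
                    }
                )
                k += 1
        decoding_df = pd.DataFrame(rows)
        decoding_df.to_csv(out_dir / "decoding.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'decoding' failed: {exc}") from exc

    # stage: behavior -------------------------------------------------------
    try:
        seed0 = stage_seed(config.seed, "behavior")
        sim = planted_similarity(config.synthetic)
        trials = generate_triplet_trials(
            sim,
            mode=config.triplet_mode,
            n_trials=config.triplet_n_trials,
            choice_model="deterministic",
            seed=seed0,
        )
        trials.to_csv(out_dir / "triplets.csv")
        est = bhv.triplet_similarity(trials)
        behavior_rdm = bhv.choice_similarity_to_rdm(est)
        fit_rows = []
        k = 0
        for layer in multi.layer_names:
            for dep in multi[layer].depictions:
                res = stats.mantel_test(
                    behavior_rdm, rdms[layer][dep], config.n_perm, seed0 + 1 + k
                )
                res.name = f"behavior_fit/{layer}/{dep}"
                records.append(res.to_record())
                fit_rows.append(
                    {"layer": layer, "depiction": dep, "rho": res.observed, "p": res.p}
                )
                k += 1
        behavior_df = pd.DataFrame(fit_rows)
        behavior_df.to_csv(out_dir / "behavior_fit.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'behavior' failed: {exc}") from exc

    # FDR within families, consolidated outputs ----------------------------
    _apply_fdr(records, config.families)
    _write_test_records(records, out_dir)

    if config.make_figures:
        _figures(profile, embeddings, decoding_df, out_dir)

    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGE_KEYS},
        "artifacts": sorted(p.name for p in out_dir.iterdir() if p.is_file()),
        "n_tests": len(records),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return ExperimentReport(
        config, profile, rdms, records, decoding_df, behavior_df, out_dir
    )


def _figures(profile, embeddings, decoding_df, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for pair in profile.rho.columns:
        ax.plot(profile.layer_names, profile.rho[pair], marker="o", label=pair)
    ax.set_xlabel("layer")
    ax.set_ylabel("RDM Spearman rho")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "profile.png", dpi=120)
    plt.close(fig)

    for layer, emb in embeddings.items():
        fig, ax = plt.subplots(figsize=(5, 5))
        deps = [l.split(":")[1] for l in emb.labels]
        for dep in dict.fromkeys(deps):
            idx = [i for i, d in enumerate(deps) if d == dep]
            ax.scatter(emb.coords[idx, 0], emb.coords[idx, 1], s=12, label=dep)
        ax.legend()
        ax.set_title(f"{layer} (stress {emb.stress:.2f})")
        fig.tight_layout()
        fig.savefig(out_dir / f"mds_{layer}.png", dpi=120)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    intra = decoding_df[decoding_df["analysis"] == "intra"]
    for dep, grp in intra.groupby("train"):
        ax.errorbar(
            grp["layer"], grp["mean_accuracy"], yerr=grp["standard_error"],
            marker="o", label=dep,
        )
    ax.axhline(0.5, color="gray", ls="--", lw=0.8)
    ax.set_ylabel("decoding accuracy")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "decoding.png", dpi=120)
    plt.close(fig)


def run_comparison(
    report_a: ExperimentReport,
    report_b: ExperimentReport,
    n_perm: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Differential report between two completed runs.

    For each layer and depiction pair, tests whether run A's RDM
    correlation exceeds run B's via a label-permutation null, then
    BH-adjusts within the family of all comparisons.
    """
    layers_a = report_a.profile.layer_names
    layers_b = report_b.profile.layer_names
    if layers_a != layers_b:
        raise ValueError(f"layer mismatch between runs: {layers_a} vs {layers_b}")
    if set(report_a.profile.rho.columns) != set(report_b.profile.rho.columns):
        raise ValueError("depiction-pair mismatch between runs")
    n_perm = n_perm or report_a.config.n_perm
    seed = (
        seed
        if seed is not None
        else stage_seed(report_a.config.seed, "comparison")
    )
    rows = []
    k = 0
    for layer in layers_a:
        for pair in report_a.profile.rho.columns:
            d1, d2 = pair.split("-")
            res = stats.correlation_pair_difference_test(
                report_a.rdms[layer][d1],
                report_a.rdms[layer][d2],
                report_b.rdms[layer][d1],
                report_b.rdms[layer][d2],
                n_perm=n_perm,
                seed=seed + k,
            )
            rows.append(
                {
                    "layer": layer,
                    "pair": pair,
                    "rho_a": report_a.profile.rho.loc[layer, pair],
                    "rho_b": report_b.profile.rho.loc[layer, pair],
                    "difference": res.observed,
                    "p": res.p,
                    "n_perm": n_perm,
                    "seed": seed + k,
                }
            )
            k += 1
    df = pd.DataFrame(rows)
    df["p_fdr"] = stats.bh_fdr(df["p"])
    return df
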