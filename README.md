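# depictrsa

Representational similarity analysis (RSA) across levels of visual
abstraction: does a layered system represent the *same objects* the same
way when they are rendered as photos, line drawings, or sketches?

The package is aimed at computational visual neuroscientists who want to
quantify cross-depiction generalization in network activations (or any
stimuli × features measurements) and validate every step against
synthetic data with planted ground truth. It provides:

- **RDMs**: correlation-distance matrices `d(i, j) = 1 − Pearson r`
  between activation patterns, per layer and depiction type, plus
  super-RDMs over all depictions and metric-MDS embeddings.
- **Cross-depiction profiles**: the Spearman rank correlation
  `ρ = spearman(ltri(RDM_A), ltri(RDM_B))` between the lower triangles
  of two depictions' RDMs, tracked across layers (photo-to-drawing,
  photo-to-sketch, drawing-to-sketch similarity).
- **Permutation inference**: Mantel test (joint row/column object
  relabeling), correlation-difference and across-layer variation tests,
  sign-permutation comparison of per-object accuracies, a decoding
  permutation null — all with the add-one convention
  `p = (1 + #{null ≥ observed}) / (1 + n_perm)` — plus McNemar, TOST
  equivalence, pooled t, and Benjamini–Hochberg FDR within configured
  families.
- **Decoding**: leave-N-out linear-SVM classification of superordinate
  category (manmade vs natural) within a depiction and across
  depictions (train on photos, test the same held-out objects as
  drawings).
- **Behavior**: pairwise similarity from triplet odd-one-out choices —
  `sim(x, y)` is the fraction of trials containing x and y in which the
  third object was chosen — and synonym-aware label scoring.
- **Synthetic data**: a latent model in which a per-layer shared
  fraction α mixes object-invariant and depiction-specific latents, so
  every analysis above has a recoverable planted parameter; plus
  triplet-choice, paired-outcome and polygon-image simulators.
- **Adapter**: image preprocessing onto a gray canvas, layerwise feature
  extraction, hierarchy-aware top-1 scoring (a prediction is correct if
  it names the target or one of its hyponyms), and a frozen-boundary
  fine-tuning driver, exercised with a small built-in numpy
  convolutional network.

## Worked example

```python
from depictrsa import (SyntheticConfig, generate_activations,
                       cross_depiction_profile, mantel_test,
                       cv_decode, cross_decode, DecodeConfig)
from depictrsa.rsa import depiction_rdms

cfg = SyntheticConfig(seed=0)   # 42 objects x {photo, drawing, sketch},
                                # 5 layers, planted alpha (0.3,0.6,0.9,0.6,0.3)
multi = generate_activations(cfg)
print(cross_depiction_profile(multi).rho.round(3))

rdms = depiction_rdms(multi["layer3"])
res = mantel_test(rdms["photo"], rdms["drawing"], n_perm=1000, seed=1)
print(f"layer3 photo-drawing: rho = {res.observed:.3f}, p = {res.p:.4f}")

photo = multi["layer3"].subset_depiction("photo")
print(cv_decode(photo, None, DecodeConfig(seed=2)).summary())
```

prints

```
        photo-drawing  photo-sketch  drawing-sketch
layer
layer1          0.022         0.004           0.017
layer2          0.253         0.215           0.159
layer3          0.724         0.732           0.682
layer4          0.196         0.161           0.128
layer5          0.030         0.020           0.023
layer3 photo-drawing: rho = 0.724, p = 0.0010
decoding accuracy 0.812 +/- 0.005 SE (1000 iterations, n_test=6)
```

The profile shows exactly the planted structure: cross-depiction
representational similarity rises to the middle layer (where the shared
fraction peaks at 0.9) and falls again, the Mantel test confirms the
layer-3 correspondence at the minimum attainable p for 1000
permutations, and the manmade/natural class direction planted on the
shared latent supports above-chance decoding.

The full analysis graph — RDMs, profile, Mantel and across-layer tests,
MDS, intra/cross decoding, triplet simulation and behavioral fit, FDR,
figures, manifest — runs as one call or from the shell:

```sh
depictrsa run-exp1 --seed 7 --out results/exp1
depictrsa report results/exp1
```

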