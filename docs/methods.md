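# Methods

This note documents the models, procedures and numerical choices behind
`depictrsa`, and what the synthetic benchmarks do and do not establish.

## Scientific setting

The package implements the analysis machinery used to ask how object
representations generalize across levels of visual abstraction: the same
objects rendered as photos, line drawings and sketches are passed through
a layered system (a convolutional network, or the synthetic stand-in
below), and the representational geometry of each depiction type is
compared across types, across layers, and against human similarity
judgments. The canonical empirical signature this machinery is built to
detect is a cross-depiction similarity profile that rises toward
intermediate layers and falls toward late layers, together with
classification (decoding) of superordinate category that may or may not
transfer across depiction types.

## Representational dissimilarity

For one layer and one depiction type, the RDM entry for stimuli *i*, *j*
is the correlation distance

    d(i, j) = 1 − Pearson r(x_i, x_j)

over the activation (or flattened pixel) patterns, giving a symmetric
matrix with zero diagonal and entries in [0, 2]. No feature scaling is
applied before the distance: the Pearson correlation is already
location- and scale-invariant per pattern. A zero-variance pattern makes
the correlation undefined and is treated as an error naming the stimulus;
silently dropping rows would desynchronize labels across depictions.

All RDM comparisons use the strictly-below-diagonal entries, extracted
row-major (row 1 col 0; row 2 cols 0, 1; …), and two RDMs are compared
by the Spearman rank correlation of those vectors (average ranks on
ties). RDMs are always aligned by label before extraction, never by
position. Super-RDMs place all objects × all depiction types in one
matrix, grouped in depiction blocks; restricting a super-RDM to one
block reproduces that depiction's own RDM exactly.

Metric MDS embeddings of super-RDMs minimize raw stress via SMACOF, with
one run seeded by Torgerson classical scaling (exact whenever the
distances are Euclidean-realizable in the target dimension) plus random
restarts under a fixed seed; convergence tolerance is 1e−12 on the
stress. Embeddings are identified only up to rotation/reflection, so
tests compare recovered pairwise distances, not coordinates.

## Permutation inference

All randomization tests share the add-one one-sided p-value

    p = (1 + #{null ≥ observed}) / (1 + n_perm),

which counts the observed statistic as one realization of its null,
keeping the test valid with minimum p = 1/(n_perm + 1). Every result
records its statistic, null sample, n_perm and seed.

RDM nulls always permute *object labels* — rows and columns jointly —
never individual cells: a relabeling preserves the geometry of the
matrix while breaking its correspondence with the reference RDM. The
implemented tests:

- **Mantel test**: observed Spearman correlation of two RDMs against the
  null of relabeled copies of one of them. At n = 4 an exhaustive
  24-permutation reference is available and the Monte-Carlo p converges
  to it.
- **Correlation-difference test**: rho(shared, x) − rho(shared, y) with
  the shared RDM relabeled in both correlations per draw; a variant for
  comparing the same correlation between two runs relabels the second
  member of each correlation with one permutation per draw.
- **Across-layer variation test**: the sum of squared deviations of the
  per-layer correlations from their mean, with one relabeling per
  depiction applied identically across layers and independently between
  depictions.
- **Sign-permutation test**: mean per-object human accuracy minus a
  network accuracy, with the null flipping the sign of each object's
  accuracy independently. The literal accuracy-flipping construction is
  the default; flipping the per-object human-minus-network differences —
  the conventional paired form — is available via a flag. For
  nonnegative accuracies the literal form is extremely conservative in
  one direction and anti-conservative in the other; it is provided
  as-specified and the flag documents the alternative without presuming
  intent.
- **Decoding permutation null**: the full cross-validated decoding
  analysis repeated under label shuffles.

**Known limitation — dependent correlations.** The across-layer
variation test is exchangeable-valid when the depiction RDMs are
uncorrelated (its rejection rate is at the nominal level under an
all-zero shared-fraction profile). When the true profile is flat but
*nonzero*, relabeling destroys the common correlation, so the null
underestimates the sampling variance of dependent layerwise correlation
estimates and the test is anticonservative (we measure roughly a 0.24
rejection rate at the 0.05 level for a flat 0.5 profile with 128-feature
layers). This is a property of the randomization construction itself;
users comparing flat-but-correlated profiles should interpret small
p-values cautiously.

Classical tests are delegated to standard implementations behind the
same module surface: McNemar's χ² = (b − c)²/(b + c) on discordant
counts (no continuity correction by default; a flag enables it), the
pooled-variance two-sample t, the two one-sided paired-t equivalence
procedure (TOST; the equivalence bounds are a required user input, with
the degenerate zero-variance case resolved to p = 0 inside the bounds
and p = 1 outside), and Benjamini-Hochberg step-up FDR adjustment,
applied within explicitly configured test families.

## Decoding

Superordinate category (manmade vs natural) is decoded with a linear
SVM (cost = 1, no hyperparameter search, no feature scaling by default;
scaling is an off-by-default logged option) in a leave-N-out scheme:
each of `n_iter` iterations draws N = 6 test stimuli uniformly without
replacement, trains on the rest, and scores the held-out sample; the
mean and SE over iterations summarize the analysis. Test draws are not
stratified; an all-one-class *test* fold is allowed and scored as-is,
while a draw leaving the *training* fold single-class is rejected and
redrawn with a logged count (impossible at the default 42-stimulus
design but reachable in small synthetic sets).

Cross-domain decoding trains on one depiction type and evaluates the
same held-out *object identities* rendered in another type, so object
identity never appears on both sides of a split. With identical train
and test sets, cross-domain decoding reproduces the intra-domain
analysis exactly under the same seed.

A caveat the synthetic benchmarks surfaced: for a *fixed* pattern set,
per-iteration accuracies are not independent evidence about chance
level — a held-out object's prediction is stable across folds whenever
the classifier is pinned by stable structure, so the mean accuracy
retains dataset-level variance (roughly binomial over objects) that the
per-iteration SE cannot see. Chance-level claims in the test suite are
therefore evaluated as means over replicate generated datasets, with
uncertainty taken across replicates. Low-dimensional noise patterns
additionally show the well-known pessimistic bias of unstratified
cross-validation; at the feature dimensionalities of real activation
sets (64+) the bias is negligible, and the chance benchmarks use that
regime.

## Triplet odd-one-out similarity

In each trial three objects are shown and the least-similar one is
chosen. The pairwise similarity estimate is the fraction of trials
containing a pair in which the *third* object was chosen, marginalizing
over the third object's identity. Pairs that never co-occur are flagged
undefined rather than imputed, and converting to a behavioral RDM
(d = 1 − similarity, the canonical transform for choice probabilities)
fails loudly while listing them. The simulator offers exhaustive
enumeration of all C(n, 3) triples or budgeted random sampling, and a
deterministic choice rule (argmin of summed similarity to the other two,
ties uniform under the seed) or a softmax rule with temperature.

## The synthetic activation model

Each object has a shared latent z_o ~ N(0, I) and independent
per-depiction idiosyncratic latents u_{o,d} ~ N(0, I) in a
`latent_dim`-dimensional space (default 12). A layer with shared
fraction α responds to α·z_o + √(1 − α²)·u_{o,d}, pushed through one
random linear map per layer — shared across depictions, mirroring
shared network weights — plus isotropic Gaussian noise (default SD 0.1
against unit-scale features). Because the idiosyncratic latents are
independent across depictions, α alone drives cross-depiction
representational similarity, rising from uncorrelated RDMs at α = 0 to
identical geometry at α = 1. The default α profile (0.3, 0.6, 0.9, 0.6,
0.3) over five 128-feature layers plants the intermediate-layer peak;
the stimulus design constants (42 objects, 21 manmade, three depiction
types) follow the emulated study design.

A manmade/natural class direction of strength `class_signal` is added in
latent space. On the shared latent (default) its decodability transfers
across depictions in proportion to α; in the `idiosyncratic` mode one
class direction per depiction is added to the u's instead, and these
directions are drawn *mutually orthogonal* (QR of a random matrix), so
zero cross-depiction transfer of the class code holds by construction
rather than only on average over direction draws. This gives the
clean mechanism-level contrast — intra-depiction decoding succeeds while
cross-depiction decoding sits at chance — that mirrors successful
drawing-to-sketch versus failed photo-to-drawing transfer.

The planted object-similarity matrix used by the triplet simulator is
the Pearson correlation of the shared latents rescaled to [0, 1] — the
depiction-invariant part of the planted representation.

Expected cross-depiction RDM correlation is approximately α⁴ for small
α (both RDMs weight the shared geometry by α², and the correlation
multiplies the weights), so the low end of an α grid is intrinsically
hard to resolve. Recovery benchmarks therefore use common random
numbers — the same seed set at every grid point — so latent draws cancel
from the monotonicity comparison, and average the three depiction-pair
correlations.

**What the generator does not emulate**: real image statistics,
receptive-field structure, nonlinearities between layers (each layer is
an independent linear readout of the latents rather than a composition),
attention or semantic context in human choices, and respondent-level
behavioral variability. Passing benchmarks therefore establish that the
estimators and tests recover planted structure under a faithful noise
model, not that real networks or observers behave this way.

## Synthetic images and the network adapter

The image generator renders each object as one random star-convex
polygon in two variants sharing identical vertices: a filled variant
with per-pixel texture noise ("photo-like") and a thin contour on the
same gray background ("drawing-like"). Preprocessing finds the
foreground (alpha channel when informative, else a background-color
mask), scales its bounding box — aspect ratio preserved, configurable
margin — onto a square gray canvas (default 224), and normalizes per
channel with configurable constants defaulting to the canonical
natural-image statistics (the choice between per-image and dataset
statistics is config data, not code).

The network used to exercise the adapter contracts is a small
pure-numpy convolutional network (im2col convolutions, 2×2 max pooling
with tie-splitting gradients, dense heads) with named layers, feature
capture at any layer (convolutional maps flattened row-wise), SGD with
momentum, and bit-exact freezing of all parameters up to a named
boundary layer. Hierarchy-aware top-1 scoring consumes an is-a edge
list (child → parent TSV) as a directed acyclic graph; a prediction is
correct when it names the target class or any of its descendants, and
an edgeless taxonomy reduces to exact-match accuracy.

## Pipeline reproducibility

`run_experiment1` executes activation generation → RDMs → profile →
Mantel and variation tests → super-RDM MDS → intra/cross decoding →
triplet simulation and behavioral fit, writing tidy CSVs, a JSON record
per test (statistic, p, n_perm, seed, family), FDR-adjusted consolidated
results, optional PNG figures, and a manifest with the config hash and
all stage seeds. Stage k derives its seed as
`SeedSequence(global_seed, spawn_key=(k,))` from a fixed stage table, so
any stage is reproducible without re-running the others; two runs with
one seed produce byte-identical CSVs.

Benchmark problem sizes (42 objects, 128-feature layers, hundreds of
permutations and iterations, tens of seeds per property) were chosen so
the full property suite runs on a single CPU in a few minutes while
keeping every calibration check at the replicate counts stated in the
test docstrings.
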