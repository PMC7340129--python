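# Methods

`omicsfusion` implements a network-fusion approach to multi-omics
integration together with the cross-validated analysis plan used to turn
it into compact predictive signatures. This note records the model, its
tunable parameters, the numerical choices, what the synthetic benchmark
does and does not emulate, and the design decisions taken where the
design was genuinely open.

## Similarity network fusion

Each omics layer is a real matrix of `n` patients by `p_l` features.
After column-wise z-scoring (population SD; constant columns map to
zeros), a patient-similarity network is built per layer with the scaled
exponential Euclidean-distance kernel

    W(i,j) = exp( -d(i,j)^2 / (alpha * eps_ij) ),
    eps_ij = ( m_i + m_j + d(i,j) ) / 3,

where `m_i` is the mean distance from patient `i` to its `K` nearest
neighbours (self excluded). This is the formula-level kernel of the
original fusion method; we deliberately do not use the Gaussian-density
variant found in some re-implementations, because one canonical form has
to be pinned for the hand-computable kernel oracle used in the tests
(three 1-D points 0/1/10 with `K=1`, `alpha=0.5` give affinities exactly
`e^-2` and `e^-30`). The raw kernel diagonal is stored as 0 and the
matrix symmetrized; coincident samples receive the kernel maximum 1.

Fusion iterates cross-diffusion between layers. Per layer, a
row-stochastic *status matrix* `P` (diagonal 1/2, off-diagonal row mass
1/2) and a sparse *local affinity* `S` (row-normalized restriction of
`W` to each patient's `K` nearest neighbours, ties broken by sample
index) are formed, and

    P_v  <-  S_v  x  mean_{u != v}( P_u )  x  S_v^T

is applied for up to `T` rounds with re-symmetrization and
re-normalization after each update. The fused network is the symmetrized
mean of the final status matrices. A single layer returns its normalized
status matrix without iteration. `T` defaults to 20 with an early stop
when the fused matrix moves by less than `1e-6` in max norm — the
iteration count is not prescribed anywhere authoritative, and diffusion
on desk-scale problems converges well before 20 rounds. No final
diagonal-stabilization step is applied (plain symmetrization only);
cross-checks against other fusion implementations must account for this.

Sub-communities of patients are found by normalized spectral clustering:
the `k` leading eigenvectors of `D^-1/2 W D^-1/2`, row-normalized, then
seeded k-means with 10 restarts (best inertia). The k-means seed resolves
the embedding's sign/rotation ambiguity deterministically. Partition
agreement is scored by normalized mutual information with geometric-mean
normalization and the `0/0 := 0` convention, so a single-cluster
partition scores 0; the bound in `[0,1]`, symmetry and relabeling
invariance are all property-tested.

## Network-consistency feature ranking (rSNF)

The fused network over all layers is clustered into as many clusters as
there are phenotype classes, giving a reference partition `C*`. For each
feature `f_i` a patient network `W_i` is built from `f_i` alone — same
z-scoring and kernel, distances on the standardized scalar — clustered
the same way, and scored by `NMI(C_i, C*)`. The descending score order is
the ranking; exact ties keep (layer order, feature index) order, which is
stable and reproducible. A higher score means the single feature's
geometry reproduces more of the fused structure.

Kernel hyperparameters are searched over `alpha` in {0.3, 0.35, ..., 0.8}
and `K` in {10, ..., 30} by repeated stratified cross-validation: per
fold, the fused network over the fold-training samples is clustered and
scored by NMI against the true phenotypes; the grid point maximizing the
mean is chosen, ties to the smallest `K` then smallest `alpha`. Two
points were open and are pinned here as package decisions: (i) the
tuning objective is labels-vs-clusters NMI on the fold-training portion
(the fusion has no out-of-sample extension, so validation folds are
unused rather than inventing one); (ii) inside the full-flavor analysis
plan the reference clustering is recomputed per fold together with the
ranking, since both derive from fold-training samples.

## The analysis plan

Each run draws 10 stratified 50/30/20 TR/TS/TS2 partitions (largest-
remainder apportionment per class, so every partition's class mix tracks
the dataset within one sample). On the development set, a stratified
10x5-fold CV is repeated: per fold, features are ranked (ANOVA F for the
juxtaposed path, network consistency for the fusion path), classifiers
are trained at 5/10/25/50/75/100% of the features (round-half-up,
minimum 1, deduplicated — the half-up rule is what makes 25% of 10
features equal 3), and scored on the held-out fold by MCC, precision and
recall. Fold-level lists are Borda-aggregated (score `L - position`,
ties by feature id); the feature count maximizing mean CV MCC is kept
(ties to the smaller count, favouring compact signatures); the model is
refit on the full development set at that count and scored once on the
held-out partition. Split-level Borda lists aggregate again into a
Borda-of-Bordas (BoB), and `Nf` is the median best count across splits
(reported unrounded, so it may be half-integer; signatures take the top
`floor(Nf)` BoB features).

Classifiers: Random Forest with 500 trees and Gini impurity splits, or a
linear SVM whose `C` is tuned over {1e-2 ... 1e3} by 10 stratified
Monte-Carlo 50/50 resamples of the fold-training data (mean validation
MCC, ties to the smallest `C`). The SVM is re-tuned on every
fold-training set — leakage-safe, at extra cost — because nothing pins
tuning to once per split. Multiclass MCC uses the standard confusion-
matrix correlation generalization (it reduces exactly to the binary
formula at k=2; both routes are cross-tested); multiclass precision and
recall are macro-averaged. The binary positive class is a configuration
knob (default: the second class in discovery order).

Three integration paths share this machinery. *juXT*: ANOVA-F ranking on
the column-concatenated layers, developed on TR, tested on TS. *rSNF*:
the same juxtaposed matrix with the network-consistency ranking,
developed on TR, tested on TS. *rSNFi*: the juxtaposed matrix restricted
to the intersection of the juXT and rSNF top lists, developed on TS and
tested on TS2 so that feature selection and model training never share
samples. The intersection is split-local by default — each split's Borda
lists truncated at that split's selected count, juXT order preserved —
because the compact model trains on the same split's TS; a BoB-level
variant is available by configuration. An empty intersection is an
explicit error (or a skipped-with-reason rSNFi path in the full
workflow), never a silent fallback. Because rSNFi universes are
split-local, their BoB aggregates over the union universe, with a list
contributing nothing for features it never ranked.

The *accelerated* flavor computes the network-consistency ranking once
per split on the full development set and reuses it in every fold; the
*full* flavor recomputes it inside each fold. Agreement between the two
is measured by the Canberra distance between their Borda lists
(`sum |p1 - p2| / (p1 + p2)` over 1-based positions, full lists, no
top-k truncation) against a random-permutation null.

A *random-labels* mode permutes each development set's labels (seeded)
before everything, including the ranking; an unbiased procedure then
scores mean CV MCC near 0.

Uncertainty on the per-split metric means uses 95% studentized
(bootstrap-t) intervals: 1000 outer resamples studentized with a
100-resample nested bootstrap each, quantiles applied to the plug-in
standard error. Degenerate all-equal inputs give a zero-width interval;
outer resamples with zero inner spread are dropped. Coverage is
Monte-Carlo-tested on standard-normal samples.

All randomness — splits, CV folds, classifier seeds, label shuffles,
bootstraps, k-means restarts — derives from one master seed through a
keyed hash (`blake2b` of the seed plus a stage tag, reduced below 2^31),
so a run is reproducible end to end; identical configuration and seed
give bit-identical results, which is asserted by test.

## The synthetic benchmark

The generator emulates a two-class multi-omics study: 380 patients
(70/30 class balance via largest-remainder rounding, i.e. 266/114),
three pseudo-omics layers of 100/50/250 features with 10/5/25
informative features, class separations 1.0/1.2/0.8, a x10
multiplicative factor on layer 3, per-layer random states 1/2/3, no
label noise, no feature shuffling. Layers are drawn with scikit-learn's
`make_classification`; informative columns are class-conditional
Gaussian clusters on hypercube vertices at half-side `class_sep`, the
rest standard Gaussian noise. Choices the generator's description left
open, fixed here: redundant/repeated feature counts are 0 and one
Gaussian cluster per class is used, so the leading `n_informative`
columns carry *all* the class signal and recovery tests are exact; the
multiplicative factor is a global scale on the layer's values, which
creates exactly the cross-layer scale heterogeneity the kernel's local
scaling must absorb; the class assignment is drawn once and shared by
every layer (all layers describe the same patients — the unshuffled
generator emits block-ordered labels identically for every layer seed);
optional label noise is applied to the shared phenotype vector after
generation so the layers stay in sync.

What the benchmark does not emulate: correlated features within or
across layers, heavy-tailed or count-valued measurements, batch effects,
missing data, and class-conditional covariance structure. Passing tests
therefore demonstrate that the machinery recovers planted signal under
clean Gaussian conditions, not that it will rank real omics features
correctly; the real-data behaviour depends on properties the generator
deliberately omits.

## Problem sizes used by tests

The test suite runs the full 380-sample benchmark wherever the check is
about the benchmark itself (informative-feature recovery by the
network-consistency ranking, the random-labels null at 1 split with
5x5-CV and the full fraction schedule, accelerated-vs-full agreement,
signal-over-null margins at 1 split with 2x3-CV) and reduced
configurations elsewhere (a 120-sample two-layer dataset for
pipeline-shape and determinism checks, toy datasets for kernel and
ranking oracles). Kernel parameters for benchmark runs are fixed at
`alpha = 0.5`, `K = 20` — the mid-points of the tuning grids — since
grid search at full scale adds cost without changing what those checks
measure; the tuning search itself is exercised on small grids and data.

## Known limitations

- The fusion has no out-of-sample extension; all clustering is
  transductive, and the tuning objective uses training folds only.
- Per-feature clustering makes the ranking O(p) eigendecompositions of
  n x n matrices; the accelerated flavor exists precisely because the
  full flavor multiplies that by the number of CV rounds.
- Borda aggregation over split-local universes (the compact path) has no
  unique convention; the union-universe rule used here is documented
  above and in the aggregation docstring.
- Degenerate networks (a sample with zero affinity mass) are normalized
  uniformly rather than rejected; with the Gaussian kernel this can only
  arise from pathological inputs.
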