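# Methods

## Problem and model

The package classifies cysteine-dense peptides (CDPs, 30–50 aa) as
recombinantly expressible or not, from per-residue representations
produced by a structure-prediction network.  Four blocks are consumed
per peptide: `single` (L×384), `pair` (L×L×128, reduced to L×128 by
averaging the first axis: out[j,c] = meanᵢ pair[i,j,c]), `msa` (L×256)
and `structure` (L×384), plus a pLDDT confidence track in [0, 100].
When several prediction runs are available (up to five), only the run
with the highest mean pLDDT is used; ties break to the lowest run index
so selection is deterministic and permutation-invariant up to that rule.

Two classifier heads cover the two feature routes:

* **Random forest** (300 trees, otherwise library defaults, fixed seed)
  on mean-pooled 1152-vectors or on the flattened 50×1152 tensor.
  Forests see raw features — their splits are invariant to monotone
  rescaling.
* **L2-regularized logistic regression** on random-convolution features,
  after per-column standardization by training-set statistics (ppv and
  max features live on different scales; zero-variance columns are
  scaled by 1).  The inverse regularization strength C defaults to 1.0;
  an optional cross-validated grid 10⁻³…10³ (5-fold, selected by ROC
  AUC) is available because C is the head's only consequential free
  parameter.

Knottin and non-knottin peptides get fully independent model instances
with no parameter sharing.

## Random convolutional kernel transform

Per kernel: length uniform on {7, 9, 11}; weights i.i.d. standard normal
then mean-centred over all entries; bias uniform on [−1, 1]; dilation
⌊2^a⌋ with a uniform on [0, log₂((L−1)/(ℓ−1))], so an unpadded kernel's
span never exceeds the input; "same" zero-padding of ((ℓ−1)d)//2 on each
side with probability ½.  The transform is multichannel: each kernel
draws a channel subset whose size is uniform on a log₂ scale over
[1, C] and convolves only those channels with a shared bias.  An
`"all"`-channels mode exists for sensitivity analysis.  Each kernel
contributes ppv (fraction of outputs strictly > 0 — values exactly zero
count as non-positive) and the maximum.  Zero pad rows of the 50-row
tensor participate in the convolution as ordinary zeros.  Banks are
regenerated bit-identically from (seed, n_kernels, input_length,
n_channels, channel_mode) and serialize to HDF5 exactly.

Padding is appended at the C-terminal end so that N-terminal position
indices are stable across peptide lengths; mean pooling uses only the
true residues, which makes pooling and padding commute.

## Evaluation protocol

* **Balanced folds**: records are stratified into the four
  knottin × expressed cells; within each cell they are shuffled by the
  plan seed and dealt round-robin, so per-cell fold counts differ by at
  most one.  The plan depends only on (flags, k, seed) and is reused
  across representation types ("same shuffle").  A cell smaller than k
  warns; an empty cell is skipped with a warning.
* **Cross-validation** reports per-fold rank-based AUC (ties ½;
  identical to U/(n₁n₀)), their mean and SD, and the aggregated
  out-of-fold confidences.  A fold whose training labels are
  single-class is skipped with a warning rather than failing the run.
* **Leave-one-out** trains n models, aggregates the n held-out
  confidences into one ROC/AUC, and derives sensitivity, specificity,
  precision, accuracy and F1 from the 0.5-threshold confusion matrix.
  Metrics with zero denominators are reported absent; reports round to
  3 decimals while full precision is retained internally.
* **Ranking**: 50 random stratified 90–10 splits (every nonempty stratum
  keeps at least one validation record), one split shared by all models
  per permutation; models ranked by validation AUC (1 = best, average
  ranks on ties).  Mean ranks are compared by a Friedman omnibus
  followed by the Nemenyi critical difference
  CD = q_α √(k(k+1)/(6N)) with q_α the studentized-range quantile over
  √2.  If the omnibus is not significant at α all models form one
  group; with exactly two models (where the Friedman test is undefined)
  the critical difference alone decides.
* **Paired permutation test on AUC**: observed statistic is the AUC
  difference over shared out-of-fold confidences; the null swaps each
  sample's score pair between the two models with probability ½ (a
  fold-level swap mode is available), two-tailed, with +1 smoothing
  p = (b+1)/(m+1) so Monte-Carlo p-values are never zero.  Default
  10,000 iterations.
* **Mann-Whitney U**: exact enumeration of all C(n, n₁) assignments of
  the pooled mid-ranked values when min(n) ≤ 8 (ties handled by
  midranks; two-sided p = P(|U − μ| ≥ |U_obs − μ|)); otherwise the
  normal approximation with tie correction.

## Shapley attribution

Forest predictions on flattened position × channel features are
explained by exact path-dependent tree Shapley values, implemented here
and verified in the test suite against brute-force enumeration of all
feature subsets on small random trees (agreement to ~1e−16).  The value
function conditions on a feature set by following splits on known
features and averaging the children of unknown splits by training
cover.  Per-tree attributions average across the forest, so local
accuracy holds against the forest probability to machine precision; the
stated tolerance is 1e−6.  A Monte-Carlo permutation-sampling fallback
(≥ 2,000 draws recommended, seed recorded) covers small models where the
exact path algorithm is not wanted.  Attribution targets the
positive-class ("expressed") probability and is refused for non-forest
heads and for random-kernel features, whose columns no longer correspond
to residue positions.

Positional importance sums |contribution| over samples and channels per
position and divides position p by the number of peptides whose length
exceeds p (the padding-aware reading; the literal per-exact-length
normalization is available as `mode="exact_length"`).  Positions no
peptide occupies are reported absent.  Block importance sums
|contribution| within each of the four blocks; the block totals
partition the overall absolute attribution.

## Synthetic data generator

The generator emulates the study conditions, not real embeddings:
lengths uniform on [30, 50]; knottin fraction 351/1227 ≈ 0.286 and
positive fraction 0.55 matching the real dataset's geometry; all four
blocks i.i.d. standard normal per channel; pLDDT = 60 + 35·σ(z) with z
standard normal, clipped to [0, 100]; sequences random over the 20
standard residues with six cysteines forced into knottins (cosmetic
only).  The expressed class receives a constant effect δ added at a
chosen (positions × channels) window of one block — default positions
{7, 8, 9}, eight channels of `single`, anchored at the N-terminus so
trailing-pad conventions cannot shift it (a C-terminal anchor exists) —
and labels can be flipped with a noise probability after planting.
Everything is deterministic under the seed, and
`make_paper_shaped_dataset` emits the exact 876/513 + 351/165 class
geometry for fold-balancing and metric-shape checks.

Because the background is independent Gaussian with no covariance
between channels, positions or blocks, passing the recovery tests shows
the pipeline's mechanics (feature routing, fold hygiene, attribution
arithmetic) — it does not certify performance on real embeddings, whose
correlations and non-stationarity the generator deliberately omits.

## Problem sizes and numerical choices

Study sizes used by the test suite and the acceptance script, chosen
once as realistic desk-scale conditions: recovery experiments at n = 300
with δ ∈ {0, 2}; ranking over 50 permutations; AUC permutation test at
10,000 iterations; kernel-count contract exercised at 10,000 kernels
(20,000 features) while power experiments use ~1,000 kernels.  For the
planted-signal recovery, both halves of the check use the forest on the
flattened 50×1152 representation — the same model that produces the
positional importances.  Measured across seeds it recovers the signal at
CV AUC ≈ 1.0, whereas mean pooling dilutes a 3-position signal by 3/L
(AUC ≈ 0.9) and random-kernel summaries dilute it further (AUC ≈ 0.7):
a constant localized mean-shift is exactly the kind of feature that
per-position models retain and global summaries blur.

Other fixed choices: deduplication keys on the (accession, sequence)
pair, first occurrence kept, and is idempotent; records outside 30–50 aa
are flagged, never dropped; duplicate accessions with differing
sequences are kept distinct with a warning.  Scores are probabilities in
[0, 1]; the decision threshold is 0.5 everywhere.  File writers are
byte-deterministic (HDF5 written without timestamps).  The container
accepts both raw (L×L×128) and pre-reduced (L×128) pair dialects,
tagging and reducing raw input on load.

## Known limitations

* Real AUC levels reported for this task (≈ 0.8 LOOCV) require the
  actual embedding dataset of 1,227 peptides; the package treats
  embedding generation as out of scope and certifies mechanics on
  synthetic data only.
* The exact Shapley algorithm covers axis-aligned binary trees (the
  forest head); the sampling fallback is quadratic and intended for
  small models.
* The multichannel kernel transform uses random channel subsets; the
  univariate original leaves multichannel handling open, and an
  all-channels mode is provided for sensitivity analysis rather than as
  a validated default.
* The Mann-Whitney exact branch enumerates up to C(n, n₁) ≤ 200,000
  assignments; larger samples fall back to the tie-corrected normal
  approximation.
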