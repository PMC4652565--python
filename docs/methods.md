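# Methods

This note documents the statistical procedures implemented in `xplatclass`,
the synthetic data model used to exercise them, the numerical and design
choices that were genuinely open, and the known limitations.

## Data model and representations

Inputs are complete, strictly positive features × samples expression
matrices (features vastly outnumber samples) with a four-class subtype
label per sample (PN, N, CL, M) and a pool of normal reference samples per
platform. Missing values are rejected rather than imputed.

**Fold change.** `FC[f,s] = log2(T[f,s]/median_j N[f,j])`, computed as
`log2 T − log2 median N` so that the very wide dynamic ranges a nonlinear
platform scale produces cannot overflow the ratio. Nonpositive values are
hard errors: silently pseudo-counting would shift the zero point of FC
differently on each platform, corrupting exactly the cross-platform
comparison the pipeline is about. In cross-platform runs each platform's FC
is computed against that platform's own normal pool; making scales
comparable is the discretizer's job, not FC's.

**Discretization.** All three methods are *local* (fitted per feature) and
*refit on every dataset* they are applied to, training and testing splits
alike. Refitting is the load-bearing choice: applying platform A's bin
boundaries to platform B's values would reintroduce the scale difference,
whereas refitting makes equal-frequency bins a pure function of
within-dataset ranks.

* *Equal width*: cut points at `min + j·(max−min)/k`; value `v` maps to
  `⌊(v−min)/width⌋+1`, clamped so the maximum lands in bin k. Invariant
  under positive affine maps of a feature, but not under general monotone
  maps.
* *Equal frequency*: the value with 1-based ordinal rank r maps to bin
  `⌈r·k/n⌉`. Ties all receive the bin of their smallest tied rank
  (rank method "min"), which is deterministic and platform-consistent
  whenever the tie structure matches. Exactly invariant under any strictly
  increasing per-feature transform; on tie-free data bin occupancies differ
  by at most one.
* *1-D k-means*: Lloyd iterations initialized at the midpoints of the k
  equal-frequency quantile intervals (deterministic — random initialization
  is a known weakness of k-means discretization and is avoided entirely),
  at most 200 iterations, clusters relabeled 1..k by ascending centroid.
  Affine-invariant because both the initialization and the update are
  affine-equivariant.

Degenerate constant features collapse to bin 1 under every method, with a
logged warning. The default bin count is k = 10; the `2·ln(l)` heuristic
for the maximum bin number is provided (`dougherty_max_bins`, natural log
with floor — the only base/rounding combination consistent with a maximum
of 11 bins at 342 samples), and bin sweeps are configurable.

## Feature selection

* **CV ranking** (filter): descending `σ/µ` with the sample (n−1) standard
  deviation, ties broken by feature id. CV is computed on the positive
  expression scale of the *training platform*, not on fold change — FC
  matrices have means near or below zero, where σ/µ is undefined or
  meaningless. This is the one place the pipeline departs from
  "selection runs on the classifier's representation"; SVM-RFE and the RF
  importance ranking do run on the representation the classifier consumes,
  which is why selected feature counts differ per representation.
* **Pre-filter**: greedy Pearson redundancy scan in CV order (a feature is
  kept iff |r| ≤ 0.8 against every kept feature; exact linear duplicates
  are always dropped; zero-variance features are dropped with a warning),
  then the top 2,000 survivors by CV. Scanning in CV order guarantees the
  higher-CV member of a correlated pair survives. The full feature-set
  correlation matrix is never materialized against all pairs — only
  kept-vs-candidate rows.
* **SVM-RFE** (multiclass): features are standardized on the training data;
  each iteration fits one-vs-one linear SVMs (C = 1) and scores feature i
  by Σ w_i² over all C(C−1)/2 binary classifiers — the standard multiclass
  extension of the squared-weight criterion. The `⌈step_fraction·survivors⌉`
  lowest-criterion features (at least one) are eliminated per iteration;
  step_fraction defaults to 0.1 for tractability at 2,000 features and
  recovers one-at-a-time elimination when small enough. The ranking is the
  reverse elimination order, ties broken by feature id, so the procedure is
  invariant to input feature order.
* **RF backward elimination**: a forest on all features fixes the
  importance ordering (importances are *not* recomputed between
  iterations); each step discards the least-important 20% and refits,
  recording the out-of-bag error and its binomial standard error; the
  chosen set is the smallest visited set whose OOB error is within one
  standard error of the minimum. This is a minimal-gene-set procedure: it
  deliberately returns very small sets (high precision on truly informative
  features) rather than exhaustive ones. Because the benchmark tables sweep
  feature counts, the pipeline's "rf" *selector* is the initial importance
  ranking; the elimination procedure itself is exposed separately with its
  full trace.

## Classifiers

SVM (linear one-vs-one with majority voting; ties resolved by aggregate
decision values, then label order), random forest, and naive Bayes are
standard library-backed implementations behind this package's interface.
Discretized inputs are fed to SVM/RF as ordinal integers — bins encode a
monotone expression order, which one-hot coding would destroy. NB is
categorical with additive smoothing (α = 1 by default) on bins and Gaussian
on fold change: the natural likelihood family per representation, both
exposed in configuration.

**PAM (nearest shrunken centroid)** is implemented from its equations. With
n samples, K classes, n_k per class:

    d_ik   = (x̄_ik − x̄_i) / (m_k (s_i + s0)),   m_k = √(1/n_k − 1/n)
    d'_ik  = sign(d_ik) · max(|d_ik| − Δ, 0)
    x̄'_ik = x̄_i + m_k (s_i + s0) d'_ik

with s_i the pooled within-class SD (denominator n − K) and s0 the median
of the s_i. A sample is assigned to the class minimizing
`Σ_i (x_i − x̄'_ik)²/(s_i+s0)² − 2·log π_k`; exact ties go to the first
class in label order. Δ is selected on a 30-point grid from 0 to max|d_ik|
by 5-fold stratified internal cross-validation, ties resolved toward the
larger Δ (fewer surviving features). Two numerical guards matter on
degenerate data: pooled SDs below `1e-10·max|X|` are snapped to exact zero
(pure float jitter on noiseless features would otherwise make the fudge
constant vanish inside CV folds but not in the full fit, inflating the
standardized differences inconsistently), and when every s_i is zero the
fudge constant falls back to the smallest positive SD, or 1. At Δ = 0 the
classifier reduces exactly to standardized nearest centroids with priors,
which is pinned against a brute-force oracle in the tests; at
Δ ≥ max|d_ik| every centroid collapses to the overall centroid and the
maximum-prior class is returned everywhere.

## Evaluation

Accuracy is percent correct to one decimal. Sensitivity and specificity are
one-vs-rest per class, `tp/(tp+fn)` and `tn/(tn+fp)`; a class absent from
the truth has undefined sensitivity and is reported as missing, never zero.
The stratified split allocates each class's training count by ceiling
(`⌈fraction·n_c⌉`), deterministically per seed; classes below two samples
cannot be split.

The benchmark sweeps representation × selector × classifier over the
feature grid {10..100 by 10, 150..1000 by 50}, clipped to the available
pool; "best cell" is the maximum accuracy with ties going to fewer
features. Per-class Sn/Sp is recorded at the 100-feature models.
Reports are pure functions of (data, config, seed); the single global seed
is fanned out to stages by fixed offsets (+0 split, +1 discretization,
+2 selection, +3 classification).

## Synthetic paired-platform generator

Latent log2 expression for feature f, sample s:

    L[f,s] = baseline_f + effect·1{f informative for class(s)} + N(0, σ_bio)

with baselines uniform on [4, 12] log2 units (a realistic dynamic range
that guarantees positivity after back-transform) and, by default, disjoint
10-feature signatures per class. Matched samples are observed on both
platforms through strictly monotone transforms with independent technical
noise: `O_p = 2^(T_p(L) + N(0, σ_platform))`. Platform A is the identity
scale; platform B defaults to the nonlinear monotone map
`x ↦ 3·x^1.8 + 10`, so the two platforms differ in scale, magnitude and
curvature but agree on within-feature ranks. Normal reference individuals
are simulated once in latent space and observed through each platform —
platform-matched references, and the degenerate case (identity transforms,
zero platform noise) makes the two platforms coincide exactly, a tested
contract. The default scenario has 50 training tumors per class on
platform A and 19 matched held-out test tumors per class (76 test
samples), 8 normals per platform, effect 1.5, σ_bio 0.5, σ_platform 0.3.
Generation is a pure function of the seed.

**What the generator does not emulate — and what that means for passing
tests.** Real platform pairs disagree in ways that are *not* a per-feature
monotone map of a shared latent signal: probe sets and read mapping
disagree at the feature level, normalization pipelines shift each
platform's reference point independently, and the normal pools are
profiled separately per platform. Under this generator's idealization,
fold change against the platform's own normal median *cancels* any
monotone platform map up to noise — `FC_B = h(T) − h(median N)` with h
monotone preserves each feature's sign and zero — so value-based FC
transfer looks far better here than on real platform pairs: a linear
one-vs-one SVM's votes are invariant under per-feature positive rescaling,
and even threshold- and distance-based classifiers degrade only partially
(the worked example's RF drops to ~63%). Equal-frequency binning, by
contrast, transfers *exactly* in the noiseless limit — a theorem about
ranks, tested as exact matrix equality — and near-exactly under noise.
Passing tests therefore demonstrate the rank-invariance mechanism and the
pipeline's correctness, not the full magnitude of the value-transfer
failure seen on real cross-platform data; conversely, nothing in the
idealization favors the discretized representations.

Scale: test problems use hundreds of features and tens of samples per
class rather than the ~115k isoforms and hundreds of samples of a real
cohort; the stages are all linear or low-polynomial in features, and the
2,000-feature pre-filter bound is exercised as a configuration, not a
limit of the implementation.

## Known limitations

* Supervised (entropy/MDL) discretization and dynamic, interdependent
  binning are out of scope.
* The RF backward elimination's one-standard-error rule optimizes for a
  minimal set; when a class signature is redundant, the chosen set
  intentionally keeps only one or two representatives per class.
* NB degrades when strongly correlated features pass the pre-filter, as
  conditional independence is violated.
* The CLI's serialized models embed pickled estimators (base64 inside
  JSON) and are not an archival format across library versions.
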