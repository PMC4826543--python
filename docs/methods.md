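# Methods

## Problem setting and assumptions

Peptides are fixed-length sequences (15-mers throughout the defaults) over
a 21-symbol alphabet: the 20 canonical amino acids plus citrulline (`Z`), a
deiminated arginine that appears in designed peptides but is rare in
natural libraries. Each peptide carries a microarray fluorescence signal
intensity measuring its reactivity with pooled human antibodies (IVIg).
The binary learning problem assumes two well-separated reactivity regimes:
binders with intensity strictly above 10,000 units and non-binders strictly
below 1,000 in every replicate assay. Intensities between the thresholds
are treated as unlabeled and excluded from pool construction — the model
makes no claim about that band.

The classifier assumes binding is predictable from sequence alone (local
composition, substring content, residue physicochemistry) plus, optionally,
rigid-docking score distributions supplied externally. It does not model
peptide conformation, the assay chemistry, or position-of-attachment
effects.

## Ensemble classifier

Each base member is a soft-margin SVM. String-kernel members use
precomputed Gram matrices; all shipped kernels are explicit substring-count
inner products, hence symmetric positive semidefinite by construction:

* **k-spectrum** — counts of length-k substrings; the spectra for
  k = 3, 4, 5, 6 are summed into a single kernel feeding one member (a
  per-k member per kernel is available via `KernelSpec(spectrum_ks=(k,))`).
* **sparse spatial sample** — counts of ordered probe pairs `(a, t, b)`
  with start-position displacement `1 ≤ t ≤ 6`; probe length defaults to 1.
  The published kernel family admits several probe configurations; the
  single-character two-probe variant is the simplest member consistent
  with a single displacement parameter, and probe length/displacement are
  configurable.
* **bounded-range substring** — counts of all substrings of length 1..8,
  unit weight per length (per-length weights configurable).

Kernels treat `Z` as an ordinary 21st symbol — this is deliberately the
only route by which citrulline content can influence classification.

Vector-feature members use an RBF kernel on:

* **BLOSUM50 row encoding** — each residue replaced by its 20-entry
  BLOSUM50 row (20·d dimensions). The matrix comes from Biopython,
  restricted to the 20 canonical residues; the ambiguity code `Z` (Glx) in
  the published matrix is *not* used for citrulline.
* **Reduced residue matrices** (18 and 10 columns) — stand-ins for
  published dimensionality-reduced physicochemical matrices, derived here
  by PCA of the column-stacked bundled-property/BLOSUM50 residue-property
  matrix, with a deterministic sign convention. They are synthetic
  placeholders: `load_matrix_file` accepts the published matrices when the
  user has them.
* **Window composition** — for each residue-property scale and each window
  length w ∈ {3, 4, 5}, the vector of means over all fully contained
  windows (d − w + 1 entries per property per window). Window means (not
  histograms) are used; the windows are never padded, which is what fixes
  the dimension at d − w + 1. The package bundles seven widely used scales
  (hydropathy, hydrophilicity, helix/sheet propensity, polarity, molecular
  weight, isoelectric point) and reads AAIndex1 flat files for larger
  collections; properties with missing residue values are dropped at load
  time with a logged count.
* **Docking-score histogram** (optional) — a 20-bin normalized histogram of
  per-pose docking scores. Bin edges are fixed at fit time to span the
  training corpus min/max and reused at prediction time (train and test
  must share bins); out-of-range scores clip into the end bins. This member
  joins the ensemble only when score lists are supplied — without them the
  ensemble simply has fewer members and the weights renormalize.

Residues without a row in a numeric encoding (citrulline, by default)
encode as the all-zero row with a one-time logged warning; a strict
error policy is available per matrix.

**Hyperparameters.** Grid search over C (and γ for RBF members) with
stratified k-fold cross-validation (default 5 folds), scored by fold-mean
accuracy. The default grids are the conventional libsvm log₂ ranges thinned
to step 4 (C ∈ 2^{−5,−1,3,7,11,15}, γ ∈ 2^{−15,−11,−7,−3,1}); grids are
scanned in ascending order and only strict improvements move the selection,
so ties break toward smaller C, then smaller γ — training is deterministic
for a fixed seed. The winning point is refit on all training data with
Platt sigmoid calibration (libsvm's built-in probability estimates), and
its cross-validation accuracy becomes the member weight `a_j`.

**Combination.** `p_ens = (Σ_j a_j p_j) / (Σ_j a_j)`. The normalizer sums
over exactly the members that contribute terms, making the output a convex
combination (bounded by the member min/max). Class calls use raw ensemble
probabilities against τ (boundary inclusive, `≥ τ`); τ defaults to 0.5 and
is configuration only — it is never learned. Rank-ordered lists use a
separate path in which each member's probability vector over the evaluation
set is scaled to unit standard deviation before the weighted sum;
zero-variance members are skipped with a warning, and ties in the final
score break by peptide id. Both paths are exposed because class calls and
ranked lists serve different downstream uses; scaling is monotone per
member, so with a single member the two orderings coincide.

Class imbalance (binders:non-binders ≈ 1:3) is left unweighted by default;
a `class_weight` passthrough exists.

## Designer

One walk per seed. The walk checks constraints *before* the first mutation
(a seed already satisfying them returns unchanged with mutation count 0),
then repeatedly substitutes a uniform random position with a uniform random
different symbol from the full 21-letter alphabet, returning the first
constraint-satisfying sequence. Because `Z` is absent or rare in reference
sets, substituting it is an easy escape from the shared-4-mer rule — the
citrulline enrichment of designed peptides is an expected consequence of
the constraint system, not a learned preference.

Constraint semantics, chosen where the rules were genuinely open:

* The 11-residue window rule is evaluated at **every ungapped relative
  offset** of candidate and reference with overlap ≥ 11 (gapped
  subsequences would make nearly every 15-mer a violation). Pairs whose
  overlap is everywhere shorter than the window are compared over the
  whole overlap.
* The shared-k-mer rule applies against same-category training sequences
  and against the whole test set regardless of category; the window rule
  applies to both sets as well.
* A walk that exhausts its mutation budget (default 10,000) raises a
  failure naming the seed rather than returning a violating sequence, and
  the campaign runner re-verifies every emitted candidate.

Campaign defaults mirror the study conditions: 3,000 highest- and 3,000
lowest-intensity training peptides as seeds, candidates sorted by ensemble
probability, top 1,500 → H, bottom 1,500 → L, middle 3,000 → M. Tests and
the acceptance script run the identical pipeline at reduced sizes (300
walks; classes 75/150/75) so the whole campaign fits in seconds.

## Evaluation

* **AUROC / AUPR** via scikit-learn (trapezoidal ROC area = Mann–Whitney
  with half tie credit; stepwise PR interpolation), cross-checked in tests
  against a brute-force pairwise concordance count.
* **Grey-zone metrics**: the closed band `[5500 − δ, 5500 + δ]` of measured
  intensities is excluded from numerator and denominator alike; remaining
  peptides are truly high iff intensity > 5500 + δ (strict). At δ = 0
  nothing is excluded and the metrics reduce to plain threshold-5500
  precision/recall/accuracy. δ = 4500 excludes exactly the 1,000–10,000
  band that separates the training pools. When every peptide is excluded
  the result is flagged undefined rather than fabricated.
* **Permutation F1 test**: H is the positive class;
  `p = (1 + #{F1_perm ≥ F1_obs}) / (B + 1)` with B = 1,000 label
  permutations by default, so p ≥ 1/(B+1) and the test is valid
  (sub-uniform under the null). The permuted F1 values are computed by a
  vectorized implementation that the tests cross-check against
  scikit-learn's `f1_score`. Note the statistic is discrete — F1 is a
  function of the integer true-positive count — so null p-values carry
  atoms of size ≈ 1/sd(TP); uniformity checks in the tests use label
  vectors long enough (n = 1,200) that the atoms are small relative to the
  resolution of a 200-replicate KS test. Degenerate all-one-class
  predictions get F1 = 0.
* **Diversity profile**: vertices are peptides, edges join pairs at
  Hamming distance strictly below the cutoff c; for each vertex a maximal
  independent set containing it is grown greedily, scanning the remaining
  vertices in ascending input order (maximal independent sets containing a
  vertex are not unique; the fixed scan order makes profiles reproducible).
  The mean set size is reported per cutoff and is non-increasing in c.
* **Propensity matrix**: position-specific residue frequencies of the
  true-positive set divided by those of the negative set. Default
  pseudocount 1/(set size + alphabet size) per set keeps every ratio
  finite and positive; 1 means no enrichment.

## Synthetic data

The generator emulates the statistical structure the classifier assumes:
positives carry at least one planted 4-mer motif (defaults: two motifs,
insertion probability ½ each, at least one forced) at a uniform random
position on an i.i.d. background over the 20 canonical residues; negatives
are rejection-sampled to be motif-free. Intensities are log₁₀-normal
(location 4.5/spread 0.25 for positives, 2.3/0.35 for negatives) truncated
to the label-consistent side of the 10,000 / 1,000 thresholds, so pool
construction recovers the configured counts exactly — tests need
determinate pool sizes. Synthetic docking scores are normal per pose
(2,000 poses per peptide) with a configurable mean shift for binders.

What this does **not** emulate: the real intensity distribution's shape
inside and between the threshold bands, replicate noise structure,
position-dependent motif effects, and any non-motif sequence signal.
Passing recovery tests therefore show that the pipeline can learn and
design around a clean planted signal, not that it reproduces real-assay
accuracy; the planted-motif AUROC ≥ 0.95 gate is an internal-consistency
check, not a benchmark claim.

A documented consequence of the constraint system: with planted 4-mer
motifs present in all positive training peptides, no designed candidate
may contain the exact motif. The graded `motif_proximity_score` (best
per-motif alignment identity, summed) is the ground-truth surrogate used
for design-loop checks; H-class designs score higher than L-class designs
on it even though both have exact-motif count 0.

## Numerical and engineering choices

* Gram matrices are computed as sparse count-matrix products (`X Xᵀ`), so
  symmetry is exact; kernel matrices serialize to text with 17 significant
  digits, which round-trips doubles bit-exactly.
* Train/test splitting permutes each pool with a seeded generator and
  takes the first n; equal seeds give equal splits, and train/test are
  disjoint by construction.
* Peptide identity is the sequence string; ids are metadata.
* FASTA and tabular I/O go through Biopython/pandas; duplicate FASTA ids
  are suffix-deduplicated with a warning.
* All stochastic components (splits, walks, SVM internals, permutation
  tests, synthetic data) accept explicit seeds; fixed seeds give
  bit-identical weights, rankings, and designs.

## Known limitations

* The reduced residue matrices are synthetic placeholders, not the
  published 18/10-column matrices; members built on them are typically the
  weakest of the zoo.
* The bundled property table has 7 scales; the full AAIndex collection
  must be supplied by the user (AAIndex1 flat-file reader included).
* Docking itself is out of scope: only featurization of supplied score
  lists is implemented.
* The designer enforces diversity against reference sets, not among the
  candidates themselves; mutual candidate diversity is measured (high in
  practice) but not guaranteed.
* Selection of designs for wet-lab synthesis (stratified sampling against
  external classifiers) is out of scope.
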