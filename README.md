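# epidesign

Design of diverse linear epitopes with desired antibody-binding affinity.

Antibodies in pooled human immunoglobulin (IVIg) recognize short linear
epitopes — here modeled as 15-mer peptides over the 20 canonical amino acids
plus citrulline (`Z`). Microarray assays label each peptide with a
fluorescence signal intensity: binders above 10,000 units, non-binders below
1,000 in every replicate. `epidesign` is for immunologists and computational
biologists who want to (a) classify peptides as high- or low-affinity IVIg
binders and (b) *design* novel peptides of a requested binding class that
are provably dissimilar from every peptide the classifier was trained or
tested on.

## The model

**Classifier.** An ensemble of `M` maximum-margin classifiers (libsvm via
scikit-learn), one per featurization: summed k-spectrum string kernel
(k = 3..6), sparse spatial sample kernel (displacement ≤ 6), bounded-range
substring kernel (lengths ≤ 8), BLOSUM50 row encoding, two reduced
physicochemical residue matrices (18 and 10 columns), sliding-window
property means (windows 3–5), and optionally a docking-score histogram.
Each member `j` is Platt-calibrated to emit a posterior probability
`p_+^j(x)` of the binder class and carries its cross-validation accuracy
`a^j` as a weight. The ensemble probability is the convex combination

    p_+^ens(x) = (1/A) Σ_{j=1..M} a^j p_+^j(x),   A = Σ_j a^j,

with the decision rule `x ∈ C+ iff p_+^ens(x) ≥ τ` (default τ = 0.5). For
rank-ordered candidate lists, each member's probability vector over the
evaluation set is first scaled to unit standard deviation.

**Designer.** A seeded random walk in sequence space: starting from a
high- (or low-) intensity training peptide, residues are substituted
uniformly at random until the sequence shares **no 4-mer** with any
same-category training peptide or any test peptide, and has **at most 6
identities in any 11-residue window** at any ungapped alignment offset
against those sets. Candidates from all walks are scored with the ensemble;
the top-ranked become class **H**, the bottom class **L**, the middle **M**.

**Evaluation.** ROC/PR areas; grey-zone metrics that exclude measured
intensities within `5500 ± δ` before scoring precision/recall/accuracy; a
permutation F1 test (`p = (1 + #{F1_perm ≥ F1_obs}) / (B + 1)`); diversity
as the mean size of per-vertex maximal independent sets in the graph
joining peptides at Hamming distance `< c`; and positional residue
propensities (true-positive position frequencies over negative-set
frequencies, pseudocounted).

## Worked example

Train the sequence-based ensemble on a synthetic planted-motif pool and
validate on held-out peptides (`examples/03_train_and_validate.py`):

```
member                   weight a_j   AUROC
k_spectrum                    1.000   1.000
sparse_spatial_sample         0.994   1.000
bounded_range                 0.972   1.000
blosum_encoding               0.744   0.872
reduced_matrix_18             0.733   0.767
reduced_matrix_10             0.706   0.756
local_composition             0.672   0.644
ensemble                              1.000

ensemble >= median member: True
```

Each `a_j` is the member's 3-fold cross-validation accuracy on the training
split and becomes its weight in the combination rule; the AUROC column is
measured on the held-out test peptides. The string-kernel members see the
planted 4-mer motifs directly and dominate; the ensemble matches the best
member. The other examples cover pool construction and splitting (`01`),
kernels and feature dimensioning (`02`), the design campaign (`04`), and
grey-zone / permutation / propensity evaluation of designs (`05`); each
prints a short explanation with its numbers.

A thin CLI wraps the same functions for shell pipelines:

```sh
epidesign synth --n-pos 40 --n-neg 80 --seed 5 --out train/
epidesign train --train train/peptides.tsv --out model/
epidesign design --model model/ --train train/peptides.tsv --n-seeds 10 \
    --n-high 2 --n-low 2 --seed 3 --out designs/
epidesign evaluate --predictions designs/designs.tsv --measured measured.tsv --out eval/
```

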