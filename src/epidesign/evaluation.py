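"""Evaluation metrics for affinity classification and designed peptides.

* ROC / precision-recall areas for classifier validation.
* Grey-zone ("delta") metrics for designed peptides: measured intensities in
  the band [center - delta, center + delta] (center 5500, the middle of the
  unlabeled intensity range) are excluded; the rest are called truly high
  iff intensity > center + delta, and precision / recall / accuracy of the
  predicted H class are computed on the remainder.
* Permutation F1 test: probability of the observed H/L separation arising
  by chance, estimated by permuting the true labels B times.
* Diversity profile: mean size of per-vertex greedy maximal independent
  sets in the graph joining peptides at Hamming distance below a cutoff c.
* Positional propensity matrix: position-specific residue frequencies of a
  true-positive set divided by those of a negative set (with pseudocount).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

from .core import DEFAULT_ALPHABET, PeptideAlphabet

DELTA_CENTER = 5500.0


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney statistic; ties get 0.5
    credit). Both classes must be present."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def aupr(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve (stepwise interpolation)."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUPR needs both classes present")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class DeltaMetrics:
    delta: float
    precision: float
    recall: float
    accuracy: float
    excluded_fraction: float
    n_used: int
    defined: bool = True


def delta_metrics(
    intensities: Sequence[float],
    predicted_high: Sequence[bool],
    delta: float,
    center: float = DELTA_CENTER,
) -> DeltaMetrics:
    """Grey-zone metrics at a single delta.

    Peptides with measured intensity inside [center - delta, center + delta]
    are excluded from numerator and denominator alike. Among the remainder,
    the true label is high iff intensity > center + delta (strict);
    precision and recall are for the predicted-H class, accuracy over both
    classes. When every peptide is excluded the result is flagged undefined.
    """
    if delta < 0 or delta > center - 1:
        raise ValueError(f"delta must lie in [0, {center - 1:g}]")
    x = np.asarray(intensities, dtype=float)
    pred = np.asarray(predicted_high, dtype=bool)
    if x.shape != pred.shape:
        raise ValueError("intensities and predictions differ in length")
    keep = (x < center - delta) | (x > center + delta)
    # delta = 0: nothing is excluded; the point x == center splits as low
    if delta == 0:
        keep = np.ones_like(keep)
    excluded_fraction = 1.0 - keep.mean() if len(x) else 0.0
    if not keep.any():
        return DeltaMetrics(delta, np.nan, np.nan, np.nan, 1.0, 0, defined=False)
    truth = x[keep] > center + delta
    p = pred[keep]
    tp = int(np.sum(p & truth))
    fp = int(np.sum(p & ~truth))
    fn = int(np.sum(~p & truth))
    tn = int(np.sum(~p & ~truth))
    precision = tp / (tp + fp) if tp + fp else np.nan
    recall = tp / (tp + fn) if tp + fn else np.nan
    accuracy = (tp + tn) / keep.sum()
    return DeltaMetrics(
        delta, precision, recall, float(accuracy), float(excluded_fraction), int(keep.sum())
    )


def delta_metrics_curve(
    intensities: Sequence[float],
    predicted_high: Sequence[bool],
    deltas: Sequence[float],
    center: float = DELTA_CENTER,
) -> list[DeltaMetrics]:
    return [delta_metrics(intensities, predicted_high, d, center) for d in deltas]


def _f1_vectorized(pred: np.ndarray, labels_matrix: np.ndarray) -> np.ndarray:
    """F1 of a fixed prediction vector against each row of a label matrix
    (positive class = True). Degenerate cases give F1 = 0."""
    tp = labels_matrix @ pred
    npred = pred.sum()
    npos = labels_matrix.sum(axis=1)
    denom = npred + npos
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2.0 * tp / denom, 0.0)
    return f1


@dataclass
class PermutationTestResult:
    observed_f1: float
    permuted_f1: np.ndarray
    n_permutations: int
    p_value: float


def permutation_f1_pvalue(
    predicted_high: Sequence[bool],
    true_high: Sequence[bool],
    n_permutations: int = 1000,
    seed: int = 0,
) -> PermutationTestResult:
    """Permutation test of the H-class F1 score.

    The observed F1 of the predictions is compared with the F1 distribution
    obtained by randomly permuting the true labels ``n_permutations`` times;
    p = (1 + #{permuted F1 >= observed}) / (n_permutations + 1), so p is
    never below 1/(B+1). With B = 0 the test degenerates to p = 1.
    """
    pred = np.asarray(predicted_high, dtype=float)
    truth = np.asarray(true_high, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("prediction/label length mismatch")
    observed = float(_f1_vectorized(pred, truth[None, :])[0])
    rng = np.random.default_rng(seed)
    if n_permutations > 0:
        keys = rng.random((n_permutations, len(truth)))
        perm_idx = np.argsort(keys, axis=1)
        permuted = truth[perm_idx]
        perm_f1 = _f1_vectorized(pred, permuted)
    else:
        perm_f1 = np.empty(0)
    p = (1.0 + float(np.sum(perm_f1 >= observed))) / (n_permutations + 1.0)
    return PermutationTestResult(
        observed_f1=observed, permuted_f1=perm_f1, n_permutations=n_permutations, p_value=p
    )


def observed_f1_sklearn(predicted_high: Sequence[bool], true_high: Sequence[bool]) -> float:
    """Reference F1 via scikit-learn (used as an independent cross-check of
    the vectorized implementation)."""
    return float(
        f1_score(np.asarray(true_high, dtype=int), np.asarray(predicted_high, dtype=int),
                 zero_division=0)
    )


def hamming(seq1: str, seq2: str) -> int:
    """Number of disagreeing positions between equal-length sequences."""
    if len(seq1) != len(seq2):
        raise ValueError("Hamming distance needs equal-length sequences")
    return sum(a != b for a, b in zip(seq1, seq2))


@dataclass
class DiversityProfile:
    cutoffs: list[int]
    mean_mis_size: list[float]
    n_peptides: int


def _greedy_mis_sizes(adj: np.ndarray) -> np.ndarray:
    """For each vertex v: grow a maximal independent set seeded at v,
    scanning the remaining vertices in ascending index order. Deterministic."""
    n = adj.shape[0]
    sizes = np.empty(n, dtype=int)
    for v in range(n):
        members = [v]
        blocked = adj[v].copy()
        for u in range(n):
            if u == v or blocked[u]:
                continue
            members.append(u)
            blocked |= adj[u]
        sizes[v] = len(members)
    return sizes


def diversity_profile(
    sequences: Sequence[str],
    cutoffs: Sequence[int],
    alphabet: PeptideAlphabet = DEFAULT_ALPHABET,
) -> DiversityProfile:
    """Mean maximal-independent-set size as a function of the Hamming
    cutoff c. Two peptides are joined by an edge when their Hamming
    distance is strictly below c; for each vertex a greedy maximal
    independent set containing it is grown (vertices scanned in ascending
    input order), and the mean of the n set sizes is reported. Larger means
    more mutually dissimilar peptides."""
    codes = np.vstack([alphabet.encode(s) for s in sequences])
    dist = (codes[:, None, :] != codes[None, :, :]).sum(axis=2)
    means = []
    for c in cutoffs:
        adj = dist < c
        np.fill_diagonal(adj, False)
        means.append(float(_greedy_mis_sizes(adj).mean()))
    return DiversityProfile(
        cutoffs=list(cutoffs), mean_mis_size=means, n_peptides=len(sequences)
    )


@dataclass
class PropensityMatrix:
    """values[i, j]: enrichment of residue j at position i in the
    true-positive set relative to the negative set (1 = no enrichment)."""

    residues: str
    values: np.ndarray

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("# position-specific propensity: freq_TP / freq_neg (pseudocounted)\n")
            fh.write("position\t" + "\t".join(self.residues) + "\n")
            for i, row in enumerate(self.values, start=1):
                fh.write(f"{i}\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def propensity_matrix(
    true_positives: Sequence[str],
    negatives: Sequence[str],
    pseudocount: float | None = None,
    alphabet: PeptideAlphabet = DEFAULT_ALPHABET,
) -> PropensityMatrix:
    """Ratio of position-specific residue frequencies, true-positive set
    over negative set, with a pseudocount keeping every ratio finite and
    positive. Default pseudocount: 1 / (set size + alphabet size), applied
    to each set with its own size."""
    if not true_positives or not negatives:
        raise ValueError("both peptide sets must be non-empty")
    d = len(true_positives[0])
    for s in list(true_positives) + list(negatives):
        if len(s) != d:
            raise ValueError("all peptides must have equal length")

    def freqs(seqs: Sequence[str], eps: float) -> np.ndarray:
        counts = np.zeros((d, len(alphabet)))
        for s in seqs:
            for i, a in enumerate(s):
                counts[i, alphabet.index_of(a)] += 1
        counts += eps
        return counts / counts.sum(axis=1, keepdims=True)

    eps_tp = pseudocount if pseudocount is not None else 1.0 / (len(true_positives) + len(alphabet))
    eps_neg = pseudocount if pseudocount is not None else 1.0 / (len(negatives) + len(alphabet))
    ratio = freqs(true_positives, eps_tp) / freqs(negatives, eps_neg)
    return PropensityMatrix(residues=alphabet.symbols, values=ratio)
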