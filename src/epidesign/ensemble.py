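"""Probabilistic SVM ensemble over heterogeneous peptide featurizations.

Each base classifier is a maximum-margin classifier (libsvm via
scikit-learn) trained either on a precomputed string-kernel Gram matrix or
on numeric feature vectors with a radial-basis kernel. Hyperparameters are
selected by grid search with stratified k-fold cross-validation; the
cross-validation accuracy of the selected point, ``a_j``, becomes the
member's weight. Probabilities are Platt-calibrated sigmoid outputs
(libsvm's built-in probability estimates).

The ensemble prediction is the accuracy-weighted average

    p_ens(x) = (1/A) * sum_j a_j * p_j(x),   A = sum_j a_j,

a convex combination of the member probabilities. A peptide is called a
binder when p_ens >= tau (default 0.5). For rank-ordered candidate lists a
second combination is offered in which each member's test-set probability
vector is first scaled to unit standard deviation before the weighted sum.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import joblib
import numpy as np
import yaml
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core import Label, LabeledPeptideRecord, Peptide
from .encoders import (
    AAIndexTable,
    DockScoreBinner,
    ResidueEncodingMatrix,
    WindowFeatureConfig,
    aaindex_feature_block,
    blosum50_matrix,
    bundled_property_table,
    encode_with_matrix,
    reduced_residue_matrix,
)
from .kernels import KernelSpec, build_kernel_matrix, kernel_matrix_between

logger = logging.getLogger(__name__)

#: Coarse log2 grids in the libsvm convention (step 4).
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-5, 16, 4))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-15, 2, 4))


class FeatureExtractor(Protocol):
    """Vector featurization with optional training-time state."""

    def fit(self, records: Sequence[LabeledPeptideRecord]) -> None: ...

    def transform(self, peptides: Sequence[Peptide]) -> np.ndarray: ...


@dataclass
class MatrixEncodingFeature:
    """Residue-matrix encoding (BLOSUM50 / reduced physicochemical rows)."""

    matrix: ResidueEncodingMatrix

    def fit(self, records: Sequence[LabeledPeptideRecord]) -> None:
        pass

    def transform(self, peptides: Sequence[Peptide]) -> np.ndarray:
        return np.vstack([encode_with_matrix(p, self.matrix) for p in peptides])


@dataclass
class WindowCompositionFeature:
    """Sliding-window property means over a residue-property table."""

    table: AAIndexTable
    cfg: WindowFeatureConfig = field(default_factory=WindowFeatureConfig)

    def fit(self, records: Sequence[LabeledPeptideRecord]) -> None:
        pass

    def transform(self, peptides: Sequence[Peptide]) -> np.ndarray:
        return np.vstack([aaindex_feature_block(p, self.table, self.cfg) for p in peptides])


@dataclass
class DockHistogramFeature:
    """Docking-score histogram features; ``scores`` maps peptide id to its
    per-pose score list. Bin edges are fixed on the training corpus."""

    scores: dict[str, list[float]]
    binner: DockScoreBinner = field(default_factory=DockScoreBinner)

    def fit(self, records: Sequence[LabeledPeptideRecord]) -> None:
        self.binner.fit([self.scores[r.peptide.id] for r in records])

    def transform(self, peptides: Sequence[Peptide]) -> np.ndarray:
        return np.vstack([self.binner.transform(self.scores[p.id]) for p in peptides])


@dataclass
class BaseClassifierSpec:
    """One ensemble member: either a precomputed string kernel or a vector
    featurization with an RBF kernel, plus its hyperparameter grid."""

    name: str
    kernel: KernelSpec | None = None
    feature: FeatureExtractor | None = None
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    cv_folds: int = 5
    class_weight: str | dict | None = None

    def __post_init__(self) -> None:
        if (self.kernel is None) == (self.feature is None):
            raise ValueError(f"member {self.name!r}: exactly one of kernel/feature required")
        if not self.c_grid:
            raise ValueError("empty C grid")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def _fit_quietly(model: SVC, X: np.ndarray, y: np.ndarray) -> None:
    # SVC(probability=True) is libsvm's built-in Platt sigmoid calibration,
    # exactly the calibration wanted here; silence sklearn's deprecation nudge
    # toward CalibratedClassifierCV (a different, CV-ensembled calibrator).
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*probability.*", category=FutureWarning)
        model.fit(X, y)


def _labels(records: Sequence[LabeledPeptideRecord]) -> np.ndarray:
    y = np.array([1 if r.label is Label.POSITIVE else 0 for r in records], dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training records must contain both classes")
    return y


def _cv_accuracy_precomputed(
    G: np.ndarray, y: np.ndarray, C: float, folds: int, seed: int, class_weight
) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(G, y):
        clf = SVC(kernel="precomputed", C=C, class_weight=class_weight)
        clf.fit(G[np.ix_(tr, tr)], y[tr])
        accs.append(float(np.mean(clf.predict(G[np.ix_(te, tr)]) == y[te])))
    return float(np.mean(accs))


def _cv_accuracy_rbf(
    X: np.ndarray, y: np.ndarray, C: float, gamma: float, folds: int, seed: int, class_weight
) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        clf = SVC(kernel="rbf", C=C, gamma=gamma, class_weight=class_weight)
        clf.fit(X[tr], y[tr])
        accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
    return float(np.mean(accs))


@dataclass
class TrainedBaseClassifier:
    """A fitted, Platt-calibrated member with its CV-accuracy weight."""

    spec: BaseClassifierSpec
    model: SVC
    cv_accuracy: float
    selected_params: dict
    train_peptides: list[Peptide] | None = None  # kept for precomputed kernels

    def predict_probability(self, peptides: Sequence[Peptide]) -> np.ndarray:
        """Calibrated probability of the positive (binder) class, one per
        peptide, order-preserving."""
        if self.spec.kernel is not None:
            K = kernel_matrix_between(peptides, self.train_peptides, self.spec.kernel).values
            proba = self.model.predict_proba(K)
        else:
            X = self.spec.feature.transform(peptides)
            proba = self.model.predict_proba(X)
        pos_col = int(np.where(self.model.classes_ == 1)[0][0])
        return proba[:, pos_col]


def train_base_classifier(
    spec: BaseClassifierSpec, train_records: Sequence[LabeledPeptideRecord], seed: int
) -> TrainedBaseClassifier:
    """Grid-search hyperparameters by stratified CV accuracy, refit on the
    full training data at the best point, and record that accuracy as the
    member weight. Ties break toward smaller C, then smaller gamma (grids
    are scanned in ascending order and only strict improvements move the
    selection), so training is deterministic for a fixed seed.
    """
    y = _labels(train_records)
    peptides = [r.peptide for r in train_records]
    folds = min(spec.cv_folds, int(np.bincount(y).min()))
    if folds < 2:
        raise ValueError("too few examples of the minority class for cross-validation")

    if spec.kernel is not None:
        G = build_kernel_matrix(peptides, spec.kernel).values
        if not np.any(G):
            raise ValueError(f"member {spec.name!r}: degenerate all-zero kernel matrix")
        best_acc, best = -1.0, None
        for C in sorted(spec.c_grid):
            acc = _cv_accuracy_precomputed(G, y, C, folds, seed, spec.class_weight)
            if acc > best_acc:
                best_acc, best = acc, {"C": C}
        model = SVC(
            kernel="precomputed",
            C=best["C"],
            probability=True,
            class_weight=spec.class_weight,
            random_state=seed,
        )
        _fit_quietly(model, G, y)
        return TrainedBaseClassifier(
            spec=spec,
            model=model,
            cv_accuracy=best_acc,
            selected_params=best,
            train_peptides=list(peptides),
        )

    spec.feature.fit(train_records)
    X = spec.feature.transform(peptides)
    best_acc, best = -1.0, None
    for C in sorted(spec.c_grid):
        for gamma in sorted(spec.gamma_grid):
            acc = _cv_accuracy_rbf(X, y, C, gamma, folds, seed, spec.class_weight)
            if acc > best_acc:
                best_acc, best = acc, {"C": C, "gamma": gamma}
    model = SVC(
        kernel="rbf",
        C=best["C"],
        gamma=best["gamma"],
        probability=True,
        class_weight=spec.class_weight,
        random_state=seed,
    )
    _fit_quietly(model, X, y)
    return TrainedBaseClassifier(
        spec=spec, model=model, cv_accuracy=best_acc, selected_params=best
    )


def combine_ensemble(member_probabilities: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Accuracy-weighted average of member probabilities:
    p_ens = (1/A) sum_j a_j p_j with A = sum_j a_j. ``member_probabilities``
    is (n_instances, M); returns one value in [0, 1] per instance."""
    P = np.atleast_2d(np.asarray(member_probabilities, dtype=float))
    a = np.asarray(weights, dtype=float)
    if P.shape[1] != a.shape[0]:
        raise ValueError(f"got {P.shape[1]} member columns but {a.shape[0]} weights")
    if np.any(a <= 0):
        raise ValueError("member weights must be positive")
    return P @ a / a.sum()


def classify(p_ens: np.ndarray | float, tau: float = 0.5) -> np.ndarray:
    """Decision rule: positive class iff p_ens >= tau (boundary inclusive)."""
    return np.asarray(p_ens, dtype=float) >= tau


def rank_predictions(
    member_probabilities: np.ndarray,
    weights: np.ndarray,
    peptide_ids: Sequence[str],
) -> tuple[list[str], np.ndarray]:
    """Rank-ordered candidate list: each member's probability vector over the
    evaluation set is scaled to unit standard deviation, then combined with
    the accuracy weights; peptides are returned sorted by descending score,
    ties broken by peptide id. Zero-variance members are skipped with a
    warning."""
    P = np.atleast_2d(np.asarray(member_probabilities, dtype=float))
    if P.shape[0] < 2:
        raise ValueError("ranking needs at least 2 peptides (SD undefined otherwise)")
    a = np.asarray(weights, dtype=float)
    sd = P.std(axis=0, ddof=0)
    keep = sd > 0
    if not np.all(keep):
        logger.warning("skipping %d zero-variance member(s) in ranking", int((~keep).sum()))
    if not np.any(keep):
        raise ValueError("all member probability vectors have zero variance")
    scores = (P[:, keep] / sd[keep]) @ a[keep] / a[keep].sum()
    order = sorted(range(len(peptide_ids)), key=lambda i: (-scores[i], peptide_ids[i]))
    return [peptide_ids[i] for i in order], scores[order]


@dataclass
class EnsembleModel:
    """The trained ensemble: members, their CV-accuracy weights, and tau."""

    members: list[TrainedBaseClassifier]
    tau: float = 0.5

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        if not 0.0 < self.tau < 1.0:
            raise ValueError("tau must lie in (0, 1)")

    @property
    def weights(self) -> np.ndarray:
        return np.array([m.cv_accuracy for m in self.members], dtype=float)

    def member_probabilities(self, peptides: Sequence[Peptide]) -> np.ndarray:
        """(n_peptides, M) matrix of calibrated member probabilities."""
        return np.column_stack([m.predict_probability(peptides) for m in self.members])

    def predict_probability(self, peptides: Sequence[Peptide]) -> np.ndarray:
        return combine_ensemble(self.member_probabilities(peptides), self.weights)

    def predict_class(self, peptides: Sequence[Peptide]) -> np.ndarray:
        return classify(self.predict_probability(peptides), self.tau)

    def rank(self, peptides: Sequence[Peptide]) -> tuple[list[str], np.ndarray]:
        return rank_predictions(
            self.member_probabilities(peptides), self.weights, [p.id for p in peptides]
        )

    def save(self, directory: str | os.PathLike) -> None:
        os.makedirs(directory, exist_ok=True)
        manifest = {
            "tau": self.tau,
            "members": [
                {
                    "name": m.spec.name,
                    "cv_accuracy": m.cv_accuracy,
                    "selected_params": m.selected_params,
                    "input": "kernel" if m.spec.kernel is not None else "feature",
                }
                for m in self.members
            ],
        }
        with open(os.path.join(directory, "manifest.yaml"), "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        joblib.dump(self, os.path.join(directory, "model.joblib"))

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "EnsembleModel":
        return joblib.load(os.path.join(directory, "model.joblib"))


def fit_ensemble(
    specs: Sequence[BaseClassifierSpec],
    train_records: Sequence[LabeledPeptideRecord],
    seed: int,
    tau: float = 0.5,
) -> EnsembleModel:
    """Train every member on the same training records and assemble the
    accuracy-weighted ensemble."""
    members = []
    for j, spec in enumerate(specs):
        member = train_base_classifier(spec, train_records, seed=seed + j)
        logger.info(
            "member %s: cv accuracy %.4f at %s", spec.name, member.cv_accuracy, member.selected_params
        )
        members.append(member)
    return EnsembleModel(members=members, tau=tau)


def default_ensemble_specs(
    dock_scores: dict[str, list[float]] | None = None,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID,
    cv_folds: int = 5,
) -> list[BaseClassifierSpec]:
    """The standard member zoo: summed k-spectrum (k=3..6), sparse spatial
    sample, bounded-range substring, BLOSUM50 encoding, two reduced
    physicochemical-matrix encodings (18- and 10-column synthetic
    placeholders), and window-composition features; plus a docking-score
    histogram member when per-peptide docking scores are supplied."""
    common = dict(c_grid=c_grid, gamma_grid=gamma_grid, cv_folds=cv_folds)
    specs = [
        BaseClassifierSpec(name="k_spectrum", kernel=KernelSpec(kind="spectrum"), **common),
        BaseClassifierSpec(name="sparse_spatial_sample", kernel=KernelSpec(kind="sssk"), **common),
        BaseClassifierSpec(
            name="bounded_range", kernel=KernelSpec(kind="bounded_range"), **common
        ),
        BaseClassifierSpec(
            name="blosum_encoding", feature=MatrixEncodingFeature(blosum50_matrix()), **common
        ),
        BaseClassifierSpec(
            name="reduced_matrix_18",
            feature=MatrixEncodingFeature(reduced_residue_matrix(18, name="nlf_style_synthetic")),
            **common,
        ),
        BaseClassifierSpec(
            name="reduced_matrix_10",
            feature=MatrixEncodingFeature(reduced_residue_matrix(10, name="sa_style_synthetic")),
            **common,
        ),
        BaseClassifierSpec(
            name="local_composition",
            feature=WindowCompositionFeature(bundled_property_table()),
            **common,
        ),
    ]
    if dock_scores is not None:
        specs.append(
            BaseClassifierSpec(name="structure", feature=DockHistogramFeature(dock_scores), **common)
        )
    return specs
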