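"""Numeric peptide featurizations.

Three families:

* residue-matrix encodings — replace each residue by its row in a numeric
  residue matrix (BLOSUM50, or reduced physicochemical matrices), giving an
  ``m * d``-dimensional vector for a length-``d`` peptide;
* sliding-window property features — per physicochemical property scale and
  window length ``w``, the vector of window means, ``d - w + 1`` entries;
* docking-score histograms — a normalized histogram of externally computed
  rigid-docking scores (one score per docking pose), used as a structural
  feature vector.

Citrulline ('Z') has no entry in the canonical matrices or property scales;
by default it is encoded as an all-zero row (with a warning), so its effect
on classification comes through the string kernels, which treat it as an
ordinary 21st symbol.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from ._properties import BUNDLED_PROPERTIES
from .core import CANONICAL_AMINO_ACIDS, Peptide

logger = logging.getLogger(__name__)

_WARNED_ZERO_ROWS: set[tuple[str, str]] = set()


@dataclass(frozen=True)
class ResidueEncodingMatrix:
    """Mapping residue -> numeric row of fixed width ``m``.

    ``unknown_policy`` controls residues without a row: ``"zero"``
    substitutes the all-zero row (logged), ``"error"`` raises.
    """

    name: str
    rows: dict[str, tuple[float, ...]]
    unknown_policy: str = "zero"

    def __post_init__(self) -> None:
        widths = {len(v) for v in self.rows.values()}
        if len(widths) != 1:
            raise ValueError(f"matrix {self.name!r}: rows have unequal widths {widths}")
        if self.unknown_policy not in ("zero", "error"):
            raise ValueError("unknown_policy must be 'zero' or 'error'")

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())))

    def row(self, residue: str) -> np.ndarray:
        if residue in self.rows:
            return np.asarray(self.rows[residue], dtype=float)
        if self.unknown_policy == "zero":
            if (self.name, residue) not in _WARNED_ZERO_ROWS:
                _WARNED_ZERO_ROWS.add((self.name, residue))
                logger.warning(
                    "matrix %r has no row for residue %r; substituting zero row (warned once)",
                    self.name,
                    residue,
                )
            return np.zeros(self.width)
        raise KeyError(f"matrix {self.name!r} has no row for residue {residue!r}")


def encode_with_matrix(p: Peptide, matrix: ResidueEncodingMatrix) -> np.ndarray:
    """Concatenate the matrix rows of the peptide's residues:
    ``row(a_0) || row(a_1) || ... || row(a_{d-1})``, dimension ``m * d``."""
    return np.concatenate([matrix.row(a) for a in p.sequence])


def blosum50_matrix(unknown_policy: str = "zero") -> ResidueEncodingMatrix:
    """BLOSUM50 rows restricted to the 20 canonical residues (20 columns).

    Biopython's BLOSUM50 carries extra rows/columns for ambiguity codes
    (B, Z=Glx, X, *); these are dropped so that citrulline 'Z' is handled
    by the unknown-residue policy rather than silently read as Glx.
    """
    m = substitution_matrices.load("BLOSUM50")
    rows = {
        a: tuple(float(m[a, b]) for b in CANONICAL_AMINO_ACIDS)
        for a in CANONICAL_AMINO_ACIDS
    }
    return ResidueEncodingMatrix(name="BLOSUM50", rows=rows, unknown_policy=unknown_policy)


def load_matrix_file(
    path: str | os.PathLike, name: str | None = None, unknown_policy: str = "zero"
) -> ResidueEncodingMatrix:
    """Load a residue encoding matrix from whitespace-delimited text: one row
    per residue, first token the residue letter, remaining tokens numbers.
    A header line of column labels (first token not a known single letter
    followed by numbers) is permitted and ignored."""
    rows: dict[str, tuple[float, ...]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                values = tuple(float(x) for x in parts[1:])
            except ValueError:
                continue  # header row of column labels
            if len(parts[0]) == 1 and parts[0].isalpha() and values:
                rows[parts[0].upper()] = values
    if not rows:
        raise ValueError(f"{path}: no matrix rows found")
    return ResidueEncodingMatrix(
        name=name or os.path.basename(str(path)), rows=rows, unknown_policy=unknown_policy
    )


def write_matrix_file(matrix: ResidueEncodingMatrix, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# residue encoding matrix {matrix.name} (width {matrix.width})\n")
        for residue, values in matrix.rows.items():
            fh.write(residue + " " + " ".join(f"{v:.10g}" for v in values) + "\n")


def reduced_residue_matrix(
    n_components: int,
    name: str | None = None,
    properties: dict[str, dict[str, float]] | None = None,
    unknown_policy: str = "zero",
) -> ResidueEncodingMatrix:
    """Synthetic reduced physicochemical residue matrix.

    Stand-in for published dimensionality-reduced residue matrices (e.g.
    the 20x18 nonlinear-Fisher and 20x10 clustering/PCA matrices): we
    column-stack the bundled property scales with BLOSUM50, standardize
    columns, and keep the top ``n_components`` principal-component scores
    per residue. Use :func:`load_matrix_file` to supply the published
    matrices instead.
    """
    props = properties if properties is not None else BUNDLED_PROPERTIES
    cols = [
        [props[pid][a] for a in CANONICAL_AMINO_ACIDS] for pid in sorted(props)
    ]
    b50 = blosum50_matrix()
    cols.extend(
        [b50.rows[a][j] for a in CANONICAL_AMINO_ACIDS] for j in range(b50.width)
    )
    X = np.asarray(cols, dtype=float).T  # residues x properties
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    # PCA via SVD; deterministic sign convention (largest |loading| positive)
    U, S, Vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
    if n_components > len(S):
        raise ValueError(f"cannot extract {n_components} components from rank-{len(S)} data")
    scores = U[:, :n_components] * S[:n_components]
    signs = np.sign(scores[np.argmax(np.abs(scores), axis=0), np.arange(n_components)])
    scores = scores * signs
    rows = {
        a: tuple(scores[i]) for i, a in enumerate(CANONICAL_AMINO_ACIDS)
    }
    return ResidueEncodingMatrix(
        name=name or f"pca{n_components}_synthetic", rows=rows, unknown_policy=unknown_policy
    )


# ---------------------------------------------------------------------------
# Sliding-window property features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AAIndexTable:
    """An ordered collection of per-residue property scales."""

    properties: tuple[tuple[str, dict[str, float]], ...]

    def __post_init__(self) -> None:
        ids = [pid for pid, _ in self.properties]
        if len(set(ids)) != len(ids):
            raise ValueError("property ids must be unique")

    def __len__(self) -> int:
        return len(self.properties)

    def subset(self, ids: list[str]) -> "AAIndexTable":
        lookup = dict(self.properties)
        return AAIndexTable(tuple((i, lookup[i]) for i in ids))


def bundled_property_table() -> AAIndexTable:
    return AAIndexTable(tuple(sorted(BUNDLED_PROPERTIES.items())))


def read_aaindex1(path: str | os.PathLike) -> AAIndexTable:
    """Parse an AAIndex1 flat file. Properties with missing ('NA') residue
    values are dropped, with a logged count."""
    order = "ARNDCQEGHILKMFPSTWYV"
    properties: list[tuple[str, dict[str, float]]] = []
    dropped = 0
    accession = None
    values: list[str] = []
    in_values = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("H "):
                accession = line[2:].strip()
                values, in_values = [], False
            elif line.startswith("I "):
                in_values = True
            elif line.startswith("//"):
                if accession is not None and len(values) == 20:
                    if "NA" in values:
                        dropped += 1
                    else:
                        properties.append(
                            (accession, {a: float(v) for a, v in zip(order, values)})
                        )
                accession, values, in_values = None, [], False
            elif in_values:
                values.extend(line.split())
    if dropped:
        logger.warning("dropped %d AAIndex properties with missing residue values", dropped)
    return AAIndexTable(tuple(properties))


@dataclass(frozen=True)
class WindowFeatureConfig:
    """Window lengths and optional property subset for window features."""

    window_lengths: tuple[int, ...] = (3, 4, 5)
    property_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if any(w < 1 for w in self.window_lengths):
            raise ValueError("window lengths must be >= 1")


def aaindex_window_features(
    p: Peptide, prop: dict[str, float], w: int, unknown_value: float = 0.0
) -> np.ndarray:
    """Window means of a property scale along the peptide.

    Entry ``i`` is the mean of the property over positions ``i..i+w-1``
    (0-based, fully contained windows only), giving ``d - w + 1`` entries.
    Residues without a property value (citrulline) contribute
    ``unknown_value``.
    """
    d = len(p)
    if w > d:
        raise ValueError(f"window length {w} exceeds peptide length {d}")
    vals = np.array([prop.get(a, unknown_value) for a in p.sequence], dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    return (csum[w:] - csum[:-w]) / w


def aaindex_feature_block(
    p: Peptide, table: AAIndexTable, cfg: WindowFeatureConfig = WindowFeatureConfig()
) -> np.ndarray:
    """Concatenate window features over all configured properties and window
    lengths: properties in table order (or the configured subset order),
    window lengths innermost. Dimension = #properties * sum_w (d - w + 1)."""
    tab = table.subset(list(cfg.property_ids)) if cfg.property_ids is not None else table
    blocks = [
        aaindex_window_features(p, prop, w)
        for _, prop in tab.properties
        for w in cfg.window_lengths
    ]
    return np.concatenate(blocks)


# ---------------------------------------------------------------------------
# Docking-score histogram features
# ---------------------------------------------------------------------------

@dataclass
class DockScoreBinner:
    """Histogram bins for docking-score featurization.

    Bin edges are fixed at fit time — equal-width bins spanning the
    min/max over the training corpus — and reused at predict time; scores
    outside the fitted range are clipped into the boundary bins.
    """

    n_bins: int = 20
    bin_edges: np.ndarray | None = field(default=None)

    def fit(self, score_lists: list[list[float]]) -> "DockScoreBinner":
        flat = np.concatenate([np.asarray(s, dtype=float) for s in score_lists])
        lo, hi = float(flat.min()), float(flat.max())
        if hi == lo:
            hi = lo + 1.0
        self.bin_edges = np.linspace(lo, hi, self.n_bins + 1)
        return self

    def transform(self, scores: list[float]) -> np.ndarray:
        if self.bin_edges is None:
            raise RuntimeError("DockScoreBinner is not fitted")
        return dock_score_histogram(scores, self.bin_edges)


def dock_score_histogram(scores: list[float], bin_edges: np.ndarray) -> np.ndarray:
    """Normalized histogram (counts / total) of docking scores over the given
    bins; scores outside the bin range are clipped into the end bins."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("empty docking-score list")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing with >= 2 entries")
    clipped = np.clip(arr, edges[0], edges[-1])
    counts, _ = np.histogram(clipped, bins=edges)
    return counts / counts.sum()
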