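"""Peptide string kernels and kernel (Gram) matrices.

All kernels here are explicit-feature inner products: each peptide maps to a
sparse vector of substring-feature counts and the kernel value is the dot
product. Consequently every Gram matrix is symmetric positive semidefinite.

* k-spectrum — counts of all length-k substrings; by default the spectra for
  k = 3,4,5,6 are summed into a single kernel.
* sparse spatial sample (SSSK) — counts of ordered probe pairs ``(a, t, b)``:
  substrings ``a`` and ``b`` (default probe length 1) whose start positions
  differ by a displacement ``t`` with ``1 <= t <= d_s`` (default 6).
* bounded-range substring — counts of all substrings of length 1..r
  (default r = 8), unit weight per length by default.

Citrulline 'Z' participates as an ordinary 21st symbol.
"""

from __future__ import annotations

import dataclasses
import os
from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
import scipy.sparse as sp

from .core import Peptide


@dataclass(frozen=True)
class KernelSpec:
    """Configuration of a string kernel.

    kind: 'spectrum', 'sssk' or 'bounded_range'.
    spectrum_ks: substring lengths summed for the spectrum kernel.
    sssk_displacement: max probe displacement d_s; sssk_probe_length: probe size.
    bounded_range_r: max substring length; bounded_range_weights: optional
    per-length weights (length -> weight, default 1 each).
    normalize: apply cosine normalization K/sqrt(K_ii K_jj).
    """

    kind: str = "spectrum"
    spectrum_ks: tuple[int, ...] = (3, 4, 5, 6)
    sssk_displacement: int = 6
    sssk_probe_length: int = 1
    bounded_range_r: int = 8
    bounded_range_weights: tuple[float, ...] | None = None
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("spectrum", "sssk", "bounded_range"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if any(k < 1 for k in self.spectrum_ks):
            raise ValueError("spectrum k must be positive")
        if self.sssk_displacement < 1 or self.sssk_probe_length < 1:
            raise ValueError("SSSK parameters must be positive")
        if self.bounded_range_r < 1:
            raise ValueError("bounded-range r must be positive")

    @property
    def name(self) -> str:
        if self.kind == "spectrum":
            return f"spectrum_k{'_'.join(map(str, self.spectrum_ks))}"
        if self.kind == "sssk":
            return f"sssk_d{self.sssk_displacement}"
        return f"bounded_range_r{self.bounded_range_r}"


def _spectrum_features(seq: str, ks: Sequence[int]) -> Counter:
    feats: Counter = Counter()
    for k in ks:
        if k > len(seq):
            raise ValueError(f"spectrum k={k} exceeds peptide length {len(seq)}")
        for i in range(len(seq) - k + 1):
            feats[(k, seq[i : i + k])] += 1
    return feats


def _sssk_features(seq: str, d_s: int, probe_len: int) -> Counter:
    feats: Counter = Counter()
    n_probes = len(seq) - probe_len + 1
    for i in range(n_probes):
        a = seq[i : i + probe_len]
        for t in range(1, min(d_s, n_probes - 1 - i) + 1):
            b = seq[i + t : i + t + probe_len]
            feats[(a, t, b)] += 1
    return feats


def _bounded_range_features(
    seq: str, r: int, weights: tuple[float, ...] | None
) -> Counter:
    feats: Counter = Counter()
    for length in range(1, min(r, len(seq)) + 1):
        w = 1.0 if weights is None else weights[length - 1]
        if w == 0.0:
            continue
        sw = np.sqrt(w)
        for i in range(len(seq) - length + 1):
            feats[seq[i : i + length]] += sw
    return feats


def feature_counts(p: Peptide | str, spec: KernelSpec) -> Counter:
    """Explicit substring-feature counts of a peptide under a kernel spec."""
    seq = p.sequence if isinstance(p, Peptide) else p
    if spec.kind == "spectrum":
        return _spectrum_features(seq, spec.spectrum_ks)
    if spec.kind == "sssk":
        return _sssk_features(seq, spec.sssk_displacement, spec.sssk_probe_length)
    return _bounded_range_features(seq, spec.bounded_range_r, spec.bounded_range_weights)


def _dot(c1: Counter, c2: Counter) -> float:
    if len(c2) < len(c1):
        c1, c2 = c2, c1
    return float(sum(v * c2[k] for k, v in c1.items() if k in c2))


def kernel_value(p1: Peptide | str, p2: Peptide | str, spec: KernelSpec) -> float:
    """Evaluate the kernel between two peptides (un-normalized unless the
    spec asks for cosine normalization)."""
    c1, c2 = feature_counts(p1, spec), feature_counts(p2, spec)
    v = _dot(c1, c2)
    if spec.normalize:
        denom = np.sqrt(_dot(c1, c1) * _dot(c2, c2))
        v = v / denom if denom > 0 else 0.0
    return v


def spectrum_kernel(p1: Peptide | str, p2: Peptide | str, k: int) -> float:
    """Inner product of length-k substring count vectors."""
    return kernel_value(p1, p2, KernelSpec(kind="spectrum", spectrum_ks=(k,)))


def sssk_kernel(p1: Peptide | str, p2: Peptide | str, spec: KernelSpec | None = None) -> float:
    """Sparse spatial sample kernel: counts of (probe, displacement, probe)
    triples with displacement <= d_s."""
    spec = spec if spec is not None else KernelSpec(kind="sssk")
    if spec.kind != "sssk":
        raise ValueError("spec.kind must be 'sssk'")
    return kernel_value(p1, p2, spec)


def bounded_range_kernel(p1: Peptide | str, p2: Peptide | str, r: int = 8) -> float:
    """Sum over substring lengths 1..r of substring-count inner products."""
    return kernel_value(p1, p2, KernelSpec(kind="bounded_range", bounded_range_r=r))


@dataclass
class KernelMatrix:
    """A kernel matrix aligned to an ordered peptide-id list. Square
    (symmetric Gram) or rectangular (rows vs columns, e.g. test vs train)."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("matrix shape does not match id lists")

    @property
    def is_square(self) -> bool:
        return self.row_ids == self.col_ids

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("#rows " + " ".join(self.row_ids) + "\n")
            fh.write("#cols " + " ".join(self.col_ids) + "\n")
            for row in self.values:
                fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")

    @classmethod
    def load(cls, path: str | os.PathLike) -> "KernelMatrix":
        with open(path) as fh:
            rows_line = fh.readline()
            cols_line = fh.readline()
            if not rows_line.startswith("#rows") or not cols_line.startswith("#cols"):
                raise ValueError(f"{path}: missing #rows/#cols header")
            row_ids = rows_line.split()[1:]
            col_ids = cols_line.split()[1:]
            values = np.loadtxt(fh, ndmin=2)
        return cls(row_ids=row_ids, col_ids=col_ids, values=values)


def _count_matrix(
    peptides: Sequence[Peptide], spec: KernelSpec, vocab: dict[Hashable, int] | None = None
) -> tuple[sp.csr_matrix, dict[Hashable, int]]:
    counters = [feature_counts(p, spec) for p in peptides]
    grow = vocab is None
    if vocab is None:
        vocab = {}
    data, indices, indptr = [], [], [0]
    for c in counters:
        for feat, cnt in c.items():
            if feat not in vocab:
                if grow:
                    vocab[feat] = len(vocab)
                else:
                    continue
            indices.append(vocab[feat])
            data.append(cnt)
        indptr.append(len(indices))
    X = sp.csr_matrix(
        (np.asarray(data, dtype=float), indices, indptr),
        shape=(len(peptides), max(len(vocab), 1)),
    )
    return X, vocab


def build_kernel_matrix(peptides: Sequence[Peptide], spec: KernelSpec) -> KernelMatrix:
    """Square Gram matrix M[i][j] = kernel(p_i, p_j); symmetric by
    construction (computed as X X^T on explicit feature counts)."""
    X, _ = _count_matrix(peptides, spec)
    G = np.asarray((X @ X.T).todense(), dtype=float)
    if spec.normalize:
        d = np.sqrt(np.diag(G))
        d[d == 0] = 1.0
        G = G / np.outer(d, d)
    ids = [p.id for p in peptides]
    return KernelMatrix(row_ids=ids, col_ids=list(ids), values=G)


def kernel_matrix_between(
    rows: Sequence[Peptide], cols: Sequence[Peptide], spec: KernelSpec
) -> KernelMatrix:
    """Rectangular kernel evaluation (e.g. test peptides vs training
    peptides for a precomputed-kernel SVM)."""
    Xc, vocab = _count_matrix(cols, spec)
    Xr, _ = _count_matrix(rows, spec, vocab=vocab)
    K = np.asarray((Xr @ Xc.T).todense(), dtype=float)
    if spec.normalize:
        raw = dataclasses.replace(spec, normalize=False)
        dr = np.array([kernel_value(p, p, raw) for p in rows])
        dc = np.array([kernel_value(p, p, raw) for p in cols])
        dr, dc = np.sqrt(dr), np.sqrt(dc)
        dr[dr == 0] = 1.0
        dc[dc == 0] = 1.0
        K = K / np.outer(dr, dc)
    return KernelMatrix(row_ids=[p.id for p in rows], col_ids=[p.id for p in cols], values=K)
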