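"""Domain types: peptide alphabet, peptides, labeled records, pools and splits.

Peptides are short fixed-length amino-acid sequences (typically 15-mers)
probed on an epitope microarray against pooled human antibodies (IVIg).
Each peptide carries a measured fluorescence signal intensity; peptides
with intensity above a high threshold form the positive (binder) pool and
peptides below a low threshold, in every replicate, form the negative
(non-binder) pool. The band between the thresholds is left unlabeled.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: The 20 canonical amino acids in alphabetical one-letter order.
CANONICAL_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Citrulline, a non-standard amino acid produced by arginine deimination.
CITRULLINE = "Z"


class Label(enum.Enum):
    """Binding class of a peptide record."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNLABELED = "unlabeled"


@dataclass(frozen=True)
class PeptideAlphabet:
    """Ordered residue alphabet; default is the 20 canonical amino acids
    plus citrulline ('Z') as a first-class 21st symbol."""

    symbols: str = CANONICAL_AMINO_ACIDS + CITRULLINE

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        for s in self.symbols:
            if len(s) != 1 or not s.isupper():
                raise ValueError(f"alphabet symbol {s!r} is not a single uppercase character")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def index_of(self, symbol: str) -> int:
        idx = self.symbols.find(symbol)
        if idx < 0:
            raise KeyError(f"symbol {symbol!r} not in alphabet")
        return idx

    def validate(self, sequence: str) -> None:
        """Raise ValueError naming the first offending symbol, if any."""
        for pos, ch in enumerate(sequence):
            if ch not in self.symbols:
                raise ValueError(
                    f"residue {ch!r} at position {pos} is not in the alphabet {self.symbols!r}"
                )

    def encode(self, sequence: str) -> np.ndarray:
        """Sequence -> int codes (0-based ordinals), validating on the way."""
        self.validate(sequence)
        lut = {c: i for i, c in enumerate(self.symbols)}
        return np.fromiter((lut[c] for c in sequence), dtype=np.int8, count=len(sequence))


DEFAULT_ALPHABET = PeptideAlphabet()


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with an identifier. Identity and deduplication are
    by sequence string; the id is metadata."""

    id: str
    sequence: str
    alphabet: PeptideAlphabet = field(default=DEFAULT_ALPHABET, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        self.alphabet.validate(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LabeledPeptideRecord:
    """A peptide plus its measured signal intensity (fluorescence units).

    ``replicate_intensities`` optionally carries the per-replicate
    measurements (e.g. triplicate assays); ``intensity`` is the working
    value used for thresholding when replicates are absent.
    """

    peptide: Peptide
    intensity: float
    label: Label = Label.UNLABELED
    replicate_intensities: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("signal intensity must be non-negative")


@dataclass(frozen=True)
class PoolConfig:
    """Thresholds defining the positive / negative pools.

    Defaults match the microarray study conventions: binders have signal
    intensity above 10,000; non-binders are below 1,000 in every replicate.
    """

    positive_threshold: float = 10_000.0
    negative_threshold: float = 1_000.0
    replicate_rule: bool = True

    def __post_init__(self) -> None:
        if not self.negative_threshold < self.positive_threshold:
            raise ValueError("negative_threshold must be below positive_threshold")


@dataclass
class TrainTestSplit:
    train: list[LabeledPeptideRecord]
    test: list[LabeledPeptideRecord]
    seed: int


def build_pools(
    records: Iterable[LabeledPeptideRecord], cfg: PoolConfig = PoolConfig()
) -> tuple[list[LabeledPeptideRecord], list[LabeledPeptideRecord]]:
    """Partition records into (positive pool, negative pool) by intensity.

    Positive: intensity strictly above ``cfg.positive_threshold``.
    Negative: intensity strictly below ``cfg.negative_threshold`` — in every
    replicate when replicate intensities are present and the replicate rule
    is on. Records in the middle band belong to neither pool and are
    returned with their label left unassigned.
    """
    positive: list[LabeledPeptideRecord] = []
    negative: list[LabeledPeptideRecord] = []
    for rec in records:
        if rec.intensity > cfg.positive_threshold:
            positive.append(dataclasses.replace(rec, label=Label.POSITIVE))
            continue
        if cfg.replicate_rule and rec.replicate_intensities is not None:
            is_neg = all(v < cfg.negative_threshold for v in rec.replicate_intensities)
        else:
            is_neg = rec.intensity < cfg.negative_threshold
        if is_neg:
            negative.append(dataclasses.replace(rec, label=Label.NEGATIVE))
    return positive, negative


def make_train_test_split(
    positive_pool: Sequence[LabeledPeptideRecord],
    negative_pool: Sequence[LabeledPeptideRecord],
    n_pos_train: int,
    n_neg_train: int,
    seed: int,
) -> TrainTestSplit:
    """Uniform random sample (without replacement) of ``n_pos_train``
    positives and ``n_neg_train`` negatives into the training set; every
    remaining pool member goes to the test set."""
    if n_pos_train > len(positive_pool):
        raise ValueError(
            f"n_pos_train={n_pos_train} exceeds positive pool size {len(positive_pool)}"
        )
    if n_neg_train > len(negative_pool):
        raise ValueError(
            f"n_neg_train={n_neg_train} exceeds negative pool size {len(negative_pool)}"
        )
    rng = np.random.default_rng(seed)
    train: list[LabeledPeptideRecord] = []
    test: list[LabeledPeptideRecord] = []
    for pool, n_train in ((positive_pool, n_pos_train), (negative_pool, n_neg_train)):
        idx = rng.permutation(len(pool))
        chosen = set(idx[:n_train].tolist())
        train.extend(pool[i] for i in sorted(chosen))
        test.extend(pool[i] for i in range(len(pool)) if i not in chosen)
    return TrainTestSplit(train=train, test=test, seed=seed)
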