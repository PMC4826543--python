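"""Diversity-constrained design of novel peptides by seeded random walks.

A design walk starts from a seed peptide drawn from a reactivity category
(H = highest measured intensities, L = lowest) and repeatedly substitutes a
uniformly chosen residue at a uniformly chosen position until the sequence
satisfies two hard diversity rules against its reference sets:

* it shares no length-k substring (default k = 4) with any same-category
  training sequence, nor with any sequence in the withheld test set;
* at no ungapped alignment offset does any window of length 11 contain more
  than 6 positional identities with any reference sequence.

The walk stops at the first satisfying sequence. Candidates from all seeds
are scored with the trained ensemble and partitioned by rank into classes
H (top), L (bottom) and M (the rest).

The replacement residue is drawn from the full alphabet including
citrulline 'Z'; because 'Z' is rare or absent in typical reference sets it
trivially helps a walk escape the shared-k-mer rule, which is why designed
peptides tend to be citrulline-rich.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import DEFAULT_ALPHABET, LabeledPeptideRecord, Peptide, PeptideAlphabet
from .ensemble import EnsembleModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiversityConstraints:
    """Hard sequence-diversity rules for designed peptides."""

    kmer_length: int = 4
    window_length: int = 11
    max_identities: int = 6

    def __post_init__(self) -> None:
        if not self.max_identities < self.window_length:
            raise ValueError("max_identities must be below window_length")
        if self.kmer_length > self.window_length:
            raise ValueError("kmer_length must not exceed window_length")
        if self.kmer_length < 1:
            raise ValueError("kmer_length must be positive")


class KmerIndex:
    """Per-category set of all length-k substrings of the reference
    sequences, for O(1) shared-k-mer checks."""

    def __init__(self, k: int) -> None:
        self.k = k
        self._by_category: dict[str, set[str]] = {}

    def add(self, category: str, sequences: Sequence[str]) -> None:
        kmers = self._by_category.setdefault(category, set())
        for seq in sequences:
            for i in range(len(seq) - self.k + 1):
                kmers.add(seq[i : i + self.k])

    def kmers(self, category: str) -> set[str]:
        return self._by_category.get(category, set())

    def categories(self) -> list[str]:
        return sorted(self._by_category)


def build_constraint_index(
    constraints: DiversityConstraints, reference_sets: dict[str, Sequence[str]]
) -> KmerIndex:
    """Index every length-k substring of every reference sequence, keyed by
    reactivity category."""
    index = KmerIndex(constraints.kmer_length)
    for category, seqs in reference_sets.items():
        index.add(category, seqs)
    return index


def violates_shared_kmer(candidate: str, index: KmerIndex, category: str) -> bool:
    """True iff any length-k substring of the candidate occurs in the
    category's reference index."""
    k = index.k
    if len(candidate) < k:
        raise ValueError(f"candidate shorter than k={k}")
    kmers = index.kmers(category)
    return any(candidate[i : i + k] in kmers for i in range(len(candidate) - k + 1))


def _window_match_violation(
    cand_codes: np.ndarray, ref_codes: np.ndarray, w: int, max_ident: int
) -> bool:
    """Check one candidate against a stack of equal-length references:
    any length-w window at any ungapped offset with > max_ident matches?"""
    n_cand, n_ref = len(cand_codes), ref_codes.shape[1]
    max_shift = min(n_cand, n_ref) - w
    if max_shift < 0:
        # overlap everywhere shorter than the window: compare whole overlaps
        L = min(n_cand, n_ref)
        return bool(np.any((ref_codes[:, :L] == cand_codes[:L]).sum(axis=1) > max_ident))
    for shift in range(-max_shift, max_shift + 1):
        if shift >= 0:
            c, r = cand_codes[shift:], ref_codes[:, : n_cand - shift]
        else:
            c, r = cand_codes[: n_cand + shift], ref_codes[:, -shift:]
        L = min(len(c), r.shape[1])
        eq = (r[:, :L] == c[:L]).astype(np.int32)
        csum = np.concatenate([np.zeros((eq.shape[0], 1), dtype=np.int32), eq.cumsum(axis=1)], axis=1)
        window_matches = csum[:, w:] - csum[:, :-w]
        if window_matches.size and window_matches.max() > max_ident:
            return True
    return False


def violates_window_identity(
    candidate: str,
    reference: str | Sequence[str] | np.ndarray,
    constraints: DiversityConstraints = DiversityConstraints(),
    alphabet: PeptideAlphabet = DEFAULT_ALPHABET,
) -> bool:
    """True iff, at some ungapped relative alignment offset with overlap of
    at least the window length, a window of ``window_length`` positions has
    more than ``max_identities`` matches between candidate and any
    reference. Pairs whose overlap is everywhere shorter than the window
    are compared over the whole overlap."""
    cand_codes = alphabet.encode(candidate)
    if isinstance(reference, str):
        refs = [reference]
    else:
        refs = list(reference)
    if not refs:
        return False
    if isinstance(refs[0], str):
        by_len: dict[int, list[np.ndarray]] = {}
        for r in refs:
            by_len.setdefault(len(r), []).append(alphabet.encode(r))
        stacks = [np.vstack(v) for v in by_len.values()]
    else:
        stacks = [np.atleast_2d(np.asarray(refs))]
    return any(
        _window_match_violation(
            cand_codes, stack, constraints.window_length, constraints.max_identities
        )
        for stack in stacks
    )


@dataclass(frozen=True)
class DesignCandidate:
    sequence: str
    seed_id: str
    seed_category: str
    mutation_count: int
    probability: float | None = None
    assigned_class: str | None = None  # 'H', 'M' or 'L'


@dataclass
class ReferenceSets:
    """The sequences a candidate must diversify away from: same-category
    training sequences (k-mer and window rules) and the withheld test-set
    sequences (both rules, regardless of category)."""

    training_by_category: dict[str, list[str]]
    test_sequences: list[str] = field(default_factory=list)


class _ConstraintChecker:
    """Precomputed state for fast repeated constraint evaluation."""

    def __init__(
        self,
        constraints: DiversityConstraints,
        refs: ReferenceSets,
        alphabet: PeptideAlphabet = DEFAULT_ALPHABET,
    ) -> None:
        self.constraints = constraints
        self.alphabet = alphabet
        self.index = build_constraint_index(
            constraints,
            {**refs.training_by_category, "__test__": refs.test_sequences},
        )
        self._stacks: dict[str, list[np.ndarray]] = {}
        for cat, seqs in refs.training_by_category.items():
            self._stacks[cat] = self._stack(seqs)
        self._stacks["__test__"] = self._stack(refs.test_sequences)

    def _stack(self, seqs: Sequence[str]) -> list[np.ndarray]:
        by_len: dict[int, list[np.ndarray]] = {}
        for s in seqs:
            by_len.setdefault(len(s), []).append(self.alphabet.encode(s))
        return [np.vstack(v) for v in by_len.values()]

    def satisfies(self, candidate: str, category: str) -> bool:
        for cat in (category, "__test__"):
            if self.index.kmers(cat) and violates_shared_kmer(candidate, self.index, cat):
                return False
            cand_codes = self.alphabet.encode(candidate)
            for stack in self._stacks.get(cat, []):
                if _window_match_violation(
                    cand_codes,
                    stack,
                    self.constraints.window_length,
                    self.constraints.max_identities,
                ):
                    return False
        return True


class DesignWalkError(RuntimeError):
    """Raised when a walk exhausts its mutation budget."""


def random_walk_design(
    seed_peptide: Peptide,
    category: str,
    constraints: DiversityConstraints,
    refs: ReferenceSets,
    rng: np.random.Generator | int,
    max_mutations: int = 10_000,
    alphabet: PeptideAlphabet = DEFAULT_ALPHABET,
    _checker: "_ConstraintChecker | None" = None,
) -> DesignCandidate:
    """Walk from the seed by uniform point substitutions (position uniform,
    replacement uniform over the alphabet minus the current residue) until
    the sequence violates neither diversity rule against the same-category
    training references and the test set; return the first satisfying
    sequence. Raises :class:`DesignWalkError` past ``max_mutations``."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    checker = _checker if _checker is not None else _ConstraintChecker(constraints, refs, alphabet)
    seq = list(seed_peptide.sequence)
    symbols = alphabet.symbols
    for n_mut in range(max_mutations + 1):
        candidate = "".join(seq)
        if checker.satisfies(candidate, category):
            return DesignCandidate(
                sequence=candidate,
                seed_id=seed_peptide.id,
                seed_category=category,
                mutation_count=n_mut,
            )
        pos = int(rng.integers(len(seq)))
        choices = [s for s in symbols if s != seq[pos]]
        seq[pos] = choices[int(rng.integers(len(choices)))]
    raise DesignWalkError(
        f"walk from seed {seed_peptide.id!r} exceeded {max_mutations} mutations"
    )


def run_design_campaign(
    positive_pool: Sequence[LabeledPeptideRecord],
    negative_pool: Sequence[LabeledPeptideRecord],
    model: EnsembleModel,
    test_sequences: Sequence[str],
    n_high_seeds: int = 3000,
    n_low_seeds: int = 3000,
    n_high_class: int = 1500,
    n_low_class: int = 1500,
    constraints: DiversityConstraints = DiversityConstraints(),
    seed: int = 0,
    max_mutations: int = 10_000,
    alphabet: PeptideAlphabet = DEFAULT_ALPHABET,
) -> list[DesignCandidate]:
    """Full design campaign.

    Seeds are the ``n_high_seeds`` highest-intensity and ``n_low_seeds``
    lowest-intensity training peptides; one walk per seed, with reference
    sets formed from the same-category training sequences plus the test
    set. All candidates are scored with the ensemble; the ``n_high_class``
    highest-probability candidates are assigned class H, the
    ``n_low_class`` lowest class L, and the remainder class M.
    """
    if n_high_seeds > len(positive_pool) or n_low_seeds > len(negative_pool):
        raise ValueError("fewer training peptides than requested seeds")
    if n_high_class + n_low_class > n_high_seeds + n_low_seeds:
        raise ValueError("class sizes exceed candidate count")

    by_intensity_desc = sorted(positive_pool, key=lambda r: (-r.intensity, r.peptide.id))
    by_intensity_asc = sorted(negative_pool, key=lambda r: (r.intensity, r.peptide.id))
    seeds = [("H", r.peptide) for r in by_intensity_desc[:n_high_seeds]] + [
        ("L", r.peptide) for r in by_intensity_asc[:n_low_seeds]
    ]

    refs = ReferenceSets(
        training_by_category={
            "H": [r.peptide.sequence for r in positive_pool],
            "L": [r.peptide.sequence for r in negative_pool],
        },
        test_sequences=list(test_sequences),
    )
    checker = _ConstraintChecker(constraints, refs, alphabet)
    rng = np.random.default_rng(seed)

    candidates = []
    for category, pep in seeds:
        candidates.append(
            random_walk_design(
                pep, category, constraints, refs, rng,
                max_mutations=max_mutations, alphabet=alphabet, _checker=checker,
            )
        )

    probs = model.predict_probability(
        [Peptide(id=f"design{i}", sequence=c.sequence, alphabet=alphabet)
         for i, c in enumerate(candidates)]
    )
    order = sorted(range(len(candidates)), key=lambda i: (-probs[i], candidates[i].sequence))
    classed: list[DesignCandidate] = [None] * len(candidates)  # type: ignore[list-item]
    for rank, i in enumerate(order):
        if rank < n_high_class:
            cls = "H"
        elif rank >= len(order) - n_low_class:
            cls = "L"
        else:
            cls = "M"
        c = candidates[i]
        classed[i] = DesignCandidate(
            sequence=c.sequence,
            seed_id=c.seed_id,
            seed_category=c.seed_category,
            mutation_count=c.mutation_count,
            probability=float(probs[i]),
            assigned_class=cls,
        )
    return classed
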