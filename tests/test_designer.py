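"""Diversity constraints, random-walk design, and campaign structure."""

import numpy as np
import pytest

import epidesign as ed
from epidesign.designer import DesignWalkError, ReferenceSets


# --- independent naive constraint checkers (oracles) -----------------------

def naive_shares_kmer(candidate, references, k=4):
    cand_kmers = {candidate[i : i + k] for i in range(len(candidate) - k + 1)}
    for ref in references:
        for i in range(len(ref) - k + 1):
            if ref[i : i + k] in cand_kmers:
                return True
    return False


def naive_window_violation(candidate, references, w=11, max_ident=6):
    for ref in references:
        max_shift = min(len(candidate), len(ref)) - w
        if max_shift < 0:
            L = min(len(candidate), len(ref))
            if sum(a == b for a, b in zip(candidate[:L], ref[:L])) > max_ident:
                return True
            continue
        for shift in range(-max_shift, max_shift + 1):
            c = candidate[shift:] if shift >= 0 else candidate[: len(candidate) + shift]
            r = ref[: len(candidate) - shift] if shift >= 0 else ref[-shift:]
            L = min(len(c), len(r))
            for start in range(L - w + 1):
                matches = sum(
                    a == b for a, b in zip(c[start : start + w], r[start : start + w])
                )
                if matches > max_ident:
                    return True
    return False


class TestKmerIndex:
    def test_single_reference(self):
        idx = ed.build_constraint_index(ed.DiversityConstraints(), {"H": ["ACDEF"]})
        assert idx.kmers("H") == {"ACDE", "CDEF"}

    def test_empty_reference_set(self):
        idx = ed.build_constraint_index(ed.DiversityConstraints(), {"H": []})
        assert idx.kmers("H") == set()
        assert not ed.violates_shared_kmer("ACDEFGHIKLMNPQR", idx, "H")

    def test_union_property(self, rng):
        from conftest import random_peptides

        x = [p.sequence for p in random_peptides(rng, 5, 15)]
        y = [p.sequence for p in random_peptides(rng, 5, 15, prefix="y")]
        c = ed.DiversityConstraints()
        ix = ed.build_constraint_index(c, {"H": x})
        iy = ed.build_constraint_index(c, {"H": y})
        ixy = ed.build_constraint_index(c, {"H": x + y})
        assert ixy.kmers("H") == ix.kmers("H") | iy.kmers("H")


class TestSharedKmer:
    def test_detects_shared_4mer(self):
        idx = ed.build_constraint_index(ed.DiversityConstraints(), {"H": ["ACDEF"]})
        assert ed.violates_shared_kmer("WWACDEWWWWWWWWW", idx, "H")

    def test_shared_3mer_only_is_allowed(self):
        idx = ed.build_constraint_index(ed.DiversityConstraints(), {"H": ["ACDEF"]})
        assert not ed.violates_shared_kmer("WWACDWWWWWWWWWW", idx, "H")

    def test_disjoint_alphabets_never_violate(self):
        idx = ed.build_constraint_index(ed.DiversityConstraints(), {"H": ["ACDEFGHIKLMNPQR"]})
        assert not ed.violates_shared_kmer("WYZWYZWYZWYZWYZ", idx, "H")


class TestWindowIdentity:
    def test_seven_consecutive_identities_violate(self):
        ref = "ACDEFGHIKLMNPQR"
        cand = ref[:7] + "WWWWWWWW"  # identical in 7 consecutive positions
        assert ed.violates_window_identity(cand, ref)

    def test_six_identities_per_window_pass(self):
        ref = "A" * 15
        # alternate: every 11-window has at most 6 matches at zero offset;
        # shifted offsets only lower the match count for this pattern
        cand = "AW" * 7 + "A"
        assert not ed.violates_window_identity(cand, ref)

    def test_identical_sequences_violate(self):
        ref = "ACDEFGHIKLMNPQR"
        assert ed.violates_window_identity(ref, ref)

    def test_offset_alignment_is_checked(self):
        ref = "ACDEFGHIKLMNPQR"
        cand = "WWWW" + ref[:11]  # 11 identities at relative offset 4
        assert ed.violates_window_identity(cand, ref)

    def test_matches_naive_checker_on_random_pairs(self, rng):
        from conftest import random_peptides

        # biased alphabet raises match counts enough to exercise both outcomes
        symbols = np.array(list("ACD"))
        for i in range(50):
            cand = "".join(rng.choice(symbols, size=15))
            refs = ["".join(rng.choice(symbols, size=15)) for _ in range(5)]
            assert ed.violates_window_identity(cand, refs) == naive_window_violation(
                cand, refs
            )


class TestRandomWalk:
    def constraints(self):
        return ed.DiversityConstraints()

    def test_empty_references_return_seed_unchanged(self):
        seed = ed.Peptide("s", "ACDEFGHIKLMNPQR")
        refs = ReferenceSets(training_by_category={"H": []})
        cand = ed.random_walk_design(seed, "H", self.constraints(), refs, rng=0)
        assert cand.sequence == seed.sequence and cand.mutation_count == 0

    def test_walk_result_passes_both_naive_checkers(self, rng):
        from conftest import random_peptides

        refs_h = [p.sequence for p in random_peptides(rng, 20, 15)]
        test_seqs = [p.sequence for p in random_peptides(rng, 10, 15, prefix="t")]
        refs = ReferenceSets(training_by_category={"H": refs_h}, test_sequences=test_seqs)
        seed = ed.Peptide("s", refs_h[0])
        cand = ed.random_walk_design(seed, "H", self.constraints(), refs, rng=7)
        for ref_set in (refs_h, test_seqs):
            assert not naive_shares_kmer(cand.sequence, ref_set)
            assert not naive_window_violation(cand.sequence, ref_set)
        assert len(cand.sequence) == len(seed.sequence)

    def test_fixed_rng_seed_reproduces_candidate(self, rng):
        from conftest import random_peptides

        refs_h = [p.sequence for p in random_peptides(rng, 10, 15)]
        refs = ReferenceSets(training_by_category={"H": refs_h})
        seed = ed.Peptide("s", refs_h[0])
        c1 = ed.random_walk_design(seed, "H", self.constraints(), refs, rng=99)
        c2 = ed.random_walk_design(seed, "H", self.constraints(), refs, rng=99)
        assert c1.sequence == c2.sequence and c1.mutation_count == c2.mutation_count

    def test_mutation_cap_raises_named_failure(self):
        # an impossible constraint set: candidate must avoid every 4-mer over
        # a 2-letter alphabet while staying on that alphabet is unachievable
        alphabet = ed.PeptideAlphabet("AC")
        seqs = []
        import itertools

        for tup in itertools.product("AC", repeat=4):
            seqs.append("".join(tup) * 4)  # every possible 4-mer occurs
        refs = ReferenceSets(training_by_category={"H": seqs})
        seed = ed.Peptide("stuck", "AC" * 8, alphabet=alphabet)
        with pytest.raises(DesignWalkError, match="stuck"):
            ed.random_walk_design(
                seed, "H", self.constraints(), refs, rng=0, max_mutations=200, alphabet=alphabet
            )


class TestCampaign:
    def test_class_sizes_and_score_ordering(self, mini_model, small_split):
        pos, neg = ed.build_pools(small_split.train)
        test_seqs = [r.peptide.sequence for r in small_split.test[:40]]
        cands = ed.run_design_campaign(
            pos, neg, mini_model, test_seqs,
            n_high_seeds=12, n_low_seeds=12, n_high_class=6, n_low_class=6, seed=5,
        )
        assert len(cands) == 24
        counts = {c: sum(x.assigned_class == c for x in cands) for c in "HML"}
        assert counts == {"H": 6, "M": 12, "L": 6}
        h = [c.probability for c in cands if c.assigned_class == "H"]
        m = [c.probability for c in cands if c.assigned_class == "M"]
        l = [c.probability for c in cands if c.assigned_class == "L"]
        assert min(h) >= max(m) and min(m) >= max(l)

    def test_two_seeds_one_high_one_low(self, mini_model, small_split):
        pos, neg = ed.build_pools(small_split.train)
        cands = ed.run_design_campaign(
            pos, neg, mini_model, [], n_high_seeds=1, n_low_seeds=1,
            n_high_class=1, n_low_class=1, seed=5,
        )
        by_class = {c.assigned_class: c for c in cands}
        assert set(by_class) == {"H", "L"}
        assert by_class["H"].probability >= by_class["L"].probability

    def test_more_seeds_than_pool_is_an_error(self, mini_model, small_split):
        pos, neg = ed.build_pools(small_split.train)
        with pytest.raises(ValueError, match="seeds"):
            ed.run_design_campaign(
                pos, neg, mini_model, [], n_high_seeds=len(pos) + 1, n_low_seeds=1,
                n_high_class=1, n_low_class=1,
            )

    def test_candidate_length_equals_seed_length(self, mini_model, small_split):
        pos, neg = ed.build_pools(small_split.train)
        cands = ed.run_design_campaign(
            pos, neg, mini_model, [], n_high_seeds=5, n_low_seeds=5,
            n_high_class=2, n_low_class=2, seed=1,
        )
        assert all(len(c.sequence) == 15 for c in cands)

    def test_h_candidates_avoid_planted_motifs_but_keep_proximity(
        self, mini_model, small_split
    ):
        # the planted motifs occur in every positive training peptide, so the
        # shared-4-mer rule forbids them in any candidate; graded motif
        # proximity can still be positive
        pos, neg = ed.build_pools(small_split.train)
        cands = ed.run_design_campaign(
            pos, neg, mini_model, [], n_high_seeds=10, n_low_seeds=10,
            n_high_class=5, n_low_class=5, seed=2,
        )
        from epidesign.synthetic import DEFAULT_MOTIFS

        for c in cands:
            if c.assigned_class == "H":
                assert ed.oracle_binding_score(c.sequence, DEFAULT_MOTIFS) == 0
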