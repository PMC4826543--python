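"""Classifier and design-evaluation metrics."""

import numpy as np
import pytest
from scipy import stats

import epidesign as ed


def brute_force_auroc(scores, labels):
    """Pairwise concordance with 0.5 tie credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocPr:
    def test_perfect_separation(self):
        assert ed.auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert ed.aupr([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_random_scores_near_half(self, rng):
        labels = rng.integers(0, 2, size=4000)
        scores = rng.uniform(size=4000)
        assert abs(ed.auroc(scores, labels) - 0.5) < 0.05

    def test_all_equal_scores_give_half_by_tie_convention(self):
        assert ed.auroc([0.5] * 10, [1, 0] * 5) == 0.5

    def test_matches_brute_force_concordance(self, rng):
        scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=80)  # ties included
        labels = rng.integers(0, 2, size=80)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        assert ed.auroc(scores, labels) == pytest.approx(
            brute_force_auroc(scores, labels)
        )

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            ed.auroc([0.1, 0.9], [1, 1])


class TestDeltaMetrics:
    def test_delta_zero_equals_plain_threshold_metrics(self, rng):
        intensities = rng.uniform(0, 11000, size=200)
        predicted = rng.random(size=200) < 0.5
        m = ed.delta_metrics(intensities, predicted, delta=0.0)
        truth = intensities > 5500.0
        tp = np.sum(predicted & truth)
        assert m.excluded_fraction == 0.0
        assert m.precision == pytest.approx(tp / predicted.sum())
        assert m.recall == pytest.approx(tp / truth.sum())
        assert m.accuracy == pytest.approx(np.mean(predicted == truth))

    def test_grey_zone_at_4500_is_1000_to_10000(self):
        intensities = np.array([999.9, 1000.0, 5500.0, 9999.9, 10000.0, 10001.0])
        predicted = np.array([False, False, True, True, True, True])
        m = ed.delta_metrics(intensities, predicted, delta=4500.0)
        # [1000, 10000] closed band excluded; 999.9 kept low, 10000.0 excluded
        assert m.n_used == 2
        assert m.excluded_fraction == pytest.approx(4 / 6)
        assert m.precision == 1.0 and m.recall == 1.0 and m.accuracy == 1.0

    def test_perfect_predictions_at_any_delta(self, rng):
        intensities = np.concatenate([rng.uniform(0, 900, 50), rng.uniform(12000, 20000, 50)])
        predicted = intensities > 5500
        for delta in (0.0, 1000.0, 4500.0):
            m = ed.delta_metrics(intensities, predicted, delta)
            assert m.precision == 1.0 and m.recall == 1.0 and m.accuracy == 1.0

    def test_excluded_fraction_monotone_in_delta(self, rng):
        intensities = rng.uniform(0, 11000, size=300)
        predicted = rng.random(size=300) < 0.5
        deltas = np.linspace(0, 5000, 50)
        curve = ed.delta_metrics_curve(intensities, predicted, deltas)
        excl = [m.excluded_fraction for m in curve]
        assert np.all(np.diff(excl) >= 0)

    def test_all_excluded_is_flagged_undefined(self):
        m = ed.delta_metrics([5500.0, 5400.0], [True, False], delta=4000.0)
        assert not m.defined and m.excluded_fraction == 1.0

    def test_delta_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            ed.delta_metrics([100.0], [True], delta=5500.0)


class TestPermutationTest:
    def test_perfect_predictions_give_minimal_p(self, rng):
        truth = np.array([True] * 30 + [False] * 30)
        res = ed.permutation_f1_pvalue(truth, truth, n_permutations=1000, seed=0)
        assert res.p_value == pytest.approx(1.0 / 1001.0)

    def test_p_never_below_one_over_b_plus_one(self, rng):
        for b in (10, 100):
            truth = rng.random(40) < 0.5
            pred = rng.random(40) < 0.5
            res = ed.permutation_f1_pvalue(pred, truth, n_permutations=b, seed=1)
            assert res.p_value >= 1.0 / (b + 1)

    def test_b_zero_degenerates_to_p_one(self):
        res = ed.permutation_f1_pvalue([True, False], [True, False], n_permutations=0)
        assert res.p_value == 1.0

    def test_observed_f1_matches_sklearn(self, rng):
        from epidesign.evaluation import observed_f1_sklearn

        for _ in range(20):
            truth = rng.random(50) < 0.4
            pred = rng.random(50) < 0.5
            res = ed.permutation_f1_pvalue(pred, truth, n_permutations=0)
            assert res.observed_f1 == pytest.approx(observed_f1_sklearn(pred, truth))

    def test_null_pvalues_approximately_uniform(self, rng):
        # predictions independent of labels: p-values should be ~U(0,1).
        # F1 is discrete (ties in the TP count), so the p-value carries atoms
        # of size ~1/sd(TP); n is chosen large enough that the atoms are
        # small relative to the KS resolution at 200 replicates.
        n, B, reps = 1200, 1000, 200
        pvals = []
        for i in range(reps):
            truth = np.concatenate([np.ones(n // 2, bool), np.zeros(n // 2, bool)])
            rng.shuffle(truth)
            pred = np.concatenate([np.ones(n // 2, bool), np.zeros(n // 2, bool)])
            rng.shuffle(pred)
            pvals.append(
                ed.permutation_f1_pvalue(pred, truth, n_permutations=B, seed=1000 + i).p_value
            )
        pvals = np.asarray(pvals)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
        # distribution-free validity: P(p <= alpha) <= alpha (+ binomial noise)
        for alpha in (0.01, 0.05, 0.1, 0.25):
            se = np.sqrt(alpha * (1 - alpha) / reps)
            assert (pvals <= alpha).mean() <= alpha + 3 * se


class TestHammingAndDiversity:
    def test_hamming_basics(self):
        assert ed.hamming("ACDEF", "ACDEF") == 0
        assert ed.hamming("A" * 15, "C" * 15) == 15
        assert ed.hamming("ACD", "AWD") == ed.hamming("AWD", "ACD") == 1
        with pytest.raises(ValueError):
            ed.hamming("AC", "ACD")

    def test_all_distant_peptides_give_full_mis(self):
        seqs = ["AAAAA", "CCCCC", "DDDDD", "EEEEE"]  # pairwise distance 5
        prof = ed.diversity_profile(seqs, cutoffs=[1, 3, 5])
        assert prof.mean_mis_size == [4.0, 4.0, 4.0]

    def test_identical_pair_collapses_at_cutoff_one(self):
        prof = ed.diversity_profile(["AAAAA", "AAAAA"], cutoffs=[1])
        assert prof.mean_mis_size == [1.0]

    def test_mean_mis_nonincreasing_in_cutoff(self, rng):
        from conftest import random_peptides

        seqs = [p.sequence for p in random_peptides(rng, 25, 15)]
        prof = ed.diversity_profile(seqs, cutoffs=list(range(1, 16)))
        assert np.all(np.diff(prof.mean_mis_size) <= 1e-12)

    def test_min_distance_9_construction_spans_graph_until_9(self):
        # shared 6-residue prefix + 9 private positions: every pair is at
        # Hamming distance exactly 9
        import itertools

        seqs = ["WWWWWW" + c * 9 for c in "ACDEFGHIKLMN"]
        dists = [ed.hamming(a, b) for a, b in itertools.combinations(seqs, 2)]
        assert min(dists) == max(dists) == 9
        prof = ed.diversity_profile(seqs, cutoffs=list(range(1, 10)))
        assert all(m == len(seqs) for m in prof.mean_mis_size)
        collapsed = ed.diversity_profile(seqs, cutoffs=[10])
        assert collapsed.mean_mis_size == [1.0]


class TestPropensity:
    def test_equal_sets_give_unit_ratios(self):
        seqs = ["ACDEF", "GHIKL", "MNPQR"]
        pm = ed.propensity_matrix(seqs, list(seqs))
        assert np.allclose(pm.values, 1.0)

    def test_enriched_residue_exceeds_one_and_stays_finite(self):
        tp = ["WAAAA"] * 10
        neg = ["CAAAA"] * 10
        pm = ed.propensity_matrix(tp, neg)
        w_col = ed.DEFAULT_ALPHABET.index_of("W")
        assert np.isfinite(pm.values).all()
        assert pm.values[0, w_col] > 1.0
        assert (pm.values > 0).all()

    def test_order_invariance(self, rng):
        from conftest import random_peptides

        tp = [p.sequence for p in random_peptides(rng, 10, 8)]
        neg = [p.sequence for p in random_peptides(rng, 12, 8, prefix="n")]
        pm1 = ed.propensity_matrix(tp, neg)
        pm2 = ed.propensity_matrix(tp[::-1], neg[::-1])
        assert np.array_equal(pm1.values, pm2.values)

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            ed.propensity_matrix([], ["AAAAA"])
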