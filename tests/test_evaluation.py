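"""Evaluation machinery: AUC/ROC, subsampling, HWE, MAF trend, correlation."""
import itertools

import numpy as np
import pytest
from scipy.special import gammaln

import truncscore as ts
from truncscore import evaluation as ev

from conftest import make_variant


def pairwise_auc_oracle(scores, labels):
    """AUC by explicit enumeration of all (positive, negative) pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1 for p, n in itertools.product(pos, neg) if p > n)
    ties = sum(1 for p, n in itertools.product(pos, neg) if p == n)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert ev.auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert ev.auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_three_of_four_pairs(self):
        assert ev.auc([0.9, 0.3, 0.5, 0.1], [1, 1, 0, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            ev.auc([0.1, 0.2], [1, 1])

    def test_matches_enumeration_oracle_with_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert ev.auc(scores, labels) == pytest.approx(
                pairwise_auc_oracle(scores, labels), abs=1e-12
            )

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        assert ev.auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_complement_labels_sum_to_one(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        assert ev.auc(scores, labels) + ev.auc(scores, 1 - labels) == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        assert ev.auc(np.exp(scores), labels) == pytest.approx(ev.auc(scores, labels))


class TestRocCurve:
    def test_curve_properties_and_trapezoid_equals_mann_whitney(self, rng):
        scores = rng.choice(np.linspace(0, 1, 20), size=150)
        labels = rng.integers(0, 2, 150)
        labels[:2] = [0, 1]
        fpr, tpr = ev.roc_curve(scores, labels)
        assert fpr[0] == tpr[0] == 0.0 and fpr[-1] == tpr[-1] == 1.0
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)
        assert np.trapezoid(tpr, fpr) == pytest.approx(ev.auc(scores, labels), abs=1e-12)


class TestRocSubsample:
    def test_separable_classes_give_perfect_auc(self):
        rng = np.random.default_rng(0)
        X = np.r_[rng.normal(10, 0.5, (60, 1)), rng.normal(-10, 0.5, (60, 1))]
        c = np.r_[np.ones(60, int), np.zeros(60, int)]
        roc = ev.roc_subsample(X, c, iters=200, seed=1)
        assert roc.auc == 1.0

    def test_permuted_labels_give_chance_auc(self):
        # per-iteration label permutation: the Mann-Whitney null applies to
        # the pooled held-out scores
        rng = np.random.default_rng(5)
        X = np.r_[rng.normal(1, 1, (200, 2)), rng.normal(0, 1, (200, 2))]
        c = np.r_[np.ones(200, int), np.zeros(200, int)]
        roc = ev.roc_subsample(X, c, iters=200, seed=2, shuffle_labels=True)
        assert abs(roc.auc - 0.5) < 0.05

    def test_seeded_runs_identical(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 2))
        c = np.r_[np.ones(20, int), np.zeros(20, int)]
        a = ev.roc_subsample(X, c, iters=1, seed=9)
        b = ev.roc_subsample(X, c, iters=1, seed=9)
        assert a.auc == b.auc
        np.testing.assert_array_equal(a.fpr, b.fpr)
        np.testing.assert_array_equal(a.tpr, b.tpr)

    def test_pooled_auc_converges_to_full_data_auc(self):
        """With many iterations the pooled held-out AUC approaches the AUC of
        the classifier fit and evaluated on the full planted sample."""
        cfg = ts.FixtureConfig(seed=11)
        train = ts.sample_feature_matrix(cfg, n_per_class=300)
        from truncscore import classifier as nb

        params = nb.fit(nb.TrainingSet(train.X, train.c))
        full_auc = ev.auc(nb.posterior(train.X, params), train.c)
        roc = ev.roc_subsample(train.X, train.c, iters=300, seed=4)
        assert abs(roc.auc - full_auc) < 0.02


class TestRandomization:
    def test_shuffling_destroys_feature_label_coupling(self):
        cfg = ts.FixtureConfig(seed=21)
        train = ts.sample_feature_matrix(cfg, n_per_class=200)
        rnd = ev.randomization_test(train.X, train.c, iters=200, seed=5)
        assert abs(rnd.auc - 0.5) < 0.05

    def test_constant_single_column_is_exactly_chance(self):
        # a fixed prior keeps the degenerate posterior constant across
        # iterations; all pooled scores tie and the curve is the diagonal
        # a constant continuous column: class means coincide exactly, the
        # floored variances are equal, so the likelihood ratio is exactly 1
        X = np.full((40, 1), 0.5)
        c = np.r_[np.ones(20, int), np.zeros(20, int)]
        rnd = ev.randomization_test(X, c, iters=5, seed=6,
                                    fit_kwargs={"p1": 0.5})
        assert rnd.auc == 0.5

    def test_seeded_repeat_identical(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 2))
        c = np.r_[np.ones(15, int), np.zeros(15, int)]
        a = ev.randomization_test(X, c, iters=3, seed=7)
        b = ev.randomization_test(X, c, iters=3, seed=7)
        np.testing.assert_array_equal(a.tpr, b.tpr)
        assert a.auc == b.auc


class TestScoreCombination:
    def test_joint_score_examples(self):
        assert ev.joint_score(1.0, 0.7) == pytest.approx(0.7)
        assert ev.joint_score(0.5, 0.5) == pytest.approx(0.25)
        with pytest.raises(ValueError, match="outside"):
            ev.joint_score(1.2, 0.5)

    def test_rvis_logistic_of_negation(self):
        assert ev.rvis_to_prob(0.0) == pytest.approx(0.5)
        assert ev.rvis_to_prob(-np.log(3)) == pytest.approx(0.75)
        # intolerant genes (negative RVIS) map to high pathogenicity
        assert ev.rvis_to_prob(-2.0) > 0.8


class TestRankPercentile:
    def test_strict_count_definition(self):
        got = ev.rank_percentile([0.9, 0.5, 0.1])
        np.testing.assert_allclose(got, [0.0, 100 / 3, 200 / 3])

    def test_ties_share_percentile_and_all_equal_is_zero(self):
        np.testing.assert_allclose(ev.rank_percentile([0.3, 0.3, 0.3]), [0, 0, 0])
        np.testing.assert_allclose(ev.rank_percentile([0.5]), [0.0])

    def test_lower_is_more_pathogenic_direction(self):
        got = ev.rank_percentile([0.9, 0.5, 0.1], higher_is_more_pathogenic=False)
        np.testing.assert_allclose(got, [200 / 3, 100 / 3, 0.0])

    def test_invariant_under_prior_change(self, rng):
        """Rank percentiles of posteriors coincide for any two priors."""
        from test_classifier import random_params, random_row
        from truncscore import classifier as nb

        params = random_params(rng)
        Y = np.array([random_row(rng) for _ in range(50)])
        p_a = nb.posterior(Y, params)
        q = nb.ClassifierParams(
            params.feature_names, params.feature_kinds, params.mu1, params.mu0,
            params.nu, params.theta1, params.theta0, p1=0.9,
        )
        p_b = nb.posterior(Y, q)
        np.testing.assert_allclose(
            ev.rank_percentile(p_a), ev.rank_percentile(p_b), atol=1e-9
        )


def hwe_enumeration_oracle(n_hom_ref, n_het, n_hom_alt):
    """Full enumeration of the conditional distribution of heterozygote
    counts given allele counts; exact factorials via gammaln."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    n_minor = min(n_alt, 2 * n - n_alt)
    n_major = 2 * n - n_minor
    if n_minor == 0:
        return 1.0
    probs = {}
    for h in range(n_minor % 2, min(n_minor, n_major) + 1, 2):
        logp = (
            gammaln(n + 1) + gammaln(n_minor + 1) + gammaln(n_major + 1)
            - gammaln((n_minor - h) // 2 + 1) - gammaln(h + 1)
            - gammaln((n_major - h) // 2 + 1) - gammaln(2 * n + 1)
            + h * np.log(2)
        )
        probs[h] = np.exp(logp)
    p_obs = probs[n_het]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


class TestHweExactTest:
    def test_single_minor_allele_is_uninformative(self):
        assert ev.hwe_exact_test(1, 1, 0) == pytest.approx(1.0)

    def test_monomorphic_site(self):
        assert ev.hwe_exact_test(2, 0, 0) == 1.0

    def test_all_homozygous_configuration(self):
        # 10 minor alleles in 10 diploids, zero heterozygotes: extreme config
        p = ev.hwe_exact_test(5, 0, 5)
        assert p == pytest.approx(hwe_enumeration_oracle(5, 0, 5), rel=1e-10)
        assert p < 0.01

    def test_probabilities_sum_to_one_for_all_allele_counts(self):
        for n in (3, 10, 25):
            for n_minor in range(0, n + 1):
                if n_minor == 0:
                    continue
                _, probs = ev.hwe_heterozygote_distribution(n_minor, 2 * n - n_minor)
                assert probs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ev.hwe_exact_test(-1, 2, 0)

    def test_filter_keeps_hwe_consistent_variants(self):
        good = make_variant(10, vid="good", genotype_counts=(48, 2, 0))
        bad = make_variant(20, vid="bad", genotype_counts=(45, 0, 5))
        nocounts = make_variant(30, vid="nc")
        kept = ev.filter_hwe([good, bad, nocounts], alpha=0.05)
        assert [v.variant_id for v in kept] == ["good", "nc"]


class TestMafTrend:
    def test_planted_null_has_small_z(self, rng):
        mafs = 10 ** rng.uniform(-4, -0.5, 400)
        feature = rng.random(400) < 0.4  # independent of MAF
        vclass = np.r_[["stop_gain"] * 200, ["synonymous"] * 200]
        fits = ev.maf_trend_by_class(feature, mafs, vclass)
        z, p = ev.heterogeneity_test(*fits["stop_gain"], *fits["synonymous"])
        assert abs(z) < 3

    def test_planted_trend_is_detected(self, rng):
        from scipy.special import expit

        logm = rng.uniform(-9, -1, 500)
        y = rng.random(500) < expit(1.5 * logm + 5)
        beta, se = ev.maf_trend(y, np.exp(logm))
        assert (beta - 1.5) / se == pytest.approx(0, abs=3)

    def test_heterogeneity_definition(self):
        z, p = ev.heterogeneity_test(1.0, 0.3, 1.0, 0.4)
        assert (z, p) == (0.0, 1.0)
        z, _ = ev.heterogeneity_test(2.0, 0.6, 1.0, 0.8)
        assert z == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="distinct MAF"):
            ev.maf_trend([0, 1, 0, 1], [0.01] * 4)
        with pytest.raises(ValueError, match="present"):
            ev.maf_trend([1, 1, 1, 1], [0.1, 0.2, 0.3, 0.4])


class TestCorrelateScores:
    def test_perfect_and_inverse_correlation(self, rng):
        a = rng.normal(size=50)
        rho, _ = ev.correlate_scores(a, a, n_boot=50, seed=0)
        assert rho == pytest.approx(1.0)
        rho, _ = ev.correlate_scores(a, -a, n_boot=50, seed=0)
        assert rho == pytest.approx(-1.0)

    def test_independent_vectors_ci_covers_zero(self, rng):
        a, b = rng.random(1000), rng.random(1000)
        rho, (lo, hi) = ev.correlate_scores(a, b, n_boot=200, seed=1)
        assert abs(rho) < 0.1 and lo < 0 < hi

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ev.correlate_scores([1, 1, 1, 1], [1, 2, 3, 4])
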