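"""Evaluation statistics against independent oracles."""

import numpy as np
import pytest

from usexpand import (GaussianStats, ScoreSet, auc, balanced_accuracy,
                      binarize_malignant, bootstrap_ci, constrained_youden,
                      delong_paired, fid, fit_gaussian, frechet_distance,
                      holm_bonferroni, roc_points, sens_spec_at_threshold_ci,
                      significance_matrix, RandomConvExtractor)
from usexpand.evaluation import delong_variance


def pair_count_auc(scores, labels):
    """Exhaustive Mann–Whitney oracle."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_youden(scores, labels, floor):
    """Try a threshold in every interval between sorted scores (and beyond)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    uniq = np.unique(scores)
    cands = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, uniq,
                            [uniq[-1] + 1]])
    best = None
    for t in cands:
        sens = np.mean(scores[labels == 1] >= t)
        spec = np.mean(scores[labels == 0] < t)
        best = best or (sens, spec)
        feasible_new = sens >= floor
        feasible_old = best[0] >= floor
        key_new = (feasible_new, sens + spec)
        key_old = (feasible_old, best[0] + best[1])
        if key_new > key_old:
            best = (sens, spec)
    return best


def _score_set(rng, n=30):
    probs = rng.dirichlet(np.ones(3), size=n)
    classes = np.array(["normal", "benign", "malignant"])[rng.integers(0, 3, n)]
    return ScoreSet(probs, classes.tolist(), [f"p{i}" for i in range(n)])


class TestBinarizeAndAuc:
    def test_binarize_extracts_malignant_column(self):
        ss = ScoreSet(np.array([[0.1, 0.2, 0.7], [0.5, 0.3, 0.2]]),
                      ["malignant", "benign"], ["a", "b"])
        scores, labels = binarize_malignant(ss)
        assert np.allclose(scores, [0.7, 0.2])
        assert labels.tolist() == [1, 0]

    def test_perfect_separation_and_ties(self):
        assert auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0
        assert auc([0.2, 0.9, 0.3, 0.8], [1, 1, 0, 0]) == 0.5  # 2 of 4 pair wins
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_matches_pair_counting_on_random_instances(self, rng):
        for _ in range(25):
            n = rng.integers(4, 50)
            scores = rng.choice(np.linspace(0, 1, 11), size=n)
            labels = np.zeros(n, int)
            labels[rng.choice(n, size=max(1, int(n) // 3), replace=False)] = 1
            if labels.min() == labels.max():
                continue
            assert auc(scores, labels) == pytest.approx(pair_count_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class TestConstrainedYouden:
    def test_perfect_scores_reach_j_one(self):
        roc = roc_points([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        op = constrained_youden(roc, 0.9)
        assert op.J == pytest.approx(1.0) and op.sensitivity == 1.0

    def test_floor_overrides_unconstrained_optimum(self):
        scores = [0.9, 0.6, 0.2, 0.5, 0.4, 0.3]
        labels = [1, 1, 1, 0, 0, 0]
        op = constrained_youden(roc_points(scores, labels), 0.9)
        assert op.sensitivity == 1.0 and op.specificity == 0.0
        assert op.J == pytest.approx(0.0)
        unconstrained = constrained_youden(roc_points(scores, labels), 0.0)
        assert unconstrained.J == pytest.approx(2 / 3)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 40))
            scores = rng.choice(np.linspace(0, 1, 7), size=n)
            labels = np.zeros(n, int)
            labels[rng.choice(n, size=n // 2, replace=False)] = 1
            if labels.min() == labels.max():
                continue
            for floor in (0.0, 0.9):
                op = constrained_youden(roc_points(scores, labels), floor)
                sens, spec = brute_force_youden(scores, labels, floor)
                assert op.sensitivity + op.specificity == pytest.approx(sens + spec)


class TestBootstrap:
    def test_constant_metric_gives_point_interval(self, rng):
        ss = _score_set(rng)
        lo, hi = bootstrap_ci(ss, lambda s: 0.42, B=50, seed=0)
        assert lo == hi == 0.42

    def test_seeded_determinism(self, rng):
        ss = _score_set(rng, n=40)
        metric = lambda s: auc(*binarize_malignant(s))
        assert bootstrap_ci(ss, metric, B=100, seed=3) \
            == bootstrap_ci(ss, metric, B=100, seed=3)

    def test_fixed_threshold_cis_degenerate_when_separated(self):
        probs = np.array([[0.05, 0.05, 0.9]] * 5 + [[0.8, 0.1, 0.1]] * 5)
        ss = ScoreSet(probs, ["malignant"] * 5 + ["normal"] * 5,
                      [f"p{i}" for i in range(10)])
        cis = sens_spec_at_threshold_ci(ss, threshold=0.5, B=50, seed=0)
        assert cis["sensitivity"] == (1.0, 1.0)
        assert cis["specificity"] == (1.0, 1.0)

    def test_invalid_b_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_ci(_score_set(rng), lambda s: 0.0, B=0, seed=0)


class TestBalancedAccuracy:
    def test_perfect_and_constant_predictions(self):
        probs = np.eye(3)[[0, 1, 2, 0]]
        ss = ScoreSet(probs, ["normal", "benign", "malignant", "normal"],
                      list("abcd"))
        assert balanced_accuracy(ss) == 1.0
        const = ScoreSet(np.tile([[0.8, 0.1, 0.1]], (3, 1)),
                         ["normal", "benign", "malignant"], list("abc"))
        assert const and balanced_accuracy(const) == pytest.approx(1 / 3)

    def test_hand_computed_recall_mean(self):
        # recalls: normal 2/2=1.0, benign 1/2=0.5, malignant 3/4=0.75
        truth = ["normal"] * 2 + ["benign"] * 2 + ["malignant"] * 4
        pred_idx = [0, 0, 1, 0, 2, 2, 2, 0]
        probs = np.eye(3)[pred_idx]
        ss = ScoreSet(probs, truth, [f"p{i}" for i in range(8)])
        assert balanced_accuracy(ss) == pytest.approx(0.75)


class TestFrechet:
    def test_identical_gaussians_zero(self):
        g = GaussianStats(np.array([1.0, 2.0]), np.eye(2))
        assert frechet_distance(g, g) == pytest.approx(0.0, abs=1e-10)

    def test_one_dimensional_closed_form(self):
        a = GaussianStats(np.array([0.0]), np.array([[1.0]]))
        b = GaussianStats(np.array([2.0]), np.array([[1.0]]))
        assert frechet_distance(a, b) == pytest.approx(4.0)
        c = GaussianStats(np.array([0.0]), np.array([[4.0]]))
        # (mu diff)^2 + (sigma diff)^2 = 0 + (2-1)^2
        assert frechet_distance(a, c) == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        for _ in range(10):
            q1 = rng.normal(size=(5, 5))
            q2 = rng.normal(size=(5, 5))
            s1, s2 = q1 @ q1.T + 1e-3 * np.eye(5), q2 @ q2.T + 1e-3 * np.eye(5)
            mu1, mu2 = rng.normal(size=5), rng.normal(size=5)
            # oracle: sqrtm via eigendecomposition of the symmetrised product
            r1 = _sym_sqrt(s1)
            inner = _sym_sqrt(r1 @ s2 @ r1)
            oracle = float((mu1 - mu2) @ (mu1 - mu2)
                           + np.trace(s1 + s2 - 2 * inner))
            ours = frechet_distance(GaussianStats(mu1, s1), GaussianStats(mu2, s2))
            assert ours == pytest.approx(oracle, abs=1e-8)

    def test_symmetry_and_nonnegativity(self, rng):
        feats_a = rng.normal(size=(40, 6))
        feats_b = rng.normal(size=(40, 6)) + 0.5
        ga, gb = fit_gaussian(feats_a), fit_gaussian(feats_b)
        d_ab = frechet_distance(ga, gb)
        assert d_ab >= 0
        assert d_ab == pytest.approx(frechet_distance(gb, ga), abs=1e-8)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            frechet_distance(GaussianStats(np.zeros(2), np.eye(2)),
                             GaussianStats(np.zeros(3), np.eye(3)))


def _sym_sqrt(m):
    vals, vecs = np.linalg.eigh(m)
    return (vecs * np.sqrt(np.clip(vals, 0, None))) @ vecs.T


class TestFid:
    def test_identical_sets_zero_and_symmetry(self, rng):
        imgs_a = rng.random((30, 32, 32))
        imgs_b = rng.random((30, 32, 32)) ** 2
        ex = RandomConvExtractor(seed=1, width=8)
        assert fid(imgs_a, imgs_a, ex) == pytest.approx(0.0, abs=1e-8)
        assert fid(imgs_a, imgs_b, ex) == pytest.approx(fid(imgs_b, imgs_a, ex), abs=1e-8)

    def test_between_domain_exceeds_within_domain(self, standard_cohort, pocus_cohort):
        from usexpand import pixel_stack
        ex = RandomConvExtractor(seed=2, width=8)
        poc = pixel_stack(pocus_cohort)
        half = len(poc) // 2
        between = fid(pixel_stack(standard_cohort), poc, ex)
        within = fid(poc[:half], poc[half:], ex)
        assert between > within

    def test_too_few_images_rejected(self, rng):
        with pytest.raises(ValueError):
            fid(rng.random((1, 16, 16)), rng.random((10, 16, 16)))


class TestDeLong:
    def test_identical_scores_give_p_one(self, rng):
        scores = rng.random(40)
        labels = (rng.random(40) < 0.5).astype(int)
        labels[:2] = [0, 1]
        a1, a2, z, p = delong_paired(scores, scores, labels)
        assert a1 == a2 and p == 1.0

    def test_variance_agrees_with_bootstrap(self, rng):
        n = 200
        labels = np.r_[np.ones(100, int), np.zeros(100, int)]
        scores = np.r_[rng.normal(1, 1, 100), rng.normal(0, 1, 100)]
        v_delong = delong_variance(scores, labels)
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if labels[idx].min() == labels[idx].max():
                continue
            boots.append(auc(scores[idx], labels[idx]))
        v_boot = np.var(boots)
        assert abs(v_delong - v_boot) / v_boot < 0.25

    def test_detects_a_large_auc_difference(self, rng):
        labels = np.r_[np.ones(100, int), np.zeros(100, int)]
        good = np.r_[rng.normal(2, 1, 100), rng.normal(0, 1, 100)]
        noise = rng.random(200)
        _, _, _, p = delong_paired(good, noise, labels)
        assert p < 1e-4


class TestHolm:
    def test_single_p_unchanged(self):
        adj, rej = holm_bonferroni([0.03])
        assert adj[0] == pytest.approx(0.03) and rej[0]

    def test_worked_stepdown_triple(self):
        adj, rej = holm_bonferroni([0.01, 0.04, 0.03])
        assert np.allclose(adj, [0.03, 0.06, 0.06])
        assert rej.tolist() == [True, False, False]

    def test_all_ones_none_rejected(self):
        adj, rej = holm_bonferroni([1.0, 1.0, 1.0])
        assert np.all(adj == 1.0) and not rej.any()

    def test_monotone_in_sorted_order(self, rng):
        for _ in range(50):
            p = rng.random(int(rng.integers(2, 12)))
            adj, _ = holm_bonferroni(p)
            order = np.argsort(p, kind="stable")
            assert np.all(np.diff(adj[order]) >= -1e-12)
            assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.2])


class TestSignificanceMatrix:
    def test_identical_models_all_ns(self, rng):
        ss = _score_set(rng, n=40)
        sm = significance_matrix({"a": ss, "b": ss})
        assert all(mark == "ns" for row in sm.stars for mark in row)
        assert np.allclose(sm.adjusted_p, sm.adjusted_p.T)

    def test_noise_model_flagged_against_strong_models(self, rng):
        n = 400
        classes = np.array(["normal", "benign", "malignant"])[rng.integers(0, 3, n)]
        is_mal = classes == "malignant"
        strong = np.clip(0.75 * is_mal + 0.25 * rng.random(n), 0, 1)
        sets = {}
        for name, pm in (("good1", strong), ("good2", np.clip(strong + 0.05 * rng.random(n), 0, 1)),
                         ("noise", rng.random(n))):
            probs = np.c_[(1 - pm) / 2, (1 - pm) / 2, pm]
            sets[name] = ScoreSet(probs, classes.tolist(), [f"p{i}" for i in range(n)])
        sm = significance_matrix(sets, alpha=0.05)
        assert sm.star("noise", "good1") in ("*", "**")
        assert sm.star("noise", "good2") in ("*", "**")
        assert all(sm.stars[i][i] == "ns" for i in range(3))

    def test_mismatched_test_sets_rejected(self, rng):
        a = _score_set(rng, n=10)
        b = _score_set(np.random.default_rng(5), n=10)
        with pytest.raises(ValueError, match="identical test set"):
            significance_matrix({"a": a, "b": b})
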