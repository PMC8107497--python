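import numpy as np
import pytest

from nflreflect import stats as st


def brute_force_auc(pos, neg):
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


class TestClusteredAuc:
    def test_perfect_separation(self):
        r = st.auc_clustered([5, 6, 1, 2], [1, 1, 0, 0])
        assert r.auc == 1.0

    def test_tie_counted_half(self):
        r = st.auc_clustered([3, 4, 1, 2, 3], [1, 1, 0, 0, 0])
        assert r.auc == pytest.approx(5.5 / 6)

    def test_equals_pair_counting_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(4, 15)
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, rng.integers(1, n), replace=False)] = 1
            if labels.all() or not labels.any():
                continue
            scores = rng.integers(0, 6, n).astype(float)  # many ties
            clusters = rng.integers(0, max(2, n // 2), n)
            r = st.auc_clustered(scores, labels, clusters)
            assert r.auc == pytest.approx(brute_force_auc(scores[labels == 1],
                                                          scores[labels == 0]))

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=400)
        labels = rng.uniform(size=400) < 0.5
        r = st.auc_clustered(scores, labels)
        assert abs(r.auc - 0.5) < 3 * r.se

    def test_singleton_clusters_match_delong_structure(self):
        """With one observation per cluster the variance equals the
        DeLong-type structural-components estimator."""
        rng = np.random.default_rng(2)
        pos = rng.normal(1, 1, 12)
        neg = rng.normal(0, 1, 15)
        scores = np.concatenate([pos, neg])
        labels = np.array([1] * 12 + [0] * 15)
        r = st.auc_clustered(scores, labels)
        psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
        v10, v01 = psi.mean(axis=1), psi.mean(axis=0)
        expected = np.var(v10, ddof=1) / 12 + np.var(v01, ddof=1) / 15
        assert r.se**2 == pytest.approx(expected, rel=1e-9)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            st.auc_clustered([1, 2, 3], [1, 1, 1])

    def test_flipped_scores_complement(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=30)
        labels = rng.uniform(size=30) < 0.4
        if labels.all() or not labels.any():
            labels[:2] = [True, False]
        a = st.auc_clustered(scores, labels).auc
        b = st.auc_clustered(-scores, labels).auc
        assert a + b == pytest.approx(1.0)


class TestSensitivityAtSpecificity:
    def test_gaussian_overlap_closed_form(self):
        rng = np.random.default_rng(10)
        normal = rng.normal(0, 1, 100000)
        disease = rng.normal(-3, 1, 100000)
        sens = st.sensitivity_at_specificity(normal, disease, 0.99)
        from scipy.stats import norm
        assert sens == pytest.approx(norm.cdf(3 - norm.ppf(0.99)), abs=0.01)

    def test_exchangeable_scores_give_one_minus_spec(self):
        rng = np.random.default_rng(11)
        normal = rng.normal(0, 1, 5000)
        disease = rng.normal(0, 1, 5000)
        sens = st.sensitivity_at_specificity(normal, disease, 0.95)
        assert sens == pytest.approx(0.05, abs=0.015)

    def test_complete_separation(self):
        rng = np.random.default_rng(12)
        normal = rng.normal(0, 0.5, 200)
        disease = normal.min() - 5 - rng.uniform(0, 1, 50)
        assert st.sensitivity_at_specificity(normal, disease, 0.99) == 1.0

    def test_monotone_in_specificity(self):
        rng = np.random.default_rng(13)
        normal = rng.normal(0, 1, 2000)
        disease = rng.normal(-2, 1, 2000)
        sens = [st.sensitivity_at_specificity(normal, disease, s)
                for s in (0.80, 0.90, 0.95, 0.99)]
        assert all(a >= b for a, b in zip(sens, sens[1:]))

    def test_degenerate_normals_rejected(self):
        with pytest.raises(ValueError):
            st.sensitivity_at_specificity(np.ones(20), np.zeros(5))


class TestMcNemar:
    def test_eight_zero_discordant(self):
        a = np.array([1] * 8 + [1] * 4, dtype=bool)
        b = np.array([0] * 8 + [1] * 4, dtype=bool)
        assert st.mcnemar(a, b) == pytest.approx(2 * 0.5**8)

    def test_identical_detections(self):
        d = np.array([1, 0, 1, 1, 0], dtype=bool)
        assert st.mcnemar(d, d) == 1.0

    def test_symmetric_discordance(self):
        a = np.array([1] * 5 + [0] * 5, dtype=bool)
        b = np.array([0] * 5 + [1] * 5, dtype=bool)
        assert st.mcnemar(a, b) == pytest.approx(1.0)

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(4)
        hits = 0
        n_sim = 300
        for _ in range(n_sim):
            a = rng.uniform(size=50) < 0.5
            b = rng.uniform(size=50) < 0.5
            hits += st.mcnemar(a, b) < 0.05
        # exact test is conservative; rate should not exceed nominal
        assert hits / n_sim <= 0.05 + 2.576 * np.sqrt(0.05 * 0.95 / n_sim)


class TestPooledSd:
    def test_identical_repeats_zero(self):
        eye = np.tile(np.arange(10.0), (3, 1))
        assert st.pooled_sd([eye]) == 0.0

    def test_two_point_formula(self):
        # two repeats differing by +-1 around the mean: per-cell SD = sqrt(2)
        eye = np.stack([np.zeros(8) + 1.0, np.zeros(8) - 1.0])
        assert st.pooled_sd([eye]) == pytest.approx(np.sqrt(2.0))

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        eye = rng.normal(size=(2, 20))
        assert st.pooled_sd([eye]) == pytest.approx(st.pooled_sd([eye + 7.5]))

    def test_scales_with_noise_sd(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(2, 4000))
        assert st.pooled_sd([3.0 * base]) == pytest.approx(3 * st.pooled_sd([base]))

    def test_single_repeat_rejected(self):
        with pytest.raises(ValueError):
            st.pooled_sd([np.zeros((1, 10))])


class TestPearsonCompare:
    def test_perfect_vs_independent(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=100)
        x2 = rng.normal(size=100)
        r1, r2, p = st.pearson_compare_bootstrap(y, x2, y, reps=500, seed=0)
        assert r1 == pytest.approx(1.0)
        assert p < 0.01

    def test_same_parameter_not_different(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=80)
        y = x + rng.normal(0, 0.5, 80)
        _, _, p = st.pearson_compare_bootstrap(x, x, y, reps=200, seed=0)
        assert p == 1.0

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        y = x + rng.normal(0, 1, 50)
        r1, _, _ = st.pearson_compare_bootstrap(x, x, y, reps=10, seed=0)
        r1n, _, _ = st.pearson_compare_bootstrap(-x, x, y, reps=10, seed=0)
        assert r1n == pytest.approx(-r1)


class TestGmm:
    def test_three_separated_blobs(self):
        rng = np.random.default_rng(14)
        f = np.concatenate([rng.normal(0, 0.1, 40), rng.normal(-2, 0.15, 40),
                            rng.normal(-5, 0.2, 40)])
        a = np.concatenate([rng.normal(0, 0.1, 40), rng.normal(-2, 0.15, 40),
                            rng.normal(-1, 0.2, 40)])
        labels, means = st.gmm_cluster(f, a, k=3, seed=0)
        truth = np.repeat([0, 1, 2], 40)
        # agreement up to permutation
        from itertools import permutations
        best = max(np.mean(np.array(perm)[truth] == labels)
                   for perm in permutations(range(3)))
        assert best >= 0.98

    def test_single_component(self):
        rng = np.random.default_rng(15)
        labels, _ = st.gmm_cluster(rng.normal(size=30), rng.normal(size=30), k=1, seed=0)
        assert np.all(labels == 0)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(16)
        f, a = rng.normal(size=60), rng.normal(size=60)
        l1, m1 = st.gmm_cluster(f, a, seed=5)
        l2, m2 = st.gmm_cluster(f, a, seed=5)
        assert np.array_equal(l1, l2) and np.allclose(m1, m2)


class TestPiecewiseFit:
    def test_global_line_recovered_in_both_segments(self):
        x = np.linspace(-15, 2, 60)
        fit = st.piecewise_fit(x, x, breakpoint=-6.0)
        assert fit["high_md"]["slope"] == pytest.approx(1.0)
        assert fit["low_md"]["slope"] == pytest.approx(1.0)
        assert fit["high_md"]["r"] == pytest.approx(1.0)

    def test_floor_effect_construction(self):
        rng = np.random.default_rng(18)
        x = np.concatenate([rng.uniform(-6, 2, 50), rng.uniform(-20, -6, 50)])
        floor = -8.0
        y = np.where(x > -6, x, floor)
        y = y + rng.normal(0, 0.1 * np.ptp(y), 100)
        fit = st.piecewise_fit(x, y, breakpoint=-6.0)
        assert fit["high_md"]["r"] > 0.9
        assert abs(fit["low_md"]["r"]) < 0.3

    def test_empty_segment_flagged(self):
        x = np.linspace(0, 2, 20)
        fit = st.piecewise_fit(x, x, breakpoint=-6.0)
        assert not fit["low_md"]["fitted"]
        assert np.isnan(fit["low_md"]["slope"])


class TestWilcoxon:
    def test_identical_groups(self):
        g = np.arange(20.0)
        assert st.wilcoxon_ranksum(g, g) == pytest.approx(1.0, abs=0.05)

    def test_fully_separated_exact(self):
        assert st.wilcoxon_ranksum([1, 2, 3, 4, 5], [6, 7, 8, 9, 10]) == pytest.approx(2 / 252)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(19)
        a, b = rng.normal(0, 1, 20), rng.normal(1, 1, 20)
        assert st.wilcoxon_ranksum(a, b) == pytest.approx(
            st.wilcoxon_ranksum(np.exp(a), np.exp(b)))
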