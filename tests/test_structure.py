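import numpy as np
import pytest
from scipy import stats as sps

from ripplering.structure import (
    classification_score,
    modulation_strength_correlation,
    partial_total_correlation,
    pca_weights,
    shuffle_null,
    total_correlation,
    train_hd_classifier,
)


class TestPcaWeights:
    def test_rank_one_input(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(30)
        X = np.outer(rng.standard_normal(40), base)
        with pytest.warns(RuntimeWarning, match="rank"):
            w = pca_weights(X)
        assert w.explained_variance_ratio[0] > 0.999

    def test_reconstruction_error_equals_discarded_variance(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 30))
        from sklearn.decomposition import PCA

        pca = PCA(n_components=10).fit(X)
        scores = pca.transform(X)
        recon = pca.inverse_transform(scores)
        resid = np.sum((X - recon) ** 2)
        discarded = np.sum(pca.explained_variance_[10:]) if pca.explained_variance_.size > 10 else None
        total_var = np.sum((X - X.mean(axis=0)) ** 2)
        kept = np.sum(pca.explained_variance_ratio_)
        assert resid == pytest.approx((1 - kept) * total_var, rel=1e-8)

    def test_row_permutation_permutes_scores(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((50, 20))
        perm = rng.permutation(50)
        w1 = pca_weights(X).weights
        w2 = pca_weights(X[perm]).weights
        # same fitted basis up to sign; compare permuted rows allowing column sign flips
        signs = np.sign(np.sum(w1[perm] * w2, axis=0))
        np.testing.assert_allclose(w1[perm] * signs, w2, atol=1e-8)

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            pca_weights(np.random.default_rng(3).standard_normal((5, 30)), n_components=10)


class TestTotalCorrelation:
    def test_identical_weights_rho2_one(self):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((100, 10))
        assert total_correlation(A, A).rho2 == 1.0

    def test_single_pc_equals_squared_pearson(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(300)
        y = 0.6 * x + 0.8 * rng.standard_normal(300)
        rho2 = total_correlation(x[:, None], y[:, None]).rho2
        assert rho2 == pytest.approx(sps.pearsonr(x, y)[0] ** 2, abs=1e-12)

    def test_independent_below_shuffle_95th(self):
        rng = np.random.default_rng(6)
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            A = rng.standard_normal((500, 3))
            B = rng.standard_normal((500, 3))
            res = shuffle_null(A, B, n=60, seed=rep)
            hits += res["observed"] < np.percentile(res["null"], 95)
        assert hits / n_rep >= 0.8

    def test_constant_column_rejected(self):
        A = np.ones((50, 2))
        B = np.random.default_rng(7).standard_normal((50, 2))
        with pytest.raises(ValueError):
            total_correlation(A, B)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(8)
        A = rng.standard_normal((80, 4))
        B = rng.standard_normal((80, 4)) + 0.5 * A
        r1 = total_correlation(A, B).rho2
        flip = np.array([1, -1, 1, -1])
        r2 = total_correlation(A * flip, B).rho2
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestShuffleNull:
    def test_identical_data_minimal_p(self):
        rng = np.random.default_rng(9)
        A = rng.standard_normal((100, 5))
        res = shuffle_null(A, A, n=200, seed=0)
        assert res["p"] <= 1 / 201 + 1e-12

    def test_global_null_p_uniform(self):
        rng = np.random.default_rng(10)
        ps = []
        for rep in range(60):
            A = rng.standard_normal((120, 4))
            B = rng.standard_normal((120, 4))
            ps.append(shuffle_null(A, B, n=99, seed=rep)["p"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_within_shank_null_exceeds_global_with_shank_structure(self):
        # inject shank-level (not unit-level) common signal into A and B
        rng = np.random.default_rng(11)
        n_units, n_shanks = 120, 12
        shank_ids = np.repeat(np.arange(n_shanks), n_units // n_shanks)
        shank_factor = rng.standard_normal(n_shanks)[shank_ids]
        A = 1.0 * shank_factor[:, None] + rng.standard_normal((n_units, 3))
        B = 1.0 * shank_factor[:, None] + rng.standard_normal((n_units, 3))
        g = shuffle_null(A, B, mode="global", n=150, seed=1)
        w = shuffle_null(A, B, mode="within_shank", n=150, seed=1, shank_ids=shank_ids)
        assert w["null"].mean() > g["null"].mean()

    def test_within_shank_requires_groups(self):
        rng = np.random.default_rng(12)
        A = rng.standard_normal((10, 2))
        with pytest.raises(ValueError, match="single unit"):
            shuffle_null(A, A, mode="within_shank", n=10, seed=0, shank_ids=np.arange(10))


class TestPartialTotalCorrelation:
    def test_orthogonal_factor_leaves_rho2(self):
        rng = np.random.default_rng(13)
        A = rng.standard_normal((200, 3))
        B = rng.standard_normal((200, 3)) + 0.4 * A
        f = rng.standard_normal(200)
        # orthogonalize f against every weight column
        W = np.hstack([A, B])
        Wc = W - W.mean(axis=0)
        f = f - f.mean()
        f -= Wc @ np.linalg.lstsq(Wc, f, rcond=None)[0]
        raw = total_correlation(A, B).rho2
        part = partial_total_correlation(A, B, f).rho2
        assert part == pytest.approx(raw, abs=1e-6)

    def test_common_factor_reduces_rho2(self):
        rng = np.random.default_rng(14)
        f = rng.standard_normal(300)
        A = np.column_stack([0.8 * f + 0.6 * rng.standard_normal(300) for _ in range(3)])
        B = np.column_stack([0.8 * f + 0.6 * rng.standard_normal(300) for _ in range(3)])
        assert partial_total_correlation(A, B, f).rho2 < total_correlation(A, B).rho2

    def test_constant_factor_rejected(self):
        rng = np.random.default_rng(15)
        A = rng.standard_normal((50, 2))
        with pytest.raises(ValueError):
            partial_total_correlation(A, A, np.ones(50))


class TestModulationStrengthCorrelation:
    def test_identity_r_one(self):
        x = np.linspace(0, 1, 50)
        r, _ = modulation_strength_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_coupled_generation(self):
        rng = np.random.default_rng(16)
        u = rng.uniform(0, 1, 100)
        depths = 0.1 + 0.7 * u + 0.05 * rng.standard_normal(100)
        energies = 5 + 20 * u + 2 * rng.standard_normal(100)
        r, p = modulation_strength_correlation(depths, energies)
        assert r > 0.5 and p < 0.01

    def test_independent_generation(self):
        rng = np.random.default_rng(17)
        hits = 0
        for _ in range(20):
            r, _ = modulation_strength_correlation(rng.uniform(0, 1, 100), rng.uniform(0, 1, 100))
            hits += abs(r) < 0.2
        assert hits / 20 >= 0.9

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            modulation_strength_correlation([1.0, 2.0], [1.0, 2.0])


class TestClassificationScore:
    def test_perfect_predictor(self):
        rng = np.random.default_rng(18)
        c = rng.integers(0, 2, 100)
        c_hat_s = c.copy()
        flip = rng.choice(100, 63, replace=False)
        c_hat_s[flip] = 1 - c_hat_s[flip]  # 37 correct
        assert classification_score(c, c, c_hat_s) == 1.0

    def test_shuffle_matching_predictor(self):
        rng = np.random.default_rng(19)
        c = rng.integers(0, 2, 100)
        c_hat_s = c.copy()
        flip = rng.choice(100, 63, replace=False)
        c_hat_s[flip] = 1 - c_hat_s[flip]
        assert classification_score(c, c_hat_s, c_hat_s) == 0.0

    def test_worse_than_shuffle(self):
        c = np.zeros(100, int)
        c_hat = np.r_[np.zeros(50, int), np.ones(50, int)]
        c_hat_s = np.r_[np.zeros(60, int), np.ones(40, int)]
        assert classification_score(c, c_hat, c_hat_s) == pytest.approx(-0.25)

    def test_perfect_shuffle_rejected(self):
        c = np.zeros(10, int)
        with pytest.raises(ValueError):
            classification_score(c, c, c)

    def test_score_one_iff_perfect(self):
        rng = np.random.default_rng(20)
        c = rng.integers(0, 2, 50)
        c_hat = c.copy()
        c_hat[3] = 1 - c_hat[3]
        c_hat_s = c.copy()
        c_hat_s[:25] = 1 - c_hat_s[:25]
        assert classification_score(c, c_hat, c_hat_s) < 1.0
        assert classification_score(c, c, c_hat_s) == 1.0


class TestHdClassifier:
    def test_contrast_score_high(self, contrast_session):
        from ripplering.dynamics import stack_autocorr_features

        truth, units = contrast_session
        X = stack_autocorr_features(units, truth.epochs)
        hd = np.array([u.kind == "hd" for u in units])
        reports = train_hd_classifier(X, hd, max_lags_s=(0.040,), n_iter=100, n_shuffles=3, seed=0)
        assert reports[0].score > 0.8

    def test_null_score_near_zero(self, contrast_session):
        from ripplering.dynamics import stack_autocorr_features

        truth, units = contrast_session
        # homogeneous feature set: non-HD units only, random labels
        nonhd = [u for u in units if u.kind == "nonhd"]
        X = stack_autocorr_features(nonhd, truth.epochs)
        rng = np.random.default_rng(1)
        scores = []
        for k in range(5):
            y = rng.permutation(np.r_[np.zeros(len(nonhd) // 2, int), np.ones(len(nonhd) - len(nonhd) // 2, int)])
            rep = train_hd_classifier(X, y, max_lags_s=(0.040,), n_iter=50, n_shuffles=3, seed=k)
            scores.append(rep[0].score)
        # individual runs are noisy at this n; the replicate mean is chance-level
        assert abs(np.mean(scores)) < 0.15

    def test_score_grows_with_duration(self, contrast_session):
        from ripplering.dynamics import stack_autocorr_features

        truth, units = contrast_session
        X = stack_autocorr_features(units, truth.epochs)
        hd = np.array([u.kind == "hd" for u in units])
        reports = train_hd_classifier(X, hd, max_lags_s=(0.004, 0.012, 0.040), n_iter=60, n_shuffles=2, seed=0)
        scores = [r.score for r in reports]
        rho = sps.spearmanr(np.arange(3), scores).statistic
        assert rho > 0 or scores[-1] >= 0.95 * max(scores)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_hd_classifier(np.random.default_rng(2).standard_normal((20, 30)), np.zeros(20, int))
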