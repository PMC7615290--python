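import itertools

import numpy as np
import pandas as pd
import pytest

from cnvsig import (
    CNV_GROUPS,
    CONTROL,
    DEFAULT_GRID,
    NoiseConfig,
    SignatureConfig,
    adjust_confounds,
    coeff_vs_performance,
    cohens_d_map,
    fit_binary_lda,
    fit_ensemble,
    loo_select_alpha,
    make_signatures,
    mcc,
    multiclass_lda_embedding,
    network_summary,
    pca_embedding,
    permutation_null,
    shrunk_covariance,
    simulate_clinical,
    zscore_columns,
)
from cnvsig.ensemble import (
    DegenerateEmbeddingError,
    EnsembleSignature,
    SingularCovarianceError,
    _loo_confusions,
)


def _data_with_pooled_cov(cov, dmu, n_per_class=4, seed=0):
    """Two classes whose pooled ML covariance is exactly ``cov``; means differ by dmu."""
    L = np.linalg.cholesky(np.asarray(cov, dtype=float))
    p = L.shape[0]
    rows = []
    for j in range(p):
        a = np.sqrt(p) * L[:, j]
        rows.extend([a, -a])
    block = np.asarray(rows)  # centered, block.T @ block / (2p) = cov
    X0 = block
    X1 = block + np.asarray(dmu, dtype=float)
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(len(X0)), np.ones(len(X1))]
    return X, y


class TestShrunkCovariance:
    def test_alpha_zero_reproduces_ml_covariance(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 4))
        S = shrunk_covariance(X, 0.0).matrix
        Xc = X - X.mean(axis=0)
        assert np.allclose(S, Xc.T @ Xc / 30, atol=1e-12)

    def test_alpha_one_is_scaled_identity(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 4))
        S = shrunk_covariance(X, 1.0).matrix
        Xc = X - X.mean(axis=0)
        mu = np.trace(Xc.T @ Xc / 30) / 4
        assert np.allclose(S, mu * np.eye(4), atol=1e-12)

    def test_hand_interpolation(self):
        X, _ = _data_with_pooled_cov([[2.0, 1.0], [1.0, 2.0]], [0.0, 0.0])
        # the centered block alone has ML covariance [[2,1],[1,2]]
        half = X[: len(X) // 2]
        S = shrunk_covariance(half, 0.5).matrix
        assert np.allclose(S, [[2.0, 0.5], [0.5, 2.0]], atol=1e-12)

    @pytest.mark.parametrize("alpha", [-0.1, 1.1])
    def test_alpha_range_checked(self, alpha):
        with pytest.raises(ValueError):
            shrunk_covariance(np.eye(3), alpha)


class TestBinaryLDA:
    def test_identity_covariance_axis_aligned(self):
        X, y = _data_with_pooled_cov(np.eye(2), [1.0, 0.0])
        m = fit_binary_lda(X, y, 0.0)
        w = m.w / np.linalg.norm(m.w)
        assert np.allclose(np.abs(w), [1.0, 0.0], atol=1e-10)

    def test_hand_inverse(self):
        X, y = _data_with_pooled_cov([[1.0, 0.0], [0.0, 4.0]], [1.0, 1.0])
        m = fit_binary_lda(X, y, 0.0)
        assert m.w[1] / m.w[0] == pytest.approx(0.25, abs=1e-12)

    def test_alpha_one_reduces_to_mean_difference(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 6))
        y = np.r_[np.zeros(20), np.ones(20)]
        X[y == 1] += rng.standard_normal(6)
        m = fit_binary_lda(X, y, 1.0)
        dmu = X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0)
        cos = m.w @ dmu / (np.linalg.norm(m.w) * np.linalg.norm(dmu))
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_oracle_small_p(self):
        """w agrees with an explicit inv(Sigma) @ dmu computation to 1e-8."""
        rng = np.random.default_rng(3)
        for p in (1, 2, 3):
            X = rng.standard_normal((25, p))
            y = (rng.random(25) < 0.5).astype(int)
            y[:2] = [0, 1]
            for alpha in (0.0, 0.3, 1.0):
                m = fit_binary_lda(X, y, alpha)
                X0, X1 = X[y == 0], X[y == 1]
                Xc = np.vstack([X0 - X0.mean(0), X1 - X1.mean(0)])
                S = Xc.T @ Xc / len(X)
                Sigma = (1 - alpha) * S + alpha * np.trace(S) / p * np.eye(p)
                w_oracle = np.linalg.inv(Sigma) @ (X1.mean(0) - X0.mean(0))
                assert np.allclose(m.w, w_oracle, atol=1e-8)

    def test_matches_sklearn_direction(self):
        """Independent oracle: sklearn's lsqr+shrinkage LDA is collinear."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(4)
        X = rng.standard_normal((60, 8))
        y = np.r_[np.zeros(25), np.ones(35)].astype(int)
        X[y == 1] += 0.5
        for alpha in (0.1, 0.5, 0.9):
            m = fit_binary_lda(X, y, alpha)
            sk = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=alpha).fit(X, y)
            cos = m.w @ sk.coef_[0] / (
                np.linalg.norm(m.w) * np.linalg.norm(sk.coef_[0])
            )
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_singular_at_alpha_zero_advises_shrinkage(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((10, 20))  # p >= n
        y = np.r_[np.zeros(5), np.ones(5)]
        with pytest.raises(SingularCovarianceError, match="alpha > 0"):
            fit_binary_lda(X, y, 0.0)


class TestMCC:
    def test_perfect_and_degenerate(self):
        assert mcc(7, 5, 0, 0) == 1.0
        assert mcc(0, 0, 5, 7) == -1.0
        assert mcc(12, 0, 8, 0) == 0.0  # everything predicted positive

    def test_hand_example(self):
        assert mcc(3, 4, 1, 2) == pytest.approx(10.0 / np.sqrt(600.0))

    def test_exhaustive_against_sklearn(self):
        """All confusion matrices with total <= 6 match sklearn's score."""
        import warnings

        from sklearn.metrics import matthews_corrcoef

        for tp, tn, fp, fn in itertools.product(range(7), repeat=4):
            total = tp + tn + fp + fn
            if total < 1 or total > 6:
                continue
            y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
            y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                expected = matthews_corrcoef(y_true, y_pred)
            assert mcc(tp, tn, fp, fn) == pytest.approx(expected, abs=1e-12)


class TestLOOSelection:
    def test_exact_against_naive_refits(self):
        """The downdated LOO engine equals literal per-sample refitting."""
        rng = np.random.default_rng(6)
        X = rng.standard_normal((30, 5))
        y = (rng.random(30) < 0.4).astype(int)
        alphas = np.array([0.1, 0.4, 0.8])
        fast = _loo_confusions(X, y, alphas)
        naive = np.zeros((3, 4), dtype=int)
        for k, a in enumerate(alphas):
            for i in range(30):
                mask = np.ones(30, bool)
                mask[i] = False
                m = fit_binary_lda(X[mask], y[mask], a)
                pred = m.predict(X[i : i + 1])[0]
                naive[k, 0] += pred == 1 and y[i] == 1
                naive[k, 1] += pred == 0 and y[i] == 0
                naive[k, 2] += pred == 1 and y[i] == 0
                naive[k, 3] += pred == 0 and y[i] == 1
        assert np.array_equal(fast, naive)

    def test_separable_problem_ties_to_smallest_alpha(self):
        X, y = _data_with_pooled_cov(0.0001 * np.eye(2), [10.0, 0.0], seed=1)
        assert loo_select_alpha(X, y) == 0.0

    def test_high_dimensional_excludes_alpha_zero(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((20, 40))
        y = np.r_[np.zeros(10), np.ones(10)]
        assert loo_select_alpha(X, y) > 0.0

    def test_grid_with_only_alpha_zero_in_singular_regime(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((10, 30))
        y = np.r_[np.zeros(5), np.ones(5)]
        with pytest.raises(SingularCovarianceError):
            loo_select_alpha(X, y, grid=(0.0,))


def _one_group_fit(adjusted, cohort, truth, group="16p11.2del", B=25, seed=0):
    grp = cohort.group
    carriers = grp.index[grp == group]
    controls = grp.index[grp == CONTROL]
    sub = carriers.append(controls)
    z = zscore_columns(adjusted.values.loc[sub], over_subjects=sub)
    d = cohens_d_map(z, carriers, controls, group=group)
    y = np.r_[np.ones(len(carriers)), np.zeros(len(controls))]
    sig = fit_ensemble(adjusted.values.loc[sub], y, B=B, seed=seed, d_map=d,
                       group=group)
    return sig, d


class TestEnsemble:
    def test_single_bootstrap_equals_its_discriminant(self, adjusted_small,
                                                      clinical_small, truth100):
        sig, _ = _one_group_fit(adjusted_small, clinical_small, truth100, B=1, seed=3)
        assert sig.discriminants.shape[0] == 1
        assert np.allclose(sig.W, sig.discriminants[0])
        assert np.linalg.norm(sig.W) == pytest.approx(1.0)

    def test_determinism(self, adjusted_small, clinical_small, truth100):
        a, _ = _one_group_fit(adjusted_small, clinical_small, truth100, B=5, seed=9)
        b, _ = _one_group_fit(adjusted_small, clinical_small, truth100, B=5, seed=9)
        assert np.array_equal(a.W, b.W)
        assert np.array_equal(a.oob_mcc, b.oob_mcc)
        assert np.array_equal(a.significant, b.significant)

    def test_signature_recovers_planted_map(self, adjusted_small, clinical_small,
                                            truth100):
        """Strong planted effect at n=50/150, p=100: W tracks the true map."""
        sig, _ = _one_group_fit(adjusted_small, clinical_small, truth100,
                                B=25, seed=13)
        assert abs(np.corrcoef(sig.W, truth100.beta[4])[0, 1]) >= 0.7
        assert sig.mean_mcc > 0.5

    def test_recovery_monotone_in_theta(self, atlas100):
        means = []
        for theta in (0.25, 0.5, 1.0):
            vals = []
            for s in range(2):
                truth = make_signatures(
                    atlas100, SignatureConfig(theta=theta), seed=800 + s
                )
                sizes = {g: 2 for g in CNV_GROUPS}
                sizes.update({"16p11.2del": 50, CONTROL: 150})
                cohort = simulate_clinical(truth, atlas100, sizes=sizes,
                                           seed=900 + s)
                adj, _ = adjust_confounds(cohort.volumes, cohort.confounds)
                sig, _ = _one_group_fit(adj, cohort, truth, B=10, seed=s)
                vals.append(abs(np.corrcoef(sig.W, truth.beta[4])[0, 1]))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_pure_noise_significance_near_nominal(self):
        """Pure-noise labels at B=100: <= 10% significant coefficients."""
        rng = np.random.default_rng(14)
        X = pd.DataFrame(rng.standard_normal((120, 40)))
        y = np.r_[np.ones(30), np.zeros(90)]
        d = rng.standard_normal(40)
        sig = fit_ensemble(X, y, B=100, seed=15, d_map=d)
        assert sig.significant.mean() <= 0.10
        assert -0.3 < sig.mean_mcc < 0.3

    def test_tiny_class_iterations_handled(self):
        rng = np.random.default_rng(16)
        X = pd.DataFrame(rng.standard_normal((20, 5)))
        y = np.r_[np.ones(2), np.zeros(18)]
        sig = fit_ensemble(X, y, B=10, seed=17)
        assert sig.oob_mcc.shape[0] + sig.n_invalid == 10


class TestPermutationNull:
    def test_single_permutation_threshold(self):
        rng = np.random.default_rng(18)
        X = rng.standard_normal((60, 10))
        y = np.r_[np.ones(15), np.zeros(45)]
        null, thr = permutation_null(X, y, B=5, n_perm=1, seed=19)
        assert null.shape == (1,)
        assert thr == pytest.approx(null[0])

    def test_planted_effect_beats_null(self, adjusted_small, clinical_small,
                                       truth100):
        sig, _ = _one_group_fit(adjusted_small, clinical_small, truth100,
                                B=10, seed=20)
        grp = clinical_small.group
        carriers = grp.index[grp == "16p11.2del"]
        controls = grp.index[grp == CONTROL]
        sub = carriers.append(controls)
        y = np.r_[np.ones(len(carriers)), np.zeros(len(controls))]
        null, thr = permutation_null(
            adjusted_small.values.loc[sub], y, B=10, n_perm=10, seed=21, B_null=5
        )
        assert sig.mean_mcc > thr


def _fake_signature(mask, mean_mcc=0.5, group="g"):
    p = len(mask)
    return EnsembleSignature(
        discriminants=np.zeros((2, p)),
        W=np.zeros(p),
        ci_low=np.where(mask, 0.1, -0.1),
        ci_high=np.where(mask, 0.2, 0.1),
        significant=np.asarray(mask, dtype=bool),
        oob_mcc=np.array([mean_mcc]),
        mean_mcc=mean_mcc,
        alphas=np.array([0.5]),
        n_invalid=0,
        group=group,
    )


class TestInspection:
    def test_network_summary_trivial_masks(self, atlas40):
        p = atlas40.n_regions
        none = network_summary(_fake_signature(np.zeros(p, bool)), atlas40)
        assert (none.fraction == 0).all()
        only3 = network_summary(
            _fake_signature(atlas40.network_label == 3), atlas40
        )
        assert only3.fraction[2] == 1.0
        assert only3.fraction.sum() == 1.0

    def test_network_concentrated_effect_detected(self, atlas100):
        # significance concentrated where a planted network-weighted map lives
        mask = np.zeros(atlas100.n_regions, bool)
        target = 5
        mask[atlas100.network_label == target] = True
        mask[::17] = True  # sprinkle a few elsewhere
        summary = network_summary(_fake_signature(mask), atlas100)
        assert np.argmax(summary.fraction) == target - 1

    def test_coeff_vs_performance_proportional(self):
        sigs = [
            _fake_signature(np.arange(20) < k, mean_mcc=0.1 * k, group=str(k))
            for k in (2, 4, 6, 8)
        ]
        r, p = coeff_vs_performance(sigs)
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_fewer_than_three_rejected(self):
        sigs = [_fake_signature(np.zeros(5, bool))] * 2
        with pytest.raises(ValueError):
            coeff_vs_performance(sigs)

    def test_constant_inputs_rejected(self):
        sigs = [_fake_signature(np.zeros(5, bool), mean_mcc=0.5)] * 4
        with pytest.raises(ValueError):
            coeff_vs_performance(sigs)


class TestEmbeddings:
    def test_pca_single_axis_explains_everything(self):
        t = np.linspace(-1, 1, 20)
        X = pd.DataFrame(np.outer(t, [1.0, 2.0, -1.0]) )
        X.iloc[:, :] += 1e-9 * np.random.default_rng(0).standard_normal(X.shape)
        emb = pca_embedding(X, fit_subjects=X.index)
        assert emb.explained_variance[0] == pytest.approx(1.0, abs=1e-6)

    def test_pca_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(22)
        X = pd.DataFrame(rng.standard_normal((5, 4)))
        emb = pca_embedding(X, fit_subjects=X.index)
        Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / 5)
        order = np.argsort(evals)[::-1][:2]
        for j in range(2):
            v = evecs[:, order[j]]
            cos = abs(v @ emb.loadings[:, j])
            assert cos == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(
            sorted(emb.explained_variance, reverse=True),
            sorted(evals[order] / evals.sum(), reverse=True),
            atol=1e-8,
        )

    def test_pca_isotropic_high_dim_explains_little(self):
        rng = np.random.default_rng(23)
        X = pd.DataFrame(rng.standard_normal((200, 100)))
        emb = pca_embedding(X, fit_subjects=X.index)
        assert emb.explained_variance.sum() < 0.10

    def test_pca_projection_consistency(self):
        rng = np.random.default_rng(24)
        X = pd.DataFrame(rng.standard_normal((30, 6)),
                         index=[f"s{i}" for i in range(30)])
        emb = pca_embedding(X, fit_subjects=X.index[:20],
                            project_subjects=X.index[20:])
        manual = (X.loc[X.index[20:]].to_numpy() - emb.center) @ emb.loadings
        assert np.allclose(emb.coordinates.loc[X.index[20:]].to_numpy(), manual)

    def test_pca_needs_three_subjects(self):
        X = pd.DataFrame(np.eye(2))
        with pytest.raises(ValueError):
            pca_embedding(X, fit_subjects=X.index)

    def test_multiclass_two_classes_single_dimension(self):
        rng = np.random.default_rng(25)
        X = pd.DataFrame(rng.standard_normal((40, 5)),
                         index=[f"s{i}" for i in range(40)])
        X.iloc[:20] += 2.0
        labels = pd.Series(["a"] * 20 + ["b"] * 20, index=X.index)
        emb = multiclass_lda_embedding(X, labels)
        assert emb.coordinates.shape[1] == 1
        assert list(emb.coordinates.columns) == ["LD1"]

    def test_multiclass_leading_dimension_separates_extreme_pair(self):
        """Two well-separated classes sit at opposite LD1 extremes."""
        rng = np.random.default_rng(26)
        means = {f"c{k}": 0.3 * rng.standard_normal(6) for k in range(4)}
        means["c0"] = np.r_[6.0, np.zeros(5)]
        means["c1"] = np.r_[-6.0, np.zeros(5)]
        rows, labs = [], []
        for lab, mu in means.items():
            rows.append(mu + rng.standard_normal((15, 6)))
            labs.extend([lab] * 15)
        X = pd.DataFrame(np.vstack(rows), index=[f"s{i}" for i in range(60)])
        labels = pd.Series(labs, index=X.index)
        emb = multiclass_lda_embedding(X, labels)
        ld1 = emb.coordinates["LD1"]
        class_means = ld1.groupby(labels).mean().sort_values()
        assert {class_means.index[0], class_means.index[-1]} == {"c0", "c1"}

    def test_multiclass_equal_means_degenerate(self):
        # three classes built from the same rows: class means coincide exactly
        rng = np.random.default_rng(27)
        block = rng.standard_normal((10, 4))
        X = pd.DataFrame(np.vstack([block, block, block]),
                         index=[f"s{i}" for i in range(30)])
        labels = pd.Series(["a"] * 10 + ["b"] * 10 + ["c"] * 10, index=X.index)
        with pytest.raises(DegenerateEmbeddingError):
            multiclass_lda_embedding(X, labels)
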