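"""One-pair PLS: NIPALS against SVD and scikit-learn oracles, confound
deflation, kernel-space CV equivalence, sign alignment, permutation
behaviour, and VIP bootstrap properties."""

import numpy as np
import pytest

import qsmpet as q
from qsmpet.plsr import (
    PLSOnePair,
    align_sign,
    crossval_scores,
    fit_one_pair,
    permutation_test,
    residualize_confounds,
    vip_single_component,
    vip_z_maps,
)


@pytest.fixture(scope="module")
def planted_blocks():
    return q.generate_latent_pair_blocks(40, 80, 120, -0.42, seed=3)


class TestResidualizeConfounds:
    def test_orthogonal_block_unchanged(self, rng):
        C = np.column_stack([np.ones(50), rng.normal(size=50)])
        B = rng.normal(size=(50, 10))
        B -= C @ np.linalg.lstsq(C, B, rcond=None)[0]
        out = residualize_confounds(B, C)
        assert np.allclose(out, B, atol=1e-10)

    def test_exact_linear_function_zeroed(self, rng):
        C = np.column_stack([np.ones(50), rng.normal(size=50), rng.normal(size=50)])
        B = C @ rng.normal(size=(3, 7))
        assert np.abs(residualize_confounds(B, C)).max() < 1e-9

    def test_residuals_orthogonal_to_confounders(self, rng):
        C = np.column_stack([np.ones(50), rng.normal(size=(50, 3))])
        B = rng.normal(size=(50, 20))
        out = residualize_confounds(B, C)
        inner = C.T @ out / (np.linalg.norm(C, axis=0)[:, None] * np.linalg.norm(out, axis=0))
        assert np.abs(inner).max() < 1e-8

    def test_rank_deficient_confounders_rejected(self, rng):
        C = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(ValueError, match="rank"):
            residualize_confounds(rng.normal(size=(20, 3)), C)


class TestFitOnePair:
    def test_weight_matches_leading_singular_vector(self, rng):
        X = rng.normal(size=(40, 200))
        Y = rng.normal(size=(40, 300))
        # random blocks have a small spectral gap; allow the iteration room
        m = PLSOnePair(max_iter=20000, tol=1e-13).fit(X, Y)
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        u = np.linalg.svd(Xc.T @ Yc, full_matrices=False)[0][:, 0]
        assert abs(u @ m.x_weights_) >= 1 - 1e-8
        assert np.isclose(np.linalg.norm(m.x_weights_), 1.0)

    def test_matches_sklearn_pls(self, planted_blocks):
        from sklearn.cross_decomposition import PLSRegression

        X, Y, *_ = planted_blocks
        m = fit_one_pair(X, Y)
        sk = PLSRegression(n_components=1, scale=False).fit(X, Y)
        w_sk = sk.x_weights_[:, 0]
        assert abs(w_sk @ m.x_weights_) >= 1 - 1e-8

    def test_strong_coupling_when_response_is_a_predictor_column(self, rng):
        # PLS maximizes covariance, not correlation, so the score correlation
        # is near 1 (exactly 1 only if the column is an eigendirection)
        X = rng.normal(size=(30, 5))
        Y = X[:, [2]].copy()
        m = fit_one_pair(X, Y)
        r = np.corrcoef(m.x_scores_, m.y_scores_)[0, 1]
        assert r > 0.97

    def test_subject_permutation_equivariance(self, planted_blocks, rng):
        X, Y, *_ = planted_blocks
        perm = rng.permutation(len(X))
        m0 = fit_one_pair(X, Y)
        m1 = fit_one_pair(X[perm], Y[perm])
        assert np.allclose(np.abs(m0.x_weights_), np.abs(m1.x_weights_), atol=1e-6)
        assert np.allclose(m0.x_scores_[perm], np.sign(m0.x_weights_ @ m1.x_weights_)
                           * m1.x_scores_, atol=1e-6)

    def test_column_shift_invariance(self, planted_blocks):
        X, Y, *_ = planted_blocks
        m0 = fit_one_pair(X, Y)
        m1 = fit_one_pair(X + 100.0, Y - 5.0)
        assert np.allclose(m0.x_weights_, m1.x_weights_, atol=1e-9)
        assert np.allclose(m0.x_scores_, m1.x_scores_, atol=1e-8)

    def test_zero_variance_block_rejected(self):
        with pytest.raises(ValueError, match="variance|degenerate"):
            fit_one_pair(np.ones((10, 4)), np.random.default_rng(0).normal(size=(10, 3)))


class TestCrossval:
    def test_kernel_equals_direct(self, planted_blocks):
        X, Y, *_ = planted_blocks
        for seed in (0, 11):
            rk = crossval_scores(X, Y, n_repeats=4, seed=seed, method="kernel")
            rd = crossval_scores(X, Y, n_repeats=4, seed=seed, method="direct")
            assert rk == pytest.approx(rd, abs=1e-3)

    def test_deterministic_for_fixed_seed(self, planted_blocks):
        X, Y, *_ = planted_blocks
        assert crossval_scores(X, Y, n_repeats=3, seed=5) == crossval_scores(
            X, Y, n_repeats=3, seed=5)

    def test_independent_blocks_near_zero(self):
        vals = [
            crossval_scores(*q.generate_latent_pair_blocks(40, 60, 80, 0.0, seed=s)[:2],
                            n_repeats=3, seed=s)
            for s in range(8)
        ]
        assert abs(np.mean(vals)) < 0.1

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            crossval_scores(rng.normal(size=(5, 4)), rng.normal(size=(5, 4)), n_folds=10)


class TestPermutation:
    def test_extreme_observed_gives_minimal_p(self, planted_blocks):
        X, Y, *_ = planted_blocks
        p, _, _ = permutation_test(X, Y, n_perm=150, seed=0, n_repeats_perm=2,
                                   observed_r=2.0)  # beyond any attainable null
        assert p == pytest.approx(1 / 151)

    def test_null_mean_centered_at_zero(self, planted_blocks):
        X, Y, *_ = planted_blocks
        _, _, null = permutation_test(X, Y, n_perm=200, seed=1, n_repeats_perm=2,
                                      observed_r=0.5)
        assert abs(null.mean()) < 0.05

    def test_small_n_perm_refused(self, planted_blocks):
        X, Y, *_ = planted_blocks
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(X, Y, n_perm=50)


class TestAlignSign:
    def test_no_op_when_aligned(self, planted_blocks):
        X, Y, *_ = planted_blocks
        m = fit_one_pair(X, Y)
        q_before = m.y_loadings_.copy()
        r_scores = np.corrcoef(m.x_scores_, m.y_scores_)[0, 1]
        roi = np.sign(np.corrcoef(X.mean(1), Y.mean(1))[0, 1])
        align_sign(m, X.mean(1), Y.mean(1))
        if np.sign(r_scores) == roi:
            assert np.array_equal(m.y_loadings_, q_before)

    def test_alignment_postcondition_under_input_negation(self, planted_blocks):
        # negating the response block flips the ROI-mean correlation; after
        # alignment both models satisfy the sign rule with equal |r|
        X, Y, *_ = planted_blocks
        m0 = align_sign(fit_one_pair(X, Y), X.mean(1), Y.mean(1))
        m1 = align_sign(fit_one_pair(X, -Y), X.mean(1), (-Y).mean(1))
        for m, yy in ((m0, Y), (m1, -Y)):
            r = np.corrcoef(m.x_scores_, m.y_scores_)[0, 1]
            roi = np.corrcoef(X.mean(1), yy.mean(1))[0, 1]
            assert np.sign(r) == np.sign(roi)
        r0 = np.corrcoef(m0.x_scores_, m0.y_scores_)[0, 1]
        r1 = np.corrcoef(m1.x_scores_, m1.y_scores_)[0, 1]
        assert abs(r0) == pytest.approx(abs(r1), abs=1e-8)

    def test_idempotent(self, planted_blocks):
        X, Y, *_ = planted_blocks
        m = align_sign(fit_one_pair(X, Y), X.mean(1), Y.mean(1))
        q1 = m.y_loadings_.copy()
        align_sign(m, X.mean(1), Y.mean(1))
        assert np.array_equal(m.y_loadings_, q1)

    def test_preserves_score_correlation_magnitude(self, planted_blocks):
        X, Y, *_ = planted_blocks
        m = fit_one_pair(X, Y)
        r0 = np.corrcoef(m.x_scores_, m.y_scores_)[0, 1]
        # force a flip: use an ROI target whose sign opposes the score corr
        align_sign(m, m.x_scores_, -np.sign(r0) * m.x_scores_)
        r1 = np.corrcoef(m.x_scores_, m.y_scores_)[0, 1]
        assert r1 == pytest.approx(-r0, abs=1e-12)

    def test_zero_roi_correlation_warns(self, planted_blocks):
        X, Y, *_ = planted_blocks
        m = fit_one_pair(X, Y)
        with pytest.warns(UserWarning, match="sign"):
            align_sign(m, np.array([1.0, -1.0] * 20), np.zeros(40))


class TestVip:
    def test_single_signal_voxel_dominates(self, rng):
        n, p = 60, 30
        f = rng.normal(size=n)
        X = 0.01 * rng.normal(size=(n, p))
        X[:, 4] += f
        Y = f[:, None] + 0.01 * rng.normal(size=(n, 10))
        m = fit_one_pair(X, Y)
        vip = vip_single_component(m.x_weights_)
        assert vip[4] == pytest.approx(np.sqrt(p), rel=0.01)
        assert np.delete(vip, 4).max() < 0.2 * np.sqrt(p)

    def test_reduces_to_general_vip_formula_at_one_component(self, planted_blocks):
        X, Y, *_ = planted_blocks
        m = fit_one_pair(X, Y)
        w = m.x_weights_
        t = m.x_scores_
        qv = m.y_loadings_
        # general multi-component VIP with A = 1:
        # VIP_j = sqrt(p * SS_1 (w_j1/||w_1||)^2 / SS_1), SS_1 = q'q t't
        ss = (qv @ qv) * (t @ t)
        general = np.sqrt(len(w) * ss * (w / np.linalg.norm(w)) ** 2 / ss)
        assert np.allclose(vip_single_component(w), general, atol=1e-10)

    def test_vip_mean_square_is_one(self, planted_blocks):
        X, Y, *_ = planted_blocks
        m = fit_one_pair(X, Y)
        assert np.mean(vip_single_component(m.x_weights_) ** 2) == pytest.approx(1.0)

    def test_planted_negative_association_gives_negative_z(self):
        X, Y, *_ = q.generate_latent_pair_blocks(40, 60, 80, -0.42, seed=6,
                                                 signal_fraction=1.0)
        m = align_sign(fit_one_pair(X, Y), X.mean(1), Y.mean(1))
        pz, rz = vip_z_maps(X, Y, m, n_boot=200, seed=0)
        # response z signs follow q, which the alignment made negative
        assert (rz < 0).mean() >= 0.95 or (pz < 0).mean() >= 0.95

    def test_bootstrap_determinism(self, planted_blocks):
        X, Y, *_ = planted_blocks
        m = fit_one_pair(X, Y)
        a = vip_z_maps(X, Y, m, n_boot=25, seed=3)
        b = vip_z_maps(X, Y, m, n_boot=25, seed=3)
        assert np.array_equal(a[0], b[0], equal_nan=True)


class TestEstimator:
    def test_end_to_end_inference(self):
        X, Y, *_ = q.generate_latent_pair_blocks(40, 60, 90, -0.42, seed=8)
        est = q.PLSBrainMapInference(n_repeats=5, n_perm=150, n_boot=50, seed=0)
        est.fit(X, Y)
        assert -1 <= est.mean_oos_r_ <= 1
        assert est.mean_oos_r_ < -0.25  # aligned to the negative association
        assert 0 < est.perm_p_ <= 1
        assert est.predictor_z_.shape == (60,) and est.response_z_.shape == (90,)
        assert est.get_params()["n_perm"] == 150

    def test_confound_deflation_path(self, rng):
        X, Y, *_ = q.generate_latent_pair_blocks(40, 30, 40, -0.42, seed=9)
        C = np.column_stack([np.ones(40), rng.normal(size=40)])
        est = q.PLSBrainMapInference(n_repeats=3, n_perm=120, n_boot=20, seed=0,
                                     confounders=C)
        est.fit(X, Y)
        assert np.isfinite(est.mean_oos_r_)
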