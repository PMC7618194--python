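"""One-pair partial least squares association between two voxel blocks
(SN-VTA susceptibility predictors, striatal Ki responses): confound
deflation, NIPALS latent-pair extraction, repeated randomized 10-fold
cross-validation, subject-level permutation inference, sign alignment to the
ROI-mean correlation, and bootstrapped VIP z-maps.

NIPALS is implemented directly (a dozen lines for one component) so that
external PLS implementations and the SVD of the cross-block covariance stay
available as independent cross-checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "PLSOnePair",
    "PLSBrainMapInference",
    "residualize_confounds",
    "fit_one_pair",
    "crossval_scores",
    "permutation_test",
    "align_sign",
    "vip_z_maps",
    "vip_single_component",
]


def residualize_confounds(block, confounders):
    """Replace each column by its least-squares residual on the confounders.

    The confounder matrix must include an intercept column and be full rank;
    output columns are orthogonal to every confounder column.
    """
    B = np.asarray(block, dtype=float)
    C = np.asarray(confounders, dtype=float)
    if C.ndim != 2:
        raise ValueError("confounders must be 2D")
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("confounder matrix is rank deficient")
    if not np.any(np.all(np.isclose(C, C[0:1, :]), axis=0) & np.all(C != 0, axis=0)):
        # no constant nonzero column -> no intercept
        raise ValueError("confounder matrix must include an intercept column")
    coef, *_ = np.linalg.lstsq(C, B, rcond=None)
    return B - C @ coef


class PLSOnePair(BaseEstimator):
    """Single latent-pair PLS (NIPALS), the two-block score model.

    fit(X, Y) extracts one component: predictor weights ``x_weights_`` (unit
    norm), response loadings ``y_loadings_``, subject scores ``x_scores_``
    and ``y_scores_``, and the centering vectors ``x_mean_`` / ``y_mean_``.
    Held-out subjects are projected with :meth:`transform` using the
    training centering (no information leakage).
    """

    def __init__(self, max_iter: int = 500, tol: float = 1e-10):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n = X.shape[0]
        if n < 3 or Y.shape[0] != n:
            raise ValueError("need >= 3 subjects and matching block rows")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        Xc = X - self.x_mean_
        Yc = Y - self.y_mean_
        if not (Xc.std(axis=0) > 0).any() or not (Yc.std(axis=0) > 0).any():
            raise ValueError("zero-variance block")
        u = Yc[:, int(np.argmax(Yc.var(axis=0)))].copy()
        if not u.any():
            u = np.ones(n)
        w = None
        for it in range(self.max_iter):
            w_new = Xc.T @ u
            norm = np.linalg.norm(w_new)
            if norm == 0:
                raise ValueError("degenerate NIPALS step (X block orthogonal to scores)")
            w_new /= norm
            t = Xc @ w_new
            q = Yc.T @ t / (t @ t)
            qn = q @ q
            u = Yc @ q / qn if qn > 0 else t.copy()
            if w is not None and np.max(np.abs(w_new - w)) < self.tol:
                w = w_new
                break
            w = w_new
        self.n_iter_ = it + 1
        self.x_weights_ = w
        self.x_scores_ = Xc @ w
        self.y_loadings_ = Yc.T @ self.x_scores_ / (self.x_scores_ @ self.x_scores_)
        qn = np.linalg.norm(self.y_loadings_)
        self.y_scores_ = Yc @ self.y_loadings_ / (qn**2 if qn > 0 else 1.0)
        return self

    def transform(self, X, Y=None):
        t = (np.asarray(X, float) - self.x_mean_) @ self.x_weights_
        if Y is None:
            return t
        q = self.y_loadings_
        qn = q @ q
        u = (np.asarray(Y, float) - self.y_mean_) @ q / (qn if qn > 0 else 1.0)
        return t, u

    def flip_y(self):
        """Negate the response side (loadings and scores) in place."""
        self.y_loadings_ = -self.y_loadings_
        self.y_scores_ = -self.y_scores_
        return self


def fit_one_pair(X, Y, **kwargs) -> PLSOnePair:
    return PLSOnePair(**kwargs).fit(X, Y)


def _fold_assignment(n, n_folds, rng):
    idx = rng.permutation(n)
    return np.array_split(idx, n_folds)


def _centered_blocks(K, tr, fold):
    """Train-train and fold-train blocks of a Gram matrix after centering
    every feature vector by the training mean."""
    Ktt = K[np.ix_(tr, tr)]
    rm = Ktt.mean(axis=0)
    gm = rm.mean()
    A = Ktt - rm[None, :] - rm[:, None] + gm
    Kft = K[np.ix_(fold, tr)]
    Aft = Kft - rm[None, :] - Kft.mean(axis=1)[:, None] + gm
    return A, Aft


def _fold_scores_kernel(Kx, Ky, rsx, rsy, tr, fold, max_iter=500, tol=1e-10):
    """Out-of-sample (t, u) scores for one fold, computed in subject space.

    Algebraically identical to fitting the one-pair NIPALS model on the
    training subjects and projecting the held-out subjects (training-mean
    centering, unit-norm predictor weights, regression response loadings):
    the x-scores satisfy t = A B t up to scale, where A and B are the
    train-centered Gram matrices of the two blocks. The fold's response
    scores are sign-reversed when the training score correlation does not
    align with the training ROI-mean correlation, which keeps pooled
    out-of-sample scores coherent across folds.
    """
    A, Afx = _centered_blocks(Kx, tr, fold)
    B, Afy = _centered_blocks(Ky, tr, fold)
    # leading eigenvector of A B by repeated squaring (power iteration with
    # 2^10 effective steps), then two polishing iterations
    M = A @ B
    for k in range(10):
        M = M @ M
        if k % 2:
            nrm = np.abs(M).max()
            if nrm == 0:
                return np.zeros(len(fold)), np.zeros(len(fold))
            M /= nrm
    t = M @ np.ones(len(tr))
    nt = np.linalg.norm(t)
    if nt == 0:
        t = M[:, 0]
        nt = np.linalg.norm(t)
        if nt == 0:
            return np.zeros(len(fold)), np.zeros(len(fold))
    t /= nt
    for _ in range(2):
        t = A @ (B @ t)
        nrm = np.linalg.norm(t)
        if nrm == 0:
            return np.zeros(len(fold)), np.zeros(len(fold))
        t /= nrm
    u = B @ t
    nu = u @ A @ u
    if nu <= 0:
        return np.zeros(len(fold)), np.zeros(len(fold))
    t_tr = A @ u / np.sqrt(nu)
    tt = t_tr @ t_tr
    bt = B @ t_tr
    qq = (t_tr @ bt) / tt**2  # ||q||^2 for q = Yc' t / (t't)
    t_f = Afx @ u / np.sqrt(nu)
    u_f = (Afy @ t_tr) / tt / qq if qq > 0 else np.zeros(len(fold))
    # orient the x side by the sign of sum(w) (a fixed convention)
    rs_c = rsx[tr] - rsx[tr].mean()
    if (u @ rs_c) < 0:
        t_f, u_f = -t_f, -u_f
    # sign-reversal rule: flip the response scores if the training score
    # correlation direction disagrees with the training ROI-mean correlation
    score_sign = np.sign(t_tr @ bt)
    a, b = rsx[tr], rsy[tr]
    roi_sign = np.sign((a - a.mean()) @ (b - b.mean()))
    if roi_sign != 0 and score_sign != 0 and score_sign != roi_sign:
        u_f = -u_f
    return t_f, u_f


def _crossval_kernel(Kx, Ky, rsx, rsy, n_folds, n_repeats, rng):
    n = Kx.shape[0]
    rs = np.empty(n_repeats)
    ts = np.empty(n)
    us = np.empty(n)
    for rep in range(n_repeats):
        folds = _fold_assignment(n, n_folds, rng)
        for i, fold in enumerate(folds):
            if len(fold) < 1:
                raise ValueError("empty fold")
            tr = np.concatenate([f for j, f in enumerate(folds) if j != i])
            if len(tr) < 3:
                raise ValueError("fold with too few training subjects")
            ts[fold], us[fold] = _fold_scores_kernel(Kx, Ky, rsx, rsy, tr, fold)
        rs[rep] = np.corrcoef(ts, us)[0, 1]
    return rs, (ts.copy(), us.copy())


def _crossval_direct(X, Y, n_folds, n_repeats, rng):
    n = X.shape[0]
    rs = np.empty(n_repeats)
    ts = np.empty(n)
    us = np.empty(n)
    for rep in range(n_repeats):
        folds = _fold_assignment(n, n_folds, rng)
        for fold in folds:
            if len(fold) < 1:
                raise ValueError("empty fold")
            train = np.setdiff1d(np.arange(n), fold)
            if len(train) < 3:
                raise ValueError("fold with too few training subjects")
            model = PLSOnePair().fit(X[train], Y[train])
            # align each training model's X-weight sign to a fixed convention
            # so pooled out-of-sample scores are comparable across folds
            if model.x_weights_.sum() < 0:
                model.x_weights_ = -model.x_weights_
                model.x_scores_ = -model.x_scores_
                model.y_loadings_ = -model.y_loadings_
                model.y_scores_ = -model.y_scores_
            # per-fold sign-reversal rule against the training ROI means
            align_sign(model, X[train].mean(axis=1), Y[train].mean(axis=1))
            t, u = model.transform(X[fold], Y[fold])
            ts[fold] = t
            us[fold] = u
        rs[rep] = np.corrcoef(ts, us)[0, 1]
    return rs, (ts.copy(), us.copy())


def crossval_scores(X, Y, n_folds: int = 10, n_repeats: int = 100, seed=0,
                    return_scores: bool = False, method: str = "kernel"):
    """Mean out-of-sample score correlation over repeated randomized k-fold CV.

    Per repeat: random fold assignment; each fold's subjects are projected
    with the model fit on the complement (training centering); pooled
    out-of-sample (x, y) scores give one Pearson r; the mean over repeats is
    returned. ``method='kernel'`` evaluates the identical model in subject
    (Gram-matrix) space, which is much faster when voxels far outnumber
    subjects; ``method='direct'`` fits :class:`PLSOnePair` per fold.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n = X.shape[0]
    if n < n_folds:
        raise ValueError("need at least as many subjects as folds")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if method == "kernel":
        rs, last = _crossval_kernel(X @ X.T, Y @ Y.T, X.sum(axis=1), Y.sum(axis=1),
                                    n_folds, n_repeats, rng)
    elif method == "direct":
        rs, last = _crossval_direct(X, Y, n_folds, n_repeats, rng)
    else:
        raise ValueError(f"unknown method {method!r}")
    mean_r = float(rs.mean())
    if return_scores:
        return mean_r, rs, last
    return mean_r


def permutation_test(X, Y, n_perm: int = 10000, seed=0, n_folds: int = 10,
                     n_repeats: int = 100, n_repeats_perm: int = 5,
                     observed_r: float | None = None):
    """Subject-level permutation p for the mean out-of-sample correlation.

    Null models permute the subject rows of Y relative to X and are
    evaluated with the identical CV procedure (with ``n_repeats_perm``
    repeats for tractability); p = (1 + #{|null| >= |observed|})/(1+n_perm).
    Returns (perm_p, observed mean_oos_r, null array).
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100: permutation inference would be meaningless")
    rng = np.random.default_rng(seed)
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n = X.shape[0]
    if observed_r is None:
        observed_r = crossval_scores(X, Y, n_folds=n_folds, n_repeats=n_repeats, seed=rng)
    Kx = X @ X.T
    Ky = Y @ Y.T
    rsx = X.sum(axis=1)
    rsy = Y.sum(axis=1)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        rs, _ = _crossval_kernel(Kx, Ky[np.ix_(perm, perm)], rsx, rsy[perm],
                                 n_folds, n_repeats_perm, rng)
        null[i] = rs.mean()
    p = float((1 + (np.abs(null) >= abs(observed_r)).sum()) / (1 + n_perm))
    return p, float(observed_r), null


def align_sign(model: PLSOnePair, x_roi_mean, y_roi_mean) -> PLSOnePair:
    """Reverse the response-side sign if the score correlation direction
    disagrees with the ROI-mean correlation between the two measures."""
    r_scores = np.corrcoef(model.x_scores_, model.y_scores_)[0, 1]
    r_roi = np.corrcoef(np.asarray(x_roi_mean, float), np.asarray(y_roi_mean, float))[0, 1]
    if r_roi == 0 or not np.isfinite(r_roi):
        warnings.warn("ROI-mean correlation is zero; sign left unchanged")
        return model
    if np.sign(r_scores) != np.sign(r_roi):
        model.flip_y()
    return model


def vip_single_component(w: np.ndarray) -> np.ndarray:
    """Single-component VIP: sqrt(p) * |w_j| / ||w|| (mean square = 1)."""
    w = np.asarray(w, float)
    return np.sqrt(w.size) * np.abs(w) / np.linalg.norm(w)


def vip_z_maps(X, Y, model: PLSOnePair, n_boot: int = 1000, seed=0):
    """Signed VIP z-maps with error from bootstrap over response voxels.

    Each replicate resamples the response-block columns (striatal voxels)
    with replacement and refits the full one-pair model, perturbing both the
    predictor weights and the response loadings. Importance is the
    normalized absolute weight (sqrt(dim) |w|/||w||, the one-component VIP)
    on the predictor side and the analogous normalized |q| on the response
    side. z_j = sign(reference w_j or q_j) * mean_boot / sd_boot; response
    voxels never drawn in a replicate are excluded from that replicate's
    statistics. Voxels whose bootstrap SD is zero get NaN (flagged).

    Returns (predictor_z, response_z).
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    p = X.shape[1]
    qdim = Y.shape[1]
    pred_imp = np.empty((n_boot, p))
    resp_sum = np.zeros(qdim)
    resp_sumsq = np.zeros(qdim)
    resp_count = np.zeros(qdim)
    for b in range(n_boot):
        cols = rng.integers(0, qdim, size=qdim)
        mb = PLSOnePair().fit(X, Y[:, cols])
        pred_imp[b] = vip_single_component(mb.x_weights_)
        q = mb.y_loadings_
        qimp = np.sqrt(qdim) * np.abs(q) / (np.linalg.norm(q) or 1.0)
        # average replicate importance back onto original voxel ids
        sums = np.bincount(cols, weights=qimp, minlength=qdim)
        cnts = np.bincount(cols, minlength=qdim)
        drawn = cnts > 0
        mean_imp = np.zeros(qdim)
        mean_imp[drawn] = sums[drawn] / cnts[drawn]
        resp_sum[drawn] += mean_imp[drawn]
        resp_sumsq[drawn] += mean_imp[drawn] ** 2
        resp_count[drawn] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        pred_mean = pred_imp.mean(axis=0)
        pred_sd = pred_imp.std(axis=0, ddof=1)
        predictor_z = np.sign(model.x_weights_) * pred_mean / pred_sd
        resp_mean = resp_sum / resp_count
        resp_var = (resp_sumsq - resp_count * resp_mean**2) / (resp_count - 1)
        resp_sd = np.sqrt(np.maximum(resp_var, 0.0))
        response_z = np.sign(model.y_loadings_) * resp_mean / resp_sd
    predictor_z[pred_sd == 0] = np.nan
    response_z[resp_sd == 0] = np.nan
    if np.isnan(predictor_z).any() or np.isnan(response_z).any():
        warnings.warn("some voxels had zero bootstrap SD; z undefined there")
    return predictor_z, response_z


class PLSBrainMapInference(BaseEstimator):
    """End-to-end one-pair PLS inference between two voxel blocks.

    fit(X, Y) residualizes confounds (if given), extracts the latent pair,
    runs repeated CV, the subject-permutation test and the VIP bootstrap.

    Fitted attributes: ``model_``, ``mean_oos_r_``, ``perm_p_``,
    ``predictor_z_``, ``response_z_``, ``null_distribution_``.
    """

    def __init__(self, n_folds: int = 10, n_repeats: int = 100, n_perm: int = 10000,
                 n_boot: int = 1000, n_repeats_perm: int = 5, seed: int = 0,
                 confounders=None):
        self.n_folds = n_folds
        self.n_repeats = n_repeats
        self.n_perm = n_perm
        self.n_boot = n_boot
        self.n_repeats_perm = n_repeats_perm
        self.seed = seed
        self.confounders = confounders

    def fit(self, X, Y):
        X = np.asarray(X, float)
        Y = np.asarray(Y, float)
        if self.confounders is not None:
            C = np.asarray(self.confounders, float)
            X = residualize_confounds(X, C)
            Y = residualize_confounds(Y, C)
        ss = np.random.SeedSequence(self.seed).spawn(3)
        self.mean_oos_r_ = crossval_scores(
            X, Y, n_folds=self.n_folds, n_repeats=self.n_repeats,
            seed=np.random.default_rng(ss[0]),
        )
        # the score sign produced by PLS is arbitrary: reverse the response
        # side if the score correlation direction disagrees with the
        # correlation between the two blocks' ROI means
        r_roi = np.corrcoef(X.mean(axis=1), Y.mean(axis=1))[0, 1]
        self.sign_flipped_ = bool(
            np.isfinite(r_roi) and r_roi != 0
            and np.sign(self.mean_oos_r_) != np.sign(r_roi)
        )
        if self.sign_flipped_:
            self.mean_oos_r_ = -self.mean_oos_r_
        self.perm_p_, _, self.null_distribution_ = permutation_test(
            X, Y, n_perm=self.n_perm, seed=ss[1], n_folds=self.n_folds,
            n_repeats=self.n_repeats, n_repeats_perm=self.n_repeats_perm,
            observed_r=self.mean_oos_r_,
        )
        model = fit_one_pair(X, Y)
        align_sign(model, X.mean(axis=1), Y.mean(axis=1))
        self.model_ = model
        self.predictor_z_, self.response_z_ = vip_z_maps(
            X, Y, model, n_boot=self.n_boot, seed=ss[2]
        )
        return self
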