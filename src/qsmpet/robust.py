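"""ROI-level statistics: Huber robust regression with confounders, effect
sizes, correlation tests and comparisons, moderation, and BH-FDR control.

The regression estimator follows the convention of mainstream robust-fitting
implementations: Huber M-estimation with tuning constant 1.345, scale from
the normalized MAD of the residuals re-estimated each iteration, and
asymptotic-normal inference on coefficient / SE ("t-score" tested against
the standard normal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DesignSpec",
    "RobustFitResult",
    "CorrComparison",
    "RobustLinearRegression",
    "build_design_matrix",
    "fit_robust_lm",
    "moderation_fit",
    "cohens_d",
    "pearson_with_p",
    "fisher_independent_comparison",
    "steiger_dependent_comparison",
    "bh_fdr",
]

_Z975 = stats.norm.ppf(0.975)


@dataclass
class DesignSpec:
    """Model specification: response, predictor of interest, confounders.

    Categorical covariates are expanded to indicator codes against a stated
    reference level (default: smoking coded as current/past against
    "never"; sex as male against "female").
    """

    response: str
    predictor_of_interest: str
    covariates: list = field(default_factory=list)
    reference_levels: dict = field(
        default_factory=lambda: {"smoking": "never", "sex": "female", "group": "control"}
    )

    def __post_init__(self):
        if self.predictor_of_interest in self.covariates:
            raise ValueError("predictor_of_interest must not appear among covariates")


@dataclass
class RobustFitResult:
    """Tidy per-term robust-fit table plus fit diagnostics.

    ``table`` is indexed by term with columns coef, se, t, p, ci_low,
    ci_high (95% normal CIs).
    """

    table: pd.DataFrame
    scale: float
    converged: bool
    n_iter: int
    n_obs: int

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]


@dataclass
class CorrComparison:
    r1: float
    r2: float
    z: float
    p: float
    n1: int | None = None
    n2: int | None = None
    r23: float | None = None


def _check_full_rank(X: np.ndarray, names) -> None:
    from scipy.linalg import qr

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(names[i] for i in piv[rank:])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


class RobustLinearRegression(BaseEstimator):
    """Huber-weighted IRLS linear model with asymptotic-normal inference.

    Parameters
    ----------
    t_const : float
        Huber tuning constant (1.345 gives 95% Gaussian efficiency).
    max_iter, tol : int, float
        IRLS stops when the largest coefficient change falls below ``tol``
        or after ``max_iter`` iterations (then flagged non-converged).

    Fitted attributes: ``coef_``, ``se_``, ``tvalues_``, ``pvalues_``,
    ``conf_int_``, ``scale_``, ``converged_``, ``n_iter_``.
    """

    def __init__(self, t_const: float = 1.345, max_iter: int = 50, tol: float = 1e-8):
        self.t_const = t_const
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y, feature_names=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2D")
        n, p = X.shape
        if n <= p:
            raise ValueError(f"need n > number of terms ({n} <= {p})")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("missing or non-finite values in modelled columns")
        names = list(feature_names) if feature_names is not None else [f"x{i}" for i in range(p)]
        _check_full_rank(X, names)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=self.t_const)).fit(
                maxiter=self.max_iter, tol=self.tol, scale_est="mad", conv="coefs", cov="H1"
            )
        hist = list(res.fit_history["params"])
        self.n_iter_ = len(hist)
        last_delta = 0.0
        if len(hist) >= 2:
            a, b = np.ravel(hist[-1]), np.ravel(hist[-2])
            if a.size == b.size:
                last_delta = float(np.max(np.abs(a - b)))
        self.converged_ = self.n_iter_ < self.max_iter or last_delta < self.tol
        self.feature_names_ = names
        self.coef_ = np.asarray(res.params)
        self.se_ = np.asarray(res.bse)
        self.tvalues_ = self.coef_ / self.se_
        self.pvalues_ = 2 * stats.norm.sf(np.abs(self.tvalues_))
        self.conf_int_ = np.column_stack(
            [self.coef_ - _Z975 * self.se_, self.coef_ + _Z975 * self.se_]
        )
        self.scale_ = float(res.scale)
        self.weights_ = np.asarray(res.weights)
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coef_

    def result(self) -> RobustFitResult:
        if not getattr(self, "converged_", False):
            raise RuntimeError("robust fit did not converge; results withheld")
        table = pd.DataFrame(
            {
                "coef": self.coef_,
                "se": self.se_,
                "t": self.tvalues_,
                "p": self.pvalues_,
                "ci_low": self.conf_int_[:, 0],
                "ci_high": self.conf_int_[:, 1],
            },
            index=pd.Index(self.feature_names_, name="term"),
        )
        return RobustFitResult(table, self.scale_, self.converged_, self.n_iter_,
                               n_obs=len(self.weights_))


def _encode_column(data: pd.DataFrame, col: str, reference_levels: dict) -> pd.DataFrame:
    s = data[col]
    if s.dtype == bool or pd.api.types.is_numeric_dtype(s):
        return pd.DataFrame({col: s.astype(float)})
    levels = list(pd.unique(s.dropna()))
    ref = reference_levels.get(col)
    if ref is None:
        ref = sorted(levels)[0]
    if ref not in levels and len(levels) > 1:
        levels.append(ref)
    out = {}
    for lev in levels:
        if lev == ref:
            continue
        out[f"{col}[{lev}]"] = (s == lev).astype(float)
    return pd.DataFrame(out)


def build_design_matrix(data: pd.DataFrame, design: DesignSpec):
    """Response vector and design matrix (intercept first) from a tidy table.

    Rows with missing modelled values are dropped; the count is reported via
    a warning so nothing disappears silently.
    """
    cols = [design.response, design.predictor_of_interest] + list(design.covariates)
    sub = data[cols].copy()
    n0 = len(sub)
    sub = sub.dropna()
    if len(sub) < n0:
        warnings.warn(f"dropped {n0 - len(sub)} rows with missing modelled values")
    y = sub[design.response].astype(float).to_numpy()
    parts = [pd.DataFrame({"(Intercept)": np.ones(len(sub))}, index=sub.index)]
    for col in [design.predictor_of_interest] + list(design.covariates):
        parts.append(_encode_column(sub, col, design.reference_levels))
    Xdf = pd.concat(parts, axis=1)
    return y, Xdf


def fit_robust_lm(data: pd.DataFrame, design: DesignSpec, **kwargs) -> RobustFitResult:
    """Robust linear model of ``design.response`` on the predictor of interest
    plus covariates; returns the tidy coefficient table."""
    y, Xdf = build_design_matrix(data, design)
    est = RobustLinearRegression(**kwargs).fit(Xdf.to_numpy(), y, feature_names=Xdf.columns)
    return est.result()


def moderation_fit(data: pd.DataFrame, y: str, x: str, moderator: str,
                   covariates=(), **kwargs):
    """Moderation model ``y ~ x + m + x:m + covariates`` with x and m
    mean-centered before forming the product (multicollinearity control).

    Returns (RobustFitResult, interaction_term_name).
    """
    cols = [y, x, moderator] + list(covariates)
    sub = data[cols].dropna().copy()
    xc = sub[x].astype(float) - sub[x].astype(float).mean()
    mc = sub[moderator].astype(float) - sub[moderator].astype(float).mean()
    inter = f"{x}:{moderator}"
    sub[f"{x}_c"] = xc
    sub[f"{moderator}_c"] = mc
    sub[inter] = xc * mc
    design = DesignSpec(response=y, predictor_of_interest=inter,
                        covariates=[f"{x}_c", f"{moderator}_c"] + list(covariates))
    return fit_robust_lm(sub, design, **kwargs), inter


def cohens_d(group_a, group_b):
    """Standardized mean difference (b − a over pooled SD) with a 95% CI.

    The CI uses the normal approximation
    ``SE = sqrt((na+nb)/(na*nb) + d^2 / (2*(na+nb)))``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    d = (b.mean() - a.mean()) / pooled
    se = np.sqrt((na + nb) / (na * nb) + d**2 / (2 * (na + nb)))
    return float(d), float(d - _Z975 * se), float(d + _Z975 * se)


def cohens_d_ci(d: float, na: int, nb: int):
    """CI for a given d and group sizes (normal approximation)."""
    se = np.sqrt((na + nb) / (na * nb) + d**2 / (2 * (na + nb)))
    return float(d - _Z975 * se), float(d + _Z975 * se)


def pearson_with_p(x, y):
    """Pearson r with the two-sided p from t = r sqrt(n-2)/sqrt(1-r^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need n >= 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a given r and n via the t-transform on n-2 df."""
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    return float(2 * stats.t.sf(abs(t), n - 2))


def fisher_independent_comparison(r1, n1, r2, n2) -> CorrComparison:
    """Fisher r-to-z comparison of two independent correlations."""
    for r in (r1, r2):
        if not -1 < r < 1:
            raise ValueError("correlations must lie strictly within (-1, 1)")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both samples")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2 * stats.norm.sf(abs(z))
    return CorrComparison(r1=r1, r2=r2, z=float(z), p=float(p), n1=n1, n2=n2)


def steiger_dependent_comparison(r12, r13, r23, n) -> CorrComparison:
    """Steiger's z for two dependent overlapping correlations (r12 vs r13
    sharing variable 1), using the back-transformed average correlation.

    With z_jk = atanh(r_jk) and rbar = tanh((z12+z13)/2):
        psi = r23 (1 - 2 rbar^2) - rbar^2 (1 - 2 rbar^2 - r23^2) / 2
        c   = psi / (1 - rbar^2)^2
        Z   = (z12 - z13) sqrt(n - 3) / sqrt(2 - 2 c)
    """
    if n <= 4:
        raise ValueError("need n > 4")
    m = np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1]], dtype=float)
    if np.linalg.eigvalsh(m).min() <= 0:
        raise ValueError(f"correlation triple is not positive definite:\n{m}")
    z12, z13 = np.arctanh(r12), np.arctanh(r13)
    rbar = np.tanh((z12 + z13) / 2)
    psi = r23 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r23**2)
    c = psi / (1 - rbar**2) ** 2
    z = (z12 - z13) * np.sqrt(n - 3) / np.sqrt(2 - 2 * c)
    p = 2 * stats.norm.sf(abs(z))
    return CorrComparison(r1=r12, r2=r13, z=float(z), p=float(p), n1=n, r23=r23)


def bh_fdr(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up control of the FDR at level ``q``.

    Returns (rejection mask, adjusted p-values).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, bool), p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj
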