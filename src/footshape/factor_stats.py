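"""Relating subject factors to foot shape.

The statistical model regresses the factor matrix on principal-component
scores, F = W B + E with E ~ N(0, sigma^2 I): factors are the responses
and PC scores the predictors.  The relevant PCs are chosen by greedy
sequential forward selection under the Bayesian information criterion,
where the multivariate BIC is the sum of the per-factor univariate
Gaussian BICs (independent residuals across factor columns).  Per factor
the fit reports R^2, the overall-regression F-test p-value, and post-hoc
power from the noncentral-F distribution with effect size
f^2 = R^2 / (1 - R^2) and noncentrality lambda = f^2 n.

Bilateral asymmetry and loading response are quantified as per-vertex
Euclidean distances between corresponded, aligned shape pairs; those
distance vectors get their own PCA + forward selection + regression.
Shape predictions for a varied factor invert the fitted linear map by
least squares (pseudo-inverse of B) and synthesize the two extreme shapes
through the PCA model, yielding the per-vertex deviation maps used for
colour-coded rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .shape_model import ShapeModel, fit_pca, synthesize

__all__ = [
    "FactorModel",
    "DeviationField",
    "forward_select_pcs",
    "fit_factor_model",
    "posthoc_power",
    "pc_factor_correlations",
    "deviation_field",
    "deviation_regression",
    "predict_shape",
]


@dataclass
class FactorModel:
    """Fitted factor regression F = W B + E on selected PC scores.

    ``coefficients`` is (k+1, m): intercept row first, then one row per
    selected PC, one column per factor.  ``factor_summary`` keeps the
    training factor distribution (mean, sd, quantiles) used when
    predicting shapes over a factor's observed range.
    """

    selected_pcs: list[int]
    factor_names: list[str]
    coefficients: np.ndarray
    residual_sds: np.ndarray
    r_squared: pd.Series
    p_values: pd.Series
    power: pd.Series
    n_obs: int
    alpha: float = 0.05
    factor_summary: pd.DataFrame | None = None

    @property
    def significant(self) -> pd.Series:
        return self.p_values < self.alpha


@dataclass
class DeviationField:
    """Non-negative per-vertex distances between two corresponded shapes."""

    values: np.ndarray
    kind: str = "asymmetry"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if (self.values < 0).any():
            raise ValueError("deviation values must be non-negative")


def _as_frame(F) -> pd.DataFrame:
    if isinstance(F, pd.DataFrame):
        return F
    return pd.DataFrame(np.asarray(F, dtype=float))


def _column_bic_terms(W_cols: np.ndarray, F: np.ndarray) -> float:
    """Sum over factor columns of n*log(RSS/n) for the design [1, W_cols]."""
    n = len(F)
    X = np.hstack([np.ones((n, 1)), W_cols]) if W_cols.size else np.ones((n, 1))
    coef, _, _, _ = np.linalg.lstsq(X, F, rcond=None)
    resid = F - X @ coef
    rss = np.einsum("ij,ij->j", resid, resid)
    rss = np.maximum(rss, 1e-300)
    return float(np.sum(n * np.log(rss / n)))


def _total_bic(W_cols: np.ndarray, F: np.ndarray) -> float:
    n, m = F.shape
    k = W_cols.shape[1] if W_cols.size else 0
    n_params = m * (k + 1) + m  # coefficients incl. intercepts + variances
    return _column_bic_terms(W_cols, F) + n_params * np.log(n)


def forward_select_pcs(
    W: np.ndarray,
    F,
    criterion: str = "bic",
    candidates: list[int] | None = None,
    return_trace: bool = False,
):
    """Greedy forward selection of PC columns that predict the factors.

    Starting from the empty set, repeatedly add the PC whose inclusion
    most decreases the total BIC of the multivariate regression
    ``F ~ W_selected`` and stop when no addition decreases it.  Ties break
    toward the lower PC index.  Returns the selected column indices of
    ``W`` in selection order; with ``return_trace`` also the BIC values
    (empty model first, then after each accepted addition).
    """
    if criterion != "bic":
        raise ValueError("only the BIC criterion is implemented")
    W = np.asarray(W, dtype=float)
    Fd = _as_frame(F)
    Fm = Fd.to_numpy(dtype=float)
    n = len(Fm)
    if n < 2:
        raise ValueError("need at least two observations")
    if W.shape[0] != n:
        raise ValueError("W and F row counts differ")
    if candidates is None:
        candidates = list(range(W.shape[1]))
    remaining = sorted(candidates)
    selected: list[int] = []
    best = _total_bic(np.empty((n, 0)), Fm)
    trace = [best]
    while remaining and len(selected) + 1 < n - 1:
        trial_bics = [_total_bic(W[:, selected + [j]], Fm) for j in remaining]
        jbest = int(np.argmin(trial_bics))
        if trial_bics[jbest] >= best:
            break
        best = trial_bics[jbest]
        trace.append(best)
        selected.append(remaining.pop(jbest))
    if return_trace:
        return selected, trace
    return selected


def posthoc_power(r2: float, n: int, k: int, alpha: float = 0.05) -> float:
    """Post-hoc power of the overall regression F-test.

    Effect size f^2 = R^2/(1-R^2), noncentrality lambda = f^2 * n, test
    degrees of freedom (k, n-k-1).  R^2 = 0 returns exactly alpha.
    """
    if not 0.0 <= r2 < 1.0:
        raise ValueError("r2 must satisfy 0 <= r2 < 1")
    if n - k - 1 <= 0:
        raise ValueError("need n > k + 1")
    lam = n * r2 / (1.0 - r2)
    crit = stats.f.isf(alpha, k, n - k - 1)
    if lam == 0.0:
        return float(alpha)
    return float(stats.ncf.sf(crit, k, n - k - 1, lam))


def fit_factor_model(
    W_selected: np.ndarray,
    F,
    selected_pcs: list[int] | None = None,
    alpha: float = 0.05,
) -> FactorModel:
    """Least-squares fit of each factor on the selected PC scores.

    Per factor column: OLS with intercept, R^2, overall F-test p-value and
    post-hoc power.  Raises on a rank-deficient design, naming the
    collinear score columns.
    """
    W = np.asarray(W_selected, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    Fd = _as_frame(F)
    n, k = W.shape
    if len(Fd) != n:
        raise ValueError("W and F row counts differ")
    X = sm.add_constant(W, has_constant="add")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [int(i) - 1 for i in np.flatnonzero(np.abs(np.diag(R)) < 1e-10)]
        raise ValueError(f"rank-deficient design; collinear score columns {bad}")
    names = list(Fd.columns)
    B = np.empty((k + 1, len(names)))
    resid_sd = np.empty(len(names))
    r2 = {}
    pvals = {}
    power = {}
    for j, name in enumerate(names):
        fit = sm.OLS(Fd[name].to_numpy(dtype=float), X).fit()
        B[:, j] = fit.params
        resid_sd[j] = np.sqrt(fit.mse_resid)
        r2[name] = float(fit.rsquared)
        pvals[name] = float(fit.f_pvalue) if k > 0 else 1.0
        power[name] = posthoc_power(min(fit.rsquared, 1.0 - 1e-12), n, k, alpha)
    summary = Fd.describe(percentiles=[0.05, 0.95]).T
    return FactorModel(
        selected_pcs=list(selected_pcs) if selected_pcs is not None else list(range(k)),
        factor_names=names,
        coefficients=B,
        residual_sds=resid_sd,
        r_squared=pd.Series(r2),
        p_values=pd.Series(pvals),
        power=pd.Series(power),
        n_obs=n,
        alpha=alpha,
        factor_summary=summary,
    )


def pc_factor_correlations(
    W: np.ndarray, F, method: str = "pearson", alpha: float = 0.05
) -> pd.DataFrame:
    """Correlations (rho, two-sided p) between each PC score and each factor.

    Returns a tidy DataFrame with columns (pc, factor, rho, p,
    significant); ``method`` is "pearson" (default) or "spearman".
    A constant PC or factor column raises ``ValueError``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    W = np.atleast_2d(np.asarray(W, dtype=float))
    Fd = _as_frame(F)
    if W.shape[0] != len(Fd):
        W = W.T
    rows = []
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    for i in range(W.shape[1]):
        w = W[:, i]
        if np.ptp(w) == 0:
            raise ValueError(f"PC column {i} is constant")
        for name in Fd.columns:
            f = Fd[name].to_numpy(dtype=float)
            if np.ptp(f) == 0:
                raise ValueError(f"factor column {name!r} is constant")
            rho, p = corr(w, f)
            rows.append(
                {
                    "pc": i + 1,
                    "factor": name,
                    "rho": float(rho),
                    "p": float(p),
                    "significant": bool(p < alpha),
                }
            )
    return pd.DataFrame(rows)


def deviation_field(
    shape_a: np.ndarray, shape_b: np.ndarray, kind: str = "asymmetry"
) -> DeviationField:
    """Per-vertex Euclidean distance between two corresponded shapes."""
    a = np.asarray(shape_a, dtype=float).reshape(-1, 3)
    b = np.asarray(shape_b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError(f"vertex count mismatch: {a.shape} vs {b.shape}")
    return DeviationField(values=np.linalg.norm(a - b, axis=1), kind=kind)


def deviation_regression(
    fields: np.ndarray,
    F,
    alpha: float = 0.05,
    n_components: int | str = "full",
) -> tuple[FactorModel, ShapeModel]:
    """PCA of per-vertex deviation vectors followed by factor regression.

    ``fields`` is (N, V): one distance vector per subject (or per
    subject-side pair).  The PCA scores go through BIC forward selection
    and the factor regression exactly as the main shape analysis.
    Constant fields (e.g. all zeros) raise ``ValueError``.
    """
    fields = np.asarray(fields, dtype=float)
    if fields.ndim != 2:
        raise ValueError("fields must be (N, V)")
    if np.allclose(fields.var(axis=0), 0.0):
        raise ValueError("deviation fields are constant; nothing to decompose")
    # PCA machinery is shared with the shape model (fields act as 'shapes')
    pca = fit_pca(fields, n_components)
    scores = pca.scores
    selected = forward_select_pcs(scores, F)
    if not selected:
        selected = [0]
    model = fit_factor_model(scores[:, selected], F, selected_pcs=selected, alpha=alpha)
    return model, pca


def _range_limits(model: FactorModel, vary: str, range_rule: str) -> tuple[float, float]:
    if model.factor_summary is None or vary not in model.factor_summary.index:
        raise ValueError(f"no training summary available for factor {vary!r}")
    row = model.factor_summary.loc[vary]
    if range_rule in ("quantile90", "quantile-contour-90"):
        return float(row["5%"]), float(row["95%"])
    if range_rule in ("mean2sd", "mean±2sd"):
        return float(row["mean"] - 2 * row["std"]), float(row["mean"] + 2 * row["std"])
    if range_rule == "minmax":
        return float(row["min"]), float(row["max"])
    raise ValueError(f"unknown range_rule {range_rule!r}")


def predict_shape(
    factor_model: FactorModel,
    shape_model: ShapeModel,
    factor_values: dict | pd.Series | None = None,
    vary: str = "",
    range_rule: str = "quantile90",
) -> tuple[np.ndarray, np.ndarray, DeviationField]:
    """Model-predicted shapes at the low/high settings of one factor.

    All factors are fixed (defaults: training means, overridable through
    ``factor_values``) except ``vary``, which sweeps the limits given by
    ``range_rule``: "quantile90" (5th/95th percentile of the training
    distribution), "mean2sd" (mu ± 2 sigma) or "minmax".  The fitted map
    F = W B is inverted by least squares (minimum-norm pseudo-inverse of
    the coefficient block), the two expected score vectors are passed
    through the PCA model, and the per-vertex distance between the two
    predicted shapes is returned for colour mapping.
    """
    names = factor_model.factor_names
    if vary not in names:
        raise ValueError(f"unknown factor {vary!r}; model factors: {names}")
    if factor_model.factor_summary is None:
        raise ValueError("factor model carries no training factor summary")
    base = factor_model.factor_summary["mean"].reindex(names).to_numpy(dtype=float)
    if factor_values:
        for key, val in dict(factor_values).items():
            if key not in names:
                raise ValueError(f"unknown factor {key!r}")
            base[names.index(key)] = float(val)
    lo, hi = _range_limits(factor_model, vary, range_rule)
    jv = names.index(vary)
    b0 = factor_model.coefficients[0]
    Bk = factor_model.coefficients[1:]  # (k, m)
    shapes = []
    for val in (lo, hi):
        f = base.copy()
        f[jv] = val
        # truncated pseudo-inverse: coefficient directions below 0.1% of
        # the leading singular value are unfittable noise, not signal
        w_sel, *_ = np.linalg.lstsq(Bk.T, f - b0, rcond=1e-3)
        w_full = np.zeros(shape_model.n_components)
        w_full[np.asarray(factor_model.selected_pcs, dtype=int)] = w_sel
        shapes.append(synthesize(shape_model, w_full))
    dev = deviation_field(shapes[0], shapes[1], kind=f"effect:{vary}")
    return shapes[0], shapes[1], dev
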