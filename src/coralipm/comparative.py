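"""Cross-assemblage statistics: two-block PLSR, ranged major axis
regression, and three-way factorial ANOVA with Tukey contrasts.

The partial least squares regression links a block of thermal predictors
(mean SST, SST coefficient of variation, spectral exponent) to a block of
demographic responses (growth rate, damping ratio, transient envelope) via
NIPALS latent components, reporting the X-variance captured per component
and the cumulative Y-variance (ry2). Ranged major axis regression is a
Type 2 (errors-in-both-variables) fit computed on range-standardized
variables and back-transformed. The factorial ANOVA crosses country,
ecoregion and life-history strategy with Type II sums of squares, followed
by Tukey HSD contrasts between ecoregions within each country-strategy cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["PLSRResult", "plsr", "RMAResult", "ranged_major_axis",
           "AnovaResult", "factorial_anova"]


# ---------------------------------------------------------------------------
# PLSR (NIPALS, two-block mode)


@dataclass
class PLSRResult:
    """NIPALS PLS2 decomposition of standardized X and Y blocks."""

    x_variance: np.ndarray        # fraction of ||X||_F^2 per component
    y_variance: np.ndarray        # fraction of ||Y||_F^2 per component
    ry2: float                    # cumulative Y-variance captured
    x_scores: np.ndarray          # T, n x ncomp
    y_scores: np.ndarray          # U, n x ncomp
    x_weights: np.ndarray         # W, p x ncomp
    x_loadings: np.ndarray        # P, p x ncomp
    y_loadings: np.ndarray        # C, q x ncomp
    condition_number: float = float("nan")
    predictor_correlations: pd.DataFrame | None = None


def _standardize(M: np.ndarray, names) -> np.ndarray:
    sd = M.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if s == 0:
            name = names[j] if names is not None else f"column {j}"
            raise ValueError(f"constant column cannot be standardized: {name}")
    return (M - M.mean(axis=0)) / sd


def plsr(X, Y, n_components: int = 2, *, scale: bool = True,
         tol: float = 1e-10, max_iter: int = 500) -> PLSRResult:
    """Two-block PLS regression by NIPALS with deflation of both blocks.

    X (n x p) predictors, Y (n x q) responses. Inputs are standardized to
    mean 0 / sd 1 unless ``scale=False`` (then they must already be
    centered). Per component h: X-variance = ||t_h p_h'||_F^2 / ||X||_F^2,
    Y-variance from the regression of Y on t_h; ry2 is their cumulative sum
    over the fitted components.
    """
    xnames = list(X.columns) if isinstance(X, pd.DataFrame) else None
    ynames = list(Y.columns) if isinstance(Y, pd.DataFrame) else None
    X = np.asarray(X, float).copy()
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Y = Y.copy()
    n, p = X.shape
    if n < n_components + 2:
        raise ValueError("need at least n_components + 2 rows")
    if scale:
        X = _standardize(X, xnames)
        Y = _standardize(Y, ynames)
    corr = pd.DataFrame(np.corrcoef(X, rowvar=False),
                        index=xnames, columns=xnames)
    cond = float(np.linalg.cond(X))

    ssx = float(np.sum(X * X))
    ssy = float(np.sum(Y * Y))
    q = Y.shape[1]
    T = np.zeros((n, n_components))
    U = np.zeros((n, n_components))
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    C = np.zeros((q, n_components))
    xvar = np.zeros(n_components)
    yvar = np.zeros(n_components)
    for h in range(n_components):
        if np.sum(X * X) < 1e-12 * max(ssx, 1.0) or \
                np.sum(Y * Y) < 1e-12 * max(ssy, 1.0):
            break  # blocks exhausted; remaining components stay zero
        u = Y[:, int(np.argmax(Y.var(axis=0)))]
        t_old = None
        for _ in range(max_iter):
            w = X.T @ u
            w = w / np.linalg.norm(w)
            t = X @ w
            c = Y.T @ t / (t @ t)
            cc = c @ c
            if cc == 0:
                break
            u = Y @ c / cc
            if t_old is not None and np.linalg.norm(t - t_old) \
                    <= tol * np.linalg.norm(t):
                break
            t_old = t
        tt = float(t @ t)
        pvec = X.T @ t / tt
        X -= np.outer(t, pvec)
        Y -= np.outer(t, c)
        T[:, h], U[:, h], W[:, h], P[:, h], C[:, h] = t, u, w, pvec, c
        xvar[h] = tt * float(pvec @ pvec) / ssx
        yvar[h] = tt * float(c @ c) / ssy
    return PLSRResult(
        x_variance=xvar, y_variance=yvar, ry2=float(yvar.sum()),
        x_scores=T, y_scores=U, x_weights=W, x_loadings=P, y_loadings=C,
        condition_number=cond, predictor_correlations=corr,
    )


# ---------------------------------------------------------------------------
# Ranged major axis (Type 2) regression


@dataclass
class RMAResult:
    slope: float
    intercept: float
    r_squared: float
    flagged: bool = False


def ranged_major_axis(x, y) -> RMAResult:
    """Type 2 regression on range-standardized variables.

    Both variables are scaled to [0, 1] by their ranges; the major-axis
    slope is computed on that scale and back-transformed by
    range(y)/range(x). The line passes through (mean x, mean y);
    r-squared is the squared Pearson correlation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    rx = float(np.ptp(x))
    ry = float(np.ptp(y))
    if rx == 0 or ry == 0:
        raise ValueError("zero range in x or y")
    xs = (x - x.min()) / rx
    ys = (y - y.min()) / ry
    s2x = float(np.var(xs, ddof=1))
    s2y = float(np.var(ys, ddof=1))
    sxy = float(np.cov(xs, ys, ddof=1)[0, 1])
    if sxy == 0:
        warnings.warn("zero covariance on ranged variables; major-axis slope "
                      "undefined", stacklevel=2)
        return RMAResult(float("nan"), float("nan"), 0.0, flagged=True)
    d = s2y - s2x
    b_scaled = (d + np.sqrt(d * d + 4 * sxy * sxy)) / (2 * sxy)
    slope = b_scaled * ry / rx
    intercept = float(y.mean() - slope * x.mean())
    r = float(np.corrcoef(x, y)[0, 1])
    return RMAResult(float(slope), intercept, r * r)


# ---------------------------------------------------------------------------
# Three-way factorial ANOVA with Tukey contrasts


@dataclass
class AnovaResult:
    table: pd.DataFrame              # term, sum_sq, df, F, PR(>F)
    tukey: pd.DataFrame              # all pairwise interaction-cell contrasts
    ecoregion_contrasts: pd.DataFrame = field(default_factory=pd.DataFrame)


def factorial_anova(data: pd.DataFrame, value: str = "value",
                    factors=("country", "ecoregion", "strategy"),
                    alpha: float = 0.05) -> AnovaResult:
    """Full-factorial linear model, Type II sums of squares, Tukey HSD.

    Requires >= 2 observations per factor-combination cell. The Tukey table
    covers all pairwise interaction-cell comparisons; the
    ``ecoregion_contrasts`` view keeps only comparisons between ecoregions
    within the same country and strategy.
    """
    f1, f2, f3 = factors
    counts = data.groupby([f1, f2, f3], observed=True)[value].count()
    levels = [data[f].unique() for f in factors]
    missing = []
    for a in levels[0]:
        for b in levels[1]:
            for c in levels[2]:
                if counts.get((a, b, c), 0) < 2:
                    missing.append((a, b, c))
    if missing:
        raise ValueError(f"cells with fewer than 2 observations: {missing}")
    formula = f"{value} ~ C({f1}) * C({f2}) * C({f3})"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.ols(formula, data=data).fit()
        table = anova_lm(fit, typ=2)
    # degenerate (essentially constant) response: flag F as undefined rather
    # than reporting ratios of rounding noise
    vals = data[value].to_numpy(float)
    total_ss = float(np.sum((vals - vals.mean()) ** 2))
    if total_ss <= 1e-12 * len(vals) * max(1.0, vals.mean() ** 2):
        warnings.warn("response is constant; F statistics undefined",
                      stacklevel=2)
        table["F"] = 0.0
        table["PR(>F)"] = np.nan

    cell = (data[f1].astype(str) + "|" + data[f2].astype(str) + "|"
            + data[f3].astype(str))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tk = pairwise_tukeyhsd(data[value].to_numpy(float), cell.to_numpy(),
                               alpha=alpha)
    tukey = pd.DataFrame(tk.summary().data[1:],
                         columns=tk.summary().data[0])
    g1 = tukey["group1"].str.split("|", expand=True)
    g2 = tukey["group2"].str.split("|", expand=True)
    within = (g1[0] == g2[0]) & (g1[2] == g2[2]) & (g1[1] != g2[1])
    return AnovaResult(table=table, tukey=tukey,
                       ecoregion_contrasts=tukey[within].reset_index(drop=True))
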