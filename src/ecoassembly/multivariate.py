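"""Constrained ordination and environmental-factor statistics.

Covers the standard vegan-style toolbox around a dissimilarity matrix:

* ``vif_screen`` — iterative variance-inflation-factor filtering of the
  environmental table (default cutoff 10) before regression modelling.
* ``dbrda`` — distance-based redundancy analysis: principal-coordinate
  embedding of the dissimilarity matrix followed by redundancy analysis on
  the constraining variables, with permutation tests.  Constraining on a
  grouping factor alone gives constrained PCoA (CPCoA).
* ``correlation_table`` — tidy Spearman/Pearson factor-response tables with
  Benjamini-Hochberg adjustment and significance stars.
* ``lmg_importance`` — LMG decomposition of a multiple regression R^2 into
  non-negative per-predictor shares (average R^2 gain over all predictor
  orderings), as in relaimpo's calc.relimp.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import PairwiseMatrix

logger = logging.getLogger("ecoassembly")

__all__ = [
    "OrdinationResult",
    "ImportanceDecomposition",
    "vif_screen",
    "dbrda",
    "correlation_table",
    "lmg_importance",
    "significance_stars",
    "bh_adjust",
]


# ---------------------------------------------------------------------------
# VIF screening

def vif_screen(env: pd.DataFrame, threshold: float = 10.0
               ) -> tuple[list[str], dict[str, float]]:
    """Iteratively drop collinear variables until all VIFs are below threshold.

    VIF_k = 1 / (1 - R^2_k) from regressing variable k on the remaining
    variables (with intercept).  The largest VIF is removed first; perfectly
    collinear variables (infinite VIF) are removed with a warning.
    Returns the retained variable list and the final VIF of each retained
    variable (a single remaining variable has VIF 1 by convention).
    """
    if env.shape[1] < 2:
        raise ValueError("VIF screening needs at least 2 variables")
    if env.shape[0] <= env.shape[1]:
        raise ValueError("need more samples than variables")
    cols = list(env.columns)

    def vifs(cs: list[str]) -> dict[str, float]:
        if len(cs) == 1:
            return {cs[0]: 1.0}
        out = {}
        x = env[cs].to_numpy(dtype=float)
        for i, c in enumerate(cs):
            y = x[:, i]
            X = np.column_stack([np.ones(len(y)), np.delete(x, i, axis=1)])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            sst = ((y - y.mean()) ** 2).sum()
            r2 = 1.0 - resid @ resid / sst if sst > 0 else 1.0
            out[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        return out

    while True:
        v = vifs(cols)
        worst = max(cols, key=lambda c: v[c])
        if v[worst] >= threshold or not np.isfinite(v[worst]):
            if not np.isfinite(v[worst]):
                logger.warning("vif_screen: %r is perfectly collinear; removed", worst)
            else:
                logger.info("vif_screen: removing %r (VIF %.3g)", worst, v[worst])
            cols.remove(worst)
            if len(cols) == 1:
                break
        else:
            break
    return cols, vifs(cols)


# ---------------------------------------------------------------------------
# db-RDA / CPCoA

@dataclass
class OrdinationResult:
    site_scores: pd.DataFrame
    constrained_proportion: float
    axis_eigenvalues: np.ndarray
    term_significance: dict[str, float] = field(default_factory=dict)
    factor_fit_r2: dict[str, tuple[float, float]] = field(default_factory=dict)
    model_p: float | None = None
    negative_eigenvalue_fraction: float = 0.0


def _pcoa_coords(dist: PairwiseMatrix) -> tuple[np.ndarray, np.ndarray, float]:
    """Principal coordinates: keep positive eigenvalues only."""
    d = dist.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    tol = 1e-8 * max(abs(w[0]), 1.0)
    neg_frac = float(np.abs(w[w < -tol]).sum() / max(np.abs(w).sum(), 1e-300))
    keep = w > tol
    coords = v[:, keep] * np.sqrt(w[keep])
    return coords, w[keep], neg_frac


def _design(df: pd.DataFrame) -> np.ndarray:
    """Centered numeric design matrix; categoricals one-hot encoded."""
    parts = []
    for c in df.columns:
        col = df[c]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
            parts.append(dummies)
        else:
            parts.append(col.to_numpy(dtype=float)[:, None])
    x = np.hstack(parts) if parts else np.empty((len(df), 0))
    return x - x.mean(axis=0, keepdims=True)


def _fitted_inertia(y: np.ndarray, x: np.ndarray) -> float:
    if x.shape[1] == 0:
        return 0.0
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    yhat = x @ beta
    return float((yhat ** 2).sum())


def dbrda(community_dist: PairwiseMatrix, env: pd.DataFrame,
          condition: pd.Series | None = None, n_perm: int = 999,
          seed: int = 0) -> OrdinationResult:
    """Distance-based redundancy analysis (capscale-style).

    The dissimilarity matrix is embedded by principal coordinates (negative
    eigenvalues are discarded and their magnitude logged), the coordinates
    are regressed on the centered constraint matrix, and the constrained
    proportion is the fitted inertia over total inertia.  Term p-values are
    marginal permutation tests (residuals permuted under the reduced model,
    (b+1)/(m+1) estimator).  ``factor_fit_r2`` carries an envfit-style
    squared correlation of each constraint with the first two constrained
    axes, with its own permutation p-value.
    """
    env = env.loc[community_dist.labels]
    n = len(community_dist.labels)
    y, eigvals, neg_frac = _pcoa_coords(community_dist)
    if neg_frac > 0:
        logger.info("dbrda: discarded negative eigenvalues (%.2f%% of total "
                    "absolute inertia)", 100 * neg_frac)
    total_inertia = float((y ** 2).sum())

    if condition is not None:
        z = _design(pd.DataFrame({"condition": condition.loc[community_dist.labels]}))
        if z.shape[1] > 0:
            bz, *_ = np.linalg.lstsq(z, y, rcond=None)
            y = y - z @ bz
            x_raw = _design(env)
            bx, *_ = np.linalg.lstsq(z, x_raw, rcond=None)
            x = x_raw - z @ bx
        else:  # one-level factor conditions out nothing
            x = _design(env)
    else:
        x = _design(env)

    if x.shape[1] >= n:
        raise ValueError("more constraints than samples - 1")

    rng = np.random.default_rng(seed)
    fitted = _fitted_inertia(y, x)
    constrained_proportion = fitted / total_inertia if total_inertia > 0 else 0.0

    # constrained axes via SVD of fitted values
    if x.shape[1] > 0:
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        yhat = x @ beta
        u, s, _vt = np.linalg.svd(yhat, full_matrices=False)
        keep = s ** 2 > 1e-10 * max(s[0] ** 2 if s.size else 1.0, 1.0)
        axes = (u[:, keep] * s[keep])
        axis_eigs = s[keep] ** 2
    else:
        axes = np.empty((n, 0))
        axis_eigs = np.array([])
    site_scores = pd.DataFrame(
        axes, index=community_dist.labels,
        columns=[f"CAP{i + 1}" for i in range(axes.shape[1])])

    # overall model test: permute rows of Y
    model_p = None
    if x.shape[1] > 0 and n_perm > 0:
        resid_df = max(n - 1 - x.shape[1], 1)
        f_obs = (fitted / x.shape[1]) / ((total_inertia - fitted) / resid_df)
        count = 0
        for _ in range(n_perm):
            yp = y[rng.permutation(n)]
            fp = _fitted_inertia(yp, x)
            f_p = (fp / x.shape[1]) / (((yp ** 2).sum() - fp) / resid_df)
            if f_p >= f_obs - 1e-12:
                count += 1
        model_p = (count + 1) / (n_perm + 1)

    # marginal term tests: residual permutation under the reduced model
    term_p: dict[str, float] = {}
    numeric_cols = list(env.columns)
    if n_perm > 0 and x.shape[1] > 0:
        for term in numeric_cols:
            reduced = _design(env.drop(columns=[term]))
            add = _design(env[[term]])
            df_term = add.shape[1]
            b_red, *_ = np.linalg.lstsq(reduced, y, rcond=None) if reduced.shape[1] \
                else (np.zeros((0, y.shape[1])),)
            y_fit_red = reduced @ b_red if reduced.shape[1] else np.zeros_like(y)
            y_res = y - y_fit_red
            full_x = np.hstack([reduced, add])
            resid_df = max(n - 1 - full_x.shape[1], 1)
            gain_obs = _fitted_inertia(y_res, full_x)
            denom_obs = (y_res ** 2).sum() - gain_obs
            f_obs = (gain_obs / df_term) / (denom_obs / resid_df)
            count = 0
            for _ in range(n_perm):
                yp = y_fit_red + y_res[rng.permutation(n)]
                yp_res = yp - (reduced @ np.linalg.lstsq(reduced, yp, rcond=None)[0]
                               if reduced.shape[1] else 0.0)
                gain = _fitted_inertia(yp_res, full_x)
                denom = (yp_res ** 2).sum() - gain
                f_p = (gain / df_term) / (denom / resid_df) if denom > 0 else np.inf
                if f_p >= f_obs - 1e-12:
                    count += 1
            term_p[term] = (count + 1) / (n_perm + 1)

    # envfit-style vector fitting on the first two constrained axes
    factor_fit: dict[str, tuple[float, float]] = {}
    if axes.shape[1] >= 1:
        ax = axes[:, :2]
        axc = ax - ax.mean(axis=0)
        for term in numeric_cols:
            col = env[term]
            if col.dtype.kind in "OUSb":
                continue
            vv = col.to_numpy(dtype=float)
            vv = vv - vv.mean()
            sst = vv @ vv
            if sst <= 0:
                continue
            bb, *_ = np.linalg.lstsq(axc, vv, rcond=None)
            r2 = float((axc @ bb) @ (axc @ bb) / sst)
            count = 0
            for _ in range(n_perm):
                vp = vv[rng.permutation(n)]
                bp, *_ = np.linalg.lstsq(axc, vp, rcond=None)
                if (axc @ bp) @ (axc @ bp) / sst >= r2 - 1e-12:
                    count += 1
            factor_fit[term] = (r2, (count + 1) / (n_perm + 1))

    return OrdinationResult(
        site_scores=site_scores,
        constrained_proportion=float(constrained_proportion),
        axis_eigenvalues=np.asarray(axis_eigs),
        term_significance=term_p,
        factor_fit_r2=factor_fit,
        model_p=model_p,
        negative_eigenvalue_fraction=neg_frac,
    )


# ---------------------------------------------------------------------------
# correlation tables

def significance_stars(p: float) -> str:
    """Star convention: * 0.01<=p<0.05, ** 0.005<=p<0.01, *** 0.001<=p<0.005,
    **** p<0.001."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "****"
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    mask = ~np.isnan(p)
    out = np.full_like(p, np.nan)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def correlation_table(x: pd.DataFrame, y: pd.DataFrame,
                      method: str = "spearman", fdr: str = "bh") -> pd.DataFrame:
    """All-pairs correlation between the columns of two tables.

    Returns tidy records (x, y, coefficient, p, p_adjusted, stars); constant
    variables yield a null record with a warning.  Stars are applied to the
    adjusted p-value when BH correction is requested.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    if fdr not in ("bh", "none"):
        raise ValueError(f"unknown fdr option {fdr!r}")
    recs = []
    for cx in x.columns:
        for cy in y.columns:
            pair = pd.concat([x[cx], y[cy]], axis=1, join="inner").dropna()
            if len(pair) < 4:
                raise ValueError(
                    f"pair ({cx!r}, {cy!r}) has fewer than 4 paired observations")
            a, b = pair.iloc[:, 0].to_numpy(float), pair.iloc[:, 1].to_numpy(float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                logger.warning("correlation_table: constant variable in pair "
                               "(%r, %r); coefficient undefined", cx, cy)
                recs.append({"x": cx, "y": cy, "coefficient": np.nan,
                             "p": np.nan, "n": len(pair)})
                continue
            if method == "spearman":
                r, p = stats.spearmanr(a, b)
            else:
                r, p = stats.pearsonr(a, b)
            recs.append({"x": cx, "y": cy, "coefficient": float(r),
                         "p": float(p), "n": len(pair)})
    df = pd.DataFrame(recs)
    df["p_adjusted"] = bh_adjust(df["p"].to_numpy()) if fdr == "bh" else df["p"]
    ref = "p_adjusted" if fdr == "bh" else "p"
    df["stars"] = [significance_stars(v) for v in df[ref]]
    return df


# ---------------------------------------------------------------------------
# LMG relative importance

@dataclass
class ImportanceDecomposition:
    response: str
    shares: dict[str, float]
    full_model_r2: float


def _subset_r2(y: np.ndarray, x: np.ndarray, cols: tuple[int, ...]) -> float:
    X = np.column_stack([np.ones(len(y))] + [x[:, c] for c in cols])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = ((y - y.mean()) ** 2).sum()
    return 1.0 - float(resid @ resid) / float(sst)


def lmg_importance(response: pd.Series, predictors: pd.DataFrame
                   ) -> ImportanceDecomposition:
    """LMG decomposition of R^2 by exact enumeration over subsets.

    The share of predictor k is the average, over all orderings of the
    predictors, of the R^2 increase when k enters the model; equivalently a
    Shapley value over subset R^2s.  Shares sum to the full-model R^2
    exactly.  Limited to 12 predictors (exact enumeration).
    """
    names = list(predictors.columns)
    p = len(names)
    if p > 12:
        raise ValueError("exact LMG enumeration limited to 12 predictors")
    y = response.to_numpy(dtype=float)
    x = predictors.to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), x])) < p + 1:
        raise ValueError("singular design matrix")
    cache: dict[tuple[int, ...], float] = {(): 0.0}
    for r in range(1, p + 1):
        for cols in itertools.combinations(range(p), r):
            cache[cols] = _subset_r2(y, x, cols)
    shares = {}
    for k in range(p):
        others = [i for i in range(p) if i != k]
        total = 0.0
        for r in range(p):
            w = math.factorial(r) * math.factorial(p - r - 1) / math.factorial(p)
            for sub in itertools.combinations(others, r):
                with_k = tuple(sorted(sub + (k,)))
                total += w * (cache[with_k] - cache[sub])
        shares[names[k]] = total
    return ImportanceDecomposition(
        response=str(response.name) if response.name is not None else "response",
        shares=shares,
        full_model_r2=cache[tuple(range(p))],
    )
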