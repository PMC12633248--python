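"""Group-level inference for band-wise EEG metrics.

Per metric x band cell: Welch's unequal-variance t-test with Satterthwaite
degrees of freedom and a 95% CI on the mean difference; Cohen's d with a
Hedges-Olkin-variance CI; Benjamini-Hochberg FDR across the 13 bands within
each metric; a covariate-adjusted robust (bisquare IRLS) regression of the
metric on group, z-scored age and sex; and a Freedman-Lane permutation
p-value for the group coefficient.  Broadband complexity additionally gets
Mann-Whitney and label-swap permutation tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.random import Generator, default_rng
from scipy import stats as sps

from .banding import BandSpec, make_bands
from .metrics import METRICS

__all__ = [
    "WelchResult",
    "RobustFitResult",
    "welch",
    "cohens_d",
    "bh_fdr",
    "robust_fit",
    "freedman_lane",
    "lzc_tests",
    "band_contrasts",
]


# --------------------------------------------------------------------------
# two-sample building blocks
# --------------------------------------------------------------------------

@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    mean_diff: float
    ci: tuple[float, float]


def welch(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> WelchResult:
    """Welch's unequal-variance t-test with a Satterthwaite-df CI on the
    mean difference (x minus y)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 observations per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both samples have zero variance")
    se2 = vx / nx + vy / ny
    se = np.sqrt(se2)
    diff = x.mean() - y.mean()
    t = diff / se
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return WelchResult(float(t), float(df), float(p), float(diff),
                       (float(diff - tcrit * se), float(diff + tcrit * se)))


def cohens_d(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Cohen's d (pooled-SD, (n-1) weights) with the Hedges-Olkin-variance
    normal-quantile CI."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 observations per sample")
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        raise ValueError("pooled SD is zero")
    d = (x.mean() - y.mean()) / np.sqrt(sp2)
    var_d = (nx + ny) / (nx * ny) + d * d / (2.0 * (nx + ny))
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(var_d)
    return float(d), (float(d - half), float(d + half))


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (textbook form).

    Missing entries (NaN) are passed through and excluded from the family.
    """
    p = np.asarray(p, float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    q[ok] = out
    return q


# --------------------------------------------------------------------------
# robust regression (bisquare IRLS)
# --------------------------------------------------------------------------

@dataclass
class RobustFitResult:
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    weights: np.ndarray
    scale: float
    fitted: np.ndarray
    resid: np.ndarray
    df_resid: int
    n_iter: int


_BISQUARE_C = 4.685


def robust_fit(
    y: np.ndarray,
    X: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> RobustFitResult:
    """Iteratively reweighted least squares with Tukey's bisquare weights.

    Scale is the MAD of residuals divided by 0.6745, re-estimated each
    iteration; iteration stops when the relative coefficient change drops
    below ``tol``.  Standard errors use the classical weighted covariance
    ``sigma^2 (X'WX)^-1`` with ``sigma^2 = sum(w r^2) / (n - p)``; t-tests
    use n - p degrees of freedom.
    """
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than design columns")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify an offending column for the message
        bad = []
        for j in range(p):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(j)
        raise ValueError(f"design is rank deficient; collinear column(s) {bad}")

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    w = np.ones(n)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        r = y - X @ beta
        scale = np.median(np.abs(r - np.median(r))) / 0.6745
        if scale <= 0:
            scale = np.mean(np.abs(r)) / 0.6745 + 1e-300
        u = r / (_BISQUARE_C * scale)
        w = np.where(np.abs(u) < 1.0, (1.0 - u * u) ** 2, 0.0)
        if w.sum() < p:  # pathological: nearly all points rejected
            w = np.ones(n)
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ Xw + 1e-12 * np.eye(p), Xw.T @ y)
        change = np.max(np.abs(beta_new - beta)) / max(np.max(np.abs(beta)), 1e-12)
        beta = beta_new
        if change < tol:
            break
    r = y - X @ beta
    scale = np.median(np.abs(r - np.median(r))) / 0.6745
    sigma2 = float(np.sum(w * r * r) / (n - p))
    cov = sigma2 * np.linalg.inv(X.T @ (X * w[:, None]) + 1e-12 * np.eye(p))
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(tvals), n - p)
    return RobustFitResult(beta, se, tvals, pvals, w, float(scale),
                           X @ beta, r, n - p, n_iter)


def design_matrix(group: np.ndarray, age: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """Intercept + group (second level = 1) + z-scored age + sex (male=1)."""
    age = np.asarray(age, float)
    sd = age.std(ddof=0)
    z_age = (age - age.mean()) / sd if sd > 0 else np.zeros_like(age)
    return np.column_stack([
        np.ones(age.size),
        np.asarray(group, float),
        z_age,
        np.asarray(sex, float),
    ])


def freedman_lane(
    y: np.ndarray,
    X_full: np.ndarray,
    X_reduced: np.ndarray,
    coef: int,
    n_perm: int = 10_000,
    rng: Generator | int = 0,
    fit=robust_fit,
) -> tuple[float, float]:
    """Permutation p-value for one coefficient with nuisance covariates.

    Residuals of the reduced (nuisance-only) model are permuted and added
    back to its fitted values; the full model is refit on each surrogate and
    the coefficient's |t| compared with the observed one.  Returns
    ``(t_obs, p_perm)`` with the add-one estimator
    ``(1 + #{|t*| >= |t|}) / (1 + B)``.
    """
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is very small for a permutation test")
    rng = default_rng(rng) if not isinstance(rng, Generator) else rng
    y = np.asarray(y, float).ravel()
    t_obs = float(fit(y, X_full).t[coef])
    red = fit(y, X_reduced)
    fitted, resid = red.fitted, red.resid
    count = 0
    for _ in range(n_perm):
        y_star = fitted + rng.permutation(resid)
        t_star = fit(y_star, X_full).t[coef]
        if abs(t_star) >= abs(t_obs):
            count += 1
    return t_obs, (1.0 + count) / (1.0 + n_perm)


# --------------------------------------------------------------------------
# LZC-specific unadjusted comparisons
# --------------------------------------------------------------------------

def lzc_tests(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10_000,
    rng: Generator | int = 0,
) -> dict[str, float]:
    """Welch, Mann-Whitney and label-swap permutation tests plus Cohen's d
    for a broadband complexity contrast (x = first group, y = second)."""
    rng = default_rng(rng) if not isinstance(rng, Generator) else rng
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = welch(x, y)
    mw = sps.mannwhitneyu(x, y, alternative="two-sided")
    d, _ = cohens_d(x, y)
    pooled = np.concatenate([x, y])
    obs = abs(x.mean() - y.mean())
    nx = x.size
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:nx].mean() - perm[nx:].mean()) >= obs:
            count += 1
    return {
        "welch_t": w.t,
        "welch_p": w.p,
        "mannwhitney_u": float(mw.statistic),
        "mannwhitney_p": float(mw.pvalue),
        "perm_p": (1.0 + count) / (1.0 + n_perm),
        "cohens_d": d,
    }


# --------------------------------------------------------------------------
# the full band-wise inferential table
# --------------------------------------------------------------------------

def band_contrasts(
    table: pd.DataFrame,
    bands: BandSpec | None = None,
    group_order: tuple[str, str] = ("HC", "MDD"),
    n_perm: int = 1000,
    rng: Generator | int = 0,
    metrics: tuple[str, ...] = METRICS,
) -> pd.DataFrame:
    """Per metric x band group comparison of a subject-level metric table.

    ``table`` needs columns ``metric@band`` plus ``group``, ``age``, ``sex``
    (as produced by :func:`eegcrit.metrics.metric_table`).  Contrasts are
    second group minus first (patients minus controls by default).  FDR is
    applied across bands within each metric.  Cells with missing values
    (gated fE/I) drop those subjects cell-wise; a cell with fewer than two
    subjects per group is flagged and skipped.
    """
    bands = bands or make_bands()
    rng = default_rng(rng) if not isinstance(rng, Generator) else rng
    g0, g1 = group_order
    is_g1 = (table["group"] == g1).to_numpy()
    sex_male = (table["sex"] == "male").to_numpy().astype(float)
    age = table["age"].to_numpy(float)

    rows = []
    for metric in metrics:
        for b_idx, label in enumerate(bands.labels()):
            col = f"{metric}@{label}"
            if col not in table.columns:
                continue
            vals = table[col].to_numpy(float)
            ok = ~np.isnan(vals)
            x = vals[ok & is_g1]  # patients
            y = vals[ok & ~is_g1]  # controls
            row: dict[str, object] = {
                "metric": metric, "band": label, "band_index": b_idx,
                "n_hc": int(y.size), "n_mdd": int(x.size),
            }
            if x.size < 2 or y.size < 2:
                row["flag"] = "insufficient data"
                rows.append(row)
                continue
            w = welch(x, y)
            d, d_ci = cohens_d(x, y)
            try:
                Xf = design_matrix(is_g1[ok], age[ok], sex_male[ok])
                rob = robust_fit(vals[ok], Xf)
                t_obs, p_perm = freedman_lane(
                    vals[ok], Xf, Xf[:, [0, 2, 3]], coef=1, n_perm=n_perm, rng=rng
                )
                beta_g, t_rob, p_rob = rob.beta[1], rob.t[1], rob.p[1]
                flag = ""
            except ValueError as exc:  # degenerate cell (tiny n, collinearity)
                beta_g = t_rob = p_rob = p_perm = np.nan
                flag = f"covariate model skipped: {exc}"
            row.update({
                "mean_hc": y.mean(), "se_hc": y.std(ddof=1) / np.sqrt(y.size),
                "mean_mdd": x.mean(), "se_mdd": x.std(ddof=1) / np.sqrt(x.size),
                "t": w.t, "df": w.df, "p": w.p,
                "mean_diff": w.mean_diff, "ci_lo": w.ci[0], "ci_hi": w.ci[1],
                "d": d, "d_ci_lo": d_ci[0], "d_ci_hi": d_ci[1],
                "beta_group": beta_g, "t_robust": t_rob,
                "p_robust": p_rob, "p_perm": p_perm, "flag": flag,
            })
            rows.append(row)
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for metric in metrics:
        sel = out["metric"] == metric
        out.loc[sel, "q"] = bh_fdr(out.loc[sel, "p"].to_numpy(float))
    return out
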