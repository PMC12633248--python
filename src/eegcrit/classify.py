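"""Sparse logistic classification of group from the band-wise metric set.

The feature pool is {BiS, E/I_HLP, fE/I, E+I_HLS} x the bands whose upper
edge stays at or below ~35 Hz (gamma above that is excluded as
muscle-artifact-prone), plus broadband LZC, age and sex -- 43 columns by
default.  DFA features are excluded by default (short-segment reliability)
and can be switched back in.  The model is an L1-penalized logistic
regression fit on a stratified 70/30 split, features z-scored by training
statistics, the penalty chosen by 10-fold cross-validated deviance with the
one-standard-error rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import Generator, default_rng
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold

from .banding import BandSpec, make_bands

__all__ = [
    "FeatureMatrix",
    "LassoLogisticModel",
    "EvalReport",
    "assemble_features",
    "split_stratified",
    "lasso_path",
    "cv_select",
    "fit_lasso_classifier",
    "evaluate",
]

GAMMA_CUTOFF_HZ = 35.2
# a band whose upper edge exceeds the cutoff by no more than the display
# rounding of the geometric edges still counts as retained
_EDGE_TOL_HZ = 0.3
CLASSIFIER_METRICS = ("bis", "ei_hlp", "fei", "ei_hls")


@dataclass
class FeatureMatrix:
    X: np.ndarray  # subjects x features, unstandardized
    y: np.ndarray  # 1 = second group (patients)
    columns: list[str]
    subject_ids: list[str]
    impute_mask: np.ndarray  # True where a value was missing pre-imputation


def assemble_features(
    table: pd.DataFrame,
    bands: BandSpec | None = None,
    include_dfa: bool = False,
    max_band_hz: float = GAMMA_CUTOFF_HZ,
    group_order: tuple[str, str] = ("HC", "MDD"),
) -> FeatureMatrix:
    """Build the classifier design from a subject-level metric table.

    Missing values (gated fE/I) are left as NaN here; imputation with
    training-column means happens inside the fitting routine so no test-set
    information leaks.  All-missing columns are dropped with a warning.
    """
    bands = bands or make_bands()
    metrics = list(CLASSIFIER_METRICS) + (["dfa"] if include_dfa else [])
    cols: list[str] = []
    for m in metrics:
        for (lo, hi), label in zip(bands, bands.labels()):
            if hi <= max_band_hz + _EDGE_TOL_HZ:
                cols.append(f"{m}@{label}")
    cols.append("lzc")
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"metric table lacks columns {missing[:3]}...")
    X_metric = table[cols].to_numpy(float)
    all_nan = np.isnan(X_metric).all(axis=0)
    if all_nan.any():
        import warnings

        dropped = [c for c, bad in zip(cols, all_nan) if bad]
        warnings.warn(f"dropping all-missing feature column(s): {dropped}")
        cols = [c for c, bad in zip(cols, all_nan) if not bad]
        X_metric = X_metric[:, ~all_nan]
    age = table["age"].to_numpy(float)[:, None]
    sex = (table["sex"] == "male").to_numpy(float)[:, None]
    X = np.hstack([X_metric, age, sex])
    columns = cols + ["age", "sex"]
    y = (table["group"] == group_order[1]).to_numpy(int)
    return FeatureMatrix(
        X=X, y=y, columns=columns,
        subject_ids=list(table.get("subject_id", pd.RangeIndex(len(table)).astype(str))),
        impute_mask=np.isnan(X),
    )


def split_stratified(
    y: np.ndarray, train_frac: float = 0.7, rng: Generator | int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test indices preserving group proportions
    to within one subject."""
    rng = default_rng(rng) if not isinstance(rng, Generator) else rng
    y = np.asarray(y)
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < 2:
            raise ValueError(f"group {cls} has fewer than 2 subjects")
        idx = rng.permutation(idx)
        k = int(round(train_frac * idx.size))
        k = min(max(k, 1), idx.size - 1)
        train.extend(idx[:k])
        test.extend(idx[k:])
    return np.sort(np.array(train)), np.sort(np.array(test))


def _lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty that zeroes every coefficient: max |X'(y - ybar)|/n."""
    r = y - y.mean()
    return float(np.max(np.abs(X.T @ r)) / y.size)


def lambda_grid(X: np.ndarray, y: np.ndarray, n: int = 100, decades: float = 4.0) -> np.ndarray:
    lam_max = _lambda_max(X, y)
    return np.geomspace(lam_max, lam_max * 10.0**-decades, n)


def lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Coefficient path of L1-penalized logistic regression.

    ``X`` must already be standardized.  Returns an array of shape
    ``(len(lambdas), n_features + 1)``: intercept (unpenalized) first.  The
    objective per sample is mean log-loss + lambda * ||w||_1, matching the
    ``C = 1 / (n * lambda)`` parameterization of scikit-learn.
    """
    n = y.size
    path = np.empty((lambdas.size, X.shape[1] + 1))
    clf = LogisticRegression(
        l1_ratio=1.0, solver="saga", warm_start=True, fit_intercept=True,
        tol=tol, max_iter=max_iter, C=1.0, random_state=0,
    )
    for i, lam in enumerate(lambdas):
        clf.C = 1.0 / (n * lam)
        clf.fit(X, y)
        if clf.n_iter_[0] >= max_iter:
            raise RuntimeError(f"lasso solver did not converge at lambda={lam:.3g}")
        path[i, 0] = clf.intercept_[0]
        path[i, 1:] = clf.coef_[0]
    return path


def _cv_deviance(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-2.0 * np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


def cv_select(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    folds: int = 10,
    rule: str = "1se",
    rng: Generator | int = 0,
    tol: float = 1e-5,
    max_iter: int = 5_000,
) -> tuple[float, pd.DataFrame]:
    """Choose the penalty by stratified K-fold cross-validated deviance.

    ``rule='min'`` takes the deviance-minimizing lambda; ``rule='1se'`` the
    largest lambda whose mean deviance is within one standard error of that
    minimum.  Returns ``(lambda_star, cv_table)``.

    CV fits use a looser tolerance and a hard epoch cap than the final
    path: held-out deviance is insensitive to the last digits of the
    coefficients, and near-separable folds at the small-lambda end of the
    grid would otherwise dominate the runtime.
    """
    rng = default_rng(rng) if not isinstance(rng, Generator) else rng
    seed = int(rng.integers(2**31 - 1))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.empty((folds, lambdas.size))
    for k, (tr, va) in enumerate(skf.split(X, y)):
        mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr, Xva = (X[tr] - mu) / sd, (X[va] - mu) / sd
        if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
            raise ValueError("a CV fold contains a single class; too few subjects")
        clf = LogisticRegression(
            l1_ratio=1.0, solver="saga", warm_start=True, fit_intercept=True,
            tol=tol, max_iter=max_iter, C=1.0, random_state=0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for i, lam in enumerate(lambdas):
                clf.C = 1.0 / (y[tr].size * lam)
                clf.fit(Xtr, y[tr])
                p = clf.predict_proba(Xva)[:, 1]
                dev[k, i] = _cv_deviance(p, y[va])
    mean = dev.mean(axis=0)
    se = dev.std(axis=0, ddof=1) / np.sqrt(folds)
    i_min = int(np.argmin(mean))
    if rule == "min":
        lam_star = float(lambdas[i_min])
    elif rule == "1se":
        thresh = mean[i_min] + se[i_min]
        ok = np.flatnonzero(mean <= thresh)
        lam_star = float(lambdas[ok.min()])  # grid is descending: first = largest
    else:
        raise ValueError("rule must be 'min' or '1se'")
    cv_table = pd.DataFrame({"lambda": lambdas, "mean_deviance": mean, "se": se})
    return lam_star, cv_table


@dataclass
class LassoLogisticModel:
    intercept: float
    coef: np.ndarray
    columns: list[str]
    lam: float
    train_mean: np.ndarray
    train_sd: np.ndarray
    impute_values: np.ndarray
    cv_table: pd.DataFrame = field(repr=False, default=None)
    path: np.ndarray = field(repr=False, default=None)
    lambdas: np.ndarray = field(repr=False, default=None)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.array(X, float, copy=True)
        nan = np.isnan(X)
        if nan.any():
            X[nan] = np.broadcast_to(self.impute_values, X.shape)[nan]
        return (X - self.train_mean) / self.train_sd

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.intercept + self.transform(X) @ self.coef
        return 1.0 / (1.0 + np.exp(-z))

    @property
    def nonzero(self) -> list[tuple[str, float]]:
        return [(c, float(b)) for c, b in zip(self.columns, self.coef) if b != 0.0]


def fit_lasso_classifier(
    fm: FeatureMatrix,
    train_idx: np.ndarray,
    folds: int = 10,
    rule: str = "1se",
    rng: Generator | int = 0,
    n_lambda: int = 100,
) -> LassoLogisticModel:
    """Impute, standardize, select the penalty by CV and refit -- all on the
    training rows only."""
    rng = default_rng(rng) if not isinstance(rng, Generator) else rng
    Xtr = np.array(fm.X[train_idx], float, copy=True)
    ytr = fm.y[train_idx]
    impute = np.nanmean(Xtr, axis=0)
    nan = np.isnan(Xtr)
    Xtr[nan] = np.broadcast_to(impute, Xtr.shape)[nan]
    mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (Xtr - mu) / sd
    lambdas = lambda_grid(Xz, ytr, n=n_lambda)
    lam_star, cv_table = cv_select(Xtr, ytr, lambdas, folds=folds, rule=rule, rng=rng)
    path = lasso_path(Xz, ytr, lambdas)
    i_star = int(np.argmin(np.abs(np.log(lambdas) - np.log(lam_star))))
    return LassoLogisticModel(
        intercept=float(path[i_star, 0]),
        coef=path[i_star, 1:].copy(),
        columns=list(fm.columns),
        lam=lam_star,
        train_mean=mu,
        train_sd=sd,
        impute_values=impute,
        cv_table=cv_table,
        path=path,
        lambdas=lambdas,
    )


@dataclass
class EvalReport:
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    roc: pd.DataFrame
    pr: pd.DataFrame


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the tie-corrected rank statistic (probability a positive
    outranks a negative, ties counting one half)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC undefined: test set contains a single class")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))


def evaluate(
    model: LassoLogisticModel,
    X: np.ndarray,
    y: np.ndarray,
    threshold: float = 0.5,
) -> EvalReport:
    """Held-out performance: rank-statistic AUC, threshold accuracy /
    sensitivity / specificity, and ROC / precision-recall point lists."""
    p = model.predict_proba(X)
    auc = auc_rank(p, y)
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    fpr, tpr, roc_thr = roc_curve(y, p)
    prec, rec, _ = precision_recall_curve(y, p)
    return EvalReport(
        auc=auc,
        accuracy=(tp + tn) / y.size,
        sensitivity=tp / (tp + fn) if tp + fn else np.nan,
        specificity=tn / (tn + fp) if tn + fp else np.nan,
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        pr=pd.DataFrame({"recall": rec, "precision": prec}),
    )
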