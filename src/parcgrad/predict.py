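"""Behavioral prediction from connectivity features.

Kernel ridge regression with a Pearson-similarity kernel (the predictor
is a similarity-weighted average of training subjects' scores, shrunk by
an L2 penalty) and linear ridge regression, wrapped in nested
cross-validation that treats both the representation resolution and the
ridge penalty as inner-loop hyperparameters.  Two outer schemes are
supported: family-preserving repeated k-fold and
leave-p-of-n-site-clusters-out.  Confound regression (age, sex, FD,
DVARS) is fit on training subjects only and applied, never refit, to
the corresponding test subjects.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

__all__ = [
    "RidgeSpec",
    "CVScheme",
    "Fold",
    "ConfoundModel",
    "default_krr_lambda_grid",
    "default_lrr_lambda_grid",
    "DEFAULT_RESOLUTION_GRIDS",
    "similarity_kernel",
    "similarity_weighted_prediction",
    "krr_fit_predict",
    "lrr_fit_predict",
    "fit_confounds",
    "apply_confounds",
    "make_folds",
    "nested_cv",
    "aggregate_accuracy",
    "category_fold_series",
    "pearson_accuracy",
]


def default_krr_lambda_grid() -> np.ndarray:
    """KRR ridge-penalty search grid: {0, 1e-5, 1e-4}, 0.001 to 1 in
    steps of 0.003, 1.5 to 4 in steps of 0.5, then {5, 10, 15, 20}."""
    return np.concatenate(
        [
            [0.0, 1e-5, 1e-4],
            np.round(np.arange(0.001, 1.0 + 1e-9, 0.003), 10),
            np.arange(1.5, 4.0 + 1e-9, 0.5),
            [5.0, 10.0, 15.0, 20.0],
        ]
    )


def default_lrr_lambda_grid() -> np.ndarray:
    """LRR ridge-penalty search grid: 0.05 to 1 in steps of 0.05."""
    return np.round(np.arange(0.05, 1.0 + 1e-9, 0.05), 10)


#: Resolution search grids per feature-construction approach.
DEFAULT_RESOLUTION_GRIDS = {
    "group-hard": list(range(100, 1001, 100)),
    "individual-hard": list(range(100, 1001, 100)),
    "soft": [50, 100, 200, 300],
    "principal-gradient": [1, 5, 10, 20, 40, 60, 80, 100],
    "local-gradient": [1],  # single fixed map: one-point grid
}


@dataclass
class RidgeSpec:
    """Predictive model plus its hyperparameter search grids."""

    model: str = "krr"
    lambda_grid: np.ndarray = None
    resolution_grid: list = None

    def __post_init__(self) -> None:
        if self.model not in ("krr", "lrr"):
            raise ValueError("model must be 'krr' or 'lrr'")
        if self.lambda_grid is None:
            self.lambda_grid = (
                default_krr_lambda_grid()
                if self.model == "krr"
                else default_lrr_lambda_grid()
            )
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        if self.lambda_grid.size == 0 or np.any(self.lambda_grid < 0):
            raise ValueError("lambda grid must be non-empty and nonnegative")


@dataclass
class CVScheme:
    """Outer cross-validation scheme.

    ``repeated_kfold`` packs families into k folds, ``replications``
    times (HCP-style); ``leave_p_siteclusters`` enumerates every
    combination of ``p_out`` held-out site clusters (ABCD-style).
    ``k_inner`` controls the grouped inner loop of the k-fold scheme;
    the site scheme always uses leave-one-training-cluster-out inside.
    """

    kind: str = "repeated_kfold"
    k: int = 20
    replications: int = 100
    p_out: int = 3
    k_inner: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("repeated_kfold", "leave_p_siteclusters"):
            raise ValueError("unknown CV scheme kind")


@dataclass
class Fold:
    replication: int
    fold: int
    train: np.ndarray
    test: np.ndarray


# --------------------------------------------------------------------------
# kernels and ridge solvers
# --------------------------------------------------------------------------


def similarity_kernel(features: np.ndarray) -> np.ndarray:
    """Subject-by-subject Pearson correlations of feature vectors."""
    x = np.asarray(features, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 features per subject")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        raise ValueError(
            f"zero-variance feature vector(s): {np.flatnonzero(sd == 0).tolist()}"
        )
    k = np.corrcoef(x)
    np.fill_diagonal(k, 1.0)
    return (k + k.T) / 2.0


def similarity_weighted_prediction(
    similarities: np.ndarray, y_train: np.ndarray
) -> float:
    """Unnormalized similarity-weighted average of training scores:
    ``sum_i Similarity(FC_i, FC) * y_i``."""
    similarities = np.asarray(similarities, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if similarities.shape != y_train.shape:
        raise ValueError("similarities and y_train must have equal length")
    return float(similarities @ y_train)


def krr_fit_predict(
    K_train: np.ndarray,
    y_train: np.ndarray,
    K_test_train: np.ndarray,
    lam: float,
) -> np.ndarray:
    """Kernel ridge in dual form: ``alpha = (K + lam*I)^-1 (y - ybar)``,
    prediction ``K_test_train @ alpha + ybar``."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    n = K_train.shape[0]
    ybar = float(np.mean(y_train))
    a = K_train + lam * np.eye(n)
    try:
        alpha = np.linalg.solve(a, y_train - ybar)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "singular kernel system at lam=0; use lam > 0"
        ) from err
    return np.atleast_2d(K_test_train) @ alpha + ybar


def _krr_sweep(
    K_train: np.ndarray,
    y_train: np.ndarray,
    K_test_train: np.ndarray,
    lams: np.ndarray,
) -> np.ndarray:
    """Predictions for every lambda from one eigendecomposition of
    K_train; returns (n_lams, n_test).  lam=0 uses a pseudo-inverse
    (eigenvalues below 1e-10 of the largest are dropped)."""
    w, u = np.linalg.eigh((K_train + K_train.T) / 2.0)
    ybar = float(np.mean(y_train))
    uy = u.T @ (y_train - ybar)
    ku = np.atleast_2d(K_test_train) @ u
    tol = 1e-10 * max(np.abs(w).max(), 1.0)
    out = np.empty((len(lams), ku.shape[0]))
    for i, lam in enumerate(lams):
        denom = w + lam
        if lam == 0:
            inv = np.where(np.abs(denom) > tol, 1.0 / np.where(denom == 0, 1.0, denom), 0.0)
        else:
            inv = 1.0 / denom
        out[i] = ku @ (inv * uy) + ybar
    return out


def lrr_fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    lam: float,
) -> np.ndarray:
    """Linear ridge regression on train-standardized features with the
    training mean as intercept."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    xtr = (X_train - mu) / sd
    xte = (np.atleast_2d(X_test) - mu) / sd
    model = Ridge(alpha=lam, fit_intercept=True, solver="cholesky")
    model.fit(xtr, y_train)
    return model.predict(xte)


def _lrr_sweep(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    lams: np.ndarray,
) -> np.ndarray:
    """Ridge predictions for every lambda via one SVD of the centered,
    train-standardized design; returns (n_lams, n_test)."""
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    xtr = (X_train - mu) / sd
    xte = (np.atleast_2d(X_test) - mu) / sd
    ybar = float(np.mean(y_train))
    u, s, vt = np.linalg.svd(xtr, full_matrices=False)
    uy = u.T @ (y_train - ybar)
    xv = xte @ vt.T
    out = np.empty((len(lams), xte.shape[0]))
    for i, lam in enumerate(lams):
        d = s / (s**2 + lam)
        if lam == 0:
            d = np.where(s > 1e-10 * max(s.max(), 1.0), d, 0.0)
        out[i] = xv @ (d * uy) + ybar
    return out


# --------------------------------------------------------------------------
# confound regression
# --------------------------------------------------------------------------


@dataclass
class ConfoundModel:
    """Linear nuisance model fit on training subjects only."""

    columns: list
    coef: np.ndarray
    intercept: float
    kept: np.ndarray  # boolean mask of retained (non-collinear) covariates

    def apply(self, y: np.ndarray, confounds: pd.DataFrame) -> np.ndarray:
        c = confounds[self.columns].to_numpy(float)[:, self.kept]
        return np.asarray(y, float) - (c @ self.coef + self.intercept)


def fit_confounds(y_train: np.ndarray, confounds_train: pd.DataFrame) -> ConfoundModel:
    """Ordinary least squares of y on the covariates plus an intercept.

    Collinear covariates are dropped with a warning (left-to-right
    greedy rank check), so training residuals are exactly orthogonal to
    the retained covariates.
    """
    cols = list(confounds_train.columns)
    c = confounds_train.to_numpy(float)
    n = c.shape[0]
    kept = np.ones(c.shape[1], dtype=bool)
    design = np.ones((n, 1))
    # rank check on scale-free columns so unit choices cannot mask rank
    sd = c.std(axis=0)
    cz = (c - c.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    probe = np.ones((n, 1))
    for j in range(c.shape[1]):
        cand = np.column_stack([probe, cz[:, j]])
        if sd[j] > 0 and np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(probe):
            probe = cand
            design = np.column_stack([design, c[:, j]])
        else:
            kept[j] = False
            warnings.warn(
                f"dropping collinear confound {cols[j]!r}", stacklevel=2
            )
    coef, *_ = np.linalg.lstsq(design, np.asarray(y_train, float), rcond=None)
    return ConfoundModel(
        columns=cols, coef=coef[1:], intercept=float(coef[0]), kept=kept
    )


def apply_confounds(
    y: np.ndarray, confounds: pd.DataFrame, model: ConfoundModel
) -> np.ndarray:
    """Residualize y with *training* coefficients (no refit on test)."""
    return model.apply(y, confounds)


# --------------------------------------------------------------------------
# fold construction
# --------------------------------------------------------------------------


def _pack_groups(
    groups: np.ndarray, k: int, rng: np.random.Generator
) -> list:
    """Randomly pack whole groups into k folds, balancing fold sizes:
    shuffle groups, then repeatedly assign to the currently smallest fold."""
    uniq = np.unique(groups)
    order = rng.permutation(len(uniq))
    folds = [[] for _ in range(k)]
    sizes = np.zeros(k, dtype=int)
    n = len(groups)
    for gi in order:
        members = np.flatnonzero(groups == uniq[gi])
        if members.size > n / k:
            warnings.warn(
                f"group {uniq[gi]!r} is larger than n/k; assigned whole to one fold",
                stacklevel=3,
            )
        j = int(np.argmin(sizes))
        folds[j].extend(members.tolist())
        sizes[j] += members.size
    return [np.sort(np.array(f, dtype=np.int64)) for f in folds]


def make_folds(
    structure: pd.DataFrame | np.ndarray, scheme: CVScheme
) -> list:
    """Outer train/test splits honoring the grouping structure.

    For ``repeated_kfold``, ``structure`` must contain (or be) family
    labels: families are never split across folds.  For
    ``leave_p_siteclusters``, site-cluster labels are used and every
    ``C(n_clusters, p_out)`` split is enumerated as one replication.
    """
    if isinstance(structure, pd.DataFrame):
        col = "family_id" if scheme.kind == "repeated_kfold" else "site_id"
        groups = structure[col].to_numpy()
    else:
        groups = np.asarray(structure)
    n = len(groups)
    all_idx = np.arange(n)
    out: list[Fold] = []
    if scheme.kind == "repeated_kfold":
        rng = np.random.default_rng(scheme.seed)
        for rep in range(scheme.replications):
            folds = _pack_groups(groups, scheme.k, rng)
            for j, test in enumerate(folds):
                train = np.setdiff1d(all_idx, test)
                out.append(Fold(replication=rep, fold=j, train=train, test=test))
    else:
        clusters = np.unique(groups)
        if scheme.p_out >= len(clusters):
            raise ValueError("p_out must be smaller than the number of clusters")
        for rep, held in enumerate(
            itertools.combinations(sorted(clusters.tolist()), scheme.p_out)
        ):
            test = np.flatnonzero(np.isin(groups, held))
            train = np.setdiff1d(all_idx, test)
            out.append(Fold(replication=rep, fold=0, train=train, test=test))
    return out


def _inner_folds(
    train_idx: np.ndarray,
    groups: np.ndarray,
    scheme: CVScheme,
    rng: np.random.Generator,
) -> list:
    """Grouped inner splits over the outer-training subjects."""
    sub_groups = groups[train_idx]
    if scheme.kind == "repeated_kfold":
        k = min(scheme.k_inner, len(np.unique(sub_groups)))
        folds = _pack_groups(sub_groups, k, rng)
        return [
            (np.setdiff1d(train_idx, train_idx[f]), train_idx[f]) for f in folds
        ]
    held_out = []
    for cl in sorted(np.unique(sub_groups).tolist()):
        val = train_idx[sub_groups == cl]
        held_out.append((np.setdiff1d(train_idx, val), val))
    return held_out


# --------------------------------------------------------------------------
# accuracy and nested CV
# --------------------------------------------------------------------------


def _rowwise_pearson(preds: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``preds`` with ``actual``; degenerate
    rows (or a degenerate actual) score 0."""
    actual = np.asarray(actual, float)
    ac = actual - actual.mean()
    an = np.linalg.norm(ac)
    pc = preds - preds.mean(axis=1, keepdims=True)
    pn = np.linalg.norm(pc, axis=1)
    if an == 0:
        return np.zeros(preds.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (pc @ ac) / (pn * an)
    return np.where(pn == 0, 0.0, r)


def pearson_accuracy(pred: np.ndarray, actual: np.ndarray) -> tuple[float, bool]:
    """Pearson r between predictions and observations; a degenerate
    (constant) series yields accuracy 0 with a raised flag."""
    pred = np.asarray(pred, float)
    actual = np.asarray(actual, float)
    if pred.std() == 0 or actual.std() == 0:
        return 0.0, True
    return float(np.corrcoef(pred, actual)[0, 1]), False


def _select_best(
    scores: np.ndarray, resolutions: list, lams: np.ndarray
) -> tuple[int, int]:
    """Argmax over the (resolution, lambda) grid; ties broken toward the
    smaller lambda, then the smaller resolution (parsimony)."""
    best = np.nanmax(scores)
    cand = np.argwhere(scores >= best - 1e-12)
    lam_vals = lams[cand[:, 1]]
    cand = cand[lam_vals == lam_vals.min()]
    res_vals = np.array([resolutions[i] for i in cand[:, 0]])
    ri, li = cand[int(np.argmin(res_vals))]
    return int(ri), int(li)


def nested_cv(
    features_by_resolution: dict,
    y: np.ndarray,
    confounds: pd.DataFrame,
    structure: pd.DataFrame,
    scheme: CVScheme,
    ridge_spec: RidgeSpec,
    approach: str = "",
    behavior: str = "",
) -> pd.DataFrame:
    """Nested cross-validation with resolution and lambda as inner-loop
    hyperparameters.

    ``features_by_resolution`` maps each resolution in the grid to a
    subject-by-feature matrix.  Per outer fold, every (resolution,
    lambda) pair is scored by the mean inner-fold Pearson r of
    predictions against confound-residualized scores; the winning pair
    is refit on the full outer-training set and evaluated on the test
    fold.  Confound regression and the behavior z-normalization are fit
    inside every training split, never on test subjects.

    Returns a long-format DataFrame with one row per outer fold.
    """
    resolutions = sorted(features_by_resolution)
    if ridge_spec.resolution_grid is not None:
        missing = set(ridge_spec.resolution_grid) - set(resolutions)
        if missing:
            raise ValueError(f"features missing for resolutions {sorted(missing)}")
        resolutions = sorted(ridge_spec.resolution_grid)
    lams = ridge_spec.lambda_grid
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    kernels = None
    if ridge_spec.model == "krr":
        kernels = {
            r: similarity_kernel(features_by_resolution[r]) for r in resolutions
        }
    folds = make_folds(structure, scheme)
    groups = (
        structure["family_id"]
        if scheme.kind == "repeated_kfold"
        else structure["site_id"]
    ).to_numpy()
    rng = np.random.default_rng(scheme.seed + 1)
    rows = []
    for fold in folds:
        tr, te = fold.train, fold.test
        inner = _inner_folds(tr, groups, scheme, rng)
        scores = np.zeros((len(resolutions), len(lams)))
        for itr, ival in inner:
            cm = fit_confounds(y[itr], confounds.iloc[itr])
            y_itr = cm.apply(y[itr], confounds.iloc[itr])
            y_ival = cm.apply(y[ival], confounds.iloc[ival])
            mu, sd = y_itr.mean(), y_itr.std()
            y_itr_z = (y_itr - mu) / (sd if sd > 0 else 1.0)
            for ri, res in enumerate(resolutions):
                if ridge_spec.model == "krr":
                    k = kernels[res]
                    preds = _krr_sweep(
                        k[np.ix_(itr, itr)], y_itr_z, k[np.ix_(ival, itr)], lams
                    )
                else:
                    x = features_by_resolution[res]
                    preds = _lrr_sweep(x[itr], y_itr_z, x[ival], lams)
                scores[ri] += _rowwise_pearson(preds, y_ival)
        scores /= max(len(inner), 1)
        ri, li = _select_best(scores, resolutions, lams)
        res, lam = resolutions[ri], float(lams[li])

        cm = fit_confounds(y[tr], confounds.iloc[tr])
        y_tr = cm.apply(y[tr], confounds.iloc[tr])
        y_te = cm.apply(y[te], confounds.iloc[te])
        mu, sd = y_tr.mean(), y_tr.std()
        sd = sd if sd > 0 else 1.0
        y_tr_z = (y_tr - mu) / sd
        if ridge_spec.model == "krr":
            k = kernels[res]
            pred = _krr_sweep(
                k[np.ix_(tr, tr)], y_tr_z, k[np.ix_(te, tr)], np.array([lam])
            )[0]
        else:
            x = features_by_resolution[res]
            pred = _lrr_sweep(x[tr], y_tr_z, x[te], np.array([lam]))[0]
        pred = pred * sd + mu  # back to the behavior's scale
        acc, degenerate = pearson_accuracy(pred, y_te)
        rows.append(
            {
                "behavior": behavior,
                "approach": approach,
                "replication": fold.replication,
                "fold": fold.fold,
                "resolution": res,
                "lambda": lam,
                "accuracy": acc,
                "n_train": len(tr),
                "n_test": len(te),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# aggregation
# --------------------------------------------------------------------------


def aggregate_accuracy(
    results: pd.DataFrame,
    grouping: str = "behavior",
    categories: dict | None = None,
) -> pd.DataFrame:
    """Mean accuracy over folds and replications.

    ``behavior`` gives one row per (approach, behavior).  ``category``
    first averages each behavior over folds, then averages the
    fold-mean accuracies over the behaviors of each category
    (``categories`` maps behavior name to category).
    """
    _check_complete(results)
    per_beh = (
        results.groupby(["approach", "behavior"], sort=True)["accuracy"]
        .mean()
        .reset_index()
    )
    if grouping == "behavior":
        return per_beh
    if grouping in ("category", "component"):
        if categories is None:
            raise ValueError("categories mapping required for category grouping")
        per_beh["category"] = per_beh["behavior"].map(categories)
        return (
            per_beh.dropna(subset=["category"])
            .groupby(["approach", "category"], sort=True)["accuracy"]
            .mean()
            .reset_index()
        )
    raise ValueError("grouping must be 'behavior', 'category', or 'component'")


def _check_complete(results: pd.DataFrame) -> None:
    counts = results.groupby(["approach", "behavior"])[["accuracy"]].count()
    if counts["accuracy"].nunique() > 1:
        gaps = counts[counts["accuracy"] != counts["accuracy"].max()]
        raise ValueError(f"missing folds for: {gaps.index.tolist()}")


def category_fold_series(
    results: pd.DataFrame, categories: dict
) -> pd.DataFrame:
    """Per-(approach, replication, fold) mean accuracy over the member
    behaviors of each category — the paired series the statistical
    comparisons consume."""
    df = results.copy()
    df["category"] = df["behavior"].map(categories)
    df = df.dropna(subset=["category"])
    return (
        df.groupby(["approach", "category", "replication", "fold"], sort=True)
        .agg(accuracy=("accuracy", "mean"), n_train=("n_train", "first"),
             n_test=("n_test", "first"))
        .reset_index()
    )
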