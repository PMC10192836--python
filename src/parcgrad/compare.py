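"""Statistical comparison of prediction approaches.

Fold-wise accuracies from repeated cross-validation are not independent
— training sets overlap heavily — so a plain paired t-test on per-fold
accuracy differences is anti-conservative.  The corrected resampled
t-test inflates the variance term from ``1/(k*r)`` to
``1/(k*r) + n2/n1`` (test/train size ratio), which restores approximate
type-I control.  Pairwise tests between approaches are collected into a
signed -log10(p) comparison matrix with Benjamini-Hochberg FDR across
all cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .predict import category_fold_series

__all__ = [
    "PairedAccuracySeries",
    "ComparisonMatrix",
    "corrected_resampled_ttest",
    "uncorrected_resampled_ttest",
    "fdr_bh",
    "paired_series",
    "build_comparison_matrix",
    "compare_categories",
    "plot_comparison_matrix",
]


@dataclass
class PairedAccuracySeries:
    """Per-(fold, replication) accuracy differences between two
    approaches evaluated on identical folds.

    ``k`` folds per replication, ``r`` replications, ``n1`` training and
    ``n2`` test subjects in a typical fold.
    """

    d: np.ndarray
    k: int
    r: int
    n1: int
    n2: int

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape[0] != self.k * self.r:
            raise ValueError("length of d must equal k * r")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("fold sizes must be positive")


@dataclass
class ComparisonMatrix:
    approaches: list
    p: np.ndarray
    t: np.ndarray
    signed_neglog10p: np.ndarray
    significant: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.signed_neglog10p, index=self.approaches, columns=self.approaches
        )


def corrected_resampled_ttest(
    series: PairedAccuracySeries,
) -> tuple[float, float, int]:
    """Corrected resampled t-test for repeated k-fold cross-validation.

    With ``m = mean(d)`` and sample variance ``s2`` (denominator
    ``k*r - 1``), the statistic is
    ``t = m / sqrt((1/(k*r) + n2/n1) * s2)`` with ``k*r - 1`` degrees of
    freedom; the p-value is two-sided.
    """
    d = series.d
    kr = series.k * series.r
    m = float(d.mean())
    s2 = float(d.var(ddof=1))
    if s2 == 0:
        raise ValueError("degenerate series: zero variance of differences")
    t = m / np.sqrt((1.0 / kr + series.n2 / series.n1) * s2)
    df = kr - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p), df


def uncorrected_resampled_ttest(
    series: PairedAccuracySeries,
) -> tuple[float, float, int]:
    """Naive paired t-test on the same series (variance term 1/(k*r)
    only) — anti-conservative under fold overlap; kept for the type-I
    contrast."""
    d = series.d
    kr = series.k * series.r
    s2 = float(d.var(ddof=1))
    if s2 == 0:
        raise ValueError("degenerate series: zero variance of differences")
    t = float(d.mean()) / np.sqrt(s2 / kr)
    df = kr - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p), df


def fdr_bh(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level q."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


# --------------------------------------------------------------------------
# building paired series from fold results
# --------------------------------------------------------------------------


def _fold_series(df: pd.DataFrame, approach: str) -> pd.DataFrame:
    sub = df[df["approach"] == approach]
    return sub.set_index(["replication", "fold"]).sort_index()


def paired_series(
    fold_df: pd.DataFrame, approach_a: str, approach_b: str
) -> PairedAccuracySeries:
    """Difference series (a minus b) on matched (replication, fold)
    cells, with k, r, and the modal train/test sizes filled in."""
    a = _fold_series(fold_df, approach_a)
    b = _fold_series(fold_df, approach_b)
    if not a.index.equals(b.index):
        raise ValueError(
            f"approaches {approach_a!r} and {approach_b!r} were evaluated "
            "on different folds"
        )
    d = a["accuracy"].to_numpy() - b["accuracy"].to_numpy()
    reps = a.index.get_level_values("replication").nunique()
    k = len(a) // reps
    n1 = int(a["n_train"].mode().iloc[0])
    n2 = int(a["n_test"].mode().iloc[0])
    return PairedAccuracySeries(d=d, k=k, r=reps, n1=n1, n2=n2)


def build_comparison_matrix(
    fold_results: pd.DataFrame,
    approaches: list | None = None,
    categories: dict | None = None,
    category: str | None = None,
    q: float = 0.05,
) -> ComparisonMatrix:
    """Pairwise corrected resampled t-tests between approaches.

    Per approach and (replication, fold), the accuracy entering the test
    is the mean over the behaviors of ``category`` (or over all
    behaviors when no category is given).  FDR is applied across all
    unique off-diagonal cells; the signed matrix carries
    ``sign(mean d) * -log10(p)`` with positive values meaning the row
    approach outperformed the column approach.
    """
    if categories is None:
        categories = {b: "all" for b in fold_results["behavior"].unique()}
        category = "all"
    series_df = category_fold_series(fold_results, categories)
    if category is not None:
        series_df = series_df[series_df["category"] == category]
    if approaches is None:
        approaches = sorted(series_df["approach"].unique())
    n = len(approaches)
    p = np.full((n, n), np.nan)
    t = np.full((n, n), np.nan)
    pair_idx, pair_p = [], []
    for i in range(n):
        for j in range(i + 1, n):
            s = paired_series(series_df, approaches[i], approaches[j])
            t_ij, p_ij, _ = corrected_resampled_ttest(s)
            t[i, j], t[j, i] = t_ij, -t_ij
            p[i, j] = p[j, i] = p_ij
            pair_idx.append((i, j))
            pair_p.append(p_ij)
    significant = np.zeros((n, n), dtype=bool)
    if pair_p:
        mask = fdr_bh(np.array(pair_p), q=q)
        for (i, j), rej in zip(pair_idx, mask):
            significant[i, j] = significant[j, i] = bool(rej)
    with np.errstate(divide="ignore"):
        signed = np.sign(t) * -np.log10(p)
    signed[~significant] = 0.0
    np.fill_diagonal(signed, 0.0)
    return ComparisonMatrix(
        approaches=list(approaches),
        p=p,
        t=t,
        signed_neglog10p=signed,
        significant=significant,
    )


def compare_categories(
    fold_results: pd.DataFrame,
    categories: dict,
    category_a: str,
    category_b: str,
    approach: str | None = None,
) -> tuple[float, float]:
    """Corrected resampled t-test on the per-fold difference of two
    behavior categories' mean accuracies (a minus b)."""
    df = fold_results
    if approach is not None:
        df = df[df["approach"] == approach]
    series_df = category_fold_series(df, categories)
    a = series_df[series_df["category"] == category_a]
    b = series_df[series_df["category"] == category_b]
    a = a.set_index(["approach", "replication", "fold"]).sort_index()
    b = b.set_index(["approach", "replication", "fold"]).sort_index()
    if not a.index.equals(b.index):
        raise ValueError("categories were not evaluated on identical folds")
    d = a["accuracy"].to_numpy() - b["accuracy"].to_numpy()
    if np.allclose(d, 0.0):  # e.g. a category compared with itself
        return 0.0, 1.0
    reps = a.index.get_level_values("replication").nunique()
    napp = a.index.get_level_values("approach").nunique()
    k = len(a) // (reps * napp)
    series = PairedAccuracySeries(
        d=d,
        k=k,
        r=reps * napp,
        n1=int(a["n_train"].mode().iloc[0]),
        n2=int(a["n_test"].mode().iloc[0]),
    )
    t, p, _ = corrected_resampled_ttest(series)
    return t, p


def plot_comparison_matrix(cm: ComparisonMatrix, path) -> None:
    """Signed -log10(p) heatmap; non-significant cells drawn black."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = np.ma.masked_where(~cm.significant, cm.signed_neglog10p)
    vmax = max(float(np.abs(cm.signed_neglog10p).max()), 1.0)
    fig, ax = plt.subplots(figsize=(4 + 0.3 * len(cm.approaches),) * 2)
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("black")
    im = ax.imshow(vals, cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(cm.approaches)), cm.approaches, rotation=45, ha="right")
    ax.set_yticks(range(len(cm.approaches)), cm.approaches)
    fig.colorbar(im, ax=ax, label="signed -log10(p)")
    ax.set_title("pairwise accuracy comparison (row vs column)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
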