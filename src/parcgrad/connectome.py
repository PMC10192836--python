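"""Parcellation-based connectivity features.

Routes runs plus a hard or soft parcellation to node time series,
connectivity matrices (full Pearson or ridge-regularized partial
correlation in the FSLNets ``ridgep`` dialect), and the vectorized
lower-triangle feature vectors used for prediction.  Also provides a
lightweight boundary-refinement individualization of a group hard
parcellation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthgen import Mesh, Run, _parcel_connected_without

__all__ = [
    "HardParcellation",
    "SoftParcellation",
    "NodeTimeseries",
    "FCMatrix",
    "FeatureVector",
    "extract_hard_timeseries",
    "individualize_parcellation",
    "dual_regression_stage1",
    "full_correlation",
    "partial_correlation_tikhonov",
    "vectorize_lower",
    "unvectorize_lower",
    "n_lower_features",
]


@dataclass(frozen=True)
class HardParcellation:
    """Per-vertex integer labels in ``1..K``; every label must occur."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        k = int(labels.max(initial=0))
        if labels.min(initial=1) < 1:
            raise ValueError("labels must start at 1")
        present = np.unique(labels)
        if present.size != k:
            missing = sorted(set(range(1, k + 1)) - set(present.tolist()))
            raise ValueError(f"empty parcel(s): labels {missing} unused")

    @property
    def K(self) -> int:
        return int(self.labels.max())

    @property
    def n_vertices(self) -> int:
        return self.labels.shape[0]


@dataclass(frozen=True)
class SoftParcellation:
    """Vertex-by-K spatial weight matrix with linearly independent,
    non-degenerate columns (overlapping components)."""

    maps: np.ndarray

    def __post_init__(self) -> None:
        maps = np.asarray(self.maps, dtype=float)
        object.__setattr__(self, "maps", maps)
        if maps.ndim != 2:
            raise ValueError("maps must be a 2-D vertex-by-component matrix")
        norms = np.linalg.norm(maps, axis=0)
        if np.any(norms == 0):
            raise ValueError("soft parcellation has an all-zero component column")
        if np.linalg.matrix_rank(maps) < maps.shape[1]:
            raise ValueError("soft parcellation columns are linearly dependent")

    @property
    def K(self) -> int:
        return self.maps.shape[1]

    @property
    def n_vertices(self) -> int:
        return self.maps.shape[0]


@dataclass(frozen=True)
class NodeTimeseries:
    """K-by-T node series over retained frames only."""

    values: np.ndarray

    @property
    def K(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FCMatrix:
    values: np.ndarray
    kind: str = "full"  # "full" | "partial"
    rho: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        object.__setattr__(self, "values", v)

    @property
    def K(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray

    def __len__(self) -> int:
        return self.values.shape[0]


# --------------------------------------------------------------------------
# node time series
# --------------------------------------------------------------------------


def _znorm_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def concat_vertex_timeseries(runs: list) -> np.ndarray:
    """Retained frames of all runs, each run z-normalized per vertex,
    concatenated in time."""
    return np.concatenate([_znorm_rows(r.retained) for r in runs], axis=1)


def extract_hard_timeseries(runs: list, parc: HardParcellation) -> NodeTimeseries:
    """Mean series over each parcel's vertices, censored frames dropped,
    per-run z-normalization of each node series before concatenation."""
    if runs[0].data.shape[0] != parc.n_vertices:
        raise ValueError("parcellation vertex count does not match runs")
    pieces = []
    for run in runs:
        x = run.retained
        node = np.stack(
            [x[parc.labels == k].mean(axis=0) for k in range(1, parc.K + 1)]
        )
        pieces.append(_znorm_rows(node))
    return NodeTimeseries(np.concatenate(pieces, axis=1))


def dual_regression_stage1(runs: list, soft: SoftParcellation) -> NodeTimeseries:
    """Stage-1 dual regression: per retained frame, least-squares
    regression of the vertex pattern onto the K spatial maps; per-run
    z-normalization of each component series before concatenation."""
    if runs[0].data.shape[0] != soft.n_vertices:
        raise ValueError("soft maps vertex count does not match runs")
    # pinv exists because the SoftParcellation invariant guarantees full rank
    pinv = np.linalg.pinv(soft.maps)
    pieces = [_znorm_rows(pinv @ run.retained) for run in runs]
    return NodeTimeseries(np.concatenate(pieces, axis=1))


# --------------------------------------------------------------------------
# individualization
# --------------------------------------------------------------------------


def _parcel_means(x: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    return np.stack([x[labels == lab].mean(axis=0) for lab in range(1, k + 1)])


def _corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    az = _znorm_rows(a)
    bz = _znorm_rows(b)
    return (az * bz).mean(axis=1)


def _mean_assignment_correlation(
    x: np.ndarray, labels: np.ndarray, k: int
) -> float:
    means = _parcel_means(x, labels, k)
    return float(_corr_rows(x, means[labels - 1]).mean())


def individualize_parcellation(
    group: HardParcellation,
    runs: list,
    mesh: Mesh,
    n_iter: int = 3,
) -> HardParcellation:
    """Boundary refinement of a group atlas against a subject's data.

    Each iteration recomputes parcel mean time courses, then reassigns
    every boundary vertex to the spatially adjacent parcel whose mean
    course correlates best with the vertex's course — provided the move
    keeps the donor parcel nonempty and contiguous.  Iterations that
    would lower the mean vertex-to-assigned-parcel correlation are
    rolled back and refinement stops, so the returned labeling never
    scores worse than the group atlas.  Returns early at a fixed point.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    x = concat_vertex_timeseries(runs)
    labels = np.array(group.labels, copy=True)
    k = group.K
    best_score = _mean_assignment_correlation(x, labels, k)
    for _ in range(n_iter):
        means = _znorm_rows(_parcel_means(x, labels, k))
        xz = _znorm_rows(x)
        proposal = labels.copy()
        changed = False
        for v in range(mesh.n_vertices):
            nbr_labs = sorted(
                {int(proposal[u]) for u in mesh.neighbors(v)} - {int(proposal[v])}
            )
            if not nbr_labs:
                continue
            cands = [int(proposal[v])] + nbr_labs
            corrs = [float(xz[v] @ means[c - 1] / x.shape[1]) for c in cands]
            best = cands[int(np.argmax(corrs))]
            if best != proposal[v]:
                if _parcel_connected_without(proposal, mesh, int(proposal[v]), v):
                    proposal[v] = best
                    changed = True
        if not changed:
            break
        score = _mean_assignment_correlation(x, proposal, k)
        if score < best_score:
            break  # roll back the degrading iteration
        labels = proposal
        best_score = score
    return HardParcellation(labels)


# --------------------------------------------------------------------------
# connectivity matrices
# --------------------------------------------------------------------------


def full_correlation(ts: NodeTimeseries) -> FCMatrix:
    """Pearson correlation matrix of the node series."""
    if ts.T < 3:
        raise ValueError("need at least 3 retained frames")
    sd = ts.values.std(axis=1)
    if np.any(sd == 0):
        raise ValueError(f"zero-variance node(s): {np.flatnonzero(sd == 0).tolist()}")
    c = np.corrcoef(ts.values)
    np.fill_diagonal(c, 1.0)
    return FCMatrix((c + c.T) / 2.0, kind="full")


def partial_correlation_tikhonov(ts: NodeTimeseries, rho: float = 0.1) -> FCMatrix:
    """Ridge-regularized partial correlation (FSLNets ``ridgep`` dialect).

    The node covariance ``C`` is rescaled by the root-mean-square of its
    diagonal, the precision ``P = inv(C_scaled + rho*I)`` is formed, and
    partial correlations are read off as ``-P_ij / sqrt(P_ii * P_jj)``
    with a unit diagonal.
    """
    if rho < 0:
        raise ValueError("rho must be >= 0")
    if ts.T <= 3:
        raise ValueError("need more than 3 retained frames")
    c = np.cov(ts.values)
    scale = np.sqrt(np.mean(np.diag(c) ** 2))
    if scale == 0:
        raise ValueError("all-zero covariance")
    c = c / scale
    a = c + rho * np.eye(ts.K)
    try:
        p = np.linalg.inv(a)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "singular covariance at rho=0; use rho > 0 for regularization"
        ) from err
    if rho == 0 and np.linalg.cond(a) > 1e12:
        raise ValueError(
            "near-singular covariance at rho=0; use rho > 0 for regularization"
        )
    d = np.sqrt(np.diag(p))
    r = -p / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return FCMatrix((r + r.T) / 2.0, kind="partial", rho=rho)


# --------------------------------------------------------------------------
# vectorization
# --------------------------------------------------------------------------


def n_lower_features(k: int) -> int:
    """Feature count of a vectorized K-node connectivity matrix."""
    return k * (k - 1) // 2


def vectorize_lower(fc: FCMatrix | np.ndarray) -> FeatureVector:
    """Strictly-lower-triangle entries in column-major order.

    The order is column by column, i.e. ``(1,0), (2,0), ..., (K-1,0),
    (2,1), ...`` — fixed so feature vectors are bit-stable across calls.
    """
    values = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc)
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    k = values.shape[0]
    iu = np.triu_indices(k, k=1)
    return FeatureVector(values.T[iu].copy())


def unvectorize_lower(vec: FeatureVector | np.ndarray, k: int) -> np.ndarray:
    """Inverse of :func:`vectorize_lower` onto a strictly-lower triangle."""
    values = vec.values if isinstance(vec, FeatureVector) else np.asarray(vec)
    if values.shape[0] != n_lower_features(k):
        raise ValueError("length does not match K(K-1)/2")
    out = np.zeros((k, k))
    iu = np.triu_indices(k, k=1)
    out.T[iu] = values
    return out
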