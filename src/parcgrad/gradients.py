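"""Gradient-based connectivity features.

Two routes: (1) principal gradients — diffusion-map embedding of a
sparsified cosine affinity between vertex connectivity profiles, with
Procrustes alignment of individual gradient sets to a group template
and concatenation of the top-m gradient maps into a feature vector;
(2) the local gradient — a single per-vertex map of how abruptly the
RSFC similarity pattern changes between mesh neighbors, highlighting
putative areal boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import orthogonal_procrustes
from scipy.sparse.csgraph import connected_components

from .connectome import FeatureVector, HardParcellation, concat_vertex_timeseries
from .synthgen import Mesh

__all__ = [
    "AffinityMatrix",
    "GradientSet",
    "LocalGradientMap",
    "DiffusionConfig",
    "vertex_fc_profiles",
    "build_affinity",
    "diffusion_embedding",
    "group_template",
    "procrustes_align",
    "concat_gradient_features",
    "local_gradient_map",
]


@dataclass(frozen=True)
class DiffusionConfig:
    """Embedding knobs: anisotropy exponent ``alpha`` (0.5 = the
    standard diffusion-map choice), per-row sparsity of the affinity
    (fraction of entries retained, top-10% by default), and diffusion
    time ``t`` (0 selects the eigenvalue-scaled ``lambda/(1-lambda)``
    components)."""

    alpha: float = 0.5
    sparsity: float = 0.1
    similarity: str = "cosine"
    t: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 < self.sparsity <= 1.0:
            raise ValueError("sparsity must lie in (0, 1]")
        if self.similarity != "cosine":
            raise ValueError("only cosine similarity is supported")


@dataclass(frozen=True)
class AffinityMatrix:
    """Nonnegative symmetric vertex affinity."""

    values: np.ndarray
    sparsity: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("affinity must be symmetric")
        if v.min() < 0:
            raise ValueError("affinity entries must be nonnegative")
        object.__setattr__(self, "values", v)

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class GradientSet:
    """Vertex-by-m gradient maps plus their (nonincreasing) eigenvalues."""

    components: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(ev) > 1e-10):
            raise ValueError("eigenvalues must be nonincreasing")
        object.__setattr__(self, "components", np.asarray(self.components, float))
        object.__setattr__(self, "eigenvalues", ev)

    @property
    def m(self) -> int:
        return self.components.shape[1]

    @property
    def n_vertices(self) -> int:
        return self.components.shape[0]


@dataclass(frozen=True)
class LocalGradientMap:
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.min() < -1e-12:
            raise ValueError("gradient magnitudes must be nonnegative")
        object.__setattr__(self, "values", np.maximum(v, 0.0))


# --------------------------------------------------------------------------
# connectivity profiles
# --------------------------------------------------------------------------


def vertex_fc_profiles(runs: list, targets=None) -> np.ndarray:
    """V-by-D matrix of Pearson correlations between each vertex's series
    and each target's series.

    ``targets`` may be None (all vertices — a symmetric V-by-V profile),
    an index array (vertex subset), or a :class:`HardParcellation`
    (targets are parcel mean series).
    """
    x = concat_vertex_timeseries(runs)
    sd = x.std(axis=1)
    if np.any(sd == 0):
        raise ValueError(
            f"zero-variance vertex(es): {np.flatnonzero(sd == 0).tolist()}"
        )
    xz = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    if targets is None:
        t = xz
    elif isinstance(targets, HardParcellation):
        node = np.stack(
            [x[targets.labels == k].mean(axis=0) for k in range(1, targets.K + 1)]
        )
        tsd = node.std(axis=1)
        if np.any(tsd == 0):
            raise ValueError("zero-variance target parcel")
        t = (node - node.mean(axis=1, keepdims=True)) / tsd[:, None]
    else:
        t = xz[np.asarray(targets, dtype=int)]
    if t.shape[0] > x.shape[0]:
        raise ValueError("cannot have more targets than vertices")
    return (xz @ t.T) / x.shape[1]


# --------------------------------------------------------------------------
# affinity and diffusion embedding
# --------------------------------------------------------------------------


def build_affinity(profiles: np.ndarray, config: DiffusionConfig | None = None) -> AffinityMatrix:
    """Row-sparsify profiles (keep each row's top ``ceil(sparsity*D)``
    entries) then take pairwise cosine similarity clamped at zero."""
    config = config or DiffusionConfig()
    p = np.asarray(profiles, dtype=float)
    v, d = p.shape
    keep = int(np.ceil(config.sparsity * d))
    thresholded = np.zeros_like(p)
    if keep >= d:
        thresholded = p.copy()
    else:
        order = np.argpartition(p, d - keep, axis=1)[:, d - keep:]
        rows = np.repeat(np.arange(v), keep)
        thresholded[rows, order.ravel()] = p[rows, order.ravel()]
    norms = np.linalg.norm(thresholded, axis=1)
    norms = np.where(norms == 0, 1.0, norms)
    unit = thresholded / norms[:, None]
    aff = np.clip(unit @ unit.T, 0.0, None)
    np.fill_diagonal(aff, 0.0)
    return AffinityMatrix((aff + aff.T) / 2.0, sparsity=config.sparsity)


def _largest_component_mask(a: np.ndarray) -> np.ndarray:
    n_comp, labels = connected_components(a > 0, directed=False)
    if n_comp == 1:
        return np.ones(a.shape[0], dtype=bool)
    sizes = np.bincount(labels)
    return labels == int(np.argmax(sizes))


def diffusion_embedding(
    aff: AffinityMatrix,
    m: int,
    config: DiffusionConfig | None = None,
    restrict_to_largest_component: bool = True,
) -> GradientSet:
    """Diffusion-map embedding of an affinity matrix.

    Anisotropic normalization ``W = D^-alpha A D^-alpha`` removes the
    density bias of the sampling (alpha = 0.5 by default), the
    row-stochastic operator ``M = Drow^-1 W`` is eigen-decomposed via
    its symmetric conjugate, the trivial constant eigenvector is
    dropped, and the next ``m`` right-eigenvectors are returned scaled
    by ``lambda/(1-lambda)`` (diffusion time t=0) or ``lambda**t``.
    Per-component sign is fixed by making the largest-magnitude element
    positive.
    """
    config = config or DiffusionConfig()
    a = aff.values
    n = a.shape[0]
    if m >= n:
        raise ValueError("number of gradients m must be smaller than V")
    mask = np.ones(n, dtype=bool)
    if restrict_to_largest_component:
        mask = _largest_component_mask(a)
        if not mask.all():
            warnings.warn(
                "affinity graph is disconnected; embedding restricted to the "
                "largest component (other vertices set to 0)",
                stacklevel=2,
            )
            a = a[np.ix_(mask, mask)]
    deg = a.sum(axis=1)
    deg = np.where(deg == 0, 1.0, deg)
    w = a / np.power(np.outer(deg, deg), config.alpha)
    drow = w.sum(axis=1)
    drow = np.where(drow == 0, 1.0, drow)
    # symmetric conjugate of M = Drow^-1 W shares its eigenvalues
    inv_sqrt = 1.0 / np.sqrt(drow)
    ms = inv_sqrt[:, None] * w * inv_sqrt[None, :]
    ms = (ms + ms.T) / 2.0
    evals, evecs = np.linalg.eigh(ms)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    # right eigenvectors of M recovered from the symmetric conjugate,
    # rescaled to unit norm (the convention of dense eigensolvers)
    vecs = inv_sqrt[:, None] * evecs[:, order]
    vecs = vecs / np.linalg.norm(vecs, axis=0, keepdims=True)
    lam = evals[1 : m + 1]
    comp = vecs[:, 1 : m + 1]
    if config.t == 0:
        scale = lam / np.where(np.abs(1.0 - lam) < 1e-12, 1e-12, 1.0 - lam)
    else:
        scale = np.sign(lam) * np.abs(lam) ** config.t
    comp = comp * scale[None, :]
    # reproducible sign: largest-|entry| element positive
    for j in range(comp.shape[1]):
        i = int(np.argmax(np.abs(comp[:, j])))
        if comp[i, j] < 0:
            comp[:, j] = -comp[:, j]
    if not mask.all():
        full = np.zeros((n, m))
        full[mask] = comp
        comp = full
    return GradientSet(components=comp, eigenvalues=lam)


def group_template(
    affinities: list,
    m: int,
    config: DiffusionConfig | None = None,
) -> GradientSet:
    """Group-level gradients: embedding of the cohort-average affinity."""
    if len(affinities) < 1:
        raise ValueError("need at least one subject affinity")
    mean_aff = AffinityMatrix(
        np.mean([a.values for a in affinities], axis=0),
        sparsity=affinities[0].sparsity,
    )
    return diffusion_embedding(mean_aff, m, config)


def procrustes_align(individual: GradientSet, template: GradientSet) -> GradientSet:
    """Rotate/reflect an individual gradient set onto the template.

    Finds the orthogonal matrix R minimizing
    ``||individual @ R - template||_F`` (no scaling, no translation)
    and returns ``individual @ R``; the Frobenius distance to the
    template never increases.
    """
    if individual.components.shape != template.components.shape:
        raise ValueError("gradient sets must share V and m")
    r, _ = orthogonal_procrustes(individual.components, template.components)
    return GradientSet(
        components=individual.components @ r,
        eigenvalues=individual.eigenvalues,
    )


def concat_gradient_features(aligned: GradientSet, m_use: int) -> FeatureVector:
    """Concatenate the top ``m_use`` gradient maps, component-major
    (all vertices of gradient 1, then gradient 2, ...)."""
    if m_use > aligned.m:
        raise ValueError("m_use exceeds the number of computed gradients")
    return FeatureVector(aligned.components[:, :m_use].ravel(order="F").copy())


# --------------------------------------------------------------------------
# local gradient
# --------------------------------------------------------------------------


def local_gradient_map(profiles: np.ndarray, mesh: Mesh) -> LocalGradientMap:
    """Per-vertex RSFC similarity gradient magnitude.

    The similarity matrix S is the row-wise Pearson correlation of the
    connectivity profiles.  For each reference column r the per-vertex
    gradient magnitude is the RMS difference of ``S[:, r]`` across the
    vertex's mesh neighbors; the map is the mean over reference columns.
    """
    p = np.asarray(profiles, dtype=float)
    if p.shape[0] != mesh.n_vertices:
        raise ValueError("profiles row count must equal mesh vertex count")
    sd = p.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("constant profile row; cannot correlate")
    s = np.corrcoef(p)
    out = np.empty(mesh.n_vertices)
    for v in range(mesh.n_vertices):
        nbrs = mesh.neighbors(v)
        if nbrs.size == 0:
            raise ValueError(f"isolated vertex {v}")
        diff = s[nbrs, :] - s[v, :][None, :]  # (deg, V) differences per reference
        out[v] = np.sqrt((diff**2).mean(axis=0)).mean()
    return LocalGradientMap(out)
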