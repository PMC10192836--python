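"""Synthetic resting-state cohorts for testing connectivity-based prediction.

This module generates desk-scale stand-ins for multi-run surface fMRI
cohorts: a cortical mesh (graph), a group-level network topography with
individual-specific spatial perturbations, latent-network BOLD-like time
courses with frame censoring, behavioral measures linearly coupled to the
subject's true latent connectivity, motion/demographic confounds, and
family / site-cluster structure for grouped cross-validation.

The generative model for a run is ``X = A @ S + E`` where ``A`` is the
subject's vertex-by-latent spatial loading matrix, ``S`` holds stationary
AR(1) latent time courses with a subject-specific latent correlation
matrix, and ``E`` is iid Gaussian observation noise.  Individual
differences enter in two places: the spatial topography (parcel
boundaries random-walked away from the group atlas) and the latent
correlation matrix, whose off-diagonal entries are the "true"
connectivity edges to which behaviors are coupled.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import trimesh
import yaml

__all__ = [
    "Mesh",
    "SynthConfig",
    "Run",
    "Subject",
    "Topography",
    "Cohort",
    "make_mesh",
    "make_group_topography",
    "soft_maps_from_labels",
    "perturb_topography",
    "hard_assignment_maps",
    "simulate_runs",
    "simulate_behavior",
    "assign_structure",
    "make_cohort",
    "save_cohort",
    "load_cohort",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Mesh:
    """Undirected connected graph standing in for a cortical surface mesh.

    Parameters
    ----------
    n_vertices
        Number of vertices.
    edges
        ``(E, 2)`` integer array of unordered vertex pairs, each stored
        with smaller index first, no duplicates, no self-loops.
    coordinates
        Optional ``(V, 3)`` vertex coordinates (arbitrary units).
    """

    n_vertices: int
    edges: np.ndarray
    coordinates: np.ndarray | None = None
    _neighbors: tuple = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=np.int64)
        if edges.ndim != 2 or edges.shape[1] != 2:
            raise ValueError("edges must be an (E, 2) array")
        if np.any(edges[:, 0] == edges[:, 1]):
            raise ValueError("mesh contains self-loops")
        canon = np.sort(edges, axis=1)
        if len({tuple(e) for e in canon.tolist()}) != len(canon):
            raise ValueError("mesh contains duplicate edges")
        nbrs: list[list[int]] = [[] for _ in range(self.n_vertices)]
        for i, j in canon.tolist():
            nbrs[i].append(j)
            nbrs[j].append(i)
        object.__setattr__(self, "edges", canon)
        object.__setattr__(
            self, "_neighbors", tuple(np.array(sorted(n), dtype=np.int64) for n in nbrs)
        )
        if not self.is_connected():
            raise ValueError("mesh graph must be connected")

    def neighbors(self, v: int) -> np.ndarray:
        return self._neighbors[v]

    def neighbor_lists(self) -> tuple:
        return self._neighbors

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_vertices))
        g.add_edges_from(map(tuple, self.edges.tolist()))
        return g

    def is_connected(self) -> bool:
        seen = np.zeros(self.n_vertices, dtype=bool)
        stack = [0]
        seen[0] = True
        while stack:
            v = stack.pop()
            for u in self._neighbors[v]:
                if not seen[u]:
                    seen[u] = True
                    stack.append(int(u))
        return bool(seen.all())


@dataclass
class SynthConfig:
    """All knobs of the cohort generator.

    Defaults are the desk-scale study conditions: 200 subjects with four
    200-frame runs on a 500-vertex lattice, six latent networks spread
    over 20 group parcels, moderate temporal autocorrelation and noise,
    10% frame censoring, and behaviors whose connectivity-explained
    variance share is ``effect_size``.
    """

    n_subjects: int = 200
    n_runs: int = 4
    T: int = 200
    n_latent: int = 6
    K_group: int = 20
    topo_shift: int = 5
    ar_coef: float = 0.3
    noise_sd: float = 1.0
    censor_frac: float = 0.1
    effect_size: float = 0.3
    n_behaviors: int = 10
    n_families: int = 100
    n_site_clusters: int = 9
    seed: int = 0
    # plumbing beyond the headline knobs
    n_vertices: int = 500
    mesh_kind: str = "lattice"
    fc_sd: float = 0.25
    confound_share: float = 0.1
    soft_scale: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "n_subjects",
            "n_runs",
            "T",
            "n_latent",
            "K_group",
            "n_behaviors",
            "n_families",
            "n_site_clusters",
            "n_vertices",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not -1.0 < self.ar_coef < 1.0:
            raise ValueError("ar_coef must lie in (-1, 1)")
        if not 0.0 <= self.censor_frac < 0.5:
            raise ValueError(
                "censor_frac must lie in [0, 0.5): runs with more than 50% "
                "censored frames are unusable and excluded by convention"
            )
        if not 0.0 <= self.effect_size < 1.0:
            raise ValueError("effect_size must lie in [0, 1)")
        if self.effect_size + self.confound_share > 1.0:
            raise ValueError("effect_size + confound_share must not exceed 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        return cls(**d)


@dataclass
class Run:
    """A single scan: vertex-by-time data plus a frame retention mask."""

    data: np.ndarray
    censor_mask: np.ndarray  # True = frame retained

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
        if self.censor_mask.shape[0] != self.data.shape[1]:
            raise ValueError("censor mask length must equal frame count")
        if int(self.censor_mask.sum()) < 2:
            raise ValueError("a run must retain at least 2 frames")

    @property
    def retained(self) -> np.ndarray:
        """Vertex-by-time data restricted to retained frames."""
        return self.data[:, self.censor_mask]


@dataclass
class Topography:
    """Group-level spatial layout: hard parcel labels, soft latent maps,
    and the parcel-to-latent-network assignment."""

    labels: np.ndarray  # (V,) int in 1..K
    soft_maps: np.ndarray  # (V, L) nonnegative, rows sum to 1
    parcel_networks: np.ndarray  # (K,) int in 1..L


@dataclass
class Subject:
    runs: list
    labels: np.ndarray
    soft_maps: np.ndarray
    latent_cov: np.ndarray


@dataclass
class Cohort:
    subjects: list
    mesh: Mesh
    phenotypes: pd.DataFrame  # subject x behavior
    confounds: pd.DataFrame  # age, sex, FD, DVARS
    family_id: np.ndarray
    site_id: np.ndarray
    config: SynthConfig
    ground_truth: dict

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def structure(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"family_id": self.family_id, "site_id": self.site_id},
            index=self.phenotypes.index,
        )


# --------------------------------------------------------------------------
# mesh construction
# --------------------------------------------------------------------------


def _lattice_shape(n: int) -> tuple[int, int]:
    """Most-square factorization rows*cols = n (rows <= cols)."""
    best = (1, n)
    for r in range(1, int(np.sqrt(n)) + 1):
        if n % r == 0:
            best = (r, n // r)
    return best


def make_mesh(n_vertices: int, kind: str = "lattice") -> Mesh:
    """Build a small surface stand-in graph.

    ``ring`` is the cycle graph; ``lattice`` is the most-square
    4-neighborhood grid with ``n_vertices`` nodes (a path if prime);
    ``icosphere`` is a subdivided icosahedron (degrees 5 and 6) with the
    smallest admissible vertex count ``10*4**s + 2 >= n_vertices``.
    Deterministic for fixed arguments.
    """
    if n_vertices < 3:
        raise ValueError("need at least 3 vertices")
    if kind == "ring":
        idx = np.arange(n_vertices)
        edges = np.stack([idx, (idx + 1) % n_vertices], axis=1)
        theta = 2 * np.pi * idx / n_vertices
        coords = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1)
        return Mesh(n_vertices, edges, coords)
    if kind == "lattice":
        rows, cols = _lattice_shape(n_vertices)
        edges = []
        for r in range(rows):
            for c in range(cols):
                v = r * cols + c
                if c + 1 < cols:
                    edges.append((v, v + 1))
                if r + 1 < rows:
                    edges.append((v, v + cols))
        coords = np.array(
            [(r, c, 0.0) for r in range(rows) for c in range(cols)], dtype=float
        )
        return Mesh(n_vertices, np.array(edges), coords)
    if kind == "icosphere":
        subdiv = 0
        while 10 * 4**subdiv + 2 < n_vertices:
            subdiv += 1
        ico = trimesh.creation.icosphere(subdivisions=subdiv)
        edges = np.unique(np.sort(ico.edges_unique, axis=1), axis=0)
        return Mesh(len(ico.vertices), edges, np.asarray(ico.vertices, dtype=float))
    raise ValueError(f"unknown mesh kind {kind!r}; use ring, lattice, or icosphere")


# --------------------------------------------------------------------------
# topography
# --------------------------------------------------------------------------


def _grow_parcels(mesh: Mesh, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded multi-source BFS (graph Voronoi) giving K contiguous parcels."""
    seeds = rng.choice(mesh.n_vertices, size=k, replace=False)
    labels = np.zeros(mesh.n_vertices, dtype=np.int64)
    frontier: list[int] = []
    for lab, s in enumerate(seeds, start=1):
        labels[s] = lab
        frontier.append(int(s))
    while frontier:
        nxt: list[int] = []
        for v in frontier:
            for u in mesh.neighbors(v):
                if labels[u] == 0:
                    labels[u] = labels[v]
                    nxt.append(int(u))
        frontier = nxt
    return labels


def make_group_topography(
    mesh: Mesh, K_group: int, n_latent: int, seed: int
) -> Topography:
    """Group atlas: K contiguous parcels grown on the mesh, each assigned
    to one of L latent networks (every network used), plus soft latent
    maps obtained by distance-kernel smoothing of the network regions."""
    if K_group > mesh.n_vertices:
        raise ValueError("K_group cannot exceed the number of vertices")
    if n_latent > K_group:
        raise ValueError("n_latent cannot exceed K_group")
    rng = np.random.default_rng(seed)
    labels = _grow_parcels(mesh, K_group, rng)
    nets = np.concatenate(
        [
            np.arange(1, n_latent + 1),
            rng.integers(1, n_latent + 1, size=K_group - n_latent),
        ]
    )
    parcel_networks = nets[rng.permutation(K_group)]
    vertex_net = parcel_networks[labels - 1]
    soft = _distance_soft_maps(mesh, vertex_net, n_latent, scale=2.0)
    return Topography(labels=labels, soft_maps=soft, parcel_networks=parcel_networks)


def _multi_source_distance(mesh: Mesh, sources: np.ndarray) -> np.ndarray:
    dist = np.full(mesh.n_vertices, np.inf)
    dist[sources] = 0.0
    frontier = list(map(int, sources))
    d = 0
    while frontier:
        d += 1
        nxt = []
        for v in frontier:
            for u in mesh.neighbors(v):
                if dist[u] > d:
                    dist[u] = d
                    nxt.append(int(u))
        frontier = nxt
    return dist


def _distance_soft_maps(
    mesh: Mesh, vertex_group: np.ndarray, n_groups: int, scale: float
) -> np.ndarray:
    """Soft maps w[v, g] ∝ exp(-graph_dist(v, region_g) / scale)."""
    w = np.zeros((mesh.n_vertices, n_groups))
    for g in range(1, n_groups + 1):
        src = np.flatnonzero(vertex_group == g)
        w[:, g - 1] = np.exp(-_multi_source_distance(mesh, src) / scale)
    return w / w.sum(axis=1, keepdims=True)


def soft_maps_from_labels(
    labels: np.ndarray, mesh: Mesh, scale: float = 2.0
) -> np.ndarray:
    """Vertex-by-K soft parcellation: smoothed indicators of the K hard
    parcels (the generator's stand-in for ICA spatial components)."""
    k = int(labels.max())
    return _distance_soft_maps(mesh, labels, k, scale)


def _parcel_connected_without(
    labels: np.ndarray, mesh: Mesh, lab: int, exclude: int
) -> bool:
    members = np.flatnonzero(labels == lab)
    members = members[members != exclude]
    if members.size == 0:
        return False
    member_set = set(members.tolist())
    seen = {int(members[0])}
    stack = [int(members[0])]
    while stack:
        v = stack.pop()
        for u in mesh.neighbors(v):
            ui = int(u)
            if ui in member_set and ui not in seen:
                seen.add(ui)
                stack.append(ui)
    return len(seen) == len(member_set)


def perturb_topography(
    group_labels: np.ndarray,
    mesh: Mesh,
    topo_shift: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Individualize an atlas by a seeded boundary random walk.

    Repeats ``topo_shift`` times: pick a random boundary vertex and a
    random differently-labeled neighbor parcel; reassign the vertex if
    its current parcel stays nonempty and contiguous.  ``topo_shift=0``
    returns the group labels unchanged; larger shifts displace more of
    the boundary in expectation.
    """
    if topo_shift < 0:
        raise ValueError("topo_shift must be >= 0")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    labels = np.array(group_labels, copy=True)
    for _ in range(int(topo_shift)):
        boundary = [
            v
            for v in range(mesh.n_vertices)
            if any(labels[u] != labels[v] for u in mesh.neighbors(v))
        ]
        if not boundary:
            break
        v = int(rng.choice(boundary))
        foreign = sorted({int(labels[u]) for u in mesh.neighbors(v)} - {int(labels[v])})
        new_lab = int(rng.choice(foreign))
        if _parcel_connected_without(labels, mesh, int(labels[v]), v):
            labels[v] = new_lab
    return labels


def hard_assignment_maps(
    labels: np.ndarray, parcel_networks: np.ndarray, n_latent: int
) -> np.ndarray:
    """One-hot vertex-by-latent loading matrix implied by hard labels."""
    vertex_net = parcel_networks[labels - 1]
    a = np.zeros((labels.shape[0], n_latent))
    a[np.arange(labels.shape[0]), vertex_net - 1] = 1.0
    return a


# --------------------------------------------------------------------------
# time series
# --------------------------------------------------------------------------


def _ar1_latents(
    n_latent: int,
    T: int,
    ar: float,
    latent_cov: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stationary AR(1) latent series with stationary covariance
    ``latent_cov`` and lag-1 autocorrelation ``ar`` per latent."""
    chol = np.linalg.cholesky(latent_cov)
    s = np.empty((n_latent, T))
    s[:, 0] = chol @ rng.standard_normal(n_latent)
    innov_scale = np.sqrt(1.0 - ar**2)
    for t in range(1, T):
        s[:, t] = ar * s[:, t - 1] + innov_scale * (
            chol @ rng.standard_normal(n_latent)
        )
    return s


def simulate_runs(
    maps: np.ndarray,
    config: SynthConfig,
    seed: int | np.random.Generator,
    latent_cov: np.ndarray | None = None,
) -> list:
    """Simulate ``config.n_runs`` runs ``X = A @ S + E`` for one subject.

    ``maps`` is the subject's vertex-by-latent loading matrix ``A``
    (one-hot for hard topographies, smooth for soft ones); ``S`` are
    AR(1) latent series with stationary covariance ``latent_cov``
    (identity by default); ``E`` is iid N(0, noise_sd^2).  Exactly
    ``floor(censor_frac * T)`` random frames per run are censored.
    """
    if config.T < 10:
        raise ValueError("T must be >= 10")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    maps = np.asarray(maps, dtype=float)
    n_latent = maps.shape[1]
    cov = np.eye(n_latent) if latent_cov is None else np.asarray(latent_cov)
    n_censor = int(np.floor(config.censor_frac * config.T))
    runs = []
    for _ in range(config.n_runs):
        s = _ar1_latents(n_latent, config.T, config.ar_coef, cov, rng)
        x = maps @ s
        if config.noise_sd > 0:
            x = x + config.noise_sd * rng.standard_normal(x.shape)
        mask = np.ones(config.T, dtype=bool)
        if n_censor:
            mask[rng.choice(config.T, size=n_censor, replace=False)] = False
        runs.append(Run(data=x, censor_mask=mask))
    return runs


# --------------------------------------------------------------------------
# latent connectivity and behavior
# --------------------------------------------------------------------------


def _nearest_correlation(a: np.ndarray, floor: float = 1e-3) -> np.ndarray:
    """Symmetrize, clip eigenvalues from below, rescale to unit diagonal."""
    a = (a + a.T) / 2.0
    w, v = np.linalg.eigh(a)
    a = (v * np.maximum(w, floor)) @ v.T
    d = np.sqrt(np.diag(a))
    return a / np.outer(d, d)


def _group_latent_correlation(L: int, rng: np.random.Generator) -> np.ndarray:
    b = rng.standard_normal((L, L))
    return _nearest_correlation(b @ b.T / L + np.eye(L))


def subject_latent_correlation(
    group_corr: np.ndarray, fc_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Subject latent correlation: group matrix plus a symmetric Gaussian
    off-diagonal perturbation, projected back to a valid correlation."""
    L = group_corr.shape[0]
    d = rng.standard_normal((L, L)) * fc_sd
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return _nearest_correlation(group_corr + d)


def true_edges(latent_cov: np.ndarray) -> np.ndarray:
    """Column-major strictly-lower triangle of a latent correlation
    matrix — the ground-truth connectivity edges behaviors couple to."""
    L = latent_cov.shape[0]
    iu = np.triu_indices(L, k=1)
    return latent_cov.T[iu]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_behavior(
    edge_matrix: np.ndarray,
    effect_sizes: np.ndarray,
    confounds: pd.DataFrame,
    confound_shares: np.ndarray,
    rng: np.random.Generator,
    behavior_names: list | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Behaviors linearly coupled to true connectivity edges.

    Each behavior ``b`` is built as
    ``sqrt(es_b) * z(edges @ beta_b) + sqrt(cs_b) * z(C @ gamma_b) + sqrt(1 - es_b - cs_b) * eps``
    so that ``es_b`` is the (expected) variance share explained by the
    ground-truth connectivity features and ``cs_b`` the share carried by
    the confounds.  Returns the phenotype table and the ground-truth
    coefficients for recovery tests.
    """
    n, n_edges = edge_matrix.shape
    effect_sizes = np.atleast_1d(np.asarray(effect_sizes, dtype=float))
    confound_shares = np.broadcast_to(
        np.atleast_1d(np.asarray(confound_shares, dtype=float)), effect_sizes.shape
    )
    if np.any(effect_sizes < 0) or np.any(effect_sizes >= 1):
        raise ValueError("effect sizes must lie in [0, 1)")
    if np.any(effect_sizes + confound_shares > 1):
        raise ValueError("effect size plus confound share must not exceed 1")
    c = np.column_stack([_zscore(confounds[col].to_numpy(float)) for col in confounds])
    names = behavior_names or [f"beh_{i:02d}" for i in range(len(effect_sizes))]
    cols, betas, gammas = {}, [], []
    for b, (es, cs) in enumerate(zip(effect_sizes, confound_shares)):
        beta = rng.standard_normal(n_edges)
        gamma = rng.standard_normal(c.shape[1])
        y = (
            np.sqrt(es) * _zscore(edge_matrix @ beta)
            + np.sqrt(cs) * _zscore(c @ gamma)
            + np.sqrt(max(1.0 - es - cs, 0.0)) * rng.standard_normal(n)
        )
        cols[names[b]] = y
        betas.append(beta)
        gammas.append(gamma)
    pheno = pd.DataFrame(cols, index=confounds.index)
    truth = {
        "beta": np.array(betas),
        "gamma": np.array(gammas),
        "effect_sizes": effect_sizes,
        "confound_shares": np.asarray(confound_shares),
    }
    return pheno, truth


def assign_structure(
    n_subjects: int,
    n_families: int,
    n_site_clusters: int,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Random balanced family and site-cluster assignments (sizes differ
    by at most one)."""
    if n_families > n_subjects or n_site_clusters > n_subjects:
        raise ValueError("cannot have more groups than subjects")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )

    def balanced(n_groups: int) -> np.ndarray:
        ids = np.empty(n_subjects, dtype=np.int64)
        perm = rng.permutation(n_subjects)
        for g, chunk in enumerate(np.array_split(perm, n_groups)):
            ids[chunk] = g
        return ids

    return balanced(n_families), balanced(n_site_clusters)


def _simulate_confounds(n: int, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": rng.uniform(20.0, 40.0, size=n),
            "sex": rng.integers(0, 2, size=n).astype(float),
            "FD": rng.lognormal(mean=-1.8, sigma=0.4, size=n),
            "DVARS": rng.lognormal(mean=0.0, sigma=0.3, size=n),
        },
        index=pd.Index([f"sub-{i:04d}" for i in range(n)], name="subject"),
    )


# --------------------------------------------------------------------------
# cohort assembly
# --------------------------------------------------------------------------


def make_cohort(
    config: SynthConfig,
    effect_sizes: np.ndarray | None = None,
    behavior_names: list | None = None,
) -> Cohort:
    """Generate a full cohort under one configuration.

    ``effect_sizes`` optionally gives a per-behavior connectivity
    variance share (length ``n_behaviors``); by default every behavior
    uses ``config.effect_size``.  Identical configurations (including
    the seed) produce identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    mesh = make_mesh(config.n_vertices, config.mesh_kind)
    topo = make_group_topography(
        mesh, config.K_group, config.n_latent, seed=int(rng.integers(2**31))
    )
    group_corr = _group_latent_correlation(config.n_latent, rng)

    subjects = []
    edge_rows = []
    for _ in range(config.n_subjects):
        sub_rng = np.random.default_rng(rng.integers(2**31))
        labels = perturb_topography(topo.labels, mesh, config.topo_shift, sub_rng)
        vertex_net = topo.parcel_networks[labels - 1]
        soft = _distance_soft_maps(
            mesh, vertex_net, config.n_latent, scale=config.soft_scale
        )
        latent_cov = subject_latent_correlation(group_corr, config.fc_sd, sub_rng)
        runs = simulate_runs(soft, config, sub_rng, latent_cov=latent_cov)
        subjects.append(
            Subject(runs=runs, labels=labels, soft_maps=soft, latent_cov=latent_cov)
        )
        edge_rows.append(true_edges(latent_cov))
    edge_matrix = np.array(edge_rows)

    confounds = _simulate_confounds(config.n_subjects, rng)
    if effect_sizes is None:
        effect_sizes = np.full(config.n_behaviors, config.effect_size)
    pheno, beh_truth = simulate_behavior(
        edge_matrix,
        effect_sizes,
        confounds,
        np.full(len(np.atleast_1d(effect_sizes)), config.confound_share),
        rng,
        behavior_names=behavior_names,
    )
    family_id, site_id = assign_structure(
        config.n_subjects, config.n_families, config.n_site_clusters, rng
    )
    ground_truth = {
        "group_labels": topo.labels,
        "parcel_networks": topo.parcel_networks,
        "group_soft_maps": topo.soft_maps,
        "group_latent_corr": group_corr,
        "subject_labels": np.array([s.labels for s in subjects]),
        "edge_matrix": edge_matrix,
        **beh_truth,
    }
    return Cohort(
        subjects=subjects,
        mesh=mesh,
        phenotypes=pheno,
        confounds=confounds,
        family_id=family_id,
        site_id=site_id,
        config=config,
        ground_truth=ground_truth,
    )


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------


def save_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a cohort to a directory: per-subject ``.npz`` arrays with
    shape metadata, TSV tables, the mesh edge list, and the config."""
    out = Path(out_dir)
    (out / "subjects").mkdir(parents=True, exist_ok=True)
    pd.DataFrame(cohort.mesh.edges, columns=["v1", "v2"]).to_csv(
        out / "mesh_edges.tsv", sep="\t", index=False
    )
    cohort.phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index_label="subject")
    cohort.confounds.to_csv(out / "confounds.tsv", sep="\t", index_label="subject")
    cohort.structure.to_csv(out / "structure.tsv", sep="\t", index_label="subject")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cohort.config.to_dict(), fh)
    for i, sub in enumerate(cohort.subjects):
        arrays = {"labels": sub.labels, "soft_maps": sub.soft_maps,
                  "latent_cov": sub.latent_cov}
        for r, run in enumerate(sub.runs):
            arrays[f"run_{r}"] = run.data
            arrays[f"mask_{r}"] = run.censor_mask
        np.savez(out / "subjects" / f"sub-{i:04d}.npz", **arrays)
    np.savez(
        out / "ground_truth.npz",
        **{k: np.asarray(v) for k, v in cohort.ground_truth.items()},
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump({"n_subjects": cohort.n_subjects, "format": "parcgrad-cohort-v1"}, fh)


def load_cohort(in_dir: str | Path) -> Cohort:
    src = Path(in_dir)
    with open(src / "config.yaml") as fh:
        config = SynthConfig.from_dict(yaml.safe_load(fh))
    edges = pd.read_csv(src / "mesh_edges.tsv", sep="\t").to_numpy()
    n_vertices = int(edges.max()) + 1
    mesh = make_mesh(config.n_vertices, config.mesh_kind)
    if mesh.n_vertices != n_vertices:  # e.g. icosphere snapped count
        mesh = Mesh(n_vertices, edges)
    pheno = pd.read_csv(src / "phenotypes.tsv", sep="\t", index_col="subject")
    confounds = pd.read_csv(src / "confounds.tsv", sep="\t", index_col="subject")
    structure = pd.read_csv(src / "structure.tsv", sep="\t", index_col="subject")
    with open(src / "manifest.json") as fh:
        n_subjects = json.load(fh)["n_subjects"]
    subjects = []
    for i in range(n_subjects):
        with np.load(src / "subjects" / f"sub-{i:04d}.npz") as z:
            runs = []
            r = 0
            while f"run_{r}" in z:
                runs.append(Run(data=z[f"run_{r}"], censor_mask=z[f"mask_{r}"]))
                r += 1
            subjects.append(
                Subject(
                    runs=runs,
                    labels=z["labels"],
                    soft_maps=z["soft_maps"],
                    latent_cov=z["latent_cov"],
                )
            )
    ground_truth = {}
    gt_path = src / "ground_truth.npz"
    if gt_path.exists():
        with np.load(gt_path, allow_pickle=False) as z:
            ground_truth = {k: z[k] for k in z.files}
    return Cohort(
        subjects=subjects,
        mesh=mesh,
        phenotypes=pheno,
        confounds=confounds,
        family_id=structure["family_id"].to_numpy(),
        site_id=structure["site_id"].to_numpy(),
        config=config,
        ground_truth=ground_truth,
    )
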