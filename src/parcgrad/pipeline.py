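"""End-to-end orchestration: cohort -> features -> fold results.

Glue that computes subject-by-feature matrices for each
feature-construction approach at one or more resolutions, stores them
with a JSON sidecar, and drives nested cross-validation over all
behaviors.  The five approaches are:

- ``group-hard``: group atlas applied to everyone, partial/full
  correlation of parcel mean series.
- ``individual-hard``: boundary-refined individualized atlas per
  subject, then the same connectivity.
- ``soft``: smoothed-parcel soft maps, stage-1 dual regression time
  courses, then the same connectivity.
- ``principal-gradient``: diffusion-map gradients aligned to a group
  template, top-m maps concatenated.
- ``local-gradient``: the single RSFC-similarity gradient map.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectome as cn
from . import gradients as gr
from .predict import CVScheme, RidgeSpec, nested_cv
from .synthgen import Cohort, make_group_topography, soft_maps_from_labels

__all__ = [
    "APPROACHES",
    "compute_features",
    "save_features",
    "load_features",
    "run_prediction",
]

APPROACHES = (
    "group-hard",
    "individual-hard",
    "soft",
    "principal-gradient",
    "local-gradient",
)


def _fc_features(ts, corr: str, rho: float) -> np.ndarray:
    fc = (
        cn.partial_correlation_tikhonov(ts, rho=rho)
        if corr == "partial"
        else cn.full_correlation(ts)
    )
    return cn.vectorize_lower(fc).values


def _parcellation_at(cohort: Cohort, resolution: int, n_latent: int | None = None):
    """Deterministic group atlas at an arbitrary resolution, grown on
    the cohort mesh with a seed tied to the cohort seed and resolution."""
    n_latent = n_latent or min(cohort.config.n_latent, resolution)
    topo = make_group_topography(
        cohort.mesh, resolution, n_latent, seed=cohort.config.seed * 1000 + resolution
    )
    return cn.HardParcellation(topo.labels)


def compute_features(
    cohort: Cohort,
    approach: str,
    resolutions: list,
    corr: str = "partial",
    rho: float = 0.1,
    n_iter: int = 3,
    diffusion=None,
    profile_targets=None,
) -> dict:
    """Subject-by-feature matrices per resolution for one approach.

    Parcellation approaches use the cohort's group atlas when the
    requested resolution equals ``K_group`` and otherwise grow a fresh
    deterministic atlas at that resolution.  Gradient approaches build
    vertex connectivity profiles (against ``profile_targets``, all
    vertices by default), embed, and align to the cohort-average
    template; ``resolutions`` are then the number of gradients kept.
    """
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}")
    diffusion = diffusion or gr.DiffusionConfig()
    out: dict[int, np.ndarray] = {}

    if approach in ("group-hard", "individual-hard"):
        for res in resolutions:
            if res == cohort.config.K_group:
                parc = cn.HardParcellation(cohort.ground_truth["group_labels"])
            else:
                parc = _parcellation_at(cohort, res)
            feats = []
            for sub in cohort.subjects:
                p = parc
                if approach == "individual-hard":
                    p = cn.individualize_parcellation(
                        parc, sub.runs, cohort.mesh, n_iter=n_iter
                    )
                ts = cn.extract_hard_timeseries(sub.runs, p)
                feats.append(_fc_features(ts, corr, rho))
            out[res] = np.array(feats)
        return out

    if approach == "soft":
        for res in resolutions:
            if res == cohort.config.K_group:
                labels = cohort.ground_truth["group_labels"]
            else:
                labels = _parcellation_at(cohort, res).labels
            soft = cn.SoftParcellation(
                soft_maps_from_labels(labels, cohort.mesh, cohort.config.soft_scale)
            )
            feats = []
            for sub in cohort.subjects:
                ts = cn.dual_regression_stage1(sub.runs, soft)
                feats.append(_fc_features(ts, corr, rho))
            out[res] = np.array(feats)
        return out

    profiles = [
        gr.vertex_fc_profiles(sub.runs, targets=profile_targets)
        for sub in cohort.subjects
    ]
    if approach == "local-gradient":
        maps = np.array(
            [gr.local_gradient_map(p, cohort.mesh).values for p in profiles]
        )
        return {res: maps for res in resolutions}

    # principal gradients
    m_max = max(resolutions)
    affs = [gr.build_affinity(p, diffusion) for p in profiles]
    template = gr.group_template(affs, m_max, diffusion)
    aligned = [
        gr.procrustes_align(gr.diffusion_embedding(a, m_max, diffusion), template)
        for a in affs
    ]
    for res in resolutions:
        out[res] = np.array(
            [gr.concat_gradient_features(g, res).values for g in aligned]
        )
    return out


def save_features(
    features: dict, out_path: str | Path, approach: str, corr: str = "partial",
    rho: float | None = None,
) -> None:
    """Write the per-resolution matrices to one ``.npz`` plus a JSON
    sidecar recording approach, resolutions, correlation kind, rho, and
    the lower-triangle ordering convention."""
    out_path = Path(out_path)
    np.savez(out_path, **{f"res_{r}": x for r, x in features.items()})
    sidecar = {
        "approach": approach,
        "resolutions": sorted(int(r) for r in features),
        "corr": corr,
        "rho": rho,
        "ordering": "strictly-lower-triangle, column-major",
    }
    out_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_features(path: str | Path) -> tuple[dict, dict]:
    path = Path(path)
    with np.load(path) as z:
        features = {int(k.split("_", 1)[1]): z[k] for k in z.files}
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return features, sidecar


def run_prediction(
    features_by_approach: dict,
    phenotypes: pd.DataFrame,
    confounds: pd.DataFrame,
    structure: pd.DataFrame,
    scheme: CVScheme,
    model: str = "krr",
    lambda_grid=None,
    behaviors: list | None = None,
) -> pd.DataFrame:
    """Nested CV for every (approach, behavior); returns the long-format
    fold-results table consumed by the comparison stage."""
    behaviors = behaviors or list(phenotypes.columns)
    frames = []
    for approach, feats in features_by_approach.items():
        spec = RidgeSpec(model=model, lambda_grid=lambda_grid)
        for beh in behaviors:
            frames.append(
                nested_cv(
                    feats,
                    phenotypes[beh].to_numpy(float),
                    confounds,
                    structure,
                    scheme,
                    spec,
                    approach=approach,
                    behavior=beh,
                )
            )
    return pd.concat(frames, ignore_index=True)
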