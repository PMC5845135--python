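"""Point-distribution model: PCA of Procrustes-aligned shape vectors.

Every shape is expressed as X = M + sum_i P_i w_i with mean shape M,
orthonormal components P_i (rows) ordered by decreasing variance, and
per-shape scores w_i.  The decomposition is computed by singular value
decomposition of the centered (N, 3V) matrix — never the 3V x 3V
covariance — so it stays cheap at scan-scale vertex counts.  Score
variances use the N-1 denominator.  A deterministic sign convention (the
largest-|entry| coordinate of each component is positive) makes models
reproducible across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment import AlignedShapeSet

__all__ = [
    "ShapeModel",
    "fit_pca",
    "synthesize",
    "project",
    "explained_variance_report",
    "save_model",
    "load_model",
]


@dataclass
class ShapeModel:
    """PCA shape model: mean, components, score SDs and training scores."""

    mean: np.ndarray  # (3V,)
    components: np.ndarray  # (n, 3V), orthonormal rows
    sds: np.ndarray  # (n,) score standard deviations (ddof=1)
    scores: np.ndarray  # (N, n)
    explained_fraction: np.ndarray  # (n,)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def n_vertices(self) -> int:
        return len(self.mean) // 3


def fit_pca(
    aligned: AlignedShapeSet | np.ndarray, n_components: int | str = "full"
) -> ShapeModel:
    """Fit the PCA point-distribution model to aligned shapes.

    ``aligned`` is an :class:`AlignedShapeSet` or a raw (N, 3V) matrix.
    ``n_components`` keeps the leading components ("full" keeps every
    component up to the data rank, at most N-1).
    """
    X = aligned.shapes if isinstance(aligned, AlignedShapeSet) else np.asarray(aligned, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two shapes")
    N = X.shape[0]
    max_rank = min(N - 1, X.shape[1])
    if n_components == "full":
        k = max_rank
    else:
        k = int(n_components)
        if not 1 <= k <= max_rank:
            raise ValueError(f"n_components must be in [1, {max_rank}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float(np.sum(s**2))  # = (N-1) * total variance
    s, Vt, U = s[:k], Vt[:k], U[:, :k]
    # sign convention: largest-|entry| coordinate of each component positive
    flip = np.sign(Vt[np.arange(k), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    scores = Xc @ Vt.T
    sds = s / np.sqrt(N - 1)
    explained = s**2 / total_var if total_var > 0 else np.zeros(k)
    return ShapeModel(
        mean=mean,
        components=Vt,
        sds=sds,
        scores=scores,
        explained_fraction=explained,
    )


def synthesize(
    model: ShapeModel, weights: np.ndarray, sigma_units: bool = False
) -> np.ndarray:
    """Shape M + sum P_i w_i for the given (possibly partial) weight vector.

    With ``sigma_units`` the weights are interpreted as multiples of each
    component's score SD (e.g. +3 for the classic +3-sigma rendering).
    """
    w = np.asarray(weights, dtype=float).reshape(-1)
    if not np.isfinite(w).all():
        raise ValueError("weights must be finite")
    if len(w) > model.n_components:
        raise ValueError(
            f"{len(w)} weights for a model with {model.n_components} components"
        )
    if sigma_units:
        w = w * model.sds[: len(w)]
    return model.mean + w @ model.components[: len(w)]


def project(model: ShapeModel, coords: np.ndarray) -> np.ndarray:
    """Scores w_i = P_i . (X - M) of a corresponded shape vector."""
    x = np.asarray(coords, dtype=float).reshape(-1)
    if len(x) != len(model.mean):
        raise ValueError(
            f"coordinate length {len(x)} != model length {len(model.mean)}"
        )
    return model.components @ (x - model.mean)


def explained_variance_report(model: ShapeModel, k: int | None = None) -> dict:
    """Per-component and cumulative explained-variance fractions.

    Returns ``{"per_pc": array, "cumulative": array}`` for the first ``k``
    components (default: all).
    """
    if k is None:
        k = model.n_components
    if not 1 <= k <= model.n_components:
        raise ValueError(f"k must be in [1, {model.n_components}]")
    per = model.explained_fraction[:k]
    return {"per_pc": per.copy(), "cumulative": np.cumsum(per)}


def save_model(model: ShapeModel, path: str | Path) -> None:
    """Serialize a model to an .npz bundle with a JSON manifest sidecar."""
    path = Path(path)
    np.savez(
        path,
        mean=model.mean,
        components=model.components,
        sds=model.sds,
        scores=model.scores,
        explained_fraction=model.explained_fraction,
    )
    manifest = {
        "n_components": model.n_components,
        "n_vertices": model.n_vertices,
        "n_shapes": int(model.scores.shape[0]),
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_model(path: str | Path) -> ShapeModel:
    """Load a model saved by :func:`save_model`."""
    with np.load(Path(path)) as data:
        return ShapeModel(
            mean=data["mean"],
            components=data["components"],
            sds=data["sds"],
            scores=data["scores"],
            explained_fraction=data["explained_fraction"],
        )
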