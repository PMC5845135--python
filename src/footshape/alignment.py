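"""Generalized Procrustes Analysis of corresponded shapes.

Shapes are flat 3V coordinate vectors sharing one template vertex order.
GPA removes position (centroid to origin), size (unit centroid size) and
orientation (least-squares rotation to the evolving mean), iterating the
mean update to convergence and repeating the whole pass a configurable
number of times with the refreshed reference.  The final configuration is
rotated into a canonical, data-derived frame so results are reproducible
across runs and input orderings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AlignedShapeSet",
    "center_shape",
    "scale_to_unit",
    "optimal_rotation",
    "gpa",
    "similarity_tangent_basis",
    "project_out_similarity",
]


@dataclass
class AlignedShapeSet:
    """Procrustes-superimposed shapes plus sizes and the mean shape.

    ``shapes`` is (N, 3V) with every row centered at the origin and at unit
    centroid size; ``centroid_sizes`` are the pre-normalization sizes (mm)
    so size-restored reporting remains possible.
    """

    shapes: np.ndarray
    mean_shape: np.ndarray
    centroid_sizes: np.ndarray
    scan_ids: list[str]
    objective_trace: list[float] = field(default_factory=list)

    @property
    def n_shapes(self) -> int:
        return len(self.shapes)

    @property
    def n_vertices(self) -> int:
        return self.shapes.shape[1] // 3


def center_shape(coords: np.ndarray) -> np.ndarray:
    """Translate a 3V coordinate vector so its centroid is at the origin."""
    pts = np.asarray(coords, dtype=float).reshape(-1, 3)
    return (pts - pts.mean(axis=0)).reshape(-1)


def scale_to_unit(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Scale a centered shape to unit centroid size; return (shape, size).

    Centroid size is the root summed squared vertex distance to the
    centroid — the standard Procrustes size measure.
    """
    flat = np.asarray(coords, dtype=float).reshape(-1)
    size = float(np.linalg.norm(flat - _centroid_component(flat)))
    if size < 1e-12:
        raise ValueError("zero-size shape cannot be normalized")
    centered = center_shape(flat)
    return centered / size, float(np.linalg.norm(centered))


def _centroid_component(flat: np.ndarray) -> np.ndarray:
    pts = flat.reshape(-1, 3)
    return np.tile(pts.mean(axis=0), len(pts))


def optimal_rotation(coords: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing sum ||R x_i - t_i||^2 (Kabsch).

    Both shapes must be centered and share vertex count.  Reflections are
    excluded (left feet are mirrored upstream); degenerate rank-<2
    configurations raise ``ValueError``.
    """
    X = np.asarray(coords, dtype=float).reshape(-1, 3)
    T = np.asarray(target, dtype=float).reshape(-1, 3)
    if X.shape != T.shape:
        raise ValueError(f"vertex count mismatch: {X.shape} vs {T.shape}")
    H = X.T @ T
    U, s, Vt = np.linalg.svd(H)
    if np.sum(s > s[0] * 1e-12) < 2:
        raise ValueError("degenerate (rank < 2) configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def _canonical_rotation(mean_flat: np.ndarray) -> np.ndarray:
    """Rotation taking the mean shape into the canonical frame.

    Principal axes of the mean are mapped to (y, x, z) — longest axis
    heel-to-toe along y — with signs fixed by the third moment of the
    projections (feet are skew along every axis), and handedness enforced.
    """
    pts = mean_flat.reshape(-1, 3)
    pts = pts - pts.mean(axis=0)
    cov = pts.T @ pts
    _, evecs = np.linalg.eigh(cov)
    axes = evecs[:, ::-1]  # columns: descending variance
    for j in range(3):
        skew = np.sum((pts @ axes[:, j]) ** 3)
        if skew < 0:
            axes[:, j] = -axes[:, j]
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    # rows of R: new x = 2nd axis, new y = 1st axis, new z = 3rd axis
    R = np.vstack([axes[:, 1], axes[:, 0], axes[:, 2]])
    if np.linalg.det(R) < 0:
        R[2] = -R[2]
    return R


def gpa(
    shapes: np.ndarray,
    reference_update_iters: int = 3,
    scan_ids: list[str] | None = None,
    tol: float = 1e-12,
    max_inner: int = 500,
    canonical: bool = True,
) -> AlignedShapeSet:
    """Generalized Procrustes superimposition of an (N, 3V) shape matrix.

    Each shape is centered and scaled to unit centroid size, then rotated
    to the current mean; the mean is recomputed and re-normalized until no
    coordinate moves by more than ``tol`` in a pass (so the result is a
    fixed point of the align-to-mean map to near machine precision).  The
    whole pass repeats ``reference_update_iters`` times with the converged
    mean as the fresh reference.  The objective is non-increasing across
    passes.
    """
    shapes = np.asarray(shapes, dtype=float)
    if shapes.ndim != 2 or shapes.shape[0] < 2:
        raise ValueError("need an (N >= 2, 3V) shape matrix")
    if shapes.shape[1] % 3 != 0:
        raise ValueError("shape vectors must have length 3V")
    N = shapes.shape[0]
    if scan_ids is None:
        scan_ids = [f"scan{i:04d}" for i in range(N)]
    if len(scan_ids) != N:
        raise ValueError("scan_ids length mismatch")

    aligned = np.empty_like(shapes)
    sizes = np.empty(N)
    for i in range(N):
        aligned[i], sizes[i] = scale_to_unit(center_shape(shapes[i]))

    trace: list[float] = []
    for _outer in range(reference_update_iters):
        ref = aligned.mean(axis=0)
        ref = ref / np.linalg.norm(center_shape(ref))
        for _inner in range(max_inner):
            motion = 0.0
            for i in range(N):
                R = optimal_rotation(aligned[i], ref)
                rotated = (aligned[i].reshape(-1, 3) @ R.T).reshape(-1)
                motion = max(motion, float(np.abs(rotated - aligned[i]).max()))
                aligned[i] = rotated
            mean = aligned.mean(axis=0)
            trace.append(float(np.sum((aligned - mean) ** 2)))
            ref = center_shape(mean)
            ref = ref / np.linalg.norm(ref)
            if motion <= tol:
                break

    mean = aligned.mean(axis=0)
    if canonical:
        R = _canonical_rotation(mean)
        for i in range(N):
            aligned[i] = (aligned[i].reshape(-1, 3) @ R.T).reshape(-1)
        mean = aligned.mean(axis=0)
    return AlignedShapeSet(
        shapes=aligned,
        mean_shape=mean,
        centroid_sizes=sizes,
        scan_ids=list(scan_ids),
        objective_trace=trace,
    )


def similarity_tangent_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (7, 3V) of similarity-transform directions at a shape.

    Rows span infinitesimal translations (3), rotations (3) and scaling (1)
    of the given configuration.  Displacement fields projected out of this
    subspace live in Procrustes shape space proper: the part of a
    deformation that survives superimposition.
    """
    pts = np.asarray(coords, dtype=float).reshape(-1, 3)
    ctr = pts - pts.mean(axis=0)
    V = len(pts)
    fields = []
    for ax in range(3):
        t = np.zeros((V, 3))
        t[:, ax] = 1.0
        fields.append(t.reshape(-1))
    for ax in range(3):
        omega = np.zeros(3)
        omega[ax] = 1.0
        fields.append(np.cross(np.broadcast_to(omega, (V, 3)), ctr).reshape(-1))
    fields.append(ctr.reshape(-1))
    basis = []
    for f in fields:
        for b in basis:
            f = f - (f @ b) * b
        n = np.linalg.norm(f)
        if n > 1e-12:
            basis.append(f / n)
    return np.vstack(basis)


def project_out_similarity(
    fields: np.ndarray, coords: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Remove similarity-transform components from displacement fields.

    Returns (projected fields renormalized to unit norm, original norms of
    the projected fields).  For a planted unit-norm mode with SD sigma, the
    SD observable in Procrustes shape space is sigma * norm.
    """
    fields = np.atleast_2d(np.asarray(fields, dtype=float))
    basis = similarity_tangent_basis(coords)
    proj = fields - (fields @ basis.T) @ basis
    norms = np.linalg.norm(proj, axis=1)
    if (norms < 1e-12).any():
        raise ValueError("a field lies entirely in the similarity subspace")
    return proj / norms[:, None], norms
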