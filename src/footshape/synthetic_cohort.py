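"""Synthetic foot-scan cohorts with known ground truth.

This module generates triangulated foot-like surfaces whose population
variation is driven by six latent deformation modes (arch height, ball
width with toe spread, global width, hallux orientation, hallux/second-toe
length trade-off, midfoot width), with mode weights linearly coupled to
subject factors.  Every downstream stage of the morphometric pipeline —
correspondence, Procrustes alignment, the PCA shape model and the factor
regression — can therefore be tested against exact ground truth: the
template-ordered vertex positions, the planted mode weights, and the
planted factor effect matrix are all retained per scan.

The default configuration emulates a cohort of 62 adults (31 female,
31 male), each scanned four times (left/right foot at half and full body
weight), with demographic distributions matching a typical adult European
cohort, per-vertex Gaussian measurement noise at a scanner accuracy of
0.3 mm, random similarity pose per scan, and optional isotropic remeshing
plus vertex shuffling so correspondence recovery is genuinely exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import trimesh
from scipy.stats import truncnorm
from skimage import measure as _skmeasure

__all__ = [
    "SubjectRecord",
    "ScanRecord",
    "GeneratorConfig",
    "build_template_foot",
    "define_modes",
    "sample_cohort",
    "planted_tangent_model",
    "FACTOR_NAMES",
]

#: subject-level factor columns, in canonical order
FACTOR_NAMES = ("sex", "age", "shoe_size", "sport_hours", "bmi")

# ---------------------------------------------------------------------------
# records and configuration


@dataclass(frozen=True)
class SubjectRecord:
    """Demographics of one simulated subject.

    ``sex`` is coded 1=male, 0=female.  BMI is consistent with weight and
    height by construction (kg / (m)^2).
    """

    subject_id: str
    sex: int
    age: float
    shoe_size: float
    weight: float
    height: float
    bmi: float
    sport_hours: float


@dataclass
class ScanRecord:
    """One simulated scan: a posed, noisy, optionally remeshed foot surface.

    ``side`` is 1=right, 0=left; ``loading`` is 1=half loaded, 0=full
    loaded.  ``true_mode_weights`` are the subject's planted latent mode
    weights.  ``true_vertex_map`` holds, per template vertex, the
    ground-truth surface position of that anatomical point in the scan's
    own (posed) frame — the oracle for correspondence error.
    """

    subject_id: str
    side: int
    loading: int
    mesh: trimesh.Trimesh
    true_mode_weights: np.ndarray
    true_vertex_map: np.ndarray


@dataclass
class GeneratorConfig:
    """Study conditions for cohort simulation.

    ``mode_sds`` (mm-scale weights on unit-norm displacement fields) must be
    strictly decreasing so principal-component order is identifiable.
    ``effect_matrix`` is the ground-truth coefficient matrix B mapping
    z-scored subject factors (rows, order :data:`FACTOR_NAMES`) to mode
    weights (columns).  ``noise_sd`` is per-vertex, per-coordinate
    measurement noise (scanner accuracy).  ``pose_jitter`` is
    (rotation deg, translation mm, scale half-range).  ``asymmetry_effect``
    optionally couples z-scored factors to the bilateral asymmetry
    amplitude (length-5 vector), for planted asymmetry studies.
    """

    n_subjects: int = 62
    n_modes: int = 6
    mode_sds: tuple[float, ...] = (60.0, 45.0, 35.0, 25.0, 18.0, 12.0)
    effect_matrix: np.ndarray | None = None
    noise_sd: float = 0.3
    asymmetry_sd: float = 6.0
    loading_effect: float = 8.0
    pose_jitter: tuple[float, float, float] = (10.0, 20.0, 0.03)
    remesh: bool = False
    seed: int = 0
    resolution: int = 2500
    asymmetry_effect: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_modes > 6:
            raise ValueError("at most 6 deformation modes are defined")
        sds = np.asarray(self.mode_sds, dtype=float)[: self.n_modes]
        if len(sds) < self.n_modes or not np.all(np.diff(sds) < 0):
            raise ValueError("mode_sds must provide n_modes strictly decreasing values")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.effect_matrix is not None:
            B = np.asarray(self.effect_matrix, dtype=float)
            if B.shape != (len(FACTOR_NAMES), self.n_modes):
                raise ValueError(
                    f"effect_matrix shape {B.shape} != "
                    f"({len(FACTOR_NAMES)}, {self.n_modes})"
                )


def default_effect_matrix(
    mode_sds: Sequence[float] = GeneratorConfig.mode_sds,
) -> np.ndarray:
    """Default ground-truth factor-to-mode coefficients.

    Entries are fractions of each mode's SD, with the sign/sparsity pattern
    of the typical adult cohort: sex and shoe size load on arch height, age
    on ball width, BMI on global width and hallux angle, sport frequency on
    arch, width and midfoot.
    """
    frac = np.zeros((len(FACTOR_NAMES), 6))
    # rows: sex, age, shoe_size, sport_hours, bmi
    frac[0, 0], frac[2, 0], frac[3, 0] = 0.35, 0.30, 0.15  # mode 1: arch
    frac[0, 1], frac[1, 1] = -0.30, 0.25                   # mode 2: ball width
    frac[4, 2], frac[3, 2] = -0.50, 0.25                   # mode 3: global width
    frac[1, 3], frac[4, 3] = -0.15, -0.15                  # mode 4: hallux angle
    frac[4, 4] = 0.20                                      # mode 5: toe lengths
    frac[3, 5] = -0.25                                     # mode 6: midfoot width
    sds = np.asarray(mode_sds, dtype=float)
    return frac[:, : len(sds)] * sds[np.newaxis, :]


# ---------------------------------------------------------------------------
# template foot

# metaball layout in an unscaled design frame; the final surface is
# anisotropically stretched to a ~250 x 95 mm plantar footprint
_BLOBS = (
    ((0.0, 38.0, 26.0), (40.0, 46.0, 34.0), 1.0),   # heel
    ((-4.0, 95.0, 22.0), (36.0, 62.0, 28.0), 1.0),  # midfoot
    ((0.0, 160.0, 20.0), (48.0, 48.0, 25.0), 1.0),  # ball
    ((0.0, 42.0, 70.0), (26.0, 30.0, 55.0), 0.9),   # ankle stub
    ((-30.0, 208.0, 12.0), (13.0, 30.0, 14.0), 0.8),  # hallux
    ((-11.0, 206.0, 11.0), (10.0, 28.0, 12.0), 0.7),  # 2nd toe
    ((4.0, 200.0, 11.0), (9.0, 26.0, 12.0), 0.7),
    ((17.0, 194.0, 10.0), (9.0, 24.0, 11.0), 0.7),
    ((29.0, 187.0, 10.0), (9.0, 21.0, 11.0), 0.7),  # 5th toe
)
_ARCH_BLOB = ((-28.0, 100.0, -10.0), (30.0, 45.0, 20.0), 1.2)
_SX, _SY = 1.283, 1.131  # design-frame stretch to a ~250 x 95 mm footprint
_Z_TOP = 70.0  # flat ankle-cap height (mm)
_FIELD_SHARPNESS = 2.0


def _metaball_field(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    f = np.zeros(np.broadcast(x, y, z).shape)
    for (cx, cy, cz), (rx, ry, rz), w in _BLOBS:
        d = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2
        f += w * np.exp(-_FIELD_SHARPNESS * d)
    (cx, cy, cz), (rx, ry, rz), w = _ARCH_BLOB
    d = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2
    f -= w * np.exp(-_FIELD_SHARPNESS * d)
    return f


def _march(pitch: float) -> trimesh.Trimesh:
    iso = float(np.exp(-_FIELD_SHARPNESS))
    xs = np.arange(-62.0 * _SX, 62.0 * _SX + pitch, pitch)
    ys = np.arange(-22.0 * _SY, 262.0 * _SY + pitch, pitch)
    zs = np.arange(-pitch, _Z_TOP + 2.0 * pitch, pitch)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    F = _metaball_field(X / _SX, Y / _SY, Z)
    F[Z < 0] = 0.0        # flat plantar cap at z = 0
    F[Z > _Z_TOP] = 0.0   # flat ankle cap
    verts, faces, _, _ = _skmeasure.marching_cubes(
        F, level=iso, spacing=(pitch, pitch, pitch)
    )
    verts = verts + np.array([xs[0], ys[0], zs[0]])
    verts[:, 2] = np.clip(verts[:, 2], 0.0, _Z_TOP)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    parts = mesh.split(only_watertight=False)
    if len(parts) > 1:
        mesh = max(parts, key=lambda p: len(p.vertices))
    if mesh.volume < 0:
        mesh.invert()
    return trimesh.Trimesh(
        vertices=np.asarray(mesh.vertices, dtype=float),
        faces=np.asarray(mesh.faces, dtype=np.int64),
        process=False,
    )


def build_template_foot(resolution: int = 2500) -> trimesh.Trimesh:
    """Build the procedural reference foot surface.

    A closed, outward-oriented, foot-like surface (elongated body, heel
    bulge, five toe lobes, medial arch concavity, flat-capped ankle stub)
    of ~250 mm plantar length in the canonical frame.  ``resolution`` is a
    vertex-count target, met within ±10% by iterating the marching-cubes
    grid pitch.  Deterministic for a fixed resolution.
    """
    if resolution < 200:
        raise ValueError("resolution must be >= 200 to realize the toe lobes")
    pitch = 6.2 * np.sqrt(2500.0 / resolution)
    mesh = _march(pitch)
    for _ in range(4):
        ratio = len(mesh.vertices) / resolution
        if abs(ratio - 1.0) <= 0.08:
            break
        pitch *= np.sqrt(ratio)
        mesh = _march(pitch)
    if abs(len(mesh.vertices) / resolution - 1.0) > 0.10:
        raise RuntimeError(
            f"could not reach {resolution} vertices (got {len(mesh.vertices)})"
        )
    return mesh


# ---------------------------------------------------------------------------
# deformation modes


def _gauss(t: np.ndarray, mu: float, s: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / s) ** 2)


def define_modes(template: trimesh.Trimesh, n_modes: int = 6) -> np.ndarray:
    """Per-vertex displacement fields for up to six anatomical shape modes.

    Returns an ``(n_modes, 3V)`` array of smooth, unit-norm, mutually
    orthogonal fields (orthogonalized in mode order, so mode 1 is exactly
    its anatomical definition).  Modes: 1 arch height (positive weight
    flattens the arch), 2 ball width + toe spread, 3 global width,
    4 hallux medio-lateral rotation, 5 hallux vs second-toe length,
    6 midfoot width.
    """
    if n_modes > 6:
        raise ValueError("only six deformation modes are defined")
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    v = np.asarray(template.vertices, dtype=float)
    x, y, z = v[:, 0], v[:, 1], v[:, 2]
    L = y.max()
    W, H = 60.0, _Z_TOP
    V = len(v)
    fields = np.zeros((6, V, 3))
    # 1: arch height — lower the medial midfoot sole (positive = flat foot)
    fields[0, :, 2] = -_gauss(y / L, 0.40, 0.10) * _gauss(x / W, -0.45, 0.25) * _gauss(
        z / H, 0.15, 0.25
    )
    # 2: ball width + toe spread
    fields[1, :, 0] = (x / W) * (
        _gauss(y / L, 0.62, 0.06) + _gauss(y / L, 0.80, 0.10)
    )
    # 3: global width
    fields[2, :, 0] = x / W
    # 4: hallux rotation about a vertical axis at the hallux base
    hal = _gauss(x / W, -0.55, 0.20) * _gauss(y / L, 0.85, 0.10)
    fields[3, :, 0] = hal * (-(y - 0.72 * L) / L)
    fields[3, :, 1] = hal * ((x + 33.0) / L)
    # 5: hallux vs second-toe length
    fields[4, :, 1] = (
        _gauss(x / W, -0.55, 0.15) - _gauss(x / W, -0.20, 0.12)
    ) * _gauss(y / L, 0.85, 0.08)
    # 6: midfoot width
    fields[5, :, 0] = (x / W) * _gauss(y / L, 0.42, 0.10)

    flat = fields.reshape(6, 3 * V)
    out = np.zeros_like(flat[:n_modes])
    for k in range(n_modes):
        f = flat[k].copy()
        for j in range(k):
            f -= (f @ out[j]) * out[j]
        nrm = np.linalg.norm(f)
        if nrm < 1e-12:
            raise RuntimeError(f"mode {k + 1} degenerate after orthogonalization")
        out[k] = f / nrm
    return out


def planted_tangent_model(
    template: trimesh.Trimesh,
    modes: np.ndarray,
    mode_sds: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Expected PCA directions and SDs in Procrustes shape space.

    Superimposition removes the similarity-transform components of each
    planted mode, so what a PCA of aligned shapes can recover is the
    eigenstructure of ``sum_k sd_k^2 m'_k m'_k^T`` with ``m'_k`` the modes
    projected out of the similarity subspace at the template.  Returns
    ``(directions, sds)``: orthonormal expected components (rows, matching
    PC sign convention is NOT applied) ordered by decreasing expected SD,
    and the expected score SDs in millimetres.
    """
    from .alignment import similarity_tangent_basis

    basis = similarity_tangent_basis(np.asarray(template.vertices, float))
    proj = modes - (modes @ basis.T) @ basis
    A = np.diag(np.asarray(mode_sds, float)[: len(modes)]) @ proj
    _, s, Vt = np.linalg.svd(A, full_matrices=False)
    return Vt, s


def _side_asymmetry_field(template: trimesh.Trimesh, modes: np.ndarray) -> np.ndarray:
    """Unit-norm bilateral-asymmetry field, orthogonal to the shape modes.

    A smooth lateral bend of the forefoot plus a heel-width change —
    plausible left/right differences that are not one of the six modes.
    """
    v = np.asarray(template.vertices, dtype=float)
    x, y, z = v[:, 0], v[:, 1], v[:, 2]
    L = y.max()
    f = np.zeros_like(v)
    f[:, 0] = _gauss(y / L, 0.85, 0.12) * 1.0 + (x / 60.0) * _gauss(y / L, 0.12, 0.10)
    f[:, 2] = 0.4 * _gauss(y / L, 0.55, 0.15) * np.sign(x)
    flat = f.reshape(-1)
    for m in modes:
        flat = flat - (flat @ m) * m
    return flat / np.linalg.norm(flat)


def _loading_field(modes: np.ndarray) -> np.ndarray:
    """Arch-flattening field applied under load (the mode-1 direction)."""
    return modes[0]


def _truncnorm(rng: np.random.Generator, mu, sd, lo, hi, size) -> np.ndarray:
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def _sample_factors(rng: np.random.Generator, n: int) -> list[SubjectRecord]:
    sex = np.zeros(n, dtype=int)
    sex[n // 2 :] = 1  # equal split (extra subject female if n is odd)
    age = _truncnorm(rng, 38.9, 13.5, 18.0, 60.0, n)
    shoe = np.where(
        sex == 1,
        _truncnorm(rng, 43.9, 1.6, 36.0, 46.0, n),
        _truncnorm(rng, 39.8, 2.2, 36.0, 46.0, n),
    )
    height = _truncnorm(rng, 175.0, 9.3, 156.0, 196.0, n)
    # BMI correlated with age (rho ~ 0.35), resampled into the healthy range
    z_age = (age - age.mean()) / age.std() if n > 1 and age.std() > 0 else np.zeros(n)
    bmi = np.empty(n)
    for i in range(n):
        while True:
            b = 23.7 + 3.5 * (0.35 * z_age[i] + np.sqrt(1 - 0.35**2) * rng.standard_normal())
            if 18.6 <= b <= 35.8:
                bmi[i] = b
                break
    weight = bmi * (height / 100.0) ** 2
    sport = _truncnorm(rng, 3.7, 4.1, 0.0, 15.0, n)
    return [
        SubjectRecord(
            subject_id=f"S{i:03d}",
            sex=int(sex[i]),
            age=float(age[i]),
            shoe_size=float(shoe[i]),
            weight=float(weight[i]),
            height=float(height[i]),
            bmi=float(bmi[i]),
            sport_hours=float(sport[i]),
        )
        for i in range(n)
    ]


def subjects_to_matrix(subjects: Sequence[SubjectRecord]) -> np.ndarray:
    """Stack subject factors into an (n_subjects, 5) array (FACTOR_NAMES order)."""
    return np.array(
        [[s.sex, s.age, s.shoe_size, s.sport_hours, s.bmi] for s in subjects],
        dtype=float,
    )


def _zscore(a: np.ndarray) -> np.ndarray:
    if len(a) < 2:
        return np.zeros_like(a)
    sd = a.std(axis=0, ddof=1)
    sd = np.where(~np.isfinite(sd) | (sd == 0), 1.0, sd)
    return (a - a.mean(axis=0)) / sd


def _random_pose(
    rng: np.random.Generator, jitter: tuple[float, float, float]
) -> tuple[np.ndarray, np.ndarray, float]:
    rot_deg, trans_mm, scale_half = jitter
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-rot_deg, rot_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t = rng.uniform(-trans_mm, trans_mm, size=3)
    s = 1.0 + rng.uniform(-scale_half, scale_half)
    return R, t, s


def _remesh(
    vertices: np.ndarray,
    faces: np.ndarray,
    rng: np.random.Generator,
    cell: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic re-sampling: subdivide, then vertex-cluster on a shifted grid.

    Produces a mesh with different vertex count and connectivity; vertex
    order is additionally shuffled by the caller.
    """
    v, f = trimesh.remesh.subdivide_to_size(vertices, faces, max_edge=1.5 * cell)
    offset = rng.uniform(0.0, cell, size=3)
    keys = np.floor((v + offset) / cell).astype(np.int64)
    _, inverse, counts = np.unique(
        keys, axis=0, return_inverse=True, return_counts=True
    )
    new_v = np.zeros((len(counts), 3))
    np.add.at(new_v, inverse, v)
    new_v /= counts[:, None]
    new_f = inverse[f]
    ok = (
        (new_f[:, 0] != new_f[:, 1])
        & (new_f[:, 1] != new_f[:, 2])
        & (new_f[:, 0] != new_f[:, 2])
    )
    new_f = new_f[ok]
    # drop duplicate faces (same vertex triple in any order)
    key = np.sort(new_f, axis=1)
    _, first = np.unique(key, axis=0, return_index=True)
    new_f = new_f[np.sort(first)]
    m = trimesh.Trimesh(vertices=new_v, faces=new_f, process=False)
    m.remove_unreferenced_vertices()
    return np.asarray(m.vertices, dtype=float), np.asarray(m.faces, dtype=np.int64)


def sample_cohort(
    config: GeneratorConfig,
    template: trimesh.Trimesh | None = None,
    modes: np.ndarray | None = None,
) -> tuple[list[SubjectRecord], list[ScanRecord]]:
    """Simulate a cohort of subjects with four scans each.

    Scan vertices are ``template + sum_k w_k mode_k + side asymmetry +
    loading arch-flattening + N(0, noise_sd)`` followed by a random
    similarity pose (and optional remeshing + vertex shuffling).  Mode
    weights are ``B_true^T z + residual`` with z-scored factors; residuals
    are rescaled so each mode's realized weight SD equals the configured
    ``mode_sds`` exactly (moment-matched sampling).  Ground truth (weights
    and template-ordered posed positions) is stored per scan.

    Passing a prebuilt ``template``/``modes`` avoids rebuilding them; they
    must come from :func:`build_template_foot` / :func:`define_modes` with
    matching resolution and n_modes.
    """
    rng = np.random.default_rng(config.seed)
    if template is None:
        template = build_template_foot(config.resolution)
    if modes is None:
        modes = define_modes(template, config.n_modes)
    V = len(template.vertices)
    tmpl = np.asarray(template.vertices, dtype=float)
    faces = np.asarray(template.faces, dtype=np.int64)
    asym_field = _side_asymmetry_field(template, modes).reshape(V, 3)
    load_field = _loading_field(modes).reshape(V, 3)

    subjects = _sample_factors(rng, config.n_subjects)
    Z = _zscore(subjects_to_matrix(subjects))
    sds = np.asarray(config.mode_sds, dtype=float)[: config.n_modes]
    B = (
        np.asarray(config.effect_matrix, dtype=float)
        if config.effect_matrix is not None
        else default_effect_matrix(sds)[:, : config.n_modes]
    )
    if B.shape != (len(FACTOR_NAMES), config.n_modes):
        raise ValueError(
            f"effect_matrix shape {B.shape} != ({len(FACTOR_NAMES)}, {config.n_modes})"
        )

    signal = Z @ B  # (n_subjects, n_modes)
    resid = rng.standard_normal((config.n_subjects, config.n_modes))
    if config.n_subjects > config.n_modes + len(FACTOR_NAMES) + 1:
        resid = resid - resid.mean(axis=0)
        # decorrelate residual weights from the factors so zero entries of
        # the effect matrix mean exactly zero sample association
        proj, *_ = np.linalg.lstsq(Z, resid, rcond=None)
        resid = resid - Z @ proj
        # per-mode residual scaling so realized weight SD == configured SD
        W = np.empty_like(signal)
        for k in range(config.n_modes):
            s, e = signal[:, k], resid[:, k]
            vs = s.var(ddof=1)
            ve = e.var(ddof=1)
            cov = np.cov(s, e, ddof=1)[0, 1]
            # solve vs + 2 c cov + c^2 ve = sd^2 for c >= 0
            disc = cov**2 - ve * (vs - sds[k] ** 2)
            if ve < 1e-12 or disc < 0:
                raise ValueError(
                    f"effect_matrix too strong for mode_sds[{k}]={sds[k]}"
                )
            c = (-cov + np.sqrt(disc)) / ve
            W[:, k] = s + c * e
        # whiten to the exact target covariance diag(sds^2): removes sample
        # cross-mode covariance so planted and recovered spectra align
        cov_w = np.cov(W, rowvar=False, ddof=1)
        T = np.linalg.solve(
            np.linalg.cholesky(cov_w).T, np.diag(sds)
        )
        W = W @ T
    else:
        W = signal + resid * sds

    asym_amp = rng.normal(0.0, config.asymmetry_sd, size=config.n_subjects)
    if config.asymmetry_effect is not None:
        ae = np.asarray(config.asymmetry_effect, dtype=float)
        if ae.shape != (len(FACTOR_NAMES),):
            raise ValueError("asymmetry_effect must have length 5")
        asym_amp = asym_amp + Z @ ae

    scans: list[ScanRecord] = []
    for i, subj in enumerate(subjects):
        deform = tmpl + (W[i] @ modes).reshape(V, 3)
        for side in (0, 1):
            for loading in (0, 1):
                clean = deform.copy()
                if side == 1:
                    clean = clean + asym_amp[i] * asym_field
                if loading == 1:
                    clean = clean - config.loading_effect * load_field
                noisy = clean + rng.normal(0.0, config.noise_sd, size=(V, 3))
                R, t, s = _random_pose(rng, config.pose_jitter)
                posed = (s * noisy) @ R.T + t
                true_map = (s * clean) @ R.T + t
                if config.remesh:
                    rv, rf = _remesh(posed, faces, rng)
                    perm = rng.permutation(len(rv))
                    inv = np.empty_like(perm)
                    inv[perm] = np.arange(len(rv))
                    mesh = trimesh.Trimesh(
                        vertices=rv[perm], faces=inv[rf], process=False
                    )
                else:
                    mesh = trimesh.Trimesh(
                        vertices=posed, faces=faces, process=False
                    )
                scans.append(
                    ScanRecord(
                        subject_id=subj.subject_id,
                        side=side,
                        loading=loading,
                        mesh=mesh,
                        true_mode_weights=W[i].copy(),
                        true_vertex_map=true_map,
                    )
                )
    return subjects, scans
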