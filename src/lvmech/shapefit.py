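"""Fitting the idealized shape family to images and surface clouds.

Two fitting problems are solved here:

* **image fitting** — recover the six shape parameters (plus a rigid pose)
  from a labeled cavity/wall voxel image by minimizing the two-class overlap
  functional ``J = 1 - (Jaccard_cavity + Jaccard_wall)/2`` with Nelder-Mead;
  before every evaluation the candidate is rigidly aligned to the target by
  matching long axes (total-least-squares line through slice centroids) and
  centers of gravity;

* **surface re-parameterization** — recover the parameters of a deformed
  configuration from epicardial/endocardial point clouds by an alternating
  two-block minimization of the mean point-to-profile distance: block 1 fits
  {R_b, Z, e, psi0} on the epicardial cloud, block 2 fits {L, H} on the
  endocardial cloud, iterated to convergence.  This is how forward-solver
  outputs are mapped back into the 6-parameter family.

A synthetic label-image generator (voxelization plus seeded boundary label
noise) stands in for segmented short-axis cine-MRI stacks, whose
characteristic anisotropic voxels are about 1.36 x 1.36 x 8.8 mm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .geometry import (
    LVGeometry,
    RigidPose,
    _auto_extent,
    _profiles,
    body_centroid,
    voxelize,
)
from .image import LabelImage

__all__ = [
    "SurfaceSamples",
    "similarity_J",
    "dice",
    "estimate_long_axis",
    "fit_to_image",
    "fit_to_surfaces",
    "generate_label_image",
    "sample_surfaces",
    "FitResult",
]

#: Typical short-axis cine-MRI voxel size (mm): in-plane x in-plane x slice.
MRI_SPACING = (1.36, 1.36, 8.8)


@dataclass(frozen=True)
class SurfaceSamples:
    """Epicardial / endocardial point clouds (mm, canonical pose)."""

    epi_points: np.ndarray | None
    endo_points: np.ndarray | None

    def __post_init__(self) -> None:
        for name in ("epi_points", "endo_points"):
            pts = getattr(self, name)
            if pts is not None:
                pts = np.asarray(pts, dtype=float).reshape(-1, 3)
                if pts.size == 0 or not np.isfinite(pts).all():
                    raise ValueError(f"{name} must be nonempty and finite")
                object.__setattr__(self, name, pts)
        if self.epi_points is None and self.endo_points is None:
            raise ValueError("at least one cloud is required")


@dataclass(frozen=True)
class FitResult:
    geometry: LVGeometry
    pose: RigidPose
    score: float
    converged: bool


# ---------------------------------------------------------------------------
# overlap metrics
# ---------------------------------------------------------------------------

def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = np.count_nonzero(a | b)
    if union == 0:
        warnings.warn("empty union for one label class; Jaccard set to 0",
                      stacklevel=3)
        return 0.0
    return np.count_nonzero(a & b) / union


def similarity_J(img_a: LabelImage, img_b: LabelImage) -> float:
    """Two-class dissimilarity: 1 - (Jaccard_cavity + Jaccard_wall)/2.

    0 for identical images, 1 for fully disjoint label sets; both images must
    live on the same voxel grid.
    """
    if not img_a.same_grid(img_b):
        raise ValueError("images must share shape, spacing and origin")
    j_cav = _jaccard(img_a.voxels == 1, img_b.voxels == 1)
    j_wall = _jaccard(img_a.voxels == 2, img_b.voxels == 2)
    return 1.0 - 0.5 * (j_cav + j_wall)


def dice(geom_a: LVGeometry, geom_b: LVGeometry, spacing: float = 1.0) -> float:
    """Wall-label Dice overlap of two shapes, voxelized in canonical pose.

    Both geometries are rasterized on a common bounding grid at the given
    isotropic spacing; Dice = 2|Wa n Wb| / (|Wa| + |Wb|).
    """
    exts, origs = zip(*(_auto_extent(g) for g in (geom_a, geom_b)))
    lo = np.minimum(*origs)
    hi = np.maximum(*(o + e for o, e in zip(origs, exts)))
    kw = dict(spacing=spacing, extent=hi - lo, origin=lo)
    wa = voxelize(geom_a, **kw).voxels == 2
    wb = voxelize(geom_b, **kw).voxels == 2
    na, nb = np.count_nonzero(wa), np.count_nonzero(wb)
    if na == 0 or nb == 0:
        raise ValueError("empty wall label in one of the images")
    return 2.0 * np.count_nonzero(wa & wb) / (na + nb)


# ---------------------------------------------------------------------------
# rigid pre-alignment
# ---------------------------------------------------------------------------

def estimate_long_axis(img: LabelImage) -> tuple:
    """Long axis of a segmented ventricle: TLS line through slice centroids.

    Returns ``(direction, centroid)``: a unit vector oriented base -> apex
    (label area decreases toward the apex) and the center of gravity (mm)
    of all labeled voxels.
    """
    lab = img.voxels > 0
    nz = [k for k in range(lab.shape[2]) if lab[:, :, k].any()]
    if len(nz) < 2:
        raise ValueError("need at least 2 nonempty axial slices")
    centers = img.voxel_centers()
    cents, areas = [], []
    for k in nz:
        m = lab[:, :, k]
        cents.append(centers[:, :, k][m].mean(axis=0))
        areas.append(int(np.count_nonzero(m)))
    cents = np.asarray(cents)
    areas = np.asarray(areas, dtype=float)
    mean = cents.mean(axis=0)
    _, _, vt = np.linalg.svd(cents - mean)
    d = vt[0] / np.linalg.norm(vt[0])
    centroid = centers[lab].mean(axis=0)
    # slice centroids of a tilted, tapering body are biased off-axis; the
    # principal inertia axis of the labeled voxels is exact for an
    # axisymmetric body, so refine with the inertia eigenvector closest to
    # the centroid-line direction
    pts = centers[lab] - centroid
    cov = pts.T @ pts / len(pts)
    _, vecs = np.linalg.eigh(cov)
    k = int(np.argmax(np.abs(vecs.T @ d)))
    d = vecs[:, k] / np.linalg.norm(vecs[:, k])
    # orient base -> apex: area should decrease along +d
    proj = (cents - mean) @ d
    if np.polyfit(proj, areas, 1)[0] > 0:
        d = -d
    return d, centroid


def _rotation_to(v: np.ndarray) -> np.ndarray:
    """Proper rotation taking +z to the unit vector v (Rodrigues)."""
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    c = float(z @ v)
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(z, v)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def _aligned_pose(geom: LVGeometry, axis_ba: np.ndarray,
                  centroid: np.ndarray) -> RigidPose:
    """Pose matching the canonical long axis and center of gravity."""
    R = _rotation_to(-axis_ba)  # canonical +zeta is apex -> base
    t = centroid - R @ body_centroid(geom)
    return RigidPose(translation=t, rotation=R)


# ---------------------------------------------------------------------------
# image fitting
# ---------------------------------------------------------------------------

_FIT_SCALES = np.array([10.0, 10.0, 5.0, 5.0, 0.2, 0.2])  # R_b Z L H e psi0


def _candidate_geom(x: np.ndarray) -> LVGeometry | None:
    R_b, Z, L, H, e, psi0 = x
    if not (R_b > L + 0.5 and L > 0.2 and Z > H + 0.5 and H > 0.2
            and 0.0 <= e <= 1.0 and -1.55 < psi0 < -0.005):
        return None
    return LVGeometry(R_b=R_b, Z=Z, L=L, H=H, e=e, psi0=psi0)


def fit_to_image(
    img: LabelImage,
    init: LVGeometry | None = None,
    n_restarts: int = 3,
    seed: int | None = None,
    maxiter: int = 400,
) -> FitResult:
    """Fit the 6-parameter family to a labeled image (Nelder-Mead).

    Every candidate is rigidly pre-aligned to the target (long axes and
    centers of gravity made coincident) before the overlap functional is
    evaluated.  Restarts perturb the initial guess by 10 % of the parameter
    scales; the best result is returned, flagged ``converged=False`` if no
    restart met the simplex tolerance.
    """
    if not ((img.voxels == 1).any() and (img.voxels == 2).any()):
        raise ValueError("image must contain both cavity and wall labels")
    axis_ba, centroid = estimate_long_axis(img)
    grid_kw = dict(
        spacing=img.spacing,
        extent=img.spacing * np.array(img.voxels.shape),
        origin=img.origin,
        allow_clip=True,
    )
    if init is None:
        from .datasets import population_stats

        mean, _ = population_stats(phase="EoD")
        init = LVGeometry.from_array(mean)

    def objective(y: np.ndarray) -> float:
        g = _candidate_geom(y * _FIT_SCALES)
        if g is None:
            return 2.0
        pose = _aligned_pose(g, axis_ba, centroid)
        cand = voxelize(g, pose=pose, **grid_kw)
        return similarity_J(cand, img)

    rng = np.random.default_rng(seed)
    y0 = init.as_array() / _FIT_SCALES
    best = None
    for k in range(1 + n_restarts):
        start = y0 if k == 0 else y0 + rng.normal(0, 0.1, size=6)
        res = optimize.minimize(
            objective, start, method="Nelder-Mead",
            options=dict(maxiter=maxiter, fatol=1e-3, xatol=1e-3),
        )
        if best is None or res.fun < best.fun:
            best = res
        if best.fun < 1e-6:
            break
    g = _candidate_geom(best.x * _FIT_SCALES)
    if g is None:  # pragma: no cover - optimizer stayed in the invalid region
        raise RuntimeError("image fit did not produce a valid geometry")
    if not best.success:
        warnings.warn("image fit did not fully converge; returning best-so-far",
                      stacklevel=2)
    return FitResult(
        geometry=g,
        pose=_aligned_pose(g, axis_ba, centroid),
        score=float(best.fun),
        converged=bool(best.success),
    )


# ---------------------------------------------------------------------------
# surface re-parameterization
# ---------------------------------------------------------------------------

def sample_surfaces(
    geom: LVGeometry, n_psi: int = 48, n_theta: int = 16
) -> SurfaceSamples:
    """Sample both boundary surfaces of a shape (canonical pose)."""
    psi = np.linspace(geom.psi0, math.pi / 2 - 1e-3, n_psi)
    theta = np.linspace(0, 2 * math.pi, n_theta, endpoint=False)
    re, ze, rn, zn = _profiles(geom, psi)
    P, TH = np.meshgrid(psi, theta, indexing="ij")
    out = []
    for r, z in ((re, ze), (rn, zn)):
        R, _ = np.meshgrid(r, theta, indexing="ij")
        Zc, _ = np.meshgrid(z, theta, indexing="ij")
        out.append(
            np.stack([R * np.cos(TH), R * np.sin(TH), Zc], axis=-1).reshape(-1, 3)
        )
    return SurfaceSamples(epi_points=out[0], endo_points=out[1])


def _mean_profile_distance(pts: np.ndarray, rho_c: np.ndarray,
                           zeta_c: np.ndarray) -> float:
    """Mean distance of points (in the rho-zeta half-plane) to a profile."""
    rho = np.hypot(pts[:, 0], pts[:, 1])
    zeta = pts[:, 2]
    d2 = (rho[:, None] - rho_c[None, :]) ** 2 + (zeta[:, None] - zeta_c[None, :]) ** 2
    j = np.argmin(d2, axis=1)
    n = rho_c.size
    # parabolic refinement on the discrete minimum
    jm = np.clip(j, 1, n - 2)
    d0 = d2[np.arange(len(j)), jm - 1]
    d1 = d2[np.arange(len(j)), jm]
    d2v = d2[np.arange(len(j)), jm + 1]
    denom = d0 - 2 * d1 + d2v
    shift = np.where(np.abs(denom) > 1e-30, 0.5 * (d0 - d2v) / np.where(denom == 0, 1, denom), 0.0)
    shift = np.clip(shift, -1, 1)
    d_min = d1 - 0.25 * (d0 - d2v) * shift
    d_min = np.where(j == np.clip(j, 1, n - 2), d_min, d2[np.arange(len(j)), j])
    return float(np.sqrt(np.maximum(d_min, 0.0)).mean())


def _profile_curves(geom: LVGeometry, n: int = 384):
    psi = np.linspace(geom.psi0, math.pi / 2, n)
    return _profiles(geom, psi)


def _symmetric_profile_distance(pts: np.ndarray, rho_c: np.ndarray,
                                zeta_c: np.ndarray) -> float:
    """Bidirectional mean cloud/profile distance in the rho-zeta plane.

    The reverse term (curve sample -> nearest cloud point) makes the
    truncation angle identifiable: a candidate profile extending past the
    cloud's basal rim pays for the uncovered curve segment.  Root-mean-square
    averaging keeps the objective well curved near the optimum.
    """
    d_fwd = _mean_profile_distance(pts, rho_c, zeta_c)
    rho = np.hypot(pts[:, 0], pts[:, 1])
    zeta = pts[:, 2]
    d2 = (rho_c[:, None] - rho[None, :]) ** 2 + (zeta_c[:, None] - zeta[None, :]) ** 2
    d_rev = float(np.sqrt(d2.min(axis=1).mean()))
    return d_fwd + d_rev


def fit_to_surfaces(
    samples: SurfaceSamples,
    init: LVGeometry,
    max_alternations: int = 20,
    tol: float = 1e-3,
    monolithic: bool = False,
) -> LVGeometry:
    """Alternating two-block fit of the shape family to surface clouds.

    Block 1 adjusts {R_b, Z, e, psi0} against the epicardial cloud; block 2
    adjusts {L, H} against the endocardial cloud; the blocks alternate until
    the relative parameter change falls below ``tol``.  With only one cloud
    supplied the other block is skipped and its parameters retain the
    initial values.  ``monolithic=True`` instead optimizes all six
    parameters at once on the sum of the two cloud distances.
    """
    x = init.as_array()

    def epi_dist(x6):
        g = _candidate_geom(x6)
        if g is None:
            return 1e6
        re, ze, _, _ = _profile_curves(g)
        return _symmetric_profile_distance(samples.epi_points, re, ze)

    def endo_dist(x6):
        g = _candidate_geom(x6)
        if g is None:
            return 1e6
        _, _, rn, zn = _profile_curves(g)
        return _symmetric_profile_distance(samples.endo_points, rn, zn)

    if monolithic:
        def total(y):
            x6 = y * _FIT_SCALES
            d = 0.0
            if samples.epi_points is not None:
                d += epi_dist(x6)
            if samples.endo_points is not None:
                d += endo_dist(x6)
            return d

        res = optimize.minimize(
            total, x / _FIT_SCALES, method="Nelder-Mead",
            options=dict(maxiter=2000, fatol=1e-8, xatol=1e-6),
        )
        g = _candidate_geom(res.x * _FIT_SCALES)
        if g is None:
            raise RuntimeError("surface fit left the feasible region")
        return g

    idx1 = [0, 1, 4, 5]  # R_b, Z, e, psi0
    idx2 = [2, 3]        # L, H
    for _ in range(max_alternations):
        x_prev = x.copy()
        if samples.epi_points is not None:
            def block1(sub):
                x6 = x.copy()
                x6[idx1] = sub * _FIT_SCALES[idx1]
                return epi_dist(x6)

            res = optimize.minimize(
                block1, x[idx1] / _FIT_SCALES[idx1], method="Nelder-Mead",
                options=dict(maxiter=800, fatol=1e-9, xatol=1e-7),
            )
            x[idx1] = res.x * _FIT_SCALES[idx1]
        if samples.endo_points is not None:
            def block2(sub):
                x6 = x.copy()
                x6[idx2] = sub * _FIT_SCALES[idx2]
                return endo_dist(x6)

            res = optimize.minimize(
                block2, x[idx2] / _FIT_SCALES[idx2], method="Nelder-Mead",
                options=dict(maxiter=400, fatol=1e-9, xatol=1e-7),
            )
            x[idx2] = res.x * _FIT_SCALES[idx2]
        rel = np.abs(x - x_prev) / np.maximum(np.abs(x_prev), 1e-6)
        if rel.max() < tol:
            break
    else:
        warnings.warn("surface fit: alternation limit reached; best-so-far",
                      stacklevel=2)
    g = _candidate_geom(x)
    if g is None:
        raise RuntimeError("surface fit left the feasible region")
    return g


# ---------------------------------------------------------------------------
# synthetic label images
# ---------------------------------------------------------------------------

def generate_label_image(
    xi_true: LVGeometry,
    pose: RigidPose | None = None,
    spacing=MRI_SPACING,
    label_noise_rate: float = 0.0,
    seed: int | None = None,
) -> LabelImage:
    """Voxelize a shape and corrupt boundary labels at the given rate.

    Only voxels with at least one differently-labeled 6-neighbor are
    eligible; each flips independently with probability
    ``label_noise_rate`` to the label of one of its differing neighbors
    (segmentation-style boundary uncertainty).  Reproducible via ``seed``.
    """
    if not (0.0 <= label_noise_rate <= 1.0):
        raise ValueError("label_noise_rate must be in [0, 1]")
    img = voxelize(xi_true, pose=pose, spacing=spacing)
    if label_noise_rate == 0.0:
        return img
    lab = img.voxels.copy()
    rng = np.random.default_rng(seed)

    # neighbor labels along the 6 axis directions (edge-padded)
    neighbors = []
    for axis in range(3):
        for shift in (1, -1):
            rolled = np.roll(lab, shift, axis=axis)
            sl = [slice(None)] * 3
            sl[axis] = 0 if shift == 1 else -1
            rolled[tuple(sl)] = lab[tuple(sl)]
            neighbors.append(rolled)
    neighbors = np.stack(neighbors)
    differs = neighbors != lab[None]
    boundary = differs.any(axis=0)

    flip = boundary & (rng.random(lab.shape) < label_noise_rate)
    idx = np.argwhere(flip)
    for i, j, k in idx:
        choices = neighbors[:, i, j, k][differs[:, i, j, k]]
        lab[i, j, k] = rng.choice(choices)
    return LabelImage(voxels=lab, spacing=img.spacing, origin=img.origin)
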