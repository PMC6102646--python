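"""Analytic truncated-prolate-spheroid left-ventricle shape family.

The left ventricle is idealized as an axisymmetric solid of revolution whose
endocardial and epicardial profiles are generated from a single angle variable
``psi`` running from the truncation angle ``psi0`` (base) to ``pi/2`` (apex):

    rho_epi(psi)  = R_b  * [e*cos(psi) + (1 - e)*(1 - sin(psi))]
    zeta_epi(psi) = Z * (1 - sin(psi))
    rho_end(psi)  = (R_b - L) * [e*cos(psi) + (1 - e)*(1 - sin(psi))]
    zeta_end(psi) = (Z - H) * (1 - sin(psi)) + H

Six parameters define a shape: ``R_b`` outer basal radius (mm), ``Z`` outer
longitudinal semi-axis (mm), ``L``/``H`` basal/apical wall thickness (mm),
``e`` sphericity (dimensionless, 1 = ellipsoid of revolution) and ``psi0``
the truncation angle (radians, negative in all database cases).

Canonical pose: the epicardial apex sits at the origin, the long axis is +zeta
(apex -> base) and the basal plane lies at ``zeta_base = Z*(1 - sin(psi0))``.
All internal computation happens in this pose; a :class:`RigidPose` is applied
only at image interfaces.

Conventions for closing the open base (the source geometry only defines the
two profiles):

* the *wall* is the image of the transmural chart — the linear blend between
  endocardial and epicardial profiles at equal ``psi`` — whose basal boundary
  is the straight chord between the two profile rims;
* the *cavity* is the endocardial solid of revolution extended by a cylinder
  at the endocardial rim radius up to the basal plane (a flat cap at
  ``zeta_base``);
* the thin sliver between the chord and the basal plane belongs to neither
  region.  This keeps analytic wall volume and quadrature weights mutually
  consistent.

Units: mm for lengths, ml for volumes (1 ml = 1000 mm^3), radians internally.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .image import LabelImage

__all__ = [
    "LVGeometry",
    "RigidPose",
    "MaterialCoordinate",
    "ProfilePoint",
    "FiberFrame",
    "QuadratureGrid",
    "PARAM_NAMES",
    "evaluate_profile",
    "point",
    "cavity_volume",
    "wall_volume",
    "fiber_frame",
    "make_quadrature",
    "region_mask",
    "classify_points",
    "voxelize",
]

#: Canonical ordering of the six shape parameters.
PARAM_NAMES = ("R_b", "Z", "L", "H", "e", "psi0")

_GL_NODES = 96  # fixed Gauss-Legendre order for profile integrals


@dataclass(frozen=True)
class LVGeometry:
    """Six-parameter idealized LV shape.

    The constructor enforces only cheap pointwise bounds (positivity of the
    outer axes, ``e`` in [0, 1], ``|psi0| < pi/2``) so that samplers may
    construct candidate shapes freely; the full feasibility screen (wall
    thinner than the radius, minimum cavity size, ...) lives in
    :func:`lvmech.design.is_feasible`.
    """

    R_b: float
    Z: float
    L: float
    H: float
    e: float
    psi0: float

    def __post_init__(self) -> None:
        if not (self.R_b > 0 and self.Z > 0):
            raise ValueError("outer semi-axes R_b and Z must be positive")
        if self.L < 0 or self.H < 0:
            raise ValueError("wall thicknesses L, H must be nonnegative")
        if not (-1e-9 <= self.e <= 1 + 1e-9):
            raise ValueError(f"sphericity e={self.e} outside [0, 1]")
        if not (-math.pi / 2 < self.psi0 < math.pi / 2):
            raise ValueError(f"truncation angle psi0={self.psi0} outside (-pi/2, pi/2)")

    # -- parameter-vector interface -------------------------------------
    def as_array(self) -> np.ndarray:
        return np.array([self.R_b, self.Z, self.L, self.H, self.e, self.psi0])

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "LVGeometry":
        x = np.asarray(x, dtype=float)
        return cls(*(float(v) for v in x))

    def replace(self, **kw) -> "LVGeometry":
        return dataclasses.replace(self, **kw)

    # -- derived scalars -------------------------------------------------
    @property
    def zeta_base(self) -> float:
        """Height of the basal plane (epicardial truncation)."""
        return self.Z * (1.0 - math.sin(self.psi0))

    @property
    def zeta_rim(self) -> float:
        """Height of the endocardial rim (endo profile at psi0)."""
        return (self.Z - self.H) * (1.0 - math.sin(self.psi0)) + self.H

    @property
    def rho_rim(self) -> float:
        """Endocardial rim radius."""
        return float(_profile_factor(self, self.psi0) * (self.R_b - self.L))

    def validate(self) -> None:
        """Raise if the shape violates the family's strict invariants."""
        if not self.R_b > self.L > 0:
            raise ValueError("requires R_b > L > 0")
        if not self.Z > self.H > 0:
            raise ValueError("requires Z > H > 0")
        if cavity_volume(self) <= 0:
            raise ValueError("cavity volume must be positive")


@dataclass(frozen=True)
class RigidPose:
    """Rigid placement of a canonical-pose shape into image space."""

    translation: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(3)
    )
    rotation: np.ndarray = dataclasses.field(
        default_factory=lambda: np.eye(3)
    )

    def __post_init__(self) -> None:
        t = np.asarray(self.translation, dtype=float).reshape(3)
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "rotation", r)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts) @ self.rotation.T + self.translation

    def inverse_apply(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts) - self.translation) @ self.rotation


@dataclass(frozen=True)
class MaterialCoordinate:
    """Chart coordinate (psi, t, theta); t=0 endocardium, t=1 epicardium."""

    psi: float
    t: float
    theta: float


@dataclass(frozen=True)
class ProfilePoint:
    rho_epi: float
    zeta_epi: float
    rho_end: float
    zeta_end: float


@dataclass(frozen=True)
class FiberFrame:
    """Orthonormal right-handed (fiber, sheet, sheet-normal) triad."""

    f: np.ndarray
    s: np.ndarray
    n: np.ndarray


# ---------------------------------------------------------------------------
# profile and chart evaluation (vectorized internals)
# ---------------------------------------------------------------------------

def _profile_factor(geom: LVGeometry, psi) -> np.ndarray:
    psi = np.asarray(psi, dtype=float)
    return geom.e * np.cos(psi) + (1.0 - geom.e) * (1.0 - np.sin(psi))


def _profiles(geom: LVGeometry, psi):
    """Vectorized profile coordinates (rho_epi, zeta_epi, rho_end, zeta_end)."""
    psi = np.asarray(psi, dtype=float)
    g = _profile_factor(geom, psi)
    one_minus_sin = 1.0 - np.sin(psi)
    rho_epi = geom.R_b * g
    zeta_epi = geom.Z * one_minus_sin
    rho_end = (geom.R_b - geom.L) * g
    zeta_end = (geom.Z - geom.H) * one_minus_sin + geom.H
    return rho_epi, zeta_epi, rho_end, zeta_end


def evaluate_profile(geom: LVGeometry, psi: float) -> ProfilePoint:
    """Evaluate the two boundary profiles at angle ``psi`` (radians).

    Raises ``ValueError`` when ``psi`` lies outside ``[psi0, pi/2]``.
    """
    if not (geom.psi0 - 1e-12 <= psi <= math.pi / 2 + 1e-12):
        raise ValueError(f"psi={psi} outside [psi0={geom.psi0}, pi/2]")
    re, ze, rn, zn = _profiles(geom, psi)
    return ProfilePoint(float(re), float(ze), float(rn), float(zn))


def _chart(geom: LVGeometry, psi, t, theta) -> np.ndarray:
    """Transmural linear blend of the two profiles -> 3-D points (..., 3)."""
    psi, t, theta = np.broadcast_arrays(
        np.asarray(psi, float), np.asarray(t, float), np.asarray(theta, float)
    )
    re, ze, rn, zn = _profiles(geom, psi)
    rho = (1.0 - t) * rn + t * re
    zeta = (1.0 - t) * zn + t * ze
    return np.stack([rho * np.cos(theta), rho * np.sin(theta), zeta], axis=-1)


def point(geom: LVGeometry, q: MaterialCoordinate) -> np.ndarray:
    """3-D position of a material coordinate in canonical pose (mm)."""
    if not (geom.psi0 - 1e-12 <= q.psi <= math.pi / 2 + 1e-12):
        raise ValueError("psi outside [psi0, pi/2]")
    if not (-1e-12 <= q.t <= 1 + 1e-12):
        raise ValueError("transmural fraction t outside [0, 1]")
    return _chart(geom, q.psi, q.t, q.theta).reshape(3)


def chart_jacobian_analytic(geom: LVGeometry, psi, t, theta, trig=None) -> np.ndarray:
    """Closed-form chart Jacobian (..., 3, 3); equals the central-difference
    version to ~1e-10 and is used in solver hot paths.

    ``trig`` optionally carries precomputed (cos psi, sin psi, cos theta,
    sin theta) arrays for repeated evaluation on a fixed grid.
    """
    psi = np.asarray(psi, dtype=float)
    t = np.asarray(t, dtype=float)
    if trig is None:
        theta = np.asarray(theta, dtype=float)
        cos_psi, sin_psi = np.cos(psi), np.sin(psi)
        cos_t, sin_t = np.cos(theta), np.sin(theta)
    else:
        cos_psi, sin_psi, cos_t, sin_t = trig
    e = geom.e
    g = e * cos_psi + (1.0 - e) * (1.0 - sin_psi)
    gp = -e * sin_psi - (1.0 - e) * cos_psi
    m = (geom.R_b - geom.L) + t * geom.L
    a = (geom.Z - geom.H) + t * geom.H
    rho = m * g
    rho_psi = m * gp
    rho_t = geom.L * g
    zeta_psi = -a * cos_psi
    zeta_t = -geom.H * sin_psi
    J = np.empty(np.broadcast(psi, t, cos_t).shape + (3, 3))
    J[..., 0, 0] = rho_psi * cos_t
    J[..., 0, 1] = rho_t * cos_t
    J[..., 0, 2] = -rho * sin_t
    J[..., 1, 0] = rho_psi * sin_t
    J[..., 1, 1] = rho_t * sin_t
    J[..., 1, 2] = rho * cos_t
    J[..., 2, 0] = zeta_psi
    J[..., 2, 1] = zeta_t
    J[..., 2, 2] = 0.0
    return J


def chart_jacobian(geom: LVGeometry, psi, t, theta, step: float = 1e-5) -> np.ndarray:
    """Jacobian d(x,y,z)/d(psi,t,theta) by central differences, shape (..., 3, 3)."""
    cols = []
    for i in range(3):
        d = [np.zeros_like(np.asarray(psi, float))] * 3
        h = [0.0, 0.0, 0.0]
        h[i] = step
        plus = _chart(geom, psi + h[0], t + h[1], theta + h[2])
        minus = _chart(geom, psi - h[0], t - h[1], theta - h[2])
        cols.append((plus - minus) / (2.0 * step))
        del d
    return np.stack(cols, axis=-1)


# ---------------------------------------------------------------------------
# fiber architecture
# ---------------------------------------------------------------------------

HELIX_ENDO_DEG = 90.0   # fully longitudinal at the endocardium
HELIX_EPI_DEG = -60.0   # at the epicardium


def helix_angle(t) -> np.ndarray:
    """Rule-based helix angle (radians), linear through the wall."""
    t = np.asarray(t, dtype=float)
    deg = HELIX_ENDO_DEG + (HELIX_EPI_DEG - HELIX_ENDO_DEG) * t
    return np.deg2rad(deg)


def _frames(geom: LVGeometry, psi, t, theta) -> np.ndarray:
    """Orthonormal (f, s, n) triads as columns of (..., 3, 3) matrices."""
    psi, t, theta = np.broadcast_arrays(
        np.asarray(psi, float), np.asarray(t, float), np.asarray(theta, float)
    )
    g = _profile_factor(geom, psi)
    gp = -geom.e * np.sin(psi) - (1.0 - geom.e) * np.cos(psi)
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    # d(chart)/dpsi at fixed (t, theta); apex->base longitudinal = -d/dpsi
    rho_psi = ((1.0 - t) * (geom.R_b - geom.L) + t * geom.R_b) * gp
    zeta_psi = -((1.0 - t) * (geom.Z - geom.H) + t * geom.Z) * np.cos(psi)
    e_long = np.stack([-rho_psi * cos_t, -rho_psi * sin_t, -zeta_psi], axis=-1)
    e_long /= np.linalg.norm(e_long, axis=-1, keepdims=True)

    e_circ = np.stack([-sin_t, cos_t, np.zeros_like(cos_t)], axis=-1)

    alpha = helix_angle(t)[..., None]
    f = np.cos(alpha) * e_circ + np.sin(alpha) * e_long

    # transmural (endo->epi) direction orthogonalized against f
    d_rho = geom.L * g
    d_zeta = -geom.H * (1.0 - np.sin(psi)) + geom.H  # zeta_epi - zeta_end
    s_raw = np.stack([d_rho * cos_t, d_rho * sin_t, d_zeta], axis=-1)
    nrm = np.linalg.norm(s_raw, axis=-1, keepdims=True)
    radial = np.stack([cos_t, sin_t, np.zeros_like(cos_t)], axis=-1)
    s_raw = np.where(nrm > 1e-12, s_raw / np.where(nrm > 0, nrm, 1.0), radial)
    s = s_raw - np.sum(s_raw * f, axis=-1, keepdims=True) * f
    s /= np.linalg.norm(s, axis=-1, keepdims=True)
    n = np.cross(f, s)
    return np.stack([f, s, n], axis=-1)


def fiber_frame(geom: LVGeometry, q: MaterialCoordinate) -> FiberFrame:
    """Fiber/sheet/normal triad at a material coordinate.

    The helix angle varies linearly from +90 deg at the endocardium to
    -60 deg at the epicardium, measured from the local circumferential
    direction in the tangent plane of the iso-``t`` surface.
    """
    psi = min(q.psi, math.pi / 2 - 1e-7)  # one-sided limit at the apex
    V = _frames(geom, psi, q.t, q.theta).reshape(3, 3)
    return FiberFrame(f=V[:, 0].copy(), s=V[:, 1].copy(), n=V[:, 2].copy())


# ---------------------------------------------------------------------------
# volumes (solid-of-revolution integrals)
# ---------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=32)
def _leggauss_unit(n: int):
    return np.polynomial.legendre.leggauss(n)


def _leggauss(a: float, b: float, n: int = _GL_NODES):
    x, w = _leggauss_unit(n)
    xm, xr = 0.5 * (a + b), 0.5 * (b - a)
    return xm + xr * x, xr * w


def _epi_solid_volume_mm3(geom: LVGeometry) -> float:
    psi, w = _leggauss(geom.psi0, math.pi / 2)
    re, _, _, _ = _profiles(geom, psi)
    return float(math.pi * geom.Z * np.sum(w * re**2 * np.cos(psi)))


def _cavity_volume_mm3(geom: LVGeometry) -> float:
    psi, w = _leggauss(geom.psi0, math.pi / 2)
    _, _, rn, _ = _profiles(geom, psi)
    v = math.pi * (geom.Z - geom.H) * np.sum(w * rn**2 * np.cos(psi))
    cap_height = geom.zeta_base - geom.zeta_rim  # = -H*sin(psi0)
    if cap_height > 0:
        v += math.pi * geom.rho_rim**2 * cap_height
    elif cap_height < 0:
        # endocardial rim above the basal plane (psi0 > 0): clip at zeta_base
        zeta, wz = _leggauss(geom.zeta_base, geom.zeta_rim)
        arg = np.clip(1.0 - (zeta - geom.H) / (geom.Z - geom.H), -1.0, 1.0)
        rn_z = (geom.R_b - geom.L) * _profile_factor(geom, np.arcsin(arg))
        v -= math.pi * np.sum(wz * rn_z**2)
    return float(v)


def _sliver_volume_mm3(geom: LVGeometry) -> float:
    """Volume between the basal chord and the basal plane (background)."""
    z_rim, z_base = geom.zeta_rim, geom.zeta_base
    if z_base <= z_rim:
        return 0.0
    rho_rim = geom.rho_rim
    rho_epi0 = float(geom.R_b * _profile_factor(geom, geom.psi0))
    zeta, w = _leggauss(z_rim, z_base)
    frac = (zeta - z_rim) / (z_base - z_rim)
    rho_chord = rho_rim + frac * (rho_epi0 - rho_rim)  # chord radius at height zeta
    # the sliver is the annulus between the cavity cap cylinder and the chord
    return float(math.pi * np.sum(w * np.maximum(rho_chord**2 - rho_rim**2, 0.0)))


def cavity_volume(geom: LVGeometry) -> float:
    """Blood-pool volume in ml (endocardial solid + flat basal cap)."""
    v = _cavity_volume_mm3(geom)
    if v <= 0:
        raise ValueError("infeasible geometry: nonpositive cavity volume")
    return v / 1000.0


def wall_volume(geom: LVGeometry) -> float:
    """Myocardial wall volume in ml (chord-closed transmural region)."""
    v = _epi_solid_volume_mm3(geom) - _cavity_volume_mm3(geom) - _sliver_volume_mm3(geom)
    if v <= 0:
        raise ValueError("infeasible geometry: nonpositive wall volume")
    return v / 1000.0


def _zeta_moment_mm4(geom: LVGeometry) -> float:
    """First zeta-moment of the cavity+wall solid (for centroid alignment)."""
    psi, w = _leggauss(geom.psi0, math.pi / 2)
    re, ze, _, _ = _profiles(geom, psi)
    m_epi = math.pi * geom.Z * np.sum(w * re**2 * np.cos(psi) * ze)
    z_rim, z_base = geom.zeta_rim, geom.zeta_base
    m_sliver = 0.0
    if z_base > z_rim:
        rho_rim = geom.rho_rim
        rho_epi0 = float(geom.R_b * _profile_factor(geom, geom.psi0))
        zeta, wz = _leggauss(z_rim, z_base)
        frac = (zeta - z_rim) / (z_base - z_rim)
        rho_chord = rho_rim + frac * (rho_epi0 - rho_rim)
        m_sliver = math.pi * np.sum(
            wz * np.maximum(rho_chord**2 - rho_rim**2, 0.0) * zeta
        )
    return float(m_epi - m_sliver)


def body_centroid(geom: LVGeometry) -> np.ndarray:
    """Centroid (mm, canonical pose) of the cavity+wall solid."""
    v = _epi_solid_volume_mm3(geom) - _sliver_volume_mm3(geom)
    return np.array([0.0, 0.0, _zeta_moment_mm4(geom) / v])


# ---------------------------------------------------------------------------
# quadrature grid over the wall
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuadratureGrid:
    """Tensor-product quadrature over the wall in (psi, t, theta).

    Gauss-Legendre nodes in ``psi`` and ``t``, uniform midpoints in ``theta``;
    weights are reference-volume elements (mm^3) from the chart Jacobian so
    their sum equals the wall volume.  ``frames`` holds the (f, s, n) triads
    as matrix columns.
    """

    psi: np.ndarray
    t: np.ndarray
    theta: np.ndarray
    weights: np.ndarray
    frames: np.ndarray
    zeta: np.ndarray
    shape: tuple
    zeta_base: float

    @property
    def n_points(self) -> int:
        return self.psi.size


def make_quadrature(
    geom: LVGeometry, n_psi: int = 24, n_t: int = 8, n_theta: int = 24
) -> QuadratureGrid:
    psi_n, psi_w = _leggauss(geom.psi0, math.pi / 2, n_psi)
    t_n, t_w = _leggauss(0.0, 1.0, n_t)
    theta_n = (np.arange(n_theta) + 0.5) * (2.0 * math.pi / n_theta)
    theta_w = 2.0 * math.pi / n_theta

    P, T, TH = np.meshgrid(psi_n, t_n, theta_n, indexing="ij")
    WP, WT, _ = np.meshgrid(psi_w, t_w, theta_n, indexing="ij")
    psi, t, theta = P.ravel(), T.ravel(), TH.ravel()

    jac = chart_jacobian(geom, psi, t, theta)
    det = np.abs(np.linalg.det(jac))
    weights = det * WP.ravel() * WT.ravel() * theta_w
    if np.any(weights <= 0):
        raise ValueError("degenerate chart: nonpositive quadrature weights")

    frames = _frames(geom, psi, t, theta)
    _, ze, _, zn = _profiles(geom, psi)
    zeta = (1.0 - t) * zn + t * ze
    return QuadratureGrid(
        psi=psi, t=t, theta=theta, weights=weights, frames=frames,
        zeta=zeta, shape=(n_psi, n_t, n_theta), zeta_base=geom.zeta_base,
    )


def region_mask(
    grid: QuadratureGrid,
    thickness_range: Sequence[float] = (0.4, 0.6),
    longitudinal_range: Sequence[float] = (0.45, 0.55),
) -> np.ndarray:
    """Boolean mask selecting the midwall slab of a quadrature grid.

    Points are kept when their transmural fraction lies in
    ``thickness_range`` and their normalized height ``zeta/zeta_base`` lies
    in ``longitudinal_range`` (defaults: 40-60 % of wall thickness,
    45-55 % of the apex-base distance).
    """
    t_lo, t_hi = thickness_range
    z_lo, z_hi = longitudinal_range
    if not (0 <= t_lo < t_hi <= 1) and not (t_lo < t_hi):
        raise ValueError("thickness_range must be an increasing interval")
    u = grid.zeta / grid.zeta_base
    mask = (grid.t >= t_lo) & (grid.t <= t_hi) & (u >= z_lo) & (u <= z_hi)
    if not mask.any():
        raise ValueError(
            "empty midwall selection: use a finer quadrature grid or wider ranges"
        )
    return mask


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def _boundary_radius(scale: float, e: float, axis: float, z) -> np.ndarray:
    """Profile radius at height ``z`` above the surface's apex.

    Uses sin(psi) = 1 - z/axis, so rho = scale*[e*cos(psi) + (1-e)*(z/axis)]
    without an explicit arcsin (monotone height-angle relation).
    """
    u = np.clip(z / axis, 0.0, 2.0)
    sin_psi = 1.0 - u
    cos_psi = np.sqrt(np.maximum(1.0 - sin_psi**2, 0.0))
    return scale * (e * cos_psi + (1.0 - e) * u)


def _classify_rz(geom: LVGeometry, rho: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Label points by (radius, height) in canonical pose."""
    labels = np.zeros(np.broadcast(rho, z).shape, dtype=np.uint8)
    z_base, z_rim = geom.zeta_base, geom.zeta_rim
    in_band = (z >= 0.0) & (z <= z_base)
    if not in_band.any():
        return labels

    rho_epi_z = _boundary_radius(geom.R_b, geom.e, geom.Z, z)
    inside_epi = in_band & (rho <= rho_epi_z)

    # cavity: endocardial solid below the rim, cylinder cap above it
    cav = np.zeros_like(inside_epi)
    hi = min(z_rim, z_base)
    endo_band = (z >= geom.H) & (z <= hi)
    if endo_band.any():
        rho_end_z = _boundary_radius(
            geom.R_b - geom.L, geom.e, geom.Z - geom.H, z - geom.H
        )
        cav |= endo_band & (rho <= rho_end_z)
    if z_base > z_rim:
        cav |= (z > z_rim) & (z <= z_base) & (rho <= geom.rho_rim)

    # sliver between basal chord and basal plane -> background
    sliver = np.zeros_like(inside_epi)
    if z_base > z_rim:
        rho_rim = geom.rho_rim
        rho_epi0 = geom.R_b * _profile_factor(geom, geom.psi0)
        span = max(rho_epi0 - rho_rim, 1e-12)
        chord_z = z_rim + (rho - rho_rim) / span * (z_base - z_rim)
        sliver = (rho >= rho_rim) & (rho <= rho_epi0) & (z > chord_z)

    labels[cav & in_band] = 1
    labels[inside_epi & ~cav & ~sliver] = 2
    return labels


def classify_points(geom: LVGeometry, pts: np.ndarray) -> np.ndarray:
    """Label canonical-pose points: 0 background, 1 cavity, 2 wall."""
    pts = np.asarray(pts, dtype=float)
    rho = np.hypot(pts[..., 0], pts[..., 1])
    return _classify_rz(geom, rho, pts[..., 2])


def surface_mesh(
    geom: LVGeometry,
    surface: str = "epi",
    n_psi: int = 48,
    n_theta: int = 48,
    pose: RigidPose | None = None,
):
    """Triangulated boundary surface as ``(vertices, faces)`` arrays.

    ``surface`` is ``"epi"`` or ``"endo"``; the apex ring degenerates to a
    point, so the last psi row is collapsed into a single apex vertex.
    """
    if surface not in ("epi", "endo"):
        raise ValueError("surface must be 'epi' or 'endo'")
    psi = np.linspace(geom.psi0, math.pi / 2, n_psi)
    theta = np.linspace(0.0, 2 * math.pi, n_theta, endpoint=False)
    re, ze, rn, zn = _profiles(geom, psi[:-1])
    r, z = (re, ze) if surface == "epi" else (rn, zn)
    R, TH = np.meshgrid(r, theta, indexing="ij")
    Zc, _ = np.meshgrid(z, theta, indexing="ij")
    verts = np.stack(
        [R * np.cos(TH), R * np.sin(TH), Zc], axis=-1
    ).reshape(-1, 3)
    apex = np.array([[0.0, 0.0, 0.0 if surface == "epi" else geom.H]])
    verts = np.vstack([verts, apex])
    apex_idx = len(verts) - 1

    faces = []
    nt = n_theta
    for i in range(n_psi - 2):
        for j in range(nt):
            a = i * nt + j
            b = i * nt + (j + 1) % nt
            c = (i + 1) * nt + j
            d = (i + 1) * nt + (j + 1) % nt
            faces.append([a, b, d])
            faces.append([a, d, c])
    last = (n_psi - 2) * nt
    for j in range(nt):
        faces.append([last + j, last + (j + 1) % nt, apex_idx])
    faces = np.asarray(faces, dtype=np.int64)
    if pose is not None:
        verts = pose.apply(verts)
    return verts, faces


def export_surface(
    geom: LVGeometry,
    path: str,
    surface: str = "epi",
    pose: RigidPose | None = None,
    n_psi: int = 48,
    n_theta: int = 48,
) -> None:
    """Write a boundary surface to a mesh file (format from the extension,
    e.g. ``.ply`` or ``.stl``)."""
    import trimesh

    verts, faces = surface_mesh(geom, surface, n_psi, n_theta, pose)
    trimesh.Trimesh(vertices=verts, faces=faces, process=False).export(path)


def _auto_extent(geom: LVGeometry, margin: float = 3.0):
    psi = np.linspace(geom.psi0, math.pi / 2, 361)
    re, _, _, _ = _profiles(geom, psi)
    r = float(re.max()) + margin
    return np.array([2 * r, 2 * r, geom.zeta_base + 2 * margin]), np.array(
        [-r, -r, -margin]
    )


def voxelize(
    geom: LVGeometry,
    pose: RigidPose | None = None,
    spacing: float | Sequence[float] = 1.0,
    extent: Sequence[float] | None = None,
    origin: Sequence[float] | None = None,
    allow_clip: bool = False,
) -> LabelImage:
    """Rasterize a shape into a 3-D label image (0 bg, 1 cavity, 2 wall).

    Each voxel is labeled by the class of its center.  ``spacing`` is mm per
    axis; when ``extent``/``origin`` are omitted a bounding grid around the
    posed geometry is used.  Raises if a supplied extent clips the geometry
    (unless ``allow_clip``); a disjoint extent yields an all-zero image.
    """
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    pose = pose or RigidPose()

    ext_can, orig_can = _auto_extent(geom)
    corners_can = orig_can + ext_can * np.array(
        [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=float
    )
    corners_img = pose.apply(corners_can)
    lo_geom, hi_geom = corners_img.min(axis=0), corners_img.max(axis=0)

    if extent is None:
        origin = lo_geom
        extent = hi_geom - lo_geom
    else:
        extent = np.asarray(extent, dtype=float)
        origin = (
            np.asarray(origin, dtype=float)
            if origin is not None
            else (lo_geom + hi_geom) / 2 - extent / 2
        )
        hi = origin + extent
        overlaps = np.all(hi > lo_geom) and np.all(origin < hi_geom)
        contains = np.all(origin <= lo_geom + 1e-9) and np.all(hi >= hi_geom - 1e-9)
        if overlaps and not contains and not allow_clip:
            raise ValueError("extent too small to contain the geometry")
        if not overlaps:
            shape = np.maximum(np.floor(extent / spacing).astype(int), 1)
            return LabelImage(
                voxels=np.zeros(shape, dtype=np.uint8),
                spacing=spacing,
                origin=np.asarray(origin, dtype=float),
            )

    shape = np.maximum(np.ceil(np.asarray(extent) / spacing).astype(int), 1)
    axes = [
        origin[i] - pose.translation[i] + (np.arange(shape[i]) + 0.5) * spacing[i]
        for i in range(3)
    ]
    ax = axes[0][:, None, None]
    ay = axes[1][None, :, None]
    az = axes[2][None, None, :]
    # canonical height = (p - t) . (R column 2); radius from the norm identity
    R = pose.rotation
    z = sum(
        R[i, 2] * a for i, a in enumerate((ax, ay, az)) if abs(R[i, 2]) > 1e-15
    )
    r2 = ax**2 + ay**2 + az**2 - z**2
    rho = np.sqrt(np.maximum(r2, 0.0))
    labels = _classify_rz(geom, rho, z)
    return LabelImage(voxels=labels, spacing=spacing, origin=np.asarray(origin, float))
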