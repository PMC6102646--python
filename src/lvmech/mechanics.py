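"""Reduced-order forward model of passive LV inflation.

Quasi-static pressurization is solved by a Rayleigh-Ritz approach: the
deformed configuration is constrained to the same 6-parameter shape family as
the reference, and the shape parameters minimize the total potential energy

    Pi(xi_d) = sum_q w_q [ W(C_bar_q) + kappa/2 (J_q - 1)^2 ]
               - P (V_cav(xi_d) - V_cav(xi_u)),

where the deformation gradient at each quadrature point follows from the
material chart shared by the two configurations, ``C_bar = J^(-2/3) C`` is
the isochoric right Cauchy-Green tensor, and a quadratic volumetric penalty
(kappa, default 250 kPa) enforces near-incompressibility.  The basal plane
height ``zeta_base`` is held fixed during inflation (the axial basal boundary
condition of the full 3-D problem), which ties ``Z`` to ``psi0`` and leaves
five free parameters.

Pressure is applied by continuation in increments of at most 0.25 kPa; each
step is minimized by bounded quasi-Newton (L-BFGS-B, finite-difference
gradients) warm-started from the previous step, with a Nelder-Mead fallback.
The model is fully deterministic.

The midwall fiber stretch — the mean of sqrt(f . C f) over the slab between
40-60 % of wall thickness and 45-55 % of the apex-base distance — is the
scalar loading summary used by the strain-conditioned unloading surrogates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .geometry import (
    LVGeometry,
    MaterialCoordinate,
    QuadratureGrid,
    _cavity_volume_mm3,
    chart_jacobian,
    chart_jacobian_analytic,
    make_quadrature,
    region_mask,
)
from .materials import MaterialModel, energy_density, stiffness_scale

__all__ = [
    "SolverOptions",
    "REDUCED_OPTIONS",
    "LoadedState",
    "InflationTrajectory",
    "InflationError",
    "deformation_gradient",
    "potential_energy",
    "inflate",
    "inflate_multi",
    "inflation_sweep",
    "midwall_fiber_stretch",
    "pressure_at_stretch",
]

_BIG = 1e8  # objective value for rejected candidates


class InflationError(RuntimeError):
    """Raised when the quasi-static solve fails for a geometry."""


_REF_STIFFNESS: list = []  # packaged Fung-type set, resolved lazily


def _kappa_for(mat: MaterialModel, kappa: float) -> float:
    """Material-relative volumetric penalty (kPa).

    The penalty must stay large relative to the deviatoric stiffness for
    uniform incompressibility enforcement, and scaling it with the material
    keeps the solution exactly invariant under a homogeneous rescaling of
    the law (with pressure rescaled accordingly).  Normalized so the
    packaged Fung-type set uses ``kappa`` as given.
    """
    if not _REF_STIFFNESS:
        from .materials import load_material

        _REF_STIFFNESS.append(stiffness_scale(load_material("usyk")))
    return kappa * stiffness_scale(mat) / _REF_STIFFNESS[0]


@dataclass(frozen=True)
class SolverOptions:
    """Discretization and optimizer settings for the Ritz solver."""

    n_psi: int = 24
    n_t: int = 8
    n_theta: int = 24
    kappa: float = 500.0        # volumetric penalty, kPa
    dP_cont: float = 0.25       # continuation pressure step, kPa
    maxiter: int = 80
    maxiter_inner: int = 12     # cap at intermediate continuation steps
    gtol: float = 1e-7
    ftol: float = 1e-13
    store_fields: bool = True


#: Coarser quadrature for cohort-scale studies (training sets, fixed-point
#: cohorts); the tensor-product rule is still effectively exact for wall
#: volume (the chart Jacobian is cubic in t and a low-order trigonometric
#: polynomial in psi) while being ~25x cheaper than the default grid.
REDUCED_OPTIONS = SolverOptions(n_psi=8, n_t=3, n_theta=8)

# free parameters during inflation (Z is tied through the fixed basal plane)
_FREE = ("R_b", "L", "H", "e", "psi0")
_SCALES = np.array([10.0, 10.0, 10.0, 0.2, 0.2])


@dataclass(frozen=True)
class LoadedState:
    """One equilibrium configuration of a pressure sweep."""

    pressure: float
    xi_deformed: LVGeometry
    lambda_ff_midwall: float
    cavity_vol: float  # ml
    wall_vol: float    # ml
    lambda_ff_field: np.ndarray | None = None
    midwall_mask: np.ndarray | None = None
    C_field: np.ndarray | None = None


@dataclass(frozen=True)
class InflationTrajectory:
    """Sequence of loaded states at strictly increasing pressures."""

    unloaded: LVGeometry
    material: MaterialModel
    states: tuple

    def __post_init__(self) -> None:
        p = self.pressures
        if np.any(np.diff(p) <= 0):
            raise ValueError("pressures must be strictly increasing")

    @property
    def pressures(self) -> np.ndarray:
        return np.array([s.pressure for s in self.states])

    @property
    def midwall_stretches(self) -> np.ndarray:
        return np.array([s.lambda_ff_midwall for s in self.states])

    def to_frame(self):
        import pandas as pd

        rows = []
        for s in self.states:
            g = s.xi_deformed
            rows.append(
                dict(P=s.pressure, R_b=g.R_b, Z=g.Z, L=g.L, H=g.H, e=g.e,
                     psi0=g.psi0, lambda_ff_midwall=s.lambda_ff_midwall,
                     cavity_vol=s.cavity_vol, wall_vol=s.wall_vol)
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

class _RefCache:
    """Reference-configuration quantities reused across objective calls."""

    def __init__(self, xi_u: LVGeometry, opts: SolverOptions):
        self.xi_u = xi_u
        self.grid: QuadratureGrid = make_quadrature(
            xi_u, opts.n_psi, opts.n_t, opts.n_theta
        )
        self._trig = (
            np.cos(self.grid.psi), np.sin(self.grid.psi),
            np.cos(self.grid.theta), np.sin(self.grid.theta),
        )
        jac_u = chart_jacobian_analytic(
            xi_u, self.grid.psi, self.grid.t, self.grid.theta, self._trig
        )
        self.inv_jac_u = np.linalg.inv(jac_u)
        self.frames = self.grid.frames
        self.weights = self.grid.weights
        # midwall slab; widen around its center on coarse grids that would
        # otherwise have no quadrature node inside the default windows
        t_half, z_half = 0.1, 0.05
        while True:
            try:
                self.mask = region_mask(
                    self.grid, (0.5 - t_half, 0.5 + t_half),
                    (0.5 - z_half, 0.5 + z_half),
                )
                break
            except ValueError:
                t_half *= 1.5
                z_half *= 1.5
        self.v_cav_u = _cavity_volume_mm3(xi_u)
        self.wall_vol_u = float(self.weights.sum())

    def def_grad(self, xi_d: LVGeometry) -> np.ndarray:
        jac_d = chart_jacobian_analytic(
            xi_d, self.grid.psi, self.grid.t, self.grid.theta, self._trig
        )
        return jac_d @ self.inv_jac_u


def deformation_gradient(
    xi_u: LVGeometry, xi_d: LVGeometry, q: MaterialCoordinate
) -> np.ndarray:
    """F at one material coordinate for the in-family deformation map."""
    psi = np.atleast_1d(min(q.psi, math.pi / 2 - 1e-6))
    t, theta = np.atleast_1d(q.t), np.atleast_1d(q.theta)
    jac_u = chart_jacobian(xi_u, psi, t, theta)[0]
    jac_d = chart_jacobian(xi_d, psi, t, theta)[0]
    F = jac_d @ np.linalg.inv(jac_u)
    if np.linalg.det(F) <= 0:
        raise ValueError("non-positive Jacobian determinant")
    return F


def _det3(A: np.ndarray) -> np.ndarray:
    return (
        A[..., 0, 0] * (A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1])
        - A[..., 0, 1] * (A[..., 1, 0] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 0])
        + A[..., 0, 2] * (A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0])
    )


def _energy_terms(cache: _RefCache, xi_d: LVGeometry, mat: MaterialModel,
                  kappa: float):
    """(internal strain + penalty energy in mJ, J field, C field) or None."""
    F = cache.def_grad(xi_d)
    J = _det3(F)
    if np.any(J <= 1e-8):
        return None
    with np.errstate(over="ignore", invalid="ignore"):
        C = np.swapaxes(F, -1, -2) @ F
        C_bar = C * (J ** (-2.0 / 3.0))[:, None, None]
        W = energy_density(mat, C_bar, cache.frames)
        e_int = np.sum(cache.weights * (W + 0.5 * kappa * (J - 1.0) ** 2)) / 1000.0
    return e_int, J, C


def potential_energy(
    xi_u: LVGeometry,
    xi_d: LVGeometry,
    mat: MaterialModel,
    P: float,
    options: SolverOptions | None = None,
    _cache: _RefCache | None = None,
) -> float:
    """Total potential energy (mJ) of a candidate deformed shape.

    Returns ``+inf`` for candidates with a non-positive Jacobian anywhere.
    """
    opts = options or SolverOptions()
    cache = _cache or _RefCache(xi_u, opts)
    terms = _energy_terms(cache, xi_d, mat, _kappa_for(mat, opts.kappa))
    if terms is None:
        return math.inf
    e_int, _, _ = terms
    work = P * (_cavity_volume_mm3(xi_d) - cache.v_cav_u) / 1000.0
    return float(e_int - work)


# ---------------------------------------------------------------------------
# the Ritz solve
# ---------------------------------------------------------------------------

def _free_to_geom(x: np.ndarray, zeta_base: float) -> LVGeometry | None:
    R_b, L, H, e, psi0 = x
    if not (-1.55 < psi0 < -0.005):
        return None
    Z = zeta_base / (1.0 - math.sin(psi0))
    if not (R_b > L + 0.5 and L > 0.2 and Z > H + 0.5 and H > 0.2 and
            0.01 <= e <= 1.0):
        return None
    return LVGeometry(R_b=R_b, Z=Z, L=L, H=H, e=e, psi0=psi0)


def _geom_to_free(g: LVGeometry) -> np.ndarray:
    return np.array([g.R_b, g.L, g.H, g.e, g.psi0])


def _bounds(xi_u: LVGeometry) -> list:
    x0 = _geom_to_free(xi_u)
    lo = [0.5 * x0[0], 0.25 * x0[1], 0.25 * x0[2],
          max(0.02, x0[3] - 0.4), max(-1.54, x0[4] - 0.6)]
    hi = [2.5 * x0[0], 1.6 * x0[1], 1.6 * x0[2],
          min(1.0, x0[3] + 0.4), min(-0.01, x0[4] + 0.6)]
    return [(l / s, h / s) for l, h, s in zip(lo, hi, _SCALES)]


def _solve_continuation(
    xi_u: LVGeometry,
    mat: MaterialModel,
    record_pressures: Sequence[float],
    options: SolverOptions | None = None,
) -> dict:
    """Continuation in pressure; returns {pressure: LoadedState}."""
    opts = options or SolverOptions()
    record = sorted(float(p) for p in record_pressures)
    if record and record[0] < 0:
        raise ValueError("pressure must be nonnegative")
    cache = _RefCache(xi_u, opts)

    out = {}
    if record and record[0] == 0.0:
        out[0.0] = _make_state(cache, xi_u, 0.0, opts)
        record = record[1:]
    if not record:
        return out

    p_max = record[-1]
    n_cont = max(1, math.ceil(round(p_max / opts.dP_cont, 9)))
    grid = np.union1d(
        np.linspace(0.0, p_max, n_cont + 1)[1:], np.asarray(record)
    )
    zeta_base = xi_u.zeta_base
    bounds = _bounds(xi_u)
    kappa = _kappa_for(mat, opts.kappa)

    def objective(y: np.ndarray, P: float) -> float:
        g = _free_to_geom(y * _SCALES, zeta_base)
        if g is None:
            return _BIG
        terms = _energy_terms(cache, g, mat, kappa)
        if terms is None:
            return _BIG
        e_int, _, _ = terms
        val = e_int - P * (_cavity_volume_mm3(g) - cache.v_cav_u) / 1000.0
        return val if np.isfinite(val) else _BIG

    y = _geom_to_free(xi_u) / _SCALES
    record_set = {round(p, 9) for p in record}
    for P in grid:
        # intermediate continuation nodes only provide warm starts; solve
        # them loosely and converge fully at recorded pressures
        recorded = round(float(P), 9) in record_set
        maxiter = opts.maxiter if recorded else opts.maxiter_inner
        res = optimize.minimize(
            objective, y, args=(float(P),), method="L-BFGS-B", bounds=bounds,
            options=dict(maxiter=maxiter, ftol=opts.ftol, gtol=opts.gtol),
        )
        if not np.isfinite(res.fun) or res.fun >= _BIG:
            raise InflationError(
                f"inflation failed at P={P:.3g} kPa for geometry "
                f"{tuple(round(v, 3) for v in xi_u.as_array())}"
            )
        if recorded and not res.success and res.nit < 3:
            # genuine line-search failure near the start -> simplex fallback
            res_nm = optimize.minimize(
                objective, res.x, args=(float(P),), method="Nelder-Mead",
                options=dict(maxiter=400, fatol=1e-10, xatol=1e-8),
            )
            if res_nm.fun < res.fun:
                res = res_nm
        y = res.x
        if recorded:
            g = _free_to_geom(y * _SCALES, zeta_base)
            out[float(P)] = _make_state(cache, g, float(P), opts)
    return out


def _make_state(
    cache: _RefCache, xi_d: LVGeometry, P: float, opts: SolverOptions
) -> LoadedState:
    F = cache.def_grad(xi_d)
    C = np.swapaxes(F, -1, -2) @ F
    f = cache.frames[..., 0]
    lam = np.sqrt(np.einsum("ni,nij,nj->n", f, C, f, optimize=True))
    wall_mm3 = float(np.sum(cache.weights * _det3(F)))
    return LoadedState(
        pressure=P,
        xi_deformed=xi_d,
        lambda_ff_midwall=float(lam[cache.mask].mean()),
        cavity_vol=_cavity_volume_mm3(xi_d) / 1000.0,
        wall_vol=wall_mm3 / 1000.0,
        lambda_ff_field=lam if opts.store_fields else None,
        midwall_mask=cache.mask if opts.store_fields else None,
        C_field=C if opts.store_fields else None,
    )


def inflate(
    xi_u: LVGeometry,
    mat: MaterialModel,
    P: float,
    options: SolverOptions | None = None,
) -> LoadedState:
    """Inflate an unloaded shape to pressure ``P`` (kPa)."""
    if P < 0:
        raise ValueError("pressure must be nonnegative")
    return _solve_continuation(xi_u, mat, [P], options)[float(P)]


def inflate_multi(
    xi_u: LVGeometry,
    mat: MaterialModel,
    pressures: Sequence[float],
    options: SolverOptions | None = None,
) -> dict:
    """One continuation run recording states at several pressures (kPa)."""
    return _solve_continuation(xi_u, mat, pressures, options)


def inflation_sweep(
    xi_u: LVGeometry,
    mat: MaterialModel,
    P_max: float = 5.0,
    dP: float = 0.05,
    options: SolverOptions | None = None,
) -> InflationTrajectory:
    """Pressure sweep at ``dP`` increments (defaults: 100 states to 5 kPa)."""
    if dP <= 0:
        raise ValueError("dP must be positive")
    n = int(round(P_max / dP))
    pressures = dP * np.arange(1, n + 1)
    states = _solve_continuation(xi_u, mat, pressures, options)
    ordered = tuple(states[p] for p in sorted(states))
    return InflationTrajectory(unloaded=xi_u, material=mat, states=ordered)


# ---------------------------------------------------------------------------
# loading summaries
# ---------------------------------------------------------------------------

def midwall_fiber_stretch(state: LoadedState) -> float:
    """Unweighted mean fiber stretch over the midwall slab."""
    if state.lambda_ff_field is None or state.midwall_mask is None:
        return state.lambda_ff_midwall
    mask = state.midwall_mask
    if not mask.any():
        raise ValueError("empty midwall mask")
    return float(state.lambda_ff_field[mask].mean())


def pressure_at_stretch(traj: InflationTrajectory, target: float) -> float:
    """Pressure (kPa) at which midwall fiber stretch first reaches ``target``.

    Linear interpolation between sweep states; the reference state (P=0,
    stretch 1) is included implicitly.
    """
    if target < 1.0:
        raise ValueError("stretch target must be >= 1")
    if target == 1.0:
        return 0.0
    P = np.concatenate([[0.0], traj.pressures])
    lam = np.concatenate([[1.0], traj.midwall_stretches])
    above = np.nonzero(lam >= target)[0]
    if above.size == 0:
        raise ValueError(
            f"stretch target unreachable: max midwall stretch "
            f"{lam.max():.4f} < {target} within the sweep"
        )
    i = int(above[0])
    if lam[i] == target or i == 0:
        return float(P[i])
    frac = (target - lam[i - 1]) / (lam[i] - lam[i - 1])
    return float(P[i - 1] + frac * (P[i] - P[i - 1]))
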