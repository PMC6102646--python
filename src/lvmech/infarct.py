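"""Infarct geometry study: lesion parameterization, reduced cardiac cycle,
and kriging emulation of stroke volume.

A lesion on the idealized ventricle is described by four features:
longitudinal position ``Long`` in [0, 1] (0 base, 1 apex), circumferential
extension ``dCirc`` in [0, pi] radians, longitudinal extension ``dLong`` in
[0, 1] (fraction of the apex-base span) and transmural ``depth`` in [0, 1]
growing from the endocardium.  Membership is a sharp box in the material
chart: a point (psi, t, theta) is infarcted when its normalized longitudinal
coordinate u = (psi - psi0)/(pi/2 - psi0) lies within dLong/2 of Long, its
circumferential angle within dCirc/2 of the lesion center (theta = 0), and
t <= depth.

Cardiac output is produced by a time-varying-elastance reduced cycle model:
the end-diastolic volume comes from passive inflation of the unloaded
baseline to the end-diastolic pressure; the end-systolic volume follows from
an effective maximal elastance scaled by the healthy wall fraction,

    E_max_eff = E_min + (E_max - E_min) * (1 - infarct_fraction),
    ESV = V0 + P_ao / E_max_eff,        SV = EDV - ESV,

so contraction is deactivated in the lesion while passive filling is
unchanged.  Both elastances are calibrated once per baseline from two
stroke-volume anchors: the lesion-free beat of the failing baseline gives
49 ml and the maximal admissible lesion (half the wall) gives 21 ml.  In
this reduced model SV depends on the lesion only through its volume
fraction — a deliberate simplification of the full 3-D picture, where
lesion location retains a small residual effect.

The 4-D lesion space is probed by a uniform latin hypercube (default
40 = 10 x 4 samples) and emulated by the same GP stack used for unloading;
5-fold cross-validation measures emulator accuracy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ParameterBox, lhs_uniform
from .geometry import LVGeometry, QuadratureGrid, make_quadrature
from .materials import MaterialModel
from .mechanics import SolverOptions, inflate, inflation_sweep
from .unloading import GPShapeRegressor

__all__ = [
    "InfarctSpec",
    "HemoSettings",
    "CycleResult",
    "LESION_BOX",
    "lesion_membership",
    "infarct_volume",
    "calibrate_emax",
    "simulate_cycle",
    "run_study",
    "train_sv_surrogate",
    "slice_map",
    "all_slice_maps",
    "kfold_cv",
]

from functools import lru_cache


@lru_cache(maxsize=8)
def default_baseline(options: SolverOptions | None = None) -> LVGeometry:
    """Baseline failing ventricle for lesion studies.

    The unloaded shape obtained by fixed-point unloading of the HF-I-02
    end-diastolic geometry at 1 kPa with the Fung-type material set.
    """
    from .datasets import get_geometry
    from .materials import load_material
    from .unloading import fixed_point_unload

    eod = get_geometry("HF-I-02", "EoD")
    xi_u, _ = fixed_point_unload(eod, 1.0, load_material("usyk"), options=options)
    return xi_u


#: Admissible lesion-parameter box (Long, dCirc, dLong, depth).
LESION_BOX = ParameterBox(
    names=("long_pos", "d_circ", "d_long", "depth"),
    lower=np.array([0.0, 0.0, 0.0, 0.0]),
    upper=np.array([1.0, math.pi, 1.0, 1.0]),
)


@dataclass(frozen=True)
class InfarctSpec:
    """Lesion descriptor on the idealized ventricle."""

    long_pos: float
    d_circ: float
    d_long: float
    depth: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.long_pos <= 1.0):
            raise ValueError("long_pos must be in [0, 1]")
        if not (0.0 <= self.d_circ <= math.pi):
            raise ValueError("d_circ must be in [0, pi]")
        if not (0.0 <= self.d_long <= 1.0):
            raise ValueError("d_long must be in [0, 1]")
        if not (0.0 <= self.depth <= 1.0):
            raise ValueError("depth must be in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.long_pos, self.d_circ, self.d_long, self.depth])


@dataclass(frozen=True)
class HemoSettings:
    """Lumped hemodynamic settings for the reduced cycle model.

    The two elastance levels are calibrated (per baseline ventricle) from
    two stroke-volume anchors: the lesion-free beat must give ``SV_target``
    and the maximal lesion of the admissible box (transmural, full
    longitudinal extent, half the circumference — wall fraction 1/2) must
    give ``SV_max_lesion``.
    """

    EDP: float = 1.5            # end-diastolic pressure, kPa
    P_ao: float = 12.0          # aortic (end-ejection) pressure, kPa
    V0: float = 10.0            # elastance volume intercept, ml
    SV_target: float = 49.0     # lesion-free stroke volume, ml
    SV_max_lesion: float = 21.0  # stroke volume at the maximal lesion, ml


@dataclass(frozen=True)
class CycleResult:
    EDV: float
    ESV: float
    SV: float
    infarct_volume: float
    infarct_fraction: float
    pv_volume: np.ndarray | None = None
    pv_pressure: np.ndarray | None = None


# ---------------------------------------------------------------------------
# lesion geometry
# ---------------------------------------------------------------------------

def lesion_membership(
    geom: LVGeometry, spec: InfarctSpec, psi, t, theta
) -> np.ndarray:
    """Boolean lesion membership for material coordinates (vectorized)."""
    psi = np.asarray(psi, dtype=float)
    t = np.asarray(t, dtype=float)
    theta = np.asarray(theta, dtype=float)
    u = (psi - geom.psi0) / (math.pi / 2 - geom.psi0)
    lo = max(spec.long_pos - spec.d_long / 2.0, 0.0)
    hi = min(spec.long_pos + spec.d_long / 2.0, 1.0)
    ang = np.mod(theta + math.pi, 2 * math.pi) - math.pi  # wrap to [-pi, pi)
    return (
        (u >= lo) & (u <= hi)
        & (np.abs(ang) <= spec.d_circ / 2.0)
        & (t <= spec.depth)
    )


def _chart_area_integral(geom: LVGeometry, psi_lo, psi_hi, t_lo, t_hi,
                         n_psi: int = 32, n_t: int = 16) -> float:
    """Integral of |det(chart Jacobian)| over a (psi, t) sub-rectangle.

    The Jacobian determinant is theta-independent (axisymmetry), so wall
    sub-volumes are this integral times the circumferential width.
    """
    from lvmech.geometry import _leggauss, chart_jacobian_analytic

    if psi_hi <= psi_lo or t_hi <= t_lo:
        return 0.0
    psi, wp = _leggauss(psi_lo, psi_hi, n_psi)
    t, wt = _leggauss(t_lo, t_hi, n_t)
    P, T = np.meshgrid(psi, t, indexing="ij")
    WP, WT = np.meshgrid(wp, wt, indexing="ij")
    jac = chart_jacobian_analytic(geom, P.ravel(), T.ravel(),
                                  np.zeros(P.size))
    det = np.abs(np.linalg.det(jac))
    return float(np.sum(det * WP.ravel() * WT.ravel()))


def infarct_volume(
    geom: LVGeometry,
    spec: InfarctSpec,
    grid: QuadratureGrid | None = None,
) -> tuple:
    """Lesion volume (ml) and its fraction of the wall volume.

    The lesion is an axis-aligned box in chart coordinates, so its volume is
    integrated exactly over the sub-domain (boundary-aligned quadrature);
    the wall volume in the denominator uses the same integral over the full
    chart for a consistent, exactly d_circ-linear fraction.  ``grid`` is
    accepted for interface compatibility but unused.
    """
    u_lo = max(spec.long_pos - spec.d_long / 2.0, 0.0)
    u_hi = min(spec.long_pos + spec.d_long / 2.0, 1.0)
    span = math.pi / 2 - geom.psi0
    psi_lo = geom.psi0 + u_lo * span
    psi_hi = geom.psi0 + u_hi * span
    sub = _chart_area_integral(geom, psi_lo, psi_hi, 0.0, spec.depth)
    full = _chart_area_integral(geom, geom.psi0, math.pi / 2, 0.0, 1.0)
    v_mm3 = spec.d_circ * sub
    frac = v_mm3 / (2.0 * math.pi * full)
    return v_mm3 / 1000.0, frac


# ---------------------------------------------------------------------------
# reduced cardiac cycle
# ---------------------------------------------------------------------------

#: Wall fraction of the maximal admissible lesion (dCirc = pi covers half
#: the circumference; depth = dLong = 1): exactly one half by symmetry.
_MAX_LESION_FRACTION = 0.5


def calibrate_emax(
    edv: float, hemo: HemoSettings = HemoSettings()
) -> tuple:
    """Elastance pair (E_max, E_min) in kPa/ml matching the SV anchors."""
    d_base = edv - hemo.V0 - hemo.SV_target
    d_max = edv - hemo.V0 - hemo.SV_max_lesion
    if d_base <= 0 or d_max <= d_base:
        raise ValueError(
            f"EDV={edv:.1f} ml incompatible with the SV anchors "
            f"({hemo.SV_target}, {hemo.SV_max_lesion} ml)"
        )
    e_max = hemo.P_ao / d_base
    e_eff_star = hemo.P_ao / d_max
    e_min = (e_eff_star - (1.0 - _MAX_LESION_FRACTION) * e_max) / _MAX_LESION_FRACTION
    if not (0.0 < e_min < e_max):
        raise ValueError(
            f"calibrated elastances out of order: E_min={e_min:.4f}, "
            f"E_max={e_max:.4f} kPa/ml"
        )
    return e_max, e_min


def simulate_cycle(
    geom_unloaded: LVGeometry,
    mat: MaterialModel,
    spec: InfarctSpec,
    hemo: HemoSettings = HemoSettings(),
    options: SolverOptions | None = None,
    edv: float | None = None,
    elastances: tuple | None = None,
    grid: QuadratureGrid | None = None,
    with_pv_loop: bool = False,
) -> CycleResult:
    """One reduced beat of an infarcted ventricle.

    ``edv`` / ``elastances`` may carry precomputed values (the passive
    inflation and calibration are lesion-independent); otherwise both are
    computed here.  The optional PV loop is assembled from the passive
    filling curve plus isovolumic/ejection segments for reporting.
    """
    pv_v = pv_p = None
    if edv is None:
        if with_pv_loop:
            traj = inflation_sweep(
                geom_unloaded, mat, P_max=hemo.EDP, dP=hemo.EDP / 10, options=options
            )
            edv = traj.states[-1].cavity_vol
            pv_fill_v = np.array([s.cavity_vol for s in traj.states])
            pv_fill_p = traj.pressures
        else:
            edv = inflate(geom_unloaded, mat, hemo.EDP, options).cavity_vol
    elif with_pv_loop:
        pv_fill_v = np.array([edv])
        pv_fill_p = np.array([hemo.EDP])
    if elastances is None:
        elastances = calibrate_emax(edv, hemo)
    e_max, e_min = elastances

    v_les, frac = infarct_volume(geom_unloaded, spec, grid=grid)
    e_eff = e_min + (e_max - e_min) * (1.0 - frac)
    esv = max(hemo.V0 + hemo.P_ao / e_eff, hemo.V0)
    sv = edv - esv
    if sv < 0:
        warnings.warn("ESV exceeds EDV; stroke volume clamped at 0",
                      stacklevel=2)
        sv, esv = 0.0, edv

    if with_pv_loop:
        pv_v = np.concatenate([pv_fill_v, [edv, esv, esv]])
        pv_p = np.concatenate([pv_fill_p, [hemo.P_ao, hemo.P_ao, 0.0]])
    return CycleResult(
        EDV=float(edv), ESV=float(esv), SV=float(sv),
        infarct_volume=v_les, infarct_fraction=frac,
        pv_volume=pv_v, pv_pressure=pv_p,
    )


def run_study(
    baseline: LVGeometry,
    mat: MaterialModel,
    n: int = 40,
    seed: int | None = None,
    hemo: HemoSettings = HemoSettings(),
    options: SolverOptions | None = None,
) -> pd.DataFrame:
    """Uniform-LHS lesion study on a common baseline ventricle.

    Runs the reduced cycle for ``n`` lesions (default 40 = 10 x 4) and
    returns one row per lesion with its parameters, volume, fraction and
    the cycle volumes.
    """
    samples = lhs_uniform(n, LESION_BOX, seed=seed)
    edv = inflate(baseline, mat, hemo.EDP, options).cavity_vol
    elastances = calibrate_emax(edv, hemo)
    grid = make_quadrature(baseline)
    rows = []
    for row in samples:
        spec = InfarctSpec(*row)
        res = simulate_cycle(
            baseline, mat, spec, hemo, options, edv=edv,
            elastances=elastances, grid=grid,
        )
        rows.append(
            dict(
                long_pos=spec.long_pos, d_circ=spec.d_circ,
                d_long=spec.d_long, depth=spec.depth,
                infarct_volume=res.infarct_volume,
                infarct_fraction=res.infarct_fraction,
                EDV=res.EDV, ESV=res.ESV, SV=res.SV,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SV emulation
# ---------------------------------------------------------------------------

_LESION_COLS = ["long_pos", "d_circ", "d_long", "depth"]


def train_sv_surrogate(
    table: pd.DataFrame, seed: int | None = None
) -> GPShapeRegressor:
    """Kriging emulator of SV over the 4-D lesion space."""
    if len(table) < 5:
        raise ValueError("need at least 5 study rows")
    reg = GPShapeRegressor(random_state=seed)
    reg.fit(table[_LESION_COLS].to_numpy(), table["SV"].to_numpy())
    return reg


def slice_map(
    reg: GPShapeRegressor,
    axes: tuple,
    n_grid: int = 25,
    fixed: dict | None = None,
) -> tuple:
    """2-D SV map over one axis pair, others fixed at mid-range.

    Returns ``(x_values, y_values, sv_grid)`` for the requested pair of
    lesion-parameter names.
    """
    names = _LESION_COLS
    i, j = names.index(axes[0]), names.index(axes[1])
    mid = 0.5 * (LESION_BOX.lower + LESION_BOX.upper)
    if fixed:
        for k, v in fixed.items():
            mid[names.index(k)] = v
    xi = np.linspace(LESION_BOX.lower[i], LESION_BOX.upper[i], n_grid)
    yj = np.linspace(LESION_BOX.lower[j], LESION_BOX.upper[j], n_grid)
    X = np.tile(mid, (n_grid * n_grid, 1))
    gx, gy = np.meshgrid(xi, yj, indexing="ij")
    X[:, i] = gx.ravel()
    X[:, j] = gy.ravel()
    sv = reg.predict(X)[:, 0].reshape(n_grid, n_grid)
    return xi, yj, sv


def all_slice_maps(reg: GPShapeRegressor, n_grid: int = 25) -> dict:
    """SV maps for all six axis pairs of the 4-D lesion space."""
    from itertools import combinations

    return {
        pair: slice_map(reg, pair, n_grid)
        for pair in combinations(_LESION_COLS, 2)
    }


def kfold_cv(
    table: pd.DataFrame,
    k: int = 5,
    seed: int | None = None,
    n_rows: int | None = None,
) -> float:
    """Mean relative SV error (%) of seeded k-fold cross-validation.

    Rows with zero simulated SV are excluded from the error average (their
    relative error is undefined).  ``n_rows`` optionally subsamples the
    table first (for learning-curve studies).
    """
    if len(table) < k:
        raise ValueError("need at least k rows")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(table))
    if n_rows is not None:
        idx = idx[:n_rows]
    folds = np.array_split(idx, k)
    errors = []
    X = table[_LESION_COLS].to_numpy()
    y = table["SV"].to_numpy()
    for f in range(k):
        test = folds[f]
        train = np.concatenate([folds[g] for g in range(k) if g != f])
        reg = GPShapeRegressor(random_state=seed)
        reg.fit(X[train], y[train])
        pred = reg.predict(X[test])[:, 0]
        nz = y[test] != 0
        if not nz.all():
            warnings.warn("rows with SV=0 excluded from CV error", stacklevel=2)
        if nz.any():
            errors.extend(np.abs(pred[nz] - y[test][nz]) / y[test][nz])
    return float(np.mean(errors) * 100.0)
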