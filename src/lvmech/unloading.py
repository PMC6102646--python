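"""Inverse estimation of the unloaded (stress-free) ventricular shape.

A ventricle is never imaged at zero transmural pressure, so the reference
configuration needed by mechanics simulations must be inferred.  Two routes
are implemented on top of the reduced forward solver:

* **fixed-point iteration** (the backward-displacement scheme): update a
  candidate unloaded shape by the parameter-space residual between the
  target loaded shape and the forward-inflated candidate,
  ``xi_u <- xi_u + (xi_target - inflate(xi_u, P))``, starting from the
  target itself.  Converges in a handful of iterations for diastolic
  pressures and serves as the oracle;

* **Gaussian-process (kriging) regression**: train on pairs
  (loaded shape -> unloaded shape) generated by inflating sampled unloaded
  candidates, one independent anisotropic-RBF GP per output parameter,
  conditioned either on the inflation pressure (one surrogate per pressure)
  or on a midwall fiber-stretch target (in which case the located pressure
  is an additional output).  After training, unloading costs microseconds.

Dice overlap of voxelized walls is the agreement metric between the two
routes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.utils.validation import check_is_fitted

from .geometry import PARAM_NAMES, LVGeometry
from .materials import MaterialModel
from .mechanics import (
    InflationError,
    SolverOptions,
    inflate,
    inflate_multi,
    inflation_sweep,
    pressure_at_stretch,
)
from .shapefit import dice

__all__ = [
    "GPShapeRegressor",
    "GPSurrogate",
    "TrainingSet",
    "fixed_point_unload",
    "build_training_set",
    "train_gp",
    "predict_unloaded",
    "evaluate_against_fixed_point",
    "FixedPointError",
]

logger = logging.getLogger(__name__)

# convergence scales for the fixed-point residual: 0.1 mm on lengths,
# 0.005 on sphericity, 0.5 deg on the truncation angle
_RESID_SCALES = np.array([0.1, 0.1, 0.1, 0.1, 0.005, np.deg2rad(0.5)])


class FixedPointError(RuntimeError):
    """Fixed-point iteration failed; carries the residual history."""

    def __init__(self, msg: str, history=None):
        super().__init__(msg)
        self.history = history or []


def fixed_point_unload(
    xi_loaded: LVGeometry,
    P: float,
    mat: MaterialModel,
    tol: float = 1.0,
    max_iter: int = 25,
    options: SolverOptions | None = None,
) -> tuple:
    """Backward-displacement estimate of the unloaded shape.

    Iterates in the 6-parameter space from ``xi_u = xi_loaded``; converged
    when the maximum scaled parameter residual is below ``tol`` (scales:
    0.1 mm for lengths, 0.005 for e, 0.5 deg for psi0).  Returns
    ``(xi_unloaded, n_iterations)``.

    Two standard robustness devices are layered on the plain iteration:

    * Aitken (Irons-Tuck) dynamic relaxation — for compliant ventricles at
      diastolic pressures the forward map can amplify reference-shape
      perturbations by more than 2x, making the undamped update
      non-contractive; the classic secant-based relaxation factor restores
      and accelerates convergence;
    * projected convergence — targets whose unloaded shape lies on the
      boundary of the representable family (sphericity pinned at 1) never
      drive the raw residual to zero, so a stationary projected iterate
      also counts as converged;
    * stagnation detection — the residual cannot fall below the forward
      solver's own accuracy; when it stops improving near that floor the
      best iterate so far is returned.
    """
    if P < 0:
        raise ValueError("pressure must be nonnegative")
    target = xi_loaded.as_array()
    x = target.copy()
    history = []
    prev = None
    r_prev = None
    best = None
    omega = 0.5
    for it in range(1, max_iter + 1):
        xi_u = _clip_geometry(x)
        clip_active = bool(np.max(np.abs(xi_u.as_array() - x)) > 1e-10)
        try:
            loaded = inflate(xi_u, mat, P, options)
        except (InflationError, ValueError) as err:
            raise FixedPointError(
                f"infeasible iterate at iteration {it}: {err}", history
            ) from err
        resid = target - loaded.xi_deformed.as_array()
        r = resid / _RESID_SCALES
        scaled = float(np.max(np.abs(r)))
        history.append(scaled)
        if scaled < tol:
            return xi_u, it
        if best is None or scaled < best[0]:
            best = (scaled, xi_u, it)
        stagnated = (
            it >= 5
            and best[0] < 5 * tol
            and (
                (it - best[2] >= 3 and min(history[-3:]) > 0.95 * best[0])
                or (it >= 8 and min(history[-4:]) > 0.8 * best[0])
            )
        )
        if stagnated:
            return best[1], best[2]
        if clip_active and prev is not None:
            step = float(
                np.max(np.abs(xi_u.as_array() - prev) / _RESID_SCALES)
            )
            if step < 0.25 * tol:
                return xi_u, it
        if r_prev is not None:
            dr = r - r_prev
            denom = float(dr @ dr)
            if denom > 1e-30:
                omega = float(np.clip(-omega * (r_prev @ dr) / denom,
                                      0.1, 1.0))
        prev = xi_u.as_array()
        r_prev = r
        x = x + omega * resid
    raise FixedPointError(
        f"fixed-point iteration did not converge in {max_iter} iterations "
        f"(residual history: {[round(h, 3) for h in history]})",
        history,
    )


# ---------------------------------------------------------------------------
# training sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingSet:
    """Loaded -> unloaded parameter pairs sharing one conditioning mode.

    ``X`` holds loaded 6-parameter vectors; ``Y`` the unloaded vectors, with
    the located pressure appended as a 7th column in stretch mode.
    """

    X: np.ndarray
    Y: np.ndarray
    material: str
    mode: str                   # "pressure" or "stretch"
    conditioning: float         # pressure (kPa) or stretch target
    dropped: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        if len(X) != len(Y) or len(X) < 2:
            raise ValueError("training set needs >= 2 aligned records")
        if self.mode not in ("pressure", "stretch"):
            raise ValueError("mode must be 'pressure' or 'stretch'")

    @property
    def n_train(self) -> int:
        return len(self.X)


def build_training_set(
    samples,
    mat: MaterialModel,
    pressures=None,
    stretch_targets=None,
    options: SolverOptions | None = None,
    sweep_P_max: float = 5.0,
    sweep_dP: float = 0.25,
) -> dict:
    """Forward-simulate sampled unloaded shapes into training sets.

    In pressure mode each sample is inflated once (continuation recording
    every requested pressure) and a :class:`TrainingSet` is built per
    pressure.  In stretch mode a sweep locates, per sample, the pressure at
    which the midwall fiber stretch reaches each target; the loaded shape at
    that pressure maps to (unloaded shape, located pressure).  Samples whose
    solve fails are dropped and logged.  Returns ``{key: TrainingSet}``
    keyed by pressure or stretch target.
    """
    if (pressures is None) == (stretch_targets is None):
        raise ValueError("specify exactly one of pressures / stretch_targets")

    samples = list(samples)
    records: dict = {}
    dropped: list = []
    if pressures is not None:
        keys = [float(p) for p in pressures]
        for g in samples:
            try:
                states = inflate_multi(g, mat, keys, options)
            except (InflationError, ValueError) as err:
                logger.warning("dropping geometry %s: %s",
                               np.round(g.as_array(), 3), err)
                dropped.append(g)
                continue
            for p in keys:
                records.setdefault(p, []).append(
                    (states[p].xi_deformed.as_array(), g.as_array())
                )
        mode = "pressure"
    else:
        keys = [float(s) for s in stretch_targets]
        for g in samples:
            try:
                traj = inflation_sweep(g, mat, sweep_P_max, sweep_dP, options)
                for lam in keys:
                    p_star = pressure_at_stretch(traj, lam)
                    loaded = inflate(g, mat, p_star, options)
                    records.setdefault(lam, []).append(
                        (loaded.xi_deformed.as_array(),
                         np.concatenate([g.as_array(), [p_star]]))
                    )
            except (InflationError, FixedPointError, ValueError) as err:
                logger.warning("dropping geometry %s: %s",
                               np.round(g.as_array(), 3), err)
                dropped.append(g)
                continue
        mode = "stretch"

    if not records:
        raise RuntimeError("all samples failed the forward solve")
    out = {}
    for key, recs in records.items():
        X = np.array([r[0] for r in recs])
        Y = np.array([r[1] for r in recs])
        out[key] = TrainingSet(
            X=X, Y=Y, material=mat.name or mat.law, mode=mode,
            conditioning=key, dropped=tuple(dropped),
        )
    return out


# ---------------------------------------------------------------------------
# GP regression
# ---------------------------------------------------------------------------

class GPShapeRegressor(BaseEstimator, RegressorMixin):
    """Multi-output kriging with one independent GP per output column.

    Inputs and outputs are standardized internally (the statistics are
    fitted attributes); each output gets an anisotropic squared-exponential
    kernel with a signal-variance prefactor and an additive white-noise
    term, with hyperparameters chosen by maximizing the log marginal
    likelihood over seeded restarts.  Zero-variance outputs fall back to a
    constant predictor with a warning.
    """

    def __init__(
        self,
        noise_level: float = 1e-6,
        n_restarts: int = 5,
        random_state: int | None = None,
    ):
        self.noise_level = noise_level
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if len(X) != len(y) or len(X) < 2:
            raise ValueError("need >= 2 aligned samples")
        self.n_features_in_ = X.shape[1]
        self.n_outputs_ = y.shape[1]
        self.X_mean_ = X.mean(axis=0)
        self.X_scale_ = np.where(X.std(axis=0) > 1e-12, X.std(axis=0), 1.0)
        self.X_min_ = X.min(axis=0)
        self.X_max_ = X.max(axis=0)
        self.y_mean_ = y.mean(axis=0)
        ystd = y.std(axis=0)
        self.y_scale_ = np.where(ystd > 1e-12, ystd, 1.0)
        Xs = (X - self.X_mean_) / self.X_scale_
        ys = (y - self.y_mean_) / self.y_scale_

        self.gps_ = []
        self.constant_outputs_ = np.zeros(self.n_outputs_, dtype=bool)
        for j in range(self.n_outputs_):
            if ystd[j] <= 1e-12:
                warnings.warn(
                    f"output {j} has zero variance; constant predictor used",
                    stacklevel=2,
                )
                self.constant_outputs_[j] = True
                self.gps_.append(None)
                continue
            kernel = (
                ConstantKernel(1.0, (1e-3, 1e3))
                * RBF(np.ones(self.n_features_in_), (1e-2, 1e3))
                + WhiteKernel(self.noise_level, (1e-10, 1e-1))
            )
            gp = GaussianProcessRegressor(
                kernel=kernel,
                n_restarts_optimizer=self.n_restarts,
                random_state=self.random_state,
                normalize_y=False,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp.fit(Xs, ys[:, j])
            self.gps_.append(gp)
        return self

    def predict(self, X, return_std: bool = False):
        check_is_fitted(self, "gps_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xs = (X - self.X_mean_) / self.X_scale_
        mean = np.empty((len(X), self.n_outputs_))
        sd = np.empty_like(mean)
        for j in range(self.n_outputs_):
            if self.constant_outputs_[j]:
                mean[:, j] = self.y_mean_[j]
                sd[:, j] = 0.0
                continue
            m, s = self.gps_[j].predict(Xs, return_std=True)
            mean[:, j] = m * self.y_scale_[j] + self.y_mean_[j]
            sd[:, j] = s * self.y_scale_[j]
        if return_std:
            return mean, sd
        return mean

    def noise_sd(self) -> np.ndarray:
        """Fitted white-noise standard deviation per output (output units)."""
        check_is_fitted(self, "gps_")
        out = np.zeros(self.n_outputs_)
        for j, gp in enumerate(self.gps_):
            if gp is None:
                continue
            out[j] = float(np.sqrt(gp.kernel_.k2.noise_level)) * self.y_scale_[j]
        return out


@dataclass(frozen=True)
class GPSurrogate:
    """A fitted unloading surrogate plus its conditioning metadata."""

    regressor: GPShapeRegressor
    mode: str
    conditioning: float
    material: str
    input_names: tuple = PARAM_NAMES
    output_names: tuple = PARAM_NAMES
    tie_basal_plane: bool = True

    def training_box(self):
        reg = self.regressor
        return reg.X_mean_, reg.X_scale_


_Z_IDX = PARAM_NAMES.index("Z")
_PSI0_IDX = PARAM_NAMES.index("psi0")


def train_gp(ts: TrainingSet, seed: int | None = None,
             n_restarts: int = 5, tie_basal_plane: bool = True) -> GPSurrogate:
    """Fit the per-output GP stack on one training set.

    With ``tie_basal_plane`` (default) the longitudinal semi-axis Z is not
    regressed: the forward model holds the basal-plane height
    ``Z (1 - sin psi0)`` fixed during inflation, so the unloaded Z follows
    exactly from the loaded configuration and the predicted psi0.  The
    remaining five parameters (plus the located pressure in stretch mode)
    each get an independent GP.
    """
    Y = ts.Y
    if tie_basal_plane:
        Y = np.delete(Y, _Z_IDX, axis=1)
    reg = GPShapeRegressor(n_restarts=n_restarts, random_state=seed)
    reg.fit(ts.X, Y)
    out_names = PARAM_NAMES if ts.Y.shape[1] == 6 else PARAM_NAMES + ("pressure",)
    return GPSurrogate(
        regressor=reg, mode=ts.mode, conditioning=ts.conditioning,
        material=ts.material, output_names=tuple(out_names),
        tie_basal_plane=tie_basal_plane,
    )


def predict_unloaded(
    gp,
    xi_loaded: LVGeometry,
    conditioning: float | None = None,
    pressure_tol: float = 0.025,
):
    """Predict the unloaded shape for one loaded configuration.

    ``gp`` is a :class:`GPSurrogate` or a ``{pressure: GPSurrogate}``
    dictionary (the per-pressure model bank); in the latter case the
    surrogate trained at the nearest pressure within ``pressure_tol`` kPa is
    used.  Returns ``(LVGeometry, per-output predictive sd)`` in pressure
    mode and ``(LVGeometry, predicted pressure, sd)`` in stretch mode.
    Inputs far outside the training cloud trigger an extrapolation warning.
    """
    if isinstance(gp, dict):
        if conditioning is None:
            raise ValueError("conditioning pressure required for a model bank")
        keys = np.array(sorted(gp))
        j = int(np.argmin(np.abs(keys - conditioning)))
        if abs(keys[j] - conditioning) > pressure_tol:
            raise ValueError(
                f"no surrogate within {pressure_tol} kPa of P={conditioning}"
            )
        gp = gp[float(keys[j])]

    x = xi_loaded.as_array()[None, :]
    reg = gp.regressor
    center = 0.5 * (reg.X_min_ + reg.X_max_)
    half = np.maximum(0.5 * (reg.X_max_ - reg.X_min_), 1e-9)
    if np.any(np.abs(x[0] - center) > 1.5 * half):
        warnings.warn("extrapolation: input outside 1.5x the training box",
                      stacklevel=2)
    mean, sd = reg.predict(x, return_std=True)
    mean, sd = mean[0], sd[0]
    if gp.tie_basal_plane:
        # reinsert Z from the conserved basal-plane height; psi0 sits one
        # slot earlier once Z is removed from the output vector
        zeta_base = xi_loaded.zeta_base
        psi0 = min(max(mean[_PSI0_IDX - 1], -1.55), -0.01)
        z_u = zeta_base / (1.0 - np.sin(psi0))
        mean = np.insert(mean, _Z_IDX, z_u)
        sd = np.insert(sd, _Z_IDX, 0.0)
    geom = _clip_geometry(mean[:6])
    if gp.mode == "stretch" and len(mean) == 7:
        return geom, float(mean[6]), sd
    return geom, sd


def _clip_geometry(x: np.ndarray) -> LVGeometry:
    """Clamp a predicted parameter vector into the representable family."""
    R_b, Z, L, H, e, psi0 = x
    e = min(max(e, 0.0), 1.0)
    psi0 = min(max(psi0, -1.55), -0.01)
    L = max(min(L, R_b - 1.0), 0.5)
    H = max(min(H, Z - 1.0), 0.5)
    return LVGeometry(R_b=R_b, Z=Z, L=L, H=H, e=e, psi0=psi0)


# ---------------------------------------------------------------------------
# serialization (self-describing JSON bundle)
# ---------------------------------------------------------------------------

def save_surrogate(gp: GPSurrogate, path: str) -> None:
    """Write a surrogate to a JSON bundle (kernel hyperparameters,
    standardization statistics, training arrays, conditioning metadata)."""
    import json

    reg = gp.regressor
    bundle = dict(
        format="lvmech-gp-surrogate-v1",
        mode=gp.mode,
        conditioning=gp.conditioning,
        material=gp.material,
        tie_basal_plane=gp.tie_basal_plane,
        input_names=list(gp.input_names),
        output_names=list(gp.output_names),
        X_mean=reg.X_mean_.tolist(),
        X_scale=reg.X_scale_.tolist(),
        X_min=reg.X_min_.tolist(),
        X_max=reg.X_max_.tolist(),
        y_mean=reg.y_mean_.tolist(),
        y_scale=reg.y_scale_.tolist(),
        X=next(
            (g.X_train_.tolist() for g in reg.gps_ if g is not None), None
        ),
        theta=[
            None if g is None else g.kernel_.theta.tolist() for g in reg.gps_
        ],
        y_std=[
            None if g is None else g.y_train_.tolist() for g in reg.gps_
        ],
        constant=reg.constant_outputs_.tolist(),
    )
    with open(path, "w") as fh:
        json.dump(bundle, fh)


def load_surrogate(path: str) -> GPSurrogate:
    """Rebuild a surrogate from a JSON bundle (hyperparameters fixed)."""
    import json

    with open(path) as fh:
        b = json.load(fh)
    if b.get("format") != "lvmech-gp-surrogate-v1":
        raise ValueError("not an lvmech surrogate bundle")
    reg = GPShapeRegressor()
    reg.X_mean_ = np.array(b["X_mean"])
    reg.X_scale_ = np.array(b["X_scale"])
    reg.X_min_ = np.array(b["X_min"])
    reg.X_max_ = np.array(b["X_max"])
    reg.y_mean_ = np.array(b["y_mean"])
    reg.y_scale_ = np.array(b["y_scale"])
    reg.n_features_in_ = reg.X_mean_.size
    reg.n_outputs_ = reg.y_mean_.size
    reg.constant_outputs_ = np.array(b["constant"], dtype=bool)
    Xs = np.array(b["X"])
    reg.gps_ = []
    for j in range(reg.n_outputs_):
        if reg.constant_outputs_[j]:
            reg.gps_.append(None)
            continue
        kernel = (
            ConstantKernel(1.0, (1e-3, 1e3))
            * RBF(np.ones(reg.n_features_in_), (1e-2, 1e3))
            + WhiteKernel(1e-6, (1e-10, 1e-1))
        )
        kernel.theta = np.array(b["theta"][j])
        gp = GaussianProcessRegressor(kernel=kernel, optimizer=None)
        gp.fit(Xs, np.array(b["y_std"][j]))
        reg.gps_.append(gp)
    return GPSurrogate(
        regressor=reg,
        mode=b["mode"],
        conditioning=b["conditioning"],
        material=b["material"],
        tie_basal_plane=bool(b.get("tie_basal_plane", True)),
        input_names=tuple(b["input_names"]),
        output_names=tuple(b["output_names"]),
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_against_fixed_point(
    cohort,
    gp,
    P: float,
    mat: MaterialModel,
    options: SolverOptions | None = None,
    dice_spacing: float = 1.0,
) -> dict:
    """Dice agreement between GP-predicted and fixed-point unloaded shapes.

    ``cohort`` holds loaded (end-diastole-like) geometries.  For each case
    the fixed-point result is the oracle; reported per case are the Dice of
    the GP prediction and — as imaged-configuration proxies — the Dice of
    the loaded shape itself against the oracle.  Returns a dict with the
    per-case table and summary statistics (mean, 10th percentile, min).
    """
    rows = []
    for g in cohort:
        xi_fp, n_iter = fixed_point_unload(g, P, mat, options=options)
        xi_gp, *_ = predict_unloaded(gp, g, conditioning=P)
        rows.append(
            dict(
                dice_gp=dice(xi_gp, xi_fp, dice_spacing),
                dice_loaded=dice(g, xi_fp, dice_spacing),
                n_iter=n_iter,
            )
        )
    d = np.array([r["dice_gp"] for r in rows])
    return dict(
        cases=rows,
        mean=float(d.mean()),
        p10=float(np.percentile(d, 10)),
        min=float(d.min()),
        max_fp_iterations=int(max(r["n_iter"] for r in rows)),
    )
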