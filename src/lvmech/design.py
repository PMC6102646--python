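"""Parameter-space construction and latin-hypercube experiment designs.

The unloading study samples candidate unloaded shapes from a 6-D normal
distribution centered on the population-average beginning-of-diastole (BoD)
state with doubled standard deviation, stratified by latin hypercube sampling
(600 = 100 x 6 points in the full-scale study).  The admissible box spans
mean +/- 3.5 sd per parameter, intersected with hard physical bounds; samples
falling outside are projected onto the closest admissible point (a clip).
Joint constraints (minimum cavity size, wall thinner than radius) are
screened separately by :func:`is_feasible` before any simulation, mirroring
the ~11 % of sampled shapes that cannot be simulated at full scale.

The infarct study uses a plain uniform latin hypercube on a 4-D lesion box
(40 = 10 x 4 points).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, qmc

from .geometry import PARAM_NAMES, LVGeometry, _profiles, cavity_volume

__all__ = [
    "PopulationStats",
    "ParameterBox",
    "HARD_BOUNDS",
    "build_box",
    "lhs_normal",
    "lhs_uniform",
    "is_feasible",
    "sample_feasible",
]

#: Per-parameter hard physical bounds (mm / dimensionless / radians).
#: The 2 mm floor on wall thicknesses excludes sub-millimeter walls that no
#: imaged ventricle approaches (observed minima are 7.1 mm basal / 5.0 mm
#: apical) and that the forward solver cannot reliably pressurize.
HARD_BOUNDS = {
    "R_b": (5.0, 120.0),
    "Z": (5.0, 150.0),
    "L": (2.0, 40.0),
    "H": (2.0, 40.0),
    "e": (0.0, 1.0),
    "psi0": (math.radians(-88.0), math.radians(-10.0)),
}


@dataclass(frozen=True)
class PopulationStats:
    """Per-parameter mean and standard deviation, canonical order."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float).reshape(len(PARAM_NAMES))
        sd = np.asarray(self.sd, dtype=float).reshape(len(PARAM_NAMES))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)
        if np.any(sd <= 0):
            raise ValueError("all standard deviations must be positive")


@dataclass(frozen=True)
class ParameterBox:
    """Axis-aligned box of admissible parameter vectors."""

    names: tuple
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != upper.shape or len(self.names) != lower.size:
            raise ValueError("inconsistent box dimensions")
        if np.any(lower >= upper):
            raise ValueError("box is empty: lower >= upper somewhere")

    @property
    def dim(self) -> int:
        return self.lower.size

    def contains(self, x: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return np.all(
            (x >= self.lower - atol) & (x <= self.upper + atol), axis=1
        )

    def project(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


def build_box(stats: PopulationStats, k_sd: float = 3.5) -> ParameterBox:
    """Admissible box: mean +/- k_sd * sd, clipped to the hard bounds."""
    if k_sd <= 0:
        raise ValueError("k_sd must be positive (a zero box is degenerate)")
    hard_lo = np.array([HARD_BOUNDS[p][0] for p in PARAM_NAMES])
    hard_hi = np.array([HARD_BOUNDS[p][1] for p in PARAM_NAMES])
    lower = np.maximum(stats.mean - k_sd * stats.sd, hard_lo)
    upper = np.minimum(stats.mean + k_sd * stats.sd, hard_hi)
    if np.any(lower >= upper):
        raise ValueError("empty box after intersecting with hard bounds")
    if np.any((stats.mean < lower) | (stats.mean > upper)):
        raise ValueError("box does not contain the population mean")
    return ParameterBox(names=PARAM_NAMES, lower=lower, upper=upper)


def lhs_normal(
    n: int,
    stats: PopulationStats,
    sd_scale: float = 2.0,
    box: ParameterBox | None = None,
    seed: int | None = None,
) -> list:
    """LHS draw of candidate unloaded shapes from N(mean, (sd_scale*sd)^2).

    Stratified uniforms are mapped through per-parameter normal quantiles;
    samples beyond the admissible box are projected onto the closest
    admissible point.  Returns a list of :class:`LVGeometry` (possibly
    jointly infeasible — screen with :func:`is_feasible`).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    box = box or build_box(stats)
    sampler = qmc.LatinHypercube(d=len(PARAM_NAMES), seed=seed)
    u = sampler.random(n)
    x = norm.ppf(u, loc=stats.mean, scale=sd_scale * stats.sd)
    x = box.project(x)
    return [LVGeometry.from_array(row) for row in x]


def lhs_uniform(
    n: int, box: ParameterBox, seed: int | None = None
) -> np.ndarray:
    """Uniform LHS on an arbitrary box; returns an (n, dim) array."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=box.dim, seed=seed)
    return qmc.scale(sampler.random(n), box.lower, box.upper)


def is_feasible(geom: LVGeometry) -> tuple:
    """Feasibility screen; returns ``(flag, reason)``.

    A shape is feasible when the per-parameter hard bounds hold, the wall is
    thinner than its radius (R_b - L >= 5 mm, Z - H >= 5 mm), the endocardial
    radius stays above 1 mm over the profile (up to 85 % of the apex angle —
    every imaged ventricle closes below 1 mm nearer the apex), and the
    cavity holds at least 5 ml.
    """
    x = geom.as_array()
    for name, v in zip(PARAM_NAMES, x):
        lo, hi = HARD_BOUNDS[name]
        if not (lo - 1e-9 <= v <= hi + 1e-9):
            return False, f"{name}={v:.4g} outside hard bounds [{lo:.4g}, {hi:.4g}]"
    if geom.R_b - geom.L < 5.0:
        return False, "cavity too small: R_b - L < 5 mm"
    if geom.Z - geom.H < 5.0:
        return False, "cavity too small: Z - H < 5 mm"
    psi = np.linspace(geom.psi0, 0.85 * math.pi / 2, 181)
    _, _, rho_end, _ = _profiles(geom, psi)
    if rho_end.min() <= 1.0:
        return False, "endocardial radius below 1 mm along the profile"
    try:
        v_cav = cavity_volume(geom)
    except ValueError:
        return False, "cavity too small: nonpositive volume"
    if v_cav < 5.0:
        return False, f"cavity too small: {v_cav:.2f} ml < 5 ml"
    return True, "feasible"


def load_design_spec(path: str):
    """Materialize an experiment design from a YAML spec.

    Keys: ``distribution`` ("normal" or "uniform"), ``n``, ``seed``, and for
    the normal case ``sd_scale`` (default 2), ``group``/``phase`` selecting
    the population statistics, ``k_sd`` and optional per-parameter ``box``
    overrides ``{name: [lo, hi]}``.  Uniform designs require an explicit
    ``box``.  Returns a list of shapes (normal) or an (n, dim) array
    (uniform).
    """
    import yaml

    with open(path) as fh:
        spec = yaml.safe_load(fh)
    dist = spec.get("distribution", "normal")
    n = int(spec["n"])
    seed = spec.get("seed")
    if dist == "normal":
        from .datasets import population_stats

        stats = PopulationStats(
            *population_stats(group=spec.get("group"),
                              phase=spec.get("phase", "BoD"))
        )
        box = build_box(stats, k_sd=float(spec.get("k_sd", 3.5)))
        if "box" in spec:
            lower, upper = box.lower.copy(), box.upper.copy()
            for name, (lo, hi) in spec["box"].items():
                j = list(PARAM_NAMES).index(name)
                lower[j], upper[j] = lo, hi
            box = ParameterBox(names=box.names, lower=lower, upper=upper)
        return lhs_normal(n, stats, float(spec.get("sd_scale", 2.0)), box,
                          seed)
    if dist == "uniform":
        names = tuple(spec["box"])
        lower = np.array([spec["box"][k][0] for k in names], dtype=float)
        upper = np.array([spec["box"][k][1] for k in names], dtype=float)
        return lhs_uniform(n, ParameterBox(names, lower, upper), seed)
    raise ValueError(f"unknown distribution {dist!r}")


def sample_feasible(
    n: int,
    stats: PopulationStats,
    sd_scale: float = 2.0,
    box: ParameterBox | None = None,
    seed: int | None = None,
    max_factor: int = 8,
) -> list:
    """First ``n`` feasible shapes from the LHS-normal stream (deterministic).

    Oversamples in growing batches until enough shapes pass the feasibility
    screen; raises if the infeasibility rate is implausibly high.
    """
    box = box or build_box(stats)
    factor = 2
    while factor <= max_factor:
        cands = lhs_normal(n * factor, stats, sd_scale, box, seed)
        keep = [g for g in cands if is_feasible(g)[0]]
        if len(keep) >= n:
            return keep[:n]
        factor *= 2
    raise RuntimeError("could not draw enough feasible geometries")
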