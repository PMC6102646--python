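"""Passive myocardium constitutive laws.

Two strain-energy densities are implemented:

* a Fung-type orthotropic exponential (Usyk-style),
  ``W = C/2 (exp(Q) - 1)`` with
  ``Q = bff Eff^2 + bss Ess^2 + bnn Enn^2 + bfs(Efs^2+Esf^2)
  + bfn(Efn^2+Enf^2) + bns(Ens^2+Esn^2)``, where E is the Green-Lagrange
  tensor in the local fiber/sheet/normal frame;

* the Holzapfel-Ogden invariant form,
  ``W = a/(2b) exp[b(I1-3)]
  + sum_{i=ff,ss} a_i/(2b_i) {exp[b_i (I4i-1)^2] - 1}
  + afs/(2bfs) {exp[bfs I8fs^2] - 1}``.

The isotropic Holzapfel-Ogden term carries a constant offset ``a/(2b)`` at
C = I; the offset has no effect on stress and is kept so the density matches
the published functional form.  The anisotropic I4 terms contribute only in
tension (I4 > 1) by default — standard practice for fiber families that
cannot support compression; the switch is configurable per material.

Three literature parameter sets ship in a JSON registry (``usyk`` canine
Fung-type; ``whow`` swine and ``whog`` human Holzapfel-Ogden); at equal fiber
stretch they rank in increasing stiffness as usyk < whog < whow.

All moduli in kPa; energies in kPa (= mJ/ml).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

__all__ = [
    "MaterialModel",
    "StrainState",
    "LAW_FUNG",
    "LAW_HO",
    "load_material",
    "material_registry",
    "strain_energy",
    "energy_density",
    "fiber_stretch",
    "pk2_stress",
]

LAW_FUNG = "fung_usyk"
LAW_HO = "holzapfel_ogden"

_FUNG_COEFFS = frozenset({"C", "b_ff", "b_ss", "b_nn", "b_fs", "b_fn", "b_ns"})
_HO_COEFFS = frozenset({"a", "b", "a_ff", "b_ff", "a_ss", "b_ss", "a_fs", "b_fs"})


@dataclass(frozen=True)
class MaterialModel:
    """A constitutive-law identifier plus its named coefficients (kPa)."""

    law: str
    coefficients: Mapping[str, float]
    name: str = ""
    tension_only_i4: bool = True

    def __post_init__(self) -> None:
        expected = {LAW_FUNG: _FUNG_COEFFS, LAW_HO: _HO_COEFFS}.get(self.law)
        if expected is None:
            raise ValueError(f"unknown constitutive law {self.law!r}")
        got = frozenset(self.coefficients)
        if got != expected:
            raise ValueError(
                f"{self.law} expects coefficients {sorted(expected)}, got {sorted(got)}"
            )
        for k, v in self.coefficients.items():
            if v <= 0:
                raise ValueError(f"coefficient {k}={v} must be positive")
        object.__setattr__(self, "coefficients", dict(self.coefficients))

    def scaled(self, factor: float) -> "MaterialModel":
        """Homogeneously scale all stiffness-like (kPa) coefficients."""
        stiff = {"C", "a", "a_ff", "a_ss", "a_fs"}
        coeffs = {
            k: (v * factor if k in stiff else v) for k, v in self.coefficients.items()
        }
        return MaterialModel(
            law=self.law, coefficients=coeffs,
            name=f"{self.name}x{factor:g}" if self.name else "",
            tension_only_i4=self.tension_only_i4,
        )


@dataclass(frozen=True)
class StrainState:
    """Kinematic state at a material point (all tensors in a common basis)."""

    C_tensor: np.ndarray
    E_tensor: np.ndarray = field(default=None)  # type: ignore[assignment]
    J_det: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        C = np.asarray(self.C_tensor, dtype=float).reshape(3, 3)
        object.__setattr__(self, "C_tensor", C)
        if self.E_tensor is None:
            object.__setattr__(self, "E_tensor", (C - np.eye(3)) / 2.0)
        if self.J_det is None:
            det = np.linalg.det(C)
            object.__setattr__(self, "J_det", float(math.sqrt(max(det, 0.0))))

    @classmethod
    def from_deformation_gradient(cls, F: np.ndarray) -> "StrainState":
        F = np.asarray(F, dtype=float).reshape(3, 3)
        return cls(C_tensor=F.T @ F, J_det=float(np.linalg.det(F)))


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def material_registry() -> dict:
    """Raw contents of the packaged material-parameter registry."""
    text = resources.files("lvmech.data").joinpath("materials.json").read_text()
    return json.loads(text)


def load_material(key: str) -> MaterialModel:
    """Load one of the packaged parameter sets: 'usyk', 'whow' or 'whog'."""
    reg = material_registry()
    if key not in reg:
        raise KeyError(f"unknown material {key!r}; available: {sorted(reg)}")
    entry = reg[key]
    return MaterialModel(law=entry["law"], coefficients=entry["coefficients"], name=key)


# ---------------------------------------------------------------------------
# energies (vectorized core + per-point public wrappers)
# ---------------------------------------------------------------------------

def energy_density(mat: MaterialModel, C: np.ndarray, frames: np.ndarray) -> np.ndarray:
    """Strain-energy density (kPa) for batched tensors.

    ``C`` has shape (..., 3, 3); ``frames`` holds the (f, s, n) triads as
    columns of (..., 3, 3) matrices in the same basis as C.
    """
    C = np.asarray(C, dtype=float)
    V = np.asarray(frames, dtype=float)
    c = mat.coefficients
    # components in the material frame: Cf = V^T C V
    Cf = np.swapaxes(V, -1, -2) @ C @ V
    if mat.law == LAW_FUNG:
        E = (Cf - np.eye(3)) / 2.0
        Q = (
            c["b_ff"] * E[..., 0, 0] ** 2
            + c["b_ss"] * E[..., 1, 1] ** 2
            + c["b_nn"] * E[..., 2, 2] ** 2
            + c["b_fs"] * (E[..., 0, 1] ** 2 + E[..., 1, 0] ** 2)
            + c["b_fn"] * (E[..., 0, 2] ** 2 + E[..., 2, 0] ** 2)
            + c["b_ns"] * (E[..., 1, 2] ** 2 + E[..., 2, 1] ** 2)
        )
        return c["C"] / 2.0 * np.expm1(Q)
    # Holzapfel-Ogden
    I1 = np.einsum("...ii->...", C)
    I4ff = Cf[..., 0, 0]
    I4ss = Cf[..., 1, 1]
    I8fs = 0.5 * (Cf[..., 0, 1] + Cf[..., 1, 0])
    W = c["a"] / (2.0 * c["b"]) * np.exp(c["b"] * (I1 - 3.0))
    for I4, ak, bk in ((I4ff, "a_ff", "b_ff"), (I4ss, "a_ss", "b_ss")):
        stretch = I4 - 1.0
        if mat.tension_only_i4:
            stretch = np.maximum(stretch, 0.0)
        W = W + c[ak] / (2.0 * c[bk]) * np.expm1(c[bk] * stretch**2)
    W = W + c["a_fs"] / (2.0 * c["b_fs"]) * np.expm1(c["b_fs"] * I8fs**2)
    return W


def stiffness_scale(mat: MaterialModel) -> float:
    """Scalar stiffness of a material set (kPa): strain energy accumulated
    along an isochoric uniaxial fiber stretch to 1.15, reference offset
    removed.  Homogeneous in the stiffness-like coefficients, so numerical
    parameters tied to it (e.g. the volumetric penalty) scale consistently
    when a law is rescaled."""
    lam = 1.15
    C = np.diag([lam**2, 1.0 / lam, 1.0 / lam])
    w = float(energy_density(mat, C, np.eye(3)))
    w0 = float(energy_density(mat, np.eye(3), np.eye(3)))
    return w - w0


def strain_energy(mat: MaterialModel, state: StrainState, frame) -> float:
    """Strain-energy density (kPa) at a single material point.

    ``frame`` is a :class:`lvmech.geometry.FiberFrame` (or a 3x3 matrix with
    f, s, n as columns) expressed in the same basis as the state's tensors.
    """
    C = state.C_tensor
    eig = np.linalg.eigvalsh((C + C.T) / 2.0)
    if eig[0] <= 0:
        raise ValueError("right Cauchy-Green tensor must be positive definite")
    V = frame if isinstance(frame, np.ndarray) else np.stack(
        [frame.f, frame.s, frame.n], axis=-1
    )
    return float(energy_density(mat, C, V))


def fiber_stretch(C: np.ndarray, f: np.ndarray) -> float:
    """Stretch of a line element along ``f``: sqrt(f . C f)."""
    C = np.asarray(C, dtype=float).reshape(3, 3)
    f = np.asarray(f, dtype=float).reshape(3)
    nrm = np.linalg.norm(f)
    if abs(nrm - 1.0) > 1e-8:
        warnings.warn("fiber direction not unit length; normalizing", stacklevel=2)
        f = f / nrm
    return float(math.sqrt(f @ C @ f))


def pk2_stress(mat: MaterialModel, state: StrainState, frame) -> np.ndarray:
    """Second Piola-Kirchhoff stress (kPa), 2 dW/dC by central differences.

    Each tensor entry of C is perturbed by ±1e-6 and the resulting derivative
    matrix is symmetrized, which reproduces the analytic derivative of the
    smooth energy branches to ~1e-6 relative.
    """
    V = frame if isinstance(frame, np.ndarray) else np.stack(
        [frame.f, frame.s, frame.n], axis=-1
    )
    C0 = state.C_tensor
    eig = np.linalg.eigvalsh((C0 + C0.T) / 2.0)
    if eig[0] <= 0:
        raise ValueError("right Cauchy-Green tensor must be positive definite")
    h = 1e-6
    D = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Cp, Cm = C0.copy(), C0.copy()
            Cp[i, j] += h
            Cm[i, j] -= h
            D[i, j] = (energy_density(mat, Cp, V) - energy_density(mat, Cm, V)) / (2 * h)
    S = D + D.T  # = 2 * sym(dW/dC)
    return (S + S.T) / 2.0
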