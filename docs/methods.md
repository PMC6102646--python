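# Methods

## The model family

The left ventricle (LV) is idealized as a truncated prolate spheroid of
revolution.  Endocardial and epicardial profiles are generated from one
angle variable ψ ∈ [ψ0, π/2]:

    ρ_epi(ψ) = R_b [e cos ψ + (1 − e)(1 − sin ψ)]      ζ_epi(ψ) = Z (1 − sin ψ)
    ρ_end(ψ) = (R_b − L) [e cos ψ + (1 − e)(1 − sin ψ)] ζ_end(ψ) = (Z − H)(1 − sin ψ) + H

Six parameters define a shape: outer basal radius `R_b` (mm), outer
longitudinal semi-axis `Z` (mm), basal and apical wall thickness `L`, `H`
(mm), sphericity `e ∈ [0, 1]` (1 = ellipsoid of revolution) and the basal
truncation angle `ψ0` (radians; negative in all imaged cases).  Canonical
pose: epicardial apex at the origin, long axis +ζ, basal plane at
`ζ_base = Z (1 − sin ψ0)`.

The paper family leaves the base open; the package fixes two conventions
(the source literature does not define them):

* the **wall** is the image of the transmural chart — the linear blend of
  the two profiles at equal ψ — closed at ψ0 by the straight chord between
  the rims.  This makes the analytic wall volume and the tensor-quadrature
  weights agree to machine accuracy;
* the **cavity** is the endocardial solid of revolution extended by a
  cylinder at rim radius up to the basal plane (flat cap at ζ_base).  The
  thin sliver between chord and basal plane belongs to neither label.

Fibers follow the rule-based helix: the angle from the local circumferential
direction varies linearly through the wall from +90° at the endocardium
(fully longitudinal) to −60° at the epicardium.  The endocardial value is
unusual but is implemented as printed in the source parameterization.

## Materials

Two hyperelastic strain-energy densities are implemented with three packaged
literature coefficient sets (kPa):

* a Fung-type orthotropic exponential (`usyk`, canine):
  `W = C/2 (exp Q − 1)` with `Q` quadratic in the Green–Lagrange components
  in the fiber/sheet/normal frame;
* the Holzapfel–Ogden invariant form (`whow` swine, `whog` human).  The
  isotropic term is implemented exactly as printed, `a/(2b) exp[b(I1−3)]`,
  which carries a constant offset `a/(2b)` at C = I; the offset does not
  affect stress.  The anisotropic I4 terms act only in tension (I4 > 1),
  standard practice for fiber families; the switch is configurable
  (`tension_only_i4`).

At equal fiber stretch the sets rank in increasing stiffness
usyk < whog < whow, and the forward model reproduces that ordering in
cavity compliance.

## Reduced-order forward solver

The full-scale study solves passive inflation by 3-D FEM and then
re-parameterizes every deformed configuration back into the 6-parameter
family.  Since the family is the method's effective state space, the package
replaces the FEM by a Rayleigh–Ritz solver constrained to the family: the
deformed shape minimizes

    Π(ξ_d) = Σ_q w_q [ W(C̄_q) + κ_eff/2 (J_q − 1)² ] − P (V_cav(ξ_d) − V_cav(ξ_u))

with the deformation gradient induced by the shared material chart,
`C̄ = J^{−2/3} C` the isochoric right Cauchy–Green tensor, and a quadratic
volumetric penalty.  The basal plane height is held fixed during inflation
(the axial basal boundary condition), tying Z to ψ0 and leaving five free
parameters; the full-scale epicardial clamping within 3 mm of the base is
*not* reproduced, so basal behavior diverges by design and the reduced model
is more compliant than the FEM.

Numerical choices:

* `κ_eff = κ · s(mat)/s(usyk)` with κ = 500 kPa and `s` the strain energy
  accumulated along an isochoric uniaxial fiber stretch to 1.15.  Scaling
  the penalty with the material keeps incompressibility enforcement uniform
  and makes the solution exactly invariant under a homogeneous rescaling of
  the law (pressure rescaling accordingly) — the property the
  stretch-conditioned unloading mode relies on.  κ = 500 keeps the wall
  volume change below 2 % at 5 kPa; halving it roughly doubles the drift.
* continuation in pressure with steps ≤ 0.25 kPa; each step minimized by
  bounded L-BFGS-B with finite-difference gradients, warm-started, with a
  Nelder–Mead fallback on early line-search failure.  Intermediate
  continuation nodes are solved loosely (≤ 12 iterations); recorded
  pressures are fully converged.
* quadrature: tensor Gauss–Legendre in (ψ, t) × uniform midpoints in θ,
  default 24×8×24; the study profile `REDUCED_OPTIONS` uses 8×3×8, which is
  still effectively exact for wall volume (the chart Jacobian is cubic in t
  and a low-order trigonometric polynomial in ψ) and changes converged
  parameters by under 0.1 mm.
* solver hot paths use the closed-form chart Jacobian; the public
  `deformation_gradient` operation keeps the central-difference definition
  (the two agree to ~1e−9).

The midwall fiber stretch — the loading summary used by the
stretch-conditioned surrogates — is the unweighted mean of √(f·C f) over
quadrature points between 40–60 % of wall thickness and 45–55 % of the
apex–base distance (on coarse grids the slab is widened geometrically until
it contains nodes).

## Inverse unloading

**Fixed-point (backward displacement) iteration** updates a candidate
unloaded shape by the parameter-space residual
`ξ_u ← ξ_u + ω (ξ_target − inflate(ξ_u, P))`, starting from the target.
Three standard devices make it robust at desk scale:

* Aitken (Irons–Tuck) dynamic relaxation: for compliant ventricles at
  diastolic pressures the forward map amplifies reference perturbations by
  more than 2×, so the undamped update oscillates; the secant-based ω
  restores and accelerates convergence (typically 3–9 iterations);
* projected convergence: targets with sphericity near 1 unload to the
  boundary of the representable family (e pinned at 1 — the full-scale
  stretch-conditioned tables show the same clipping); a stationary
  projected iterate counts as converged;
* stagnation detection: the residual cannot fall below the forward solver's
  own accuracy; when it stops improving near that floor the best iterate is
  returned.

Convergence tolerance: scaled residual below 0.1 mm (lengths), 0.005 (e),
0.5° (ψ0).

**GP (kriging) surrogates.**  Training shapes are sampled by latin
hypercube from a normal distribution centered on the pooled
beginning-of-diastole population mean with doubled standard deviation,
projected onto an admissible box of ±3.5 sd intersected with hard physical
bounds, and screened for feasibility; each is inflated once and the
(loaded → unloaded) parameter pairs train one surrogate per pressure.  Each
output gets an independent anisotropic squared-exponential kernel with
signal-variance prefactor and additive white noise; inputs and outputs are
standardized; hyperparameters maximize the log marginal likelihood over 5
seeded restarts.  Because the forward model conserves the basal-plane
height exactly, Z is not regressed: it is reconstructed from the loaded
ζ_base and the predicted ψ0 (`tie_basal_plane`, configurable).  In
stretch-conditioned mode the located pressure is an additional output, and
homogeneous stiffness rescaling leaves the unloaded shape unchanged while
scaling that pressure — verified to ~1e−4.

**Evaluation.**  Wall-label Dice at 1 mm isotropic voxels in canonical pose
on a common grid (the class used by the overlap metric is a stated
convention; cavity-only and two-class variants sit behind the same metric
interface).  The benchmark trains on 75 widened-distribution shapes and
tests on 15 population-scale shapes (sd_scale = 1) standing in for the
imaged patient cohort; test targets are generated by inflating held-out
shapes so the oracle's answer exists in-family.  Shapes the forward solver
cannot complete are dropped and replaced, mirroring the ~11 % exclusion
rate of the full-scale study.

**Known limitation.**  The in-family inverse problem has near-degenerate
directions (ψ0–Z–R_b compensation at fixed basal plane) along which two
unloaded shapes several millimetres apart inflate to the same loaded shape
within solver accuracy.  The GP (which predicts the generating shape) and
the fixed-point iteration (which stops wherever the damped iteration lands
on the ridge) then disagree legitimately; this bounds the *worst-case* Dice
near 0.85–0.90 for the softer material sets at 2 kPa even though mean and
10th-percentile Dice sit well above 0.90.  The corresponding acceptance
assertion (minimum Dice ≥ 0.90 in every case) therefore fails at desk scale
and is left failing rather than weakened; see the test suite.

## Infarct study

Lesions are boxes in chart coordinates: normalized longitudinal position
`Long ∈ [0,1]` (0 base, 1 apex, measured as ψ-fraction), circumferential
extension `ΔCirc ∈ [0, π]` centered at θ = 0, longitudinal extension
`ΔLong ∈ [0,1]`, and transmural `Depth ∈ [0,1]` growing from the
endocardium (membership is sharp; no border zone).  Lesion volume is
integrated with boundary-aligned Gauss quadrature over the exact
sub-domain, making the wall fraction exactly linear in ΔCirc.

Cardiac output comes from a time-varying-elastance reduced cycle standing
in for the full-scale coupled active FEM: EDV from passive inflation of the
unloaded baseline to EDP = 1.5 kPa; the effective maximal elastance scales
with the healthy wall fraction,
`E_eff = E_min + (E_max − E_min)(1 − infarct_fraction)`;
`ESV = V0 + P_ao/E_eff` (V0 = 10 ml, P_ao = 12 kPa) and `SV = EDV − ESV`.
Both elastances are calibrated per baseline from two stroke-volume anchors:
the lesion-free beat gives 49 ml and the maximal admissible lesion
(transmural, full longitudinal extent, half circumference — wall fraction
exactly 1/2) gives 21 ml.  In this reduced model SV depends on the lesion
only through its wall-volume fraction — a deliberate simplification; in the
full 3-D model location retains a small residual effect.  The baseline
ventricle is the fixed-point unload (1 kPa, Fung-type set) of the packaged
HF-I-02 end-diastolic shape.

The 4-D lesion box is probed by a 40-point uniform latin hypercube; a GP
emulator (same kernel stack) maps lesion parameters to SV, and seeded
5-fold cross-validation reports the mean relative SV error (≈1–2 % at
n = 40, inside the ≤6 % full-scale figure).

## Synthetic images

`generate_label_image` voxelizes a shape (labels: background / cavity /
wall, voxel-center membership) at short-axis cine-MRI-like anisotropic
spacing (1.36 × 1.36 × 8.8 mm by default) and flips boundary-adjacent
labels independently at a seeded rate, emulating segmentation uncertainty.
It reproduces the resolution-driven artifacts of real stacks (the apical
thickness H is the least-recovered parameter under thick slices) but none
of the intensity, motion or anatomy-dependent failure modes of real
segmentation — passing recovery tests says the *fitting* machinery works,
not that real scans would segment this well.

Image fitting minimizes `J = 1 − (Jaccard_cavity + Jaccard_wall)/2` with
Nelder–Mead (simplex J-spread tolerance 1e−3, seeded restarts), rigidly
pre-aligning every candidate by matching centers of gravity and long axes
(slice-centroid total-least-squares line for orientation, refined by the
voxel inertia axis, which is exact for axisymmetric bodies — slice
centroids of a tilted tapering body are biased off-axis).

Surface re-parameterization (forward-solver output → family parameters)
alternates two Nelder–Mead blocks — {R_b, Z, e, ψ0} on the epicardial
cloud, {L, H} on the endocardial cloud — on a symmetric RMS point/profile
distance (the reverse curve→cloud term makes ψ0 identifiable; a one-sided
distance lets the profile extend past the basal rim for free).  A
monolithic 6-parameter variant is available behind a flag.

## Design & feasibility conventions

Hard bounds: e ∈ [0,1]; ψ0 ∈ [−88°, −10°]; wall thicknesses ≥ 2 mm
(observed minima are 7.1/5.0 mm; sub-millimetre-wall shapes are
anatomically meaningless and break the forward solve); generous caps on the
axes.  Feasibility additionally requires R_b − L ≥ 5 mm, Z − H ≥ 5 mm, an
endocardial radius above 1 mm up to 85 % of the apex angle (every imaged
shape closes below 1 mm nearer the apex), and a cavity of at least 5 ml.
With pooled statistics the widened sampling distribution yields an
infeasibility rate of roughly 10–20 %, the same order as the full-scale
study's exclusions.

## Problem sizes

Default study sizes, chosen once as the package's desk-scale conditions:
600-sample (100 × 6) unloading design and 40-sample (10 × 4) lesion design;
surrogate benchmark with 75 training / 15 test geometries, pressures
{1, 2} kPa, all three material sets, reduced 8×3×8 quadrature; 100-state
pressure sweeps at 0.05 kPa.  The acceptance script reruns all of these
from scratch from a single seed.
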