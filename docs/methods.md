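# Methods

## Pipeline model

The package treats a 4D-flow study as three coupled inputs: a velocity
field u(x, t) sampled on the regular acquisition grid (cm/s; grid geometry
in mm as in the NIfTI affine, node-centred samples, axis-aligned affines
only), a time-resolved tetrahedral mesh of the segmented vessel with fixed
connectivity (node coordinates in cm), and one ordered centerline polyline
per branch.  All metrics are functionals of these three objects; nothing
is re-segmented or registered here.

**Velocity transfer.**  Grid velocities reach mesh nodes and slice
vertices by trilinear interpolation (`scipy` RegularGridInterpolator).
Temporal pairing between mesh frames and velocity frames is
nearest-neighbour by default (matching per-frame reconstructions), with
linear-in-time blending available.  Points outside the grid either raise
or are zero-filled with a warning, per configuration.

**Differential operators.**  The velocity gradient is the element-wise
constant tensor from the linear shape functions of each tetrahedron:
solving E Gᵀ = U with edge matrices E and nodal velocity differences U.
This is exact for affine fields u = A x + b (and therefore for solid-body
rotation and simple shear), objective under uniform translation, and
first-order convergent in general; on the smooth Poiseuille profile the
volume-averaged vorticity converges faster (roughly second order), which
the refinement test records as "at least halves when h halves".  Strain
S = (G + Gᵀ)/2, rotation Ω = (G − Gᵀ)/2, vorticity ω = curl u (twice the
axial vector of Ω, asserted to 1e-10), Q = ½(‖Ω‖²_F − ‖S‖²_F).

**Slicing.**  A cross-section at arc-length fraction f of a branch is the
plane through the centerline point at f with normal equal to the local
tangent of the 5-point moving-average-smoothed polyline.  The
plane/tet-mesh intersection is built by marching tetrahedra (3- and
4-sided polygons, quad vertices ordered by in-plane angle); the plane is
nudged by 1e-7 cm when a node lies exactly on it.  Only the connected
component (polygons linked through shared cut edges) nearest the
centerline point is kept, so a plane that also cuts another branch keeps
the intended lumen.  Fractions are measured from the cap end of each
branch (fraction 0 at the inflow/outflow cap), so the 10% slice sits near
the branch inflow and the 50% slice mid-branch.  Surface integrals use
centroid (midpoint) quadrature per triangle, exact for linearly
interpolated integrands.  Slice normals are oriented so the time-mean flux
is positive; that orientation defines "forward" for the reverse-flow
fraction.

**Branch regions.**  Each tetrahedron joins the branch whose centerline is
nearest (point-to-polyline distance via a densely resampled KD-tree,
0.5 mm resolution).  The bifurcation region is the ball centred where the
daughter centerlines first come within one local maximal-inscribed radius
(or a configured radius) of the parent centerline; its elements are
excluded from every branch metric but still counted in the whole-mesh
volume, so branch + bifurcation volumes add up exactly.

**Keyframe interpolation.**  When only minimum- and maximum-volume
keyframe meshes exist, intermediate frames blend node positions linearly,
x(t) = (1 − α(t)) x_min + α(t) x_max, with a clipped-cosine α(t) rising
from the min-volume time to the max-volume time and falling back over the
rest of the cycle.  This requires node correspondence; diffeomorphic
registration to establish correspondence is deliberately out of scope, and
linear blending is only as good as the correspondence it is given — it
preserves per-frame volumes and areas, which is what the downstream
metrics consume.

**Windows and summaries.**  Systole is [t_ED, t_ES), diastole the
complement (wrapping past the cycle end).  When the subject record has no
timepoints, t_ED is the last sample before the systolic upstroke exceeds
10% of peak flow and t_ES the first post-peak sample below it; a
degenerate (constant) waveform yields cycle statistics only.  Means are
time-weighted trapezoids with interpolated window endpoints; max/min are
taken over samples in the window plus those endpoints.

## Metric conventions

* Vorticity is reported in both senses the field uses: the literal
  spatial average |(1/V)∫ω dV| ("vector-mean", which cancels for
  symmetric swirl) and (1/V)∫|ω| dV ("magnitude-mean").  Both live in the
  metrics table (`vorticity_vectormean`, `vorticity_magmean`); neither is
  silently preferred.
* H_d = u·ω uses element-centroid velocity (node mean) and the element
  vorticity; units cm/s² on the package's cm-based scale.  The
  positive-helicity fraction counts H_d > 0 strictly, so exact zeros
  (analytic fields) count as non-positive.
* HFI averages |cos ∠(u, ω)| with elements below a floor
  |u||ω| < 1e-6 excluded (the angle is undefined there); exclusion counts
  are logged.  HFI ∈ [0, 1] by construction.
* The acceleration time ratio is implemented as the non-negative
  (t_peak − t_ED)/(t_ES − t_ED): the time from systole onset to peak flow
  over systolic duration.  A printed form with the opposite sign
  convention appears in the literature; the non-negative convention is
  the standard acceleration-time definition and is what the tests pin.
* The Dean number uses the area-weighted mean *through-plane* velocity
  u·n on the mid slice (axial mean flow), not mean speed, with effective
  diameter D = 2√(A/π) and R_c from the centerline curvature
  κ = |r′×r″|/|r′|³ at the slice fraction (smoothed polyline, finite
  differences; straight lines return R_c = ∞ and De = 0).
* Percent-predicted RV metrics use age in years, height in cm, weight in
  kg with the published sex-specific power-law constants (RVEF a=0.0706,
  b=−0.00771, c=−0.0782, m=75.19 F / 71.52 M; RVEDV a=−0.258, b=1.582,
  c=0.382, m=27.94/31.50; RVESV a=−0.417, b=1.501, c=0.617, m=5.58/7.24;
  RVSV a=−0.187, b=1.574, c=0.304, m=21.12/22.42).
* Conservation QC: |Q_MPA − (Q_LPA + Q_RPA)|/Q_MPA with time-mean flows;
  pass below 0.20.
* Statistics: Shapiro-Wilk at 0.05 gates the paired comparison (normal →
  paired t, else Wilcoxon signed-rank; all-zero differences report "no
  difference", a constant non-zero shift is reported directly since the t
  statistic diverges).  Welch's t-test serves unpaired contrasts.  No
  multiple-testing correction is applied; significance threshold 0.05.

## Defaults that matter

| parameter | default | rationale |
|---|---|---|
| slice fractions | 0.10, 0.50 | proximal inflow slice; mid-branch slice |
| centerline-velocity core | 0.30 of slice radius | central-jet definition |
| element size | 0.12 cm | matches the finest acquisition resolution |
| voxel spacing (phantoms) | 0.10 cm | fine end of typical 4D-flow voxels |
| frames (pulsatile phantoms) | 20 over 1 s | typical cardiac frame count |
| systolic duration (phantoms) | 0.4 s | typical at rest; puts the half-sine peak on a sample |
| blood ρ, μ | 1.06 g/cm³, 0.04 P | standard blood properties |
| conservation threshold | 0.20 | QC pass criterion |
| vortex speed threshold | 30 cm/s | low-speed gate for Q>0 regions |
| HFI floor ε | 1e-6 | excludes undefined angles |
| venc (phantoms) | 300 cm/s | upper end of clinical encoding |

## Synthetic phantoms

`pa4dflow.synthetic` builds tube and Y-junction meshes by triangulating a
disc (boundary n-gon + interior hexagonal lattice, Delaunay) and extruding
along the axis; each triangular prism splits into three tetrahedra with a
globally conforming diagonal rule keyed on the smallest node index, so
face adjacency (used by vortex-region labelling) is watertight.  Curved
tubes bend the straight mesh onto a torus segment; pulsating tubes scale
the cross-section as r(t) = R(1 + δ sin 2πt/T); the Y-junction
concatenates a parent and two tilted daughter tubes meeting at the
junction point, with caps labelled MPA/LPA/RPA and centerlines ordered
cap→junction.

The analytic fields (Poiseuille u_z = u_max(1 − r²/R²), solid-body
(−Ωy, Ωx, 0), helical solid-body + W ẑ, shear (γy, 0, 0), and a
streamfunction-based mirror pair ψ = s·x·exp(−(x²+y²)/2σ²) over an axial
plug) are evaluated as smooth formulas over the whole grid: the mesh, not
the field, defines the vessel.  This keeps interpolation and
differentiation testable against exact values.  Real acquisitions instead
have noise outside the lumen and a genuine wall discontinuity;
partial-volume smoothing at the wall biases gradient-based metrics there
(a clamped-wall variant of the Poiseuille phantom shows a few-percent low
bias in magnitude-mean vorticity), which is a known limitation of any
voxel-based vorticity estimate and is not corrected for.  The Y-junction
field assigns each voxel to its nearest branch axis with mass-conserving
Poiseuille profiles (Q_parent split across daughters; an `outflow_scale`
below 1 deliberately violates conservation for QC testing).  Optional
Gaussian noise (σ as % of venc) is seeded; phantoms are otherwise
deterministic, and identical specs give identical outputs.

Ground truths come from closed forms (flow u_maxπR²/2, magnitude-mean
vorticity 4u_max/3R, helical HFI 2W(√(W²+Ω²R²) − W)/(Ω²R²), RAC
4δ/(1−δ)², Q = Ω² for solid body) or from ≥10⁶-point Monte-Carlo
quadrature of the analytic field with finite-difference curl — never from
the pipeline.

## What the phantom tests do and do not show

The phantoms exercise every reader, every operator and every metric with
known answers, including discretisation error at realistic mesh/voxel
resolutions.  They do not emulate velocity noise inside the lumen, phase
wraps, eddy-current offsets, wall-segmentation error, or genuinely
unsteady (Womersley) profiles; agreement on phantoms bounds numerical
error, not acquisition error.  Cohort-level correlation magnitudes from
any specific patient population are not reproducible from phantoms and
are not asserted anywhere.

## Problem sizes

Validation suites use the standard tube (R = 1 cm, L = 10 cm, 1.2 mm
elements → ~130k tetrahedra, 1 mm voxels) for the Poiseuille and helical
cases, a shorter L = 4–5 cm tube for the pulsating and mirror-pair cases
(20 and 4 frames respectively), and a parent 6 cm / daughters 5 cm
junction (~150k tetrahedra).  The statistical null calibration runs 1000
replicates of 20 pairs.  A full validation pass takes well under a minute
on one CPU.
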