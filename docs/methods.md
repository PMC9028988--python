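# Methods

This note records the models implemented in `srcdti`, the conventions
that make the results deterministic, the default parameters and why
they were chosen, and what the synthetic experiments can and cannot
show about real scanner data.

## Numerical left-ventricle phantom

The wall is the family of ellipsoid shells

((x−x_c)/(R_min+d_r))² + ((y−y_c)/(R_min+d_r))² + ((z−z_c)/(R_max+d_r))² = 1

with R_min = 16, R_max = 60 voxels and the shell parameter
d_r ∈ [0, 14] (the distance to the endocardium), truncated to the apex
half z ≤ z_c.  Truncating at the equator is our reading of
"semi-ellipsoid"; the cut plane acts as the base and the +z direction
as the apex-to-base long axis.  d_r is solved per voxel as a
*continuous* quantity (bisection on the monotone shell equation) so the
transmural coordinate — wall fraction d_r/14 — and hence the helix-angle
ramp are not stair-cased by the integer shell family.  The helix angle
varies linearly from +84° at the endocardial border to −84° at the
epicardial border; the transverse angle is 0° everywhere.  Local
frames are analytic (the exact shell normal), so the ground truth
carries no surface-fitting error.  The default generation grid is
160 × 160 × 128 at 1 mm; all shipped experiments use 96 × 96 × 80 with
the same radii, which holds the whole object with margin while keeping
each run in tens of seconds.

Diffusion tensors are D = Σ λ_k e_k e_kᵀ with
λ = (2, 1.5, 1) × 10⁻³ mm²/s; e₁ follows (HA, TA) in the local frame,
e₂ is the in-tangent-plane direction orthogonal to e₁'s projection and
e₃ completes the right-handed triad.  Signals follow
S = S₀ exp(−b gᵀ D g) with one b = 0 volume and the six-direction
dual-gradient scheme at b = 350 s/mm².  Outside the wall the signal is
zero (the background of the numerical study); the helicoidal phantom
instead embeds its annulus in an isotropic water compartment
(D = 2 × 10⁻³ mm²/s · I), mimicking a water-immersed physical object.

## Degradation chain

Low-resolution stacks are produced by (i) cropping the centered band of
each slice's 2-D k-space by a factor of 2 (for even sizes the extra
sample sits on the negative-frequency side of the fftshifted spectrum;
output voxel centers sit at the centroid of the aggregated input
voxels), (ii) averaging 8 consecutive planes with an ideal rectangular
slice profile, and (iii) magnitude (Rician) noise
√((S+n₁)² + n₂²), n₁, n₂ ~ N(0, σ).  σ is referenced to the in-mask
b = 0 mean of the ground truth divided by the target SNR, so all
stacks of one experiment share one noise level.  The default
SNR_LR = 40 with the stated LR/HR ratio of 4 (thin-slice voxels excite
an eighth of the spins but gain nothing back, hence SNR_HR = 10).
The absolute noise level is not pinned down by the acquisition
parameters themselves; 40 is a round mid-range value for thick-slice
cardiac DWI and all shipped checks that depend on it are directional
or carry wide tolerances.

Motion is modeled as per-slice world-space rigid transforms applied to
the slice plane during sampling — nothing else (no intra-shot motion,
EPI distortion or eddy currents; these are out of scope).

## Acquisition operator and reconstruction

The forward model of one stack is the composition D·B·T: trilinear
resampling of the isotropic volume at the slice-profile tap points
(the taps subdivide the slab at iso spacing, rectangular weights),
realized as one sparse matrix.  The adjoint is the exact matrix
transpose — *not* resampling along the inverse rotation — so the
inner-product identity holds to machine precision, which the solver
relies on.  Out-of-footprint contributions are zero (Dirichlet),
matching the zero-background phantoms.  World coordinates are NIfTI
RAS+ with 0-based voxel indices and voxel-center affines throughout.

The objective Σᵢ‖Fᵢx − yᵢ‖² + λΣ√(1 + β²|∇x|²) (forward-difference
gradient, Neumann boundary) is minimized by preconditioned gradient
descent with Armijo backtracking; the preconditioner is the row-sum
diagonal surrogate of 2ΣFᵢᵀFᵢ, the deterministic initialization is the
adjoint average ΣFᵢᵀyᵢ normalized by a ones-image projection, and the
stopping rule is a relative gradient norm of 10⁻⁶ or 500 iterations.
A Barzilai–Borwein trial-step option (`step_rule="bb"`, still
safeguarded by the line search, objective monotone) converges much
faster on well-conditioned problems and is used in tests that compare
against a dense normal-equations oracle; both rules give identical
study-level results.  The Beltrami root is smooth at zero gradient, so
no smoothing constant is needed (ε is kept only for TV-mode
experiments).  Each DWI channel is reconstructed independently —
the data term operates on scalar volumes and the channels share
operators but nothing else.

λ = 10⁻⁵ and β = 1 follow prior practice.  At these values the
regularizer is numerically negligible against the data term at any
intensity scale; the reconstruction is effectively a least-squares
fusion, and its noise behavior is governed by the operator spectrum
(see Limitations).

## Slice-to-stack registration

Each floating slice is realigned by maximizing
S(μ) = Σ_pairs r, the sum of Pearson correlations between intensity
profiles sampled (linear interpolation) along the intersection lines of
the moved slice plane and every slice of the other stacks, clipped to
both fields of view and to the world box of the shared domain Ω.
Conventions and robustness choices:

* μ = (r_x, r_y, r_z, t_x, t_y, t_z): intrinsic Z-Y-X Euler angles (deg)
  about the slice's field-of-view center, then world translations (mm).
  The center pivot decouples rotation from translation.
* Profiles from all DWI channels (b = 0 included) are standardized per
  channel and concatenated, giving one r per slice pair.
* Both profiles are averaged over the *other* slice's slab thickness
  (4 taps along the respective normals), so at the true pose both carry
  the same double blur; pairs with fewer than 8 samples are dropped and
  channels whose profile SD falls below 5 % of the stack intensity
  scale are excluded — background noise and truncation ringing carry no
  alignment information and their "correlations" are spurious.
* The term set of a slice is frozen at its pre-correction pose.  If it
  could change with the trial pose, the optimizer would raise S simply
  by acquiring additional valid intersections, a failure mode we
  observed as systematic drift toward the object center.
* The bounded search (rotations < 5°, translations < 8 mm, enforced on
  the *cumulative* correction across sweeps) runs in two stages with
  L-BFGS-B on finite-difference gradients: translations first, then a
  full 6-DOF refinement that is accepted only if it raises S by more
  than 0.01 per pair.  Rationale: out-of-plane rotation of an 8 mm slab
  is near-unidentifiable from line profiles (a 1° tilt displaces the
  sampled content by a fraction of a voxel at the line ends), and the
  residual model-mismatch slope otherwise walks the rotation parameters
  to the bounds — the local-minima risk that the near-rotational
  symmetry of the heart creates.  Multi-start at half-bound
  translations is used when the search stalls at a poor similarity.
* Sweeps are Gauss–Seidel (each corrected slice immediately informs the
  next), stacks in acquisition order, slices in index order, five outer
  sweeps by default; the per-sweep maximum parameter change is reported
  and collapses after the first sweeps.

The planted-motion experiment perturbs ~30 % of the slices that
actually intersect the phantom, with uniform rotations up to 0.5° and
translations up to 4 mm — breath-hold repositioning is
translation-dominant, and slabs containing no anatomy are unknowable to
any intersection-based method.  Under these conditions the median
recovery error is ≈ 0.4° / 0.9 mm.

## Tensor fit, frames, angles

The fit is ordinary log-linear least squares on ln S with the 7-column
design (six tensor components, ln S₀); signals are clamped at
10⁻⁶ S₀ before the log; a one-pass weighted refinement is available.
Non-positive-definite results are flagged, never silently repaired.
Eigenvalues are sorted descending; each eigenvector's sign makes its
largest-magnitude component positive and e₃ = e₁ × e₂ restores
right-handedness.  FA of the zero tensor is defined as 0; angle
statistics exclude frame-degenerate voxels (apex cap) and voxels where
e₁ ∥ e_r.

HA = atan2(e₁·e_l, e₁·e_c) after flipping e₁ to a non-negative
circumferential component (ties to the longitudinal side), hence
HA ∈ [−90°, 90°] and invariance under the antipodal ambiguity of e₁;
TA = atan2(e₁·e_r, |in-plane projection|).  Positive HA means the
fiber tilts toward the base while running counter-clockwise viewed
from the base.

The LV surface for in vivo-style frames is a variational implicit fit:
contour points constrain the zero level, points offset ±2 mm along
outward directions constrain ±2 mm, and a cubic polyharmonic RBF
(degree-1 polynomial tail) interpolates.  Two passes are made — the
second re-derives the offset directions from the first fit's own
gradient — which brings the normal error on a five-contour ellipsoid
test from ≈ 2.5° to ≈ 0.5°.  Contour duplicates (shared apex points)
are removed before solving.  For noisy contours the smoothing
parameter should be raised (σ = 0.5 mm noise needs smoothing ≈ 100 to
stay under 1 mm surface error).

## Analysis

Comparative analysis resamples every degraded or reconstructed series
back to the ground-truth grid (trilinear) before fitting, and takes
statistics over the wall mask eroded by 1 voxel at that resolution —
enough to suppress first-order partial-volume contamination while
keeping the sample large.  The transmural profile uses five equal-width
half-open wall-depth bins and an OLS slope of HA on depth in percent
(Theil–Sen available); the phantom's ramp gives −1.68 °/% exactly.
ROI SNR is mean(signal ROI)/SD(noise ROI); the shipped experiments use
a background corner box as the noise ROI because the LV cavity is
dominated by deterministic truncation ringing, not noise.

The helicoidal-phantom helix angle is averaged over a disc ROI of
radius 8 mm centred on the mid-annulus radius (replicated per slice and
intersected with the bundle), matching how a circular ROI is placed on
the bundle section in practice; because HA is linear in radius and the
disc is symmetric about the mid radius, the ROI mean equals the
mid-radius angle up to a small arc-curvature term (≈ +0.3° at these
radii).

## Problem sizes

Shipped experiments use: the 96 × 96 × 80 phantom (default radii) for
ground-truth and reconstruction studies; a 64 × 64 × 48 phantom with
proportionally smaller radii for the registration experiment; 8³–16³
lattices for operator-level checks against dense oracles.  These sizes
were chosen so that each study runs in seconds to a couple of minutes
on one CPU while leaving every wall thick enough (≥ 8 voxels) to carry
the transmural ramp.

## Known limitations

* With λ = 10⁻⁵ the reconstruction is an (almost) unregularized
  least-squares inversion.  Deconvolving the 4× slab average amplifies
  weakly-determined through-plane frequencies, so on *pure noise* the
  SR volume's background SD is higher than that of a single trilinearly
  interpolated stack; any SNR advantage observed on scanner data must
  involve effects absent from this idealized simulation (EPI-artifact
  averaging across orientations, coil noise correlations, breath-hold
  variability).  The simulation does reproduce the error *structure*:
  thin-slice scans are noise-limited everywhere, single-orientation
  thick-slice scans fail near the apex where the through-plane
  curvature is largest, and SR improves on both there.
* Thick-slice partial volume against a *zero* background cancels in the
  log-ratio of the tensor fit, so the simulated single-stack MD shows
  only the (small) Rician-floor bias, not necessarily the larger
  underestimation seen on real data.
* Out-of-plane rotations of individual slices are structurally
  near-unobservable to intersection-profile registration on a smooth,
  nearly rotationally symmetric ventricle; the implementation therefore
  corrects them conservatively (see above) rather than pretending
  sub-degree rotational accuracy.
* No EPI distortion, eddy currents, GRAPPA/partial-Fourier effects,
  intra-shot motion, multi-compartment diffusion or tractography.
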