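# srcdti — super-resolution cardiac diffusion tensor MRI

In vivo cardiac diffusion tensor imaging (cDTI) maps the helical
arrangement of cardiomyocytes, but scan-time limits force thick slices
(typically 2 × 2 × 8 mm³), which blur the through-plane structure of
the myocardium.  One remedy is to acquire **three stacks of thick
slices in different orientations** (short axis, horizontal and vertical
long axis) and combine them into an isotropic volume by
**super-resolution reconstruction (SR)**:

    ρ̂_iso = argmin_ρ  Σᵢ ‖ Dᵢ Bᵢ Tᵢ ρ − ρᵢ ‖²  +  λ Q(ρ),
    Q(ρ)  = Σ_voxels √(1 + β² |∇ρ|²)

where `Tᵢ` rotates/resamples the isotropic volume into stack *i*'s
frame, `Bᵢ` blurs along the slice-selection axis with the slice
profile, `Dᵢ` keeps one sample per thick slice, and `Q` is the Beltrami
energy — a smooth, edge-preserving relative of total variation
(defaults λ = 10⁻⁵, β = 1).  Because each slice is acquired in its own
breath-hold, a slice may be rigidly displaced; before reconstruction
every slice is re-aligned by maximizing the Pearson correlation of the
intensity profiles along its intersection lines with all slices of the
other stacks (bounded 6-parameter rigid search, rotations < 5°,
translations < 8 mm, five sequential sweeps).

From the reconstructed diffusion-weighted volumes the package fits the
tensor per voxel by log-linear least squares, derives the eigensystem,
mean diffusivity MD = (λ₁+λ₂+λ₃)/3 and fractional anisotropy FA, and
converts the primary eigenvector e₁ into the **helix angle (HA)** and
**transverse angle (TA)** in a local cardiac frame (radial e_r,
circumferential e_c, longitudinal e_l) built from an implicit surface
fitted to sparse LV contours.

The package is aimed at method developers: everything needed to study
the approach on synthetic data is included —

* a numerical left-ventricle phantom (semi-ellipsoid wall with a linear
  transmural HA ramp +84° → −84°, TA = 0°, fixed eigenvalues
  (2, 1.5, 1) × 10⁻³ mm²/s, dual-gradient scheme at b = 350 s/mm²);
* a helicoidal fiber-bundle phantom (annulus with HA linear in radius,
  34.57° → 49.57°, mean 42.07°, b = 0/500 s/mm²) immersed in water;
* the full degradation chain (k-space crop, ideal rectangular slice
  profile, Rician noise at a target SNR) and planted per-slice rigid
  motion;
* analysis utilities: eroded-mask statistics, Bland–Altman agreement,
  per-slice MAE curves, five-layer transmural HA profiles with the
  slope in °/% wall depth, and ROI SNR.

## Worked example

Simulate the numerical phantom, degrade it into three noisy orthogonal
thick-slice stacks plus a repeated single-orientation stack at matched
scan time, reconstruct, fit tensors and compare to the ground truth:

```python
from srcdti import LvPhantomSpec, DegradationSpec, ReconConfig
from srcdti.simulation import simulate_comparison

spec = LvPhantomSpec(grid_shape=(64, 64, 48), r_min=10, r_max=28, dr_max=8)
study = simulate_comparison(spec, DegradationSpec(), ReconConfig(max_iters=100),
                            seed=7, strategies=("sr", "lr"))
for name in ("sr", "lr"):
    res = study[name]
    print(f"{name.upper()}: MD = {res['md_stats']['mean']*1e3:.3f} x 10^-3 mm^2/s, "
          f"FA = {res['fa_stats']['mean']:.3f}, "
          f"HA MAE = {res['ha_mae']:.2f} deg, "
          f"TA mean = {res['ta_stats']['mean']:.3f} deg")
```

prints

```
SR: MD = 1.499 x 10^-3 mm^2/s, FA = 0.321, HA MAE = 15.37 deg, TA mean = 0.024 deg
LR: MD = 1.495 x 10^-3 mm^2/s, FA = 0.299, HA MAE = 13.00 deg, TA mean = -0.064 deg
```

Both strategies recover the ground-truth MD of 1.5 × 10⁻³ mm²/s and a
near-zero TA; the HA error at this deliberately small grid is dominated
by partial volume in the thin (8-voxel) wall — at the full study grid
(96 × 96 × 80) it drops to a few degrees.  A command-line interface
mirrors the library (`srcdti simulate|degrade|register|reconstruct|
fit|frames|report|run`); `srcdti run --config demo.yaml --out out/`
executes the whole pipeline from one YAML file and writes NIfTI
volumes, FSL-style b-tables, per-slice pose sidecars, a JSON report
and a hash manifest.

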