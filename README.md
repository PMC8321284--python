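# dbtrecon

Model-based iterative reconstruction for **digital breast tomosynthesis
(DBT)**: a limited-angle cone-beam X-ray modality that recovers the
compressed breast as a stack of thin slices from a handful (~11) of
low-dose projection views over a narrow (~30°) arc. The inverse problem is
severely underdetermined and noisy; edge-preserving regularization and
careful solver design decide whether sub-millimetre microcalcifications and
low-contrast masses are visible.

The package is aimed at researchers in tomographic image reconstruction who
want a compact, fully testable reference implementation of the
optimization-based reconstruction chain, exercisable end-to-end on synthetic
phantom data (no scanner data required).

## The model

With `x ≥ 0` the voxelized attenuation map, `b` the log-transformed
projection data (Lambert–Beer: `∫ μ dR = −ln(P/P0)`), and `M` the system
matrix, three closely related formulations are solved:

- `min_{x≥0}  ‖Mx − b‖² + λ·TV_β(x)`  — **SGP**, scaled gradient projection
  with alternating Barzilai–Borwein steps and Armijo backtracking;
- `min_x      ‖Mx − b‖² + λ·TV_β(x)`  — **FP**, lagged-diffusivity fixed
  point solving `(2MᵀM + λL(x)) d = −∇f(x)` with a few CG iterations,
  projected once at the end;
- `min_x λ·TV(x)  s.t. ‖Mx − b‖ ≤ ε, x ≥ 0` — **CP**, Chambolle–Pock
  primal-dual splitting on the four-block operator `K = (M; ∇x; ∇y; ∇z)`.

Here `TV(x) = Σ_j ‖∇x_j‖₂` is the total variation (forward differences,
periodic boundaries) and `TV_β` its smooth version `Σ_j √(‖∇x_j‖² + β²)`.
`M` is a matrix-free distance-driven cone-beam projector whose
backprojector is its exact adjoint. A fully automatic rule sets the
regularization weight: `λ₀ = 0`, `λ₁ = LS(x⁽¹⁾)/TV(x⁽¹⁾)`, `λ_k = λ₁/k`.

Reconstructions are scored with the field's standard figures of merit:
contrast-to-noise ratios for masses and microcalcifications, Gaussian-fit
FWHM of in-plane profiles (times the pixel pitch: the apparent object
width), and the artifact spread function along `Z`.

## Worked example

Simulate a textured two-tissue slab (64×64×8 voxels of 0.09×0.09×1 mm)
containing a 0.9 mm mass and a 230 µm calcium speck, scan it from 11 views
over 30°, reconstruct with SGP and the automatic λ schedule, and score the
speck:

```python
import numpy as np
import dbtrecon as d
from dbtrecon.solvers import SolverConfig, sgp_solve
from dbtrecon.metrics import ROISpec, cnr_microcalc, fwhm_from_profile, plane_profile

g = d.Geometry(
    n_angles=11, angular_range_deg=30.0, source_to_detector_mm=700.0,
    detector_rows=96, detector_cols=128, detector_pitch_mm=0.085,
    grid_shape=(64, 64, 8), voxel_size_mm=(0.09, 0.09, 1.0),
    volume_origin_mm=(-2.88, -2.88, 0.0),
)
speck_xy = -2.88 + 43.5 * 0.09  # centered on voxel (43, 43)
spec = d.PhantomSpec(
    background=d.BackgroundSpec(seed=5, texture_scale_mm=0.6),
    masses=(d.MassSpec(center_mm=(-1.2, -1.2, 4.5), diameter_mm=0.9),),
    mc_clusters=(d.MCClusterSpec(center_mm=(speck_xy, speck_xy, 4.5),
                                 n_specks=1, speck_diameter_um=230,
                                 spread_mm=0.0, seed=7),),
)
truth = d.generate_phantom(spec, g)
proj, noise_norm = d.simulate_projections(
    truth, g, d.SimulationSpec(photon_count_p0=1e5, poisson=True, seed=9))
print(f"noise norm ||b - Mx||: {noise_norm:.4f}")

mc = ROISpec("microcalc", (43, 43), 5, 4)
bg = ROISpec("background", (20, 43), 20, 4)
for iters in (5, 15):
    vol, trace = sgp_solve(proj, g, SolverConfig(lambda_="auto", max_iter=iters, tol=0.0))
    cnr = cnr_microcalc(vol, mc, bg)
    print(f"SGP {iters:2d} it: objective {trace.objective_values[-1]:.4f}  "
          f"lambda_k {trace.lambda_values[-1]:.5f}  CNR(MC) {cnr:.2f}")
profile = plane_profile(vol, 4, 43)
fwhm, width_um = fwhm_from_profile(profile[35:52], g.voxel_size_mm[1])
print(f"FWHM {fwhm:.2f} samples -> width {width_um} um (true speck: 230 um)")
```

prints

```
noise norm ||b - Mx||: 1.3010
SGP  5 it: objective 170.6689  lambda_k 0.39158  CNR(MC) 0.10
SGP 15 it: objective 25.4745  lambda_k 0.11188  CNR(MC) 4.50
FWHM 2.07 samples -> width 186 um (true speck: 230 um)
```

At 5 iterations the speck is barely above the textured background
(CNR ≈ 0.1); ten more iterations raise its contrast-to-noise ratio to ≈ 4.5,
and the Gaussian fit of the in-plane profile sizes it at 186 µm — the right
order for a two-voxel object whose 230 µm extent is diluted by the 1 mm
slice thickness.

The same experiment runs from the shell:

```sh
dbt-recon pipeline --config pipeline.yaml
```

with a YAML file naming the geometry, phantom, solvers (`sgp`, `fp`, `cp`),
iteration checkpoints and regions of interest; it writes reconstructed
volumes (32-bit TIFF), per-iteration traces (CSV), metric reports (JSON), a
solver-comparison table and a reproducibility manifest. `dbt-recon
simulate`, `reconstruct` and `metrics` expose the individual stages.

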