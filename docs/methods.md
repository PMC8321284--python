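# Methods

## Imaging model

DBT acquisition is modeled monochromatically through the Lambert–Beer law:
for view angle θ and detector cell i, the log-transformed measurement is
the line integral of the attenuation coefficient, `∫_R μ dR = −ln(P_iθ/P0)`.
Discretizing the volume into `Nv = Nx·Ny·Nz` voxels and stacking all
`Nd = Np·Nθ` measurements gives the linear system `M x = b` with `Nv ≫ Nd`
(severely underdetermined: ~11 views over ~30°). Polychromatic beam
physics, scatter and detector blur are out of scope.

**World frame.** Detector in the plane z = 0 (pixel grid centered at the
origin, X along columns, Y along rows), volume slab on top of it, source on
a circular arc of radius `source_to_detector_mm` in the XZ plane, centered
on the detector center and symmetric about the vertical. For the nominal
clinical preset: 11 views over exactly 30.0° (spacing `range/(Nθ−1)`),
700 mm arc radius, 0.085 mm pixel pitch, 0.09×0.09×1.0 mm voxels. The
vendor's exact per-angle calibration is not public; every field is
configurable.

## Distance-driven projector

`M` is matrix-free. For each view and each detector-parallel voxel slice,
the voxel's axis-aligned x/y extents are perspectively projected from the
source point through the slice **mid-plane** directly onto the detector
plane (the detector is parallel to the compression plane, so no
intermediate plane is needed). The weight coupling cell i to voxel j is the
separable overlap of the two footprints divided by the cell area, times
`Δz / cos ψ` with ψ the angle between the vertical and the ray through the
cell center. Consequences:

- a vertical ray through one voxel accumulates exactly `μ·Δz`, and a
  uniform slab yields `μ × (chord length)`: projections are length-weighted
  line integrals;
- all weights are nonnegative, and rays exiting the volume laterally simply
  accumulate less (no padding);
- the backprojector reuses the identical factors, so it is the exact
  adjoint `Mᵀ` (relative inner-product error ~1e-16 in the tests, not just
  the 1e-10 the suite demands).

Using the slice mid-plane rather than the full z extent is a deliberate
simplification: at Δz = 1 mm and ±15° the footprint shift across a slice is
≤ 0.27 mm and the approximation does not affect any qualitative result at
desk scale. All arithmetic is double precision.

`build_dense_matrix` materializes `M` for small geometries (guarded at 1e8
entries) as the oracle for equivalence and adjointness tests; the
`small-test` preset (11 views, 32×48 detector, 24×24×4 voxels) is sized to
fit under that guard.

## Regularization

`TV(x) = Σ_j ‖∇x_j‖₂` with forward differences and periodic boundaries,
taken on voxel indices (voxel anisotropy is *not* divided out; it enters
only through the projector — this convention fixes the scale of λ). The
smoothed `TV_β(x) = Σ_j √(‖∇x_j‖² + β²)` is used wherever differentiability
is needed; β defaults to 0.001. Its gradient is the negative weighted
divergence `Dᵀ(Dx/φ)`, `φ_j = √(‖∇x_j‖²+β²)`, and the lagged-diffusivity
operator `L(x₀)` freezes `1/φ` at a state `x₀`, giving a symmetric PSD
weighted Laplacian with `L(x)x = ∇TV_β(x)` exactly. The β-smoothed
diffusivity is used inside `L` (the unsmoothed form is undefined on flat
regions).

## Solvers

All three solvers share the data term `LS(x) = ‖Mx − b‖²` and cost one to
two projector pairs per iteration; none ever stores a matrix.

**SGP** (for `min LS + λTV_β` s.t. `x ≥ 0`). Iterates
`x⁺ = x + η·(P₊(x − α S ∇f(x)) − x)`. The diagonal scaling
`S = clip(x/V, [1/ρ_k, ρ_k])` uses the positive part of the gradient split
`∇f = V − U`, with `V = 2MᵀMx + λV_tv + 10⁻¹²` assembled from the diagonal
terms of the weighted-Laplacian form (both parts are nonnegative for
`x ≥ 0`); `ρ_k = 1 + 10¹⁵/k^2.1` relaxes the bound to 1 as k grows. Step
lengths alternate the two scaled Barzilai–Borwein rules
(`bb1 = ⟨s,S⁻²s⟩/⟨s,S⁻¹y⟩`, `bb2 = ⟨s,Sy⟩/⟨y,S²y⟩`): bb2 with a 3-value
minimum memory when `bb2/bb1 < 0.5`, else bb1; nonpositive curvature falls
back to `α_max`. The Armijo backtracking (σ = 1e-4, γ = 0.5) guarantees a
monotone objective, and iterates stay nonnegative by convexity of the
update. Degenerate-start tie-break: at an identically zero start the
scaling ratios `x_j/V_j` all vanish, so the first iteration uses `S = I`
with the step length set to the exact line minimizer of the quadratic data
term along the first direction — a scale-invariant choice (a fixed unit
step would make the first iterate, and with it the automatic λ₁, depend on
the arbitrary unit scaling of `b`).

**FP** (for the unconstrained `min LS + λTV_β`). Each outer step solves the
linearized system `(2MᵀM + λL(x)) d = −∇f(x)` with exactly `cg_iters`
(default 4) conjugate-gradient iterations — deliberately truncated, both
for cost and as implicit regularization — then updates `x ← x + d`.
Nonnegativity is enforced once, on the returned volume; intermediate
iterates may dip negative. The `2MᵀM` block is the actual Hessian of
`‖Mx−b‖²`; pairing the gradient `2(MᵀMx−Mᵀb)+λ∇TV_β` with an `MᵀM`-only
model would make an exact inner solve overshoot by a factor 2 and
oscillate instead of converging. Iteration accounting for cross-solver
comparisons counts one outer step as `1 + cg_iters` iterations (so a
"15-iteration" FP run is 3 outer steps).

**CP** (for `min λTV(x)` s.t. `‖Mx−b‖ ≤ ε`, `x ≥ 0`). Primal-dual splitting
on `K = (M; ∇x; ∇y; ∇z)` with `τ = σ = 1/Γ`, `Γ ≈ ‖K‖` from a seeded power
method, extrapolation `θ = 1`. Dual updates: a radial shrinkage of
`y + σ(Mx̄ − b)` by `σε` (global 2-norm), and a per-voxel projection of the
gradient dual onto the λ-radius ball. The primal update is the plain
nonnegativity projection. ε defaults to `0.01·‖b‖` unless supplied — the
synthetic simulator returns the true noise norm `‖b − Mx_true‖`, which is
the natural choice. With λ = 0 the TV dual block is dropped and the
iteration reduces to nonnegative feasibility on the data-fit ball. The
default of 2 power iterations follows common practice but can underestimate
`‖K‖` noticeably (≈40% on the small test geometry, whose `KᵀK` has a small
spectral gap); all runs converged regardless, but `power_iters` is exposed
and raising it to ~10–20 is cheap insurance. The automatic λ schedule is
not applied to CP: λ there only gates the dual TV projection while ε
governs the data fit, so a decreasing λ would weaken the regularizer
without the compensating mechanism the penalized forms have.

**Automatic regularization weight.** `λ₀ = 0` (first iteration fits data
only), `λ₁ = LS(x⁽¹⁾)/TV(x⁽¹⁾)` balances the two terms at the first
iterate, `λ_k = λ₁/k` afterwards. A flat first iterate (TV = 0) is rejected
as degenerate. Constant-λ defaults, used when the schedule is off: 0.005
for SGP and CP, 0.001 for FP.

**Stopping.** `|f(x⁽ᵏ⁾) − f(x⁽ᵏ⁻¹⁾)| / |f(x⁽ᵏ⁾)| < tol` (default 1e-6).
The absolute value makes the same test usable for the non-monotone CP
iteration; fixed-iteration runs set `tol = 0`.

## Image-quality metrics

- Mass CNR: `(μ_MS − μ_BG)/(σ_MS − σ_BG)` over circular ROIs (population
  standard deviations). The difference-of-σ denominator is unusual — it can
  vanish or change sign — and is implemented verbatim with an error branch;
  a `denominator="background"` switch provides the common `σ_BG`-only
  variant without changing the default.
- Microcalcification CNR: `(max_MC − μ_BG)/σ_BG`.
- Plane profile: the intensity trace along Y through the object on its
  slice. FWHM: a Gaussian with additive offset, `a + h·exp(−(y−c)²/2d²)`,
  is fitted by nonlinear least squares (offset included because real
  backgrounds are nonzero; width initialized from the half-maximum crossing
  count, which is robust to baseline noise where a central second moment is
  not); `FWHM = 2√(2 ln 2)·d` and `w = FWHM·Δy` (reported in integer µm)
  approximates the physical object width. Flat or unfittable profiles raise
  a `FitError`, mirroring objects not discernible from background.
- ASF: `|μ_MC(z) − μ_BG(z)| / |μ_MC(z̄) − μ_BG(z̄)|` per slice with
  3-pixel-diameter circles; equals 1 at the in-focus slice by construction.
  On heterogeneous backgrounds the off-focus values mix limited-angle smear
  with genuine texture differences between the two columns; it is cleanest
  on locally flat backgrounds.

ROIs are the voxels whose in-plane center distance to the ROI center is at
most half the diameter (Euclidean, voxel units).

## Synthetic phantom and noise

The generator emulates a swirled two-tissue breast imaging slab:

- background: a seeded Gaussian random field, smoothed at `texture_scale_mm`
  and thresholded at the quantile matching the gland fraction (default
  50/50), valued `mu_adipose = 0.05 /mm` vs `mu_gland = 0.08 /mm`;
- masses: low-contrast spheres (default `0.09 /mm`, diameters at the
  millimetre scale);
- microcalcification clusters: high-contrast specks (default `0.4 /mm`,
  130–400 µm) placed at seeded offsets within a disc around the cluster
  center, all on one slice.

Attenuation defaults are nominal ~20 keV contrast orderings — configuration
values, not physics claims. Spheres are rendered with partial-volume
blending: each boundary voxel gets the sub-sampled sphere-voxel overlap
fraction, with the sub-grid refined per axis to about a quarter of the
sphere radius — without this, a 130 µm speck inside a 1 mm-thick voxel
would fall between sample points and vanish. The 1 mm slice thickness
therefore caps a speck's rendered peak far below its true μ, which is
physically faithful.

Projections: expected counts `P0·exp(−Mx)`, optional per-cell Poisson draws
(seeded), counts clipped to ≥ 1 before the log (−ln 0 guard), and the exact
noise norm `‖b − Mx‖` returned for use as CP's ε. Default photon budget
`P0 = 1e5` per cell; the low-dose fixtures use `P0 = 5e3`.

What the generator does **not** emulate: anatomy-shaped breast outlines,
scatter, detector MTF or electronic noise, polychromatic hardening. Passing
tests demonstrate correctness of the operators, solvers and metrics under
the stated noise model — not clinical image quality.

## Numerical choices and test design

- Problem sizes: the oracle geometry (24×24×4 voxels, 11 views on a 32×48
  detector) keeps the dense `Nd×Nv` matrix materializable; end-to-end runs
  use 64×64×8 voxels on a 96×128 detector. Both reconstruct in seconds on
  one CPU while exhibiting the limited-angle behavior of interest.
- Cross-solver agreement is measured at matched λ = 0.005, β = 0.001 on a
  seeded noisy textured slab; SGP and FP converge to the same optimum to
  ~1e-4 % in data fit, and CP with ε set to the true noise norm lands
  within a few percent (it sits exactly on the ε-ball boundary, the
  penalized optimum slightly inside).
- The auto-λ-vs-no-regularization RMSE comparison uses a genuinely
  piecewise-constant phantom (uniform slab + objects) at low dose — the
  regime TV regularization targets. On a fine binary texture the schedule's
  early large λ over-smooths at small iteration counts, which is expected
  behavior, not a defect.
- FWHM recovery under noise is tested on densely sampled profiles: with a
  free offset the Cramér–Rao bound for the width of a unit-spaced 64-sample
  Gaussian at 5% noise is ≈4% — above the 2% test tolerance — so the
  fixture samples at 0.0125-unit spacing where the bound is ≈0.9%.
- The power-method oracle test runs 150 iterations: the small spectral gap
  of `KᵀK` on the test geometry makes shorter runs settle only to ~2e-3
  relative.
- Degenerate inputs: zero-curvature BB steps fall back to `α_max`;
  exhausted line searches raise; CG flags indefinite operators; a zero
  objective makes the relative stopping rule report convergence.

## Known limitations

- The distance-driven footprint uses the slice mid-plane; very thick slices
  or much steeper arcs would need the full z-extent treatment.
- Periodic TV boundaries couple opposite volume faces; negligible for slabs
  with quiet borders, but visible if objects touch the boundary.
- The mass-CNR denominator `σ_MS − σ_BG` is kept verbatim for
  comparability; prefer the background-σ variant for new work.
- No GPU path and no ordered-subsets acceleration; the implementation
  favors verifiability over throughput.
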