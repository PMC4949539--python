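# Methods

## Four-compartment voxel model

A voxel's water is split into myelin water (v_mwf), intra-axonal (v_in),
extra-axonal (v_ex) and free water (v_iso), fractions summing to 1.
Multi-echo T2 relaxometry observes all four pools; diffusion-weighted
imaging observes only the last three, because myelin water's T2 (~20 ms) has
decayed by the diffusion echo time. The diffusion fit therefore estimates
*primed* fractions on the visible pool, and fusion rescales them by
(1 − v_mwf). The bulk g-ratio treats axons as long concentric cylinders, so
that the ratio of cross-sectional areas gives Γ = (v_mwf/v_in + 1)^(−1/2)
per voxel — a population average, not a per-axon geometry.

## Relaxometry

The echo train (default 32 echoes, 12 ms spacing, matching the GraSE
acquisition this framework targets) is modelled as a nonnegative mixture of
EPG decay curves over a log-spaced T2 grid. Defaults and rationale:

- **T2 grid**: 60 log-spaced points on [15, 2000] ms — spans the myelin
  band and the free-water band with the 50/350 ms cutoffs interior to the
  grid.
- **Band edges**: v_mwf is spectral mass strictly below 50 ms, v_iso
  strictly above 350 ms; grid points exactly at a cutoff count as tissue.
- **Tissue T2**: amplitude-weighted geometric mean of the mid-band, the
  common multi-component convention for a single representative T2.
- **Flip-angle estimation**: stimulated echoes from imperfect refocusing
  distort short-T2 estimates if ignored, so each voxel's refocusing angle α
  is estimated first from a three-component EPG fit (fixed T2 triplet
  {20, 120, 800} ms) over a 1° grid on [90°, 180°], ties toward 180°, then
  held fixed for the full spectrum fit (two-stage scheme).
- **Solver**: plain NNLS by default; a Tikhonov term (λ‖m‖²,
  `regularization`) is exposed because unregularized NNLS on dense grids
  yields spiky spectra — band *sums* are robust either way, which is why the
  default stays 0.
- **T1**: fixed at 2000 ms (neonatal tissue scale); it only enters the EPG
  stimulated-echo pathways and is configurable. T1 regrowth of equilibrium
  magnetization during the short train is neglected.

## Diffusion

Three compartments on two shells (default protocol: 1 b=0, 16 directions at
b=750 s·mm⁻², 32 at b=2000 s·mm⁻², directions from deterministic Fibonacci
hemispheres):

- **Intra-axonal**: sticks dispersed by a Watson distribution
  (density ∝ exp(κ(μ·n)²)). The dispersed-stick signal
  ∫f(n)exp(−b d∥(x·n)²)dΩ is evaluated by product quadrature in the frame
  of μ — 28-point Gauss–Legendre in cosθ on [0,1] × 32-point trapezoid in
  φ, exploiting the joint antipodal symmetry; the same rule normalizes the
  kernel, so the κ=0 limit is exact and the worst error against a dense
  spherical oracle is ~2·10⁻⁵ for κ ≤ 150.
- **Dispersion index**: κ is optimized as log κ on [e⁻⁴, e⁵]; reported
  dispersion is γ = (2/π)·arctan(1/κ), monotone with γ=0 for parallel
  sticks and γ=1 for isotropic orientations.
- **Extra-axonal**: axially symmetric tensor aligned with μ, perpendicular
  diffusivity from the tortuosity rule d⊥ = d∥(1 − v′_in/(v′_in+v′_ex)).
- **Diffusivities**: d∥ = 1.9·10⁻³ and d_iso = 3.0·10⁻³ mm²/s, fixed
  (neonatal-tissue convention for this model family), configurable.
- **Fitting**: signals are normalized by the mean b=0; trust-region
  nonlinear least squares with the fractions parameterized on the simplex
  (v_iso plus the intra share of the anisotropic pool, both box-bounded),
  multi-started from the log-linear tensor-fit principal eigenvector plus
  five fixed icosahedral-style directions (6 starts total), lowest cost
  kept with deterministic tie-breaking by start order.

## ROI and cohort statistics

Weighted regional means use Σwx/Σw with NaN voxels excluded from both sums;
the confidence half-width is 1.96 × the weighted SE with Kish effective
sample size n_eff = (Σw)²/Σw². The CI level (95%) is a documented
convention, configurable via the multiplier. Regional Γ uncertainty uses
the first-order delta method with analytic partials and independent errors;
correlated-error terms are omitted. ROI-level Γ is the mean of per-voxel Γ,
not Γ of the ROI-mean fractions — voxels with v_in < 0.01 are excluded as
effectively unmyelinated/empty to avoid ratio blow-up (threshold in
config).

Trends are OLS on EGA with Pearson r and t-distribution p-values; repeated
scans enter cross-sectional fits as independent points (a per-subject
two-point rate summary is provided separately). Partial correlations
residualize both variables on the covariates; an exactly collinear variable
yields r_partial = 0 by convention. Fisher z compares two correlations with
the usual 1/(n−3) variances. Significance is two-sided at 0.05 with no
multiplicity correction, by design.

## Synthetic data

The generator emulates every input with known truth: four-compartment
voxels (default compartment T2s 20/110/130/1500 ms — inside the spectral
bands the summaries integrate), EPG-consistent echo trains at a per-voxel
flip angle, Watson-dispersed two-shell DWI signals emitted at primed
fractions (so the fusion correction is exactly invertible), Rician noise
with SNR referenced to the first echo (T2) or b=0 (DWI), Gaussian-profile
"tract" weight tubes between region centroids, and cohorts with linear
EGA trends sampled uniformly on 27–58 weeks. Everything is a pure function
of (spec, seed).

What passing the synthetic tests does **not** show: the phantoms have
piecewise-constant truths with at most linear v_mwf ramps, no anatomy, no
partial-volume mixing beyond the model itself, no inter-compartment water
exchange, no motion or eddy-current artifacts, and both modalities are
perfectly co-registered by construction. Recovery numbers on real data will
be worse in proportion to how far those assumptions fail.

## Problem sizes and numerical choices

The validation suite uses 200-voxel batches for noisy recovery claims
(relaxometry at SNR 200, diffusion and the fused g-ratio at SNR 25), an
8×8×2 demo phantom for the end-to-end drivers, and 500 seeded cohorts of
n=40 for trend-CI coverage — sizes chosen so the whole suite runs on a
single CPU in a few minutes while keeping Monte-Carlo error well below the
tolerances tested. Degenerate inputs return missing values rather than
raising wherever the ambiguity is physical (all-zero echo train, empty ROI,
v_in = 0 in Γ) and raise for contract violations (shape mismatches,
out-of-range fractions, missing b=0).

## Known limitations

- At SNR 25 on the two-shell protocol the extra-axonal/free-water split is
  weakly identified (their noisy errors are several times v'_in's); v'_in,
  v_mwf and Γ are the robust outputs.
- The flip-angle grid is 1°; sub-degree B1 variation maps into ≤ ~0.005
  v_mwf variation and is ignored.
- Inputs to fusion must already share a voxel grid; no resampling is
  provided.
- The fixed-diffusivity convention biases fractions if the true
  diffusivities differ substantially; both are exposed in config.
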