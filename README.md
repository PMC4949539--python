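# neomyelin

Joint multi-echo T2 relaxometry and multi-shell diffusion MRI quantification
of developing white matter.

Diffusion MRI is sensitive to tissue microstructure but blind to myelin: the
T2 of myelin-bound water is far below the diffusion echo time, so an
increasing intra-axonal volume fraction can reflect either axonal growth or
myelination. Multi-echo T2 relaxometry resolves the fast-decaying myelin
water pool but carries no orientation information. This package implements
the joint framework that reconciles the two for the developing (neonatal)
brain: voxels are modelled as four water compartments — myelin water,
intra-axonal, extra-axonal, and free water — with relaxometry measuring the
first and diffusion the other three, and the fused model yields a
myelin-corrected axonal fraction and a bulk g-ratio per voxel. It is aimed
at researchers analysing quantitative MRI of preterm/neonatal cohorts and at
anyone who needs an EPG-corrected myelin-water fit or a Watson dispersed-stick
diffusion fit with a fully synthetic validation path.

## Model

**Relaxometry.** The echo train is a nonnegative superposition over a
log-spaced T2 grid, `S_n = Σ_j m(T2_j) E_n(T2_j; α)`, where `E_n` are
extended-phase-graph (EPG) echo amplitudes at the local refocusing angle α
(estimated per voxel from a coarse three-component fit, then fixed). The
myelin water fraction is the spectral mass at T2 < 50 ms, free water the
mass above 350 ms, and the mid band is tissue water with a geometric-mean
tissue T2.

**Diffusion.** A three-compartment dispersed-stick model on the DWI-visible
pool:

    S(b,x) = S0 [ v'_iso e^(−b d_iso)
                + v'_in ∫ f(n; κ) e^(−b d∥ (x·n)²) dΩ
                + v'_ex e^(−b xᵀD*x) ]

with `f` a Watson distribution of concentration κ (reported as dispersion
γ = (2/π)·arctan(1/κ)) and `D*` the tortuosity-scaled extra-axonal tensor.

**Fusion.** Because DWI sees no myelin water, the primed fractions are
rescaled to total-water fractions by `v_in = v'_in (1 − v_mwf)` (and likewise
for v'_ex, v'_iso), and the bulk g-ratio follows from the volume fractions
of a long-cylinder population:

    Γ = (v_mwf / v_in + 1)^(−1/2)

Weighted-ROI aggregation (uniform or tractography-visitation weights),
delta-method uncertainty for regional Γ, and cohort statistics (linear
parameter-vs-EGA trends, EGA-adjusted partial correlations, Fisher-z rate
comparison) complete the pipeline.

## Worked example

The package ships the published longitudinal regional means for seven very
preterm infants scanned twice (preterm and term-equivalent). Recomputing the
myelin correction and the attribution statistic from the printed v'_in and
v_mwf columns:

```
$ python analysis/01_longitudinal_tables.py
thalamus corrected v_in: recomputed vs printed, max |dev| = 0.0005
PWM corrected v_in: recomputed vs printed, max |dev| = 0.0004
myelin-attributable share of the thalamic v'_in increase over 7 infants: 0.27 +/- 0.06 ...
```

The first two lines say the printed corrected-v_in columns are reproduced to
their printed precision; the third is the headline statistic: myelin growth
accounts for 0.27 ± 0.06 of the apparent intra-axonal increase in the
thalamus — most of the diffusion change is not myelination.

A fully synthetic round trip (generate phantom → fit both modalities → fuse):

```
$ python analysis/02_phantom_roundtrip.py
     case parameter  mean_abs_error  ...
noiseless   g_ratio        0.008922  ...
```

i.e. the bulk g-ratio is recovered to ~0.01 noiseless (0.017 worst voxel)
and to a median ~0.03 under realistic noise (Rician SNR 200 for the echo
trains, 25 for DWI). `analysis/03_cohort_trends.py` does the same for the
cohort statistics (e.g. a −2.24 ms/week tissue-T2 trend is recovered as
−2.29 ms/week, r = −0.98).

A `neomyelin` CLI wraps the same library: `simulate`, `t2fit`, `dwifit`,
`fuse`, `roi`, `stats` and `run` (the chained pipeline). For example:

```
neomyelin simulate --out sim/ --seed 3
neomyelin run --echoes sim/echoes.nii.gz --dwi sim/dwi.nii.gz \
    --bvals sim/bvals --bvecs sim/bvecs --mask sim/mask.nii.gz --out out/
```

## Layout

- `src/neomyelin/` — library: `epg`, `relaxometry`, `diffusion`, `fusion`,
  `roi`, `cohort`, `synthetic`, `tables`, `io`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers writing tables under `results/`.
- `docs/methods.md` — model, assumptions, numerical choices, limitations.
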