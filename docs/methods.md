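# Methods

## Binding model

A probe carries two sites for a protein complex. At equilibrium the four
microstates (empty, site A only, site B only, both) have Boltzmann weights
`{1, α, α, Cα²}` with `α = [P]/K_d` the statistical weight of single-site
occupancy and `C` the cooperativity factor; grouping by the number of bound
complexes gives `P0, P1, P2 = (1, 2α, Cα²)/Z`, `Z = 1 + 2α + Cα²`. The
second-site dissociation constant is `K_d/C` by construction. A two-site
competent fraction `f` mixes this with the one-site polynomial `1 + 2α`:
the `1−f` component contributes to `P0` and `P1` only. The model is
equilibrium-thermodynamic; no kinetics, no more than two sites, one `K_d`
shared by both sites.

Assumptions worth stating explicitly:

- **Nominal concentrations.** `α` uses the titrated protein concentration
  as loaded; no free/total (ligand-depletion) correction is applied even
  though the probe (≈1.75 nM in the emulated design) is comparable to the
  lowest titration point (2.5 nM). At the low end of the ladder the
  effective free concentration is therefore slightly overstated.
- **Per-lane normalization.** Band fractions are `band_i / Σ bands`,
  assuming probe conservation within a lane; there is no cross-lane loading
  correction and no no-protein reference normalization.
- **Three states only.** Lanes containing species outside the
  0/1/2-complex ladder must be pre-aggregated by the user.
- `α = 0` returns exactly `(1, 0, 0)` without forming `Cα²`, so extreme
  `C` cannot generate 0·∞ artifacts at zero concentration.

All concentrations are nM throughout.

## Parameters

| parameter | units | domain | role |
| --- | --- | --- | --- |
| `K_d` | nM | > 0 | single-site dissociation constant |
| `C` | – | > 0 | second-site enhancement; `K_d,2nd = K_d/C` |
| `f` | – | [0, 1] | fraction of probes able to bind two complexes |

## Fitting

The objective is unweighted least squares on normalized band fractions,
one residual per lane and band (inverse-variance weighting by replicate SD
is available but off by default; fitting per-concentration replicate means
instead of all lanes is likewise optional). Fits are always per condition,
never pooled.

Optimization runs in `(log10 K_d, log10 C, f)` — logs for conditioning over
the ladder's dynamic range, `f` bounded natively — with box bounds
`K_d ∈ [1e-3, 1e6] nM`, `C ∈ [1e-3, 1e3]`, `f ∈ [0, 1]`, using SciPy's
trust-region-reflective least squares with an analytic Jacobian. Starts
form a fixed deterministic grid: `K_d` at each power of ten spanning the
ladder × `C ∈ {0.1, 1, 10}` × `f ∈ {0.5, 0.9}` (24 starts for the default
ladder). The lowest SSR wins; SSR ties within 1e-12 break toward the `C`
closest to 1, the conservative no-cooperativity default. Estimates within
1e-6 (internal coordinates) of a bound are flagged `at_bound`. Designs with
fewer than 3 distinct concentrations are rejected as unidentifiable.

A brute-force grid search (`grid_oracle`, default 40×40×20 over the same
box) provides an independent check that the optimizer's SSR is never worse
than exhaustive enumeration; it is a verification tool, not the estimator.

## Bootstrap

Percentile bootstrap, default 5,000 resamples at the 95% level. Each
resample redraws every lane's fractions independently per band from a
Gaussian centred on the concentration's replicate mean, truncates at 0 and
renormalizes the lane; refits warm-start from the point estimate plus one
no-cooperativity fallback start (the full multistart grid is unnecessary
for perturbations of a solved problem and would make coverage studies
impractically slow). Sub-seeds are spawned from the master seed by NumPy's
`SeedSequence.spawn`, so enlarging `n_boot` extends the resample stream
without reshuffling earlier draws; results are bit-reproducible per seed.

The Gaussian scale is *calibrated*, which is the one place this
implementation goes beyond the obvious recipe. Drawing at the observed SD
and then renormalizing each lane shrinks the realized per-band SD by about
`sqrt(1 − 2m + 3m²)` (delta method, `m` the band's mean fraction), and the
sample SD of `n` replicates underestimates the underlying scale by the
normal-theory factor `c4(n)` (≈0.886 at n = 3). Both factors are divided
out so resamples actually carry the data's mean and SD; without the
correction, resampled datasets are systematically quieter than the data and
the nominal 95% interval covers at only ~85%. With it, empirical coverage
in the simulation study is ~93%. The calibration ignores the effect of
zero-truncation on cells whose mean fraction is near 0, where resample
moments remain slightly off.

Independence across bands and Gaussianity are modelling choices — the
minimal reading of "same mean and SD" — not derived properties.
Single-replicate concentrations have no measurable spread; resampling then
refuses to run unless an explicit `sd_override` supplies the noise scale.
More than 50% failed refits aborts with a failure census.

## Synthetic data

The generator emulates a gel titration: a geometric concentration ladder
(default 4-fold, 2.5–640 nM — five points bracketing the default
`K_d = 40 nM` by more than an order of magnitude each way), 3 replicates
per concentration, true mixture-model fractions per lane perturbed by
additive Gaussian noise on the fraction scale (default SD 0.02), clipped at
0, renormalized, and scaled by a constant lane total of 10,000 arbitrary
units. Presets encode the four study conditions: `wt_sps` (C = 5) and
`ra_sps`, `wt_2xcsl`, `ra_2xcsl` (C = 1), all with `K_d = 40 nM` and
`f = 0.85`. The `K_d` and `f` defaults are synthetic choices placed
mid-ladder for identifiability (and `f < 1` reflecting that single-shift
bands persist at saturation); they are not measured values.

What the generator does **not** emulate: raw-intensity (multiplicative or
Poisson-like) noise, lane-to-lane loading variation, band smearing or
background, correlations between bands beyond the renormalization
constraint, and ligand depletion. Passing tests therefore demonstrate
correctness of the estimator under its own noise model, not robustness to
every artifact of real densitometry.

## Numerical choices

- Occupancy normalization holds to 1e-10 over 10⁶ random parameter draws
  (exactly by construction, up to rounding).
- Optimizer tolerances `xtol = ftol = gtol = 1e-12`; analytic Jacobian
  verified against finite differences.
- CSV round-trips doubles bit-exactly (`%.17g` on write,
  `float_precision="round_trip"` on read).
- Replicate SD uses ddof = 1; a single replicate reports SD 0 plus a
  `single_replicate` flag rather than NaN.
- Degenerate resample draws whose lane sums to 0 after truncation fall back
  to the mean fractions (vanishingly rare at realistic noise).

## Study sizes used in the shipped checks

The test suite's simulation studies use 200 synthetic series for parameter
recovery, 20 series against the grid oracle, and 500 datasets × 200
resamples for bootstrap coverage; the acceptance script runs the recovery
study at 200 series and coverage at 200 × 200, with 500-resample bootstrap
intervals per condition. These sizes make Monte-Carlo error small relative
to the bands being checked while keeping a full run in the minutes range.

## Limitations

- `C` and `f` trade off weakly when the supershift saturates early; designs
  whose ladder does not bracket `K_d` can push estimates to bounds (the
  `at_bound` flag and the grid oracle are the diagnostics).
- Percentile intervals are not bias-corrected (no BCa); with 3 replicates
  the coverage of the 95% interval sits a little below nominal even after
  SD calibration.
- The bootstrap models band fractions, not raw intensities; if densitometry
  noise is strongly multiplicative the resampling scale is approximate.
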