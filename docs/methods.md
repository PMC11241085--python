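# Methods

## Model and scope

The package estimates the one-tailed lower 95% confidence limit (CL) of
PB_max — the maximum monosyllable identification score, in percent — as a
function of the pure-tone average (PTA, dB HL, mean of the 0.5/1/2/4 kHz
air-conduction thresholds), for ears with sensorineural loss. Ears with an
air–bone gap ≥ 15 dB at two or more of 0.5/1/2 kHz are excluded as
conductive. Left and right ears are analyzed separately throughout; the
record model keys on (participant, ear), and the split-half harness splits
by participant so that paired ears never straddle a fitting/test boundary.

All three estimators express the limit through one link function,

    PB_max(PTA) = β1 (2 − exp(β2 · PTA^β3)),   β1 ∈ (0, 110], β2 ∈ [0, 1], β3 ∈ [0, 5],

anchored at β1 for PTA ≤ 0 and clamped below at 0. The form decays to zero
steeply at high PTA, matching clinical data in which scores approach zero
near 90 dB HL. The corner case β3 = 0 is defined as the flat curve at β1
(taking 0⁰ = 1 would break the PTA = 0 anchor), and the exponent argument
is capped at 700 to avoid overflow at extreme parameter/PTA combinations.

## Sub-group conventions

Published bin labels ("<15", "16–25", …) nominally leave gaps. Bins here
are contiguous intervals with cut points at label midpoints (…, 15.5],
(15.5, 25.5], …), so every PTA on the 1.25-dB audiometric grid is
assignable to exactly one bin; this preserves the printed group means while
making assignment total. How a PTA of exactly 15.x was binned in the source
tables is not recoverable; the midpoint convention is this package's
choice. Sub-group moments use the sample SD (n − 1); skewness is the third
standardized moment and kurtosis the fourth *without* excess correction
(normal → 3), the convention under which near-normal clinical groups print
kurtosis ≈ 3–5. Scores off the 4-point grid are warned about but kept by
default (simulation intermediates are continuous); a strict mode rejects
them for cohort files.

## Method 1: censored-normal Monte Carlo

Per sub-group, 50,000 draws from Normal(mean, SD) are *clamped* into
[0, 100] — censoring, not truncate-and-resample, following the procedure's
"set to 100 / set to 0" wording — and the CL is the order statistic at rank
⌈0.05 · n_sims⌉ ("the value below which 5% fell"), rounded to the nearest
multiple of 4 with halves away from zero. At 50,000 draws the choice among
standard percentile definitions is immaterial (< 0.01 difference). The SE
uses the asymptotic order-statistic formula at the *clinical* sub-group's
N with the fitted normal density; this reproduces published SE columns to
about 1%. A historical SD variant (1.62 × binomial SD of a 25-trial
proportion) is exposed as `sd_mode="binomial_x1.62"` for comparison only.
Per-bin seeds are spawned from the master seed by bin index, so adding or
removing a bin does not perturb the other bins' draws.

Some published rows are not arithmetically self-consistent (their printed
CL cannot be derived from their printed measured SD under the stated
censoring); reference checks therefore use only the eight self-consistent
rows.

## Method 2: Harrell–Davis

Weights are computed from the regularized incomplete Beta function (never
Monte Carlo), cached per (n, q), with denormal-negative increments from
floating-point rounding clamped to zero. Bootstrap SEs use n_boot = 1000
by default (run-to-run SE stability better than 5% at that size; the
source procedure does not state a count). Bins under 10 ears get a
small-sample warning; no further bias correction is applied beyond the
estimator itself.

## Method 3: nonlinear quantile regression

The check-loss objective is non-smooth and the link is nonlinear in β, so
the fit uses derivative-free Nelder–Mead over (β1, log10 β2, β3) — β2
spans several decades — restarted from a fixed 3×3×3 grid
(β1 ∈ {80, 90, 100}, β2 ∈ {10⁻⁵, 10⁻³, 10⁻²}, β3 ∈ {1.0, 1.5, 2.2})
covering the plausible fitted range, with the winning solution polished by
two further simplex restarts. The fit is deterministic. Box constraints
are enforced by a quadratic penalty outside the box plus clipping inside
the objective. Noise-free data are recovered to better than 10⁻³ relative;
on tiny instances the minimized loss matches an exhaustive coarse grid
search. Goodness of fit is R¹(τ) = 1 − (fitted check loss)/(check loss of
the constant sample-τ-quantile model), the Koenker–Machado analog of R².
Parameter SEs are participant-level bootstrap SDs (n_boot ≥ 200), each
resample refitted from the full-data solution.

The least-squares curve fit to sub-group points uses bounded trust-region
least squares from the same start grid; it is unweighted by default (a
sub-group-size-weighted mode exists) and reports R².

## Evaluation harness

DEV = 5 − percent_below, where percent_below counts test-half ears
*strictly* below the curve (scores exactly on the limit are not "below" —
this matters on a discrete 4-point grid). Negative DEV means the curve
sits too high and over-flags ears. The harness uses 25 draws of 50%
participant splits by default; per-draw sub-group DEV uses the test-half
members of each bin, with bins emptied by a draw recorded as missing and
excluded from that bin's mean/SD. Grouping sensitivity fits the CL curve
under each binning scheme on the full cohort and reports RMS/extreme
signed differences on a 0–90 dB grid (step 1); the Monte-Carlo stream is
keyed on the scheme's name so listing the same scheme twice yields RMS 0
exactly.

## Synthetic cohorts

The generator emulates the structure the estimators face clinically:
PTA drawn from bin-weighted mixtures (published sub-group counts; uniform
within bin — the least-informative choice consistent with printed counts
and means — snapped to the 1.25-dB grid), then a score from a conditional
family at that PTA, clamped into [0, 100] and rounded to multiples of 4.
Defaults are ear-specific tables of sub-group means/SDs from a
642-participant clinical cohort, linearly interpolated between sub-group
centers. Two families: `censored_normal` makes the simulation method
unbiased by construction (a null check); `skewed_beta` (moment-matched
Beta on [0, 100], variance capped at 99% of the Beta bound where the
requested SD is infeasible) reproduces the ceiling pile-up and left skew
of real score data. A link-form mean curve can replace the table when a
smooth, exactly-representable truth is needed for pointwise
curve-recovery tests — the tabulated default's piecewise-linear quantile
curve has kinks the smooth family cannot track to within a point or two.
`true_quantile` returns the exact conditional quantile of the
latent-then-censored law (before discretization): clamp(μ + σz_τ) for the
normal family, the scaled Beta inverse CDF otherwise. Ears are generated
i.i.d. by default; a latent cross-ear correlation knob exists (default 0).

What the generator does *not* emulate: measurement error in PTA itself,
list-difficulty effects, age structure, or any PTA–skewness coupling
beyond what the moment tables imply. Passing tests therefore show the
estimators behave correctly under realistic score distributions, not that
the shipped curves are clinical norms for any particular test material.

The high PTA mixture bin is capped at 100 dB HL (audiometer-realistic)
although the corresponding label extends to 120; bin assignment still
accepts PTAs to 120.

## Problem sizes and numerical choices

Validation runs use cohorts of 642 participants (the clinical study size)
for coverage and DEV checks, 2,500 participants for pointwise oracle
recovery, 50,000 Monte-Carlo draws per sub-group, 25 split-half draws, and
10 replicate cohorts for the accuracy-ordering comparison; bootstrap
counts are reduced (100–200) inside the repeated-fit harness where the SE
itself is not the quantity under test. Ties in rounding go away from zero;
quantile ranks use the "count strictly below" order statistic stated
above; all stochastic stages take explicit seeds and spawn child streams
via `numpy.random.SeedSequence`, so every reported number is
bit-reproducible given the master seed.

## Known limitations

- The fitted link function is monotone non-increasing only for positive
  β2, β3; degenerate flat fits (β2 = 0) are used for constant data.
- Harrell–Davis estimates in bins with n < 10 can carry large sampling
  error; they are flagged, not suppressed.
- The quantile-regression optimizer is a local method with fixed
  restarts; pathological cohorts far outside the calibrated parameter
  box could require a wider start grid.
- `quantile_se` assumes by default that the sub-group really is normal
  with the measured moments, inheriting the simulation method's
  distributional assumption; passing the raw sample switches to a
  kernel-density empirical variant.
- A Huberized check loss (optional `huber_width`, default off) is
  available to smooth the pinball kink; all shipped results use the exact
  non-smooth loss.
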