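# Methods

This note records the modelling and numerical decisions behind
`vbikit`, the assumptions they rest on, and what the synthetic-data
experiments do and do not demonstrate.

## Refraction and cohort definitions

Spherical equivalent refraction is SER = sphere + cylinder/2 (diopters),
averaged over the two eyes; cylinder input must follow the
minus-cylinder convention and is rejected otherwise. Myopia is
SER ≤ −0.50 D (boundary inclusive). Anisometropia is the absolute
inter-eye **SER** difference — the source data define the exclusion
threshold (< 1.00 D, strict) without naming the scalar, and SER is the
only refraction scalar the analysis uses, so it is the natural choice.
Cohort SD uses the n−1 denominator and is reported as undefined for a
single-subject cohort.

## Stream ingestion and pairing

Sensor ranges (WD 15–60 cm, LI 1–65,536 lux) are inclusive at both
ends; out-of-range samples are dropped rather than clamped (a clamped
value would silently pile mass on the range edge), with the count kept
in metadata and the policy overridable. Streams are segmented wherever
the inter-sample gap exceeds `gap_factor` (default 2.0) times the
nominal interval — tolerant of a single missed tick, splitting at
anything longer.

WD (5 s) and LI (120 s) samples are paired by carrying the most recent
LI observation forward onto each WD timestamp, with a staleness bound
of 120 s (one LI interval). Indoor illuminance is piecewise stable on
that timescale, and LI is the 24×-slower channel, so
last-observation-carried-forward is the least-assuming alignment. WD
samples with no eligible LI are dropped. Each paired sample represents
5 s of wall-clock behaviour (`sample_weight`), which is what the
occupancy grid accumulates.

## Spectral denoising

Both channels are filtered with an ideal low-pass: real FFT, zero all
coefficients strictly above the cutoff, inverse FFT, real part. The DC
coefficient is untouched, so segment means are preserved exactly;
removing spectral energy can only reduce variance (Parseval); and the
projection is idempotent. LI is log10-scaled *before* filtering
(sub-unit lux clamps to 0 log-lux, the sensor floor).

Cutoff defaults are WD 0.01 Hz (100 s period) and LI 1/600 Hz. They
suppress sample-to-sample sensor jitter while keeping fluctuations on
the timescale of activity changes (minutes and longer); both are
config-exposed and echoed in output metadata. Segments shorter than
`min_segment_len` (4 samples) pass through unfiltered — a 4-point FFT
filter would be mostly projection artifact. Filtering is applied per
contiguous wear segment, never across gaps: the week is not one
uniform series, and filtering across a night would leak behaviour
between days. Filtered WD may overshoot the sensor range slightly
(Gibbs ringing); it is deliberately not re-clamped, because the
occupancy grid's 0–70 cm axis absorbs it.

## Behaviour space

The grid is 40 × 40 over WD 0–70 cm × log-LI 0–5 (bin widths 1.75 cm,
0.125 log10-lux). The illuminance axis is read as log10-lux in [0, 5],
i.e. 1 lux to 10^5 lux — log of 0 lux is undefined and the sensor floor
is 1 lux. Bins are half-open with the top bin closed; values outside
the ranges clamp to the edge bins (they are real behaviour, slightly
distorted by filtering, not junk). Axis 0 is WD, axis 1 is log-LI, in
all stored maps.

## Per-pixel regression

The estimator treats the Gaussian kernel weights (w = exp(−d²/2σ²),
neighbourhood radius exactly 2σ in pixel units) as folding into the
predictor: for pixel (i, j) and subject m,
x_m = Σ_{(a,b) ∈ N(i,j)} w_ab · PoT_m[a, b], followed by ordinary
least squares of SER on x across subjects. The weights index pixels,
not subjects, so an observation-weighted regression is not
constructible from them; the smoothed-predictor reading is the one
estimator consistent with that structure. Default σ = 1 pixel
(config-exposed): the 13-pixel neighbourhood spans ±3.5 cm × ±0.25
log10-lux, comparable to the within-activity spread of real behaviour.

p values use the two-sided t test with n−2 degrees of freedom. No
multiple-testing correction is applied by default (the B map thresholds
each pixel at a raw α = 0.05, strict inequality); Benjamini–Hochberg
across defined pixels is available behind `correction="bh"`. Pixels
whose smoothed predictor has zero variance across subjects (nobody in
the neighbourhood) are undefined: β and p are NaN in the maps and B is
forced to 0, so they drop out of every VBI sum.

The full-map fit is computed with closed-form OLS vectorised over
pixels (the smoothed predictors for all pixels at once are a
correlation of each subject's grid with the truncated kernel stencil,
zero-padded so off-grid neighbours contribute nothing — identical to
explicit neighbourhood enumeration). The test suite verifies the
vectorised route against the pixel-by-pixel route exactly.

## VBI

VBI_m = Σ_ij PoT_m[i,j]·B[i,j]; since PoT sums to 1, |VBI| is bounded
by max|B| and the score is linear in the grid. The cohort regression is
SER on VBI (slope in D per VBI unit). The package supports fitting
maps on one cohort and scoring another; the default scores in-sample,
which is optimistic — the same SER values choose which pixels enter B
and then sit on the left-hand side of the VBI regression — and should
be read as descriptive, not predictive.

## Synthetic cohort generator

The generator emulates a week (default 7 days) of daytime wear
(07:30–21:30, with 2 random non-wear gaps of 10–40 min per day).
Behaviour is a seeded renewal process over activity states: at each
renewal the next state is drawn from the subject's preference vector
(Dirichlet around the population mix, concentration 30, giving
realistic between-child heterogeneity) and held for an exponential
dwell. Defaults:

| state         | WD (cm)    | log10 LI     | mean dwell |
|---------------|------------|--------------|------------|
| near_reading  | 25 ± 3.5   | 2.3 ± 0.35   | 25 min     |
| desk_work     | 50 ± 4     | 2.5 ± 0.35   | 30 min     |
| screen        | 33 ± 4     | 2.0 ± 0.35   | 30 min     |
| dim_near      | 17 ± 1.5   | 0.3 ± 0.3    | 30 min     |
| outdoor       | no target  | 4.2 ± 0.4    | 40 min     |
| indoor_other  | no target  | 1.9 ± 0.5    | 20 min     |

States with no near target emit no WD sample (nothing in the distance
sensor's field); LI is emitted throughout wear. WD draws are clipped to
15–60 cm and quantised to 0.1 cm; LI draws are log-normal per state,
clipped to 1–65,536 lux, integer lux — so generated streams pass ingest
validation with zero flags.

Illumination is attached to **locations**: each near-work bout is
sandwiched between "ambient" interludes (300–900 s) lit like the bout
itself but with no near target — the subject is in the room before
picking up the task and lingers afterwards. Without this, instantaneous
jumps between light environments combine with the LI low-pass into
several-minute illumination ramps attributed to the *new* task's
working distance, i.e. physically impossible (distance, light) joint
states; with it, the ramps fall in periods that contribute no paired
sample. The interludes also keep consecutive near bouts segmented in
the WD stream.

Refraction follows the additive exposure model the analysis assumes:
SER_m = baseline + Σ_ij PoT_m[i,j]·truth[i,j] + ε, ε ~ N(0, σ_SER),
with PoT computed by the *real* pipeline on the simulated streams. The
default ground-truth map is myopiagenic (−6 D per unit PoT) on pixels
with centre WD < 40 cm and log-LI < 3.8 (close work without bright
light), mildly protective (+3) on the dim-light near-work niche
(WD < 20 cm, log-LI < 1), zero elsewhere. The baseline (3.89 D) is the
refraction of a hypothetical child with zero risky exposure; with the
default behaviour mix (mean exposure ≈ −3.7 D) and noise SD 0.75 D,
the default cohort lands near mean +0.22 D, SD 1.18 D — typical
descriptives for a fourth-grade cohort. Subject seeds derive from the
master seed via `SeedSequence((seed, subject_index))`, so cohorts are
reproducible subject by subject and byte-identical when re-serialised.

What the generator does **not** emulate: circadian and seasonal light
structure, weekday/weekend differences, posture and head-angle
artifacts, sensor drift, autocorrelated within-bout behaviour beyond
the state mean, or any nonlinear or interactive exposure→refraction
physiology. Passing recovery tests therefore show that the estimator
recovers the generative model's additive structure from realistic
stream artifacts (clipping, quantisation, gaps, filtering distortion) —
not that real myopia development is additive over pixels.

A fast direct grid sampler (`sample_random_grids`) generates
heterogeneous PoT grids without streams for calibration studies where
stream realism is irrelevant (e.g. null calibration of the per-pixel
tests).

## Problem sizes in tests and the acceptance script

Unit and property tests run on small grids (8–20 bins) and short
streams. The end-to-end studies use: 100 two-day subjects for the
normalisation sweep; 200 seven-day subjects for effect-map sign
recovery (agreement ≥ 90% required on pixels occupied by ≥ 10 subjects
with nonzero truth — occupancy is compositional, so truth-zero pixels
legitimately acquire significant opposite-sign slopes and say nothing
about recovery); 20 replicates of 200 two-day subjects for the VBI
slope-recovery rate; 200 null cohorts of 50 subjects on 20 × 20 grids
for type-I calibration; and a 20-subject single-day cohort for
determinism of the full run. These sizes give stable statistics while
keeping the whole suite around a minute of compute.

## Known limitations

- In-sample VBI regression overstates R² (selection of significant
  pixels and scoring share the same data); use the train/score split
  for honest prediction claims.
- Per-pixel marginal regression cannot separate a pixel's causal
  contribution from compositional correlation with the rest of the
  grid; the B map is a descriptive risk surface, not a causal field.
- The raw α = 0.05 threshold over ~1,000 defined pixels admits ~50
  false positives under the null; they enter the VBI with small
  weights. BH correction trades this for conservatism.
- The brick-wall filter's ringing near segment edges slightly spreads
  occupancy; with the default cutoffs the effect is confined to
  neighbouring bins.
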