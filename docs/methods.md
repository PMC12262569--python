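# Methods

This note documents the models, conventions and design choices behind
`cvifkit`, what the synthetic task emulator does and does not reproduce,
and the numerical decisions that matter when interpreting its output.

## Regressor construction

Events are half-open intervals `[onset, onset + duration)` in seconds
from run start.  Neural signals are sampled on a microtime grid of
`dt / oversampling` (default 0.8 s / 50 = 16 ms), convolved with the
canonical double-gamma HRF (response peak delay 6 s, undershoot delay
16 s, unit dispersions, peak:undershoot ratio 6; sampled via nilearn's
`spm_hrf`), and read out at scan onsets.

Three scale conventions interlock and are deliberate:

* the kernel is normalized to **unit sum**, so a sustained unit neural
  input converges to a BOLD plateau of 1 and a short boxcar's amplitude
  is roughly proportional to its duration (the duration–amplitude
  confound that motivates response-time modeling);
* boxcars enter at their event amplitude (default 1), un-normalized
  after convolution;
* impulses enter as **unit point masses** (`amplitude / dt_micro` at the
  onset sample), making impulse regressors sampled HRF densities.

With these conventions regressor values are invariant to the
oversampling factor (checked to <1% RMS when doubling it).  The default
oversampling of 50 keeps the emulator's tens-of-milliseconds
outcome-dependent duration differences from being quantized away.  The
temporal derivative is the first-order finite difference of the kernel,
left un-normalized: only its column space matters for fitting and for
collinearity diagnostics.  Drift nuisance uses a per-run unit-norm DCT
high-pass basis with `K = floor(2T / cutoff)` columns (cutoff default
128 s).  Simulation-style designs use a single intercept across the
concatenated runs; per-run drift blocks are available for
real-data-style designs.

## Diagnostics

For contrast `c` on design `X`, `Var(cβ̂) = c(XᵀX)⁻¹cᵀσ²` and
`efficiency = 1/(c(XᵀX)⁻¹cᵀ)`.  The traditional VIF of column `j` is the
ratio of `Var(β̂ⱼ)` in the full model to its variance in the two-column
model (intercept + that regressor).

The contrast VIF generalizes the same comparison.  The full model is
reparameterized as `[x_c, Z, nuisance, intercept]`, where
`x_c = X_task cᵀ/(ccᵀ)` is the effective regressor whose coefficient
equals `cβ`, and `Z` spans the image under `X` of the contrast's null
space.  cVIF is the coefficient's variance in that full model divided by
its variance in the best-case model holding only an intercept and `x_c`.
Consequences:

* elementary contrasts reduce exactly to tVIF;
* cVIF ≥ 1 always (adding regressors cannot shrink a coefficient's
  variance);
* nuisance columns inflate the numerator but never enter the reduced
  model, matching how diagnostics are computed on complete first-level
  designs.

**Parameterization.**  A design matrix alone cannot reveal condition
overlap once it has been reparameterized: an orthogonalized design with
the correspondingly transformed contrast is indistinguishable from a
genuinely orthogonal design with an oblique contrast.  cVIF is therefore
defined relative to the condition parameterization (the design whose
columns are the condition signals).  For a statistically equivalent
reparameterization, `cvif(design, c, condition_design=...)` maps the
contrast through the invariant estimator functional
`ℓ = X(XᵀX)⁻¹cᵀ` back onto the condition basis and evaluates it there;
the full-model variance is identical in both parameterizations, which is
exactly why reparameterizing away regressor correlation (all tVIFs → 1)
does not reduce the true inflation of the condition contrast.

Working thresholds: a contrast cVIF above 5 warrants inspecting the data
for outliers; above 20 is treated as excessive.  Designs whose
cross-product condition number exceeds 1e10 raise a singularity error
rather than returning a meaninglessly large VIF.  Omitted candidate
regressors are reported as model-comparison warnings, not as VIFs —
omission trades variance for bias, which no VIF can measure.

## The MID emulator

The emulator reproduces the *marginal* structure of the ABCD-style MID
task: 2 runs × 50 trials, 10 per cue type in a uniformly random order
per run, components abutting with no inter-trial gaps, run length
rounded up to whole 0.8 s scans.  Durations are uniform draws within the
observed ranges, shifted ±half the observed Hit−Miss offset by outcome
and clipped: Probe +29 ms for Hits, Fixation +112 ms for Hits
(midpoints of the reported 26–33 ms and 63–160 ms ranges), response
times +89 ms for Misses.  RTs draw from a U(0.150, 1.000) s base so the
shifted values always stay inside the legal 0.105–1.581 s range; Too
Soon trials carry an RT with probability 0.5 (premature single presses
go unrecorded).  Outcomes are i.i.d. (0.57, 0.36, 0.07) by default; an
optional staircase instead adjusts the Probe window every third trial
against the accuracy of the last six, simulated against a latent
N(300, 80²) ms responder, and settles near the 60% target.

What the emulator does **not** reproduce: each participant's empirical
trial order and timing file (the motivation for emulating at all),
autocorrelated noise, scanner drift, motion, RT differences between Too
Soon and Too Slow, and any dependence of outcome on cue type.  Passing
tests therefore demonstrate properties of the modeling machinery under
realistic timing *structure*, not estimates of real-data effect sizes;
quantities that depend on the exact ABCD timings (e.g. a specific
real-data cVIF) are expected to differ.

Model builders: `CUEFEEDBACK` (impulses at Cue and Feedback onsets split
by cue type and cue type × Hit/Miss, each with temporal derivative; 30
task columns) and `SATURATED` (duration-matched boxcars for Cue,
Fixation, Probe split Win/Loss/Neutral, a Probe-onset/RT-duration
regressor, and Feedback; 24 task columns; 49 parameters with intercept
when every regressor gains a derivative).  On emulated sessions the
Saturated model keeps the routinely studied contrasts at cVIF ≈ 1–6
while the derivative variant pushes most parameters far above 20 —
which is why the derivative-free Saturated model is the recommended
default despite its inability to absorb onset shifts.

## Simulation

Truth is always generated from the Saturated design; the CueFeedback
model is only ever a fitting model.  Per subject,
`Y = X_sat β_s + ε`, `ε ~ N(0, σ_w²I)`, `β_s ~ N(μ_scenario, σ_b²I)`
independently for all 24 amplitudes, with σ_w = 1 and σ_b = 1.5.  The
scenario means (e.g. Cue(Win): both win-cue amplitudes 0.22; Probe(Win):
0.85; RT: 0.35; Feedback: both LargeWin feedback amplitudes 0.25) are
calibrated so group power for the signal-carrying parameter is near 80%
at 500 subjects.  With these components the total-to-within SD ratio
(`√(c(XᵀX)⁻¹cᵀσ_w² + ccᵀσ_b²) / √(c(XᵀX)⁻¹cᵀσ_w²)`) sits around 3.4–3.5
for the condition-difference contrasts on emulated designs, inside the
2–4.2 band typical of such analyses.

Each study draws a fixed pool of subject schedules, reused across all
simulated datasets and scenarios.  Contrast estimates are obtained by
applying the precomputed estimator rows `c(XᵀX)⁻¹Xᵀ` to the simulated
time series — algebraically identical to refitting OLS per dataset
(asserted in a unit test) and what makes thousand-dataset grids cheap.
Per dataset, each contrast gets a two-sided one-sample t-test across
subjects at α = 0.05.  Summaries per (scenario, model, contrast) cell:
rejection rate; bias (grand mean minus truth) with its Monte-Carlo SE
and a ±1.96·SE significance flag; the average group t against truth (the
heat-map color); and an inflation flag from a one-sided exact binomial
test of the rejection count against α, computed only for cells whose
contrast involves no true-signal parameter.  The inflation flag is a
per-cell display indicator at the 5% level; when *validating* that a
whole 14-cell null grid is calibrated, the test suite instead applies
per-cell exact binomial tests at a Bonferroni-adjusted level (0.05/14),
since at nominal error rates roughly one of 14 unadjusted 95% bands is
expected to fail by chance.

Because fitting the generating model yields exactly unbiased estimates,
Saturated-model bias checks are pure Monte-Carlo-noise checks (|bias| <
3 SE).  The CueFeedback biases mirror the omitted-variable structure:
unmodeled Fixation or Probe signal loads onto the feedback-versus-
baseline and feedback-between-condition contrasts with inflated type-I
error, while randomized trial order protects cue contrasts from
unmodeled Feedback signal.

Problem sizes: the default grids run 500 subjects × 1000 datasets; the
test suite exercises the same machinery at 48 subjects × 250–1000
datasets, and the power computation at the full 500 subjects × 200
datasets.

## Group inference

Run-level estimates combine by inverse-variance weighting.  The group
test is a one-sample two-sided t; `d = t/√n` for display.  The
permutation test flips subject signs jointly within scanner site
(preserving site structure under the symmetric-error null), enumerating
all `2^sites` assignments when ≤ `max_perms` (8192 for 13 sites) and
sampling uniformly otherwise, identity always included.  Clusters form
at |t| > 3.1 with face-adjacent (6-)connectivity; positive and negative
excursions are labeled separately and pooled into a single
maximum-cluster-size statistic per permutation (one two-sided null);
observed clusters exceeding the null's 95th percentile are significant.
Zero-variance voxels yield ±max-float t with a warning (degenerate
input), or 0 when the data are identically zero.

A granularity caveat: on spatially white noise the null max-cluster-size
distribution concentrates on sizes 1–2, and the strictly-greater
percentile rule then rejects almost never — an artifact of discreteness,
not conservatism of the method.  Family-wise error calibration is
therefore validated on spatially smoothed null maps (Gaussian σ = 1
voxel, matching the smoothness of real preprocessed data), where the
empirical FWER is statistically consistent with 5%.

## Known limitations

* cVIF requires knowing (or reconstructing) the condition
  parameterization; handed only an already-orthogonalized matrix and an
  elementary contrast, it reports that parameterization's inflation,
  like any purely design-based diagnostic.
* The simulator's i.i.d. noise ignores temporal autocorrelation; this
  changes absolute variances but not the bias structure the simulation
  quantifies.
* The emulator's uniform-with-offset duration distributions are an
  assumption; only ranges and mean outcome offsets are constrained by
  the observed data.
* The group module tests a mean against zero only (no covariates,
  no variance smoothing, no TFCE).
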