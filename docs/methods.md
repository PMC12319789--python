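# Methods

## Ground-truth worlds

All simulations share one temporal skeleton: `n_trials` trials placed
sequentially on a uniform 100 Hz grid, each stimulus following the previous
response by a uniform inter-trial interval (default 1.5–2.5 s, wide enough
that stimulus- and response-lag regressors are jointly identifiable), with
2 s of silence padding each end of the recording.  Reaction times are drawn
from a shifted lognormal, `RT = shift + exp(N(log(median − shift), σ))` with
shift 0.2 s, median 0.8 s, σ = 0.35 — right-skewed with well-separated
10th/90th percentiles (≈ 0.58 / 1.14 s).  Event times and RTs are quantized
to the sample grid so that noise-free worlds are *exactly* representable by
the regression designs; this is what makes the exact-recovery assertions
meaningful rather than approximate.  All randomness flows from a single
seed through `numpy.random.SeedSequence` spawns (trials, ITIs, sensor
noise, delays), so identical configs are bit-identical.

**SR world.** Each trial is the sum of a stimulus-locked kernel and a
response-locked kernel, identical across trials.  Kernels are raised-cosine
(Hann) bumps with compact support: S peaks 300 ms post-stimulus (width
600 ms, amplitude 1.0), R peaks 100 ms before the response (width 600 ms,
amplitude 1.5).  Compact support keeps each kernel strictly inside its
time-expansion window, so the FIR fit can in principle recover it exactly.
There is no RT effect anywhere in this ground truth; everything seen in
RT-split averages is overlap.

**RAMP world.** No event-locked components.  Each trial is zero until an
onset delay (default 100 ms) after the stimulus, rises linearly to the
decision bound evaluated at the trial's RT, and returns linearly to zero
over 100 ms after the response.  The default bound collapses
exponentially, `b(t) = b_∞ + (b_0 − b_∞)·e^{−t/τ}` with `b_0 = 1`,
`b_∞ = 0.3`, `τ = 0.6 s` — a moderate collapse such that the 10th-to-90th
percentile RT range spans terminal amplitudes of roughly 0.64 to 0.42.
Slope is `b(rt)/(rt − onset)`, so fast trials genuinely build faster and
end higher.  The post-response decay is a modelling decision (the
response-locked interval after 0 must contain something); its 100 ms
default keeps it well inside the R expansion window.  The bound is
evaluated at the RT (time since stimulus) for the ramp's endpoint, and on
the accumulation clock for the diffusion's crossing test; the two
conventions differ only by the onset/non-decision delay and either would
serve.

**DDM world.** A single-bound diffusion: after a pre-accumulation
(encoding) delay the accumulator integrates `μ dt + σ√dt·N(0,1)`
(Euler–Maruyama, `dt = 1 ms`, decimated ×10 to the 100 Hz grid) until it
first crosses `b(t)`; the trajectory holds at the crossing value through a
post-accumulation (motor) delay, then decays as in the RAMP world.
`RT = pre + decision + post`.  Defaults: drift 1, diffusion SD 0.3, the
collapsing bound above, delays normal-truncated-at-zero with means
0.2 / 0.15 s and SDs 0.035 s.  Non-crossing trials (possible in principle
with heavy collapse or low drift) are redrawn up to 50 times within a 4 s
decision budget, then rejected with a diagnostic.  With σ = 0 the process
degenerates to the RAMP world with onset delay equal to the encoding
delay — an assertable consistency limit, and the noiseless crossing time
`b_0/μ` is exact to one integration step.

What the generators deliberately do *not* emulate: multi-channel/topographic
structure, 1/f or oscillatory background noise, artifacts, two-boundary
decisions with errors, or trial-to-trial amplitude variability of the SR
kernels.  Passing tests therefore certify the *logic* of the overlap
correction under each ground truth, not its behaviour under realistic EEG
noise; sensor noise defaults to zero precisely so that the allocation
behaviour of the estimator is measured without a stochastic floor.

## Deconvolution

The design matrix is the standard time-expanded FIR ("stick") form: one 0/1
indicator column per (event type, RT category, lag), lags on the sample
grid over the expansion windows S: [−0.2, +1.0] s and R: [−0.8, +0.2] s.
RT-category splits use separate indicator columns per category (no shared
reference level), so each category's kernel is read directly off the betas.
No intercept by default (the simulated recordings are zero between trials);
an intercept column is a config option.  No regularization anywhere —
shrinkage would bias exactly the allocation behaviour under study.

These designs have at most a few hundred columns, so the estimator forms
the Gram matrix `XᵀX` from the sparse design and solves the normal
equations by dense Cholesky: machine-precision betas in milliseconds.
Rank deficiency is detected from the Gram condition number (limit 1e10)
before solving, and the error names the most-implicated predictor pair via
the smallest eigenvector — the practically relevant case being too little
RT jitter, which makes stimulus and response columns near-collinear.  The
test suite checks this solver against an independent dense SVD
(`numpy.linalg.lstsq`) route on randomized small instances to 1e−8
relative error.

## Measurements

All epoching is plain windowing (stimulus-locked [−0.3, 1.2] s,
response-locked [−1.0, 0.3] s) with no implicit baseline correction.
Reported quantities, every effect signed fast − slow:

* **pre-response amplitude** — mean over [−50, 0] ms of the response-locked
  category average;
* **buildup slope** — OLS line slope over [−300, −50] ms;
* **baseline difference** — fast − slow mean over [−200, 0] ms pre-stimulus,
  applied to the *estimated S kernels* of RT-split fits;
* **attenuation ratio** — |corrected effect| / |uncorrected effect| after
  subtracting the fitted pooled-S component from the recording;
* **S variance share** — variance of the S-only prediction divided by the
  variance of the full event-locked prediction, both as continuous signals;
* **residual fraction** — residual variance over recording variance.

The measurement windows are free parameters with the defaults above; they
sit inside the R expansion window and before response execution, and every
report records the windows it used.

## Analysis ladders

`run_uncorrected_averages` → raw RT-split averages, both alignments.
`run_s_subtraction` → pooled-S + RT-split-R joint fit, subtract the S
prediction, re-measure (the "corrected" waveforms).  `run_split_component_fit`
→ RT-split S and R fit for the baseline diagnostic, plus the RT-agnostic
pooled fit for the residual fraction.  `run_jitter_experiment` → sweep of
the post/pre non-decision jitter-SD ratio over {0, 0.5, 1, 2, 4}.  For the
sweep, delay means stay fixed and the *total* jitter SD
(√(pre² + post²) = 0.05 s) is held constant while the ratio varies, so the
RT distribution is comparable across grid points and truncation of the
delay distributions stays negligible; fixing only the pre-SD instead would
confound the ratio with total RT variance.  Defaults: 500 trials per
scenario — enough for stable kernel estimates at 100 Hz while keeping every
ladder in the seconds range.

## Numerical and degenerate-input choices

* Median-RT split assigns a trial exactly at the median to *fast*; an
  all-tied RT distribution (empty slow category) is an error.
* RTs shorter than one sample, ramps not exceeding their onset delay, and
  epoch/expansion windows leaving the recording are all hard errors, not
  clamps.
* Degenerate configurations that destroy identifiability (zero diffusion
  noise with zero delay jitter → identical RTs) surface as the rank /
  degenerate-split errors above rather than silently fitting.
* `residual_fraction` refuses a zero-variance recording.

## Known limitations

The attenuation *magnitude* depends strongly on the geometry between the RT
distribution and the expansion windows: with median ramp duration (≈0.7 s)
shorter than the R window's pre-response extent (0.8 s), most of the ramp
is absorbable by the response-locked kernels and the stimulus-locked kernel
receives only a few percent of the predicted variance, giving partial
(≈0.5–0.7×) rather than dramatic attenuation.  Longer RTs or narrower
windows push the allocation further toward S and strengthen the
attenuation; the qualitative signatures (signs of effects, baseline shift,
low residuals, jitter monotonicity) are robust to this geometry and to the
seed.  Single-channel only; no inference across simulated participants is
provided or intended.
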