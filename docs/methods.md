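# Methods

## The model

A fluorescence trace is modelled as a non-negative spike train convolved
with a calcium impulse response plus noise:

    F(t) = (s * k)(t) + noise,        s(t) >= 0.

Deconvolution minimizes

    ||F - s * k||^2 + lambda * L(s),      s >= 0,

with three penalty choices: `L(s) = 0` (unconstrained non-negative
deconvolution, NND), `L(s) = ||s||_1` (L1), and `L(s) = ||s||_0` (L0, the
number of nonzero samples).  Amplitudes live on the trace's own sample
grid; a "spike" is a nonzero sample, and coincident events merge
additively.  At `lambda = 0` all three problems coincide, so the L0 and
L1 entry points route that case to the exact convex solver.

## Kernels

Kernels are a decaying exponential `exp(-t/tau_d)` or a difference of
exponentials `exp(-t/tau_d) - exp(-t/tau_r)` with the rise timescale a
fraction (0 to 0.5) of the decay.  All kernels are **peak-normalized to
1**, so deconvolved amplitudes are in trace units, and truncated where
the amplitude falls below 1% of the peak (for difference kernels the
support is extended until that threshold is genuinely reached, since
normalization lifts the tail relative to the sub-unit raw peak).
Decay timescales are categorical -- fast 0.7 s, medium 1.25 s, slow
2 s -- assigned per sensor from a plain-text table
(`src/spikedeconv/data/sensor_timescales.txt`); GCaMP6 variants are
mapped by version (6f fast, 6m medium, 6s slow), following the published
ordering of their decay times.  A literature discrepancy exists for the
"fast" class (0.7 vs 0.75 s); we use 0.7 s, and the table and
`TIMESCALES` dict make the choice overridable.

Kernel estimation from ground truth (`estimate_kernel_from_ground_truth`)
is a diagnostic only: ordinary least squares on a Toeplitz design of
lagged spike counts with an intercept, negative coefficients clipped,
peak-normalized.  Deconvolution always uses fixed parametric kernels --
fitting per-cell kernels is deliberately out of scope because it is
counterproductive in practice.

## Solvers

**NND / L1 (convex).**  Three interchangeable back ends solve the same
program; which one runs is a matter of problem shape:

- *Dense active-set* (traces <= 1024 samples): Lawson-Hanson iteration on
  the normal equations of the explicit Toeplitz design; the L1 term only
  shifts the linear coefficient by lambda/2.  Exact to machine
  precision; this is the reference implementation that the acceptance
  checks certify against an independent bound-constrained oracle and
  KKT conditions.
- *Pool adjacent violators* (long traces, exponential kernels): the
  AR(1) reformulation c[t] = g c[t-1] + s[t] turns `s >= 0` into a
  chain constraint solved exactly in O(T) by pool merging; the L1
  penalty is absorbed by tilting the data with lambda/2 * (1-g).
  With the trace shorter than the kernel support this is exactly the
  dense solution; for longer traces the 1% kernel truncation introduces
  a <1% model difference that is irrelevant for scoring.
- *L-BFGS-B with FFT gradients* (long traces, rise-time kernels): the
  objective and gradient cost two FFT convolutions per iteration; runs
  to tight tolerances (ftol 1e-15, up to 800 iterations).  Used only
  for benchmark sweeps, where scoring accuracy, not certificate-grade
  optimality, is needed.

**L0 (greedy matching pursuit with spike relocation).**  Iterate:
correlate the residual with the kernel (matched filter), add the sample
with the largest squared-error reduction if that reduction exceeds
lambda, then let existing spikes adapt: each atom may move by up to
+/-5 samples (50 ms at 100 Hz) with a re-optimized amplitude, be
re-scaled in place, or be removed outright (recovering lambda).  Every
candidate change is scored exactly using precomputed partial kernel
autocorrelations, so boundary effects are handled without
approximation.  Relocation passes repeat to a fixed point (at most 10
per iteration); atoms whose matched-filter neighbourhood has not
changed since they were last found optimal are skipped, which is an
exact optimization, not a heuristic.  Because one-at-a-time amplitude
updates converge slowly when transients overlap heavily (adjacent-spike
kernel correlation ~0.96 at 10 ms spacing), a final joint banded
least-squares re-fit of all support amplitudes is applied; atoms whose
joint amplitude would be non-positive are dropped.  Both the relocation
step and the polish are monotone in the objective.  Ties in greedy
selection break toward the earliest sample; outputs are deterministic.

The stopping threshold "reduction > lambda" is the L0-consistent greedy
criterion; no separate minimum-amplitude parameter exists.  The
`max_atoms` guard (2T) only protects against pathological inputs.

**Lambda calibration.**  `calibrate_lambda` bisects lambda on a log
scale until the pooled nonzero fraction is within +/-20% of a target
(30 iterations max).  The conventional target is 5% of samples at
100 Hz.  Two caveats discovered on simulated data: the L1 nonzero count
can jump discontinuously in lambda (whole pools vanish together), in
which case the bisection converges to the jump straddling the target;
and greedy L0 cannot reach 5% on sparse low-noise simulations at any
lambda, because pursuit exhausts positive-gain atoms near 1-2% -- the
Poisson-bias experiment therefore calibrates L0 at 1%, roughly the true
spike occupancy.

## The simulator

Spike counts are Poisson in 10 ms bins with rate
`r(t) = r_tonic + r_burst * b(t)`.  Burst onsets are a Poisson process
(2 per minute), epochs last exactly 250 ms and are non-overlapping
(re-drawn on collision); `b(t)` is the 0/1 indicator.  Given the
baseline rate `r0` and burstiness `alpha` (target fraction of spikes
inside bursts), the split solves

    r_tonic + r_burst * p_b = r0,
    (r_tonic + r_burst) * p_b = alpha * r0,

with `p_b = burst_rate * burst_duration` the expected burst occupancy
(1/120 at defaults).  `alpha <= p_b` (including the homogeneous case
alpha = 0) clips `r_burst` to 0; `alpha >= 1` is an error.

Fluorescence filters the counts with an exponential of timescale 1 s
via the exact AR(1) recursion.  The transient amplitude per spike is
`bin_width / tau_sim` (= 0.01 at defaults), i.e. the discretization of
the unit-area continuous filter `(1/tau) exp(-t/tau)`.  This choice
matters: the randomized noise ranges (shot noise beta in [0, 0.02],
correlated noise gamma in [0, 0.015]) are only meaningful if a single
spike's transient is commensurate with them, and it is this regime that
produces the realistic spread of recovery quality (sigma_gt from ~0.1
to ~1.0) across randomized datasets.  The amplitude is exposed as
`SimParams.spike_amplitude` for anyone preferring unit-peak transients.

Shot noise is iid Gaussian per sample.  Correlated noise -- the stand-in
for movement and neuropil contamination -- is white noise smoothed with
a Gaussian whose **half width at half maximum** is 500 ms
(SD = 0.5/sqrt(2 ln 2) ~ 0.42 s), renormalized to unit variance before
scaling by gamma so beta and gamma are directly comparable.

Randomized datasets draw (r0, alpha, beta, gamma) uniformly from
r0 in [0.05, 1] Hz, alpha in [0, 0.5], beta in [0, 0.02],
gamma in [0, 0.015], shared across the cells of a dataset.

The stimulus-repeat generator builds two session halves, each holding
full random permutations of the stimulus set in contiguous 2 s trials.
Per-neuron, per-stimulus tuning gains are log-normal with log-SD 0.5
(mean 1); per-trial rate is `r0 * gain`.  Spikes depend only on the
structural seed, noise only on a separate noise seed, so identical
spike trains can be re-dressed with different noise levels
(`StimExperiment.with_noise`).

What the simulator does **not** emulate: biophysical calcium dynamics
(buffering, saturation, nonlinear sensor response), spatially
structured motion or neuropil, drifting baselines, and inter-neuronal
correlation.  Passing tests therefore certify the inference machinery
under the linear-convolution generative model, not performance on any
particular real recording.

## Metrics

- `sigma_gt`: Pearson correlation of estimate and ground truth, both
  binned at 40 ms (half-open bins anchored at 0).  The benchmark
  pipeline order is: deconvolve at 100 Hz -> optionally smooth the
  estimate (Gaussian, SD in samples; ground truth is never smoothed) ->
  optionally apply one dataset-wide integer lag (ties: smallest |lag|,
  then negative) -> bin -> correlate.
- `van_rossum_corr`: Pearson correlation of the two trains after both
  are Gaussian-smoothed at the native rate; symmetric, and sd -> 0
  recovers the unsmoothed correlation.
- `auc`: probability that a spike-containing bin outranks a spike-free
  bin, ties counted exactly 0.5; computed by the rank method, which with
  average ranks reproduces the pairwise enumeration exactly.
- `autocorrelogram`: normalized autocovariance at lags >= 1 bin;
  homogeneous Poisson input is flat within ~4/sqrt(N).
- `sigma_stim`: per neuron, the Spearman correlation over stimuli of
  trial-averaged responses computed separately on the two halves;
  benchmark value is the mean over neurons.  Spearman is used
  deliberately: a monotone nonlinearity applied to the deconvolution
  output leaves it unchanged.  Per-trial response is the summed
  amplitude over the full trial window.  Ties get average ranks.

Undefined scores (zero variance, degenerate ground truth, constant
tuning curves) propagate as NaN and are excluded from means -- silent
zeros would bias method comparisons.

## Validation experiments and problem sizes

All experiment scales below were chosen to give stable statistics at
desk scale and are fixed in the acceptance script and tests:

- **Solver certificate**: 200 random instances (T <= 200, random decay /
  rise / lambda); the convex solver must match an independent
  bound-constrained quadratic oracle to 1e-6 relative objective and
  satisfy the KKT conditions.
- **Noiseless recovery**: 6 cells x 300 s, beta = gamma = 0, three
  burstiness levels; NND reaches sigma_gt >= 0.99 at 40 ms.
- **Sparsity sweep**: 3 randomized datasets x 12 cells x 200 s;
  L1 grid {0, 0.5, 2, 8}, L0 grid {0, 3e-5, 3e-4, 3e-3} (grids bracket
  the calibrated operating points in trace units).  Unconstrained
  lambda = 0 is best to within one standard error.  The comparison is
  paired per cell (`penalty_sweep_margins`): a strong penalty can zero
  out an entire hard cell, whose undefined score would otherwise vanish
  only from the penalized mean, leaving marginal means computed over
  different cell subsets.  Weak L1 occasionally gains ~0.01 on a random
  dataset -- a real but minimal effect, well inside the one-SE slack.
- **Kernel robustness**: same dataset scale; decay scaled by
  {0.5, 1, 2}: mean sigma_gt moves by < 0.1.  Rise sweep (2 x 6 x
  120 s, grid 0-0.5): the optimum is a pure exponential.  With a
  mismatched rise kernel the inferred spikes also acquire a latency
  shift of order the rise time, which the unlagged 40 ms benchmark
  punishes heavily; the argmax at 0 is unaffected.
- **Split-half validation**: three fixed spike-train sets (0.3, 0.6,
  1.0 Hz; 36 neurons x 14 stimuli x 4 repeats per half, tuning log-SD
  1.0), each re-dressed with 12 noise combinations spanning the full
  beta/gamma ranges under one shared noise realization (common random
  numbers), deconvolved by NND, two L1 strengths, and L0 on two noise
  levels (38 variants).  sigma_gt here uses the smoothed benchmark
  variant (SD 8 samples) because the trial-summed sigma_stim is
  structurally insensitive to sub-bin timing jitter that the raw 40 ms
  correlation punishes; with matched timing tolerance the two metrics'
  Pearson correlation within each set is >= 0.9.
- **Relocation soundness**: 1000 random L0 problems; the objective
  never increases across relocation passes and the relocation-enabled
  result never loses to plain matching pursuit.
- **Poisson bias**: 4 cells x 300 s of alpha = 0 (Poisson) firing,
  beta = 0.01, gamma = 0.005; penalties calibrated on a 60 s excerpt
  (L1 at 5%, L0 at 1% nonzero).  The L0 autocorrelogram stays inside
  the pooled 4/sqrt(n_cells * N) flatness band at all lags <= 0.5 s,
  while the raw trace shows the strong short-lag correlation that
  deconvolution is supposed to remove.  NND and L1 sit in between, with
  L1 exhibiting a distinct lag-1 excess.

## Numerical conventions

Seconds everywhere; 0-based sample indices; half-open bins [t, t+dt).
Text output uses 9 significant digits; binary is little-endian float64
with a YAML sidecar.  NaN input samples are rejected at parse and
deconvolution boundaries.  Active-set tolerances scale with max|A'b|;
greedy/relocation improvement thresholds scale with the initial
residual power.  Baseline handling defaults to none (inputs are assumed
baseline-corrected); an optional constant-percentile mode (percentile
10) is provided as a convenience.

## Known limitations

The greedy L0 solution carries no global optimality certificate (only
monotonicity and the exhaustive-oracle checks at small scale).  The
PAVA back end models the infinite exponential rather than the truncated
kernel (difference < 1% of a transient).  The simulator's noise model
is stationary and Gaussian; real recordings have photon (Poisson) noise,
drift, and correlated across-cell artifacts.  sigma_stim values depend
on the tuning-gain spread and trial counts, so absolute values are not
comparable across experiment designs -- only across algorithms within
one design, which is exactly how the benchmark is used.
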