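# spikedeconv

Spike inference from calcium imaging, for people who process two-photon
recordings and for methodologists who benchmark spike-inference
algorithms.  Fluorescence is modelled as a non-negative spike train
convolved with a calcium kernel,

    F(t) = (s * k)(t) + noise,      s(t) >= 0,

and spikes are inferred by minimizing

    || F - s * k ||^2  +  lambda * L(s),       s >= 0,

with `L(s) = 0` (plain non-negative deconvolution, NND),
`L(s) = ||s||_1`, or `L(s) = ||s||_0`.  The convex NND/L1 problem is
solved exactly (active-set on short traces, an O(T)
pool-adjacent-violators pass on the AR(1) form for exponential kernels,
FFT-gradient L-BFGS for rise-time kernels).  The L0 problem is solved by
greedy matching pursuit extended with a *spike relocation* step: at each
iteration existing spikes may shift by a few samples, re-scale, or drop
out, which resolves the bursts that trap plain matching pursuit in local
optima.

Around the solvers the package provides:

- **Kernels**: exponential and difference-of-exponential calcium
  responses, peak-normalized, with sensor-to-timescale assignment
  (fast 0.7 s / medium 1.25 s / slow 2 s) and a diagnostic regression
  that recovers the kernel from ground-truth spikes.
- **A simulator**: Poisson spiking with tonic/bursting rate switching,
  exponential calcium dynamics, shot noise and temporally correlated
  noise, randomized multi-dataset generation, and stimulus-repeat
  experiments with fixed spike trains under interchangeable noise.
- **Metrics**: the 40 ms binned correlation `sigma_gt` against ground
  truth (with optional smoothing and dataset-wide lag), a van
  Rossum-style smoothed correlation, exact tie-aware AUC,
  autocorrelograms, and `sigma_stim` -- a ground-truth-free benchmark
  that scores an algorithm by the Spearman correlation of tuning curves
  across two stimulus-repeat halves.
- **Benchmarks**: sparsity-penalty sweeps, kernel-timescale and
  rise-time robustness sweeps, cross-validated penalty selection, and a
  Poisson autocorrelogram bias diagnostic.

The headline empirical findings the test suite reproduces on simulated
data: unconstrained NND matches or beats its L0/L1-regularized variants
(the best penalty is ~0); performance is robust to halving or doubling
the kernel timescale; a pure exponential kernel beats kernels with a
rise component on exponential data; `sigma_stim` tracks the
ground-truth score almost perfectly within a fixed spike train; and L0
deconvolution leaves Poisson spike statistics unbiased where raw traces
(and to a lesser degree NND/L1) show spurious autocorrelation.

## Worked example

```python
from spikedeconv import DeconvConfig, deconvolve, make_exponential_kernel
from spikedeconv.metrics import sigma_gt
from spikedeconv.simulate import simulate_dataset

cells, params = simulate_dataset(n_cells=5, duration=120.0, seed=7)
print(f"dataset: r0={params.r0:.3f} Hz, alpha={params.alpha:.3f}, "
      f"beta={params.beta:.4f}, gamma={params.gamma:.4f}")
kernel = make_exponential_kernel(params.tau_sim, params.sampling_rate)
for i, cell in enumerate(cells):
    res = deconvolve(cell.trace, DeconvConfig("nnd", kernel))
    score = sigma_gt(res.amplitudes, cell.spike_counts.astype(float),
                     0.04, sampling_rate=params.sampling_rate)
    print(f"cell {i}: {cell.spike_counts.sum()} true spikes, "
          f"{res.n_nonzero} nonzero samples, sigma_gt = {score:.3f}")
```

prints

```
dataset: r0=0.644 Hz, alpha=0.449, beta=0.0155, gamma=0.0034
cell 0: 64 true spikes, 2657 nonzero samples, sigma_gt = 0.551
cell 1: 71 true spikes, 2680 nonzero samples, sigma_gt = 0.532
cell 2: 100 true spikes, 2630 nonzero samples, sigma_gt = 0.666
cell 3: 63 true spikes, 2610 nonzero samples, sigma_gt = 0.747
cell 4: 75 true spikes, 2546 nonzero samples, sigma_gt = 0.638
```

One randomly parameterized dataset of five cells is simulated (here a
moderately bursty ~0.6 Hz population with mid-range shot noise), each
trace is deconvolved with the default 1 s exponential kernel, and each
cell is scored against its own ground truth at 40 ms resolution.  NND
output is dense (many small nonzero samples); `sigma_gt` around 0.5-0.75
is typical for this noise level, and rises to ~1 as noise goes to zero.

The same pipeline is available from the shell:

```sh
spikedeconv simulate --preset dataset --out sim/ --seed 7 --n-cells 5 --duration 120
spikedeconv deconvolve --method nnd --tau 1.0 --in sim/traces.csv --out est.csv
spikedeconv evaluate --metric sigma_gt --est est.csv --gt sim/spikes.csv --out scores.csv
```

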