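"""Generative model for ground-truth spike trains and fluorescence.

Spikes are Poisson counts in 10 ms bins with a rate that switches
between a tonic level and an elevated level during short bursting
epochs: ``r(t) = r_tonic + r_burst * b(t)`` with ``b(t)`` a 0/1 burst
indicator.  Burst onsets are a Poisson process (default twice per
minute), each epoch lasting 250 ms; ``r_tonic`` and ``r_burst`` are
solved so that the mean rate is ``r0`` and the expected fraction of
spikes inside bursts is the burstiness ``alpha``.

Fluorescence is the spike train filtered with a 1 s exponential kernel
plus two noise terms: per-sample iid Gaussian shot noise of amplitude
``beta``, and temporally correlated noise -- Gaussian-smoothed white
noise (500 ms half-width at half maximum), normalized to unit variance
and scaled by ``gamma`` -- standing in for movement and neuropil
contamination.

Multi-dataset generation draws (r0, alpha, beta, gamma) uniformly over
r0 in [0.05, 1] Hz, alpha in [0, 0.5], beta in [0, 0.02] and gamma in
[0, 0.015], shared by all cells of a dataset.  A separate constructor
builds stimulus-repeat experiments for the split-half reliability
benchmark: randomized stimulus order in each of two halves, fixed
per-neuron tuning gains, and spike trains that can be reused under
different noise levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .deconv import Trace

__all__ = [
    "SimParams",
    "SimulatedCell",
    "StimExperiment",
    "simulate_spikes",
    "simulate_fluorescence",
    "simulate_cell",
    "simulate_dataset",
    "simulate_stim_experiment",
    "PARAM_RANGES",
]

#: Uniform sampling ranges for randomized multi-dataset generation.
PARAM_RANGES = {
    "r0": (0.05, 1.0),
    "alpha": (0.0, 0.5),
    "beta": (0.0, 0.02),
    "gamma": (0.0, 0.015),
}


@dataclass(frozen=True)
class SimParams:
    """Generative parameters for a simulated cell or dataset."""

    duration: float
    r0: float = 0.5
    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    bin_width: float = 0.01
    burst_rate: float = 2.0 / 60.0
    burst_duration: float = 0.25
    tau_sim: float = 1.0
    corr_noise_halfwidth: float = 0.5
    spike_amplitude: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.alpha >= 1.0 or self.alpha < 0.0:
            raise ValueError("alpha must be in [0, 1)")
        if self.r0 < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("rates and noise amplitudes must be non-negative")
        if self.duration <= 0 or self.bin_width <= 0:
            raise ValueError("duration and bin_width must be positive")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.bin_width

    @property
    def transient_amplitude(self) -> float:
        """Fluorescence jump caused by a single spike.

        Defaults to ``bin_width / tau_sim`` -- the discretization of the
        unit-area continuous filter ``(1/tau) exp(-t/tau)`` -- so a
        single spike produces a transient of height 0.01 at the default
        100 Hz / 1 s settings, commensurate with the shot-noise (up to
        0.02) and correlated-noise (up to 0.015) amplitude ranges.
        """
        if self.spike_amplitude is not None:
            return self.spike_amplitude
        return self.bin_width / self.tau_sim

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.bin_width))

    @property
    def burst_occupancy(self) -> float:
        """Expected fraction of time spent inside bursts."""
        return self.burst_rate * self.burst_duration

    def rate_split(self) -> tuple[float, float]:
        """Solve (r_tonic, r_burst) from (r0, alpha).

        The mean-rate and burst-spike-fraction constraints give
        ``r_burst = r0 (alpha - p_b) / (p_b (1 - p_b))`` with p_b the
        burst occupancy; alpha <= p_b (fewer burst spikes than burst
        occupancy itself provides) degenerates to homogeneous firing.
        """
        p = self.burst_occupancy
        if not 0 < p < 1:
            raise ValueError("burst occupancy must be in (0, 1)")
        r_burst = max(self.r0 * (self.alpha - p) / (p * (1.0 - p)), 0.0)
        r_tonic = self.r0 - r_burst * p
        if r_tonic < 0:
            raise ValueError("impossible rate split: tonic rate would be negative")
        return r_tonic, r_burst


@dataclass
class SimulatedCell:
    """Ground-truth spikes (10 ms bins) and, once generated, the trace."""

    spike_counts: np.ndarray
    rate: np.ndarray
    burst_indicator: np.ndarray
    params: SimParams
    trace: Trace | None = None


def _burst_indicator(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """0/1 indicator of burst epochs on the simulation bins.

    Onset count is Poisson at ``burst_rate * duration``; onsets are
    placed uniformly and redrawn as a set until no two epochs overlap,
    so every epoch lasts exactly ``burst_duration``.
    """
    n_bins = params.n_bins
    b = np.zeros(n_bins)
    burst_bins = int(round(params.burst_duration / params.bin_width))
    latest = params.duration - params.burst_duration
    if latest <= 0:
        return b
    n_bursts = rng.poisson(params.burst_rate * params.duration)
    if n_bursts == 0:
        return b
    for _ in range(1000):
        onsets = np.sort(rng.uniform(0.0, latest, size=n_bursts))
        if np.all(np.diff(onsets) >= params.burst_duration):
            break
    else:
        # dense regime: fall back to evenly jittered non-overlapping onsets
        onsets = np.linspace(0.0, latest, n_bursts, endpoint=False)
    for onset in onsets:
        i = int(round(onset / params.bin_width))
        b[i : i + burst_bins] = 1.0
    return b


def simulate_spikes(params: SimParams,
                    rng: np.random.Generator | None = None) -> SimulatedCell:
    """Draw one cell's ground-truth spike train (no fluorescence yet)."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    r_tonic, r_burst = params.rate_split()
    if params.alpha == 0.0 or r_burst == 0.0:
        b = np.zeros(params.n_bins)
        rate = np.full(params.n_bins, params.r0)
    else:
        b = _burst_indicator(params, rng)
        rate = r_tonic + r_burst * b
    counts = rng.poisson(rate * params.bin_width)
    return SimulatedCell(counts.astype(np.int64), rate, b, params)


def _correlated_noise(n: int, halfwidth_s: float, sampling_rate: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian-smoothed white noise.

    ``halfwidth_s`` is the smoother's half width at half maximum, so the
    Gaussian SD is ``halfwidth / sqrt(2 ln 2)``.  The filter output is
    renormalized by its exact per-sample standard deviation
    ``sqrt(sum w_j^2)`` so the caller's amplitude scales a unit-variance
    process.
    """
    sd = halfwidth_s / np.sqrt(2.0 * np.log(2.0)) * sampling_rate
    half = max(int(np.ceil(4.0 * sd)), 1)
    w = np.exp(-0.5 * (np.arange(-half, half + 1) / sd) ** 2)
    w /= w.sum()
    white = rng.standard_normal(n + 2 * half)
    out = np.convolve(white, w, mode="valid")
    return out / np.sqrt(np.sum(w**2))


def simulate_fluorescence(cell: SimulatedCell, params: SimParams,
                          rng: np.random.Generator | None = None) -> Trace:
    """Fluorescence from a spike train: exponential filtering plus noise.

    The spike counts are filtered with an exponential kernel of
    timescale ``tau_sim`` (exact AR(1) recursion): a single spike of
    count 1 yields the exponential kernel scaled by the transient
    amplitude (``bin_width / tau_sim`` by default, see
    :attr:`SimParams.transient_amplitude`), exactly.  Shot noise
    ``beta * N(0, 1)`` and correlated noise ``gamma * (smoothed white
    noise)`` are then added per sample.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate
    g = np.exp(-1.0 / (params.tau_sim * fs))
    values = params.transient_amplitude * lfilter(
        [1.0], [1.0, -g], cell.spike_counts.astype(float)
    )
    n = len(values)
    if params.beta > 0:
        values = values + params.beta * rng.standard_normal(n)
    if params.gamma > 0:
        values = values + params.gamma * _correlated_noise(
            n, params.corr_noise_halfwidth, fs, rng
        )
    return Trace(values, fs)


def simulate_cell(params: SimParams,
                  rng: np.random.Generator | None = None) -> SimulatedCell:
    """Spike train plus fluorescence for one cell."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    cell = simulate_spikes(params, rng)
    cell.trace = simulate_fluorescence(cell, params, rng)
    return cell


def simulate_dataset(n_cells: int, duration: float, seed: int,
                     params: SimParams | None = None
                     ) -> tuple[list[SimulatedCell], SimParams]:
    """A dataset of cells sharing one random parameter tuple.

    One draw of (r0, alpha, beta, gamma) uniform over the documented
    ranges is shared by all cells; spike and noise realizations are
    independent per cell.  Fully reproducible from ``seed``.  Passing
    ``params`` skips the random draw and uses those values for every
    cell.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    if params is None:
        draws = {k: float(rng.uniform(*v)) for k, v in PARAM_RANGES.items()}
        params = SimParams(duration=duration, seed=seed, **draws)
    else:
        params = replace(params, duration=duration, seed=seed)
    cells = [simulate_cell(params, rng) for _ in range(n_cells)]
    return cells, params


@dataclass
class StimExperiment:
    """A two-half stimulus-repeat experiment with ground truth.

    Stimuli are presented in a freshly randomized order within each
    repeat block; the session is split into two halves for the
    split-half reliability benchmark.  ``spike_counts`` is
    (n_neurons, n_bins) at the simulation bin width; ``traces`` holds
    the corresponding fluorescence.  ``trial_table`` has columns
    trial_index, onset_s, stimulus_id, repeat_half.
    """

    trial_table: pd.DataFrame
    spike_counts: np.ndarray
    traces: list[Trace]
    gains: np.ndarray
    trial_duration: float
    bin_width: float
    r0: float
    beta: float
    gamma: float
    tau_sim: float = 1.0
    corr_noise_halfwidth: float = 0.5

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.bin_width

    @property
    def trial_bins(self) -> int:
        return int(round(self.trial_duration / self.bin_width))

    def with_noise(self, beta: float, gamma: float,
                   noise_seed: int) -> "StimExperiment":
        """Same ground-truth spike trains under a different noise draw."""
        rng = np.random.default_rng(noise_seed)
        params = SimParams(
            duration=self.spike_counts.shape[1] * self.bin_width,
            r0=self.r0, beta=beta, gamma=gamma, bin_width=self.bin_width,
            tau_sim=self.tau_sim,
            corr_noise_halfwidth=self.corr_noise_halfwidth,
        )
        traces = []
        for counts in self.spike_counts:
            cell = SimulatedCell(counts, np.array([]), np.array([]), params)
            traces.append(simulate_fluorescence(cell, params, rng))
        return StimExperiment(
            self.trial_table, self.spike_counts, traces, self.gains,
            self.trial_duration, self.bin_width, self.r0, beta, gamma,
            self.tau_sim, self.corr_noise_halfwidth,
        )


def simulate_stim_experiment(
    n_neurons: int,
    n_stimuli: int,
    n_repeats_per_half: int,
    r0: float,
    noise: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    noise_seed: int | None = None,
    trial_duration: float = 2.0,
    gain_log_sd: float = 0.5,
    bin_width: float = 0.01,
    tau_sim: float = 1.0,
) -> StimExperiment:
    """Simulate a randomized stimulus-repeat session.

    Each half contains ``n_repeats_per_half`` blocks, each a random
    permutation of the ``n_stimuli`` stimuli; trials are contiguous
    windows of ``trial_duration``.  Per-neuron tuning gains are drawn
    once, log-normal with log-SD ``gain_log_sd`` and mean 1 (``0`` gives
    flat tuning); the per-trial firing rate is ``r0 * gain``.  Spikes
    depend only on ``seed``; noise only on ``noise_seed`` (derived from
    ``seed`` when omitted), so the same spike trains can be re-dressed
    with different noise via :meth:`StimExperiment.with_noise`.
    """
    if n_stimuli < 2:
        raise ValueError("need at least two stimuli")
    beta, gamma = noise
    rng = np.random.default_rng(seed)
    if noise_seed is None:
        noise_seed = seed + 777_001
    gains = rng.lognormal(-0.5 * gain_log_sd**2, gain_log_sd,
                          size=(n_neurons, n_stimuli)) if gain_log_sd > 0 \
        else np.ones((n_neurons, n_stimuli))
    order = []
    halves = []
    for half in (1, 2):
        for _ in range(n_repeats_per_half):
            order.extend(rng.permutation(n_stimuli).tolist())
            halves.extend([half] * n_stimuli)
    n_trials = len(order)
    trial_bins = int(round(trial_duration / bin_width))
    n_bins = n_trials * trial_bins
    trial_table = pd.DataFrame(
        {
            "trial_index": np.arange(n_trials),
            "onset_s": np.arange(n_trials) * trial_duration,
            "stimulus_id": np.array(order),
            "repeat_half": np.array(halves),
        }
    )
    rates = np.empty((n_neurons, n_bins))
    for i, stim in enumerate(order):
        rates[:, i * trial_bins : (i + 1) * trial_bins] = (
            r0 * gains[:, stim]
        )[:, None]
    spike_counts = rng.poisson(rates * bin_width).astype(np.int64)
    exp = StimExperiment(
        trial_table, spike_counts, [], gains, trial_duration, bin_width,
        r0, beta, gamma, tau_sim,
    )
    return exp.with_noise(beta, gamma, noise_seed)
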