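"""Spike-train similarity metrics.

The primary ground-truth metric is ``sigma_gt``: the Pearson correlation
of estimated and true spike trains after binning both at 40 ms.  Because
binned correlation punishes a one-bin offset as a complete miss, two
softened variants are provided: Gaussian smoothing of the deconvolved
output before binning, and a van Rossum-style correlation of smoothed
trains.  AUC (probability that a spike-containing bin outranks a
spike-free bin, ties scored 0.5) gives a rank-based alternative.

``sigma_stim`` needs no ground truth: it is the Spearman correlation of
trial-averaged tuning curves computed from two halves of a recording in
which stimuli were presented in random order.  The rank correlation is
used deliberately -- a monotone nonlinearity applied by a deconvolution
algorithm leaves it unchanged.

Undefined scores (zero-variance inputs, degenerate ground truth) are
returned as NaN and must be excluded from averages, never silently
scored 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import rankdata, spearmanr

__all__ = [
    "SpikeTrain",
    "bin_signal",
    "sigma_gt",
    "smooth_gaussian",
    "best_timelag",
    "van_rossum_corr",
    "auc",
    "autocorrelogram",
    "trial_responses",
    "sigma_stim",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times as events (seconds) or counts per fixed-width bin."""

    duration: float
    events: np.ndarray | None = None
    counts: np.ndarray | None = None
    bin_width: float | None = None

    def __post_init__(self) -> None:
        if (self.events is None) == (self.counts is None):
            raise ValueError("give exactly one of events or counts")
        if self.events is not None:
            ev = np.asarray(self.events, dtype=float)
            if np.any(ev < 0) or np.any(ev >= self.duration):
                raise ValueError("event times must lie in [0, duration)")
            object.__setattr__(self, "events", ev)
        else:
            c = np.asarray(self.counts, dtype=float)
            if np.any(c < 0):
                raise ValueError("counts must be non-negative")
            if self.bin_width is None or self.bin_width <= 0:
                raise ValueError("counts need a positive bin_width")
            object.__setattr__(self, "counts", c)

    def binned(self, bin_width: float) -> np.ndarray:
        return bin_signal(self, bin_width)


def _coerce(x, sampling_rate: float | None):
    """Return (mass-per-sample array, sample width) for array-like input."""
    if isinstance(x, SpikeTrain):
        if x.events is not None:
            return np.asarray(x.events, float), None
        return np.asarray(x.counts, float), x.bin_width
    if sampling_rate is None:
        raise ValueError("array input needs a sampling_rate")
    return np.asarray(x, float), 1.0 / sampling_rate


def bin_signal(x, bin_width: float, sampling_rate: float | None = None
               ) -> np.ndarray:
    """Sum signal mass into half-open bins ``[t, t + bin_width)``.

    ``x`` may be a :class:`SpikeTrain` (events or counts) or an array of
    per-sample mass (deconvolved amplitudes) with ``sampling_rate``.
    Total mass is conserved exactly.  Binning below the source sampling
    interval is rejected.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    data, dt = _coerce(x, sampling_rate)
    if dt is None:  # event representation
        n_bins = int(np.ceil(x.duration / bin_width))
        idx = np.floor(data / bin_width).astype(np.int64)
        out = np.zeros(n_bins)
        np.add.at(out, idx, 1.0)
        return out
    if bin_width < dt - 1e-12:
        raise ValueError(
            f"bin_width {bin_width} s is below the source interval {dt} s"
        )
    n = len(data)
    # the 1e-9 guards against float rounding pushing a sample whose start
    # time lies exactly on a bin edge into the previous bin
    idx = np.floor((np.arange(n) * dt) / bin_width + 1e-9).astype(np.int64)
    out = np.zeros(idx[-1] + 1 if n else 0)
    np.add.at(out, idx, data)
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = min(len(a), len(b))
    a, b = a[:n] - a[:n].mean(), b[:n] - b[:n].mean()
    va, vb = a @ a, b @ b
    if va <= 0 or vb <= 0:
        return float("nan")
    return float((a @ b) / np.sqrt(va * vb))


def sigma_gt(est, gt, bin_width: float = 0.04,
             sampling_rate: float | None = None,
             gt_sampling_rate: float | None = None) -> float:
    """Pearson correlation of estimated and true trains binned at 40 ms.

    Returns NaN when either binned train has zero variance; such cells
    are excluded from dataset averages.
    """
    e = bin_signal(est, bin_width, sampling_rate)
    g = bin_signal(gt, bin_width,
                   gt_sampling_rate if gt_sampling_rate is not None
                   else sampling_rate)
    return _pearson(e, g)


def smooth_gaussian(x: np.ndarray, sd: float) -> np.ndarray:
    """Gaussian smoothing with SD in samples; ``sd == 0`` is identity.

    The kernel is normalized to unit sum and the boundary is reflective.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    x = np.asarray(x, float)
    if sd == 0:
        return x.copy()
    return gaussian_filter1d(x, sd, mode="reflect")


def _shift(x: np.ndarray, lag: int) -> np.ndarray:
    """Shift so sample i moves to i + lag, zero-padding the exposed end."""
    out = np.zeros_like(x)
    if lag == 0:
        out[:] = x
    elif lag > 0:
        out[lag:] = x[: len(x) - lag]
    else:
        out[:lag] = x[-lag:]
    return out


def best_timelag(est_cells, gt_cells, lag_range: int = 10,
                 bin_width: float = 0.04,
                 sampling_rate: float | None = None) -> int:
    """Dataset-wide integer lag maximizing mean sigma_gt across cells.

    The lag (in native samples) is added to the estimate's sample
    indices before binning and is shared by all cells of the dataset.
    Ties prefer the smallest ``|lag|``, then the negative lag.
    """
    lags = sorted(range(-lag_range, lag_range + 1), key=lambda l: (abs(l), l))
    best_lag, best_score = 0, -np.inf
    for lag in lags:
        scores = [
            sigma_gt(_shift(np.asarray(e, float), lag), g, bin_width,
                     sampling_rate=sampling_rate)
            for e, g in zip(est_cells, gt_cells)
        ]
        score = np.nanmean(scores) if np.any(np.isfinite(scores)) else np.nan
        if np.isfinite(score) and score > best_score:
            best_lag, best_score = lag, score
    return best_lag


def van_rossum_corr(est, gt, sd: float, sampling_rate: float) -> float:
    """Correlation of Gaussian-smoothed trains at the native rate.

    ``sd`` is in seconds; both trains are smoothed (unlike the binned
    sigma_gt pipeline, where only the estimate is smoothed) so the
    metric is symmetric.  ``sd -> 0`` recovers the plain correlation of
    the sampled trains.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    e = np.asarray(est, float)
    g = np.asarray(gt, float)
    sd_samples = sd * sampling_rate
    return _pearson(smooth_gaussian(e, sd_samples), smooth_gaussian(g, sd_samples))


def auc(deconv_binned, gt_binned) -> float:
    """Probability a spike bin outranks a non-spike bin; ties count 0.5.

    Computed exactly by the rank (Mann-Whitney) method: with average
    ranks, every tied spike/non-spike pair contributes exactly 0.5.
    Degenerate ground truth (all bins spiking or none) returns NaN.
    """
    d = np.asarray(deconv_binned, float)
    pos = np.asarray(gt_binned, float) > 0
    n1 = int(pos.sum())
    n0 = len(pos) - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(d)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def autocorrelogram(x, max_lag: float, bin_width: float,
                    sampling_rate: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Normalized autocovariance of the binned signal at lags >= 1 bin.

    Returns ``(lags_seconds, values)`` with ``values[l] = c_l / c_0``
    where ``c_l`` is the (biased) autocovariance at lag ``l`` bins.  A
    homogeneous Poisson train is flat: all values within ~4/sqrt(N) of 0
    for N bins.  Zero lag is excluded (it is 1 by construction).
    """
    if max_lag < bin_width:
        raise ValueError("max_lag must be >= bin_width")
    b = bin_signal(x, bin_width, sampling_rate)
    b = b - b.mean()
    n = len(b)
    n_lags = int(np.floor(max_lag / bin_width + 1e-12))
    c0 = float(b @ b) / n
    vals = np.empty(n_lags)
    for l in range(1, n_lags + 1):
        vals[l - 1] = float(b[:-l] @ b[l:]) / n / c0 if c0 > 0 else np.nan
    return np.arange(1, n_lags + 1) * bin_width, vals


def trial_responses(experiment, amplitudes) -> np.ndarray:
    """Per-trial responses: summed deconvolved amplitude in each trial.

    The response window is the full inter-trial interval starting at
    stimulus onset.  ``amplitudes`` is (n_neurons, n_samples) at the
    experiment's sampling rate; returns (n_neurons, n_trials).
    """
    amplitudes = np.atleast_2d(np.asarray(amplitudes, float))
    tb = experiment.trial_bins
    n_trials = len(experiment.trial_table)
    out = np.zeros((amplitudes.shape[0], n_trials))
    for i in range(n_trials):
        out[:, i] = amplitudes[:, i * tb : (i + 1) * tb].sum(axis=1)
    return out


def sigma_stim(experiment, responses) -> tuple[np.ndarray, float]:
    """Split-half tuning-curve reliability.

    For each neuron, trial-averaged responses per stimulus are computed
    separately on the two halves (each half saw every stimulus in
    randomized order); ``sigma_stim`` is their Spearman correlation over
    stimuli, and the benchmark value is the mean over neurons.  Neurons
    with a constant tuning curve in either half score NaN and are
    excluded from the mean.

    Returns ``(per_neuron_values, mean)``.
    """
    responses = np.atleast_2d(np.asarray(responses, float))
    table = experiment.trial_table
    stims = np.sort(table["stimulus_id"].unique())
    curves = {}
    for half in (1, 2):
        mask_half = table["repeat_half"].to_numpy() == half
        curve = np.empty((responses.shape[0], len(stims)))
        for j, stim in enumerate(stims):
            sel = mask_half & (table["stimulus_id"].to_numpy() == stim)
            if not np.any(sel):
                raise ValueError(f"stimulus {stim} missing from half {half}")
            curve[:, j] = responses[:, sel].mean(axis=1)
        curves[half] = curve
    vals = np.empty(responses.shape[0])
    for n in range(responses.shape[0]):
        r1, r2 = curves[1][n], curves[2][n]
        if np.ptp(r1) == 0 or np.ptp(r2) == 0:
            vals[n] = np.nan
        else:
            vals[n] = spearmanr(r1, r2).statistic
    mean = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else float("nan")
    return vals, mean
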