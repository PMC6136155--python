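"""Calcium impulse-response kernels.

A kernel models the fluorescence response to a single spike: either a
decaying exponential ``exp(-t/tau_d)`` or, to model a finite rise time,
a difference of exponentials ``exp(-t/tau_d) - exp(-t/tau_r)`` with the
rise timescale a fraction (0-0.5) of the decay timescale.  All kernels
are peak-normalized to 1 so deconvolved amplitudes stay in trace units,
and truncated where the amplitude falls below 1% of the peak (at most
~1% of the kernel energy is discarded).

Decay timescales are categorical -- fast (0.7 s), medium (1.25 s), slow
(2 s) -- assigned per calcium sensor from a plain-text lookup table.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import toeplitz

__all__ = [
    "Kernel",
    "TIMESCALES",
    "make_exponential_kernel",
    "make_difference_kernel",
    "sensor_timescale",
    "load_sensor_table",
    "estimate_kernel_from_ground_truth",
    "write_kernel",
]

#: Decay timescales (seconds) for the three sensor speed classes.
TIMESCALES = {"fast": 0.7, "medium": 1.25, "slow": 2.0}

#: Truncation threshold as a fraction of the peak amplitude.
TRUNCATION = 0.01


@dataclass(frozen=True)
class Kernel:
    """Discretized, peak-normalized calcium impulse response.

    Attributes
    ----------
    sampling_rate : float
        Samples per second (Hz).
    tau_decay : float
        Decay timescale in seconds (> 0).
    tau_rise : float
        Rise timescale in seconds (0 for a pure exponential).
    values : np.ndarray
        Non-negative amplitudes with ``max(values) == 1``, truncated
        where the amplitude falls below 1% of the peak.
    """

    sampling_rate: float
    tau_decay: float
    tau_rise: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(len(self.values)) / self.sampling_rate


def _truncate(values: np.ndarray) -> np.ndarray:
    """Clip the tail once the amplitude has fallen below 1% of the peak.

    The first sub-threshold sample after the peak is kept, so the last
    value is guaranteed to be <= the threshold.
    """
    peak = int(np.argmax(values))
    below = np.nonzero(values[peak:] <= TRUNCATION * values[peak])[0]
    if below.size == 0:
        return values
    return values[: peak + below[0] + 1]


def make_exponential_kernel(tau_decay: float, sampling_rate: float) -> Kernel:
    """Single decaying exponential: ``k[i] = exp(-i / (tau_decay * fs))``.

    Parameters
    ----------
    tau_decay : float
        Decay timescale in seconds; must be positive.
    sampling_rate : float
        Sampling rate in Hz; must be positive.
    """
    if tau_decay <= 0:
        raise ValueError(f"tau_decay must be positive, got {tau_decay}")
    if sampling_rate <= 0:
        raise ValueError(f"sampling_rate must be positive, got {sampling_rate}")
    # support is ~tau * ln(1/threshold); +2 gives headroom for truncation
    n = int(np.ceil(tau_decay * sampling_rate * np.log(1.0 / TRUNCATION))) + 2
    values = _truncate(np.exp(-np.arange(n) / (tau_decay * sampling_rate)))
    return Kernel(sampling_rate, tau_decay, 0.0, values)


def make_difference_kernel(
    tau_decay: float, rise_fraction: float, sampling_rate: float
) -> Kernel:
    """Difference of exponentials modelling a finite fluorescence rise.

    The unnormalized shape is ``g(t) = exp(-t/tau_d) - exp(-t/tau_r)``
    with ``tau_r = rise_fraction * tau_d``; the result is ``g / max(g)``.
    ``rise_fraction == 0`` degenerates to the pure exponential kernel.

    Parameters
    ----------
    rise_fraction : float
        Rise timescale as a fraction of the decay timescale, in [0, 0.5].
    """
    if not 0.0 <= rise_fraction <= 0.5:
        raise ValueError(f"rise_fraction must be in [0, 0.5], got {rise_fraction}")
    if rise_fraction == 0.0:
        return make_exponential_kernel(tau_decay, sampling_rate)
    if tau_decay <= 0:
        raise ValueError(f"tau_decay must be positive, got {tau_decay}")
    if sampling_rate <= 0:
        raise ValueError(f"sampling_rate must be positive, got {sampling_rate}")
    tau_rise = rise_fraction * tau_decay
    if tau_rise == 0.0:  # underflow guard for vanishingly small fractions
        return make_exponential_kernel(tau_decay, sampling_rate)
    # normalization lifts the tail relative to the (sub-unit) peak of g,
    # so the support may need to extend beyond the exponential's; grow
    # until the truncation threshold is reached
    n = int(np.ceil(tau_decay * sampling_rate * np.log(1.0 / TRUNCATION))) + 2
    for _ in range(8):
        t = np.arange(n) / sampling_rate
        with np.errstate(over="ignore"):
            g = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
        values = _truncate(g / g.max())
        if values[-1] <= TRUNCATION:
            break
        n *= 2
    return Kernel(sampling_rate, tau_decay, tau_rise, values)


def load_sensor_table() -> dict[str, str]:
    """Parse the shipped sensor -> speed-class lookup table."""
    text = (
        importlib.resources.files("spikedeconv")
        .joinpath("data/sensor_timescales.txt")
        .read_text()
    )
    table = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        label, speed = line.split()
        table[_normalize_label(label)] = speed
    return table


def _normalize_label(label: str) -> str:
    return "".join(label.lower().split())


def sensor_timescale(sensor_label: str) -> float:
    """Decay timescale (seconds) assigned to a calcium sensor.

    Sensors are grouped into fast (0.7 s), medium (1.25 s) and slow
    (2 s) classes; lookup is case- and whitespace-insensitive.

    Raises
    ------
    KeyError
        If the sensor is not in the shipped lookup table; the message
        lists the known sensors.
    """
    table = load_sensor_table()
    key = _normalize_label(sensor_label)
    if key not in table:
        raise KeyError(
            f"unknown sensor {sensor_label!r}; known sensors: "
            + ", ".join(sorted(table))
        )
    return TIMESCALES[table[key]]


def estimate_kernel_from_ground_truth(trace, spikes, length: int) -> Kernel:
    """Estimate the kernel by regressing fluorescence onto known spikes.

    Builds a Toeplitz design matrix of lagged spike counts (plus an
    intercept column absorbing any constant offset), solves by ordinary
    least squares, clips negative coefficients to zero and
    peak-normalizes.  This is a diagnostic: deconvolution itself always
    uses fixed parametric kernels.

    Parameters
    ----------
    trace : Trace
        Fluorescence trace.
    spikes : np.ndarray
        Spike counts per sample, same length and rate as ``trace``.
    length : int
        Kernel support in samples.

    Raises
    ------
    ValueError
        If the spike train contains no spikes.
    """
    counts = np.asarray(spikes, dtype=float)
    y = np.asarray(trace.values, dtype=float)
    if counts.shape != y.shape:
        raise ValueError("trace and spikes must cover the same samples")
    if not np.any(counts > 0):
        raise ValueError("cannot estimate a kernel from an empty spike train")
    first_col = counts
    first_row = np.zeros(length)
    first_row[0] = counts[0]
    design = toeplitz(first_col, first_row)
    design = np.column_stack([design, np.ones(len(y))])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    values = np.clip(coef[:-1], 0.0, None)
    peak = values.max()
    if peak <= 0:
        raise ValueError("regression produced an all-zero kernel")
    values = values / peak
    return Kernel(trace.sampling_rate, float("nan"), float("nan"), values)


def write_kernel(kernel: Kernel, path) -> None:
    """Write a kernel as two-column delimited text (time_s, amplitude)."""
    data = np.column_stack([kernel.times, kernel.values])
    np.savetxt(path, data, fmt="%.9g", delimiter=",", header="time_s,amplitude",
               comments="")
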