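"""File formats: trace matrices, spike trains, trial tables.

Conventions used throughout: times in seconds, 0-based sample indices,
half-open bins ``[t, t + dt)``.  Delimited text is comma-separated with
a mandatory header row and 9-significant-digit numbers; the binary
alternative is little-endian float64 row-major with a small YAML
sidecar (``<path>.meta.yaml``) declaring rate and dimensions.  NaN
samples are rejected at parse time because deconvolution requires
finite input.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .deconv import Trace
from .metrics import SpikeTrain

__all__ = [
    "read_traces",
    "write_traces",
    "read_spikes",
    "write_spikes",
    "read_trial_table",
    "write_trial_table",
]


def write_traces(traces, path, fmt: str = "text") -> None:
    """Write traces (one row per cell) as delimited text or flat binary.

    Text: a header row of sample times in seconds, then one row per
    cell.  Binary: raw little-endian float64 plus a ``.meta.yaml``
    sidecar with sampling_rate, n_cells, n_samples, dtype, byte_order.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces to write")
    fs = traces[0].sampling_rate
    n = len(traces[0])
    for t in traces:
        if abs(t.sampling_rate - fs) > 1e-9 or len(t) != n:
            raise ValueError("all traces must share rate and length")
    mat = np.vstack([t.values for t in traces])
    path = Path(path)
    if fmt == "text":
        header = ",".join(f"{i / fs:.9g}" for i in range(n))
        np.savetxt(path, mat, fmt="%.9g", delimiter=",", header=header,
                   comments="")
    elif fmt == "binary":
        mat.astype("<f8").tofile(path)
        meta = {"sampling_rate": float(fs), "n_cells": int(mat.shape[0]),
                "n_samples": int(mat.shape[1]), "dtype": "float64",
                "byte_order": "little"}
        Path(str(path) + ".meta.yaml").write_text(yaml.safe_dump(meta))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_traces(path, sampling_rate: float | None = None) -> list[Trace]:
    """Read a trace matrix written by :func:`write_traces`.

    Binary files are recognized by their ``.meta.yaml`` sidecar.  For
    text files the sampling rate is inferred from the header times
    unless given explicitly.
    """
    path = Path(path)
    meta_path = Path(str(path) + ".meta.yaml")
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text())
        expected = meta["n_cells"] * meta["n_samples"] * 8
        actual = path.stat().st_size
        if actual != expected:
            raise ValueError(
                f"truncated binary payload in {path}: expected {expected} "
                f"bytes, found {actual}"
            )
        mat = np.fromfile(path, dtype="<f8").reshape(
            meta["n_cells"], meta["n_samples"]
        )
        fs = float(meta["sampling_rate"])
    else:
        try:
            raw = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
            header = path.read_text().splitlines()[0]
            times = np.array([float(x) for x in header.split(",")])
        except Exception as exc:
            raise ValueError(f"unreadable trace file {path}: {exc}") from exc
        if raw.shape[1] != len(times):
            raise ValueError(
                f"{path}: header declares {len(times)} samples but rows "
                f"have {raw.shape[1]}"
            )
        if sampling_rate is None:
            if len(times) < 2:
                raise ValueError("cannot infer sampling rate from one sample")
            sampling_rate = 1.0 / (times[1] - times[0])
        mat, fs = raw, sampling_rate
    if not np.all(np.isfinite(mat)):
        bad = np.argwhere(~np.isfinite(mat))[0]
        raise ValueError(
            f"{path}: non-finite sample at cell {bad[0]}, sample {bad[1]}"
        )
    return [Trace(row, fs) for row in mat]


def write_spikes(spikes, path, fmt: str = "events") -> None:
    """Write spike trains as an event list or a binned-count matrix.

    Events: CSV with columns ``cell_id,time_s``.  Counts: a first
    header line ``bin_width=<s>``, then one row of counts per cell.
    """
    spikes = list(spikes)
    path = Path(path)
    if fmt == "events":
        rows = []
        for i, st in enumerate(spikes):
            if st.events is None:
                raise ValueError("count-based trains cannot be written as events")
            for t in st.events:
                rows.append((i, t))
        with open(path, "w") as fh:
            fh.write("cell_id,time_s\n")
            for cid, t in rows:
                fh.write(f"{cid},{t:.9g}\n")
    elif fmt == "counts":
        if any(st.counts is None for st in spikes):
            raise ValueError("event-based trains cannot be written as counts")
        bw = spikes[0].bin_width
        mat = np.vstack([st.counts for st in spikes])
        np.savetxt(path, mat, fmt="%.9g", delimiter=",",
                   header=f"bin_width={bw:.9g}", comments="")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_spikes(path, duration: float | None = None) -> list[SpikeTrain]:
    """Read spike trains written by :func:`write_spikes`.

    The representation is detected from the header line.  For event
    files ``duration`` defaults to just past the last event.
    """
    path = Path(path)
    first = path.read_text().splitlines()[0].strip()
    if first == "cell_id,time_s":
        df = pd.read_csv(path)
        if len(df) and (df["time_s"] < 0).any():
            raise ValueError(f"{path}: negative event times")
        if len(df) and (df["cell_id"] < 0).any():
            raise ValueError(f"{path}: negative cell ids")
        n_cells = int(df["cell_id"].max()) + 1 if len(df) else 0
        if duration is None:
            duration = float(df["time_s"].max()) + 1e-9 if len(df) else 1.0
        return [
            SpikeTrain(duration,
                       events=df.loc[df["cell_id"] == i, "time_s"].to_numpy())
            for i in range(n_cells)
        ]
    if first.startswith("bin_width="):
        bw = float(first.split("=", 1)[1])
        mat = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        if np.any(mat < 0):
            raise ValueError(f"{path}: negative counts")
        return [SpikeTrain(mat.shape[1] * bw, counts=row, bin_width=bw)
                for row in mat]
    raise ValueError(
        f"{path}: unrecognized spike file header {first!r}; expected an "
        "event list ('cell_id,time_s') or a count matrix ('bin_width=...')"
    )


def write_trial_table(table: pd.DataFrame, path) -> None:
    """Write a trial table (trial_index, onset_s, stimulus_id, repeat_half)."""
    cols = ["trial_index", "onset_s", "stimulus_id", "repeat_half"]
    table[cols].to_csv(path, index=False, float_format="%.9g")


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial table."""
    df = pd.read_csv(path)
    required = {"trial_index", "onset_s", "stimulus_id", "repeat_half"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if not np.all(np.diff(df["onset_s"]) > 0):
        raise ValueError(f"{path}: trial onsets must be strictly increasing")
    for stim in df["stimulus_id"].unique():
        halves = set(df.loc[df["stimulus_id"] == stim, "repeat_half"])
        if halves != {1, 2}:
            raise ValueError(
                f"{path}: stimulus {stim} must appear in both halves"
            )
    return df
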