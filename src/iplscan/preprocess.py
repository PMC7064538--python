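"""Trace preprocessing: stimulus synchronization, 64 Hz resampling, detrending.

Raw ROI traces are sampled at the scan's frame rate and must be (1) cut into
per-repeat snippets at the stimulus time markers, (2) resampled onto a uniform
64 Hz grid (one 32-s presentation = 2048 samples), (3) high-pass filtered at
0.1 Hz to remove slow drift, and (4) averaged across repeats into the N x T
response matrix consumed by the models.

All operations are linear, and the Butterworth detrending is applied
forward-backward (zero phase) so that no response timing is shifted — essential
for the downstream speed analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .errors import ConfigError

__all__ = [
    "synchronize",
    "resample",
    "detrend",
    "average_repeats",
    "preprocess_roi",
    "TARGET_RATE_HZ",
]

TARGET_RATE_HZ = 64.0


def synchronize(
    trace: np.ndarray,
    rate_hz: float,
    marker_times_s,
    repeat_duration_s: float,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Cut a raw trace into per-repeat snippets at stimulus time markers.

    Returns one ``(times_rel_s, values)`` pair per marker, covering one full
    stimulus presentation; times are relative to the marker.  One sample of
    context on each side is kept so later interpolation can cover the window
    edges.  Repeats extending beyond the recording are dropped with a warning.
    """
    trace = np.asarray(trace, dtype=float)
    markers = np.asarray(marker_times_s, dtype=float)
    if markers.size and np.any(np.diff(markers) <= 0):
        raise ConfigError("marker times must be strictly increasing")
    total_s = trace.size / rate_hz
    snippets = []
    dropped = 0
    for m in markers:
        if m < 0 or m + repeat_duration_s > total_s:
            dropped += 1
            continue
        i0 = max(int(np.floor(m * rate_hz)) - 1, 0)
        i1 = min(int(np.ceil((m + repeat_duration_s) * rate_hz)) + 1, trace.size)
        idx = np.arange(i0, i1)
        snippets.append((idx / rate_hz - m, trace[idx]))
    if dropped:
        warnings.warn(f"dropped {dropped} truncated repeat(s)", stacklevel=2)
    return snippets


def resample(
    times_s: np.ndarray,
    values: np.ndarray,
    duration_s: float,
    rate_hz: float = TARGET_RATE_HZ,
) -> np.ndarray:
    """Linear-interpolation resampling onto a uniform grid.

    The grid spans ``[0, duration_s)`` at ``rate_hz``; a 32-s snippet at 64 Hz
    yields exactly 2048 samples.
    """
    times_s = np.asarray(times_s, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ConfigError("resampling needs at least 2 samples")
    if rate_hz <= 0:
        raise ConfigError("target rate must be positive")
    t_target = np.arange(int(round(duration_s * rate_hz))) / rate_hz
    return np.interp(t_target, times_s, values)


def detrend(
    trace: np.ndarray,
    cutoff_hz: float = 0.1,
    rate_hz: float = TARGET_RATE_HZ,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth high-pass (default order 2, cutoff 0.1 Hz).

    Removes slow drift and the DC level while preserving response timing
    (forward-backward filtering has no group delay).
    """
    if cutoff_hz >= rate_hz / 2:
        raise ConfigError(f"cutoff {cutoff_hz} Hz must be below Nyquist ({rate_hz / 2} Hz)")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=rate_hz, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(trace, dtype=float))


def average_repeats(snippets: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Elementwise mean over repeat snippets (all must share one length)."""
    arrs = [np.asarray(s, dtype=float) for s in snippets]
    if not arrs:
        raise ConfigError("need at least one snippet")
    lengths = {a.shape[-1] for a in arrs}
    if len(lengths) != 1:
        raise ConfigError(f"snippet lengths differ: {sorted(lengths)}")
    return np.mean(np.stack(arrs), axis=0)


def preprocess_roi(
    trace: np.ndarray,
    rate_hz: float,
    marker_times_s,
    repeat_duration_s: float,
    cutoff_hz: float = 0.1,
    target_rate_hz: float = TARGET_RATE_HZ,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full chain for one ROI: synchronize, resample, detrend, average.

    Returns ``(mean_trace, detrended_repeats, resampled_repeats)``: the
    repeat-averaged detrended 64 Hz trace (model input), the R x T detrended
    repeats, and the R x T repeats before detrending.  The quality index is
    best computed on the pre-detrend repeats — zero-phase high-pass filtering
    inflates the variance of the reliability estimator for noise traces.
    """
    snips = synchronize(trace, rate_hz, marker_times_s, repeat_duration_s)
    if not snips:
        raise ConfigError("no complete repeats found")
    reps_raw = np.stack([resample(t, v, repeat_duration_s, target_rate_hz) for t, v in snips])
    reps = np.stack([detrend(r, cutoff_hz, target_rate_hz) for r in reps_raw])
    return reps.mean(axis=0), reps, reps_raw
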