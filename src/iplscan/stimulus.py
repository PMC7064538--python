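"""Chirp light stimuli.

The chirp is the standard full-field fingerprinting stimulus for retinal response
kinetics: a light-On step, a frequency-accelerating sinusoid at full contrast and a
contrast-ramped sinusoid at fixed frequency, separated by half-intensity plateaus.
It is presented in two sizes, local (100 µm diameter) and global (800 µm); both
share the same time course here.

The waveform is fully deterministic for a given configuration; intensities are
normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

__all__ = ["ChirpConfig", "ChirpStimulus", "generate_chirp"]

DEFAULT_RATE_HZ = 64.0


@dataclass(frozen=True)
class ChirpConfig:
    """Segment durations (s) and modulation ranges of the chirp.

    Defaults give the canonical 32-s chirp: 2 s dark baseline, 3 s On step, 2 s
    half intensity, 8 s frequency sweep (0.5→8 Hz, full contrast), 2 s half,
    8 s contrast ramp (0→100 % at 2 Hz), 2 s half, 5 s dark baseline.
    """

    rate_hz: float = DEFAULT_RATE_HZ
    baseline_s: float = 2.0
    step_s: float = 3.0
    half1_s: float = 2.0
    freq_sweep_s: float = 8.0
    half2_s: float = 2.0
    contrast_ramp_s: float = 8.0
    half3_s: float = 2.0
    tail_s: float = 5.0
    freq_start_hz: float = 0.5
    freq_end_hz: float = 8.0
    ramp_freq_hz: float = 2.0
    size_label: str = "local"

    @property
    def duration_s(self) -> float:
        return (
            self.baseline_s
            + self.step_s
            + self.half1_s
            + self.freq_sweep_s
            + self.half2_s
            + self.contrast_ramp_s
            + self.half3_s
            + self.tail_s
        )

    def validate(self) -> None:
        durations = (
            self.baseline_s,
            self.step_s,
            self.half1_s,
            self.freq_sweep_s,
            self.half2_s,
            self.contrast_ramp_s,
            self.half3_s,
            self.tail_s,
        )
        if any(d < 0 for d in durations):
            raise ConfigError("chirp segment durations must be non-negative")
        if self.rate_hz <= 0:
            raise ConfigError("rate_hz must be positive")
        if self.size_label not in ("local", "global"):
            raise ConfigError(f"size_label must be 'local' or 'global', got {self.size_label!r}")


@dataclass(frozen=True)
class ChirpStimulus:
    """A sampled chirp: normalized intensity in [0, 1] at a fixed rate.

    ``segment_markers`` lists (label, start_index) for each segment in order;
    ``trigger_times`` holds repeat-onset times in seconds (empty for a single
    presentation; filled in by the simulator when repeats are laid out).
    """

    samples: np.ndarray
    rate_hz: float
    duration_s: float
    size_label: str = "local"
    segment_markers: tuple[tuple[str, int], ...] = ()
    trigger_times: tuple[float, ...] = field(default=())

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def segment_slice(self, label: str) -> slice:
        """Index slice of a named segment (e.g. ``"step"``)."""
        starts = dict(self.segment_markers)
        if label not in starts:
            raise KeyError(f"no segment {label!r}; have {list(starts)}")
        labels = [lbl for lbl, _ in self.segment_markers]
        i = labels.index(label)
        start = self.segment_markers[i][1]
        stop = (
            self.segment_markers[i + 1][1]
            if i + 1 < len(self.segment_markers)
            else self.n_samples
        )
        return slice(start, stop)


def generate_chirp(config: ChirpConfig | None = None) -> ChirpStimulus:
    """Sample the chirp waveform described by ``config``.

    The waveform contains, in order: dark baseline, full-intensity On step,
    half-intensity plateau, frequency sweep, plateau, contrast ramp, plateau,
    dark tail.  Sinusoidal segments modulate around half intensity.  Output is
    clipped to [0, 1] and deterministic for a given configuration.
    """
    cfg = config or ChirpConfig()
    cfg.validate()
    rate = cfg.rate_hz

    def n(dur: float) -> int:
        return int(round(dur * rate))

    pieces: list[np.ndarray] = []
    markers: list[tuple[str, int]] = []
    cursor = 0

    def add(label: str, arr: np.ndarray) -> None:
        nonlocal cursor
        markers.append((label, cursor))
        pieces.append(arr)
        cursor += arr.size

    add("baseline", np.zeros(n(cfg.baseline_s)))
    add("step", np.ones(n(cfg.step_s)))
    add("half1", np.full(n(cfg.half1_s), 0.5))

    # Frequency sweep: linear chirp, instantaneous frequency f0 -> f1, full contrast.
    t = np.arange(n(cfg.freq_sweep_s)) / rate
    dur = max(cfg.freq_sweep_s, 1e-12)
    phase = 2 * np.pi * (cfg.freq_start_hz * t + (cfg.freq_end_hz - cfg.freq_start_hz) * t**2 / (2 * dur))
    add("freq_sweep", 0.5 + 0.5 * np.sin(phase))

    add("half2", np.full(n(cfg.half2_s), 0.5))

    # Contrast ramp: fixed frequency, amplitude 0 -> 0.5.
    t = np.arange(n(cfg.contrast_ramp_s)) / rate
    amp = 0.5 * t / max(cfg.contrast_ramp_s, 1e-12)
    add("contrast_ramp", 0.5 + amp * np.sin(2 * np.pi * cfg.ramp_freq_hz * t))

    add("half3", np.full(n(cfg.half3_s), 0.5))
    add("tail", np.zeros(n(cfg.tail_s)))

    samples = np.clip(np.concatenate(pieces) if pieces else np.empty(0), 0.0, 1.0)
    return ChirpStimulus(
        samples=samples,
        rate_hz=rate,
        duration_s=cfg.duration_s,
        size_label=cfg.size_label,
        segment_markers=tuple(markers),
    )
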