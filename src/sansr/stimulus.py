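"""Injected-current protocols: sine-wave and zero-mean white-noise epochs.

Amplitude convention: a sine segment of amplitude ``a`` is the waveform
``a * sin(2*pi*F*t)`` — peak ``a`` pA, peak-to-peak ``2a``, where ``a`` is
the current amplitude in one direction.  Positive current is depolarizing
at this level of the API.

Noise segments are band-limited white noise realized as sample-and-hold:
a new value is drawn uniformly from [-a, +a] every ``hold_ms`` from a
seeded generator, so a segment is a pure function of (amplitude, hold,
seed).  The uniform draw keeps every sample inside the stated one-direction
amplitude; the flat part of its power spectrum extends far beyond the
cell's sub-10-Hz resonance band.  Gaussian draws (SD = a) are available
behind a flag.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "StimulusSegment", "StimulusTrace", "sine_segment", "noise_segment",
    "quiet_segment", "noise_run", "sine_sweep", "SINE_AMPLITUDES_PA",
    "NOISE_AMPLITUDES_PA", "SWEEP_FREQUENCIES_HZ",
]

#: Amplitude series used throughout the study (pA, one direction).
SINE_AMPLITUDES_PA = (10.0, 20.0, 25.0, 50.0)
NOISE_AMPLITUDES_PA = (25.0, 31.25, 62.5, 125.0)
#: Default sine-sweep frequencies (Hz).
SWEEP_FREQUENCIES_HZ = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)


@dataclasses.dataclass(frozen=True)
class StimulusSegment:
    kind: str                  # "none" | "sine" | "noise"
    amplitude: float = 0.0     # pA, one-direction amplitude
    frequency: float = 0.0     # Hz, sine only
    duration: float = 0.0      # s
    hold_ms: float = 1.0       # noise only
    seed: int | None = None    # noise only
    gaussian: bool = False     # noise only

    def __post_init__(self):
        if self.kind not in ("none", "sine", "noise"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.kind == "sine" and self.frequency <= 0:
            raise ValueError("sine frequency must be > 0")
        if self.kind == "noise" and self.hold_ms <= 0:
            raise ValueError("noise hold interval must be > 0")

    def _noise_values(self, n: int) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        if self.gaussian:
            return rng.normal(0.0, self.amplitude, size=n)
        return rng.uniform(-self.amplitude, self.amplitude, size=n)

    def sample(self, t) -> np.ndarray:
        """Waveform value at local time ``t`` (s, measured from segment start).

        Pure: the same ``t`` always yields the same value.
        """
        t = np.asarray(t, dtype=float)
        if self.kind == "none":
            return np.zeros_like(t)
        if self.kind == "sine":
            return self.amplitude * np.sin(2.0 * np.pi * self.frequency * t)
        hold = self.hold_ms * 1e-3
        n = int(np.ceil(self.duration / hold))
        vals = self._noise_values(n)
        idx = np.clip((t / hold).astype(np.int64), 0, n - 1)
        return vals[idx]


@dataclasses.dataclass(frozen=True)
class StimulusTrace:
    """Ordered segments tiling [0, total duration] without overlap."""

    segments: tuple

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    def segment_bounds(self):
        """(start, end) of each segment, s."""
        starts = np.concatenate([[0.0], np.cumsum([s.duration for s in self.segments])])
        return [(starts[i], starts[i + 1]) for i in range(len(self.segments))]

    def sample(self, t) -> np.ndarray:
        """Current (pA, depolarizing positive) at absolute time(s) ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros_like(t)
        for seg, (t0, t1) in zip(self.segments, self.segment_bounds()):
            m = (t >= t0) & (t < t1)
            if m.any():
                out[m] = seg.sample(t[m] - t0)
        return out

    def build_array(self, grid_dt: float, duration: float) -> np.ndarray:
        """Sample-and-hold the waveform onto a uniform grid of spacing
        ``grid_dt`` covering [0, duration)."""
        n = int(np.ceil(duration / grid_dt))
        t = np.arange(n) * grid_dt
        return self.sample(t)

    def to_csv(self, path, grid_dt: float = 1e-3) -> None:
        import pandas as pd
        t = np.arange(int(np.ceil(self.duration / grid_dt))) * grid_dt
        pd.DataFrame({"time_s": t, "current_pA": self.sample(t)}).to_csv(
            path, index=False)


def sine_segment(a: float, f_hz: float, duration: float) -> StimulusSegment:
    """Sine epoch ``a*sin(2*pi*F*t)`` (peak ``a`` pA, peak-to-peak ``2a``)."""
    return StimulusSegment(kind="sine", amplitude=a, frequency=f_hz,
                           duration=duration)


def noise_segment(a: float, duration: float, hold_ms: float = 1.0,
                  seed: int | None = None,
                  gaussian: bool = False) -> StimulusSegment:
    """Zero-mean white-noise epoch, uniform sample-and-hold on [-a, +a]."""
    return StimulusSegment(kind="noise", amplitude=a, duration=duration,
                           hold_ms=hold_ms, seed=seed, gaussian=gaussian)


def quiet_segment(duration: float) -> StimulusSegment:
    return StimulusSegment(kind="none", duration=duration)


def noise_run(a: float, seed: int | None = None, quiet_before: float = 10.0,
              noise_duration: float = 10.0, quiet_after: float = 10.0,
              hold_ms: float = 1.0, gaussian: bool = False) -> StimulusTrace:
    """The standard noise protocol: quiet, then noise, then quiet tail.

    Defaults follow the experimental protocol in which noise is applied
    from 10 to 20 s of a 30 s recording.
    """
    segs = []
    if quiet_before > 0:
        segs.append(quiet_segment(quiet_before))
    segs.append(noise_segment(a, noise_duration, hold_ms=hold_ms, seed=seed,
                              gaussian=gaussian))
    if quiet_after > 0:
        segs.append(quiet_segment(quiet_after))
    return StimulusTrace(segments=segs)


def sine_sweep(a: float, freqs=SWEEP_FREQUENCIES_HZ,
               epoch_duration: float = 10.0,
               gap_duration: float = 0.0) -> StimulusTrace:
    """Consecutive sine epochs at the given frequencies (default 0.5-6 Hz).

    Pass a finer frequency grid (e.g. 0.25-Hz steps) for continuous-spectrum
    protocols.
    """
    freqs = tuple(freqs)
    if not freqs:
        raise ValueError("at least one sweep frequency is required")
    segs = []
    for i, f in enumerate(freqs):
        if i and gap_duration > 0:
            segs.append(quiet_segment(gap_duration))
        segs.append(sine_segment(a, f, epoch_duration))
    return StimulusTrace(segments=segs)
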