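"""AP detection and firing metrics: rate, CV, capture, resonance spectra.

The study's working quantities: per-beat instantaneous firing frequency,
its coefficient of variation (CV = SD/mean; lower CV means more rhythmic
firing), population class bands (fast > 2.5 Hz, moderate 1-2.5 Hz, slow
< 1 Hz, dormant = no APs), and one-to-one capture by a sine stimulus
(mean firing frequency within +-0.1 Hz of the stimulus frequency).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = [
    "APTrain", "FiringMetrics", "ResonanceSpectrum",
    "detect_aps", "firing_metrics", "capture_test", "resonance_spectrum",
    "burst_detect", "CAPTURE_TOL_HZ",
]

#: One-to-one capture tolerance (Hz).
CAPTURE_TOL_HZ = 0.1


@dataclasses.dataclass(frozen=True)
class APTrain:
    """Ordered AP upstroke times plus the detector settings that made them."""

    times: np.ndarray          # s, strictly increasing
    threshold: float = -20.0   # mV
    refractory_ms: float = 80.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("AP times must be strictly increasing")
        if t.size and np.any(np.diff(t) < self.refractory_ms * 1e-3 - 1e-12):
            raise ValueError("AP times closer than the refractory period")

    def __len__(self):
        return self.times.size

    def shifted(self, dt: float) -> "APTrain":
        return APTrain(self.times + dt, self.threshold, self.refractory_ms)

    def within(self, t0: float, t1: float) -> np.ndarray:
        return self.times[(self.times >= t0) & (self.times <= t1)]


@dataclasses.dataclass(frozen=True)
class FiringMetrics:
    mean_frequency: float      # Hz
    cv: float                  # nan when < 3 APs in window
    n_aps: int
    cell_class: str            # fast | moderate | slow | dormant
    cv_defined: bool
    window: tuple

    @property
    def firing(self) -> bool:
        return self.cell_class != "dormant"


def classify_rate(mean_frequency: float, n_aps: int) -> str:
    """Population class bands: >2.5 Hz fast, 1-2.5 moderate, <1 slow."""
    if n_aps == 0:
        return "dormant"
    if mean_frequency > 2.5:
        return "fast"
    if mean_frequency >= 1.0:
        return "moderate"
    return "slow"


def detect_aps(time: np.ndarray, vm: np.ndarray, threshold: float = -20.0,
               refractory_ms: float = 80.0, debounce_ms: float = 10.0,
               min_dwell_ms: float = 40.0, max_dwell_ms: float = 400.0,
               max_slew_mv_ms: float = 5.0) -> APTrain:
    """Detect AP upstrokes as upward threshold crossings with a waveform
    stereotypy check.

    An upward crossing opens a suprathreshold *event*; the event ends when
    the potential stays below threshold for ``debounce_ms`` (brief noise
    dips do not fragment an AP plateau).  The event is an AP when

    * it lasts between ``min_dwell_ms`` and ``max_dwell_ms`` — a real AP
      holds a depolarized plateau for tens to hundreds of ms, whereas the
      spikes produced by very strong stochastic stimuli cross threshold
      only fleetingly;
    * its plateau is smooth: the median per-ms voltage change stays below
      ``max_slew_mv_ms``.  During a genuine AP the membrane conductance is
      high and the trajectory stereotyped; noise-dominated excursions are
      jagged.  This is what lets extreme noise show "high-amplitude
      fluctuations instead of APs";
    * its upstroke is at least ``refractory_ms`` after the previous AP.

    Subthreshold oscillations never cross and yield no events.  Crossing
    times are linearly interpolated between samples.
    """
    time = np.asarray(time, dtype=float)
    vm = np.asarray(vm, dtype=float)
    if time.ndim != 1 or time.shape != vm.shape or time.size < 2:
        raise ValueError("time and vm must be 1-D arrays of equal length >= 2")
    dt = np.diff(time)
    if np.any(np.abs(dt - dt[0]) > 1e-9 + 1e-6 * dt[0]):
        raise ValueError("detect_aps requires a uniform time grid")
    if refractory_ms <= 0:
        raise ValueError("refractory must be > 0")

    step = float(dt[0])
    above = vm >= threshold
    deb = max(1, int(round(debounce_ms * 1e-3 / step)))
    accepted = []
    t_last = -math.inf
    i, n = 0, vm.size
    while i < n - 1:
        if not above[i] and above[i + 1]:
            start = i + 1
            v0, v1 = vm[i], vm[i + 1]
            frac = (threshold - v0) / (v1 - v0) if v1 != v0 else 1.0
            t_cross = time[i] + frac * step
            # extend the event through sub-debounce dips below threshold
            j, below_run = start, 0
            while j < n - 1:
                j += 1
                if above[j]:
                    below_run = 0
                else:
                    below_run += 1
                    if below_run >= deb:
                        break
            end = j - below_run
            dwell_ms = (end - start) * step * 1e3
            ok = (min_dwell_ms <= dwell_ms <= max_dwell_ms
                  and t_cross - t_last >= refractory_ms * 1e-3)
            if ok and end > start + 1:
                slew = np.median(np.abs(np.diff(vm[start:end + 1]))) \
                    / (step * 1e3)
                ok = slew <= max_slew_mv_ms
            if ok:
                accepted.append(t_cross)
                t_last = t_cross
            i = j
        else:
            i += 1
    return APTrain(np.asarray(accepted), threshold, refractory_ms)


def firing_metrics(train: APTrain, window: tuple) -> FiringMetrics:
    """Rate and rhythmicity over ``window = (t0, t1)``.

    The mean frequency is the mean of per-beat instantaneous frequencies
    (reciprocal inter-AP intervals); CV is their SD/mean.  With fewer than
    two APs the rate falls back to count/window-length and the CV is
    flagged undefined.
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must satisfy t1 > t0")
    times = train.within(t0, t1)
    n = times.size
    if n >= 2:
        freqs = 1.0 / np.diff(times)
        mean_f = float(freqs.mean())
        if n >= 3:
            cv = float(freqs.std(ddof=1) / freqs.mean())
            cv_defined = True
        else:
            cv, cv_defined = float("nan"), False
    else:
        mean_f = n / (t1 - t0)
        cv, cv_defined = float("nan"), False
    return FiringMetrics(mean_frequency=mean_f, cv=cv, n_aps=int(n),
                         cell_class=classify_rate(mean_f, n),
                         cv_defined=cv_defined, window=(float(t0), float(t1)))


def capture_test(train: APTrain, f_hz: float, window: tuple,
                 tol_hz: float = CAPTURE_TOL_HZ) -> bool:
    """One-to-one capture: mean firing frequency within ``tol_hz`` of the
    stimulus frequency, requiring at least two APs in the window."""
    m = firing_metrics(train, window)
    return bool(m.n_aps >= 2 and abs(m.mean_frequency - f_hz) <= tol_hz)


def burst_detect(train: APTrain, f_hz: float, window: tuple,
                 phase0: float = 0.0, depol_fraction: float = 0.9) -> bool:
    """Burst firing under a sine stimulus: APs confined to depolarizing
    half-cycles with at least one fully silent hyperpolarizing half-cycle.

    ``phase0`` is the time (s) at which the sine starts; the depolarizing
    half-cycle is where ``sin(2*pi*F*(t - phase0)) > 0``.
    """
    if f_hz <= 0:
        raise ValueError("sine frequency must be > 0")
    t0, t1 = window
    times = train.within(t0, t1)
    if times.size == 0:
        return False
    period = 1.0 / f_hz
    phase = np.mod(times - phase0, period) / period
    in_depol = phase < 0.5
    if in_depol.mean() < depol_fraction:
        return False
    # silent hyperpolarizing half-cycles within the window
    n_cycles = int(np.floor((t1 - phase0) / period))
    for k in range(max(0, int(np.ceil((t0 - phase0) / period))), n_cycles):
        h0 = phase0 + (k + 0.5) * period
        h1 = phase0 + (k + 1.0) * period
        if h0 >= t0 and h1 <= t1 and not np.any((times >= h0) & (times < h1)):
            return True
    return False


@dataclasses.dataclass
class ResonanceSpectrum:
    """Capture flags on an (amplitude, frequency) grid."""

    amplitudes: np.ndarray       # pA
    frequencies: np.ndarray      # Hz
    captured: np.ndarray         # bool, shape (n_amp, n_freq)
    mean_rates: np.ndarray       # Hz, same shape

    def captured_frequencies(self, amplitude: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.amplitudes - amplitude)))
        return self.frequencies[self.captured[i]]

    def span(self, amplitude: float) -> tuple | None:
        """(lowest, highest) captured frequency at this amplitude."""
        f = self.captured_frequencies(amplitude)
        return (float(f.min()), float(f.max())) if f.size else None

    def to_frame(self):
        import pandas as pd
        rows = [(a, f, bool(self.captured[i, j]), self.mean_rates[i, j])
                for i, a in enumerate(self.amplitudes)
                for j, f in enumerate(self.frequencies)]
        return pd.DataFrame(rows, columns=["amplitude_pA", "frequency_Hz",
                                           "captured", "mean_rate_Hz"])


def resonance_spectrum(params, amplitudes, frequencies,
                       epoch_duration: float = 10.0, settle: float = 2.0,
                       dt_ms: float = 0.01, detector_kwargs: dict | None = None,
                       init=None) -> ResonanceSpectrum:
    """Simulate one sine epoch per (amplitude, frequency) and test capture.

    Each epoch starts from the shipped initial state (or ``init``); capture
    is evaluated on ``[settle, epoch_duration]`` so the first cycles, in
    which entrainment establishes itself, are excluded.
    """
    from .model import simulate_cell
    from .stimulus import StimulusTrace, sine_segment

    amplitudes = np.asarray(list(amplitudes), dtype=float)
    frequencies = np.asarray(list(frequencies), dtype=float)
    captured = np.zeros((amplitudes.size, frequencies.size), dtype=bool)
    rates = np.zeros_like(captured, dtype=float)
    dkw = detector_kwargs or {}
    for i, a in enumerate(amplitudes):
        for j, f in enumerate(frequencies):
            stim = StimulusTrace(segments=[sine_segment(a, f, epoch_duration)])
            try:
                res = simulate_cell(params, stimulus=stim,
                                    duration=epoch_duration, dt_ms=dt_ms,
                                    init=init)
            except Exception as exc:
                raise RuntimeError(
                    f"simulation failed at amplitude {a} pA, "
                    f"frequency {f} Hz") from exc
            train = detect_aps(res.time, res.vm, **dkw)
            window = (settle, epoch_duration)
            captured[i, j] = capture_test(train, f, window)
            rates[i, j] = firing_metrics(train, window).mean_frequency
    return ResonanceSpectrum(amplitudes=amplitudes, frequencies=frequencies,
                             captured=captured, mean_rates=rates)
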