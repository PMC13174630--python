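"""Seeded synthetic-data generators for every analysis stage.

The movie generator emulates the statistical structure of Ca recordings
from intact SAN tissue: periodic global AP-induced Ca transients (APCTs)
appearing as one spatial gain map times one time course (a rank-1 term),
plus three patterns of local background activity —

1. cell-width Ca waves propagating along the cell axis (50-150 um/s),
2. small, fast local Ca releases lasting a few frames,
3. incoherent AP-like flashes of whole cell-shaped footprints out of
   synchrony with the global transient —

plus i.i.d. Gaussian sensor noise.  Event amplitudes default to the APCT
amplitude, matching the observation that background signals are
comparable in magnitude to the global transients.  Every generator is a
pure function of its spec and seed and returns ground truth alongside the
data.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy import ndimage

from .imaging import CaMovie
from .ap_metrics import APTrain

__all__ = [
    "MovieSpec", "TruthEvent", "TruthTable", "synth_movie", "synth_vm_ca",
    "synth_ap_train",
]


@dataclasses.dataclass(frozen=True)
class MovieSpec:
    """Parameters of a synthetic Ca movie."""

    shape: tuple = (300, 64, 64)       # (T, H, W)
    frame_interval_ms: float = 10.0
    pixel_size_um: float = 1.0
    baseline: float = 100.0            # camera counts
    apct_rate_hz: float = 4.0          # global transient rate
    apct_amplitude: float = 1.0        # dF/F0 peak of the global flash
    apct_rise_ms: float = 20.0
    apct_decay_ms: float = 120.0
    n_waves: int = 0                   # pattern 1
    wave_speed_um_s: tuple = (50.0, 150.0)
    wave_width_um: float = 6.0
    wave_length_um: float = 40.0
    n_lcrs: int = 0                    # pattern 2
    lcr_radius_px: tuple = (1.5, 4.0)
    lcr_duration_frames: tuple = (2, 6)
    lcr_area_dist: str = "lognormal"   # or "gpd"
    lcr_area_params: tuple = (3.0, 0.6)   # lognormal: (mu, sigma) of log-area
                                          # gpd: (scale, shape)
    n_flashes: int = 0                 # pattern 3
    flash_axes_px: tuple = (8.0, 3.0)
    event_amplitude: float | None = None   # None -> apct_amplitude
    noise_sd: float = 0.0              # dF/F0 units
    seed: int = 0

    def __post_init__(self):
        t, h, w = self.shape
        if t < 2 or h < 8 or w < 8:
            raise ValueError("movie must be at least 2 x 8 x 8")
        for name in ("apct_rate_hz", "baseline", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.n_waves, self.n_lcrs, self.n_flashes) < 0:
            raise ValueError("event counts must be >= 0")


@dataclasses.dataclass
class TruthEvent:
    pattern: str                  # "wave" | "lcr" | "flash"
    start_frame: int
    end_frame: int
    path_area_px: float
    centroid_xy: tuple
    footprint: np.ndarray         # boolean (H, W) path footprint


@dataclasses.dataclass
class TruthTable:
    events: list
    apct_times: np.ndarray        # s

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame([
            {"pattern": e.pattern, "start_frame": e.start_frame,
             "end_frame": e.end_frame, "path_area_px": e.path_area_px,
             "centroid_x": e.centroid_xy[0], "centroid_y": e.centroid_xy[1]}
            for e in self.events])

    def to_json(self, path) -> None:
        payload = {"apct_times_s": self.apct_times.tolist(),
                   "events": self.to_frame().to_dict(orient="records")}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def draw_lcr_areas(dist: str, params: tuple, n: int, rng) -> np.ndarray:
    """Sample nominal LCR path areas (px^2) from the requested family.

    ``lognormal`` takes (mu, sigma) of the log-area; ``gpd`` takes (scale,
    shape) of a generalized-Pareto excess over a 4 px^2 floor.
    """
    if dist == "lognormal":
        return rng.lognormal(params[0], params[1], n)
    if dist == "gpd":
        scale, shape = params
        if shape == 0:
            return 4.0 + rng.exponential(scale, n)
        u = rng.uniform(size=n)
        return 4.0 + (scale / shape) * ((1 - u) ** (-shape) - 1.0)
    raise ValueError("lcr_area_dist must be 'lognormal' or 'gpd'")


def _apct_kernel(spec: MovieSpec) -> np.ndarray:
    """Rise/decay kernel of one global transient, unit peak, per frame."""
    dt = spec.frame_interval_ms
    n = max(2, int(np.ceil((spec.apct_rise_ms + 5 * spec.apct_decay_ms) / dt)))
    t = np.arange(n) * dt
    k = (1 - np.exp(-t / spec.apct_rise_ms)) * np.exp(-t / spec.apct_decay_ms)
    m = k.max()
    return k / m if m > 0 else k


def _smooth_gain_map(h: int, w: int, rng) -> np.ndarray:
    g = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=6.0)
    g = g - g.min()
    return 0.5 + g / (g.max() + 1e-12)   # positive, O(1)


def _insert(canvas: np.ndarray, frame: int, image: np.ndarray) -> None:
    if 0 <= frame < canvas.shape[0]:
        canvas[frame] += image


def synth_movie(spec: MovieSpec):
    """Generate ``(CaMovie, TruthTable)`` for the given spec.

    The noiseless, event-free movie is exactly rank-1:
    ``gain(x, y) * (baseline + apct(t))``, so the global-subtraction stage
    has an exact target.  Inserted events add localized dF/F0 on top.
    """
    t_frames, h, w = spec.shape
    rng = np.random.default_rng(spec.seed)
    dt_s = spec.frame_interval_ms * 1e-3

    # --- rank-1 global part ------------------------------------------------
    gain = _smooth_gain_map(h, w, rng)
    apct = np.zeros(t_frames)
    if spec.apct_rate_hz > 0:
        kernel = _apct_kernel(spec)
        period = 1.0 / spec.apct_rate_hz
        times = np.arange(0.3, t_frames * dt_s, period)
        for t0 in times:
            i0 = int(round(t0 / dt_s))
            seg = kernel[:t_frames - i0]
            apct[i0:i0 + seg.size] += seg * spec.apct_amplitude
    else:
        times = np.empty(0)
    rel = 1.0 + apct                    # relative brightness time course
    movie = gain[None, :, :] * (spec.baseline * rel[:, None, None])

    amp_df = (spec.event_amplitude if spec.event_amplitude is not None
              else spec.apct_amplitude)
    local_df = np.zeros((t_frames, h, w))   # event dF/F0
    events: list = []

    yy, xx = np.mgrid[0:h, 0:w]
    px = spec.pixel_size_um

    # --- pattern 1: propagating cell-width waves ---------------------------
    for _ in range(spec.n_waves):
        speed = rng.uniform(*spec.wave_speed_um_s)       # um/s
        theta = rng.uniform(0, 2 * np.pi)
        ux, uy = np.cos(theta), np.sin(theta)
        x0 = rng.uniform(0.2 * w, 0.8 * w)
        y0 = rng.uniform(0.2 * h, 0.8 * h)
        travel = spec.wave_length_um / px                # px
        n_fr = max(2, int(round(travel * px / speed / dt_s)))
        t_start = rng.integers(0, max(1, t_frames - n_fr))
        sig_w = spec.wave_width_um / px / 2.355
        fp = np.zeros((h, w), bool)
        for k in range(n_fr):
            d = travel * k / (n_fr - 1)
            cx, cy = x0 + ux * d, y0 + uy * d
            blob = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2)
                            / (2 * sig_w ** 2)))
            _insert(local_df, t_start + k, amp_df * blob)
            fp |= blob > 0.5
        ys, xs = np.nonzero(fp)
        if xs.size == 0:
            continue
        events.append(TruthEvent("wave", int(t_start),
                                 int(min(t_start + n_fr - 1, t_frames - 1)),
                                 float(fp.sum()),
                                 (float(xs.mean()), float(ys.mean())), fp))

    # --- pattern 2: small fast LCRs ---------------------------------------
    areas = draw_lcr_areas(spec.lcr_area_dist, spec.lcr_area_params,
                           spec.n_lcrs, rng)
    for area in areas:
        radius = np.sqrt(max(area, 2.0) / np.pi)
        dur = int(rng.integers(spec.lcr_duration_frames[0],
                               spec.lcr_duration_frames[1] + 1))
        cx = rng.uniform(radius + 1, w - radius - 1)
        cy = rng.uniform(radius + 1, h - radius - 1)
        t_start = int(rng.integers(0, max(1, t_frames - dur)))
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        # binary footprint: the path area is then insensitive to the
        # detection threshold
        disk = r2 <= radius ** 2
        blob = disk.astype(float)
        for k in range(dur):
            _insert(local_df, t_start + k, amp_df * blob)
        fp = disk
        ys, xs = np.nonzero(fp)
        if xs.size == 0:
            continue
        events.append(TruthEvent("lcr", t_start,
                                 int(min(t_start + dur - 1, t_frames - 1)),
                                 float(fp.sum()),
                                 (float(xs.mean()), float(ys.mean())), fp))

    # --- pattern 3: incoherent AP-like flashes -----------------------------
    kernel = _apct_kernel(spec)
    for _ in range(spec.n_flashes):
        a_ax, b_ax = spec.flash_axes_px
        theta = rng.uniform(0, np.pi)
        cx = rng.uniform(a_ax, w - a_ax)
        cy = rng.uniform(a_ax, h - a_ax)
        ct, st = np.cos(theta), np.sin(theta)
        xr = (xx - cx) * ct + (yy - cy) * st
        yr = -(xx - cx) * st + (yy - cy) * ct
        blob = np.exp(-0.5 * ((xr / a_ax) ** 2 + (yr / b_ax) ** 2) * 4.0)
        t_start = int(rng.integers(0, max(1, t_frames - kernel.size)))
        # jitter off the APCT grid so the flash is out of synchrony
        for k, g in enumerate(kernel):
            _insert(local_df, t_start + k, amp_df * g * blob)
        fp = blob > 0.5
        ys, xs = np.nonzero(fp)
        events.append(TruthEvent("flash", t_start,
                                 int(min(t_start + kernel.size - 1,
                                         t_frames - 1)),
                                 float(fp.sum()),
                                 (float(xs.mean()), float(ys.mean())), fp))

    movie = movie * (1.0 + local_df)
    if spec.noise_sd > 0:
        movie = movie + rng.normal(0.0, spec.noise_sd * spec.baseline,
                                   movie.shape)
    movie = np.maximum(movie, 0.0)
    return (CaMovie(movie, spec.frame_interval_ms, spec.pixel_size_um),
            TruthTable(events=events, apct_times=times))


def synth_vm_ca(duration: float = 10.0, dt_ms: float = 1.0,
                coupling: float = 0.8, lag_ms: float = 50.0,
                noise_sd: float = 0.1, bandwidth_hz: float = 5.0,
                ap_times=None, seed: int = 0):
    """Paired subthreshold V_m / Ca fluctuation traces with known coupling.

    A band-limited latent fluctuation drives both channels: V_m carries it
    directly, Ca carries it scaled by ``coupling`` and delayed by
    ``lag_ms``; each adds independent white noise of ``noise_sd`` (in
    units of the latent SD).  Optional AP/Ca-transient pairs are stamped
    at ``ap_times`` to emulate firing episodes.  Returns ``(t, vm, ca,
    truth)`` with V_m in mV around -55 mV and Ca in dF/F0-like units.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    dt = dt_ms * 1e-3
    n = int(round(duration / dt))
    lag = int(round(lag_ms * 1e-3 / dt))
    sigma = 1.0 / (2 * np.pi * bandwidth_hz * dt)
    latent = ndimage.gaussian_filter1d(rng.normal(size=n + lag), sigma)
    latent /= latent.std() + 1e-12
    vm = latent[lag:] + noise_sd * rng.normal(size=n)
    ca = coupling * latent[:n] + noise_sd * rng.normal(size=n)
    t = np.arange(n) * dt
    vm_mv = -55.0 + 3.0 * vm
    ca_a = 0.05 * ca
    if ap_times is not None:
        spike = np.exp(-np.arange(0, 0.2, dt) / 0.03)
        for t0 in np.asarray(ap_times, dtype=float):
            i0 = int(round(t0 / dt))
            seg = spike[:max(0, n - i0)]
            if i0 < 0 or seg.size == 0:
                continue
            vm_mv[i0:i0 + seg.size] += 75.0 * seg
            ca_a[i0:i0 + seg.size] += 1.0 * spike[:seg.size]
    truth = {"coupling": coupling, "lag_ms": lag_ms, "noise_sd": noise_sd,
             "bandwidth_hz": bandwidth_hz, "seed": seed}
    return t, vm_mv, ca_a, truth


def synth_ap_train(rate_hz: float, cv: float, duration: float,
                   seed: int = 0) -> APTrain:
    """Gamma-renewal AP train with the requested mean rate and interval CV.

    ``cv = 0`` gives an exactly periodic train.  Inter-AP intervals are
    gamma with shape 1/cv^2 and mean 1/rate.
    """
    if rate_hz <= 0:
        raise ValueError("rate must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    mean_ivi = 1.0 / rate_hz
    rng = np.random.default_rng(seed)
    times = []
    t = mean_ivi
    while t <= duration:
        times.append(t)
        if cv == 0:
            t += mean_ivi
        else:
            shape = 1.0 / cv ** 2
            t += rng.gamma(shape, mean_ivi / shape)
    return APTrain(np.asarray(times), threshold=np.nan, refractory_ms=0.0)
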