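"""Ca-imaging analysis: global-transient subtraction, LCR detection,
heavy-tail statistics and V_m-Ca cross-correlation.

Pipeline for a movie of SAN tissue loaded with a Ca indicator:

1. normalize to dF/F0 per pixel (F0 = low temporal percentile);
2. remove the spatially coherent AP-induced Ca transient (APCT) as the
   leading principal component of the pixel x time matrix, leaving a
   residual movie of local Ca releases (LCRs) and noise;
3. threshold the residual at a robust per-pixel noise scale and extract
   spatiotemporally connected events; an event's size is its *path area*,
   the area of the 2-D footprint swept over its lifetime, which credits
   propagating waves with the full territory they recruit;
4. characterize the path-area distribution's tail with the L-kurtosis and
   the mean-excess function (flat for exponential tails, increasing for
   heavy, Pareto-type tails).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "CaMovie", "LCREvent", "LCRStats", "XCorrResult",
    "normalize_movie", "subtract_global_component", "detect_lcrs",
    "l_moments", "l_kurtosis", "mean_excess_curve", "vm_ca_crosscorr",
    "events_to_frame",
]


@dataclasses.dataclass
class CaMovie:
    """T x H x W intensity stack with acquisition metadata."""

    data: np.ndarray
    frame_interval_ms: float = 10.0
    pixel_size_um: float = 1.0
    mask: np.ndarray | None = None   # True = valid tissue pixel

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3 or d.shape[0] < 2:
            raise ValueError("movie must be a (T, H, W) stack with T >= 2")
        if not np.all(np.isfinite(d)):
            raise ValueError("movie intensities must be finite")
        self.data = d
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != d.shape[1:]:
                raise ValueError("mask shape must match frame shape")
            self.mask = m

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def to_tiff(self, path) -> None:
        import tifffile
        tifffile.imwrite(path, self.data.astype(np.float32))

    @classmethod
    def from_tiff(cls, path, frame_interval_ms: float = 10.0,
                  pixel_size_um: float = 1.0) -> "CaMovie":
        import tifffile
        return cls(tifffile.imread(path),
                   frame_interval_ms=frame_interval_ms,
                   pixel_size_um=pixel_size_um)


def normalize_movie(movie: CaMovie, f0_percentile: float = 10.0,
                    f0_floor: float = 1e-6) -> CaMovie:
    """Per-pixel dF/F0 with F0 the given temporal percentile.

    Pixels whose baseline is at or below ``f0_floor`` are masked out; an
    all-zero movie has no estimable baseline and is rejected.
    """
    f0 = np.percentile(movie.data, f0_percentile, axis=0)
    valid = f0 > f0_floor
    if movie.mask is not None:
        valid &= movie.mask
    if not valid.any():
        raise ValueError("no pixel has a positive baseline; "
                         "cannot normalize an all-zero movie")
    out = np.zeros_like(movie.data)
    out[:, valid] = movie.data[:, valid] / f0[valid] - 1.0
    return CaMovie(out, movie.frame_interval_ms, movie.pixel_size_um,
                   mask=valid)


def subtract_global_component(movie: CaMovie, n_components: int = 1):
    """Split a normalized movie into its rank-``n_components`` global part
    and a residual of local activity.

    The global AP-induced transient lights up the whole field with one
    shared time course, i.e. it is (near) rank-1 in the pixel x time
    matrix; the leading principal component(s) of the uncentered matrix
    capture it.  Returns ``(residual_movie, global_trace, spatial_map)``
    where ``global_trace`` (T,) carries the component's temporal profile
    scaled to unit-norm spatial map.
    """
    t, h, w = movie.shape
    valid = movie.mask if movie.mask is not None else np.ones((h, w), bool)
    x = movie.data.reshape(t, h * w)[:, valid.ravel()]
    if x.size == 0 or not np.any(x):
        raise ValueError("degenerate movie: no signal to decompose")
    k = int(n_components)
    if k < 1:
        raise ValueError("n_components must be >= 1")
    # economy SVD on the (small) T x P matrix
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if s[0] == 0:
        raise ValueError("degenerate (rank-0) movie")
    recon = (u[:, :k] * s[:k]) @ vt[:k]
    residual = np.zeros_like(movie.data)
    residual.reshape(t, h * w)[:, valid.ravel()] = x - recon
    global_trace = u[:, 0] * s[0]
    spatial_map = np.zeros((h, w))
    spatial_map.ravel()[valid.ravel()] = vt[0]
    res_movie = CaMovie(residual, movie.frame_interval_ms,
                        movie.pixel_size_um, mask=valid)
    return res_movie, global_trace, spatial_map


@dataclasses.dataclass(frozen=True)
class LCREvent:
    start_frame: int
    end_frame: int
    path_area_px: float           # area of the 2-D footprint over lifetime
    path_area_um2: float
    peak_dff: float
    centroid_xy: tuple            # (x, y), 0-based pixels

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def detect_lcrs(residual: CaMovie, k_mad: float = 3.0, min_area: int = 4,
                min_duration: int = 2, connectivity: int = 26) -> list:
    """Detect local Ca-release events in a residual movie.

    Pixels exceeding ``k_mad`` times their own robust noise scale (MAD
    over time, Gaussian-consistent) are grouped into connected components
    in (t, y, x); components spanning at least ``min_duration`` frames
    with a spatial-projection area of at least ``min_area`` pixels become
    events.  Path area is the area of that 2-D projection.
    """
    data = residual.data
    med = np.median(data, axis=0)
    sigma = 1.4826 * np.median(np.abs(data - med), axis=0)
    sigma = np.maximum(sigma, 1e-12)
    hot = data > med + k_mad * sigma
    if residual.mask is not None:
        hot &= residual.mask
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    labels, n = ndimage.label(hot, structure=structure)
    events: list = []
    if n == 0:
        return events
    px2um2 = residual.pixel_size_um ** 2
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        comp = labels[sl] == lab
        t0, t1 = sl[0].start, sl[0].stop - 1
        if t1 - t0 + 1 < min_duration:
            continue
        footprint = comp.any(axis=0)
        area = int(footprint.sum())
        if area < min_area:
            continue
        peak = float(data[sl][comp].max())
        ys, xs = np.nonzero(footprint)
        cy = float(ys.mean() + sl[1].start)
        cx = float(xs.mean() + sl[2].start)
        events.append(LCREvent(start_frame=int(t0), end_frame=int(t1),
                               path_area_px=float(area),
                               path_area_um2=float(area * px2um2),
                               peak_dff=peak, centroid_xy=(cx, cy)))
    return events


def events_to_frame(events: list):
    import pandas as pd
    return pd.DataFrame([dataclasses.asdict(e) for e in events])


# ---------------------------------------------------------------------------
# Heavy-tail statistics
# ---------------------------------------------------------------------------

def l_moments(sample, n_moments: int = 4) -> np.ndarray:
    """Unbiased sample L-moments lambda_1..lambda_r.

    Computed from the order statistics via the probability-weighted
    moments b_r = n^-1 sum_i C(i-1, r)/C(n-1, r) x_(i).
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < n_moments:
        raise ValueError(f"need at least {n_moments} observations")
    b = np.empty(n_moments)
    i = np.arange(1, n + 1, dtype=float)
    w = np.ones(n)
    b[0] = x.mean()
    for r in range(1, n_moments):
        w *= (i - r) / (n - r)
        b[r] = (w * x).mean()
    lam = np.empty(n_moments)
    lam[0] = b[0]
    if n_moments > 1:
        lam[1] = 2 * b[1] - b[0]
    if n_moments > 2:
        lam[2] = 6 * b[2] - 6 * b[1] + b[0]
    if n_moments > 3:
        lam[3] = 20 * b[3] - 30 * b[2] + 12 * b[1] - b[0]
    return lam


def l_kurtosis(sample) -> float:
    """Fourth L-moment ratio tau_4 = lambda_4 / lambda_2.

    A robust tail-weight statistic: 0 for the uniform distribution, 1/6
    for the exponential, larger for heavier tails; invariant under affine
    rescaling of the sample.
    """
    lam = l_moments(sample, 4)
    if lam[1] == 0:
        raise ValueError("degenerate sample: zero L-scale")
    return float(lam[3] / lam[1])


@dataclasses.dataclass
class LCRStats:
    """Path-area sample with its tail characterization."""

    areas: np.ndarray
    tau4: float
    thresholds: np.ndarray
    mean_excess: np.ndarray      # nan where undefined
    n_exceed: np.ndarray

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"threshold": self.thresholds,
                             "mean_excess": self.mean_excess,
                             "n_exceedances": self.n_exceed})


def mean_excess_curve(sample, thresholds=None, min_exceedances: int = 10,
                      n_thresholds: int = 20) -> LCRStats:
    """Mean-excess function e(u) = mean(x - u | x > u).

    Filters the sample above each threshold u and compares the mean of the
    exceedances with u: e(u) is flat for an exponential tail and grows
    linearly (slope xi/(1-xi)) for a generalized-Pareto tail with shape
    xi > 0.  Thresholds with fewer than ``min_exceedances`` points are
    reported as NaN.
    """
    x = np.asarray(sample, dtype=float)
    if thresholds is None:
        thresholds = np.quantile(x, np.linspace(0.0, 0.95, n_thresholds))
    thresholds = np.asarray(thresholds, dtype=float)
    me = np.full(thresholds.size, np.nan)
    ne = np.zeros(thresholds.size, dtype=int)
    for k, u in enumerate(thresholds):
        exc = x[x > u]
        ne[k] = exc.size
        if exc.size >= min_exceedances:
            me[k] = float((exc - u).mean())
    tau4 = l_kurtosis(x) if x.size >= 4 and np.unique(x).size > 1 else float("nan")
    return LCRStats(areas=x, tau4=tau4, thresholds=thresholds,
                    mean_excess=me, n_exceed=ne)


# ---------------------------------------------------------------------------
# V_m - Ca cross-correlation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class XCorrResult:
    lags_ms: np.ndarray
    values: np.ndarray           # normalized, |values| <= 1
    peak_value: float
    peak_lag_ms: float           # > 0 means Ca lags V_m


def vm_ca_crosscorr(vm, ca, dt_ms: float, window: tuple,
                    max_lag_ms: float = 500.0,
                    subthreshold: bool = True,
                    ap_threshold: float = -20.0) -> XCorrResult:
    """Normalized cross-correlation of co-sampled V_m and Ca traces.

    Both traces are linearly detrended over the window, then correlated at
    lags up to ``max_lag_ms`` with energy normalization (Cauchy-Schwarz
    bounds the values by 1).  With ``subthreshold=True`` the window must
    end before the first threshold crossing of V_m — once APs fire, each
    AP is strictly correlated with its own Ca transient and the
    correlation becomes trivially strong.
    """
    vm = np.asarray(vm, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if vm.shape != ca.shape or vm.ndim != 1:
        raise ValueError("vm and ca must be 1-D arrays of equal length")
    dt = dt_ms * 1e-3
    t0, t1 = window
    i0, i1 = int(round(t0 / dt)), int(round(t1 / dt))
    if not (0 <= i0 < i1 <= vm.size):
        raise ValueError("window outside the sampled range")
    if subthreshold:
        crossings = np.flatnonzero((vm[:-1] < ap_threshold)
                                   & (vm[1:] >= ap_threshold))
        if crossings.size and crossings[0] * dt < t1:
            raise ValueError(
                "subthreshold window overlaps an AP (first crossing at "
                f"{crossings[0] * dt:.3f} s); shorten the window")
    a = signal.detrend(vm[i0:i1])
    b = signal.detrend(ca[i0:i1])
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("degenerate (constant) trace in window")
    full = signal.correlate(b, a, mode="full") / (na * nb)
    lags = signal.correlation_lags(b.size, a.size, mode="full") * dt_ms
    keep = np.abs(lags) <= max_lag_ms
    lags, vals = lags[keep], full[keep]
    k = int(np.argmax(vals))
    return XCorrResult(lags_ms=lags, values=vals,
                       peak_value=float(vals[k]), peak_lag_ms=float(lags[k]))
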