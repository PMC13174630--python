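"""Imaging pipeline: normalization, global-component subtraction, LCR
detection, L-moment tail statistics and V_m-Ca cross-correlation."""

import itertools

import numpy as np
import pytest

from sansr.imaging import (CaMovie, detect_lcrs, l_kurtosis, l_moments,
                           mean_excess_curve, normalize_movie,
                           subtract_global_component, vm_ca_crosscorr)


def rank1_movie(t=120, h=32, w=32, seed=0, baseline=100.0, amp=1.0):
    rng = np.random.default_rng(seed)
    gain = 0.5 + rng.random((h, w))
    trace = 1.0 + amp * np.abs(np.sin(2 * np.pi * 3 * np.arange(t) / t)) ** 4
    return CaMovie(gain[None] * (baseline * trace[:, None, None]))


class TestNormalize:
    def test_constant_movie_normalizes_to_zero(self):
        m = CaMovie(np.full((10, 8, 8), 50.0))
        out = normalize_movie(m)
        assert np.allclose(out.data, 0.0)

    def test_dff_arithmetic(self):
        data = np.full((20, 8, 8), 100.0)
        data[10, 3, 3] = 150.0
        out = normalize_movie(CaMovie(data))
        assert out.data[10, 3, 3] == pytest.approx(0.5)

    def test_all_zero_movie_rejected(self):
        with pytest.raises(ValueError):
            normalize_movie(CaMovie(np.zeros((10, 8, 8))))

    def test_movie_validation(self):
        with pytest.raises(ValueError):
            CaMovie(np.zeros((1, 8, 8)))
        with pytest.raises(ValueError):
            CaMovie(np.full((5, 8, 8), np.nan))


class TestGlobalSubtraction:
    def test_exact_rank1_leaves_no_residual(self):
        norm = normalize_movie(rank1_movie())
        res, trace, smap = subtract_global_component(norm)
        assert np.abs(res.data).max() < 1e-6 * np.abs(norm.data).max()
        assert trace.size == norm.shape[0]

    def test_constant_movie_zero_residual(self):
        norm = normalize_movie(CaMovie(np.full((10, 8, 8), 42.0)))
        # dF/F0 of a constant movie is all-zero -> nothing to decompose
        with pytest.raises(ValueError):
            subtract_global_component(norm)

    def test_local_events_survive_subtraction(self):
        """Rank-1 flashes plus known local blobs: the residual keeps the
        blobs and discards the global transient."""
        base = rank1_movie(t=400, h=32, w=32, seed=1)
        events = np.zeros_like(base.data)
        yy, xx = np.mgrid[0:32, 0:32]
        for (cy, cx, t0) in [(8, 8, 30), (20, 24, 70), (15, 5, 110)]:
            blob = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / 8.0)
            events[t0:t0 + 8] += 60.0 * blob
        noisy = CaMovie(base.data + events)
        norm = normalize_movie(noisy)
        res, _, _ = subtract_global_component(norm)
        norm_events = normalize_movie(base)   # same F0 scale, no events
        inserted = norm.data - norm_events.data
        # energy accounting, restricted to event frames/pixels
        mask = inserted > 0.05
        kept = float(np.sum(res.data[mask] ** 2))
        put_in = float(np.sum(inserted[mask] ** 2))
        assert kept >= 0.8 * put_in
        # global flashes are gone: off-event residual energy is tiny
        off = ~mask
        assert np.sum(res.data[off] ** 2) < 0.1 * np.sum(norm.data[off] ** 2)

    def test_second_extraction_explains_less(self):
        base = rank1_movie(t=150, seed=2)
        events = np.zeros_like(base.data)
        events[40:46, 10:14, 10:14] = 80.0
        events[90:98, 22:25, 5:9] = 60.0
        events[120:124, 4:7, 26:30] = 70.0
        norm = normalize_movie(CaMovie(base.data + events))
        res1, _, _ = subtract_global_component(norm)
        def share(m):
            x = m.data.reshape(m.shape[0], -1)
            s = np.linalg.svd(x, compute_uv=False)
            return s[0] ** 2 / np.sum(s ** 2)
        assert share(res1) < share(norm)


def _noisy_residual(events, shape=(100, 40, 40), sigma=0.02, seed=0):
    rng = np.random.default_rng(seed)
    data = rng.normal(0.0, sigma, shape)
    for (t0, t1, mask, amp) in events:
        data[t0:t1 + 1] += amp * mask
    return CaMovie(data - data.min() + 0.0)


class TestDetectLCRs:
    def test_pure_noise_movie_yields_nothing(self):
        rng = np.random.default_rng(1)
        res = CaMovie(rng.normal(0, 0.01, (80, 24, 24)))
        assert detect_lcrs(res, k_mad=6.0) == []

    def test_single_stationary_event_area(self):
        yy, xx = np.mgrid[0:40, 0:40]
        disk = ((yy - 20) ** 2 + (xx - 20) ** 2 <= 9.5).astype(float)
        area_true = disk.sum()
        res = _noisy_residual([(40, 45, disk, 0.5)])
        events = detect_lcrs(res, k_mad=4.0, min_area=4, min_duration=2)
        assert len(events) == 1
        ev = events[0]
        assert ev.path_area_px == pytest.approx(area_true, rel=0.2)
        assert ev.start_frame == pytest.approx(40, abs=1)
        assert ev.centroid_xy == pytest.approx((20.0, 20.0), abs=1.0)

    def test_propagating_wave_sweeps_larger_path(self):
        yy, xx = np.mgrid[0:40, 0:40]
        disk = ((yy - 20) ** 2 + (xx - 8) ** 2 <= 9.5).astype(float)
        rng = np.random.default_rng(3)
        data = rng.normal(0.0, 0.02, (100, 40, 40))
        data[40:46] += 0.5 * disk          # stationary, ~30 px^2
        for k in range(12):                 # wave sweeping 24 px to the right
            blob = ((yy - 10) ** 2 + (xx - (8 + 2 * k)) ** 2 <= 9.5)
            data[60 + k] += 0.5 * blob
        events = detect_lcrs(CaMovie(data), k_mad=4.0)
        areas = sorted(e.path_area_px for e in events)
        assert len(events) == 2
        assert areas[1] / areas[0] > 5.0

    def test_min_filters(self):
        yy, xx = np.mgrid[0:40, 0:40]
        spot = ((yy - 5) ** 2 + (xx - 5) ** 2 <= 1.1).astype(float)  # 5 px
        res = _noisy_residual([(10, 10, spot, 0.5)])  # single frame
        assert detect_lcrs(res, min_duration=2) == []
        assert detect_lcrs(res, min_duration=1, min_area=9) == []


class TestLMoments:
    def test_uniform_tau4_near_zero(self, rng):
        x = rng.uniform(size=100_000)
        assert abs(l_kurtosis(x)) < 0.01

    def test_exponential_tau4_near_one_sixth(self, rng):
        x = rng.exponential(size=100_000)
        assert l_kurtosis(x) == pytest.approx(1 / 6, abs=0.01)

    def test_affine_invariance(self, rng):
        x = rng.lognormal(size=500)
        assert l_kurtosis(3.7 * x + 11.0) == pytest.approx(l_kurtosis(x),
                                                           abs=1e-12)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            l_kurtosis(np.full(50, 2.5))

    def test_against_subset_enumeration_oracle(self, rng):
        """Unbiased L-moments equal order-statistic averages over all
        subsets of size r (direct combinatorial definition)."""
        x = np.sort(rng.normal(size=12))
        lam = l_moments(x, 4)
        n = x.size
        # lambda_r = (1/r) * E[ sum_k (-1)^k C(r-1,k) X_{r-k:r} ]
        from math import comb
        for r, lr in [(1, lam[0]), (2, lam[1]), (3, lam[2]), (4, lam[3])]:
            acc = 0.0
            for subset in itertools.combinations(range(n), r):
                xs = x[list(subset)]
                acc += sum((-1) ** k * comb(r - 1, k) * xs[r - 1 - k]
                           for k in range(r))
            est = acc / comb(n, r) / r
            assert lr == pytest.approx(est, abs=1e-10)


class TestMeanExcess:
    def test_exponential_is_flat(self, rng):
        x = rng.exponential(1.0, size=50_000)
        st = mean_excess_curve(x, thresholds=np.linspace(0.0, 3.0, 10))
        good = ~np.isnan(st.mean_excess)
        assert np.all(np.abs(st.mean_excess[good] - 1.0) < 0.1)

    def test_threshold_above_maximum_is_undefined(self, rng):
        x = rng.exponential(size=1000)
        st = mean_excess_curve(x, thresholds=[x.max() + 1.0])
        assert np.isnan(st.mean_excess[0])
        assert st.n_exceed[0] == 0

    def test_heavy_tail_increases(self, rng):
        xi = 0.4   # generalized Pareto shape; slope xi/(1-xi) = 2/3
        u = rng.uniform(size=80_000)
        x = ((1 - u) ** -xi - 1) / xi
        th = np.quantile(x, np.linspace(0.1, 0.9, 9))
        st = mean_excess_curve(x, thresholds=th)
        slope = np.polyfit(st.thresholds, st.mean_excess, 1)[0]
        assert slope == pytest.approx(xi / (1 - xi), rel=0.2)
        assert np.all(np.diff(st.mean_excess) > -0.05)


class TestCrossCorrelation:
    def test_identical_traces_peak_one_at_zero(self, rng):
        x = -50 + rng.normal(size=2000).cumsum() * 0.01
        out = vm_ca_crosscorr(x, x, dt_ms=1.0, window=(0.0, 2.0),
                              subthreshold=False)
        assert out.peak_value == pytest.approx(1.0, abs=1e-9)
        assert out.peak_lag_ms == 0.0
        assert np.all(np.abs(out.values) <= 1.0 + 1e-9)

    def test_independent_noise_uncorrelated(self, rng):
        a = rng.normal(size=10_000)
        b = rng.normal(size=10_000)
        out = vm_ca_crosscorr(a, b, dt_ms=1.0, window=(0.0, 10.0),
                              max_lag_ms=100.0, subthreshold=False)
        assert abs(out.peak_value) < 0.1

    def test_delay_recovered(self, rng):
        latent = np.convolve(rng.normal(size=4050),
                             np.ones(30) / 30, mode="same")
        vm = latent[50:] + 0.02 * rng.normal(size=4000)
        ca = latent[:4000] + 0.02 * rng.normal(size=4000)   # 50 ms later
        out = vm_ca_crosscorr(vm, ca, dt_ms=1.0, window=(0.0, 4.0),
                              max_lag_ms=200.0, subthreshold=False)
        assert out.peak_value > 0.9
        assert out.peak_lag_ms == pytest.approx(50.0, abs=5.0)

    def test_subthreshold_guard_rejects_ap_window(self):
        vm = np.full(3000, -50.0)
        vm[1500:1560] = 10.0    # an AP at 1.5 s
        ca = np.zeros(3000)
        with pytest.raises(ValueError, match="AP"):
            vm_ca_crosscorr(vm, ca + np.sin(np.arange(3000) / 50), dt_ms=1.0,
                            window=(0.5, 2.5), subthreshold=True)
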