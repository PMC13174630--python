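"""Synthetic-data generators: determinism, structure and calibration."""

import numpy as np
import pytest
from scipy import stats

from sansr.ap_metrics import firing_metrics
from sansr.imaging import (detect_lcrs, normalize_movie,
                           subtract_global_component, vm_ca_crosscorr)
from sansr.synth import (MovieSpec, draw_lcr_areas, synth_ap_train,
                         synth_movie, synth_vm_ca)


class TestMovieGenerator:
    def test_pure_function_of_seed(self):
        spec = MovieSpec(shape=(60, 32, 32), n_lcrs=5, noise_sd=0.02, seed=9)
        m1, t1 = synth_movie(spec)
        m2, t2 = synth_movie(spec)
        assert np.array_equal(m1.data, m2.data)
        assert len(t1.events) == len(t2.events)
        m3, _ = synth_movie(MovieSpec(shape=(60, 32, 32), n_lcrs=5,
                                      noise_sd=0.02, seed=10))
        assert not np.array_equal(m1.data, m3.data)

    def test_event_free_noiseless_movie_is_rank_one(self):
        spec = MovieSpec(shape=(100, 32, 32), noise_sd=0.0, seed=1)
        movie, truth = synth_movie(spec)
        assert len(truth.events) == 0
        res, _, _ = subtract_global_component(normalize_movie(movie))
        assert np.abs(res.data).max() < 1e-6

    def test_event_amplitude_matches_global_transients(self):
        # background signals sized like the AP-induced transients
        spec = MovieSpec(shape=(120, 32, 32), apct_rate_hz=0.0, n_lcrs=1,
                         lcr_area_params=(3.4, 0.01), noise_sd=0.0, seed=4)
        movie, truth = synth_movie(spec)
        norm = normalize_movie(movie)
        peak = norm.data.max()
        assert peak == pytest.approx(spec.apct_amplitude, rel=0.05)

    def test_truth_records_all_patterns(self):
        spec = MovieSpec(shape=(200, 48, 48), n_waves=2, n_lcrs=6,
                         n_flashes=2, noise_sd=0.01, seed=3)
        _, truth = synth_movie(spec)
        kinds = {e.pattern for e in truth.events}
        assert kinds == {"wave", "lcr", "flash"}
        df = truth.to_frame()
        assert (df["path_area_px"] > 0).all()

    def test_detector_recovers_seeded_lcrs(self):
        """End-to-end: >= 90% of inserted events recovered with <20% area
        error at high SNR."""
        spec = MovieSpec(shape=(240, 64, 64), n_lcrs=20, noise_sd=0.1,
                         lcr_area_params=(3.3, 0.4), seed=12)
        movie, truth = synth_movie(spec)
        res, _, _ = subtract_global_component(normalize_movie(movie))
        found = detect_lcrs(res, k_mad=3.0)
        hits = 0
        errs = []
        for ev in truth.events:
            match = [f for f in found
                     if abs(f.centroid_xy[0] - ev.centroid_xy[0]) < 4
                     and abs(f.centroid_xy[1] - ev.centroid_xy[1]) < 4
                     and not (f.end_frame < ev.start_frame
                              or f.start_frame > ev.end_frame)]
            if match:
                hits += 1
                best = match[0]
                errs.append(abs(best.path_area_px - ev.path_area_px)
                            / ev.path_area_px)
        assert hits >= 0.9 * len(truth.events)
        assert np.median(errs) < 0.2

    def test_area_distribution_goodness(self):
        rng = np.random.default_rng(5)
        x = draw_lcr_areas("lognormal", (3.0, 0.6), 10_000, rng)
        ks = stats.kstest(np.log(x), "norm", args=(3.0, 0.6))
        assert ks.pvalue > 0.01
        y = draw_lcr_areas("gpd", (10.0, 0.3), 10_000, rng)
        ks2 = stats.kstest(y - 4.0, "genpareto", args=(0.3, 0.0, 10.0))
        assert ks2.pvalue > 0.01

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            MovieSpec(shape=(1, 32, 32))
        with pytest.raises(ValueError):
            MovieSpec(noise_sd=-1.0)


class TestVmCaGenerator:
    def test_zero_coupling_uncorrelated(self):
        t, vm, ca, _ = synth_vm_ca(duration=20.0, coupling=0.0, seed=2)
        out = vm_ca_crosscorr(vm, ca, dt_ms=1.0, window=(0.0, 20.0),
                              subthreshold=False)
        assert abs(out.peak_value) < 0.15

    def test_full_coupling_with_lag(self):
        t, vm, ca, _ = synth_vm_ca(duration=20.0, coupling=1.0, lag_ms=50.0,
                                   noise_sd=0.02, seed=2)
        out = vm_ca_crosscorr(vm, ca, dt_ms=1.0, window=(0.0, 20.0),
                              max_lag_ms=200.0, subthreshold=False)
        assert out.peak_value > 0.9
        assert out.peak_lag_ms == pytest.approx(50.0, abs=10.0)

    def test_coupling_monotone_in_peak(self):
        peaks = []
        for c in (0.0, 0.4, 0.8):
            _, vm, ca, _ = synth_vm_ca(duration=30.0, coupling=c,
                                       noise_sd=0.5, seed=7)
            out = vm_ca_crosscorr(vm, ca, dt_ms=1.0, window=(0.0, 30.0),
                                  subthreshold=False)
            peaks.append(out.peak_value)
        assert peaks[0] < peaks[1] < peaks[2]

    def test_inserted_aps_dominate_correlation(self):
        # firing windows correlate strongly regardless of coupling: the
        # reason the analysis restricts itself to pre-AP windows
        _, vm, ca, _ = synth_vm_ca(duration=20.0, coupling=0.0, seed=3,
                                   ap_times=np.arange(1.0, 19.0, 0.5))
        out = vm_ca_crosscorr(vm, ca, dt_ms=1.0, window=(0.0, 20.0),
                              subthreshold=False)
        assert out.peak_value > 0.6


class TestAPTrainGenerator:
    def test_zero_cv_is_periodic(self):
        train = synth_ap_train(2.0, 0.0, 10.0, seed=1)
        ivis = np.diff(train.times)
        assert np.allclose(ivis, 0.5, atol=1e-12)

    def test_gamma_moments(self):
        train = synth_ap_train(2.0, 0.3, 500.0, seed=8)
        m = firing_metrics(train, (0.0, 500.0))
        ivis = np.diff(train.times)
        n = ivis.size
        # interval mean and CV within 3 SE of targets
        se_mean = 0.3 * 0.5 / np.sqrt(n)
        assert ivis.mean() == pytest.approx(0.5, abs=3 * se_mean)
        cv = ivis.std(ddof=1) / ivis.mean()
        assert cv == pytest.approx(0.3, abs=0.03)
        assert m.n_aps == n + 1

    def test_short_duration_gives_few_events(self):
        train = synth_ap_train(2.0, 0.0, 0.4, seed=1)
        assert len(train) == 0

    def test_validation(self):
        with pytest.raises(ValueError):
            synth_ap_train(0.0, 0.1, 10.0)
        with pytest.raises(ValueError):
            synth_ap_train(1.0, -0.1, 10.0)
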