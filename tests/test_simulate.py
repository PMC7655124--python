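import dataclasses

import numpy as np
import pytest
from scipy import signal as sps

from hippofeat.filtering import ParameterError, bandpass
from hippofeat.hfo import HfoDetector
from hippofeat.simulate import (
    GroupParams,
    generate_background,
    generate_cohort,
    hfo_template,
    ied_template,
    inject_hfo,
    inject_ied,
    visible_fraction,
)

FS = 2000.0


def _loglog_slope(x, fs):
    f, p = sps.welch(x, fs=fs, nperseg=4096)
    sel = (f > 2) & (f < fs / 2 * 0.8)
    return np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]


class TestBackground:
    def test_white_noise_slope(self):
        x = generate_background(30, FS, spectral_exponent=0.0, seed=1)
        assert abs(_loglog_slope(x, FS)) < 0.1

    def test_pink_noise_slope(self):
        x = generate_background(30, FS, spectral_exponent=1.0, seed=2)
        assert abs(_loglog_slope(x, FS) + 1.0) < 0.2

    def test_amplitude_scale_sets_sd(self):
        x = generate_background(30, FS, amplitude_scale=42.0, seed=3)
        assert abs(x.std() - 42.0) < 1e-9

    def test_deterministic_given_seed(self):
        a = generate_background(5, FS, seed=9)
        b = generate_background(5, FS, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ParameterError):
            generate_background(0, FS)


class TestInjectHfo:
    def test_truth_duration(self):
        x = np.zeros(int(2 * FS))
        _, rec = inject_hfo(x, FS, 0.5, 150.0, 6, 10.0)
        assert rec["duration_s"] == pytest.approx(6 / 150)

    def test_zero_amplitude_is_identity(self, rng):
        x = rng.standard_normal(int(FS))
        out, _ = inject_hfo(x, FS, 0.2, 150.0, 6, 0.0)
        np.testing.assert_array_equal(out, x)

    def test_burst_periodogram_peak(self):
        x = np.zeros(int(4 * FS))
        out, _ = inject_hfo(x, FS, 1.0, 150.0, 12, 10.0)
        spec = np.abs(np.fft.rfft(out)) ** 2
        f = np.fft.rfftfreq(len(out), 1 / FS)
        assert abs(f[np.argmax(spec)] - 150.0) <= f[1] * 2

    def test_out_of_range_placement_rejected(self):
        with pytest.raises(ParameterError):
            inject_hfo(np.zeros(100), FS, 5.0, 150.0, 6, 1.0)
        with pytest.raises(ParameterError):
            inject_hfo(np.zeros(int(FS)), FS, 0.1, 30.0, 6, 1.0)


class TestInjectIed:
    def test_zero_amplitude_is_identity(self, rng):
        x = rng.standard_normal(int(FS))
        out, _ = inject_ied(x, FS, 0.2, 0.0)
        np.testing.assert_array_equal(out, x)

    def test_peak_matches_requested_amplitude(self):
        bg = np.zeros(int(2 * FS))
        out, rec = inject_ied(bg, FS, 0.5, 300.0)
        assert abs(np.max(np.abs(out)) - 300.0) / 300.0 < 0.05

    def test_spike_energy_concentrated_low(self):
        # the sharp transient lives in the 20-50 Hz detection band, not in
        # the ripple band
        tpl = ied_template(FS, 40.0)
        buf = np.zeros(int(2 * FS))
        buf[1000:1000 + len(tpl)] = tpl
        low = np.sum(bandpass(buf, FS, 20, 50) ** 2)
        high = np.sum(bandpass(buf, FS, 80, 250) ** 2)
        assert low > 5 * high


class TestVisibleFraction:
    def test_zero_at_or_below_threshold(self):
        assert visible_fraction(2.9) == 0.0
        assert visible_fraction(3.0) == 0.0

    def test_monotone_in_amplitude(self):
        zs = np.linspace(3.5, 12, 10)
        fr = [visible_fraction(z) for z in zs]
        assert all(b >= a for a, b in zip(fr, fr[1:]))
        assert 0.4 < fr[0] < fr[-1] < 1.0


class TestCohort:
    def test_zero_rates_zero_coupling_no_events(self, calibrator):
        params = GroupParams.table_defaults()
        quiet = dataclasses.replace(
            params.eh_rest, r_rate=0, fr_rate=0, ied_rate=0,
            r_coupling=0, fr_coupling=0,
        )
        p = dataclasses.replace(params, eh_rest=quiet, neh_rest=quiet)
        segs, truth = generate_cohort((1, 1), 2, ("rest",), p, 20.0, FS,
                                      seed=5, calibrator=calibrator)
        assert len(truth.hfo_events) == 0
        assert len(truth.ied_events) == 0

    def test_deterministic_given_seed(self, calibrator):
        a, ta = generate_cohort((1, 1), 2, ("rest",), None, 20.0, FS,
                                seed=42, calibrator=calibrator)
        b, tb = generate_cohort((1, 1), 2, ("rest",), None, 20.0, FS,
                                seed=42, calibrator=calibrator)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.signals, sb.signals)
        assert ta.hfo_events.equals(tb.hfo_events)

    def test_events_lie_within_segment(self, small_cohort):
        _, truth = small_cohort
        ev = truth.hfo_events
        assert (ev.onset_s >= 0).all()
        assert (ev.onset_s + ev.injected_duration_s <= 40.0).all()
        assert (truth.ied_events.t_peak <= 40.0).all()

    def test_poisson_rate_calibration(self, calibrator):
        # rate 120/10 min in 10-min segments: mean count over seeds within
        # 3 standard errors of 120
        params = GroupParams.table_defaults()
        cell = dataclasses.replace(
            params.eh_rest, r_rate=120.0, fr_rate=0, ied_rate=0,
        )
        p = dataclasses.replace(params, eh_rest=cell, hippocampus_effect_sd=0.0)
        n_seeds = 50
        counts = []
        for seed in range(n_seeds):
            _, truth = generate_cohort((1, 0), 1, ("rest",), p, 600.0, FS,
                                       seed=seed, calibrator=calibrator)
            counts.append(len(truth.hfo_events))
        assert abs(np.mean(counts) - 120.0) < 3 * np.sqrt(120.0 / n_seeds)

    def test_coupling_yields_target_band_correlation(self, calibrator):
        params = GroupParams.table_defaults()
        cell = dataclasses.replace(
            params.eh_rest, r_rate=0, fr_rate=0, ied_rate=0,
            r_coupling=0.8, fr_coupling=0.8, r_ren=0.0, fr_ren=0.0,
        )
        p = dataclasses.replace(params, eh_rest=cell)
        segs, _ = generate_cohort((1, 0), 2, ("rest",), p, 30.0, FS,
                                  seed=3, calibrator=calibrator)
        # steep filter: excludes skirt leakage of the strong sub-80 Hz
        # private background from the band-limited coupling measurement
        a = bandpass(segs[0].signals[0], FS, 80, 250, order=8)
        b = bandpass(segs[0].signals[1], FS, 80, 250, order=8)
        r = np.corrcoef(a, b)[0, 1]
        assert 0.7 < r < 0.9

    def test_rate_monotonicity_through_detector(self, calibrator):
        # doubling the injected ripple rate raises the detected R rate
        params = GroupParams.table_defaults()
        det = HfoDetector()
        means = []
        for rate in (40.0, 160.0):
            cell = dataclasses.replace(
                params.eh_rest, r_rate=rate, fr_rate=0, ied_rate=0,
            )
            p = dataclasses.replace(params, eh_rest=cell, hippocampus_effect_sd=0.0)
            counts = []
            for seed in range(3):
                segs, _ = generate_cohort((1, 0), 1, ("rest",), p, 60.0, FS,
                                          seed=seed, calibrator=calibrator)
                ev = det.detect_segment(segs[0])
                counts.append((ev.band_label == "R").sum())
            means.append(np.mean(counts))
        assert means[1] > means[0]

    def test_zero_channels_rejected(self):
        with pytest.raises(ParameterError):
            generate_cohort((1, 1), 0, ("rest",), None, 20.0, FS, seed=1)


class TestTemplates:
    def test_tukey_template_has_flat_core(self):
        tpl = hfo_template(FS, 200.0, 10, taper="tukey")
        env = np.abs(sps.hilbert(tpl))
        mid = env[len(env) // 4: -len(env) // 4]
        assert mid.min() > 0.9

    def test_unknown_taper_rejected(self):
        with pytest.raises(ParameterError):
            hfo_template(FS, 200.0, 6, taper="boxcar")
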