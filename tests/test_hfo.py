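import networkx as nx
import numpy as np
import pytest

from hippofeat.hfo import (
    BandEnvelopeStack,
    HfoDetector,
    band_centers,
    band_edges,
    characterize_and_filter,
    compute_band_envelopes,
    join_detections,
    label_band,
    threshold_bands,
    zscore_stat_windows,
    LengthError,
)
from hippofeat.simulate import generate_background, inject_hfo

FS = 2000.0


class TestBandGeometry:
    def test_geometric_spacing(self):
        c = band_centers(300, 60, 800)
        assert c[0] == pytest.approx(60.0)
        assert c[-1] == pytest.approx(800.0)
        ratios = c[1:] / c[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_constant_relative_width(self):
        c = band_centers(10, 60, 800)
        lo, hi = band_edges(c, 0.35)
        np.testing.assert_allclose((hi - lo) / c, 0.7, rtol=1e-12)


class TestEnvelopes:
    def test_white_noise_z_is_standardized(self, rng):
        x = rng.standard_normal(int(20 * FS))
        stack = compute_band_envelopes(x, FS, n_bands=20, stat_window_s=10)
        w = int(10 * FS)
        for b in (0, 10, 19):
            for k in (0, 1):
                win = stack.z[b, k * w:(k + 1) * w]
                assert abs(win.mean()) < 1e-4
                assert abs(win.std() - 1.0) < 1e-3

    def test_pure_tone_peaks_in_matching_band(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 200.0 * t)
        stack = compute_band_envelopes(x, FS, n_bands=50, stat_window_s=10)
        best = int(np.argmax(stack.z.mean(axis=1)))
        in_band = (stack.band_lo <= 200.0) & (stack.band_hi >= 200.0)
        assert in_band[best]

    def test_short_signal_rejected(self):
        with pytest.raises(LengthError):
            zscore_stat_windows(np.zeros(100), FS, 10.0)

    def test_zero_signal_gives_zero_z(self):
        z = zscore_stat_windows(np.zeros(int(10 * FS)), FS, 10.0)
        assert np.all(z == 0)


def _stack_from_z(z):
    n_bands = z.shape[0]
    c = band_centers(n_bands, 60, 800)
    lo, hi = band_edges(c)
    return BandEnvelopeStack(z.astype(np.float32), c, lo, hi, FS, 10.0)


class TestThreshold:
    def test_no_intervals_on_zero(self):
        stack = _stack_from_z(np.zeros((5, 100)))
        assert all(len(iv) == 0 for iv in threshold_bands(stack))

    def test_single_constructed_interval(self):
        z = np.zeros((3, 400))
        z[1, 100:150] = 5.0
        ivs = threshold_bands(_stack_from_z(z))
        assert len(ivs[1]) == 1
        assert tuple(ivs[1][0]) == (100, 150)
        assert len(ivs[0]) == 0

    def test_gaussian_tail_fraction(self, rng):
        z = rng.standard_normal((1, 400_000))
        ivs = threshold_bands(_stack_from_z(z), z_threshold=3.0)
        frac = sum(e - s for s, e in ivs[0]) / z.shape[1]
        expect = 0.00135
        assert 0.5 * expect < frac < 1.5 * expect


class TestJoin:
    def test_adjacent_overlap_joins(self):
        per_band = [np.empty((0, 2), int)] * 15
        per_band[10] = np.array([[100, 200]])
        per_band[11] = np.array([[150, 250]])
        assert len(join_detections(per_band)) == 1

    def test_band_gap_does_not_join(self):
        per_band = [np.empty((0, 2), int)] * 15
        per_band[10] = np.array([[100, 200]])
        per_band[12] = np.array([[100, 200]])
        assert len(join_detections(per_band)) == 2

    def test_shared_boundary_sample_does_not_join(self):
        per_band = [np.empty((0, 2), int)] * 3
        per_band[0] = np.array([[100, 200]])
        per_band[1] = np.array([[200, 300]])  # half-open: no intersection
        assert len(join_detections(per_band)) == 2

    def test_matches_graph_component_oracle(self, rng):
        # random interval sets: blob count equals the connected-component
        # count of the explicit overlap graph
        for trial in range(10):
            per_band = []
            for b in range(8):
                starts = np.sort(rng.choice(200, size=rng.integers(0, 6), replace=False))
                ivs = []
                pos = 0
                for s in starts:
                    s = max(s, pos)
                    e = s + int(rng.integers(1, 30))
                    if e <= 200:
                        ivs.append((s, e))
                        pos = e + 1
                per_band.append(np.array(ivs, dtype=int).reshape(-1, 2))
            blobs = join_detections(per_band)
            g = nx.Graph()
            nodes = [(b, k) for b in range(8) for k in range(len(per_band[b]))]
            g.add_nodes_from(nodes)
            for b in range(7):
                for i, (s1, e1) in enumerate(per_band[b]):
                    for j, (s2, e2) in enumerate(per_band[b + 1]):
                        if s1 < e2 and s2 < e1:
                            g.add_edge((b, i), (b + 1, j))
            assert len(blobs) == nx.number_connected_components(g)
            got = {frozenset(blob) for blob in blobs}
            expect = {frozenset(c) for c in nx.connected_components(g)}
            assert got == expect


class TestCharacterize:
    def _fixture(self, duration_ms):
        """One blob at ~150 Hz lasting duration_ms, away from the floor band."""
        n_bands, n = 300, int(10 * FS)
        z = np.zeros((n_bands, n))
        c = band_centers(n_bands, 60, 800)
        b150 = int(np.argmin(np.abs(c - 150.0)))
        s, e = 1000, 1000 + int(duration_ms / 1e3 * FS)
        for b in (b150 - 1, b150, b150 + 1):
            z[b, s:e] = 4.0
        z[b150, (s + e) // 2] = 6.0
        stack = _stack_from_z(z)
        ivs = threshold_bands(stack)
        return characterize_and_filter(join_detections(ivs), stack, ivs)

    def test_three_cycles_rejected(self):
        assert self._fixture(20.0) == []

    def test_six_cycles_accepted(self):
        events = self._fixture(40.0)
        assert len(events) == 1
        ev = events[0]
        assert ev.band_label == "R"
        assert ev.duration_ms == pytest.approx(40.0)
        assert ev.relative_amplitude == pytest.approx(6.0)
        assert 130 < ev.peak_frequency < 170

    def test_floor_band_blob_rejected(self):
        n_bands, n = 20, int(10 * FS)
        z = np.zeros((n_bands, n))
        z[0, 1000:3000] = 8.0  # long and strong, but touches the floor band
        stack = _stack_from_z(z)
        ivs = threshold_bands(stack)
        assert characterize_and_filter(join_detections(ivs), stack, ivs) == []


class TestLabel:
    @pytest.mark.parametrize(
        "freq,expected",
        [(176.75, "R"), (399.6, "FR"), (700.0, "none"), (80.0, "R"),
         (250.0, "FR"), (70.0, "none")],
    )
    def test_band_label(self, freq, expected):
        assert label_band(freq) == expected


class TestDetector:
    def test_threshold_monotonicity(self, calibrator):
        x = generate_background(30, FS, seed=4)
        for onset in np.arange(2, 28, 2.0):
            a = calibrator.amplitude_for_z(180.0, 8, 6.0)
            x, _ = inject_hfo(x, FS, onset, 180.0, 8, a)
        counts = [
            len(HfoDetector(z_threshold=thr).detect(x, FS))
            for thr in (2.5, 3.0, 4.0, 6.0)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_emitted_events_respect_rules(self, small_cohort):
        seg = small_cohort[0][0]
        det = HfoDetector()
        ev = det.detect(seg.signals[0], FS)
        assert ((ev.t_end - ev.t_start) * ev.peak_frequency > det.min_cycles).all()
        assert (ev.f_min > 60.0).all()

    def test_detects_injected_burst(self, calibrator):
        x = generate_background(30, FS, seed=6)
        a = calibrator.amplitude_for_z(150.0, 9, 8.0)
        x, rec = inject_hfo(x, FS, 15.0, 150.0, 9, a)
        ev = HfoDetector().detect(x, FS)
        hit = ev[(ev.t_start < 15.0 + rec["duration_s"]) & (ev.t_end > 15.0)]
        assert len(hit) >= 1
        assert hit.relative_amplitude.max() > 3.0


def test_noise_false_positive_bound():
    """On pure colored noise the detector emits well under 10 R+FR events
    per 10 minutes at default settings."""
    from hippofeat.validation import noise_false_positive_rate

    assert noise_false_positive_rate(seed=11, n_channels=2, duration_s=300.0) < 10.0
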