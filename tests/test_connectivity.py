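import numpy as np
import pytest

from hippofeat.connectivity import (
    PairConnectivitySeries,
    UndefinedMetricError,
    channel_connectivity_summary,
    linear_correlation,
    relative_entropy,
    windowed_connectivity,
)
from hippofeat.filtering import bandpass
from hippofeat.io import ChannelInfo, RecordingSegment

FS = 2000.0


def _segment(signals, contacts=None):
    n = signals.shape[0]
    channels = [
        ChannelInfo(f"c{i}", "s", "el", (contacts or range(1, n + 1))[i], "hip", "EH")
        for i in range(n)
    ]
    return RecordingSegment(signals, FS, channels)


class TestLinearCorrelation:
    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(500)
        assert linear_correlation(x, x) == 1.0

    def test_antisymmetry(self, rng):
        x = rng.standard_normal(500)
        assert linear_correlation(x, -x) == -1.0

    def test_hand_computed_fixture(self):
        # cov/sd formula on x=[1,2,3,4], y=[2,1,4,3] gives 0.6
        assert linear_correlation([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(500)
        y = rng.standard_normal(500)
        r = linear_correlation(x, y)
        assert linear_correlation(3.0 * x + 7.0, 0.5 * y - 2.0) == pytest.approx(r)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedMetricError):
            linear_correlation(np.ones(10), np.arange(10.0))


def _ren_direct(x, y, n_bins):
    """Independent direct-summation oracle with the documented smoothing."""
    lo, hi = min(np.min(x), np.min(y)), max(np.max(x), np.max(y))
    edges = np.linspace(lo, hi, n_bins + 1)
    px = np.histogram(x, bins=edges)[0] / len(x)
    py = np.histogram(y, bins=edges)[0] / len(y)
    eps = 1.0 / (len(x) * n_bins)
    px = (px + eps) / (1 + eps * n_bins)
    py = (py + eps) / (1 + eps * n_bins)
    total = 0.0
    for a, b in zip(px, py):
        total += a * np.log(a / b)
    return total


class TestRelativeEntropy:
    def test_identical_windows_zero(self, rng):
        x = rng.standard_normal(1000)
        assert relative_entropy(x, x.copy()) == 0.0

    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(5):
            x = rng.standard_normal(400)
            y = rng.standard_normal(400) * rng.uniform(0.5, 2.0)
            got = relative_entropy(x, y, n_bins=10)
            assert got == pytest.approx(_ren_direct(x, y, 10), abs=1e-12)

    def test_two_bin_closed_form(self):
        # histograms [0.5, 0.5] vs [0.25, 0.75]: with vanishing smoothing the
        # divergence approaches 0.5 ln2 + 0.5 ln(2/3)
        x = np.tile([0.25, 0.75], 2000)
        y = np.tile([0.25, 0.75, 0.75, 0.75], 1000)
        expect = 0.5 * np.log(2) + 0.5 * np.log(2 / 3)
        assert relative_entropy(x, y, n_bins=2) == pytest.approx(expect, abs=1e-3)

    def test_directed_asymmetry(self, rng):
        x = rng.standard_normal(500)
        y = 2.0 * rng.standard_normal(500)
        assert relative_entropy(x, y) != relative_entropy(y, x)

    def test_nonnegative(self, rng):
        for _ in range(10):
            x = rng.standard_normal(200)
            y = rng.standard_normal(200)
            assert relative_entropy(x, y) >= 0.0

    def test_degenerate_range_rejected(self):
        with pytest.raises(UndefinedMetricError):
            relative_entropy(np.ones(10), np.ones(10))


class TestWindowed:
    def test_window_tiling(self, rng):
        seg = _segment(rng.standard_normal((2, int(10 * FS))))
        series = windowed_connectivity(seg)
        assert len(series) == 2  # R and FR for the single adjacent pair
        assert all(len(s.corr) == 10 for s in series)

    def test_single_contact_yields_empty(self, rng):
        seg = _segment(rng.standard_normal((1, int(5 * FS))))
        assert windowed_connectivity(seg) == []

    def test_nonconsecutive_contacts_not_paired(self, rng):
        seg = _segment(rng.standard_normal((2, int(5 * FS))), contacts=[1, 3])
        assert windowed_connectivity(seg) == []

    def test_shared_component_correlation(self, rng):
        # 80% shared band-limited signal: window correlations near 0.8
        n = int(10 * FS)
        s = rng.standard_normal(n)
        x = np.sqrt(0.8) * s + np.sqrt(0.2) * rng.standard_normal(n)
        y = np.sqrt(0.8) * s + np.sqrt(0.2) * rng.standard_normal(n)
        seg = _segment(np.vstack([x, y]))
        series = windowed_connectivity(seg)
        r = np.nanmean(series[0].corr)
        assert 0.75 < r < 0.85

    def test_independent_channels_near_zero(self, rng):
        seg = _segment(rng.standard_normal((2, int(10 * FS))))
        series = windowed_connectivity(seg)
        bound = 3.0 / np.sqrt(FS * 1.0)
        assert abs(np.nanmean(series[0].corr)) < bound

    def test_matches_brute_force_loop(self, rng):
        seg = _segment(rng.standard_normal((2, int(3 * FS))))
        series = windowed_connectivity(seg, n_bins=8)
        for s in series:
            band = {"R": (80.0, 250.0), "FR": (250.0, 600.0)}[s.band]
            xa = bandpass(seg.signals[0], FS, *band)
            xb = bandpass(seg.signals[1], FS, *band)
            w = int(FS)
            for k in range(3):
                sl = slice(k * w, (k + 1) * w)
                assert s.corr[k] == pytest.approx(
                    np.corrcoef(xa[sl], xb[sl])[0, 1], abs=1e-9
                )
                assert s.ren_xy[k] == pytest.approx(_ren_direct(xa[sl], xb[sl], 8), abs=1e-12)


class TestSummary:
    def _series(self, pair, band, corr, ren):
        corr = np.asarray(corr, float)
        ren = np.asarray(ren, float)
        return PairConnectivitySeries(pair, band, 1.0, corr, ren, ren)

    def test_single_pair_channel_mean_is_pair_mean(self):
        s = self._series(("a", "b"), "R", [0.2, 0.4], [0.1, 0.3])
        df = channel_connectivity_summary([s])
        row = df[(df.channel_id == "a") & (df.band == "R")].iloc[0]
        assert row["corr"] == pytest.approx(0.3)
        assert row["ren"] == pytest.approx(0.2)

    def test_middle_contact_averages_both_pairs(self):
        s1 = self._series(("a", "b"), "R", [0.4, 0.4], [0.0, 0.0])
        s2 = self._series(("b", "c"), "R", [0.6, 0.6], [0.0, 0.0])
        df = channel_connectivity_summary([s1, s2])
        mid = df[(df.channel_id == "b") & (df.band == "R")].iloc[0]
        assert mid["corr"] == pytest.approx(0.5)

    def test_constant_windows_pass_through(self):
        s = self._series(("a", "b"), "FR", [0.7] * 5, [0.2] * 5)
        df = channel_connectivity_summary([s])
        assert (df["corr"] == pytest.approx(0.7)) is not False
        assert df.loc[df.channel_id == "a", "ren"].iloc[0] == pytest.approx(0.2)

    def test_ren_group_contrast_on_cohort(self, cohort_features):
        eh = cohort_features[cohort_features.label == "EH"]
        neh = cohort_features[cohort_features.label == "NEH"]
        assert eh.r_ren.mean() > neh.r_ren.mean()
        assert eh.fr_ren.mean() > neh.fr_ren.mean()
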