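"""Normalization, background subtraction, FFT spectra, peak picking."""

import numpy as np
import pytest

from echomod import (
    PulseTiming3p,
    TimeTrace1D,
    TimeTrace2D,
    eseem_powder,
    line_prominence,
    normalize_trace,
    peak_height_ratio,
    pick_peaks,
    process_trace,
    region_centroid,
    subtract_background,
    to_spectrum,
)
from echomod.processing import DegenerateTraceError, Peak, PeakList


def make_trace(values, dt=16.0, t0=12.0):
    values = np.asarray(values, dtype=float)
    return TimeTrace1D(t0 + dt * np.arange(len(values)), values)


class TestNormalize:
    def test_constant_trace(self):
        tr = normalize_trace(make_trace(np.full(32, 5.0)))
        assert np.allclose(tr.values, 1.0)
        assert tr.metadata["normalized_first_point"] is True

    def test_idempotent(self):
        tr = make_trace(np.linspace(2.0, 1.0, 32))
        once = normalize_trace(tr)
        twice = normalize_trace(once)
        assert np.array_equal(once.values, twice.values)

    def test_zero_first_point_rejected(self):
        with pytest.raises(DegenerateTraceError):
            normalize_trace(make_trace([0.0, 1.0, 2.0]))

    def test_2d_first_element(self):
        vals = np.outer(np.linspace(2, 1, 8), np.linspace(1, 0.5, 8))
        tr = TimeTrace2D(np.arange(8.0), np.arange(8.0), vals)
        out = normalize_trace(tr)
        assert out.values[0, 0] == pytest.approx(1.0)


class TestBackground:
    def test_pure_exponential_leaves_zero_residual(self):
        t = 12 + 16 * np.arange(200)
        tr = make_trace(2.0 * np.exp(-t / 3000.0) + 0.1)
        out = subtract_background(tr, "exponential")
        assert np.abs(out.values).max() < 1e-8

    def test_modulated_decay_residual_is_oscillation(self):
        t = 12 + 16 * np.arange(400)
        f = 1.0  # MHz
        decay = np.exp(-t / 4000.0)
        tr = make_trace(decay * (1 + 0.2 * np.cos(2e-3 * np.pi * f * t)))
        out = subtract_background(tr, "exponential")
        # zero-mean oscillation whose spectrum peaks at the input frequency
        assert abs(out.values.mean()) < 0.01 * np.ptp(tr.values)
        spec = to_spectrum(out, window="none", zerofill=2048)
        assert spec.freq_MHz[np.argmax(spec.magnitude)] == pytest.approx(f, abs=0.05)

    def test_constant_trace_zero_residual(self):
        out = subtract_background(make_trace(np.full(64, 3.0)), "polynomial3")
        assert np.abs(out.values).max() < 1e-10

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(make_trace([1.0, 2.0, 3.0]), "exponential")

    def test_residual_mean_below_one_percent_for_fixture_decay(self):
        t = 12 + 16 * np.arange(602)
        tr = make_trace(np.exp(-t / 4000.0) * (1 + 0.3 * np.cos(2e-3 * np.pi * 0.6 * t)))
        out = subtract_background(tr, "exponential")
        assert abs(out.values.mean()) < 0.01 * np.ptp(tr.values)


class TestSpectrum:
    def test_single_cosine_peak_within_one_bin(self):
        t = 12 + 16 * np.arange(602)
        tr = make_trace(np.cos(2e-3 * np.pi * 1.0 * t))
        spec = to_spectrum(tr, window="none", zerofill=2048)
        bin_width = spec.freq_MHz[1] - spec.freq_MHz[0]
        assert abs(spec.freq_MHz[np.argmax(spec.magnitude)] - 1.0) <= bin_width

    def test_two_cosines_resolved(self):
        t = 12 + 16 * np.arange(602)
        tr = make_trace(
            np.cos(2e-3 * np.pi * 0.33 * t) + 0.7 * np.cos(2e-3 * np.pi * 2.75 * t)
        )
        spec = to_spectrum(tr, window="hamming", zerofill=2048)
        pk = pick_peaks(spec, min_height_frac=0.2, box=0.1)
        pos = sorted(p.nu1 for p in pk.entries[:2])
        assert pos[0] == pytest.approx(0.33, abs=0.03)
        assert pos[1] == pytest.approx(2.75, abs=0.03)

    def test_zero_input_zero_spectrum(self):
        spec = to_spectrum(make_trace(np.zeros(64)), window="chebyshev", zerofill=256)
        assert np.all(spec.magnitude == 0)

    def test_zerofill_shorter_than_trace_rejected(self):
        with pytest.raises(ValueError):
            to_spectrum(make_trace(np.zeros(64)), zerofill=32)

    def test_parseval_without_window(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=256)
        x -= x.mean()
        tr = make_trace(x)
        spec = to_spectrum(tr, window="none", zerofill=256)
        # rfft magnitude: double the positive-frequency bins except DC/Nyquist
        mags = spec.magnitude**2
        total = 2 * mags.sum() - mags[0] - mags[-1]
        assert total / 256 == pytest.approx((x**2).sum(), rel=1e-6)

    def test_deterministic(self):
        t = 12 + 16 * np.arange(128)
        tr = make_trace(np.cos(2e-3 * np.pi * 0.8 * t))
        a = to_spectrum(tr, zerofill=512).magnitude
        b = to_spectrum(tr, zerofill=512).magnitude
        assert np.array_equal(a, b)

    def test_2d_cosine_product_peak_position(self):
        t1 = 40 + 32 * np.arange(64)
        t2 = 40 + 32 * np.arange(64)
        vals = np.cos(2e-3 * np.pi * 1.5 * t1)[:, None] * np.cos(
            2e-3 * np.pi * 3.0 * t2
        )[None, :]
        tr = TimeTrace2D(t1, t2, vals)
        spec = to_spectrum(tr, window="none", zerofill=256)
        i, j = np.unravel_index(np.argmax(spec.magnitude), spec.magnitude.shape)
        assert spec.f1_MHz[i] == pytest.approx(1.5, abs=0.07)
        assert spec.f2_MHz[j] == pytest.approx(3.0, abs=0.07)


class TestPeaks:
    def test_single_cosine_single_peak(self):
        t = 12 + 16 * np.arange(602)
        spec = to_spectrum(make_trace(np.cos(2e-3 * np.pi * 2.0 * t)),
                           window="hamming", zerofill=2048)
        pk = pick_peaks(spec, min_height_frac=0.3, box=0.2)
        assert len(pk) == 1

    def test_flat_spectrum_empty_list(self):
        from echomod import Spectrum1D

        spec = Spectrum1D(np.linspace(0, 10, 100), np.zeros(100))
        assert len(pick_peaks(spec)) == 0

    def test_parabolic_refinement_beats_bin_width(self):
        # frequency deliberately off-bin
        t = 12 + 16 * np.arange(602)
        nu = 1.2345
        spec = to_spectrum(make_trace(np.cos(2e-3 * np.pi * nu * t)),
                           window="hamming", zerofill=2048)
        pk = pick_peaks(spec, min_height_frac=0.5, box=0.2)
        assert pk.entries[0].nu1 == pytest.approx(nu, abs=0.01)

    def test_deterministic_ordering(self):
        from echomod import Spectrum1D

        f = np.linspace(0, 10, 501)
        y = np.zeros_like(f)
        y[50] = y[300] = 1.0  # equal heights -> ascending nu1 breaks the tie
        y[49] = y[299] = 0.5
        y[51] = y[301] = 0.5
        pk = pick_peaks(Spectrum1D(f, y), min_height_frac=0.5, box=0.1)
        assert pk.entries[0].nu1 < pk.entries[1].nu1

    def test_linearity_scaling_preserves_ratios(self, sys_two_n15, field):
        timing = PulseTiming3p(n_points=301)
        tr = eseem_powder(sys_two_n15, timing, grid_size=50, field=field)
        tr2 = TimeTrace1D(tr.t_axis, 3.7 * tr.values, dict(tr.metadata))
        s1 = process_trace(tr, background="polynomial3")
        s2 = process_trace(tr2, background="polynomial3")
        # first-point normalization makes the pipeline scale invariant
        assert np.allclose(s1.magnitude, s2.magnitude, rtol=1e-9)

    def test_height_ratio_reference_and_missing(self):
        peaks = PeakList([
            Peak(nu1=0.3, nu2=None, height=10.0, label="a"),
            Peak(nu1=0.6, nu2=None, height=6.0, label="b"),
        ])
        assert peak_height_ratio(peaks, "a", ["b"]) == pytest.approx([1.0, 0.6])
        with pytest.raises(KeyError):
            peak_height_ratio(peaks, "missing", ["b"])

    def test_single_peak_ratio_list(self):
        peaks = PeakList([Peak(nu1=1.0, nu2=None, height=2.0, label="only")])
        assert peak_height_ratio(peaks, "only", []) == [1.0]


class TestRegionMeasures:
    def test_centroid_of_symmetric_line(self):
        from echomod import Spectrum1D

        f = np.linspace(0, 5, 1001)
        y = np.exp(-((f - 2.0) ** 2) / 0.02)
        assert region_centroid(Spectrum1D(f, y), (1.5, 2.5)) == pytest.approx(2.0, abs=1e-3)

    def test_prominence_ignores_monotone_skirt(self):
        from echomod import Spectrum1D

        f = np.linspace(0, 5, 1001)
        skirt = 1.0 / (0.5 + f)  # smooth decaying skirt, no line
        prom, _ = line_prominence(Spectrum1D(f, skirt), (1.0, 3.0))
        y = skirt + np.exp(-((f - 2.0) ** 2) / 0.01)
        prom2, pos = line_prominence(Spectrum1D(f, y), (1.0, 3.0))
        assert prom < 0.05
        assert prom2 > 0.9
        assert pos == pytest.approx(2.0, abs=0.02)
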