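"""The four time-frequency estimators and their analytic properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import label, maximum_filter
from scipy.signal import hilbert

from tfrinfo import (
    BurstSpec,
    ChoiWilliamsParams,
    MorletParams,
    Signal,
    SuperletParams,
    choi_williams,
    cwt_morlet,
    make_burst,
    morlet_wavelet,
    stft,
    superlet,
    wvd,
)

FS = 1000.0


def gaussian_atom(center_t, f, n_cycles=6, duration=1.0, fs=FS):
    return make_burst(BurstSpec(center_t, f, n_cycles), fs, duration)


@pytest.fixture(scope="module")
def two_atom_signal():
    """40 Hz and 48 Hz atoms at separate times (cross-term test bed)."""
    a = gaussian_atom(0.15, 40, duration=0.5)
    b = gaussian_atom(0.35, 48, duration=0.5)
    return Signal(a.samples + b.samples, FS)


class TestStft:
    def test_zero_signal_zero_grid(self):
        g = stft(Signal(np.zeros(1000), FS))
        assert np.all(g.values == 0.0)

    def test_pad_to_sets_frequency_spacing(self):
        g = stft(Signal(np.zeros(1000), FS), pad_to=2.0)
        assert np.allclose(np.diff(g.freq_axis), 0.5)

    def test_sinusoid_marginal_peaks_at_its_frequency(self):
        t = np.arange(1000) / FS
        g = stft(Signal(np.sin(2 * np.pi * 40.0 * t), FS), freq_range=(1, 100))
        marginal = g.values.sum(axis=1)
        assert g.freq_axis[np.argmax(marginal)] == pytest.approx(40.0, abs=0.5)

    def test_empty_freq_range_errors(self):
        with pytest.raises(ValueError, match="frequency bins"):
            stft(Signal(np.zeros(1000), FS), freq_range=(600.0, 700.0))

    def test_window_longer_than_signal_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            stft(Signal(np.zeros(100), FS), window_len=0.25)


class TestMorletWavelet:
    def test_bandwidth_formula(self):
        # B_c = c / (5 f)
        assert MorletParams(3.0).bandwidth(10.0) == pytest.approx(0.06)
        assert MorletParams(7.0).bandwidth(20.0) == pytest.approx(0.07)

    def test_envelope_maximum_at_zero(self):
        t, psi = morlet_wavelet(10.0, MorletParams(3.0), FS)
        assert t[np.argmax(np.abs(psi))] == 0.0

    def test_time_compression_between_frequencies(self):
        # psi_{2f}(t) = 2 psi_f(2t): doubling f halves B_c and doubles the
        # 1/(B_c sqrt(2 pi)) normalization
        t10, psi10 = morlet_wavelet(10.0, MorletParams(3.0), FS)
        t20, psi20 = morlet_wavelet(20.0, MorletParams(3.0), FS)
        # compare psi20 at t with psi10 at 2t on the even samples
        half = (len(t10) - 1) // 2
        quarter = (len(t20) - 1) // 2
        for k in (0, 5, 17, quarter):
            np.testing.assert_allclose(
                psi20[quarter + k], 2.0 * psi10[half + 2 * k], rtol=1e-10
            )

    def test_rejects_nyquist_frequency(self):
        with pytest.raises(ValueError, match="Nyquist"):
            morlet_wavelet(500.0, MorletParams(3.0), FS)


class TestCwt:
    def test_zero_signal(self):
        g = cwt_morlet(Signal(np.zeros(300), FS), [10.0, 20.0])
        assert np.all(g.values == 0.0)

    def test_amplitude_scaling_is_quadratic(self, rng):
        x = rng.standard_normal(400)
        g1 = cwt_morlet(Signal(x, FS), [15.0, 40.0])
        g3 = cwt_morlet(Signal(3.0 * x, FS), [15.0, 40.0])
        np.testing.assert_allclose(g3.values, 9.0 * g1.values, rtol=1e-10)

    def test_atom_argmax_at_planted_coordinates(self):
        sig = gaussian_atom(0.5, 40.0)
        g = cwt_morlet(sig, np.arange(20.0, 60.5, 0.5))
        fi, ti = np.unravel_index(np.argmax(g.values), g.values.shape)
        assert g.freq_axis[fi] == pytest.approx(40.0, abs=1.0)
        assert g.time_axis[ti] == pytest.approx(0.5, abs=0.01)

    def test_row_matches_direct_summation_convolution(self, rng):
        # oracle: dense direct-summation convolution, no FFT
        x = rng.standard_normal(256)
        f = 25.0
        _, psi = morlet_wavelet(f, MorletParams(3.0), FS)
        direct = np.convolve(x, psi, mode="same") / FS
        expected = 2.0 * np.abs(direct) ** 2
        g = cwt_morlet(Signal(x, FS), [f])
        np.testing.assert_allclose(g.values[0], expected, rtol=1e-8, atol=1e-12)


class TestSuperlet:
    def test_order_one_equals_cwt(self, rng):
        x = rng.standard_normal(500)
        freqs = np.arange(10.0, 100.0, 5.0)
        c = cwt_morlet(Signal(x, FS), freqs, MorletParams(3.0))
        s = superlet(Signal(x, FS), freqs, SuperletParams(3.0, 1))
        np.testing.assert_allclose(s.values, c.values, rtol=1e-9)

    def test_geometric_mean_sandwich(self, rng):
        x = rng.standard_normal(400)
        freqs = np.arange(10.0, 80.0, 10.0)
        s = superlet(Signal(x, FS), freqs, SuperletParams(2.0, 3))
        parts = [
            cwt_morlet(Signal(x, FS), freqs, MorletParams(2.0 * i)).values
            for i in (1, 2, 3)
        ]
        assert np.all(s.values >= np.minimum.reduce(parts) - 1e-12)
        assert np.all(s.values <= np.maximum.reduce(parts) + 1e-12)

    def test_cycle_progressions(self):
        assert SuperletParams(2.0, 4).cycle_set() == [2.0, 4.0, 6.0, 8.0]
        assert SuperletParams(2.0, 4, "additive").cycle_set() == [2.0, 3.0, 4.0, 5.0]

    def test_frequency_super_resolution_of_cotemporal_atoms(self):
        # two co-temporal atoms 8 Hz apart: CWT (c=3) merges them into one
        # half-peak maximum; the high-order superlet resolves both
        sig = Signal(
            gaussian_atom(1.0, 40, n_cycles=12, duration=2.0).samples
            + gaussian_atom(1.0, 48, n_cycles=12, duration=2.0).samples,
            FS,
        )
        freqs = np.arange(30.0, 60.25, 0.25)

        def half_peak_frequencies(values):
            peaks = (values == maximum_filter(values, size=9)) & (
                values > 0.5 * values.max()
            )
            labelled, n = label(peaks)
            out = []
            for i in range(1, n + 1):
                fi, _ = np.unravel_index(
                    np.argmax(np.where(labelled == i, values, -np.inf)), values.shape
                )
                out.append(freqs[fi])
            return out

        cwt_peaks = half_peak_frequencies(cwt_morlet(sig, freqs, MorletParams(3)).values)
        slt_peaks = half_peak_frequencies(
            superlet(sig, freqs, SuperletParams(3, 10)).values
        )
        assert len(cwt_peaks) == 1 and 42.0 < cwt_peaks[0] < 46.0  # merged
        assert any(abs(p - 40.0) < 1.0 for p in slt_peaks)
        assert any(abs(p - 48.0) < 1.0 for p in slt_peaks)


class TestWvd:
    def test_single_atom_global_maximum(self):
        sig = gaussian_atom(0.25, 60.0, duration=0.5)
        g = wvd(sig)
        fi, ti = np.unravel_index(np.argmax(g.values), g.values.shape)
        assert g.freq_axis[fi] == pytest.approx(60.0, abs=1.0)
        assert g.time_axis[ti] == pytest.approx(0.25, abs=0.01)

    def test_cross_term_between_two_atoms(self, two_atom_signal):
        # oscillatory cross-term at the (time, frequency) midpoint
        g = wvd(two_atom_signal)
        mid = (
            (g.freq_axis > 42) & (g.freq_axis < 46),
            (g.time_axis > 0.2) & (g.time_axis < 0.3),
        )
        cross = g.values[np.ix_(*mid)]
        auto = g.values.max()
        assert np.abs(cross).max() > 0.1 * auto
        assert cross.min() < 0  # ripples oscillate through negative values

    def test_time_marginal_recovers_instantaneous_power(self):
        # sum_f WVD(t, f) df ~= |analytic signal|^2
        sig = gaussian_atom(0.25, 60.0, duration=0.5)
        g = wvd(sig)
        df = g.freq_axis[1] - g.freq_axis[0]
        marginal = g.values.sum(axis=0) * df
        power = np.abs(hilbert(sig.samples)) ** 2
        np.testing.assert_allclose(marginal, power, atol=1e-10 * power.max())

    def test_too_short_signal_errors(self):
        with pytest.raises(ValueError, match="4 samples"):
            wvd(Signal(np.ones(3), FS))


class TestChoiWilliams:
    def test_single_atom_peak_matches_wvd(self):
        sig = gaussian_atom(0.25, 60.0, duration=0.5)
        w = wvd(sig)
        c = choi_williams(sig, ChoiWilliamsParams(3.0))
        wi = np.unravel_index(np.argmax(w.values), w.values.shape)
        ci = np.unravel_index(np.argmax(c.values), c.values.shape)
        assert abs(wi[0] - ci[0]) <= 1 and abs(wi[1] - ci[1]) <= 1

    def test_cross_term_suppressed_relative_to_wvd(self, two_atom_signal):
        w = wvd(two_atom_signal)
        c = choi_williams(two_atom_signal, ChoiWilliamsParams(3.0))
        region = (
            (w.freq_axis > 42) & (w.freq_axis < 46),
            (w.time_axis > 0.2) & (w.time_axis < 0.3),
        )
        assert (
            np.abs(c.values[np.ix_(*region)]).max()
            < np.abs(w.values[np.ix_(*region)]).max()
        )

    def test_large_sigma_approaches_wvd(self, two_atom_signal):
        w = wvd(two_atom_signal)
        c = choi_williams(two_atom_signal, ChoiWilliamsParams(1e6))
        err = np.linalg.norm(c.values - w.values) / np.linalg.norm(w.values)
        assert err < 0.01

    def test_deviation_from_wvd_decreases_with_sigma(self, two_atom_signal):
        w = wvd(two_atom_signal)
        errs = [
            np.linalg.norm(
                choi_williams(two_atom_signal, ChoiWilliamsParams(s)).values - w.values
            )
            for s in (1.0, 10.0, 100.0, 1e4)
        ]
        assert all(a > b for a, b in zip(errs, errs[1:]))

    def test_sigma_validation(self):
        with pytest.raises(ValueError, match="positive"):
            ChoiWilliamsParams(0.0)


class TestSharedInvariants:
    @pytest.mark.parametrize("method", ["stft", "cwt", "slt", "wvd", "choiw"])
    def test_zero_in_zero_out(self, method):
        from tfrinfo import compute_tfr

        sig = Signal(np.zeros(512), FS)
        kwargs = {"freqs": [20.0, 40.0]} if method in ("cwt", "slt") else {}
        grid = compute_tfr(sig, method, **kwargs)
        assert np.all(grid.values == 0.0)

    def test_time_shift_equivariance_cwt(self, rng):
        # shifting the input by k samples shifts interior time bins by k
        x = np.zeros(600)
        burst = gaussian_atom(0.25, 40.0, duration=0.5).samples
        x[:500] += burst
        y = np.roll(x, 50)
        g_x = cwt_morlet(Signal(x, FS), [40.0])
        g_y = cwt_morlet(Signal(y, FS), [40.0])
        np.testing.assert_allclose(
            g_y.values[0, 150:450], g_x.values[0, 100:400], rtol=1e-6, atol=1e-12
        )

    @settings(deadline=None, max_examples=10)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_superlet_order_one_equals_cwt_property(self, seed):
        x = np.random.default_rng(seed).standard_normal(200)
        freqs = [12.0, 33.0, 71.0]
        c = cwt_morlet(Signal(x, FS), freqs, MorletParams(2.5))
        s = superlet(Signal(x, FS), freqs, SuperletParams(2.5, 1))
        np.testing.assert_allclose(s.values, c.values, rtol=1e-9)
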