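"""Time-frequency estimators for single-trial neural signals.

Four estimators are provided, all returning a :class:`TFRGrid` (frequency x
time matrix with explicit axes):

* :func:`stft` -- squared-magnitude spectrogram with a configurable window,
  zero padding, and time step.
* :func:`cwt_morlet` -- continuous wavelet transform with complex Morlet
  wavelets parameterized by a cycle count ``c``; bandwidth ``B_c = c / (5 f)``.
* :func:`superlet` -- geometric mean of a set of Morlet CWTs of increasing
  cycle count at each frequency (time-frequency super-resolution).
* :func:`wvd` / :func:`choi_williams` -- discrete pseudo Wigner-Ville
  distribution of the analytic signal and its reduced-interference variant
  smoothed by the Choi-Williams ambiguity kernel ``exp(-(theta*tau)^2/sigma)``.

STFT/CWT/SLT grids are non-negative power-like quantities; WVD and
Choi-Williams grids are real-valued energy distributions that may go
negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "Signal",
    "TFRGrid",
    "MorletParams",
    "SuperletParams",
    "ChoiWilliamsParams",
    "stft",
    "morlet_wavelet",
    "cwt_morlet",
    "superlet",
    "wvd",
    "choi_williams",
    "compute_tfr",
]

# Morlet envelope is truncated where it falls below this fraction of its peak.
_ENVELOPE_CUTOFF = 1e-6
# Lag window length for the pseudo-WVD (odd, capped).
_MAX_WVD_LAGS = 1024


@dataclass(frozen=True)
class Signal:
    """A sampled single-trial trace.

    Parameters
    ----------
    samples
        Real-valued samples (signal units).
    sampling_rate
        Samples per second; must be positive.
    t0
        Time of the first sample relative to trial / stimulus onset (s).
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError(f"signal must be 1-D, got shape {samples.shape}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def nyquist(self) -> float:
        return self.sampling_rate / 2.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate


@dataclass
class TFRGrid:
    """A real-valued time-frequency matrix with explicit axes.

    ``values`` has shape ``(len(freq_axis), len(time_axis))``; both axes are
    uniformly spaced and strictly increasing.  ``valid_mask``, when present,
    marks time bins unaffected by boundary effects (same shape as ``values``
    or length of ``time_axis``).
    """

    values: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freq_axis = np.asarray(self.freq_axis, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.values.shape != (self.freq_axis.size, self.time_axis.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match axes "
                f"({self.freq_axis.size} freqs, {self.time_axis.size} times)"
            )
        for name, ax in (("freq_axis", self.freq_axis), ("time_axis", self.time_axis)):
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError(f"{name} must be strictly increasing")

    def restrict_freqs(self, fmin: float, fmax: float) -> "TFRGrid":
        """Return a copy keeping only frequency rows within [fmin, fmax]."""
        keep = (self.freq_axis >= fmin) & (self.freq_axis <= fmax)
        if not keep.any():
            raise ValueError(
                f"no frequency bins inside [{fmin}, {fmax}] Hz "
                f"(grid covers {self.freq_axis[0]:g}-{self.freq_axis[-1]:g} Hz)"
            )
        return TFRGrid(
            values=self.values[keep],
            freq_axis=self.freq_axis[keep],
            time_axis=self.time_axis.copy(),
            method=self.method,
            params=dict(self.params),
            valid_mask=self.valid_mask,
        )


@dataclass(frozen=True)
class MorletParams:
    """Morlet wavelet cycle count; bandwidth ``B_c = c / (5 f)`` seconds."""

    cycles: float = 3.0

    def __post_init__(self) -> None:
        if self.cycles <= 0:
            raise ValueError("cycles must be positive")

    def bandwidth(self, freq: float) -> float:
        return self.cycles / (5.0 * freq)


@dataclass(frozen=True)
class SuperletParams:
    """Superlet: base cycle count ``c1`` and order ``o``.

    The cycle progression is multiplicative by default, ``c_i = i * c1``
    (``i = 1..o``), with an additive alternative ``c_i = c1 + (i - 1)``.
    """

    base_cycles: float = 3.0
    order: int = 10
    progression: str = "multiplicative"

    def __post_init__(self) -> None:
        if self.base_cycles <= 0:
            raise ValueError("base_cycles must be positive")
        if self.order < 1 or int(self.order) != self.order:
            raise ValueError("order must be an integer >= 1")
        if self.progression not in ("multiplicative", "additive"):
            raise ValueError("progression must be 'multiplicative' or 'additive'")

    def cycle_set(self) -> list[float]:
        if self.progression == "multiplicative":
            cycles = [i * self.base_cycles for i in range(1, self.order + 1)]
        else:
            cycles = [self.base_cycles + (i - 1) for i in range(1, self.order + 1)]
        return cycles


@dataclass(frozen=True)
class ChoiWilliamsParams:
    """Choi-Williams ambiguity-kernel smoothing factor (dimensionless)."""

    sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


# ---------------------------------------------------------------------------
# Short-time Fourier transform
# ---------------------------------------------------------------------------

def stft(
    sig: Signal,
    window_len: float = 0.25,
    window_type: str = "blackman",
    pad_to: float = 2.0,
    step: float = 0.001,
    freq_range: tuple[float, float] | None = None,
) -> TFRGrid:
    """Squared-magnitude spectrogram.

    Parameters
    ----------
    sig
        Input trace.
    window_len
        Analysis window length in seconds (default 250 ms).
    window_type
        Any window name accepted by :func:`scipy.signal.get_window`.
    pad_to
        Zero-padded DFT length in seconds; the frequency bin spacing is
        ``1 / pad_to`` Hz (default 2 s -> 0.5 Hz).
    step
        Hop between window centers in seconds (default 1 ms).
    freq_range
        Optional (low, high) Hz restriction of the output rows.
    """
    fs = sig.sampling_rate
    n_win = int(round(window_len * fs))
    if n_win < 2:
        raise ValueError("window_len too short for the sampling rate")
    if n_win > sig.n_samples:
        raise ValueError(
            f"window_len {window_len} s exceeds signal duration {sig.duration} s"
        )
    n_fft = int(round(pad_to * fs))
    if n_fft < n_win:
        raise ValueError("pad_to must be at least window_len")
    hop = max(1, int(round(step * fs)))

    win = sps.get_window(window_type, n_win, fftbins=False)
    sft = sps.ShortTimeFFT(win, hop=hop, fs=fs, mfft=n_fft, scale_to=None)
    spec = sft.spectrogram(sig.samples)  # |STFT|^2, shape (n_freq, n_frames)
    t_frames = sig.t0 + sft.t(sig.n_samples)
    freqs = sft.f

    # keep frames whose center lies within the signal span
    inside = (t_frames >= sig.t0 - 0.5 / fs) & (
        t_frames <= sig.t0 + (sig.n_samples - 0.5) / fs
    )
    spec = spec[:, inside]
    t_frames = t_frames[inside]

    half = window_len / 2.0
    valid = (t_frames >= sig.t0 + half) & (t_frames <= sig.t0 + sig.duration - half)

    grid = TFRGrid(
        values=spec,
        freq_axis=freqs,
        time_axis=t_frames,
        method="stft",
        params={
            "window_len": window_len,
            "window_type": window_type,
            "pad_to": pad_to,
            "step": step,
        },
        valid_mask=valid,
    )
    if freq_range is not None:
        grid = grid.restrict_freqs(*freq_range)
    return grid


# ---------------------------------------------------------------------------
# Morlet CWT and superlets
# ---------------------------------------------------------------------------

def morlet_wavelet(
    freq: float, params: MorletParams, sampling_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled complex Morlet wavelet ``psi_{f,c}``.

    ``psi(t) = (1 / (B_c sqrt(2 pi))) exp(-t^2 / (2 B_c^2)) exp(j 2 pi f t)``
    with ``B_c = c / (5 f)``, sampled on a symmetric support truncated where
    the Gaussian envelope falls below ``1e-6`` of its peak.

    Returns ``(t, psi)``: the sample times (s, centered on 0) and the complex
    kernel values.
    """
    if freq <= 0:
        raise ValueError("frequency must be positive")
    if freq >= sampling_rate / 2.0:
        raise ValueError(
            f"frequency {freq} Hz is at or above Nyquist ({sampling_rate / 2} Hz)"
        )
    bc = params.bandwidth(freq)
    # envelope exp(-t^2 / (2 B^2)) < cutoff  <=>  |t| > B sqrt(2 ln(1/cutoff))
    t_max = bc * np.sqrt(2.0 * np.log(1.0 / _ENVELOPE_CUTOFF))
    n_half = int(np.ceil(t_max * sampling_rate))
    t = np.arange(-n_half, n_half + 1) / sampling_rate
    envelope = np.exp(-(t**2) / (2.0 * bc**2)) / (bc * np.sqrt(2.0 * np.pi))
    psi = envelope * np.exp(2j * np.pi * freq * t)
    return t, psi


def _cwt_row(x: np.ndarray, psi: np.ndarray, dt: float) -> np.ndarray:
    """Power row ``2 |(psi * x)(t)|^2`` with the convolution as dt-weighted sum."""
    conv = sps.fftconvolve(x, psi, mode="same") * dt
    return 2.0 * np.abs(conv) ** 2


def cwt_morlet(
    sig: Signal, freqs: Sequence[float], params: MorletParams = MorletParams()
) -> TFRGrid:
    """Morlet continuous wavelet transform, ``CWT(t, f) = 2 |(psi_{f,c} * x)(t)|^2``.

    One time bin per signal sample; one row per requested frequency.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("freqs must be non-empty")
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("freqs must be strictly increasing")
    dt = 1.0 / sig.sampling_rate
    values = np.empty((freqs.size, sig.n_samples))
    support = np.zeros(freqs.size)
    for i, f in enumerate(freqs):
        t_k, psi = morlet_wavelet(f, params, sig.sampling_rate)
        values[i] = _cwt_row(sig.samples, psi, dt)
        support[i] = t_k[-1]
    valid = _interior_mask(sig, support.max())
    return TFRGrid(
        values=values,
        freq_axis=freqs,
        time_axis=sig.times,
        method="cwt",
        params={"cycles": params.cycles},
        valid_mask=valid,
    )


def _interior_mask(sig: Signal, half_support: float) -> np.ndarray:
    t = sig.times
    return (t >= sig.t0 + half_support) & (t <= sig.t0 + sig.duration - half_support)


def superlet(
    sig: Signal, freqs: Sequence[float], params: SuperletParams = SuperletParams()
) -> TFRGrid:
    """Superlet transform: geometric mean of ``order`` Morlet CWTs per frequency.

    ``SLT(t, f) = [prod_i CWT(t, f, c_i)]^(1/o)``; sharper joint localization
    than any constituent wavelet because short wavelets suppress responses
    outside the burst's time span and long ones outside its frequency band.
    """
    cycles = params.cycle_set()
    order = len(cycles)
    base = cwt_morlet(sig, freqs, MorletParams(cycles[0]))
    # geometric mean in log space; exact zeros stay zero
    log_acc = _safe_log(base.values)
    for c in cycles[1:]:
        log_acc += _safe_log(cwt_morlet(sig, freqs, MorletParams(c)).values)
    with np.errstate(over="ignore"):
        values = np.exp(log_acc / order)
    values[~np.isfinite(log_acc)] = 0.0
    return TFRGrid(
        values=values,
        freq_axis=base.freq_axis,
        time_axis=base.time_axis,
        method="slt",
        params={
            "base_cycles": params.base_cycles,
            "order": params.order,
            "progression": params.progression,
        },
        valid_mask=base.valid_mask,
    )


def _safe_log(a: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(a > 0, np.log(np.where(a > 0, a, 1.0)), -np.inf)


# ---------------------------------------------------------------------------
# Wigner-Ville and Choi-Williams distributions
# ---------------------------------------------------------------------------

def _instantaneous_autocorrelation(sig: Signal) -> tuple[np.ndarray, np.ndarray]:
    """Windowed IAF ``K[m, n] = z[n + m] conj(z[n - m])`` of the analytic signal.

    Returns ``(K, tau)`` where rows index the lag ``m = 0 .. L-1`` arranged for
    an FFT over the lag axis (non-negative lags first, then negative), and
    ``tau`` gives the physical lag ``2 m dt`` in the same arrangement.
    """
    n = sig.n_samples
    if n < 4:
        raise ValueError("signal must have at least 4 samples")
    z = sps.hilbert(sig.samples)
    # odd lag-window length: signal length, capped
    n_lags = min(n, _MAX_WVD_LAGS)
    if n_lags % 2 == 0:
        n_lags -= 1
    half = (n_lags - 1) // 2
    dt = 1.0 / sig.sampling_rate
    L = n_lags
    K = np.zeros((L, n), dtype=complex)
    idx = np.arange(n)
    for m in range(half + 1):
        lead = np.clip(idx + m, 0, n - 1)
        lag = np.clip(idx - m, 0, n - 1)
        row = np.zeros(n, dtype=complex)
        ok = (idx + m < n) & (idx - m >= 0)
        row[ok] = z[lead[ok]] * np.conj(z[lag[ok]])
        K[m] = row
        if m > 0:
            K[L - m] = np.conj(row)
    m_idx = np.concatenate([np.arange(half + 1), np.arange(-half, 0)])
    tau = 2.0 * m_idx * dt
    return K, tau


def _wvd_from_iaf(K: np.ndarray, sig: Signal) -> TFRGrid:
    L = K.shape[0]
    dt = 1.0 / sig.sampling_rate
    # FFT over lag: W(t, f_k) = sum_m K[m, t] exp(-j 2 pi k m / L), f_k = k / (2 L dt)
    W = np.fft.fft(K, axis=0)
    values = np.real(W) * 2.0 * dt  # Riemann weight of the tau integral (dtau = 2 dt)
    freqs = np.arange(L) / (2.0 * L * dt)
    keep = freqs < sig.sampling_rate / 2.0
    half_support = ((L - 1) // 2) * dt
    valid = _interior_mask(sig, half_support)
    return TFRGrid(
        values=values[keep],
        freq_axis=freqs[keep],
        time_axis=sig.times,
        method="wvd",
        params={"n_lags": L},
        valid_mask=valid,
    )


def wvd(sig: Signal, freq_range: tuple[float, float] | None = None) -> TFRGrid:
    """Discrete pseudo Wigner-Ville distribution of the analytic signal.

    Real-valued; achieves optimal localization for a single Gaussian atom but
    produces oscillatory cross-terms midway between pairs of components.
    """
    K, _ = _instantaneous_autocorrelation(sig)
    grid = _wvd_from_iaf(K, sig)
    if freq_range is not None:
        grid = grid.restrict_freqs(*freq_range)
    return grid


def choi_williams(
    sig: Signal,
    params: ChoiWilliamsParams = ChoiWilliamsParams(),
    freq_range: tuple[float, float] | None = None,
) -> TFRGrid:
    """Choi-Williams reduced-interference distribution.

    The WVD's instantaneous autocorrelation is transported to the ambiguity
    (doppler theta, lag tau) plane, weighted by the kernel
    ``Phi(theta, tau) = exp(-(theta tau)^2 / sigma)`` (theta in Hz, tau in s),
    and transported back before the lag -> frequency transform.  The kernel
    equals 1 along both axes, preserving auto-terms while attenuating
    cross-terms, which live at large ``|theta tau|``.
    """
    K, tau = _instantaneous_autocorrelation(sig)
    n = sig.n_samples
    dt = 1.0 / sig.sampling_rate
    # time -> doppler along axis 1
    A = np.fft.fft(K, axis=1)
    theta = np.fft.fftfreq(n, d=dt)  # Hz
    kernel = np.exp(-((theta[None, :] * tau[:, None]) ** 2) / params.sigma)
    K_s = np.fft.ifft(A * kernel, axis=1)
    grid = _wvd_from_iaf(K_s, sig)
    grid.method = "choi_williams"
    grid.params = {"sigma": params.sigma, "n_lags": K.shape[0]}
    if freq_range is not None:
        grid = grid.restrict_freqs(*freq_range)
    return grid


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def compute_tfr(
    sig: Signal,
    method: str,
    freqs: Sequence[float] | None = None,
    freq_range: tuple[float, float] | None = None,
    **kwargs,
) -> TFRGrid:
    """Compute a TFR by method name.

    ``method`` is one of ``stft``, ``cwt``, ``slt``, ``wvd``, ``choiw``.
    Wavelet methods require ``freqs``; ``stft``/``wvd``/``choiw`` accept
    ``freq_range`` applied after computation (their native frequency binning
    is fixed by the DFT length or the sampling rate).
    """
    method = method.lower()
    if method == "stft":
        return stft(sig, freq_range=freq_range, **kwargs)
    if method == "cwt":
        if freqs is None:
            raise ValueError("cwt requires an explicit frequency axis")
        return cwt_morlet(sig, freqs, MorletParams(**kwargs) if kwargs else MorletParams())
    if method == "slt":
        if freqs is None:
            raise ValueError("slt requires an explicit frequency axis")
        return superlet(sig, freqs, SuperletParams(**kwargs) if kwargs else SuperletParams())
    if method == "wvd":
        return wvd(sig, freq_range=freq_range)
    if method in ("choiw", "choi_williams"):
        params = ChoiWilliamsParams(**kwargs) if kwargs else ChoiWilliamsParams()
        return choi_williams(sig, params, freq_range=freq_range)
    raise ValueError(f"unknown TFR method {method!r}")
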