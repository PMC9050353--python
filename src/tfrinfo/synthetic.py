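"""Seeded surrogate datasets with class-structured oscillation bursts.

Three protocols are emulated, mirroring common visual-neuroscience designs:

* ``rf_like`` -- receptive-field mapping: each trial carries a single gamma
  burst whose latency is a monotone function of the class (stimulus
  direction), so classes are separated purely in time.
* ``srcs_like`` -- drifting-grating stimulation: a periodic train of gamma
  bursts at the grating temporal frequency (1.75 cycles/s) whose onset phase
  depends on the class.
* ``eeg_like`` -- a two-class visual recognition design with unbalanced
  trial counts (90 "seen" vs 60 "nothing"); the "seen" class carries more
  alpha/low-beta (8-15 Hz) burst power.

All trials ride on 1/f background noise, optionally contaminated with brief
broadband transients (5 ms white-noise clicks) scheduled by a Poisson
process.  Every random draw flows through one explicit numpy Generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tfr import Signal

__all__ = [
    "BurstSpec",
    "NoiseSpec",
    "ProtocolSpec",
    "make_burst",
    "make_background",
    "make_dataset",
]

# width of a broadband transient click (s)
_CLICK_DURATION = 0.005
# click amplitude relative to the background standard deviation
_CLICK_GAIN = 5.0

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class BurstSpec:
    """A single oscillation packet: a cosine under a Gaussian envelope.

    ``n_cycles`` sets the envelope's full width at half maximum to
    ``n_cycles / center_freq`` seconds, making the packet's duration
    commensurate with wavelet cycle counts.
    """

    center_time: float
    center_freq: float
    n_cycles: float = 6.0
    amplitude: float = 1.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.center_freq <= 0:
            raise ValueError("center_freq must be positive")
        if self.n_cycles <= 0:
            raise ValueError("n_cycles must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def duration(self) -> float:
        return self.n_cycles / self.center_freq


@dataclass(frozen=True)
class NoiseSpec:
    """Background noise model: 1/f^exponent spectrum plus Poisson clicks."""

    one_over_f_exponent: float = 1.0
    noise_power: float = 0.1
    transient_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.one_over_f_exponent < 0:
            raise ValueError("one_over_f_exponent must be non-negative")
        if self.noise_power < 0:
            raise ValueError("noise_power must be non-negative")
        if self.transient_rate < 0:
            raise ValueError("transient_rate must be non-negative")


@dataclass(frozen=True)
class ProtocolSpec:
    """Geometry and effect structure of one synthetic experiment.

    Defaults depend on ``kind``; use :meth:`default` to obtain them.
    ``effect_size`` scales the planted class effect: burst amplitude for the
    LFP-like protocols, and the power surplus ``(1 + effect_size)`` of the
    "seen" class for ``eeg_like``.
    """

    kind: str
    n_classes: int
    trial_counts: tuple[int, ...]
    trial_duration: float
    sampling_rate: float
    band: tuple[float, float]
    effect_size: float = 1.0
    t0: float = 0.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        if self.kind not in ("rf_like", "srcs_like", "eeg_like"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if len(self.trial_counts) != self.n_classes:
            raise ValueError("one trial count per class required")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.band[0] <= 0 or self.band[1] <= self.band[0]:
            raise ValueError("band must satisfy 0 < low < high")
        if self.band[1] >= self.sampling_rate / 2.0:
            raise ValueError("band upper edge must be below Nyquist")

    @property
    def n_trials(self) -> int:
        return int(sum(self.trial_counts))

    @staticmethod
    def default(kind: str, effect_size: float = 1.0, **overrides) -> "ProtocolSpec":
        """Canonical spec per protocol.

        rf_like: 8 classes x 10 trials, 3 s at 1000 samples/s, 50-70 Hz.
        srcs_like: 8 classes x 10 trials, 4 s at 1000 samples/s, 35-55 Hz.
        eeg_like: 2 classes (90, 60), 0.7 s at 1024 samples/s, 8-15 Hz
        effect band inside a 5-55 Hz analysis range, trials starting 300 ms
        after stimulus onset.
        """
        if kind == "rf_like":
            base = dict(
                kind=kind,
                n_classes=8,
                trial_counts=(10,) * 8,
                trial_duration=3.0,
                sampling_rate=1000.0,
                band=(50.0, 70.0),
                effect_size=effect_size,
            )
        elif kind == "srcs_like":
            base = dict(
                kind=kind,
                n_classes=8,
                trial_counts=(10,) * 8,
                trial_duration=4.0,
                sampling_rate=1000.0,
                band=(35.0, 55.0),
                effect_size=effect_size,
            )
        elif kind == "eeg_like":
            base = dict(
                kind=kind,
                n_classes=2,
                trial_counts=(90, 60),
                trial_duration=0.7,
                sampling_rate=1024.0,
                band=(8.0, 15.0),
                effect_size=effect_size,
                t0=0.3,
            )
        else:
            raise ValueError(f"unknown protocol kind {kind!r}")
        base.update(overrides)
        return ProtocolSpec(**base)


def make_burst(
    spec: BurstSpec, sampling_rate: float, duration: float, t0: float = 0.0
) -> Signal:
    """Render a Gaussian-windowed cosine packet into a trace of ``duration`` s."""
    if spec.center_freq >= sampling_rate / 2.0:
        raise ValueError(
            f"burst frequency {spec.center_freq} Hz is at or above Nyquist "
            f"({sampling_rate / 2} Hz)"
        )
    n = int(round(duration * sampling_rate))
    t = t0 + np.arange(n) / sampling_rate
    sigma = spec.duration * _FWHM_TO_SIGMA
    envelope = spec.amplitude * np.exp(-((t - spec.center_time) ** 2) / (2 * sigma**2))
    samples = envelope * np.cos(
        2 * np.pi * spec.center_freq * (t - spec.center_time) + spec.phase
    )
    return Signal(samples, sampling_rate, t0)


def burst_energy(spec: BurstSpec) -> float:
    """Closed-form energy of the packet, envelope-squared integral halved.

    ``int a^2 exp(-t^2/sigma^2) cos^2(...) dt ~= (a^2 / 2) sigma sqrt(pi)``
    (the cos^2 ripple integrates to 1/2 for packets of a few cycles or more).
    """
    sigma = spec.duration * _FWHM_TO_SIGMA
    return 0.5 * spec.amplitude**2 * sigma * np.sqrt(np.pi)


def make_background(
    sampling_rate: float,
    duration: float,
    noise: NoiseSpec = NoiseSpec(),
    rng: np.random.Generator | int | None = None,
    t0: float = 0.0,
) -> Signal:
    """Colored 1/f^exponent noise plus Poisson-scheduled broadband clicks.

    ``noise_power`` is the target variance of the colored component.  Clicks
    are 5 ms white-noise packets with amplitude ``5 x`` the background
    standard deviation (or 1 if the background is silent), emulating
    movement/electrical artifacts that smear across all frequencies.
    """
    rng = np.random.default_rng(rng)
    n = int(round(duration * sampling_rate))
    samples = np.zeros(n)

    if noise.noise_power > 0:
        white = rng.standard_normal(n)
        spectrum = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
        shaping = np.ones_like(freqs)
        nonzero = freqs > 0
        shaping[nonzero] = freqs[nonzero] ** (-noise.one_over_f_exponent / 2.0)
        shaping[0] = 0.0  # no DC drift
        colored = np.fft.irfft(spectrum * shaping, n=n)
        std = colored.std()
        if std > 0:
            colored *= np.sqrt(noise.noise_power) / std
        samples += colored

    if noise.transient_rate > 0:
        n_clicks = rng.poisson(noise.transient_rate * duration)
        click_len = max(1, int(round(_CLICK_DURATION * sampling_rate)))
        gain = _CLICK_GAIN * np.sqrt(noise.noise_power) if noise.noise_power > 0 else 1.0
        for _ in range(n_clicks):
            start = rng.integers(0, max(1, n - click_len))
            samples[start : start + click_len] += gain * rng.standard_normal(click_len)

    return Signal(samples, sampling_rate, t0)


# grating temporal frequency driving the periodic bursting (cycles/s)
_SRCS_BURST_RATE = 1.75
# eeg_like broadband distractor oscillations: frequency range (Hz) and
# Poisson mean count per trial, identical for both classes
_EEG_DISTRACTOR_BAND = (5.0, 55.0)
_EEG_DISTRACTOR_MEAN_COUNT = 6.0


def _class_trials(spec: ProtocolSpec) -> list[int]:
    labels: list[int] = []
    for k, count in enumerate(spec.trial_counts):
        labels.extend([k] * count)
    return labels


def make_dataset(
    spec: ProtocolSpec, seed: int | np.random.Generator | None = 0
) -> tuple[list[Signal], np.ndarray]:
    """Generate one synthetic dataset: (signals, integer class labels).

    The planted effects are:

    * ``rf_like``: class ``k`` gets one burst at band-center frequency with
      latency ``t0 + (k + 0.5) / n_classes * trial_duration``.
    * ``srcs_like``: bursts every ``1 / 1.75`` s with class-dependent onset
      ``(k / n_classes)`` of the burst period.
    * ``eeg_like``: both classes get alpha-band bursts; class 0 ("seen") has
      its burst amplitude scaled by ``sqrt(1 + effect_size)`` so its band
      power is ``(1 + effect_size)`` times that of class 1.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(_class_trials(spec), dtype=int)
    f_center = 0.5 * (spec.band[0] + spec.band[1])
    signals: list[Signal] = []

    for label in labels:
        trace = make_background(
            spec.sampling_rate, spec.trial_duration, spec.noise, rng, t0=spec.t0
        )
        samples = trace.samples.copy()
        if spec.kind == "rf_like":
            latency = spec.t0 + (label + 0.5) / spec.n_classes * spec.trial_duration
            burst = BurstSpec(
                center_time=latency,
                center_freq=f_center,
                n_cycles=6.0,
                amplitude=spec.effect_size,
                phase=rng.uniform(0, 2 * np.pi),
            )
            samples += make_burst(
                burst, spec.sampling_rate, spec.trial_duration, spec.t0
            ).samples
        elif spec.kind == "srcs_like":
            period = 1.0 / _SRCS_BURST_RATE
            onset = spec.t0 + (label / spec.n_classes) * period
            t_burst = onset
            while t_burst < spec.t0 + spec.trial_duration:
                burst = BurstSpec(
                    center_time=t_burst,
                    center_freq=f_center,
                    n_cycles=6.0,
                    amplitude=spec.effect_size,
                    phase=rng.uniform(0, 2 * np.pi),
                )
                samples += make_burst(
                    burst, spec.sampling_rate, spec.trial_duration, spec.t0
                ).samples
                t_burst += period
        elif spec.kind == "eeg_like":
            # baseline amplitude keeps packets visible above the 1/f noise
            base_amp = 2.0 * np.sqrt(spec.noise.noise_power) if spec.noise.noise_power > 0 else 1.0
            # class-independent broadband "distractor" oscillations: without
            # them the per-sample z-scoring done downstream would relocate the
            # class contrast into the quiet high-frequency rows
            f_hi = min(_EEG_DISTRACTOR_BAND[1], 0.45 * spec.sampling_rate)
            for _ in range(rng.poisson(_EEG_DISTRACTOR_MEAN_COUNT)):
                distractor = BurstSpec(
                    center_time=spec.t0 + spec.trial_duration * rng.uniform(0.1, 0.9),
                    center_freq=rng.uniform(_EEG_DISTRACTOR_BAND[0], f_hi),
                    n_cycles=4.0,
                    amplitude=base_amp * rng.uniform(0.5, 1.5),
                    phase=rng.uniform(0, 2 * np.pi),
                )
                samples += make_burst(
                    distractor, spec.sampling_rate, spec.trial_duration, spec.t0
                ).samples
            # the class effect: one packet in the effect band whose power is
            # (1 + effect_size) times larger for class 0 ("seen")
            amp = base_amp * (np.sqrt(1.0 + spec.effect_size) if label == 0 else 1.0)
            burst = BurstSpec(
                center_time=spec.t0 + spec.trial_duration * rng.uniform(0.3, 0.7),
                center_freq=rng.uniform(*spec.band),
                n_cycles=4.0,
                amplitude=amp,
                phase=rng.uniform(0, 2 * np.pi),
            )
            samples += make_burst(
                burst, spec.sampling_rate, spec.trial_duration, spec.t0
            ).samples
        signals.append(Signal(samples, spec.sampling_rate, spec.t0))

    return signals, labels
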