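"""Synthetic two-channel motor-imagery EEG trials with controllable ERD/ERS.

During unilateral hand motor imagery, the mu rhythm (8-12 Hz) over the
contralateral sensorimotor cortex attenuates (event-related
desynchronization, ERD) while the beta rhythm (12-25 Hz) over the
ipsilateral cortex strengthens (event-related synchronization, ERS).  The
generator emulates a two-class (left-hand vs right-hand) protocol recorded
from the C3/C4 electrode pair: each 7 s trial carries 1/f background noise
plus narrowband mu and beta oscillations whose amplitudes are modulated,
class-dependently, inside a 3.5 s imagery window.

Channel/handedness convention (standard 10-20 physiology): C3 sits over the
left hemisphere and is contralateral to RIGHT-hand imagery; C4 is
contralateral to LEFT-hand imagery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

LABELS = ("left", "right")
CHANNELS = ("C3", "C4")

#: default analysis bands, Hz
MU_BAND = (8.0, 12.0)
BETA_BAND = (12.0, 25.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic motor-imagery trial generator.

    Amplitudes are RMS values in arbitrary microvolt-scaled units.
    ``erd_depth`` is the fractional mu-amplitude reduction applied to the
    channel contralateral to the imagined hand inside the imagery window;
    ``ers_gain`` is the fractional beta-amplitude increase on the
    ipsilateral channel.
    """

    sampling_rate_hz: float = 100.0
    trial_duration_s: float = 7.0
    imagery_onset_s: float = 1.5
    imagery_duration_s: float = 3.5
    mu_band_hz: tuple[float, float] = MU_BAND
    beta_band_hz: tuple[float, float] = BETA_BAND
    mu_base_amplitude: float = 1.0
    beta_base_amplitude: float = 0.7
    erd_depth: float = 0.5
    ers_gain: float = 0.5
    noise_amplitude: float = 1.0
    seed: int = 0
    oscillation_mode: str = "narrowband"  # "narrowband" | "sinusoid"
    ramp_s: float = 0.1

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0 or self.trial_duration_s <= 0:
            raise ValueError("sampling rate and trial duration must be positive")
        if self.imagery_onset_s < 0 or self.imagery_duration_s < 0:
            raise ValueError("imagery window must be nonnegative")
        if self.imagery_onset_s + self.imagery_duration_s > self.trial_duration_s + 1e-12:
            raise ValueError("imagery window must lie inside the trial")
        nyq = self.sampling_rate_hz / 2.0
        for name in ("mu_band_hz", "beta_band_hz"):
            low, high = getattr(self, name)
            if not (0.0 < low < high < nyq):
                raise ValueError(f"{name}=({low}, {high}) must satisfy 0 < low < high < Nyquist")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        if self.ers_gain < 0 or self.noise_amplitude < 0:
            raise ValueError("ers_gain and noise_amplitude must be nonnegative")
        if self.mu_base_amplitude < 0 or self.beta_base_amplitude < 0:
            raise ValueError("base amplitudes must be nonnegative")
        if self.oscillation_mode not in ("narrowband", "sinusoid"):
            raise ValueError("oscillation_mode must be 'narrowband' or 'sinusoid'")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration_s * self.sampling_rate_hz))

    @property
    def imagery_window(self) -> tuple[float, float]:
        """(start_s, duration_s) of the imagery period."""
        return (self.imagery_onset_s, self.imagery_duration_s)


@dataclass(frozen=True)
class Trial:
    """One labelled two-channel EEG trial; rows are C3 then C4."""

    samples: np.ndarray
    label: str
    channel_names: tuple[str, str] = CHANNELS

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if s.ndim != 2 or s.shape[0] != 2:
            raise ValueError("samples must be a [2 x n_samples] matrix")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class TrialSet:
    """Ordered collection of equally sized trials plus the generating config."""

    trials: tuple[Trial, ...]
    config: GeneratorConfig

    def __post_init__(self) -> None:
        trials = tuple(self.trials)
        object.__setattr__(self, "trials", trials)
        if trials:
            n = trials[0].n_samples
            if any(t.n_samples != n for t in trials):
                raise ValueError("all trials must share the same length")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def labels(self) -> np.ndarray:
        """Integer labels, 0 = left, 1 = right."""
        return np.array([LABELS.index(t.label) for t in self.trials], dtype=int)

    def to_array(self) -> np.ndarray:
        """Stack trials into an [n_trials x 2 x n_samples] array."""
        return np.stack([t.samples for t in self.trials], axis=0)

    def crop(self, start_s: float, duration_s: float) -> "TrialSet":
        """Extract a time slice [start, start+duration) from every trial."""
        fs = self.config.sampling_rate_hz
        i0 = int(round(start_s * fs))
        i1 = int(round((start_s + duration_s) * fs))
        if i0 < 0 or i1 > self.config.n_samples or i1 <= i0:
            raise ValueError("crop window must lie inside the trial")
        onset, dur = self.config.imagery_onset_s, self.config.imagery_duration_s
        new_onset = min(max(onset - start_s, 0.0), duration_s)
        new_off = min(max(onset + dur - start_s, 0.0), duration_s)
        cfg = dataclasses.replace(
            self.config,
            trial_duration_s=duration_s,
            imagery_onset_s=new_onset,
            imagery_duration_s=new_off - new_onset,
        )
        trials = tuple(
            Trial(samples=t.samples[:, i0:i1], label=t.label) for t in self.trials
        )
        return TrialSet(trials=trials, config=cfg)


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def _pink_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped Gaussian noise with unit RMS (spectrum flat below 1 Hz)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec /= np.sqrt(np.maximum(freqs, 1.0))
    x = np.fft.irfft(spec, n)
    return x / _rms(x)


def _narrowband(n: int, fs: float, band: tuple[float, float], mode: str,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS oscillatory process confined to ``band``.

    ``narrowband`` mode band-pass filters white noise (realistic variance
    structure for CSP); ``sinusoid`` mode emits a random-phase sinusoid at
    the band centre (analytically tractable, used by the oracle tests).
    """
    if mode == "sinusoid":
        f_c = 0.5 * (band[0] + band[1])
        phase = rng.uniform(0.0, 2.0 * np.pi)
        t = np.arange(n) / fs
        return np.sqrt(2.0) * np.cos(2.0 * np.pi * f_c * t + phase)
    white = rng.standard_normal(n)
    sos = sps.butter(2, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    return x / _rms(x)


def _modulation_envelope(config: GeneratorConfig, factor: float) -> np.ndarray:
    """Amplitude envelope: 1 outside the imagery window, ``factor`` inside.

    Raised-cosine ramps of length ``ramp_s`` sit just OUTSIDE the window, so
    that inside [onset, onset+duration) the envelope equals ``factor``
    exactly.
    """
    fs = config.sampling_rate_hz
    n = config.n_samples
    t = np.arange(n) / fs
    onset, offset = config.imagery_onset_s, config.imagery_onset_s + config.imagery_duration_s
    ramp = config.ramp_s
    w = np.zeros(n)
    w[(t >= onset) & (t < offset)] = 1.0
    if ramp > 0:
        rise = (t >= onset - ramp) & (t < onset)
        w[rise] = 0.5 * (1.0 - np.cos(np.pi * (t[rise] - (onset - ramp)) / ramp))
        fall = (t >= offset) & (t < offset + ramp)
        w[fall] = 0.5 * (1.0 + np.cos(np.pi * (t[fall] - offset) / ramp))
    return 1.0 + (factor - 1.0) * w


def generate_trial(config: GeneratorConfig, label: str,
                   rng: np.random.Generator) -> Trial:
    """Generate one labelled trial.

    Each channel is the sum of 1/f background noise and mu/beta narrowband
    oscillations.  Inside the imagery window the mu amplitude of the
    channel contralateral to the imagined hand is scaled by
    ``1 - erd_depth`` (ERD) and the beta amplitude of the ipsilateral
    channel by ``1 + ers_gain`` (ERS).
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")
    n, fs = config.n_samples, config.sampling_rate_hz
    erd_env = _modulation_envelope(config, 1.0 - config.erd_depth)
    ers_env = _modulation_envelope(config, 1.0 + config.ers_gain)
    flat = np.ones(n)

    # C3 is contralateral to right-hand imagery, C4 to left-hand imagery.
    contralateral = "C3" if label == "right" else "C4"
    channels = []
    for name in CHANNELS:
        noise = _pink_noise(n, fs, rng) * config.noise_amplitude
        mu = _narrowband(n, fs, config.mu_band_hz, config.oscillation_mode, rng)
        beta = _narrowband(n, fs, config.beta_band_hz, config.oscillation_mode, rng)
        mu_env = erd_env if name == contralateral else flat
        beta_env = ers_env if name != contralateral else flat
        channels.append(
            noise
            + config.mu_base_amplitude * mu_env * mu
            + config.beta_base_amplitude * beta_env * beta
        )
    return Trial(samples=np.stack(channels, axis=0), label=label)


def generate_dataset(config: GeneratorConfig, n_per_class: int) -> TrialSet:
    """Generate a balanced TrialSet of ``2 * n_per_class`` trials.

    Fully reproducible from ``config.seed``: the same config yields
    bit-identical sample arrays.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(config.seed)
    trials = []
    for _ in range(n_per_class):
        for label in LABELS:
            trials.append(generate_trial(config, label, rng))
    return TrialSet(trials=tuple(trials), config=config)


def band_power(signal: np.ndarray, sampling_rate_hz: float,
               band: tuple[float, float]) -> float:
    """Power of ``signal`` within ``band``, by periodogram integration.

    Uses a boxcar periodogram with per-bin power scaling, summed over bins
    inside [low, high]; a unit-amplitude sinusoid at an exact bin frequency
    yields A^2/2 = 0.5.  Linear in squared amplitude.
    """
    low, high = band
    nyq = sampling_rate_hz / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) must lie inside (0, Nyquist={nyq})")
    freqs, power = sps.periodogram(
        np.asarray(signal, dtype=float), fs=sampling_rate_hz,
        window="boxcar", scaling="spectrum",
    )
    mask = (freqs >= low) & (freqs <= high)
    return float(np.sum(power[mask]))
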