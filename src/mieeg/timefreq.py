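"""Time-frequency preprocessing: STFT spectrograms and Morlet-wavelet scalograms.

Two alternative front ends turn a two-channel trial into a
frequency x time x channel feature tensor:

* a short-time Fourier transform with a 0.5 s Hamming window, hop 10
  samples and transform length 64, which on a 3.5 s imagery segment at
  100 Hz yields the canonical 33 x 35 x 2 tensor;
* a continuous wavelet transform with the real Morlet-like mother wavelet
  ``psi(x) = exp(-x^2) * cos(pi * sqrt(2/ln 2) * x)`` over 35 log-spaced
  scales covering pseudo-frequencies 4-40 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synth import CHANNELS, Trial

#: angular centre frequency of the Morlet-like mother wavelet, rad/s
MORLET_OMEGA0 = np.pi * np.sqrt(2.0 / np.log(2.0))

DEFAULT_WINDOW_S = 0.5
DEFAULT_HOP = 10
DEFAULT_NFFT = 64


@dataclass(frozen=True)
class Spectrogram:
    """Magnitude STFT |S(f, k)| of one channel."""

    magnitudes: np.ndarray  # [n_freq_bins x n_time_windows]
    freqs_hz: np.ndarray
    times_s: np.ndarray
    window_length_s: float
    hop_samples: int
    transform_length: int


@dataclass(frozen=True)
class Scalogram:
    """Real CWT coefficients W(a, b); one row per scale, one column per shift."""

    coefficients: np.ndarray  # [n_scales x n_samples]
    scales: np.ndarray  # scale a, in samples
    pseudo_freqs_hz: np.ndarray


@dataclass(frozen=True)
class WaveletMoments:
    """Time/frequency localization moments of a mother wavelet.

    ``center_time`` and ``time_span`` are the mean and RMS spread of
    |psi(t)|^2; ``center_frequency`` and ``bandwidth`` the analogous moments
    of |Psi(omega)|^2 restricted to omega >= 0 (for a real wavelet the
    two-sided first moment vanishes identically, so the one-sided domain is
    the only one that yields a meaningful centre frequency).
    """

    center_time: float
    time_span: float
    center_frequency: float  # rad/s
    bandwidth: float  # rad/s
    omega: np.ndarray  # one-sided frequency grid used for the moments
    spectrum: np.ndarray  # |Psi(omega)| on that grid


@dataclass(frozen=True)
class FeatureTensor:
    """Frequency x time x channel array produced by STFT or CWT preprocessing."""

    values: np.ndarray  # [n_rows x n_cols x 2]
    row_values: np.ndarray
    row_kind: str  # "frequency_hz" | "scale"
    col_values: np.ndarray
    channel_names: tuple[str, str] = CHANNELS
    pseudo_freqs_hz: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 3 or v.shape[2] != 2:
            raise ValueError("feature tensor must be [rows x cols x 2]")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature tensor contains non-finite values")


def stft(signal: np.ndarray, sampling_rate_hz: float,
         window_length_s: float = DEFAULT_WINDOW_S,
         hop_samples: int = DEFAULT_HOP,
         transform_length: int = DEFAULT_NFFT) -> Spectrogram:
    """Magnitude spectrogram on centred, edge-zero-padded frames.

    Frame ``k`` is centred at sample ``k * hop_samples``; the frame is
    multiplied by a Hamming window of ``window_length_s`` seconds and
    zero-padded to ``transform_length`` before the DFT.  With 3.5 s of
    100 Hz signal and the defaults this yields 33 bins x 35 frames.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    win_len = int(round(window_length_s * sampling_rate_hz))
    if win_len < 1 or x.size < win_len:
        raise ValueError("signal shorter than one analysis window")
    if win_len > transform_length:
        raise ValueError("window length must not exceed transform_length")
    if hop_samples < 1:
        raise ValueError("hop_samples must be >= 1")

    window = np.hamming(win_len)
    n = x.size
    n_frames = int(np.ceil(n / hop_samples))
    half = win_len // 2
    frames = np.zeros((n_frames, win_len))
    for k in range(n_frames):
        start = k * hop_samples - half
        lo, hi = max(start, 0), min(start + win_len, n)
        frames[k, lo - start:hi - start] = x[lo:hi]
    spec = np.abs(np.fft.rfft(frames * window, n=transform_length, axis=1)).T
    freqs = np.fft.rfftfreq(transform_length, d=1.0 / sampling_rate_hz)
    times = np.arange(n_frames) * hop_samples / sampling_rate_hz
    return Spectrogram(
        magnitudes=spec, freqs_hz=freqs, times_s=times,
        window_length_s=window_length_s, hop_samples=hop_samples,
        transform_length=transform_length,
    )


def _imagery_segment(trial: Trial, sampling_rate_hz: float,
                     imagery_window: tuple[float, float]) -> np.ndarray:
    start_s, duration_s = imagery_window
    i0 = int(round(start_s * sampling_rate_hz))
    i1 = int(round((start_s + duration_s) * sampling_rate_hz))
    if i0 < 0 or i1 > trial.n_samples or i1 <= i0:
        raise ValueError("imagery window must lie inside the trial")
    return trial.samples[:, i0:i1]


def stft_feature_tensor(trial: Trial, sampling_rate_hz: float = 100.0,
                        imagery_window: tuple[float, float] = (1.5, 3.5),
                        window_length_s: float = DEFAULT_WINDOW_S,
                        hop_samples: int = DEFAULT_HOP,
                        transform_length: int = DEFAULT_NFFT) -> FeatureTensor:
    """Stack per-channel spectrograms of the imagery segment into [33 x 35 x 2]."""
    segment = _imagery_segment(trial, sampling_rate_hz, imagery_window)
    specs = [
        stft(segment[ch], sampling_rate_hz, window_length_s, hop_samples,
             transform_length)
        for ch in range(2)
    ]
    values = np.stack([s.magnitudes for s in specs], axis=-1)
    return FeatureTensor(
        values=values, row_values=specs[0].freqs_hz, row_kind="frequency_hz",
        col_values=specs[0].times_s,
    )


def morlet_mother(x: np.ndarray | float) -> np.ndarray | float:
    """Real Morlet-like mother wavelet exp(-x^2) * cos(pi*sqrt(2/ln 2)*x)."""
    x = np.asarray(x, dtype=float)
    out = np.exp(-x ** 2) * np.cos(MORLET_OMEGA0 * x)
    return out if out.ndim else float(out)


def wavelet_moments(psi=morlet_mother, x_max: float = 8.0,
                    dx: float = 1.0 / 512.0) -> WaveletMoments:
    """Centre time, time span, centre frequency and bandwidth of a wavelet.

    Time moments by trapezoidal quadrature of |psi(t)|^2 on a symmetric
    grid; frequency moments from the numerically evaluated spectrum
    |Psi(omega)| restricted to omega >= 0.
    """
    x = np.arange(-x_max, x_max + dx / 2, dx)
    p = np.asarray(psi(x), dtype=float)
    if max(abs(p[0]), abs(p[-1])) >= 1e-8:
        raise ValueError("grid too narrow: |psi| at the boundary must be < 1e-8")
    p2 = p ** 2
    norm = np.trapezoid(p2, x)
    t0 = np.trapezoid(x * p2, x) / norm
    time_span = float(np.sqrt(np.trapezoid((x - t0) ** 2 * p2, x) / norm))

    spectrum = np.abs(np.fft.rfft(p)) * dx  # |Psi(omega)|, phase irrelevant
    omega = 2.0 * np.pi * np.fft.rfftfreq(p.size, d=dx)
    q = spectrum ** 2
    qnorm = np.trapezoid(q, omega)
    w0 = float(np.trapezoid(omega * q, omega) / qnorm)
    bandwidth = float(np.sqrt(np.trapezoid((omega - w0) ** 2 * q, omega) / qnorm))
    return WaveletMoments(
        center_time=float(t0), time_span=time_span, center_frequency=w0,
        bandwidth=bandwidth, omega=omega, spectrum=spectrum,
    )


def cwt(signal: np.ndarray, sampling_rate_hz: float,
        scales: np.ndarray) -> Scalogram:
    """Continuous wavelet transform W(a, b) on the sample grid.

    ``W(a, b) = sum_n x[n] * psi((n - b) / a) / sqrt(a)`` with one shift b
    per sample and scales ``a`` expressed in samples.  Computed by FFT
    convolution with the full (untruncated) wavelet kernel, so it agrees
    with the literal double sum to round-off.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a nonempty vector")
    a = np.asarray(scales, dtype=float)
    if np.any(a <= 0):
        raise ValueError("scales must be strictly positive")
    n = x.size
    offsets = np.arange(-(n - 1), n)  # full kernel support: exact equality
    coeffs = np.empty((a.size, n))
    for i, scale in enumerate(a):
        kernel = morlet_mother(offsets / scale) / np.sqrt(scale)
        coeffs[i] = sps.fftconvolve(x, kernel, mode="same")
    pseudo = MORLET_OMEGA0 * sampling_rate_hz / (2.0 * np.pi * a)
    return Scalogram(coefficients=coeffs, scales=a, pseudo_freqs_hz=pseudo)


def scales_for_freqs(freqs_hz: np.ndarray, sampling_rate_hz: float) -> np.ndarray:
    """Scales (in samples) whose pseudo-frequency equals ``freqs_hz``."""
    f = np.asarray(freqs_hz, dtype=float)
    return MORLET_OMEGA0 * sampling_rate_hz / (2.0 * np.pi * f)


def cwt_feature_tensor(trial: Trial, sampling_rate_hz: float = 100.0,
                       n_scales: int = 35,
                       freq_range_hz: tuple[float, float] = (4.0, 40.0)
                       ) -> FeatureTensor:
    """Stack per-channel scalograms into [n_scales x n_samples x 2].

    Scales are log-spaced so their pseudo-frequencies cover
    ``freq_range_hz`` (descending frequency = ascending scale).
    """
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    freqs = np.geomspace(freq_range_hz[1], freq_range_hz[0], n_scales)
    scales = scales_for_freqs(freqs, sampling_rate_hz)
    grams = [cwt(trial.samples[ch], sampling_rate_hz, scales) for ch in range(2)]
    values = np.stack([g.coefficients for g in grams], axis=-1)
    return FeatureTensor(
        values=values, row_values=scales, row_kind="scale",
        col_values=np.arange(trial.n_samples) / sampling_rate_hz,
        pseudo_freqs_hz=grams[0].pseudo_freqs_hz,
    )
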