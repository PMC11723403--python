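"""Short-time Fourier analysis of the complex baseband signal.

The spectrogram is the first stage of both estimation chains.  Because the
input is complex (I/Q), the spectrum is two-sided: positive frequencies
carry the closing (approaching) motion, negative frequencies the opening
motion.  Bins are scaled to a power spectral density so that integrating
|X|² over a frequency band approximates the signal power in that band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fft, fftfreq, fftshift
from scipy.signal import butter, filtfilt, get_window

from .types import BasebandSignal


@dataclass
class STFTParams:
    """STFT analysis parameters.

    Defaults: 40 ms Hann window, 10 ms hop, 4x zero padding — 6.25 Hz bin
    spacing at 5 kHz, resolving the 50 Hz lower band edge while following
    sub-tap dynamics.
    """

    window_length: float = 0.040   # s
    hop: float = 0.010             # s
    window_shape: str = "hann"
    zero_padding: int = 4          # fft_length = zero_padding * window samples

    def __post_init__(self) -> None:
        if not 0 < self.hop <= self.window_length:
            raise ValueError("need 0 < hop <= window_length")
        if self.zero_padding < 1:
            raise ValueError("zero_padding must be >= 1")

    def window_samples(self, sample_rate: float) -> int:
        return int(round(self.window_length * sample_rate))

    def hop_samples(self, sample_rate: float) -> int:
        return max(int(round(self.hop * sample_rate)), 1)

    def fft_length(self, sample_rate: float) -> int:
        return self.zero_padding * self.window_samples(sample_rate)


@dataclass
class Spectrogram:
    """Complex STFT matrix indexed (frame, signed frequency).

    ``freqs`` is strictly increasing and spans [-fs/2, fs/2); ``times``
    are window-center instants.  |X|² has density (power per Hz) scaling.
    """

    X: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    params: STFTParams
    sample_rate: float

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.times), len(self.freqs)):
            raise ValueError("X shape inconsistent with times/freqs")
        if not (np.any(self.freqs < 0) and np.any(self.freqs > 0)):
            raise ValueError("two-sided spectrum expected (complex input)")

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.X) ** 2


def compute_spectrogram(signal: BasebandSignal, params: STFTParams | None = None) -> Spectrogram:
    """Two-sided PSD-scaled STFT of a baseband record.

    Frames are fully contained in the signal (no edge padding); the frame
    time is the center of its window.  With the chosen scaling,
    ``sum(|X[t,f]|^2) * df`` equals the Hann-weighted signal power of the
    frame (discrete Parseval), so band integrals approximate band power.
    """
    params = params or STFTParams()
    fs = signal.sample_rate
    L = params.window_samples(fs)
    H = params.hop_samples(fs)
    N = params.fft_length(fs)
    x = signal.samples
    if len(x) < L:
        raise ValueError(f"signal shorter than one window ({len(x)} < {L} samples)")

    w = get_window(params.window_shape, L)
    scale = 1.0 / np.sqrt(fs * np.sum(w ** 2))
    n_frames = (len(x) - L) // H + 1
    frames = np.lib.stride_tricks.sliding_window_view(x, L)[::H][:n_frames]
    X = fftshift(fft(frames * w, n=N, axis=1), axes=1) * scale
    freqs = fftshift(fftfreq(N, 1.0 / fs))
    times = signal.start_time + (np.arange(n_frames) * H + (L - 1) / 2.0) / fs
    return Spectrogram(X=X, times=times, freqs=freqs, params=params, sample_rate=fs)


def to_db(spec: Spectrogram, floor_db: float = -120.0) -> np.ndarray:
    """Spectrogram magnitude in dB, 10·log10(|X|²), floored at ``floor_db``."""
    p = spec.power
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(p)
    return np.maximum(db, floor_db)


def suppress_stationary(signal: BasebandSignal, cutoff_hz: float = 25.0,
                        order: int = 4) -> BasebandSignal:
    """High-pass the complex baseband to reject the stationary return.

    The stationary hand and carrier leakage form a strong near-0 Hz tone
    whose window sidelobes would otherwise leak into the analysis band; a
    zero-phase Butterworth high-pass (applied to I and Q independently,
    so both frequency signs are attenuated symmetrically) removes it.
    The cutoff must stay below the analysis band (default 25 Hz for the
    [50, 500] Hz band).
    """
    if cutoff_hz <= 0:
        return signal
    nyq = signal.sample_rate / 2.0
    if cutoff_hz >= nyq:
        raise ValueError("cutoff must be below Nyquist")
    b, a = butter(order, cutoff_hz / nyq, btype="highpass")
    x = signal.samples
    y = filtfilt(b, a, x.real) + 1j * filtfilt(b, a, x.imag)
    return BasebandSignal(y, signal.sample_rate, signal.start_time)
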