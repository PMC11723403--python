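"""Core signal container shared by the simulator and the analysis chain."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class BasebandSignal:
    """Uniformly sampled complex (I + jQ) demodulated baseband record.

    The in-phase/quadrature pair preserves the sign of the Doppler shift:
    positive instantaneous frequency means the scatterer approaches the
    sensor, negative means it recedes.

    Parameters
    ----------
    samples : ndarray of complex
        I + jQ samples, arbitrary amplitude units.
    sample_rate : float
        Sampling frequency in Hz.
    start_time : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    sample_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples.view(np.float64))):
            raise ValueError("samples contain non-finite values")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return len(self.samples) / self.sample_rate

    def times(self) -> np.ndarray:
        """Sample instants in seconds."""
        return self.start_time + np.arange(len(self.samples)) / self.sample_rate

    def shifted(self, dt: float) -> "BasebandSignal":
        """Same samples with the time origin moved by ``dt`` seconds."""
        return BasebandSignal(self.samples.copy(), self.sample_rate, self.start_time + dt)
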