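"""Tap-rate estimation: band power, smoothing, peak detection, statistics.

The closing stroke of every tap concentrates energy at positive Doppler
frequencies; integrating the spectrogram over the positive [50, 500] Hz
band yields a power envelope P(t) with one burst per tap.  Peaks of the
smoothed, normalized envelope mark the instants of maximum closing
radial velocity; reciprocal inter-tap delays give the instantaneous rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .tfa import Spectrogram


@dataclass
class DetectionConfig:
    """Band-power and peak-detection parameters.

    ``band`` is positive-frequency only (closing phase).  The smoothing
    window suppresses residual low-velocity (thumb) ripple; the peak
    spacing bound (120 ms ⇒ at most ~8 taps/s) and prominence floor come
    from physiological tapping limits.
    """

    band: tuple[float, float] = (50.0, 500.0)
    smooth_window: float = 0.040      # s
    min_peak_distance: float = 0.120  # s
    min_prominence: float = 0.10      # fraction of max normalized power
    min_burst_ratio: float = 3.0      # peak-to-median envelope ratio for activity

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("need 0 < band_low < band_high")
        if self.smooth_window <= 0 or self.min_peak_distance <= 0:
            raise ValueError("windows must be positive")


@dataclass
class PowerSeries:
    """Band power P(t) sampled at the spectrogram frame times."""

    times: np.ndarray
    P: np.ndarray
    normalized: bool = False
    frame_hop: float = 0.010  # s, spacing of the frame grid

    def __post_init__(self) -> None:
        if len(self.times) != len(self.P):
            raise ValueError("times and P must have the same length")
        if np.any(self.P < 0):
            raise ValueError("band power must be non-negative")


@dataclass
class TapSeries:
    """Detected tap instants with inter-tap delays and instantaneous rates.

    The rate of each tap pair is assigned to the *later* tap for plotting.
    """

    tap_times: np.ndarray
    inter_tap_delays: np.ndarray = field(default=None)  # type: ignore[assignment]
    instantaneous_rates: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.tap_times = np.asarray(self.tap_times, dtype=float)
        if np.any(np.diff(self.tap_times) <= 0):
            raise ValueError("tap times must be strictly increasing")
        if self.inter_tap_delays is None:
            self.inter_tap_delays = np.diff(self.tap_times)
        if self.instantaneous_rates is None:
            with np.errstate(divide="ignore"):
                self.instantaneous_rates = 1.0 / self.inter_tap_delays

    @property
    def n_taps(self) -> int:
        return len(self.tap_times)


@dataclass
class RateStats:
    """Summary statistics of the instantaneous tap rate.

    Both variance flavors are reported: the variance of the rates
    ((taps/s)²) and the variance of the inter-tap intervals (s²).
    Undefined statistics (too few taps) are NaN.
    """

    median_rate: float
    rate_variance: float
    interval_variance: float
    n_taps: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.median_rate)


def band_power(spec: Spectrogram, band: tuple[float, float] = (50.0, 500.0)) -> PowerSeries:
    """Per-frame trapezoidal integral of |X(t,f)|² over f ∈ [band_low, band_high].

    The band must be strictly positive: only the closing (approaching)
    phase contributes, which is what makes the envelope single-peaked per
    tap.
    """
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError("need 0 < band_low < band_high (positive-frequency band)")
    if hi > spec.freqs[-1]:
        raise ValueError("band exceeds the spectrogram frequency range")
    m = (spec.freqs >= lo) & (spec.freqs <= hi)
    if m.sum() < 2:
        raise ValueError("band covers fewer than two frequency bins")
    P = np.maximum(np.trapezoid(spec.power[:, m], spec.freqs[m], axis=1), 0.0)
    hop = float(np.median(np.diff(spec.times))) if len(spec.times) > 1 else spec.params.hop
    return PowerSeries(times=spec.times.copy(), P=P, normalized=False, frame_hop=hop)


def smooth_and_normalize(p: PowerSeries, cfg: DetectionConfig | None = None) -> PowerSeries:
    """Moving-average smoothing followed by division by the maximum.

    Smoothing removes residual ripple (e.g. thumb leakage) from the
    envelope; normalization makes the prominence threshold a fraction of
    the strongest tap.  An all-zero series is returned unchanged with a
    "no activity" warning.
    """
    cfg = cfg or DetectionConfig()
    if len(p.P) == 0:
        raise ValueError("empty power series")
    k = max(int(round(cfg.smooth_window / p.frame_hop)), 1)
    sm = np.maximum(uniform_filter1d(p.P, size=k, mode="nearest"), 0.0)
    peak = sm.max()
    if peak <= 0:
        warnings.warn("band power is identically zero: no activity in band")
        return PowerSeries(p.times.copy(), sm, normalized=True, frame_hop=p.frame_hop)
    return PowerSeries(p.times.copy(), sm / peak, normalized=True, frame_hop=p.frame_hop)


def detect_taps(p: PowerSeries, cfg: DetectionConfig | None = None) -> TapSeries:
    """Peak detection on the normalized power envelope.

    Local maxima with prominence ≥ ``min_prominence`` and pairwise spacing
    ≥ ``min_peak_distance`` are taps; of two closer candidates the larger
    survives.  The envelope is zero-padded at both ends so taps adjacent
    to the record boundaries remain detectable.  Fewer than two peaks
    yield an empty rate series.
    """
    cfg = cfg or DetectionConfig()
    if not p.normalized:
        raise ValueError("detect_taps expects a normalized PowerSeries")
    # tapping produces bursts: the envelope peak towers over its median.
    # A flat envelope (pure noise, or no motion in band) has no taps.
    baseline = float(np.median(p.P))
    if baseline > 0 and 1.0 / baseline < cfg.min_burst_ratio:
        warnings.warn("no burst activity in band: envelope is flat, 0 taps")
        return TapSeries(np.array([]), np.array([]), np.array([]))
    dist = max(int(round(cfg.min_peak_distance / p.frame_hop)), 1)
    padded = np.concatenate([[0.0], p.P, [0.0]])
    idx, _ = find_peaks(padded, prominence=cfg.min_prominence, distance=dist)
    idx = idx - 1
    tap_times = p.times[idx]
    if len(tap_times) < 2:
        warnings.warn(f"only {len(tap_times)} tap(s) detected: rate undefined")
        return TapSeries(tap_times, np.array([]), np.array([]))
    return TapSeries(tap_times)


def rate_stats(taps: TapSeries) -> RateStats:
    """Median rate and sample variances (ddof=1) of rates and intervals."""
    rates = np.asarray(taps.instantaneous_rates, dtype=float)
    delays = np.asarray(taps.inter_tap_delays, dtype=float)
    median = float(np.median(rates)) if len(rates) >= 1 else float("nan")
    rate_var = float(np.var(rates, ddof=1)) if len(rates) >= 2 else float("nan")
    int_var = float(np.var(delays, ddof=1)) if len(delays) >= 2 else float("nan")
    return RateStats(median_rate=median, rate_variance=rate_var,
                     interval_variance=int_var, n_taps=taps.n_taps)
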