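"""Finger-velocity tracking and per-tap displacement estimation.

The index fingertip is both the fastest and the dominant scatterer during
a tap, so its radial velocity is read off the spectrogram as the Doppler
frequency of the dominant in-band component, converted through the
one-way relation v = (c/f0)·fD, and integrated over each closing stroke
to obtain the per-tap radial displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .taprate import TapSeries
from .tfa import Spectrogram


@dataclass
class TrackerConfig:
    """Maximum-Doppler tracking parameters.

    The detection threshold is referenced to the noise floor, estimated
    as the ``noise_floor_quantile`` of bin powers over the signal-free
    ``noise_band``; the per-frame estimates are pooled over the recording
    (median across frames) because the noise is stationary and a single
    frame spans too few independent bins.  ``mode`` selects how the
    Doppler of the finger is read off a frame:

    ``"ridge"`` (default)
        frequency of the strongest in-band component.  The index finger
        dominates the spectrum, and this reading is insensitive to window
        sidelobes and noise excursions above the ridge.
    ``"highest"``
        highest in-band frequency above threshold (upper-envelope
        reading).  Retained for comparison; with long analysis windows it
        overestimates stroke displacement severely because the window
        smears the chirp upward and outward.

    A frame whose in-band argmax falls on the first (lowest) band bin is
    treated as containing no in-band component: a genuine component peaks
    at an interior bin, while leakage from below-band content decays
    monotonically into the band and pins the argmax to the boundary.
    """

    search_band: tuple[float, float] = (50.0, 500.0)
    noise_band: tuple[float, float] = (600.0, 1000.0)
    noise_floor_quantile: float = 0.5
    threshold_db: float = 10.0
    c: float = 343.0
    f0: float = 40_000.0
    mode: str = "ridge"
    hop: float = 0.005  # s, tracking-stage STFT hop (finer than the tap-rate stage)

    def __post_init__(self) -> None:
        if self.threshold_db <= 0:
            raise ValueError("threshold_db must be positive")
        if not 0 < self.noise_floor_quantile < 1:
            raise ValueError("noise_floor_quantile must be in (0, 1)")
        if self.mode not in ("ridge", "highest"):
            raise ValueError("mode must be 'ridge' or 'highest'")
        lo, hi = self.search_band
        nlo, nhi = self.noise_band
        if not (0 < lo < hi and 0 < nlo < nhi):
            raise ValueError("bands must be positive and increasing")
        if hi > nlo:
            raise ValueError("search and noise bands must not overlap")


@dataclass
class IntegrationRule:
    """Per-tap integration-window rule for ``per_tap_displacement``.

    Around each tap the maximal run of frames with defined, positive
    velocity is taken, clipped to the midpoints toward the neighboring
    taps.  Short dropouts (up to ``max_gap`` frames) inside the run are
    bridged and linearly interpolated.  ``rel_power_db`` discards frames
    whose ridge power is that far below the strongest frame of the tap
    window: the echo is constant-modulus while the stroke is in band, so
    much weaker frames contain only window-edge leakage, not the stroke.
    """

    max_gap: int = 2
    rel_power_db: float | None = 8.0


@dataclass
class VelocityTrack:
    """Tracked Doppler frequency and radial velocity per frame.

    ``fD_max`` is NaN where no in-band component exceeds the threshold;
    ``vf = (c/f0)·fD_max`` elementwise.  ``ridge_power`` (optional) is the
    |X|² of the tracked bin, used by the integration-window rule.
    """

    times: np.ndarray
    fD_max: np.ndarray
    vf: np.ndarray
    ridge_power: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.fD_max) == len(self.vf)):
            raise ValueError("times, fD_max and vf must have equal length")

    @property
    def frame_hop(self) -> float:
        return float(np.median(np.diff(self.times)))


@dataclass
class DisplacementSeries:
    """Per-tap radial closing displacements with integration windows."""

    tap_times: np.ndarray
    Di: np.ndarray                 # m, NaN where no velocity was measurable
    integration_windows: list[tuple[float, float]]

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.Di)


@dataclass
class DisplacementStats:
    """Median and sample variance of the valid per-tap displacements."""

    median_displacement: float       # m
    displacement_variance: float     # m²
    n_taps: int

    @property
    def median_cm(self) -> float:
        return self.median_displacement * 100.0

    @property
    def variance_cm2(self) -> float:
        return self.displacement_variance * 1e4

    @property
    def defined(self) -> bool:
        return np.isfinite(self.median_displacement)


def doppler_to_velocity(fD, c: float = 343.0, f0: float = 40_000.0):
    """One-way Doppler-to-velocity conversion v = (c/f0)·fD, sign preserved."""
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    return (c / f0) * np.asarray(fD, dtype=float) if np.ndim(fD) else float((c / f0) * fD)


def track_max_doppler(spec: Spectrogram, cfg: TrackerConfig | None = None) -> VelocityTrack:
    """Per-frame Doppler frequency of the closing-phase finger echo.

    The noise floor is the recording-pooled quantile of the noise-band
    bin powers; a frame counts as containing signal only where the
    selected bin power exceeds ``noise floor × 10^(threshold_db/10)``.
    See ``TrackerConfig.mode`` for the two reading conventions.
    """
    cfg = cfg or TrackerConfig()
    lo, hi = cfg.search_band
    nlo, nhi = cfg.noise_band
    if nhi > spec.freqs[-1] or hi > spec.freqs[-1]:
        raise ValueError("bands exceed the spectrogram frequency range")

    P = spec.power
    noise_sel = (spec.freqs >= nlo) & (spec.freqs <= nhi)
    per_frame_floor = np.quantile(P[:, noise_sel], cfg.noise_floor_quantile, axis=1)
    floor = float(np.median(per_frame_floor))
    threshold = floor * 10.0 ** (cfg.threshold_db / 10.0)

    band_sel = np.nonzero((spec.freqs >= lo) & (spec.freqs <= hi))[0]
    fb = spec.freqs[band_sel]
    Pb = P[:, band_sel]

    n = len(spec.times)
    fD = np.full(n, np.nan)
    pw = np.full(n, np.nan)
    if cfg.mode == "ridge":
        arg = np.argmax(Pb, axis=1)
        peak = Pb[np.arange(n), arg]
        ok = (peak > threshold) & (arg > 0)
        fD[ok] = fb[arg[ok]]
        pw[ok] = peak[ok]
    else:  # highest supra-threshold bin
        above = Pb > threshold
        has = above.any(axis=1)
        idx = Pb.shape[1] - 1 - np.argmax(above[:, ::-1], axis=1)
        fD[has] = fb[idx[has]]
        pw[has] = Pb[np.arange(n), idx][has]

    vf = (cfg.c / cfg.f0) * fD
    return VelocityTrack(times=spec.times.copy(), fD_max=fD, vf=vf, ridge_power=pw)


def per_tap_displacement(track: VelocityTrack, taps: TapSeries,
                         rule: IntegrationRule | None = None) -> DisplacementSeries:
    """Trapezoidal integral of the closing-stroke velocity around each tap.

    For tap i the integration window is the maximal run of frames around
    Ti with defined positive velocity (bridging dropouts up to
    ``rule.max_gap`` frames, linearly interpolated), clipped to the
    midpoints toward the neighboring taps.  A tap with no measurable
    velocity yields NaN, not zero.
    """
    rule = rule or IntegrationRule()
    tt = np.asarray(taps.tap_times, dtype=float)
    if len(tt) == 0:
        return DisplacementSeries(tt, np.array([]), [])
    if tt[0] < track.times[0] - 0.5 or tt[-1] > track.times[-1] + 0.5:
        raise ValueError("velocity track does not cover the tap series")

    hop = track.frame_hop
    times = track.times
    mids = np.concatenate([[times[0]], (tt[1:] + tt[:-1]) / 2.0, [times[-1]]])

    Di = np.full(len(tt), np.nan)
    windows: list[tuple[float, float]] = []
    for i, T in enumerate(tt):
        sel = np.nonzero((times >= mids[i]) & (times <= mids[i + 1]))[0]
        if len(sel) == 0:
            windows.append((T, T))
            continue
        v = track.vf[sel]
        valid = np.isfinite(v) & (v > 0)
        if rule.rel_power_db is not None and track.ridge_power is not None:
            p = track.ridge_power[sel]
            if np.isfinite(p).any():
                pmax = np.nanmax(p)
                valid &= p > pmax * 10.0 ** (-rule.rel_power_db / 10.0)
        if not valid.any():
            windows.append((T, T))
            continue
        ctr = int(np.argmin(np.abs(times[sel] - T)))
        if not valid[ctr]:
            near = np.nonzero(valid)[0]
            cand = near[np.argmin(np.abs(near - ctr))]
            if abs(cand - ctr) > rule.max_gap + 1:
                windows.append((T, T))
                continue
            ctr = int(cand)

        def _extend(pos: int, step: int) -> int:
            while True:
                nxt = pos + step
                if nxt < 0 or nxt >= len(v):
                    return pos
                if valid[nxt]:
                    pos = nxt
                    continue
                # bridge a short dropout only if valid frames resume behind it
                bridged = False
                for g in range(1, rule.max_gap + 1):
                    probe = pos + step * (g + 1)
                    if 0 <= probe < len(v) and valid[probe]:
                        pos = probe
                        bridged = True
                        break
                if not bridged:
                    return pos

        a = _extend(ctr, -1)
        b = _extend(ctr, +1)
        vv = v[a:b + 1].copy()
        hole = ~(np.isfinite(vv) & valid[a:b + 1])
        if hole.all():
            windows.append((T, T))
            continue
        if hole.any():
            good = np.nonzero(~hole)[0]
            vv[hole] = np.interp(np.nonzero(hole)[0], good, vv[good])
        Di[i] = np.trapezoid(vv, dx=hop)
        windows.append((float(times[sel[a]]), float(times[sel[b]])))

    return DisplacementSeries(tap_times=tt, Di=Di, integration_windows=windows)


def displacement_stats(d: DisplacementSeries) -> DisplacementStats:
    """Median and sample variance (ddof=1) over taps with a valid Di."""
    vals = d.Di[d.valid]
    median = float(np.median(vals)) if len(vals) >= 1 else float("nan")
    var = float(np.var(vals, ddof=1)) if len(vals) >= 2 else float("nan")
    return DisplacementStats(median_displacement=median, displacement_variance=var,
                             n_taps=int(len(vals)))
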