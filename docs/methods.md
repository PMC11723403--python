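# Methods

## Measurement model

A continuous-wave sonar emits a monochromatic carrier at f0 = 40 kHz
(wavelength ≈ 8.5 mm in air at c = 343 m/s) toward the tapping hand from a
standoff of ~0.30 m, at roughly 60° to the plane of finger motion. The echo
is I/Q-demodulated against the carrier; a scatterer at radial distance r(t)
then contributes a baseband component

    x(t) ∝ exp(−j·2π·κ·(f0/c)·r(t)),

whose instantaneous frequency is the Doppler shift of its radial velocity.
The sign convention is fixed so that closing (approaching) motion appears at
positive frequencies and opening at negative frequencies. `doppler_factor`
κ selects the Doppler convention: κ = 1 is the one-way relation
fD = v·f0/c that the velocity estimator inverts; κ = 2 is the physical
round-trip relation of a co-located transmit/receive pair. The default is
κ = 1 so that the simulator and the estimator share one convention; the
package deliberately keeps κ = 2 available to *measure* the factor-2
displacement bias that follows from mixing the two conventions, rather than
silently correcting either side (see the acceptance script's
`round_trip_doppler_bias_ratio`).

Finger Doppler shifts stay within ±500 Hz, i.e. radial speeds within
(c/f0)·500 ≈ ±4.3 m/s.

## Synthetic kinematics

The generator models the index fingertip's radial trajectory

    r(t) = standoff + projection · a(t),

where a(t) ≥ 0 is the instantaneous aperture opening and
projection = cos 30° ≈ 0.866 encodes the line-of-sight geometry (a
parameter, since the mounting angle does not uniquely determine it). Each
tap cycle consists of one **ballistic open/close gesture** — a raised-cosine
a(t) = A·(1 − cos 2πξ)/2 over the active fraction of the cycle — followed by
dwell with the fingers closed. Cycle timing follows `rate_profile` (taps/s,
constant or time-varying), optionally modulated by a smooth random
cycle-timing jitter (`timing_jitter`, fractional SD; scenarios use 2%,
matching the small but nonzero variability of a healthy subject tapping
"regularly"). Ground truth per cycle: the tap instant is the moment of peak
closing radial speed (3/4 through the gesture), and the per-tap radial
closing displacement is projection × aperture.

The gesture time (`stroke_duration`, open+close) defaults to 95 ms for a
5 cm aperture and scales as √aperture across scenarios. Rationale: the
band the motion occupies pins down the briskness — with Doppler content
concentrated between 50 and 500 Hz, peak radial speeds must be of order
1 m/s and more (a 50 Hz lower edge corresponds to 0.43 m/s), which for
centimeter apertures implies stroke times well under 200 ms. A slow
sinusoidal open/close at the nominal tap rate would place the entire
signature below the band and is therefore not a faithful model of the
measured gesture. The √A scaling is the usual sub-linear amplitude-duration
coupling of ballistic movements (duration grows much more slowly than
amplitude); it keeps peak radial speeds near 1.0–1.4 m/s for apertures of
2.5–5 cm. A stroke still running when the recording ends is dropped
(`end_margin`), as a subject stops tapping before the operator stops the
recording; `lead_in` inserts the initial idle second fraction.

The channel model adds, to the unit-amplitude index echo: a constant
carrier-leakage DC term (default 0.05), a thumb-clutter component — the
mirrored stroke waveform scaled to a peak radial speed of 0.25 m/s with
amplitude 0.1, emulating the almost-suppressed counter-moving thumb — and
complex white Gaussian noise calibrated to `snr_db` (default 20 dB) against
the index echo power. Optional 16-bit quantization happens at WAV-write
time, matching the acquisition precision.

What the generator does **not** model: acoustic multipath, transducer beam
pattern, amplitude falloff with range, electronics transfer functions,
micro-Doppler from other fingers or the palm, amplitude modulation from the
changing cross-section, or tremor. Recovery results on these synthetics
therefore validate the algorithm chain and its conventions, not the
hardware; field performance on real recordings may be worse in proportion
to how far these effects dominate.

## Time-frequency analysis

STFT with a 40 ms Hann window, 10 ms hop, 4× zero padding (6.25 Hz bin
spacing at 5 kHz). The window resolves the 50 Hz band edge while following
sub-tap dynamics; all parameters are configurable. Bins carry power
spectral density scaling — per frame, Σ_f |X|²·df equals the Hann-weighted
signal power — so band integrals approximate physical band power. dB
conversion floors at −120 dB to avoid log of zero.

**Stationary-clutter rejection.** The stationary hand return plus carrier
leakage form a strong tone at exactly 0 Hz during dwell. The Hann window's
first sidelobe (−31.5 dB, at ±62.5 Hz for a 40 ms window) falls *inside*
the [50, 500] Hz analysis band and above any reasonable detection
threshold, which corrupts maximum-Doppler tracking during dwell. As in any
CW-Doppler system, a moving-target-indication filter removes it: a
zero-phase 4th-order Butterworth high-pass at 25 Hz applied to I and Q
before the STFT (`PipelineConfig.clutter_highpass_hz`; set 0 to disable).
The cutoff must stay below the analysis band.

## Tap-rate chain

Band power (Eq. P(t) above) integrates positive frequencies only, so each
tap contributes a single burst from its closing stroke; the opening stroke
(negative frequencies) and the slow thumb residue (below 50 Hz) are
excluded by construction. The envelope is smoothed by a 40 ms moving
average, normalized to peak 1, and peaks with prominence ≥ 0.10 and spacing
≥ 120 ms (≈ the physiological 8 taps/s ceiling) are taps. The envelope is
zero-padded at its ends so taps adjacent to the record boundary remain
detectable, and a record whose envelope has no burst structure (median
above 1/3 of the peak) is declared tap-free rather than peak-picked —
otherwise normalized noise would always yield spurious "taps". Rates are
reciprocal inter-tap delays, assigned to the later tap of each pair.

Both regularity flavors are reported — variance of the rates ((taps/s)²)
and variance of the intervals (s²) — because the two are not
interchangeable and published summaries are often ambiguous about which is
meant.

## Velocity tracking and displacement

The per-frame finger Doppler f_D,max is read from the [50, 500] Hz band of
the spectrogram. A frame counts as containing signal only where the
selected bin exceeds the noise floor by `threshold_db` (10 dB); the floor
is the median bin power over the signal-free [600, 1000] Hz band, pooled
over the whole recording (the noise is stationary, and a single frame spans
too few independent bins for a stable estimate). Two readings are
implemented (`TrackerConfig.mode`):

- **`ridge`** (default): the frequency of the *strongest* in-band
  component. The geometry makes the index finger dominate the spectrum, so
  the dominant ridge is the finger; this reading is insensitive to window
  sidelobes and to noise excursions above the ridge, and tracks the
  instantaneous frequency at the window center without systematic
  dilation.
- **`highest`**: the highest supra-threshold in-band frequency
  (upper-envelope reading). Conceptually the "fastest scatterer" reading,
  but with a 40 ms window and a high-SNR tone the supra-threshold contour
  sits tens of dB below the ridge: it rides the smear/sidelobe skirt
  (≈ +60 Hz) and morphologically dilates the stroke in time, overestimating
  per-tap displacements by large factors in simulation. It is retained for
  comparison and as documentation of that failure mode, not used by
  default.

A frame whose in-band argmax falls on the first band bin is discarded:
genuine components peak at an interior bin, whereas leakage from below-band
content decays monotonically into the band and pins the argmax to the
boundary.

The tracking stage runs on a finer 5 ms hop (same window) than the
tap-rate stage: a closing stroke spends only a few tens of milliseconds in
band, and the trapezoidal integral needs several samples across it.

Per tap, the integration window is the maximal run of frames with defined,
positive velocity around the tap instant, clipped to the midpoints toward
neighboring taps; dropouts up to 2 frames are bridged by linear
interpolation, and a tap with no measurable velocity yields NaN (missing),
never zero. Frames whose ridge power lies more than 8 dB below the
strongest frame of the tap window are excluded: the echo is
constant-modulus while the stroke is in band, so much weaker frames see
only window-edge leakage of the stroke, not the stroke itself. The run
gate (8 dB), the tracking hop and the boundary-bin rule were set by
parameter-recovery calibration on the synthetic scenarios — they are
estimator internals with no counterpart in the hardware description — and
with the defaults the median per-tap displacement recovers the ground
truth within ~10% across the wide/narrow scenarios (see
`scripts/acceptance.py`).

Displacements are *radial*; no back-projection through the mounting
geometry is applied by default (the projection divisor is available in the
simulator, and dividing reported Di by `projection` converts to motion-axis
displacement if desired). Estimates cover the closing stroke only; under
the kinematic model the opening displacement is redundant.

## Numerical choices and degenerate inputs

- Trapezoidal quadrature for both band power and displacement integrals;
  band powers are clamped at zero against −1e−17-scale roundoff.
- Sample variances use ddof = 1; statistics with too few taps are NaN and
  flagged undefined rather than raising.
- All internal quantities are SI; reports print displacements in cm.
- Reports embed the full configuration snapshot and are byte-reproducible
  from the same input and configuration.
- WAV I/O: channel 0 = I, channel 1 = Q; PCM16 scaled by 2¹⁵; CSV
  timebases must be uniform and strictly increasing (shuffled files are
  rejected, not silently re-sorted).

## Known limitations

- The [50, 500] Hz band makes radial speeds below 0.43 m/s invisible; the
  slow tails of each stroke are unmeasured, so per-tap displacements carry
  a small truncation deficit that partly offsets the smearing surplus.
  Motions that are slow throughout (severe bradykinesia at small
  amplitude) would need a lower band edge and a longer window.
- Displacement accuracy degrades when the stroke's in-band dwell shrinks
  below a few tracking frames (very small and very fast gestures).
- The tracker assumes a single dominant moving scatterer; two fingers
  moving at comparable echo strength would need multi-component tracking.
- Scenario statistics are desk-scale (7 s, ≈ 7–20 taps): variances are
  noisy in the way short clinical recordings are.
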