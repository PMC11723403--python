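# tapsonar

Quantitative analysis of the clinical **finger-tapping test** from a
contactless 40 kHz continuous-wave ultrasound sonar.

In the finger-tapping test a subject repeatedly taps index finger and thumb;
clinicians rate the speed, amplitude and regularity of the movement by eye
when screening for bradykinesia (e.g. in Parkinson's disease). A CW sonar
pointed at the hand measures the same movement physically: the echo of a
monochromatic 40 kHz wave is Doppler-shifted by the moving fingers, and after
I/Q demodulation the baseband signal carries the radial finger velocity as a
signed instantaneous frequency, fD = v·f0/c (closing → positive, opening →
negative). `tapsonar` turns such baseband records into two movement measures:

- **instantaneous tap rate** — the spectrogram band power
  P(t) = ∫₅₀⁵⁰⁰ |X(t,f)|² df peaks once per closing stroke; peak instants Tᵢ
  are the taps and 1/(Tᵢ₊₁ − Tᵢ) the instantaneous rate;
- **per-tap finger displacement** — the finger radial velocity
  v_f(t) = (c/f0)·f_D,max(t) is read off the spectrogram (dominant in-band
  component per frame) and integrated over each closing stroke,
  Dᵢ = ∫ v_f(t) dt.

Because real recordings require the sonar hardware, the package ships a
physics-based **synthetic baseband generator**: ballistic open/close finger
strokes with configurable rate, aperture, line-of-sight projection and
cycle-timing jitter, phase-modulated onto the baseband with carrier leakage,
a weak thumb-clutter component and calibrated Gaussian noise. Every generated
scenario carries its ground truth, so both estimators are validated end to
end by parameter recovery.

## Worked example

Simulate a fast regular tapping acquisition (7 s at 5 kHz, 20 dB SNR,
3 taps/s, 5 cm aperture) and analyze it:

```sh
$ tapsonar simulate --scenario fast_regular --seed 42 -o sig.wav --truth truth.json
wrote sig.wav: fast_regular, 7 s @ 5000 Hz, 20 taps
wrote truth.json
$ tapsonar analyze sig.wav -o report.json --csv taps.csv
wrote report.json: 20 taps, median rate 3.03030303030303 taps/s, median displacement 4.562167968749903 cm
```

The report recovers the simulated ground truth: 20/20 taps detected, median
rate 3.03 taps/s against a true 3.03 taps/s (the generator adds 2% human
timing jitter, so the realized rate is not exactly 3), and a median per-tap
radial displacement of 4.56 cm against a true 4.33 cm (projection
cos 30° × 5 cm aperture), a +5% recovery error. `report.json` also carries
both regularity measures — rate variance 0.0061 (taps/s)² and inter-tap
interval variance 7.6·10⁻⁵ s² — and the per-tap table:

```
time_s,rate_hz,displacement_cm
0.2799,,4.448281
0.5999,3.125,4.475078
0.9399,2.941176,4.394687
```

The same pipeline is available as a library:

```python
import tapsonar as ts

scenario = ts.make_scenario("decreasing_rate", seed=0)   # bradykinesia-like slowing
report = ts.analyze(scenario.signal)
print(report.to_dict()["rate"]["interval_variance_s2"])  # ≈ 0.02, vs ~1e-4 when regular
```

Six named scenarios mirror the study protocol: `fast_regular`,
`slow_regular`, `decreasing_rate` (rate analysis) and `wide_regular`,
`narrow_regular`, `decreasing_aperture` (displacement analysis). Irregular
scenarios separate cleanly from regular ones in both variance measures, and
the wide/narrow median displacements differ by the expected factor of two.

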