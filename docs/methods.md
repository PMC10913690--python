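# Methods

## Signal model and assumptions

The pipeline inverts two-channel PPG intensities under the modified
Beer–Lambert law (MBLL): the absorbance change at wavelength λ is
ΔA(λ,t) = −log₁₀ I(λ,t)/I_ref(λ), and the 2×2 hemoglobin extinction matrix
maps ΔA to the "NIRS signals" N_HbO2, N_Hb = Δ[c·L] (mM·cm), changes in
molar concentration × optical path length relative to a reference instant.
The model treats the path length explicitly as L(t) = L_LF(t) + L_AC(t) with
|L_AC| ≪ L_LF; no differential path-length factor is applied (it would only
rescale both species jointly). Within an analysis window the AC NIRS signals
are sinusoids of common cardiac frequency, the deoxy component lagging by a
small phase delay Δθ; total hemoglobin concentration is constant, so the
concentration pulsations cancel (c_HbO2,AC + c_Hb,AC = 0) and
L_AC = (N_HbO2,AC + N_Hb,AC)/c₀.

Key modeling assumptions, stated once and inherited everywhere:

- StO2 ≈ SaO2 at the measurement site (capillary-rich, shallow penetration).
  This is a site-selection assumption, untestable in software.
- Δθ is small (|Δθ| < π/4; the observed scale is ≲0.25 rad). The small-angle
  step replacing 2·sin(Δθ/2) by Δθ errs by <0.05% at 0.1 rad and <0.4% at
  0.3 rad.
- Amplitudes, heart rate and Δθ vary slowly relative to one beat.

The reference intensity is the per-span mean of each channel. Any positive
constant would do: changing it offsets/rescales ΔA but leaves the band-passed
AC content untouched, and MI is built solely from AC quantities — which is
also why multiplicative source drift (tested at ±5%/min) moves the session
mean MI by far less than 1%.

## Processing chain and parameters

1. **Band-pass** 0.8–10 Hz (≤3 dB passband loss, ≥10 dB stopband attenuation
   at 0.4/15 Hz). The order is chosen by `scipy.signal.buttord` from this
   specification (order 3 at 100 Hz) rather than fixed, and is logged and
   recorded in the run manifest. Applied forward–backward
   (`sosfiltfilt`): a causal filter's phase at the cardiac frequency would be
   common to both species and cancel in Δθ anyway, but zero-phase
   application removes even that concern and is standard offline practice.
2. **Trough detection** on the oxyhemoglobin channel only (`find_peaks` on
   the negated signal, minimum separation one period of the upper heart-rate
   band edge 3 Hz, prominence floor 0.3·σ). One common trimming preserves
   the inter-channel phase relation. Boundaries within 1 s of the record
   edges are discarded (filtfilt transients).
3. **Windows** of 4 consecutive beats, non-overlapping, trimmed
   trough-to-trough and mean-subtracted (the zero-cycle-mean assumption).
4. **Spectrum**: linear resampling to the next power of two over the *same
   time span* (frequency grid anchored to physical time), periodic (DFT-even)
   Hamming window, FFT. The periodic Hamming has exact spectral nulls at
   integer bin offsets, so an on-bin tone contributes nothing to its own
   image leakage: on-bin amplitudes are exact and the phase *difference* is
   invariant under common time shifts to machine precision. The symmetric
   (N−1) Hamming does not have this property (residual ~10⁻⁵).
5. **Peak**: maximum oxyhemoglobin magnitude inside the heart-rate search
   band (0.7–3 Hz); both species read at that bin; amplitudes calibrated by
   2/Σw. Spectral SNR = peak / median off-peak magnitude computed *inside
   the filter passband* (out-of-band bins are already attenuated and would
   flatter pure noise); windows with SNR < 10 are flagged `low_snr`, windows
   with amplitude sum < 10⁻⁴ mM·cm flagged `rejected` (the false-hyperglycemia
   guard: α grows as the amplitude sum shrinks). Flagged windows are kept in
   the output, never silently dropped.
6. **Estimates**: SaO2 = A_HbO2/(A_HbO2+A_Hb); Δθ = phase(HbO2) − phase(Hb),
   wrapped to (−π, π], positive when deoxy lags (reported signed; MI uses the
   absolute value); MI = SaO2(1−SaO2)|Δθ|;
   α = ((A_HbO2+A_Hb)/a₀)^(1−1/n) with MI′ = α·MI. Default n = 0.5 — a
   tentative value meaning the pulsatile path amplitude scales as the square
   root of the baseline path length; a sweep utility re-evaluates r(n) over a
   grid, and n = 1 reproduces the uncorrected index exactly. The baseline a₀
   is the median amplitude sum over the first 10 min of the session (a
   resting/fasting proxy), overridable in config.
7. **Post-processing**: 1-min chunks; within each chunk the 1.5×IQR rule
   (linear-interpolation percentiles) removes obvious outliers, chunks of
   fewer than 4 values are kept whole, and a chunk whose rule would discard
   >40% of its values is marked missing rather than averaged from a
   minority. Savitzky–Golay smoothing of the minute means, order 1, window
   29 one-minute points (shrunk, with a log message, for shorter series);
   edges are handled by evaluating the terminal-window least-squares fit —
   no padding, so no data are invented at session boundaries. Missing chunks
   are bridged by linear interpolation only for gaps ≤3 min; longer gaps
   propagate and split the smoothing into independent runs. Interpolation
   onto reference timestamps is linear, exact at knots, and never
   extrapolates.
8. **Reference alignment**: a constant per-sensor delay is compensated by
   shifting reference timestamps by −delay (a reading at t reflects blood at
   t − delay). Windows independent; no cross-window phase unwrapping.

## Calibration and agreement metrics

Calibration is ordinary least squares of reference glucose on the index,
per subject and per study (no cross-subject transfer; individual
calibration factors vary). It is exposed as a scikit-learn regressor
(`GlucoseCalibrator`); Pearson r is 0 by convention when the reference is
constant, and a zero-variance index is a degenerate-fit error. MARD is the
mean of |est−ref|/ref in percent; RMSE in mg/dL. Clinical risk uses the
Parkes (consensus) error grid for type 1 diabetes: the standard boundary
polylines are embedded as a versioned CSV resource, extended beyond
550 mg/dL by continuing the final segment slopes, and assignment is by
strict which-side-of-boundary tests — structurally total on [0, 600]² with
no gaps or overlaps, with boundary points falling to the lower-risk zone.
When evaluating against a CGM reference, r/MARD/RMSE fold together the
index's error and the reference sensor's own error; the metrics are
reported agnostically.

## The simulator: what it emulates, and what it does not

`simulate_window`/`simulate_session` generate intensities through the *same
physics the inverse assumes*: sinusoidal AC NIRS signals with configurable
Δθ(t), shared pulsatile path length derived from the conservation constraint
(so the sum rule c₀·L_AC = N_HbO2,AC + N_Hb,AC holds to round-off by
construction), forward MBLL to absorbances, exponentiation to intensities,
then multiplicative slow drift, additive white noise, and optional
quantization. Defaults describe a resting fingertip: 75 bpm with ±5% slow
heart-rate modulation, SaO2 0.90 (shallow sites read below arterial SpO2),
c₀ = 2.3 mM, 1 cm baseline path with 2% pulsatile amplitude
(perfusion-index scale), Δθ = 0.1 rad, a 30% second harmonic (so fundamental
selection is non-trivial), noise sd = 5% of the per-channel *pulsatile*
intensity amplitude — the scale PPG signal quality is quoted on; relative to
the DC level the same figure would be ~100× larger and physically absurd —
and no quantization (detector units are continuous unless an ADC bit depth
is requested).

Sessions couple Δθ linearly to a double-sigmoid oral-challenge glucose
profile at 0.1 rad per 40 mg/dL — the observed magnitude; the true
physiological transfer function is unknown, and the linear map is explicitly
a stand-in of the right size and sign. The CGM-like reference reports
delayed glucose at 1-min cadence. With perfusion modulation enabled, the
baseline path length is slowly modulated, the pulsatile amplitude follows it
with a configurable power exponent, and the deoxy pulsation amplitude (the
oxygen-consumption signal) is held at its glucose-coupled target — so the
raw Δθ inherits exactly the distortion the α correction is designed to
remove, and sweeping n recovers the generating exponent (a plateau around
the true value, not a sharp peak).

The simulator does **not** model tissue optics (photon transport,
scattering changes), motion artifacts, baseline wander beyond sinusoidal
drift, 1/f noise, camera spectral response, or any real glucose→Δθ
physiology. Passing tests therefore demonstrate that the *inverse pipeline
is correct and robust for the assumed signal class*, not that the method is
clinically accurate: accuracy on real subjects can only be established with
recorded clinical data, which this package deliberately does not include.

## Numerical choices and degenerate inputs

- Phase wrap to (−π, π] via the complex exponential; the −π edge maps to +π.
- 2×2 MBLL inversion by the analytic inverse; |det ε| < 10⁻⁹ raises a
  singular-matrix error naming the channel pair. Embedded 650/930 nm
  coefficients are approximate literature values (condition number ≈ 3.7);
  the pipeline's results depend on them only through invertibility, and a
  user matrix (e.g. for camera pseudo-visible channels) passes through
  unchanged.
- Results CSV printed with 12 significant digits so write→read round-trips
  within 10⁻⁹ relative; NaN rows are emitted with empty cells and quality
  forced to `rejected`.
- Flat/zero signals: trough detection raises an insufficient-signal error;
  pure-noise records process but every window is flagged, and the CLI exits
  0 with a warning (exit codes: 2 config, 3 data, 4 insufficient signal).
- Per-window Δθ noise at the single-bin DFT limit is ≈0.24 rad × noise_rel
  for a 4-beat window; at the default 5% noise the smoothed flat-session
  range/mean sits near 5% (3–9% across seeds), dominated by this floor plus
  the variance inflation of the Savitzky–Golay edge fits — the same
  mechanism that makes smoothed trends appear to rise under fasting
  conditions in real recordings.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
12–20 s windows for parameter recovery (20 seeded replicates), 10-min
records for drift robustness, 90-min sessions at 100 Hz (~1690 four-beat
windows) for end-to-end trend recovery and the α sweep, and a 1 mg/dL
rasterization of the 601×601 error grid. A full run takes a few seconds on
one CPU.

## Known limitations

- Single constant heart-rate band (0.7–3 Hz) — tachycardia beyond 180 bpm or
  severe bradycardia needs reconfiguration.
- Non-overlapping windows; the hop is configurable only down to the beat
  grid.
- No sub-bin frequency/phase interpolation (the fundamental-bin reading is
  deliberate; a config extension could add it).
- Calibration is linear and per-session; no transfer, no uncertainty on the
  fitted coefficients beyond r.
- The glucose detection floor is structural: MI ≥ 0, so trends below the
  resting index (≈70 mg/dL regime) compress toward zero; hypoglycemia
  alarms are out of scope.
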