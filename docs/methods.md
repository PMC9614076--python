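# Methods

## Signal model

An IR-UWB radar transmits short pulses and records the reflected amplitude
versus round-trip delay ("fast time"; each sample is a range bin) for each
pulse repetition ("slow time"; here 20 frames/s). The recorded matrix
`y[n, k]` decomposes into static clutter (cradle, walls), a quasi-periodic
respiration component concentrated at the body-center bin, episodic limb
movement at bins nearer the radar than the body center, and sensor noise.
Two radars face the infant from the left and right; each radar's bins
`0..L_signal` (nearer than the body center) are attributed to its own side.

## Pipeline

**Bandpass filtering.** A 4th-order Butterworth filter is applied along
slow time per bin, forward-backward (`sosfiltfilt`) so movement events are
not time-shifted relative to the other modalities. Default band
0.1–9 Hz at 20 frames/s: keeps respiration (~0.5–1 Hz) and brisk limb
motion, removes DC and near-Nyquist noise. The filter acts on slow time,
not fast time, because the quantification step compares consecutive
frames — temporal denoising is what matters.

**Clutter removal.** Background subtraction, either the per-bin temporal
mean (default for offline batch processing) or an exponential running
background `b_n = α·b_{n−1} + (1−α)·y_n` (α = 0.98, initialized to the
warm-up mean, subtracted with a one-frame lag) for drifting backgrounds.
Both are linear; mean subtraction is idempotent.

**Body-center localization.** Per-bin Welch power spectral densities
(30 s segments, Hann, 50% overlap — robust to movement bursts) are
integrated over the infant respiratory band, default 0.3–1.2 Hz
(18–72 breaths/min). `L_signal` is the argmax bin; ties break toward the
smaller index. The estimate requires at least 10 respiration periods of
data at the band's low edge. Confidence is reported as
`1 − median(band power)/best(band power)`, which lies in [0, 1]: near 1
when one bin towers over a flat background, near 0 for a flat spectrum.
`L_signal` is estimated once per session segment.

**Movement statistic.** `E[n] = Σ_{k=0..L_signal} |y_n[k] − y_{n−1}[k]|`,
each bin contributing only when the *current* frame's amplitude exceeds a
per-bin threshold `T[k]`. The gate deliberately tests only `y_n[k]` — not
the previous frame — matching the statistic's printed definition exactly;
`E[0] = 0` because frame −1 does not exist. Bins accumulate left to right
(sequential `cumsum`), so the optimized implementation is bit-identical to
a naive per-bin loop and exactly monotone in `L_signal`. The threshold is
estimated from a designated movement-free calibration window (default the
first 5 s): per-bin 0.95-quantile of |y| (default), or mean + 3·std.
The threshold-setting rule is this package's own procedure (method,
parameters and window are config-exposed and logged).

**Aggregation and exclusion.** Per-second values are the arithmetic mean
of that second's frames (trailing partial second dropped). Seconds
overlapping any caregiver-interference interval become missing (NaN) —
never zero, which would deflate totals and bias both the asymmetry ratio
and the CCC.

**Lateralization.** Totals are taken over seconds valid on *both* sides;
`Lt/Total = 100·ΣE_left/(ΣE_left+ΣE_right)`. An optional gain
normalization (divide each side by its session-median nonzero per-second
value) compensates for unequal radar distances; it is off by default
because the phantom's radars are gain-matched, and the choice is recorded
in the output.

**Agreement.** Lin's CCC with population (1/n) moments (a 1/(n−1) toggle
exists for cross-checking other software). Series are z-scored by default
before the CCC because radar amplitude-difference sums, activity counts
and pixel displacements are in incommensurate units and the CCC penalizes
scale shifts; the normalization used is recorded in every output row.
Confidence intervals: `fisher_simple` (default) back-transforms
`atanh(ρ̂_c) ± z_{1−α/2}/√(n−3)`; `lin_variance` uses Lin's asymptotic
variance of the transformed estimate; `bootstrap` is a seeded percentile
bootstrap. The reported point estimate is labeled `rho_z` on the CCC
scale (the Fisher transform is used only to build the interval).

**Video tracking.** Classical CAMSHIFT: a normalized hue histogram
(16 bins, pixels with saturation ≥ 0.2 and value ≥ 0.1) back-projected
per frame, mean-shift to convergence (≤ 20 iterations or < 0.5 px), window
re-sized from second moments. If the search window loses all
back-projection mass the state freezes and is flagged; frozen frames
propagate as missing seconds. One tracker per limb blob gives
side-resolved displacement series. This is the standard algorithm, built
on numpy with scikit-image's RGB→HSV conversion.

## Phantom generator

The phantom emulates the measurement scene: static clutter (smooth per-bin
profile), respiration as sinusoidal amplitude modulation over ±2 bins
around the body-center bin (not true delay modulation — sufficient for
localization-by-band-power, far simpler than waveform-accurate UWB
simulation), limb events as amplitude-modulated scatterers (2–3.5 Hz
envelope, ±2-bin positional wander) on each side, and i.i.d. Gaussian
noise. One seed drives independent sub-streams per modality and per event,
so (a) modalities can be regenerated independently, and (b) two scenarios
differing only in event amplitude share envelopes bit-exactly, making
frame-difference energy exactly monotone in amplitude.

Canonical session defaults: 60 s, 20 frames/s, 128 bins, body center at
bin 40, respiration 0.7 Hz at amplitude 1.0, noise σ = 0.02 (amplitude SNR
of event echoes ≈ 34–44 dB, realistic for limb reflections at ~30 cm), a
movement-free first 5 s (the threshold calibration window), then movement
bursts of 1.5–3.5 s separated by 1.5–4 s. Both sides share the burst
schedule (generalized movements involve both sides) with independent
envelope phases; the left:right amplitude pair (default 3.0:1.0) sets the
latent energy ratio, emulating a left-dominant session; equal amplitudes
give a symmetric one. Actigraphy is the per-second integral of latent
activity scaled to count magnitude with a small additive floor and
multiplicative log-normal noise (counts are nonnegative and
heteroscedastic). Video renders one saturated elliptical blob per side on
a gray background; blob displacement per frame is proportional to latent
activity, clamped to each side's half-frame.

What the phantom does *not* emulate: electromagnetic pulse propagation,
multipath, body-shadowing, multi-subject scenes, camera noise/occlusion,
or actigraphy-specific band-pass count processing. Passing recovery tests
therefore shows the chain is correct and well-calibrated under the model's
assumptions, not that it is robust to every artifact of real recordings.

## Numerical choices and degenerate inputs

- Zero-phase filtering requires the series length to exceed the filter
  warm-up; shorter inputs are rejected, not padded.
- All-zero (no-variation) series are a localization error, not bin 0.
- `|ρ̂_c| = 1` yields a degenerate point-mass CI with a warning.
- Asymmetry with zero total movement is flagged undefined (NaN), not 50%.
- Missing values serialize as empty CSV fields, never sentinels.
- Problem sizes in the test-suite and acceptance script (60 s sessions,
  10–20 seeds per condition, 15 s video clips) were chosen as the smallest
  sizes at which the statistical recovery properties are stable.

## Known limitations

- The threshold rule and the respiration band are this package's own
  defaults; real deployments should calibrate both per device.
- `L_signal` is static per session segment; a migrating infant would need
  re-estimation (config hook exists, interval-based re-estimation is not
  implemented).
- The CAMSHIFT variant is the classical algorithm; hue-based tracking
  assumes a color-distinct target and fails on unsaturated scenes (the
  tracker then freezes and flags rather than guessing).
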