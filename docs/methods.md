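# Methods

`fabricmotion` implements a comparison pipeline for paired tri-axial
accelerometers — one strapped to the body, one sewn to the garment over
the same anatomical site — sampled at 50 Hz in units of g. The package
answers two questions: *how similar is the clothing-mounted signal to
the body-worn signal once synchronisation and orientation are
corrected?* and *does a simple activity classifier produce the same
labels from both?*

## Signal model and synthetic generator

Real paired recordings are large and subject-specific, so the pipeline
is validated on a seeded generator that reproduces the statistical
structure the method assumes:

* **Posture.** The sensor is worn with y nominally along gravity.
  Upright postures (standing, walking, running) have baseline
  acceleration (0, 1, 0) g; seated postures (sitting, bus ride) rotate
  the thigh horizontal, putting gravity on z: (0, 0, 1) g. Noise-free
  static segments therefore have unit magnitude exactly.
* **Gait.** Walking and running superimpose a two-harmonic waveform per
  stride (period 0.7 s walking, 0.3 s running; a stride is two steps,
  so the dominant spectral line sits at 2/stride ≈ 2.86 Hz and
  6.67 Hz). The second harmonic with a phase offset gives the
  double-peak-per-stride morphology seen in thigh data. Default peak
  amplitudes are 0.6 g (walking) and 1.2 g (running) on the gravity
  axis — thigh-scale values; x and z receive 35% and 20% of that.
* **Transitions.** Posture baselines change through a linear 0.5 s ramp
  (a boxcar moving average of the step function), producing the sudden
  moving-variance rise the classifier keys on. The boxcar sums window
  samples and divides once, so constant stretches remain bit-exact.
* **Markers.** The wear protocol starts each recording with a jump
  (biphasic y spike, 5 g peak, at 0.5 s) followed by four taps (3.5 g,
  0.5 s apart) and ends with another jump — the synchronisation markers
  a wearer produces to let pairs be aligned.
* **Clothing channel.** `clothing(t) = R·(s·body(t − L)) + w(t)·x̂ + ε`:
  an integer sample delay `L` (fabric couples to the limb elastically),
  a fixed rotation offset `R` (the sewn sensor sits tilted), amplitude
  scaling `s` (fabric can overshoot the limb), an additive swing
  sinusoid on the anterior–posterior axis (pendulum-like garment
  motion), and white Gaussian noise. The delayed leading edge is padded
  with the first sample so lengths stay equal; lag tests exclude that
  edge. With zero noise and zero swing the transform is exactly
  invertible.

What the generator does **not** emulate: biomechanically realistic
gait (no stance/swing asymmetry, no step-to-step variability), cloth
dynamics beyond a single sinusoid (real garments swing with
activity-dependent, broadband motion), sensor clock drift, and
non-stationary noise. Passing the synthetic studies therefore
demonstrates that the *algorithms* recover the distortions they model —
not that any particular garment will correlate well in the field.

## Synchronisation

Coarse alignment shifts a pair so the start-jump markers (magnitude
argmax over a window, 2 g floor) coincide; taps are the n largest local
maxima separated by ≥ 0.2 s. The residual lag is estimated as the
integer shift k ∈ [−max_lag, +max_lag] maximising the Pearson
correlation of the overlapping samples of one axis (each overlap
re-centred and re-scaled). This per-shift normalisation makes the
estimate invariant to the amplitude scaling between channels, unlike a
raw sliding dot product. Exact ties break toward the smallest |k|
(favouring the null hypothesis of synchrony, and resolving exactly
periodic inputs deterministically). Defaults: axis y — the
gravity axis carries the strongest activity signal; max_lag = 100
samples (2 s), generous against the sub-second lags observed.
Correcting the lag only ever trims samples; nothing is fabricated, so
the post-alignment correlation can never be computed on invented data.
By construction the chosen shift's correlation is ≥ the zero-shift
correlation, which is the alignment-improves-correlation property the
acceptance study asserts pair by pair.

Sub-sample (interpolated) lag and time-varying clock drift are out of
scope; the end-of-day jump is only reported, not used quantitatively.

## Orientation

Gravity is estimated either as the mean over the quietest 2 s window
(`static_window`, default — means over dynamic activity are biased
along the movement axis) or as the overall mean of a 0.25 Hz low-passed
signal (`low_pass_mean`). An optional time window restricts the search;
the pipeline defaults to the opening ~30–50 s because the synthetic
wear protocol (like the marker protocol it mimics) begins with a
standing calibration stance. This matters with noisy data: the single
quietest 2-s window of a whole day is arbitrarily a sitting *or* a
standing window, which would make the two streams of a pair align to
different postures. Anchoring both on the opening stance removes that
ambiguity. For sub-degree rotation recovery the windowed
`low_pass_mean` is preferred: averaging the full stance (≈500 samples)
rather than a 2-s snippet reduces the noise-driven angular scatter from
≈0.4° to ≈0.1° per stream at 0.05 g noise.

The stream is then rotated by the minimal rotation taking the estimated
gravity direction ĝ onto +y, via Rodrigues' formula
R = I + sinθ·K + (1−cosθ)·K², with axis k = (ĝ×ŷ)/|ĝ×ŷ| and
θ = atan2(|ĝ×ŷ|, ĝ·ŷ). Degenerate cases: parallel vectors give the
identity; antiparallel vectors give a half-turn about a deterministic
perpendicular axis (the coordinate axis least aligned with ĝ, projected
perpendicular — x whenever usable). Rotation about gravity (heading) is
unobservable from an accelerometer and left uncorrected; this caps
x/z-axis correlations between pair members independently of any garment
effect, which is one reason the y axis is the headline axis throughout.

## Correlation analysis

Per activity, up to three instances of 1500–2000 samples (30–40 s) are
carved from the interior of diary entries (0.5 s guard bands avoid
transition contamination; long entries may contribute several
instances). Pearson's r is computed per axis under five cumulative
variants: original, time-aligned, rotated, time-aligned + rotated, and
time-aligned + rotated + activity-wise re-alignment (the lag
re-estimated within each instance, search range 50 samples). The
rotation variant is applied file-wise — each whole stream gets one
rotation — because a single orientation correction per data set is what
"rotated data set" means here; per-segment gravity remains available
via configuration for postures (e.g. a shifted frock sensor when
seated) where one rotation cannot fit the whole day.

A Shapiro–Wilk normality check (on a fixed-seed subsample of ≤ 5000
points) is computed and logged but never gates the correlation —
silently switching statistics would change outputs invisibly.

Instances aggregate as median and population variance (ddof = 0; the
convention is configurable). Single-instance groups report the median
only. On noise-free lag + rotation pairs the fully corrected variant
reaches r = 1 on y exactly: the lag search recovers the integer delay,
gravity alignment of both streams makes their y components equal up to
the unobservable heading (which does not touch y), and Pearson r is
scale-invariant, absorbing the amplitude factor.

## Classification

Features, both from the y axis of an aligned stream: the acceleration
itself (posture: ≈1 g upright thigh, ≈0 g seated) and its moving
variance over a 250 ms centred window (movement intensity). 250 ms at
50 Hz is 12.5 samples, rounded half-up to 13 — odd windows centre
cleanly. Edges use the truncated available window. The implementation
subtracts the global mean before the cumulative-sum pass so constant
input yields exact zeros (variance is shift-invariant; the subtraction
only improves conditioning).

The tree tests variance before posture, because movement masks the
postural reading: var ≥ 0.05 g² → walking/running; var ≥ 0.005 g² →
transition; else y ≥ 0.7 g → standing, y ≤ 0.5 g → sitting, otherwise
transition. The defaults follow from the stated physics (upright ≈ 1 g,
seated ≈ 0 g, static variance at the noise floor, gait variance ≥
~0.1 g² for a ≥0.6 g oscillation sampled over 13 points) rather than
from fitting any recording; all are overridable, and a data-driven
`quantile` mode anchors the variance thresholds by geometric
interpolation between the 50th and 90th percentiles of the observed
moving variance (which bracket the static floor and the movement
plateau whenever the day contains both rest and gait) and the posture
thresholds between the two dominant modes of the low-variance y
histogram, falling back to the defaults when the histogram is unimodal
or the modes sit closer than 0.3 g. Walking and running are one class;
splitting them is not attempted. Labels are per-sample with no temporal
smoothing.

Agreement is a 4×4 confusion matrix with the body-worn labels as
reference rows, row-normalised to percentages (empty rows are reported
as missing, not zero). The end-to-end synthetic study (540 s
stand/walk/sit/run day; 38-sample lag, 15° tilt, swing at 0.2× the
walking amplitude, 1.1 amplitude scaling, 0.02 g noise) keeps every
non-transition diagonal above 80% — in practice ≈99%, the residual
disagreement living at transition boundaries.

## Determinism and problem sizes

Every random draw flows from one integer seed (trial seeds are spawned
with `numpy.random.SeedSequence`); run reports contain no timestamps
and serialise with sorted keys, so identical configs reproduce
artefacts byte for byte.

Validation studies use desk-scale sizes chosen to estimate each
property comfortably: 200 seeded 40 s walking pairs for lag recovery
(lags uniform in [−50, 50], 0.05 g noise, no swing; search range 60),
20 trials for rotation recovery (tilts 5–45° about random horizontal
axes), 1000 random vector pairs for the Rodrigues sweep, five random
signals each for the brute-force oracle cross-checks, three walking
instances for the variant-ordering study, and a 540 s day (~27 000
samples) for classification agreement.

## Known limitations

* Heading about gravity is uncorrected; x/z correlations are
  interpretable only up to that ambiguity.
* Lag is integer-sample; a true lag of 0.76 s is representable at
  50 Hz, but fractional lags alias to their nearest sample.
* The gravity calibration assumes some quiet wear time; a recording
  that is never still (or never upright near the chosen calibration
  window) will align to whatever posture dominates that window.
* The fixed thresholds assume g units and a thigh placement; waist or
  ankle sites need re-estimated posture thresholds.
* Synthetic validation bounds what can be claimed about real garments;
  with recorded CSVs the same pipeline runs unchanged via the `inputs`
  config block, but no recorded data ships with the package.
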