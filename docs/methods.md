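# Methods

This note documents the models and procedures implemented in `bbbeeg`,
the parameter choices that matter, what the synthetic-data generator
does and does not emulate, and the numerical conventions adopted where
the method leaves room for interpretation.

## Feature extraction

Recordings are analysed in **shifting windows** of duration δ = 60 s
advanced by τ = 10 s; a recording of duration T yields
⌊(T − δ)/τ⌋ + 1 windows (trailing partial windows are dropped). A
window inherits the condition label of the epoch containing its start
time — a deterministic rule for windows straddling an epoch boundary.

Within a window, the one-sided FFT magnitude spectrum is computed per
channel with a rectangular window (no taper, no detrending); a taper can
be supplied via `window_fn`, but the plain transform is the default
because band powers enter only through *ratios of logs*, which are
insensitive to the common scale a taper would introduce. **Band power**
is the mean of squared harmonic amplitudes over the harmonics of the
band. Conventions:

* Bands are half-open, [low, high): γ [30, 50), β [12, 30), α [8, 12),
  θ [4, 8), δ [1, 4) Hz. This makes the five bands a partition of
  [1, 50) Hz on the 1/60-Hz harmonic grid — no harmonic is counted
  twice and none in range is dropped (tested).
* The divisor is the *count* of included harmonics, not the difference
  of the first and last harmonic indices (which is one less for an
  inclusive range).
* The absolute scaling of FFT amplitudes is irrelevant downstream:
  normalization 2 is exactly invariant to a common positive factor on
  all band powers, and normalization 1's scale sensitivity is part of
  its design (below).

**Normalization 1** divides each log band power by the sum of the five
log band powers; components sum to 1 by construction. **Normalization 2**
min–max rescales the five log powers to [0, 1]. Degenerate windows —
all-zero power, a normalization-1 denominator within 10⁻³ (ln units) of
zero, or zero dynamic range under normalization 2 — are carried through
every table as rows flagged `valid = False` with NaN features, never
silently dropped; smoothing and statistics treat them as gaps.
Non-positive band powers in otherwise live windows are floored at 10⁻¹²
of the window's maximum band power so the logarithms stay defined.

## Classifier

A fully connected 5-150-2 network: SELU hidden layer with bias, softmax
output without bias. Choices the architecture description leaves open,
and the defaults adopted:

| parameter | default | rationale |
| --- | --- | --- |
| loss | categorical cross-entropy | the standard companion of a softmax output |
| regularization | L2, λ = 10⁻⁴, on the non-output layer's weights *and* biases | "everything but the output layer" |
| optimizer | Adam, lr 10⁻³, batch 32, 200 epochs | ordinary modern defaults; curves recorded per epoch |
| initialisation | LeCun normal (fan-in) | the scheme paired with SELU's self-normalizing property |

Training data are normalization-1 feature vectors from the two classes
*normal behavior* (output index 0) and *artificial OBBB* (index 1),
split 70/30 **per class** with ⌊0.7·n⌋ training examples — 715 windows
per class give exactly 500/215. The split shuffles at the window level;
overlapping windows can therefore share samples across the split, which
is leakage in a strict sense but is what reproduces the printed split
arithmetic. The chance-level and label-permutation controls in the test
suite guard against this leakage manufacturing skill where none exists:
with identical class profiles, or permuted labels, held-out accuracy
stays inside the binomial 95 % band around 50 %.

Everything is plain numpy; training is reproducible bit for bit from the
seed, and a fitted model serialises to a single JSON file (layer shapes,
flat weight arrays, config echo).

## Decision stage

The raw per-window response (OBBB-class softmax output) is averaged in a
**16-min (960 s) sliding window** on the response's own 10-s grid.
Edges use truncated means (all available points), so the smoothed curve
spans the whole recording; gaps are excluded from the means. The
**threshold** is the mean of the smoothed response over the *entire
recording* (a per-condition alternative is a one-line change via
`binarize` on epoch slices); the binary answer is 1 strictly above the
threshold, so a constant trace never fires.

Condition statistics are computed on the **binary-gated smoothed
response** (smoothed value where the answer is 1, else 0): box-plot
five-number summaries pooled over animals per condition, plus the count
and mean of the windows that fired. A **per-animal detection** is any
binary-1 run of at least 60 s (one analysis window) inside the condition
epoch; the cohort detection fraction averages these flags. Because the
960-s smoother leaves long-range autocorrelation, runs of 60 s above the
recording mean also occur without any effect — the null detection rate
of this rule is high, and the informative readout is the *contrast*
between condition summaries, not the absolute fraction. The run-length
threshold is configurable (`min_run_s`).

## Spectral trajectories

Welch densities (60-s Hann subwindows, 30-s offset = 50 % overlap, no
detrending, density scaling) are averaged over a band's frequency range
and over the two channels, inside 250-s sliding windows stepped by 50 s;
window centers timestamp the trajectory. The normalized change index
Δ = (m₁ − m₀)/m₀ uses median trajectory values over the baseline and
anesthesia epochs (points belong to an epoch when their window center
does). Δ is exactly invariant to a global rescaling of the recording's
power and is bounded below by −1 for non-negative powers.

## Synthetic-data generator

Each condition is a `StateProfile`: five band-power targets, an optional
1/f^a background, a white measurement floor, and an optional exponential
collapse. Synthesis is direct spectral construction: per band, Gaussian
white noise is band-pass filtered (4th-order Butterworth, zero-phase)
and scaled; the five component variances are obtained by solving the
5×5 linear system of expected band-power contributions (computed from
the filters' |H|⁴ responses on the 60-s harmonic grid), which removes
the bias from Butterworth roll-off leaking past shared band edges and
from the flat floor contribution. Calibration is therefore
deterministic, and extracted band powers converge to their targets as
duration grows (tested at two durations; at 1800-s epochs recovery is
well inside ±15 %).

Two channels are independent draws from the profile mixed with a shared
component (weight 0.5 by default; per-channel band power is preserved by
the √-weighting). The sampling rate defaults to 250 Hz — comfortably
above twice the 50-Hz γ edge; no rate is prescribed by the method, so it
is a configuration choice.

**Units.** Band-power targets are expressed directly in the measurement
convention (mean squared 60-s-window FFT amplitude, arbitrary power
units). Because normalization 1 is *not* scale-invariant, the unit in
which powers are measured is part of the method: the defaults place
normal EEG band powers at ln X ≈ 4–6 and the white floor near
ln X ≈ 0.4, which keeps the log-features informative across the full
dynamic range of the collapse instead of saturating.

**The standard study conditions** (the generator defaults):

| profile | band targets (δ, θ, α, β, γ) | extras |
| --- | --- | --- |
| normal behavior / baseline | 200, 150, 110, 80, 60 | white floor 10⁻⁴ µV² |
| artificial OBBB | 2000, 1350, 880, 640, 480 (×10, ×9, ×8, ×8, ×8) | — |
| 1 % isoflurane | normal → OBBB log-ray at effect 0.75 | — |
| 4 % isoflurane | OBBB-level onset | exponential collapse, τ = 300 s |
| death | all zero | floor only |

The design encodes the working model of the biology: drainage activation
is a *broadband* power elevation weighted toward the slow bands, shared
between the sound-induced training condition and 1 % isoflurane; the
lethal dose starts from full activation and collapses toward the
measurement floor. Under these conditions the two normalizations
dissociate mechanistically: normalization 1 reads the power *scale*
(its log-sum denominator grows with broadband power, flattening the
feature vector toward the OBBB class), so it responds to 1 % anesthesia
and partially to the pre-collapse phase of 4 %; normalization 2 removes
scale entirely and responds only when the collapse whitens the spectrum
and scrambles the band ordering. Effect-size sweeps interpolate
log-linearly along the normal → OBBB ray (`interpolate_profiles`).

**What the generator does not emulate:** spindles, K-complexes,
movement or electrode artifacts, line noise, burst suppression's
alternating structure, inter-animal variability in spectral shape, and
any EMG channel. Passing tests therefore demonstrate that the pipeline
recovers the states *its own forward model generates* — a correctness
statement about the analysis code and the internal consistency of the
method, not evidence that real recordings would be classified at the
same accuracy.

## Problem sizes

The standard corpus is five 1480-s recordings per class (143 windows
each, 715 per class, 1430 total — chosen so the per-class 70/30 split
lands on 500/215); the standard cohort is four to six animals at
1800 s per condition epoch. These sizes keep a full study surrogate —
generation, training, application under both normalizations, spectra —
in well under a minute of compute while leaving every statistic far from
its small-sample regime.

## Known limitations

* EDF support writes a minimal single-record, 16-bit file (symmetric
  physical range, zero offset) and reads through MNE; EDF+ annotation
  streams are not written — condition epochs travel in a plain-text
  sidecar table next to the signal file in either format.
* The per-animal detection rule (60-s binary run) is an explicit
  stand-in: the method itself does not define how an animal counts as
  "recognized", and the rule's null rate is high (see Decision stage).
* The in-vivo cohort fractions reported for real animals are not
  reproducible from synthetic data and are out of scope; the surrogate
  demonstrates the mechanism and the qualitative condition ordering.
* Normalization 1's behaviour depends on the power unit (see Units);
  analyses of real recordings must fix that unit before training and
  keep it fixed at application time.
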