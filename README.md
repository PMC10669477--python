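# bbbeeg

EEG band-power markers of blood–brain-barrier opening (OBBB) and
brain-drainage-system (BDS) activation.

The blood–brain barrier normally seals the brain's vasculature; a lethal
dose of inhalation anesthesia (4 % isoflurane) disrupts it, while a
surgical dose (1 %) leaves it intact but activates the brain's drainage of
interstitial fluid. Both states leave signatures in cortical EEG, which
makes a cheap, non-invasive bedside monitor conceivable. `bbbeeg`
implements the complete signal-analysis pipeline for detecting these
states from two-channel EEG — for neurophysiologists and methods
developers who want the detector as tested, reusable code rather than a
one-off script — together with a synthetic-EEG generator that emulates
the experimental conditions, so the whole pipeline runs and is tested
end to end without any animal recordings.

## Method

**Features.** Each recording is cut into 60-s windows advanced by 10 s.
Per window and channel *c*, the FFT magnitude spectrum gives the band
power

> P(c, κ) = (1 / N_κ) Σ_i F_i²,  κ ∈ {γ [30, 50), β [12, 30), α [8, 12),
> θ [4, 8), δ [1, 4) Hz},

the mean of squared harmonic amplitudes over the N_κ harmonics in band
κ. Channel powers are summed, X_κ = P(1, κ) + P(2, κ), and log powers
are normalized either by their sum over the five bands
(**normalization 1**, components sum to 1, sensitive to the absolute
power scale) or by the within-window min–max range (**normalization 2**,
scale-invariant):

> X̄_κ = ln X_κ / Σ_κ ln X_κ    or    X̄*_κ = (ln X_κ − ln X_min) / (ln X_max − ln X_min).

**Classifier.** A fully connected 5-150-2 network — SELU hidden layer
with bias, softmax output without bias, L2 regularization of the
non-output layer — is trained by backpropagation (Adam, categorical
cross-entropy) on normalization-1 features from two classes, *normal
behavior* and *artificial OBBB*, split 70/30 per class. The per-window
response is the OBBB-class softmax output.

**Decision.** The raw response is averaged in a 16-min sliding window
(10-s step), binarized against the mean level of the smoothed curve over
the recording (above = barrier opened / drainage activated), and
summarised per condition epoch as box statistics and per-animal
detection calls.

**Spectra.** Delta- and theta-band power trajectories are tracked by
Welch estimates (60-s Hann subwindows, 30-s offset) in 250-s sliding
windows stepped by 50 s, and the anesthesia effect is summarised by the
normalized change index Δ = (m₁ − m₀)/m₀ of median band power.

The two normalizations dissociate the two states: the scale-sensitive
normalization 1 responds to the broadband power rise of drainage
activation (1 % isoflurane), while the scale-invariant normalization 2
ignores it and fires only on the spectral collapse toward the
measurement floor that precedes death under 4 %.

## Worked example

```python
from bbbeeg import RunConfig, run_study

cfg = RunConfig(seed=1, n_animals=4)   # 715 windows/class, 4 test animals
study = run_study(cfg)

print(study["results"].summary())
for norm in (1, 2):
    print(study[f"summary_norm{norm}"].per_condition[
        ["label", "mean", "q50", "detection_fraction"]].to_string(index=False))
print(study["spectra"].groupby("band")["delta"].mean())
```

prints

```
Band-power state classifier
===========================
architecture      5-150-2 (SELU hidden with bias, softmax output without bias)
regularization    L2 lambda=0.0001 on non-output weights and biases
optimizer         Adam lr=0.001, batch=32, epochs=200, seed=1
training examples normal_behavior: 500, artificial_obbb: 500
final accuracy    train=0.993, test=0.988

normalization 1:
   label     mean      q50  detection_fraction
baseline 0.006250 0.000000                0.25
    iso1 0.583019 0.610999                1.00
    iso4 0.287084 0.000000                1.00
normalization 2:
   label     mean  q50  detection_fraction
baseline 0.000000  0.0                 0.0
    iso1 0.000000  0.0                 0.0
    iso4 0.056907  0.0                 1.0

delta    4.691251
theta    4.180794
```

Reading the numbers: the network separates the two training classes
almost perfectly (98.8 % held-out accuracy). Applied to the anesthesia
cohort with normalization 1, the binary-gated response is highest under
1 % isoflurane (drainage activation), intermediate under 4 % (activation
followed by spectral collapse) and near zero at baseline; with
normalization 2 only the 4 % collapse produces a response. The Δ index
shows the delta-band power rise under 1 % anesthesia exceeding the
theta-band rise.

The same workflow is available from the shell:

```sh
bbbeeg generate --config run.yaml     # synthetic corpus + cohort
bbbeeg train    --config run.yaml     # model.json + training_log.tsv
bbbeeg apply    --config run.yaml --norm 1
bbbeeg spectra  --config run.yaml
bbbeeg report   --config run.yaml     # simple figures
```

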