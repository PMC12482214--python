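# Methods

This note documents the models, numerical choices and limitations behind
the `mcsv` package: a pipeline that classifies multichannel EEG windows
into pre-ictal (PIL, the minutes before a seizure) and inter-ictal (IIL,
baseline) states and converts window probabilities into seizure alarms.

## Problem setting

Let `X(t) ∈ R^{C×T}` be a multichannel EEG segment. The pipeline learns
`f_θ : X(t) → {0, 1}` with `y = 1` for pre-ictal windows, then scores
alarms under SPH/SOP semantics: an alarm at time `t` is a true positive if
some seizure onset falls in `[t + SPH, t + SPH + SOP]`, where SPH (seizure
prediction horizon) is the minimum usable warning time and SOP (seizure
occurrence period) the window in which the predicted seizure must begin.
An alarm whose onset lands inside the SPH, or that matches no onset,
counts as a false positive; sensitivity is `TP/(TP+FN)` over seizures and
the false-prediction rate is `FP` per inter-ictal hour.

## Preprocessing: multiresolution adaptive filtering (MRAF)

Records are cut into non-overlapping 4-s segments (`k = floor(samples /
window_samples)`; a trailing partial segment is dropped). Each segment and
channel is processed as follows.

**Wavelet denoising.** A `db4` DWT with symmetric extension and
`floor(log2(n)) − 2` levels (7 levels for a 1000-sample segment). Detail
coefficients are soft-thresholded, `sign(c)·max(|c| − Z, 0)`, with the
universal threshold `Z = σ·sqrt(2 ln P)` where `P` is the segment sample
count. The noise scale `σ` is estimated robustly from the finest detail
level as `MAD/0.6745`, the standard Donoho–Johnstone estimator. We
deliberately do *not* threshold each level at the standard deviation of its
own coefficients: `|c| ≤ 3.7·std(c)` holds for almost every coefficient of
any distribution, so that rule annihilates structured oscillatory content
along with the noise. The exposed `universal_threshold(coeffs, P)`
primitive computes `std(coeffs)·sqrt(2 ln P)` for whatever coefficients it
is given.

**Band streams.** For each band (δ 0.5–4, θ 4–8, α 8–13, β 13–30,
γ 30–100 Hz capped at Nyquist, plus the full band `fb`; an optional 7-band
variant splits γ into 30–70 and 70–128 Hz), a *desired* signal is
reconstructed from the wavelet scales whose centre frequency (geometric
mean of the dyadic edges) lies inside the band. Centre-frequency
assignment partitions the scales disjointly across the standard bands, so
the band components are orthogonal and their energies add to the denoised
signal's energy; an overlap rule (any scale intersecting the band) is used
only as a fallback for bands so narrow they contain no scale centre. An
8-tap causal FIR filter, zero-initialised and adapted sample-by-sample
with normalised LMS (step size μ = 0.01, regulariser 1e−12), tracks the
desired signal; its output is the band's preprocessed stream. The `fb`
stream is the denoised signal itself. On 4-s segments the filter converges
well inside the first half: an in-band sinusoid is preserved with
correlation ≥ 0.99 over the second half, a large 1 Hz artifact is
attenuated by ~58 dB in the γ stream, and ≥ 99 % of the output power stays
in band.

## Features: the Critical Spectral Verge (CSV)

Per band stream and segment, a boxcar periodogram is zero-padded to the
smallest power-of-two FFT giving ≤ 0.1 Hz bin spacing (4096 bins at
250 Hz). The *spectral verge* (SV) is the highest in-band frequency whose
power strictly exceeds the band's mean power — a summary of how far
meaningful activity reaches into high frequencies. The SV seeds a
flower-pollination optimisation of

    f(m) = m                 if power(nearest bin to m) > band mean,
    f(m) = −10⁹              otherwise,

over the band's own frequency range (`[0, Nyquist]` for `fb`; a CSV
outside its band would be meaningless in the feature map). The penalty is
a large negative constant rather than bin removal so the search domain
stays continuous. The optimiser uses the canonical flower-pollination
settings — population 20 (seed point included verbatim), switch
probability 0.8, Mantegna Lévy steps with exponent 1.5 scaled by 0.1
toward the best-so-far candidate, uniform local mixing otherwise, 100
iterations, candidates clamped to the bounds — and returns the best-ever
candidate, never worse than the seed. Because the objective is resolved at
bin granularity the exhaustive grid maximum is a cheap independent oracle;
the optimiser agrees with it to within one bin by construction, and the
test suite checks this on random spectra for every band. A vectorised
batch variant refines all segments of a band/channel stream in one pass.

The per-channel feature map stacks rows in the order α, β, γ, θ, δ, fb ×
segments. Maps export to NPZ and long-format CSV.

## Synthetic EEG generator

The generator emulates the statistical structure the method assumes, not
forward-modelled physiology:

* **Background (IIL):** per-channel independent 1/f-coloured noise
  (5 µV RMS) over a small white sensor floor (0.5 µV), plus one narrowband
  oscillation per band (δ 2 Hz/20 µV, θ 6 Hz/10 µV, α 10 Hz/15 µV,
  β 20 Hz/5 µV, γ 40 Hz/2 µV; ±20 % per-channel amplitude jitter, random
  phases).
* **Pre-ictal span** `[onset − pil_minutes·60, onset)`: the γ component is
  multiplied by `preictal_gamma_gain` (> 1 required; default 4) and short
  high-frequency-oscillation bursts are injected — 0.3-s Hann-windowed
  90 Hz tones at 2 events/s, amplitude 1.5 × γ-amplitude × gain. The burst
  rate/length are chosen so the bursts register in a 4-s periodogram
  against the sustained γ peak; this moves the γ-band and full-band CSV
  upward in pre-ictal segments (γ row ≈ 66 → 81 Hz at gain 4), which is
  the planted effect the classifier learns.
* **Ictal spans** (default 30 s): high-amplitude 4 Hz spike-wave-like
  activity; generated so the state labels partition the record, but
  excluded from classification.
* **Artifacts (optional):** Poisson-timed blink transients (0.7-s 120 µV
  bumps, < 2 Hz content, frontal channels) and broadband 0.3-s muscle
  bursts.
* Samples are quantised to a 16-bit grid spanning the signal range.

`SimulationConfig.balanced` lays out `IIL | PIL | ictal` with the seizure
at the record end so the inter-ictal : pre-ictal ratio is met exactly
(default 15:1, the imbalance the method assumes). Everything is
reproducible from the config seed.

What the generator does **not** emulate: volume conduction and channel
correlation structure, patient-specific seizure morphologies, drifting
baselines, electrode artifacts beyond the two stereotypes, or pre-ictal
signatures other than elevated high-γ power. Passing end-to-end tests
therefore demonstrate that the pipeline recovers a planted spectral
effect under realistic imbalance and noise — not clinical performance.

## Classifier

Windows of `W` consecutive segments (default 8, i.e. 32 s) are cut from
the feature map with stride one segment; the input image is
(channels × bands) rows by `W` columns. Rows are standardised with
training-fold statistics only and clipped at ±6 SD — quiet band rows have
~0.05–0.1 Hz standard deviation, and without clipping a single odd bin can
map to z ≈ 27 and saturate the network into a confident false alarm.
Windows that straddle the IIL→PIL transition or touch ictal activity are
excluded from training and window-level metrics (their probabilities still
feed the alarm trigger); a window is labelled pre-ictal only if all its
segments are.

The network is a compact six-layer CNN in NHWC layout with 'same'
convolution padding: conv 3×3×8 stride 1×1 → maxpool 2×2/2 → conv 5×5×16
stride 1×3 → maxpool 2×2/2 → conv 3×3×32 stride 1×3 → dense 256 → dense
128 → dense 2 (softmax), ReLU activations, dropout 0.5 after the first two
dense layers. Training uses categorical cross-entropy, Adam (lr 0.001,
β₁ 0.9, β₂ 0.999), batches of 100, a 150-epoch cap and early stopping
after ten consecutive epochs of rising validation error; the
best-validation weights are restored, keeping the *latest* snapshot among
equal validation errors (further epochs at unchanged validation error mean
lower training loss). Same-padding was chosen so the row dimension
survives the stride chain; the window must span ≥ 8 segments or the
pooling chain collapses (`build_model` raises a sizing error). The
implementation is plain numpy (im2col convolutions, argmax-tracked
pooling, inverted dropout) with backprop verified against numerical
gradients to ~1e−11 relative error.

Class imbalance is handled on training folds only: random oversampling
(default), random undersampling, or borderline-SMOTE-1 (danger points =
minority samples whose m = 10 neighbourhood is majority-dominated but not
pure; synthetic rows interpolate toward k = 5 minority neighbours, with
optional clipping to per-feature bounds).

**Sub-band voting.** Besides the default single-stream model, per-band
streams (one CNN per band row group) can be fused by majority vote (ties
break toward inter-ictal, favouring fewer false alarms) or by probability
averaging; the ablation variants are `no_multiresolution` (single raw
full-band periodogram row, no MRAF), `no_subband_voting` (averaging
fusion) and `shallow` (two convolutions).

## Alarm generation and evaluation

An alarm fires at the end of the κ-th consecutive window with PIL
probability above τ; subsequent alarms are suppressed for a refractory
period (default = SOP). τ is tuned on training records only, by scanning
0.10–0.95 in steps of 0.05 and keeping the value maximising pooled
training sensitivity minus 0.5 per false alarm (ties resolve to the
highest τ). Event-level TP/FP/FN use the SPH/SOP semantics above with
greedy earliest-onset matching; window-level accuracy/AUC (rank-based)
are reported alongside, because the two granularities answer different
questions. Inter-ictal hours for the FPR exclude ictal, pre-ictal and
post-alarm SPH+SOP spans. Validation protocols: stratified 80/20 holdout,
leave-one-seizure-out (LOSO), and leave-one-patient-out.

## The scaled-down study

The bundled end-to-end experiment (`ExperimentConfig`) uses six synthetic
patients with 20.5-minute single-seizure records at 8 channels, γ-gain 4
and IIL:PIL exactly 15:1, evaluated LOSO. Scaling choices, fixed once:

* With one onset per 20-minute record, a 15:1 ratio forces the pre-ictal
  span to 75 s (`pil_minutes = 1.25`), so the SPH must shrink with it.
  The minimum achievable alarm lead is `PIL − W·4 s − κ·4 s`; with κ = 2
  that is 35 s, and SPH = 15 s leaves a 20-s margin by construction.
  SOP stays at the standard 10 min.
* The classifier epoch cap is 20 here (validation error reaches zero
  within a few epochs on this task); the 150-epoch default applies
  elsewhere.
* The full-vs-shallow comparison trains each variant with three seeds on
  one stratified holdout and scores the seed-averaged probabilities —
  repeated-seed averaging is also how the evaluation protocol itself is
  defined. Both variants sit at ceiling on this separable task, so the
  expected qualitative result is full ≥ shallow with ties.

On one CPU core the whole study (generation → features → 6 LOSO folds →
ablation) runs in about 5 minutes and typically yields sensitivity 1.0
(6/6 seizures), zero false alarms over ~1.9 inter-ictal hours, and
window-level AUC > 0.99. `scripts/acceptance.py` recomputes these numbers
from scratch for any seed.

## Known limitations

* The NLMS band filters have only 8 taps; at 250 Hz they cannot sharply
  separate neighbouring low-frequency bands, which is why the desired
  signal (and hence the energy partition) is defined by wavelet scales.
* The EDF writer requires integer sampling rates and pads records to
  whole seconds; channel-specific annotation assignments survive only in
  the TUH-style CSV sidecar, not in the EDF TALs.
* LOSO folds hold out whole records (one seizure per synthetic record);
  with multiple seizures per record the current grouping excludes the
  entire record from training, which is conservative.
* Reported synthetic metrics say nothing about clinical data; see the
  generator's non-goals above.
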