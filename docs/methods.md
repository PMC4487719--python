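# Methods

## The detection problem

A movement-related cortical potential (MRCP) is a slow negative deflection
of the EEG that develops up to ~2 s before a self-initiated, imagined or
attempted movement. Detecting it before the movement onset is the core of
BCI-driven neurorehabilitation: the detector must discriminate a 2 s
pre-onset window ("movement" epoch) from a resting window ("noise" epoch)
of the same subject. This package implements that offline study end to end
— signal generation, preprocessing, epoching, two feature families, two
detectors, and a nested cross-validated evaluation with cross-subject
statistics — on synthetic recordings, because the original human data were
never deposited.

## Synthetic recordings (`synthdata`)

The generator emulates a cue-paced ankle-dorsiflexion protocol with two
tasks per subject, 50 trials each: `f60` (ramp to 60% of maximum voluntary
contraction in 0.5 s) and `s20` (ramp to 20% MVC in 3 s), in randomized
block order at a 12 s inter-trial interval (any value ≥ 10 s keeps the
noise window, −5…−3 s, and the force-baseline window, −4…−2 s, inside the
trial).

Per channel of the ten-channel 10–20 montage (FP1, F3, Fz, F4, C3, Cz, C4,
P3, Pz, P4; 500 Hz) the EEG is:

* **background**: 1/f ("pink") noise — white Gaussian noise spectrally
  shaped with a 1/√f amplitude profile, DC bin zeroed, rescaled to sample
  SD 2 µV — plus a 10 Hz sinusoid of amplitude 1 µV with random phase,
  independently per channel. An optional 50 Hz line component is off by
  default (the pipeline applies no notch filter).
* **MRCP**: a half-cosine ramp from 0 at 2 s before the true movement onset
  to a −10 µV peak at the onset, recovering to baseline over 1 s
  afterwards. The half-cosine was chosen for its smooth, zero-derivative
  endpoints; only its monotone pre-onset course matters, since epochs end
  at the onset. Scalp gains peak at Cz (1.0), are 0.4 on the surrounding
  ring and 0 at FP1 (the EOG site), so the large-Laplacian surrogate keeps
  a net MRCP gain of 1 − 0.4 = 0.6 (peak −6 µV).

The force channel (2000 Hz, in fractions of MVC) is a linear ramp — the
shape of the visual cue subjects track — held at target for 0.5 s and
released over 0.5 s, plus white sensor noise of SD 0.001 MVC. For
executed/attempted movements the true onset lags the cue by a uniform
0–0.3 s reaction delay; for imagined movements the force stays at baseline
and the true onset is the cue itself.

The force-noise default deserves a note: with the onset rule below (a full
200 ms window strictly above the pre-cue baseline mean), white sensor noise
of SD σ delays detection of a ramp of slope a until the ramp sustains
roughly 2.5 σ, i.e. by ≈ 2.5 σ/a. For the slow task (a = 0.067 MVC/s)
σ = 0.001 gives a ~30–45 ms delay; a noisier sensor (σ = 0.005) would make
the same rule ~200 ms late. 0.1% MVC is a realistic figure for a
strain-gauge torque pedal, and it keeps onset timing accurate to within the
50 ms the downstream epoch alignment needs.

What the generator deliberately does **not** model: spatial correlation of
the background between electrodes, event-related
desynchronisation/synchronisation of the mu and beta rhythms,
eye-blink/EOG artifacts, movement artifacts, and nonstationary noise.
Consequences for interpreting results are discussed under *Limitations*.

## Preprocessing (`preprocess`)

A large Laplacian spatial filter reduces the nine scalp channels to one
surrogate: Cz minus the mean of the eight surrounding electrodes (uniform
weights; with nine channels the full ring is the natural neighbour set).
FP1 is excluded as the EOG site. The weights sum to zero, so any
common-mode/reference shift cancels exactly.

Two temporally filtered versions of the surrogate are kept, both 2nd-order
Butterworth filters applied forward and reverse (zero net phase, squared
magnitude response): a 0.05–10 Hz band-pass ("temporal path", the MRCP
band) and a 0.05 Hz high-pass ("spectral path", full EEG band). The
high-pass family/order mirrors the band-pass for symmetry. Spatial
filtering is applied before temporal filtering; by linearity the order is
irrelevant, and filtering one channel instead of nine is cheaper. Filtering
uses `scipy.signal.sosfiltfilt` with its default odd-reflection padding;
epochs are cut well inside the recording, so edge transients never reach
them.

## Onsets and epochs (`epochs`)

Movement onset is determined from the force trace: the baseline is the mean
force 2–4 s before the cue, and the onset is the first sample at or after
the cue for which *every* sample of the following 200 ms window strictly
exceeds that baseline, windows advancing one sample at a time. "Exceeds"
is read literally as strictly-greater-than the baseline mean; an optional
`k·SD` margin is available (default 0). Onsets are found on the 2000 Hz
force clock in seconds and mapped to the nearest EEG sample by rounding.
For imagined movements the cue-defined task onset is used directly and a
guard flags any trial whose force rises more than 5% MVC above baseline.
Trials without a detectable onset are dropped and logged.

Per trial, the movement epoch is `[onset − 2 s, onset)` and the noise epoch
`[onset − 5 s, onset − 3 s)`, both from the requested preprocessing path.
Windows are half-open with 0-based indices (`start = round(t · fs)`), so a
2 s epoch at 500 Hz is exactly 1000 samples and the two epochs of a trial
are separated by exactly 1 s.

## Features (`features`)

**Temporal** (from the 0.05–10 Hz path): latency of the minimum sample
(ties to the earliest; encoded as a time because the amplitude information
is already carried by the mean features), mean amplitude, and
slope/intercept of OLS line fits over the full epoch and over the final
0.5 s. Executed movements use all six; imagery uses five (both slopes, no
intercepts, plus the mean of the final 0.5 s). The full-epoch regression
runs to the epoch end — the detection point coincides with the movement
onset — with `regression_until="max_negativity"` available as an
alternative reading.

**Spectral** (from the 0.05 Hz high-pass path): mean Welch power density in
delta (0–4), theta/mu (4–8), alpha (8–13), beta (13–30) and gamma
(30–100 Hz). Welch uses Hamming windows with 50% overlap and 1 s segments
(three per epoch), chosen to give 1 Hz resolution so the delta band holds
four bins. Segments are *not* detrended (the Matlab `pwelch` convention):
mean-detrending would strip exactly the sub-delta content that carries the
MRCP. Band edges are half-open `[lo, hi)` to avoid double-counting the
shared edges; the gamma band closes at 100 Hz. The PSD convention is
one-sided density (µV²/Hz); any fixed convention gives identical LDA
decisions since LDA is affine-invariant.

## Detectors (`detect`)

**LDA**: closed-form Fisher/Gaussian discriminant with pooled within-class
covariance and equal priors (epoch classes are balanced by construction),
`w = Σ⁻¹(µ₁ − µ₀)`, boundary at the midpoint of the class means. If the
pooled covariance is ill-conditioned (condition number > 10⁸) it is ridged
by `10⁻⁶ · trace(Σ)/d · I`. Movement is called on strictly positive score;
a score exactly on the boundary is noise.

**Template matching**: the template is the pointwise ensemble average of
the training movement epochs (temporal path); an epoch is scored by its
Pearson correlation with the template (gain- and offset-invariant), and
movement is called when the correlation strictly exceeds a threshold
fitted by grid search over −1…1 in steps of 0.01, minimising training
detection error with ties broken toward the lower threshold (favouring
sensitivity).

## Evaluation (`evaluate`)

The nested **5-fold test** procedure: epochs are split into five
class-stratified parts by a seeded shuffle (stratification keeps the parts
balanced; unbalanced parts would distort error comparisons). For each
choice of test part, the remaining four undergo a 4-fold validation
rotation — train on three, validate on one — and the fold-trained model
with the lowest validation error (ties to the lowest validation-part
index) is applied *unchanged* to the test part; there is no retraining on
all four parts. The subject's score is the mean of the five fold errors.
Rotation order is cyclic by default; a seeded random rotation is available
as a flag.

Detection error is `(FP + FN)/n`, sensitivity the true-positive rate over
movements, specificity the true-negative rate over noise. The study runs
the three methods per subject and movement task (50 movement + 50 noise
epochs per task) and averages the two tasks per subject.

Methods are compared per subject group with the **Friedman test** (methods
ranked within each subject, mean ranks on ties, chi-square statistic with
the standard tie correction and k−1 degrees of freedom; fully tied data
give statistic 0, p 1): first temporal vs spectral features, then the
better of the two vs template matching; significance at 0.05. Aggregates
report mean ± standard error (sd/√n) across subjects. Feature spaces are
visualised with a 3-class Fisher discriminant projection (f60 / s20 /
noise): generalized eigenvectors of between- vs within-class scatter, data
projected on the two leading directions and each dimension affinely mapped
to span [−1, 1], with a deterministic sign convention.

The template method accepts an optional onset-jitter degradation
(`template_onset_jitter_sd`, default 0): epochs for that method are cut at
onsets perturbed by Gaussian jitter, emulating the timing uncertainty
template matching faces outside a cue-locked laboratory setting. It is off
by default; the study reports the clean comparison.

## Problem sizes and runtime

The full study — 12 executing, 12 imagining and 6 attempting subjects at
2 × 50 trials each — simulates and evaluates in about a minute on one CPU;
the test suite uses 10-trial-per-task subjects for unit-level checks and
the full 12-subject cohorts for the analysis-level recovery checks, with
the amplitude sweep run on 6-subject cohorts over two seed blocks per
amplitude.

## What passing tests do and do not show

With this generator, LDA on temporal features is nearly error-free
(~0.1%), template matching reaches a few percent, and LDA on spectral
features sits near 9–10% at the default amplitude. The spectral figure has
a computable ceiling: the only spectral signature of the simulated MRCP is
excess delta-band power (the generator injects no rhythm modulation), and
at a −6 µV surrogate peak against a 2.12 µV surrogate background the
delta-power separation is d′ ≈ 2.7, which caps any classifier on linear
band powers near ~7% error. On real EEG the ranking reverses — temporal
amplitude features degrade under nonstationary, artifact-laden noise,
while spectral features additionally pick up movement-related band-power
modulation — so the synthetic comparison validates the machinery (epoch
alignment, leak-free nested evaluation, statistics), not the field ranking
of feature families. The null-amplitude cohort sits at chance for every
method, and error decreases monotonically with MRCP amplitude, which is
the recovery behaviour the simulation is designed to certify.

## Known limitations

* Background EEG is stationary, Gaussian and independent across channels;
  real recordings violate all three.
* No EOG/artifact modelling or rejection (none is part of the pipeline).
* The evaluation is strictly offline; no sliding-window online detection.
* The minimal EDF writer targets round-tripping this package's recordings
  (integer sampling rate, 1 s records, 16-bit precision); it is not a
  general-purpose EDF library.
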