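# Methods

`szuq` estimates, for each patient, how much a CNN seizure detector's
predictions on that patient's EEG can be trusted. This note describes the
model and the procedure, the choices that were genuinely open, and what the
synthetic evaluation does and does not establish.

## The detection pipeline

EEG recordings (channels × samples, microvolts) are reduced to the
22-channel longitudinal bipolar montage, DC-centred and bandpass filtered
(zero-phase FIR, 1–60 Hz, 513 taps at 256 Hz), min–max normalized to
[0, 1] per channel per recording, and cut into 1-second windows. Ictal
intervals are tiled at a 0.5 s stride (50% overlap, which roughly doubles
the seizure sample count); the 30 s before and after each seizure are kept
as non-seizure windows tagged preictal/postictal; everything else is
interictal. Non-seizure windows are subsampled to at most 5 per seizure
window. The classifier is a four-block CNN over the channels × time image:
one spatial block with a (5 time × 2 channel) kernel, then three temporal
blocks with kernels of 3, 10 and 20 samples, each followed by a rectifier
and time-wise max pooling, then dropout (0.5) and a 128-unit softmax head.
Training uses Adam, cross-entropy, batch 32; the full-scale defaults are
100 epochs at learning rate 1e-4.

Filtering precedes normalization: normalizing first could not deliver the
[0, 1]-bounded input the network expects, since filtering would immediately
leave that range. Normalization scope (per channel, per recording) is
configurable; the per-channel default preserves relative within-recording
dynamics. The 0.5 s overlapped stride is applied to training folds only;
held-out patients are segmented at a plain 1 s stride for both classes so
no test window is duplicated.

## Patient-level uncertainty

After training, the training set itself is pushed back through the
classifier and partitioned by outcome into TP, FP, TN and FN groups. The
flattened activations of the final convolutional block (the "features",
4032-dimensional under the default architecture) are collected per group,
and one Deep SVDD out-of-distribution detector is fitted per group: a
bias-free three-hidden-layer encoder (feature → 128 → 64 → 32) trained to
pull its group's features toward a fixed latent centre, with the binary
flag set by whether a query's squared latent distance exceeds the 0.95
quantile of the group's training distances. At inference each 1 s window
yields a prediction plus four flags, and a rule declares the prediction
*confident* only when the flags cohere with it: a non-seizure prediction
needs at least one non-seizure group (TN or FN) to claim the window as
in-distribution while both seizure groups (TP, FP) reject it; a seizure
prediction needs the mirror image. Of the 32 possible combinations exactly
6 are confident. The patient's score is the mean uncertain bit over their
windows; 0.5 or above classifies the patient as one the detector should
not be trusted on (the boundary resolves to "uncertain" — the conservative
branch for a safety tool).

### Deep SVDD numerical choices

* **Anti-collapse.** Bias-free layers, a centre frozen at the mean latent
  output of the first pass, and autoencoder pretraining (30 epochs of
  reconstruction before the one-class phase). Without pretraining the
  encoder contracts *everything* toward the centre, so slightly shifted
  but legitimate data (an unseen patient's background EEG) is rejected
  wholesale. A variance floor on the latent output turns silent collapse
  into an explicit fit failure.
* **Standardization.** Features are standardized per dimension on the
  fitting set, with the scale floored at 5% of the mean standard
  deviation so near-constant dimensions cannot dominate.
* **Shared pretraining corpus for the group detectors.** Inside the
  grouped model the autoencoder bases are pretrained on the *full*
  training feature set, and each group detector is derived by re-running
  only the one-class contraction (and threshold) on the group's own
  features. A base pretrained only on, say, TP features has an undefined
  latent map for background data — background can land arbitrarily close
  to the TP centre, making every non-seizure prediction unconfident.
  Anchoring the map on all training data removes that failure mode and
  lets the (expensive) pretraining be shared across groups.
* **Few one-class epochs (5) in the experiment pipeline.** On a few
  hundred 4032-dimensional vectors, prolonged one-class training shrinks
  the sphere onto the training identities and every unseen patient is
  flagged; a short contraction after pretraining keeps the boundary
  meaningful. (The detector class's own default is 30 epochs, appropriate
  for lower-dimensional inputs.)
* **Seed ensembles.** Small Deep SVDDs are volatile: the acceptance rate
  on an unseen patient can swing widely with the initialization seed. Each group detector is therefore a majority vote of 3
  independently seeded members, which keeps each member's geometry intact
  while substantially cutting the seed-to-seed variance of the flag
  rates.
  The overfitting and volatility risk of small groups is inherent to the
  approach; groups below 20 members are not fitted at all — their flag is
  pinned to "out-of-distribution" and the condition reported.
* **Threshold calibration for unseen patients.** The in-sample quantile
  rho is calibrated on patients that are *in* the training set; a new
  patient's data sits systematically farther out, by a factor that varies
  from fold to fold, so a raw quantile threshold classifies a
  legitimate unseen patient's entire background as out-of-distribution or
  not as an all-or-nothing coin flip. The grouped model therefore
  estimates the inflation empirically — leave one *training* patient out
  of the contraction, measure their median distance relative to that
  model's rho, take the 75th percentile across training patients — and
  widens each member's threshold by that factor, but never so far that
  more than ~5% of the *complementary class's* training features (background
  for the seizure groups, ictal for the non-seizure groups) would pass as
  in-distribution. Without patient identities the threshold falls back to
  a fixed configurable margin. The standalone single-SVDD baseline keeps
  the vanilla in-sample quantile threshold: it has no groups and therefore
  no complementary set, and the comparison is against the method as
  commonly implemented.
* **Boundary.** A distance exactly at the threshold counts as
  in-distribution; flags are monotone in distance by construction.

## Baselines and evaluation

Three standard uncertainty estimators are aggregated to patient level for
comparison: SoftMax confidence (per window `2·(1 − max p)`, mapping the
two-class range [0.5, 1] onto [0, 1]), Monte Carlo dropout (30 stochastic
passes of the dropout + head layers — the convolutional stack is
deterministic, so its features are computed once — with the normalized
predictive entropy of the mean class-1 probability as the window
uncertainty), and a single Deep SVDD fitted on the undivided training
features (same ensemble construction as the group detectors, for a
like-for-like comparison). SoftMax and MC-dropout scores cluster near 0,
so cohort min–max rescaling is applied before thresholded classification;
correlations and rank-AUC use the raw scores, which rescaling cannot
change.

Ground truth for "should the model be uncertain about this patient" is the
detector's own held-out F1: confident iff F1 strictly exceeds a threshold
(0.5 by default; 0.7 and 0.8 model more conservative use). Methods are
scored by the Pearson correlation of patient score with F1 (effective
methods are strongly negative) and by patient-level
accuracy/sensitivity/specificity/rank-AUC with "uncertain" as the positive
class. Cohort summaries report means and sample (n−1) standard deviations
to two decimals; the bundled 23-patient CHB-MIT reference table of the CNN
architecture reproduces its printed aggregate row under exactly these
conventions.

## The synthetic cohort

Real multi-patient EEG at the scale needed for leave-one-patient-out
training is tens of gigabytes and days of compute, so the package ships a
generator that reproduces the *structural* properties the method depends
on, with every quantity seeded and reproducible:

* **Background**: 1/f-filtered Gaussian noise mixed through a low-rank
  spatial matrix shared across the cohort (scalp channels are correlated
  the same way across people) with a small per-patient perturbation, and a
  stationary Ornstein–Uhlenbeck log-amplitude modulation (σ = 0.25,
  τ = 20 s) emulating vigilance-like waxing and waning. The modulation
  matters: it gives each patient's background a realistic within-patient
  spread, without which any detector keys on microscopic per-patient
  normalization differences and flags every unseen patient.
* **Seizures**: rare annotated bursts (defaults: two 6 s seizures in
  600 s, 2% ictal time) from a *morphology family* — a (frequency,
  waveform, amplitude-ratio) triple. In-distribution families are classic
  high-amplitude 3 Hz spike-wave and 5 Hz polyspike discharges (3.5–4×
  background). The out-of-distribution family is a 9 Hz narrowband-noise
  rhythm at 1.02× background: nearly invisible in the time domain to a
  detector trained on sharp high-amplitude discharges, which is precisely
  the failure mode the method exists to catch — the detector misses these
  seizures *confidently*, so probability-based baselines stay blind while
  the feature-space detectors see a shifted distribution.
* **Interictal epileptiform discharges**: brief (0.4 s) isolated spikes
  of the patient's own family waveform scattered through the background
  (10 per minute, 2× background amplitude), unannotated — clinical
  annotations mark seizures only. This reproduces a central fact of
  epilepsy EEG: a patient with a distinct pathology differs *throughout*
  the record, not just during the seconds of ictal activity. It is what
  gives an out-of-distribution patient a patient-level (rather than
  2%-of-windows) uncertainty signal, while the classifier — which saw
  in-distribution-family spikelets labelled non-seizure in training —
  confidently labels them background.
* **Cohort**: 8 patients by default, two of which carry the
  out-of-distribution family that no other patient has; per-patient seeds
  derive from one cohort seed.

What passing the synthetic suite shows: the full chain — preprocessing,
LOPO training, group partitioning, detector fitting, the rule, aggregation
and evaluation — behaves as designed, detects held-out patients with
unseen morphologies as uncertain, and anticorrelates with detection skill
more strongly than all three baselines. What it does not show: performance
on real EEG, with its artifacts, electrode variability, non-stationary
pathology and far messier morphology families; the printed CHB-MIT results
bundled with the package are the reference point for that setting.

## Scaled experiment conditions

The default end-to-end experiment (`ExperimentConfig.scaled()`) is sized
for a single CPU: 8 patients × 600 s recordings, CNN trained 8 epochs at
learning rate 1e-3 (the larger rate compensating the shorter schedule;
full-scale defaults remain 100 epochs at 1e-4), Deep SVDDs with 30
pretraining + 5 one-class epochs and 3-member votes. A complete
leave-one-patient-out run takes roughly 16 minutes.

## Known limitations

* The rule's degenerate-group fallback (flag pinned to 1) makes a
  near-perfect classifier's FP/FN groups uninformative; confidence then
  rests entirely on the TP/TN detectors.
* Patient scores concentrate where the detectors' flag rates put them;
  with 95%-quantile thresholds an in-distribution patient's score floors
  around 0.05 per informative group and in practice sits well above it.
  The 0.5 decision threshold is therefore best treated as configurable.
* Deep SVDD on small groups remains intrinsically volatile; the ensemble
  reduces but does not remove this.
* The EDF writer covers plain EDF with one-second records and 16-bit
  quantization — sufficient for fixtures and round-trips, not a general
  EDF+ implementation.
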