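# Methods

This note documents the models, the numerical choices and the synthetic
data assumptions behind the `aecopd` pipeline, and what the tests do and
do not establish about real clinical recordings.

## Signal conditioning

Recordings are two-channel (tracheal + environmental reference),
8000 Hz, amplitudes normalized to [-1, 1] on read; all thresholds are
defined on that scale.

**Band-pass filter.** Lung-sound energy lives between 100 and 2000 Hz;
heart and muscle sounds dominate below 100 Hz. The filter is a
linear-phase equiripple FIR designed by Parks–McClellan with band edges
100/2000 Hz, 50 Hz transition bands on each side, 0.5 dB pass-band
ripple and 80 dB stop-band attenuation. The order is estimated by
Bellanger's formula (≈ 499 taps at these specs) and increased until the
evaluated response meets the specification on a dense grid; a
Kaiser-window design is the fallback if the exchange algorithm fails.
Group delay ((N−1)/2 samples) is compensated so features stay aligned
with the raw timeline.

**RLS noise cancellation.** A tapped-delay-line RLS filter (order 16
per reference, forgetting factor λ = 0.995, initial inverse-correlation
matrix P(0) = 100·I) predicts the interference in the band-passed
signal from (a) the environmental microphone and (b) a heart-sound
surrogate — the raw tracheal channel low-pass filtered below 100 Hz,
which is the standard stand-in when no dedicated heart estimate is
available (it can be disabled). With λ < 1 and a narrowband reference
the inverse-correlation matrix grows without bound along unexcited
directions and the weights diverge; P is therefore symmetrized every
step and its trace bounded at 10⁴ per tap. The bound never activates on
well-excited (broadband) references, and with λ = 1 the recursion
reduces to growing-window least squares, verified in the tests against
the normal-equation solution.

## The 112-feature bank

Ordering: 13 STFT means, 13 STFT SDs, 13 MFCC means, 13 MFCC SDs,
18 db8 DWT, 18 bior1.5 DWT, 12 instantaneous-frequency means, 12 SDs.

**STFT parameters** are computed per 64 ms Hamming frame (512 samples,
25% overlap, i.e. hop 384). Each frame's power spectrum is restricted
to the 100–2000 Hz analysis band and renormalized to unit mass — our
reading of "frequency normalization"; it makes all 13 parameters
functionals of a probability distribution over in-band frequency.
Parameters: mean frequency Σf·p(f); median frequency (smallest f with
cumulative mass ≥ 0.5, ties broken low); crest factor max(p)/mean(p);
Shannon entropy −Σp·log₂p; Rényi and Tsallis entropies with orders
α = q = 2 (the quadratic-entropy convention in the lung-sound
literature; configurable); relative power in the four octave bands
100–200/200–400/400–800/800–2000 Hz; the second central spectral
moment; and spectral skewness and kurtosis as 3rd/4th standardized
moments about the mean frequency (kurtosis non-excess; all three
moment-type parameters are 0 for a degenerate single-bin spectrum).
Zero-energy frames are dropped rather than propagating NaNs.

**MFCCs** reuse the same framing: magnitude spectrum → 26 triangular
mel filters spanning 0–4000 Hz → log with floor 10⁻¹⁰ → orthonormal
DCT-II → coefficients 1–13 ("first thirteen" excludes the 0th, overall
energy, coefficient, the standard speech-processing convention).

**DWT features** use a 2-level decomposition (periodization boundary
mode, so A2 + D2 reconstructs A1 exactly) for each of Daubechies-8 and
Biorthogonal-1.5. Subbands at 8 kHz sampling: A1 (0–2000 Hz), A2
(0–1000 Hz), D2 (1000–2000 Hz). Per subband: mean absolute value,
average power, SD, ratio of adjacent-subband absolute means (A1/A2,
A2/D2, D2/A2 — one ratio per subband; zero denominator → 0), skewness
and kurtosis (Fisher–Pearson, non-excess, zero-variance → 0).

**HHT features.** Empirical mode decomposition is implemented in the
package: cubic-spline envelopes through the local extrema
(mirror-extended by the two nearest extrema at each edge to tame spline
overshoot), mean-envelope subtraction, a Cauchy-type sifting criterion
(normalized squared change < 0.2, at most 10 sifts per mode), at most
12 modes, extraction stopping when the residual is monotonic. The
identity IMFs + residual = input holds to round-off by construction.
Instantaneous frequency is the central-difference derivative of the
unwrapped analytic-signal phase divided by 2π, applied to the full
recording (not per frame); the first and last 5% of samples are trimmed
before mean/SD to suppress Hilbert end effects, and missing IMF slots
are zero-filled. On pure tones the first mode's IF recovers the tone
frequency to well under 2%.

## Dataset construction

An onset and the 7 preceding days form the positive class (8 labelled
days per clean event, truncated at the series start); days 1–14 after
an onset are recovery and are masked out of training and evaluation; an
onset inside the previous event's recovery window is a non-recovered
exacerbation and is dropped. Features are smoothed per patient with a
**trailing** (causal) 14-day calendar window — a centred window would
leak post-onset information into the prodrome — with missing days
skipped (mean of available days) rather than imputed. Smoothing runs
over all recorded days, including later-masked ones: masking expresses
evaluation exclusion, not data absence. When label and mask windows of
distinct events overlap, masking wins.

## Classifier and model selection

Features are z-scored and decomposed by correlation-matrix PCA — the
feature families have wildly different units, so covariance PCA would
be dominated by a few scales, and the eigenvalue-greater-than-1 Kaiser
rule presumes the correlation metric. The retained k eigenvectors,
scaled by √eigenvalue, are Varimax-rotated with Kaiser row
normalization; the rotation is computed by Kaiser's pairwise planar
updates with the optimal angle in closed form (tolerance 10⁻⁸, 500
sweeps), which does not stall at the symmetric saddle points where
gradient-projection updates can; projection uses the rotated
orthonormal axes, so the spanned subspace and retained variance are
rotation-invariant.

The SVM uses K(x, y) = exp(−‖x−y‖²/(2σ²)) (so scikit-learn's
γ = 1/(2σ²)). Hyperparameter grids: σ ∈ {0.001, 1, 2, …, 20} and
C ∈ {0.1, 1, 10, 10², 10³, 10⁴, 5·10⁴} — the C range read as
multiplicative steps of 10; a linear step of 10 over [0.1, 50 000]
would give 5000 grid points inside a nested CV, which is implausible.
Both grids are configurable, and the canned experiments use reduced
grids (σ ∈ {1, 3, 10}, C ∈ {1, 10, 100}, k ∈ {4, 8, 17}) to keep a
full nested run on one CPU in the minutes range; the selected values
have always sat in the interior of these ranges in our runs.

Selection is nested: an outer stratified 10-fold loop scores every
candidate k by the mean held-out G_M = √(Se·Sp) and RMSE; with hard 0/1
outputs RMSE is exactly √(held-out error rate), so accuracy + RMSE² = 1.
The inner 4-fold grid search maximizes G_M with ties broken toward
smaller C, then larger σ. k is selected at the RMSE minimum (ties to
smaller k); the G_M-maximal k, the mean eigenvalue profile (Kaiser
count) and the cumulative-variance curve are reported alongside. The
final model is refitted on all valid rows at the selected k. Evaluation
uses the pooled outer-fold held-out predictions, never in-sample refit
outputs.

**Fold design.** Two options are provided and the distinction matters:

- *Pooled patient-blind stratified folds* (default) mirror the original
  telemonitoring protocol, which pools all patients' days.
- *Patient-grouped folds* hold out whole patients and measure
  generalization to unseen subjects. When the outer folds are grouped,
  the inner grid search is grouped as well — a pooled inner CV would
  reward hyperparameters that memorize a patient's neighbouring days.

The 14-day smoothing makes adjacent days near-duplicates of each other.
Under pooled folding a flexible classifier can therefore score far
above chance on a cohort with *no* signal at all (we measure CV G_M
≈ 0.88 on null cohorts) purely by memorizing a held-out day's
neighbours; this is a property of the protocol, not an implementation
leak — training-fold artifacts are verified bit-for-bit unchanged under
held-out label shuffling. Consequently the package's null-calibration
experiments always use patient-grouped folds (null G_M ≈ 0.2–0.3,
i.e. chance), while detection-capability experiments use the pooled
protocol. Absolute day-level metrics obtained under pooled folding
should be read with this caveat.

**Alarm rule.** An alarm fires on day t iff the classifier is positive
on `rule_days` = 2 consecutive calendar days ending at t, both valid;
gaps (missing recordings, recovery masks) break consecutiveness. An
event is detected iff at least one alarm day falls in
[onset − 7, onset]; the margin is onset minus the first such alarm day.
A false-alarm episode is a maximal run of consecutive alarm days wholly
outside every event's prodromal window, so n isolated false-positive
days collapse into few counted episodes.

## Synthetic cohorts

Two generators, both pure functions of (parameters, seed):

**Feature-level** (`synth_cohort_features`): baseline days are drawn
from a stationary low-rank factor model — 4 shared factors explaining
60% of each feature's unit variance, plus independent noise — so PCA
has realistic correlated structure to find. During each prodromal
window, 12 randomly chosen features (of 112) ramp linearly from 0 to
`effect_size` SD at onset; the default effect size 1.5 SD represents a
clearly present but noisy day-level drift. Defaults: 15 patients × 180
days, 2 events per patient (~30 events), onsets spaced to guarantee
clean recovery, 10% of days missing at random. These are the study
conditions of the end-to-end experiments.

**Audio-level** (`synth_breath`, `synth_cohort_audio`): the main
channel is breathing-envelope-modulated band-limited noise plus
amplitude-modulated sinusoidal wheezes (default 400/620 Hz), damped
crackle transients, sub-100 Hz heart thumps and ambient interference;
the reference channel carries the ambient component only, so adaptive
cancellation is learnable. Amplitudes are soft-limited by tanh. Along a
cohort, wheeze intensity and crackle rate follow the prodromal ramp.

What the generators do *not* emulate: patient-specific acoustics and
sensor coupling, respiratory-phase structure within a breath,
day-to-day autocorrelated baselines (colds, weather), label noise in
onset dates, and the heterogeneity of real exacerbation phenotypes.
Passing the end-to-end tests therefore shows that the pipeline recovers
the kind of structure it is designed for at realistic sample sizes —
not that comparable performance would be obtained on real recordings.

## Degenerate inputs and conventions

Silent or constant signals: zero-energy frames are dropped, the MFCC
log floor keeps features finite, EMD of a constant yields an all-zero
HHT block with a warning. Single-channel WAVs get an all-zero reference
(RLS becomes a no-op). Metrics with zero denominators are reported as
undefined rather than 0. Constant feature columns are guarded with unit
scale in standardization.

## Known limitations

- EMD has no uniqueness guarantees; different sifting parameters change
  the mode split (the defaults are the common SD-0.2/10-sift choice).
- The heart-reference surrogate is a documented stand-in; a dedicated
  heart-sound estimator would likely cancel cardiac interference
  better.
- Day-level metrics under the pooled protocol are optimistic for the
  reason discussed above; event-level detection with patient-grouped
  folds is the stricter, more transferable claim and is noticeably
  harder (detection drops from ~100% to ~70–90% on the same cohorts).
- The full σ/C/k grids are expensive; the reduced defaults of the
  canned experiments trade exhaustiveness for runtime and are stated
  explicitly so results are reproducible.
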