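# aecopd — early detection of COPD exacerbations from daily respiratory sounds

Acute exacerbations of chronic obstructive pulmonary disease (AECOPD)
drive most of the hospitalisation burden of the disease, and they are
usually preceded by a prodromal phase of roughly seven days in which
airway obstruction — and with it adventitious lung sounds such as
wheezes — builds up gradually. This package implements a complete
telemonitoring analysis pipeline that turns daily self-recorded
tracheal sounds into an early-warning alarm:

1. **Signal conditioning** — DC removal, a 100–2000 Hz equiripple FIR
   band-pass (≥ 80 dB stop-band attenuation) and recursive-least-squares
   (RLS) adaptive noise cancellation driven by an environmental
   reference microphone and a heart-sound surrogate.
2. **Feature bank** — each recording is summarised by 112 features:
   26 STFT spectral parameters (mean/median frequency, crest factor,
   Shannon/Rényi/Tsallis entropies, octave-band relative powers,
   spectral moments; mean and SD over 64 ms Hamming frames with 25%
   overlap), 26 MFCC statistics, 36 wavelet subband statistics (db8 and
   bior1.5, subbands A1/A2/D2) and 24 Hilbert–Huang features (mean and
   SD of the instantaneous frequencies of 12 intrinsic mode functions).
3. **Dataset construction** — each exacerbation onset and the 7 days
   before it are labelled positive, the 14 days after are masked as
   recovery, and features are smoothed with a trailing 14-day window.
4. **Classifier** — correlation-matrix PCA with Varimax rotation
   followed by an RBF-kernel SVM, K(x, y) = exp(−‖x−y‖²/(2σ²)); the
   component count k and (σ, C) are chosen by nested cross-validation
   (outer 10-fold scored by G_M = √(Se·Sp) and RMSE = √(error rate),
   inner 4-fold grid search).
5. **Alarm rule** — an alarm is raised only after two consecutive
   positive days, screening out isolated bad days; an exacerbation
   counts as detected when an alarm falls inside its 8-day prodromal
   window.

No public corpus of daily patient recordings exists, so the package
ships a synthetic generator (`aecopd.synthgen`) at two fidelities —
raw two-channel breath audio and day-level feature tables — with
planted prodromal drift, and every stage is validated against
brute-force oracles and end-to-end recovery experiments on those
cohorts.

## Worked example

```python
from aecopd.experiments import run_cohort_experiment
from aecopd.evaluation import render_report

res = run_cohort_experiment(seed=3, effect_size=1.5, n_patients=6, n_days=120)
print(render_report(res.report))
```

prints (day-level metrics are over the pooled held-out predictions of
the outer cross-validation folds; the event-level rows apply the 2-day
alarm rule on top):

```
Classifier performance evaluation
  True Positives (TP)              76
  True Negatives (TN)              398
  False Positives (FP)             7
  False Negatives (FN)             11
  Sensitivity (Se)                 87.36%
  Specificity (Sp)                 98.27%
  Geometric mean (G_M)             0.927
  RMSE                             0.1913
  Positive Predictive Value (PPV)  91.57%
  Negative Predictive Value (NPV)  97.31%
  Accuracy                         96.34%
  False alarm episodes             1
  Events detected                  12 / 12 (100.00%)
  Prediction margin (days)         4.6 ± 1.3
```

All 12 planted exacerbations were flagged, on average 4.6 days before
onset, with a single false-alarm episode across ~500 monitored days.
The `examples/` directory holds one short script per capability
(conditioning, feature extraction, dataset construction,
training/alarms), each printing the numbers it computes.

A command-line interface mirrors the stages for shell use:

```bash
aecopd run-all --out run/ --patients 4 --days 90 --seed 0
aecopd simulate --audio --out cohort/   # daily WAV files instead
```

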