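"""Synthetic breath-sound and cohort generators with planted prodromes.

Two fidelities:

- :func:`synth_breath` renders one day's two-channel audio: breathing-
  envelope-modulated band-limited noise (the normal lung sound), wheezes
  (amplitude-modulated sinusoids in 200–800 Hz), crackles (short damped
  impulses), heart thumps below 100 Hz and ambient interference shared
  with the reference channel.
- :func:`synth_cohort_features` skips the audio and draws day-level
  112-feature vectors directly from a correlated baseline (low-rank
  factor model), ramping a chosen subset of features upward over the
  prodromal window before each planted exacerbation.  This keeps
  dataset/model/evaluation tests off the audio-processing cost.

All generators are pure functions of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from aecopd.cohort import ExacerbationEvent, PRODROME_DAYS, RECOVERY_DAYS
from aecopd.features import feature_names
from aecopd.preprocess import AudioRecording

__all__ = [
    "SoundParams",
    "CohortParams",
    "synth_breath",
    "synth_cohort_features",
    "synth_cohort_audio",
]


@dataclass
class SoundParams:
    """Acoustic composition of one synthetic recording."""

    duration_s: float = 10.0
    breaths_per_min: float = 15.0
    wheeze_intensity: float = 0.0
    wheeze_freqs: tuple[float, ...] = (400.0, 620.0)
    crackle_rate: float = 0.0      # events per second
    heart_level: float = 0.2
    ambient_level: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for lvl in (self.wheeze_intensity, self.heart_level, self.ambient_level):
            if not (0 <= lvl <= 1):
                raise ValueError("levels must lie in [0, 1]")
        for f in self.wheeze_freqs:
            if not (100 <= f <= 2000):
                raise ValueError("wheeze frequencies must lie in 100-2000 Hz")


@dataclass
class CohortParams:
    """Layout of a synthetic monitored cohort.

    ``effect_size`` is the standardized mean shift reached by each
    affected feature at onset; the prodromal drift ramps linearly up to
    it over ``prodrome_len`` days.
    """

    n_patients: int = 15
    n_days: int = 180
    events_per_patient: int = 2
    prodrome_len: int = PRODROME_DAYS
    effect_size: float = 1.5
    n_affected_features: int = 12
    missing_day_rate: float = 0.1
    n_factors: int = 4
    factor_strength: float = 0.6   # fraction of baseline variance from factors
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        min_gap = self.prodrome_len + RECOVERY_DAYS + 2
        if self.events_per_patient * min_gap > self.n_days:
            raise ValueError(
                f"{self.events_per_patient} events need more than "
                f"{self.events_per_patient * min_gap} monitored days"
            )


def _breath_envelope(n: int, rate: float, breaths_per_min: float,
                     rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / rate
    f_b = breaths_per_min / 60.0
    phase = 2 * np.pi * (f_b * t + 0.02 * rng.standard_normal() )
    env = 0.25 + np.abs(np.sin(phase)) ** 1.5
    return env


def synth_breath(params: SoundParams, rate: int = 8000) -> AudioRecording:
    """Render one synthetic two-channel breath recording.

    The reference channel carries only the ambient interference, so
    adaptive cancellation of the correlated component is learnable.
    Amplitudes are softly limited to [-1, 1].
    """
    if rate <= 4000:
        raise ValueError("rate must exceed 4000 Hz for the 100-2000 Hz band")
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * rate))
    t = np.arange(n) / rate
    env = _breath_envelope(n, rate, params.breaths_per_min, rng)

    # normal lung sound: band-limited (100-1000 Hz) noise under the envelope
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1 / rate)
    shape = np.exp(-((freqs - 300.0) ** 2) / (2 * 350.0**2))
    shape[freqs < 80] = 0.0
    base = np.fft.irfft(spec * shape, n)
    base = 0.25 * base / (np.std(base) + 1e-12) * env

    wheeze = np.zeros(n)
    if params.wheeze_intensity > 0:
        for f in params.wheeze_freqs:
            ph = rng.uniform(0, 2 * np.pi)
            jitter = 1.0 + 0.01 * np.sin(2 * np.pi * 0.7 * t + rng.uniform(0, 6))
            wheeze += np.sin(2 * np.pi * f * jitter * t + ph)
        wheeze *= 0.2 * params.wheeze_intensity * env / max(1, len(params.wheeze_freqs))

    crackles = np.zeros(n)
    if params.crackle_rate > 0:
        n_crackles = rng.poisson(params.crackle_rate * params.duration_s)
        for _ in range(n_crackles):
            i0 = rng.integers(0, max(1, n - 80))
            dur = int(rng.integers(30, 80))
            tt = np.arange(dur) / rate
            f_c = rng.uniform(600, 1400)
            crackles[i0 : i0 + dur] += (
                0.3 * np.exp(-tt / 0.004) * np.sin(2 * np.pi * f_c * tt)
            )

    heart = np.zeros(n)
    if params.heart_level > 0:
        hr = rng.uniform(60, 80) / 60.0
        for beat_t in np.arange(rng.uniform(0, 0.5), params.duration_s, 1 / hr):
            i0 = int(beat_t * rate)
            dur = min(int(0.12 * rate), n - i0)
            if dur <= 0:
                continue
            tt = np.arange(dur) / rate
            heart[i0 : i0 + dur] += (
                params.heart_level
                * 0.5
                * np.exp(-tt / 0.03)
                * np.sin(2 * np.pi * 45.0 * tt)
            )

    ambient = np.zeros(n)
    if params.ambient_level > 0:
        amb_white = rng.standard_normal(n)
        spec_a = np.fft.rfft(amb_white)
        shape_a = 1.0 / (1.0 + (freqs / 500.0) ** 2)
        ambient = np.fft.irfft(spec_a * shape_a, n)
        ambient = params.ambient_level * 0.3 * ambient / (np.std(ambient) + 1e-12)

    main = base + wheeze + crackles + heart + 0.8 * ambient
    main = np.tanh(main)  # soft limiter keeps [-1, 1]
    return AudioRecording("", 0, main, ambient, rate=rate)


def _plan_onsets(params: CohortParams, rng: np.random.Generator) -> list[int]:
    """Evenly spread onset days with jitter, respecting recovery spacing."""
    min_gap = params.prodrome_len + RECOVERY_DAYS + 2
    k = params.events_per_patient
    if k == 0:
        return []
    slots = np.linspace(params.prodrome_len + 3, params.n_days - 2, k + 1)
    onsets = []
    prev = -min_gap
    for i in range(k):
        lo = max(int(slots[i]), prev + min_gap)
        hi = max(lo + 1, int(slots[i + 1]) - 3)
        d = int(rng.integers(lo, hi))
        d = min(d, params.n_days - 1)
        if d <= prev + min_gap - 1:
            continue
        onsets.append(d)
        prev = d
    return onsets


def synth_cohort_features(
    params: CohortParams,
) -> tuple[dict[str, pd.DataFrame], list[ExacerbationEvent]]:
    """Draw day-level feature tables with a planted prodromal drift.

    Baseline days come from a stationary low-rank factor model (shared
    factors + independent noise, unit total variance per feature).
    During each prodromal window, ``n_affected_features`` randomly chosen
    features ramp linearly from 0 to ``effect_size`` standard deviations
    at onset.  Days are dropped independently at ``missing_day_rate``.
    Deterministic given the params (including seed).
    """
    rng = np.random.default_rng(params.seed)
    names = list(feature_names())
    p = len(names)
    affected = rng.choice(p, size=params.n_affected_features, replace=False)
    load = rng.standard_normal((p, params.n_factors))
    load /= np.linalg.norm(load, axis=1, keepdims=True)
    load *= np.sqrt(params.factor_strength)
    noise_sd = np.sqrt(1.0 - params.factor_strength)
    baseline_mean = rng.normal(0.0, 2.0, size=p)

    per_patient: dict[str, pd.DataFrame] = {}
    events: list[ExacerbationEvent] = []
    for pi in range(params.n_patients):
        pid = f"P{pi:02d}"
        onsets = _plan_onsets(params, rng)
        drift = np.zeros((params.n_days, p))
        for d in onsets:
            for back in range(params.prodrome_len + 1):
                day = d - back
                if day < 0:
                    continue
                level = params.effect_size * (1 - back / params.prodrome_len) \
                    if params.prodrome_len > 0 else params.effect_size
                drift[day, affected] = np.maximum(drift[day, affected], level)
            kind = "medical_attention" if rng.random() < 0.75 else "self_medication"
            events.append(ExacerbationEvent(pid, d, kind))
        factors = rng.standard_normal((params.n_days, params.n_factors))
        X = (
            baseline_mean
            + factors @ load.T
            + noise_sd * rng.standard_normal((params.n_days, p))
            + drift
        )
        present = rng.random(params.n_days) >= params.missing_day_rate
        present[0] = True  # anchor the series start
        idx = np.nonzero(present)[0]
        per_patient[pid] = pd.DataFrame(X[idx], index=idx, columns=names)
    return per_patient, events


def synth_cohort_audio(
    params: CohortParams,
    base_sound: SoundParams | None = None,
    rate: int = 8000,
) -> tuple[list[AudioRecording], list[ExacerbationEvent]]:
    """Render daily audio for a cohort whose wheeze content ramps up
    before each planted exacerbation.

    Per day, wheeze intensity and crackle rate follow the linear
    prodromal ramp (scaled by ``effect_size`` capped at intensity 1).
    Returns one recording per monitored day (missing days dropped) plus
    the event log.  Deterministic given params and seed.
    """
    base_sound = base_sound or SoundParams()
    rng = np.random.default_rng(params.seed)
    recordings: list[AudioRecording] = []
    events: list[ExacerbationEvent] = []
    for pi in range(params.n_patients):
        pid = f"P{pi:02d}"
        onsets = _plan_onsets(params, rng)
        ramp = np.zeros(params.n_days)
        for d in onsets:
            for back in range(params.prodrome_len + 1):
                day = d - back
                if day >= 0 and params.prodrome_len > 0:
                    ramp[day] = max(ramp[day], 1 - back / params.prodrome_len)
            events.append(ExacerbationEvent(pid, d))
        for day in range(params.n_days):
            if day > 0 and rng.random() < params.missing_day_rate:
                continue
            level = min(1.0, ramp[day] * params.effect_size / 1.5)
            sp = replace(
                base_sound,
                wheeze_intensity=min(1.0, base_sound.wheeze_intensity + 0.7 * level),
                crackle_rate=base_sound.crackle_rate + 3.0 * level,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rec = synth_breath(sp, rate=rate)
            rec.patient_id = pid
            rec.day_index = day
            recordings.append(rec)
    return recordings, events
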