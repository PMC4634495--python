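"""Day-level supervised dataset construction.

An exacerbation's prodromal phase — roughly the seven days of worsening
symptoms before the onset — is the positive class: the onset day and the
seven preceding days are labelled 1, everything else 0.  The two weeks
after an onset are a recovery period and are masked out of training and
evaluation.  An onset falling inside the previous event's recovery window
is a non-recovered exacerbation and is dropped from the event list.

Daily feature vectors are smoothed with a trailing (causal) 14-day mean
before labelling; a centred window would leak post-onset information into
the prodrome and invalidate "early" detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExacerbationEvent",
    "CohortDataset",
    "label_days",
    "filter_recovered_events",
    "smooth_features",
    "assemble",
    "PRODROME_DAYS",
    "RECOVERY_DAYS",
]

PRODROME_DAYS = 7   # days before onset labelled positive (plus the onset)
RECOVERY_DAYS = 14  # days after onset masked out


@dataclass(frozen=True)
class ExacerbationEvent:
    """One exacerbation onset for one patient."""

    patient_id: str
    onset_day: int
    kind: str = "medical_attention"  # or "self_medication"


@dataclass
class CohortDataset:
    """Per-patient day-indexed feature table with labels and validity mask.

    ``rows`` has one row per (patient, day) ordered by patient then day,
    with the smoothed feature columns plus ``patient_id``, ``day_index``,
    ``label`` and ``valid``.  Invalid rows (recovery periods) are retained
    but excluded from training and evaluation selections.
    """

    rows: pd.DataFrame
    events: list[ExacerbationEvent] = field(default_factory=list)
    smoothing_window_days: int = 14

    @property
    def feature_columns(self) -> list[str]:
        meta = {"patient_id", "day_index", "label", "valid"}
        return [c for c in self.rows.columns if c not in meta]

    def valid_rows(self) -> pd.DataFrame:
        return self.rows[self.rows["valid"]]

    def X_y(self) -> tuple[np.ndarray, np.ndarray]:
        """Feature matrix and labels over valid rows only."""
        v = self.valid_rows()
        return v[self.feature_columns].to_numpy(float), v["label"].to_numpy(int)


def filter_recovered_events(
    onsets: list[int], recovery_days: int = RECOVERY_DAYS
) -> tuple[list[int], list[int]]:
    """Split onsets into clean events and non-recovered ones.

    An onset inside the recovery window (``d+1 .. d+recovery_days``) of
    the last retained event took place before the patient recovered; it is
    excluded and generates no labels.
    """
    kept: list[int] = []
    dropped: list[int] = []
    for d in onsets:
        if kept and d <= kept[-1] + recovery_days:
            dropped.append(d)
        else:
            kept.append(d)
    return kept, dropped


def label_days(
    n_days: int,
    onsets: list[int],
    prodrome_days: int = PRODROME_DAYS,
    recovery_days: int = RECOVERY_DAYS,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-day (label, valid) arrays for one patient.

    For each clean onset *d*: days ``max(0, d-7) .. d`` get label 1
    (window truncated at trial start) and days ``d+1 .. d+14`` are masked
    invalid.  Masking wins over labelling when windows of distinct events
    overlap.  Onsets must be strictly increasing and inside
    ``[0, n_days)``.
    """
    onsets = list(onsets)
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("onset days must be strictly increasing")
    for d in onsets:
        if not (0 <= d < n_days):
            raise ValueError(f"onset day {d} outside monitored range [0, {n_days})")
    kept, _dropped = filter_recovered_events(onsets, recovery_days)
    label = np.zeros(n_days, dtype=int)
    valid = np.ones(n_days, dtype=bool)
    for d in kept:
        label[max(0, d - prodrome_days) : d + 1] = 1
        valid[d + 1 : min(n_days, d + recovery_days + 1)] = False
    label[~valid] = 0  # invalid days carry no label
    return label, valid


def smooth_features(
    features: pd.DataFrame, window: int = 14
) -> pd.DataFrame:
    """Trailing-window mean over up to ``window`` available days.

    ``features`` is indexed by day for one patient; missing days may be
    absent from the index or hold NaN rows and are skipped (mean of the
    available days in the window).  The window is truncated at the series
    start, so day 0 equals its raw vector.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    full = features.reindex(
        range(int(features.index.min()), int(features.index.max()) + 1)
    )
    sm = full.rolling(window=window, min_periods=1).mean()
    return sm.loc[features.index.intersection(sm.index)].dropna(how="all")


def assemble(
    per_patient_features: dict[str, pd.DataFrame],
    events: list[ExacerbationEvent],
    window: int = 14,
    n_days: int | None = None,
) -> CohortDataset:
    """Build the supervised cohort dataset.

    ``per_patient_features`` maps patient id → day-indexed raw feature
    frame (missing days simply absent).  Smoothing is applied per patient
    over all recorded days before labels and validity masks are joined;
    masking expresses evaluation exclusion, not data absence.
    """
    known = set(per_patient_features)
    for ev in events:
        if ev.patient_id not in known:
            raise ValueError(f"event for unknown patient {ev.patient_id!r}")
    frames = []
    for pid in per_patient_features:
        feats = per_patient_features[pid].sort_index()
        horizon = n_days if n_days is not None else int(feats.index.max()) + 1
        onsets = sorted(
            ev.onset_day for ev in events if ev.patient_id == pid
        )
        label, valid = label_days(horizon, onsets)
        sm = smooth_features(feats, window=window)
        block = sm.copy()
        days = block.index.to_numpy(int)
        block.insert(0, "patient_id", pid)
        block.insert(1, "day_index", days)
        block["label"] = label[days]
        block["valid"] = valid[days]
        frames.append(block.reset_index(drop=True))
    rows = pd.concat(frames, ignore_index=True)
    return CohortDataset(rows=rows, events=list(events), smoothing_window_days=window)


def save_dataset(ds: CohortDataset, path) -> None:
    """Write the dataset as CSV (feature columns + metadata columns)."""
    ds.rows.to_csv(path, index=False)


def load_dataset(path, events: list[ExacerbationEvent] | None = None) -> CohortDataset:
    """Read a dataset CSV written by :func:`save_dataset`."""
    rows = pd.read_csv(path)
    rows["valid"] = rows["valid"].astype(bool)
    return CohortDataset(rows=rows, events=events or [])


def load_events(path) -> list[ExacerbationEvent]:
    """Read an event log CSV with columns patient_id, onset_day[, kind]."""
    df = pd.read_csv(path)
    kinds = df["kind"] if "kind" in df.columns else ["medical_attention"] * len(df)
    return [
        ExacerbationEvent(str(p), int(d), str(k))
        for p, d, k in zip(df["patient_id"], df["onset_day"], kinds)
    ]
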