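"""Performance metrics for the day-level classifier and the alarm system.

Day-level metrics (sensitivity, specificity, their geometric mean G_M,
RMSE of hard 0/1 outputs, predictive values, accuracy) are computed over
valid — non-recovery-masked — days only.  Event-level metrics ask the
clinically relevant question: was there at least one alarm inside the
8-day prodromal window (onset and the 7 days before it)?  The prediction
margin of a detected event is the number of days between the first such
alarm and the onset; a false-alarm episode is a maximal run of
consecutive alarm days wholly outside every event's prodromal window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from aecopd.cohort import ExacerbationEvent, PRODROME_DAYS

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "confusion",
    "metrics",
    "event_detection",
    "report",
    "evaluate_cohort",
    "render_report",
]


@dataclass
class ConfusionCounts:
    """Day-level confusion counts over valid labelled days."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class EvaluationReport:
    """Full evaluation: day-level metrics + event-level detection."""

    counts: ConfusionCounts
    se: float | None
    sp: float | None
    gm: float | None
    rmse: float
    ppv: float | None
    npv: float | None
    accuracy: float | None
    events_total: int = 0
    events_detected: int = 0
    margins: list[int] = field(default_factory=list)
    false_alarm_episodes: int = 0

    @property
    def detection_rate(self) -> float | None:
        if self.events_total == 0:
            return None
        return self.events_detected / self.events_total

    @property
    def margin_mean(self) -> float | None:
        return float(np.mean(self.margins)) if self.margins else None

    @property
    def margin_sd(self) -> float | None:
        if len(self.margins) < 2:
            return None
        return float(np.std(self.margins, ddof=1))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["detection_rate"] = self.detection_rate
        d["margin_mean"] = self.margin_mean
        d["margin_sd"] = self.margin_sd
        return d


def confusion(
    predictions: np.ndarray,
    labels: np.ndarray,
    valid: np.ndarray | None = None,
) -> ConfusionCounts:
    """Tally day-level confusion counts over valid days only."""
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must be aligned")
    if valid is None:
        valid = np.ones_like(labels, dtype=bool)
    else:
        valid = np.asarray(valid, dtype=bool)
        if valid.shape != labels.shape:
            raise ValueError("valid mask must be aligned with labels")
    p, y = predictions[valid], labels[valid]
    return ConfusionCounts(
        tp=int(np.sum((p == 1) & (y == 1))),
        tn=int(np.sum((p == 0) & (y == 0))),
        fp=int(np.sum((p == 1) & (y == 0))),
        fn=int(np.sum((p == 0) & (y == 1))),
    )


def _ratio(num: int, den: int) -> float | None:
    """A metric with a zero denominator is undefined, not 0."""
    return num / den if den > 0 else None


def metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Derived day-level metrics from confusion counts.

    Returns se, sp, gm, ppv, npv, accuracy and rmse, where
    rmse = √((fp+fn)/total) — for hard binary outputs the RMSE equals the
    square root of the error rate, so accuracy + rmse² = 1.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    se = _ratio(tp, tp + fn)
    sp = _ratio(tn, tn + fp)
    gm = float(np.sqrt(se * sp)) if se is not None and sp is not None else None
    total = counts.total
    return {
        "se": se,
        "sp": sp,
        "gm": gm,
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
        "accuracy": _ratio(tp + tn, total),
        "rmse": float(np.sqrt((fp + fn) / total)) if total > 0 else 0.0,
    }


def event_detection(
    alarm_days: dict[str, np.ndarray],
    events: list[ExacerbationEvent],
    prodrome_days: int = PRODROME_DAYS,
) -> tuple[int, list[int], int]:
    """Event-level detection from per-patient alarm-day indices.

    ``alarm_days`` maps patient id → sorted array of day indices on which
    an alarm was active.  An event is detected iff at least one alarm day
    falls inside ``[onset - prodrome_days, onset]``; its margin is
    ``onset - first such alarm day`` (0 = alarm on the onset day).  A
    false-alarm episode is a maximal run of consecutive alarm days wholly
    outside all events' prodromal windows.

    Returns ``(events_detected, margins, false_alarm_episodes)``.
    """
    detected = 0
    margins: list[int] = []
    windows: dict[str, list[tuple[int, int]]] = {}
    for ev in events:
        windows.setdefault(ev.patient_id, []).append(
            (ev.onset_day - prodrome_days, ev.onset_day)
        )
    for ev in events:
        days = np.asarray(alarm_days.get(ev.patient_id, []), dtype=int)
        lo, hi = ev.onset_day - prodrome_days, ev.onset_day
        inside = days[(days >= lo) & (days <= hi)]
        if inside.size:
            detected += 1
            margins.append(int(ev.onset_day - inside.min()))
    episodes = 0
    for pid, days in alarm_days.items():
        days = np.sort(np.asarray(days, dtype=int))
        wins = windows.get(pid, [])
        in_window = np.array(
            [any(lo <= d <= hi for lo, hi in wins) for d in days], dtype=bool
        ) if days.size else np.array([], dtype=bool)
        run_outside = False
        prev = None
        for d, inw in zip(days, in_window):
            new_run = prev is None or d != prev + 1
            if new_run:
                if run_outside:
                    episodes += 1
                run_outside = not inw
            else:
                run_outside = run_outside and not inw
            prev = d
        if run_outside:
            episodes += 1
    return detected, margins, episodes


def report(
    predictions: np.ndarray,
    labels: np.ndarray,
    valid: np.ndarray,
    alarm_days: dict[str, np.ndarray],
    events: list[ExacerbationEvent],
    prodrome_days: int = PRODROME_DAYS,
) -> EvaluationReport:
    """Assemble the full evaluation report from a complete prediction run."""
    counts = confusion(predictions, labels, valid)
    m = metrics(counts)
    detected, margins, episodes = event_detection(alarm_days, events, prodrome_days)
    return EvaluationReport(
        counts=counts,
        se=m["se"], sp=m["sp"], gm=m["gm"], rmse=m["rmse"],
        ppv=m["ppv"], npv=m["npv"], accuracy=m["accuracy"],
        events_total=len(events),
        events_detected=detected,
        margins=margins,
        false_alarm_episodes=episodes,
    )


def evaluate_cohort(
    dataset,
    outputs_valid: np.ndarray,
    rule_days: int = 2,
    prodrome_days: int = PRODROME_DAYS,
) -> EvaluationReport:
    """Full report from day-level outputs over a dataset's valid rows.

    ``outputs_valid`` is aligned with ``dataset.valid_rows()`` (e.g. the
    pooled cross-validated outputs of model selection, or a trained
    model's predictions).  Invalid (recovery) days are treated as
    classifier-silent: they break alarm consecutiveness and are excluded
    from day-level counts.
    """
    from aecopd.predictor import alarm_rule

    rows = dataset.rows.copy()
    rows["output"] = 0
    rows.loc[rows["valid"], "output"] = np.asarray(outputs_valid, dtype=int)
    alarm_days: dict[str, np.ndarray] = {}
    for pid, grp in rows.groupby("patient_id"):
        grp = grp.sort_values("day_index")
        alarms = alarm_rule(
            grp["output"].to_numpy(int),
            grp["valid"].to_numpy(bool),
            grp["day_index"].to_numpy(int),
            rule_days=rule_days,
        )
        alarm_days[str(pid)] = grp["day_index"].to_numpy(int)[alarms]
    return report(
        rows["output"].to_numpy(int),
        rows["label"].to_numpy(int),
        rows["valid"].to_numpy(bool),
        alarm_days,
        dataset.events,
        prodrome_days=prodrome_days,
    )


def _pct(x: float | None) -> str:
    return "undefined" if x is None else f"{100 * x:.2f}%"


def render_report(rep: EvaluationReport) -> str:
    """Human-readable summary of an evaluation report."""
    c = rep.counts
    lines = [
        "Classifier performance evaluation",
        f"  True Positives (TP)              {c.tp}",
        f"  True Negatives (TN)              {c.tn}",
        f"  False Positives (FP)             {c.fp}",
        f"  False Negatives (FN)             {c.fn}",
        f"  Sensitivity (Se)                 {_pct(rep.se)}",
        f"  Specificity (Sp)                 {_pct(rep.sp)}",
        f"  Geometric mean (G_M)             "
        + ("undefined" if rep.gm is None else f"{rep.gm:.3f}"),
        f"  RMSE                             {rep.rmse:.4f}",
        f"  Positive Predictive Value (PPV)  {_pct(rep.ppv)}",
        f"  Negative Predictive Value (NPV)  {_pct(rep.npv)}",
        f"  Accuracy                         {_pct(rep.accuracy)}",
        f"  False alarm episodes             {rep.false_alarm_episodes}",
        f"  Events detected                  {rep.events_detected} / {rep.events_total}"
        + (
            f" ({_pct(rep.detection_rate)})"
            if rep.detection_rate is not None
            else ""
        ),
    ]
    if rep.margins:
        sd = rep.margin_sd
        lines.append(
            f"  Prediction margin (days)         {rep.margin_mean:.1f}"
            + (f" ± {sd:.1f}" if sd is not None else "")
        )
    return "\n".join(lines)


def save_report(rep: EvaluationReport, path) -> None:
    """Write the report as JSON."""
    with open(path, "w") as fh:
        json.dump(rep.to_dict(), fh, indent=2)
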