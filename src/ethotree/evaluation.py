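"""Accuracy assessment and daily time budgets.

Accuracy is estimated the way field calibrations are scored: observation
*events* (intervals of continuously observed behavior) are the unit, an
event counts as correct when the modal predicted label over its span equals
the observed label at the requested hierarchy level, and the per-class
accuracy is averaged over repeated stratified subsamples (default 100
repetitions of 50 events per class) so that rare behaviors weigh equally.
Two independent checks complement it: nocturnal 15-s samples that a diurnal
nest-sleeping animal should spend in the nest, and low-resolution 7-min
scans scored on their inner 5 minutes against the modal prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ObservationLog
from .labels import LABELS_AT_LEVEL, LabelSeries, aggregate_label, has_level

# §-style seasonal windows shipped as defaults (month, day) inclusive
DEFAULT_SEASON_WINDOWS = {
    "winter": ((2, 15), (2, 25)),
    "mating": ((3, 10), (3, 20)),
    "summer": ((6, 10), (6, 20)),
    "autumn": ((9, 5), (9, 15)),
}


@dataclass
class AccuracyReport:
    level: int
    per_class: dict[str, tuple[float, float]]  # class -> (mean %, sd %)
    overall: tuple[float, float]  # (mean %, sd %)
    confusion: pd.DataFrame = field(repr=False)
    reps: int = 0
    n_per_class: int = 0

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"class": c, "mean_pct": m, "sd_pct": s}
            for c, (m, s) in self.per_class.items()
        ]
        rows.append(
            {"class": "overall", "mean_pct": self.overall[0],
             "sd_pct": self.overall[1]}
        )
        return pd.DataFrame(rows)


@dataclass
class TimeBudget:
    day: int  # calendar-day index since deployment start
    proportions: dict[str, float]
    unclassified: float = 0.0


def _modal_label(labels: np.ndarray) -> str | None:
    if len(labels) == 0:
        return None
    vals, counts = np.unique(labels, return_counts=True)
    return str(vals[np.argmax(counts)])


def _score_events(
    pred: LabelSeries, obs: ObservationLog, level: int
) -> pd.DataFrame:
    """One row per scorable observation event: observed and modal predicted
    label at ``level``.  Events whose label has no representative at the
    level (e.g. stationary movement at level 6) are dropped with a warning.
    """
    plabels = pred.at_level(level).labels
    n = len(plabels)
    rows = []
    n_dropped = 0
    for s, e, lab in obs.intervals:
        if not has_level(lab, level):
            n_dropped += 1
            continue
        i0, i1 = max(0, int(np.ceil(s))), min(n, int(np.ceil(e)))
        if i1 <= i0:
            n_dropped += 1
            continue
        rows.append(
            {
                "start": s,
                "end": e,
                "observed": aggregate_label(lab, level),
                "predicted": _modal_label(plabels[i0:i1]),
            }
        )
    if n_dropped:
        warnings.warn(
            f"{n_dropped} observation event(s) not scorable at level {level}",
            stacklevel=3,
        )
    return pd.DataFrame(rows)


def _subsample_report(
    events: pd.DataFrame,
    level: int,
    n_per_class: int,
    reps: int,
    seed: int | None,
) -> AccuracyReport:
    rng = np.random.default_rng(seed)
    classes = sorted(events["observed"].unique())
    correct = (events["observed"] == events["predicted"]).to_numpy()
    by_class_idx = {
        c: np.flatnonzero((events["observed"] == c).to_numpy())
        for c in classes
    }
    for c in list(by_class_idx):
        if len(by_class_idx[c]) == 0:
            warnings.warn(f"class {c!r} has no events; excluded", stacklevel=3)
            del by_class_idx[c]
    per_class_accs = {c: [] for c in by_class_idx}
    overall_accs = []
    for _ in range(reps):
        class_means = []
        for c, idx in by_class_idx.items():
            k = min(n_per_class, len(idx))
            if k < n_per_class:
                warnings.warn(
                    f"class {c!r}: only {len(idx)} events available "
                    f"(< {n_per_class}); using all",
                    stacklevel=3,
                )
            pick = rng.choice(idx, size=k, replace=False)
            acc = float(np.mean(correct[pick])) * 100.0
            per_class_accs[c].append(acc)
            class_means.append(acc)
        overall_accs.append(float(np.mean(class_means)))
    vocab = [c for c in LABELS_AT_LEVEL[level] if c in by_class_idx]
    confusion = pd.crosstab(
        events["observed"], events["predicted"], dropna=False
    ).reindex(index=vocab, columns=vocab, fill_value=0)
    return AccuracyReport(
        level=level,
        per_class={
            c: (float(np.mean(a)), float(np.std(a, ddof=1)) if reps > 1 else 0.0)
            for c, a in per_class_accs.items()
        },
        overall=(
            float(np.mean(overall_accs)),
            float(np.std(overall_accs, ddof=1)) if reps > 1 else 0.0,
        ),
        confusion=confusion,
        reps=reps,
        n_per_class=n_per_class,
    )


def subsample_accuracy(
    pred: LabelSeries,
    obs: ObservationLog,
    level: int,
    n_per_class: int = 50,
    reps: int = 100,
    seed: int | None = None,
) -> AccuracyReport:
    """Repeated stratified-subsampling accuracy at one hierarchy level."""
    events = _score_events(pred, obs, level)
    if events.empty:
        raise ValueError("no scorable observation events")
    return _subsample_report(events, level, n_per_class, reps, seed)


def low_resolution_validation(
    pred: LabelSeries,
    scans: list[tuple[float, float, str]],
    n_per_class: int = 15,
    reps: int = 100,
    seed: int | None = None,
    inner_s: int = 300,
    level: int = 5,
) -> AccuracyReport:
    """Score 7-min scan records on their inner 5 minutes.

    ``scans`` carry ``(start, end, dominant_label)`` where the dominant
    behavior covered at least 95% of the scan.  Traveling is any
    combination of foraging and running for this test, which the level-5
    aggregation provides.  Events with no prediction overlap are skipped.
    """
    plabels = pred.at_level(level).labels
    n = len(plabels)
    rows = []
    for s, e, lab in scans:
        mid = 0.5 * (s + e)
        i0 = max(0, int(np.ceil(mid - inner_s / 2)))
        i1 = min(n, int(np.ceil(mid + inner_s / 2)))
        if i1 <= i0:
            warnings.warn(
                f"scan ({s}, {e}) has no prediction overlap; skipped",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "start": s,
                "end": e,
                "observed": aggregate_label(lab, level),
                "predicted": _modal_label(plabels[i0:i1]),
            }
        )
    events = pd.DataFrame(rows)
    if events.empty:
        raise ValueError("no scorable scans")
    return _subsample_report(events, level, n_per_class, reps, seed)


def night_nest_check(
    pred: LabelSeries,
    seconds_of_day: np.ndarray,
    n: int = 400,
    sample_len_s: int = 15,
    night: tuple[int, int] = (22, 4),
    seed: int | None = None,
) -> float:
    """Fraction of random nocturnal 15-s samples classified as in the nest.

    A diurnal animal that sleeps in a nest should be in it essentially all
    of 10 p.m.-4 a.m.; this provides a labeled check without observations.
    """
    rng = np.random.default_rng(seed)
    labels2 = pred.at_level(2).labels
    sod = np.asarray(seconds_of_day)
    h0, h1 = night
    in_night = (sod >= h0 * 3600) | (sod < h1 * 3600) if h0 > h1 else (
        (sod >= h0 * 3600) & (sod < h1 * 3600)
    )
    # candidate starts whose whole window stays inside the night
    ok = np.flatnonzero(
        np.convolve(in_night, np.ones(sample_len_s, dtype=int), mode="valid")
        == sample_len_s
    )
    if len(ok) == 0:
        raise ValueError("predictions do not cover any full night window")
    starts = rng.choice(ok, size=n, replace=len(ok) < n)
    hits = 0
    for s in starts:
        if _modal_label(labels2[s:s + sample_len_s]) == "in_nest":
            hits += 1
    return hits / n


def augment_with_night_nest_events(
    obs: ObservationLog,
    seconds_of_day: np.ndarray,
    n: int = 400,
    sample_len_s: int = 15,
    night: tuple[int, int] = (22, 4),
    seed: int | None = None,
    drop_observed_in_nest: bool = True,
) -> ObservationLog:
    """Add nocturnal 15-s events labeled in_nest to an observation log.

    Field observers cannot score behavior inside a nest, so in-nest
    accuracy is assessed from randomly placed night samples under the
    assumption that a diurnal nest-sleeping animal is in its nest at
    night.  By default any daytime intervals labeled in_nest are dropped
    so the nest class is scored purely from the night samples.
    """
    rng = np.random.default_rng(seed)
    sod = np.asarray(seconds_of_day)
    h0, h1 = night
    in_night = (sod >= h0 * 3600) | (sod < h1 * 3600) if h0 > h1 else (
        (sod >= h0 * 3600) & (sod < h1 * 3600)
    )
    ok = np.flatnonzero(
        np.convolve(in_night, np.ones(sample_len_s, dtype=int), mode="valid")
        == sample_len_s
    )
    if len(ok) == 0:
        raise ValueError("no full night windows available")
    starts = np.sort(rng.choice(ok, size=min(n, len(ok)), replace=False))
    # keep night samples non-overlapping
    intervals = [
        iv for iv in obs.intervals
        if not (drop_observed_in_nest and iv[2] == "in_nest")
    ]
    last_end = -1
    for s in starts:
        if s < last_end:
            continue
        intervals.append((float(s), float(s + sample_len_s), "in_nest"))
        last_end = s + sample_len_s
    return ObservationLog(obs.deployment_id, intervals, source=obs.source)


def daily_time_budget(
    pred: LabelSeries,
    seconds_of_day: np.ndarray,
) -> list[TimeBudget]:
    """Per-calendar-day proportion of each level-6 behavior.

    Partial first and last days are excluded.  Seconds without a level-6
    label (never produced by the tree, but possible with gaps) are reported
    in ``unclassified`` rather than silently dropped.
    """
    labels = pred.at_level(6).labels if pred.level == 6 else None
    if labels is None:
        raise ValueError("daily time budgets require level-6 predictions")
    sod = np.asarray(seconds_of_day)
    n = len(labels)
    day = (np.arange(n) + int(sod[0])) // 86400
    budgets = []
    for d in np.unique(day):
        mask = day == d
        if mask.sum() < 86400:  # partial first/last day
            continue
        sub = labels[mask]
        classified = np.isin(sub, LABELS_AT_LEVEL[6])
        props = {}
        denom = classified.sum()
        for c in LABELS_AT_LEVEL[6]:
            props[c] = float(np.sum(sub == c)) / denom if denom else 0.0
        budgets.append(
            TimeBudget(
                int(d), props, unclassified=float(np.mean(~classified))
            )
        )
    return budgets


def budgets_to_frame(budgets: list[TimeBudget]) -> pd.DataFrame:
    rows = []
    for b in budgets:
        row = {"day": b.day, "unclassified": b.unclassified}
        row.update(b.proportions)
        rows.append(row)
    return pd.DataFrame(rows)


def seasonal_budget_summary(
    budgets: list[TimeBudget],
    dates: pd.DatetimeIndex,
    season_windows: dict | None = None,
) -> pd.DataFrame:
    """Mean +/- s.e. of daily proportions within each seasonal date window.

    ``dates`` gives the calendar date of each budget's day.
    """
    windows = season_windows or DEFAULT_SEASON_WINDOWS
    df = budgets_to_frame(budgets)
    if len(df) != len(dates):
        raise ValueError("dates must match budgets one-to-one")
    df = df.assign(month=dates.month, dayofmonth=dates.day)
    rows = []
    for season, ((m0, d0), (m1, d1)) in windows.items():
        sel = (
            (df["month"] * 100 + df["dayofmonth"] >= m0 * 100 + d0)
            & (df["month"] * 100 + df["dayofmonth"] <= m1 * 100 + d1)
        )
        sub = df[sel]
        if sub.empty:
            continue
        for c in LABELS_AT_LEVEL[6]:
            vals = sub[c].to_numpy()
            rows.append(
                {
                    "season": season,
                    "behavior": c,
                    "mean": float(np.mean(vals)),
                    "se": float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                    if len(vals) > 1 else 0.0,
                    "n_days": len(vals),
                }
            )
    return pd.DataFrame(rows)
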