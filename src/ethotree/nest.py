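"""Thermal-refuge (nest) detection from collar temperature.

A collar on an animal inside an insulated nest reads warm and stable; out in
the open it tracks cold, variable ambient air.  For every noon-to-noon day
the smoothed temperatures are split into two clusters by an exact 1-D
2-means (global optimum found by scanning the sorted-order split point, so
there is no seed sensitivity); the midpoint of the two cluster centers is
that day's in-nest threshold.  A movement-based correction then flips any
"in nest" bout in which the animal was moving more than half the time —
nests are used for resting, so a bout dominated by movement is more likely
basking or activity in warm sun than nest use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import AccelTrace
from .preprocess import smooth_temperature

DAY_S = 86400
NOON_S = 43200


class DegenerateDayError(ValueError):
    """Raised when a day's temperatures cannot support a 2-cluster split."""


@dataclass
class DailyThreshold:
    day_index: int
    temp_threshold: float
    cluster_centers: tuple[float, float]  # (cold, warm)
    degenerate: bool = False


@dataclass
class NestBout:
    start: int
    end: int  # exclusive
    state: str  # "in_nest" | "out_of_nest"
    moving_fraction: float = np.nan
    threshold_used: float = np.nan

    @property
    def duration(self) -> int:
        return self.end - self.start


def two_means_1d(values: np.ndarray) -> tuple[float, float]:
    """Exact 1-D k-means with k=2: scan the split point on sorted data.

    Returns the (low, high) cluster centers minimizing within-cluster sum of
    squares.  Raises :class:`DegenerateDayError` if fewer than 2 distinct
    values exist.
    """
    x = np.sort(np.asarray(values, dtype=float))
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 2 or x[0] == x[-1]:
        raise DegenerateDayError("need at least two distinct temperature values")
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    # split after index k: left = x[:k+1], right = x[k+1:]
    k = np.arange(n - 1)
    n1 = k + 1.0
    n2 = n - n1
    s1 = csum[k]
    s2 = csum[-1] - s1
    sse = (csq[k] - s1 * s1 / n1) + (csq[-1] - csq[k] - s2 * s2 / n2)
    best = int(np.argmin(sse))
    lo = s1[best] / n1[best]
    hi = (csum[-1] - csum[best]) / n2[best]
    return float(lo), float(hi)


def daily_temp_threshold(
    temps: np.ndarray,
    day_index: int = 0,
    min_separation_c: float = 4.0,
) -> DailyThreshold:
    """Daily in-nest temperature threshold from one noon-to-noon day.

    The threshold is the midpoint of the two 1-D 2-means cluster centers.
    A nest offset shows up as a gap of 10 C or more between the clusters;
    when the centers are separated by less than ``min_separation_c`` the
    split is only carving up ambient variation (a diurnal cycle splits
    into two "clusters" a couple of degrees apart) and the day is flagged
    degenerate.
    """
    x = np.asarray(temps, dtype=float)
    x = x[np.isfinite(x)]
    lo, hi = two_means_1d(x)
    thr = 0.5 * (lo + hi)
    if (hi - lo) < min_separation_c:
        raise DegenerateDayError(
            f"cluster separation {hi - lo:.2f} C below the "
            f"{min_separation_c} C required for a credible nest signal"
        )
    return DailyThreshold(day_index, thr, (lo, hi))


def noon_day_index(trace: AccelTrace) -> np.ndarray:
    """Noon-to-noon day index (12 p.m.-12 p.m.) for every sample."""
    abs_s = (
        int(
            (trace.start_time - trace.start_time.normalize()).total_seconds()
        )
        + trace.t
    )
    return (abs_s - NOON_S) // DAY_S - ((int(abs_s[0]) - NOON_S) // DAY_S)


def _merge_states(states: np.ndarray) -> list[tuple[int, int, str]]:
    """Run-length encode a per-second state array into (start, end, state)."""
    n = len(states)
    change = np.flatnonzero(states[1:] != states[:-1]) + 1
    bounds = np.concatenate([[0], change, [n]])
    return [
        (int(bounds[i]), int(bounds[i + 1]), str(states[bounds[i]]))
        for i in range(len(bounds) - 1)
    ]


def segment_nest_bouts(
    temp_smooth: np.ndarray,
    day_index: np.ndarray,
    thresholds: dict[int, DailyThreshold],
) -> list[NestBout]:
    """Per-second thresholding into in/out-of-nest, merged into bouts."""
    days = np.unique(day_index)
    missing = [int(d) for d in days if int(d) not in thresholds]
    if missing:
        raise ValueError(f"no daily threshold for day(s) {missing}")
    thr = np.empty(len(temp_smooth))
    for d in days:
        thr[day_index == d] = thresholds[int(d)].temp_threshold
    state = np.where(temp_smooth > thr, "in_nest", "out_of_nest")
    bouts = []
    for s, e, st in _merge_states(state):
        bouts.append(
            NestBout(s, e, st, threshold_used=float(np.median(thr[s:e])))
        )
    return bouts


def movement_ratio_correction(
    bouts: list[NestBout], moving: np.ndarray
) -> list[NestBout]:
    """Flip in-nest bouts in which moving strictly outnumbers not-moving.

    ``moving`` is the per-second boolean from the movement gate.  A bout
    with a moving:not-moving ratio of exactly 1 stays in the nest (the rule
    is strictly above 1).  Adjacent same-state bouts are re-merged.
    """
    corrected = []
    for b in bouts:
        state = b.state
        frac = float(np.mean(moving[b.start:b.end]))
        if state == "in_nest":
            n_mov = int(np.sum(moving[b.start:b.end]))
            if n_mov > (b.duration - n_mov):
                state = "out_of_nest"
        corrected.append(
            NestBout(b.start, b.end, state, frac, b.threshold_used)
        )
    merged: list[NestBout] = []
    for b in corrected:
        if merged and merged[-1].state == b.state:
            prev = merged[-1]
            dur = prev.duration + b.duration
            merged[-1] = NestBout(
                prev.start,
                b.end,
                b.state,
                (prev.moving_fraction * prev.duration
                 + b.moving_fraction * b.duration) / dur,
                prev.threshold_used,
            )
        else:
            merged.append(b)
    return merged


def bouts_to_frame(bouts: list[NestBout]):
    """Nest bouts as a DataFrame (start, end, state, moving_fraction,
    threshold_used) ready for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "start": b.start,
                "end": b.end,
                "state": b.state,
                "moving_fraction": b.moving_fraction,
                "threshold_used": b.threshold_used,
            }
            for b in bouts
        ]
    )


def bouts_to_states(bouts: list[NestBout], n: int) -> np.ndarray:
    """Per-second in_nest boolean from a bout partition."""
    out = np.zeros(n, dtype=bool)
    for b in bouts:
        if b.state == "in_nest":
            out[b.start:b.end] = True
    return out


class NestDetector:
    """Estimator detecting in-nest seconds from collar temperature.

    Parameters
    ----------
    smooth_window_s : int
        Rolling-median window for the temperature pre-filter.
    min_separation_c : float
        Minimum cluster-center gap (deg C) for a credible warm/cold split;
        days below it inherit the nearest valid day's threshold (with a
        warning).

    Attributes (after :meth:`fit`)
    ------------------------------
    daily_thresholds_ : dict mapping noon-day index -> DailyThreshold
    n_degenerate_days_ : int
    """

    def __init__(self, smooth_window_s: int = 5, min_separation_c: float = 4.0):
        self.smooth_window_s = smooth_window_s
        self.min_separation_c = min_separation_c

    # -- sklearn-style plumbing -------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "smooth_window_s": self.smooth_window_s,
            "min_separation_c": self.min_separation_c,
        }

    def set_params(self, **params) -> "NestDetector":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # ---------------------------------------------------------------------
    def fit(self, trace: AccelTrace) -> "NestDetector":
        """Estimate a per-day temperature threshold for the deployment."""
        if not isinstance(trace, AccelTrace):
            raise TypeError("fit expects an AccelTrace")
        temp = smooth_temperature(trace.temp, self.smooth_window_s)
        day_index = noon_day_index(trace)
        thresholds: dict[int, DailyThreshold] = {}
        degenerate_days = []
        for d in np.unique(day_index):
            temps_d = temp[day_index == d]
            try:
                thresholds[int(d)] = daily_temp_threshold(
                    temps_d, int(d), self.min_separation_c
                )
            except DegenerateDayError:
                degenerate_days.append(int(d))
        for d in degenerate_days:
            valid = sorted(thresholds)
            if not valid:
                continue
            nearest = min(valid, key=lambda v: abs(v - d))
            src = thresholds[nearest]
            thresholds[d] = DailyThreshold(
                d, src.temp_threshold, src.cluster_centers, degenerate=True
            )
            warnings.warn(
                f"day {d}: degenerate temperature clustering; inheriting "
                f"threshold from day {nearest}",
                stacklevel=2,
            )
        if not thresholds:
            warnings.warn(
                "no day with a valid temperature split; all seconds will be "
                "classified out of nest",
                stacklevel=2,
            )
        self.daily_thresholds_ = thresholds
        self.n_degenerate_days_ = len(degenerate_days)
        self._temp_smooth_ = temp
        self._day_index_ = day_index
        return self

    def predict_bouts(
        self, trace: AccelTrace, moving: np.ndarray | None = None
    ) -> list[NestBout]:
        """Nest bouts for the fitted deployment (optionally ratio-corrected).

        ``moving`` is the per-second moving/not-moving boolean from the
        movement gate; when given, in-nest bouts dominated by movement are
        reclassified as out of nest.
        """
        if not hasattr(self, "daily_thresholds_"):
            raise RuntimeError("NestDetector is not fitted")
        n = len(trace)
        if not self.daily_thresholds_:
            return [NestBout(0, n, "out_of_nest")]
        bouts = segment_nest_bouts(
            self._temp_smooth_, self._day_index_, self.daily_thresholds_
        )
        if moving is not None:
            if len(moving) != n:
                raise ValueError("moving mask length != trace length")
            bouts = movement_ratio_correction(bouts, np.asarray(moving, bool))
        return bouts

    def fit_predict(
        self, trace: AccelTrace, moving: np.ndarray | None = None
    ) -> np.ndarray:
        """Per-second in-nest boolean."""
        self.fit(trace)
        return bouts_to_states(self.predict_bouts(trace, moving), len(trace))
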