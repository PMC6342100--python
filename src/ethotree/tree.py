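"""Hierarchical threshold decision tree over windowed acceleration statistics.

The tree classifies every second of a deployment in four stages, each at a
sample window matched to the natural duration of the behavior it separates:

1. *nest gate* — in/out of the thermal refuge from collar temperature
   (see :mod:`ethotree.nest`);
2. *movement gate* — delta-DBA over 14 s windows against a threshold
   calibrated on motionless devices (default 1.06 g): moving vs not moving,
   applied everywhere including inside the nest;
3. *ODBA split* — out-of-nest moving seconds are split into feeding (low
   ODBA) vs traveling (high ODBA) over 10 s windows (default 6.2 g);
4. *surge split* — traveling seconds are split into foraging vs running by
   the maximum surge-axis dynamic value over 4 s windows (default 1.15 g,
   running high), 4 s being the typical duration of a running bout.

All comparisons are strict ``>``.  Stages re-tile independently within the
segments produced by their parent stage; each second inherits the label of
the innermost window that classified it.  A trailing window shorter than
half the nominal length inherits the preceding window's label; one at least
half-length is classified on its own statistic, prorated to the nominal
window (delta-DBA by difference terms, ODBA by samples; a maximum needs no
proration).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .io import AccelTrace
from .labels import LabelSeries
from .nest import NestBout, NestDetector, bouts_to_states
from .preprocess import DynamicTrace, split_static_dynamic

DEFAULT_DDBA_THRESHOLD = 1.06
DEFAULT_DDBA_WINDOW_S = 14
DEFAULT_ODBA_THRESHOLD = 6.2
DEFAULT_FEED_WINDOW_S = 10
DEFAULT_SURGE_MAX_THRESHOLD = 1.15
DEFAULT_RUN_WINDOW_S = 4


@dataclass
class ThresholdSet:
    """Calibrated decision constants and window lengths of the tree."""

    ddba_threshold: float = DEFAULT_DDBA_THRESHOLD
    ddba_window_s: int = DEFAULT_DDBA_WINDOW_S
    odba_threshold: float = DEFAULT_ODBA_THRESHOLD
    feed_window_s: int = DEFAULT_FEED_WINDOW_S
    surge_max_threshold: float = DEFAULT_SURGE_MAX_THRESHOLD
    run_window_s: int = DEFAULT_RUN_WINDOW_S
    # side assignment at each split (configurable; defaults follow the
    # signature amplitudes: locomotion > feeding, running peaks > foraging)
    travel_high_odba: bool = True
    run_high_surge: bool = True

    def __post_init__(self) -> None:
        for name in ("ddba_threshold", "odba_threshold", "surge_max_threshold"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("ddba_window_s", "feed_window_s", "run_window_s"):
            if int(getattr(self, name)) < 2:
                raise ValueError(f"{name} must span at least 2 samples")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdSet":
        return cls(**d)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) of maximal True runs in a boolean array."""
    m = np.asarray(mask, bool)
    if not m.any():
        return []
    d = np.diff(m.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(len(m))
    return list(zip(starts, ends))


def _window_ddba(dx, dy, dz) -> np.ndarray:
    return (
        np.abs(np.diff(dx, axis=-1)).sum(axis=-1)
        + np.abs(np.diff(dy, axis=-1)).sum(axis=-1)
        + np.abs(np.diff(dz, axis=-1)).sum(axis=-1)
    )


def classify_moving(dyn: DynamicTrace, ts: ThresholdSet) -> np.ndarray:
    """Per-second moving / not-moving boolean from windowed delta-DBA.

    Non-overlapping ``ddba_window_s`` windows tile the trace; a window is
    moving when its delta-DBA is strictly above ``ddba_threshold`` and every
    second inherits its window's label.  A trailing partial window of at
    least half the nominal length is classified on its own delta-DBA scaled
    up by (t_full-1)/(t_partial-1); shorter remainders inherit the previous
    window.
    """
    w = int(ts.ddba_window_s * dyn.rate_hz)
    n = len(dyn)
    if n < w:
        raise ValueError(f"trace ({n} samples) shorter than one {w}-s window")
    n_full = n // w
    dx = dyn.dyn_x[: n_full * w].reshape(n_full, w)
    dy = dyn.dyn_y[: n_full * w].reshape(n_full, w)
    dz = dyn.dyn_z[: n_full * w].reshape(n_full, w)
    with np.errstate(invalid="ignore"):
        ddba = _window_ddba(dx, dy, dz)
    win_moving = ddba > ts.ddba_threshold
    # windows with missing samples (NaN delta-DBA) inherit their predecessor
    bad = ~np.isfinite(ddba)
    for i in np.flatnonzero(bad):
        win_moving[i] = win_moving[i - 1] if i > 0 else False
    out = np.repeat(win_moving, w)
    p = n - n_full * w
    if p:
        if p >= (w + 1) // 2 and p >= 2:
            d = _window_ddba(
                dyn.dyn_x[-p:], dyn.dyn_y[-p:], dyn.dyn_z[-p:]
            ) * (w - 1) / (p - 1)
            tail = bool(d > ts.ddba_threshold) if np.isfinite(d) else bool(
                win_moving[-1]
            )
        else:
            tail = bool(win_moving[-1])
        out = np.concatenate([out, np.full(p, tail)])
    return out


def _threshold_stage(
    dyn: DynamicTrace,
    segments: list[tuple[int, int]],
    window_s: int,
    stat: str,
    threshold: float,
    high_label: str,
    low_label: str,
) -> list[tuple[int, int, str]]:
    """Tile ``window_s`` windows within each segment and threshold ``stat``.

    ``stat`` is one of ``odba`` (prorated on partials) or ``max_x`` (not
    prorated).  Returns per-window (start, end, label) spans.
    """
    w = int(window_s * dyn.rate_hz)
    half = (w + 1) // 2
    spans: list[tuple[int, int, str]] = []
    for s, e in segments:
        n_full = (e - s) // w
        prev: str | None = None
        with np.errstate(invalid="ignore"):
            for i in range(n_full):
                a, b = s + i * w, s + (i + 1) * w
                val = _segment_stat(dyn, a, b, stat)
                lab = _side(val, threshold, high_label, low_label, prev)
                spans.append((a, b, lab))
                prev = lab
            a = s + n_full * w
            p = e - a
            if p:
                if prev is None or p >= half:
                    val = _segment_stat(dyn, a, e, stat)
                    if stat == "odba" and p < w:
                        val = val * w / p  # prorate to the nominal window
                    lab = _side(val, threshold, high_label, low_label, prev)
                else:
                    lab = prev
                spans.append((a, e, lab))
    return spans


def _segment_stat(dyn: DynamicTrace, a: int, b: int, stat: str) -> float:
    if stat == "odba":
        return float(
            np.abs(dyn.dyn_x[a:b]).sum()
            + np.abs(dyn.dyn_y[a:b]).sum()
            + np.abs(dyn.dyn_z[a:b]).sum()
        )
    if stat == "max_x":
        return float(np.max(dyn.dyn_x[a:b]))
    raise ValueError(f"unknown stage statistic {stat!r}")


def _side(val, threshold, high_label, low_label, prev):
    if not np.isfinite(val):
        return prev if prev is not None else low_label
    return high_label if val > threshold else low_label


def classify_feed_travel(
    dyn: DynamicTrace,
    segments: list[tuple[int, int]],
    ts: ThresholdSet,
) -> list[tuple[int, int, str]]:
    """Split moving out-of-nest segments into feeding vs traveling by ODBA."""
    high, low = (
        ("traveling", "feeding") if ts.travel_high_odba
        else ("feeding", "traveling")
    )
    return _threshold_stage(
        dyn, segments, ts.feed_window_s, "odba", ts.odba_threshold, high, low
    )


def classify_forage_run(
    dyn: DynamicTrace,
    segments: list[tuple[int, int]],
    ts: ThresholdSet,
) -> list[tuple[int, int, str]]:
    """Split traveling spans into foraging vs running by max surge value."""
    high, low = (
        ("running", "foraging") if ts.run_high_surge
        else ("foraging", "running")
    )
    return _threshold_stage(
        dyn, segments, ts.run_window_s, "max_x", ts.surge_max_threshold,
        high, low,
    )


def classify_hierarchical(
    trace: AccelTrace,
    ts: ThresholdSet | None = None,
    nest_bouts: list[NestBout] | None = None,
    level: int = 6,
    dyn: DynamicTrace | None = None,
    nest_detector: NestDetector | None = None,
) -> LabelSeries:
    """Run the full decision tree on a deployment, clipped at ``level``.

    When ``nest_bouts`` is not supplied, a :class:`NestDetector` is fitted
    to the trace and its bouts are movement-ratio corrected with the
    movement gate's output.
    """
    if ts is None:
        ts = ThresholdSet()
    if level not in (2, 4, 5, 6):
        raise ValueError("level must be 2, 4, 5 or 6")
    if dyn is None:
        dyn = split_static_dynamic(trace)
    n = len(trace)
    moving = classify_moving(dyn, ts)
    if nest_bouts is None:
        det = nest_detector or NestDetector()
        nest_bouts = det.fit(trace).predict_bouts(trace, moving)
    in_nest = bouts_to_states(nest_bouts, n)

    provenance = np.full(n, "moving_gate", dtype=object)
    provenance[in_nest] = "nest"
    if level == 2:
        labels = np.where(in_nest, "in_nest", "out_of_nest")
        return LabelSeries(trace.t, labels, 2, provenance)

    labels = np.empty(n, dtype=object)
    labels[in_nest & moving] = "in_nest_moving" if level == 6 else "in_nest"
    labels[in_nest & ~moving] = "in_nest_not_moving" if level == 6 else "in_nest"
    labels[~in_nest & ~moving] = "not_moving"
    out_moving = ~in_nest & moving
    if level == 4:
        labels[out_moving] = "moving"
        return LabelSeries(trace.t, labels.astype(str), 4, provenance)

    feed_travel = classify_feed_travel(dyn, _runs(out_moving), ts)
    travel_mask = np.zeros(n, dtype=bool)
    for a, b, lab in feed_travel:
        labels[a:b] = lab
        provenance[a:b] = "odba_split"
        if lab == "traveling":
            travel_mask[a:b] = True
    if level == 5:
        return LabelSeries(trace.t, labels.astype(str), 5, provenance)

    for a, b, lab in classify_forage_run(dyn, _runs(travel_mask), ts):
        labels[a:b] = lab
        provenance[a:b] = "surge_split"
    return LabelSeries(trace.t, labels.astype(str), 6, provenance)


class BehaviorTreeClassifier:
    """sklearn-style estimator wrapping the hierarchical decision tree.

    Parameters are the published defaults of the tree; :meth:`fit`
    recalibrates them from labeled data (see :mod:`ethotree.calibration`):
    the movement gate from motionless-device recordings (99.9% quantile of
    windowed delta-DBA), and the ODBA and surge thresholds by balanced
    accuracy scans over training segments selected with the purity rules.
    Fitted values carry a trailing underscore; :meth:`predict` uses fitted
    values when present and the configured parameters otherwise.
    """

    def __init__(
        self,
        ddba_threshold: float = DEFAULT_DDBA_THRESHOLD,
        ddba_window_s: int = DEFAULT_DDBA_WINDOW_S,
        odba_threshold: float = DEFAULT_ODBA_THRESHOLD,
        feed_window_s: int = DEFAULT_FEED_WINDOW_S,
        surge_max_threshold: float = DEFAULT_SURGE_MAX_THRESHOLD,
        run_window_s: int = DEFAULT_RUN_WINDOW_S,
        travel_high_odba: bool = True,
        run_high_surge: bool = True,
        level: int = 6,
        still_quantile: float = 0.999,
        grid_step: float = 0.01,
        hierarchical_cleaning: bool = True,
    ):
        self.ddba_threshold = ddba_threshold
        self.ddba_window_s = ddba_window_s
        self.odba_threshold = odba_threshold
        self.feed_window_s = feed_window_s
        self.surge_max_threshold = surge_max_threshold
        self.run_window_s = run_window_s
        self.travel_high_odba = travel_high_odba
        self.run_high_surge = run_high_surge
        self.level = level
        self.still_quantile = still_quantile
        self.grid_step = grid_step
        self.hierarchical_cleaning = hierarchical_cleaning

    _param_names = (
        "ddba_threshold", "ddba_window_s", "odba_threshold", "feed_window_s",
        "surge_max_threshold", "run_window_s", "travel_high_odba",
        "run_high_surge", "level", "still_quantile", "grid_step",
        "hierarchical_cleaning",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "BehaviorTreeClassifier":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # ---------------------------------------------------------------------
    def threshold_set(self) -> ThresholdSet:
        """Current decision constants (fitted values when available)."""
        g = lambda name: getattr(self, name + "_", getattr(self, name))
        return ThresholdSet(
            ddba_threshold=g("ddba_threshold"),
            ddba_window_s=self.ddba_window_s,
            odba_threshold=g("odba_threshold"),
            feed_window_s=self.feed_window_s,
            surge_max_threshold=g("surge_max_threshold"),
            run_window_s=self.run_window_s,
            travel_high_odba=self.travel_high_odba,
            run_high_surge=self.run_high_surge,
        )

    def fit(
        self,
        obs=None,
        dyn: DynamicTrace | None = None,
        still_dyn: DynamicTrace | list | None = None,
    ) -> "BehaviorTreeClassifier":
        """Calibrate thresholds from labeled data.

        Parameters
        ----------
        obs : ObservationLog, optional
            Aligned behavioral observations; calibrates the ODBA and surge
            thresholds (requires ``dyn``).
        dyn : DynamicTrace, optional
            Preprocessed trace the observations refer to.
        still_dyn : DynamicTrace or list thereof, optional
            Recordings of motionless devices; calibrates the movement gate.
        """
        from . import calibration as cal

        if still_dyn is not None:
            traces = still_dyn if isinstance(still_dyn, list) else [still_dyn]
            self.ddba_threshold_ = cal.stationary_quantile_threshold(
                traces, q=self.still_quantile, window_s=self.ddba_window_s
            )
        if obs is not None:
            if dyn is None:
                raise ValueError("calibrating from observations requires dyn")
            res = cal.calibrate_tree_thresholds(
                obs,
                dyn,
                feed_window_s=self.feed_window_s,
                run_window_s=self.run_window_s,
                grid_step=self.grid_step,
                hierarchical_cleaning=self.hierarchical_cleaning,
            )
            self.odba_threshold_ = res["odba"].threshold
            self.surge_max_threshold_ = res["surge"].threshold
            self.calibration_results_ = res
        return self

    def predict(
        self,
        trace: AccelTrace,
        dyn: DynamicTrace | None = None,
        nest_bouts: list[NestBout] | None = None,
        level: int | None = None,
    ) -> LabelSeries:
        """Classify every second of a deployment."""
        if not isinstance(trace, AccelTrace):
            raise TypeError("predict expects an AccelTrace")
        return classify_hierarchical(
            trace,
            self.threshold_set(),
            nest_bouts=nest_bouts,
            level=self.level if level is None else level,
            dyn=dyn,
        )
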