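"""Threshold calibration and the random-forest window-size benchmark.

The decision tree's constants are not universal: they are re-derived for a
study system from (a) recordings of motionless devices — the movement gate
is the 99.9% quantile of windowed delta-DBA while the device sat still —
and (b) behavioral observations aligned to the logger, from which training
windows are selected under purity rules (a window counts as feeding only if
100% of it was feeding; as foraging if at least 75% was foraging with no
running; as running if at least 51% was running, since running rarely lasts
longer than the window itself).  Each binary split's threshold is then the
argmax of a balanced-accuracy scan over the candidate statistic.

The random-forest benchmark asks how classification accuracy varies
with the sample window, by fitting
a forest on the 25 statistics at each window length and scoring a holdout,
and reports the mean classified bout duration per behavior, which inflates
with window length because tiled windows quantize bouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .features import FEATURE_NAMES, WindowSpec, window_features
from .io import ObservationLog
from .preprocess import DynamicTrace

RF_WINDOWS_S = (2, 4, 7, 10, 14, 20, 30)
ACTIVE_CLASSES = ("feeding", "foraging", "running")


@dataclass
class TrainingSegment:
    """One qualifying sample window of observed behavior."""

    start: int
    end: int
    label: str
    purity: float
    source: str = ""


@dataclass
class CalibrationResult:
    """Outcome of a balanced-accuracy threshold scan for one statistic."""

    statistic_name: str
    threshold: float
    high_label: str  # class assigned when the statistic is strictly above
    accuracy_by_class: dict[str, float]
    overall: float
    scan: pd.DataFrame = field(repr=False)


def windowed_ddba_values(dyn: DynamicTrace, window_s: int) -> np.ndarray:
    """Delta-DBA of non-overlapping windows tiling a trace."""
    w = int(window_s * dyn.rate_hz)
    n_full = len(dyn) // w
    if n_full == 0:
        raise ValueError("trace shorter than one window")
    dx = dyn.dyn_x[: n_full * w].reshape(n_full, w)
    dy = dyn.dyn_y[: n_full * w].reshape(n_full, w)
    dz = dyn.dyn_z[: n_full * w].reshape(n_full, w)
    vals = (
        np.abs(np.diff(dx, axis=1)).sum(axis=1)
        + np.abs(np.diff(dy, axis=1)).sum(axis=1)
        + np.abs(np.diff(dz, axis=1)).sum(axis=1)
    )
    return vals[np.isfinite(vals)]


def stationary_quantile_threshold(
    still_traces: list[DynamicTrace],
    q: float = 0.999,
    window_s: int = 14,
) -> float:
    """Movement-gate threshold: the ``q`` quantile of still-device delta-DBA.

    ``still_traces`` are dynamic traces recorded while the devices sat
    motionless (e.g. packaged on a table before deployment).
    """
    if not still_traces:
        raise ValueError("no still-device recordings supplied")
    vals = np.concatenate(
        [windowed_ddba_values(d, window_s) for d in still_traces]
    )
    if len(vals) == 0:
        raise ValueError("no complete windows in still-device recordings")
    if len(vals) < 1000:
        warnings.warn(
            f"only {len(vals)} still windows; the {q:.1%} quantile is "
            "poorly determined below ~1,000 windows",
            stacklevel=2,
        )
    return float(np.quantile(vals, q, method="linear"))


def _observation_sessions(labels_1s: np.ndarray) -> list[tuple[int, int]]:
    covered = labels_1s != ""
    if not covered.any():
        return []
    d = np.diff(covered.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if covered[0]:
        starts.insert(0, 0)
    if covered[-1]:
        ends.append(len(covered))
    return list(zip(starts, ends))


def select_training_segments(
    obs: ObservationLog,
    dyn: DynamicTrace,
    window_s: int,
) -> list[TrainingSegment]:
    """Tile observed spans into windows and keep those passing purity rules.

    Rules per window: 100% feeding -> feeding; >= 75% foraging with 0%
    running -> foraging; >= 51% running -> running.  Windows touching
    missing acceleration samples are dropped.
    """
    w = int(window_s * dyn.rate_hz)
    n = len(dyn)
    lab = obs.labels_per_second(n)
    missing = dyn.missing
    out: list[TrainingSegment] = []
    for s0, e0 in _observation_sessions(lab):
        n_win = (e0 - s0) // w
        if n_win == 0:
            continue
        block = lab[s0:s0 + n_win * w].reshape(n_win, w)
        miss = missing[s0:s0 + n_win * w].reshape(n_win, w).any(axis=1)
        f_feed = (block == "feeding").mean(axis=1)
        f_forage = (block == "foraging").mean(axis=1)
        f_run = (block == "running").mean(axis=1)
        for i in range(n_win):
            if miss[i]:
                continue
            a, b = s0 + i * w, s0 + (i + 1) * w
            if f_feed[i] == 1.0:
                out.append(TrainingSegment(a, b, "feeding", 1.0, obs.deployment_id))
            elif f_run[i] >= 0.51:
                out.append(
                    TrainingSegment(a, b, "running", float(f_run[i]), obs.deployment_id)
                )
            elif f_forage[i] >= 0.75 and f_run[i] == 0.0:
                out.append(
                    TrainingSegment(a, b, "foraging", float(f_forage[i]), obs.deployment_id)
                )
    return out


def segment_feature_matrix(
    dyn: DynamicTrace, segments: list[TrainingSegment]
) -> pd.DataFrame:
    """The 25 statistics for each training segment, plus its label."""
    if not segments:
        raise ValueError("no training segments")
    w = segments[0].end - segments[0].start
    df = window_features(
        dyn,
        spec=WindowSpec(w),
        segments=[(s.start, s.end) for s in segments],
    )
    df["label"] = [s.label for s in segments]
    return df


def optimize_threshold(
    values: np.ndarray,
    labels: np.ndarray,
    grid_step: float = 0.01,
    statistic_name: str = "",
) -> CalibrationResult:
    """Scan thresholds for a binary split maximizing balanced accuracy.

    Candidates run over [min, max] of the values at ``grid_step``; the
    overall score is the unweighted mean of the two per-class accuracies
    (matching an equal-n training design); ties resolve to the lowest
    threshold; the orientation (which class sits above the threshold) is
    chosen to maximize the score.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    a, b = classes
    va = np.sort(values[labels == a])
    vb = np.sort(values[labels == b])
    lo, hi = values.min(), values.max()
    cand = np.arange(lo, hi + grid_step, grid_step)
    # fraction of each class strictly above each candidate
    above_a = 1.0 - np.searchsorted(va, cand, side="right") / len(va)
    above_b = 1.0 - np.searchsorted(vb, cand, side="right") / len(vb)
    score_a_high = 0.5 * (above_a + (1.0 - above_b))  # a above, b below
    score_b_high = 0.5 * (above_b + (1.0 - above_a))
    best_a = int(np.argmax(score_a_high))
    best_b = int(np.argmax(score_b_high))
    if score_a_high[best_a] >= score_b_high[best_b]:
        idx, high, low = best_a, a, b
        per_high, per_low = above_a[best_a], 1.0 - above_b[best_a]
        score = score_a_high
    else:
        idx, high, low = best_b, b, a
        per_high, per_low = above_b[best_b], 1.0 - above_a[best_b]
        score = score_b_high
    scan = pd.DataFrame({"threshold": cand, "overall_accuracy": score})
    return CalibrationResult(
        statistic_name=statistic_name,
        threshold=float(cand[idx]),
        high_label=str(high),
        accuracy_by_class={str(high): float(per_high), str(low): float(per_low)},
        overall=float(score[idx]),
        scan=scan,
    )


def histogram_compare(
    feature_df: pd.DataFrame,
    label_col: str = "label",
    grid_step: float = 0.01,
    plot_path=None,
) -> pd.DataFrame:
    """Rank the 25 statistics by two-class separability.

    The separability index of a statistic is the balanced accuracy of its
    best single threshold.  When ``plot_path`` is given, class-conditional
    histograms of every statistic are written there (one panel each).
    """
    labels = feature_df[label_col].to_numpy()
    rows = []
    for stat in FEATURE_NAMES:
        if stat not in feature_df.columns:
            continue
        res = optimize_threshold(
            feature_df[stat].to_numpy(), labels, grid_step, stat
        )
        rows.append(
            {"statistic": stat, "separability": res.overall,
             "threshold": res.threshold, "high_label": res.high_label}
        )
    out = (
        pd.DataFrame(rows)
        .sort_values("separability", ascending=False)
        .reset_index(drop=True)
    )
    out["rank"] = np.arange(1, len(out) + 1)
    if plot_path is not None:
        _plot_histograms(feature_df, label_col, out, plot_path)
    return out


def _plot_histograms(feature_df, label_col, ranking, plot_path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stats = list(ranking["statistic"])
    ncol = 5
    nrow = int(np.ceil(len(stats) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 2.5 * nrow))
    for ax, stat in zip(np.ravel(axes), stats):
        for lab, grp in feature_df.groupby(label_col):
            ax.hist(grp[stat], bins=30, alpha=0.5, label=str(lab))
        ax.set_title(stat, fontsize=8)
    for ax in np.ravel(axes)[len(stats):]:
        ax.axis("off")
    np.ravel(axes)[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(plot_path, dpi=100)
    plt.close(fig)


def calibrate_tree_thresholds(
    obs: ObservationLog,
    dyn: DynamicTrace,
    feed_window_s: int = 10,
    run_window_s: int = 4,
    grid_step: float = 0.01,
    hierarchical_cleaning: bool = True,
) -> dict[str, CalibrationResult]:
    """Calibrate the ODBA (feeding/traveling) and surge (foraging/running)
    thresholds from aligned observations.

    With ``hierarchical_cleaning`` the surge calibration uses only segments
    that the freshly calibrated ODBA split classifies correctly as
    traveling (its statistic prorated to the feeding window length).
    """
    segs10 = select_training_segments(obs, dyn, feed_window_s)
    if not segs10:
        raise ValueError("no qualifying training segments at the feed window")
    fm10 = segment_feature_matrix(dyn, segs10)
    split1 = np.where(fm10["label"] == "feeding", "feeding", "traveling")
    odba_res = optimize_threshold(
        fm10["odba"].to_numpy(), split1, grid_step, "odba"
    )

    segs4 = [
        s for s in select_training_segments(obs, dyn, run_window_s)
        if s.label in ("foraging", "running")
    ]
    if not segs4:
        raise ValueError("no qualifying training segments at the run window")
    fm4 = segment_feature_matrix(dyn, segs4)
    if hierarchical_cleaning:
        odba_scaled = fm4["odba"].to_numpy() * (feed_window_s / run_window_s)
        above = odba_scaled > odba_res.threshold
        as_travel = above if odba_res.high_label == "traveling" else ~above
        keep = as_travel
        if keep.sum() < 2 or len(np.unique(fm4["label"][keep])) < 2:
            warnings.warn(
                "hierarchical cleaning left fewer than two classes; "
                "using all segments",
                stacklevel=2,
            )
            keep = np.ones(len(fm4), dtype=bool)
        fm4 = fm4[keep]
    surge_res = optimize_threshold(
        fm4["max_x"].to_numpy(), fm4["label"].to_numpy(), grid_step, "max_x"
    )
    return {"odba": odba_res, "surge": surge_res}


def _merged_bout_durations(window_labels: np.ndarray, window_s: int) -> dict:
    """Mean duration per class after merging consecutive same-label windows."""
    out: dict[str, float] = {}
    if len(window_labels) == 0:
        return out
    durations: dict[str, list[int]] = {}
    run_len = 1
    for i in range(1, len(window_labels) + 1):
        if i < len(window_labels) and window_labels[i] == window_labels[i - 1]:
            run_len += 1
        else:
            durations.setdefault(str(window_labels[i - 1]), []).append(
                run_len * window_s
            )
            run_len = 1
    for lab, ds in durations.items():
        out[lab] = float(np.mean(ds))
    return out


def rf_window_benchmark(
    obs: ObservationLog,
    dyn: DynamicTrace,
    windows: tuple[int, ...] = RF_WINDOWS_S,
    n_trees: int = 2000,
    train_frac: float = 0.75,
    seed: int | None = None,
    min_per_class: int = 30,
    gate_threshold: float = 1.06,
    gate_window_s: int = 14,
    n_splits: int = 1,
    bout_windows: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Random-forest accuracy vs sample-window length.

    For each window length: select training segments under the purity
    rules, subsample equal numbers per class, fit a forest on the 25
    statistics with ``train_frac`` of the pool, and score the remainder
    (overall = unweighted mean of per-class accuracies).  With
    ``n_splits`` > 1 the train/test split is redrawn that many times and
    accuracies averaged, which stabilizes the estimate when long windows
    leave only a few dozen qualifying segments (pools of 500+ segments per
    class are already stable and use a single split).  The mean classified
    bout duration per class is measured by tiling the whole trace, keeping
    movement-gated windows (delta-DBA above the gate threshold prorated to
    the window length) and merging consecutive same-label windows;
    ``bout_windows`` restricts this diagnostic to a subset of window
    lengths (it dominates the runtime on long traces).
    """
    rows = []
    for w in windows:
        # per-window stream: results for one window length do not depend on
        # which other windows are in the sweep
        rng = np.random.default_rng([seed if seed is not None else 0, w])
        segs = select_training_segments(obs, dyn, w)
        counts = {c: sum(s.label == c for s in segs) for c in ACTIVE_CLASSES}
        if min(counts.values()) == 0:
            warnings.warn(
                f"window {w}s: class(es) absent "
                f"({ {c: n for c, n in counts.items()} }); skipped",
                stacklevel=2,
            )
            continue
        n_bal = min(counts.values())
        if n_bal < min_per_class:
            warnings.warn(
                f"window {w}s: only {n_bal} segments in the rarest class",
                stacklevel=2,
            )
        balanced: list[TrainingSegment] = []
        for c in ACTIVE_CLASSES:
            pool = [s for s in segs if s.label == c]
            pick = rng.choice(len(pool), size=n_bal, replace=False)
            balanced.extend(pool[i] for i in pick)
        fm = segment_feature_matrix(dyn, balanced)
        X = fm[list(FEATURE_NAMES)].to_numpy()
        y = fm["label"].to_numpy()
        split_accs = {c: [] for c in ACTIVE_CLASSES}
        eff_splits = 1 if n_bal >= 500 else n_splits
        for _ in range(eff_splits):
            Xtr, Xte, ytr, yte = train_test_split(
                X, y, train_size=train_frac, stratify=y,
                random_state=int(rng.integers(2**31 - 1)),
            )
            rf = RandomForestClassifier(
                n_estimators=n_trees,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            rf.fit(Xtr, ytr)
            pred = rf.predict(Xte)
            for c in ACTIVE_CLASSES:
                mask = yte == c
                if mask.any():
                    split_accs[c].append(float(np.mean(pred[mask] == c)))
        row: dict = {"window_s": w, "n_per_class": n_bal}
        per_class = []
        for c in ACTIVE_CLASSES:
            acc = float(np.mean(split_accs[c])) if split_accs[c] else np.nan
            row[f"acc_{c}"] = acc
            per_class.append(acc)
        row["acc_overall"] = float(np.nanmean(per_class))

        # Table-2-style diagnostic: bout durations of the classified trace
        if bout_windows is not None and w not in bout_windows:
            rows.append(row)
            continue
        thr_w = gate_threshold * (w - 1) / (gate_window_s - 1)
        n_full = len(dyn) // w
        allfeat = window_features(
            dyn, spec=WindowSpec(w), segments=[(0, n_full * w)]
        )
        moving_mask = allfeat["delta_dba"].to_numpy() > thr_w
        if moving_mask.any():
            pred_all = np.full(len(allfeat), "not_moving", dtype=object)
            pred_all[moving_mask] = rf.predict(
                allfeat.loc[moving_mask, list(FEATURE_NAMES)].to_numpy()
            )
            durs = _merged_bout_durations(pred_all, w)
            for c in ACTIVE_CLASSES:
                row[f"mean_bout_s_{c}"] = durs.get(c, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
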