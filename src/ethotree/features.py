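"""Per-window summary statistics of dynamic acceleration.

Each "sample window" is a run of consecutive 1 Hz records.  Within a window
we compute six statistics per axis on the dynamic acceleration (mean,
standard deviation, maximum, sum, range, and sum of absolute first
differences), plus seven cross-axis statistics — ODBA, delta-DBA, the
minimum/maximum per-sample summed absolute difference, the maximum
per-sample total dynamic magnitude, and mean pitch and roll from the static
component — for 25 statistics in all.

ODBA (overall dynamic body acceleration) is the window sum of |dynamic|
across the three axes.  Delta-DBA is the window sum of sample-to-sample
absolute changes in dynamic acceleration across the three axes; with t
samples it has t-1 difference terms, all taken within the window so that
tiled windows stay independent of their neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import DynamicTrace

AXES = ("x", "y", "z")
PER_AXIS_STATS = ("mean", "sd", "max", "sum", "range", "sum_abs_diff")
CROSS_STATS = (
    "odba",
    "delta_dba",
    "min_abs_diff_sample",
    "max_abs_diff_sample",
    "max_accel",
    "mean_pitch",
    "mean_roll",
)
FEATURE_NAMES = tuple(
    f"{stat}_{ax}" for stat in PER_AXIS_STATS for ax in AXES
) + CROSS_STATS
assert len(FEATURE_NAMES) == 25


@dataclass(frozen=True)
class WindowSpec:
    """Tiling specification: non-overlapping windows from segment start."""

    length_s: int
    stride_s: int | None = None
    alignment: str = "tiled_from_segment_start"

    def __post_init__(self):
        if self.length_s < 2:
            raise ValueError("window must span at least 2 samples")
        stride = self.stride_s if self.stride_s is not None else self.length_s
        object.__setattr__(self, "stride_s", stride)


def delta_dba(dx, dy, dz) -> float:
    """Sum over the window of |Δdx| + |Δdy| + |Δdz| (t−1 terms)."""
    dx, dy, dz = (np.asarray(a, dtype=float) for a in (dx, dy, dz))
    if len(dx) < 2:
        raise ValueError("delta_dba needs at least 2 samples")
    return float(
        np.sum(np.abs(np.diff(dx)))
        + np.sum(np.abs(np.diff(dy)))
        + np.sum(np.abs(np.diff(dz)))
    )


def odba(dx, dy, dz) -> float:
    """Sum over the window of |dx| + |dy| + |dz|."""
    dx = np.asarray(dx, dtype=float)
    if len(dx) == 0:
        raise ValueError("odba needs a non-empty window")
    return float(
        np.sum(np.abs(dx)) + np.sum(np.abs(dy)) + np.sum(np.abs(dz))
    )


def pitch_roll_deg(static_x, static_y, static_z) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample pitch and roll (degrees) from static acceleration.

    pitch = atan2(gx, sqrt(gy^2 + gz^2)), roll = atan2(gy, sqrt(gx^2 + gz^2)).
    """
    gx, gy, gz = (np.asarray(a, dtype=float) for a in (static_x, static_y, static_z))
    pitch = np.degrees(np.arctan2(gx, np.hypot(gy, gz)))
    roll = np.degrees(np.arctan2(gy, np.hypot(gx, gz)))
    return pitch, roll


def _tile_starts(seg_start: int, seg_end: int, length: int) -> np.ndarray:
    n_win = (seg_end - seg_start) // length
    return seg_start + length * np.arange(n_win, dtype=np.int64)


def window_features(
    dyn: DynamicTrace,
    spec: WindowSpec,
    segments: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Compute the 25 summary statistics on tiled windows.

    Windows tile from the start of each segment (default: one segment
    covering the whole trace); a trailing remainder shorter than the window
    is not emitted here.  Windows touching missing samples are dropped; the
    count of dropped windows is in ``df.attrs["n_dropped_missing"]``.
    """
    length = int(spec.length_s * dyn.rate_hz)
    if segments is None:
        segments = [(0, len(dyn))]
    starts = np.concatenate(
        [_tile_starts(s, e, length) for s, e in segments]
    ) if segments else np.empty(0, dtype=np.int64)
    if starts.size == 0:
        raise ValueError("trace does not cover a single full window")

    # gather (n_win, length) blocks per channel
    idx = starts[:, None] + np.arange(length)[None, :]
    D = {ax: getattr(dyn, f"dyn_{ax}")[idx] for ax in AXES}
    S = {ax: getattr(dyn, f"static_{ax}")[idx] for ax in AXES}

    ok = np.ones(len(starts), dtype=bool)
    for ax in AXES:
        ok &= np.isfinite(D[ax]).all(axis=1)
    n_dropped = int((~ok).sum())
    starts = starts[ok]
    for ax in AXES:
        D[ax] = D[ax][ok]
        S[ax] = S[ax][ok]

    cols: dict[str, np.ndarray] = {}
    for ax in AXES:
        d = D[ax]
        cols[f"mean_{ax}"] = d.mean(axis=1)
        cols[f"sd_{ax}"] = d.std(axis=1, ddof=1)
        cols[f"max_{ax}"] = d.max(axis=1)
        cols[f"sum_{ax}"] = d.sum(axis=1)
        cols[f"range_{ax}"] = d.max(axis=1) - d.min(axis=1)
        cols[f"sum_abs_diff_{ax}"] = np.abs(np.diff(d, axis=1)).sum(axis=1)

    abs_diff_per_sample = sum(
        np.abs(np.diff(D[ax], axis=1)) for ax in AXES
    )  # (n_win, length-1)
    total_mag = sum(np.abs(D[ax]) for ax in AXES)  # (n_win, length)

    cols["odba"] = total_mag.sum(axis=1)
    cols["delta_dba"] = abs_diff_per_sample.sum(axis=1)
    cols["min_abs_diff_sample"] = abs_diff_per_sample.min(axis=1)
    cols["max_abs_diff_sample"] = abs_diff_per_sample.max(axis=1)
    cols["max_accel"] = total_mag.max(axis=1)
    pitch, roll = pitch_roll_deg(S["x"], S["y"], S["z"])
    cols["mean_pitch"] = pitch.mean(axis=1)
    cols["mean_roll"] = roll.mean(axis=1)

    df = pd.DataFrame(cols, columns=list(FEATURE_NAMES))
    df.insert(0, "start", starts)
    df.insert(1, "end", starts + length)
    df.attrs["n_dropped_missing"] = n_dropped
    return df


def window_features_single(dx, dy, dz, sx=None, sy=None, sz=None) -> dict:
    """The 25 statistics for one explicit window (reference-friendly path)."""
    out = {}
    for ax, d in zip(AXES, (dx, dy, dz)):
        d = np.asarray(d, dtype=float)
        out[f"mean_{ax}"] = d.mean()
        out[f"sd_{ax}"] = d.std(ddof=1)
        out[f"max_{ax}"] = d.max()
        out[f"sum_{ax}"] = d.sum()
        out[f"range_{ax}"] = d.max() - d.min()
        out[f"sum_abs_diff_{ax}"] = np.abs(np.diff(d)).sum()
    dx, dy, dz = (np.asarray(a, dtype=float) for a in (dx, dy, dz))
    ad = np.abs(np.diff(dx)) + np.abs(np.diff(dy)) + np.abs(np.diff(dz))
    mag = np.abs(dx) + np.abs(dy) + np.abs(dz)
    out["odba"] = mag.sum()
    out["delta_dba"] = ad.sum()
    out["min_abs_diff_sample"] = ad.min()
    out["max_abs_diff_sample"] = ad.max()
    out["max_accel"] = mag.max()
    if sx is None:
        sx = np.zeros_like(dx)
        sy = np.zeros_like(dx)
        sz = np.ones_like(dx)
    pitch, roll = pitch_roll_deg(sx, sy, sz)
    out["mean_pitch"] = pitch.mean()
    out["mean_roll"] = roll.mean()
    return out
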