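"""Reading and writing logger CSVs, observation logs, label series and config.

The canonical CSV dialect is comma-separated with a header row, a time column
in epoch seconds or ISO-8601, and axis order x, y, z = surge, sway, heave.
Time is held internally as integer seconds since deployment start so that a
1 Hz grid never accumulates float drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .labels import DEFAULT_ETHOGRAM_MAP, LabelSeries, has_level

ACCEL_RANGE_G = 8.0  # logger full-scale: forces recorded between -8 and +8 g

DEFAULT_COLUMN_MAP = {
    "time": "time",
    "x": "ax",
    "y": "ay",
    "z": "az",
    "temp": "temp",
}


class TraceValidationError(ValueError):
    """Raised when a trace violates the data-model invariants."""


@dataclass
class AccelTrace:
    """Raw 1 Hz tri-axial acceleration + collar temperature for one deployment.

    ``ax``/``ay``/``az`` are surge/sway/heave in g; ``temp`` is in degrees
    Celsius.  ``t`` is integer seconds since the deployment epoch on a strict
    uniform grid.  Samples lost to logger dropouts are carried as NaN rows on
    the grid rather than silently interpolated.
    """

    deployment_id: str
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    temp: np.ndarray
    rate_hz: float = 1.0
    start_time: pd.Timestamp = field(
        default_factory=lambda: pd.Timestamp("2014-03-01 00:00:00")
    )

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        for name in ("ax", "ay", "az", "temp"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self) -> None:
        n = len(self.t)
        for name in ("ax", "ay", "az", "temp"):
            if len(getattr(self, name)) != n:
                raise TraceValidationError(f"column {name} length != time length")
        if n == 0:
            raise TraceValidationError("empty trace")
        step = np.diff(self.t)
        if n > 1 and not np.all(step == round(1 / self.rate_hz)):
            raise TraceValidationError(
                "time grid is not uniform at the declared sampling rate"
            )
        for name in ("ax", "ay", "az"):
            vals = getattr(self, name)
            finite = vals[np.isfinite(vals)]
            if finite.size and (
                finite.min() < -ACCEL_RANGE_G or finite.max() > ACCEL_RANGE_G
            ):
                raise TraceValidationError(
                    f"{name} outside the logger range of +/-{ACCEL_RANGE_G} g"
                )
        if np.isinf(self.temp).any():
            raise TraceValidationError("non-finite temperature values")

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of grid seconds lost to dropouts."""
        return ~(
            np.isfinite(self.ax) & np.isfinite(self.ay) & np.isfinite(self.az)
        )

    def __len__(self) -> int:
        return len(self.t)

    def seconds_of_day(self) -> np.ndarray:
        """Clock second-of-day (0..86399) for every sample."""
        sod0 = (
            self.start_time - self.start_time.normalize()
        ).total_seconds()
        return (int(sod0) + self.t) % 86400


@dataclass
class ObservationLog:
    """Behavioral observation intervals for one deployment.

    ``intervals`` is a sorted list of ``(start, end, label)`` with ``end``
    exclusive, in seconds on the observation clock (which may be offset from
    the logger clock; see :mod:`ethotree.align`).
    """

    deployment_id: str
    intervals: list[tuple[float, float, str]]
    source: str = "focal"

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals, key=lambda iv: (iv[0], iv[1]))
        for (s0, e0, l0), (s1, e1, l1) in zip(ivs, ivs[1:]):
            if e0 > s1:
                raise ValueError(
                    f"overlapping observation intervals at t={s1} "
                    f"({l0!r} vs {l1!r})"
                )
        for s, e, lab in ivs:
            if not e > s:
                raise ValueError(f"interval ({s}, {e}) has end <= start")
        self.intervals = [(float(s), float(e), str(l)) for s, e, l in ivs]

    def __len__(self) -> int:
        return len(self.intervals)

    def shifted(self, offset_s: float) -> "ObservationLog":
        """Return a copy with all interval times shifted by ``offset_s``."""
        return ObservationLog(
            self.deployment_id,
            [(s + offset_s, e + offset_s, l) for s, e, l in self.intervals],
            source=self.source,
        )

    def labels_per_second(self, n: int) -> np.ndarray:
        """Dense per-second label array over ``[0, n)``; '' where unobserved."""
        out = np.full(n, "", dtype=object)
        for s, e, lab in self.intervals:
            i0, i1 = max(0, int(np.ceil(s))), min(n, int(np.ceil(e)))
            if i1 > i0:
                out[i0:i1] = lab
        return out


def _parse_time_column(col: pd.Series) -> tuple[np.ndarray, pd.Timestamp]:
    """Accept epoch/relative seconds or ISO-8601; return (seconds, start)."""
    if pd.api.types.is_numeric_dtype(col):
        secs = col.to_numpy(dtype=float)
        start = pd.Timestamp("2014-03-01 00:00:00")
        return secs - secs[0], start
    ts = pd.to_datetime(col, format="ISO8601")
    secs = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    return secs, ts.iloc[0]


def read_accel_csv(
    path,
    column_map: dict | None = None,
    deployment_id: str | None = None,
    rate_hz: float = 1.0,
    fill_gaps: bool = True,
) -> AccelTrace:
    """Read a logger CSV export into a validated :class:`AccelTrace`.

    ``column_map`` names the file's columns for ``time, x, y, z, temp``
    (logger exports differ; the default expects ``time, ax, ay, az, temp``).
    Gaps in the time grid are reported via a warning and, when ``fill_gaps``,
    re-inserted as NaN rows — never interpolated.
    """
    cmap = dict(DEFAULT_COLUMN_MAP, **(column_map or {}))
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    missing_cols = [cmap[k] for k in ("time", "x", "y", "z", "temp")
                    if cmap[k] not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    for key in ("x", "y", "z", "temp"):
        if not pd.api.types.is_numeric_dtype(df[cmap[key]]):
            bad = df.index[pd.to_numeric(df[cmap[key]], errors="coerce").isna()
                           & df[cmap[key]].notna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise ValueError(
                f"{path}: non-numeric value in column {cmap[key]!r} "
                f"near line {line}"
            )
    secs, start = _parse_time_column(df[cmap["time"]])
    step = 1.0 / rate_hz
    idx = secs / step
    idx_round = np.round(idx).astype(np.int64)
    if np.max(np.abs(idx - idx_round)) > 0.01:
        raise TraceValidationError(
            f"{path}: sampling is not uniform at {rate_hz} Hz beyond tolerance"
        )
    if len(np.unique(idx_round)) != len(idx_round):
        raise TraceValidationError(f"{path}: duplicate timestamps")
    n_grid = idx_round[-1] + 1
    if n_grid != len(df):
        n_gap = int(n_grid - len(df))
        warnings.warn(
            f"{path}: {n_gap} missing samples on the time grid", stacklevel=2
        )
        if not fill_gaps:
            raise TraceValidationError(f"{path}: gaps in time grid")
    cols = {}
    for key in ("x", "y", "z", "temp"):
        full = np.full(n_grid, np.nan)
        full[idx_round] = df[cmap[key]].to_numpy(dtype=float)
        cols[key] = full
    return AccelTrace(
        deployment_id=deployment_id or str(path),
        t=np.arange(n_grid, dtype=np.int64),
        ax=cols["x"],
        ay=cols["y"],
        az=cols["z"],
        temp=cols["temp"],
        rate_hz=rate_hz,
        start_time=start,
    )


def write_accel_csv(trace: AccelTrace, path) -> None:
    """Write a trace in the canonical dialect (round-trips losslessly)."""
    df = pd.DataFrame(
        {
            "time": trace.t,
            "ax": trace.ax,
            "ay": trace.ay,
            "az": trace.az,
            "temp": trace.temp,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_observation_log(
    path,
    ethogram_map: dict | None = None,
    deployment_id: str | None = None,
    source: str = "focal",
) -> ObservationLog:
    """Read an observation log CSV (columns ``start,end,label``).

    Raw ethogram codes (caching, clipping cones, digging, slow travel,
    grooming, vocalizing, ...) are collapsed onto the classification
    categories via ``ethogram_map``; unknown codes raise with the offending
    code named.  Abutting intervals with identical labels are merged.
    """
    emap = dict(DEFAULT_ETHOGRAM_MAP, **(ethogram_map or {}))
    df = pd.read_csv(path)
    for col in ("start", "end", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    intervals = []
    for row in df.itertuples(index=False):
        code = str(row.label).strip().lower()
        if code not in emap:
            raise ValueError(f"{path}: unknown ethogram code {row.label!r}")
        intervals.append((float(row.start), float(row.end), emap[code]))
    return ObservationLog(
        deployment_id=deployment_id or str(path),
        intervals=merge_abutting(intervals),
        source=source,
    )


def merge_abutting(
    intervals: list[tuple[float, float, str]],
) -> list[tuple[float, float, str]]:
    """Sort intervals and merge abutting ones that share a label."""
    ivs = sorted(intervals)
    out: list[tuple[float, float, str]] = []
    for s, e, lab in ivs:
        if out and out[-1][2] == lab and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(e, out[-1][1]), lab)
        else:
            out.append((s, e, lab))
    return out


def write_observation_log(obs: ObservationLog, path) -> None:
    pd.DataFrame(obs.intervals, columns=["start", "end", "label"]).to_csv(
        path, index=False
    )


def write_label_csv(series: LabelSeries, path) -> None:
    """One row per second with the label at every available coarser level."""
    cols = {"t": series.t}
    for level in (2, 4, 5, 6):
        if level <= series.level:
            cols[f"label_level{level}"] = series.at_level(level).labels
    pd.DataFrame(cols).to_csv(path, index=False)


def read_label_csv(path, level: int = 6) -> LabelSeries:
    df = pd.read_csv(path)
    col = f"label_level{level}"
    if col not in df.columns:
        avail = [c for c in df.columns if c.startswith("label_level")]
        raise ValueError(f"{path}: no {col}; available: {avail}")
    return LabelSeries(df["t"].to_numpy(), df[col].to_numpy(dtype=str), level)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def validate_observation_labels(obs: ObservationLog, level: int) -> None:
    """Check every observed label can be scored at ``level`` (or is the
    stationary-movement category, which callers may drop)."""
    for _, _, lab in obs.intervals:
        if not has_level(lab, level) and lab != "stationary_movement":
            raise ValueError(
                f"observed label {lab!r} cannot be scored at level {level}"
            )
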