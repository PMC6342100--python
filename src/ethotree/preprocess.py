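"""Static/dynamic decomposition of raw acceleration and temperature smoothing.

Gravity shows up in a tri-axial record as a slowly varying ("static")
component; body movement rides on top of it.  The static part is estimated
with a centered running mean (default 91 s at 1 Hz) and the dynamic part is
the raw signal minus that estimate, so raw = static + dynamic holds on
every sample (to within one floating-point rounding).  Collar temperature gets a short rolling median to knock
out single-sample sensor glitches before nest detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AccelTrace

DEFAULT_SMOOTH_WINDOW_S = 91
DEFAULT_TEMP_WINDOW_S = 5


@dataclass
class DynamicTrace:
    """Per-axis static/dynamic decomposition of an :class:`AccelTrace`."""

    t: np.ndarray
    static_x: np.ndarray
    static_y: np.ndarray
    static_z: np.ndarray
    dyn_x: np.ndarray
    dyn_y: np.ndarray
    dyn_z: np.ndarray
    temp_smooth: np.ndarray
    rate_hz: float = 1.0
    source: AccelTrace | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def missing(self) -> np.ndarray:
        return ~(
            np.isfinite(self.dyn_x)
            & np.isfinite(self.dyn_y)
            & np.isfinite(self.dyn_z)
        )

    def dyn(self) -> np.ndarray:
        """Dynamic samples stacked as an (n, 3) array (surge, sway, heave)."""
        return np.column_stack([self.dyn_x, self.dyn_y, self.dyn_z])


def _check_window(window: int, n: int) -> int:
    window = int(window)
    if window < 3:
        raise ValueError(f"window must span at least 3 samples, got {window}")
    if window % 2 == 0:
        raise ValueError(f"window must be odd for a centered mean, got {window}")
    if window > n:
        raise ValueError(f"window ({window}) longer than series ({n})")
    return window


def running_mean(signal, window_s: int = DEFAULT_SMOOTH_WINDOW_S) -> np.ndarray:
    """Centered running mean with symmetric truncation at the edges.

    At index ``i`` the half-width shrinks to ``min(h, i, n-1-i)`` so the
    window stays centered on the sample; output length equals input length.
    NaNs are ignored within each window (a window of all-NaN yields NaN).
    """
    x = np.asarray(signal, dtype=float)
    n = len(x)
    window = _check_window(window_s, n)
    h = window // 2
    finite = np.isfinite(x)
    vals = np.where(finite, x, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    ccnt = np.concatenate([[0], np.cumsum(finite.astype(np.int64))])
    i = np.arange(n)
    k = np.minimum(h, np.minimum(i, n - 1 - i))
    lo, hi = i - k, i + k + 1
    tot = csum[hi] - csum[lo]
    cnt = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    return out


def rolling_median(signal, window_s: int = DEFAULT_TEMP_WINDOW_S) -> np.ndarray:
    """Centered rolling median, symmetric shrinking windows at the edges."""
    x = np.asarray(signal, dtype=float)
    n = len(x)
    window = _check_window(window_s, n)
    h = window // 2
    out = np.empty(n)
    if n >= window:
        sw = np.lib.stride_tricks.sliding_window_view(x, window)
        out[h:n - h] = np.nanmedian(sw, axis=1)
    for i in range(h):
        k = i
        out[i] = np.nanmedian(x[: 2 * k + 1]) if k else x[0]
        j = n - 1 - i
        out[j] = np.nanmedian(x[j - k:]) if k else x[-1]
    return out


def smooth_temperature(temp, window_s: int = DEFAULT_TEMP_WINDOW_S) -> np.ndarray:
    """Filter erroneous collar-temperature recordings.

    A centered rolling median (default 5 s): single-sample spikes are
    rejected while monotone warming/cooling ramps pass through unchanged.
    """
    return rolling_median(temp, window_s)


def split_static_dynamic(
    trace: AccelTrace,
    window_s: int = DEFAULT_SMOOTH_WINDOW_S,
    temp_window_s: int = DEFAULT_TEMP_WINDOW_S,
) -> DynamicTrace:
    """Decompose a raw trace into static + dynamic acceleration per axis."""
    window = int(round(window_s * trace.rate_hz))
    if window % 2 == 0:
        window += 1
    statics = {}
    dyns = {}
    for name, raw in (("x", trace.ax), ("y", trace.ay), ("z", trace.az)):
        st = running_mean(raw, window)
        statics[name] = st
        dyns[name] = raw - st
    return DynamicTrace(
        t=trace.t,
        static_x=statics["x"],
        static_y=statics["y"],
        static_z=statics["z"],
        dyn_x=dyns["x"],
        dyn_y=dyns["y"],
        dyn_z=dyns["z"],
        temp_smooth=smooth_temperature(
            trace.temp, int(round(temp_window_s * trace.rate_hz)) | 1
        ),
        rate_hz=trace.rate_hz,
        source=trace,
    )
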