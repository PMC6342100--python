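"""Synthetic 1 Hz collar traces with known per-second behavior.

The generator emulates the statistical structure the classifier assumes,
not squirrel biomechanics: a semi-Markov behavior sequence with
gamma-distributed bout durations, behavior-specific zero-mean dynamic
acceleration emissions (a caricature of real signatures — stationary noise
for foraging-like search, an alternating heave component for rhythmic food
handling, high-amplitude surge bursts for running), a gravity static
component, and collar temperature that relaxes toward ambient outside the
nest and ambient-plus-offset inside it.  The daily schedule is
budget-driven: the animal nests through the nocturnal window and daytime
bouts are drawn with probability proportional to each behavior's remaining
share of a configured daily time budget, so realized budgets track the
configuration while bout durations keep their configured distributions.

Every trace comes with exact per-second ground-truth labels and simulated
focal-observation intervals, optionally shifted by a configured clock
offset/drift for alignment experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .io import AccelTrace, ObservationLog, merge_abutting
from .labels import LEVEL6, LabelSeries

DAY = 86400

IN_NEST = ("in_nest_moving", "in_nest_not_moving")
ACTIVE = ("not_moving", "feeding", "foraging", "running")


@dataclass
class SynthConfig:
    """Study conditions for one simulated deployment."""

    duration_days: float = 1.0
    start_time: str = "2014-03-01 00:00:00"

    # diel schedule
    night_start_h: float = 21.0
    night_end_h: float = 6.5
    nocturnal_nest_prob: float = 1.0

    # daily time budget over level-6 behaviors (fractions of 24 h)
    daily_budget: dict = field(
        default_factory=lambda: {
            "in_nest_not_moving": 0.52,
            "in_nest_moving": 0.03,
            "not_moving": 0.10,
            "feeding": 0.12,
            "foraging": 0.18,
            "running": 0.05,
        }
    )

    # semi-Markov bout durations: gamma(mean, shape) in seconds
    mean_duration_s: dict = field(
        default_factory=lambda: {
            "feeding": 30.0,     # observed feeding bouts run ~24-46 s
            "foraging": 10.0,    # ~8-11 s
            "running": 4.5,      # ~4-5 s
            "not_moving": 90.0,
            "in_nest_moving": 40.0,
            "in_nest_not_moving": 900.0,
        }
    )
    duration_shape: dict = field(
        default_factory=lambda: {
            "feeding": 3.0,
            "foraging": 2.0,
            "running": 1.0,
            "not_moving": 1.5,
            "in_nest_moving": 2.0,
            "in_nest_not_moving": 2.0,
        }
    )
    # hard caps on bout length (s): sustained sprints are physiologically
    # bounded, so a long "running" stretch is really several strides broken
    # by pauses or slow travel
    duration_cap_s: dict = field(
        default_factory=lambda: {"running": 10.0}
    )
    nest_visit_mean_s: float = 1800.0  # daytime nest-visit length
    nest_visit_shape: float = 2.0

    # emissions: per-behavior dynamic noise sd per axis (surge, sway, heave)
    noise_sd: dict = field(
        default_factory=lambda: {
            "not_moving": (0.02, 0.02, 0.02),
            "in_nest_not_moving": (0.02, 0.02, 0.02),
            "in_nest_moving": (0.25, 0.25, 0.25),
            "feeding": (0.11, 0.11, 0.11),
            "foraging": (0.33, 0.33, 0.33),
            "running": (0.33, 0.33, 0.33),
        }
    )
    feeding_amp: float = 0.20      # alternating heave component (g)
    running_burst_amp: float = 1.4  # stride surge spikes (g)
    running_burst_prob: float = 0.35
    # foraging digging/caching jolt clusters: a few-second volley of
    # running-amplitude surge spikes starting at this per-second rate
    foraging_jolt_rate: float = 0.05
    foraging_jolt_len_s: int = 4
    foraging_jolt_prob: float = 0.8  # per-second spike prob inside a volley

    # temperature model (deg C)
    amb_mean: float = 5.0
    amb_diurnal_amp: float = 5.0
    nest_offset_c: float = 20.0
    temp_tau_s: float = 180.0      # collar mean-reversion time constant
    sensor_noise_sd: float = 0.2
    spike_prob: float = 1e-4
    spike_amp: float = 15.0

    # observation simulation
    n_focals_per_day: int = 8
    focal_min_s: int = 120
    focal_max_s: int = 600
    clock_offset_s: float = 0.0        # observer clock lags logger by this
    clock_drift_s_per_day: float = 0.0

    def validate(self) -> None:
        bad = []
        if not 0 < self.duration_days:
            bad.append("duration_days must be positive")
        if abs(sum(self.daily_budget.values()) - 1.0) > 1e-9:
            bad.append("daily_budget must sum to 1")
        if set(self.daily_budget) != set(LEVEL6):
            bad.append("daily_budget must cover all six level-6 behaviors")
        for k, v in self.mean_duration_s.items():
            if v <= 0:
                bad.append(f"mean_duration_s[{k}] must be positive")
        if self.nest_offset_c < 0:
            bad.append("nest_offset_c must be >= 0")
        if bad:
            raise ValueError("invalid SynthConfig: " + "; ".join(bad))


def _night_mask_day(cfg: SynthConfig) -> np.ndarray:
    sod = np.arange(DAY)
    s, e = int(cfg.night_start_h * 3600), int(cfg.night_end_h * 3600)
    if s > e:
        return (sod >= s) | (sod < e)
    return (sod >= s) & (sod < e)


def _draw_duration(rng, cfg: SynthConfig, behavior: str) -> int:
    mean = cfg.mean_duration_s[behavior]
    shape = cfg.duration_shape.get(behavior, 2.0)
    d = rng.gamma(shape, mean / shape)
    cap = cfg.duration_cap_s.get(behavior)
    if cap is not None:
        d = min(d, cap)
    return max(1, int(round(d)))


def _nest_block(labels, rng, cfg, t, end) -> int:
    """Fill [t, end) with strictly alternating in-nest sub-bouts.

    The in-nest moving share is governed by the two configured bout means
    (mu_moving / (mu_moving + mu_resting)), not the daily budget.
    """
    state = "in_nest_not_moving"
    while t < end:
        dur = min(_draw_duration(rng, cfg, state), end - t)
        labels[t:t + dur] = state
        t += dur
        state = (
            "in_nest_moving"
            if state == "in_nest_not_moving"
            else "in_nest_not_moving"
        )
    return t


def _schedule_day(labels, rng, cfg: SynthConfig, day_start: int, n: int) -> None:
    """Write one day's ground-truth labels into ``labels``."""
    night = _night_mask_day(cfg)
    # index of the next night second at or after each second-of-day
    idx = np.arange(DAY)
    next_night = np.minimum.accumulate(
        np.where(night, idx, 2 * DAY)[::-1]
    )[::-1]
    day_end = min(day_start + DAY, n)
    nests_tonight = rng.random() < cfg.nocturnal_nest_prob
    targets = {b: cfg.daily_budget[b] * DAY for b in ACTIVE}
    nest_total = (
        cfg.daily_budget["in_nest_moving"]
        + cfg.daily_budget["in_nest_not_moving"]
    ) * DAY
    night_len = int(night.sum()) if nests_tonight else 0
    targets["in_nest"] = max(0.0, nest_total - night_len)

    t = day_start
    current = None
    while t < day_end:
        sod = t - day_start
        if night[sod] and nests_tonight:
            # nest through to the end of this night stretch
            stretch = sod
            while stretch < DAY and night[stretch]:
                stretch += 1
            t = _nest_block(
                labels, rng, cfg, t, min(day_start + stretch, day_end)
            )
            current = "in_nest"
            continue
        # daytime: draw next behavior proportional to remaining deficit
        cands = [b for b in ("in_nest",) + ACTIVE if b != current]
        weights = np.array([max(targets[b], 0.0) for b in cands])
        if weights.sum() <= 0:
            weights = np.array(
                [
                    cfg.daily_budget[b]
                    if b != "in_nest"
                    else cfg.daily_budget["in_nest_moving"]
                    + cfg.daily_budget["in_nest_not_moving"]
                    for b in cands
                ]
            )
        b = str(rng.choice(cands, p=weights / weights.sum()))
        if b == "in_nest":
            mean = cfg.nest_visit_mean_s
            dur = max(
                60,
                int(round(rng.gamma(cfg.nest_visit_shape, mean / cfg.nest_visit_shape))),
            )
            dur = min(dur, int(max(targets["in_nest"], 60.0)))
        else:
            dur = _draw_duration(rng, cfg, b)
        # clip at the next night boundary and day end
        limit = day_end - t
        if nests_tonight:
            limit = min(limit, int(next_night[sod] - sod))
        dur = min(dur, max(1, limit))
        if b == "in_nest":
            _nest_block(labels, rng, cfg, t, t + dur)
        else:
            labels[t:t + dur] = b
        targets[b] -= dur
        current = b
        t += dur


def _emit_acceleration(labels: np.ndarray, rng, cfg: SynthConfig):
    n = len(labels)
    sd = np.empty((n, 3))
    for b, s in cfg.noise_sd.items():
        m = labels == b
        sd[m] = s
    dyn = rng.standard_normal((n, 3)) * sd
    feed = labels == "feeding"
    alt = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    dyn[:, 2] += np.where(feed, cfg.feeding_amp * alt, 0.0)
    runm = labels == "running"
    burst = runm & (rng.random(n) < cfg.running_burst_prob)
    forage = labels == "foraging"
    if cfg.foraging_jolt_rate > 0:
        starts = forage & (rng.random(n) < cfg.foraging_jolt_rate)
        in_volley = (
            np.convolve(starts, np.ones(cfg.foraging_jolt_len_s), mode="full")[
                :n
            ]
            > 0
        )
        burst |= forage & in_volley & (rng.random(n) < cfg.foraging_jolt_prob)
    dyn[burst, 0] += cfg.running_burst_amp * rng.choice([-1.0, 1.0], burst.sum())
    static = np.column_stack(
        [np.zeros(n), np.zeros(n), np.ones(n)]
    )
    raw = np.clip(static + dyn, -8.0, 8.0)
    return raw


def _emit_temperature(labels: np.ndarray, rng, cfg: SynthConfig, sod0: int):
    n = len(labels)
    sod = (sod0 + np.arange(n)) % DAY
    ambient = cfg.amb_mean + cfg.amb_diurnal_amp * np.sin(
        2 * np.pi * (sod - 9 * 3600) / DAY
    )
    in_nest = np.isin(labels, IN_NEST)
    target = ambient + cfg.nest_offset_c * in_nest
    alpha = 1.0 / cfg.temp_tau_s
    zi = np.array([(1 - alpha) * target[0]])
    temp, _ = lfilter([alpha], [1.0, -(1 - alpha)], target, zi=zi)
    temp = temp + rng.normal(0.0, cfg.sensor_noise_sd, n)
    spikes = rng.random(n) < cfg.spike_prob
    temp[spikes] += cfg.spike_amp * rng.choice([-1.0, 1.0], spikes.sum())
    return temp


def _simulate_focals(
    labels: np.ndarray, rng, cfg: SynthConfig, n: int
) -> ObservationLog:
    night = _night_mask_day(cfg)
    intervals = []
    taken: list[tuple[int, int]] = []
    n_days = int(np.ceil(n / DAY))
    for d in range(n_days):
        day_start = d * DAY
        day_secs = np.flatnonzero(~night) + day_start
        day_secs = day_secs[day_secs < n - cfg.focal_max_s]
        if len(day_secs) == 0:
            continue
        shift = cfg.clock_offset_s + cfg.clock_drift_s_per_day * d
        for _ in range(cfg.n_focals_per_day):
            s = int(rng.choice(day_secs))
            dur = int(rng.integers(cfg.focal_min_s, cfg.focal_max_s + 1))
            e = min(s + dur, n)
            if any(s < te and e > ts for ts, te in taken):
                continue  # focal windows cannot overlap
            taken.append((s, e))
            seg = labels[s:e]
            change = np.flatnonzero(seg[1:] != seg[:-1]) + 1
            bounds = np.concatenate([[0], change, [len(seg)]])
            for i in range(len(bounds) - 1):
                lab = str(seg[bounds[i]])
                if lab in IN_NEST:
                    lab = "in_nest"
                intervals.append(
                    (
                        float(s + bounds[i] - shift),
                        float(s + bounds[i + 1] - shift),
                        lab,
                    )
                )
    return ObservationLog(
        "sim", merge_abutting(sorted(intervals)), source="focal"
    )


def generate_trace(
    cfg: SynthConfig, seed: int | None = None
) -> tuple[AccelTrace, LabelSeries, ObservationLog]:
    """Simulate one deployment.

    Returns the raw trace, the exact per-second level-6 ground truth, and
    simulated focal-observation intervals (shifted by the configured clock
    offset/drift, as a real observer's clock would be).
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    n = int(round(cfg.duration_days * DAY))
    start = pd.Timestamp(cfg.start_time)
    sod0 = int((start - start.normalize()).total_seconds())
    if sod0 != 0:
        raise ValueError("start_time must fall on midnight for day scheduling")

    labels = np.empty(n, dtype=object)
    for d in range(int(np.ceil(n / DAY))):
        _schedule_day(labels, rng, cfg, d * DAY, n)
    labels = labels.astype(str)

    raw = _emit_acceleration(labels, rng, cfg)
    temp = _emit_temperature(labels, rng, cfg, sod0)
    trace = AccelTrace(
        deployment_id="sim",
        t=np.arange(n, dtype=np.int64),
        ax=raw[:, 0],
        ay=raw[:, 1],
        az=raw[:, 2],
        temp=temp,
        rate_hz=1.0,
        start_time=start,
    )
    truth = LabelSeries(trace.t, labels, level=6)
    obs = _simulate_focals(labels, rng, cfg, n)
    return trace, truth, obs


def truth_to_observation_log(truth: LabelSeries) -> ObservationLog:
    """Ground truth as a dense observation log (an idealized observer)."""
    labels = truth.labels
    n = len(labels)
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    bounds = np.concatenate([[0], change, [n]])
    intervals = []
    for i in range(len(bounds) - 1):
        lab = str(labels[bounds[i]])
        if lab in IN_NEST:
            lab = "in_nest"
        intervals.append((float(bounds[i]), float(bounds[i + 1]), lab))
    return ObservationLog("sim", merge_abutting(intervals), source="video")


def generate_still_trace(
    cfg: SynthConfig, duration_s: int = 20000, seed: int | None = None
):
    """A motionless-device recording (for movement-gate calibration)."""
    rng = np.random.default_rng(seed)
    sd = cfg.noise_sd["not_moving"]
    dyn = rng.standard_normal((duration_s, 3)) * np.asarray(sd)
    from .preprocess import DynamicTrace

    z = np.zeros(duration_s)
    return DynamicTrace(
        t=np.arange(duration_s, dtype=np.int64),
        static_x=z,
        static_y=z,
        static_z=np.ones(duration_s),
        dyn_x=dyn[:, 0],
        dyn_y=dyn[:, 1],
        dyn_z=dyn[:, 2],
        temp_smooth=np.full(duration_s, 20.0),
    )


def scenario_library() -> dict[str, SynthConfig]:
    """Named presets spanning the regimes the pipeline must handle.

    * ``separable`` — emission distributions far apart and bout durations
      long relative to the classification windows, so end-to-end recovery
      is limited only by implementation correctness, not by window
      quantization at behavior boundaries.
    * ``field_like`` — bout durations at the observed field values and
      overlapping emissions, putting full-pipeline level-6 accuracy in the
      intermediate regime a field calibration actually sees.
    * ``no_temp_contrast`` — zero nest/ambient offset: nest detection must
      degrade gracefully (degenerate daily clusterings).
    * ``drifted_clock`` — field_like plus +3 s/day observer clock drift.
    """
    separable = SynthConfig(
        mean_duration_s={
            "feeding": 300.0,
            "foraging": 150.0,
            "running": 30.0,
            "not_moving": 900.0,
            "in_nest_moving": 90.0,
            "in_nest_not_moving": 2700.0,
        },
        nest_visit_mean_s=3600.0,
        temp_tau_s=60.0,
        duration_shape={
            "feeding": 4.0,
            "foraging": 3.0,
            "running": 2.0,
            "not_moving": 2.0,
            "in_nest_moving": 2.0,
            "in_nest_not_moving": 2.0,
        },
        noise_sd={
            "not_moving": (0.01, 0.01, 0.01),
            "in_nest_not_moving": (0.01, 0.01, 0.01),
            "in_nest_moving": (0.3, 0.3, 0.3),
            "feeding": (0.05, 0.05, 0.05),
            "foraging": (0.40, 0.40, 0.40),
            "running": (0.50, 0.50, 0.60),
        },
        feeding_amp=0.30,
        running_burst_amp=2.5,
        running_burst_prob=0.9,
        foraging_jolt_rate=0.0,
        duration_cap_s={},
        nest_offset_c=20.0,
    )
    field_like = SynthConfig()
    no_temp_contrast = replace(
        SynthConfig(), nest_offset_c=0.0, amb_diurnal_amp=1.0
    )
    drifted = replace(SynthConfig(), clock_drift_s_per_day=3.0)
    return {
        "separable": separable,
        "field_like": field_like,
        "no_temp_contrast": no_temp_contrast,
        "drifted_clock": drifted,
    }
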