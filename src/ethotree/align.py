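"""Clock-offset estimation between observation logs and the logger.

The logger and the device used for observations keep time independently, so
their clocks drift apart by seconds — enough to wreck second-scale scoring.
The correction matches abrupt activity transitions (resting-to-traveling
and vice versa) seen simultaneously in both records: the per-second summed
absolute change in dynamic acceleration crosses an activity threshold at
the same real moment the observer logs the behavior change.  A 1-s grid
search over candidate shifts maximizes the number of direction-matched
event pairs; observation days without any abrupt transition cannot be
aligned and are rejected (mirroring their exclusion from analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ObservationLog
from .preprocess import DynamicTrace

ONSET = "onset"   # rest -> travel
OFFSET = "offset"  # travel -> rest

# observation labels that count as "travel" for transition purposes
_TRAVEL_OBS = {"traveling", "foraging", "running", "moving"}
_REST_OBS = {"not_moving", "in_nest", "in_nest_not_moving"}


@dataclass
class TransitionEvent:
    time: float
    direction: str  # "onset" | "offset"
    magnitude: float


def detect_transitions(
    dyn: DynamicTrace,
    jump_threshold: float = 0.5,
    sustain_s: int = 3,
    debounce_s: int = 10,
) -> list[TransitionEvent]:
    """Abrupt activity transitions in the acceleration record.

    The per-second activity is a(i) = |d_x(i+1)-d_x(i)| + |d_y ...| +
    |d_z ...|.  An onset fires at the start of a run of at least
    ``sustain_s`` activity values strictly above ``jump_threshold``; an
    offset at the start of a sustained quiet run.  Event times are the
    first active sample (onsets, i + 1) and the first quiet index
    (offsets, i): the difference sample straddling the true boundary
    contains one active sample and usually classifies as active, so these
    conventions keep the expected detection error below half a second in
    both directions — small enough for the residual tie-break in
    :func:`estimate_offset` to pin the true shift.  Events closer than
    ``debounce_s`` to the previous event are suppressed.
    """
    a = (
        np.abs(np.diff(dyn.dyn_x))
        + np.abs(np.diff(dyn.dyn_y))
        + np.abs(np.diff(dyn.dyn_z))
    )
    active = a > jump_threshold  # a[i] spans samples (i, i+1)
    events: list[TransitionEvent] = []
    state = bool(active[:sustain_s].all()) if len(active) >= sustain_s else False
    last_time = -np.inf
    n = len(active)
    i = 0
    while i <= n - sustain_s:
        run = active[i:i + sustain_s]
        if not state and run.all():
            t = float(i + 1)
            if t - last_time >= debounce_s:
                events.append(TransitionEvent(t, ONSET, float(a[i])))
                last_time = t
            state = True
            i += sustain_s
        elif state and not run.any():
            t = float(i)
            if t - last_time >= debounce_s:
                events.append(
                    TransitionEvent(t, OFFSET, float(a[i - 1] if i else 0))
                )
                last_time = t
            state = False
            i += sustain_s
        else:
            i += 1
    return events


def observation_transitions(obs: ObservationLog) -> list[TransitionEvent]:
    """Rest/travel boundaries in an observation log.

    Only boundaries between a resting label and a traveling label (in
    either order) within continuous observation are used; feeding and
    stationary movement are neither clearly at rest nor traveling.
    """
    events: list[TransitionEvent] = []
    ivs = obs.intervals
    for (s0, e0, l0), (s1, e1, l1) in zip(ivs, ivs[1:]):
        if e0 != s1:  # boundary not continuously observed
            continue
        if l0 in _REST_OBS and l1 in _TRAVEL_OBS:
            events.append(TransitionEvent(float(s1), ONSET, np.nan))
        elif l0 in _TRAVEL_OBS and l1 in _REST_OBS:
            events.append(TransitionEvent(float(s1), OFFSET, np.nan))
    return events


def estimate_offset(
    obs_transitions: list[TransitionEvent],
    acc_transitions: list[TransitionEvent],
    max_offset_s: int = 60,
    match_tol_s: int = 2,
) -> int | None:
    """Clock offset to *add to observation times* to align with the logger.

    Grid search over integer shifts in [-max_offset_s, +max_offset_s].
    Each observation transition with a direction-matched logger transition
    within ``match_tol_s`` contributes a triangular weight
    (match_tol_s + 1 - |dt|), so exact pairings dominate near-misses and
    the score peaks sharply at the true shift instead of plateauing across
    the tolerance band.  Tied scores resolve to the smallest |offset|
    (then the smaller offset).  Returns ``None`` (rejection) when the
    observations contain no transition or nothing matches.
    """
    if not obs_transitions:
        return None
    if not acc_transitions:
        return None
    acc_by_dir = {
        d: np.array(
            sorted(e.time for e in acc_transitions if e.direction == d)
        )
        for d in (ONSET, OFFSET)
    }
    offsets = np.arange(-max_offset_s, max_offset_s + 1)
    scores = np.zeros(len(offsets))
    for e in obs_transitions:
        acc_times = acc_by_dir[e.direction]
        if len(acc_times) == 0:
            continue
        shifted = e.time + offsets
        pos = np.searchsorted(acc_times, shifted)
        best = np.full(len(offsets), np.inf)
        for side in (np.clip(pos - 1, 0, len(acc_times) - 1),
                     np.clip(pos, 0, len(acc_times) - 1)):
            best = np.minimum(best, np.abs(acc_times[side] - shifted))
        scores += np.maximum(0.0, match_tol_s + 1 - best)
    if scores.max() == 0:
        return None
    cand = offsets[scores == scores.max()]
    return int(min(cand, key=lambda o: (abs(o), o)))


def align_observations(
    obs: ObservationLog,
    dyn: DynamicTrace,
    jump_threshold: float = 0.5,
    max_offset_s: int = 60,
) -> tuple[ObservationLog | None, int | None]:
    """Estimate the clock offset and return shifted observations.

    Returns ``(None, None)`` when the observation day has no abrupt
    transition and must be rejected.
    """
    obs_tr = observation_transitions(obs)
    acc_tr = detect_transitions(dyn, jump_threshold)
    off = estimate_offset(obs_tr, acc_tr, max_offset_s)
    if off is None:
        return None, None
    return obs.shifted(off), off
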