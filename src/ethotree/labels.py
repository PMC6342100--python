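"""Behavior label hierarchy.

The classifier emits labels at four nested levels of detail.  Every label at
a finer level has exactly one parent at each coarser level, so a label series
can always be "clipped" to a simpler ethogram:

* level 6: ``in_nest_moving``, ``in_nest_not_moving``, ``not_moving``,
  ``feeding``, ``foraging``, ``running``
* level 5: ``in_nest``, ``not_moving``, ``feeding``, ``traveling``
* level 4: ``in_nest``, ``not_moving``, ``moving``
* level 2: ``in_nest``, ``out_of_nest``

``stationary_movement`` (grooming, vocalizing) is a valid *observation*
category but is not a leaf of the classification tree; it aggregates to
``moving`` / ``out_of_nest`` and has no parent at levels 5 and 6.
"""

from __future__ import annotations

import numpy as np

LEVELS = (2, 4, 5, 6)

LEVEL6 = (
    "in_nest_moving",
    "in_nest_not_moving",
    "not_moving",
    "feeding",
    "foraging",
    "running",
)
LEVEL5 = ("in_nest", "not_moving", "feeding", "traveling")
LEVEL4 = ("in_nest", "not_moving", "moving")
LEVEL2 = ("in_nest", "out_of_nest")

LABELS_AT_LEVEL = {2: LEVEL2, 4: LEVEL4, 5: LEVEL5, 6: LEVEL6}

# parent of each level-6 label at level 5
_6_TO_5 = {
    "in_nest_moving": "in_nest",
    "in_nest_not_moving": "in_nest",
    "not_moving": "not_moving",
    "feeding": "feeding",
    "foraging": "traveling",
    "running": "traveling",
}
_5_TO_4 = {
    "in_nest": "in_nest",
    "not_moving": "not_moving",
    "feeding": "moving",
    "traveling": "moving",
}
_4_TO_2 = {
    "in_nest": "in_nest",
    "not_moving": "out_of_nest",
    "moving": "out_of_nest",
}

# Observation-only category: scored against the moving gate but not a tree leaf.
STATIONARY_MOVEMENT = "stationary_movement"

# Raw ethogram codes -> observation categories (video + focal scoring).
DEFAULT_ETHOGRAM_MAP = {
    "caching": "foraging",
    "clipping_cones": "foraging",
    "clipping cones": "foraging",
    "digging": "foraging",
    "slow_travel": "foraging",
    "slow travel": "foraging",
    "grooming": STATIONARY_MOVEMENT,
    "vocalizing": STATIONARY_MOVEMENT,
    "vocalization": STATIONARY_MOVEMENT,
    "feed": "feeding",
    "feeding": "feeding",
    "run": "running",
    "running": "running",
    "foraging": "foraging",
    "not_moving": "not_moving",
    "not moving": "not_moving",
    "in_nest": "in_nest",
    "in nest": "in_nest",
    "in_nest_moving": "in_nest_moving",
    "in_nest_not_moving": "in_nest_not_moving",
    "traveling": "traveling",
    "stationary_movement": STATIONARY_MOVEMENT,
    "stationary movement": STATIONARY_MOVEMENT,
}


def _build_ancestry() -> dict[str, dict[int, str]]:
    anc: dict[str, dict[int, str]] = {}
    for lab in LEVEL6:
        l5 = _6_TO_5[lab]
        l4 = _5_TO_4[l5]
        anc[lab] = {6: lab, 5: l5, 4: l4, 2: _4_TO_2[l4]}
    for lab in LEVEL5:
        l4 = _5_TO_4[lab]
        anc.setdefault(lab, {5: lab, 4: l4, 2: _4_TO_2[l4]})
    for lab in LEVEL4:
        anc.setdefault(lab, {4: lab, 2: _4_TO_2[lab]})
    for lab in LEVEL2:
        anc.setdefault(lab, {2: lab})
    # in_nest exists at 5 and 4 and 2; merge dicts for coarse labels
    anc["in_nest"] = {5: "in_nest", 4: "in_nest", 2: "in_nest"}
    anc[STATIONARY_MOVEMENT] = {4: "moving", 2: "out_of_nest"}
    return anc


_ANCESTRY = _build_ancestry()


def aggregate_label(label: str, level: int) -> str:
    """Map *label* to its ancestor at the requested hierarchy *level*.

    Raises ``ValueError`` if the label is unknown or has no representative at
    that level (e.g. ``in_nest`` cannot be refined to level 6, and
    ``stationary_movement`` has no parent at levels 5/6).
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    try:
        anc = _ANCESTRY[label]
    except KeyError:
        raise ValueError(f"unknown behavior label {label!r}") from None
    try:
        return anc[level]
    except KeyError:
        raise ValueError(
            f"label {label!r} has no representative at level {level}"
        ) from None


def has_level(label: str, level: int) -> bool:
    """True if *label* can be expressed at hierarchy *level*."""
    return label in _ANCESTRY and level in _ANCESTRY[label]


def aggregate_series(labels: np.ndarray, level: int) -> np.ndarray:
    """Vectorized :func:`aggregate_label` over an array of labels."""
    labels = np.asarray(labels)
    out = np.empty(labels.shape, dtype=object)
    for lab in np.unique(labels):
        out[labels == lab] = aggregate_label(str(lab), level)
    return out.astype(str)


class LabelSeries:
    """Per-second behavior labels at one hierarchy level.

    Parameters
    ----------
    t : array of int
        Seconds since deployment start (uniform 1 Hz grid).
    labels : array of str
        One label per second, drawn from the vocabulary of ``level``.
    level : int
        Hierarchy level the labels live at (2, 4, 5 or 6).
    provenance : array of str, optional
        Which classification stage assigned each second.
    """

    def __init__(self, t, labels, level: int = 6, provenance=None):
        self.t = np.asarray(t, dtype=np.int64)
        self.labels = np.asarray(labels, dtype=str)
        if self.t.shape != self.labels.shape:
            raise ValueError("t and labels must have the same length")
        if level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")
        vocab = set(LABELS_AT_LEVEL[level])
        bad = set(np.unique(self.labels)) - vocab
        if bad:
            raise ValueError(f"labels {sorted(bad)} not valid at level {level}")
        self.level = level
        if provenance is None:
            provenance = np.full(self.t.shape, "", dtype=object)
        self.provenance = np.asarray(provenance, dtype=str)

    def __len__(self) -> int:
        return len(self.t)

    def at_level(self, level: int) -> "LabelSeries":
        """Clip to a coarser level by aggregating each second's label."""
        if level == self.level:
            return self
        if level > self.level:
            raise ValueError(
                f"cannot refine level-{self.level} labels to level {level}"
            )
        return LabelSeries(
            self.t,
            aggregate_series(self.labels, level),
            level=level,
            provenance=self.provenance,
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LabelSeries)
            and self.level == other.level
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.labels, other.labels)
        )
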