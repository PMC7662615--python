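"""Binaural hearing-loss indexing and the study discretizations.

The "social" hearing-loss index used for disability assessment in Spain:
per ear, the monaural loss percentage is

    monaural = (mean(thresholds at 500/1000/2000/3000 Hz) - 25 dB) * 1.5

clamped to [0, 100]; 25 dB HL is the low fence below which no social handicap
is counted and 1.5 converts dB above the fence into percentage points.  The
binaural index weights the better (smaller-loss) ear five to one:

    binaural = (5 * better + worse) / 6

Clamping at both ends is our reading: the index is defined as a percentage
and observed cohort minima sit at exactly 0 %, which forces the floor; the
100 % cap mirrors the standard social-hearing-loss method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

AUDIOMETRY_FREQS_HZ = (500, 1000, 2000, 3000)
LOW_FENCE_DB = 25.0
SLOPE_PCT_PER_DB = 1.5
BETTER_EAR_WEIGHT = 5.0

#: Loss-group boundaries in percent: group 1 is exactly 0, then lower-exclusive
#: / upper-inclusive bins (0,15], (15,30], (30,45], (45,100].
LOSS_GROUP_EDGES = (0.0, 15.0, 30.0, 45.0)

#: Age-group boundaries in years: lower-inclusive / upper-exclusive bins
#: [<29), [29,35), [35,40), [40,49), [49,...).
AGE_GROUP_EDGES = (29, 35, 40, 49)


@dataclass(frozen=True)
class Audiogram:
    """Per-ear pure-tone thresholds in dB HL at (500, 1000, 2000, 3000) Hz."""

    left: tuple[float, float, float, float]
    right: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        for side, ts in (("left", self.left), ("right", self.right)):
            if len(ts) != 4:
                raise ValueError(f"{side} ear needs exactly 4 thresholds, got {len(ts)}")
            if not all(math.isfinite(t) for t in ts):
                raise ValueError(f"{side} ear has a non-finite threshold: {ts}")


@dataclass(frozen=True)
class LossPercentages:
    monaural_left: float
    monaural_right: float
    binaural: float


def monaural_loss_percent(thresholds: Sequence[float]) -> float:
    """Monaural loss percentage of one ear from its four thresholds."""
    if len(thresholds) != 4:
        raise ValueError(f"expected 4 thresholds, got {len(thresholds)}")
    if not all(math.isfinite(t) for t in thresholds):
        raise ValueError(f"non-finite threshold in {thresholds!r}")
    raw = (sum(thresholds) / 4.0 - LOW_FENCE_DB) * SLOPE_PCT_PER_DB
    return min(100.0, max(0.0, raw))


def binaural_loss_percent(loss_a: float, loss_b: float) -> float:
    """Binaural loss percentage from the two monaural percentages.

    Symmetric in its arguments; the result always lies between the better
    and the worse ear.
    """
    for v in (loss_a, loss_b):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"monaural loss {v} outside [0, 100]")
    better, worse = min(loss_a, loss_b), max(loss_a, loss_b)
    return (BETTER_EAR_WEIGHT * better + worse) / (BETTER_EAR_WEIGHT + 1.0)


def binaural_loss_from_audiogram(audiogram: Audiogram) -> LossPercentages:
    left = monaural_loss_percent(audiogram.left)
    right = monaural_loss_percent(audiogram.right)
    return LossPercentages(left, right, binaural_loss_percent(left, right))


def discretize_binaural_loss(pct: float) -> int:
    """Loss group 1-5 for a binaural percentage.

    Group 1 is reserved for exactly 0 % (no measurable loss); the remaining
    bins are lower-exclusive / upper-inclusive.
    """
    if not (0.0 <= pct <= 100.0):
        raise ValueError(f"binaural loss {pct} outside [0, 100]")
    if pct == 0.0:
        return 1
    for g, edge in enumerate(LOSS_GROUP_EDGES[1:], start=2):
        if pct <= edge:
            return g
    return 5


def discretize_age(age_years: int) -> int:
    """Age quintile 1-5; bins are lower-inclusive / upper-exclusive."""
    if age_years < 0:
        raise ValueError(f"negative age {age_years}")
    for g, edge in enumerate(AGE_GROUP_EDGES, start=1):
        if age_years < edge:
            return g
    return 5
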