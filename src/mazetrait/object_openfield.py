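"""Open-field occupancy/speed and novel-object preference ratios.

The object tasks (recognition and location, 1- and 15-minute retention:
OR1, OR15, OL1, OL15) are scored as the preference ratio
T_novel / (T_novel + T_familiar) over the choice phase; 0.5 is chance.
Open-field measures (zone occupancy fractions and arena speed) assay anxiety
and locomotion, not cognition, and are kept out of the cognitive Z-score
combination downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .io_formats import ValidationError

logger = logging.getLogger("mazetrait")

OBJECT_TASKS = ("OR1", "OR15", "OL1", "OL15")
PHASES = ("sample", "choice")


@dataclass(frozen=True)
class ExplorationBout:
    """Accumulated exploration of one object in one task phase."""

    mouse_id: str
    age_months: int
    task: str
    phase: str
    object: str  # "novel" | "familiar"
    duration: float

    def __post_init__(self) -> None:
        if self.task not in OBJECT_TASKS:
            raise ValidationError(f"unknown task {self.task!r}")
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")
        if self.object not in ("novel", "familiar"):
            raise ValidationError(f"object must be novel/familiar, got {self.object!r}")
        if self.duration < 0:
            raise ValidationError("bout duration must be non-negative")


@dataclass(frozen=True)
class FieldOccupancy:
    """Zone-resolved open-field occupancy for one mouse at one age."""

    mouse_id: str
    age_months: int
    centre_s: float
    inner_s: float
    outer_s: float
    total_s: float
    path_cm: float

    def __post_init__(self) -> None:
        if min(self.centre_s, self.inner_s, self.outer_s) < 0:
            raise ValidationError("zone durations must be non-negative")
        if abs((self.centre_s + self.inner_s + self.outer_s) - self.total_s) > 1e-6:
            raise ValidationError("zone durations must sum to the total time")


def preference_ratio(bouts: Iterable[ExplorationBout]) -> float:
    """Novel-object preference for one (mouse, age, task, phase).

    Returns T_novel / (T_novel + T_familiar).  When the mouse explored
    neither object the ratio is undefined and returned as NaN with a logged
    warning rather than silently scored 0 -- near-zero exploration is a real
    phenotype that must stay visible downstream.
    """
    t_novel = 0.0
    t_familiar = 0.0
    seen = set()
    for b in bouts:
        seen.add((b.mouse_id, b.age_months, b.task, b.phase))
        if len(seen) > 1:
            raise ValidationError(f"bouts span multiple conditions: {sorted(seen)}")
        if b.object == "novel":
            t_novel += b.duration
        else:
            t_familiar += b.duration
    total = t_novel + t_familiar
    if total == 0:
        key = next(iter(seen)) if seen else "<no bouts>"
        logger.warning("zero object exploration for %s: preference undefined", key)
        return math.nan
    return t_novel / total


def preference_table(bouts: Iterable[ExplorationBout], phase: str = "choice") -> pd.DataFrame:
    """Mice x tasks table of preference ratios for one phase."""
    groups: dict[tuple, list[ExplorationBout]] = {}
    for b in bouts:
        if b.phase != phase:
            continue
        groups.setdefault((b.mouse_id, b.age_months, b.task), []).append(b)
    rows: dict[tuple, dict[str, float]] = {}
    for (mouse, age, task), g in groups.items():
        rows.setdefault((mouse, age), {})[task] = preference_ratio(g)
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    if not df.empty:
        df.index = pd.MultiIndex.from_tuples(df.index, names=["mouse_id", "age_months"])
        df = df.reindex(columns=[t for t in OBJECT_TASKS if t in df.columns])
    return df


def zone_fractions(occ: FieldOccupancy) -> tuple[float, float, float]:
    """(centre, inner, outer) occupancy fractions; they sum to exactly 1."""
    if occ.total_s <= 0:
        raise ValidationError("zone_fractions needs a positive total time")
    c = occ.centre_s / occ.total_s
    i = occ.inner_s / occ.total_s
    o = occ.outer_s / occ.total_s
    s = c + i + o
    return (c / s, i / s, o / s)


def arena_speed(occ: FieldOccupancy) -> float:
    """Mean open-field speed (cm/s): path length over total time."""
    if occ.total_s <= 0:
        raise ValidationError("arena_speed needs a positive total time")
    return occ.path_cm / occ.total_s
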