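"""Nine-arm radial-maze performance measures.

A trial records the ordered arm entries of one mouse on one day, the trial
duration (at most 600 s: the trial ends after ten minutes or after nine arm
entries, revisits included), per-entry dwell times, the path length, and the
set of maze regions visited.  From a 16-day session block this module derives
the five cognitive metrics used throughout the longitudinal analysis

* decision-making time  -- mean of T_trial/(n+1) over days,
* error count           -- arm entries minus distinct arms, averaged per day,
* unique-sequence score -- length-weighted sum of squared counts of maximal
                           repeat-free runs of arm entries,
* learning rate         -- negated slope of daily errors against day,
* exploration ratio     -- fraction of the 27 explorable regions entered,

plus two non-cognitive ones (cumulative arm time, mean running speed) and the
circular offset histogram of consecutive arm choices.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ArenaLayout,
    DEFAULT_LAYOUT,
    ValidationError,
    VisitEvent,
)

MAX_TRIAL_SECONDS = 600.0
MAX_ARM_ENTRIES = 9
DAYS_PER_SESSION = 16


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Trial:
    """One maze session of one mouse on one day."""

    mouse_id: str
    age_months: int
    day: int
    arm_entries: list[int]
    entry_times: list[float]
    t_trial: float
    arm_dwell: list[float]
    distance_cm: float
    regions_visited: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_trial <= MAX_TRIAL_SECONDS + 1e-9:
            raise ValidationError(
                f"trial duration {self.t_trial} outside [0, {MAX_TRIAL_SECONDS}]"
            )
        if len(self.arm_entries) > MAX_ARM_ENTRIES:
            raise ValidationError(
                f"{len(self.arm_entries)} arm entries exceed the "
                f"{MAX_ARM_ENTRIES}-entry termination rule"
            )
        if len(self.arm_dwell) != len(self.arm_entries):
            raise ValidationError("arm_dwell must align with arm_entries")
        if any(d < 0 for d in self.arm_dwell):
            raise ValidationError("dwell times must be non-negative")

    @property
    def n_entries(self) -> int:
        return len(self.arm_entries)

    @property
    def n_distinct(self) -> int:
        return len(set(self.arm_entries))


@dataclass
class SessionBlock:
    """The (up to 16) trials of one mouse at one age, ordered by day."""

    mouse_id: str
    age_months: int
    trials: list[Trial]

    def __post_init__(self) -> None:
        days = [t.day for t in self.trials]
        if len(set(days)) != len(days):
            raise ValidationError(f"duplicate days in session block: {sorted(days)}")
        if any(not 1 <= d <= DAYS_PER_SESSION for d in days):
            raise ValidationError(f"days must lie in 1..{DAYS_PER_SESSION}")
        for t in self.trials:
            if t.mouse_id != self.mouse_id or t.age_months != self.age_months:
                raise ValidationError("trial does not belong to this block")
        self.trials = sorted(self.trials, key=lambda t: t.day)

    def __len__(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class UniqueSequenceDecomposition:
    """Greedy left-to-right split of an entry list into repeat-free segments."""

    lengths: tuple[int, ...]

    @property
    def counts(self) -> dict[int, int]:
        """f_i: number of segments of each length i."""
        return dict(Counter(self.lengths))

    @property
    def n_entries(self) -> int:
        return sum(self.lengths)


# ---------------------------------------------------------------------------
# sequence decomposition and per-trial scores
# ---------------------------------------------------------------------------


def decompose_unique_sequences(arm_entries: Sequence[int]) -> UniqueSequenceDecomposition:
    """Split arm entries into maximal runs containing no repeated arm.

    The parse is greedy: a segment grows until the next entry repeats an arm
    already inside it; that entry closes the segment and starts the next one,
    so segments partition the entry list.  The trailing segment counts even
    when no repeat closed it.  A unique sequence is found anywhere in the
    trial, never nested inside another.
    """
    lengths: list[int] = []
    current: set[int] = set()
    size = 0
    for arm in arm_entries:
        if arm in current:
            lengths.append(size)
            current = {arm}
            size = 1
        else:
            current.add(arm)
            size += 1
    if size:
        lengths.append(size)
    return UniqueSequenceDecomposition(tuple(lengths))


def count_errors(trial: Trial) -> int:
    """Returns to an already-visited arm within the trial."""
    return trial.n_entries - trial.n_distinct


def trial_uss(trial: Trial) -> float:
    """Weighted Euclidean sum-square product score for one trial.

    USS = sum over segment lengths i of i * f_i**2, with f_i the number of
    repeat-free segments of length i in this trial's decomposition.
    """
    counts = decompose_unique_sequences(trial.arm_entries).counts
    return float(sum(i * f * f for i, f in counts.items()))


# ---------------------------------------------------------------------------
# day-level table and session-level metrics
# ---------------------------------------------------------------------------


def daily_metrics(
    block: SessionBlock, layout: ArenaLayout = DEFAULT_LAYOUT
) -> pd.DataFrame:
    """Per-day values of the maze metrics for one session block.

    Session-level metrics are the column means of this table; the day-level
    resolution is what the per-mouse lifespan regressions consume.
    """
    if not block.trials:
        raise ValidationError("empty session block")
    rows = []
    centre = layout.inner_centre_region
    for tr in block.trials:
        n = tr.n_entries
        explored = {r for r in tr.regions_visited if r != centre}
        rows.append(
            {
                "day": tr.day,
                "DMT": tr.t_trial / (n + 1),
                "errors": float(count_errors(tr)),
                "USS": trial_uss(tr),
                "exploration_ratio": len(explored) / layout.n_explorable,
                "cumulative_arm_time": float(sum(tr.arm_dwell)),
                "velocity": tr.distance_cm / tr.t_trial if tr.t_trial > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("day")


def decision_time(block: SessionBlock) -> float:
    """Mean decision-making time (s): T_trial/(n+1) averaged over days.

    n counts arm entries (revisits included); the +1 keeps a zero-visit trial
    finite (a 600 s trial with no entries scores 600 s).  Missing days reduce
    the divisor: the session mean is over observed days.
    """
    if not block.trials:
        raise ValidationError("decision_time of an empty block")
    return float(np.mean([t.t_trial / (t.n_entries + 1) for t in block.trials]))


def mean_errors(block: SessionBlock) -> float:
    """Daily error count averaged over the observed days of the session."""
    if not block.trials:
        raise ValidationError("mean_errors of an empty block")
    return float(np.mean([count_errors(t) for t in block.trials]))


def unique_sequence_score(block: SessionBlock) -> float:
    """Session USS: the per-trial score averaged over observed days."""
    if not block.trials:
        raise ValidationError("unique_sequence_score of an empty block")
    return float(np.mean([trial_uss(t) for t in block.trials]))


def learning_rate(block: SessionBlock) -> float:
    """Negated OLS slope of daily errors against day number (errors/day).

    Falling errors across the session give a positive learning rate.
    """
    days = np.array([t.day for t in block.trials], dtype=float)
    if len(np.unique(days)) < 2:
        raise ValidationError("learning_rate needs at least 2 distinct days")
    errs = np.array([count_errors(t) for t in block.trials], dtype=float)
    slope = np.polyfit(days, errs, 1)[0]
    return float(-slope)


def exploration_ratio(block: SessionBlock, layout: ArenaLayout = DEFAULT_LAYOUT) -> float:
    """Mean fraction of the 27 non-centre maze regions entered per day."""
    if not block.trials:
        raise ValidationError("exploration_ratio of an empty block")
    return float(daily_metrics(block, layout)["exploration_ratio"].mean())


def cumulative_arm_time(block: SessionBlock) -> float:
    """Mean total time (s) spent on the arms per day."""
    if not block.trials:
        raise ValidationError("cumulative_arm_time of an empty block")
    return float(np.mean([sum(t.arm_dwell) for t in block.trials]))


def mean_speed(block: SessionBlock) -> float:
    """Mean running speed (cm/s): path length over trial time, per day."""
    if not block.trials:
        raise ValidationError("mean_speed of an empty block")
    speeds = []
    for t in block.trials:
        if t.t_trial <= 0:
            raise ValidationError(f"zero-duration trial on day {t.day}")
        speeds.append(t.distance_cm / t.t_trial)
    return float(np.mean(speeds))


def session_metrics(
    block: SessionBlock, layout: ArenaLayout = DEFAULT_LAYOUT
) -> dict[str, float]:
    """All seven maze metrics of one session block, keyed by registry name."""
    return {
        "DMT": decision_time(block),
        "errors": mean_errors(block),
        "USS": unique_sequence_score(block),
        "learning_rate": learning_rate(block),
        "exploration_ratio": exploration_ratio(block, layout),
        "cumulative_arm_time": cumulative_arm_time(block),
        "velocity": mean_speed(block),
    }


# ---------------------------------------------------------------------------
# adjacent-arm offsets
# ---------------------------------------------------------------------------


def arm_offset(a: int, b: int, n_arms: int = 9) -> int:
    """Signed circular offset of a consecutive arm transition a -> b.

    Offsets live in -(n//2)..+(n//2); re-entry into the same arm scores 0;
    for nine arms the wrap-around means 8 -> 1 is a move of +2.
    """
    half = n_arms // 2
    return (b - a + half) % n_arms - half


def adjacent_offset_distribution(
    block: SessionBlock,
    n_arms: int = 9,
    normalise: bool = False,
) -> dict[int, float]:
    """Histogram of circular offsets over all consecutive arm entries.

    With ``normalise`` the counts are scaled to the histogram maximum, the
    convention used when plotting normalised choice frequencies.
    """
    half = n_arms // 2
    counts = Counter()
    for tr in block.trials:
        for a, b in zip(tr.arm_entries, tr.arm_entries[1:]):
            counts[arm_offset(a, b, n_arms)] += 1
    if not counts:
        raise ValidationError("no consecutive arm entries in block")
    hist = {k: float(counts.get(k, 0)) for k in range(-half, half + 1)}
    if normalise:
        peak = max(hist.values())
        if peak > 0:
            hist = {k: v / peak for k, v in hist.items()}
    return hist


# ---------------------------------------------------------------------------
# building trials from event logs
# ---------------------------------------------------------------------------


def trials_from_events(
    events: Iterable[VisitEvent],
    trial_table: pd.DataFrame,
    layout: ArenaLayout = DEFAULT_LAYOUT,
) -> list[SessionBlock]:
    """Assemble session blocks from an event log and its per-trial table.

    Arm entries and dwell times come from paired entry/exit events on arm
    regions; trial duration and path length come from the companion table.
    """
    info: dict[tuple[str, int, int], tuple[float, float]] = {}
    for row in trial_table.itertuples(index=False):
        info[(str(row.mouse_id), int(row.age_months), int(row.day))] = (
            float(row.t_trial),
            float(row.distance_cm),
        )

    grouped: dict[tuple[str, int, int], list[VisitEvent]] = {}
    for ev in events:
        grouped.setdefault((ev.mouse_id, ev.age_months, ev.day), []).append(ev)

    blocks: dict[tuple[str, int], list[Trial]] = {}
    for key, evs in grouped.items():
        if key not in info:
            raise ValidationError(f"trial {key} has events but no trial-table row")
        t_trial, distance = info[key]
        evs = sorted(evs, key=lambda e: e.t)
        arm_entries: list[int] = []
        entry_times: list[float] = []
        dwell: list[float] = []
        open_arm: dict[int, float] = {}
        regions: set[str] = set()
        for ev in evs:
            regions.add(ev.region)
            arm = layout.arm_index(ev.region)
            if arm is None:
                continue
            if ev.kind == "entry":
                arm_entries.append(arm)
                entry_times.append(ev.t)
                open_arm[len(arm_entries) - 1] = ev.t
                dwell.append(0.0)
            else:
                # match the most recent unclosed entry of this arm
                for idx in range(len(arm_entries) - 1, -1, -1):
                    if arm_entries[idx] == arm and idx in open_arm:
                        dwell[idx] = ev.t - open_arm.pop(idx)
                        break
        # an unclosed arm visit dwells until trial end
        for idx, t0 in open_arm.items():
            dwell[idx] = t_trial - t0
        mouse_id, age, day = key
        trial = Trial(
            mouse_id=mouse_id,
            age_months=age,
            day=day,
            arm_entries=arm_entries,
            entry_times=entry_times,
            t_trial=t_trial,
            arm_dwell=dwell,
            distance_cm=distance,
            regions_visited=regions,
        )
        blocks.setdefault((mouse_id, age), []).append(trial)

    return [
        SessionBlock(mouse_id=m, age_months=a, trials=trs)
        for (m, a), trs in sorted(blocks.items())
    ]
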