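"""Readers and writers for the pipeline's on-disk formats.

Event logs, trial tables, weight tables and object-bout tables are long-format
CSV (dialect modelled on video-tracking exports); metric, Z-score and stability
tables are TSV with a commented header that records the RNG seed, the software
version and a configuration hash so a run can be reproduced bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__version__ = "0.1.0"

logger = logging.getLogger("mazetrait")

EVENT_COLUMNS = ["mouse_id", "age_months", "day", "t", "region", "kind"]
TRIAL_COLUMNS = ["mouse_id", "age_months", "day", "t_trial", "distance_cm"]

#: The eleven metrics the longitudinal analysis registers, in canonical order.
METRIC_NAMES = [
    "DMT",
    "errors",
    "USS",
    "learning_rate",
    "exploration_ratio",
    "cumulative_arm_time",
    "velocity",
    "OR1",
    "OR15",
    "OL1",
    "OL15",
]

#: Metrics where a lower raw value means better performance; their Z-scores
#: are sign-inverted so that higher always means better.
INVERTED_METRICS = frozenset({"DMT", "errors"})

#: The five radial-maze metrics used for per-mouse decline screening.
MAZE_METRICS = ["USS", "errors", "DMT", "exploration_ratio", "cumulative_arm_time"]


class ParseError(ValueError):
    """A malformed row in an input file (message carries the line number)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a pipeline invariant."""


# ---------------------------------------------------------------------------
# arena layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArenaLayout:
    """Region naming for the nine-arm radial maze and the open-field arena.

    The maze is split into 3*n_arms + 1 regions: one arm, one bridge and one
    outer-centre region per arm, plus a single inner-centre region.  Arms are
    numbered consecutively clockwise so that circular offset arithmetic between
    consecutive arm entries is well defined.
    """

    n_arms: int = 9

    def __post_init__(self) -> None:
        if self.n_arms < 2:
            raise ValidationError(f"need at least 2 arms, got {self.n_arms}")

    @property
    def arm_regions(self) -> list[str]:
        return [f"A{i}" for i in range(self.n_arms)]

    @property
    def bridge_regions(self) -> list[str]:
        return [f"B{i}" for i in range(self.n_arms)]

    @property
    def outer_centre_regions(self) -> list[str]:
        return [f"O{i}" for i in range(self.n_arms)]

    @property
    def inner_centre_region(self) -> str:
        return "C"

    @property
    def maze_regions(self) -> list[str]:
        return (
            self.arm_regions
            + self.bridge_regions
            + self.outer_centre_regions
            + [self.inner_centre_region]
        )

    @property
    def n_explorable(self) -> int:
        """Explorable regions per day: everything except the inner centre."""
        return 3 * self.n_arms

    def arm_index(self, region: str) -> int | None:
        """Arm number for an arm region id, else None."""
        if region.startswith("A") and region[1:].isdigit():
            idx = int(region[1:])
            if idx < self.n_arms:
                return idx
        return None

    #: open-field zones (centre / inner / outer annuli)
    field_zones = ("centre", "inner", "outer")


DEFAULT_LAYOUT = ArenaLayout()


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class VisitEvent:
    """One region entry or exit, timed in seconds from trial start."""

    mouse_id: str
    age_months: int
    day: int
    t: float
    region: str
    kind: str  # "entry" | "exit"

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValidationError(f"negative timestamp {self.t}")
        if self.kind not in ("entry", "exit"):
            raise ValidationError(f"kind must be entry/exit, got {self.kind!r}")


def read_event_log(path: str | Path, layout: ArenaLayout = DEFAULT_LAYOUT) -> list[VisitEvent]:
    """Read a long-format event CSV into time-sorted, validated events.

    Rows are grouped per (mouse, age, day) and must carry non-decreasing
    timestamps within each trial; unknown region ids are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")

    known = set(layout.maze_regions)
    events: list[VisitEvent] = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        region = str(row.region)
        if region not in known:
            raise ParseError(
                f"{path}:{lineno}: unknown region {region!r} for a "
                f"{layout.n_arms}-arm layout"
            )
        try:
            ev = VisitEvent(
                mouse_id=str(row.mouse_id),
                age_months=int(row.age_months),
                day=int(row.day),
                t=float(row.t),
                region=region,
                kind=str(row.kind),
            )
        except (TypeError, ValueError, ValidationError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        events.append(ev)

    events.sort(key=lambda e: (e.mouse_id, e.age_months, e.day, e.t))
    # non-decreasing timestamps within a trial come free from the sort; what we
    # must verify is that the file did not claim an impossible ordering, i.e.
    # exit-before-entry for a region within one trial.
    open_since: dict[tuple, float] = {}
    last_key = None
    for ev in events:
        key = (ev.mouse_id, ev.age_months, ev.day)
        if key != last_key:
            open_since.clear()
            last_key = key
        rkey = ev.region
        if ev.kind == "entry":
            if rkey in open_since:
                raise ValidationError(
                    f"double entry into {ev.region} at t={ev.t} for {key}"
                )
            open_since[rkey] = ev.t
        else:
            if rkey not in open_since:
                raise ValidationError(
                    f"exit without entry for {ev.region} at t={ev.t} for {key}"
                )
            if ev.t < open_since[rkey]:
                raise ValidationError(
                    f"non-monotone timestamps for {ev.region} in trial {key}"
                )
            del open_since[rkey]
    return events


def write_event_log(events: Iterable[VisitEvent], path: str | Path) -> None:
    """Write events as CSV in the dialect :func:`read_event_log` accepts."""
    rows = [
        (e.mouse_id, e.age_months, e.day, e.t, e.region, e.kind) for e in events
    ]
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    df.to_csv(path, index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    """Companion per-trial table (duration and path length)."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    df["mouse_id"] = df["mouse_id"].astype(str)
    return df


def write_trial_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=TRIAL_COLUMNS)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Pipeline configuration; serialised to JSON, hashed into output headers."""

    seed: int = 0
    n_arms: int = 9
    metrics: Sequence[str] = field(default_factory=lambda: list(METRIC_NAMES))
    ridge_lambda: float = 0.0
    n_resamples_per_size: int | None = None
    population_sd: bool = True  # population (ddof=0) vs sample sd in Z-scores
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.ridge_lambda < 0:
            raise ValidationError(f"ridge_lambda must be >= 0, got {self.ridge_lambda}")
        unknown = [m for m in self.metrics if m not in METRIC_NAMES]
        if unknown:
            raise ValidationError(f"unknown metrics {unknown}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# metric / Z tables
# ---------------------------------------------------------------------------


def _header_lines(seed: int | None, config: RunConfig | None) -> list[str]:
    lines = [f"# mazetrait {__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config is not None:
        lines.append(f"# config_hash={config.config_hash()}")
    return lines


def write_metric_table(
    table: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: RunConfig | None = None,
) -> None:
    """Write a mice x metrics table as TSV with a reproducibility header.

    Raises before touching the filesystem if the table is empty.
    """
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValidationError("refusing to write an empty metric table")
    path = Path(path)
    body = table.to_csv(sep="\t", index=True, index_label="mouse_id")
    text = "\n".join(_header_lines(seed, config)) + "\n" + body
    path.write_text(text)
    logger.info("wrote %d x %d metric table to %s", *table.shape, path)


def read_metric_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="mouse_id")
    df.index = df.index.astype(str)
    return df


# Z-tables share the metric-table format.
write_z_table = write_metric_table
read_z_table = read_metric_table


def setup_logging(level: str = "INFO") -> None:
    """Configure stderr logging for CLI use."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
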