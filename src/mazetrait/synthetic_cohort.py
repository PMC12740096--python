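"""Synthetic longitudinal cohorts for end-to-end pipeline testing.

No public dataset exists for this kind of study, so the generator emulates
one: a cohort of female mice tested at 4, 8, 12 and 18 months with 16 maze
trials per age, object-preference bouts, open-field occupancy and body
weights.  Each mouse carries one stable cognitive trait g ~ N(0, 1); its
session-level ability on each behavioural channel (entry latency, arm choice,
region exploration, arm dwell) at age t is

    a_channel(t) = sqrt(rho) * g + sqrt(1 - rho) * eps_channel(t)

so any two ages correlate at exactly rho (0.7 for maze channels by default).
Ability acts primarily on entry latency -- and hence on how much of the maze
a mouse completes within the 10-minute budget -- with a weaker effect on
revisit propensity; this makes the planted trait identifiable from 16 trials
per age, which a revisit-only mechanism cannot achieve (see docs/methods.md).
Speed and object preference get their own latent classes (rho 0.3 and 0.0),
reproducing the dissociation in which maze metrics are predictive across ages
while speed and short-term object memory are not.  An optional decliner mouse
drifts downward on every channel from its onset age.

Arm choices follow an offset-biased kernel concentrated on moves of +/-2
arms, the preferred step size of real mice; already-visited arms are
down-weighted.  All randomness flows from one seed through named
SeedSequence streams: trait draws are keyed per mouse, per-age fluctuations
per (mouse, age, channel), and within-trial draws per (mouse, day) -- with no
age in the key, so a fully stable cohort (rho = 1, zero noise) reproduces
identical trials, and hence identical maze metrics, at every age.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import ValidationError, VisitEvent, write_event_log, write_trial_table
from .maze_metrics import SessionBlock, Trial
from .object_openfield import OBJECT_TASKS, ExplorationBout, FieldOccupancy

# ---------------------------------------------------------------------------
# frozen generator constants (calibrated once; see docs/methods.md)
# ---------------------------------------------------------------------------

#: next-arm weights over circular offsets -4..+4 (peaks at +/-2, trough at 0)
OFFSET_KERNEL = np.array([0.15, 0.25, 0.9, 0.5, 0.1, 0.5, 0.9, 0.25, 0.15])

LAT_MEDIAN = 105.0     # s, median inter-entry interval at average ability
LAT_GAIN = 0.24        # entry rate rises linearly with latency-channel ability
LAT_FLOOR = 0.12       # lower bound of the rate factor (very poor ability)
LAT_SIGMA = 0.06       # lognormal sd of interval noise
KAPPA0 = 0.06          # revisit down-weight at average choice ability
KAPPA_GAIN = 0.2       # revisit propensity falls with choice ability
DWELL_MEDIAN = 18.0    # s per arm visit at average dwell ability
DWELL_GAIN = 0.20
DWELL_SIGMA = 0.3
MAZE_SPEED = 8.0       # cm/s at average speed trait
MAZE_SPEED_GAIN = 0.20
MAZE_SPEED_SIGMA = 0.05
OF_SPEED_BASE = 12.71  # cm/s open-field speed at 4 months (cohort mean)
OF_OUTER_BASE = 0.7288  # outer-zone occupancy fraction at 4 months

CHANNELS = ("latency", "choice", "explore", "dwell")
TRIAL_SECONDS = 600.0
MAX_ENTRIES = 9

# stream domains for named SeedSequence keys
_D_TRAIT, _D_ABILITY, _D_TRIAL, _D_AGEPOINT, _D_WEIGHT = range(5)


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeclinerSpec:
    """One mouse whose ability drifts down from an onset age."""

    mouse_index: int = 20
    onset_age: int = 8
    drift_per_age: float = 1.5  # latent-SD units per age point


@dataclass(frozen=True)
class CohortSpec:
    """Study design and generative parameters of a synthetic cohort."""

    seed: int
    n_mice: int = 22
    ages: tuple[int, ...] = (4, 8, 12, 18)
    trials_per_age: int = 16
    ability_sd: float = 1.0
    rho_maze: float = 0.7
    rho_speed: float = 0.3
    rho_object: float = 0.0
    weight_slope: float = 0.45       # g/month, strictly positive growth
    speed_age_slope: float = -0.26   # cm/s per month in the open field
    outer_age_slope: float = 0.00667  # outer-zone fraction per month
    decliner: DeclinerSpec | None = None
    noise_scale: float = 1.0
    attrition: bool = False

    def __post_init__(self) -> None:
        for name in ("rho_maze", "rho_speed", "rho_object"):
            rho = getattr(self, name)
            if not 0.0 <= rho <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {rho}")
        if self.n_mice < 1 or self.trials_per_age < 1:
            raise ValidationError("n_mice and trials_per_age must be >= 1")
        if self.noise_scale < 0 or self.ability_sd < 0:
            raise ValidationError("noise_scale and ability_sd must be >= 0")
        if self.decliner is not None:
            if not 0 <= self.decliner.mouse_index < self.n_mice:
                raise ValidationError("decliner mouse_index outside cohort")
            if self.decliner.onset_age not in self.ages:
                raise ValidationError("decliner onset_age not a tested age")
        if self.attrition and self.n_mice != 58:
            raise ValidationError("the attrition schedule applies to a 58-mouse cohort")

    def mice_at(self, age: int) -> list[int]:
        """Mouse indices tested at an age (attrition schedule 58/46/31/22)."""
        if not self.attrition:
            return list(range(self.n_mice))
        counts = dict(zip(self.ages, (58, 46, 31, 22)))
        return list(range(counts.get(age, self.n_mice)))


@dataclass
class CohortData:
    """Everything one synthetic study produces, in memory."""

    spec: CohortSpec
    blocks: dict[tuple[int, int], SessionBlock]  # (mouse index, age) -> block
    weights: pd.DataFrame                        # mouse_id, age_months, weight_g
    bouts: list[ExplorationBout]
    occupancy: list[FieldOccupancy]
    truth: pd.DataFrame

    def mouse_ids(self) -> list[str]:
        return [f"m{i:02d}" for i in range(self.spec.n_mice)]


# ---------------------------------------------------------------------------
# latent structure
# ---------------------------------------------------------------------------


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _latent_abilities(spec: CohortSpec) -> dict:
    """Per-mouse traits and per-age channel abilities (before decline)."""
    out: dict = {
        "g": {}, "speed_trait": {}, "channels": {},
        "speed": {}, "object": {}, "anxiety": {},
    }
    n_tasks = len(OBJECT_TASKS)
    for i in range(spec.n_mice):
        rng_trait = _rng(spec.seed, _D_TRAIT, i)
        g = rng_trait.normal() * spec.ability_sd
        h = rng_trait.normal()                      # speed trait
        anx = rng_trait.normal()                    # thigmotaxis trait
        obj_g = rng_trait.normal(size=n_tasks)      # per-task object traits
        out["g"][i] = g
        out["speed_trait"][i] = h
        for j, age in enumerate(spec.ages):
            rng_age = _rng(spec.seed, _D_ABILITY, i, j)
            eps = rng_age.normal(size=len(CHANNELS)) * spec.ability_sd
            ch = {
                c: math.sqrt(spec.rho_maze) * g
                + math.sqrt(1.0 - spec.rho_maze) * eps[k]
                for k, c in enumerate(CHANNELS)
            }
            if spec.decliner is not None and i == spec.decliner.mouse_index:
                onset_j = spec.ages.index(spec.decliner.onset_age)
                if j >= onset_j:
                    shift = spec.decliner.drift_per_age * (j - onset_j + 1)
                    ch = {c: v - shift for c, v in ch.items()}
            out["channels"][(i, age)] = ch
            out["speed"][(i, age)] = (
                math.sqrt(spec.rho_speed) * h
                + math.sqrt(1.0 - spec.rho_speed) * rng_age.normal()
            )
            out["object"][(i, age)] = (
                math.sqrt(spec.rho_object) * obj_g
                + math.sqrt(1.0 - spec.rho_object) * rng_age.normal(size=n_tasks)
            )
            out["anxiety"][(i, age)] = (
                math.sqrt(spec.rho_speed) * anx
                + math.sqrt(1.0 - spec.rho_speed) * rng_age.normal()
            )
    return out


def truth_table(spec: CohortSpec) -> pd.DataFrame:
    """Planted parameters per mouse: the oracle for recovery tests."""
    lat = _latent_abilities(spec)
    rows = []
    for i in range(spec.n_mice):
        row = {
            "mouse_id": f"m{i:02d}",
            "stable_trait": lat["g"][i],
            "speed_trait": lat["speed_trait"][i],
            "is_decliner": (
                spec.decliner is not None and i == spec.decliner.mouse_index
            ),
            "rho_maze": spec.rho_maze,
            "rho_speed": spec.rho_speed,
            "rho_object": spec.rho_object,
        }
        for age in spec.ages:
            row[f"ability_{age}mo"] = float(
                np.mean(list(lat["channels"][(i, age)].values()))
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("mouse_id")


# ---------------------------------------------------------------------------
# single-trial simulation
# ---------------------------------------------------------------------------


def _simulate_trial(
    mouse: int,
    age: int,
    day: int,
    ch: dict[str, float],
    speed_lat: float,
    spec: CohortSpec,
) -> Trial:
    rng = _rng(spec.seed, _D_TRIAL, mouse, day)
    lat_scale = LAT_MEDIAN / max(LAT_FLOOR, 1.0 + LAT_GAIN * ch["latency"])
    kappa = min(1.0, KAPPA0 * math.exp(-KAPPA_GAIN * ch["choice"]))
    sig = LAT_SIGMA * spec.noise_scale

    entries: list[int] = []
    times: list[float] = []
    visited: set[int] = set()
    t = lat_scale * math.exp(rng.normal(0.0, sig)) if sig > 0 else lat_scale
    if t <= TRIAL_SECONDS:
        arm = int(rng.integers(MAX_ENTRIES))
        entries.append(arm)
        times.append(t)
        visited.add(arm)
        while len(entries) < MAX_ENTRIES:
            dt = lat_scale * math.exp(rng.normal(0.0, sig)) if sig > 0 else lat_scale
            if t + dt > TRIAL_SECONDS:
                t = TRIAL_SECONDS
                break
            t += dt
            w = OFFSET_KERNEL.copy()
            cand = (arm + np.arange(-4, 5)) % MAX_ENTRIES
            for k, c in enumerate(cand):
                if c in visited:
                    w[k] *= kappa
            cw = np.cumsum(w)
            arm = int(cand[np.searchsorted(cw, rng.random() * cw[-1], side="right")])
            entries.append(arm)
            times.append(t)
            visited.add(arm)
        else:
            t = min(t, TRIAL_SECONDS)
    else:
        t = TRIAL_SECONDS

    t_trial = t

    # dwell on each arm, capped so the visit ends before the next bridge crossing
    dsig = DWELL_SIGMA * spec.noise_scale
    dwell = []
    for k in range(len(entries)):
        gap = (times[k + 1] if k + 1 < len(entries) else t_trial) - times[k]
        draw = DWELL_MEDIAN * math.exp(DWELL_GAIN * ch["dwell"])
        if dsig > 0:
            draw *= math.exp(rng.normal(0.0, dsig))
        dwell.append(float(min(max(0.0, 0.85 * gap), max(0.0, gap - 1.5), draw)))

    # regions: entered arms and their bridges, plus bridge-only and
    # outer-centre visits governed by the exploration channel
    distinct = sorted(visited)
    regions = {"C"}
    regions.update(f"A{a}" for a in distinct)
    regions.update(f"B{a}" for a in distinct)
    p_bridge = _logistic(0.4 + 0.8 * ch["explore"])
    p_outer = _logistic(1.2 + 0.8 * ch["explore"])
    unvisited_arms = [a for a in range(MAX_ENTRIES) if a not in visited]
    for a in unvisited_arms:
        if rng.random() < p_bridge:
            regions.add(f"B{a}")
    for a in range(MAX_ENTRIES):
        if rng.random() < p_outer:
            regions.add(f"O{a}")

    v = MAZE_SPEED * math.exp(MAZE_SPEED_GAIN * speed_lat)
    if MAZE_SPEED_SIGMA * spec.noise_scale > 0:
        v *= math.exp(rng.normal(0.0, MAZE_SPEED_SIGMA * spec.noise_scale))
    distance = v * t_trial

    return Trial(
        mouse_id=f"m{mouse:02d}",
        age_months=age,
        day=day,
        arm_entries=entries,
        entry_times=times,
        t_trial=t_trial,
        arm_dwell=dwell,
        distance_cm=distance,
        regions_visited=regions,
    )


# ---------------------------------------------------------------------------
# whole-cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(spec: CohortSpec) -> CohortData:
    """Generate the full study in memory (the fast path for analysis)."""
    lat = _latent_abilities(spec)
    blocks: dict[tuple[int, int], SessionBlock] = {}
    weights_rows = []
    bouts: list[ExplorationBout] = []
    occupancy: list[FieldOccupancy] = []

    for i in range(spec.n_mice):
        mouse_id = f"m{i:02d}"
        rng_w = _rng(spec.seed, _D_WEIGHT, i)
        weight = rng_w.normal(22.0, 1.5)
        prev_age = spec.ages[0]
        for j, age in enumerate(spec.ages):
            if i not in spec.mice_at(age):
                continue
            if j > 0:
                growth = spec.weight_slope * (age - prev_age)
                jitter = (
                    math.exp(rng_w.normal(0.0, 0.08 * spec.noise_scale))
                    if spec.noise_scale > 0
                    else 1.0
                )
                weight += growth * jitter
            prev_age = age
            weights_rows.append(
                {"mouse_id": mouse_id, "age_months": age, "weight_g": weight}
            )

            ch = lat["channels"][(i, age)]
            s = lat["speed"][(i, age)]
            trials = [
                _simulate_trial(i, age, day, ch, s, spec)
                for day in range(1, spec.trials_per_age + 1)
            ]
            blocks[(i, age)] = SessionBlock(
                mouse_id=mouse_id, age_months=age, trials=trials
            )

            rng_a = _rng(spec.seed, _D_AGEPOINT, i, j)
            # open field: 600 s of free exploration
            of_speed = max(
                0.5,
                (OF_SPEED_BASE + spec.speed_age_slope * (age - spec.ages[0]))
                * math.exp(0.15 * s),
            )
            outer = OF_OUTER_BASE + spec.outer_age_slope * (age - spec.ages[0])
            outer += 0.05 * lat["anxiety"][(i, age)]
            if spec.noise_scale > 0:
                outer += 0.02 * spec.noise_scale * rng_a.normal()
            outer = float(np.clip(outer, 0.35, 0.97))
            c_share = 0.35
            if spec.noise_scale > 0:
                c_share = float(np.clip(0.35 + 0.05 * spec.noise_scale * rng_a.normal(), 0.05, 0.8))
            centre = (1.0 - outer) * c_share
            inner = 1.0 - outer - centre
            occupancy.append(
                FieldOccupancy(
                    mouse_id=mouse_id,
                    age_months=age,
                    centre_s=600.0 * centre,
                    inner_s=600.0 * inner,
                    outer_s=600.0 * outer,
                    total_s=600.0,
                    path_cm=of_speed * 600.0,
                )
            )

            # object tasks: sample phase near chance, choice phase trait-driven
            for k, task in enumerate(OBJECT_TASKS):
                o = lat["object"][(i, age)][k]
                p_choice = float(np.clip(0.58 + 0.09 * o, 0.02, 0.98))
                p_sample = 0.49
                if spec.noise_scale > 0:
                    p_sample = float(
                        np.clip(0.49 + 0.05 * spec.noise_scale * rng_a.normal(), 0.05, 0.95)
                    )
                total_sample = float(rng_a.gamma(6.0, 7.0))
                total_choice = float(rng_a.gamma(6.0, 7.0))
                for phase, p, total in (
                    ("sample", p_sample, total_sample),
                    ("choice", p_choice, total_choice),
                ):
                    for obj, frac in (("novel", p), ("familiar", 1.0 - p)):
                        bouts.append(
                            ExplorationBout(
                                mouse_id=mouse_id,
                                age_months=age,
                                task=task,
                                phase=phase,
                                object=obj,
                                duration=total * frac,
                            )
                        )

    weights = pd.DataFrame(weights_rows)
    return CohortData(
        spec=spec,
        blocks=blocks,
        weights=weights,
        bouts=bouts,
        occupancy=occupancy,
        truth=truth_table(spec),
    )


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------


def _events_from_trial(trial: Trial, rng: np.random.Generator) -> list[VisitEvent]:
    """Expand one trial into region entry/exit events.

    Every arm entry is preceded by a short bridge crossing; bridge-only and
    outer-centre visits are placed in free gaps; the inner centre is occupied
    from the start of the trial to the first bridge crossing.
    """
    ev: list[VisitEvent] = []
    base = dict(mouse_id=trial.mouse_id, age_months=trial.age_months, day=trial.day)
    first_move = trial.entry_times[0] - 1.0 if trial.arm_entries else trial.t_trial
    ev.append(VisitEvent(**base, t=0.0, region="C", kind="entry"))
    ev.append(VisitEvent(**base, t=max(0.0, first_move), region="C", kind="exit"))
    arm_regions_used: set[str] = set()
    for k, (arm, t_in) in enumerate(zip(trial.arm_entries, trial.entry_times)):
        ev.append(VisitEvent(**base, t=max(0.0, t_in - 1.0), region=f"B{arm}", kind="entry"))
        ev.append(VisitEvent(**base, t=t_in, region=f"B{arm}", kind="exit"))
        ev.append(VisitEvent(**base, t=t_in, region=f"A{arm}", kind="entry"))
        ev.append(
            VisitEvent(
                **base, t=min(trial.t_trial, t_in + trial.arm_dwell[k]),
                region=f"A{arm}", kind="exit",
            )
        )
        arm_regions_used.update({f"A{arm}", f"B{arm}"})
    # remaining visited regions (bridge-only, outer-centre) as brief visits
    for region in sorted(trial.regions_visited - arm_regions_used - {"C"}):
        t0 = float(rng.uniform(0.0, max(1.0, trial.t_trial - 1.0)))
        ev.append(VisitEvent(**base, t=t0, region=region, kind="entry"))
        ev.append(VisitEvent(**base, t=min(trial.t_trial, t0 + 0.8), region=region, kind="exit"))
    return ev


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> CohortData:
    """Simulate a cohort and write every dataset the readers understand.

    Files: events.csv, trials.csv, weights.csv, bouts.csv, openfield.csv,
    truth.csv and spec.json.  Invalid specs fail before any file is written.
    """
    data = simulate_cohort(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    events: list[VisitEvent] = []
    trial_rows = []
    rng_ev = _rng(spec.seed, 9)
    for (_, _), block in sorted(data.blocks.items()):
        for tr in block.trials:
            events.extend(_events_from_trial(tr, rng_ev))
            trial_rows.append(
                {
                    "mouse_id": tr.mouse_id,
                    "age_months": tr.age_months,
                    "day": tr.day,
                    "t_trial": tr.t_trial,
                    "distance_cm": tr.distance_cm,
                }
            )
    write_event_log(sorted(events), out / "events.csv")
    write_trial_table(pd.DataFrame(trial_rows), out / "trials.csv")
    data.weights.to_csv(out / "weights.csv", index=False)
    pd.DataFrame([asdict(b) for b in data.bouts]).to_csv(out / "bouts.csv", index=False)
    pd.DataFrame([asdict(o) for o in data.occupancy]).to_csv(
        out / "openfield.csv", index=False
    )
    data.truth.to_csv(out / "truth.csv")
    cfg = asdict(spec)
    if spec.decliner is not None:
        cfg["decliner"] = asdict(spec.decliner)
    (out / "spec.json").write_text(json.dumps(cfg, indent=2) + "\n")
    return data
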