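import numpy as np
import pytest

from mazetrait import SessionBlock, Trial


def make_trial(
    entries,
    mouse_id="m00",
    age=4,
    day=1,
    t_trial=600.0,
    dwell=None,
    distance=600.0,
    regions=None,
):
    entries = list(entries)
    n = len(entries)
    times = list(np.linspace(30.0, min(t_trial, 590.0), n)) if n else []
    if dwell is None:
        dwell = [1.0] * n
    if regions is None:
        regions = {f"A{a}" for a in entries} | {f"B{a}" for a in entries} | {"C"}
    return Trial(
        mouse_id=mouse_id,
        age_months=age,
        day=day,
        arm_entries=entries,
        entry_times=times,
        t_trial=t_trial,
        arm_dwell=list(dwell),
        distance_cm=distance,
        regions_visited=set(regions),
    )


def make_block(trial_specs, mouse_id="m00", age=4):
    """Build a session block from per-day keyword dicts."""
    trials = [
        make_trial(mouse_id=mouse_id, age=age, day=day, **spec)
        for day, spec in enumerate(trial_specs, start=1)
    ]
    return SessionBlock(mouse_id=mouse_id, age_months=age, trials=trials)


@pytest.fixture
def perfect_block():
    """Every trial visits all nine arms once: the perfect-performance case."""
    return make_block([{"entries": list(range(9))} for _ in range(4)])
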