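import numpy as np
import pandas as pd
import pytest

from antbridge import (
    EventStream,
    ModelSpec,
    Phase,
    SynthConfig,
    TrialRecord,
    field_nb_models,
    generate_dataset,
)


def make_interval_trial(
    gaps,
    n_starts,
    joins,
    leaves,
    phases=None,
    interval_s=30,
    trial_id="toy",
):
    """Hand-built trial with prescribed per-interval state and event counts.

    The structural series holds ``n_starts[i]`` ants throughout interval
    ``i``.  Join/leave totals are balanced by parking compensating events
    in an appended broken tail interval, which every fitting routine
    excludes.
    """
    gaps = np.asarray(gaps, dtype=float)
    n_int = len(gaps)
    if phases is None:
        phases = [Phase.EXPANSION.value] * n_int
    rows, ev_times, ev_kinds = [], [], []
    for i in range(n_int):
        for s in range(interval_s):
            rows.append((i * interval_s + s, gaps[i], phases[i], n_starts[i]))
        for j in range(joins[i]):
            ev_times.append(i * interval_s + (j + 1) * interval_s / (joins[i] + 1))
            ev_kinds.append("join")
        for j in range(leaves[i]):
            ev_times.append(i * interval_s + (j + 1) * interval_s / (leaves[i] + 1))
            ev_kinds.append("leave")
    # balancing events in a broken tail
    deficit = sum(joins) - sum(leaves)
    tail_start = n_int * interval_s
    for s in range(interval_s):
        rows.append((tail_start + s, 0.0, Phase.CONTRACTION.value
                     if phases[-1] != Phase.EXPANSION.value else phases[-1], 0))
    for j in range(abs(deficit)):
        ev_times.append(tail_start + (j + 1) * interval_s / (abs(deficit) + 1))
        ev_kinds.append("leave" if deficit > 0 else "join")
    times, gap_col, phase_col, n_col = zip(*rows)
    structural = pd.DataFrame(
        {
            "time": times,
            "gap": gap_col,
            "phase": phase_col,
            "volume": 57.0 * np.asarray(n_col),
            "n_ants": n_col,
            "cross_section": 5.0,
            "tautness": 0.5,
            "broken": [t >= tail_start for t in times],
        }
    )
    events = EventStream(pd.DataFrame({"time": ev_times, "kind": ev_kinds}))
    return TrialRecord(trial_id, structural, events)


@pytest.fixture(scope="session")
def field_model():
    return ModelSpec.baseline(field_nb_models())


@pytest.fixture(scope="session")
def small_dataset():
    """Three synthetic trials from the default (field-parameter) generator."""
    trials, ledger = generate_dataset(SynthConfig(n_trials=3, seed=11))
    return trials, ledger
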