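"""Synthetic field trials with the statistical structure the analyses assume.

The generator emulates the three measured streams of a real trial —
per-second structural metrics, timestamped join/leave events, and
per-10-s optical flow — by simulating a configured joining/leaving
model over a gap schedule and dressing the resulting ant-count
trajectory with structural and flow observables:

* event times are placed at uniform offsets within their gap interval
  (real event timing is uniform within intervals);
* volume is proportional to ant count plus Gaussian noise scaled to hit
  a target volume-ants correlation;
* tautness decreases monotonically with the excess of ants (a slack,
  low-hanging bridge has more ants than its equilibrium size);
* platform flows follow an AR(1) process and bridge flow is a linear
  response plus residual noise, with an optional performance elevation
  injected into the window preceding joining events (and an optional
  tautness depression before leaving events);
* optional broken periods are marked and mirrored per second.

Real trials balance join and leave totals because every bridge starts
and ends empty; simulated trajectories may end with ants still in the
bridge, so a forced disassembly tail is appended after the schedule and
flagged broken so downstream statistics exclude it.

Every generated trial passes :mod:`antbridge.trial_io` validation, and
:func:`generate_dataset` returns a machine-readable ledger of all true
parameters and injected effects for test assertions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .simulator import (
    ModelSpec,
    build_schedule,
    example_accumulator_model,
    run_simulation,
)
from .trial_io import (
    EventKind,
    EventStream,
    FlowSeries,
    GapSchedule,
    ParameterError,
    Phase,
    TrialRecord,
)

__all__ = ["SynthConfig", "generate_trial", "generate_dataset"]

FIELD_RHO_STAR = 0.51  # ants per mm of gap, from the original field study
FIELD_VOLUME_PER_ANT = 57.0  # mm^3; 1080 mm^3 at ~18.9 ants


def _default_model() -> ModelSpec:
    # real bridges are density-regulated, so the deficit-feedback model
    # (the field study's best-supported one) is the default generator
    return example_accumulator_model()


@dataclass
class SynthConfig:
    """Ground-truth parameters of a synthetic dataset.

    Defaults mirror the original study's conditions: ten trials on the
    61-interval expansion-contraction schedule (1 mm per 30 s up to
    30 mm), events from the deficit-feedback accumulator model with the
    field-estimated slopes and equilibrium density (real bridges are
    density-regulated), a volume-ants correlation in the observed
    0.88-0.98 range, and no injected cue effects or broken periods
    unless requested.
    """

    n_trials: int = 10
    schedule: GapSchedule = field(default_factory=build_schedule)
    model: ModelSpec = field(default_factory=_default_model)
    rho_star: float = FIELD_RHO_STAR

    # structural series
    volume_per_ant: float = FIELD_VOLUME_PER_ANT  # mm^3 per ant
    target_volume_corr: float | None = 0.93  # mid-range of the observed 0.88-0.98
    volume_noise_sd: float = 50.0  # used only when target_volume_corr is None
    tautness_base: float = 0.5  # relative height of an equilibrium bridge
    tautness_slope: float = 0.02  # drop per excess ant
    tautness_noise_sd: float = 0.03

    # optical flow (px/frame)
    flow_mean: float = 8.0
    flow_ar_phi: float = 0.8
    flow_ar_sd: float = 1.0
    bridge_flow_intercept: float = 1.0
    bridge_flow_slope: float = 0.45
    bridge_flow_resid_sd: float = 0.8

    # injected cue effects
    prejoin_perf_boost: float = 0.0  # px/frame added before joining events
    prejoin_window_s: float = 10.0
    preleave_tautness_drop: float = 0.0
    preleave_window_s: float = 10.0

    # broken periods
    broken_rate: float = 0.0  # expected broken periods per trial
    broken_duration_s: tuple[float, float] = (20.0, 60.0)

    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "volume_noise_sd", "tautness_noise_sd", "flow_ar_sd",
            "bridge_flow_resid_sd",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.target_volume_corr is not None and not (
            0 < self.target_volume_corr <= 1
        ):
            raise ParameterError("target_volume_corr must lie in (0, 1]")
        if self.broken_rate < 0:
            raise ParameterError("broken_rate must be non-negative")

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_trials": self.n_trials,
            "schedule": {
                "n_intervals": self.schedule.n_intervals,
                "duration": self.schedule.duration,
                "max_gap": float(self.schedule.gaps.max()),
            },
            "model": self.model.to_dict(),
            "rho_star": self.rho_star,
            "volume_per_ant": self.volume_per_ant,
            "target_volume_corr": self.target_volume_corr,
            "volume_noise_sd": self.volume_noise_sd,
            "tautness_base": self.tautness_base,
            "tautness_slope": self.tautness_slope,
            "tautness_noise_sd": self.tautness_noise_sd,
            "flow_mean": self.flow_mean,
            "flow_ar_phi": self.flow_ar_phi,
            "flow_ar_sd": self.flow_ar_sd,
            "bridge_flow_intercept": self.bridge_flow_intercept,
            "bridge_flow_slope": self.bridge_flow_slope,
            "bridge_flow_resid_sd": self.bridge_flow_resid_sd,
            "prejoin_perf_boost": self.prejoin_perf_boost,
            "prejoin_window_s": self.prejoin_window_s,
            "preleave_tautness_drop": self.preleave_tautness_drop,
            "preleave_window_s": self.preleave_window_s,
            "broken_rate": self.broken_rate,
            "broken_duration_s": list(self.broken_duration_s),
            "seed": self.seed,
        }


def _event_times(
    counts: np.ndarray, duration: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform offsets within each interval for per-interval event counts."""
    times = []
    for t, c in enumerate(counts):
        if c:
            times.append(t * duration + rng.uniform(0, duration, size=int(c)))
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


def generate_trial(cfg: SynthConfig, trial_index: int) -> tuple[TrialRecord, dict]:
    """Generate one synthetic trial and its ground-truth ledger entry."""
    ss = np.random.SeedSequence([cfg.seed, trial_index])
    sim_seed = int(ss.generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(ss.spawn(1)[0])

    traj = run_simulation(cfg.model, cfg.schedule, seed=sim_seed)
    duration = cfg.schedule.duration
    sched_T = int(round(cfg.schedule.total_time))

    join_times = _event_times(traj.joins, duration, rng)
    leave_times = _event_times(traj.leaves, duration, rng)

    # forced disassembly tail: the remaining ants leave after the schedule
    # ends, flagged broken so analyses exclude it (real trials end empty)
    n_end = int(traj.n_ants[-1])
    tail_s = 0
    if n_end > 0:
        tail_s = int(duration * np.ceil(max(30.0, 2.0 * n_end) / duration))
        tail_times = np.sort(rng.uniform(sched_T, sched_T + tail_s - 1, size=n_end))
        leave_times = np.concatenate([leave_times, tail_times])

    T = sched_T + tail_s
    sec = np.arange(T, dtype=float)
    n_ants = (
        np.searchsorted(join_times, sec, side="right")
        - np.searchsorted(leave_times, sec, side="right")
    )
    n_ants = np.maximum(n_ants, 0)

    interval = np.minimum(
        (sec // duration).astype(int), cfg.schedule.n_intervals - 1
    )
    gap = cfg.schedule.gaps[interval].copy()
    phase = cfg.schedule.phase_array()[interval].copy()
    in_tail = sec >= sched_T
    gap[in_tail] = 0.0
    phase[in_tail] = Phase.CONTRACTION.value

    broken = in_tail.copy()
    n_breaks = rng.poisson(cfg.broken_rate)
    for _ in range(n_breaks):
        dur = rng.uniform(*cfg.broken_duration_s)
        start = rng.uniform(0, max(sched_T - dur, 1))
        broken |= (sec >= start) & (sec < start + dur)

    # volume: proportional to ant count, noise scaled to the target correlation
    sd_n = float(n_ants[~in_tail].std())
    if cfg.target_volume_corr is not None:
        r = cfg.target_volume_corr
        if sd_n == 0 and r < 1:
            raise ParameterError(
                "ant count has no variance; only a correlation of exactly 1 "
                "is reachable (set target_volume_corr=1 or None)"
            )
        noise_sd = cfg.volume_per_ant * sd_n * np.sqrt(1 / r**2 - 1)
    else:
        noise_sd = cfg.volume_noise_sd
    volume = cfg.volume_per_ant * n_ants + rng.normal(0, noise_sd, T) if noise_sd else (
        cfg.volume_per_ant * n_ants
    ).astype(float)
    volume = np.maximum(volume, 0.0)
    cross_section = volume / (gap + 10.0)

    excess = n_ants - cfg.rho_star * gap
    tautness = (
        cfg.tautness_base
        - cfg.tautness_slope * excess
        + rng.normal(0, cfg.tautness_noise_sd, T)
    )
    if cfg.preleave_tautness_drop:
        for te in leave_times[leave_times < sched_T]:
            lo, hi = te - cfg.preleave_window_s, te
            tautness[(sec >= lo) & (sec < hi)] -= cfg.preleave_tautness_drop
    tautness = np.clip(tautness, 0.01, None)

    structural = pd.DataFrame(
        {
            "time": sec,
            "gap": gap,
            "phase": phase,
            "volume": volume,
            "n_ants": n_ants,
            "cross_section": cross_section,
            "tautness": tautness,
            "broken": broken,
        }
    )

    events = EventStream(
        pd.DataFrame(
            {
                "time": np.concatenate([join_times, leave_times]),
                "kind": [EventKind.JOIN.value] * len(join_times)
                + [EventKind.LEAVE.value] * len(leave_times),
            }
        )
    )

    flow = _generate_flow(cfg, T, join_times[join_times < sched_T], rng)

    trial = TrialRecord(
        trial_id=f"synthetic_trial_{trial_index:03d}",
        structural=structural,
        events=events,
        flow=flow,
    )
    ledger = {
        "trial_id": trial.trial_id,
        "sim_seed": sim_seed,
        "n_joins": int(len(join_times)),
        "n_leaves": int(len(leave_times)),
        "n_tail_leaves": n_end,
        "tail_seconds": tail_s,
        "volume_noise_sd": float(noise_sd),
        "per_interval_joins": traj.joins.tolist(),
        "per_interval_leaves": traj.leaves.tolist(),
    }
    return trial, ledger


def _generate_flow(
    cfg: SynthConfig,
    T: int,
    join_times: np.ndarray,
    rng: np.random.Generator,
) -> FlowSeries:
    t0 = np.arange(0, T - 9, 10, dtype=float)
    n = len(t0)
    platforms = np.empty((2, n))
    for k in range(2):
        f = cfg.flow_mean
        for i in range(n):
            f = cfg.flow_mean + cfg.flow_ar_phi * (f - cfg.flow_mean) + rng.normal(
                0, cfg.flow_ar_sd
            )
            platforms[k, i] = max(f, 0.0)
    bridge = (
        cfg.bridge_flow_intercept
        + cfg.bridge_flow_slope * (platforms[0] + platforms[1])
        + rng.normal(0, cfg.bridge_flow_resid_sd, n)
    )
    if cfg.prejoin_perf_boost:
        boost = np.zeros(n)
        for te in join_times:
            lo, hi = te - cfg.prejoin_window_s, te
            overlap = (t0 + 10 > lo) & (t0 < hi)
            boost[overlap] = cfg.prejoin_perf_boost
        bridge = bridge + boost
    bridge = np.maximum(bridge, 0.0)
    return FlowSeries(
        pd.DataFrame(
            {
                "t0": t0,
                "flow_bridge": bridge,
                "flow_platform_a": platforms[0],
                "flow_platform_b": platforms[1],
            }
        )
    )


def generate_dataset(cfg: SynthConfig) -> tuple[list[TrialRecord], dict]:
    """Generate ``cfg.n_trials`` trials plus a ground-truth ledger.

    The ledger records the full configuration and one entry per trial
    (seed, event totals, injected effects) so tests can assert against
    the generating truth.
    """
    trials, entries = [], []
    for i in range(cfg.n_trials):
        trial, entry = generate_trial(cfg, i)
        trials.append(trial)
        entries.append(entry)
    ledger = {"config": cfg.to_dict(), "trials": entries}
    return trials, ledger
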