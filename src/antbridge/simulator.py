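"""Discrete-time stochastic simulation of bridge ant counts.

Three models of ants joining/leaving a self-assembled bridge while the
gap it spans is expanded and contracted:

* **baseline** — fixed-probability: per-interval join/leave counts are
  drawn from phase-specific negative binomial distributions;
* **delay** — as baseline, but each leave *decision* is executed a
  constant number of intervals later (joining has no delay), using
  leave distributions refit under the same delay;
* **accumulator** — dynamic-probability: expected join/leave counts
  depend log-linearly on the deficit ``delta = rho* * gap - n_ants``,
  the deviation of the bridge from its equilibrium size.

One simulation timestep is one gap interval (default 30 s between 1-mm
gap adjustments).  Every simulation starts with a zero gap and zero
ants, and ants can never leave a bridge below zero occupants: executed
leaves are clamped, while the pre-clamp draws are retained on the
trajectory so alternative clamp rules can be replayed.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import hysteresis_metrics as hm
from .model_params import DeficitRegression, EquilibriumDensity, NBEventModel, nb_draw
from .trial_io import (
    DEFAULT_INTERVAL_S,
    BridgeTrajectory,
    EventKind,
    GapSchedule,
    ParameterError,
    Phase,
)

__all__ = [
    "ModelSpec",
    "PendingLeaves",
    "StepResult",
    "ExperimentResult",
    "field_nb_models",
    "example_accumulator_model",
    "build_schedule",
    "step_baseline",
    "step_delay",
    "step_accumulator",
    "run_simulation",
    "run_experiment",
]

MAX_DELAY_STEPS = 6
EXTREME_LOW = 5  # a vibration-phase bridge below this count is "extreme"
EXTREME_HIGH = 25  # ... or above this
DEFAULT_VIBRATION_STEPS = 60  # 30 min of 1-mm back-and-forth shifts

# clamp rules: executed leaves limited by the count after joins (default,
# least restrictive consistent with never going negative) or before joins
CLAMP_AFTER_JOINS = "after_joins"
CLAMP_BEFORE_JOINS = "before_joins"

# how linear models treat vibration intervals: by the sign of the gap change
VIB_RULE_GAP_DELTA = "gap_delta"
VIB_RULE_EXPANSION = "expansion"
VIB_RULE_CONTRACTION = "contraction"


def field_nb_models() -> dict[tuple[EventKind, Phase], NBEventModel]:
    """Per-phase NB event models estimated in the original field study.

    Means/dispersions per 30-s gap interval: joins 1.13 (theta 1.33) and
    leaves 0.67 (theta 1.98) during expansion; joins 0.33 (theta 0.65)
    and leaves 1.04 (theta 8.10) during contraction.
    """
    vals = {
        (EventKind.JOIN, Phase.EXPANSION): (1.13, 1.33),
        (EventKind.LEAVE, Phase.EXPANSION): (0.67, 1.98),
        (EventKind.JOIN, Phase.CONTRACTION): (0.33, 0.65),
        (EventKind.LEAVE, Phase.CONTRACTION): (1.04, 8.10),
    }
    return {
        key: NBEventModel(mu=mu, theta=theta, phase=key[1], kind=key[0])
        for key, (mu, theta) in vals.items()
    }


def example_accumulator_model(
    rate_at_equilibrium: float = 0.6,
    rho_star: float = 0.51,
) -> "ModelSpec":
    """Accumulator model with the field-study regression slopes.

    The deficit-regression slopes and dispersions (joins: beta 0.049,
    theta 0.773; leaves: beta -0.067, theta 1.96) and the equilibrium
    packing density come from the original field study.  The regression
    intercepts were never reported, so both default to
    ``log(rate_at_equilibrium)``: join and leave rates balance exactly
    at equilibrium, at a per-interval event rate within the observed
    0.33-1.13 range.  Refit them from data for real analyses.
    """
    alpha = float(np.log(rate_at_equilibrium))
    join = DeficitRegression(alpha, 0.049, 0.773, EventKind.JOIN)
    leave = DeficitRegression(alpha, -0.067, 1.96, EventKind.LEAVE)
    # logit intercepts chosen so the field-study slopes cross at rho_star
    a_leave = -0.7
    a_join = a_leave + (0.95 + 1.8) * rho_star
    eq = EquilibriumDensity(rho_star, (a_join, -1.8), (a_leave, 0.95))
    return ModelSpec.accumulator(join, leave, eq)


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Complete parameterization of one simulation model family."""

    family: str  # "baseline" | "delay" | "accumulator"
    nb_models: dict | None = None  # {(kind, phase): NBEventModel}
    delay_d: int | None = None
    deficit_models: dict | None = None  # {kind: DeficitRegression}
    equilibrium: EquilibriumDensity | None = None

    def __post_init__(self) -> None:
        if self.family in ("baseline", "delay"):
            if self.nb_models is None:
                raise ParameterError(f"{self.family} model requires nb_models")
            needed = {
                (k, p)
                for k in (EventKind.JOIN, EventKind.LEAVE)
                for p in (Phase.EXPANSION, Phase.CONTRACTION)
            }
            if set(self.nb_models) != needed:
                raise ParameterError(
                    "nb_models must hold the four (kind, phase) combinations"
                )
            if self.family == "delay":
                if self.delay_d is None or not 1 <= self.delay_d <= MAX_DELAY_STEPS:
                    raise ParameterError(
                        f"delay model requires delay_d in [1, {MAX_DELAY_STEPS}]"
                    )
            elif self.delay_d is not None:
                raise ParameterError("baseline model takes no delay_d")
        elif self.family == "accumulator":
            if self.deficit_models is None or self.equilibrium is None:
                raise ParameterError(
                    "accumulator model requires deficit_models and equilibrium"
                )
            if set(self.deficit_models) != {EventKind.JOIN, EventKind.LEAVE}:
                raise ParameterError("deficit_models must hold join and leave")
        else:
            raise ParameterError(f"unknown model family {self.family!r}")

    @classmethod
    def baseline(cls, nb_models: dict) -> "ModelSpec":
        return cls(family="baseline", nb_models=dict(nb_models))

    @classmethod
    def delay(cls, nb_models: dict, d: int) -> "ModelSpec":
        """Delay model; ``nb_models`` leave entries must be the d-step refits."""
        return cls(family="delay", nb_models=dict(nb_models), delay_d=d)

    @classmethod
    def accumulator(
        cls,
        join: DeficitRegression,
        leave: DeficitRegression,
        equilibrium: EquilibriumDensity,
    ) -> "ModelSpec":
        return cls(
            family="accumulator",
            deficit_models={EventKind.JOIN: join, EventKind.LEAVE: leave},
            equilibrium=equilibrium,
        )

    # --- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        out: dict = {"family": self.family}
        if self.nb_models is not None:
            out["nb_models"] = {
                f"{k.value}_{p.value}": {"mu": m.mu, "theta": m.theta}
                for (k, p), m in sorted(
                    self.nb_models.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
                )
            }
        if self.delay_d is not None:
            out["delay_d"] = self.delay_d
            out["nb_models"]["refit_delay"] = self.delay_d
        if self.deficit_models is not None:
            out["deficit_models"] = {
                k.value: {"intercept": m.intercept, "slope": m.slope, "theta": m.theta}
                for k, m in sorted(self.deficit_models.items(), key=lambda kv: kv[0].value)
            }
        if self.equilibrium is not None:
            eq = self.equilibrium
            out["equilibrium"] = {
                "rho_star": eq.rho_star,
                "join_logit": list(eq.join_logit),
                "leave_logit": list(eq.leave_logit),
            }
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ModelSpec":
        family = data["family"]
        nb_models = None
        if "nb_models" in data:
            raw = dict(data["nb_models"])
            refit = raw.pop("refit_delay", None)
            if family == "delay" and refit is not None and refit != data.get("delay_d"):
                raise ParameterError(
                    f"leave distributions were refit for delay {refit} but the "
                    f"model requests delay {data.get('delay_d')}"
                )
            nb_models = {}
            for key, val in raw.items():
                kind_s, phase_s = key.split("_", 1)
                kind, phase = EventKind(kind_s), Phase(phase_s)
                nb_models[(kind, phase)] = NBEventModel(
                    mu=val["mu"], theta=val["theta"], phase=phase, kind=kind
                )
        deficit = None
        if "deficit_models" in data:
            deficit = {
                EventKind(k): DeficitRegression(
                    intercept=v["intercept"], slope=v["slope"],
                    theta=v["theta"], kind=EventKind(k),
                )
                for k, v in data["deficit_models"].items()
            }
        equilibrium = None
        if "equilibrium" in data:
            eq = data["equilibrium"]
            equilibrium = EquilibriumDensity(
                rho_star=eq["rho_star"],
                join_logit=tuple(eq["join_logit"]),
                leave_logit=tuple(eq["leave_logit"]),
            )
        return cls(
            family=family, nb_models=nb_models, delay_d=data.get("delay_d"),
            deficit_models=deficit, equilibrium=equilibrium,
        )


@dataclass
class PendingLeaves:
    """FIFO queue of scheduled leave executions for the delay model."""

    queue: collections.deque = field(default_factory=collections.deque)

    def push(self, due_interval: int, count: int) -> None:
        if count > 0:
            self.queue.append((due_interval, count))

    def pop_due(self, interval: int) -> int:
        """Total decisions due at ``interval``; drained entries are removed."""
        total = 0
        while self.queue and self.queue[0][0] <= interval:
            total += self.queue.popleft()[1]
        return total

    def remaining(self) -> int:
        return sum(c for _, c in self.queue)


@dataclass(frozen=True)
class StepResult:
    joins: int
    leaves: int  # executed (post-clamp)
    joins_drawn: int
    leaves_decided: int  # pre-clamp draw (decision count for the delay model)


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------


def build_schedule(
    protocol: str = "expansion_contraction",
    max_gap: float = 30.0,
    step: float = 1.0,
    interval: float = DEFAULT_INTERVAL_S,
    vib_steps: int = 0,
) -> GapSchedule:
    """Gap schedule for a simulated experiment.

    ``expansion_contraction``: gap climbs 0..max_gap in ``step`` increments
    (``max_gap/step + 1`` intervals including the initial zero-gap one),
    then descends ``max_gap - step``..0.  ``vibration`` inserts a block of
    ``vib_steps`` intervals alternating between ``max_gap - step`` and
    ``max_gap`` between the two ramps.  Scaled-gap and rate-sensitivity
    protocols are the same geometry with a different ``max_gap``/``step``.
    """
    n = max_gap / step
    if abs(n - round(n)) > 1e-9 or max_gap <= 0 or step <= 0:
        raise ParameterError("max_gap must be a positive multiple of step")
    n = int(round(n))
    if vib_steps < 0:
        raise ParameterError("vib_steps must be non-negative")
    if protocol in ("expansion_contraction", "expand_contract", "scaled", "rate"):
        if protocol in ("expansion_contraction", "expand_contract") and vib_steps:
            raise ParameterError(f"{protocol} takes no vibration block")
        vib = 0
    elif protocol == "vibration":
        vib = vib_steps if vib_steps > 0 else DEFAULT_VIBRATION_STEPS
    else:
        raise ParameterError(f"unknown protocol {protocol!r}")
    gaps = list(step * np.arange(n + 1))  # 0 .. max_gap
    phases = [Phase.EXPANSION] * (n + 1)
    for i in range(vib):
        gaps.append(max_gap - step if i % 2 == 0 else max_gap)
        phases.append(Phase.VIBRATION)
    gaps.extend(step * np.arange(n - 1, -1, -1))  # max_gap - step .. 0
    phases.extend([Phase.CONTRACTION] * n)
    return GapSchedule(np.array(gaps), tuple(phases), duration=interval, step=step)


def _effective_phase(
    phase: Phase, gap: float, prev_gap: float, vibration_rule: str
) -> Phase:
    """Phase whose event distributions govern a linear-model interval."""
    if phase is not Phase.VIBRATION:
        return phase
    if vibration_rule == VIB_RULE_EXPANSION:
        return Phase.EXPANSION
    if vibration_rule == VIB_RULE_CONTRACTION:
        return Phase.CONTRACTION
    return Phase.CONTRACTION if gap < prev_gap else Phase.EXPANSION


def _clamp_leaves(n: int, joins: int, leaves_drawn: int, clamp: str) -> int:
    if clamp == CLAMP_AFTER_JOINS:
        return min(leaves_drawn, n + joins)
    if clamp == CLAMP_BEFORE_JOINS:
        return min(leaves_drawn, n)
    raise ParameterError(f"unknown clamp rule {clamp!r}")


# ---------------------------------------------------------------------------
# Single steps
# ---------------------------------------------------------------------------


def step_baseline(
    n: int,
    phase: Phase,
    nb_models: dict,
    rng: np.random.Generator,
    clamp: str = CLAMP_AFTER_JOINS,
) -> StepResult:
    """One fixed-probability interval: NB draws for the phase, leaves clamped."""
    joins = int(nb_draw(nb_models[(EventKind.JOIN, phase)].mu,
                        nb_models[(EventKind.JOIN, phase)].theta, rng))
    leaves_drawn = int(nb_draw(nb_models[(EventKind.LEAVE, phase)].mu,
                               nb_models[(EventKind.LEAVE, phase)].theta, rng))
    leaves = _clamp_leaves(n, joins, leaves_drawn, clamp)
    return StepResult(joins, leaves, joins, leaves_drawn)


def step_delay(
    n: int,
    phase: Phase,
    nb_models: dict,
    pending: PendingLeaves,
    d: int,
    t: int,
    rng: np.random.Generator,
    clamp: str = CLAMP_AFTER_JOINS,
) -> StepResult:
    """One delay-model interval.

    Leave decisions drawn now (from the d-refit distributions) are
    enqueued for interval ``t + d``; the leaves executed now are the
    decisions that fell due, clamped to the available ants.
    """
    joins = int(nb_draw(nb_models[(EventKind.JOIN, phase)].mu,
                        nb_models[(EventKind.JOIN, phase)].theta, rng))
    decided = int(nb_draw(nb_models[(EventKind.LEAVE, phase)].mu,
                          nb_models[(EventKind.LEAVE, phase)].theta, rng))
    pending.push(t + d, decided)
    due = pending.pop_due(t)
    leaves = _clamp_leaves(n, joins, due, clamp)
    return StepResult(joins, leaves, joins, decided)


def step_accumulator(
    n: int,
    gap: float,
    deficit_models: dict,
    rho_star: float,
    rng: np.random.Generator,
    clamp: str = CLAMP_AFTER_JOINS,
) -> StepResult:
    """One accumulator interval: NB draws with deficit-dependent means."""
    delta = rho_star * gap - n
    jm = deficit_models[EventKind.JOIN]
    lm = deficit_models[EventKind.LEAVE]
    joins = int(nb_draw(float(jm.mu(delta)), jm.theta, rng))
    leaves_drawn = int(nb_draw(float(lm.mu(delta)), lm.theta, rng))
    leaves = _clamp_leaves(n, joins, leaves_drawn, clamp)
    return StepResult(joins, leaves, joins, leaves_drawn)


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------


def run_simulation(
    model: ModelSpec,
    schedule: GapSchedule,
    seed: int,
    clamp: str = CLAMP_AFTER_JOINS,
    vibration_rule: str = VIB_RULE_GAP_DELTA,
) -> BridgeTrajectory:
    """Simulate one bridge over a schedule; bit-reproducible under ``seed``.

    The bridge starts empty; each interval's joins and leaves are drawn
    from the state at the interval's start.  The delay model's pending
    queue starts empty (no phantom pre-trial decisions).
    """
    rng = np.random.default_rng(seed)
    T = schedule.n_intervals
    n_ants = np.zeros(T, dtype=int)
    joins = np.zeros(T, dtype=int)
    leaves = np.zeros(T, dtype=int)
    joins_drawn = np.zeros(T, dtype=int)
    leaves_decided = np.zeros(T, dtype=int)
    pending = PendingLeaves()
    n = 0
    prev_gap = schedule.gaps[0]
    for t in range(T):
        gap = schedule.gaps[t]
        phase = schedule.phases[t]
        if model.family == "accumulator":
            res = step_accumulator(
                n, gap, model.deficit_models, model.equilibrium.rho_star, rng, clamp
            )
        else:
            eff = _effective_phase(phase, gap, prev_gap, vibration_rule)
            if model.family == "baseline":
                res = step_baseline(n, eff, model.nb_models, rng, clamp)
            else:
                res = step_delay(
                    n, eff, model.nb_models, pending, model.delay_d, t, rng, clamp
                )
        n = n + res.joins - res.leaves
        n_ants[t] = n
        joins[t] = res.joins
        leaves[t] = res.leaves
        joins_drawn[t] = res.joins_drawn
        leaves_decided[t] = res.leaves_decided
        prev_gap = gap
    return BridgeTrajectory(
        schedule=schedule, n_ants=n_ants, joins=joins, leaves=leaves,
        joins_drawn=joins_drawn, leaves_decided=leaves_decided,
        seed=int(seed), model_id=model.family,
    )


@dataclass
class ExperimentResult:
    """Trajectories plus summary statistics of a simulation experiment."""

    trajectories: list[BridgeTrajectory]
    extents: np.ndarray  # per-simulation hysteresis extents (NaN if undefined)
    mean_trajectory: np.ndarray  # mean ant count per timestep
    summary: dict

    @property
    def mean_extent(self) -> float:
        return self.summary["mean_extent"]


def run_experiment(
    model: ModelSpec,
    schedule: GapSchedule | None = None,
    n_sims: int = 100,
    seed: int = 0,
    protocol: str | None = None,
    span: float = hm.DEFAULT_SPAN,
    clamp: str = CLAMP_AFTER_JOINS,
    vibration_rule: str = VIB_RULE_GAP_DELTA,
    **schedule_kwargs,
) -> ExperimentResult:
    """Run ``n_sims`` independent simulations and summarize them.

    The summary includes the mean trajectory, per-simulation hysteresis
    extents with the fractions negative/positive, and — when the
    schedule has a vibration block — the fraction of runs that turn
    "extreme" (ant count outside [5, 25] during vibration) and the
    fraction that reach zero ants during vibration.
    """
    if n_sims < 1:
        raise ParameterError("n_sims must be at least 1")
    if schedule is None:
        schedule = build_schedule(protocol or "expansion_contraction", **schedule_kwargs)
    seeds = [int(s.generate_state(1)[0]) for s in np.random.SeedSequence(seed).spawn(n_sims)]
    trajectories = [
        run_simulation(model, schedule, s, clamp=clamp, vibration_rule=vibration_rule)
        for s in seeds
    ]
    extents = hm.extents_for_trajectories(trajectories, span=span)
    valid = extents[~np.isnan(extents)]
    counts = np.stack([tr.n_ants for tr in trajectories])
    summary = {
        "n_sims": n_sims,
        "mean_extent": float(valid.mean()) if len(valid) else float("nan"),
        "frac_negative": float((valid < 0).mean()) if len(valid) else float("nan"),
        "frac_positive": float((valid > 0).mean()) if len(valid) else float("nan"),
    }
    vib_mask = schedule.phase_array() == Phase.VIBRATION.value
    if vib_mask.any():
        vib_counts = counts[:, vib_mask]
        extreme = ((vib_counts < EXTREME_LOW) | (vib_counts > EXTREME_HIGH)).any(axis=1)
        reached_zero = (vib_counts == 0).any(axis=1)
        summary["frac_extreme"] = float(extreme.mean())
        summary["frac_reached_zero"] = float(reached_zero.mean())
    return ExperimentResult(
        trajectories=trajectories,
        extents=extents,
        mean_trajectory=counts.mean(axis=0),
        summary=summary,
    )
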