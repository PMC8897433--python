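"""Domain types and tidy-CSV input/output for bridge trials.

A field trial of a self-assembled army-ant bridge produces three data
streams at different temporal resolutions:

* a per-second *structural* series (gap size, phase, bridge volume,
  number of ants, mean cross-sectional area, tautness, broken flag),
* a timestamped *event* stream of individual joining/leaving events,
* an optional per-10-s *optical-flow* series for the bridge and the two
  adjacent platforms.

This module hosts the shared domain types for those streams (plus the
gap schedule that drives a trial and the trajectory record produced by
the simulator) and reads/writes them as plain CSV bundles.  The column
dialect is fixed: snake_case headers, comma separator, UTF-8, ``.``
decimal, times in seconds from trial start, gaps in millimetres.

Broken periods — spans during which the bridge was broken or recovering
— are carried both as inclusive ``[start_s, end_s]`` metadata lines in
``structural.csv`` and as a per-second boolean column; all downstream
statistics consult the boolean only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence


import numpy as np
import pandas as pd

__all__ = [
    "Phase",
    "EventKind",
    "GapSchedule",
    "EventStream",
    "FlowSeries",
    "TrialRecord",
    "BridgeTrajectory",
    "FormatError",
    "IntegrityError",
    "ParameterError",
    "read_trial",
    "write_trial",
    "read_trajectories",
    "write_trajectories",
]

DEFAULT_INTERVAL_S = 30.0  # seconds between successive gap adjustments
FLOW_INTERVAL_S = 10.0  # width of one optical-flow measurement interval


class FormatError(ValueError):
    """A file does not match the documented column dialect."""


class IntegrityError(ValueError):
    """Data violate a domain invariant (e.g. unbalanced join/leave totals)."""


class ParameterError(ValueError):
    """An operation received an out-of-range or inconsistent parameter."""


class Phase(str, enum.Enum):
    """Experimental phase of a gap interval."""

    EXPANSION = "expansion"
    VIBRATION = "vibration"
    CONTRACTION = "contraction"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class EventKind(str, enum.Enum):
    """Kind of an individual decision event."""

    JOIN = "join"
    LEAVE = "leave"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_PHASE_ORDER = [Phase.EXPANSION, Phase.VIBRATION, Phase.CONTRACTION]


# ---------------------------------------------------------------------------
# Gap schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GapSchedule:
    """Ordered sequence of gap intervals driving a trial or simulation.

    Parameters
    ----------
    gaps
        Gap size (mm) held during each interval.
    phases
        Phase label of each interval.  Labels must form contiguous blocks
        in the order expansion [, vibration], contraction.
    duration
        Length of one interval in seconds (constant within a schedule).
    step
        Maximum change of gap size between consecutive intervals (mm).
    """

    gaps: np.ndarray
    phases: tuple[Phase, ...]
    duration: float = DEFAULT_INTERVAL_S
    step: float = 1.0

    def __post_init__(self) -> None:
        gaps = np.asarray(self.gaps, dtype=float)
        object.__setattr__(self, "gaps", gaps)
        object.__setattr__(self, "phases", tuple(Phase(p) for p in self.phases))
        if len(gaps) != len(self.phases):
            raise ParameterError("gaps and phases must have equal length")
        if len(gaps) == 0:
            raise ParameterError("schedule must have at least one interval")
        if self.duration <= 0:
            raise ParameterError("interval duration must be positive")
        if np.any(gaps < 0):
            raise IntegrityError("gap sizes must be non-negative")
        if np.any(np.abs(np.diff(gaps)) > self.step + 1e-9):
            raise IntegrityError(
                f"consecutive gaps differ by more than step={self.step} mm"
            )
        # phase blocks must be contiguous and ordered
        seen: list[Phase] = []
        for p in self.phases:
            if not seen or seen[-1] is not p:
                seen.append(p)
        if seen != [p for p in _PHASE_ORDER if p in seen]:
            raise IntegrityError(
                "phase labels must form contiguous blocks ordered "
                "expansion [, vibration], contraction"
            )

    def __len__(self) -> int:
        return len(self.gaps)

    @property
    def n_intervals(self) -> int:
        return len(self.gaps)

    @property
    def total_time(self) -> float:
        """Total scheduled time in seconds."""
        return self.n_intervals * self.duration

    def interval_of(self, time_s: np.ndarray | float) -> np.ndarray:
        """Map a time in seconds to the index of its containing interval."""
        idx = np.floor(np.asarray(time_s, dtype=float) / self.duration).astype(int)
        return np.clip(idx, 0, self.n_intervals - 1)

    def phase_array(self) -> np.ndarray:
        return np.array([p.value for p in self.phases], dtype=object)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "interval": np.arange(self.n_intervals),
                "gap": self.gaps,
                "phase": self.phase_array(),
                "duration": self.duration,
            }
        )


# ---------------------------------------------------------------------------
# Event stream
# ---------------------------------------------------------------------------


@dataclass
class EventStream:
    """Timestamped joining/leaving events of one trial.

    ``events`` holds columns ``time`` (seconds from trial start, float)
    and ``kind`` (``join`` / ``leave``), sorted by time.
    """

    events: pd.DataFrame

    def __post_init__(self) -> None:
        ev = pd.DataFrame(self.events)
        missing = {"time", "kind"} - set(ev.columns)
        if missing:
            raise FormatError(f"events missing columns: {sorted(missing)}")
        ev = ev.copy()
        ev["time"] = ev["time"].astype(float)
        ev["kind"] = ev["kind"].map(lambda k: EventKind(k).value)
        ev = ev.sort_values("time", kind="stable").reset_index(drop=True)
        self.events = ev

    def __len__(self) -> int:
        return len(self.events)

    @property
    def times(self) -> np.ndarray:
        return self.events["time"].to_numpy()

    def of_kind(self, kind: EventKind | str) -> pd.DataFrame:
        kind = EventKind(kind).value
        return self.events[self.events["kind"] == kind]

    def total(self, kind: EventKind | str) -> int:
        return int(len(self.of_kind(kind)))

    def counts_per_interval(
        self, n_intervals: int, interval_s: float = DEFAULT_INTERVAL_S
    ) -> pd.DataFrame:
        """Aggregate events into per-interval join/leave counts J(t), L(t)."""
        idx = np.floor(self.events["time"].to_numpy() / interval_s).astype(int)
        idx = np.clip(idx, 0, n_intervals - 1)
        out = pd.DataFrame(
            {
                "interval": np.arange(n_intervals),
                "joins": 0,
                "leaves": 0,
            }
        )
        for kind, col in ((EventKind.JOIN, "joins"), (EventKind.LEAVE, "leaves")):
            mask = self.events["kind"].to_numpy() == kind.value
            counts = np.bincount(idx[mask], minlength=n_intervals)
            out[col] = counts.astype(int)
        return out


# ---------------------------------------------------------------------------
# Flow series
# ---------------------------------------------------------------------------


@dataclass
class FlowSeries:
    """Per-10-s optical-flow measurements (px/frame) for one trial."""

    flow: pd.DataFrame
    interval_s: float = FLOW_INTERVAL_S

    _COLUMNS = ("t0", "flow_bridge", "flow_platform_a", "flow_platform_b")

    def __post_init__(self) -> None:
        fl = pd.DataFrame(self.flow)
        missing = set(self._COLUMNS) - set(fl.columns)
        if missing:
            raise FormatError(f"flow missing columns: {sorted(missing)}")
        fl = fl[list(self._COLUMNS)].astype(float)
        fl = fl.sort_values("t0", kind="stable").reset_index(drop=True)
        t0 = fl["t0"].to_numpy()
        if len(t0) > 1:
            widths = np.diff(t0)
            if np.any(widths < self.interval_s - 1e-9):
                raise IntegrityError("flow intervals overlap or are non-uniform")
        for col in self._COLUMNS[1:]:
            if (fl[col] < 0).any():
                raise IntegrityError(f"negative optical flow in column {col}")
        self.flow = fl

    def __len__(self) -> int:
        return len(self.flow)


# ---------------------------------------------------------------------------
# Trial record
# ---------------------------------------------------------------------------

STRUCTURAL_COLUMNS = (
    "time",
    "gap",
    "phase",
    "volume",
    "n_ants",
    "cross_section",
    "tautness",
    "broken",
)


@dataclass
class TrialRecord:
    """One observed or synthetic trial: structural series + events (+ flow)."""

    trial_id: str
    structural: pd.DataFrame
    events: EventStream
    flow: FlowSeries | None = None

    def __post_init__(self) -> None:
        st = pd.DataFrame(self.structural)
        missing = set(STRUCTURAL_COLUMNS) - set(st.columns)
        if missing:
            raise FormatError(f"structural missing columns: {sorted(missing)}")
        st = st[list(STRUCTURAL_COLUMNS)].copy()
        for col in ("time", "gap", "volume", "cross_section", "tautness"):
            st[col] = st[col].astype(float)
        st["n_ants"] = st["n_ants"].astype(int)
        st["broken"] = st["broken"].astype(bool)
        st["phase"] = st["phase"].map(lambda p: Phase(p).value)
        st = st.sort_values("time", kind="stable").reset_index(drop=True)
        self.structural = st
        self.validate()

    def validate(self) -> None:
        st = self.structural
        if (st["n_ants"] < 0).any():
            raise IntegrityError("n_ants must be non-negative everywhere")
        joins = self.events.total(EventKind.JOIN)
        leaves = self.events.total(EventKind.LEAVE)
        if joins != leaves:
            raise IntegrityError(
                f"unbalanced event totals: {joins} joins vs {leaves} leaves"
            )
        t0, t1 = st["time"].min(), st["time"].max()
        times = self.events.times
        if len(times) and (times.min() < t0 - 1e-9 or times.max() > t1 + 1 + 1e-9):
            raise IntegrityError("event times fall outside the recorded span")

    @property
    def span(self) -> tuple[float, float]:
        t = self.structural["time"]
        return float(t.min()), float(t.max())

    def broken_mask(self) -> np.ndarray:
        """Per-second boolean broken flag, aligned with ``structural``."""
        return self.structural["broken"].to_numpy()

    def broken_fraction(self) -> float:
        return float(self.broken_mask().mean())

    def second_is_broken(self, times: np.ndarray) -> np.ndarray:
        """Broken flag looked up at arbitrary times (floored to seconds)."""
        st = self.structural
        sec = np.clip(
            np.searchsorted(st["time"].to_numpy(), np.asarray(times), side="right") - 1,
            0,
            len(st) - 1,
        )
        return st["broken"].to_numpy()[sec]


# ---------------------------------------------------------------------------
# Bridge trajectory (simulation output)
# ---------------------------------------------------------------------------


@dataclass
class BridgeTrajectory:
    """Per-interval state history of one simulated bridge.

    ``joins``/``leaves`` are the executed event counts; ``joins_drawn``
    and ``leaves_decided`` retain the pre-clamp draws so alternative
    clamping rules can be replayed.  The count obeys
    ``n_ants[t] = n_ants[t-1] + joins[t] - leaves[t]`` with ``n_ants >= 0``
    and an implicit empty bridge before the first interval.
    """

    schedule: GapSchedule
    n_ants: np.ndarray
    joins: np.ndarray
    leaves: np.ndarray
    joins_drawn: np.ndarray
    leaves_decided: np.ndarray
    seed: int
    model_id: str

    def __post_init__(self) -> None:
        n = self.schedule.n_intervals
        for name in ("n_ants", "joins", "leaves", "joins_drawn", "leaves_decided"):
            arr = np.asarray(getattr(self, name), dtype=int)
            if arr.shape != (n,):
                raise ParameterError(f"{name} must have length {n}")
            object.__setattr__(self, name, arr)
        if np.any(self.n_ants < 0):
            raise IntegrityError("trajectory has negative ant counts")
        prev = np.concatenate([[0], self.n_ants[:-1]])
        if np.any(self.n_ants != prev + self.joins - self.leaves):
            raise IntegrityError("n_ants inconsistent with join/leave counts")

    def __len__(self) -> int:
        return self.schedule.n_intervals

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestep": np.arange(len(self)),
                "gap": self.schedule.gaps,
                "phase": self.schedule.phase_array(),
                "joins": self.joins,
                "leaves": self.leaves,
                "joins_drawn": self.joins_drawn,
                "leaves_decided": self.leaves_decided,
                "n_ants": self.n_ants,
            }
        )


# ---------------------------------------------------------------------------
# CSV round-tripping
# ---------------------------------------------------------------------------


def _broken_periods(structural: pd.DataFrame) -> list[tuple[float, float]]:
    """Inclusive [start, end] spans of consecutive broken seconds."""
    st = structural
    broken = st["broken"].to_numpy()
    times = st["time"].to_numpy()
    periods = []
    start = None
    for t, b in zip(times, broken):
        if b and start is None:
            start = t
        elif not b and start is not None:
            periods.append((start, prev_t))
            start = None
        prev_t = t
    if start is not None:
        periods.append((start, times[-1]))
    return periods


def write_trial(trial: TrialRecord, path: str | Path) -> Path:
    """Write a trial as a CSV bundle ``structural.csv``/``events.csv``[/``flow.csv``]."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    periods = _broken_periods(trial.structural)
    with open(path / "structural.csv", "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# trial_id: {trial.trial_id}\n")
        for a, b in periods:
            fh.write(f"# broken_period: {a:g},{b:g}\n")
        trial.structural.to_csv(fh, index=False, float_format="%.17g")
    trial.events.events.to_csv(path / "events.csv", index=False, float_format="%.17g")
    if trial.flow is not None:
        trial.flow.flow.to_csv(path / "flow.csv", index=False, float_format="%.17g")
    return path


def read_trial(path: str | Path) -> TrialRecord:
    """Read a trial CSV bundle written by :func:`write_trial`.

    Raises
    ------
    FormatError
        If a mandatory file or column is missing.
    IntegrityError
        If a domain invariant is violated (negative ant counts,
        unbalanced join/leave totals, ...).
    """
    path = Path(path)
    spath = path / "structural.csv"
    epath = path / "events.csv"
    if not spath.exists() or not epath.exists():
        raise FormatError(f"trial bundle at {path} lacks structural.csv/events.csv")
    trial_id = path.name
    head = []
    with open(spath, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            head.append(line[1:].strip())
    structural = pd.read_csv(spath, skiprows=len(head), float_precision="round_trip")
    for entry in head:
        if entry.startswith("trial_id:"):
            trial_id = entry.split(":", 1)[1].strip()
    events = _read_events(epath)
    flow = None
    fpath = path / "flow.csv"
    if fpath.exists():
        flow = FlowSeries(pd.read_csv(fpath, float_precision="round_trip"))
    return TrialRecord(trial_id, structural, events, flow)


def _read_events(path: Path) -> EventStream:
    df = pd.read_csv(path, float_precision="round_trip")
    return EventStream(df)


_TRAJ_COLUMNS = (
    "simulation_id",
    "seed",
    "timestep",
    "gap",
    "phase",
    "joins",
    "leaves",
    "joins_drawn",
    "leaves_decided",
    "n_ants",
)


def write_trajectories(
    trajectories: Sequence[BridgeTrajectory], path: str | Path
) -> Path:
    """Write simulated trajectories as one tidy CSV.

    Rows are sorted by (simulation id, timestep) so repeated writes of
    the same trajectories are byte-identical.  All trajectories must
    share a schedule.
    """
    path = Path(path)
    trajectories = list(trajectories)
    if trajectories:
        ref = trajectories[0].schedule
        for tr in trajectories[1:]:
            if (
                len(tr.schedule) != len(ref)
                or not np.array_equal(tr.schedule.gaps, ref.gaps)
                or tr.schedule.phases != ref.phases
            ):
                raise ParameterError("all trajectories must share one schedule")
    frames = []
    for i, tr in enumerate(trajectories):
        df = tr.to_frame()
        df.insert(0, "simulation_id", i)
        df.insert(1, "seed", tr.seed)
        frames.append(df)
    if frames:
        out = pd.concat(frames, ignore_index=True)
        out = out.sort_values(["simulation_id", "timestep"], kind="stable")
    else:
        out = pd.DataFrame(columns=list(_TRAJ_COLUMNS))
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, columns=list(_TRAJ_COLUMNS), float_format="%.17g")
    return path


def read_trajectories(
    path: str | Path,
    duration: float = DEFAULT_INTERVAL_S,
    step: float = 1.0,
    model_id: str = "",
) -> list[BridgeTrajectory]:
    """Read back a trajectories CSV into :class:`BridgeTrajectory` objects."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"trajectories missing columns: {sorted(missing)}")
    out = []
    for _, grp in df.groupby("simulation_id", sort=True):
        grp = grp.sort_values("timestep")
        sched = GapSchedule(
            grp["gap"].to_numpy(),
            tuple(Phase(p) for p in grp["phase"]),
            duration=duration,
            step=step,
        )
        out.append(
            BridgeTrajectory(
                schedule=sched,
                n_ants=grp["n_ants"].to_numpy(),
                joins=grp["joins"].to_numpy(),
                leaves=grp["leaves"].to_numpy(),
                joins_drawn=grp["joins_drawn"].to_numpy(),
                leaves_decided=grp["leaves_decided"].to_numpy(),
                seed=int(grp["seed"].iloc[0]),
                model_id=model_id,
            )
        )
    return out
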