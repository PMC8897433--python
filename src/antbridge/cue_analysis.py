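"""Event-triggered cue analyses: bridge performance and tautness.

*Performance* measures how easily ants cross a bridge: the signed
residual of bridge optical flow from a per-trial least-squares
regression on the optical flow of the two adjacent platforms.  High
performance means the bridge impedes traffic less than usual, after
accounting for the overall traffic level.

Whether performance (or bridge tautness) acts as a *cue* for joining or
leaving is tested with a resampling null: the mean of the cue over the
10 s preceding each event is compared with the distribution of the same
statistic from many simulated experiments in which event times are
randomized within each trial and phase, keeping per-trial-and-phase
event counts fixed.  Phases are analyzed separately to remove phase as
a confounder, and an event is deemed significant when the observed mean
falls outside the central 95% of the null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model_params import FitError
from .trial_io import (
    DEFAULT_INTERVAL_S,
    EventKind,
    FlowSeries,
    ParameterError,
    Phase,
    TrialRecord,
)

__all__ = [
    "PerformanceSeries",
    "ResampleResult",
    "compute_performance",
    "event_preceding_mean",
    "resample_null",
    "tautness_resample",
    "window_sensitivity",
    "event_timing_uniformity",
]

DEFAULT_WINDOW_S = 10.0
DEFAULT_N_RESAMPLES = 10_000
MIN_FLOW_INTERVALS = 10
_RESAMPLE_CHUNK = 2000

PREDICTOR_SUM = "sum"  # regress bridge flow on the summed platform flows
PREDICTOR_BOTH = "both"  # ... or on the two platform flows as covariates


@dataclass
class PerformanceSeries:
    """Per-10-s signed performance residuals of one trial."""

    perf: pd.DataFrame  # columns: t0, performance
    interval_s: float = 10.0

    def __len__(self) -> int:
        return len(self.perf)


@dataclass(frozen=True)
class ResampleResult:
    """Observed event-preceding mean against its resampling null."""

    observed_mean: float
    null_means: np.ndarray
    frac_below: float  # fraction of null means <= observed
    frac_above: float  # fraction of null means >= observed
    p_two_tailed: float
    significant: bool  # observed outside the central 95% of the null
    n_events: int
    window: float


# ---------------------------------------------------------------------------
# Performance
# ---------------------------------------------------------------------------


def compute_performance(
    flow: FlowSeries,
    broken: np.ndarray | None = None,
    predictor: str = PREDICTOR_SUM,
) -> PerformanceSeries:
    """Per-trial performance residuals from the flow regression.

    ``broken`` optionally flags flow intervals to exclude (any broken
    second inside the interval).  The default regresses bridge flow on
    the sum of the two platform flows; ``predictor="both"`` uses the two
    platforms as separate covariates.
    """
    fl = flow.flow
    keep = np.ones(len(fl), dtype=bool) if broken is None else ~np.asarray(broken)
    fl = fl[keep]
    if len(fl) < MIN_FLOW_INTERVALS:
        raise ParameterError(
            f"need at least {MIN_FLOW_INTERVALS} non-broken flow intervals, "
            f"got {len(fl)}"
        )
    y = fl["flow_bridge"].to_numpy(dtype=float)
    fa = fl["flow_platform_a"].to_numpy(dtype=float)
    fb = fl["flow_platform_b"].to_numpy(dtype=float)
    if predictor == PREDICTOR_SUM:
        X = np.column_stack([np.ones(len(fl)), fa + fb])
    elif predictor == PREDICTOR_BOTH:
        X = np.column_stack([np.ones(len(fl)), fa, fb])
    else:
        raise ParameterError(f"unknown predictor {predictor!r}")
    if np.any(np.ptp(X[:, 1:], axis=0) == 0):
        raise FitError("platform flow has no variance; regression degenerate")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return PerformanceSeries(
        perf=pd.DataFrame({"t0": fl["t0"].to_numpy(dtype=float), "performance": resid}),
        interval_s=flow.interval_s,
    )


def trial_flow_broken(trial: TrialRecord) -> np.ndarray:
    """Per-flow-interval flag: any second of the interval is broken."""
    if trial.flow is None:
        raise ParameterError(f"trial {trial.trial_id!r} has no flow series")
    st = trial.structural
    sec_times = st["time"].to_numpy()
    broken = st["broken"].to_numpy()
    out = []
    for t0 in trial.flow.flow["t0"].to_numpy(dtype=float):
        in_iv = (sec_times >= t0) & (sec_times < t0 + trial.flow.interval_s)
        out.append(bool(broken[in_iv].any()) if in_iv.any() else True)
    return np.array(out)


def trial_performance(
    trial: TrialRecord, predictor: str = PREDICTOR_SUM
) -> PerformanceSeries:
    """Performance residuals of one trial, broken flow intervals excluded."""
    return compute_performance(trial.flow, broken=trial_flow_broken(trial), predictor=predictor)


# ---------------------------------------------------------------------------
# Per-second series and window means
# ---------------------------------------------------------------------------


def _per_second_values(
    trial: TrialRecord, perf: PerformanceSeries | None
) -> tuple[np.ndarray, np.ndarray]:
    """(value, valid) per structural second.

    With a performance series, each second inherits the performance of
    its containing 10-s flow interval; without one, the structural
    tautness is used directly.  Broken seconds are invalid either way.
    """
    st = trial.structural
    times = st["time"].to_numpy(dtype=float)
    not_broken = ~st["broken"].to_numpy()
    if perf is None:
        return st["tautness"].to_numpy(dtype=float), not_broken
    t0 = perf.perf["t0"].to_numpy()
    pv = perf.perf["performance"].to_numpy()
    value = np.full(len(times), np.nan)
    idx = np.searchsorted(t0, times, side="right") - 1
    inside = (idx >= 0) & (times < np.where(idx >= 0, t0[np.clip(idx, 0, None)], -np.inf) + perf.interval_s)
    value[inside] = pv[idx[inside]]
    return value, not_broken & inside


def _window_means(
    value: np.ndarray, valid: np.ndarray, window: int
) -> np.ndarray:
    """W[s] = mean of value over seconds [s - window, s); NaN if unusable."""
    n = len(value)
    W = np.full(n, np.nan)
    v = np.where(valid, value, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    cval = np.concatenate([[0], np.cumsum(valid.astype(int))])
    s = np.arange(window, n)
    full = (cval[s] - cval[s - window]) == window
    W[s[full]] = (csum[s[full]] - csum[s[full] - window]) / window
    return W


@dataclass
class _TrialArrays:
    """Precomputed per-trial arrays for the resampling machinery."""

    W: np.ndarray  # window mean per second
    candidate_W: np.ndarray  # window means at candidate seconds
    observed_W: np.ndarray  # window means at usable observed events


def _prepare(
    trial: TrialRecord,
    perf: PerformanceSeries | None,
    kind: EventKind,
    phase: Phase,
    window: int,
) -> _TrialArrays:
    st = trial.structural
    value, valid = _per_second_values(trial, perf)
    W = _window_means(value, valid, window)
    in_phase = st["phase"].to_numpy() == phase.value
    not_broken = ~st["broken"].to_numpy()
    candidates = in_phase & not_broken & ~np.isnan(W)
    times = st["time"].to_numpy(dtype=float)
    ev = trial.events.of_kind(kind)
    ev_sec = np.searchsorted(times, ev["time"].to_numpy(dtype=float), side="right") - 1
    ev_sec = ev_sec[(ev_sec >= 0) & (ev_sec < len(times))]
    ev_sec = ev_sec[in_phase[ev_sec] & ~np.isnan(W[ev_sec])]
    return _TrialArrays(W=W, candidate_W=W[candidates], observed_W=W[ev_sec])


def event_preceding_mean(
    trials: list[tuple[TrialRecord, PerformanceSeries | None]],
    kind: EventKind | str,
    phase: Phase | str,
    window: float = DEFAULT_WINDOW_S,
) -> float:
    """Mean cue value in the ``window`` seconds before events, pooled.

    Each event contributes the mean of the per-second cue series over
    ``[t_event - window, t_event)``; seconds inherit the performance of
    their containing 10-s flow interval.  Events whose window overlaps a
    broken period (or falls before coverage starts) are excluded.
    """
    kind, phase = EventKind(kind), Phase(phase)
    obs = [
        _prepare(trial, perf, kind, phase, int(round(window))).observed_W
        for trial, perf in trials
    ]
    pooled = np.concatenate(obs) if obs else np.empty(0)
    if len(pooled) == 0:
        raise ParameterError(f"no usable {kind.value} events in the {phase.value} phase")
    return float(pooled.mean())


def _resample(
    prepared: list[_TrialArrays],
    n_resamples: int,
    seed: int,
    window: float,
) -> ResampleResult:
    observed = np.concatenate([p.observed_W for p in prepared])
    n_events = len(observed)
    if n_events == 0:
        raise ParameterError("no usable events for resampling")
    for p in prepared:
        if len(p.observed_W) > len(p.candidate_W):
            raise ParameterError(
                "fewer candidate seconds than events in one trial-phase"
            )
    rng = np.random.default_rng(seed)
    null_sums = np.zeros(n_resamples)
    for p in prepared:
        k = len(p.observed_W)
        if k == 0:
            continue
        m = len(p.candidate_W)
        done = 0
        while done < n_resamples:
            chunk = min(_RESAMPLE_CHUNK, n_resamples - done)
            keys = rng.random((chunk, m))
            idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
            null_sums[done : done + chunk] += p.candidate_W[idx].sum(axis=1)
            done += chunk
    null_means = null_sums / n_events
    obs_mean = float(observed.mean())
    frac_below = float((null_means <= obs_mean).mean())
    frac_above = float((null_means >= obs_mean).mean())
    p_two = min(1.0, 2.0 * min(frac_below, frac_above))
    lo, hi = np.quantile(null_means, [0.025, 0.975])
    significant = bool(obs_mean < lo or obs_mean > hi)
    return ResampleResult(
        observed_mean=obs_mean, null_means=null_means,
        frac_below=frac_below, frac_above=frac_above,
        p_two_tailed=p_two, significant=significant,
        n_events=n_events, window=window,
    )


def resample_null(
    trials: list[tuple[TrialRecord, PerformanceSeries | None]],
    kind: EventKind | str,
    phase: Phase | str,
    window: float = DEFAULT_WINDOW_S,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
) -> ResampleResult:
    """Resampling test of whether a cue precedes events of one kind/phase.

    Each of ``n_resamples`` null draws relocates every trial's events to
    uniformly chosen candidate seconds (without replacement within a
    trial-phase; candidates are non-broken, in-phase seconds with a
    fully usable preceding window) and recomputes the pooled
    event-preceding mean.  Significance follows the central-95% rule.
    """
    kind, phase = EventKind(kind), Phase(phase)
    prepared = [
        _prepare(trial, perf, kind, phase, int(round(window)))
        for trial, perf in trials
    ]
    return _resample(prepared, n_resamples, seed, window)


def tautness_resample(
    trials: list[TrialRecord],
    phase: Phase | str,
    kind: EventKind | str = EventKind.LEAVE,
    window: float = DEFAULT_WINDOW_S,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
) -> ResampleResult:
    """Resampling test of bridge tautness preceding (by default) leaving events."""
    kind, phase = EventKind(kind), Phase(phase)
    prepared = [
        _prepare(trial, None, kind, phase, int(round(window))) for trial in trials
    ]
    return _resample(prepared, n_resamples, seed, window)


def window_sensitivity(
    trials: list[tuple[TrialRecord, PerformanceSeries | None]],
    kind: EventKind | str,
    phase: Phase | str,
    windows: list[float],
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeat :func:`resample_null` across window lengths.

    Returns one row per window with the observed mean, tail fractions,
    two-tailed p and the central-95% significance flag.
    """
    rows = []
    for w in windows:
        res = resample_null(
            trials, kind, phase, window=w, n_resamples=n_resamples, seed=seed
        )
        rows.append(
            {
                "window": w,
                "observed_mean": res.observed_mean,
                "frac_below": res.frac_below,
                "frac_above": res.frac_above,
                "p_two_tailed": res.p_two_tailed,
                "significant": res.significant,
                "n_events": res.n_events,
            }
        )
    return pd.DataFrame(rows)


def event_timing_uniformity(
    times: np.ndarray,
    interval_s: float = DEFAULT_INTERVAL_S,
) -> tuple[float, float]:
    """Test event offsets within their gap interval against uniformity.

    Events that are direct responses to gap adjustments would cluster at
    the start of the 30-s intervals; a Kolmogorov-Smirnov test of the
    offsets against Uniform(0, interval) quantifies the departure.
    Returns ``(statistic, p_value)``.
    """
    times = np.asarray(times, dtype=float)
    if len(times) == 0:
        raise ParameterError("no events supplied")
    offsets = np.mod(times, interval_s)
    res = stats.kstest(offsets, "uniform", args=(0, interval_s))
    return float(res.statistic), float(res.pvalue)
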