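"""Parameter fitting for the bridge joining/leaving models.

All event-count models share one negative-binomial (NB) convention:
a distribution with mean ``mu`` and dispersion ``theta`` has variance
``mu + mu**2 / theta`` (the ecology NB2 parameterization).  Fitting and
drawing convert internally to whatever a backend requires.

Fitted quantities:

* per-phase NB distributions of join/leave event counts per 30-s gap
  interval (medians of per-trial maximum-likelihood fits),
* the same distributions after reassigning early-contraction leaving
  events to the expansion, for the constant-leaving-delay model,
* the equilibrium packing density ``rho*`` (ants per mm of gap) at which
  logistic regressions of join and leave occurrence intersect,
* NB regressions of event counts on the deficit
  ``delta = rho* * gap - n_ants`` (too few ants: ``delta > 0``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trial_io import (
    DEFAULT_INTERVAL_S,
    EventKind,
    ParameterError,
    Phase,
    TrialRecord,
)

__all__ = [
    "NBEventModel",
    "DeficitRegression",
    "EquilibriumDensity",
    "FitError",
    "NoEquilibriumError",
    "interval_table",
    "fit_nb_counts",
    "apply_delay_reassignment",
    "estimate_equilibrium_density",
    "fit_deficit_regression",
    "deficit_dispersion_diagnostic",
    "nb_draw",
]

# theta above this is reported as the near-Poisson boundary
THETA_CAP = 1e6
# trials broken/recovering for more than this fraction of seconds are
# excluded from fitting altogether (analog of a mostly-broken field trial)
MOSTLY_BROKEN_FRACTION = 0.5

MAX_DELAY_STEPS = 6


class FitError(RuntimeError):
    """A model fit failed or was degenerate."""


class NoEquilibriumError(FitError):
    """Join/leave occurrence curves do not intersect in the observed range."""

    def __init__(self, msg: str, join_logit=None, leave_logit=None):
        super().__init__(msg)
        self.join_logit = join_logit
        self.leave_logit = leave_logit


@dataclass(frozen=True)
class NBEventModel:
    """NB distribution of event counts per gap interval for one phase."""

    mu: float
    theta: float
    phase: Phase
    kind: EventKind

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ParameterError("mu must be non-negative")
        if not self.theta > 0:
            raise ParameterError("theta must be positive")

    @property
    def variance(self) -> float:
        return self.mu + self.mu**2 / self.theta


@dataclass(frozen=True)
class DeficitRegression:
    """Log-link NB regression of event counts on the deficit delta."""

    intercept: float
    slope: float
    theta: float
    kind: EventKind

    def __post_init__(self) -> None:
        if not self.theta > 0:
            raise ParameterError("theta must be positive")

    def mu(self, delta: float | np.ndarray) -> float | np.ndarray:
        """Expected events per interval at deficit ``delta``."""
        return np.exp(self.intercept + self.slope * np.asarray(delta, dtype=float))


@dataclass(frozen=True)
class EquilibriumDensity:
    """Equilibrium packing density and the logistic fits defining it."""

    rho_star: float
    join_logit: tuple[float, float]  # (intercept, slope) on packing density
    leave_logit: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.rho_star > 0:
            raise ParameterError("rho_star must be positive")
        gap = abs(float(self.p_join(self.rho_star) - self.p_leave(self.rho_star)))
        if gap > 1e-6:
            raise ParameterError(
                f"join/leave probabilities differ by {gap:.2g} at rho_star; "
                "not an equilibrium"
            )

    def p_join(self, rho: float | np.ndarray) -> np.ndarray:
        a, b = self.join_logit
        return _expit(a + b * np.asarray(rho, dtype=float))

    def p_leave(self, rho: float | np.ndarray) -> np.ndarray:
        a, b = self.leave_logit
        return _expit(a + b * np.asarray(rho, dtype=float))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Interval aggregation
# ---------------------------------------------------------------------------


def interval_table(
    trial: TrialRecord, interval_s: float = DEFAULT_INTERVAL_S
) -> pd.DataFrame:
    """Aggregate one trial into per-gap-interval rows.

    Columns: ``interval``, ``phase`` (at interval start), ``gap`` and
    ``n_start`` (state at interval start), ``joins``, ``leaves`` and a
    ``broken`` flag set when any second of the interval is broken.
    """
    st = trial.structural
    times = st["time"].to_numpy()
    n_intervals = int(np.floor(times.max() / interval_s)) + 1
    idx = np.clip(np.floor(times / interval_s).astype(int), 0, n_intervals - 1)
    first = pd.Series(np.arange(len(st))).groupby(idx).min().to_numpy()
    counts = trial.events.counts_per_interval(n_intervals, interval_s)
    broken = (
        pd.Series(st["broken"].to_numpy()).groupby(idx).any()
        .reindex(np.arange(n_intervals), fill_value=True)
        .to_numpy()
    )
    return pd.DataFrame(
        {
            "interval": np.arange(n_intervals),
            "phase": st["phase"].to_numpy()[first],
            "gap": st["gap"].to_numpy()[first],
            "n_start": st["n_ants"].to_numpy()[first],
            "joins": counts["joins"].to_numpy(),
            "leaves": counts["leaves"].to_numpy(),
            "broken": broken,
        }
    )


def _usable_trials(trials: list[TrialRecord]) -> list[TrialRecord]:
    usable = []
    for trial in trials:
        if trial.broken_fraction() > MOSTLY_BROKEN_FRACTION:
            warnings.warn(
                f"trial {trial.trial_id!r} is broken for "
                f"{trial.broken_fraction():.0%} of its span; excluded from fits",
                stacklevel=3,
            )
            continue
        usable.append(trial)
    return usable


# ---------------------------------------------------------------------------
# NB distribution fitting
# ---------------------------------------------------------------------------


def fit_nb_mle(counts: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood (mu, theta) of an NB distribution on counts.

    The MLE of ``mu`` is the sample mean; ``theta`` maximizes the profile
    likelihood.  Under-dispersed samples push ``theta`` to the Poisson
    boundary, reported as ``THETA_CAP``.  All-zero samples leave ``theta``
    undefined and raise :class:`FitError`.
    """
    counts = np.asarray(counts, dtype=float)
    if len(counts) < 2:
        raise FitError("need at least two intervals to fit an NB distribution")
    if np.any(counts < 0) or np.any(counts != np.floor(counts)):
        raise ParameterError("counts must be non-negative integers")
    mu = float(counts.mean())
    if mu == 0:
        raise FitError("all counts are zero; theta is undefined")

    def nll(log_theta: float) -> float:
        theta = np.exp(log_theta)
        p = theta / (theta + mu)
        return -stats.nbinom.logpmf(counts, theta, p).sum()

    res = optimize.minimize_scalar(
        nll, bounds=(np.log(1e-4), np.log(THETA_CAP)), method="bounded",
        options={"xatol": 1e-8},
    )
    theta = float(np.exp(res.x))
    if theta > THETA_CAP * 0.5:
        theta = THETA_CAP
    return mu, theta


def _per_trial_counts(
    trials: list[TrialRecord],
    kind: EventKind,
    phase: Phase,
    interval_s: float,
    delay: int = 0,
) -> list[np.ndarray]:
    """Usable per-interval counts of one kind/phase for each trial.

    ``delay`` > 0 reassigns leaving events in the first ``delay``
    contraction intervals to the expansion before selecting the phase.
    """
    kind = EventKind(kind)
    phase = Phase(phase)
    col = "joins" if kind is EventKind.JOIN else "leaves"
    out = []
    for trial in trials:
        tab = interval_table(trial, interval_s)
        phases = tab["phase"].to_numpy().copy()
        if delay and kind is EventKind.LEAVE:
            con = np.flatnonzero(phases == Phase.CONTRACTION.value)
            phases[con[:delay]] = Phase.EXPANSION.value
        mask = (phases == phase.value) & ~tab["broken"].to_numpy()
        out.append(tab.loc[mask, col].to_numpy())
    return out


def fit_nb_counts(
    trials: list[TrialRecord],
    kind: EventKind | str,
    phase: Phase | str,
    interval_s: float = DEFAULT_INTERVAL_S,
    _delay: int = 0,
) -> NBEventModel:
    """Fit the per-interval event-count NB distribution for one kind/phase.

    An NB distribution is fitted to each trial separately and the model
    returned carries the across-trial medians of ``mu`` and ``theta``.
    Broken intervals and mostly-broken trials are excluded; trials whose
    dispersion is inestimable (all counts zero) are dropped from the
    median with a warning.
    """
    kind, phase = EventKind(kind), Phase(phase)
    trials = _usable_trials(list(trials))
    mus, thetas = [], []
    for trial, counts in zip(
        trials, _per_trial_counts(trials, kind, phase, interval_s, _delay)
    ):
        if len(counts) < 2:
            warnings.warn(
                f"trial {trial.trial_id!r}: fewer than 2 usable "
                f"{phase.value} intervals; dropped", stacklevel=2,
            )
            continue
        try:
            mu, theta = fit_nb_mle(counts)
        except FitError as exc:
            warnings.warn(
                f"trial {trial.trial_id!r}: {exc}; dropped from median",
                stacklevel=2,
            )
            continue
        mus.append(mu)
        thetas.append(theta)
    if not mus:
        raise FitError(f"no trial yields a usable NB fit for {kind}/{phase}")
    return NBEventModel(
        mu=float(np.median(mus)), theta=float(np.median(thetas)),
        phase=phase, kind=kind,
    )


def apply_delay_reassignment(
    trials: list[TrialRecord],
    d: int,
    interval_s: float = DEFAULT_INTERVAL_S,
) -> tuple[NBEventModel, NBEventModel]:
    """Refit leaving distributions under a constant leaving delay of ``d`` steps.

    Leaving events observed in the first ``d`` contraction intervals of
    each trial reflect decisions made late in the expansion, so they are
    counted as expansion events before refitting.  Joining distributions
    are untouched (joining has no delay).  Returns the refit
    (expansion, contraction) leave models.
    """
    if not (1 <= d <= MAX_DELAY_STEPS):
        raise ParameterError(
            f"delay must be between 1 and {MAX_DELAY_STEPS} intervals, got {d}"
        )
    exp_model = fit_nb_counts(
        trials, EventKind.LEAVE, Phase.EXPANSION, interval_s, _delay=d
    )
    con_model = fit_nb_counts(
        trials, EventKind.LEAVE, Phase.CONTRACTION, interval_s, _delay=d
    )
    return exp_model, con_model


# ---------------------------------------------------------------------------
# Equilibrium packing density
# ---------------------------------------------------------------------------


def _pooled_intervals(
    trials: list[TrialRecord], interval_s: float
) -> pd.DataFrame:
    frames = []
    for trial in _usable_trials(list(trials)):
        tab = interval_table(trial, interval_s)
        tab = tab[~tab["broken"]]
        tab = tab.assign(trial_id=trial.trial_id)
        frames.append(tab)
    if not frames:
        raise FitError("no usable intervals in any trial")
    return pd.concat(frames, ignore_index=True)


def estimate_equilibrium_density(
    trials: list[TrialRecord],
    interval_s: float = DEFAULT_INTERVAL_S,
) -> EquilibriumDensity:
    """Estimate the packing density at which join and leave are equally likely.

    Logistic regressions of per-interval event occurrence (any join /
    any leave during the interval) on packing density ``rho = n/gap``
    are fitted pooled across trials; ``rho*`` is the root of the
    difference of the two linear predictors, bracketed within the
    observed density range.
    """
    import statsmodels.api as sm

    tab = _pooled_intervals(trials, interval_s)
    tab = tab[tab["gap"] > 0]
    if len(tab) < 4:
        raise FitError("too few positive-gap intervals for logistic fits")
    rho = (tab["n_start"] / tab["gap"]).to_numpy(dtype=float)
    X = sm.add_constant(rho)
    fits = {}
    for name, col in (("join", "joins"), ("leave", "leaves")):
        occ = (tab[col] > 0).astype(float).to_numpy()
        if occ.min() == occ.max():
            raise FitError(f"{name} occurrence is constant; logistic fit degenerate")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(occ, X).fit(disp=0)
        fits[name] = (float(res.params[0]), float(res.params[1]))

    (aj, bj), (al, bl) = fits["join"], fits["leave"]

    def diff(r: float) -> float:
        return (aj + bj * r) - (al + bl * r)

    lo, hi = float(rho.min()), float(rho.max())
    if diff(lo) * diff(hi) > 0:
        raise NoEquilibriumError(
            f"join/leave probability curves do not intersect in "
            f"[{lo:.3g}, {hi:.3g}]",
            join_logit=fits["join"], leave_logit=fits["leave"],
        )
    rho_star = float(optimize.brentq(diff, lo, hi, xtol=1e-12))
    return EquilibriumDensity(
        rho_star=rho_star, join_logit=fits["join"], leave_logit=fits["leave"]
    )


# ---------------------------------------------------------------------------
# Deficit regression
# ---------------------------------------------------------------------------


def fit_deficit_regression(
    trials: list[TrialRecord],
    rho_star: float,
    kind: EventKind | str,
    interval_s: float = DEFAULT_INTERVAL_S,
) -> DeficitRegression:
    """NB regression of per-interval event counts on the start-of-interval deficit.

    The deficit ``delta = rho_star * gap - n_ants`` is computed from the
    state at the beginning of each interval (real-valued equilibrium
    count, integer ants).  A log-link NB regression with a single global
    dispersion ``theta`` per event kind is fitted pooled across trials.
    """
    import statsmodels.api as sm

    kind = EventKind(kind)
    tab = _pooled_intervals(trials, interval_s)
    delta = (rho_star * tab["gap"] - tab["n_start"]).to_numpy(dtype=float)
    y = tab["joins" if kind is EventKind.JOIN else "leaves"].to_numpy(dtype=float)
    if np.ptp(delta) < 1e-9:
        raise FitError("deficit has no variation; regression is degenerate")
    X = sm.add_constant(delta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.NegativeBinomial(y, X, loglike_method="nb2")
        res = model.fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", False):
            res = model.fit(disp=0, method="bfgs", maxiter=500)
    if not res.mle_retvals.get("converged", False):
        raise FitError(
            "NB regression failed to converge; "
            f"delta range [{delta.min():.3g}, {delta.max():.3g}], "
            f"mean count {y.mean():.3g}"
        )
    alpha = float(res.params[-1])
    if alpha <= 0:
        theta = THETA_CAP
    else:
        theta = 1.0 / alpha
    return DeficitRegression(
        intercept=float(res.params[0]), slope=float(res.params[1]),
        theta=float(theta), kind=kind,
    )


def deficit_dispersion_diagnostic(
    trials: list[TrialRecord],
    model: DeficitRegression,
    rho_star: float,
    n_bins: int = 5,
    interval_s: float = DEFAULT_INTERVAL_S,
) -> pd.DataFrame:
    """Binned Pearson-residual variance across deficit values.

    Mirrors the residual check that the regression dispersion is
    constant across deficits: each bin's mean squared Pearson residual
    should be close to 1 under the fitted model.
    """
    tab = _pooled_intervals(trials, interval_s)
    delta = (rho_star * tab["gap"] - tab["n_start"]).to_numpy(dtype=float)
    y = tab["joins" if model.kind is EventKind.JOIN else "leaves"].to_numpy(float)
    mu = model.mu(delta)
    resid = (y - mu) / np.sqrt(mu + mu**2 / model.theta)
    bins = pd.qcut(delta, q=n_bins, duplicates="drop")
    out = (
        pd.DataFrame({"delta": delta, "pearson_sq": resid**2})
        .groupby(bins, observed=True)
        .agg(delta_mid=("delta", "mean"), dispersion=("pearson_sq", "mean"),
             n=("pearson_sq", "size"))
        .reset_index(drop=True)
    )
    return out


# ---------------------------------------------------------------------------
# NB draws
# ---------------------------------------------------------------------------


def nb_draw(
    mu: float,
    theta: float,
    rng: np.random.Generator,
    size: int | tuple | None = None,
):
    """Draw event counts from NB(mean ``mu``, dispersion ``theta``).

    Variance is ``mu + mu**2/theta``; ``theta = inf`` degenerates to a
    Poisson draw and ``mu = 0`` always yields zero.
    """
    if mu < 0:
        raise ParameterError("mu must be non-negative")
    if not theta > 0:
        raise ParameterError("theta must be positive")
    if mu == 0:
        return 0 if size is None else np.zeros(size, dtype=np.int64)
    if not np.isfinite(theta):
        return rng.poisson(mu, size=size)
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p, size=size)
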