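"""Hysteresis quantification between expansion and contraction curves.

For one trial or simulated trajectory, a structural metric (number of
ants, volume, ...) is plotted against gap size separately for the
expansion and contraction phases, each smoothed by local polynomial
regression (LOESS).  The *extent of hysteresis* is the area between the
two smoothed curves normalized by the area under the higher curve — a
unitless, signed proportion in [-1, 1], negative when the expansion
curve is the higher one.

The smoother is a classical LOESS: for each evaluation point the
nearest ``span`` fraction of samples is fitted by weighted polynomial
least squares with tricube weights.  Because the fitted value is linear
in the responses, the smoother is exposed as a matrix so thousands of
simulated trajectories sharing one schedule can be smoothed with a
single matrix product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trial_io import (
    BridgeTrajectory,
    ParameterError,
    Phase,
    TrialRecord,
)

__all__ = [
    "PhaseCurves",
    "HysteresisResult",
    "TTestResult",
    "loess_matrix",
    "loess_smooth",
    "smooth_phase_curves",
    "trajectory_phase_curves",
    "extent_of_hysteresis",
    "extents_for_trajectories",
    "hysteresis_ttest",
    "correlate_volume_ants",
]

DEFAULT_SPAN = 0.75
DEFAULT_DEGREE = 2
DEFAULT_GRID_SPACING = 0.5  # mm
MIN_SAMPLES_PER_PHASE = 10


@dataclass(frozen=True)
class PhaseCurves:
    """Smoothed metric-vs-gap curves for the two directional phases."""

    gap_grid: np.ndarray
    expansion: np.ndarray
    contraction: np.ndarray
    metric_name: str = ""


@dataclass(frozen=True)
class HysteresisResult:
    """Signed, normalized extent of hysteresis between two phase curves."""

    extent: float
    area_between: float
    area_upper: float
    sign_source: str  # "contraction_higher" | "expansion_higher"
    reason: str = ""

    @property
    def defined(self) -> bool:
        return not np.isnan(self.extent)


@dataclass(frozen=True)
class TTestResult:
    """One-sample two-tailed t-test of per-trial hysteresis extents."""

    mean: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# LOESS
# ---------------------------------------------------------------------------


def loess_matrix(
    x: np.ndarray,
    grid: np.ndarray,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
) -> np.ndarray:
    """Linear LOESS smoothing operator ``S`` with ``smoothed = S @ y``.

    Row ``i`` of ``S`` gives the weights of a tricube-weighted degree-
    ``degree`` polynomial fit to the ``floor(span * len(x))`` samples
    nearest ``grid[i]``, evaluated at ``grid[i]`` (the neighborhood
    rule of the classical LOESS implementations).
    """
    x = np.asarray(x, dtype=float)
    grid = np.asarray(grid, dtype=float)
    n = len(x)
    if not 0 < span <= 1:
        raise ParameterError("span must be in (0, 1]")
    q = min(n, max(int(np.floor(span * n + 1e-9)), degree + 1))
    S = np.zeros((len(grid), n))
    for i, g in enumerate(grid):
        d = np.abs(x - g)
        order = np.argsort(d, kind="stable")[:q]
        dmax = d[order[-1]]
        w = np.zeros(n)
        if dmax == 0:
            w[order] = 1.0
        else:
            u = np.clip(d[order] / dmax, 0.0, 1.0)
            w[order] = (1 - u**3) ** 3
            if w[order].sum() <= 0:  # all mass at the window edge
                w[order] = 1.0
        active = np.flatnonzero(w > 0)
        B = np.vander(x[active] - g, degree + 1, increasing=True)
        Wv = w[active]
        A = B.T * Wv  # (degree+1, m)
        M = A @ B
        # value at the evaluation point is the intercept coefficient
        coef_rows = np.linalg.lstsq(M, A, rcond=None)[0]
        S[i, active] = coef_rows[0]
    return S


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
) -> np.ndarray:
    """LOESS-smooth samples ``(x, y)`` onto ``grid``."""
    return loess_matrix(x, grid, span, degree) @ np.asarray(y, dtype=float)


def _overlap_grid(
    gap_e: np.ndarray, gap_c: np.ndarray, spacing: float
) -> np.ndarray:
    lo = max(gap_e.min(), gap_c.min())
    hi = min(gap_e.max(), gap_c.max())
    if hi <= lo:
        raise ParameterError("expansion and contraction gap ranges do not overlap")
    n = int(np.floor((hi - lo) / spacing + 1e-9)) + 1
    return lo + spacing * np.arange(n)


def _mean_by_gap(gap: np.ndarray, value: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gaps, inv = np.unique(gap, return_inverse=True)
    sums = np.bincount(inv, weights=value)
    counts = np.bincount(inv)
    return gaps, sums / counts


def smooth_phase_curves(
    gap: np.ndarray,
    value: np.ndarray,
    phase: np.ndarray,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
    grid_spacing: float = DEFAULT_GRID_SPACING,
    metric_name: str = "",
    smoothing: bool = True,
) -> PhaseCurves:
    """Phase-stratified smoothed curves of a metric against gap size.

    Samples must already exclude broken periods.  The curves are
    evaluated on a uniform grid over the overlap of the two phases'
    gap supports.  With ``smoothing=False`` the per-gap means are
    linearly interpolated instead (useful for simulated trajectories
    with one value per integer gap).
    """
    gap = np.asarray(gap, dtype=float)
    value = np.asarray(value, dtype=float)
    phase = np.asarray(phase)
    curves = {}
    masks = {
        "expansion": phase == Phase.EXPANSION.value,
        "contraction": phase == Phase.CONTRACTION.value,
    }
    for name, mask in masks.items():
        if mask.sum() < MIN_SAMPLES_PER_PHASE:
            raise ParameterError(
                f"need at least {MIN_SAMPLES_PER_PHASE} samples in the "
                f"{name} phase, got {int(mask.sum())}"
            )
    grid = _overlap_grid(gap[masks["expansion"]], gap[masks["contraction"]], grid_spacing)
    for name, mask in masks.items():
        if smoothing:
            curves[name] = loess_smooth(gap[mask], value[mask], grid, span, degree)
        else:
            gx, gy = _mean_by_gap(gap[mask], value[mask])
            curves[name] = np.interp(grid, gx, gy)
    return PhaseCurves(
        gap_grid=grid,
        expansion=curves["expansion"],
        contraction=curves["contraction"],
        metric_name=metric_name,
    )


def trial_phase_curves(
    trial: TrialRecord,
    metric: str = "n_ants",
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
    grid_spacing: float = DEFAULT_GRID_SPACING,
    smoothing: bool = True,
) -> PhaseCurves:
    """Phase curves of one structural metric of a trial (broken seconds excluded)."""
    st = trial.structural
    ok = ~st["broken"].to_numpy()
    return smooth_phase_curves(
        st["gap"].to_numpy()[ok],
        st[metric].to_numpy(dtype=float)[ok],
        st["phase"].to_numpy()[ok],
        span=span, degree=degree, grid_spacing=grid_spacing,
        metric_name=metric, smoothing=smoothing,
    )


def trajectory_phase_curves(
    traj: BridgeTrajectory,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
    grid_spacing: float = DEFAULT_GRID_SPACING,
    smoothing: bool = True,
) -> PhaseCurves:
    """Ant-count-vs-gap phase curves of one simulated trajectory."""
    phases = traj.schedule.phase_array()
    keep = phases != Phase.VIBRATION.value
    return smooth_phase_curves(
        traj.schedule.gaps[keep],
        traj.n_ants[keep].astype(float),
        phases[keep],
        span=span, degree=degree, grid_spacing=grid_spacing,
        metric_name="n_ants", smoothing=smoothing,
    )


# ---------------------------------------------------------------------------
# Extent of hysteresis
# ---------------------------------------------------------------------------


def _extent_from_areas(
    area_between: float, area_e: float, area_c: float
) -> tuple[float, float, str, str]:
    area_upper = max(area_e, area_c)
    if area_upper <= 0:
        return np.nan, area_upper, "contraction_higher", "area under both curves is zero"
    sign_source = "expansion_higher" if area_e > area_c else "contraction_higher"
    extent = min(area_between / area_upper, 1.0)
    if sign_source == "expansion_higher":
        extent = -extent
    return extent, area_upper, sign_source, ""


def extent_of_hysteresis(curves: PhaseCurves) -> HysteresisResult:
    """Signed, normalized area between the expansion and contraction curves.

    ``area_between`` is the trapezoidal integral of the absolute
    difference; ``area_upper`` is the larger of the areas under the two
    curves; the extent is their ratio (capped at 1), negative when the
    area under the expansion curve is larger.  If both curves enclose
    zero area the extent is undefined and returned as NaN with a reason.
    """
    g = curves.gap_grid
    e, c = curves.expansion, curves.contraction
    area_between = float(np.trapezoid(np.abs(c - e), g))
    area_e = float(np.trapezoid(e, g))
    area_c = float(np.trapezoid(c, g))
    extent, area_upper, sign_source, reason = _extent_from_areas(
        area_between, area_e, area_c
    )
    return HysteresisResult(
        extent=extent, area_between=area_between, area_upper=area_upper,
        sign_source=sign_source, reason=reason,
    )


def extents_for_trajectories(
    trajectories: list[BridgeTrajectory],
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
    grid_spacing: float = DEFAULT_GRID_SPACING,
    smoothing: bool = True,
) -> np.ndarray:
    """Hysteresis extents of many trajectories sharing one schedule.

    Exploits the linearity of the LOESS smoother: the smoothing matrices
    for the (fixed) expansion and contraction gap sequences are built
    once and applied to all trajectories as matrix products.  Undefined
    extents come back as NaN.
    """
    if not trajectories:
        return np.empty(0)
    sched = trajectories[0].schedule
    phases = sched.phase_array()
    mask_e = phases == Phase.EXPANSION.value
    mask_c = phases == Phase.CONTRACTION.value
    gap_e, gap_c = sched.gaps[mask_e], sched.gaps[mask_c]
    grid = _overlap_grid(gap_e, gap_c, grid_spacing)
    Y = np.stack([tr.n_ants.astype(float) for tr in trajectories])
    if smoothing:
        Se = loess_matrix(gap_e, grid, span, degree)
        Sc = loess_matrix(gap_c, grid, span, degree)
        E = Y[:, mask_e] @ Se.T
        C = Y[:, mask_c] @ Sc.T
    else:
        # one value per gap in each phase of a simulated schedule
        E = np.stack(
            [np.interp(grid, *_mean_by_gap(gap_e, row)) for row in Y[:, mask_e]]
        )
        C = np.stack(
            [np.interp(grid, *_mean_by_gap(gap_c, row)) for row in Y[:, mask_c]]
        )
    area_between = np.trapezoid(np.abs(C - E), grid, axis=1)
    area_e = np.trapezoid(E, grid, axis=1)
    area_c = np.trapezoid(C, grid, axis=1)
    area_upper = np.maximum(area_e, area_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        extents = np.minimum(area_between / area_upper, 1.0)
    extents = np.where(area_e > area_c, -extents, extents)
    extents[area_upper <= 0] = np.nan
    return extents


# ---------------------------------------------------------------------------
# Across-trial statistics
# ---------------------------------------------------------------------------


def hysteresis_ttest(extents: np.ndarray) -> TTestResult:
    """One-sample two-tailed t-test of hysteresis extents against zero."""
    extents = np.asarray(extents, dtype=float)
    if len(extents) < 2:
        raise ParameterError("need at least two trials for a t-test")
    n = len(extents)
    mean = float(extents.mean())
    if np.ptp(extents) == 0:
        return TTestResult(
            mean=mean, ci_low=mean, ci_high=mean, t=np.nan, df=n - 1,
            p=np.nan, degenerate=True,
        )
    res = stats.ttest_1samp(extents, 0.0)
    sem = extents.std(ddof=1) / np.sqrt(n)
    half = stats.t.ppf(0.975, n - 1) * sem
    return TTestResult(
        mean=mean, ci_low=mean - half, ci_high=mean + half,
        t=float(res.statistic), df=n - 1, p=float(res.pvalue),
    )


def correlate_volume_ants(trial: TrialRecord) -> float:
    """Pearson correlation of bridge volume and ant count over non-broken seconds."""
    st = trial.structural
    ok = ~st["broken"].to_numpy()
    v = st["volume"].to_numpy(dtype=float)[ok]
    n = st["n_ants"].to_numpy(dtype=float)[ok]
    if len(v) < 3:
        raise ParameterError("need at least 3 non-broken seconds")
    if np.ptp(v) == 0 or np.ptp(n) == 0:
        warnings.warn("zero variance; volume-ants correlation undefined", stacklevel=2)
        return np.nan
    return float(stats.pearsonr(v, n).statistic)
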