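"""Exponential-decay model of the post-event activity boost.

The paired-week differences ``y`` over post-event weeks ``x`` are modelled as

    y = a * exp(-b * x)

where ``a`` (days/week) is the initial boost in weekly devoted days and ``b``
(per week) the decay constant.  Derived quantities: the boost's half-life
``ln(2)/b`` and the cumulative extra recording days per continuing
participant ``a/b`` (the integral of the curve over an infinite horizon).

Projects differ in how strong a boost they trigger, so the default
``two_stage`` estimator treats the amplitude as project-specific and the
decay rate as shared.  Stage 1 builds weighted project-week mean curves:
users are weighted by the inverse variance of their own difference series
— high-baseline veterans contribute the same boost signal as new users but
far more noise — with the variance *cross-fitted* by week parity (the
weight applied to odd weeks is estimated from even weeks and vice versa)
so weights are independent of the errors they multiply.  Stage 2 fits a
single (a, b) to the pooled weighted mean curve by one-dimensional least
squares (the amplitude is linear given b and is profiled out), recovers
per-project amplitudes given the fitted rate, and attaches standard errors
from a project-level nonparametric bootstrap, which is honest about
between-project heterogeneity.  Estimating ``b`` jointly rather than
project-by-project matters: with a handful of continuing users per
project, a per-project exponential fit is close to unidentifiable and
averaging such fits is strongly biased.  A single pooled NLS over all
user-week rows is available as a fallback.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize_scalar

__all__ = [
    "DecayFit",
    "ExtrapolationInput",
    "fit_decay",
    "half_life",
    "cumulative_boost",
    "extrapolate",
]

#: pseudo-project collecting projects with too few continuing users
POOLED_SMALL = "__pooled_small__"


@dataclass
class DecayFit:
    """Population decay-fit result.

    ``n_points`` counts the user-week panel rows behind the fit (the natural
    sample size to report for this design).  ``project_effects`` holds the
    stage-1 per-project estimates; ``excluded_projects`` lists projects
    dropped from pooling (non-convergence or non-positive parameters) with
    reasons.
    """

    a_hat: float
    b_hat: float
    se_a: float
    se_b: float
    n_points: int
    method: str
    converged: bool
    degenerate: bool = False
    project_effects: pd.DataFrame = field(default_factory=pd.DataFrame)
    excluded_projects: list[tuple[str, str]] = field(default_factory=list)

    @property
    def half_life_weeks(self) -> float:
        return half_life(self.b_hat)

    @property
    def cumulative_boost_days(self) -> float:
        return cumulative_boost(self.a_hat, self.b_hat)


def _model(x: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * np.exp(-b * x)


def _initial_guess(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Starting values: a0 = mean difference over weeks 1-4; b0 from the OLS
    slope of log weekly means on weeks with positive means (fallback 0.05)."""
    early = y[x <= 4]
    a0 = float(np.mean(early)) if early.size else float(np.mean(y))
    a0 = max(a0, 0.01)
    pos = y > 0
    if pos.sum() >= 3:
        slope = np.polyfit(x[pos], np.log(np.maximum(y[pos], 0.01)), 1)[0]
        b0 = float(np.clip(-slope, 1e-3, 2.0))
    else:
        b0 = 0.05
    return a0, b0


def _nls(x: np.ndarray, y: np.ndarray, rng: np.random.Generator,
         restarts: int = 8) -> tuple[float, float, float, float] | None:
    """Unbounded NLS of y on a*exp(-b x); jittered restarts on failure.
    Returns (a, b, se_a, se_b) or None."""
    a0, b0 = _initial_guess(x, y)
    p0 = (a0, b0)
    for attempt in range(restarts + 1):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(_model, x, y, p0=p0, maxfev=5000)
            if not np.all(np.isfinite(popt)):
                raise RuntimeError("non-finite estimate")
            se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
            return float(popt[0]), float(popt[1]), float(se[0]), float(se[1])
        except (RuntimeError, TypeError, ValueError):
            p0 = (a0 * rng.lognormal(0.0, 0.5), b0 * rng.lognormal(0.0, 0.5))
    return None


_VAR_FLOOR = 0.02  # devoted-days units²; keeps weights finite for quiet users


def _user_weights(panel: pd.DataFrame, weighting: str) -> np.ndarray:
    """Per-row regression weights.

    ``cross_fitted``: inverse of the user's difference variance, estimated
    on the opposite week parity from the row it is applied to, floored at
    ``_VAR_FLOOR``.  ``uniform``: all ones.
    """
    if weighting == "uniform":
        return np.ones(len(panel))
    parity = (panel["week_after"] % 2).to_numpy()
    var_by_parity = panel.groupby(["user_id", panel["week_after"] % 2])["diff"].var()
    v = var_by_parity.unstack()
    v = v.reindex(columns=[0, 1]).clip(lower=_VAR_FLOOR).fillna(_VAR_FLOOR)
    w_even = panel["user_id"].map(1.0 / v[1]).to_numpy()  # even rows <- odd-week var
    w_odd = panel["user_id"].map(1.0 / v[0]).to_numpy()
    return np.where(parity == 0, w_even, w_odd)


def _panel_matrices(panel: pd.DataFrame, min_users_per_project: int,
                    weighting: str) -> tuple[list[str], np.ndarray, np.ndarray,
                                             np.ndarray, np.ndarray]:
    """Project-level sufficient statistics for the weighted fit.

    Returns (project ids, weeks, SW, SWY, n_users): SW[p, t] the summed row
    weights of project p in week t (0 where the week is missing), SWY the
    weight-times-difference sums.
    """
    users = panel.groupby("project_id")["user_id"].nunique()
    small = set(users.index[users < min_users_per_project])
    pid = panel["project_id"].where(~panel["project_id"].isin(small), POOLED_SMALL)
    w = _user_weights(panel, weighting)
    tmp = pd.DataFrame({"pid": pid, "week": panel["week_after"],
                        "w": w, "wy": w * panel["diff"].to_numpy()})
    g = tmp.groupby(["pid", "week"])
    SW = g["w"].sum().unstack(fill_value=0.0)
    SWY = g["wy"].sum().unstack(fill_value=0.0)
    weeks = SW.columns.to_numpy(dtype=float)
    n_users = panel.groupby(pid)["user_id"].nunique().reindex(SW.index).to_numpy()
    return list(SW.index), weeks, SW.to_numpy(), SWY.to_numpy(), n_users.astype(int)


_B_LO, _B_HI = 1e-5, 5.0


def _curve_fit_1d(weeks: np.ndarray, SW: np.ndarray, SWY: np.ndarray
                  ) -> tuple[float, float]:
    """Fit (a, b) to the pooled weighted mean curve; a is profiled out."""
    tot = SW.sum(axis=0)
    ybar = SWY.sum(axis=0) / np.where(tot > 0, tot, 1.0)

    def amplitude(b: float) -> float:
        e = np.exp(-b * weeks)
        return float((tot * ybar * e).sum() / (tot * e * e).sum())

    def sse(b: float) -> float:
        e = np.exp(-b * weeks)
        r = ybar - amplitude(b) * e
        return float((tot * r * r).sum())

    # the profiled SSE can be multimodal on noisy curves: coarse log-grid
    # scan first, then local refinement inside the best bracket
    grid = np.geomspace(_B_LO, _B_HI, 80)
    i = int(np.argmin([sse(b) for b in grid]))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    b = float(res.x)
    return amplitude(b), b


def _project_amplitudes(b: float, weeks: np.ndarray, SW: np.ndarray,
                        SWY: np.ndarray) -> np.ndarray:
    """Per-project least-squares amplitudes at the fitted common rate."""
    e = np.exp(-b * weeks)
    denom = SW @ (e * e)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = SWY @ e / denom
    return np.where(denom > 0, a, 0.0)


def _bootstrap_se(weeks: np.ndarray, SW: np.ndarray, SWY: np.ndarray,
                  rng: np.random.Generator, n_boot: int = 200
                  ) -> tuple[float, float]:
    """Project-level nonparametric bootstrap SEs for (a, b)."""
    n_proj = SW.shape[0]
    if n_proj < 2:
        return float("nan"), float("nan")
    a_rep, b_rep = [], []
    for _ in range(n_boot):
        idx = rng.integers(0, n_proj, n_proj)
        if not np.any(SWY[idx] != 0):
            continue
        a, b = _curve_fit_1d(weeks, SW[idx], SWY[idx])
        a_rep.append(a)
        b_rep.append(b)
    if len(a_rep) < 2:
        return float("nan"), float("nan")
    return float(np.std(a_rep, ddof=1)), float(np.std(b_rep, ddof=1))


def _degenerate(panel: pd.DataFrame, method: str) -> DecayFit:
    return DecayFit(a_hat=0.0, b_hat=float("nan"), se_a=float("nan"),
                    se_b=float("nan"), n_points=int(len(panel)), method=method,
                    converged=False, degenerate=True)


def fit_decay(panel: pd.DataFrame, method: str = "two_stage",
              min_users_per_project: int = 3, seed: int = 0,
              weighting: str = "cross_fitted") -> DecayFit:
    """Fit the population decay model to a difference panel.

    Parameters
    ----------
    panel
        Rows (user_id, project_id, week_after, diff) from
        :func:`bioblitz.engagement.difference_panel`.
    method
        ``"two_stage"`` (default): stage 1 builds user-weighted project-week
        mean curves; stage 2 fits a shared decay rate with the amplitude
        profiled out, recovers per-project amplitudes at that rate, and
        bootstraps projects for the standard errors.
        ``"pooled"``: one NLS over all user-week rows; no project effects.
    min_users_per_project
        Projects with fewer continuing users are merged into a single
        pseudo-project before stage 1 (amplitude estimates on 1-2 users are
        unstable).
    seed
        Seeds the project-level bootstrap (two_stage) and the jittered
        restarts used on NLS non-convergence (pooled); point estimates are
        fully deterministic.
    weighting
        ``"cross_fitted"`` (default): rows weighted by the inverse of the
        user's difference variance, estimated on the opposite week parity.
        ``"uniform"``: unweighted; on a single-project panel this makes the
        two-stage fit coincide with the pooled one.
    """
    if panel.empty:
        raise ValueError("panel is empty")
    if method not in ("two_stage", "pooled"):
        raise ValueError(f"unknown method {method!r}")
    if weighting not in ("cross_fitted", "uniform"):
        raise ValueError(f"unknown weighting {weighting!r}")
    rng = np.random.default_rng(seed)
    n_points = int(len(panel))

    if method == "pooled":
        x = panel["week_after"].to_numpy(dtype=float)
        y = panel["diff"].to_numpy(dtype=float)
        if not np.any(y != 0):
            return _degenerate(panel, method)
        res = _nls(x, y, rng)
        if res is None:
            return DecayFit(float("nan"), float("nan"), float("nan"), float("nan"),
                            n_points, method, converged=False)
        a, b, se_a, se_b = res
        return DecayFit(a, b, se_a, se_b, n_points, method,
                        converged=b > 0, degenerate=abs(a) < 1e-6)

    pids, weeks, SW, SWY, n_users = _panel_matrices(panel, min_users_per_project,
                                                    weighting)
    if not np.any(SWY != 0):
        return _degenerate(panel, method)

    a_hat, b_hat = _curve_fit_1d(weeks, SW, SWY)
    a_p = _project_amplitudes(b_hat, weeks, SW, SWY)
    se_a, se_b = _bootstrap_se(weeks, SW, SWY, rng)

    excluded: list[tuple[str, str]] = []
    flagged = a_p <= 0
    for pid_, a_val in zip(pids, a_p):
        if a_val <= 0:
            excluded.append((str(pid_), f"non-positive amplitude (a={a_val:.3g})"))
    eff = pd.DataFrame({
        "project_id": pids, "a": a_p, "b": b_hat,
        "n_users": n_users,
        "flagged": flagged,
    })
    at_bound = not (_B_LO * 2 < b_hat < _B_HI * 0.9)
    return DecayFit(a_hat, b_hat, se_a, se_b, n_points, method,
                    converged=not at_bound, degenerate=abs(a_hat) < 1e-6,
                    project_effects=eff, excluded_projects=excluded)


def half_life(b: float) -> float:
    """Half-life in weeks of a boost decaying at rate ``b`` per week:
    ``ln(2)/b``.  Undefined for non-positive rates."""
    if not b > 0:
        raise ValueError("half_life requires a positive decay constant")
    return math.log(2.0) / b


def cumulative_boost(a: float, b: float, horizon_weeks: float | None = None) -> float:
    """Cumulative extra devoted days: the integral of ``a*exp(-b t)``.

    Infinite horizon (default) gives ``a/b``; a finite horizon ``W`` gives
    ``a/b * (1 - exp(-b W))``.
    """
    if a < 0:
        raise ValueError("cumulative_boost requires a >= 0")
    if not b > 0:
        raise ValueError("cumulative_boost requires b > 0")
    total = a / b
    if horizon_weeks is not None:
        total *= 1.0 - math.exp(-b * horizon_weeks)
    return total


@dataclass(frozen=True)
class ExtrapolationInput:
    """Inputs for scaling the per-participant boost to a platform total."""

    n_participants: int
    continuation_rate: float
    cumulative_days: float
    obs_per_day: float
    total_observations: int

    def __post_init__(self) -> None:
        if min(self.n_participants, self.cumulative_days, self.obs_per_day,
               self.total_observations) < 0:
            raise ValueError("extrapolation inputs must be non-negative")
        if not 0.0 <= self.continuation_rate <= 1.0:
            raise ValueError("continuation_rate must be in [0, 1]")


def extrapolate(inp: ExtrapolationInput) -> tuple[float, float]:
    """Additional observations implied by the boost, and their share of the
    corpus total.

    additional = participants x continuation rate x cumulative extra days x
    observations per extra day; share = additional / total observations.
    """
    additional = (inp.n_participants * inp.continuation_rate
                  * inp.cumulative_days * inp.obs_per_day)
    if inp.total_observations == 0:
        raise ValueError("total_observations is zero; share undefined")
    return additional, additional / inp.total_observations
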