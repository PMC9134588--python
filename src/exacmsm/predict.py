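"""Transition probabilities and state occupancy from a parametric fit.

For a Markov process with intensity matrix Q(t) (off-diagonal entries
are the fitted transition hazards for a covariate profile, rows sum to
zero) the transition probability matrix solves the Kolmogorov forward
equations

    dP(t0, t)/dt = P(t0, t) Q(t),      P(t0, t0) = I.

The system is integrated with a high-order adaptive Runge-Kutta method
(DOP853, atol 1e-10 / rtol 1e-8).  Because the process is progressive,
Q is upper triangular and the structural zeros of P are preserved
exactly by the integration.  An initial step over [t0, t0+eps] uses the
exact interval cumulative hazards through a matrix exponential, which
also handles hazards that are singular at t = 0 (e.g. Weibull shape
below 1).

Confidence intervals for any functional of the parameters follow the
asymptotic-normal simulation approach: parameter vectors are drawn from
MVN(MLE, vcov) on the unconstrained scale and the functional is
recomputed for each draw.  Reporting per 10,000 patients happens only at
the formatting layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .events import PERMITTED_TRANSITIONS, STATES
from .nonparam import OccupancyEstimate
from .parametric import DAYS_PER_YEAR, ParametricFit, _clone_with_theta

__all__ = [
    "IntensityMatrix",
    "ProbabilityMatrix",
    "intensity_matrix",
    "homogeneous_intensity",
    "transition_probabilities",
    "occupancy_curves",
    "eight_profiles",
    "profile_grid",
    "simulate_normal_ci",
    "four_week_matrix",
    "per_10000",
    "default_grid_days",
    "FORBIDDEN_MASK",
    "Q_FORBIDDEN_MASK",
]

#: entries of P that are structurally zero: backward moves (state 5 is
#: absorbing, so its row is zero off-diagonal).  Note P[1,3] is NOT zero:
#: although the direct 1 -> 3 jump is forbidden in Q, state 3 is reachable
#: from state 1 through state 2.
FORBIDDEN_MASK = np.tril(np.ones((5, 5), dtype=bool), k=-1)

#: entries of Q that must be zero: backward moves, the direct 1 -> 3 jump,
#: and all exits from the absorbing death state
Q_FORBIDDEN_MASK = FORBIDDEN_MASK.copy()
Q_FORBIDDEN_MASK[0, 2] = True
Q_FORBIDDEN_MASK[4, :] = True
Q_FORBIDDEN_MASK[np.arange(5), np.arange(5)] = False


@dataclass
class IntensityMatrix:
    """Q(t) plus exact interval cumulative hazards, time in years."""

    q_of_t: Callable[[float], np.ndarray]
    interval_cumhaz: Callable[[float, float], np.ndarray]
    label: str = ""

    def Q(self, t_years: float) -> np.ndarray:
        if t_years < 0:
            raise ValueError("intensity requested at negative time")
        return self.q_of_t(float(t_years))


@dataclass
class ProbabilityMatrix:
    """P(t0, t1) with optional simulation CIs, times in years."""

    t0: float
    t1: float
    matrix: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def to_frame(self, scale: float = 1.0) -> pd.DataFrame:
        rows = []
        for r in STATES:
            for s in STATES:
                row = {
                    "from_state": r, "to_state": s,
                    "estimate": self.matrix[r - 1, s - 1] * scale,
                }
                if self.ci_low is not None:
                    row["ci_low"] = self.ci_low[r - 1, s - 1] * scale
                    row["ci_high"] = self.ci_high[r - 1, s - 1] * scale
                rows.append(row)
        return pd.DataFrame(rows)


def _q_from_hazards(hazards: dict, t: float) -> np.ndarray:
    Q = np.zeros((5, 5))
    for (r, s), h in hazards.items():
        Q[r - 1, s - 1] = h(t)
    np.fill_diagonal(Q, 0.0)
    Q[np.arange(5), np.arange(5)] = -Q.sum(axis=1)
    return Q


def intensity_matrix(
    fit: ParametricFit, profile: Mapping | None = None
) -> IntensityMatrix:
    """Assemble the 5x5 intensity function from fitted hazards.

    ``profile`` maps baseline columns (e.g. ``age``, ``fev1pp``) to raw
    values; covariates absent from the profile are held at their
    centring values.  Forbidden transitions have intensity exactly 0.
    """
    profile = dict(profile or {})
    known = {t.column for t in fit.spec} | {t.interaction_column
                                            for t in fit.spec
                                            if t.interaction_column}
    unknown = set(profile) - known
    if unknown:
        raise KeyError(
            f"profile covariates {sorted(unknown)} not in the fitted "
            f"specification (expected among {sorted(known)})"
        )
    hazards = {}
    cumhaz = {}
    for rs in fit.transitions + fit.dropped_transitions:
        hazards[rs] = (lambda t, rs=rs: float(fit.hazard(rs, t, profile)))
        cumhaz[rs] = (lambda t, rs=rs:
                      float(fit.cumulative_hazard(rs, t, profile)))

    def q_of_t(t):
        return _q_from_hazards(hazards, t)

    def interval(t0, t1):
        A = np.zeros((5, 5))
        for rs, H in cumhaz.items():
            A[rs[0] - 1, rs[1] - 1] = H(t1) - H(t0)
        A[np.arange(5), np.arange(5)] = -A.sum(axis=1)
        return A

    return IntensityMatrix(q_of_t, interval, label=fit.family)


def homogeneous_intensity(Q: np.ndarray) -> IntensityMatrix:
    """Wrap a constant intensity matrix (useful for oracles and tests)."""
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (5, 5):
        raise ValueError("Q must be 5x5")
    if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-12):
        raise ValueError("rows of Q must sum to 0")
    off = Q.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off < 0):
        raise ValueError("off-diagonal intensities must be >= 0")
    if np.any(off[Q_FORBIDDEN_MASK] != 0.0):
        raise ValueError("forbidden transitions must have zero intensity")
    return IntensityMatrix(lambda t: Q, lambda t0, t1: Q * (t1 - t0),
                           label="homogeneous")


def transition_probabilities(
    intensity: IntensityMatrix,
    t0: float,
    t1: float,
    *,
    atol: float = 1e-10,
    rtol: float = 1e-8,
    dense: bool = False,
):
    """Solve the Kolmogorov forward equations from t0 to t1 (years).

    Returns a :class:`ProbabilityMatrix` (or the ODE solution object
    when ``dense`` is requested, for evaluating a whole grid in one
    solve).  Rows are renormalised only if the drift from 1 is below
    1e-8; larger drift raises.
    """
    if t1 < t0:
        raise ValueError("t1 must be >= t0")
    if t1 == t0:
        return ProbabilityMatrix(t0, t1, np.eye(5))
    eps = min(1e-8, (t1 - t0) * 1e-6)
    P0 = expm(intensity.interval_cumhaz(t0, t0 + eps))

    def rhs(t, y):
        P = y.reshape(5, 5)
        return (P @ intensity.Q(t)).ravel()

    sol = solve_ivp(rhs, (t0 + eps, t1), P0.ravel(), method="DOP853",
                    atol=atol, rtol=rtol, dense_output=dense)
    if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
        raise RuntimeError(
            f"Kolmogorov integration failed: {sol.message}"
        )
    if dense:
        return sol
    P = sol.y[:, -1].reshape(5, 5)
    return ProbabilityMatrix(t0, t1, _renormalise(P))


def _renormalise(P: np.ndarray) -> np.ndarray:
    drift = np.abs(P.sum(axis=1) - 1.0)
    if np.any(drift > 1e-8):
        raise RuntimeError(
            f"probability rows drifted from 1 by up to {drift.max():.2e}"
        )
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


def default_grid_days(horizon_years: float = 5.0) -> np.ndarray:
    """Weekly within the 52-week trial window, then every 4 weeks."""
    weekly = np.arange(0, 365, 7)
    later = np.arange(364 + 28, horizon_years * DAYS_PER_YEAR + 1, 28)
    return np.concatenate([weekly, later])


def occupancy_curves(
    fit: ParametricFit,
    profile: Mapping | None = None,
    grid_days: Sequence[float] | None = None,
    *,
    theta: np.ndarray | None = None,
) -> OccupancyEstimate:
    """State occupancy from study start on a day grid (first P row)."""
    if theta is not None:
        fit = _clone_with_theta(fit, theta)
    if grid_days is None:
        grid_days = default_grid_days()
    grid_days = np.asarray(grid_days, dtype=float)
    if np.any(grid_days < 0):
        raise ValueError("grid must be non-negative")
    grid_years = grid_days / fit.time_scale
    t_max = float(grid_years.max())
    imat = intensity_matrix(fit, profile)
    if t_max == 0.0:
        probs = np.tile(np.eye(5)[0], (len(grid_days), 1))
        return OccupancyEstimate(grid_days, probs, f"parametric-{fit.family}")
    sol = transition_probabilities(imat, 0.0, t_max, dense=True)
    probs = np.empty((len(grid_days), 5))
    for i, t in enumerate(grid_years):
        if t <= 1e-8:
            probs[i] = np.eye(5)[0]
        else:
            P = _renormalise(sol.sol(t).reshape(5, 5))
            probs[i] = P[0]
    return OccupancyEstimate(np.asarray(grid_days), probs,
                             f"parametric-{fit.family}")


# ---------------------------------------------------------------------------
# asymptotic-normal simulation CIs


def _nearest_psd(V: np.ndarray) -> np.ndarray:
    w, U = np.linalg.eigh(0.5 * (V + V.T))
    if w.min() >= 0:
        return V
    warnings.warn("vcov not positive semi-definite; clipping eigenvalues",
                  RuntimeWarning)
    return (U * np.clip(w, 0.0, None)) @ U.T


def simulate_normal_ci(
    fit: ParametricFit,
    functional: Callable[[np.ndarray], np.ndarray],
    *,
    n_samples: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    level: float = 0.95,
):
    """Percentile CI of a parameter functional under MVN(MLE, vcov).

    ``functional`` receives an unconstrained parameter vector and returns
    an array; sampling is on the unconstrained scale so positivity
    constraints are respected automatically.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    V = _nearest_psd(fit.vcov)
    draws = rng.multivariate_normal(fit.theta, V, size=n_samples,
                                    method="eigh")
    samples = np.stack([np.asarray(functional(d), dtype=float)
                        for d in draws])
    alpha = 100.0 * (1.0 - level) / 2.0
    lo = np.percentile(samples, alpha, axis=0)
    hi = np.percentile(samples, 100.0 - alpha, axis=0)
    return lo, hi


def four_week_matrix(
    fit: ParametricFit,
    profile: Mapping | None = None,
    *,
    days: float = 28.0,
    n_samples: int = 1000,
    seed: int | None = None,
    with_ci: bool = True,
) -> ProbabilityMatrix:
    """P(0, 28 days) with asymptotic-normal simulation CIs per entry."""
    t1 = days / fit.time_scale
    point = transition_probabilities(intensity_matrix(fit, profile), 0.0, t1)

    if not with_ci:
        return point

    def functional(theta):
        alt = _clone_with_theta(fit, theta)
        return transition_probabilities(
            intensity_matrix(alt, profile), 0.0, t1
        ).matrix

    lo, hi = simulate_normal_ci(fit, functional, n_samples=n_samples,
                                seed=seed)
    return ProbabilityMatrix(0.0, t1, point.matrix, lo, hi)


def per_10000(P: np.ndarray) -> np.ndarray:
    """Report a probability matrix per 10,000 patients (plain rounding)."""
    return np.rint(np.asarray(P) * 10000.0).astype(int)


# ---------------------------------------------------------------------------
# patient profiles


def profile_grid(
    age=(55.0, 70.0), fev1pp=(40.0, 55.0), prior_exacs=(1.0, 2.0)
) -> list[dict]:
    """The 2x2x2 grid of patient profiles used for scenario curves."""
    return [
        {"age": a, "fev1pp": f, "prior_exacs": p}
        for a in age for f in fev1pp for p in prior_exacs
    ]


#: cumulative state groupings reported for profile curves
GROUPINGS = {
    "death": (5,),
    "severe_or_death": (4, 5),
    "ge2_moderate_severe_or_death": (3, 4, 5),
    "any_state_ge2": (2, 3, 4, 5),
}


def eight_profiles(
    fit: ParametricFit,
    grid_days: Sequence[float] | None = None,
    **grid_kwargs,
) -> pd.DataFrame:
    """Occupancy-group probabilities for the eight standard profiles.

    Requires a covariate-adjusted fit including FEV1 %-predicted,
    prior-year exacerbations and age.  Returns a tidy frame with one
    row per profile, time and cumulative grouping.
    """
    needed = {"fev1pp", "prior_exacs", "age"}
    fitted_cols = {t.column for t in fit.spec}
    missing = needed - fitted_cols
    if missing:
        raise ValueError(
            f"profile covariates {sorted(missing)} missing from the fit"
        )
    if grid_days is None:
        grid_days = default_grid_days()
    rows = []
    for pid, profile in enumerate(profile_grid(**grid_kwargs), start=1):
        occ = occupancy_curves(fit, profile, grid_days)
        for name, states in GROUPINGS.items():
            probs = occ.probabilities[:, [s - 1 for s in states]].sum(axis=1)
            for t, p in zip(occ.times, probs):
                rows.append({
                    "profile": pid, **profile, "time_days": float(t),
                    "grouping": name, "probability": float(p),
                })
    return pd.DataFrame(rows)
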