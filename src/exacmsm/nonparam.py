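"""Non-parametric reference estimators for the multi-state data.

Four estimators mirror the exploratory analyses of the study:

* Kaplan-Meier curves for death from the time of *entry* to each state
  (the clock resets at state entry; competing exacerbation transitions
  are treated as censorings),
* a Cox model for death with a time-dependent indicator of a prior
  severe exacerbation,
* Nelson-Aalen cumulative transition hazards on the study clock with
  delayed entry (a subject is at risk for exits from state r only from
  the time it enters r),
* the Aalen-Johansen product-integral estimator of state occupancy.

Tied event times on the integer-day scale are aggregated (Breslow
style): the Nelson-Aalen increment at a tie is d/n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import DESTINATIONS, PERMITTED_TRANSITIONS, STATES

__all__ = [
    "StepFunction",
    "OccupancyEstimate",
    "occupancy_table",
    "km_from_state_entry",
    "cox_time_dependent_severe",
    "nelson_aalen",
    "aalen_johansen",
]


@dataclass
class StepFunction:
    """A right-continuous step function given by jump times and values."""

    times: np.ndarray
    values: np.ndarray
    variance: np.ndarray | None = None
    start_value: float = 0.0
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("jump times must be strictly increasing")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            out = np.full(t.shape, self.start_value)
            return out if out.ndim else float(self.start_value)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)],
                       self.start_value)
        return out if out.ndim else float(out)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times, "estimate": self.values})
        if self.variance is not None:
            df["variance"] = self.variance
        if self.label:
            df["label"] = self.label
        return df


@dataclass
class OccupancyEstimate:
    """State occupancy probabilities P(state s at t | state 1 at 0)."""

    times: np.ndarray
    probabilities: np.ndarray      # (len(times), 5)
    estimator: str

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probabilities,
                          columns=[f"state_{s}" for s in STATES])
        df.insert(0, "time", self.times)
        df["estimator"] = self.estimator
        return df


occupancy_table = OccupancyEstimate  # legacy-friendly alias


def _occupancies(dataset: pd.DataFrame) -> pd.DataFrame:
    """One row per (patient, occupied state): entry, exit, realised dest."""
    df = dataset.copy()
    ev_rows = df[df["status"] == "event"]
    dest = ev_rows.set_index(["patient_id", "from_state"])["to_state"]
    occ = (df.groupby(["patient_id", "from_state"])
             .agg(entry=("entry_time", "first"), exit=("exit_time", "max"))
             .reset_index())
    key = list(zip(occ["patient_id"], occ["from_state"]))
    occ["dest"] = [int(dest.get(k, 0)) for k in key]  # 0 = censored
    return occ


def km_from_state_entry(dataset: pd.DataFrame, state: int) -> StepFunction:
    """Kaplan-Meier survival from death, clock reset at entry to ``state``.

    Exacerbation transitions out of the state censor the survival time,
    exactly as in the exploratory by-state-of-entry mortality curves.
    """
    if state not in (1, 2, 3, 4):
        raise ValueError("state must be a transient state 1-4")
    occ = _occupancies(dataset)
    occ = occ[occ["from_state"] == state]
    if not len(occ):
        warnings.warn(f"no entrants to state {state}", RuntimeWarning)
        return StepFunction(np.zeros(0), np.zeros(0), start_value=1.0,
                            label=f"km_state_{state}")
    durations = (occ["exit"] - occ["entry"]).to_numpy()
    died = (occ["dest"] == 5).to_numpy()
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(durations, event_observed=died)
    sf = km.survival_function_
    times = sf.index.to_numpy(dtype=float)
    vals = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = times > 0
    return StepFunction(times[keep], vals[keep], start_value=1.0,
                        label=f"km_state_{state}")


def cox_time_dependent_severe(dataset: pd.DataFrame) -> dict:
    """HR for death after a severe exacerbation, time-dependent indicator.

    The indicator switches from 0 to 1 at the first severe exacerbation
    (entry to state 4) and the partial likelihood uses Breslow ties.
    Returns the hazard ratio with its Wald 95% CI.
    """
    occ = _occupancies(dataset)
    rows = []
    for pid, grp in occ.groupby("patient_id", sort=False):
        grp = grp.sort_values("entry")
        death_time = None
        if (grp["dest"] == 5).any():
            death_time = float(grp.loc[grp["dest"] == 5, "exit"].iloc[0])
        t4 = grp.loc[grp["from_state"] == 4, "entry"]
        t_end = float(grp["exit"].max())
        if len(t4):
            t4 = float(t4.iloc[0])
            if t4 > 0:
                rows.append((pid, 0.0, t4, 0, 0))
            rows.append((pid, t4, t_end, 1, int(death_time is not None)))
        else:
            rows.append((pid, 0.0, t_end, 0, int(death_time is not None)))
    tv = pd.DataFrame(rows, columns=["id", "start", "stop", "severe", "death"])
    if tv["death"].sum() == 0:
        raise ValueError("no deaths observed: hazard ratio is undefined")
    if tv["severe"].nunique() < 2:
        raise ValueError("severe-exacerbation indicator is constant: "
                         "coefficient undefined")
    from lifelines import CoxTimeVaryingFitter
    from lifelines.exceptions import ConvergenceError, ConvergenceWarning

    ctv = None
    err: Exception | str | None = None
    for step_size in (0.95, 0.5, 0.25, 0.1):  # damp Newton when needed
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("error", ConvergenceWarning)
                ctv = CoxTimeVaryingFitter()
                ctv.fit(tv, id_col="id", event_col="death",
                        start_col="start", stop_col="stop",
                        fit_options={"step_size": step_size})
            if abs(float(ctv.params_["severe"])) > 20:
                ctv, err = None, "diverged coefficient"
                continue
            break
        except (ConvergenceError, ConvergenceWarning, ValueError) as e:
            ctv, err = None, e
    if ctv is None:
        raise ValueError(f"time-dependent Cox fit failed: {err}")
    coef = float(ctv.params_["severe"])
    se = float(ctv.standard_errors_["severe"])
    return {
        "hr": float(np.exp(coef)),
        "ci_low": float(np.exp(coef - 1.959963984540054 * se)),
        "ci_high": float(np.exp(coef + 1.959963984540054 * se)),
        "coef": coef,
        "se": se,
        "n_deaths": int(tv["death"].sum()),
    }


def _risk_and_events(occ: pd.DataFrame, times: np.ndarray):
    """n_r(t) and d_rs(t) at each time, with delayed entry."""
    n_at = {}
    d_at = {}
    for r in (1, 2, 3, 4):
        sub = occ[occ["from_state"] == r]
        entries = np.sort(sub["entry"].to_numpy())
        exits = np.sort(sub["exit"].to_numpy())
        # at risk in r at t: entry < t <= exit
        n_at[r] = (np.searchsorted(entries, times, side="left")
                   - np.searchsorted(exits, times, side="left"))
        for s in DESTINATIONS[r]:
            ex = np.sort(sub.loc[sub["dest"] == s, "exit"].to_numpy())
            d_at[(r, s)] = (np.searchsorted(ex, times, side="right")
                            - np.searchsorted(ex, times, side="left"))
    return n_at, d_at


def nelson_aalen(dataset: pd.DataFrame, transition: tuple) -> StepFunction:
    """Nelson-Aalen cumulative hazard of one transition, study clock.

    A(t) = sum over event times t_i <= t of d_i / n_i, where n_i counts
    subjects occupying the origin state just before t_i (left-truncated,
    right-censored risk set) and ties are aggregated.
    """
    transition = tuple(transition)
    if transition not in PERMITTED_TRANSITIONS:
        raise ValueError(f"not a permitted transition: {transition}")
    r, s = transition
    occ = _occupancies(dataset)
    sub = occ[occ["from_state"] == r]
    ev_times = np.unique(sub.loc[sub["dest"] == s, "exit"].to_numpy())
    if ev_times.size == 0:
        return StepFunction(np.zeros(0), np.zeros(0),
                            label=f"na_{r}->{s}")
    n_at, d_at = _risk_and_events(occ, ev_times)
    n = n_at[r].astype(float)
    d = d_at[(r, s)].astype(float)
    inc = d / n
    var = np.cumsum(d / n ** 2)
    return StepFunction(ev_times, np.cumsum(inc), variance=var,
                        label=f"na_{r}->{s}")


def aalen_johansen(
    dataset: pd.DataFrame, grid=None, *, full_matrix: bool = False
):
    """Aalen-Johansen occupancy: product-integral of Nelson-Aalen steps.

    P(0, t) = prod over event times t_i <= t of (I + dA(t_i)), where
    dA(t_i) has off-diagonal d_rs/n_r and rows summing to zero.  Returns
    the first row (everyone starts in state 1) on the requested grid, or
    the full matrix path when ``full_matrix`` is set.
    """
    occ = _occupancies(dataset)
    ev_times = np.unique(occ.loc[occ["dest"] > 0, "exit"].to_numpy())
    n_at, d_at = _risk_and_events(occ, ev_times)

    P = np.eye(5)
    mats = []
    for i, t in enumerate(ev_times):
        dA = np.zeros((5, 5))
        for r in (1, 2, 3, 4):
            n = n_at[r][i]
            if n <= 0:
                continue
            for s in DESTINATIONS[r]:
                d = d_at[(r, s)][i]
                if d:
                    dA[r - 1, s - 1] = d / n
            dA[r - 1, r - 1] = -dA[r - 1].sum()
        P = P @ (np.eye(5) + dA)
        mats.append(P.copy())

    if grid is None:
        grid = ev_times
    grid = np.asarray(grid, dtype=float)
    idx = np.searchsorted(ev_times, grid, side="right") - 1
    out = np.empty((len(grid), 5, 5))
    for j, i in enumerate(idx):
        out[j] = np.eye(5) if i < 0 else mats[i]
    if full_matrix:
        return grid, out
    return OccupancyEstimate(grid, out[:, 0, :], "aalen-johansen")
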