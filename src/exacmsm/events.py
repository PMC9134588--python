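"""Event-history preparation for the five-state exacerbation/death process.

Raw trial records (exacerbation episodes, death/censoring, baseline
covariates) are converted into a progressive multi-state dataset over the
states

    1  no exacerbation since study start
    2  one moderate exacerbation (no severe)
    3  two or more moderate exacerbations (no severe)
    4  one or more severe exacerbations
    5  death

Only forward moves are allowed, jumps may skip states, but a direct
1 -> 3 jump is impossible by construction (a second moderate episode
requires a first).  The output is a long-format counting-process table
with delayed entry: one row per occupied state and permitted exit, on the
study-time clock (clock-forward), which is the common input of every
fitting module.

Time convention
---------------
Day numbers are used directly as the time coordinate (day 1 = first
treatment day, study start = time 0).  Two adjustments keep all sojourns
strictly positive:

* an episode starting on day 1 enters the new state at t = 0.5 (the
  State-1 sojourn has length zero on the day scale);
* a death on the same day as the current state's entry is offset to
  entry + 0.5, ordering the exacerbation before the death.

Deaths more than 30 days after the last day of treatment are treated as
censorings at ``last_treatment_day + 30``.  Exacerbation transitions are
censored at ``last_treatment_day``; the death transition is followed for
the extra 30-day window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STATES",
    "PERMITTED_TRANSITIONS",
    "EXACERBATION_TRANSITIONS",
    "DEATH_TRANSITIONS",
    "EventRecord",
    "Episode",
    "StatePath",
    "merge_episodes",
    "build_state_path",
    "paths_to_transition_dataset",
    "cohort_to_paths",
    "cohort_to_transition_dataset",
    "transition_counts",
    "death_percentages",
    "read_events",
    "read_outcomes",
    "read_baseline",
]

STATES = (1, 2, 3, 4, 5)

#: permitted (from, to) moves of the progressive process
PERMITTED_TRANSITIONS = (
    (1, 2), (1, 4), (1, 5),
    (2, 3), (2, 4), (2, 5),
    (3, 4), (3, 5),
    (4, 5),
)

DEATH_TRANSITIONS = tuple(t for t in PERMITTED_TRANSITIONS if t[1] == 5)
EXACERBATION_TRANSITIONS = tuple(t for t in PERMITTED_TRANSITIONS if t[1] != 5)

#: exits available from each transient state
DESTINATIONS = {
    1: (2, 4, 5),
    2: (3, 4, 5),
    3: (4, 5),
    4: (5,),
}

#: episodes closer than this many days (end to next start) are one event
EPISODE_GAP_DAYS = 7

#: deaths beyond this many days after last treatment are censored
DEATH_WINDOW_DAYS = 30

MODERATE = "moderate"
SEVERE = "severe"
_SEVERITY_RANK = {MODERATE: 0, SEVERE: 1}


class ValidationError(ValueError):
    """Raised when input records violate the process structure."""


@dataclass(frozen=True)
class EventRecord:
    """A raw exacerbation interval as recorded in the trial database."""

    patient_id: str
    start_day: int
    end_day: int
    severity: str

    def __post_init__(self) -> None:
        if self.severity not in _SEVERITY_RANK:
            raise ValidationError(
                f"patient {self.patient_id}: unknown severity {self.severity!r}"
            )
        if self.start_day < 1:
            raise ValidationError(
                f"patient {self.patient_id}: start_day {self.start_day} < 1"
            )
        if self.end_day < self.start_day:
            raise ValidationError(
                f"patient {self.patient_id}: event ({self.start_day}, "
                f"{self.end_day}) has end before start"
            )


@dataclass(frozen=True)
class Episode:
    """A distinct exacerbation episode after merging nearby records."""

    patient_id: str
    start_day: int
    end_day: int
    severity: str


@dataclass
class StatePath:
    """A patient's ordered walk through the five states.

    ``visits`` holds (state, entry time) pairs starting with (1, 0.0);
    ``terminal`` is ``"death"`` or ``"censored"`` at ``terminal_time``.
    """

    patient_id: str
    visits: list[tuple[int, float]]
    terminal: str
    terminal_time: float
    last_treatment_day: float = np.inf

    def states(self) -> list[int]:
        return [s for s, _ in self.visits]

    def final_state(self) -> int:
        return self.visits[-1][0]

    def validate(self) -> None:
        states = self.states()
        times = [t for _, t in self.visits]
        if states[0] != 1 or times[0] != 0.0:
            raise ValidationError(
                f"patient {self.patient_id}: path must start in state 1 at t=0"
            )
        for (a, b) in zip(states, states[1:]):
            if b <= a:
                raise ValidationError(
                    f"patient {self.patient_id}: non-increasing states {a}->{b}"
                )
            if (a, b) not in PERMITTED_TRANSITIONS:
                raise ValidationError(
                    f"patient {self.patient_id}: forbidden transition {a}->{b}"
                )
        if any(t1 < t0 for t0, t1 in zip(times, times[1:])):
            raise ValidationError(
                f"patient {self.patient_id}: entry times decrease along path"
            )
        if 5 in states and states[-1] != 5:
            raise ValidationError(
                f"patient {self.patient_id}: state 5 must be terminal"
            )
        if self.terminal_time < times[-1]:
            raise ValidationError(
                f"patient {self.patient_id}: terminal day {self.terminal_time} "
                f"precedes last state entry {times[-1]}"
            )


def merge_episodes(events: Sequence[EventRecord]) -> list[Episode]:
    """Collapse raw exacerbation records into distinct episodes.

    Records whose gap (next start minus previous end) is <= 7 days belong
    to the same episode; a gap must be strictly greater than 7 days to
    start a new one.  A merged episode spans the earliest start to the
    latest end and takes the maximum severity of its constituents.
    """
    if not events:
        return []
    pids = {e.patient_id for e in events}
    if len(pids) > 1:
        raise ValidationError(f"merge_episodes mixes patients: {sorted(pids)}")
    recs = sorted(events, key=lambda e: (e.start_day, e.end_day))
    merged: list[list] = [[recs[0].start_day, recs[0].end_day, recs[0].severity]]
    for rec in recs[1:]:
        start, end, sev = merged[-1]
        if rec.start_day - end <= EPISODE_GAP_DAYS:
            merged[-1][1] = max(end, rec.end_day)
            if _SEVERITY_RANK[rec.severity] > _SEVERITY_RANK[sev]:
                merged[-1][2] = rec.severity
        else:
            merged.append([rec.start_day, rec.end_day, rec.severity])
    pid = recs[0].patient_id
    return [Episode(pid, s, e, sev) for s, e, sev in merged]


def _episode_time(start_day: int) -> float:
    # day-1 episodes are assigned immediately after study start
    return 0.5 if start_day == 1 else float(start_day)


def build_state_path(
    episodes: Sequence[Episode],
    *,
    death_day: float | None = None,
    censor_day: float | None = None,
    last_treatment_day: float | None = None,
) -> StatePath:
    """Derive the state path of one patient from merged episodes.

    State moves happen at episode start days: a moderate episode moves
    1 -> 2 or 2 -> 3 (further moderates in state 3 are absorbed), a severe
    episode moves any of states 1-3 to state 4.  Death within 30 days of
    the last treatment day ends the path in state 5; later deaths are
    censorings at ``last_treatment_day + 30``.
    """
    if (death_day is None) == (censor_day is None):
        raise ValidationError("exactly one of death_day/censor_day is required")
    if episodes:
        pid = episodes[0].patient_id
    else:
        pid = ""
    if last_treatment_day is None:
        last_treatment_day = death_day if death_day is not None else censor_day

    visits: list[tuple[int, float]] = [(1, 0.0)]
    state = 1
    for ep in sorted(episodes, key=lambda e: e.start_day):
        if ep.start_day > last_treatment_day:
            continue  # off-treatment event, outside the modelled process
        if ep.severity == SEVERE and state < 4:
            new_state = 4
        elif ep.severity == MODERATE and state == 1:
            new_state = 2
        elif ep.severity == MODERATE and state == 2:
            new_state = 3
        else:
            continue  # absorbed: repeat moderates in 3, anything in 4
        visits.append((new_state, _episode_time(ep.start_day)))
        state = new_state

    if death_day is not None:
        if death_day <= last_treatment_day + DEATH_WINDOW_DAYS:
            t_death = float(death_day)
            if t_death <= visits[-1][1]:
                if t_death < visits[-1][1]:
                    raise ValidationError(
                        f"patient {pid}: death day {death_day} precedes last "
                        f"episode at t={visits[-1][1]}"
                    )
                t_death = visits[-1][1] + 0.5  # same-day tie: event first
            path = StatePath(pid, visits + [(5, t_death)], "death", t_death,
                             float(last_treatment_day))
            path.validate()
            return path
        terminal_time = float(last_treatment_day) + DEATH_WINDOW_DAYS
    else:
        terminal_time = float(min(censor_day, last_treatment_day))
    if terminal_time < visits[-1][1]:
        raise ValidationError(
            f"patient {pid}: censoring at {terminal_time} precedes last "
            f"episode at t={visits[-1][1]}"
        )
    path = StatePath(pid, visits, "censored", terminal_time,
                     float(last_treatment_day))
    path.validate()
    return path


_DATASET_COLUMNS = [
    "patient_id", "from_state", "to_state",
    "entry_time", "exit_time", "status",
]


def paths_to_transition_dataset(
    paths: Iterable[StatePath],
    covariates: pd.DataFrame | None = None,
    *,
    require_complete: bool = True,
) -> pd.DataFrame:
    """Expand state paths into the long-format transition dataset.

    For each visited transient state ``r`` and each permitted move
    ``r -> s`` one row is emitted with delayed entry at the time of
    entering ``r`` and exit at the time of leaving it; ``status`` is
    ``"event"`` for the realised destination and ``"censored"`` otherwise.
    Exacerbation rows of the final sojourn are censored at the last
    treatment day, the death row at the terminal time.

    If ``covariates`` is given (indexed or keyed by ``patient_id``),
    patients with any missing value are dropped from the output and the
    number dropped is reported via the returned frame's
    ``attrs["n_dropped_missing_covariates"]``.
    """
    cov = None
    dropped = 0
    if covariates is not None:
        cov = covariates.copy()
        if "patient_id" in cov.columns:
            cov = cov.set_index("patient_id")
        incomplete = cov.index[cov.isna().any(axis=1)]
        dropped = len(incomplete)
        cov = cov.drop(index=incomplete)

    rows: list[tuple] = []
    for path in paths:
        path.validate()
        if cov is not None and path.patient_id not in cov.index:
            continue
        visits = path.visits
        for i, (state, t_in) in enumerate(visits):
            if state == 5:
                break
            is_last = i == len(visits) - 1
            if not is_last:
                t_out = visits[i + 1][1]
                realised = visits[i + 1][0]
                for dest in DESTINATIONS[state]:
                    status = "event" if dest == realised else "censored"
                    rows.append((path.patient_id, state, dest,
                                 t_in, t_out, status))
            else:
                for dest in DESTINATIONS[state]:
                    if dest == 5:
                        t_out = path.terminal_time
                    else:
                        t_out = min(path.terminal_time, path.last_treatment_day)
                    if t_out <= t_in:
                        continue  # zero-exposure censored row
                    rows.append((path.patient_id, state, dest,
                                 t_in, t_out, "censored"))
    df = pd.DataFrame(rows, columns=_DATASET_COLUMNS)
    if cov is not None and len(df):
        df = df.join(cov, on="patient_id")
    df.attrs["n_dropped_missing_covariates"] = dropped
    return df


def cohort_to_paths(
    events: pd.DataFrame, outcomes: pd.DataFrame
) -> list[StatePath]:
    """Run the full raw-record pipeline: merge, then path derivation."""
    ev_by_pid: dict = {}
    for row in events.itertuples(index=False):
        rec = EventRecord(str(row.patient_id), int(row.start_day),
                          int(row.end_day), str(row.severity))
        ev_by_pid.setdefault(rec.patient_id, []).append(rec)
    paths = []
    for row in outcomes.itertuples(index=False):
        pid = str(row.patient_id)
        episodes = merge_episodes(ev_by_pid.get(pid, []))
        death = getattr(row, "death_day", None)
        censor = getattr(row, "censor_day", None)
        death = None if death is None or pd.isna(death) else float(death)
        censor = None if censor is None or pd.isna(censor) else float(censor)
        path = build_state_path(
            episodes,
            death_day=death,
            censor_day=censor,
            last_treatment_day=float(row.last_treatment_day),
        )
        path.patient_id = pid
        paths.append(path)
    return paths


def cohort_to_transition_dataset(
    events: pd.DataFrame,
    outcomes: pd.DataFrame,
    baseline: pd.DataFrame | None = None,
) -> pd.DataFrame:
    return paths_to_transition_dataset(cohort_to_paths(events, outcomes),
                                       covariates=baseline)


def transition_counts(dataset: pd.DataFrame) -> dict:
    """Tally realised transitions and deaths by the state they came from.

    Returns a dict with a 5x5 ``counts`` frame of observed events, a
    ``deaths_by_state`` frame (count and percentage of all deaths by the
    occupied state at death) and the total number of patients at risk.
    """
    counts = pd.DataFrame(
        0, index=list(STATES), columns=list(STATES), dtype=int
    )
    if len(dataset):
        ev = dataset[dataset["status"] == "event"]
        tally = ev.groupby(["from_state", "to_state"]).size()
        for (r, s), n in tally.items():
            counts.loc[r, s] = int(n)
    deaths = counts[5]
    total_deaths = int(deaths.sum())
    pct = 100.0 * deaths / total_deaths if total_deaths else deaths * 0.0
    deaths_by_state = pd.DataFrame(
        {"deaths": deaths[:4], "percent": pct[:4].round(1)}
    )
    return {
        "counts": counts,
        "deaths_by_state": deaths_by_state,
        "total_deaths": total_deaths,
        "n_patients": dataset["patient_id"].nunique() if len(dataset) else 0,
    }


def death_percentages(
    total_deaths: int, deaths_after_any_exac: int, deaths_after_severe: int
) -> dict[str, float]:
    """Percentage breakdown of deaths by prior exacerbation experience.

    Deaths without any prior exacerbation are the complement of deaths
    after at least one moderate or severe exacerbation.
    """
    if not (0 <= deaths_after_severe <= deaths_after_any_exac <= total_deaths):
        raise ValidationError("death counts must be nested and non-negative")
    if total_deaths == 0:
        return {"no_prior_exacerbation": 0.0, "after_any_exacerbation": 0.0,
                "after_severe_exacerbation": 0.0}
    f = 100.0 / total_deaths
    return {
        "no_prior_exacerbation": round((total_deaths - deaths_after_any_exac) * f, 1),
        "after_any_exacerbation": round(deaths_after_any_exac * f, 1),
        "after_severe_exacerbation": round(deaths_after_severe * f, 1),
    }


# ---------------------------------------------------------------------------
# delimited-text I/O


def read_events(path, delimiter: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter,
                     dtype={"patient_id": str, "severity": str})
    _require(df, ["patient_id", "start_day", "end_day", "severity"], path)
    return df


def read_outcomes(path, delimiter: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, dtype={"patient_id": str})
    _require(df, ["patient_id", "last_treatment_day"], path)
    for col in ("death_day", "censor_day"):
        if col not in df.columns:
            df[col] = np.nan
    return df


def read_baseline(path, delimiter: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, dtype={"patient_id": str})
    _require(df, ["patient_id"], path)
    return df


def _require(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def counts_summary_json(dataset: pd.DataFrame) -> str:
    """JSON rendering of `transition_counts` for the report bundle."""
    res = transition_counts(dataset)
    payload = {
        "n_patients": int(res["n_patients"]),
        "total_deaths": int(res["total_deaths"]),
        "events": {
            f"{r}->{s}": int(res["counts"].loc[r, s])
            for (r, s) in PERMITTED_TRANSITIONS
        },
        "deaths_by_state": {
            str(r): {
                "deaths": int(res["deaths_by_state"].loc[r, "deaths"]),
                "percent": float(res["deaths_by_state"].loc[r, "percent"]),
            }
            for r in (1, 2, 3, 4)
        },
    }
    return json.dumps(payload, indent=2, sort_keys=True)
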