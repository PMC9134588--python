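"""Event processing: episode merging, state paths, long-format datasets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exacmsm import events as ev


def rec(pid, start, end, sev="moderate"):
    return ev.EventRecord(pid, start, end, sev)


class TestMergeEpisodes:
    @pytest.mark.parametrize(
        "records, expected",
        [
            # gap of exactly 7 days is NOT a new episode (rule is > 7)
            ([("A", 3, 10, "moderate"), ("A", 17, 20, "moderate")],
             [(3, 20, "moderate")]),
            ([], []),
            # gap of 8 days: two episodes, severities preserved
            ([("A", 3, 10, "moderate"), ("A", 18, 20, "severe")],
             [(3, 10, "moderate"), (18, 20, "severe")]),
            # overlap/merge takes the maximum severity
            ([("A", 3, 10, "moderate"), ("A", 12, 14, "severe")],
             [(3, 14, "severe")]),
        ],
    )
    def test_gap_rule_and_severity(self, records, expected):
        out = ev.merge_episodes([rec(*r) for r in records])
        assert [(e.start_day, e.end_day, e.severity) for e in out] == expected

    def test_invalid_interval_names_offender(self):
        with pytest.raises(ev.ValidationError, match="end before start"):
            rec("A", 10, 3)

    def test_mixed_patients_rejected(self):
        with pytest.raises(ev.ValidationError, match="mixes patients"):
            ev.merge_episodes([rec("A", 1, 2), rec("B", 1, 2)])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(1, 300), st.integers(0, 15),
                  st.sampled_from(["moderate", "severe"])),
        max_size=12,
    ))
    def test_output_invariants(self, raw):
        records = [rec("A", s, s + w, sev) for s, w, sev in raw]
        out = ev.merge_episodes(records)
        starts = [e.start_day for e in out]
        assert starts == sorted(starts)
        for a, b in zip(out, out[1:]):
            assert b.start_day - a.end_day > 7
        # total covered days never shrinks and severities are maxima
        if records:
            assert min(e.start_day for e in out) == min(
                r.start_day for r in records)
            assert max(e.end_day for e in out) == max(
                r.end_day for r in records)
            n_severe_in = sum(r.severity == "severe" for r in records)
            n_severe_out = sum(e.severity == "severe" for e in out)
            assert (n_severe_out > 0) == (n_severe_in > 0)


class TestBuildStatePath:
    def test_full_progression(self):
        eps = [
            ev.Episode("A", 56, 63, "moderate"),
            ev.Episode("A", 168, 175, "moderate"),
            ev.Episode("A", 196, 203, "severe"),
        ]
        path = ev.build_state_path(eps, death_day=280, last_treatment_day=280)
        assert path.visits == [(1, 0.0), (2, 56.0), (3, 168.0),
                               (4, 196.0), (5, 280.0)]
        assert path.terminal == "death"

    def test_no_events_censored(self):
        path = ev.build_state_path([], censor_day=364, last_treatment_day=364)
        assert path.visits == [(1, 0.0)]
        assert path.terminal == "censored" and path.terminal_time == 364

    def test_day_one_severe_direct_jump(self):
        eps = [ev.Episode("A", 1, 8, "severe")]
        path = ev.build_state_path(eps, censor_day=200,
                                   last_treatment_day=200)
        assert [s for s, _ in path.visits] == [1, 4]
        assert path.visits[1][1] == 0.5  # immediate assignment, offset

    def test_death_without_exacerbation(self):
        path = ev.build_state_path([], death_day=200, last_treatment_day=200)
        assert [s for s, _ in path.visits] == [1, 5]

    def test_late_death_becomes_censoring(self):
        # death 31+ days after last treatment day is censored at ltd + 30
        path = ev.build_state_path([], death_day=300, last_treatment_day=250)
        assert path.terminal == "censored"
        assert path.terminal_time == 280

    def test_moderate_in_state3_absorbed(self):
        eps = [ev.Episode("A", d, d + 7, "moderate") for d in (30, 60, 90)]
        path = ev.build_state_path(eps, censor_day=364,
                                   last_treatment_day=364)
        assert [s for s, _ in path.visits] == [1, 2, 3]

    def test_terminal_before_last_episode_rejected(self):
        eps = [ev.Episode("A", 100, 107, "moderate")]
        with pytest.raises(ev.ValidationError, match="precede"):
            ev.build_state_path(eps, censor_day=50, last_treatment_day=364)


class TestTransitionDataset:
    def test_competing_risks_long_format(self):
        path = ev.StatePath("A", [(1, 0.0), (2, 56.0)], "censored", 364.0,
                            364.0)
        df = ev.paths_to_transition_dataset([path])
        got = {(r.from_state, r.to_state): (r.entry_time, r.exit_time,
                                            r.status)
               for r in df.itertuples()}
        assert got == {
            (1, 2): (0.0, 56.0, "event"),
            (1, 4): (0.0, 56.0, "censored"),
            (1, 5): (0.0, 56.0, "censored"),
            (2, 3): (56.0, 364.0, "censored"),
            (2, 4): (56.0, 364.0, "censored"),
            (2, 5): (56.0, 364.0, "censored"),
        }

    def test_never_leaving_state1(self):
        path = ev.StatePath("A", [(1, 0.0)], "censored", 364.0, 364.0)
        df = ev.paths_to_transition_dataset([path])
        assert len(df) == 3
        assert (df["status"] == "censored").all()
        assert (df["exit_time"] == 364.0).all()

    def test_same_day_severe_and_death_tie(self):
        eps = [ev.Episode("A", 100, 107, "severe")]
        path = ev.build_state_path(eps, death_day=100,
                                   last_treatment_day=100)
        assert path.visits == [(1, 0.0), (4, 100.0), (5, 100.5)]
        df = ev.paths_to_transition_dataset([path])
        row = df[(df.from_state == 4) & (df.to_state == 5)].iloc[0]
        assert (row.entry_time, row.exit_time, row.status) == \
            (100.0, 100.5, "event")

    def test_forbidden_path_rejected(self):
        path = ev.StatePath("A", [(1, 0.0), (3, 50.0)], "censored",
                            364.0, 364.0)
        with pytest.raises(ev.ValidationError, match="forbidden"):
            ev.paths_to_transition_dataset([path])

    def test_missing_covariates_drop_patient(self):
        paths = [
            ev.StatePath("A", [(1, 0.0)], "censored", 364.0, 364.0),
            ev.StatePath("B", [(1, 0.0)], "censored", 364.0, 364.0),
        ]
        cov = pd.DataFrame({"patient_id": ["A", "B"],
                            "age": [60.0, np.nan]})
        df = ev.paths_to_transition_dataset(paths, covariates=cov)
        assert set(df["patient_id"]) == {"A"}
        assert df.attrs["n_dropped_missing_covariates"] == 1

    def test_no_one_three_rows_exist(self, dataset):
        assert not ((dataset.from_state == 1) & (dataset.to_state == 3)).any()

    def test_one_event_row_per_state_change(self, dataset, cohort):
        n_changes = sum(len(seq) - 1 for seq in cohort.state_sequences)
        assert (dataset["status"] == "event").sum() == n_changes


class TestCounts:
    def test_hand_tally(self):
        paths = [
            ev.StatePath("A", [(1, 0.0), (2, 10.0), (4, 30.0), (5, 60.0)],
                         "death", 60.0, 60.0),
            ev.StatePath("B", [(1, 0.0), (5, 20.0)], "death", 20.0, 20.0),
            ev.StatePath("C", [(1, 0.0)], "censored", 364.0, 364.0),
        ]
        res = ev.transition_counts(ev.paths_to_transition_dataset(paths))
        c = res["counts"]
        assert c.loc[1, 2] == 1 and c.loc[2, 4] == 1 and c.loc[4, 5] == 1
        assert c.loc[1, 5] == 1 and res["total_deaths"] == 2
        assert res["deaths_by_state"].loc[1, "percent"] == 50.0
        assert res["deaths_by_state"].loc[4, "percent"] == 50.0

    def test_empty_dataset_all_zero(self):
        res = ev.transition_counts(ev.paths_to_transition_dataset([]))
        assert res["counts"].to_numpy().sum() == 0
        assert res["total_deaths"] == 0

    def test_death_percentage_breakdown(self):
        pct = ev.death_percentages(134, 76, 42)
        assert pct["after_severe_exacerbation"] == 31.3
        assert pct["after_any_exacerbation"] == 56.7
        assert pct["no_prior_exacerbation"] == 43.3

    def test_death_percentages_validate_nesting(self):
        with pytest.raises(ev.ValidationError):
            ev.death_percentages(100, 40, 60)


class TestRoundTrip:
    def test_simulator_output_reprocesses_identically(self, cohort):
        paths = ev.cohort_to_paths(cohort.events, cohort.outcomes)
        derived = {p.patient_id: p.visits for p in paths}
        pids = cohort.baseline["patient_id"].tolist()
        for pid, seq in zip(pids, cohort.state_sequences):
            assert derived[pid] == seq, pid

    def test_internal_tally_matches_dataset_counts(self, cohort, dataset):
        res = ev.transition_counts(dataset)
        for (r, s), n in cohort.transition_tally.items():
            assert res["counts"].loc[r, s] == n

    def test_merging_is_identity_on_simulator_output(self, cohort):
        for pid, grp in cohort.events.groupby("patient_id"):
            recs = [ev.EventRecord(pid, int(r.start_day), int(r.end_day),
                                   r.severity)
                    for r in grp.itertuples()]
            merged = ev.merge_episodes(recs)
            assert len(merged) == len(recs)
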