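"""Threshold scoring: eligibility, transition labels, bimonthly aggregation,
alert events and reporting volume, checked against hand counts and an
independent pure-python recount."""

import io

import pandas as pd
import pytest

from carealert.cohort import generate_cohort, write_checkins
from carealert.config import CohortConfig
from carealert.errors import DataError
from carealert.scoring import (
    aggregate_bimonthly,
    emit_alerts,
    filter_eligible,
    label_transitions,
    per_caregiver_volume,
    pretest_first_checkin_tables,
)
from helpers import brute_force_recount, checkin_rows, frame, stream


def _transition(df, symptom, k):
    row = df[(df["symptom"] == symptom) & (df["checkin_index"] == k)]
    assert len(row) == 1
    return row.iloc[0]


def test_transition_labels_follow_the_improvement_definition():
    """pain 9 then 8 and pain 7 then 6 are improved; a tie is not; the last
    check-in is terminal because nothing follows it."""
    rows = stream(
        "D1",
        "CONTROL",
        [
            {"pain": 9, "nausea": 7, "fatigue": 5},
            {"pain": 8, "nausea": 7, "fatigue": 9},
            {"pain": 7, "nausea": 6},
            {"pain": 6},
        ],
    )
    t = label_transitions(frame(rows))
    first = _transition(t, "pain", 1)
    assert first["is_threshold"] and first["transition"] == "IMPROVED"
    third = _transition(t, "pain", 3)
    assert third["is_threshold"] and third["transition"] == "IMPROVED"
    tie = _transition(t, "nausea", 1)
    assert tie["is_threshold"] and tie["transition"] == "SAME"
    worse = _transition(t, "fatigue", 1)
    assert not worse["is_threshold"] and worse["transition"] == "WORSENED"
    last = _transition(t, "pain", 4)
    assert last["transition"] == "TERMINAL"


def test_transitions_pair_consecutive_online_checkins_despite_gaps():
    """next_rating is the next *online* check-in regardless of calendar gap."""
    rows = checkin_rows("D1", "CONTROL", 1, 7, "ONLINE", {"pain": 8})
    rows += checkin_rows("D1", "CONTROL", 2, 49, "ONLINE", {"pain": 5})
    t = label_transitions(frame(rows))
    assert _transition(t, "pain", 1)["transition"] == "IMPROVED"


def test_duplicate_observation_is_a_data_error():
    rows = checkin_rows("D1", "CONTROL", 1, 7, "ONLINE")
    with pytest.raises(DataError, match="duplicate"):
        label_transitions(frame(rows + rows))


def test_eligibility_drops_single_checkin_caregivers_but_keeps_pretests():
    rows = stream("D1", "CONTROL", [{"pain": 5}], pretest={"pain": 9})
    rows += stream("D2", "ALERT", [{}, {}], pretest={})
    kept, log = filter_eligible(frame(rows))
    assert set(log["dyad_id"]) == {"D1"}
    d1 = kept[kept["dyad_id"] == "D1"]
    assert set(d1["source"]) == {"PRETEST"}
    assert len(kept[kept["dyad_id"] == "D2"]) == 30


def test_eligibility_is_identity_when_all_dyads_qualify(small_cohort):
    kept, log = filter_eligible(small_cohort)
    assert len(log) == 0
    pd.testing.assert_frame_equal(kept, small_cohort)


def test_hand_counted_bimonthly_aggregate():
    """One dyad, check-ins at days 7 and 14, one threshold symptom rated 8
    then 5: period 1 assesses 20 symptoms, 1 threshold, 1 improved."""
    rows = stream("D1", "CONTROL", [{"pain": 8}, {"pain": 5}])
    idx = aggregate_bimonthly(label_transitions(frame(rows)))
    p1 = idx[(idx["arm"] == "CONTROL") & (idx["period"] == "1")].iloc[0]
    assert p1["n_assessed"] == 20
    assert p1["n_threshold"] == 1
    assert p1["n_improved"] == 1
    assert p1["n_same"] == 0 and p1["n_worsened"] == 0


def test_cohort_without_thresholds_counts_only_assessed(small_cohort):
    low = small_cohort.copy()
    low["rating"] = low["rating"].clip(upper=5)
    idx = aggregate_bimonthly(label_transitions(low))
    assert (idx["n_threshold"] == 0).all()
    total = idx[idx["period"] == "ALL"]["n_assessed"].sum()
    assert total == (low["source"] == "ONLINE").sum()


def test_terminal_policy_include_vs_exclude():
    """A threshold rating at the final check-in counts as 'same' under the
    include policy and vanishes from the threshold count under exclude."""
    rows = stream("D1", "CONTROL", [{"pain": 8}, {"pain": 9}])
    t = label_transitions(frame(rows))
    inc = aggregate_bimonthly(t, terminal_policy="include")
    exc = aggregate_bimonthly(t, terminal_policy="exclude")
    inc1 = inc[inc["period"] == "1"].iloc[0]
    exc1 = exc[exc["period"] == "1"].iloc[0]
    assert inc1["n_threshold"] == 2 and inc1["n_same"] == 1
    assert inc1["n_worsened"] == 1
    assert exc1["n_threshold"] == 1 and exc1["n_same"] == 0
    # assessed count never changes
    assert inc1["n_assessed"] == exc1["n_assessed"] == 20


@pytest.mark.parametrize("policy", ["include", "exclude"])
def test_partition_and_bounds_invariants(small_cohort, policy):
    idx = aggregate_bimonthly(label_transitions(small_cohort), terminal_policy=policy)
    assert (
        idx["n_improved"] + idx["n_same"] + idx["n_worsened"] == idx["n_threshold"]
    ).all()
    assert (idx["n_threshold"] <= idx["n_assessed"]).all()
    assert (idx["n_assessed"] % 10 == 0).all()


@pytest.mark.parametrize("policy", ["include", "exclude"])
@pytest.mark.parametrize("seed", [0, 1])
def test_aggregation_matches_independent_recount(policy, seed):
    """On tiny cohorts the pandas aggregation must agree exactly with a
    brute-force recount written directly over the CSV rows."""
    cfg = CohortConfig(
        n_dyads_per_arm=2,
        study_days=120,
        attrition_hazard_per_checkin=0.05,
        bias_report_prob=0.8,
        seed=seed,
    )
    df = generate_cohort(cfg)
    buf = io.StringIO()
    write_checkins(df, buf)
    oracle = brute_force_recount(buf.getvalue(), terminal_policy=policy)
    kept, _ = filter_eligible(df)
    idx = aggregate_bimonthly(label_transitions(kept), terminal_policy=policy)
    for _, row in idx.iterrows():
        cell = oracle.get((row["arm"], row["period"]), {})
        for col in ("n_assessed", "n_threshold", "n_improved", "n_same", "n_worsened"):
            assert row[col] == cell.get(col, 0), (row["arm"], row["period"], col)


def test_online_day_must_be_positive():
    rows = checkin_rows("D1", "CONTROL", 1, 0, "ONLINE")
    rows += checkin_rows("D1", "CONTROL", 2, 7, "ONLINE")
    t = label_transitions(frame(rows))
    with pytest.raises(DataError, match="day"):
        aggregate_bimonthly(t)


def test_alert_events_list_all_symptoms_of_concern():
    rows = checkin_rows("D1", "ALERT", 1, 7, "ONLINE", {"pain": 7, "nausea": 9})
    rows += checkin_rows("D1", "ALERT", 2, 14, "ONLINE", {"pain": 6})
    rows += checkin_rows("D2", "CONTROL", 1, 7, "ONLINE", {"pain": 10})
    alerts = emit_alerts(frame(rows))
    assert len(alerts) == 2
    assert set(alerts["symptom"]) == {"pain", "nausea"}
    assert (alerts["day"] == 7).all()
    # control-arm reports never alert anyone
    assert not (alerts["dyad_id"] == "D2").any()


def test_every_alert_arm_threshold_observation_has_an_alert_row(small_cohort):
    t = label_transitions(small_cohort)
    hot = t[(t["arm"] == "ALERT") & t["is_threshold"]]
    alerts = emit_alerts(small_cohort)
    merged = hot.merge(alerts, on=["dyad_id", "day", "symptom"], how="left")
    assert merged["rating_y"].notna().all()
    assert len(alerts) == len(hot)


def test_per_caregiver_volume_counts_ten_per_checkin():
    rows = stream("D1", "CONTROL", [{}, {}, {}])
    rows += stream("D2", "ALERT", [{}])
    vol = per_caregiver_volume(frame(rows))
    vol = vol.set_index("arm")
    assert vol.loc["CONTROL", "mean_symptoms_per_caregiver"] == 30
    assert vol.loc["ALERT", "total_symptoms"] == 10


def test_pretest_pairing_uses_first_online_checkin():
    rows = stream(
        "D1", "ALERT", [{"pain": 3, "nausea": 8}, {"pain": 9}], pretest={"pain": 9}
    )
    tables = pretest_first_checkin_tables(frame(rows))
    t = tables["ALERT"]
    # pain: threshold at pretest only; nausea: at first check-in only
    assert t.n_pre_only == 1 and t.n_post_only == 1
    assert t.n_both == 0 and t.n_neither == 8
    assert t.n_total == 10
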