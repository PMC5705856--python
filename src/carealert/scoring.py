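"""Threshold-symptom scoring of check-in streams.

Turns long-format check-in tables into the three counts the trial analysis
runs on, aggregated per arm and 2-month period:

* assessed symptoms  -- 10 per completed check-in;
* threshold symptoms -- individual ratings >= 7;
* improved / same / worsened threshold symptoms -- a threshold symptom is
  *improved* when the same symptom is rated strictly lower at the
  immediately following completed online check-in, regardless of the
  calendar gap between them.

A symptom observation at a dyad's last online check-in has no follow-up and
is labelled TERMINAL.  Two bookkeeping policies are supported for terminal
threshold observations: ``include`` (the default) keeps them in the
threshold count and tallies them under "same"; ``exclude`` drops them from
the threshold count and the improvement denominator (the assessed count is
never affected).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ALERT, ONLINE, PRETEST, ALERT_THRESHOLD
from .errors import DataError

logger = logging.getLogger(__name__)

IMPROVED = "IMPROVED"
SAME = "SAME"
WORSENED = "WORSENED"
TERMINAL = "TERMINAL"

N_PERIODS = 6
ALL_PERIODS = "ALL"


@dataclass(frozen=True)
class PairedChangeCounts:
    """2x2 cross-classification of symptom observations for one arm:
    threshold status at pretest x threshold status at first online check-in.
    """

    n_both: int  # threshold at pretest and at first check-in
    n_pre_only: int  # threshold at pretest only (shift toward fewer)
    n_post_only: int  # threshold at first check-in only
    n_neither: int

    def __post_init__(self):
        for f in (self.n_both, self.n_pre_only, self.n_post_only, self.n_neither):
            if f < 0:
                raise DataError("cell counts must be nonnegative")

    @property
    def n_total(self) -> int:
        return self.n_both + self.n_pre_only + self.n_post_only + self.n_neither


def filter_eligible(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop online records of caregivers with fewer than two online check-ins.

    Such caregivers supply no before/after pair to compare.  Pretest records
    are always retained (the response-bias analysis needs them).  Returns the
    filtered table and an exclusion log with one row per excluded dyad.
    """
    online = records[records["source"] == ONLINE]
    counts = online.groupby("dyad_id")["checkin_index"].nunique()
    excluded = counts[counts < 2]
    log = pd.DataFrame(
        {
            "dyad_id": excluded.index,
            "n_online_checkins": excluded.to_numpy(),
            "reason": "fewer than two online check-ins",
        }
    ).reset_index(drop=True)
    drop = (records["source"] == ONLINE) & records["dyad_id"].isin(excluded.index)
    kept = records[~drop].reset_index(drop=True)
    if len(log):
        logger.info("excluded %d dyads' online records (<2 check-ins)", len(log))
    return kept, log


def clip_to_window(records: pd.DataFrame, max_day: int = 366) -> pd.DataFrame:
    """Discard online check-ins after the analysis window, with a warning."""
    late = (records["source"] == ONLINE) & (records["day"] > max_day)
    if late.any():
        n = records.loc[late, ["dyad_id", "checkin_index"]].drop_duplicates()
        logger.warning(
            "discarding %d online check-ins after day %d", len(n), max_day
        )
    return records[~late].reset_index(drop=True)


def label_transitions(records: pd.DataFrame) -> pd.DataFrame:
    """Label every (dyad, symptom, online check-in) observation.

    Returns one row per observation with ``is_threshold`` (rating >= 7),
    ``next_rating`` (the same symptom at the next online check-in, NA for
    the last one) and ``transition`` in {IMPROVED, SAME, WORSENED, TERMINAL}.
    """
    online = records[records["source"] == ONLINE].copy()
    if online.duplicated(subset=["dyad_id", "checkin_index", "symptom"]).any():
        raise DataError("duplicate (dyad, checkin_index, symptom) observation")
    online = online.sort_values(
        ["dyad_id", "symptom", "checkin_index"], kind="mergesort"
    )
    nxt = online.groupby(["dyad_id", "symptom"], sort=False)["rating"].shift(-1)
    online["next_rating"] = nxt.astype("Int64")
    online["is_threshold"] = online["rating"] >= ALERT_THRESHOLD
    cond = [
        online["next_rating"].isna().to_numpy(),
        (online["next_rating"] < online["rating"]).fillna(False).to_numpy(dtype=bool),
        (online["next_rating"] > online["rating"]).fillna(False).to_numpy(dtype=bool),
    ]
    online["transition"] = np.select(cond, [TERMINAL, IMPROVED, WORSENED], SAME)
    return online.sort_values(
        ["dyad_id", "checkin_index", "symptom"], kind="mergesort"
    ).reset_index(drop=True)


def aggregate_bimonthly(
    transitions: pd.DataFrame,
    bin_days: int = 61,
    terminal_policy: str = "include",
) -> pd.DataFrame:
    """Sum the three counts per arm x 2-month period, plus a totals row.

    Check-ins are assigned to period ``ceil(day / bin_days)`` clamped to
    1..6; a threshold symptom belongs to the period of its own check-in even
    if its follow-up rating falls in the next one.
    """
    if terminal_policy not in ("include", "exclude"):
        raise DataError("terminal_policy must be 'include' or 'exclude'")
    t = transitions
    if (t["day"] <= 0).any():
        raise DataError("online check-ins must have day >= 1")
    t = t.copy()
    t["period"] = np.minimum(
        np.ceil(t["day"] / bin_days).astype(int), N_PERIODS
    )

    is_thr = t["is_threshold"]
    if terminal_policy == "exclude":
        in_denominator = is_thr & (t["transition"] != TERMINAL)
    else:
        in_denominator = is_thr
    t["_thr"] = in_denominator
    t["_imp"] = in_denominator & (t["transition"] == IMPROVED)
    t["_wor"] = in_denominator & (t["transition"] == WORSENED)
    # TERMINAL tallied under "same" when included
    t["_sam"] = in_denominator & t["transition"].isin([SAME, TERMINAL])

    per = (
        t.groupby(["arm", "period"])
        .agg(
            n_assessed=("rating", "size"),
            n_threshold=("_thr", "sum"),
            n_improved=("_imp", "sum"),
            n_same=("_sam", "sum"),
            n_worsened=("_wor", "sum"),
        )
        .reset_index()
    )
    per["period"] = per["period"].astype(str)
    totals = (
        per.groupby("arm")[
            ["n_assessed", "n_threshold", "n_improved", "n_same", "n_worsened"]
        ]
        .sum()
        .reset_index()
    )
    totals.insert(1, "period", ALL_PERIODS)
    out = pd.concat([per, totals], ignore_index=True)
    cols = ["arm", "period", "n_assessed", "n_threshold", "n_improved", "n_same", "n_worsened"]
    out = out[cols].sort_values(["arm", "period"], kind="mergesort").reset_index(drop=True)
    for c in cols[2:]:
        out[c] = out[c].astype(int)
    return out


def emit_alerts(records: pd.DataFrame) -> pd.DataFrame:
    """One row per alerted symptom: ALERT-arm online ratings >= 7.

    Rows sharing (dyad_id, day) belong to the same alert event, which lists
    every symptom of concern on that check-in.  Control-arm reports never
    alert anyone.
    """
    mask = (
        (records["arm"] == ALERT)
        & (records["source"] == ONLINE)
        & (records["rating"] >= ALERT_THRESHOLD)
    )
    alerts = records.loc[mask, ["dyad_id", "day", "symptom", "rating"]]
    return alerts.sort_values(
        ["dyad_id", "day", "symptom"], kind="mergesort"
    ).reset_index(drop=True)


def per_caregiver_volume(records: pd.DataFrame) -> pd.DataFrame:
    """Assessed-symptom volume per reporting caregiver, by arm.

    A reporting caregiver is one with at least one retained online check-in;
    their volume is 10 x number of completed check-ins.
    """
    online = records[records["source"] == ONLINE]
    per_dyad = online.groupby(["arm", "dyad_id"]).size().rename("n_symptoms")
    out = (
        per_dyad.groupby("arm")
        .agg(
            n_caregivers="count",
            total_symptoms="sum",
            mean_symptoms_per_caregiver="mean",
        )
        .reset_index()
    )
    out["total_symptoms"] = out["total_symptoms"].astype(int)
    return out


def caregivers_per_period(
    records: pd.DataFrame, bin_days: int = 61
) -> pd.DataFrame:
    """Distinct reporting caregivers per arm x period (pretest as period 0)."""
    df = records.copy()
    df["period"] = np.where(
        df["source"] == PRETEST,
        0,
        np.minimum(np.ceil(df["day"] / bin_days), N_PERIODS),
    ).astype(int)
    out = (
        df.groupby(["arm", "period"])["dyad_id"]
        .nunique()
        .rename("n_caregivers")
        .reset_index()
    )
    return out


def pretest_first_checkin_tables(
    records: pd.DataFrame,
) -> dict[str, PairedChangeCounts]:
    """Pair each dyad's pretest ratings with its first online check-in.

    Returns, per arm, the 2x2 cross-classification of symptom observations by
    threshold status at pretest x at first check-in, over dyads having both.
    """
    pre = records[records["source"] == PRETEST]
    online = records[records["source"] == ONLINE]
    if len(online) == 0 or len(pre) == 0:
        raise DataError("need both pretest and online records")
    first_idx = online.groupby("dyad_id")["checkin_index"].transform("min")
    first = online[online["checkin_index"] == first_idx]
    merged = pre.merge(
        first[["dyad_id", "symptom", "rating"]],
        on=["dyad_id", "symptom"],
        suffixes=("_pre", "_first"),
    )
    out: dict[str, PairedChangeCounts] = {}
    for arm, g in merged.groupby("arm"):
        a = g["rating_pre"] >= ALERT_THRESHOLD
        b = g["rating_first"] >= ALERT_THRESHOLD
        out[arm] = PairedChangeCounts(
            n_both=int((a & b).sum()),
            n_pre_only=int((a & ~b).sum()),
            n_post_only=int((~a & b).sum()),
            n_neither=int((~a & ~b).sum()),
        )
    return out
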