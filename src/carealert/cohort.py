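"""Synthetic dyad cohort generator and check-in CSV I/O.

The generator emulates the raw material of a caregiver e-alert trial: each
dyad completes a pretest paper survey at enrollment (day 0) and is then due
an online check-in every ``checkin_interval_days`` days, rating 10 symptoms
on a 0-10 scale.  Ratings come from a latent Gaussian AR(1) process per
(dyad, symptom), rounded half-up and clamped to {0..10}; the rounding step
means a rating changes between consecutive check-ins only when the latent
severity moves by at least one level, which reproduces the carry-forward
behaviour of forms pre-populated with the previous answers.

Arm-specific mechanisms, all seeded and reproducible:

* dropout -- geometric per-check-in hazard, identical in both arms;
* alert response -- after a completed check-in reports a symptom at >= 7,
  the *next* scheduled rating of that symptom is drawn conditionally: with
  the arm's improvement probability it is forced strictly lower, otherwise
  forced equal-or-higher (truncated-normal draws keep the latent process
  coherent).  Setting the probability to ``None`` disables the mechanism;
* reporting bias (ALERT arm online check-ins only) -- a due check-in is
  completed with probability ``bias_report_prob``, and latent severities are
  shifted by ``bias_rating_shift`` before rounding.  The pretest is never
  thinned or shifted: it was not forwarded to clinicians.

The canonical in-memory container is a long-format :class:`pandas.DataFrame`
(one row per rating), identical to the CSV schema written by
:func:`write_checkins`.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .config import ALERT, CONTROL, ONLINE, PRETEST, ALERT_THRESHOLD, CohortConfig
from .errors import DataError

#: Column order of the long-format check-in schema.
COLUMNS = ("dyad_id", "arm", "checkin_index", "day", "source", "symptom", "rating")


@dataclass(frozen=True)
class Dyad:
    """One enrolled patient-caregiver pair."""

    dyad_id: str
    arm: str
    enrollment_day: int = 0
    dropout_day: Optional[int] = None


@dataclass(frozen=True)
class CheckinRecord:
    """One completed check-in: all 10 ratings entered at one sitting."""

    dyad_id: str
    arm: str
    checkin_index: int
    day: int
    source: str
    ratings: Mapping[str, int]


def _dyad_rng(seed: int, dyad_id: str) -> np.random.Generator:
    """Independent substream per dyad, stable under cohort reordering."""
    key = zlib.crc32(dyad_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _to_ratings(latent: np.ndarray, shift: float) -> np.ndarray:
    """Round half-up and clamp to the 0-10 scale."""
    return np.clip(np.floor(latent + shift + 0.5), 0, 10).astype(np.int64)


def _truncated_normal(
    rng: np.random.Generator,
    mean: np.ndarray,
    sd: float,
    cut: np.ndarray,
    below: np.ndarray,
) -> np.ndarray:
    """Draw N(mean, sd) conditioned on x < cut (where below) or x >= cut."""
    u = rng.random(mean.shape)
    mass_below = ndtr((cut - mean) / sd)
    q = np.where(below, u * mass_below, mass_below + u * (1.0 - mass_below))
    q = np.clip(q, 1e-12, 1.0 - 1e-12)
    return mean + sd * ndtri(q)


def _simulate_dyad(cfg: CohortConfig, dyad: Dyad, rows: list) -> Optional[int]:
    """Append this dyad's rating rows; return the dropout day if it dropped."""
    rng = _dyad_rng(cfg.seed, dyad.dyad_id)
    n = cfg.n_symptoms
    is_alert = dyad.arm == ALERT
    shift = cfg.bias_rating_shift if is_alert else 0.0
    report_prob = cfg.bias_report_prob if is_alert else 1.0
    p_improve = (
        cfg.improvement_prob_given_alert if is_alert else cfg.improvement_prob_control
    )
    # Innovation SD keeping the stationary marginal at N(mean, baseline_sd),
    # with shock_sd adding extra week-to-week jitter on top.
    innovation_sd = float(
        np.sqrt(
            (1.0 - cfg.persistence**2) * cfg.baseline_sd**2 + cfg.shock_sd**2
        )
    )

    latent = cfg.baseline_mean + cfg.baseline_sd * rng.standard_normal(n)
    pretest = _to_ratings(latent, 0.0)  # pretest never shifted
    for sym, r in zip(cfg.symptom_names, pretest):
        rows.append((dyad.dyad_id, dyad.arm, 0, 0, PRETEST, sym, int(r)))

    prev_reported: Optional[np.ndarray] = None  # ratings at last completed check-in
    prev_completed = False  # was the immediately previous due check-in completed?
    record_index = 1
    for k in range(1, cfg.n_scheduled_checkins + 1):
        if rng.random() < cfg.attrition_hazard_per_checkin:
            return k * cfg.checkin_interval_days
        mean = cfg.baseline_mean + cfg.persistence * (latent - cfg.baseline_mean)
        latent = mean + innovation_sd * rng.standard_normal(n)
        if p_improve is not None and prev_completed and prev_reported is not None:
            hot = prev_reported >= ALERT_THRESHOLD
            if hot.any():
                # Reported rating is clip(floor(latent + shift + .5)); it is
                # strictly below the previous rating iff latent < cut.
                cut = prev_reported - 0.5 - shift
                improve = rng.random(n) < p_improve
                forced = _truncated_normal(rng, mean, innovation_sd, cut, improve)
                latent = np.where(hot, forced, latent)
        completed = rng.random() < report_prob
        if completed:
            day = k * cfg.checkin_interval_days
            ratings = _to_ratings(latent, shift)
            for sym, r in zip(cfg.symptom_names, ratings):
                rows.append(
                    (dyad.dyad_id, dyad.arm, record_index, day, ONLINE, sym, int(r))
                )
            record_index += 1
            prev_reported = ratings
            prev_completed = True
        else:
            prev_completed = False
    return None


def make_dyads(cfg: CohortConfig) -> list[Dyad]:
    """1:1 arm allocation: dyads D0001, D0002, ... alternate CONTROL/ALERT."""
    dyads = []
    for i in range(2 * cfg.n_dyads_per_arm):
        arm = CONTROL if i % 2 == 0 else ALERT
        dyads.append(Dyad(dyad_id=f"D{i + 1:04d}", arm=arm))
    return dyads


def generate_cohort(cfg: CohortConfig) -> pd.DataFrame:
    """Generate the full cohort as a long-format check-in table.

    Returns one row per (dyad, check-in, symptom) with columns
    ``dyad_id, arm, checkin_index, day, source, symptom, rating``.
    Identical configs (including the seed) yield byte-identical CSV output.
    """
    rows: list = []
    for dyad in make_dyads(cfg):
        _simulate_dyad(cfg, dyad, rows)
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    return df


def records_to_frame(records: list[CheckinRecord]) -> pd.DataFrame:
    rows = [
        (r.dyad_id, r.arm, r.checkin_index, r.day, r.source, sym, int(rating))
        for r in records
        for sym, rating in r.ratings.items()
    ]
    return pd.DataFrame(rows, columns=list(COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[CheckinRecord]:
    out = []
    for (dyad_id, arm, idx, day, source), grp in df.groupby(
        ["dyad_id", "arm", "checkin_index", "day", "source"], sort=True
    ):
        out.append(
            CheckinRecord(
                dyad_id=dyad_id,
                arm=arm,
                checkin_index=int(idx),
                day=int(day),
                source=source,
                ratings=dict(zip(grp["symptom"], grp["rating"].astype(int))),
            )
        )
    return out


def write_checkins(df: pd.DataFrame, path) -> None:
    """Write the long-format CSV (lossless round-trip with read_checkins)."""
    validate_checkins(df)
    if isinstance(path, (str, Path)):
        Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_checkins(path) -> pd.DataFrame:
    """Read and validate a long-format check-in CSV.

    Raises
    ------
    DataError
        naming the first offending data row (1-based, header = line 1) for
        out-of-range ratings, bad labels, or incomplete check-ins.
    """
    if isinstance(path, (str, io.IOBase)) or hasattr(path, "read"):
        df = pd.read_csv(path, dtype={"dyad_id": str, "symptom": str})
    else:
        df = pd.read_csv(Path(path), dtype={"dyad_id": str, "symptom": str})
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"missing columns: {sorted(missing)}")
    df = df[list(COLUMNS)]
    validate_checkins(df, line_offset=2)
    df = df.astype(
        {"checkin_index": np.int64, "day": np.int64, "rating": np.int64}
    )
    return df


def validate_checkins(df: pd.DataFrame, line_offset: int = 0) -> None:
    """Domain checks on a long-format table.

    ``line_offset`` > 0 reports positions as file line numbers.
    """

    def _where(mask: pd.Series) -> str:
        pos = int(np.flatnonzero(mask.to_numpy())[0])
        if line_offset:
            return f"row {pos + line_offset}"
        return f"record {pos}"

    if len(df) == 0:
        return
    rating = pd.to_numeric(df["rating"], errors="coerce")
    bad = rating.isna() | (rating % 1 != 0) | (rating < 0) | (rating > 10)
    if bad.any():
        raise DataError(
            f"rating outside 0-10 at {_where(bad)}: "
            f"{df.loc[bad, 'rating'].iloc[0]!r}"
        )
    bad = ~df["arm"].isin([CONTROL, ALERT])
    if bad.any():
        raise DataError(f"unknown arm at {_where(bad)}: {df.loc[bad, 'arm'].iloc[0]!r}")
    bad = ~df["source"].isin([PRETEST, ONLINE])
    if bad.any():
        raise DataError(
            f"unknown source at {_where(bad)}: {df.loc[bad, 'source'].iloc[0]!r}"
        )
    sizes = df.groupby(["dyad_id", "checkin_index"], sort=False).size()
    if (sizes != 10).any():
        dyad, idx = sizes.index[(sizes != 10).to_numpy()][0]
        raise DataError(
            f"check-in {idx} of dyad {dyad} has {sizes.loc[(dyad, idx)]} ratings "
            "(each check-in must rate exactly 10 symptoms)"
        )
    dup = df.duplicated(subset=["dyad_id", "checkin_index", "symptom"])
    if dup.any():
        raise DataError(f"duplicate (dyad, check-in, symptom) at {_where(dup)}")
    pre = df[df["source"] == PRETEST]
    if len(pre):
        per_dyad = pre.groupby("dyad_id")["checkin_index"].nunique()
        if (per_dyad > 1).any():
            raise DataError(
                f"dyad {per_dyad.index[(per_dyad > 1).to_numpy()][0]} has more "
                "than one pretest record"
            )
        if (pd.to_numeric(pre["day"]) > 0).any():
            raise DataError("pretest records must have day <= 0")
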