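"""Hand-rolled builders and independent oracles shared by the test suite."""

from __future__ import annotations

import csv
import io
import math
from collections import defaultdict

import pandas as pd

from carealert.cohort import COLUMNS
from carealert.config import DEFAULT_SYMPTOMS

SYMPTOMS = DEFAULT_SYMPTOMS


def checkin_rows(dyad, arm, idx, day, source, overrides=None, base=0):
    """Rows for one check-in: all 10 symptoms at `base` except `overrides`."""
    ratings = {s: base for s in SYMPTOMS}
    ratings.update(overrides or {})
    return [(dyad, arm, idx, day, source, s, ratings[s]) for s in SYMPTOMS]


def frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=list(COLUMNS))


def stream(dyad, arm, series, pretest=None, interval=7):
    """A dyad's stream: `series` maps check-in number (1-based) to overrides."""
    rows = []
    if pretest is not None:
        rows += checkin_rows(dyad, arm, 0, 0, "PRETEST", pretest)
    for k, overrides in enumerate(series, start=1):
        rows += checkin_rows(dyad, arm, k, k * interval, "ONLINE", overrides)
    return rows


def brute_force_recount(csv_text, bin_days=61, terminal_policy="include"):
    """Independent recount of the bimonthly indices straight off CSV rows.

    Pure-python re-derivation (csv module, dicts, loops) of eligibility,
    transition labels and per-period counts, sharing no code with the
    implementation under test.
    """
    rows = list(csv.DictReader(io.StringIO(csv_text)))
    online = [r for r in rows if r["source"] == "ONLINE"]
    # eligibility: >= 2 online check-ins
    per_dyad = defaultdict(set)
    for r in online:
        per_dyad[r["dyad_id"]].add(int(r["checkin_index"]))
    eligible = {d for d, ks in per_dyad.items() if len(ks) >= 2}
    online = [r for r in online if r["dyad_id"] in eligible]
    # per (dyad, symptom): ratings keyed by check-in index
    series = defaultdict(dict)
    meta = {}
    for r in online:
        key = (r["dyad_id"], r["symptom"])
        series[key][int(r["checkin_index"])] = int(r["rating"])
        meta[(r["dyad_id"], int(r["checkin_index"]))] = (
            r["arm"],
            int(r["day"]),
        )
    counts = defaultdict(lambda: defaultdict(int))
    for (dyad, _sym), ratings in series.items():
        ks = sorted(ratings)
        for pos, k in enumerate(ks):
            arm, day = meta[(dyad, k)]
            period = min(math.ceil(day / bin_days), 6)
            cell = counts[(arm, str(period))]
            cell["n_assessed"] += 1
            rating = ratings[k]
            terminal = pos == len(ks) - 1
            if rating >= 7:
                if terminal and terminal_policy == "exclude":
                    continue
                cell["n_threshold"] += 1
                if terminal:
                    cell["n_same"] += 1
                else:
                    nxt = ratings[ks[pos + 1]]
                    if nxt < rating:
                        cell["n_improved"] += 1
                    elif nxt > rating:
                        cell["n_worsened"] += 1
                    else:
                        cell["n_same"] += 1
    for arm in {a for a, _ in counts}:
        total = defaultdict(int)
        for (a, p), cell in list(counts.items()):
            if a == arm:
                for k, v in cell.items():
                    total[k] += v
        counts[(arm, "ALL")] = total
    return {k: dict(v) for k, v in counts.items()}


def mn_grid_inversion(x1, n1, x2, n2, alpha=0.05, step=1e-5):
    """Brute-force MN interval: scan delta over [-1, 1] at `step`, keep the
    deltas whose score statistic stays within +-z_{1-alpha/2}."""
    import numpy as np
    from scipy.stats import norm

    from carealert.inference import TwoSampleCounts, mn_score_stat

    c = TwoSampleCounts(x1, n1, x2, n2)
    zc = norm.ppf(1 - alpha / 2)
    grid = np.arange(-1.0 + step, 1.0, step)
    z = mn_score_stat(c, grid)
    keep = grid[np.abs(z) <= zc]
    return float(keep[0]), float(keep[-1])
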