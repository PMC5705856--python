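"""End-to-end orchestration: simulate or ingest, score, infer, report.

``run_pipeline`` produces a report bundle of plain-text artifacts mirroring
the tables a trial report would print:

* caregivers.csv        -- reporting caregivers per arm x 2-month period
* indices.csv           -- the bimonthly count indices (incl. totals row)
* table_threshold.csv   -- threshold/assessed proportions with effect sizes
* table_improved.csv    -- improved/threshold proportions with effect sizes
* comparisons.csv       -- totals-based two-sample comparisons (z, p, CIs, h)
* bias.csv              -- pretest vs first-check-in contrast + two-group
                           McNemar statistic
* auc.csv               -- trapezoidal AUC contrast per index
* alerts.csv            -- one row per alerted symptom (ALERT arm)
* exclusions.csv        -- dyads dropped for having < 2 online check-ins
* report.txt            -- human-readable "n/N (%)" tables
* manifest.json         -- config, seed and package version; every number
                           in the bundle is reproducible from it

Identical config + seed produce byte-identical bundles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .auc import auc_difference_test, series_from_indices
from .cohort import generate_cohort, read_checkins
from .config import ALERT, CONTROL, RunConfig
from .errors import DataError
from .inference import TwoSampleCounts, compare, mcnemar_two_group
from .scoring import (
    aggregate_bimonthly,
    caregivers_per_period,
    clip_to_window,
    emit_alerts,
    filter_eligible,
    label_transitions,
    per_caregiver_volume,
    pretest_first_checkin_tables,
)

logger = logging.getLogger(__name__)


def render_cell(x: int, n: int) -> str:
    """Format a count pair as "x/n (pct)".

    Percentages carry 2 decimals for large denominators (n >= 1000) and 1
    decimal otherwise, matching the mixed precision of published tables.
    """
    if n <= 0:
        return f"{x}/{n} (NA)"
    prec = 2 if n >= 1000 else 1
    return f"{x}/{n} ({100.0 * x / n:.{prec}f})"


def _proportion_table(
    indices: pd.DataFrame, num: str, den: str, alpha: float
) -> pd.DataFrame:
    """Per-period proportion cells for both arms, with Cohen h."""
    rows = []
    for period in sorted(indices["period"].unique(), key=str):
        sub = indices[indices["period"] == period].set_index("arm")
        if not {CONTROL, ALERT} <= set(sub.index):
            continue
        x1, n1 = int(sub.loc[CONTROL, num]), int(sub.loc[CONTROL, den])
        x2, n2 = int(sub.loc[ALERT, num]), int(sub.loc[ALERT, den])
        row = {
            "period": period,
            "control_cell": render_cell(x1, n1),
            "alert_cell": render_cell(x2, n2),
            "x_control": x1,
            "n_control": n1,
            "x_alert": x2,
            "n_alert": n2,
        }
        if n1 > 0 and n2 > 0:
            res = compare(
                TwoSampleCounts(x1, n1, x2, n2, CONTROL, ALERT),
                methods=("mn",),
                alpha=alpha,
            )
            row["cohen_h"] = round(res.h, 4)
            row["diff"] = round(res.diff, 4)
            lo, hi = res.cis["mn"]
            row["diff_ci_low"], row["diff_ci_high"] = round(lo, 4), round(hi, 4)
        rows.append(row)
    return pd.DataFrame(rows)


def _comparison_rows(indices: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Totals-based comparisons for both proportion indices (ALERT vs CONTROL)."""
    tot = indices[indices["period"] == "ALL"].set_index("arm")
    rows = []
    for name, num, den in (
        ("improved_of_threshold", "n_improved", "n_threshold"),
        ("threshold_of_assessed", "n_threshold", "n_assessed"),
    ):
        x1, n1 = int(tot.loc[ALERT, num]), int(tot.loc[ALERT, den])
        x2, n2 = int(tot.loc[CONTROL, num]), int(tot.loc[CONTROL, den])
        if min(n1, n2) == 0:
            continue
        res = compare(
            TwoSampleCounts(x1, n1, x2, n2, ALERT, CONTROL),
            methods=cfg.methods,
            alpha=cfg.alpha,
        )
        rows.append({"index": name, **res.to_dict()})
    return pd.DataFrame(rows)


def _bias_analysis(records: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Pretest vs first-online-check-in threshold proportions and the
    two-group McNemar net-change contrast."""
    tables = pretest_first_checkin_tables(records)
    rows = []
    for stage in ("pretest", "first_checkin"):
        cells = {}
        for arm in (CONTROL, ALERT):
            t = tables.get(arm)
            if t is None:
                continue
            if stage == "pretest":
                x = t.n_both + t.n_pre_only
            else:
                x = t.n_both + t.n_post_only
            cells[arm] = (x, t.n_total)
        if len(cells) == 2:
            (x1, n1), (x2, n2) = cells[CONTROL], cells[ALERT]
            res = compare(
                TwoSampleCounts(x1, n1, x2, n2, CONTROL, ALERT),
                methods=("mn",),
                alpha=alpha,
            )
            rows.append(
                {
                    "stage": stage,
                    "control_cell": render_cell(x1, n1),
                    "alert_cell": render_cell(x2, n2),
                    "cohen_h": round(res.h, 4),
                    "p_value": res.p_value,
                }
            )
    if {CONTROL, ALERT} <= set(tables):
        z, p = mcnemar_two_group(tables[CONTROL], tables[ALERT])
        rows.append(
            {
                "stage": "mcnemar_net_change",
                "control_cell": "",
                "alert_cell": "",
                "cohen_h": float("nan"),
                "p_value": p,
                "z": z,
            }
        )
    return pd.DataFrame(rows)


def _auc_rows(indices: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    tot = indices[indices["period"] == "ALL"].set_index("arm")
    rows = []
    for name, den in (
        ("improvement", "n_threshold"),
        ("threshold", "n_assessed"),
    ):
        try:
            s1 = series_from_indices(indices, CONTROL, index=name)
            s2 = series_from_indices(indices, ALERT, index=name)
            cmp_ = auc_difference_test(
                s1,
                s2,
                int(tot.loc[CONTROL, den]),
                int(tot.loc[ALERT, den]),
                alpha=cfg.alpha,
            )
        except DataError as exc:
            logger.warning("AUC contrast for %s skipped: %s", name, exc)
            continue
        rows.append(
            {
                "index": name,
                "auc_control": cmp_.auc1,
                "auc_alert": cmp_.auc2,
                "relative_control": cmp_.relative1,
                "relative_alert": cmp_.relative2,
                "effective_n_control": cmp_.effective_n1,
                "effective_n_alert": cmp_.effective_n2,
                "z": cmp_.result.z,
                "p_value": cmp_.result.p_value,
            }
        )
    return pd.DataFrame(rows)


def _render_report(tables: dict[str, pd.DataFrame]) -> str:
    parts = []
    for title, df in tables.items():
        parts.append(f"== {title} ==")
        parts.append(df.to_string(index=False) if len(df) else "(empty)")
        parts.append("")
    return "\n".join(parts)


def run_pipeline(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full analysis and write the report bundle to cfg.output_dir."""
    if cfg.cohort is not None:
        records = generate_cohort(cfg.cohort)
        logger.info("simulated %d rating rows", len(records))
    else:
        records = read_checkins(cfg.input_path)
        logger.info("read %d rating rows from %s", len(records), cfg.input_path)

    records = clip_to_window(records, max_day=6 * cfg.bin_days)
    eligible, exclusions = filter_eligible(records)
    transitions = label_transitions(eligible)
    indices = aggregate_bimonthly(
        transitions, bin_days=cfg.bin_days, terminal_policy=cfg.terminal_policy
    )
    bundle: dict[str, pd.DataFrame] = {
        "caregivers": caregivers_per_period(eligible, bin_days=cfg.bin_days),
        "indices": indices,
        "table_threshold": _proportion_table(
            indices, "n_threshold", "n_assessed", cfg.alpha
        ),
        "table_improved": _proportion_table(
            indices, "n_improved", "n_threshold", cfg.alpha
        ),
        "comparisons": _comparison_rows(indices, cfg),
        "auc": _auc_rows(indices, cfg),
        "alerts": emit_alerts(eligible),
        "volume": per_caregiver_volume(eligible),
        "exclusions": exclusions,
    }
    try:
        bundle["bias"] = _bias_analysis(eligible, cfg.alpha)
    except DataError as exc:
        logger.warning("bias analysis skipped: %s", exc)
        bundle["bias"] = pd.DataFrame()

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.items():
        df.to_csv(out / f"{name}.csv", index=False)
    (out / "report.txt").write_text(
        _render_report(
            {
                "Reporting caregivers per period": bundle["caregivers"],
                "Threshold symptoms / assessed symptoms": bundle["table_threshold"],
                "Improved threshold symptoms / threshold symptoms": bundle[
                    "table_improved"
                ],
                "Pretest vs first online check-in": bundle["bias"],
                "AUC contrast": bundle["auc"],
            }
        )
    )
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "run_config": {
            k: v for k, v in asdict(cfg).items() if k != "cohort"
        },
        "cohort_config": cfg.cohort.to_dict() if cfg.cohort else None,
        "n_rating_rows": int(len(records)),
        "n_excluded_dyads": int(len(exclusions)),
    }
    manifest["run_config"]["methods"] = list(cfg.methods)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    if cfg.make_figure:
        _trajectory_figure(indices, out / "trajectories.png")
    return bundle


def _trajectory_figure(indices: pd.DataFrame, path: Path) -> None:
    """Simple bimonthly trajectory figure for both proportion indices."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .auc import series_from_indices

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for ax, index, title in zip(
        axes,
        ("threshold", "improvement"),
        ("threshold / assessed", "improved / threshold"),
    ):
        for arm in (CONTROL, ALERT):
            try:
                s = series_from_indices(indices, arm, index=index)
            except DataError:
                continue
            ax.plot(s.times, s.values, marker="o", label=arm)
        ax.set_xlabel("month (period midpoint)")
        ax.set_title(title)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
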