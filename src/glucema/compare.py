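"""Paired comparison of the two EMA schedules (completion, performance, events).

Each participant contributes one value per schedule per metric; metrics are
compared with a paired two-tailed t test and Cohen's dz (mean of within-pair
differences over their SD, algebraically t / sqrt(n)).  Performance metrics
aggregate participant-level means first: the participant's mean across all
completed administrations within a schedule is computed, and the table reports
the average and SD of those participant-level means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import OUTCOME_BY_TEST


@dataclass(frozen=True)
class PairedComparison:
    metric: str
    n: int
    mean_diff: float
    sd_diff: float
    t: float
    df: int
    p: float
    dz: float


def cohens_dz_from_t(t: float, n: int) -> float:
    """Paired-design effect size from a t statistic: dz = t / sqrt(n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(t) / float(np.sqrt(n))


def paired_t(x, y, metric: str = "") -> PairedComparison:
    """Two-tailed paired t test with Cohen's dz.

    ``x`` and ``y`` are participant-matched value sequences (same order).
    Raises when the differences have zero variance (statistic undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be matched sequences of equal length")
    if len(x) < 2:
        raise ValueError("paired t test requires >= 2 pairs")
    d = x - y
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise ValueError("differences have zero variance; t statistic undefined")
    n = len(d)
    mean = float(np.mean(d))
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return PairedComparison(
        metric=metric,
        n=n,
        mean_diff=mean,
        sd_diff=sd,
        t=float(t),
        df=n - 1,
        p=min(p, 1.0),
        dz=mean / sd,
    )


def _participant_means(scores: pd.DataFrame) -> pd.DataFrame:
    """Participant-level mean full score per test x schedule (completed EMAs)."""
    ok = scores.dropna(subset=["full"])
    return (
        ok.groupby(["test", "schedule", "participant_id"], observed=True)["full"]
        .mean()
        .reset_index()
    )


def schedule_table(
    scores: pd.DataFrame,
    capture: pd.DataFrame | None = None,
    reliability: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the per-metric schedule comparison table.

    ``scores``: output of :func:`glucema.scoring.score_sessions` joined with a
    ``schedule`` column.  ``capture``: per participant x schedule summary with
    completion_rate / total_events / captured_events.  ``reliability``:
    optional output of :func:`glucema.reliability.reliability_by_schedule`.

    One row per metric: per-schedule mean and SD over participant-level values,
    per-schedule reliability where available, and the paired comparison.
    Participants missing a metric under either schedule are dropped pairwise
    for that metric.  Rows whose comparison is undefined are flagged
    ``incomplete``.
    """
    schedules = sorted(scores["schedule"].unique())
    if len(schedules) != 2:
        raise ValueError(f"expected exactly 2 schedules, found {schedules}")
    # difference direction: three_per_day minus six_per_day when present
    if "three_per_day" in schedules:
        schedules = ["three_per_day"] + [s for s in schedules if s != "three_per_day"]
    s1, s2 = schedules

    metric_frames: list[tuple[str, pd.DataFrame]] = []
    pm = _participant_means(scores)
    for test in sorted(pm["test"].unique()):
        sub = pm[pm["test"] == test].rename(columns={"full": "value"})
        name = f"{test}_{OUTCOME_BY_TEST.get(test, 'score')}"
        metric_frames.append((name, sub[["participant_id", "schedule", "value"]]))
    if capture is not None:
        for col in ("completion_rate", "total_events", "captured_events"):
            sub = capture[["participant_id", "schedule", col]].rename(columns={col: "value"})
            metric_frames.append((col, sub))

    rows = []
    for name, frame in metric_frames:
        wide = frame.pivot_table(
            index="participant_id", columns="schedule", values="value", observed=True
        )
        row: dict = {"metric": name, "incomplete": False}
        for lab in (s1, s2):
            col = wide[lab].dropna() if lab in wide else pd.Series(dtype=float)
            row[f"{lab}_mean"] = float(col.mean()) if len(col) else np.nan
            row[f"{lab}_sd"] = float(col.std(ddof=1)) if len(col) > 1 else np.nan
        if reliability is not None and "_" in name:
            test = name.rsplit("_", 1)[0] if name.rsplit("_", 1)[0] in set(
                reliability["test"]
            ) else name.split("_")[0]
            for lab in (s1, s2):
                hit = reliability[
                    (reliability["test"] == test) & (reliability["schedule"] == lab)
                ]
                row[f"{lab}_reliability"] = (
                    float(hit["reliability"].iloc[0]) if len(hit) else np.nan
                )
        both = wide.dropna() if {s1, s2}.issubset(wide.columns) else pd.DataFrame()
        try:
            if len(both) < 2:
                raise ValueError("fewer than 2 complete pairs")
            cmp = paired_t(both[s1], both[s2], metric=name)
            row.update(
                n=cmp.n, mean_diff=cmp.mean_diff, sd_diff=cmp.sd_diff,
                t=cmp.t, df=cmp.df, p=cmp.p, dz=cmp.dz,
            )
        except ValueError:
            row.update(n=len(both), mean_diff=np.nan, sd_diff=np.nan,
                       t=np.nan, df=np.nan, p=np.nan, dz=np.nan, incomplete=True)
        rows.append(row)
    return pd.DataFrame(rows)


def round_for_display(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the table's display rounding conventions.

    Milliseconds to 0 dp, percentages/accuracy to 1 dp, d-prime / dz /
    reliability to 2 dp.
    """
    out = table.copy()
    def _dp(metric: str) -> int:
        if "medianRTc" in metric:
            return 0
        if "d_prime" in metric:
            return 2
        return 1
    stat_cols = [c for c in out.columns if c.endswith(("_mean", "_sd")) or c in ("mean_diff", "sd_diff")]
    for i, metric in enumerate(out["metric"]):
        out.loc[out.index[i], stat_cols] = out.loc[out.index[i], stat_cols].astype(float).round(_dp(metric))
    for c in out.columns:
        if c.endswith("_reliability") or c == "dz":
            out[c] = out[c].round(2)
    if "t" in out:
        out["t"] = out["t"].round(2)
    if "p" in out:
        out["p"] = out["p"].round(3)
    return out
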