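"""Annual percent change in tau-PET SUVR within stage ROIs, with group summaries.

Annual change is the two-timepoint difference expressed as percent of
baseline per year:  ((followup - baseline) / baseline) * 100 / dt.
Stage-level SUVR is the (optionally volume-weighted) mean over member
regions at each timepoint before the formula is applied.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def annual_percent_change(baseline, followup, dt):
    """((followup - baseline) / baseline) * 100 / dt, in %/yr.  Vectorised."""
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    t = np.asarray(dt, dtype=float)
    if np.any(b <= 0):
        raise ValueError("baseline SUVR must be positive")
    if np.any(t <= 0):
        raise ValueError("scan interval must be positive")
    out = (f - b) / b * 100.0 / t
    return float(out) if out.ndim == 0 else out


def stage_change_table(
    panel: pd.DataFrame,
    stages: Mapping[int, Sequence[str]],
    intervals: pd.Series | Mapping[str, float],
    region_weights: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Per-subject, per-stage annual percent change.

    Subjects without a complete follow-up scan are excluded (count logged).
    ``region_weights`` (e.g. region volumes) weight the within-stage SUVR
    mean; default is an unweighted mean.
    """
    base = panel[panel["timepoint"] == "baseline"].pivot(
        index="subject_id", columns="region_label", values="suvr")
    fup = panel[panel["timepoint"] == "followup"].pivot(
        index="subject_id", columns="region_label", values="suvr")
    complete = fup.dropna(how="any").index
    excluded = len(base.index) - len(complete)
    if excluded:
        log.info("stage_change_table: excluding %d subject(s) without complete follow-up", excluded)
    base_c, fup_c = base.loc[complete], fup.loc[complete]

    iv = pd.Series(intervals)
    iv = iv.reindex(complete)
    if iv.isna().any():
        raise ValueError(f"missing scan interval for subjects: {list(iv[iv.isna()].index)[:5]}")

    rows = []
    for stage, regions in sorted(stages.items()):
        regions = list(regions)
        missing = sorted(set(regions) - set(base.columns))
        if missing:
            raise ValueError(f"stage {stage}: regions not in panel: {missing}")
        if region_weights is not None:
            w = np.array([region_weights[r] for r in regions], dtype=float)
            w = w / w.sum()
        else:
            w = np.full(len(regions), 1.0 / len(regions))
        b = base_c[regions].to_numpy() @ w
        f = fup_c[regions].to_numpy() @ w
        rows.append(pd.DataFrame({
            "subject_id": complete,
            "stage": stage,
            "baseline_suvr": b,
            "interval_years": iv.to_numpy(),
            "annual_change": annual_percent_change(b, f, iv.to_numpy()),
        }))
    return pd.concat(rows, ignore_index=True)


def group_change_summary(table: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Group x stage summary: mean, t-based 95% CI, one-sample t test vs 0, min/max.

    Groups with n < 2 or zero variance get NaN CI/test and ``flagged=True``.
    Two-sided p < .05 marks ``significant``.
    """
    merged = table.merge(cohort[["subject_id", "group"]], on="subject_id", how="inner")
    rows = []
    for (group, stage), grp in merged.groupby(["group", "stage"], sort=True):
        x = grp["annual_change"].to_numpy()
        n = x.size
        row = {
            "group": group, "stage": stage, "n": n,
            "mean": float(np.mean(x)) if n else np.nan,
            "min": float(np.min(x)) if n else np.nan,
            "max": float(np.max(x)) if n else np.nan,
            "ci_low": np.nan, "ci_high": np.nan,
            "t_stat": np.nan, "p_value": np.nan,
            "significant": False, "flagged": True,
        }
        if n >= 2 and np.std(x, ddof=1) > 0:
            sem = stats.sem(x)
            lo, hi = stats.t.interval(0.95, n - 1, loc=row["mean"], scale=sem)
            t_stat, p = stats.ttest_1samp(x, 0.0)
            row.update(ci_low=float(lo), ci_high=float(hi), t_stat=float(t_stat),
                       p_value=float(p), significant=bool(p < 0.05), flagged=False)
        rows.append(row)
    return pd.DataFrame(rows)
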