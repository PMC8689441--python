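"""Trial enrichment power analysis for tau-PET annual change as an outcome.

A hypothetical two-arm trial aims to detect a fractional reduction (default
30%) of the mean annual percent change in tau-PET SUVR.  Under the two-sided
normal approximation the per-arm sample size is

    n/arm = 2 * sigma^2 * (z_{1-alpha/2} + z_{power})^2 / (effect * mu)^2 ,

so enriching the population (e.g. requiring baseline biomarker z-scores >= 2
relative to amyloid-negative CU individuals) shrinks the trial by raising mu
relative to sigma.  Percent sample-size reductions are ratio-based and come
with subject-level bootstrap CIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .predictors import aic

DEFAULT_Z_THRESHOLD = 2.0


@dataclass(frozen=True)
class TrialDesign:
    effect_fraction: float = 0.30   # treatment reduction of the mean annual change
    alpha: float = 0.05             # two-sided type-I level
    power: float = 0.80
    allocation: float = 1.0         # treated : control ratio

    def __post_init__(self) -> None:
        if not 0 < self.effect_fraction < 1:
            raise ValueError("effect_fraction must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.allocation <= 0:
            raise ValueError("allocation ratio must be positive")


def _n_per_arm_continuous(mean_change: float, sd_change: float, design: TrialDesign) -> float:
    z_a = stats.norm.ppf(1.0 - design.alpha / 2.0)
    z_b = stats.norm.ppf(design.power)
    delta = design.effect_fraction * mean_change
    return (1.0 + 1.0 / design.allocation) * sd_change**2 * (z_a + z_b) ** 2 / delta**2


def required_sample_size(mean_change: float, sd_change: float, design: TrialDesign = TrialDesign()) -> int:
    """Per-arm n (rounded up) to detect the designed fractional reduction."""
    if mean_change <= 0:
        raise ValueError("mean_change must be positive (no detectable effect direction)")
    if sd_change <= 0:
        raise ValueError("sd_change must be positive")
    return int(math.ceil(_n_per_arm_continuous(mean_change, sd_change, design)))


def monte_carlo_power(
    n_per_arm: int,
    mean_change: float,
    sd_change: float,
    design: TrialDesign = TrialDesign(),
    n_sims: int = 10_000,
    seed: int = 0,
    effect_fraction: Optional[float] = None,
) -> float:
    """Simulated power of a two-sample t test at the given per-arm n.

    ``effect_fraction`` overrides the design value (0 gives the null, where
    the rejection rate should approximate alpha).
    """
    if n_per_arm < 2:
        raise ValueError("n_per_arm must be >= 2")
    f = design.effect_fraction if effect_fraction is None else effect_fraction
    rng = np.random.default_rng(seed)
    ctrl = rng.normal(mean_change, sd_change, size=(n_sims, n_per_arm))
    trt = rng.normal((1.0 - f) * mean_change, sd_change, size=(n_sims, n_per_arm))
    _, p = stats.ttest_ind(trt, ctrl, axis=1)
    return float(np.mean(p < design.alpha))


def enrich(
    cohort: pd.DataFrame,
    z_table: pd.DataFrame,
    criteria: Mapping[str, float],
    rule: str = "all",
) -> Tuple[pd.DataFrame, float]:
    """Subjects meeting the z-threshold criteria; returns (subset, screened-in fraction).

    ``criteria`` maps sign-aligned biomarker z columns to thresholds
    (abnormal = positive).  ``rule`` is "all" (intersection, default) or
    "any" (union).  Missing z values fail their criterion.
    """
    missing = sorted(set(criteria) - set(z_table.columns))
    if missing:
        raise ValueError(f"criteria on biomarkers without z-scores: {missing}")
    if rule not in {"all", "any"}:
        raise ValueError(f"rule must be 'all' or 'any', got {rule!r}")
    z = z_table.reindex(cohort["subject_id"])
    masks = np.column_stack([(z[b] >= thr).fillna(False).to_numpy() for b, thr in criteria.items()])
    keep = masks.all(axis=1) if rule == "all" else masks.any(axis=1)
    return cohort[keep], float(keep.mean())


@dataclass
class EnrichmentReport:
    group: str
    criteria: Dict[str, float]
    rule: str
    design: TrialDesign
    n_subjects_full: int
    n_subjects_enriched: int
    fraction_screened_in: float
    mean_change_full: float
    sd_change_full: float
    mean_change_enriched: float
    sd_change_enriched: float
    n_total_unenriched: Optional[int]    # 2 * per-arm n
    n_total_enriched: Optional[int]
    reduction_percent: float             # 100 * (1 - n_enriched / n_full), NaN when flagged
    reduction_ci: Tuple[float, float]
    delta_aic: float                     # OLS(change ~ criteria z) vs intercept-only, full group
    flagged: bool
    flag_reason: str = ""


def _reduction(mu_f, sd_f, mu_e, sd_e, design) -> float:
    """Ratio-based percent reduction using the continuous sample-size formula."""
    n_f = _n_per_arm_continuous(mu_f, sd_f, design)
    n_e = _n_per_arm_continuous(mu_e, sd_e, design)
    return 100.0 * (1.0 - n_e / n_f)


def sample_size_reduction(
    cohort: pd.DataFrame,
    z_table: pd.DataFrame,
    changes: pd.DataFrame,
    stage: int,
    criteria: Mapping[str, float],
    design: TrialDesign = TrialDesign(),
    n_boot: int = 2000,
    seed: int = 0,
    rule: str = "all",
    group: str = "",
    min_enriched: int = 5,
) -> EnrichmentReport:
    """Percent sample-size reduction from biomarker enrichment, with bootstrap CI.

    The unenriched trial size comes from the observed (mean, SD) of annual
    change at ``stage`` in the full ``cohort``; the enriched size from the
    same quantities in the screened-in subset.  Enriched subsets with fewer
    than ``min_enriched`` subjects or non-positive mean change are flagged
    and reported without a reduction.
    """
    ch = changes[changes["stage"] == stage][["subject_id", "annual_change"]]
    d = cohort.merge(ch, on="subject_id", how="inner").reset_index(drop=True)
    if d.empty:
        raise ValueError(f"no stage-{stage} changes for the supplied cohort")
    z = z_table.reindex(d["subject_id"])
    masks = np.column_stack([
        (z[b] >= thr).fillna(False).to_numpy() for b, thr in criteria.items()
    ]) if criteria else np.ones((len(d), 1), dtype=bool)
    missing = sorted(set(criteria) - set(z_table.columns))
    if missing:
        raise ValueError(f"criteria on biomarkers without z-scores: {missing}")
    keep = masks.all(axis=1) if rule == "all" else masks.any(axis=1)

    x = d["annual_change"].to_numpy(dtype=float)
    mu_f, sd_f = float(np.mean(x)), float(np.std(x, ddof=1))
    xe = x[keep]
    mu_e = float(np.mean(xe)) if xe.size else np.nan
    sd_e = float(np.std(xe, ddof=1)) if xe.size >= 2 else np.nan

    flagged, reason = False, ""
    if keep.sum() < min_enriched:
        flagged, reason = True, f"enriched subset has n={int(keep.sum())} < {min_enriched}"
    elif mu_e <= 0:
        flagged, reason = True, "enriched subset has non-positive mean change"
    elif mu_f <= 0:
        flagged, reason = True, "full group has non-positive mean change"

    if not flagged:
        reduction = _reduction(mu_f, sd_f, mu_e, sd_e, design)
        n_full = 2 * required_sample_size(mu_f, sd_f, design)
        n_enr = 2 * required_sample_size(mu_e, sd_e, design)
        rng = np.random.default_rng(seed)
        n = len(d)
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            xb, kb = x[idx], keep[idx]
            xeb = xb[kb]
            if kb.sum() < min_enriched:
                continue
            mfb, meb = xb.mean(), xeb.mean()
            if mfb <= 0 or meb <= 0:
                continue
            boots.append(_reduction(mfb, xb.std(ddof=1), meb, xeb.std(ddof=1), design))
        ci = (
            (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
            if boots else (np.nan, np.nan)
        )
    else:
        reduction, ci, n_full, n_enr = np.nan, (np.nan, np.nan), None, None

    # model-fit change of using the criteria biomarkers to explain annual change
    if criteria:
        zb = z[list(criteria)].to_numpy(dtype=float)
        ok = np.isfinite(zb).all(axis=1) & np.isfinite(x)
        res1 = sm.OLS(x[ok], sm.add_constant(zb[ok], has_constant="add")).fit()
        res0 = sm.OLS(x[ok], np.ones((int(ok.sum()), 1))).fit()
        delta_aic = aic(res1.llf, len(res1.params) + 1) - aic(res0.llf, 2)
    else:
        delta_aic = 0.0

    return EnrichmentReport(
        group=group, criteria=dict(criteria), rule=rule, design=design,
        n_subjects_full=len(d), n_subjects_enriched=int(keep.sum()),
        fraction_screened_in=float(keep.mean()),
        mean_change_full=mu_f, sd_change_full=sd_f,
        mean_change_enriched=mu_e, sd_change_enriched=sd_e,
        n_total_unenriched=n_full, n_total_enriched=n_enr,
        reduction_percent=float(reduction), reduction_ci=ci,
        delta_aic=float(delta_aic), flagged=flagged, flag_reason=reason,
    )
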