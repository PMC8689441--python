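"""Baseline biomarkers as predictors of annual tau-PET change.

Each biomarker is z-scored against the amyloid-negative cognitively
unimpaired reference group, sign-aligned so that larger z means more
abnormal, and entered (one at a time) into an OLS model of annual change
with age and sex as covariates.  Models are compared with adjusted R^2 and
AIC against a demographics-only (age + sex) model fit on the same complete
cases; the best combination is found by backward stepwise elimination with
the "fewest predictors within 2 AIC of the minimum" parsimony rule.

AIC here is -2*loglik + 2*n_params with the Gaussian OLS log-likelihood and
the residual variance counted as a parameter, so absolute values are
comparable across nested OLS fits on identical cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import BIOMARKERS, LOWER_IS_ABNORMAL

DEFAULT_REFERENCE_GROUP = "Ab- CU"
DEFAULT_COVARIATES = ("age", "sex_male")


def aic(log_likelihood: float, n_params: int) -> float:
    """Akaike information criterion: -2*loglik + 2*n_params (lower is better)."""
    return -2.0 * log_likelihood + 2.0 * n_params


def encode_sex(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add a binary ``sex_male`` indicator column."""
    out = cohort.copy()
    out["sex_male"] = (out["sex"].astype(str).str.upper().str.startswith("M")).astype(float)
    return out


def zscore_biomarkers(
    cohort: pd.DataFrame,
    biomarkers: Optional[Sequence[str]] = None,
    reference_group: str = DEFAULT_REFERENCE_GROUP,
    flip: Iterable[str] = LOWER_IS_ABNORMAL,
) -> pd.DataFrame:
    """z-score biomarkers against the reference group, abnormal = positive.

    Returns a frame indexed by subject_id with one z column per biomarker.
    Biomarkers in ``flip`` (where *low* raw values are abnormal) have their
    sign inverted after standardisation.
    """
    if biomarkers is None:
        biomarkers = [b for b in BIOMARKERS if b in cohort.columns]
    ref = cohort[cohort["group"] == reference_group]
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} is empty")
    flip = set(flip)
    out = pd.DataFrame(index=pd.Index(cohort["subject_id"], name="subject_id"))
    for b in biomarkers:
        ref_vals = ref[b].dropna()
        sd = ref_vals.std(ddof=1)
        if ref_vals.empty or not np.isfinite(sd) or sd == 0:
            raise ValueError(f"reference group has zero variance (or no data) for biomarker {b!r}")
        z = (cohort[b].to_numpy() - ref_vals.mean()) / sd
        out[b] = -z if b in flip else z
    return out


@dataclass
class ModelComparison:
    group: str
    predictors: Tuple[str, ...]
    coefficient: float              # standardized coefficient of the biomarker term
    p_value: float
    adjusted_r2: float
    adj_r2_ci: Tuple[float, float]
    aic: float
    delta_aic: float                # vs demographics-only model on identical cases
    n: int


@dataclass
class StepRecord:
    predictors: Tuple[str, ...]
    adjusted_r2: float
    aic: float
    removed: Optional[str]          # predictor removed to reach this model (None for full)


@dataclass
class SelectionPath:
    steps: List[StepRecord]
    selected: Tuple[str, ...]
    selected_aic: float


def _ols(y: np.ndarray, X: np.ndarray):
    model = sm.OLS(y, sm.add_constant(X, has_constant="add"))
    return model.fit()


def _fit_aic_r2(y: np.ndarray, X: np.ndarray) -> Tuple[float, float, object]:
    res = _ols(y, X)
    return aic(res.llf, len(res.params) + 1), float(res.rsquared_adj), res


def _adjusted_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Plain lstsq adjusted R^2 (bootstrap fast path)."""
    X1 = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    ss_res = resid @ resid
    ss_tot = ((y - y.mean()) ** 2).sum()
    n, p = X1.shape
    if ss_tot == 0 or n - p <= 0:
        return np.nan
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p)


def fit_single_predictor(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    group: str = "",
    n_boot: int = 2000,
    seed: int = 0,
    min_cases: int = 10,
) -> ModelComparison:
    """OLS of annual change on one biomarker (+ covariates) vs demographics only.

    The standardized coefficient is the biomarker slope rescaled by
    sd(predictor)/sd(outcome) on the complete cases.  The adjusted-R^2 CI is
    a nonparametric percentile bootstrap.
    """
    cols = [outcome, predictor, *covariates]
    d = data[cols].dropna()
    n = len(d)
    if n < min_cases:
        raise ValueError(f"predictor {predictor!r}: only {n} complete cases (< {min_cases})")
    y = d[outcome].to_numpy(dtype=float)
    x = d[predictor].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise ValueError(f"predictor {predictor!r} is constant on the complete cases")
    C = d[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((n, 0))

    X_full = np.column_stack([x, C]) if C.size else x.reshape(-1, 1)
    aic_full, adj_r2, res = _fit_aic_r2(y, X_full)
    if C.size:
        aic_base, _, _ = _fit_aic_r2(y, C)
    else:  # intercept-only comparator when no covariates requested
        res0 = _ols(y, np.empty((n, 0)))
        aic_base = aic(res0.llf, len(res0.params) + 1)

    beta = float(res.params[1])  # [const, predictor, covariates...]
    coef_std = beta * np.std(x, ddof=1) / np.std(y, ddof=1)
    p_value = float(res.pvalues[1])

    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        r2b = _adjusted_r2(y[idx], X_full[idx])
        if np.isfinite(r2b):
            boot.append(r2b)
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5))) if boot else (np.nan, np.nan)

    return ModelComparison(
        group=group, predictors=(predictor,), coefficient=float(coef_std), p_value=p_value,
        adjusted_r2=adj_r2, adj_r2_ci=ci, aic=aic_full, delta_aic=aic_full - aic_base, n=n,
    )


def select_within_two(steps: Sequence[StepRecord]) -> Tuple[Tuple[str, ...], float]:
    """Parsimony rule: fewest predictors among models within 2 AIC (inclusive) of the minimum."""
    min_aic = min(s.aic for s in steps)
    candidates = [s for s in steps if s.aic <= min_aic + 2.0]
    best = min(candidates, key=lambda s: (len(s.predictors), s.aic))
    return best.predictors, best.aic


def backward_stepwise(
    data: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> SelectionPath:
    """Backward elimination down to one predictor, then the within-2-AIC rule.

    Complete cases are fixed at the full model so AICs stay comparable along
    the whole path.  Covariates are retained in every model.
    """
    predictors = list(predictors)
    if not predictors:
        raise ValueError("need at least one predictor")
    d = data[[outcome, *predictors, *covariates]].dropna()
    y = d[outcome].to_numpy(dtype=float)

    def fit(preds: Sequence[str]) -> Tuple[float, float]:
        X = d[[*preds, *covariates]].to_numpy(dtype=float)
        a, r2, _ = _fit_aic_r2(y, X)
        return a, r2

    current = list(predictors)
    a, r2 = fit(current)
    steps = [StepRecord(tuple(current), r2, a, None)]
    while len(current) > 1:
        trials = []
        for cand in current:
            rest = [p for p in current if p != cand]
            a, r2 = fit(rest)
            trials.append((a, r2, cand, rest))
        a, r2, removed, current = min(trials, key=lambda t: t[0])
        steps.append(StepRecord(tuple(current), r2, a, removed))

    selected, sel_aic = select_within_two(steps)
    return SelectionPath(steps=steps, selected=selected, selected_aic=sel_aic)


def comparison_table(comparisons: Sequence[ModelComparison]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "group": c.group, "predictor": "+".join(c.predictors), "coefficient": c.coefficient,
            "adjusted_r2": c.adjusted_r2, "adj_r2_ci_low": c.adj_r2_ci[0], "adj_r2_ci_high": c.adj_r2_ci[1],
            "p_value": c.p_value, "aic": c.aic, "delta_aic": c.delta_aic, "n": c.n,
        }
        for c in comparisons
    ])


def path_table(path: SelectionPath) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "predictors": "+".join(s.predictors), "n_predictors": len(s.predictors),
            "adjusted_r2": s.adjusted_r2, "aic": s.aic, "removed": s.removed or "",
            "selected": s.predictors == path.selected,
        }
        for s in path.steps
    ])
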