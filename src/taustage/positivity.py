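"""Regional tau-positivity: two-component Gaussian mixtures on baseline SUVR.

For each bilateral region, a 2-component Gaussian mixture is fit on all
available baseline SUVR values (all diagnostic groups pooled).  The component
with the larger mean is the "abnormal" (tau-positive) one; a subject's
tau-positive probability is the Bayes posterior of that component at their
SUVR, i.e. the probability that the value falls in the rightmost Gaussian.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

MIN_FIT_VALUES = 20
VARIANCE_FLOOR = 1e-4


@dataclass(frozen=True)
class PositivityModel:
    """Fitted per-region mixture; ``abnormal_index`` points at the higher-mean component."""

    region_label: str
    weights: Tuple[float, float]
    means: Tuple[float, float]
    sds: Tuple[float, float]
    abnormal_index: int
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.weights), 1.0) or min(self.weights) < 0:
            raise ValueError("mixture weights must be non-negative and sum to 1")
        if min(self.sds) <= 0:
            raise ValueError("component SDs must be positive")
        if self.abnormal_index != int(np.argmax(self.means)):
            raise ValueError("abnormal component must be the higher-mean component")


def fit_region_mixture(
    values: Iterable[float],
    region_label: str = "",
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> PositivityModel:
    """EM-fit a 2-component Gaussian mixture to one region's baseline SUVR.

    Two initialisation strategies compete on final log-likelihood: a
    quantile split at the median, and ``n_restarts`` random restarts.  A
    variance floor of 1e-4 guards against singular components.
    """
    x = np.asarray(list(values), dtype=float)
    x = x[np.isfinite(x)]
    if x.size < MIN_FIT_VALUES:
        raise ValueError(f"region {region_label!r}: need >= {MIN_FIT_VALUES} finite values, got {x.size}")
    if np.std(x) == 0:
        raise ValueError(f"region {region_label!r}: degenerate input (constant values)")
    X = x.reshape(-1, 1)

    med = np.median(x)
    lower, upper = x[x <= med], x[x > med]
    quantile_means = np.array([[lower.mean()], [upper.mean() if upper.size else lower.mean() + 1e-3]])

    candidates = []
    common = dict(n_components=2, covariance_type="full", reg_covar=VARIANCE_FLOOR,
                  max_iter=max_iter, tol=tol)
    gm_q = GaussianMixture(means_init=quantile_means, random_state=seed, **common).fit(X)
    candidates.append(gm_q)
    if n_restarts > 0:
        gm_r = GaussianMixture(n_init=n_restarts, init_params="random_from_data",
                               random_state=seed, **common).fit(X)
        candidates.append(gm_r)

    converged = [g for g in candidates if g.converged_]
    if not converged:
        raise RuntimeError(
            f"region {region_label!r}: EM did not converge in {max_iter} iterations "
            f"after {n_restarts} restarts (n={x.size}, sd={np.std(x):.4g})"
        )
    best = max(converged, key=lambda g: g.score(X))

    weights = tuple(best.weights_.ravel())
    means = tuple(best.means_.ravel())
    sds = tuple(np.sqrt(best.covariances_.ravel()))
    return PositivityModel(
        region_label=region_label,
        weights=weights,
        means=means,
        sds=sds,
        abnormal_index=int(np.argmax(means)),
        log_likelihood=float(best.score(X) * x.size),
    )


def positive_probability(model: PositivityModel, suvr) -> np.ndarray | float:
    """Posterior probability of the abnormal component at ``suvr`` (Bayes' rule).

    Vectorised; continuous and monotone increasing in SUVR when the abnormal
    component has the larger mean and no smaller SD-driven crossover occurs
    at the evaluated values.
    """
    x = np.asarray(suvr, dtype=float)
    logp = np.stack(
        [np.log(model.weights[i]) + norm.logpdf(x, model.means[i], model.sds[i]) for i in (0, 1)],
        axis=0,
    )
    post = np.exp(logp[model.abnormal_index] - logsumexp(logp, axis=0))
    return float(post) if np.isscalar(suvr) else post


def fit_positivity_models(
    panel: pd.DataFrame, n_restarts: int = 10, seed: int = 0
) -> Dict[str, PositivityModel]:
    """Fit one mixture per region on the baseline rows of a tidy SUVR panel."""
    base = panel[panel["timepoint"] == "baseline"]
    models = {}
    for i, (region, grp) in enumerate(base.groupby("region_label", sort=True)):
        models[region] = fit_region_mixture(
            grp["suvr"].to_numpy(), region_label=region, n_restarts=n_restarts, seed=seed + i
        )
    return models


def probability_matrix(panel: pd.DataFrame, models: Mapping[str, PositivityModel]) -> pd.DataFrame:
    """Subject x region tau-positive probabilities from baseline SUVR.

    Raises if any panel region lacks a fitted model; the error lists them.
    """
    base = panel[panel["timepoint"] == "baseline"]
    wide = base.pivot(index="subject_id", columns="region_label", values="suvr")
    missing = sorted(set(wide.columns) - set(models))
    if missing:
        raise ValueError(f"no positivity model for regions: {missing}")
    out = pd.DataFrame(
        {region: positive_probability(models[region], wide[region].to_numpy()) for region in wide.columns},
        index=wide.index,
    )
    return out


def models_to_json(models: Mapping[str, PositivityModel], path) -> None:
    payload = {r: dataclasses.asdict(m) for r, m in sorted(models.items())}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def models_from_json(path) -> Dict[str, PositivityModel]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return {
        r: PositivityModel(
            region_label=d["region_label"], weights=tuple(d["weights"]), means=tuple(d["means"]),
            sds=tuple(d["sds"]), abnormal_index=d["abnormal_index"],
            log_likelihood=d.get("log_likelihood", float("nan")),
        )
        for r, d in payload.items()
    }
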