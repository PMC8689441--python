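"""Data-driven stage ROIs: bootstrap consensus clustering + event-based ordering.

Two steps derive tracer-specific stage ROIs from a subject x region matrix of
tau-positive probabilities:

1. *Consensus clustering* — regions are clustered on their probability
   profiles within each bootstrap resample of subjects; the fraction of
   resamples in which two regions co-cluster forms a stability matrix, cut by
   average-linkage hierarchical clustering.  The cluster count is chosen by
   silhouette score on the (1 - stability) distances, ties broken toward
   smaller k.

2. *Event-based model (EBM)* — an event is a cluster-ROI turning abnormal.
   With cluster-level probabilities ``p`` and a uniform prior over a subject's
   unknown stage s in {0..k}, the subject likelihood of an ordering is

       L_i = 1/(k+1) * sum_s  prod_{j<=s} p_ij * prod_{j>s} (1 - p_ij),

   and the fitted sequence maximises ``sum_i log L_i``.  For k <= 6 the
   optimum is found by exhaustive enumeration; larger k uses greedy
   pairwise-swap ascent from random restarts.  Positional uncertainty comes
   from subject-level bootstrap refits.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

PROB_CLAMP = 1e-6
EXHAUSTIVE_MAX_K = 6


@dataclass
class ConsensusSolution:
    stability_matrix: pd.DataFrame            # region x region co-assignment frequency, chosen k
    labels: Dict[str, int]                    # region -> cluster id at chosen k
    labels_by_k: Dict[int, Dict[str, int]]
    silhouette: Dict[int, float]
    chosen_k: int


@dataclass
class EventSequence:
    ordering: Tuple[int, ...]                 # cluster ids, earliest event first
    log_likelihood: float
    positional_density: Optional[pd.DataFrame] = None  # cluster x position frequencies


def _correlation_distance(matrix: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between columns; undefined correlations -> distance 1."""
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(matrix, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return np.maximum(dist, 0.0)


def consensus_cluster(
    probs: pd.DataFrame,
    k_range: Sequence[int] = range(2, 9),
    n_boot: int = 100,
    seed: int = 0,
) -> ConsensusSolution:
    """Bootstrap consensus clustering of regions on their probability profiles."""
    regions = list(probs.columns)
    n_sub, n_reg = probs.shape
    if n_reg < 2 or n_sub < 2:
        raise ValueError("need at least 2 regions and 2 subjects")
    k_range = sorted(set(int(k) for k in k_range))
    if any(k < 2 or k > n_reg - 1 for k in k_range):
        raise ValueError(f"k_range must lie within [2, {n_reg - 1}], got {k_range}")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    rng = np.random.default_rng(seed)
    values = probs.to_numpy(dtype=float)
    co = {k: np.zeros((n_reg, n_reg)) for k in k_range}
    for _ in range(n_boot):
        idx = rng.integers(0, n_sub, n_sub)
        dist = _correlation_distance(values[idx])
        for k in k_range:
            lab = AgglomerativeClustering(n_clusters=k, metric="precomputed", linkage="average").fit_predict(dist)
            co[k] += lab[:, None] == lab[None, :]

    labels_by_k: Dict[int, Dict[str, int]] = {}
    sil: Dict[int, float] = {}
    stability = {}
    for k in k_range:
        M = co[k] / n_boot
        np.fill_diagonal(M, 1.0)
        D = 1.0 - M
        lab = AgglomerativeClustering(n_clusters=k, metric="precomputed", linkage="average").fit_predict(D)
        labels_by_k[k] = {r: int(c) + 1 for r, c in zip(regions, lab)}
        sil[k] = float(silhouette_score(D, lab, metric="precomputed"))
        stability[k] = M

    chosen_k = k_range[0]
    for k in k_range[1:]:                      # ties break toward smaller k
        if sil[k] > sil[chosen_k]:
            chosen_k = k
    return ConsensusSolution(
        stability_matrix=pd.DataFrame(stability[chosen_k], index=regions, columns=regions),
        labels=labels_by_k[chosen_k],
        labels_by_k=labels_by_k,
        silhouette=sil,
        chosen_k=chosen_k,
    )


def average_cluster_probabilities(probs: pd.DataFrame, labels: Mapping[str, int]) -> pd.DataFrame:
    """Per subject, arithmetic mean of member-region probabilities per cluster."""
    missing = sorted(set(probs.columns) - set(labels))
    if missing:
        raise ValueError(f"labels missing for regions: {missing}")
    clusters = sorted(set(labels[r] for r in probs.columns))
    out = {}
    for c in clusters:
        members = [r for r in probs.columns if labels[r] == c]
        if not members:
            raise ValueError(f"cluster {c} has no member regions")
        out[c] = probs[members].mean(axis=1)
    return pd.DataFrame(out, index=probs.index)


def _clamped(cluster_probs: pd.DataFrame) -> Tuple[np.ndarray, list]:
    P = np.clip(cluster_probs.to_numpy(dtype=float), PROB_CLAMP, 1.0 - PROB_CLAMP)
    return P, list(cluster_probs.columns)


def _stage_log_likelihoods(P_ordered: np.ndarray) -> np.ndarray:
    """Per-subject log-likelihood given columns already arranged in event order."""
    n, k = P_ordered.shape
    cp = np.cumprod(P_ordered, axis=1)                       # prod of first s events occurred
    cp = np.concatenate([np.ones((n, 1)), cp], axis=1)       # s = 0..k
    q = 1.0 - P_ordered
    sq = np.cumprod(q[:, ::-1], axis=1)[:, ::-1]             # prod of events > s not occurred
    sq = np.concatenate([sq, np.ones((n, 1))], axis=1)
    L = (cp * sq).sum(axis=1) / (k + 1)
    return np.log(L)


def ebm_loglik(ordering: Sequence[int], cluster_probs: pd.DataFrame) -> float:
    """Total EBM log-likelihood of ``ordering`` (a permutation of cluster ids)."""
    P, cols = _clamped(cluster_probs)
    if sorted(ordering) != sorted(cols):
        raise ValueError(f"ordering {ordering} is not a permutation of clusters {cols}")
    idx = [cols.index(c) for c in ordering]
    return float(_stage_log_likelihoods(P[:, idx]).sum())


def _per_subject_loglik_all_perms(P: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """(n_perm, n_subject) log-likelihood matrix; perms hold column indices."""
    out = np.empty((perms.shape[0], P.shape[0]))
    for i, perm in enumerate(perms):
        out[i] = _stage_log_likelihoods(P[:, perm])
    return out


def _greedy_ascent(P: np.ndarray, rng: np.random.Generator, n_restarts: int) -> Tuple[np.ndarray, float]:
    k = P.shape[1]
    best_perm, best_ll = None, -np.inf
    for _ in range(max(1, n_restarts)):
        perm = rng.permutation(k)
        ll = _stage_log_likelihoods(P[:, perm]).sum()
        improved = True
        while improved:
            improved = False
            for a, b in itertools.combinations(range(k), 2):
                cand = perm.copy()
                cand[a], cand[b] = cand[b], cand[a]
                cll = _stage_log_likelihoods(P[:, cand]).sum()
                if cll > ll + 1e-12:
                    perm, ll, improved = cand, cll, True
        if ll > best_ll:
            best_perm, best_ll = perm, ll
    return best_perm, float(best_ll)


def fit_event_sequence(
    cluster_probs: pd.DataFrame,
    n_restarts: int = 50,
    seed: int = 0,
    method: str = "auto",
) -> EventSequence:
    """Maximum-likelihood event ordering of the cluster-ROIs.

    ``method``: "auto" (exhaustive for k <= 6, greedy otherwise),
    "exhaustive", or "greedy".
    """
    P, cols = _clamped(cluster_probs)
    k = len(cols)
    if k < 2:
        raise ValueError("need at least 2 clusters to order")
    if method == "auto":
        method = "exhaustive" if k <= EXHAUSTIVE_MAX_K else "greedy"
    if method == "exhaustive":
        perms = np.array(list(itertools.permutations(range(k))))
        ll = _per_subject_loglik_all_perms(P, perms).sum(axis=1)
        best = int(np.argmax(ll))
        perm, best_ll = perms[best], float(ll[best])
    elif method == "greedy":
        perm, best_ll = _greedy_ascent(P, np.random.default_rng(seed), n_restarts)
    else:
        raise ValueError(f"unknown method {method!r}")
    return EventSequence(ordering=tuple(cols[i] for i in perm), log_likelihood=best_ll)


def ordering_uncertainty(
    cluster_probs: pd.DataFrame,
    n_mc: int = 10_000,
    seed: int = 0,
    n_restarts: int = 50,
) -> pd.DataFrame:
    """Positional density of each cluster over bootstrap refits of the ordering.

    Rows are clusters, columns positions 1..k; each row sums to 1.  For
    k <= 6 every bootstrap is an exact multinomial reweighting of the
    per-permutation per-subject log-likelihoods, which is algebraically
    identical to refitting on a subject resample but far faster.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    P, cols = _clamped(cluster_probs)
    n, k = P.shape
    rng = np.random.default_rng(seed)
    counts = np.zeros((k, k))

    if k <= EXHAUSTIVE_MAX_K:
        perms = np.array(list(itertools.permutations(range(k))))
        logl = _per_subject_loglik_all_perms(P, perms)        # (n_perm, n)
        W = rng.multinomial(n, np.full(n, 1.0 / n), size=n_mc)  # (n_mc, n)
        scores = W @ logl.T                                    # (n_mc, n_perm)
        winners = perms[np.argmax(scores, axis=1)]
        for pos in range(k):
            cluster_idx, c = np.unique(winners[:, pos], return_counts=True)
            counts[cluster_idx, pos] += c
    else:
        for _ in range(n_mc):
            idx = rng.integers(0, n, n)
            perm, _ = _greedy_ascent(P[idx], rng, n_restarts)
            for pos, ci in enumerate(perm):
                counts[ci, pos] += 1

    density = counts / n_mc
    return pd.DataFrame(density, index=cols, columns=[f"position_{i + 1}" for i in range(k)])


def stage_rois(labels: Mapping[str, int], sequence: EventSequence) -> Dict[int, Tuple[str, ...]]:
    """Map stage number (1 = earliest event) to its sorted region set."""
    clusters = set(labels.values())
    if set(sequence.ordering) != clusters:
        raise ValueError("sequence ordering and labels describe different clusters")
    return {
        pos + 1: tuple(sorted(r for r, c in labels.items() if c == cluster))
        for pos, cluster in enumerate(sequence.ordering)
    }
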