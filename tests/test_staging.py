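import itertools
import math

import numpy as np
import pandas as pd
import pytest

from taustage.staging import (
    EventSequence,
    average_cluster_probabilities,
    consensus_cluster,
    ebm_loglik,
    fit_event_sequence,
    ordering_uncertainty,
    stage_rois,
)
from .conftest import staged_probability_matrix


def brute_force_loglik(ordering, frame, clamp=1e-6):
    """Independent per-subject likelihood oracle: plain loops, no vectorisation."""
    cols = list(frame.columns)
    P = np.clip(frame.to_numpy(dtype=float), clamp, 1 - clamp)
    idx = [cols.index(c) for c in ordering]
    total = 0.0
    for i in range(P.shape[0]):
        p = [P[i, j] for j in idx]
        k = len(p)
        like = 0.0
        for s in range(k + 1):
            term = 1.0
            for j in range(k):
                term *= p[j] if j < s else (1 - p[j])
            like += term / (k + 1)
        total += math.log(like)
    return total


def block_probability_matrix(n_sub, regions_per_block, n_blocks, noise_sd, seed):
    rng = np.random.default_rng(seed)
    block_vals = rng.uniform(0, 1, size=(n_sub, n_blocks))
    cols, labels = {}, {}
    for b in range(n_blocks):
        for j in range(regions_per_block):
            name = f"r{b}_{j}"
            cols[name] = np.clip(block_vals[:, b] + rng.normal(0, noise_sd, n_sub), 0, 1)
            labels[name] = b + 1
    return pd.DataFrame(cols), labels


class TestConsensusCluster:
    def test_perfect_blocks(self):
        probs, truth = block_probability_matrix(60, 4, 3, noise_sd=0.0, seed=0)
        sol = consensus_cluster(probs, k_range=range(2, 6), n_boot=30, seed=0)
        assert sol.chosen_k == 3
        M = sol.stability_matrix
        for r1 in probs.columns:
            for r2 in probs.columns:
                if truth[r1] == truth[r2]:
                    assert M.loc[r1, r2] == pytest.approx(1.0)
                else:
                    assert M.loc[r1, r2] < 0.1
        got = {frozenset(r for r in probs.columns if sol.labels[r] == c)
               for c in set(sol.labels.values())}
        want = {frozenset(r for r in probs.columns if truth[r] == b) for b in (1, 2, 3)}
        assert got == want

    def test_duplicating_subjects_keeps_partition(self):
        probs, truth = block_probability_matrix(50, 4, 3, noise_sd=0.05, seed=1)
        doubled = pd.concat([probs, probs], ignore_index=True)
        s1 = consensus_cluster(probs, k_range=[3], n_boot=30, seed=2)
        s2 = consensus_cluster(doubled, k_range=[3], n_boot=30, seed=2)
        part = lambda labels: {frozenset(r for r in probs.columns if labels[r] == c)
                               for c in set(labels.values())}
        assert part(s1.labels) == part(s2.labels)

    def test_k_range_bounds(self):
        probs, _ = block_probability_matrix(20, 2, 2, 0.0, seed=0)
        with pytest.raises(ValueError):
            consensus_cluster(probs, k_range=[1], n_boot=5)
        with pytest.raises(ValueError):
            consensus_cluster(probs, k_range=[len(probs.columns)], n_boot=5)


class TestAverageClusterProbabilities:
    def test_identical_columns(self):
        probs = pd.DataFrame({"a": [0.1, 0.9], "b": [0.1, 0.9]})
        out = average_cluster_probabilities(probs, {"a": 1, "b": 1})
        np.testing.assert_allclose(out[1], probs["a"])

    def test_arithmetic_mean(self):
        probs = pd.DataFrame({"a": [0.2], "b": [0.6]})
        out = average_cluster_probabilities(probs, {"a": 1, "b": 1})
        assert out.iloc[0, 0] == pytest.approx(0.4)

    def test_missing_region_label(self):
        probs = pd.DataFrame({"a": [0.2], "b": [0.6]})
        with pytest.raises(ValueError, match="b"):
            average_cluster_probabilities(probs, {"a": 1})


class TestEbmLoglik:
    def test_uniform_half_probabilities_are_order_invariant(self):
        P = pd.DataFrame(np.full((40, 3), 0.5), columns=[1, 2, 3])
        vals = {perm: ebm_loglik(perm, P) for perm in itertools.permutations([1, 2, 3])}
        ref = 40 * 3 * math.log(0.5)
        for v in vals.values():
            assert v == pytest.approx(ref, rel=1e-12)

    def test_dominance(self):
        P = pd.DataFrame(np.tile([1.0, 1.0, 0.0], (30, 1)), columns=[1, 2, 3])
        good = max(ebm_loglik(p, P) for p in [(1, 2, 3), (2, 1, 3)])
        for perm in itertools.permutations([1, 2, 3]):
            if 3 in perm[:2]:
                assert ebm_loglik(perm, P) < good - 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        P = pd.DataFrame(rng.uniform(0, 1, size=(50, 3)), columns=[1, 2, 3])
        for perm in itertools.permutations([1, 2, 3]):
            assert ebm_loglik(perm, P) == pytest.approx(
                brute_force_loglik(perm, P), rel=1e-10)

    def test_subject_permutation_invariance(self):
        rng = np.random.default_rng(4)
        P = pd.DataFrame(rng.uniform(0, 1, size=(30, 4)), columns=[1, 2, 3, 4])
        shuffled = P.sample(frac=1.0, random_state=1)
        assert ebm_loglik((2, 4, 1, 3), P) == pytest.approx(
            ebm_loglik((2, 4, 1, 3), shuffled), rel=1e-12)

    def test_rejects_non_permutation(self):
        P = pd.DataFrame(np.full((5, 3), 0.5), columns=[1, 2, 3])
        with pytest.raises(ValueError):
            ebm_loglik((1, 1, 2), P)


class TestFitEventSequence:
    def test_equals_brute_force_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            P = pd.DataFrame(rng.uniform(0, 1, size=(50, 3)), columns=[1, 2, 3])
            best_brute = max(itertools.permutations([1, 2, 3]),
                             key=lambda p: brute_force_loglik(p, P))
            fit = fit_event_sequence(P, seed=0)
            assert fit.log_likelihood == pytest.approx(
                brute_force_loglik(best_brute, P), rel=1e-10)

    def test_k2_exhaustive(self):
        P = pd.DataFrame({1: [0.1, 0.2, 0.1], 2: [0.9, 0.8, 0.7]})
        fit = fit_event_sequence(P)
        assert fit.ordering == (2, 1)

    def test_staged_data_recovers_order(self):
        P = staged_probability_matrix(n_per_stage=20, k=4, seed=6)
        assert fit_event_sequence(P).ordering == (1, 2, 3, 4)

    def test_greedy_matches_exhaustive(self):
        rng = np.random.default_rng(7)
        P = pd.DataFrame(rng.uniform(0, 1, size=(60, 5)), columns=[1, 2, 3, 4, 5])
        ex = fit_event_sequence(P, method="exhaustive")
        gr = fit_event_sequence(P, method="greedy", n_restarts=50, seed=1)
        assert gr.log_likelihood == pytest.approx(ex.log_likelihood, rel=1e-10)


class TestOrderingUncertainty:
    def test_noiseless_staged_data_gives_identity(self):
        P = staged_probability_matrix(n_per_stage=30, k=3, p_hi=0.999, p_lo=0.001, seed=8)
        dens = ordering_uncertainty(P, n_mc=300, seed=0)
        np.testing.assert_allclose(np.diag(dens.to_numpy()), 1.0)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(9)
        P = pd.DataFrame(rng.uniform(0, 1, size=(40, 4)), columns=[1, 2, 3, 4])
        dens = ordering_uncertainty(P, n_mc=500, seed=0)
        np.testing.assert_allclose(dens.sum(axis=1), 1.0, rtol=1e-12)

    def test_uniform_data_approaches_uniform_density(self):
        # no cluster is special, so averaged over data draws the positional
        # density converges to 1/k everywhere
        rng = np.random.default_rng(10)
        acc = np.zeros((3, 3))
        n_rep = 40
        for i in range(n_rep):
            P = pd.DataFrame(rng.uniform(0, 1, size=(25, 3)), columns=[1, 2, 3])
            acc += ordering_uncertainty(P, n_mc=200, seed=i).to_numpy()
        assert np.abs(acc / n_rep - 1 / 3).max() < 0.15

    def test_invalid_n_mc(self):
        P = pd.DataFrame(np.full((5, 2), 0.5), columns=[1, 2])
        with pytest.raises(ValueError):
            ordering_uncertainty(P, n_mc=0)


class TestStageRois:
    def test_identity_and_reversal(self):
        labels = {f"r{i}": i for i in range(1, 6)}
        seq = EventSequence(ordering=(1, 2, 3, 4, 5), log_likelihood=0.0)
        rois = stage_rois(labels, seq)
        assert rois == {i: (f"r{i}",) for i in range(1, 6)}
        rev = stage_rois(labels, EventSequence(ordering=(5, 4, 3, 2, 1), log_likelihood=0.0))
        assert rev == {i: (f"r{6 - i}",) for i in range(1, 6)}

    def test_stages_disjoint_and_exhaustive(self, small_probs):
        cfg, _, _, probs = small_probs
        import taustage as ts

        labels = ts.true_stage_map(cfg)
        cp = average_cluster_probabilities(probs, labels)
        seq = fit_event_sequence(cp)
        rois = stage_rois(labels, seq)
        all_regions = [r for regions in rois.values() for r in regions]
        assert sorted(all_regions) == sorted(probs.columns)

    def test_earliest_stage_is_medial_temporal_on_calibrated_generator(self, small_probs):
        cfg, _, _, probs = small_probs
        import taustage as ts

        labels = ts.true_stage_map(cfg)
        cp = average_cluster_probabilities(probs, labels)
        rois = stage_rois(labels, fit_event_sequence(cp))
        assert set(rois[1]) == {"entorhinal", "hippocampus", "amygdala"}
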