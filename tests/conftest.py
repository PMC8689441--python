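import numpy as np
import pandas as pd
import pytest

import taustage as ts

#: ~200 subjects at the study's group proportions
SMALL_SIZES = {"Ab- CU": 80, "Ab+ CU": 29, "Ab- MCI": 21, "Ab+ MCI": 34, "AD dementia": 36}


@pytest.fixture(scope="session")
def default_config():
    return ts.default_config(seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """One generated ~200-subject cohort shared across read-only tests."""
    cfg = ts.default_config(seed=42, group_sizes=SMALL_SIZES)
    cohort, panel = ts.generate_cohort(cfg)
    return cfg, cohort, panel


@pytest.fixture(scope="session")
def small_probs(small_cohort):
    """Tau-positive probability matrix for the shared cohort."""
    from taustage.positivity import fit_positivity_models, probability_matrix

    cfg, cohort, panel = small_cohort
    models = fit_positivity_models(panel, n_restarts=3, seed=1)
    return cfg, cohort, panel, probability_matrix(panel, models)


def staged_probability_matrix(n_per_stage=20, k=3, p_hi=0.95, p_lo=0.05, seed=0):
    """Subjects at every true stage 0..k with crisp cluster probabilities."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(k + 1):
        for _ in range(n_per_stage):
            rows.append([p_hi if c <= s else p_lo for c in range(1, k + 1)])
    out = pd.DataFrame(rows, columns=list(range(1, k + 1)))
    return out.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)
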