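# taustage

Data-driven tau-PET staging, longitudinal change, biomarker prediction and
clinical-trial enrichment analysis for Alzheimer's disease research.

Longitudinal tau PET is increasingly used as an outcome in AD trials, which
raises two practical questions: *where* to measure change (which regions
form coherent stages of tau spread), and *who* to enrol (which baseline
biomarkers predict accumulation, and how much does enriching on them shrink
a trial).  `taustage` implements the full chain for researchers working
with regional SUVR summaries:

1. **Tau positivity** — per bilateral region, a 2-component Gaussian
   mixture on baseline SUVR converts each value into the posterior
   probability of the abnormal (higher-mean) component,
   `P(abnormal | SUVR)`.
2. **Stage ROIs** — bootstrap consensus clustering groups regions by their
   positivity profiles (stability matrix, silhouette-selected k), and an
   event-based model (EBM) orders the cluster-ROIs: with a uniform prior
   over a subject's unknown stage `s ∈ {0..k}`, the likelihood of an
   ordering is `Σ_s Π_{j≤s} p_j Π_{j>s} (1−p_j)` per subject, maximised
   over permutations, with bootstrap positional-uncertainty estimates.
3. **Annual change** — `((follow-up − baseline)/baseline)·100/Δt` %/yr
   within each stage ROI, summarised per diagnostic group with t-based 95%
   CIs and one-sample t tests.
4. **Predictors** — OLS of annual change on each z-scored biomarker
   (+ age and sex) vs a demographics-only model (adjusted R², ΔAIC), and
   backward stepwise AIC selection with the "fewest predictors within 2 AIC
   of the minimum" parsimony rule.
5. **Trial power** — per-arm `n = 2σ²(z_{1−α/2}+z_{power})²/(f·μ)²` to
   detect a fractional reduction `f` (default 30%) of mean annual change,
   and the percent sample-size reduction from enrolling only subjects with
   biomarker z ≥ 2 (vs amyloid-negative controls), with bootstrap CIs.

Because the clinical cohorts this analysis style comes from are not publicly
deposited, the package includes a first-class synthetic-cohort generator
(`taustage.cohort`) calibrated to published group-level characteristics —
five diagnostic groups, baseline SUVR and annual-change means/SDs per stage,
scan intervals, and biomarker distributions with configurable
biomarker–change correlations — built on a two-state disease-progression
cascade with a known ground-truth event sequence, so every downstream stage
is testable.  See `docs/methods.md` for the model and its limitations.

## Worked example

```python
import taustage as ts
from taustage.positivity import fit_positivity_models, probability_matrix
from taustage.staging import (consensus_cluster, average_cluster_probabilities,
                              fit_event_sequence, stage_rois)
from taustage.change import stage_change_table, group_change_summary
from taustage.power import required_sample_size

cfg = ts.default_config(seed=7)                  # calibrated 343-subject cohort
cohort, panel = ts.generate_cohort(cfg)

models = fit_positivity_models(panel, seed=7)    # one GMM per region
probs = probability_matrix(panel, models)        # subject x region P(abnormal)

sol = consensus_cluster(probs, range(2, 9), n_boot=100, seed=7)
print("chosen k:", sol.chosen_k)
cp = average_cluster_probabilities(probs, sol.labels)
stages = stage_rois(sol.labels, fit_event_sequence(cp))
print("stage I regions:", stages[1])

tab = stage_change_table(panel, stages, cohort.set_index("subject_id")["interval_years"])
summ = group_change_summary(tab, cohort)
row = summ[(summ.group == "Ab+ CU") & (summ.stage == 1)].iloc[0]
print(f"Ab+ CU stage I annual change: {row['mean']:.2f} %/yr "
      f"(95% CI {row['ci_low']:.2f} to {row['ci_high']:.2f}, n={row['n']})")
print("n per arm for a 30% slowing at 80% power:",
      required_sample_size(row["mean"], 4.57))
```

Output:

```
chosen k: 5
stage I regions: ('amygdala', 'entorhinal', 'hippocampus')
Ab+ CU stage I annual change: 3.69 %/yr (95% CI 2.47 to 4.92, n=49)
n per arm for a 30% slowing at 80% power: 267
```

The silhouette-selected 5-cluster solution re-derives the familiar staging
gradient — the earliest stage is the medial temporal lobe (entorhinal
cortex, hippocampus, amygdala), with temporal neocortex next and
sensorimotor/occipital cortex last — and amyloid-positive cognitively
unimpaired individuals accumulate ~3.7%/yr in stage I, so a 30%-slowing
trial using that outcome unenriched needs ~267 subjects per arm.

A command-line interface mirrors the library:
`taustage simulate | fit-positivity | stage | annual-change | predictors |
power | run` (see `taustage --help`); `taustage run --seed 1 --out out/`
executes the whole pipeline and writes every intermediate table plus a
machine-readable `summary.json`.

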