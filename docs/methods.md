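# Methods

`taustage` re-implements, as a reusable tested pipeline, a biomarker analysis
of longitudinal tau-PET in Alzheimer's disease: data-driven derivation of
stage ROIs from baseline scans, computation of annual percent change in SUVR
within those ROIs, comparison of baseline fluid/imaging biomarkers as
predictors of that change, and a power analysis of biomarker-enriched
clinical trials.  Because the underlying clinical cohorts are not publicly
deposited, the package ships a synthetic-cohort generator calibrated to the
published participant-characteristics table; all tests and the acceptance
script run against that generator.

## Synthetic cohort generator

**Groups and marginals.** Five diagnostic groups (Aβ− CU, Aβ+ CU, Aβ− MCI,
Aβ+ MCI, AD dementia; default sizes 137/49/36/58/63) with group-wise means
and SDs for baseline SUVR per stage cluster, annual percent change per stage
(SDs implied from the published means and 95% CIs via
`SD = (hi − lo)/(2·1.96)·√n` at the published n), scan intervals (truncated
normal with the published mean/SD/range), and plasma/imaging biomarkers.
The published table shows no Aβ− MCI column; that group's stage-I change
(1.80 %/yr, CI 0.76–2.84, n = 36) comes from the running text and its other
parameters are extrapolations between the Aβ− CU and Aβ+ MCI columns.
Plasma p-tau181 values are realistic immunoassay-scale inventions (the
calibration table reports p-tau217).  AD-dementia Centiloids are emitted as
missing, mirroring the source design in which amyloid PET is not acquired in
dementia; amyloid status falls back to the diagnostic label there.

**Two-state stage-onset cascade.** Regional tau burden follows the standard
disease-progression picture that also motivates the event-based model:
every subject carries a latent severity `s ~ N(μ_g, 1)` whose mean `μ_g`
increases across diagnostic groups (−1.7, −1.2, −0.2, 0.6, 1.6 from Aβ− CU
to AD dementia), and stage cluster `c` turns abnormal once severity exceeds
an onset `τ_c` that increases along the ground-truth event sequence
(defaults −0.4, 0.5, 1.1, 1.45, 2.3).  Within a group × cluster cell the
SUVR distribution is a two-state mixture: a *normal* state anchored at the
Aβ− CU level for that cluster, and an *abnormal* state whose mean and SD are
solved from the cell's configured (mean, SD) given the cascade prevalence
`p = Φ(μ_g − τ_c)` — so the published group-level moments are reproduced
exactly in expectation while abnormality prevalence falls with stage within
every group.  Where a cell's moments are incompatible with the cascade
prevalence (the mixture moment equations bound prevalence from below by
`Δ²/(excess variance + Δ²)`), prevalence is raised to that bound; cells with
no real elevation over the normal state are generated as a single Gaussian.
Cluster memberships are nested through a shared severity factor (loading
0.95, i.e. near-deterministic staging with modest idiosyncratic deviation);
the onset spacing and loading were fixed once so that the cascade is clearly
staged and its generating order identifiable from the generator's own
output, which is the generator's purpose.  Regions within a cluster add
independent N(0, 0.05) SUVR noise around the cluster value, and SUVR is
floored at 0.1.

**Longitudinal change and biomarkers.** Each subject draws one annual
percent change per cluster from the configured group × stage (mean, SD);
follow-up SUVR is `baseline · (1 + change·Δt/100)` region-wise, so the
annual-change formula applied to the generated panel recovers the drawn
value to machine precision.  The change in the group's *target* stage (I for
CU groups, II for Aβ+ MCI, IV for AD) is coupled to baseline target-stage
SUVR (correlation 0.36/0.66/0.50 in Aβ+ CU/Aβ+ MCI/AD) and, through a
one-factor linear latent model, to each biomarker at its configured
raw-scale correlation (e.g. plasma p-tau217: 0.53 in Aβ+ CU, 0.49 in Aβ+
MCI, matching the published standardized coefficients in magnitude).
Correlations are exact by construction up to physiologic clipping of
biomarker tails.

**What the generator does not emulate:** within-subject test–retest
measurement error of PET (the source analysis could not estimate it either),
skewed biomarker marginals (Gaussians with the published SDs are used, which
makes the z ≥ 2 screen noticeably stricter for plasma p-tau217 than in the
real cohort), longitudinal biomarker drift, attrition, and any image-space
structure — generation starts at regional SUVR summaries.  Passing tests
therefore demonstrate correctness of the statistical machinery under a
faithful but idealised cohort, not performance on real PET data.

## Tau positivity

Per region, a 2-component Gaussian mixture is fit on all pooled baseline
SUVR values (sklearn EM; candidates = a median quantile-split initialisation
plus 10 random restarts, best final log-likelihood wins; variance floor
1e-4; tolerance 1e-6; max 500 iterations; ≥ 20 finite values required).
Component variances are free: tying them biases the abnormal-component mean
on reference mixtures with unequal spreads.  The tau-positive probability is
the Bayes posterior of the higher-mean component; with unequal variances
this posterior is monotone in SUVR across the data range but not in the far
tails, where the wider component dominates on both sides.

## Stage ROIs: consensus clustering and event ordering

Consensus clustering bootstraps subjects (default 100 resamples); regions
are clustered within each resample by average-linkage agglomeration on
correlation distance between their probability profiles, co-assignment
frequencies form the stability matrix, and the final partition cuts
(1 − stability) at each candidate k.  The silhouette score on the
(1 − stability) distances selects k (ties toward smaller k).

The event-based model consumes cluster-averaged tau-positive probabilities
directly (probabilities clamped to [1e-6, 1 − 1e-6]).  With a uniform prior
over a subject's unknown stage s ∈ {0..k}, the subject likelihood of an
ordering multiplies `p` for events at or before s and `(1 − p)` after s,
summed over s; the fitted sequence maximises the summed log-likelihood —
exhaustively for k ≤ 6, otherwise by greedy pairwise-swap ascent from 50
random restarts.  Ordering uncertainty uses subject-level bootstrap refits
(default 10 000); for k ≤ 6 each bootstrap is computed exactly as a
multinomial reweighting of precomputed per-permutation subject
log-likelihoods, which is algebraically identical to refitting on a resample.

## Annual change and group summaries

Annual change is `((follow-up − baseline)/baseline)·100/Δt` in %/yr, with
stage-level SUVR the unweighted mean over member regions (volume weights
optional) at each timepoint.  Subjects lacking a complete follow-up are
excluded and counted.  Group × stage summaries report mean, Student-t 95%
CI, a two-sided one-sample t test against zero (p < .05 flagged
significant), and min/max; groups with n < 2 or zero variance are flagged
without a CI.

## Predictor models and selection

Biomarkers are z-scored against the Aβ− CU reference group and sign-aligned
so larger z means more abnormal (Aβ42/40, hippocampal volume, and cortical
thickness are flipped).  Each biomarker enters an OLS of annual change with
age and sex as covariates; the comparator is the age+sex model on identical
complete cases.  Reported: the standardized coefficient
(slope·sd(x)/sd(y)), two-sided p, adjusted R² with a 2000-resample
percentile bootstrap CI, and ΔAIC, where AIC = −2·loglik + 2·k counts the
Gaussian residual variance as a parameter.  Backward stepwise selection
starts from all predictors (covariates always retained), removes at each
step the predictor whose removal minimises AIC down to a single predictor,
and selects the fewest-predictor model within 2 AIC (inclusive) of the path
minimum.  Complete cases are fixed at the full model for the whole path so
AICs remain comparable.

## Trial power and enrichment

For a two-arm trial detecting a fractional reduction `f` (default 30%) of
the mean annual change, the per-arm size is the two-sided normal
approximation `n = 2σ²(z_{1−α/2} + z_{power})²/(f·μ)²` (α = 0.05, power =
0.80 by default — the source does not state these; they are exposed in
`TrialDesign`), rounded up, and cross-checked by a vectorised two-sample-t
Monte-Carlo simulator.  Enrichment retains subjects with sign-aligned
biomarker z ≥ 2 relative to Aβ− CU (intersection rule by default; a union
rule is available).  The percent sample-size reduction
`100·(1 − n_enriched/n_full)` uses the continuous (un-ceiled) formula so it
is a smooth function of the observed (μ, σ); subject-level bootstrap (2000
resamples) gives a percentile 95% CI, and an OLS of change on the criteria
z-scores vs an intercept-only model yields the ΔAIC reported alongside.
Enriched subsets with n < 5 or non-positive mean change are flagged and
reported without a sample size.  Because variances are taken from the
observed subpopulation without shrinkage and measurement error is not
modelled, reductions on small groups are noisy — visible in the wide
bootstrap CIs.

## Orchestration and reproducibility

`run_pipeline` chains simulate → positivity → staging → change → predictors
→ power from a single config, writes every intermediate as tidy CSV (UTF-8,
comma, header, "." decimal) plus JSON models/reports, and derives all stage
seeds from one master seed; two runs with the same config are
byte-identical (timings go to the log only).  A validation-cohort style
replication is a re-run with alternative biomarker columns (e.g. p-tau181
in place of p-tau217) — no separate code path.  If the panel has no
follow-up scans the pipeline writes the staging outputs and stops with an
explicit error.

## Problem sizes used in the shipped checks

The test-suite simulations use ~200-subject cohorts at the study's group
proportions for ordering recovery (100 seeds), 1000 size-49 replicates for
CI coverage, 20 seeds of 25-region block matrices for consensus clustering,
10 000 Monte-Carlo trials per power check, and n = 100 000 for screening
fractions.  `scripts/acceptance.py` runs the full 343-subject default
configuration end to end.

## Known limitations

* Stage II/III and IV/V of the published table are nearly exchangeable in
  group-level moments; identifiability of the full 5-event order therefore
  leans on the cascade structure the generator imposes, and a few percent of
  simulated ~200-subject cohorts still swap adjacent late events.
* Gaussian biomarker marginals make z ≥ 2 screens stricter than in skewed
  real data; intersection-rule enrichment in the small Aβ+ CU group is often
  flagged as too small rather than quantified.
* The EBM here marginalises subject stage with a uniform prior and does not
  produce per-subject stage assignments; no mixed-effects longitudinal
  modelling (two-timepoint differences only).
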