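"""Orchestration: run the full analysis chain reproducibly from one config.

simulate (or load) -> tau positivity -> consensus staging + event ordering ->
annual change -> predictor comparison & stepwise selection -> enrichment
power analysis.  Every intermediate table is written as tidy CSV and the
machine-readable results as JSON; reruns with identical config and seeds are
byte-identical (timing/version information goes to the log only).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import change as change_mod
from . import positivity as pos_mod
from . import power as power_mod
from . import predictors as pred_mod
from . import staging as staging_mod
from .cohort import BIOMARKERS, GeneratorConfig, default_config, generate_cohort

log = logging.getLogger(__name__)

CENTILOID_THRESHOLD = 19.0
TAU_PET_PREDICTOR = "tau_pet"  # baseline SUVR in the group's outcome stage


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    generator: Optional[GeneratorConfig] = None
    cohort_csv: Optional[str] = None
    panel_csv: Optional[str] = None
    centiloid_threshold: float = CENTILOID_THRESHOLD
    analysis_groups: Tuple[str, ...] = ("Ab+ CU", "Ab+ MCI")
    stage_targets: Dict[str, int] = field(
        default_factory=lambda: {"Ab+ CU": 1, "Ab+ MCI": 2, "AD dementia": 4})
    predictors: Tuple[str, ...] = (
        "plasma_ab42_40", "centiloid", "plasma_ptau217", "plasma_nfl",
        "hippocampal_volume", "ad_cortex_thickness", TAU_PET_PREDICTOR)
    reference_group: str = "Ab- CU"
    design: power_mod.TrialDesign = field(default_factory=power_mod.TrialDesign)
    z_threshold: float = power_mod.DEFAULT_Z_THRESHOLD
    k_range: Tuple[int, ...] = tuple(range(2, 9))
    n_boot_consensus: int = 100
    n_mc_ordering: int = 10_000
    n_boot_r2: int = 1000
    n_boot_power: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generator is None and (self.cohort_csv is None or self.panel_csv is None):
            self.generator = default_config(seed=self.seed)


def assign_ab_status(cohort: pd.DataFrame, threshold: float = CENTILOID_THRESHOLD) -> pd.DataFrame:
    """Label amyloid status from Centiloids (>= threshold is positive, boundary inclusive).

    Rows with missing Centiloid keep a pre-existing ``ab_status`` column;
    lacking both is an error.
    """
    out = cohort.copy()
    has_cl = "centiloid" in out.columns
    has_status = "ab_status" in out.columns
    if not has_cl and not has_status:
        raise ValueError("need a 'centiloid' or 'ab_status' column to assign amyloid status")
    if has_cl:
        cl = out["centiloid"]
        status = np.where(cl >= threshold, "Ab+", "Ab-")
        if has_status:
            status = np.where(cl.isna(), out["ab_status"], status)
        elif cl.isna().any():
            raise ValueError("missing centiloid values and no 'ab_status' fallback column")
        out["ab_status"] = status
    return out


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(payload, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def read_panel(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def _tau_pet_z(changes: pd.DataFrame, cohort: pd.DataFrame, stage: int, reference_group: str) -> pd.Series:
    """z-score of baseline stage-ROI SUVR against the reference group."""
    ch = changes[changes["stage"] == stage][["subject_id", "baseline_suvr"]].set_index("subject_id")
    ref_ids = cohort.loc[cohort["group"] == reference_group, "subject_id"]
    ref = ch["baseline_suvr"].reindex(ref_ids).dropna()
    if ref.empty or ref.std(ddof=1) == 0:
        raise PipelineError(f"predictors: reference group {reference_group!r} has no usable baseline SUVR for stage {stage}")
    return (ch["baseline_suvr"] - ref.mean()) / ref.std(ddof=1)


def run_pipeline(config: PipelineConfig, outdir) -> Dict:
    """Execute every stage, writing all intermediates under ``outdir``.

    Returns the machine-readable summary (also written to summary.json).
    Raises :class:`PipelineError` naming the failing stage.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    # --- data ---------------------------------------------------------
    if config.cohort_csv is not None and config.panel_csv is not None:
        cohort = read_cohort(config.cohort_csv)
        panel = read_panel(config.panel_csv)
    else:
        cohort, panel = generate_cohort(config.generator)
        config.generator.to_json(out / "generator_config.json")
    try:
        cohort = assign_ab_status(cohort, config.centiloid_threshold)
    except ValueError as e:
        raise PipelineError(f"ab-status: {e}") from e
    cohort.to_csv(out / "cohort.csv", index=False)
    panel.to_csv(out / "panel.csv", index=False)
    log.info("cohort: %d subjects, %d panel rows", len(cohort), len(panel))

    # --- tau positivity ----------------------------------------------
    try:
        models = pos_mod.fit_positivity_models(panel, seed=config.seed + 11)
        probs = pos_mod.probability_matrix(panel, models)
    except (ValueError, RuntimeError) as e:
        raise PipelineError(f"positivity: {e}") from e
    pos_mod.models_to_json(models, out / "positivity_models.json")
    probs.to_csv(out / "probabilities.csv")
    log.info("positivity: fitted %d regional mixtures (%.1fs)", len(models), time.time() - t0)

    # --- staging ------------------------------------------------------
    try:
        consensus = staging_mod.consensus_cluster(
            probs, k_range=config.k_range, n_boot=config.n_boot_consensus, seed=config.seed + 23)
        cluster_probs = staging_mod.average_cluster_probabilities(probs, consensus.labels)
        sequence = staging_mod.fit_event_sequence(cluster_probs, seed=config.seed + 31)
        density = staging_mod.ordering_uncertainty(
            cluster_probs, n_mc=config.n_mc_ordering, seed=config.seed + 37)
        stages = staging_mod.stage_rois(consensus.labels, sequence)
    except ValueError as e:
        raise PipelineError(f"staging: {e}") from e
    consensus.stability_matrix.to_csv(out / "stability_matrix.csv")
    density.to_csv(out / "positional_density.csv")
    _write_json({str(k): list(v) for k, v in stages.items()}, out / "stages.json")
    with open(out / "stages.tsv", "w", encoding="utf-8") as fh:
        for s in sorted(stages):
            for r in stages[s]:
                fh.write(f"{r}\t{s}\n")
    log.info("staging: chosen k=%d, ordering=%s (%.1fs)",
             consensus.chosen_k, sequence.ordering, time.time() - t0)

    summary: Dict = {
        "seed": config.seed,
        "centiloid_threshold": config.centiloid_threshold,
        "design": config.design,
        "chosen_k": consensus.chosen_k,
        "silhouette_by_k": {str(k): v for k, v in consensus.silhouette.items()},
        "event_ordering": list(sequence.ordering),
        "event_log_likelihood": sequence.log_likelihood,
        "stages": {str(k): list(v) for k, v in stages.items()},
    }

    # --- longitudinal change -----------------------------------------
    has_followup = (panel["timepoint"] == "followup").any()
    if not has_followup:
        _write_json(summary, out / "summary.json")
        raise PipelineError(
            "longitudinal-change: no follow-up scans in the panel; "
            "pipeline stopped after staging (staging outputs were written)")
    intervals = cohort.set_index("subject_id")["interval_years"]
    try:
        changes = change_mod.stage_change_table(panel, stages, intervals)
    except ValueError as e:
        raise PipelineError(f"longitudinal-change: {e}") from e
    group_summary = change_mod.group_change_summary(changes, cohort)
    changes.to_csv(out / "annual_changes.csv", index=False)
    group_summary.to_csv(out / "group_change_summary.csv", index=False)
    summary["group_change_summary"] = group_summary.to_dict(orient="records")

    # --- predictors & power ------------------------------------------
    cohort_enc = pred_mod.encode_sex(cohort)
    biomarker_cols = [b for b in BIOMARKERS if b in cohort.columns and b in config.predictors]
    try:
        z_table = pred_mod.zscore_biomarkers(cohort_enc, biomarker_cols, config.reference_group)
    except ValueError as e:
        raise PipelineError(f"predictors: {e}") from e

    comparisons: List[pred_mod.ModelComparison] = []
    selections: Dict[str, pred_mod.SelectionPath] = {}
    reports: List[power_mod.EnrichmentReport] = []
    for gi, group in enumerate(config.analysis_groups):
        stage = config.stage_targets.get(group)
        if stage is None or stage not in stages:
            raise PipelineError(f"predictors: no outcome stage configured for group {group!r}")
        ztab = z_table.copy()
        if TAU_PET_PREDICTOR in config.predictors:
            ztab[TAU_PET_PREDICTOR] = _tau_pet_z(changes, cohort, stage, config.reference_group)
        mask = cohort_enc["group"] == group
        sub = cohort_enc[mask].set_index("subject_id")
        data = ztab.join(sub[["age", "sex_male"]], how="inner").dropna(subset=["age"])
        outcome = changes[changes["stage"] == stage].set_index("subject_id")["annual_change"]
        data["annual_change"] = outcome
        data = data[data.index.isin(sub.index)]

        preds = [p for p in config.predictors if p in data.columns and data[p].notna().any()]
        for pi, p in enumerate(preds):
            try:
                comparisons.append(pred_mod.fit_single_predictor(
                    data, "annual_change", p, group=group,
                    n_boot=config.n_boot_r2, seed=config.seed + 101 + 13 * gi + pi))
            except ValueError as e:
                log.warning("predictors: skipping %s in %s: %s", p, group, e)
        try:
            path = pred_mod.backward_stepwise(data, "annual_change", preds)
        except ValueError as e:
            raise PipelineError(f"predictors: stepwise failed for {group!r}: {e}") from e
        selections[group] = path
        pred_mod.path_table(path).to_csv(out / f"selection_path_{group.replace(' ', '_')}.csv", index=False)

        # enrichment: each selected biomarker alone, plus the combination (both rules)
        crit_sets = [({b: config.z_threshold}, "all") for b in path.selected]
        if len(path.selected) > 1:
            combined = {b: config.z_threshold for b in path.selected}
            crit_sets += [(combined, "all"), (combined, "any")]
        for ci, (crit, rule) in enumerate(crit_sets):
            reports.append(power_mod.sample_size_reduction(
                cohort_enc[mask], ztab, changes, stage, crit,
                design=config.design, n_boot=config.n_boot_power,
                seed=config.seed + 211 + 29 * gi + ci, rule=rule, group=group))

    pred_mod.comparison_table(comparisons).to_csv(out / "model_comparisons.csv", index=False)
    summary["model_comparisons"] = [dataclasses.asdict(c) for c in comparisons]
    summary["selection"] = {
        g: {"selected": list(p.selected), "selected_aic": p.selected_aic,
            "path": [dataclasses.asdict(s) for s in p.steps]}
        for g, p in selections.items()
    }
    summary["enrichment"] = [dataclasses.asdict(r) for r in reports]
    _write_json(summary["enrichment"], out / "enrichment_reports.json")
    _write_json(summary, out / "summary.json")
    log.info("pipeline complete in %.1fs", time.time() - t0)
    return summary
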