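"""Synthetic multi-group cohort generator for longitudinal tau-PET analyses.

Emulates a memory-clinic cohort spanning the Alzheimer's disease continuum:
five diagnostic groups (amyloid-negative/-positive cognitively unimpaired,
amyloid-negative/-positive mild cognitive impairment, AD dementia), each
subject carrying

* regional tau-PET SUVR at two timepoints for a set of bilateral cortical /
  medial-temporal regions organised into stage clusters with a known
  ground-truth event ordering,
* a scan interval in years,
* baseline fluid and imaging biomarkers (plasma Abeta42/40 ratio, amyloid-PET
  Centiloids, plasma p-tau217 / p-tau181, plasma NfL, hippocampal volume,
  AD-signature cortical thickness) correlated with the subject's annual
  tau-PET change in the group's target stage through a Gaussian one-factor
  copula.

The default configuration reproduces the group sizes, baseline SUVR
means/SDs, annual-change means (with SDs implied from the printed 95% CIs),
scan-interval distributions and biomarker means/SDs of the emulated cohort
study; every number is overridable through :class:`GeneratorConfig`.

Follow-up SUVR is constructed multiplicatively from the drawn annual percent
change, so applying the annual-percent-change formula to the generated panel
recovers the drawn per-subject change exactly (up to float round-off).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

GROUPS: Tuple[str, ...] = ("Ab- CU", "Ab+ CU", "Ab- MCI", "Ab+ MCI", "AD dementia")
AB_POSITIVE_GROUPS = frozenset({"Ab+ CU", "Ab+ MCI", "AD dementia"})

BIOMARKERS: Tuple[str, ...] = (
    "plasma_ab42_40",
    "centiloid",
    "plasma_ptau217",
    "plasma_ptau181",
    "plasma_nfl",
    "hippocampal_volume",
    "ad_cortex_thickness",
)

#: biomarkers whose *lower* values indicate abnormality (sign-flipped on z-scoring)
LOWER_IS_ABNORMAL = frozenset({"plasma_ab42_40", "hippocampal_volume", "ad_cortex_thickness"})

SUVR_FLOOR = 0.1

# physiologic clip bounds applied after copula sampling (keeps units sane)
_BIOMARKER_BOUNDS = {
    "plasma_ab42_40": (0.01, 0.60),
    "plasma_ptau217": (0.05, None),
    "plasma_ptau181": (0.05, None),
    "plasma_nfl": (1.0, None),
    "hippocampal_volume": (500.0, None),
    "ad_cortex_thickness": (1.0, 4.5),
}

#: default bilateral region membership of the five stage clusters
#: (medial temporal -> temporal neocortex -> parietal -> frontal -> sensorimotor/occipital)
DEFAULT_STAGE_REGIONS: Dict[int, Tuple[str, ...]] = {
    1: ("entorhinal", "hippocampus", "amygdala"),
    2: ("inferior_temporal", "middle_temporal", "fusiform", "temporal_pole", "parahippocampal"),
    3: ("inferior_parietal", "supramarginal", "precuneus", "posterior_cingulate", "isthmus_cingulate"),
    4: ("rostral_middle_frontal", "superior_frontal", "lateral_orbitofrontal", "caudal_middle_frontal", "frontal_pole"),
    5: ("precentral", "postcentral", "paracentral", "cuneus", "pericalcarine"),
}


def implied_sd_from_ci(mean: float, ci_low: float, ci_high: float, n: int) -> float:
    """Back out a sample SD from a normal-theory 95% CI of a mean.

    SD = (ci_high - ci_low) / (2 * 1.96) * sqrt(n).  The mean itself does not
    enter the formula; it is accepted so callers can pass table rows verbatim.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 to imply an SD, got n={n}")
    if not ci_low < ci_high:
        raise ValueError(f"require ci_low < ci_high, got ({ci_low}, {ci_high})")
    return (ci_high - ci_low) / (2.0 * 1.96) * math.sqrt(n)


def _changes_from_ci(rows: Mapping[int, Tuple[float, float, float]], n: int) -> Dict[int, Tuple[float, float]]:
    """Convert {stage: (mean, ci_low, ci_high)} into {stage: (mean, sd)}."""
    return {s: (m, implied_sd_from_ci(m, lo, hi, n)) for s, (m, lo, hi) in rows.items()}


@dataclass
class GeneratorConfig:
    """Full parameterisation of the synthetic cohort.

    All dictionaries are keyed by group label (see :data:`GROUPS`) and, where
    applicable, by stage-cluster id.  ``annual_change`` and ``baseline_suvr``
    hold (mean, sd) pairs; annual change is in %/yr, SUVR is unitless.
    """

    group_sizes: Dict[str, int]
    stage_regions: Dict[int, Tuple[str, ...]]
    baseline_suvr: Dict[str, Dict[int, Tuple[float, float]]]
    annual_change: Dict[str, Dict[int, Tuple[float, float]]]
    scan_interval: Dict[str, Tuple[float, float, float, float]]  # mean, sd, lo, hi
    biomarker_params: Dict[str, Dict[str, Optional[Tuple[float, float]]]]
    biomarker_change_corr: Dict[str, Dict[str, float]]
    suvr_change_corr: Dict[str, float]
    target_stage: Dict[str, int]
    age_params: Dict[str, Tuple[float, float]]
    female_fraction: Dict[str, float]
    severity_weight: float = 0.95     # loading of the shared disease-severity factor across clusters
    region_noise_sd: float = 0.05     # SUVR noise of a region around its cluster value
    stage_onsets: Optional[Dict[int, float]] = None       # severity onset per stage; default: evenly spaced
    group_progression: Optional[Dict[str, float]] = None  # mean latent severity per group
    min_prevalence: float = 0.05      # below this, a group x cluster cell is single-state
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stage_regions:
            raise ValueError("event sequence is empty: stage_regions has no clusters")
        for g, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"negative group size for {g!r}")
        for g, rows in self.baseline_suvr.items():
            for s, (_, sd) in rows.items():
                if sd <= 0:
                    raise ValueError(f"non-positive baseline SUVR SD for {g!r} stage {s}")
        for g, rows in self.annual_change.items():
            for s, (_, sd) in rows.items():
                if sd <= 0:
                    raise ValueError(f"non-positive annual-change SD for {g!r} stage {s}")
        for g, (m, sd, lo, hi) in self.scan_interval.items():
            if sd <= 0 or not (0 < lo < hi):
                raise ValueError(f"invalid scan-interval parameters for {g!r}: {(m, sd, lo, hi)}")
        for g, rows in self.biomarker_change_corr.items():
            for b, r in rows.items():
                if not -1.0 <= r <= 1.0:
                    raise ValueError(f"correlation out of [-1, 1] for {g!r}/{b!r}: {r}")
        for g, r in self.suvr_change_corr.items():
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"suvr_change_corr out of [-1, 1] for {g!r}: {r}")
        if not -1.0 <= self.severity_weight <= 1.0:
            raise ValueError("severity_weight must be in [-1, 1]")
        if self.region_noise_sd < 0:
            raise ValueError("region_noise_sd must be >= 0")

    @property
    def event_sequence(self) -> Tuple[int, ...]:
        """Ground-truth event ordering: stage-cluster ids in progression order."""
        return tuple(sorted(self.stage_regions))

    @property
    def regions(self) -> Tuple[str, ...]:
        return tuple(r for s in sorted(self.stage_regions) for r in self.stage_regions[s])

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True, default=str)

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)

        def _intkeys(d):
            return {int(k): v for k, v in d.items()}

        raw["stage_regions"] = {int(k): tuple(v) for k, v in raw["stage_regions"].items()}
        raw["baseline_suvr"] = {g: {int(k): tuple(v) for k, v in d.items()} for g, d in raw["baseline_suvr"].items()}
        raw["annual_change"] = {g: {int(k): tuple(v) for k, v in d.items()} for g, d in raw["annual_change"].items()}
        raw["scan_interval"] = {g: tuple(v) for g, v in raw["scan_interval"].items()}
        raw["biomarker_params"] = {
            g: {b: (None if v is None else tuple(v)) for b, v in d.items()} for g, d in raw["biomarker_params"].items()
        }
        raw["age_params"] = {g: tuple(v) for g, v in raw["age_params"].items()}
        if raw.get("stage_onsets"):
            raw["stage_onsets"] = {int(k): float(v) for k, v in raw["stage_onsets"].items()}
        return cls(**raw)


def default_config(seed: int = 0, group_sizes: Optional[Mapping[str, int]] = None) -> GeneratorConfig:
    """Configuration calibrated to the emulated cohort's characteristics table.

    Aβ− MCI is shown only partially in that table (the stage-I change comes
    from the running text); its remaining parameters are extrapolated between
    the Aβ− CU and Aβ+ MCI columns.  Plasma p-tau181 values are realistic
    immunoassay-scale inventions (the table reports p-tau217).
    """
    sizes = dict(group_sizes) if group_sizes is not None else {
        "Ab- CU": 137, "Ab+ CU": 49, "Ab- MCI": 36, "Ab+ MCI": 58, "AD dementia": 63,
    }

    baseline_suvr = {
        "Ab- CU":      {1: (0.97, 0.13), 2: (1.27, 0.11), 3: (1.26, 0.12), 4: (1.13, 0.11), 5: (1.18, 0.11)},
        "Ab+ CU":      {1: (1.17, 0.21), 2: (1.42, 0.39), 3: (1.35, 0.36), 4: (1.16, 0.17), 5: (1.19, 0.12)},
        "Ab- MCI":     {1: (1.05, 0.18), 2: (1.32, 0.15), 3: (1.30, 0.15), 4: (1.15, 0.12), 5: (1.19, 0.12)},
        "Ab+ MCI":     {1: (1.38, 0.32), 2: (1.61, 0.45), 3: (1.55, 0.54), 4: (1.20, 0.18), 5: (1.20, 0.14)},
        "AD dementia": {1: (1.71, 0.36), 2: (2.62, 0.94), 3: (2.37, 0.91), 4: (1.69, 0.86), 5: (1.52, 0.43)},
    }

    annual_change = {
        # SDs implied from the published mean (95% CI) rows at the published n,
        # independent of how many subjects are actually generated
        "Ab- CU": _changes_from_ci({
            1: (1.38, 0.80, 1.96), 2: (0.18, -0.14, 0.49), 3: (0.17, -0.26, 0.60),
            4: (0.19, -0.18, 0.56), 5: (0.13, -0.19, 0.65)}, 137),
        "Ab+ CU": _changes_from_ci({
            1: (4.04, 2.76, 5.32), 2: (2.31, 1.33, 2.83), 3: (2.21, 1.38, 3.04),
            4: (2.17, 1.25, 3.09), 5: (1.67, 0.71, 2.63)}, 49),
        "Ab- MCI": _changes_from_ci({
            1: (1.80, 0.76, 2.84), 2: (0.30, -0.52, 1.12), 3: (0.30, -0.52, 1.12),
            4: (0.30, -0.52, 1.12), 5: (0.20, -0.62, 1.02)}, 36),
        "Ab+ MCI": _changes_from_ci({
            1: (3.97, 2.97, 4.97), 2: (4.45, 3.41, 5.49), 3: (3.87, 2.63, 5.09),
            4: (2.45, 1.44, 3.46), 5: (2.61, 1.55, 3.67)}, 58),
        "AD dementia": _changes_from_ci({
            1: (3.98, 2.92, 5.04), 2: (4.81, 3.54, 6.08), 3: (5.18, 3.94, 6.42),
            4: (5.22, 3.95, 6.49), 5: (4.02, 2.87, 5.17)}, 63),
    }

    scan_interval = {
        "Ab- CU": (1.79, 0.19, 1.12, 2.07),
        "Ab+ CU": (1.78, 0.19, 0.85, 1.95),
        "Ab- MCI": (1.75, 0.22, 0.85, 2.11),
        "Ab+ MCI": (1.72, 0.24, 0.85, 2.11),
        "AD dementia": (1.54, 0.32, 0.73, 2.06),
    }

    biomarker_params: Dict[str, Dict[str, Optional[Tuple[float, float]]]] = {
        "Ab- CU": {
            "plasma_ab42_40": (0.22, 0.03), "centiloid": (-8.11, 6.33),
            "plasma_ptau217": (1.29, 2.67), "plasma_ptau181": (2.5, 1.2),
            "plasma_nfl": (12.40, 7.38), "hippocampal_volume": (3874.64, 437.76),
            "ad_cortex_thickness": (2.76, 0.12),
        },
        "Ab+ CU": {
            "plasma_ab42_40": (0.20, 0.03), "centiloid": (50.72, 21.27),
            "plasma_ptau217": (3.22, 2.39), "plasma_ptau181": (3.8, 1.6),
            "plasma_nfl": (17.65, 5.71), "hippocampal_volume": (3636.59, 513.74),
            "ad_cortex_thickness": (2.62, 0.16),
        },
        "Ab- MCI": {
            "plasma_ab42_40": (0.21, 0.03), "centiloid": (-5.0, 7.0),
            "plasma_ptau217": (1.8, 1.5), "plasma_ptau181": (2.8, 1.4),
            "plasma_nfl": (16.0, 8.0), "hippocampal_volume": (3500.0, 500.0),
            "ad_cortex_thickness": (2.68, 0.14),
        },
        "Ab+ MCI": {
            "plasma_ab42_40": (0.18, 0.04), "centiloid": (60.88, 25.44),
            "plasma_ptau217": (3.81, 2.14), "plasma_ptau181": (4.2, 1.8),
            "plasma_nfl": (18.91, 9.80), "hippocampal_volume": (3268.75, 520.90),
            "ad_cortex_thickness": (2.52, 0.15),
        },
        "AD dementia": {
            "plasma_ab42_40": (0.19, 0.04), "centiloid": None,  # amyloid PET not acquired in dementia
            "plasma_ptau217": (8.01, 4.38), "plasma_ptau181": (6.5, 2.5),
            "plasma_nfl": (28.47, 36.10), "hippocampal_volume": (2799.20, 421.44),
            "ad_cortex_thickness": (2.38, 0.20),
        },
    }

    # raw-scale correlation between each biomarker and the subject's annual
    # change in the group's target stage (negative where low values = abnormal)
    biomarker_change_corr = {
        "Ab- CU": {"plasma_ptau217": 0.20, "plasma_ptau181": 0.15, "plasma_nfl": 0.10},
        "Ab+ CU": {
            "plasma_ab42_40": -0.05, "centiloid": 0.32, "plasma_ptau217": 0.53,
            "plasma_ptau181": 0.45, "plasma_nfl": 0.10,
            "hippocampal_volume": -0.06, "ad_cortex_thickness": -0.07,
        },
        "Ab- MCI": {"plasma_ptau217": 0.20, "plasma_ptau181": 0.15, "plasma_nfl": 0.10},
        "Ab+ MCI": {
            "plasma_ab42_40": -0.24, "centiloid": 0.16, "plasma_ptau217": 0.49,
            "plasma_ptau181": 0.42, "plasma_nfl": 0.07,
            "hippocampal_volume": -0.18, "ad_cortex_thickness": -0.16,
        },
        "AD dementia": {
            "plasma_ab42_40": -0.10, "plasma_ptau217": 0.50, "plasma_ptau181": 0.45,
            "plasma_nfl": 0.10, "hippocampal_volume": -0.10, "ad_cortex_thickness": -0.10,
        },
    }

    suvr_change_corr = {"Ab- CU": 0.20, "Ab+ CU": 0.36, "Ab- MCI": 0.20, "Ab+ MCI": 0.66, "AD dementia": 0.50}
    target_stage = {"Ab- CU": 1, "Ab+ CU": 1, "Ab- MCI": 1, "Ab+ MCI": 2, "AD dementia": 4}
    age_params = {
        "Ab- CU": (72.57, 7.33), "Ab+ CU": (72.83, 7.52), "Ab- MCI": (71.0, 7.5),
        "Ab+ MCI": (71.79, 7.97), "AD dementia": (73.06, 6.90),
    }
    female_fraction = {"Ab- CU": 0.47, "Ab+ CU": 0.53, "Ab- MCI": 0.50, "Ab+ MCI": 0.55, "AD dementia": 0.56}

    return GeneratorConfig(
        group_sizes=sizes,
        stage_regions=dict(DEFAULT_STAGE_REGIONS),
        baseline_suvr=baseline_suvr,
        annual_change=annual_change,
        scan_interval=scan_interval,
        biomarker_params=biomarker_params,
        biomarker_change_corr=biomarker_change_corr,
        suvr_change_corr=suvr_change_corr,
        target_stage=target_stage,
        age_params=age_params,
        female_fraction=female_fraction,
        seed=seed,
    )


def _clip_biomarker(name: str, values: np.ndarray) -> np.ndarray:
    lo, hi = _BIOMARKER_BOUNDS.get(name, (None, None))
    return np.clip(values, lo, hi)


#: severity onsets of the default 5-stage cascade; the first two transitions
#: are spaced wider, matching the clearer medial-temporal vs neocortical split
DEFAULT_STAGE_ONSETS: Dict[int, float] = {1: -0.4, 2: 0.5, 3: 1.1, 4: 1.45, 5: 2.3}


def default_stage_onsets(stages: Sequence[int]) -> Dict[int, float]:
    """Severity onsets for an arbitrary stage set (evenly spaced over [-0.4, 2.3])."""
    order = sorted(stages)
    k = len(order)
    if k == 5:
        return {s: DEFAULT_STAGE_ONSETS[j] for j, s in zip(sorted(DEFAULT_STAGE_ONSETS), order)}
    if k == 1:
        return {order[0]: 0.6}
    return {s: -0.4 + 2.7 * j / (k - 1) for j, s in enumerate(order)}


#: mean latent severity per diagnostic group (units of the severity scale)
DEFAULT_GROUP_PROGRESSION: Dict[str, float] = {
    "Ab- CU": -1.7, "Ab- MCI": -1.2, "Ab+ CU": -0.2, "Ab+ MCI": 0.6, "AD dementia": 1.6,
}


def _abnormal_state(
    mean_gc: float, sd_gc: float, m0: float, s0: float, p: float
) -> Optional[Tuple[float, float, float]]:
    """Abnormal-state (mean, SD, prevalence) so that a two-state mixture with
    the normal state N(m0, s0) reproduces the configured group moments.

    The cascade prevalence ``p`` is raised to the moment-feasibility bound
    Delta^2 / (excess variance + Delta^2) when the configured moments demand
    a larger abnormal fraction with smaller separation.  Returns None when
    the cell shows no real elevation over the normal state, in which case it
    is generated as a single Gaussian at (mean_gc, sd_gc).
    """
    delta = mean_gc - m0
    if delta < 2e-2:
        return None
    excess = sd_gc**2 - s0**2
    if excess > 0:
        p_feas = delta**2 / (excess + delta**2)
        p = min(max(p, 1.02 * p_feas), 0.99)
    m1 = (mean_gc - (1.0 - p) * m0) / p
    if m1 <= m0 + 1e-3:
        return None
    s1_sq = (sd_gc**2 + mean_gc**2 - (1.0 - p) * (s0**2 + m0**2) - p * m1**2) / p
    if s1_sq <= 1e-4:
        return None
    return m1, math.sqrt(s1_sq), p


def generate_cohort(config: GeneratorConfig, seed: Optional[int] = None) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort table and a tidy regional SUVR panel from ``config``.

    Returns
    -------
    cohort : DataFrame
        One row per subject: ``subject_id, group, age, sex, ab_status,
        interval_years`` plus one column per biomarker.
    panel : DataFrame
        Tidy long table ``subject_id, region_label, timepoint, suvr`` with
        timepoints ``baseline`` and ``followup`` for every region.

    Deterministic given the seed.  Follow-up SUVR is
    ``baseline * (1 + change * dt / 100)`` region-wise, with a single drawn
    change per subject and cluster, so the annual-percent-change formula
    applied to (cluster-aggregated) output recovers the drawn value exactly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lam = config.severity_weight
    stages = sorted(config.stage_regions)

    cohort_rows = []
    panel_parts = []
    sid = 0
    for group in GROUPS:
        n = config.group_sizes.get(group, 0)
        if n == 0:
            continue
        ids = [f"S{j:05d}" for j in range(sid, sid + n)]
        sid += n

        severity = rng.standard_normal(n)
        # Two-state stage-onset cascade: a subject is tau-abnormal in cluster
        # c once their latent severity crosses the cluster's onset (onsets
        # increase with stage; groups differ in mean severity, so abnormality
        # prevalence falls with stage within every group).  Normal-state SUVR
        # is anchored at the reference-group level for all groups; the
        # abnormal state is solved per group x cluster so the configured
        # (mean, SD) are reproduced exactly in expectation.
        onsets = config.stage_onsets or default_stage_onsets(stages)
        progression = config.group_progression or DEFAULT_GROUP_PROGRESSION
        mu_g = progression.get(group, 0.0)
        ref_group = "Ab- CU" if "Ab- CU" in config.baseline_suvr else group
        zc = {}
        for s in stages:
            mean_gc, sd_gc = config.baseline_suvr[group][s]
            m0, s0 = config.baseline_suvr[ref_group][s]
            sev_c = mu_g + lam * severity + math.sqrt(1.0 - lam * lam) * rng.standard_normal(n)
            p = float(stats.norm.cdf(mu_g - onsets[s]))
            state = _abnormal_state(mean_gc, sd_gc, m0, s0, p) if p >= config.min_prevalence else None
            if state is None:
                vals = mean_gc + sd_gc * rng.standard_normal(n)
            else:
                m1, s1, p_eff = state
                # threshold set so realised prevalence matches p_eff while
                # keeping the severity-based nesting across clusters
                abnormal = sev_c > mu_g - stats.norm.ppf(p_eff)
                vals = np.where(abnormal,
                                m1 + s1 * rng.standard_normal(n),
                                m0 + s0 * rng.standard_normal(n))
            zc[s] = (vals - mean_gc) / sd_gc
        tstage = config.target_stage[group]
        rho_s = config.suvr_change_corr.get(group, 0.0)
        u0 = rho_s * zc[tstage] + math.sqrt(1.0 - rho_s * rho_s) * rng.standard_normal(n)

        changes = {}
        for s in stages:
            m, sd = config.annual_change[group][s]
            v = u0 if s == tstage else rng.standard_normal(n)
            changes[s] = m + sd * v

        dt = stats.truncnorm.rvs(
            *(lambda m, sd, lo, hi: ((lo - m) / sd, (hi - m) / sd, m, sd))(*config.scan_interval[group]),
            size=n, random_state=rng,
        )

        row = {
            "subject_id": ids,
            "group": group,
            "age": np.clip(rng.normal(*config.age_params[group], size=n), 45.0, 100.0),
            "sex": np.where(rng.random(n) < config.female_fraction[group], "F", "M"),
            "ab_status": "Ab+" if group in AB_POSITIVE_GROUPS else "Ab-",
            "interval_years": dt,
        }
        corr = config.biomarker_change_corr.get(group, {})
        for name in BIOMARKERS:
            params = config.biomarker_params[group].get(name)
            if params is None:
                row[name] = np.full(n, np.nan)
                continue
            m, sd = params
            if sd < 0:
                raise ValueError(f"negative biomarker SD for {group!r}/{name!r}")
            rho = corr.get(name, 0.0)
            vals = m + sd * (rho * u0 + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n))
            vals = _clip_biomarker(name, vals)
            if name == "centiloid":
                # keep amyloid status consistent with the diagnostic label at the default cut
                vals = np.maximum(vals, 19.0) if group in AB_POSITIVE_GROUPS else np.minimum(vals, 18.9)
            row[name] = vals
        cohort_rows.append(pd.DataFrame(row))

        for s in stages:
            m, sd = config.baseline_suvr[group][s]
            cluster_val = m + sd * zc[s]
            growth = np.maximum(1.0 + changes[s] * dt / 100.0, 1e-3)
            for region in config.stage_regions[s]:
                base = np.maximum(cluster_val + rng.normal(0.0, config.region_noise_sd, n), SUVR_FLOOR)
                fu = base * growth
                panel_parts.append(pd.DataFrame({
                    "subject_id": ids * 2,
                    "region_label": region,
                    "timepoint": ["baseline"] * n + ["followup"] * n,
                    "suvr": np.concatenate([base, fu]),
                }))

    cohort = pd.concat(cohort_rows, ignore_index=True)
    panel = pd.concat(panel_parts, ignore_index=True)
    return cohort, panel


def true_stage_map(config: GeneratorConfig) -> Dict[str, int]:
    """Ground-truth region -> stage-cluster labels of the generator."""
    return {r: s for s, regions in config.stage_regions.items() for r in regions}
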