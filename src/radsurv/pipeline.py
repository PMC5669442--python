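"""End-to-end orchestration: extraction, filtering, selection, modelling.

``run_analysis`` consumes a cohort table (clinical covariates + the three
radiomic feature sets) and produces a validated, JSON-serializable
:class:`AnalysisReport` covering every stage: ICC exclusions, redundancy
groups, optimal cutpoints, the univariate screening table, the top-k
features, the radiomic / clinical / combined Cox models, concordance
indices with bootstrap confidence intervals, pairwise bootstrap
comparisons, and median-linear-predictor risk groups.  Given a seed the
whole report is reproducible byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from radsurv.errors import DegenerateInputError, RadsurvError, ValidationError
from radsurv.features import FeatureConfig, extract_all
from radsurv.io import CohortTable, ImageVolume, SegmentationMask, load_mask, load_volume
from radsurv.selection import (
    SelectionReport,
    build_feature_set_triple,
    optimal_cutpoint,
    run_selection,
    univariate_cox,
)
from radsurv.stability import ReaderPairedFeatures, filter_unstable
from radsurv.survival import (
    SurvivalData,
    backward_stepwise,
    bootstrap_compare,
    cox_fit,
    km_curve,
    median_lp_risk_groups,
)

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """All knobs of the analysis, with the study's standard defaults."""

    icc_threshold: float = Field(0.9, ge=-1.0, le=1.0)
    r_threshold: float = Field(0.95, ge=0.0, le=1.0)
    use_abs_correlation: bool = False
    top_k: int = Field(4, ge=1)
    alpha_remove: float = Field(0.05, gt=0.0, lt=1.0)
    alpha_univariate_clinical: float = Field(0.20, gt=0.0, lt=1.0)
    min_group_frac: float = Field(0.10, ge=0.0, lt=0.5)
    bootstrap_B: int = Field(1000, ge=2)
    seed: int = 0
    icc_variant: str = "agreement"


class CovariateReport(BaseModel):
    name: str
    coef: float
    hr: float
    ci_lower: float
    ci_upper: float
    p: float


class ModelReport(BaseModel):
    name: str
    covariates: list[CovariateReport]
    dropped: list[str]
    concordance: float
    concordance_ci: Optional[tuple[float, float]] = None
    risk_group_hr: Optional[float] = None
    risk_group_ci: Optional[tuple[float, float]] = None
    risk_group_logrank_p: Optional[float] = None
    km_median_low: Optional[float] = None
    km_median_high: Optional[float] = None


class CutpointReport(BaseModel):
    set_name: str
    feature: str
    cutoff: float
    hr: float
    ci_lower: float
    ci_upper: float
    p_raw: float
    p_adjusted: Optional[float] = None
    group: int
    representative: bool
    selected: bool


class AnalysisReport(BaseModel):
    """The published schema of a full analysis run."""

    config: PipelineConfig
    n_patients: int
    n_events: int
    km_median_pfs: float
    icc_report: Optional[list[dict]] = None
    icc_excluded: Optional[list[str]] = None
    groups: dict[str, list[list[str]]]
    univariate: list[CutpointReport]
    top_features: list[str]
    models: list[ModelReport]
    comparisons: list[dict]

    def to_json(self) -> str:
        """Deterministic serialization (sorted keys, plain floats)."""
        return json.dumps(self.model_dump(mode="json"), sort_keys=True, indent=2)


# ---------------------------------------------------------------------------
# feature extraction over a set of cases
# ---------------------------------------------------------------------------


def extract_features_table(
    cases: Iterable[tuple[str, ImageVolume, SegmentationMask]],
    config: FeatureConfig | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Extract all 37 features for each (patient_id, volume, mask) case.

    Per-case failures are logged and the run continues; the ids of failed
    cases are returned alongside the wide feature table.
    """
    rows = {}
    failures = []
    for patient_id, volume, mask in cases:
        try:
            rows[patient_id] = extract_all(volume, mask, config)
        except RadsurvError as exc:
            logger.error("feature extraction failed for %s: %s", patient_id, exc)
            failures.append(patient_id)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "patient_id"
    return table, failures


def run_extract(
    manifest: str | Path | pd.DataFrame,
    config: FeatureConfig | None = None,
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Extract features for every case listed in a manifest.

    The manifest (CSV path or DataFrame) has columns ``patient_id``,
    ``timepoint`` (``baseline``/``followup``), ``volume_path``,
    ``mask_path``.  Returns one wide table per timepoint plus failed ids.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    required = {"patient_id", "timepoint", "volume_path", "mask_path"}
    if not required.issubset(manifest.columns):
        raise ValidationError(f"manifest must have columns {sorted(required)}")
    tables: dict[str, pd.DataFrame] = {}
    failures: list[str] = []

    def cases_for(tp: str):
        for row in manifest[manifest["timepoint"] == tp].itertuples():
            try:
                volume = load_volume(row.volume_path)
                mask = load_mask(row.mask_path, reference=volume)
            except RadsurvError as exc:
                logger.error("loading failed for %s/%s: %s", row.patient_id, tp, exc)
                failures.append(str(row.patient_id))
                continue
            yield str(row.patient_id), volume, mask

    for tp in manifest["timepoint"].unique():
        table, failed = extract_features_table(cases_for(str(tp)), config)
        tables[str(tp)] = table
        failures.extend(failed)
    return tables, failures


# ---------------------------------------------------------------------------
# clinical covariate encoding
# ---------------------------------------------------------------------------


def encode_clinical(
    cohort: CohortTable,
    times: np.ndarray,
    events: np.ndarray,
    min_group_frac: float = 0.10,
) -> pd.DataFrame:
    """Numeric clinical design matrix for the clinical Cox model.

    Age is dichotomized at its optimal log-rank cutoff (as is standard
    for this workflow); treatment response is coded responder = 1 so a
    hazard ratio below 1 means response is protective; tumour diameter
    stays continuous (per-mm hazard ratio).
    """
    data = cohort.data
    out = pd.DataFrame(index=data.index)
    age = data["age"].to_numpy(dtype=float)
    try:
        cp = optimal_cutpoint(age, times, events, feature="age",
                              min_group_frac=min_group_frac)
        out["age_above_cutoff"] = cp.indicator.astype(float)
        out.attrs["age_cutoff"] = cp.cutoff
    except DegenerateInputError:
        out["age_above_cutoff"] = age
    out["sex_female"] = (data["sex"].astype(str) == "female").astype(float)
    out["smoker"] = (
        data["smoking_status"].astype(str).str.lower() != "never"
    ).astype(float)
    out["extrathoracic_metastasis"] = data["extrathoracic_metastasis"].astype(float)
    out["egfr_exon19_deletion"] = (
        data["egfr_mutation"].astype(str).str.contains("19").astype(float)
    )
    out["baseline_diameter"] = data["baseline_diameter"].astype(float)
    out["responder"] = (data["recist_response"] == "responder").astype(float)
    return out


# ---------------------------------------------------------------------------
# the full analysis
# ---------------------------------------------------------------------------


def _model_report(
    name: str,
    fit,
    times: np.ndarray,
    events: np.ndarray,
) -> ModelReport:
    covs = [
        CovariateReport(
            name=c,
            coef=float(fit.coefficients[c]),
            hr=float(fit.hazard_ratios[c]),
            ci_lower=float(fit.ci_lower[c]),
            ci_upper=float(fit.ci_upper[c]),
            p=float(fit.p_values[c]),
        )
        for c in fit.covariate_names
    ]
    report = ModelReport(
        name=name,
        covariates=covs,
        dropped=list(fit.dropped),
        concordance=float(fit.concordance),
        concordance_ci=fit.concordance_ci,
    )
    if len(fit.covariate_names) and np.ptp(fit.linear_predictor) > 0:
        rg = median_lp_risk_groups(fit.linear_predictor, times, events)
        report.risk_group_hr = rg.hr
        report.risk_group_ci = rg.ci
        report.risk_group_logrank_p = rg.logrank_p
        report.km_median_low = float(rg.km_low.attrs["median"])
        report.km_median_high = float(rg.km_high.attrs["median"])
    return report


def run_analysis(
    cohort: CohortTable,
    config: PipelineConfig | None = None,
    reader_pairs: ReaderPairedFeatures | None = None,
) -> AnalysisReport:
    """Run the complete analysis on a cohort table.

    Stages: (optional) ICC stability filtering, three-set redundancy
    grouping, optimal-cutpoint dichotomization, univariate Cox screening
    with BH correction, top-k selection, radiomic / clinical / combined
    multivariate Cox models with backward stepwise selection, bootstrap
    c-index comparison and median-risk-group summaries.
    """
    config = config or PipelineConfig()
    times, events = cohort.survival()
    if events.sum() == 0:
        raise ValidationError("cohort has no events")

    # ----- feature sets -----
    if "baseline" not in cohort.feature_sets or "followup" not in cohort.feature_sets:
        raise ValidationError("cohort must carry 'baseline' and 'followup' feature sets")
    baseline = cohort.features("baseline")
    followup = cohort.features("followup")
    if "percent_change" in cohort.feature_sets:
        triple = {
            "baseline": baseline,
            "followup": followup,
            "percent_change": cohort.features("percent_change"),
        }
    else:
        triple = build_feature_set_triple(baseline, followup)

    # ----- stage 1: ICC stability filtering -----
    icc_rows = None
    icc_excluded = None
    if reader_pairs is not None:
        retained, icc_table = filter_unstable(
            reader_pairs.features, reader_pairs,
            threshold=config.icc_threshold, variant=config.icc_variant,
        )
        icc_rows = icc_table.reset_index().to_dict(orient="records")
        icc_excluded = [f for f in reader_pairs.features if f not in retained]
        triple = {
            s: t[[c for c in t.columns if c in retained]] for s, t in triple.items()
        }
        logger.info("ICC filtering removed %d feature(s): %s",
                    len(icc_excluded), icc_excluded)

    # ----- stages 2-5: grouping, cutpoints, univariate screen, top-k -----
    sel: SelectionReport = run_selection(
        triple, times, events,
        r_threshold=config.r_threshold,
        use_abs=config.use_abs_correlation,
        min_group_frac=config.min_group_frac,
        top_k=config.top_k,
    )

    # ----- radiomic model: backward stepwise on the top-k indicators -----
    radiomic_design = pd.DataFrame(
        {key: sel.cutpoints[key].indicator.astype(float) for key in sel.top_features},
        index=cohort.data.index,
    )
    surv_rad = SurvivalData(times, events, radiomic_design)
    fit_rad = backward_stepwise(surv_rad, alpha_remove=config.alpha_remove)

    # ----- clinical model: univariate screen at alpha=0.20, then stepwise --
    clinical = encode_clinical(cohort, times, events, config.min_group_frac)
    candidates = []
    for c in clinical.columns:
        x = clinical[c].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            logger.warning("clinical covariate %r is constant; skipped", c)
            continue
        if univariate_cox(x, times, events, name=c)["p"] < config.alpha_univariate_clinical:
            candidates.append(c)
    if not candidates:
        logger.warning("no clinical covariate passed the univariate screen; "
                       "using all nonconstant covariates")
        candidates = [c for c in clinical.columns
                      if np.ptp(clinical[c].to_numpy(dtype=float)) > 0]
    surv_clin = SurvivalData(times, events, clinical[candidates])
    fit_clin = backward_stepwise(surv_clin, alpha_remove=config.alpha_remove)

    # ----- combined model: joint refit of the union of retained covariates --
    combined_design = pd.concat(
        [radiomic_design[fit_rad.covariate_names],
         clinical[fit_clin.covariate_names]], axis=1,
    )
    if combined_design.shape[1] == 0:
        logger.warning("both radiomic and clinical models are empty; "
                       "combined model is the null model")
    fit_comb = cox_fit(SurvivalData(times, events, combined_design))

    # ----- bootstrap c-index comparison -----
    fits = {"radiomic": fit_rad, "clinical": fit_clin, "combined": fit_comb}
    lps = {name: f.linear_predictor for name, f in fits.items()}
    usable = {n: lp for n, lp in lps.items() if np.ptp(lp) > 0}
    comparisons: list[dict] = []
    if len(usable) >= 2:
        boot = bootstrap_compare(usable, times, events,
                                 B=config.bootstrap_B, seed=config.seed)
        for name, f in fits.items():
            if name in boot.c_ci:
                object.__setattr__(f, "concordance_ci", boot.c_ci[name])
        comparisons = [
            {"model_a": a, "model_b": b, "p": p}
            for (a, b), p in boot.pairwise_p.items()
        ]

    models = [_model_report(name, f, times, events) for name, f in fits.items()]

    univariate = [
        CutpointReport(
            set_name=r.set,
            feature=r.feature,
            cutoff=r.cutoff,
            hr=r.hr,
            ci_lower=r.ci_lower,
            ci_upper=r.ci_upper,
            p_raw=r.p_raw,
            p_adjusted=None if pd.isna(r.p_adjusted) else float(r.p_adjusted),
            group=int(r.group),
            representative=bool(r.representative),
            selected=bool(r.selected),
        )
        for r in sel.table.itertuples()
    ]

    km = km_curve(times, events)
    return AnalysisReport(
        config=config,
        n_patients=len(cohort),
        n_events=int(events.sum()),
        km_median_pfs=float(km.attrs["median"]),
        icc_report=icc_rows,
        icc_excluded=icc_excluded,
        groups=sel.groups,
        univariate=univariate,
        top_features=sel.top_features,
        models=models,
        comparisons=comparisons,
    )
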