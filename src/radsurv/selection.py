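"""Feature-set construction and prognostic feature selection.

The cascade mirrors a standard radiomics workflow: build the three
feature sets (baseline, first follow-up, percent change), group features
whose pairwise Pearson correlation exceeds a threshold and keep one
representative per group, dichotomize each feature at the cutoff giving
the most significant log-rank split, screen with univariate Cox models,
adjust p-values with Benjamini-Hochberg, and keep the top-k features.

The minimum-p cutpoint approach is known to inflate type-I error; the
scan is therefore constrained to splits leaving at least a minimum
fraction of patients in each group, and downstream inference treats the
univariate p-values as a ranking device rather than calibrated tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from radsurv.errors import DegenerateInputError, ValidationError
from radsurv.survival import SurvivalData, cox_fit, logrank_scan

logger = logging.getLogger(__name__)

R_THRESHOLD_DEFAULT = 0.95
MIN_GROUP_FRAC_DEFAULT = 0.10
TOP_K_DEFAULT = 4


def percent_change(baseline, followup):
    """Relative change from baseline to follow-up, in percent.

    ``100 * (followup - baseline) / baseline``; a tumour feature that
    shrinks under therapy gets a negative sign.  Undefined (NaN) where the
    baseline value is exactly 0.  Accepts scalars or arrays.
    """
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (followup - baseline) / baseline
    out = np.where(baseline == 0, np.nan, out)
    if np.isnan(out).any():
        logger.warning("percent change undefined for %d zero-baseline value(s)",
                       int(np.sum(baseline == 0)))
    return out.item() if out.ndim == 0 else out


def build_feature_set_triple(
    baseline: pd.DataFrame, followup: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Baseline, follow-up and percent-change tables over shared patients."""
    if not baseline.index.equals(followup.index):
        raise ValidationError("baseline and follow-up tables must share patients")
    change = pd.DataFrame(
        percent_change(baseline.to_numpy(), followup.to_numpy()),
        index=baseline.index,
        columns=baseline.columns,
    )
    return {"baseline": baseline, "followup": followup, "percent_change": change}


def correlation_groups(
    table: pd.DataFrame,
    r_threshold: float = R_THRESHOLD_DEFAULT,
    use_abs: bool = False,
) -> list[list[str]]:
    """Group features whose pairwise Pearson r exceeds the threshold.

    Edges are drawn for r > threshold (signed by default; ``use_abs``
    switches to \\|r\\|) and groups are the connected components of the
    resulting graph.  Zero-variance features are excluded with a warning.
    Groups are returned sorted, members in column order.
    """
    if len(table) < 3:
        raise ValidationError("correlation grouping requires >= 3 patients")
    cols = []
    for c in table.columns:
        if np.nanstd(table[c].to_numpy(dtype=float)) == 0:
            warnings.warn(f"feature {c!r} is constant; excluded from correlation grouping")
        else:
            cols.append(c)
    corr = table[cols].corr(method="pearson")
    g = nx.Graph()
    g.add_nodes_from(cols)
    vals = corr.to_numpy()
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            r = vals[i, j]
            if np.isfinite(r) and ((abs(r) if use_abs else r) > r_threshold):
                g.add_edge(a, cols[j])
    order = {c: k for k, c in enumerate(cols)}
    groups = [sorted(comp, key=order.get) for comp in nx.connected_components(g)]
    return sorted(groups, key=lambda grp: order[grp[0]])


@dataclass(frozen=True)
class CutpointResult:
    """Optimal log-rank dichotomization of one feature."""

    feature: str
    cutoff: float
    statistic: float
    p_logrank: float
    indicator: np.ndarray  # True = above cutoff
    hr: float
    ci: tuple[float, float]
    p_cox: float


def optimal_cutpoint(
    values: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    feature: str = "",
    min_group_frac: float = MIN_GROUP_FRAC_DEFAULT,
) -> CutpointResult:
    """Dichotomize at the cutoff giving the most significant log-rank split.

    Candidate cutoffs are midpoints of consecutive sorted unique values;
    candidates leaving fewer than ``min_group_frac`` of patients on either
    side are discarded.  Ties in the statistic go to the more balanced
    split (then to the lower cutoff).  The returned univariate hazard
    ratio is for the above-cutoff group.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if events.sum() < 2:
        raise DegenerateInputError("cutpoint search requires >= 2 events")
    uniq = np.unique(values)
    if len(uniq) < 2:
        raise DegenerateInputError(f"feature {feature!r} is constant; no cutpoint")
    n = len(values)
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    below = (values[:, None] <= candidates[None, :]).sum(axis=0)
    min_size = int(np.ceil(min_group_frac * n))
    ok = (below >= min_size) & ((n - below) >= min_size)
    if not ok.any():
        raise DegenerateInputError(
            f"no admissible cutoff for feature {feature!r} with "
            f"min_group_frac={min_group_frac}"
        )
    candidates = candidates[ok]
    below = below[ok]
    memberships = values[:, None] > candidates[None, :]  # group 1 = above cutoff
    chi2 = logrank_scan(times, events, memberships)
    best_stat = chi2.max()
    tied = np.isclose(chi2, best_stat, rtol=1e-12, atol=0)
    balance = np.abs(n - 2 * below)  # |n_above - n_below|
    tie_order = np.lexsort((candidates, balance))
    best = next(i for i in tie_order if tied[i])
    cutoff = float(candidates[best])
    indicator = values > cutoff
    fit = cox_fit(
        SurvivalData(times, events, pd.DataFrame({feature or "indicator": indicator.astype(float)}))
    )
    return CutpointResult(
        feature=feature,
        cutoff=cutoff,
        statistic=float(chi2[best]),
        p_logrank=float(stats.chi2.sf(chi2[best], df=1)),
        indicator=indicator,
        hr=float(fit.hazard_ratios.iloc[0]),
        ci=(float(fit.ci_lower.iloc[0]), float(fit.ci_upper.iloc[0])),
        p_cox=float(fit.p_values.iloc[0]),
    )


def univariate_cox(
    covariate: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    name: str = "covariate",
) -> dict[str, float]:
    """Single-covariate Cox fit; returns HR, CI bounds, p and coefficient."""
    cov = np.asarray(covariate, dtype=float)
    if np.ptp(cov) == 0:
        raise DegenerateInputError(f"covariate {name!r} is constant")
    fit = cox_fit(
        SurvivalData(np.asarray(times, float), np.asarray(events, bool),
                     pd.DataFrame({name: cov}))
    )
    return {
        "coef": float(fit.coefficients.iloc[0]),
        "hr": float(fit.hazard_ratios.iloc[0]),
        "ci_lower": float(fit.ci_lower.iloc[0]),
        "ci_upper": float(fit.ci_upper.iloc[0]),
        "p": float(fit.p_values.iloc[0]),
    }


def representative_per_group(
    groups: list[list[str]], p_values: dict[str, float]
) -> list[str]:
    """Keep the smallest-p member of each correlated group (ties: alphabetical)."""
    chosen = []
    for group in groups:
        missing = [f for f in group if f not in p_values]
        if missing:
            raise ValidationError(f"no univariate p-value for {missing}")
        chosen.append(min(sorted(group), key=lambda f: p_values[f]))
    return chosen


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def select_top_k(
    adjusted: dict[str, float],
    raw: dict[str, float],
    k: int = TOP_K_DEFAULT,
) -> list[str]:
    """The k features with smallest adjusted p (ties: raw p, then name)."""
    ranked = sorted(adjusted, key=lambda f: (adjusted[f], raw.get(f, 1.0), f))
    if len(ranked) < k:
        warnings.warn(f"only {len(ranked)} features available for top-{k} selection")
    return ranked[:k]


@dataclass(frozen=True)
class SelectionReport:
    """Full record of the selection cascade over the three feature sets."""

    table: pd.DataFrame  # per (set, feature): group id, cutoff, HR, CI, p, adj p, flags
    groups: dict[str, list[list[str]]]
    cutpoints: dict[str, CutpointResult]  # keyed "<set>__<feature>"
    top_features: list[str]  # "<set>__<feature>" keys


def run_selection(
    feature_sets: dict[str, pd.DataFrame],
    times: np.ndarray,
    events: np.ndarray,
    r_threshold: float = R_THRESHOLD_DEFAULT,
    use_abs: bool = False,
    min_group_frac: float = MIN_GROUP_FRAC_DEFAULT,
    top_k: int = TOP_K_DEFAULT,
) -> SelectionReport:
    """Run the complete selection cascade.

    Per feature set: correlation grouping, optimal-cutpoint
    dichotomization, univariate Cox on the dichotomized indicator, and
    redundancy pruning to one representative per group.  The surviving
    features of all sets are pooled, BH-adjusted, and the top-k returned
    (keys are ``"<set>__<feature>"``).  Deterministic given its inputs.
    """
    groups_by_set: dict[str, list[list[str]]] = {}
    cutpoints: dict[str, CutpointResult] = {}
    rows = []
    survivors: dict[str, float] = {}  # key -> raw p
    for set_name, table in feature_sets.items():
        usable = [
            c for c in table.columns
            if table[c].notna().all() and np.ptp(table[c].to_numpy(dtype=float)) > 0
        ]
        skipped = [c for c in table.columns if c not in usable]
        if skipped:
            logger.warning("set %s: skipping unusable features %s", set_name, skipped)
        groups = correlation_groups(table[usable], r_threshold, use_abs)
        groups_by_set[set_name] = groups
        group_id = {f: gi for gi, grp in enumerate(groups) for f in grp}
        p_by_feature: dict[str, float] = {}
        for feat in usable:
            try:
                cp = optimal_cutpoint(
                    table[feat].to_numpy(dtype=float), times, events,
                    feature=feat, min_group_frac=min_group_frac,
                )
            except DegenerateInputError as exc:
                logger.warning("set %s: %s", set_name, exc)
                continue
            key = f"{set_name}__{feat}"
            cutpoints[key] = cp
            p_by_feature[feat] = cp.p_cox
        groups = [[f for f in grp if f in p_by_feature] for grp in groups]
        groups = [grp for grp in groups if grp]
        reps = set(representative_per_group(groups, p_by_feature))
        for feat in p_by_feature:
            key = f"{set_name}__{feat}"
            cp = cutpoints[key]
            rows.append(
                {
                    "set": set_name,
                    "feature": feat,
                    "group": group_id.get(feat, -1),
                    "cutoff": cp.cutoff,
                    "hr": cp.hr,
                    "ci_lower": cp.ci[0],
                    "ci_upper": cp.ci[1],
                    "p_raw": cp.p_cox,
                    "representative": feat in reps,
                }
            )
            if feat in reps:
                survivors[key] = p_by_feature[feat]

    table_df = pd.DataFrame(rows)
    keys = sorted(survivors)  # fixed order for the BH vector
    adj = bh_adjust(np.array([survivors[k] for k in keys]))
    adjusted = dict(zip(keys, (float(a) for a in adj)))
    table_df["p_adjusted"] = [
        adjusted.get(f"{r.set}__{r.feature}", np.nan) for r in table_df.itertuples()
    ]
    top = select_top_k(adjusted, {k: survivors[k] for k in keys}, k=top_k)
    table_df["selected"] = [
        f"{r.set}__{r.feature}" in top for r in table_df.itertuples()
    ]
    return SelectionReport(
        table=table_df, groups=groups_by_set, cutpoints=cutpoints, top_features=top
    )
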