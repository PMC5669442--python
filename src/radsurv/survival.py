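"""Survival machinery: Cox models, log-rank tests, Kaplan-Meier curves,
Harrell's concordance index and bootstrap model comparison.

Cox proportional-hazards fits maximize the Efron-tie-corrected partial
likelihood by Newton-Raphson (delegated to ``lifelines``); backward
stepwise selection iteratively removes the covariate with the largest
Wald p-value above the removal threshold.  Model discrimination is
measured with Harrell's c: the fraction of comparable patient pairs
(the earlier time is an observed event) whose predicted risk ordering
matches the observed ordering, prediction ties counting 1/2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from radsurv.errors import DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalData:
    """Follow-up times (months), event flags and a named covariate matrix."""

    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=bool)
        if (time <= 0).any():
            raise ValidationError("survival times must be positive")
        if not event.any():
            raise ValidationError("at least one event is required")
        if len(self.covariates) != len(time) or len(event) != len(time):
            raise ValidationError("time, event and covariates must have equal length")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset_covariates(self, names: list[str]) -> "SurvivalData":
        return SurvivalData(self.time, self.event, self.covariates[names])


@dataclass(frozen=True)
class CoxModelFit:
    """Result of a Cox proportional-hazards fit."""

    coefficients: pd.Series
    hazard_ratios: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p_values: pd.Series
    log_likelihood: float
    linear_predictor: np.ndarray
    concordance: float
    dropped: tuple[str, ...] = ()
    concordance_ci: tuple[float, float] | None = None

    @property
    def covariate_names(self) -> list[str]:
        return list(self.coefficients.index)

    def predict_lp(self, covariates: pd.DataFrame) -> np.ndarray:
        """Linear predictor beta'x for new covariate rows (original coefficients)."""
        x = covariates[self.covariate_names].to_numpy(dtype=float)
        return x @ self.coefficients.to_numpy()

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "HR": self.hazard_ratios,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.p_values,
            }
        )


def cox_fit(data: SurvivalData, ties: str = "efron") -> CoxModelFit:
    """Fit a Cox proportional-hazards model.

    Warns when events per covariate fall below 10 (the classical rule of
    thumb for stable coefficient estimates).  Raises on non-convergence or
    perfectly collinear covariates.
    """
    if ties != "efron":
        raise ValidationError("only Efron tie handling is implemented")
    names = list(data.covariates.columns)
    if data.n_events < len(names):
        raise DegenerateInputError(
            f"{data.n_events} events cannot support {len(names)} covariates"
        )
    if names and data.n_events / len(names) < 10:
        warnings.warn(
            f"only {data.n_events / len(names):.1f} events per covariate (< 10); "
            "coefficient estimates may be unstable"
        )
    if not names:
        # null model: no covariates, lp identically 0
        return CoxModelFit(
            coefficients=pd.Series(dtype=float),
            hazard_ratios=pd.Series(dtype=float),
            ci_lower=pd.Series(dtype=float),
            ci_upper=pd.Series(dtype=float),
            p_values=pd.Series(dtype=float),
            log_likelihood=float("nan"),
            linear_predictor=np.zeros(data.n),
            concordance=0.5,
        )
    x = data.covariates.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValidationError("missing covariate values; drop incomplete rows first")
    constant = [c for c in names if np.ptp(data.covariates[c].to_numpy(dtype=float)) == 0]
    if constant:
        # a constant covariate carries no information: beta = 0 by convention
        warnings.warn(f"constant covariate(s) {constant}: coefficient fixed at 0")
        varying = [c for c in names if c not in constant]
        sub = cox_fit(data.subset_covariates(varying), ties=ties)
        zeros = pd.Series(0.0, index=constant)
        ones = pd.Series(1.0, index=constant)
        nans = pd.Series(np.nan, index=constant)
        return CoxModelFit(
            coefficients=pd.concat([sub.coefficients, zeros])[names],
            hazard_ratios=pd.concat([sub.hazard_ratios, ones])[names],
            ci_lower=pd.concat([sub.ci_lower, nans])[names],
            ci_upper=pd.concat([sub.ci_upper, nans])[names],
            p_values=pd.concat([sub.p_values, pd.Series(1.0, index=constant)])[names],
            log_likelihood=sub.log_likelihood,
            linear_predictor=sub.linear_predictor,
            concordance=sub.concordance,
        )
    # name collinear pairs explicitly rather than letting the fit blow up
    if x.shape[1] > 1:
        with np.errstate(invalid="ignore"):
            cc = np.corrcoef(x, rowvar=False)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if np.isfinite(cc[i, j]) and abs(cc[i, j]) > 1 - 1e-10:
                    raise ValidationError(
                        f"collinear covariates: {names[i]!r} and {names[j]!r}"
                    )
    df = data.covariates.astype(float).copy()
    df["_time"] = data.time
    df["_event"] = data.event.astype(int)
    fitter = CoxPHFitter()
    try:
        fitter.fit(df, duration_col="_time", event_col="_event")
    except ConvergenceError as exc:
        raise DegenerateInputError(f"Cox fit did not converge: {exc}") from exc
    summ = fitter.summary
    lp = x @ fitter.params_.to_numpy()
    return CoxModelFit(
        coefficients=fitter.params_.rename_axis(None),
        hazard_ratios=np.exp(fitter.params_).rename_axis(None),
        ci_lower=np.exp(summ["coef lower 95%"]).rename_axis(None),
        ci_upper=np.exp(summ["coef upper 95%"]).rename_axis(None),
        p_values=summ["p"].rename_axis(None),
        log_likelihood=float(fitter.log_likelihood_),
        linear_predictor=lp,
        concordance=harrell_c(lp, data.time, data.event),
    )


def backward_stepwise(
    data: SurvivalData,
    candidates: list[str] | None = None,
    alpha_remove: float = 0.05,
    ties: str = "efron",
) -> CoxModelFit:
    """Backward stepwise Cox selection on the Wald p-value.

    Starting from the full candidate model, the covariate with the
    largest p > ``alpha_remove`` is dropped and the model refit, until
    every remaining covariate is significant.  If everything is dropped
    an (empty) null model is returned with the drop history flagged.
    """
    current = list(candidates if candidates is not None else data.covariates.columns)
    if not current:
        raise ValidationError("no candidate covariates")
    dropped: list[str] = []
    while current:
        fit = cox_fit(data.subset_covariates(current), ties=ties)
        worst = fit.p_values.idxmax()
        if fit.p_values[worst] <= alpha_remove:
            return CoxModelFit(**{**fit.__dict__, "dropped": tuple(dropped)})
        current.remove(worst)
        dropped.append(worst)
        logger.info("backward stepwise dropped %r (p=%.3f)", worst, fit.p_values[worst])
    null = cox_fit(data.subset_covariates([]), ties=ties)
    return CoxModelFit(**{**null.__dict__, "dropped": tuple(dropped)})


# ---------------------------------------------------------------------------
# log-rank machinery
# ---------------------------------------------------------------------------


def logrank_test(
    times: np.ndarray, events: np.ndarray, group: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p).

    ``group`` is a boolean indicator of group-1 membership.
    """
    group = np.asarray(group, dtype=bool)
    if group.all() or not group.any():
        raise ValidationError("log-rank test needs two nonempty groups")
    chi2 = logrank_scan(times, events, group[:, None])[0]
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def logrank_scan(
    times: np.ndarray, events: np.ndarray, memberships: np.ndarray
) -> np.ndarray:
    """Log-rank chi-square for many candidate group-1 memberships at once.

    ``memberships`` is (n patients x C candidates) boolean.  Returns a
    length-C array of chi-square statistics (0 where the variance term
    vanishes).  Used both for single tests and for cutpoint scans.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    memberships = np.asarray(memberships, dtype=float)
    death_times = np.unique(times[events])
    if len(death_times) == 0:
        return np.zeros(memberships.shape[1])
    at_risk = times[None, :] >= death_times[:, None]  # (J, n)
    dying = (times[None, :] == death_times[:, None]) & events[None, :]
    n_j = at_risk.sum(axis=1)  # (J,)
    d_j = dying.sum(axis=1)
    n1 = at_risk.astype(float) @ memberships  # (J, C)
    d1 = dying.astype(float) @ memberships
    frac = n1 / n_j[:, None]
    u = (d1 - d_j[:, None] * frac).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_j = (
            d_j[:, None]
            * frac
            * (1.0 - frac)
            * ((n_j - d_j) / np.maximum(n_j - 1, 1))[:, None]
        )
    v = var_j.sum(axis=0)
    chi2 = np.zeros(memberships.shape[1])
    ok = v > 0
    chi2[ok] = u[ok] ** 2 / v[ok]
    return chi2


def km_curve(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a step-function table (time, survival, at_risk) with the
    median survival stored in ``DataFrame.attrs["median"]``.
    """
    if len(times) == 0:
        raise ValidationError("empty survival input")
    kmf = KaplanMeierFitter()
    kmf.fit(times, np.asarray(events, dtype=bool))
    table = pd.DataFrame(
        {
            "time": kmf.survival_function_.index.to_numpy(dtype=float),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(dtype=float),
        }
    )
    at_risk = [int((times >= t).sum()) for t in table["time"]]
    table["at_risk"] = at_risk
    table.attrs["median"] = float(kmf.median_survival_time_)
    return table


# ---------------------------------------------------------------------------
# concordance and bootstrap comparison
# ---------------------------------------------------------------------------


def harrell_c(
    linear_predictor: np.ndarray, times: np.ndarray, events: np.ndarray
) -> float:
    """Harrell's concordance index.

    A pair (i, j) is comparable when ``times[i] < times[j]`` and patient i
    had an observed event.  The pair is concordant when the
    shorter-surviving patient has the higher linear predictor; prediction
    ties count 1/2.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    comparable = (times[:, None] < times[None, :]) & events[:, None]
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise DegenerateInputError("no comparable pairs for concordance index")
    higher = lp[:, None] > lp[None, :]
    tied = lp[:, None] == lp[None, :]
    concordant = (higher & comparable).sum() + 0.5 * (tied & comparable).sum()
    return float(concordant / n_pairs)


@dataclass(frozen=True)
class BootstrapComparison:
    """Bootstrap c-index distributions and pairwise paired t-tests."""

    c_original: dict[str, float]
    c_mean: dict[str, float]
    c_ci: dict[str, tuple[float, float]]
    pairwise_p: dict[tuple[str, str], float]
    replicates: pd.DataFrame = field(repr=False)
    n_redrawn: int = 0


def bootstrap_compare(
    models: dict[str, np.ndarray],
    times: np.ndarray,
    events: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> BootstrapComparison:
    """Compare models' Harrell c by patient bootstrap with paired t-tests.

    ``models`` maps model name to its per-patient linear predictor on the
    original cohort (original coefficients; no refitting inside the
    bootstrap).  Patients are resampled with replacement B times; each
    model's c is evaluated on every replicate, and every model pair is
    compared with a paired t-test over the B replicate differences.
    Fully determined by ``seed``.
    """
    if len(models) < 2:
        raise ValidationError("bootstrap comparison needs at least two models")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n = len(times)
    rng = np.random.default_rng(seed)
    names = list(models)
    rows = np.empty((B, len(names)))
    n_redrawn = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        try:
            for k, name in enumerate(names):
                rows[b, k] = harrell_c(models[name][idx], times[idx], events[idx])
        except DegenerateInputError:
            n_redrawn += 1
            logger.warning("bootstrap replicate had no comparable pairs; redrawn")
            continue
        b += 1
    reps = pd.DataFrame(rows, columns=names)
    alpha = (1.0 - ci_level) / 2.0
    c_ci = {
        name: (
            float(np.quantile(reps[name], alpha)),
            float(np.quantile(reps[name], 1 - alpha)),
        )
        for name in names
    }
    pairwise: dict[tuple[str, str], float] = {}
    for i, a in enumerate(names):
        for bname in names[i + 1 :]:
            diff = reps[a] - reps[bname]
            if np.allclose(diff, 0):
                pairwise[(a, bname)] = float("nan")  # identical models
            else:
                pairwise[(a, bname)] = float(stats.ttest_rel(reps[a], reps[bname]).pvalue)
    return BootstrapComparison(
        c_original={m: harrell_c(models[m], times, events) for m in names},
        c_mean={m: float(reps[m].mean()) for m in names},
        c_ci=c_ci,
        pairwise_p=pairwise,
        replicates=reps,
        n_redrawn=n_redrawn,
    )


@dataclass(frozen=True)
class RiskGroupResult:
    """Median-split risk groups with their KM curves and between-group HR."""

    group_high: np.ndarray
    hr: float
    ci: tuple[float, float]
    p_cox: float
    logrank_stat: float
    logrank_p: float
    km_low: pd.DataFrame
    km_high: pd.DataFrame


def median_lp_risk_groups(
    linear_predictor: np.ndarray, times: np.ndarray, events: np.ndarray
) -> RiskGroupResult:
    """Split patients at the median linear predictor into low/high risk."""
    lp = np.asarray(linear_predictor, dtype=float)
    if np.ptp(lp) == 0:
        raise DegenerateInputError("constant linear predictor; cannot form risk groups")
    med = np.median(lp)
    high = lp > med
    if high.all() or not high.any():
        # heavy ties at the median: fall back to a balanced rank split
        order = np.argsort(lp, kind="stable")
        high = np.zeros(len(lp), dtype=bool)
        high[order[len(lp) // 2 :]] = True
    stat, p_lr = logrank_test(times, events, high)
    fit = cox_fit(
        SurvivalData(times, np.asarray(events, dtype=bool),
                     pd.DataFrame({"high_risk": high.astype(float)}))
    )
    return RiskGroupResult(
        group_high=high,
        hr=float(fit.hazard_ratios.iloc[0]),
        ci=(float(fit.ci_lower.iloc[0]), float(fit.ci_upper.iloc[0])),
        p_cox=float(fit.p_values.iloc[0]),
        logrank_stat=stat,
        logrank_p=p_lr,
        km_low=km_curve(times[~high], np.asarray(events)[~high]),
        km_high=km_curve(times[high], np.asarray(events)[high]),
    )
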