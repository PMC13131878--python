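"""Model evaluation: Kaplan-Meier curves, VPC bands, bootstrap, GOF tables.

The TTE visual predictive check follows the usual simulation recipe:
many replicate studies are simulated from the fitted model at the
observed design (covariates and censoring times), a Kaplan-Meier curve
is computed per replicate and dose arm, and the pointwise median and
5th/95th percentiles of the replicate curves form a 90% prediction band
to compare with the observed curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .data import StudyDataset
from .nlme import (
    PAR_NAMES,
    PopulationModel,
    _subjects_from,
    empirical_bayes,
    residual_sd,
)
from .results import FitResult
from .tte import CovariateSet, TTEParameters, _events_frame, simulate_events

__all__ = ["KMCurve", "kaplan_meier", "vpc_tte", "bootstrap", "gof_tables"]


@dataclass
class KMCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray  # step-change times, starting at 0
    survival: np.ndarray  # S(t) just after each time
    at_risk: np.ndarray  # subjects at risk just before each time
    arm: str | None = None

    def __post_init__(self) -> None:
        if self.survival[0] > 1 or np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must start at <= 1 and be non-increasing")

    def evaluate(self, t) -> np.ndarray:
        """S(t) by right-continuous step interpolation."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.times) - 1)
        return self.survival[idx]


def kaplan_meier(events, arm: str | None = None) -> KMCurve:
    """Kaplan-Meier estimator of one arm's event records.

    ``events``: DataFrame with ``time`` (or ``time_h``) and ``status``
    columns, or a list of :class:`~tgitte.tte.EventRecord`.
    """
    df = _events_frame(events)
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], event_observed=df["status"])
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    if times[0] != 0.0:
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
    at_risk = np.array(
        [(df["time"].to_numpy() >= t).sum() for t in times], dtype=float
    )
    return KMCurve(times=times, survival=surv, at_risk=at_risk, arm=arm)


def _tte_params_of(fit) -> TTEParameters:
    if isinstance(fit, TTEParameters):
        return fit
    if hasattr(fit, "params_"):
        return fit.params_
    if isinstance(fit, FitResult) and hasattr(fit.model, "params_"):
        return fit.model.params_
    raise TypeError("fit must be a fitted TTE estimator, its FitResult, or TTEParameters")


def vpc_tte(
    fit,
    cov: CovariateSet,
    arms: pd.Series,
    censor_time,
    n_sim: int = 1000,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Dose-stratified TTE visual predictive check.

    Parameters
    ----------
    fit : fitted ParametricTTEEstimator, FitResult, or TTEParameters
    cov : CovariateSet
        Per-subject covariates of the observed design.
    arms : pandas.Series
        subject -> arm label (stratification variable).
    censor_time : float or pandas.Series
        Study censoring time, scalar or per subject.
    n_sim : int
        Number of replicate studies (1000 for reporting; fewer is warned
        below 100).
    grid : array, optional
        Common time grid; defaults to 61 points spanning the study.

    Returns
    -------
    DataFrame with columns arm, time_h, pred_median_S, pred_lo_S,
    pred_hi_S (pointwise median and 5th/95th percentiles).
    """
    if n_sim < 100:
        warnings.warn(f"n_sim = {n_sim} < 100: VPC percentiles will be noisy")
    p = _tte_params_of(fit)
    rng = np.random.default_rng(seed)
    subjects = cov.data["subject"].to_numpy()
    arm_arr = arms.reindex(subjects).to_numpy()
    if isinstance(censor_time, pd.Series):
        cmax = float(censor_time.max())
        censor_per_subject = censor_time.reindex(subjects).to_numpy(dtype=float)
    else:
        cmax = float(censor_time)
        censor_per_subject = np.full(len(subjects), cmax)
    if grid is None:
        grid = np.linspace(0.0, cmax, 61)

    arm_labels = pd.unique(arm_arr)
    curves = {a: np.empty((n_sim, len(grid))) for a in arm_labels}
    for r in range(n_sim):
        sim = simulate_events(p, cov, censor_time=cmax, rng=rng)
        t = np.minimum(sim["time"].to_numpy(), censor_per_subject)
        d = np.where(
            sim["time"].to_numpy() <= censor_per_subject,
            sim["status"].to_numpy(),
            0,
        )
        rep = pd.DataFrame({"subject": subjects, "time": t, "status": d})
        for a in arm_labels:
            km = kaplan_meier(rep[arm_arr == a])
            curves[a][r] = km.evaluate(grid)

    out = []
    for a in arm_labels:
        lo, med, hi = np.percentile(curves[a], [5, 50, 95], axis=0)
        out.append(
            pd.DataFrame(
                {
                    "arm": a,
                    "time_h": grid,
                    "pred_median_S": med,
                    "pred_lo_S": lo,
                    "pred_hi_S": hi,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def bootstrap(
    data,
    fit_fn,
    n_boot: int = 1000,
    seed: int = 0,
    stratify_by_arm: bool = True,
) -> pd.DataFrame:
    """Subject-resampling bootstrap of a fitting function.

    Subjects are resampled with replacement — within arm when
    ``stratify_by_arm`` and an arm variable is available, so every
    replicate preserves the per-arm subject counts. ``fit_fn`` receives
    the resampled object (same type as ``data``: a
    :class:`StudyDataset`, or a DataFrame with a ``subject`` column
    whose other columns travel with the subject) and returns a dict of
    parameter estimates or a FitResult.

    Returns a table with the median and 2.5/97.5 percentile CI per
    parameter; replicates whose refit raises are excluded and counted,
    with a warning above 10% failures.
    """
    rng = np.random.default_rng(seed)
    if isinstance(data, StudyDataset):
        subjects = np.asarray(data.subjects)
        arm_of = data.arm_of() if stratify_by_arm else None
    elif isinstance(data, pd.DataFrame):
        subjects = data["subject"].unique()
        arm_of = (
            data.groupby("subject", sort=False)["arm"].first()
            if stratify_by_arm and "arm" in data.columns
            else None
        )
    else:
        raise TypeError("data must be a StudyDataset or a DataFrame")

    if arm_of is not None:
        strata = [
            np.asarray([s for s in subjects if arm_of[s] == a])
            for a in pd.unique(arm_of.reindex(subjects).to_numpy())
        ]
    else:
        strata = [np.asarray(subjects)]
    for group in strata:
        if len(group) < 2:
            raise ValueError("each stratum needs at least 2 subjects")

    estimates = []
    failures = 0
    for _ in range(n_boot):
        chosen = np.concatenate(
            [rng.choice(group, size=len(group), replace=True) for group in strata]
        )
        relabel = [f"B{i:04d}" for i in range(len(chosen))]
        if isinstance(data, StudyDataset):
            resampled = data.subset(list(chosen), relabel=relabel)
        else:
            parts = []
            for new_id, s in zip(relabel, chosen):
                part = data[data["subject"] == s].copy()
                part["subject"] = new_id
                parts.append(part)
            resampled = pd.concat(parts, ignore_index=True)
        try:
            fitted = fit_fn(resampled)
        except Exception:
            failures += 1
            continue
        if isinstance(fitted, FitResult):
            fitted = fitted.estimates
        estimates.append(fitted)

    if failures > 0.1 * n_boot:
        warnings.warn(
            f"bootstrap: {failures}/{n_boot} refits failed; percentiles may be biased"
        )
    if not estimates:
        raise RuntimeError("all bootstrap refits failed")
    table = pd.DataFrame(estimates)
    out = table.quantile([0.5, 0.025, 0.975]).T
    out.columns = ["median", "ci_lo", "ci_hi"]
    out.index.name = "parameter"
    out["n_success"] = len(estimates)
    out["n_failed"] = failures
    return out.reset_index()


def gof_tables(data: StudyDataset, fit, pk=None) -> pd.DataFrame:
    """Goodness-of-fit table for a population TGI fit.

    One row per observation with the population prediction (typical
    parameters), individual prediction (EBE parameters) and the
    individual weighted residual IWRES = (obs - ipred)/sd(ipred). Under
    a correctly specified model the IWRES are approximately standard
    normal.
    """
    if hasattr(fit, "population_model_"):
        model: PopulationModel = fit.population_model_
        pk = pk or fit.pk
        ebes = getattr(fit, "ebes_", None)
        result = fit.result_
    elif isinstance(fit, FitResult):
        model = fit.model
        pk = pk or fit.convergence.get("pk")
        ebes = fit.ebes
        result = fit
    else:
        raise TypeError("fit must be a fitted TGIPopulationEstimator or FitResult")
    if pk is None:
        raise ValueError("PK parameters required for predictions")
    if ebes is None:
        ebes = empirical_bayes(data, result, pk=pk)
    par_table = ebes.set_index("subject")

    rows = []
    for subj in _subjects_from(data):
        pop_pred = subj.predict(dict(model.theta), pk)
        ind_par = {n: float(par_table.loc[subj.subject, n]) for n in PAR_NAMES}
        ind_pred = subj.predict(ind_par, pk)
        sd = np.maximum(
            residual_sd(ind_pred, model.residual, model.error_model), 1e-9
        )
        rows.append(
            pd.DataFrame(
                {
                    "subject": subj.subject,
                    "time_h": subj.times,
                    "observed": subj.volumes,
                    "pred_population": pop_pred,
                    "pred_individual": ind_pred,
                    "iwres": (subj.volumes - ind_pred) / sd,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
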