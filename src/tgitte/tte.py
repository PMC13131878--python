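"""Parametric time-to-event models for tumor-volume-threshold survival.

The event is the tumor reaching a predefined volume (1,500 mm3 by
default); animals that never reach it are right-censored at their last
observation. The primary hazard family is the log-logistic,

    h(t) = (s/Te) * (t/Te)^(s-1) / (1 + (t/Te)^s),      S(t) = 1 / (1 + (t/Te)^s),

whose scale Te is exactly the median event time (S(Te) = 1/2); the shape
s is fixed at 4 by default. Weibull, Gompertz and exponential families
are available for the base-model screen; their parameterizations are
spelled out in :data:`FAMILIES`.

Covariates enter on the scale parameter of animal i:

    Te_i = Te_pop * exp(b_l0 * (l0_i/med(l0) - 1))
                  * exp(b_l1 * (l1_i/med(l1) - 1))
                  * exp(b_cavg * Cavg_i/med(Cavg))
                  * exp(eta_i),        eta_i ~ N(0, omega_te^2)

where l0_i, l1_i are the animal's empirical-Bayes tumor growth rates and
Cavg_i its regimen-level average drug concentration. Note the Cavg term
is ratio-scaled but not centered by subtracting 1, so a vehicle animal
(Cavg = 0) has multiplier 1; the growth-rate terms are centered at their
medians. Negative growth-rate coefficients mean faster-growing tumors
reach the endpoint sooner; a positive Cavg coefficient means higher
exposure prolongs survival.

Estimation is right-censored maximum likelihood; the frailty eta is
marginalized by Gauss-Hermite quadrature when omega_te > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .results import FitResult

__all__ = [
    "TTEParameters",
    "CovariateSet",
    "EventRecord",
    "FAMILIES",
    "hazard",
    "survival",
    "individual_scale",
    "loglik_tte",
    "fit_tte",
    "simulate_events",
    "ParametricTTEEstimator",
]

#: Hazard/survival parameterizations, scale Te (h) and dimensionless or
#: per-scale shape s:
#:   loglogistic:  h = (s/Te)(t/Te)^(s-1)/(1+(t/Te)^s),  S = 1/(1+(t/Te)^s)
#:   weibull:      h = (s/Te)(t/Te)^(s-1),               S = exp(-(t/Te)^s)
#:   gompertz:     h = (1/Te) exp(s t/Te),               S = exp(-(exp(s t/Te)-1)/s)
#:                 (s -> 0 recovers the exponential family)
#:   exponential:  h = 1/Te,                             S = exp(-t/Te)
FAMILIES = ("loglogistic", "weibull", "gompertz", "exponential")

OMEGA_FLOOR = 1e-4  # positivity floor for the frailty SD in 'estimate' mode


@dataclass(frozen=True)
class TTEParameters:
    """Population parameters of the covariate TTE model."""

    te_pop: float
    shape_s: float = 4.0
    beta_lambda0: float = 0.0
    beta_lambda1: float = 0.0
    beta_cavg: float = 0.0
    omega_te: float = 0.0
    family: str = "loglogistic"

    def __post_init__(self) -> None:
        if not self.te_pop > 0:
            raise ValueError("te_pop must be > 0")
        if self.family != "gompertz" and not self.shape_s > 0:
            raise ValueError("shape_s must be > 0")
        if self.omega_te < 0:
            raise ValueError("omega_te must be >= 0")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; known: {FAMILIES}")


@dataclass(frozen=True)
class EventRecord:
    """One animal's event or censoring time."""

    subject: str
    time: float
    status: int  # 1 event, 0 censored

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError("event/censoring time must be > 0")
        if self.status not in (0, 1):
            raise ValueError("status must be 0 (censored) or 1 (event)")


@dataclass
class CovariateSet:
    """Per-subject TTE covariates and their population medians.

    ``data`` holds one row per subject with columns ``subject``,
    ``lambda0``, ``lambda1``, ``cavg``. Medians default to the medians
    over all subjects in ``data`` (controls included); pass ``medians``
    to normalize against a different reference population.
    """

    data: pd.DataFrame
    medians: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"subject", "lambda0", "lambda1", "cavg"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"covariate table missing columns: {sorted(missing)}")
        if self.data["subject"].duplicated().any():
            raise ValueError("duplicate subjects in covariate table")
        if (self.data["cavg"] < 0).any():
            raise ValueError("cavg must be >= 0")
        for name in ("lambda0", "lambda1", "cavg"):
            self.medians.setdefault(name, float(self.data[name].median()))
        for name in ("lambda0", "lambda1"):
            if not self.medians[name] > 0:
                raise ValueError(f"median {name} must be > 0")
        if not self.medians["cavg"] > 0:
            # all-vehicle population: Cavg ratio undefined; fall back to 1
            # so the (then zero-valued) exposure term stays well defined
            self.medians["cavg"] = 1.0

    def aligned(self, subjects) -> pd.DataFrame:
        """Covariate rows in the order of ``subjects`` (error on missing)."""
        idx = self.data.set_index("subject")
        missing = [s for s in subjects if s not in idx.index]
        if missing:
            raise KeyError(f"no covariates for subjects: {missing[:5]}")
        return idx.loc[list(subjects)].reset_index()

    def log_multiplier(self, p: TTEParameters, subjects=None) -> np.ndarray:
        """log(Te_i / Te_pop) excluding frailty, per subject."""
        rows = self.aligned(subjects) if subjects is not None else self.data
        z0 = rows["lambda0"].to_numpy() / self.medians["lambda0"] - 1.0
        z1 = rows["lambda1"].to_numpy() / self.medians["lambda1"] - 1.0
        zc = rows["cavg"].to_numpy() / self.medians["cavg"]  # not centered
        return p.beta_lambda0 * z0 + p.beta_lambda1 * z1 + p.beta_cavg * zc


def _log_hazard(t, te, s, family):
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        logr = np.log(t) - np.log(te)
    if family == "loglogistic":
        return np.log(s / te) + (s - 1.0) * logr - np.logaddexp(0.0, s * logr)
    if family == "weibull":
        return np.log(s / te) + (s - 1.0) * logr
    if family == "gompertz":
        return -np.log(te) + s * t / te
    if family == "exponential":
        return -np.log(te) * np.ones_like(t)
    raise ValueError(f"unknown family {family!r}")


def _log_survival(t, te, s, family):
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        logr = np.log(t) - np.log(te)
    if family == "loglogistic":
        return -np.logaddexp(0.0, s * logr)
    if family == "weibull":
        return -np.exp(s * logr)
    if family == "gompertz":
        if abs(s) < 1e-8:
            return -t / te
        return -np.expm1(s * t / te) / s
    if family == "exponential":
        return -t / te
    raise ValueError(f"unknown family {family!r}")


def hazard(t, te, s, family: str = "loglogistic"):
    """Hazard h(t) in 1/h. Vectorized over t."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be >= 0")
    if not te > 0:
        raise ValueError("te must be > 0")
    with np.errstate(invalid="ignore"):
        out = np.exp(_log_hazard(t, te, s, family))
    # limits at t = 0 for power-law hazards
    t_arr = np.asarray(t, dtype=float)
    if family in ("loglogistic", "weibull"):
        if s > 1:
            out = np.where(t_arr == 0.0, 0.0, out)
        elif s == 1:
            out = np.where(t_arr == 0.0, 1.0 / te, out)
    return out if np.ndim(t) else float(out)


def survival(t, te, s, family: str = "loglogistic"):
    """Survivor function S(t) = exp(-integral of h). Vectorized over t."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be >= 0")
    if not te > 0:
        raise ValueError("te must be > 0")
    out = np.exp(_log_survival(t, te, s, family))
    return out if np.ndim(t) else float(out)


def individual_scale(
    p: TTEParameters,
    cov: CovariateSet,
    subjects=None,
    eta=None,
) -> np.ndarray:
    """Per-subject scale Te_i from the covariate model (plus frailty eta)."""
    logm = cov.log_multiplier(p, subjects)
    if eta is not None:
        logm = logm + np.asarray(eta, dtype=float)
    return p.te_pop * np.exp(logm)


def _events_frame(events) -> pd.DataFrame:
    """Normalize EventRecord lists / DataFrames to (subject, time, status)."""
    if isinstance(events, pd.DataFrame):
        df = events.rename(columns={"time_h": "time"})
        required = {"subject", "time", "status"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"event table missing columns: {sorted(missing)}")
        df = df[["subject", "time", "status"]].copy()
    else:
        df = pd.DataFrame(
            [{"subject": e.subject, "time": e.time, "status": e.status} for e in events]
        )
    if len(df) == 0:
        raise ValueError("no event records")
    if (df["time"] <= 0).any():
        raise ValueError("event/censoring times must be > 0")
    if not df["status"].isin([0, 1]).all():
        raise ValueError("status must be 0 or 1")
    return df


def loglik_tte(
    p: TTEParameters,
    events,
    cov: CovariateSet | None = None,
    gh_points: int = 30,
) -> float:
    """Right-censored log-likelihood of the covariate TTE model.

    Events contribute log h + log S, censored records log S. When
    ``p.omega_te > 0`` the frailty is marginalized per subject by
    Gauss-Hermite quadrature with ``gh_points`` nodes.
    """
    df = _events_frame(events)
    t = df["time"].to_numpy(dtype=float)
    d = df["status"].to_numpy(dtype=int)
    if np.any((t == 0) & (d == 1)) or np.any(t <= 0):
        raise ValueError("event at t <= 0 has zero likelihood under s > 1")
    if cov is not None:
        logm = cov.log_multiplier(p, df["subject"])
    else:
        logm = np.zeros(len(df))
    te_base = p.te_pop * np.exp(logm)

    if p.omega_te <= 0:
        log_s = _log_survival(t, te_base, p.shape_s, p.family)
        log_h = _log_hazard(t, te_base, p.shape_s, p.family)
        ll = np.where(d == 1, log_h + log_s, log_s)
        return float(np.sum(ll))

    nodes, weights = np.polynomial.hermite_e.hermegauss(gh_points)
    # eta = omega * node; probabilists' weights sum to sqrt(2 pi)
    log_w = np.log(weights / np.sqrt(2.0 * np.pi))
    te_ij = te_base[:, None] * np.exp(p.omega_te * nodes[None, :])
    log_s = _log_survival(t[:, None], te_ij, p.shape_s, p.family)
    log_f = _log_hazard(t[:, None], te_ij, p.shape_s, p.family) + log_s
    contrib = np.where(d[:, None] == 1, log_f, log_s)
    ll_i = np.logaddexp.reduce(contrib + log_w[None, :], axis=1)
    return float(np.sum(ll_i))


def simulate_events(
    p: TTEParameters,
    cov: CovariateSet,
    censor_time: float,
    seed=None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one replicate of event/censoring records by inverse CDF.

    For the log-logistic family, t = Te_i * (1/u - 1)^(1/s) with
    u ~ Uniform(0,1) (so S(t) = u); other families use their closed-form
    survival inverses. Times exceeding ``censor_time`` are recorded as
    censored at ``censor_time``.
    """
    if not censor_time > 0:
        raise ValueError("censor_time must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(cov.data)
    eta = (
        rng.normal(0.0, p.omega_te, size=n)
        if p.omega_te > 0
        else np.zeros(n)
    )
    te_i = individual_scale(p, cov, eta=eta)
    u = rng.uniform(size=n)
    s = p.shape_s
    if p.family == "loglogistic":
        t = te_i * (1.0 / u - 1.0) ** (1.0 / s)
    elif p.family == "weibull":
        t = te_i * (-np.log(u)) ** (1.0 / s)
    elif p.family == "exponential":
        t = -te_i * np.log(u)
    elif p.family == "gompertz":
        t = te_i / s * np.log1p(-s * np.log(u))
    else:
        raise ValueError(f"unknown family {p.family!r}")
    status = (t <= censor_time).astype(int)
    time = np.minimum(t, censor_time)
    return pd.DataFrame(
        {"subject": cov.data["subject"].to_numpy(), "time": time, "status": status}
    )


class ParametricTTEEstimator(BaseEstimator):
    """Censored maximum-likelihood fit of a parametric TTE model.

    scikit-learn-style estimator. ``fit`` expects a DataFrame with
    columns ``subject``, ``time`` (h; ``time_h`` accepted) and ``status``
    (1 event / 0 censored), plus a :class:`CovariateSet` when covariates
    are modeled.

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    shape : float
        Shape parameter; for the log-logistic family fixed at 4 by
        default (set ``estimate_shape=True`` for the family screen).
    estimate_shape : bool
        Estimate the shape by ML instead of fixing it. Always on for
        Weibull/Gompertz (their shape has no conventional fixed value).
    with_covariates : bool
        Include the growth-rate and exposure covariate model on Te.
    frailty : {'estimate', 'none'} or float
        Residual between-animal variability on log Te: estimated (with a
        positivity floor of 1e-4 — weakly identified with one event per
        subject), omitted, or fixed at a given SD.
    gh_points : int
        Gauss-Hermite nodes for marginalizing the frailty.

    Attributes
    ----------
    params_ : TTEParameters
        Fitted population parameters.
    result_ : FitResult
        Estimates, SEs, -2LL and AIC.
    """

    def __init__(
        self,
        family: str = "loglogistic",
        shape: float = 4.0,
        estimate_shape: bool = False,
        with_covariates: bool = True,
        frailty="estimate",
        gh_points: int = 30,
    ):
        self.family = family
        self.shape = shape
        self.estimate_shape = estimate_shape
        self.with_covariates = with_covariates
        self.frailty = frailty
        self.gh_points = gh_points

    # -- internal parameter vector <-> TTEParameters -------------------
    def _unpack(self, x, medians_only_cov):
        i = 1
        kw = {"te_pop": float(np.exp(x[0])), "family": self.family}
        if self._est_shape:
            kw["shape_s"] = float(np.exp(x[i]))
            i += 1
        else:
            kw["shape_s"] = self.shape
        if self.with_covariates:
            kw["beta_lambda0"] = float(x[i])
            kw["beta_lambda1"] = float(x[i + 1])
            kw["beta_cavg"] = float(x[i + 2])
            i += 3
        if self._est_omega:
            kw["omega_te"] = float(np.exp(x[i]))
            i += 1
        else:
            kw["omega_te"] = self._fixed_omega
        return TTEParameters(**kw)

    def fit(self, X, y=None, cov: CovariateSet | None = None):
        df = _events_frame(X)
        if df["status"].sum() < 1:
            raise ValueError("need at least one event to fit a TTE model")
        if self.with_covariates and cov is None:
            raise ValueError("with_covariates=True requires a CovariateSet")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

        self._est_shape = self.estimate_shape or self.family in ("weibull", "gompertz")
        if self.family == "exponential":
            self._est_shape = False
        if self.frailty == "estimate":
            self._est_omega, self._fixed_omega = True, 0.0
        elif self.frailty == "none":
            self._est_omega, self._fixed_omega = False, 0.0
        else:
            self._est_omega, self._fixed_omega = False, float(self.frailty)

        t = df["time"].to_numpy(dtype=float)
        # initial scale: median observed time (events dominate the study)
        x0 = [np.log(np.median(t))]
        bounds = [(None, None)]
        names = ["te_pop"]
        if self._est_shape:
            x0.append(np.log(self.shape if self.family != "gompertz" else 1.0))
            bounds.append((np.log(1e-3), np.log(50.0)))
            names.append("shape_s")
        if self.with_covariates:
            x0 += [0.0, 0.0, 0.0]
            bounds += [(-20.0, 20.0)] * 3
            names += ["beta_lambda0", "beta_lambda1", "beta_cavg"]
        if self._est_omega:
            x0.append(np.log(0.1))
            bounds.append((np.log(OMEGA_FLOOR), np.log(5.0)))
            names.append("omega_te")

        use_cov = cov if self.with_covariates else None

        def nll(x):
            try:
                p = self._unpack(x, use_cov)
            except ValueError:
                return 1e12
            ll = loglik_tte(p, df, use_cov, gh_points=self.gh_points)
            return -ll if np.isfinite(ll) else 1e12

        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": 500}
        )
        # polish with Nelder-Mead from the L-BFGS-B solution
        res2 = optimize.minimize(
            nll, res.x, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10}
        )
        if res2.fun <= res.fun:
            res = res2
        self.params_ = self._unpack(res.x, use_cov)
        self.minus2ll_ = 2.0 * res.fun
        self.n_params_ = len(res.x)

        se = self._standard_errors(nll, res.x, names)
        estimates = {
            "te_pop": self.params_.te_pop,
            "shape_s": self.params_.shape_s,
        }
        if self.with_covariates:
            estimates.update(
                beta_lambda0=self.params_.beta_lambda0,
                beta_lambda1=self.params_.beta_lambda1,
                beta_cavg=self.params_.beta_cavg,
            )
        estimates["omega_te"] = self.params_.omega_te
        self.result_ = FitResult(
            estimates=estimates,
            se=se,
            minus2ll=self.minus2ll_,
            n_params=self.n_params_,
            n_obs=len(df),
            convergence={"success": bool(res.success or res2.success), "message": res.message},
            model=self,
        )
        self.aic_ = self.result_.aic
        self.covariates_ = use_cov
        return self

    @property
    def label(self) -> str:
        tag = "covariate" if self.with_covariates else "base"
        return f"{self.family} ({tag})"

    def _standard_errors(self, nll, x, names) -> dict:
        """Delta-method SEs from a central-difference Hessian of the NLL."""
        n = len(x)
        h = 1e-4 * np.maximum(1.0, np.abs(x))
        hess = np.zeros((n, n))
        f0 = nll(x)
        for i in range(n):
            for j in range(i, n):
                xi = np.array(x, dtype=float)
                if i == j:
                    xp, xm = xi.copy(), xi.copy()
                    xp[i] += h[i]
                    xm[i] -= h[i]
                    hess[i, i] = (nll(xp) - 2 * f0 + nll(xm)) / h[i] ** 2
                else:
                    xpp, xpm, xmp, xmm = (xi.copy() for _ in range(4))
                    xpp[[i, j]] += [h[i], h[j]]
                    xpm[i] += h[i]
                    xpm[j] -= h[j]
                    xmp[i] -= h[i]
                    xmp[j] += h[j]
                    xmm[[i, j]] -= [h[i], h[j]]
                    hess[i, j] = hess[j, i] = (
                        nll(xpp) - nll(xpm) - nll(xmp) + nll(xmm)
                    ) / (4 * h[i] * h[j])
        try:
            cov_x = np.linalg.inv(hess)
            var = np.diag(cov_x)
        except np.linalg.LinAlgError:
            var = np.full(n, np.nan)
        se = {}
        for name, xi, v in zip(names, x, var):
            s = np.sqrt(v) if v > 0 else np.nan
            if name in ("te_pop", "shape_s", "omega_te"):
                # parameters optimized on the log scale
                se[name] = float(np.exp(xi) * s)
            else:
                se[name] = float(s)
        return se

    def predict_survival(self, times, cov: CovariateSet | None = None) -> pd.DataFrame:
        """Per-subject S(t) on a time grid using the fitted parameters."""
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
        use_cov = cov or self.covariates_
        times = np.asarray(times, dtype=float)
        if use_cov is None:
            s = survival(times, self.params_.te_pop, self.params_.shape_s, self.family)
            return pd.DataFrame({"time": times, "survival": s})
        te_i = individual_scale(self.params_, use_cov)
        rows = []
        for subj, te in zip(use_cov.data["subject"], te_i):
            rows.append(
                pd.DataFrame(
                    {
                        "subject": subj,
                        "time": times,
                        "survival": survival(times, te, self.params_.shape_s, self.family),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def fit_tte(
    events,
    cov: CovariateSet | None = None,
    family: str = "loglogistic",
    **config,
) -> FitResult:
    """Fit a parametric TTE model; thin wrapper over ParametricTTEEstimator."""
    config.setdefault("with_covariates", cov is not None)
    est = ParametricTTEEstimator(family=family, **config)
    est.fit(events, cov=cov)
    return est.result_
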