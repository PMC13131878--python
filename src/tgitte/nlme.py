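"""Population (nonlinear mixed-effects) estimation of the TGI model.

Observation model for animal i at time t_ij:

    y_ij = f(t_ij; p_i) + (a + b * f) * eps_ij,   eps_ij ~ N(0, 1)

with f the TGI trajectory, a combined residual error (sd = a + b*f,
"combined1" convention) and log-normal interindividual variability

    p_i = p_pop * exp(eta_i),   eta_i ~ N(0, omega_p^2),

for p in (lambda0, lambda1, kill). The baseline volume TV0 enters as a
per-animal regressor fixed at the observed baseline measurement, not as
an estimated parameter.

Two estimation modes are provided:

* ``two-stage`` (default): each animal is fitted by weighted least
  squares on the log-parameter scale, and the individual estimates are
  pooled into population typical values and omegas by a random-effects
  (DerSimonian-Laird) summary on the log scale that accounts for each
  animal's estimation uncertainty. Fast and deterministic; the mode used
  for study-scale fits and bootstrap work.
* ``saem``: a stochastic-approximation EM scheme — per-animal
  Metropolis-within-Gibbs sampling of the random effects, stochastic
  averaging of the complete-data sufficient statistics over an
  exploration phase followed by a smoothing phase. Reference behavior
  for small datasets; considerably slower.

The marginal -2 log-likelihood is evaluated by the Laplace
approximation, importance sampling, or adaptive Gauss-Hermite
quadrature; empirical-Bayes estimates (EBEs) are the per-animal MAP
random effects, and eta-shrinkage is 100 * (1 - sd(eta_hat)/omega).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .data import StudyDataset
from .pk import PKParameters, Regimen
from .results import FitResult, compare_models
from .tgi import TGIParameters, simulate_trajectory

__all__ = [
    "PAR_NAMES",
    "PopulationModel",
    "FitResult",
    "TGIPopulationEstimator",
    "fit_population",
    "individual_params",
    "residual_sd",
    "empirical_bayes",
    "shrinkage",
    "compare_models",
    "marginal_loglik",
    "lognormal_cv_percent",
]

PAR_NAMES = ("lambda0", "lambda1", "kill")

# box constraints for per-animal log-parameter searches; generous around
# physiological mouse-xenograft scales, they only guard optimizer excursions
_LOG_BOUNDS = {
    "lambda0": (np.log(1e-4), np.log(0.5)),
    "lambda1": (np.log(5e-2), np.log(500.0)),
    "kill": (np.log(1e-8), np.log(1e-2)),
}


def lognormal_cv_percent(omega: float) -> float:
    """CV% of a lognormal with log-scale SD omega: 100*sqrt(exp(omega^2)-1)."""
    return 100.0 * np.sqrt(np.expm1(omega**2))


@dataclass(frozen=True)
class PopulationModel:
    """Typical values, IIV and residual error of the population TGI model."""

    theta: dict  # {"lambda0": 1/h, "lambda1": mm3/h, "kill": mL/ng/h}
    omega: dict  # log-scale SDs, same keys
    residual: tuple  # (a mm3, b fraction)
    error_model: str = "combined"

    def __post_init__(self) -> None:
        for name in PAR_NAMES:
            if name not in self.theta:
                raise ValueError(f"theta missing {name!r}")
            if not self.theta[name] > 0:
                raise ValueError(f"theta[{name!r}] must be > 0")
            if self.omega.get(name, 0.0) < 0:
                raise ValueError(f"omega[{name!r}] must be >= 0")
        a, b = self.residual
        if a < 0 or b < 0 or (a == 0 and b == 0):
            raise ValueError("residual (a, b) must be >= 0 and not both zero")
        if self.error_model not in ("additive", "proportional", "combined"):
            raise ValueError(f"unknown error model {self.error_model!r}")

    def cv_percent(self) -> dict:
        return {k: lognormal_cv_percent(w) for k, w in self.omega.items()}


def residual_sd(prediction, residual: tuple, error_model: str = "combined"):
    """Residual SD (mm3) at a model prediction under the chosen error model.

    combined: a + b*f ('combined1'); additive: a; proportional: b*f.
    """
    f = np.asarray(prediction, dtype=float)
    if np.any(f < 0):
        raise ValueError("prediction must be >= 0")
    a, b = residual
    if error_model == "additive":
        out = np.full_like(f, a)
    elif error_model == "proportional":
        out = b * f
    elif error_model == "combined":
        out = a + b * f
    else:
        raise ValueError(f"unknown error model {error_model!r}")
    return out if np.ndim(prediction) else float(out)


def individual_params(theta: dict, omega: dict, eta: pd.DataFrame) -> pd.DataFrame:
    """Per-subject parameters p_i = p_pop * exp(eta_i).

    ``eta`` has one row per subject with columns among PAR_NAMES
    (missing columns are treated as eta = 0).
    """
    out = pd.DataFrame(index=eta.index)
    for name in PAR_NAMES:
        e = eta[name] if name in eta.columns else 0.0
        out[name] = theta[name] * np.exp(e)
    return out


# ---------------------------------------------------------------------------
# per-subject machinery


class _Subject:
    """Cached per-animal data: times, volumes, regimen, baseline regressor."""

    def __init__(self, subject, obs: pd.DataFrame, regimen: Regimen, tv0: float):
        self.subject = subject
        times = obs["time_h"].to_numpy(dtype=float)
        order = np.argsort(times)
        self.times = times[order]
        self.volumes = obs["tv_mm3"].to_numpy(dtype=float)[order]
        self.regimen = regimen
        self.tv0 = float(tv0)
        self.treated = not regimen.is_vehicle
        if self.times[0] != 0.0:
            # prepend t=0 for simulation; baseline not observed
            self.sim_times = np.concatenate([[0.0], self.times])
            self.has_baseline = False
        else:
            self.sim_times = self.times
            self.has_baseline = True

    def predict(self, params: dict, pk: PKParameters) -> np.ndarray:
        p = TGIParameters(
            lambda0=params["lambda0"],
            lambda1=params["lambda1"],
            kill=params["kill"] if self.treated else 0.0,
            tv0=self.tv0,
        )
        traj = simulate_trajectory(p, pk, self.regimen, self.sim_times, rtol=1e-7, atol=1e-9)
        return traj.volumes if self.has_baseline else traj.volumes[1:]


def _subjects_from(data: StudyDataset) -> list:
    arm_of = data.arm_of()
    tv0 = data.baseline_tv()
    subjects = []
    for s in data.subjects:
        obs = data.subject_observations(s)
        subjects.append(_Subject(s, obs, data.regimens[arm_of[s]], tv0[s]))
    return subjects


def _gauss_loglik(y, f, residual, error_model):
    sd = residual_sd(f, residual, error_model)
    sd = np.maximum(sd, 1e-9)
    return float(np.sum(-0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((y - f) / sd) ** 2))


# ---------------------------------------------------------------------------
# two-stage estimation


def _fit_subject(
    subj: _Subject,
    pk: PKParameters,
    init: dict,
    residual: tuple,
    error_model: str,
):
    """Weighted least-squares fit of one animal on the log-parameter scale.

    Returns (log-estimates dict, log-scale covariance diag dict). The
    residuals are standardized by the model-based sd a + b*f, so the
    Jacobian-based covariance (J^T J)^-1 is on the standardized scale.
    """
    free = list(PAR_NAMES) if subj.treated else ["lambda0", "lambda1"]
    x0 = np.array([np.log(init[name]) for name in free])
    lo = np.array([_LOG_BOUNDS[n][0] for n in free])
    hi = np.array([_LOG_BOUNDS[n][1] for n in free])
    x0 = np.clip(x0, lo, hi)

    def make_params(x):
        params = {"kill": init["kill"] if not subj.treated else None}
        for name, xi in zip(free, x):
            params[name] = np.exp(xi)
        if params["kill"] is None:
            params["kill"] = init["kill"]
        return params

    def resid(x):
        f = subj.predict(make_params(x), pk)
        sd = np.maximum(residual_sd(f, residual, error_model), 1e-9)
        return (subj.volumes - f) / sd

    sol = optimize.least_squares(
        resid, x0, bounds=(lo, hi), method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10
    )
    est = {name: float(xi) for name, xi in zip(free, sol.x)}
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj)
        var = np.clip(np.diag(cov), 1e-8, np.inf)
    except np.linalg.LinAlgError:
        var = np.full(len(free), np.inf)
    se2 = {name: float(v) for name, v in zip(free, var)}
    return est, se2, sol


def _dersimonian_laird(y: np.ndarray, v: np.ndarray):
    """Random-effects pooled mean on the log scale.

    Returns (mu, se_mu, tau) where tau is the between-subject SD (the
    omega estimate) after removing within-subject estimation variance.
    """
    w = 1.0 / v
    mu_f = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - mu_f) ** 2)
    n = len(y)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (n - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    mu = np.sum(w_star * y) / np.sum(w_star)
    se_mu = np.sqrt(1.0 / np.sum(w_star))
    return float(mu), float(se_mu), float(np.sqrt(tau2))


def _fit_residual(residuals_flat, predictions_flat, error_model, init=(10.0, 0.2)):
    """ML estimate of (a, b) given pooled (obs - pred) and predictions."""
    r = np.asarray(residuals_flat)
    f = np.asarray(predictions_flat)

    def nll(x):
        a, b = x
        if error_model == "additive":
            sd = np.full_like(f, a)
        elif error_model == "proportional":
            sd = b * f
        else:
            sd = a + b * f
        sd = np.maximum(sd, 1e-9)
        return float(np.sum(np.log(sd) + 0.5 * (r / sd) ** 2))

    bounds = [(1e-6, None), (1e-6, None)]
    if error_model == "additive":
        bounds[1] = (0.0, 0.0)
        init = (init[0], 0.0)
    if error_model == "proportional":
        bounds[0] = (0.0, 0.0)
        init = (0.0, init[1] if init[1] > 0 else 0.2)
    res = optimize.minimize(nll, init, method="L-BFGS-B", bounds=bounds)
    return float(res.x[0]), float(res.x[1])


# ---------------------------------------------------------------------------
# random-effect (eta) machinery shared by EBE / likelihood / SAEM


def _free_effects(model: PopulationModel) -> list:
    return [n for n in PAR_NAMES if model.omega.get(n, 0.0) > 0]


def _joint_neg_logpost(x, free, subj, pk, model: PopulationModel):
    """-(log p(y | eta) + log p(eta)); x holds eta for the free effects."""
    eta = dict(zip(free, x))
    params = {
        name: model.theta[name] * np.exp(eta.get(name, 0.0)) for name in PAR_NAMES
    }
    try:
        f = subj.predict(params, pk)
    except (RuntimeError, ValueError):
        return 1e12
    ll = _gauss_loglik(subj.volumes, f, model.residual, model.error_model)
    lp = 0.0
    for name, e in eta.items():
        w = model.omega[name]
        lp += -0.5 * np.log(2 * np.pi * w**2) - 0.5 * (e / w) ** 2
    return -(ll + lp)


def _map_eta(subj, pk, model: PopulationModel, x0=None):
    """Per-animal MAP random effects (penalized weighted least squares).

    Returns eta over the free effects (omega > 0), in _free_effects order.
    """
    free = _free_effects(model)
    if not free:
        return np.zeros(0)
    x0 = np.zeros(len(free)) if x0 is None else np.asarray(x0, dtype=float)

    def resid(x):
        eta = dict(zip(free, x))
        params = {
            name: model.theta[name] * np.exp(eta.get(name, 0.0)) for name in PAR_NAMES
        }
        f = subj.predict(params, pk)
        sd = np.maximum(residual_sd(f, model.residual, model.error_model), 1e-9)
        pen = np.array([x_i / model.omega[n] for n, x_i in zip(free, x)])
        return np.concatenate([(subj.volumes - f) / sd, pen])

    sol = optimize.least_squares(resid, x0, method="lm", xtol=1e-10, ftol=1e-10)
    return sol.x


def _eta_hessian(subj, pk, model, free, eta_hat, h=1e-3):
    """Central-difference Hessian of the negative log joint at eta_hat."""
    d = len(eta_hat)
    hess = np.zeros((d, d))
    f0 = _joint_neg_logpost(eta_hat, free, subj, pk, model)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h
        fp = _joint_neg_logpost(eta_hat + ei, free, subj, pk, model)
        fm = _joint_neg_logpost(eta_hat - ei, free, subj, pk, model)
        hess[i, i] = (fp - 2 * f0 + fm) / h**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h
            fpp = _joint_neg_logpost(eta_hat + ei + ej, free, subj, pk, model)
            fpm = _joint_neg_logpost(eta_hat + ei - ej, free, subj, pk, model)
            fmp = _joint_neg_logpost(eta_hat - ei + ej, free, subj, pk, model)
            fmm = _joint_neg_logpost(eta_hat - ei - ej, free, subj, pk, model)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h**2)
    return hess


def _subject_loglik(subj, pk, model, method, gh_points, n_is, rng):
    """Marginal log-likelihood contribution of one animal."""
    free = _free_effects(model)
    if not free:
        f = subj.predict(dict(model.theta), pk)
        return _gauss_loglik(subj.volumes, f, model.residual, model.error_model)
    eta_hat = _map_eta(subj, pk, model)
    neg_logpost_hat = _joint_neg_logpost(eta_hat, free, subj, pk, model)
    hess = _eta_hessian(subj, pk, model, free, eta_hat)
    # regularize: fall back to prior curvature if not positive definite
    try:
        np.linalg.cholesky(hess)
    except np.linalg.LinAlgError:
        hess = np.diag([1.0 / model.omega[n] ** 2 for n in free])
    d = len(eta_hat)
    _, logdet = np.linalg.slogdet(hess)
    if method == "laplace":
        return -neg_logpost_hat + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet

    cov = np.linalg.inv(hess)
    if method == "importance":
        scale_cov = 1.5 * cov
        L = np.linalg.cholesky(scale_cov)
        z = rng.standard_normal((n_is, d))
        etas = eta_hat + z @ L.T
        logq = (
            -0.5 * d * np.log(2 * np.pi)
            - 0.5 * np.linalg.slogdet(scale_cov)[1]
            - 0.5 * np.sum(z**2, axis=1)
        )
        logj = np.array(
            [-_joint_neg_logpost(e, free, subj, pk, model) for e in etas]
        )
        return float(np.logaddexp.reduce(logj - logq) - np.log(n_is))

    if method == "agq":
        nodes, weights = np.polynomial.hermite.hermgauss(gh_points)
        L = np.linalg.cholesky(cov)
        grids = np.meshgrid(*([nodes] * d), indexing="ij")
        x = np.stack([g.ravel() for g in grids], axis=1)
        wgrids = np.meshgrid(*([weights] * d), indexing="ij")
        logw = np.sum(
            np.log(np.stack([g.ravel() for g in wgrids], axis=1)), axis=1
        )
        etas = eta_hat + np.sqrt(2.0) * x @ L.T
        logj = np.array(
            [-_joint_neg_logpost(e, free, subj, pk, model) for e in etas]
        )
        terms = logw + np.sum(x**2, axis=1) + logj
        const = 0.5 * d * np.log(2.0) + np.linalg.slogdet(L)[1]
        return float(np.logaddexp.reduce(terms) + const)

    raise ValueError(f"unknown likelihood method {method!r}")


def marginal_loglik(
    data: StudyDataset,
    model: PopulationModel,
    pk: PKParameters,
    method: str = "laplace",
    gh_points: int = 5,
    n_is: int = 1000,
    seed: int = 0,
) -> float:
    """Marginal log-likelihood of the population model on a study dataset.

    method: 'laplace' (deterministic, default), 'importance'
    (importance sampling around the MAP), or 'agq' (adaptive
    Gauss-Hermite with ``gh_points`` nodes per dimension — tensor grid,
    intended for small datasets).
    """
    rng = np.random.default_rng(seed)
    subjects = _subjects_from(data)
    return float(
        sum(
            _subject_loglik(s, pk, model, method, gh_points, n_is, rng)
            for s in subjects
        )
    )


def empirical_bayes(
    data: StudyDataset, fit: FitResult, pk: PKParameters | None = None
) -> pd.DataFrame:
    """Per-subject MAP parameters (EBEs) under a fitted population model.

    Returns one row per subject with eta_<p> and <p> columns. Subjects
    whose likelihood carries no information on a parameter (e.g. the
    kill rate of a vehicle animal) shrink to the population value.
    """
    model: PopulationModel = fit.model if isinstance(fit.model, PopulationModel) else fit.model.population_model_
    if pk is None:
        pk = getattr(fit, "pk", None) or fit.convergence.get("pk")
    if pk is None:
        raise ValueError("PK parameters required to compute EBEs")
    free = _free_effects(model)
    rows = []
    for subj in _subjects_from(data):
        x = _map_eta(subj, pk, model)
        eta = dict(zip(free, x))
        row = {"subject": subj.subject}
        for name in PAR_NAMES:
            e = eta.get(name, 0.0)
            row[f"eta_{name}"] = e
            row[name] = model.theta[name] * np.exp(e)
        rows.append(row)
    return pd.DataFrame(rows)


def shrinkage(eta_estimates, omega: float) -> float:
    """Eta-shrinkage (%) = 100 * (1 - sd(eta_hat)/omega).

    Near 0 when individual data are rich; approaches 100 as the EBEs
    collapse to the population value.
    """
    if not omega > 0:
        raise ValueError("omega must be > 0 to compute shrinkage")
    sd = float(np.std(np.asarray(eta_estimates, dtype=float), ddof=1))
    return 100.0 * (1.0 - sd / omega)


# ---------------------------------------------------------------------------
# the estimator


class TGIPopulationEstimator(BaseEstimator):
    """Population TGI model fit (scikit-learn-style estimator).

    ``fit`` takes a :class:`~tgitte.data.StudyDataset` containing tumor
    volume observations from control and treated arms; the control arms
    anchor the natural-growth parameters while the treated arms identify
    the kill rate, all fitted simultaneously against the same
    population distribution.

    Parameters
    ----------
    pk : PKParameters
        Typical-value PK used to generate Cp(t) for the kill term.
    mode : {'two-stage', 'saem'}
        Estimation scheme (see module docstring).
    init : PopulationModel or None
        Initial values; a naive default is used when None.
    error_model : {'additive', 'proportional', 'combined'}
    outer_iterations : int
        Two-stage mode: alternations of subject fits and residual-error
        re-estimation.
    saem_iterations : tuple (K_explore, K_smooth)
    mcmc_sweeps : int
        Metropolis sweeps per subject per SAEM iteration.
    loglik_method : {'laplace', 'importance', 'agq', 'none'}
        How the final -2LL is evaluated ('none' skips it for speed).
    seed : int
        Seed for SAEM and importance sampling; the two-stage path is
        deterministic.

    Attributes
    ----------
    population_model_ : PopulationModel
    result_ : FitResult
    ebes_ : pandas.DataFrame
    shrinkage_ : dict
    """

    def __init__(
        self,
        pk: PKParameters | None = None,
        mode: str = "two-stage",
        init: PopulationModel | None = None,
        error_model: str = "combined",
        outer_iterations: int = 2,
        saem_iterations: tuple = (120, 60),
        mcmc_sweeps: int = 2,
        loglik_method: str = "laplace",
        compute_ebes: bool = True,
        seed: int = 0,
    ):
        self.pk = pk
        self.mode = mode
        self.init = init
        self.error_model = error_model
        self.outer_iterations = outer_iterations
        self.saem_iterations = saem_iterations
        self.mcmc_sweeps = mcmc_sweeps
        self.loglik_method = loglik_method
        self.compute_ebes = compute_ebes
        self.seed = seed

    def _default_init(self, data: StudyDataset) -> PopulationModel:
        # naive pooled starting values: exponential rate from pooled
        # early log-slopes, linear rate from the volume scale
        obs = data.observations
        early = obs[obs["time_h"] <= 240]
        slope = 0.005
        try:
            g = early.groupby("subject")
            slopes = []
            for _, rows in g:
                if len(rows) >= 2:
                    t = rows["time_h"].to_numpy(dtype=float)
                    v = np.log(rows["tv_mm3"].to_numpy(dtype=float))
                    s = np.polyfit(t, v, 1)[0]
                    if 1e-4 < s < 0.5:
                        slopes.append(s)
            if slopes:
                slope = float(np.median(slopes))
        except Exception:
            pass
        return PopulationModel(
            theta={"lambda0": slope, "lambda1": 5.0, "kill": 1e-5},
            omega={"lambda0": 0.3, "lambda1": 0.3, "kill": 0.3},
            residual=(10.0, 0.2),
            error_model=self.error_model,
        )

    # ------------------------------------------------------------------
    def fit(self, X: StudyDataset, y=None):
        data = X
        if data.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        counts = data.observations.groupby("subject").size()
        if (counts < 2).any():
            raise ValueError("every subject needs at least 2 observations")
        if self.pk is None:
            raise ValueError("PKParameters required (kill term needs Cp(t))")
        subjects = _subjects_from(data)
        if all(not s.treated for s in subjects):
            # kill rate not identifiable from an all-control dataset
            self._kill_identifiable = False
        else:
            self._kill_identifiable = True

        init = self.init or self._default_init(data)
        if self.mode == "two-stage":
            model, se, diag = self._fit_two_stage(subjects, init)
            # the ITS refinement needs every identifiable omega strictly
            # positive; a zero naive-pooling tau would freeze it out
            omega = dict(model.omega)
            for p in PAR_NAMES:
                if p == "kill" and not self._kill_identifiable:
                    continue
                omega[p] = max(omega[p], 0.1)
            model = replace(model, omega=omega)
            model, se2, diag2 = self._fit_its(subjects, model)
            se.update(se2)
            diag.update(diag2)
        elif self.mode == "naive-two-stage":
            model, se, diag = self._fit_two_stage(subjects, init)
        elif self.mode == "saem":
            model, se, diag = self._fit_saem(subjects, init)
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

        self.population_model_ = model
        n_params = 3 + 3 + (2 if model.error_model == "combined" else 1)
        if not self._kill_identifiable:
            n_params -= 2  # kill theta and omega not estimated

        if self.loglik_method != "none":
            ll = marginal_loglik(
                data, model, self.pk, method=self.loglik_method, seed=self.seed
            )
            minus2ll = -2.0 * ll
        else:
            minus2ll = np.nan

        estimates = {
            **{f"{n}_pop": model.theta[n] for n in PAR_NAMES},
            **{f"omega_{n}": model.omega[n] for n in PAR_NAMES},
            "a": model.residual[0],
            "b": model.residual[1],
        }
        self.result_ = FitResult(
            estimates=estimates,
            se=se,
            minus2ll=minus2ll,
            n_params=n_params,
            n_obs=data.n_observations,
            convergence=diag,
            model=model,
        )
        if self.compute_ebes:
            self.ebes_ = empirical_bayes(data, self.result_, pk=self.pk)
            self.shrinkage_ = {
                n: shrinkage(self.ebes_[f"eta_{n}"], model.omega[n])
                for n in PAR_NAMES
                if model.omega[n] > 0
                and (n != "kill" or self._kill_identifiable)
            }
            self.result_.ebes = self.ebes_
            self.result_.shrinkage = self.shrinkage_
        self.minus2ll_ = minus2ll
        self.aic_ = self.result_.aic
        return self

    # ------------------------------------------------------------------
    def _fit_two_stage(self, subjects, init: PopulationModel):
        residual = init.residual
        theta = dict(init.theta)
        est_logs = {}
        est_vars = {}
        fits = {}
        for it in range(self.outer_iterations):
            est_logs = {n: [] for n in PAR_NAMES}
            est_vars = {n: [] for n in PAR_NAMES}
            all_resid, all_pred = [], []
            for subj in subjects:
                est, se2, sol = _fit_subject(
                    subj, self.pk, theta, residual, self.error_model
                )
                fits[subj.subject] = est
                for name in est:
                    est_logs[name].append(est[name])
                    est_vars[name].append(se2[name])
                params = {n: np.exp(est[n]) if n in est else theta[n] for n in PAR_NAMES}
                f = subj.predict(params, self.pk)
                all_resid.append(subj.volumes - f)
                all_pred.append(f)
            residual = _fit_residual(
                np.concatenate(all_resid),
                np.concatenate(all_pred),
                self.error_model,
                init=residual,
            )
            pooled = {}
            for name in PAR_NAMES:
                if est_logs[name]:
                    y = np.asarray(est_logs[name])
                    v = np.asarray(est_vars[name])
                    pooled[name] = _dersimonian_laird(y, v)
                else:
                    pooled[name] = (np.log(theta[name]), np.nan, 0.0)
            theta = {n: float(np.exp(pooled[n][0])) for n in PAR_NAMES}

        omega = {n: pooled[n][2] for n in PAR_NAMES}
        if not self._kill_identifiable:
            omega["kill"] = init.omega.get("kill", 0.0)
        model = PopulationModel(
            theta=theta, omega=omega, residual=residual, error_model=self.error_model
        )
        se = {f"{n}_pop": theta[n] * pooled[n][1] for n in PAR_NAMES if est_logs[n]}
        diag = {
            "mode": "two-stage",
            "n_individual_fits": len(subjects),
            "outer_iterations": self.outer_iterations,
        }
        return model, se, diag

    # ------------------------------------------------------------------
    def _fit_its(self, subjects, start: PopulationModel, max_iter: int = 25, tol: float = 1e-4):
        """Iterative two-stage (EM-like) refinement of a population model.

        Alternates per-animal MAP random effects under the current
        population distribution with moment updates: typical values are
        recentred by the mean MAP eta, and each omega^2 is the mean of
        eta_hat^2 plus the mean posterior variance from the curvature of
        the log joint — so animals whose data carry no information on a
        parameter contribute their prior variance and neither shrink nor
        inflate the estimate. Far more robust than naive pooling when
        some animals are weakly informative (few linear-phase points,
        low-dose arms), at the cost of iterated MAP fits.
        """
        model = start
        free = _free_effects(model)
        if not free:
            return model, {}, {"its_iterations": 0}
        n = len(subjects)
        eta = {s.subject: np.zeros(len(free)) for s in subjects}
        history = []
        for it in range(max_iter):
            etas = np.empty((n, len(free)))
            vars_ = np.empty((n, len(free)))
            all_resid, all_pred = [], []
            for i, subj in enumerate(subjects):
                x = _map_eta(subj, self.pk, model, x0=eta[subj.subject])
                eta[subj.subject] = x
                etas[i] = x
                hess = _eta_hessian(subj, self.pk, model, free, x)
                try:
                    v = np.diag(np.linalg.inv(hess))
                    if np.any(v <= 0):
                        raise np.linalg.LinAlgError
                except np.linalg.LinAlgError:
                    v = np.array([model.omega[p] ** 2 for p in free])
                vars_[i] = np.minimum(v, [model.omega[p] ** 2 for p in free])
                params = {
                    p: model.theta[p] * np.exp(dict(zip(free, x)).get(p, 0.0))
                    for p in PAR_NAMES
                }
                f = subj.predict(params, self.pk)
                all_resid.append(subj.volumes - f)
                all_pred.append(f)

            shift = etas.mean(axis=0)
            theta = dict(model.theta)
            for j, p in enumerate(free):
                theta[p] = float(theta[p] * np.exp(shift[j]))
            etas_c = etas - shift
            omega = dict(model.omega)
            for j, p in enumerate(free):
                omega[p] = float(np.sqrt(np.mean(etas_c[:, j] ** 2 + vars_[:, j])))
            residual = _fit_residual(
                np.concatenate(all_resid),
                np.concatenate(all_pred),
                self.error_model,
                init=model.residual,
            )
            new_model = PopulationModel(
                theta=theta, omega=omega, residual=residual, error_model=self.error_model
            )
            delta = max(
                abs(np.log(new_model.theta[p]) - np.log(model.theta[p])) for p in free
            )
            history.append(delta)
            # keep phi_hat fixed under the recentred typical values
            for s in subjects:
                eta[s.subject] = eta[s.subject] - shift
            model = new_model
            if delta < tol:
                break
        if not self._kill_identifiable:
            omega = dict(model.omega)
            omega["kill"] = start.omega.get("kill", 0.0)
            model = replace(model, omega=omega)
        # SE of a lognormal typical value: omega-scale spread over sqrt(n)
        se = {
            f"{p}_pop": model.theta[p] * model.omega[p] / np.sqrt(n) for p in free
        }
        diag = {"its_iterations": it + 1, "its_delta": history}
        return model, se, diag

    # ------------------------------------------------------------------
    def _fit_saem(self, subjects, init: PopulationModel):
        rng = np.random.default_rng(self.seed)
        k1, k2 = self.saem_iterations
        n = len(subjects)
        d = len(PAR_NAMES)
        log_theta = np.array([np.log(init.theta[p]) for p in PAR_NAMES])
        omega = np.array([max(init.omega.get(p, 0.3), 0.05) for p in PAR_NAMES])
        residual = list(init.residual)

        # current eta draws, per subject
        eta = np.zeros((n, d))
        prop_sd = np.full(d, 0.3)
        accept = np.zeros(d)
        tries = np.zeros(d)

        def subj_loglik(i, e):
            params = {
                p: float(np.exp(log_theta[j] + e[j])) for j, p in enumerate(PAR_NAMES)
            }
            try:
                f = subjects[i].predict(params, self.pk)
            except (RuntimeError, ValueError):
                return -1e12, None
            return (
                _gauss_loglik(
                    subjects[i].volumes, f, tuple(residual), self.error_model
                ),
                f,
            )

        cur_ll = np.empty(n)
        cur_f = [None] * n
        for i in range(n):
            cur_ll[i], cur_f[i] = subj_loglik(i, eta[i])

        s1 = np.zeros(d)  # SA of sum_i phi_i
        s2 = np.zeros(d)  # SA of sum_i phi_i^2
        s_resid = list(residual)

        total = k1 + k2
        for it in range(total):
            gamma = 1.0 if it < k1 else 1.0 / (it - k1 + 1)
            for sweep in range(self.mcmc_sweeps):
                for j in range(d):
                    prop = eta.copy()
                    prop[:, j] = eta[:, j] + rng.normal(0.0, prop_sd[j], size=n)
                    for i in range(n):
                        new_ll, new_f = subj_loglik(i, prop[i])
                        log_prior_ratio = (
                            -0.5 * (prop[i, j] ** 2 - eta[i, j] ** 2) / omega[j] ** 2
                        )
                        log_alpha = new_ll - cur_ll[i] + log_prior_ratio
                        tries[j] += 1
                        if np.log(rng.uniform()) < log_alpha:
                            eta[i, j] = prop[i, j]
                            cur_ll[i] = new_ll
                            cur_f[i] = new_f
                            accept[j] += 1
            # adapt proposals during exploration
            if it < k1 and (it + 1) % 10 == 0:
                rate = accept / np.maximum(tries, 1)
                prop_sd *= np.where(rate > 0.45, 1.4, np.where(rate < 0.15, 0.7, 1.0))
                prop_sd = np.clip(prop_sd, 0.01, 2.0)
                accept[:] = 0
                tries[:] = 0

            phi = log_theta[None, :] + eta  # per-subject log parameters
            s1 = s1 + gamma * (phi.sum(axis=0) - s1)
            s2 = s2 + gamma * ((phi**2).sum(axis=0) - s2)
            new_log_theta = s1 / n
            new_omega2 = np.maximum(s2 / n - new_log_theta**2, 1e-6)
            if it < k1:
                # simulated annealing: during exploration the omegas may
                # shrink only slowly, so the chain cannot collapse onto a
                # premature mode before it has mixed
                new_omega2 = np.maximum(new_omega2, (0.98 * omega) ** 2)
            # recenter etas so phi is preserved under the new typical values
            eta = phi - new_log_theta[None, :]
            log_theta = new_log_theta
            omega = np.sqrt(new_omega2)

            r = np.concatenate(
                [subjects[i].volumes - cur_f[i] for i in range(n)]
            )
            f_all = np.concatenate(cur_f)
            ab = _fit_residual(r, f_all, self.error_model, init=tuple(s_resid))
            s_resid = [
                s_resid[0] + gamma * (ab[0] - s_resid[0]),
                s_resid[1] + gamma * (ab[1] - s_resid[1]),
            ]
            residual = list(s_resid)
            # residual update changes the likelihood surface
            for i in range(n):
                cur_ll[i], cur_f[i] = subj_loglik(i, eta[i])

        theta = {p: float(np.exp(log_theta[j])) for j, p in enumerate(PAR_NAMES)}
        omega_d = {p: float(omega[j]) for j, p in enumerate(PAR_NAMES)}
        if not self._kill_identifiable:
            omega_d["kill"] = init.omega.get("kill", 0.0)
        model = PopulationModel(
            theta=theta,
            omega=omega_d,
            residual=(float(residual[0]), float(residual[1])),
            error_model=self.error_model,
        )
        # finalize the residual error at the conditional modes: residuals
        # against posterior draws carry the draws' own spread, which
        # inflates (a, b); re-estimating against the MAP predictions
        # gives the residual model the diagnostics (IWRES) assume
        free = _free_effects(model)
        map_resid, map_pred = [], []
        for subj in subjects:
            x = _map_eta(subj, self.pk, model)
            eta_map = dict(zip(free, x))
            params = {
                p: model.theta[p] * np.exp(eta_map.get(p, 0.0)) for p in PAR_NAMES
            }
            f = subj.predict(params, self.pk)
            map_resid.append(subj.volumes - f)
            map_pred.append(f)
        ab = _fit_residual(
            np.concatenate(map_resid),
            np.concatenate(map_pred),
            self.error_model,
            init=model.residual,
        )
        model = replace(model, residual=(float(ab[0]), float(ab[1])))
        # crude SEs: asymptotic lognormal-summary SE (omega/sqrt(n));
        # bootstrap is the supported route to interval estimates
        se = {f"{p}_pop": theta[p] * omega_d[p] / np.sqrt(n) for p in PAR_NAMES}
        diag = {"mode": "saem", "iterations": total, "proposal_sd": prop_sd.tolist()}
        return model, se, diag

    def predict(self, X: StudyDataset, kind: str = "individual") -> pd.DataFrame:
        """Predicted tumor volumes at the observation times.

        kind='population' uses typical values; 'individual' uses EBEs.
        """
        if not hasattr(self, "population_model_"):
            raise RuntimeError("estimator is not fitted")
        model = self.population_model_
        if kind == "individual":
            if not hasattr(self, "ebes_"):
                self.ebes_ = empirical_bayes(X, self.result_, pk=self.pk)
            par_table = self.ebes_.set_index("subject")
        rows = []
        for subj in _subjects_from(X):
            if kind == "population":
                params = dict(model.theta)
            elif kind == "individual":
                params = {n: par_table.loc[subj.subject, n] for n in PAR_NAMES}
            else:
                raise ValueError(f"unknown prediction kind {kind!r}")
            f = subj.predict(params, self.pk)
            rows.append(
                pd.DataFrame(
                    {
                        "subject": subj.subject,
                        "time_h": subj.times,
                        "pred": f,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def fit_population(
    data: StudyDataset,
    init: PopulationModel | None = None,
    pk: PKParameters | None = None,
    **config,
) -> FitResult:
    """Fit the population TGI model; thin wrapper over TGIPopulationEstimator."""
    est = TGIPopulationEstimator(pk=pk, init=init, **config)
    est.fit(data)
    est.result_.convergence["pk"] = pk
    return est.result_
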