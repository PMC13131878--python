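"""Structural tumor-growth models and forward ODE simulation.

The core model combines Simeoni-type unperturbed growth — exponential at
small tumor volume, linear above a switch volume TV* = lambda1/lambda0,
blended by a steep switching term with exponent psi = 20 — with a linear
plasma-concentration-driven kill term:

    dTV/dt = lambda0 * TV / [1 + ((lambda0/lambda1) * TV)^psi]^(1/psi)
             - k * Cp(t) * TV

TV is tumor volume (mm3), t is time (h), Cp(t) is the simulated plasma
concentration (ng/mL) and k the kill rate constant (mL/ng/h). Because
the vector field is proportional to TV, trajectories started at a
positive baseline stay positive; simulation is carried out on log TV,
which enforces this and removes stiffness from the steep bracket.

Alternative natural-growth structures used in structural-model screens
(exponential, quadratic-in-time, Koch) are provided alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .pk import PKParameters, Regimen

__all__ = [
    "TGIParameters",
    "Trajectory",
    "growth_rate",
    "natural_growth_rate",
    "simulate_trajectory",
    "time_to_threshold",
]

PSI_DEFAULT = 20.0


@dataclass(frozen=True)
class TGIParameters:
    """Parameters of the TGI model for one animal.

    Parameters
    ----------
    lambda0 : float
        Exponential growth rate (1/h).
    lambda1 : float
        Linear growth rate (mm3/h).
    kill : float
        Drug-induced cell-kill rate constant (mL/ng/h); 0 for untreated.
    tv0 : float
        Baseline tumor volume (mm3), a per-animal regressor.
    psi : float
        Switching exponent; fixed at 20 unless explicitly overridden.
    kc50 : float, optional
        If set, the drug effect is Michaelis-Menten in concentration,
        kill * Cp / (kc50 + Cp) * TV, instead of linear (kill * Cp * TV).
        Off by default: the saturable form is screened against the
        linear one during model building but tends to be unstable.
    """

    lambda0: float
    lambda1: float
    kill: float = 0.0
    tv0: float = 100.0
    psi: float = PSI_DEFAULT
    kc50: float | None = None

    def __post_init__(self) -> None:
        if not self.lambda0 > 0:
            raise ValueError("lambda0 must be > 0")
        if not self.lambda1 > 0:
            raise ValueError("lambda1 must be > 0")
        if self.kill < 0:
            raise ValueError("kill must be >= 0")
        if not self.tv0 > 0:
            raise ValueError("tv0 must be > 0")
        if not self.psi > 0:
            raise ValueError("psi must be > 0")
        if self.kc50 is not None and not self.kc50 > 0:
            raise ValueError("kc50 must be > 0 when set")

    @property
    def switch_volume(self) -> float:
        """Volume lambda1/lambda0 (mm3) where growth switches exponential -> linear."""
        return self.lambda1 / self.lambda0


@dataclass(frozen=True)
class Trajectory:
    """A simulated or observed tumor-volume time course."""

    times: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and volumes must be 1-D and aligned")
        if len(t) == 0:
            raise ValueError("empty trajectory")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "volumes", v)


def _specific_growth(tv, lambda0: float, lambda1: float, psi: float):
    """Per-volume growth rate lambda0 / (1 + ((l0/l1) TV)^psi)^(1/psi).

    Evaluated via logaddexp so the bracket never overflows for large TV.
    """
    tv = np.asarray(tv, dtype=float)
    logx = np.log(tv * (lambda0 / lambda1))
    log_bracket = np.logaddexp(0.0, psi * logx) / psi
    return lambda0 * np.exp(-log_bracket)


def growth_rate(tv, cp, p: TGIParameters):
    """Instantaneous dTV/dt (mm3/h) of the TGI model.

    Reduces to lambda0*TV well below the switch volume and to
    lambda1 - k*Cp*TV well above it.
    """
    tv = np.asarray(tv, dtype=float)
    if np.any(tv <= 0):
        raise ValueError("tv must be > 0")
    cp = np.asarray(cp, dtype=float)
    if p.kc50 is None:
        effect = p.kill * cp
    else:
        effect = p.kill * cp / (p.kc50 + cp)
    rate = _specific_growth(tv, p.lambda0, p.lambda1, p.psi) * tv - effect * tv
    return rate if rate.ndim else float(rate)


def natural_growth_rate(tv, t, params: Mapping[str, float], model: str):
    """Unperturbed dTV/dt (mm3/h) for a named natural-growth structure.

    Parameters
    ----------
    tv : float or array
        Tumor volume (mm3), > 0.
    t : float
        Time (h); used only by the quadratic (time-polynomial) model.
    params : mapping
        ``lambda0``/``lambda1`` as required by the model (``psi``
        optional for simeoni).
    model : {'exponential', 'quadratic', 'simeoni', 'koch'}
        * exponential: lambda0 * TV
        * quadratic:   lambda0 + 2*lambda1*t — TV quadratic in time,
          TV(t) = TV0 + lambda0*t + lambda1*t^2 (a documented choice of
          polynomial form; lambda0 in mm3/h, lambda1 in mm3/h^2)
        * simeoni:     the unperturbed part of :func:`growth_rate`
        * koch:        2*lambda0*lambda1*TV / (lambda1 + 2*lambda0*TV),
          exponential-like (rate 2*lambda0) at small TV, plateauing at
          lambda1 for large TV
    """
    tv = np.asarray(tv, dtype=float)
    if np.any(tv <= 0):
        raise ValueError("tv must be > 0")
    l0 = params["lambda0"]
    if model == "exponential":
        out = l0 * tv
    elif model == "quadratic":
        out = l0 + 2.0 * params["lambda1"] * np.asarray(t, dtype=float) * np.ones_like(tv)
    elif model == "simeoni":
        psi = params.get("psi", PSI_DEFAULT)
        out = _specific_growth(tv, l0, params["lambda1"], psi) * tv
    elif model == "koch":
        l1 = params["lambda1"]
        out = 2.0 * l0 * l1 * tv / (l1 + 2.0 * l0 * tv)
    else:
        raise ValueError(f"unknown growth model {model!r}")
    return out if np.ndim(tv) else float(out)


def simulate_trajectory(
    p: TGIParameters,
    pk: PKParameters | None,
    regimen: Regimen | None,
    times,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    backend: str = "numba",
) -> Trajectory:
    """Integrate the TGI ODE and return TV at the requested times.

    The state is u = log TV (positivity by construction). Dose times,
    where Cp jumps discontinuously, are mandatory step boundaries /
    solver restarts. ``pk`` and ``regimen`` may be None for untreated
    simulation.

    ``times`` must be increasing and start at t = 0 where TV = tv0.
    ``atol`` applies to log TV; the default tolerances change simulated
    volumes by < 0.1% when halved. ``backend`` selects the compiled
    RK45 stepper ('numba', default) or scipy's LSODA ('scipy'); the two
    agree to solver tolerance and serve as mutual checks.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if times[0] != 0.0:
        raise ValueError("times must start at 0 (TV(0) = tv0)")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    treated = (
        p.kill > 0
        and pk is not None
        and regimen is not None
        and not regimen.is_vehicle
    )
    l0, l1, psi, k = p.lambda0, p.lambda1, p.psi, p.kill
    if treated:
        c0 = regimen.dose_mg_per_kg * 1.0e6 / pk.volume_dist
        ke = pk.ke
        dose_times = np.asarray(regimen.dose_times, dtype=float)
    else:
        c0, ke = 0.0, 1.0
        dose_times = np.empty(0)
    kc50 = -1.0 if p.kc50 is None else p.kc50

    breakpoints = dose_times[(dose_times > 0) & (dose_times < times[-1])]
    knots = np.unique(np.concatenate([times, breakpoints]))

    if backend == "numba":
        from ._ode import integrate_log_tv

        u = integrate_log_tv(
            float(np.log(p.tv0)), knots, l0, l1, psi, k, kc50, c0, ke, dose_times, rtol, atol
        )
        if not np.all(np.isfinite(u)):
            raise RuntimeError(f"ODE integration failed with parameters {p}")
        out = np.exp(u[np.isin(knots, times)])
        return Trajectory(times=times, volumes=out)

    if backend != "scipy":
        raise ValueError(f"unknown backend {backend!r}")

    def rhs(t, u):
        if treated:
            dt = t - dose_times
            cp = c0 * np.sum(np.exp(-ke * dt[dt >= 0.0]))
        else:
            cp = 0.0
        effect = k * cp if p.kc50 is None else k * cp / (p.kc50 + cp)
        logx = psi * (u[0] + np.log(l0 / l1))
        return [l0 * np.exp(-np.logaddexp(0.0, logx) / psi) - effect]

    segments = np.unique(np.concatenate([[0.0], breakpoints, [times[-1]]]))
    u0 = np.log(p.tv0)
    out = np.empty_like(times)
    out[0] = p.tv0
    for a, b in zip(segments, segments[1:]):
        t_eval = times[(times > a) & (times <= b)]
        # always evaluate at the segment end so the next segment starts there
        t_eval_b = t_eval if len(t_eval) and t_eval[-1] == b else np.append(t_eval, b)
        sol = solve_ivp(
            rhs,
            (a, b),
            [u0],
            method="LSODA",
            t_eval=t_eval_b,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed on [{a}, {b}] with parameters {p}: {sol.message}"
            )
        if len(t_eval):
            out[np.isin(times, t_eval)] = np.exp(sol.y[0][: len(t_eval)])
        u0 = sol.y[0, -1]
    return Trajectory(times=times, volumes=out)


def time_to_threshold(
    traj: Trajectory,
    threshold: float,
    rule: str = "discrete",
) -> float | None:
    """Time at which a trajectory first reaches a volume threshold.

    rule='discrete' (default): the first grid/measurement time with
    TV >= threshold — how a caliper study observes the endpoint.
    rule='continuous': log-linear interpolation between the bracketing
    grid points, for sensitivity analysis.

    Returns None if the threshold is never reached.
    """
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    idx = np.nonzero(traj.volumes >= threshold)[0]
    if len(idx) == 0:
        return None
    i = int(idx[0])
    if rule == "discrete" or i == 0:
        return float(traj.times[i])
    if rule == "continuous":
        t0, t1 = traj.times[i - 1], traj.times[i]
        v0, v1 = traj.volumes[i - 1], traj.volumes[i]
        if v1 <= v0:
            return float(t1)
        frac = (np.log(threshold) - np.log(v0)) / (np.log(v1) - np.log(v0))
        return float(t0 + frac * (t1 - t0))
    raise ValueError(f"unknown detection rule {rule!r}")
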