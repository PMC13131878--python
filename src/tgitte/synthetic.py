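"""Synthetic xenograft study generator.

Generates complete studies with the statistical structure the analysis
assumes — Simeoni-type individual growth with log-normal between-animal
variability, combined residual error on caliper measurements, dosing per
regimen, event detection at a tumor-volume threshold and right-censoring
at the study horizon — and records every animal's generating parameters
so parameter-recovery analyses can compute bias without re-derivation.

The default design emulates the source study's conditions: 104 mice in
seven arms across three experiments (vehicle controls; 0.3, 0.6 and
0.9 mg/kg once daily x5; 2.40 mg/kg every 3 days x6 in two experiments;
2.85 mg/kg twice weekly x6), baseline volumes uniform on 37-251 mm3,
daily caliper measurements during the dosing period then twice weekly
(alternating 72/96 h gaps) to day 100, and an event threshold of
1,500 mm3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import StudyDataset
from .nlme import PAR_NAMES, PopulationModel, residual_sd
from .pk import PKParameters, Regimen, cavg, make_regimen
from .tgi import TGIParameters, simulate_trajectory
from .tte import CovariateSet, TTEParameters, simulate_events

__all__ = [
    "StudyDesign",
    "StudyDataset",
    "default_design",
    "default_population",
    "generate_study",
    "generate_events",
    "sampling_schedule",
]

# minimum recordable caliper volume; observation noise never drives a
# measurement to zero or below
VOLUME_FLOOR = 0.5


@dataclass(frozen=True)
class StudyDesign:
    """Arms, sampling schedule and event rule of a simulated study."""

    arms: tuple  # ((Regimen, n_mice), ...)
    baseline_range: tuple = (37.0, 251.0)
    daily_until_h: float | None = None  # None: each arm's last dose (vehicle: 96 h)
    twice_weekly_gaps: tuple = (72.0, 96.0)
    horizon_h: float = 2400.0
    event_threshold: float = 1500.0

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("design needs at least one arm")
        for reg, n in self.arms:
            if n < 1:
                raise ValueError(f"arm {reg.name!r} needs n >= 1")
            if reg.dose_times and self.horizon_h <= max(reg.dose_times):
                raise ValueError(f"horizon must exceed the last dose of {reg.name!r}")
        if not self.event_threshold > self.baseline_range[1]:
            raise ValueError("event threshold must exceed the largest baseline")

    @property
    def n_mice(self) -> int:
        return sum(n for _, n in self.arms)


def default_design() -> StudyDesign:
    """The emulated study: 7 arms / 104 mice across three experiments."""
    arms = (
        (make_regimen("vehicle", 0.0, ()), 20),
        (make_regimen("0.3 Q1dx5", 0.3, "Q1dx5"), 14),
        (make_regimen("0.6 Q1dx5", 0.6, "Q1dx5"), 14),
        (make_regimen("0.9 Q1dx5", 0.9, "Q1dx5"), 14),
        (make_regimen("2.40 Q3dx6", 2.40, "Q3dx6"), 14),
        (make_regimen("2.40 Q3dx6 e3", 2.40, "Q3dx6"), 14),
        (make_regimen("2.85 BIWx6", 2.85, "BIWx6"), 14),
    )
    return StudyDesign(arms=arms)


def default_population() -> PopulationModel:
    """Generating truth: the final published population TGI estimates."""
    return PopulationModel(
        theta={"lambda0": 0.0063, "lambda1": 5.93, "kill": 0.000024},
        omega={"lambda0": 0.85, "lambda1": 0.73, "kill": 0.87},
        residual=(11.22, 0.22),
        error_model="combined",
    )


def sampling_schedule(design: StudyDesign, regimen: Regimen) -> np.ndarray:
    """Measurement times (h) for one arm: daily while dosing, then twice weekly."""
    if design.daily_until_h is not None:
        daily_end = design.daily_until_h
    elif regimen.dose_times:
        daily_end = max(regimen.dose_times)
    else:
        daily_end = 96.0  # vehicle arms follow the experiment-1 dosing window
    times = list(np.arange(0.0, daily_end + 24.0, 24.0))
    gaps = design.twice_weekly_gaps
    i = 0
    t = times[-1]
    while t + gaps[i % len(gaps)] <= design.horizon_h:
        t += gaps[i % len(gaps)]
        times.append(t)
        i += 1
    return np.asarray(times)


def generate_study(
    design: StudyDesign,
    pop: PopulationModel,
    pk: PKParameters,
    seed=None,
    rng: np.random.Generator | None = None,
) -> StudyDataset:
    """Simulate a complete study under the population TGI model.

    Per animal: a uniform baseline volume, log-normal individual
    parameters, a noise-free trajectory at the arm's schedule, combined
    residual noise on each measurement, truncation at the first
    measurement at or above the event threshold (status 1) or censoring
    at the last scheduled measurement (status 0).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    obs_rows, dose_rows, event_rows, truth_rows = [], [], [], []
    regimens = {}
    subj_counter = 0
    for regimen, n_mice in design.arms:
        regimens[regimen.name] = regimen
        schedule = sampling_schedule(design, regimen)
        for _ in range(n_mice):
            subj_counter += 1
            sid = f"M{subj_counter:03d}"
            tv0 = rng.uniform(*design.baseline_range)
            eta = {p: rng.normal(0.0, pop.omega.get(p, 0.0)) for p in PAR_NAMES}
            params = {p: pop.theta[p] * np.exp(eta[p]) for p in PAR_NAMES}
            tgi = TGIParameters(
                lambda0=params["lambda0"],
                lambda1=params["lambda1"],
                kill=params["kill"] if not regimen.is_vehicle else 0.0,
                tv0=tv0,
            )
            traj = simulate_trajectory(tgi, pk, regimen, schedule)
            sd = residual_sd(traj.volumes, pop.residual, pop.error_model)
            y = traj.volumes + sd * rng.standard_normal(len(schedule))
            y = np.maximum(y, VOLUME_FLOOR)

            crossed = np.nonzero(y >= design.event_threshold)[0]
            if len(crossed):
                last = int(crossed[0])
                status, event_time = 1, float(schedule[last])
            else:
                last = len(schedule) - 1
                status, event_time = 0, float(schedule[last])

            keep = slice(0, last + 1)
            obs_rows.append(
                pd.DataFrame(
                    {
                        "subject": sid,
                        "arm": regimen.name,
                        "time_h": schedule[keep],
                        "tv_mm3": y[keep],
                    }
                )
            )
            for td in regimen.dose_times:
                if td <= event_time:
                    dose_rows.append(
                        {
                            "subject": sid,
                            "time_h": td,
                            "amount_mg_per_kg": regimen.dose_mg_per_kg,
                        }
                    )
            event_rows.append(
                {"subject": sid, "time_h": event_time, "status": status}
            )
            truth_rows.append(
                {
                    "subject": sid,
                    "arm": regimen.name,
                    "tv0_true": tv0,
                    "tv0_obs": float(y[0]),
                    **params,
                    **{f"eta_{p}": eta[p] for p in PAR_NAMES},
                }
            )
    return StudyDataset(
        observations=pd.concat(obs_rows, ignore_index=True),
        doses=pd.DataFrame(
            dose_rows, columns=["subject", "time_h", "amount_mg_per_kg"]
        ),
        events=pd.DataFrame(event_rows),
        regimens=regimens,
        truth=pd.DataFrame(truth_rows),
    )


def default_covariate_distribution(
    pop: PopulationModel | None = None,
    pk: PKParameters | None = None,
    design: StudyDesign | None = None,
) -> dict:
    """Covariate-generating distribution for TTE-only simulations.

    Growth rates are log-normal at the population TGI typical values and
    omegas; Cavg takes the regimen-level values of the study design
    (computed by NCA from the PK configuration), with arm-size weights.
    """
    from .pk import default_pk_parameters

    pop = pop or default_population()
    pk = pk or default_pk_parameters()
    design = design or default_design()
    cavg_arms = [
        (cavg(pk, regimen) if not regimen.is_vehicle else 0.0, n)
        for regimen, n in design.arms
    ]
    return {
        "lambda0": (pop.theta["lambda0"], pop.omega["lambda0"]),
        "lambda1": (pop.theta["lambda1"], pop.omega["lambda1"]),
        "cavg": cavg_arms,
    }


def generate_events(
    p: TTEParameters,
    cov_distribution: dict | None = None,
    n: int = 104,
    censor_time: float = 2400.0,
    seed=None,
):
    """Simulate TTE-only data: covariates plus event/censoring records.

    Growth-rate covariates are drawn log-normally, Cavg is assigned at
    the regimen level with counts proportional to the arm weights, and
    event times follow the covariate TTE model via its inverse CDF.

    Returns ``(events, covariates)`` where ``events`` is a DataFrame of
    subject/time/status and ``covariates`` a :class:`CovariateSet`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    dist = cov_distribution or default_covariate_distribution()
    t0, w0 = dist["lambda0"]
    t1, w1 = dist["lambda1"]
    values = np.array([v for v, _ in dist["cavg"]], dtype=float)
    weights = np.array([w for _, w in dist["cavg"]], dtype=float)
    # deterministic largest-remainder split of n across arms
    exact = n * weights / weights.sum()
    counts = np.floor(exact).astype(int)
    for i in np.argsort(-(exact - counts)):
        if counts.sum() >= n:
            break
        counts[i] += 1
    cavg_i = np.repeat(values, counts)

    subjects = [f"S{i + 1:03d}" for i in range(n)]
    table = pd.DataFrame(
        {
            "subject": subjects,
            "lambda0": t0 * np.exp(rng.normal(0.0, w0, size=n)),
            "lambda1": t1 * np.exp(rng.normal(0.0, w1, size=n)),
            "cavg": cavg_i,
        }
    )
    covset = CovariateSet(data=table)
    events = simulate_events(p, covset, censor_time=censor_time, rng=rng)
    return events, covset
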