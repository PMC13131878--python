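"""Dataset readers/writers and pipeline configuration.

The on-disk study format is a Monolix/NONMEM-style long CSV with
columns ``ID, TIME, DV, AMT, EVID, ARM, TV0``: observation rows carry
``EVID=0`` with the tumor volume in ``DV`` and ``AMT='.'``; dose rows
carry ``EVID=1`` with the dose (mg/kg) in ``AMT`` and ``DV='.'``.
Event/censoring records and TTE covariates use plain tidy CSVs.
Validation is strict and reports every offending line, not just the
first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import StudyDataset
from .pk import PKParameters, Regimen, make_regimen

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_events",
    "read_events",
    "PipelineConfig",
    "load_config",
]

_MISSING = "."


def write_dataset(data: StudyDataset, path) -> Path:
    """Write a study as a Monolix-dialect CSV; returns the path."""
    path = Path(path)
    tv0 = data.baseline_tv()
    rows = []
    for _, r in data.observations.iterrows():
        rows.append(
            {
                "ID": r["subject"],
                "TIME": r["time_h"],
                "DV": r["tv_mm3"],
                "AMT": _MISSING,
                "EVID": 0,
                "ARM": r["arm"],
                "TV0": tv0[r["subject"]],
            }
        )
    arm_of = data.arm_of()
    for _, r in data.doses.iterrows():
        rows.append(
            {
                "ID": r["subject"],
                "TIME": r["time_h"],
                "DV": _MISSING,
                "AMT": r["amount_mg_per_kg"],
                "EVID": 1,
                "ARM": arm_of[r["subject"]],
                "TV0": tv0[r["subject"]],
            }
        )
    frame = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"], kind="stable")
    frame.to_csv(path, index=False)
    return path


def read_dataset(path, dialect: str = "monolix") -> StudyDataset:
    """Read a study CSV, validating every row; raises with line numbers.

    Regimens are reconstructed per arm from that arm's dose rows
    (amount and times are assumed shared within an arm, as in a designed
    study).
    """
    if dialect != "monolix":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    raw = pd.read_csv(path, dtype=str).fillna(_MISSING)
    required = ["ID", "TIME", "DV", "AMT", "EVID", "ARM"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    errors = []
    obs_rows, dose_rows = [], []
    for i, r in raw.iterrows():
        line = i + 2  # header is line 1
        try:
            t = float(r["TIME"])
        except ValueError:
            errors.append(f"line {line}: TIME {r['TIME']!r} is not numeric")
            continue
        if t < 0:
            errors.append(f"line {line}: negative TIME {t}")
        evid = str(r["EVID"]).strip()
        if evid == "0":
            if r["DV"] == _MISSING:
                errors.append(f"line {line}: observation row (EVID=0) without DV")
                continue
            if r["AMT"] != _MISSING:
                errors.append(f"line {line}: EVID=0 row must not carry AMT")
            try:
                dv = float(r["DV"])
            except ValueError:
                errors.append(f"line {line}: DV {r['DV']!r} is not numeric")
                continue
            if dv <= 0:
                errors.append(f"line {line}: non-positive tumor volume {dv}")
                continue
            obs_rows.append(
                {"subject": r["ID"], "arm": r["ARM"], "time_h": t, "tv_mm3": dv}
            )
        elif evid == "1":
            if r["DV"] != _MISSING:
                errors.append(f"line {line}: dose row (EVID=1) must not carry DV")
            try:
                amt = float(r["AMT"])
            except ValueError:
                errors.append(f"line {line}: AMT {r['AMT']!r} is not numeric")
                continue
            if amt < 0:
                errors.append(f"line {line}: negative dose {amt}")
                continue
            dose_rows.append(
                {"subject": r["ID"], "arm": r["ARM"], "time_h": t, "amount_mg_per_kg": amt}
            )
        else:
            errors.append(f"line {line}: EVID must be 0 or 1, got {evid!r}")

    obs = pd.DataFrame(obs_rows)
    if len(obs):
        for subject, group in obs.groupby("subject"):
            t = group["time_h"].to_numpy()
            if len(np.unique(t)) != len(t):
                errors.append(f"subject {subject}: duplicate observation times")
    if errors:
        raise ValueError(
            f"{path}: {len(errors)} validation error(s):\n" + "\n".join(errors)
        )
    if not len(obs):
        raise ValueError(f"{path}: no observation rows")

    doses = pd.DataFrame(dose_rows, columns=["subject", "arm", "time_h", "amount_mg_per_kg"])
    regimens = {}
    for arm in obs["arm"].unique():
        arm_doses = doses[doses["arm"] == arm]
        if len(arm_doses) == 0:
            regimens[arm] = Regimen(name=arm, dose_mg_per_kg=0.0, dose_times=())
        else:
            first = arm_doses[arm_doses["subject"] == arm_doses["subject"].iloc[0]]
            regimens[arm] = Regimen(
                name=arm,
                dose_mg_per_kg=float(first["amount_mg_per_kg"].iloc[0]),
                dose_times=tuple(sorted(first["time_h"])),
            )
    return StudyDataset(
        observations=obs,
        doses=doses.drop(columns=["arm"]),
        events=_events_from_obs(obs),
        regimens=regimens,
    )


def _events_from_obs(obs: pd.DataFrame, threshold: float = 1500.0) -> pd.DataFrame:
    """Event table implied by the observations and the volume threshold."""
    rows = []
    for subject, group in obs.groupby("subject"):
        group = group.sort_values("time_h")
        hit = group[group["tv_mm3"] >= threshold]
        if len(hit):
            rows.append(
                {"subject": subject, "time_h": float(hit["time_h"].iloc[0]), "status": 1}
            )
        else:
            rows.append(
                {"subject": subject, "time_h": float(group["time_h"].iloc[-1]), "status": 0}
            )
    return pd.DataFrame(rows)


def write_events(events: pd.DataFrame, path, covariates: pd.DataFrame | None = None) -> Path:
    """Write event records (and optional per-subject covariates) as CSV."""
    path = Path(path)
    df = events.rename(columns={"time": "time_h"}).copy()
    if covariates is not None:
        df = df.merge(covariates, on="subject", how="left")
    df.to_csv(path, index=False)
    return path


def read_events(path) -> pd.DataFrame:
    """Read an events CSV (subject, time_h, status, + covariate columns)."""
    df = pd.read_csv(path)
    errors = []
    for col in ("subject", "time_h", "status"):
        if col not in df.columns:
            errors.append(f"missing column {col!r}")
    if not errors:
        bad_t = df.index[df["time_h"] <= 0]
        errors += [f"line {i + 2}: non-positive time" for i in bad_t]
        bad_s = df.index[~df["status"].isin([0, 1])]
        errors += [f"line {i + 2}: status must be 0/1" for i in bad_s]
        dup = df.index[df["subject"].duplicated()]
        errors += [f"line {i + 2}: duplicate subject" for i in dup]
    if errors:
        raise ValueError(f"{path}: {len(errors)} validation error(s):\n" + "\n".join(errors))
    return df


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Validated configuration of the end-to-end pipeline."""

    outdir: Path
    seed: int
    arms: list  # [{name, dose, schedule (preset or times), n}, ...]
    pk: dict  # {clearance, volume_dist}
    truth: dict | None = None  # simulation truth: {theta, omega, residual}
    estimation: dict = field(default_factory=dict)  # {mode, loglik_method, ...}
    tte: dict = field(default_factory=dict)  # {family, shape, frailty}
    evaluation: dict = field(default_factory=dict)  # {n_sim, n_boot}
    design: dict = field(default_factory=dict)  # {horizon_h, event_threshold, ...}
    stages: list = field(default_factory=lambda: ["simulate", "fit-tgi", "fit-tte", "vpc", "report"])
    dataset_path: Path | None = None

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.seed is None:
            raise ValueError("config must set a seed (all stochastic stages require it)")
        self.seed = int(self.seed)
        if self.dataset_path is not None:
            self.dataset_path = Path(self.dataset_path)
            if not self.dataset_path.exists():
                raise ValueError(f"dataset not found: {self.dataset_path}")
        if not self.arms and "simulate" in self.stages:
            raise ValueError("simulate stage requires arms")
        for key in ("clearance", "volume_dist"):
            if key not in self.pk:
                raise ValueError(f"pk config missing {key!r}")

    def pk_parameters(self) -> PKParameters:
        return PKParameters(
            clearance=float(self.pk["clearance"]),
            volume_dist=float(self.pk["volume_dist"]),
        )

    def regimen_arms(self) -> list:
        out = []
        for spec in self.arms:
            reg = make_regimen(
                spec["name"], float(spec.get("dose", 0.0)), spec.get("schedule", ())
            )
            out.append((reg, int(spec.get("n", 1))))
        return out


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    missing = [k for k in ("outdir", "seed", "pk") if k not in raw]
    if missing:
        raise ValueError(f"{path}: missing required keys {missing}")
    raw.setdefault("arms", [])
    return PipelineConfig(**raw)
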