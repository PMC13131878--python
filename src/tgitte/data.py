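"""Study-dataset container shared by the estimation and I/O layers."""

from __future__ import annotations

from dataclasses import dataclass, field


import pandas as pd

from .pk import Regimen

__all__ = ["StudyDataset"]


@dataclass
class StudyDataset:
    """A long-format xenograft study: observations, doses and events.

    Attributes
    ----------
    observations : pandas.DataFrame
        Columns ``subject``, ``arm``, ``time_h``, ``tv_mm3``; one row per
        caliper measurement. Every subject has a baseline row at t = 0.
    doses : pandas.DataFrame
        Columns ``subject``, ``time_h``, ``amount_mg_per_kg``; empty for
        all-vehicle studies.
    events : pandas.DataFrame
        Columns ``subject``, ``time_h``, ``status`` (1 = tumor reached
        the volume threshold, 0 = censored at last observation).
    regimens : dict
        Arm label -> :class:`~tgitte.pk.Regimen`.
    truth : pandas.DataFrame or None
        For synthetic studies: per-subject generating parameters
        (lambda0, lambda1, kill, tv0_true, ...) for oracle use. None for
        real data.
    """

    observations: pd.DataFrame
    doses: pd.DataFrame
    events: pd.DataFrame
    regimens: dict = field(default_factory=dict)
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        obs = self.observations
        for col in ("subject", "arm", "time_h", "tv_mm3"):
            if col not in obs.columns:
                raise ValueError(f"observations missing column {col!r}")
        if len(obs) == 0:
            raise ValueError("no observations")
        if (obs["tv_mm3"] <= 0).any():
            bad = obs.index[obs["tv_mm3"] <= 0][:5].tolist()
            raise ValueError(f"non-positive tumor volumes at rows {bad}")
        if (obs["time_h"] < 0).any():
            raise ValueError("negative observation times")
        arms = set(obs["arm"].unique())
        missing = arms - set(self.regimens)
        if missing:
            raise ValueError(f"no regimen defined for arms: {sorted(missing)}")

    @property
    def subjects(self) -> list:
        return list(self.observations["subject"].unique())

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return len(self.observations)

    def arm_of(self) -> pd.Series:
        """subject -> arm label."""
        return self.observations.groupby("subject", sort=False)["arm"].first()

    def baseline_tv(self) -> pd.Series:
        """subject -> observed baseline volume (first observation)."""
        obs = self.observations.sort_values(["subject", "time_h"], kind="stable")
        return obs.groupby("subject", sort=False)["tv_mm3"].first()

    def subject_observations(self, subject) -> pd.DataFrame:
        rows = self.observations[self.observations["subject"] == subject]
        return rows.sort_values("time_h")

    def subset(self, subjects, relabel=None) -> "StudyDataset":
        """Dataset restricted to ``subjects`` (with optional new labels).

        ``relabel`` maps old subject ids to new ones, allowing bootstrap
        resamples in which one animal appears multiple times.
        """
        frames = {}
        for name in ("observations", "doses", "events"):
            df = getattr(self, name)
            parts = []
            for new_i, s in enumerate(subjects):
                part = df[df["subject"] == s].copy()
                if relabel is not None:
                    part["subject"] = relabel[new_i]
                parts.append(part)
            frames[name] = (
                pd.concat(parts, ignore_index=True) if parts else df.iloc[0:0].copy()
            )
        truth = None
        if self.truth is not None:
            parts = []
            for new_i, s in enumerate(subjects):
                part = self.truth[self.truth["subject"] == s].copy()
                if relabel is not None:
                    part["subject"] = relabel[new_i]
                parts.append(part)
            truth = pd.concat(parts, ignore_index=True) if parts else None
        return StudyDataset(
            observations=frames["observations"],
            doses=frames["doses"],
            events=frames["events"],
            regimens=dict(self.regimens),
            truth=truth,
        )
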