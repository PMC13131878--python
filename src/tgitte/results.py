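"""Shared fit-result container for the TGI and TTE estimation stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import pandas as pd

__all__ = ["FitResult", "compare_models"]


@dataclass
class FitResult:
    """Maximum-likelihood fit summary.

    Attributes
    ----------
    estimates : dict
        Parameter point estimates by name.
    se : dict
        Standard errors by name (may be missing for fixed parameters).
    minus2ll : float
        -2 log-likelihood at the estimates.
    n_params : int
        Number of estimated parameters (AIC = minus2ll + 2 * n_params).
    n_obs : int
        Number of observations (subjects or measurements) fitted; used to
        guard model comparisons against mismatched datasets.
    ebes : pandas.DataFrame or None
        Per-subject empirical-Bayes parameter estimates, if applicable.
    shrinkage : dict or None
        Eta-shrinkage (%) per random-effect parameter, if applicable.
    convergence : dict
        Optimizer diagnostics (success flag, message, iterations, ...).
    model : Any
        The fitted model object (population model, estimator, ...).
    """

    estimates: dict
    se: dict
    minus2ll: float
    n_params: int
    n_obs: int = 0
    ebes: pd.DataFrame | None = None
    shrinkage: dict | None = None
    convergence: dict = field(default_factory=dict)
    model: Any = None

    @property
    def aic(self) -> float:
        return self.minus2ll + 2.0 * self.n_params

    @property
    def rse(self) -> dict:
        """Relative standard errors, 100 * SE / |estimate|, per parameter."""
        out = {}
        for name, s in self.se.items():
            est = self.estimates.get(name)
            if est:
                out[name] = 100.0 * s / abs(est)
        return out

    def summary(self) -> pd.DataFrame:
        rse = self.rse
        rows = []
        for name, est in self.estimates.items():
            rows.append(
                {
                    "parameter": name,
                    "estimate": est,
                    "se": self.se.get(name, float("nan")),
                    "rse_pct": rse.get(name, float("nan")),
                }
            )
        return pd.DataFrame(rows)


def compare_models(fits: list) -> pd.DataFrame:
    """Rank fits of the same dataset by AIC (ascending), with a dAIC column.

    Raises if the fits do not share the same number of observations —
    AIC comparisons across different datasets are meaningless.
    """
    if not fits:
        raise ValueError("no fits to compare")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) > 1:
        raise ValueError(f"fits are on different datasets (n_obs = {sorted(n_obs)})")
    rows = []
    for f in fits:
        label = getattr(f.model, "label", None) or getattr(
            f.model, "family", type(f.model).__name__ if f.model is not None else "model"
        )
        rows.append(
            {"model": label, "n_params": f.n_params, "minus2ll": f.minus2ll, "aic": f.aic}
        )
    table = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    table["dAIC"] = table["aic"] - table["aic"].iloc[0]
    return table
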