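"""Probability of chilling-requirement fulfillment under climate scenarios.

For each cultivar and scenario ensemble, the chilling requirement (CR, in
Chilling Portions) is drawn repeatedly within "mean CR ± sd" to propagate
the uncertainty of the requirement estimate; each draw's fulfillment
probability is the share of replicate seasons whose chill availability
meets the drawn requirement, and the reported probability is the median
(with quantiles) across draws.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .scenarios import ScenarioEnsemble

__all__ = ["FulfillmentResult", "fulfillment_probability", "risk_matrix", "plot_risk_heatmap"]

LOW_RISK_PROBABILITY = 0.80  # reporting band: >= 80 % median probability


@dataclasses.dataclass
class FulfillmentResult:
    """Median fulfillment probability across requirement draws."""

    median_probability: float
    q05: float
    q95: float
    n_draws: int
    seed: int | None = None
    cultivar: str | None = None
    scenario_id: str | None = None

    def __post_init__(self) -> None:
        for name in ("median_probability", "q05", "q95"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.q05 <= self.median_probability <= self.q95:
            raise ValueError("median must lie between the stored quantiles")

    @property
    def low_risk(self) -> bool:
        return self.median_probability >= LOW_RISK_PROBABILITY


def _cp_totals(ensemble) -> np.ndarray:
    if isinstance(ensemble, ScenarioEnsemble):
        return ensemble.cp_totals
    arr = np.asarray(ensemble, dtype=float)
    if arr.ndim != 1 or len(arr) == 0:
        raise ValueError("ensemble must be non-empty 1-D CP totals")
    return arr


def fulfillment_probability(
    cr_mean: float,
    cr_sd: float,
    ensemble,
    n_draws: int = 1000,
    seed: int | None = 0,
    distribution: str = "uniform",
    cultivar: str | None = None,
) -> FulfillmentResult:
    """Median probability that the chilling requirement is fulfilled.

    ``n_draws`` requirement values are sampled within
    [``cr_mean − cr_sd``, ``cr_mean + cr_sd``] (uniform by default;
    ``distribution="truncnorm"`` uses a normal truncated at ±1 sd).  For
    each draw the probability is the fraction of replicate seasons whose
    CP total is at least the drawn requirement (the boundary counts as
    fulfilled).  With ``cr_sd == 0`` the result is the exact empirical
    exceedance fraction, with no Monte-Carlo error.
    """
    if cr_sd < 0:
        raise ValueError("cr_sd must be nonnegative")
    totals = np.sort(_cp_totals(ensemble))
    n_seasons = len(totals)
    scenario_id = (
        ensemble.scenario.scenario_id
        if isinstance(ensemble, ScenarioEnsemble) and ensemble.scenario is not None
        else None
    )
    if cr_sd == 0.0:
        p = _exceedance(totals, np.array([cr_mean]))[0]
        return FulfillmentResult(
            median_probability=p,
            q05=p,
            q95=p,
            n_draws=n_draws,
            seed=seed,
            cultivar=cultivar,
            scenario_id=scenario_id,
        )
    rng = np.random.default_rng(seed)
    if distribution == "uniform":
        # stratified uniform draws: one value per 1/n_draws stratum of the
        # interval; same marginal distribution, far lower Monte-Carlo error
        # in the median
        u = (np.arange(n_draws) + rng.uniform(0.0, 1.0, n_draws)) / n_draws
        draws = cr_mean - cr_sd + 2.0 * cr_sd * u
    elif distribution == "truncnorm":
        draws = rng.normal(cr_mean, cr_sd, size=4 * n_draws)
        draws = draws[np.abs(draws - cr_mean) <= cr_sd][:n_draws]
        while len(draws) < n_draws:  # pragma: no cover - pathological rng streaks
            extra = rng.normal(cr_mean, cr_sd, size=4 * n_draws)
            draws = np.concatenate([draws, extra[np.abs(extra - cr_mean) <= cr_sd]])[:n_draws]
    else:
        raise ValueError(f"unknown draw distribution {distribution!r}")
    probs = _exceedance(totals, draws)
    return FulfillmentResult(
        median_probability=float(np.median(probs)),
        q05=float(np.quantile(probs, 0.05)),
        q95=float(np.quantile(probs, 0.95)),
        n_draws=n_draws,
        seed=seed,
        cultivar=cultivar,
        scenario_id=scenario_id,
    )


def _exceedance(sorted_totals: np.ndarray, requirements: np.ndarray) -> np.ndarray:
    """Fraction of seasons with CP >= requirement (inclusive boundary)."""
    n = len(sorted_totals)
    below = np.searchsorted(sorted_totals, requirements, side="left")
    return (n - below) / n


def risk_matrix(
    requirements: pd.DataFrame,
    ensembles: Sequence[ScenarioEnsemble],
    n_draws: int = 1000,
    seed: int = 0,
    distribution: str = "uniform",
) -> pd.DataFrame:
    """Fulfillment probabilities for every cultivar × scenario.

    ``requirements`` needs columns ``cultivar``, ``cp_mean`` and ``cp_sd``
    (one row per cultivar; a missing ``cp_mean`` skips the cultivar with a
    warning, and a missing sd is treated as 0).  Rows are ordered by CR
    mean, matching the heatmap layout used for reporting.
    """
    rows = []
    reqs = requirements.sort_values("cp_mean").reset_index(drop=True)
    for i, req in reqs.iterrows():
        if pd.isna(req["cp_mean"]):
            warnings.warn(
                f"cultivar {req['cultivar']!r} has no CP requirement; skipped",
                stacklevel=2,
            )
            continue
        sd = 0.0 if pd.isna(req.get("cp_sd", 0.0)) else float(req["cp_sd"])
        for ens in ensembles:
            result = fulfillment_probability(
                float(req["cp_mean"]),
                sd,
                ens,
                # common random numbers across cultivars keep the matrix
                # monotone in the requirement mean
                n_draws=n_draws,
                seed=seed,
                distribution=distribution,
                cultivar=str(req["cultivar"]),
            )
            scenario = ens.scenario
            rows.append(
                {
                    "cultivar": result.cultivar,
                    "cp_mean": float(req["cp_mean"]),
                    "scenario_id": result.scenario_id,
                    "scenario_kind": scenario.kind if scenario else None,
                    "gcm": scenario.gcm if scenario else None,
                    "rcp": scenario.rcp if scenario else None,
                    "horizon": scenario.horizon if scenario else None,
                    "reference_year": scenario.reference_year if scenario else None,
                    "median_probability": result.median_probability,
                    "q05": result.q05,
                    "q95": result.q95,
                }
            )
    return pd.DataFrame(rows)


def plot_risk_heatmap(matrix: pd.DataFrame, ax=None, title: str | None = None):
    """Cultivar × scenario heatmap of median fulfillment probabilities."""
    import matplotlib.pyplot as plt

    pivot = matrix.pivot_table(
        index="cultivar", columns="scenario_id", values="median_probability", sort=False
    )
    if ax is None:
        _, ax = plt.subplots(
            figsize=(1.0 + 0.45 * pivot.shape[1], 1.0 + 0.3 * pivot.shape[0])
        )
    im = ax.imshow(pivot.to_numpy(), vmin=0.0, vmax=1.0, cmap="RdYlGn", aspect="auto")
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(pivot.shape[0]), pivot.index, fontsize=7)
    ax.figure.colorbar(im, ax=ax, label="median P(CR fulfilled)")
    if title:
        ax.set_title(title)
    return ax
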