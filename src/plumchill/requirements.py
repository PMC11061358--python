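"""Endodormancy release, bloom dates, and agroclimatic requirements.

This module turns forcing-experiment bud weights and flowering phenology
into cultivar-specific chilling requirements (CR, in CH/CU/CP) and heating
requirements (HR, in GDH), classifies cultivars into low/medium/high
classes, and provides the nonparametric summary statistics used to compare
cultivars (Kruskal–Wallis, coefficient of variation, Spearman correlation
network).

Operational definitions
-----------------------
* Endodormancy release (ER): the first weekly sampling date at which the
  mean weight of the ~10 forced flower buds increased by at least 30 %
  between day 0 and day 8 in the forcing chamber.  Means of the weighed
  buds are compared, not per-bud majorities.
* Full bloom (F50): the first date with at least 50 % of flowers open.
* CR: chill accumulated from October 1st to ER.
* HR: GDH accumulated from the day after ER through F50 (inclusive).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import thermal
from .thermal import HourlyTempSeries

__all__ = [
    "ForcingExperiment",
    "CultivarRequirements",
    "CorrelationNetwork",
    "KruskalResult",
    "detect_endodormancy_release",
    "detect_f50",
    "chilling_requirement",
    "heating_requirement",
    "classify_cr",
    "classify_hr",
    "summarize_requirements",
    "correlation_network",
    "kruskal_wallis",
    "season_start_date",
    "days_since_season_start",
    "estimate_requirements",
    "summarize_cultivars",
]

RELEASE_THRESHOLD = 0.30
F50_THRESHOLD = 0.5

# class bounds: (upper bound of "low", lower bound of "high")
CR_CLASS_BOUNDS = {"CP": (30.0, 41.0), "CH": (300.0, 501.0), "CU": (500.0, 701.0)}
HR_CLASS_BOUNDS = (6500.0, 7000.0)  # <= low; > high


class ForcingExperiment:
    """Bud-weight records of one forcing experiment.

    Wraps a table with columns ``cultivar``, ``location``, ``season``,
    ``sampling_date``, ``bud_id``, ``weight_day0_g``, ``weight_day8_g``
    (one row per weighed bud; the day-8 weight is paired with the same
    bud's day-0 weight).
    """

    REQUIRED = (
        "cultivar",
        "location",
        "season",
        "sampling_date",
        "bud_id",
        "weight_day0_g",
        "weight_day8_g",
    )

    def __init__(self, data: pd.DataFrame) -> None:
        missing = set(self.REQUIRED) - set(data.columns)
        if missing:
            raise ValueError(f"forcing table missing columns: {sorted(missing)}")
        if len(data) == 0:
            raise ValueError("forcing table is empty")
        if data[["weight_day0_g", "weight_day8_g"]].isna().any().any():
            raise ValueError("unpaired samples: missing day-0 or day-8 weights")
        if (data[["weight_day0_g", "weight_day8_g"]] <= 0).any().any():
            raise ValueError("bud weights must be positive")
        data = data.copy()
        data["sampling_date"] = pd.to_datetime(data["sampling_date"])
        self.data = data.sort_values(["sampling_date", "bud_id"]).reset_index(drop=True)

    def weekly_means(self) -> pd.DataFrame:
        """Mean day-0/day-8 weights per sampling date, with the weight ratio."""
        g = self.data.groupby("sampling_date")[["weight_day0_g", "weight_day8_g"]].mean()
        g["ratio"] = g["weight_day8_g"] / g["weight_day0_g"]
        return g


def detect_endodormancy_release(
    experiment: ForcingExperiment | pd.DataFrame,
    threshold: float = RELEASE_THRESHOLD,
) -> _dt.date | None:
    """First sampling date whose mean bud weight gained ≥ ``threshold``.

    Returns ``None`` if the weight gain never reaches the threshold.
    """
    if isinstance(experiment, pd.DataFrame):
        experiment = ForcingExperiment(experiment)
    means = experiment.weekly_means()
    hit = means.index[means["ratio"] >= 1.0 + threshold]
    return None if len(hit) == 0 else hit[0].date()


def detect_f50(phenology: pd.DataFrame, threshold: float = F50_THRESHOLD) -> _dt.date | None:
    """First date with at least 50 % of flowers open, or ``None`` (no bloom).

    ``phenology`` is the record of one cultivar-season with columns
    ``date`` and ``fraction_open`` (fractions in [0, 1]).
    """
    frac = phenology["fraction_open"].to_numpy(dtype=float)
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("fraction_open values must lie in [0, 1]")
    dates = pd.to_datetime(phenology["date"])
    order = np.argsort(dates.to_numpy())
    for i in order:
        if frac[i] >= threshold:
            return dates.iloc[i].date()
    return None


def season_start_date(date: _dt.date, start_month: int = 10, start_day: int = 1) -> _dt.date:
    """October 1st of the dormancy season containing ``date``."""
    year = date.year if (date.month, date.day) >= (start_month, start_day) else date.year - 1
    return _dt.date(year, start_month, start_day)


def days_since_season_start(date: _dt.date) -> int:
    """Encode a date as days since October 1st of its dormancy season."""
    return (date - season_start_date(date)).days


def chilling_requirement(
    series: HourlyTempSeries,
    er_date: _dt.date,
    season_start: _dt.date | None = None,
) -> dict:
    """Chill accumulated from Oct 1st to the ER date, in CH, CU and CP.

    The window is [season start, ER] at daily resolution, both inclusive.
    An ER on the season start date yields zero in all models (no full day
    accumulated before release).
    """
    start = season_start or season_start_date(er_date)
    if er_date < start:
        raise ValueError("ER date precedes the season start")
    if er_date == start:
        return {"CH": 0.0, "CU": 0.0, "CP": 0.0}
    profile = thermal.accumulate(series, start, er_date, models=("CH", "CU", "CP"))
    return dict(profile.totals)


def heating_requirement(
    series: HourlyTempSeries,
    er_date: _dt.date,
    f50_date: _dt.date,
) -> float:
    """GDH accumulated from the day after ER through F50 (inclusive)."""
    if f50_date < er_date:
        raise ValueError("F50 date precedes the ER date")
    if f50_date == er_date:
        return 0.0
    start = er_date + _dt.timedelta(days=1)
    profile = thermal.accumulate(series, start, f50_date, models=("GDH",))
    return profile.totals["GDH"]


def _band_label(value: float, low_max: float, high_min: float) -> str:
    if value <= low_max:
        return "low"
    if value >= high_min:
        return "high"
    return "medium"


def classify_cr(cr: Mapping[str, float]) -> dict:
    """Low/medium/high chilling-requirement class per model, plus consensus.

    Band bounds: CP ≤30 low, 31–40 medium, ≥41 high; CH ≤300 / 301–500 /
    ≥501; CU ≤500 / 501–700 / ≥701.  The consensus label is the Dynamic
    model's (CP) — the model with the lowest between-year variability in
    warm-winter regions; ``agree`` flags whether all models concur.
    """
    labels = {}
    for model, (low_max, high_min) in CR_CLASS_BOUNDS.items():
        value = float(cr[model])
        if value < 0:
            raise ValueError(f"{model} requirement must be nonnegative")
        labels[model] = _band_label(value, low_max, high_min)
    labels["consensus"] = labels["CP"]
    labels["agree"] = len({labels[m] for m in CR_CLASS_BOUNDS}) == 1
    return labels


def classify_hr(hr_gdh: float) -> str:
    """Low (≤6500), medium (6501–7000) or high (>7000) heat requirement."""
    hr_gdh = float(hr_gdh)
    if hr_gdh < 0:
        raise ValueError("heat requirement must be nonnegative")
    if hr_gdh <= HR_CLASS_BOUNDS[0]:
        return "low"
    if hr_gdh > HR_CLASS_BOUNDS[1]:
        return "high"
    return "medium"


def summarize_requirements(values: Sequence[float]) -> dict:
    """Mean, sample sd (n−1) and CV% across seasons.

    With a single season the sd and CV are reported as missing (NaN); a
    zero mean with nonzero sd yields a missing CV with a warning.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("at least one seasonal value is required")
    mean = float(arr.mean())
    if arr.size == 1:
        return {"mean": mean, "sd": float("nan"), "cv_pct": float("nan")}
    sd = float(arr.std(ddof=1))
    if mean == 0.0 and sd > 0.0:
        warnings.warn("zero mean with nonzero sd: CV undefined", stacklevel=2)
        cv = float("nan")
    elif mean == 0.0:
        cv = 0.0
    else:
        cv = 100.0 * sd / mean
    return {"mean": mean, "sd": sd, "cv_pct": cv}


@dataclasses.dataclass
class CorrelationNetwork:
    """Pairwise Spearman correlations among agroclimatic variables."""

    rho: pd.DataFrame
    pvalues: pd.DataFrame
    location: str | None = None

    def edges(self, alpha: float | None = None) -> pd.DataFrame:
        """Tidy upper-triangle edge list, optionally filtered at ``alpha``."""
        rows = []
        cols = list(self.rho.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                rows.append(
                    {
                        "var_a": a,
                        "var_b": b,
                        "rho": self.rho.loc[a, b],
                        "p_value": self.pvalues.loc[a, b],
                        "location": self.location,
                    }
                )
        out = pd.DataFrame(rows)
        if alpha is not None:
            out = out[out["p_value"] <= alpha].reset_index(drop=True)
        return out


def correlation_network(
    table: pd.DataFrame,
    location: str | None = None,
    min_rows: int = 4,
) -> CorrelationNetwork:
    """Spearman correlation network across cultivars at one location.

    ``table`` holds one row per cultivar with numeric columns (CH, CU, CP,
    GDH and day-of-season encodings of ER and F50).  Ties are handled by
    midranks.  Constant variables get missing rho for all their pairs,
    with a warning.
    """
    numeric = table.select_dtypes(include=[np.number])
    if len(numeric) < min_rows:
        raise ValueError(f"need at least {min_rows} cultivars, got {len(numeric)}")
    cols = list(numeric.columns)
    n = len(cols)
    rho = pd.DataFrame(np.eye(n), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((n, n)), index=cols, columns=cols)
    constant = [c for c in cols if numeric[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant variables, rho undefined: {constant}", stacklevel=2)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if a in constant or b in constant:
                r, p = float("nan"), float("nan")
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r, p = stats.spearmanr(numeric[a], numeric[b])
            rho.loc[a, b] = rho.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p
    return CorrelationNetwork(rho=rho, pvalues=pval, location=location)


@dataclasses.dataclass
class KruskalResult:
    """Kruskal–Wallis rank test result (chi-square approximation, k−1 df)."""

    h: float
    p_value: float
    degenerate: bool = False


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalResult:
    """Kruskal–Wallis H test across ≥ 2 groups of CR or HR values.

    All-identical values make the test undefined; the result is then
    flagged degenerate with H = 0 and p = 1.
    """
    groups = [np.asarray(list(g), dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return KruskalResult(h=0.0, p_value=1.0, degenerate=True)
    h, p = stats.kruskal(*groups)
    return KruskalResult(h=float(h), p_value=float(p), degenerate=False)


# ---------------------------------------------------------------------------
# Cohort-level pipeline
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CultivarRequirements:
    """Requirements of one cultivar across seasons and locations.

    ``per_season`` has one row per (location, season) with ER/F50 dates
    and CR/HR values; ``summary`` carries mean/sd/CV% per model and the
    class labels.
    """

    cultivar: str
    per_season: pd.DataFrame
    summary: dict

    @property
    def cr_class(self) -> str:
        return self.summary["cr_class"]["consensus"]

    @property
    def hr_class(self) -> str:
        return self.summary["hr_class"]


def estimate_requirements(
    forcing: pd.DataFrame,
    phenology: pd.DataFrame,
    series_by_location: Mapping[str, HourlyTempSeries] | Mapping[tuple, HourlyTempSeries],
) -> pd.DataFrame:
    """Per (cultivar, location, season) ER, F50, CR and HR table.

    ``forcing`` and ``phenology`` follow the standard schemas;
    ``series_by_location`` maps a location (or (location, season) pair) to
    the hourly temperature series covering that dormancy season.  Seasons
    whose buds never release, or never bloom, get missing requirement
    values.
    """
    rows = []
    for (cultivar, location, season), group in forcing.groupby(
        ["cultivar", "location", "season"]
    ):
        series = _lookup_series(series_by_location, location, season)
        er = detect_endodormancy_release(ForcingExperiment(group))
        pheno = phenology[
            (phenology["cultivar"] == cultivar) & (phenology["location"] == location)
        ]
        pheno = pheno[_season_of_dates(pheno["date"]) == season]
        f50 = detect_f50(pheno) if len(pheno) else None
        row = {
            "cultivar": cultivar,
            "location": location,
            "season": season,
            "er_date": er,
            "f50_date": f50,
            "cr_ch": np.nan,
            "cr_cu": np.nan,
            "cr_cp": np.nan,
            "hr_gdh": np.nan,
        }
        if er is not None:
            cr = chilling_requirement(series, er)
            row.update(cr_ch=cr["CH"], cr_cu=cr["CU"], cr_cp=cr["CP"])
            if f50 is not None:
                row["hr_gdh"] = heating_requirement(series, er, f50)
        rows.append(row)
    return pd.DataFrame(rows)


def _season_of_dates(dates: pd.Series) -> pd.Series:
    d = pd.to_datetime(dates)
    return d.dt.year.where(d.dt.month >= 10, d.dt.year - 1)


def _lookup_series(mapping, location, season):
    if (location, season) in mapping:
        return mapping[(location, season)]
    if location in mapping:
        return mapping[location]
    raise KeyError(f"no hourly series for location {location!r}, season {season}")


def summarize_cultivars(per_season: pd.DataFrame) -> pd.DataFrame:
    """Across-season summary with class labels, one row per cultivar.

    Columns: mean/sd/CV% per model (CH, CU, CP, GDH) over all seasons and
    locations with data, plus per-model CR classes, the consensus class
    and the HR class.
    """
    rows = []
    col_by_model = {"CH": "cr_ch", "CU": "cr_cu", "CP": "cr_cp", "GDH": "hr_gdh"}
    for cultivar, group in per_season.groupby("cultivar"):
        row: dict = {"cultivar": cultivar}
        means = {}
        for model, col in col_by_model.items():
            vals = group[col].dropna()
            if len(vals) == 0:
                row[f"{model.lower()}_mean"] = np.nan
                row[f"{model.lower()}_sd"] = np.nan
                row[f"{model.lower()}_cv_pct"] = np.nan
                continue
            s = summarize_requirements(vals)
            means[model] = s["mean"]
            row[f"{model.lower()}_mean"] = s["mean"]
            row[f"{model.lower()}_sd"] = s["sd"]
            row[f"{model.lower()}_cv_pct"] = s["cv_pct"]
        if all(m in means for m in ("CH", "CU", "CP")):
            labels = classify_cr({m: means[m] for m in ("CH", "CU", "CP")})
            row["cr_class_cp"] = labels["CP"]
            row["cr_class_ch"] = labels["CH"]
            row["cr_class_cu"] = labels["CU"]
            row["cr_class"] = labels["consensus"]
            row["cr_class_agree"] = labels["agree"]
        if "GDH" in means:
            row["hr_class"] = classify_hr(means["GDH"])
        rows.append(row)
    return pd.DataFrame(rows)
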