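"""End-to-end dormancy-agroclimatics pipeline.

Composes the full analysis: synthetic (or file-based) station records →
forcing-experiment ER detection → chilling/heating requirements and
classification → historic and future climate scenarios → weather-generator
ensembles of winter chill availability → cultivar × scenario fulfillment
risk matrix.  Every stage writes a tidy CSV and the run is reproducible
from the seeds recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from . import requirements as req
from . import risk as prisk
from . import scenarios as scen
from . import synthetic as syn

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)

_PRESETS = {"badajoz_like": syn.BADAJOZ_LIKE, "zaragoza_like": syn.ZARAGOZA_LIKE}


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - wrap with stage context
                raise PipelineError(name, exc) from exc
            return out

        return wrapped

    return deco


def _climate_spec(value, fallback_seed: int) -> syn.SyntheticClimateSpec:
    if isinstance(value, syn.SyntheticClimateSpec):
        return value
    if isinstance(value, str):
        try:
            return _PRESETS[value]
        except KeyError:
            raise ValueError(
                f"unknown climate preset {value!r}; choose from {sorted(_PRESETS)}"
            ) from None
    return syn.SyntheticClimateSpec(**{"seed": fallback_seed, **dict(value)})


@_stage("climate")
def _build_climates(config: pio.PipelineConfig) -> dict:
    """Station records per region: synthetic presets or provided files."""
    climates = {}
    for i, (region, value) in enumerate(config.regions.items()):
        if region in config.station_files:
            path = config.station_files[region]
            daily = pio.read_daily_csv(path)
            spec = _climate_spec(value, config.seed + i)
            from .thermal import hourly_from_daily

            hourly = hourly_from_daily(daily, spec.latitude, station_id=region)
        else:
            spec = _climate_spec(value, config.seed + i)
            spec = dataclasses.replace(spec, seed=(config.seed * 101 + i) % 2**31)
            daily, hourly = syn.generate_station_record(
                spec, config.start_year, config.n_years, station_id=region
            )
        climates[region] = {"spec": spec, "daily": daily, "hourly": hourly}
        logger.info("climate[%s]: %d daily records", region, len(daily))
    return climates


@_stage("forcing")
def _build_forcing(config: pio.PipelineConfig, climates: dict):
    """Synthetic forcing experiments and bloom curves for the cohort."""
    last_year = config.start_year + config.n_years - 1
    season_years = [last_year - 1 - k for k in range(config.n_seasons)]
    forcing_frames = []
    pheno_frames = []
    for r, region in enumerate(climates):
        for c, (cultivar, release_offset) in enumerate(config.cultivars.items()):
            for s, year in enumerate(season_years):
                start = _dt.date(year, 11, 1)
                end = _dt.date(year + 1, 2, 10)
                release = _dt.date(year, 10, 1) + _dt.timedelta(days=int(release_offset))
                fspec = syn.SyntheticForcingSpec(
                    release_date=release,
                    noise_sd_g=config.forcing_noise_sd_g,
                    seed=(config.seed * 7919 + r * 1009 + c * 101 + s) % 2**31,
                )
                forcing_frames.append(
                    syn.generate_forcing_experiment(
                        fspec, start, end, cultivar=cultivar, location=region
                    )
                )
                # bloom roughly six weeks after release, later for higher-chill cultivars
                f50 = release + _dt.timedelta(days=45 + 2 * c)
                pheno_frames.append(
                    syn.generate_bloom_curve(
                        f50, cultivar=cultivar, location=region,
                        noise_sd=0.02,
                        seed=(config.seed * 104729 + r * 997 + c * 89 + s) % 2**31,
                    )
                )
    return pd.concat(forcing_frames, ignore_index=True), pd.concat(
        pheno_frames, ignore_index=True
    )


@_stage("requirements")
def _build_requirements(forcing, phenology, climates):
    series_by_location = {region: data["hourly"] for region, data in climates.items()}
    per_season = req.estimate_requirements(forcing, phenology, series_by_location)
    summary = req.summarize_cultivars(per_season)
    logger.info(
        "requirements: %d cultivar-seasons in, %d cultivars out",
        len(per_season),
        len(summary),
    )
    return per_season, summary


@_stage("scenarios")
def _build_scenarios(config: pio.PipelineConfig, climates: dict):
    """Historic + future scenarios and generator calibration per region."""
    out = {}
    deltas = config.rcp_deltas or syn.DEFAULT_RCP_DELTAS
    deltas = {k: {int(h): float(d) for h, d in v.items()} for k, v in deltas.items()}
    for i, (region, data) in enumerate(climates.items()):
        historic = scen.historic_scenarios(
            data["daily"],
            [y for y in config.reference_years],
        )
        baseline = scen.monthly_normals(data["daily"])
        gcm_table = syn.generate_gcm_table(
            baseline,
            n_gcms=config.n_gcms,
            rcp_deltas=deltas,
            gcm_spread_sd=config.gcm_spread_sd,
            seed=(config.seed * 31337 + i) % 2**31,
        )
        future = scen.future_scenarios(gcm_table)
        params = scen.calibrate_generator(data["daily"])
        out[region] = {
            "historic": historic,
            "future": future,
            "gcm_table": gcm_table,
            "params": params,
        }
        logger.info(
            "scenarios[%s]: %d historic + %d future", region, len(historic), len(future)
        )
    return out


@_stage("ensembles")
def _build_ensembles(config: pio.PipelineConfig, climates, scenario_sets):
    window = (scen.CHILL_WINDOW[0], tuple(int(v) for v in config.chill_window_end))
    ensembles = {}
    for i, (region, sets) in enumerate(scenario_sets.items()):
        latitude = climates[region]["spec"].latitude
        region_ens = []
        for j, scenario in enumerate(sets["historic"] + sets["future"]):
            reps = scen.simulate_seasons(
                scenario,
                sets["params"],
                n_replicates=config.n_replicates,
                seed=(config.seed * 65537 + i * 4099 + j) % 2**31,
            )
            region_ens.append(
                scen.chill_availability(reps, latitude, scenario=scenario, window=window)
            )
        ensembles[region] = region_ens
        logger.info("ensembles[%s]: %d scenarios x %d replicates",
                    region, len(region_ens), config.n_replicates)
    return ensembles


@_stage("risk")
def _build_risk(config: pio.PipelineConfig, summary: pd.DataFrame, ensembles: dict):
    frames = []
    reqs = summary.rename(columns={"cp_mean": "cp_mean", "cp_sd": "cp_sd"})[
        ["cultivar", "cp_mean", "cp_sd"]
    ]
    for region, region_ens in ensembles.items():
        matrix = prisk.risk_matrix(
            reqs,
            region_ens,
            n_draws=config.n_draws,
            seed=(config.seed * 2654435761 + 17) % 2**31,
        )
        matrix.insert(0, "region", region)
        frames.append(matrix)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: pio.PipelineConfig, output_dir=None) -> dict:
    """Run every stage and write outputs + a run manifest.

    Returns a dict with the in-memory stage outputs: ``per_season``,
    ``summary``, ``ensembles`` (region → list of ScenarioEnsemble),
    ``risk`` and ``manifest``.  Idempotent for a fixed config and seed.
    """
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    climates = _build_climates(config)
    forcing, phenology = _build_forcing(config, climates)
    per_season, summary = _build_requirements(forcing, phenology, climates)
    scenario_sets = _build_scenarios(config, climates)
    ensembles = _build_ensembles(config, climates, scenario_sets)
    risk = _build_risk(config, summary, ensembles)

    for region, data in climates.items():
        pio.write_daily_csv(data["daily"], outdir / f"station_{region}.csv")
    pio.write_forcing_csv(forcing, outdir / "forcing.csv")
    pio.write_phenology_csv(phenology, outdir / "phenology.csv")
    pio.write_requirements_csv(per_season, outdir / "requirements_per_season.csv")
    summary.to_csv(outdir / "requirements_summary.csv", index=False)
    for region, sets in scenario_sets.items():
        pio.write_gcm_csv(sets["gcm_table"], outdir / f"gcm_table_{region}.csv")
    ens_rows = []
    for region, region_ens in ensembles.items():
        for ens in region_ens:
            for rep, cp in enumerate(ens.cp_totals):
                ens_rows.append(
                    {
                        "region": region,
                        "scenario_id": ens.scenario.scenario_id,
                        "replicate": rep,
                        "cp_total": cp,
                    }
                )
    pd.DataFrame(ens_rows).to_csv(outdir / "chill_ensembles.csv", index=False)
    risk.to_csv(outdir / "risk_matrix.csv", index=False)

    from . import __version__

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "counts": {
            "cultivar_seasons": len(per_season),
            "cultivars": len(summary),
            "scenarios": {r: len(e) for r, e in ensembles.items()},
            "risk_rows": len(risk),
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return {
        "climates": climates,
        "per_season": per_season,
        "summary": summary,
        "scenario_sets": scenario_sets,
        "ensembles": ensembles,
        "risk": risk,
        "manifest": manifest,
    }
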