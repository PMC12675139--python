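"""End-to-end experiment: synthetic ensemble -> ETo/GDD -> seasons -> aggregation.

For every scenario, cell and ensemble member the pipeline generates daily
weather, derives reference evapotranspiration and degree days, finds the
adaptive sowing date year by year, runs the three management regimes on
identical weather, and reduces the seasons to per-cell statistics.  Scenario
fields are the per-cell ensemble medians; change maps compare each scenario
with the baseline on the crossmasked cell set.  Everything is deterministic
given the global seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregate as agg
from .climate import derive_climate
from .config import RunConfig, write_manifest
from .gaps import RegimeTriplet, cell_statistics, run_regimes
from .phenology import find_sowing_date
from .weather import generate_ensemble

log = logging.getLogger("maizegap")

__all__ = ["ExperimentResult", "run_experiment"]

_STAT_FIELDS = [
    "mean_ya", "mean_yw", "mean_yp", "sd_ya", "sd_yw", "sd_yp",
    "ygw", "ygp", "wpa", "wpw", "wpp",
    "mean_sowing_doy", "mean_cycle_length", "n_complete_years", "n_failures",
]


@dataclass
class ExperimentResult:
    seasons: pd.DataFrame  # one row per scenario x cell x member x year
    cell_stats: pd.DataFrame  # one row per scenario x cell x member
    scenario_fields: pd.DataFrame  # ensemble medians, one row per scenario x cell
    changes: pd.DataFrame  # relative changes vs baseline on the crossmask
    summaries: dict  # domain summaries per scenario
    manifest: dict | None = None


def _simulate_scenario(cfg: RunConfig, scenario: str):
    """All seasons and per-member statistics for one scenario."""
    season_rows = []
    stat_rows = []
    completion = np.zeros((cfg.n_members, cfg.n_years, len(cfg.cells)), dtype=bool)
    mgmt = {r: cfg.management(r) for r in ("ya", "yw", "yp")}
    for ci, (lat, lon) in enumerate(cfg.cells):
        spec = cfg.cell_spec(ci, scenario)
        members = generate_ensemble(spec, cfg.n_members, cfg.n_years, cfg.start_year)
        for mi, wx in enumerate(members):
            dx = derive_climate(wx, lat, cfg.elevation, cfg.crop.tbase, cfg.crop.tupper)
            triplets: list[RegimeTriplet] = []
            for yi, year in enumerate(range(cfg.start_year, cfg.start_year + cfg.n_years)):
                year_wx = dx.loc[str(year)]
                sowing = find_sowing_date(year_wx, cfg.sowing)
                trip = run_regimes(
                    dx, cfg.crop, cfg.soil, sowing,
                    mgmt_ya=mgmt["ya"], mgmt_yw=mgmt["yw"], mgmt_yp=mgmt["yp"],
                )
                triplets.append(trip)
                completion[mi, yi, ci] = trip.ya.complete
                season_rows.append({
                    "scenario": scenario, "lat": lat, "lon": lon, "member": mi,
                    "year": year, "sowing_doy": sowing.dayofyear,
                    "complete": trip.ya.complete,
                    "cycle_length": trip.ya.cycle_length,
                    "ya": trip.ya.yield_dry, "yw": trip.yw.yield_dry,
                    "yp": trip.yp.yield_dry,
                    "etc_a": trip.ya.etc_sum, "etc_w": trip.yw.etc_sum,
                    "etc_p": trip.yp.etc_sum,
                    "irrigation_p": trip.yp.irrigation_sum,
                })
            stats = cell_statistics(triplets, failure_threshold=cfg.unsuitable_below)
            row = {"scenario": scenario, "lat": lat, "lon": lon, "member": mi}
            row.update({f: getattr(stats, f) for f in _STAT_FIELDS})
            stat_rows.append(row)
    return season_rows, stat_rows, completion


def run_experiment(cfg: RunConfig) -> ExperimentResult:
    """Run every scenario of a configuration and aggregate the results.

    Returns in-memory tables and, if ``cfg.output_dir`` is set, writes
    ``seasons.csv``, ``cell_stats.csv``, ``scenario_fields.csv``,
    ``changes.csv``, ``fields.nc`` (when the cells form a regular grid is not
    required -- cells are stored as a flat cell dimension) and
    ``manifest.json``.
    """
    t0 = time.time()
    season_rows: list[dict] = []
    stat_rows: list[dict] = []
    masks: dict[str, np.ndarray] = {}
    for scenario in cfg.scenarios:
        t1 = time.time()
        rows, stats, completion = _simulate_scenario(cfg, scenario)
        season_rows.extend(rows)
        stat_rows.extend(stats)
        masks[scenario] = agg.inclusion_mask(completion, cfg.min_years)
        log.info("scenario %s: %d seasons in %.1fs", scenario, len(rows), time.time() - t1)

    seasons = pd.DataFrame(season_rows)
    cell_stats = pd.DataFrame(stat_rows)

    # ensemble medians per scenario and cell
    field_rows = []
    for scenario in cfg.scenarios:
        sub = cell_stats[cell_stats["scenario"] == scenario]
        for ci, (lat, lon) in enumerate(cfg.cells):
            cell = sub[(sub["lat"] == lat) & (sub["lon"] == lon)]
            med = {
                f: float(agg.ensemble_median(cell[f].to_numpy()))
                for f in _STAT_FIELDS
            }
            med.update({
                "scenario": scenario, "lat": lat, "lon": lon,
                "included": bool(masks[scenario][ci]),
                "suitability": agg.classify_suitability(
                    med["mean_ya"], cfg.unsuitable_below, cfg.profitable_above
                ) if np.isfinite(med["mean_ya"]) else "unsuitable",
            })
            field_rows.append(med)
    scenario_fields = pd.DataFrame(field_rows)

    # relative changes vs baseline on the crossmasked cells
    base = scenario_fields[scenario_fields["scenario"] == "baseline"].set_index(["lat", "lon"])
    change_rows = []
    for scenario in cfg.scenarios:
        if scenario == "baseline":
            continue
        fut = scenario_fields[scenario_fields["scenario"] == scenario].set_index(["lat", "lon"])
        joint = agg.crossmask(masks["baseline"], masks[scenario])
        for ci, (lat, lon) in enumerate(cfg.cells):
            if not joint[ci]:
                continue
            row = {"scenario": scenario, "lat": lat, "lon": lon}
            for f in ("mean_ya", "mean_yw", "mean_yp", "wpa", "mean_cycle_length"):
                b, fv = base.loc[(lat, lon), f], fut.loc[(lat, lon), f]
                row[f"d_{f}_pct"] = float(agg.relative_change_field(b, fv))
            row["d_sowing_days"] = float(
                fut.loc[(lat, lon), "mean_sowing_doy"] - base.loc[(lat, lon), "mean_sowing_doy"]
            )
            row["d_cycle_days"] = float(
                fut.loc[(lat, lon), "mean_cycle_length"] - base.loc[(lat, lon), "mean_cycle_length"]
            )
            change_rows.append(row)
    changes = pd.DataFrame(change_rows)

    summaries = {}
    for scenario in cfg.scenarios:
        sub = scenario_fields[scenario_fields["scenario"] == scenario]
        vals = sub["mean_ya"].to_numpy()
        mask = sub["included"].to_numpy(dtype=bool)
        try:
            summaries[scenario] = {
                "mean_ya": agg.domain_summary(vals, mask),
                "mean_ya_viable": agg.domain_summary(
                    vals, mask, exclude_below=cfg.unsuitable_below
                ),
            }
        except ValueError:
            summaries[scenario] = {"mean_ya": None, "mean_ya_viable": None}

    manifest = None
    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        seasons.to_csv(out / "seasons.csv", index=False, float_format="%.6f")
        cell_stats.to_csv(out / "cell_stats.csv", index=False, float_format="%.6f")
        scenario_fields.to_csv(out / "scenario_fields.csv", index=False, float_format="%.6f")
        changes.to_csv(out / "changes.csv", index=False, float_format="%.6f")
        _write_netcdf(cfg, scenario_fields, out / "fields.nc")
        manifest = write_manifest(
            cfg, out / "manifest.json",
            extra={"summaries": summaries, "runtime_s": round(time.time() - t0, 2)},
        )
    log.info("experiment finished in %.1fs", time.time() - t0)
    return ExperimentResult(seasons, cell_stats, scenario_fields, changes, summaries, manifest)


def _write_netcdf(cfg: RunConfig, scenario_fields: pd.DataFrame, path: Path) -> None:
    """Store scenario fields on a (scenario, cell) grid as NetCDF."""
    import xarray as xr

    scenarios = list(cfg.scenarios)
    lats = [c[0] for c in cfg.cells]
    lons = [c[1] for c in cfg.cells]
    data = {}
    for f in _STAT_FIELDS + ["included"]:
        arr = np.full((len(scenarios), len(cfg.cells)), np.nan)
        for si, scen in enumerate(scenarios):
            sub = scenario_fields[scenario_fields["scenario"] == scen]
            for ci, (lat, lon) in enumerate(cfg.cells):
                cell = sub[(sub["lat"] == lat) & (sub["lon"] == lon)]
                if len(cell):
                    arr[si, ci] = float(cell.iloc[0][f])
        data[f] = (("scenario", "cell"), arr)
    ds = xr.Dataset(
        data,
        coords={
            "scenario": scenarios,
            "cell": np.arange(len(cfg.cells)),
            "lat": ("cell", lats, {"units": "degrees_north"}),
            "lon": ("cell", lons, {"units": "degrees_east"}),
        },
    )
    ds.to_netcdf(path, engine="scipy")
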