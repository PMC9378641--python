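"""Reading, validating and aggregating ensemble carbon-cycle output.

Covers the standard plumbing around the attribution analysis: summing the
soil-system pools under per-model availability rules, reducing gridded
fields (kgC m-2 or kgC m-2 s-1) to regional totals in PgC, the
fossil-minus-atmosphere-minus-ocean budget residual, sanity validation of
runs, and tidy-CSV / CF-style netCDF round trips (netCDF via xarray's
scipy backend).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .containers import UNITS, AnnualSeries, ModelRun, PoolFlags, ScenarioQuartet

EARTH_RADIUS_M = 6_371_000.0
SECONDS_PER_YEAR = 365.25 * 86_400.0
KG_PER_PG = 1.0e12


# ---------------------------------------------------------------------------
# pool aggregation
# ---------------------------------------------------------------------------

def aggregate_soil_pools(run: ModelRun, region: str = "global") -> AnnualSeries:
    """Total soil-system carbon: soil + litter + coarse woody debris.

    Litter is added only when the model reports it separately from the
    soil stock (``litter_in_soil`` marks models whose soil output already
    contains it, in which case adding the litter series would double
    count).
    """
    variables = run.data[region]
    flags = run.flags
    total = variables["csoil"].values.copy()
    years = variables["csoil"].years
    if flags.has_litter and not flags.litter_in_soil:
        if "clitter" not in variables:
            raise ValueError("has_litter set but no clitter series present")
        total = total + variables["clitter"].values
    if flags.has_cwd:
        if "ccwd" not in variables:
            raise ValueError("has_cwd set but no ccwd series present")
        total = total + variables["ccwd"].values
    return AnnualSeries(years, total, "PgC")


# ---------------------------------------------------------------------------
# gridded reduction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSpec:
    """A latitude band; cells are assigned by grid-cell centre latitude.

    ``lat_min`` is inclusive, ``lat_max`` exclusive, so bands like
    [-90, 30) and [30, 90.0001) partition the globe with cells exactly at
    30 degrees going north.
    """

    name: str
    lat_min: float
    lat_max: float

    def contains(self, lat: np.ndarray) -> np.ndarray:
        return (lat >= self.lat_min) & (lat < self.lat_max)


DEFAULT_REGIONS = (
    RegionSpec("north", 30.0, 90.001),
    RegionSpec("south", -90.001, 30.0),
)


def spherical_cell_areas(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Cell areas (m^2) on a sphere for regular cell-centre coordinates."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    dlat = np.deg2rad(abs(lat[1] - lat[0]))
    dlon = np.deg2rad(abs(lon[1] - lon[0]))
    band = (
        EARTH_RADIUS_M**2
        * dlon
        * (np.sin(np.deg2rad(lat) + dlat / 2) - np.sin(np.deg2rad(lat) - dlat / 2))
    )
    return np.repeat(band[:, None], lon.size, axis=1)


def regional_totals(
    field: np.ndarray | xr.DataArray,
    cell_areas: np.ndarray,
    lat: np.ndarray | None = None,
    regions: Sequence[RegionSpec] = DEFAULT_REGIONS,
    rate: bool = False,
    missing: str = "error",
) -> dict[str, float]:
    """Area-integrate a (lat, lon) density field to per-region totals.

    Stocks (kgC m-2) convert to PgC; rate fields (kgC m-2 s-1, set
    ``rate=True``) additionally convert to PgC yr-1. A "global" entry is
    always included. ``missing`` selects the NaN policy: "error" (default)
    or "zero".
    """
    if isinstance(field, xr.DataArray):
        if lat is None:
            lat = np.asarray(field["lat"])
        field = field.values
    field = np.asarray(field, dtype=float)
    cell_areas = np.asarray(cell_areas, dtype=float)
    if field.shape != cell_areas.shape:
        raise ValueError("field and cell areas must share the grid")
    if lat is None:
        raise ValueError("latitude coordinates required for region assignment")
    lat = np.asarray(lat, dtype=float)

    if np.any(np.isnan(field)):
        if missing == "error":
            raise ValueError("field contains missing values (missing='error')")
        if missing == "zero":
            field = np.nan_to_num(field, nan=0.0)
        else:
            raise ValueError(f"unknown missing policy {missing!r}")

    scale = (SECONDS_PER_YEAR if rate else 1.0) / KG_PER_PG
    weighted = field * cell_areas * scale
    out = {"global": float(weighted.sum())}
    for region in regions:
        mask = region.contains(lat)[:, None]
        out[region.name] = float(np.where(mask, weighted, 0.0).sum())
    return out


def paint_uniform_grid(total_pgc: float, lat: np.ndarray, lon: np.ndarray,
                       cell_areas: np.ndarray | None = None) -> np.ndarray:
    """Spread a global total (PgC) uniformly per unit area (kgC m-2)."""
    if cell_areas is None:
        cell_areas = spherical_cell_areas(lat, lon)
    return np.full(cell_areas.shape, total_pgc * KG_PER_PG / cell_areas.sum())


# ---------------------------------------------------------------------------
# budget residual
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BudgetSeries:
    """Fossil emissions, atmospheric growth and ocean sink (PgC yr-1)."""

    e_fos: AnnualSeries
    g_atm: AnnualSeries
    s_ocean: AnnualSeries

    def __post_init__(self) -> None:
        for s in (self.g_atm, self.s_ocean):
            self.e_fos._check_aligned(s)


def compute_budget_residual(budget: BudgetSeries) -> AnnualSeries:
    """Observation-based net land sink: E_FOS - G_ATM - S_OCEAN."""
    return budget.e_fos - budget.g_atm - budget.s_ocean


def read_budget_csv(path: str | Path) -> BudgetSeries:
    df = pd.read_csv(path)
    years = df["year"].to_numpy()
    mk = lambda col: AnnualSeries(years, df[col].to_numpy(), "PgC yr-1")
    return BudgetSeries(mk("E_FOS"), mk("G_ATM"), mk("S_OCEAN"))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    model_id: str
    scenario: str
    year_gaps: list[int] = field(default_factory=list)
    negative_stocks: list[str] = field(default_factory=list)
    flag_issues: list[str] = field(default_factory=list)
    closure_residual: float = float("nan")

    @property
    def ok(self) -> bool:
        return not (self.year_gaps or self.negative_stocks or self.flag_issues)


def validate_run(run: ModelRun, region: str = "global") -> ValidationReport:
    """Report-only sanity checks on one run.

    The NBP vs stock-change closure residual (max abs difference between
    NBP and the backward annual change of cveg + aggregated soil carbon)
    is informational: real models carry fluxes our pool sum omits, such as
    wood-product decay.
    """
    report = ValidationReport(run.model_id, run.scenario)
    variables = run.data[region]
    years = next(iter(variables.values())).years
    gaps = np.flatnonzero(np.diff(years) != 1)
    report.year_gaps = [int(years[g]) for g in gaps]

    for name in ("cveg", "csoil", "clitter", "ccwd"):
        if name in variables and np.any(variables[name].values < 0):
            report.negative_stocks.append(name)

    flags = run.flags
    if flags.has_litter and not flags.litter_in_soil and "clitter" not in variables:
        report.flag_issues.append("has_litter set but clitter missing")
    if flags.has_cwd and "ccwd" not in variables:
        report.flag_issues.append("has_cwd set but ccwd missing")

    try:
        cs = aggregate_soil_pools(run, region)
        total = variables["cveg"].values + cs.values
        dc = np.diff(total)
        nbp = variables["nbp"].values[1:]
        report.closure_residual = float(np.max(np.abs(nbp - dc)))
    except (KeyError, ValueError):
        pass
    return report


# ---------------------------------------------------------------------------
# tidy CSV round trip
# ---------------------------------------------------------------------------

def runs_to_frame(runs: Iterable[ModelRun]) -> pd.DataFrame:
    rows = []
    for run in runs:
        for region, variables in run.data.items():
            for name, series in variables.items():
                rows.append(
                    pd.DataFrame(
                        {
                            "model": run.model_id,
                            "scenario": run.scenario,
                            "region": region,
                            "year": series.years,
                            "variable": name,
                            "value": series.values,
                            "units": series.units,
                            "has_litter": run.flags.has_litter,
                            "has_cwd": run.flags.has_cwd,
                            "litter_in_soil": run.flags.litter_in_soil,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def write_runs_csv(runs: Iterable[ModelRun], path: str | Path) -> None:
    runs_to_frame(runs).to_csv(path, index=False)


def frame_to_runs(df: pd.DataFrame) -> list[ModelRun]:
    runs = []
    for (model, scenario), group in df.groupby(["model", "scenario"], sort=True):
        flags = PoolFlags(
            bool(group["has_litter"].iloc[0]),
            bool(group["has_cwd"].iloc[0]),
            bool(group["litter_in_soil"].iloc[0]),
        )
        data: dict[str, dict[str, AnnualSeries]] = {}
        for (region, variable), sub in group.groupby(["region", "variable"]):
            sub = sub.sort_values("year")
            data.setdefault(region, {})[variable] = AnnualSeries(
                sub["year"].to_numpy(), sub["value"].to_numpy(), sub["units"].iloc[0]
            )
        runs.append(ModelRun(str(model), str(scenario), data, flags))
    return runs


def read_runs_csv(path: str | Path) -> list[ModelRun]:
    return frame_to_runs(pd.read_csv(path))


def quartets_from_runs(runs: Iterable[ModelRun]) -> list[ScenarioQuartet]:
    by_model: dict[str, dict[str, ModelRun]] = {}
    for run in runs:
        by_model.setdefault(run.model_id, {})[run.scenario] = run
    return [
        ScenarioQuartet(model_id, scenario_runs)
        for model_id, scenario_runs in sorted(by_model.items())
    ]


# ---------------------------------------------------------------------------
# netCDF round trip (scipy backend, NETCDF3)
# ---------------------------------------------------------------------------

def run_to_dataset(run: ModelRun, region: str = "global") -> xr.Dataset:
    variables = run.data[region]
    years = next(iter(variables.values())).years
    ds = xr.Dataset(
        {
            name: ("year", series.values, {"units": series.units})
            for name, series in variables.items()
        },
        coords={"year": years},
        attrs={
            "model_id": run.model_id,
            "scenario": run.scenario,
            "region": region,
            "has_litter": int(run.flags.has_litter),
            "has_cwd": int(run.flags.has_cwd),
            "litter_in_soil": int(run.flags.litter_in_soil),
        },
    )
    return ds


def write_run_netcdf(run: ModelRun, path: str | Path, region: str = "global") -> None:
    run_to_dataset(run, region).to_netcdf(path, engine="scipy")


def read_run_netcdf(path: str | Path) -> ModelRun:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    years = np.asarray(ds["year"].values, dtype=int)
    variables = {
        str(name): AnnualSeries(
            years, np.asarray(ds[name].values, float), ds[name].attrs.get("units", "1")
        )
        for name in ds.data_vars
    }
    flags = PoolFlags(
        bool(ds.attrs["has_litter"]),
        bool(ds.attrs["has_cwd"]),
        bool(ds.attrs["litter_in_soil"]),
    )
    region = str(ds.attrs.get("region", "global"))
    return ModelRun(str(ds.attrs["model_id"]), str(ds.attrs["scenario"]), {region: variables}, flags)


def write_gridded_netcdf(
    fields: Mapping[str, np.ndarray],
    lat: np.ndarray,
    lon: np.ndarray,
    path: str | Path,
    units: Mapping[str, str] | None = None,
) -> None:
    """Write (lat, lon) fields as a CF-style dataset."""
    units = units or {}
    ds = xr.Dataset(
        {
            name: (("lat", "lon"), np.asarray(arr), {"units": units.get(name, "1")})
            for name, arr in fields.items()
        },
        coords={"lat": lat, "lon": lon},
    )
    ds.to_netcdf(path, engine="scipy")
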