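"""Readers and writers for every on-disk artifact.

Delimited tables are UTF-8 CSV with a required header (depth in cm, ages
in cal yr BP); gridded fields are NetCDF with CF-style coordinates, read
and written through xarray's scipy engine.  Longitudes given on a 0..360
convention are normalized to [-180, 180) on read.  All readers validate
and return the domain types from :mod:`pollenrecon.types`.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .types import (
    AgeControl,
    CalibCurve,
    ClimateGrid,
    PollenCounts,
    TopoAnomalyField,
    ValidationError,
)

logger = logging.getLogger(__name__)

_NETCDF_KW = dict(engine="scipy", format="NETCDF3_64BIT")


# ---------------------------------------------------------------- pollen

def read_pollen_table(path: str | Path, dialect: str = "counts") -> PollenCounts:
    """Read a pollen table CSV: sample_id, depth_cm, then one column per taxon.

    ``dialect="percentages"`` divides rows by 100 and records the table as
    proportions (row sums are checked to be ~1).
    """
    if dialect not in ("counts", "percentages"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path)
    required = {"sample_id", "depth_cm"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: missing required columns {required - set(df.columns)}")
    taxa = [c for c in df.columns if c not in ("sample_id", "depth_cm")]
    values = df[taxa].to_numpy(dtype=float)
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"{path}: negative value at row {df['sample_id'].iloc[i]!r}, column {taxa[j]!r}"
        )
    is_prop = dialect == "percentages"
    if is_prop:
        values = values / 100.0
        sums = values.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 0.02):
            bad = df["sample_id"].iloc[int(np.argmax(np.abs(sums - 1.0)))]
            raise ValidationError(f"{path}: percentage rows must sum to ~100 (sample {bad!r})")
    return PollenCounts(
        sample_ids=df["sample_id"].astype(str).tolist(),
        depths=df["depth_cm"].to_numpy(dtype=float),
        taxa=taxa,
        counts=values,
        is_proportions=is_prop,
    )


def write_pollen_table(counts: PollenCounts, path: str | Path) -> None:
    counts.to_frame().to_csv(path, index=False)


# ------------------------------------------------------- taxa-PFT matrix

def read_taxa_pft_matrix(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read taxa-PFT weight matrices keyed by region.

    Layout: columns ``region_id, taxon`` then one column per PFT holding
    weights in [0, 1].  Returns ``{region_id: taxa x PFT DataFrame}``.
    """
    df = pd.read_csv(path)
    required = {"region_id", "taxon"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: missing required columns {required - set(df.columns)}")
    pfts = [c for c in df.columns if c not in required]
    weights = df[pfts].to_numpy(dtype=float)
    if np.any((weights < 0) | (weights > 1)):
        raise ValidationError(f"{path}: PFT weights must lie in [0, 1]")
    out: dict[str, pd.DataFrame] = {}
    for region, grp in df.groupby("region_id", sort=False):
        mat = grp.set_index("taxon")[pfts].astype(float)
        empty = [p for p in pfts if (mat[p] == 0).all()]
        if empty:
            logger.warning("taxa-PFT matrix %s region %s: empty PFT columns %s retained",
                           path, region, empty)
        out[str(region)] = mat
    return out


def write_taxa_pft_matrix(matrices: dict[str, pd.DataFrame], path: str | Path) -> None:
    rows = []
    for region, mat in matrices.items():
        block = mat.reset_index().rename(columns={mat.index.name or "index": "taxon"})
        block.insert(0, "region_id", region)
        rows.append(block)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def pft_coverage_report(fossil_taxa: list[str], matrix: pd.DataFrame) -> dict[str, list[str]]:
    """Which fossil taxa the matrix covers, and which it silently would not."""
    known = set(matrix.index)
    covered = [t for t in fossil_taxa if t in known]
    missing = [t for t in fossil_taxa if t not in known]
    if missing:
        logger.warning("fossil taxa absent from taxa-PFT matrix: %s", missing)
    return {"covered": covered, "missing": missing}


# ------------------------------------------------------------- NetCDF IO

def _get_coord(ds: xr.Dataset, names: tuple[str, ...], path) -> xr.DataArray:
    for n in names:
        if n in ds.coords or n in ds.variables:
            return ds[n]
    raise ValidationError(f"{path}: missing coordinate variable (tried {names})")


def _normalize_lon_axis(ds: xr.Dataset, lon_name: str) -> xr.Dataset:
    lon = ds[lon_name].values
    if lon.max() > 180.0:
        ds = ds.assign_coords({lon_name: ((lon + 180.0) % 360.0) - 180.0})
    return ds.sortby(lon_name)


def read_climate_grid(path: str | Path) -> ClimateGrid:
    """Read a gridded monthly-mean temperature + elevation NetCDF file.

    Temperatures stored in kelvin (units attribute "K" or values clearly
    above 150) are converted to deg C.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    lat = _get_coord(ds, ("lat", "latitude"), path)
    lon = _get_coord(ds, ("lon", "longitude"), path)
    ds = _normalize_lon_axis(ds.sortby(lat.name), lon.name)
    if "temp" not in ds or "elev" not in ds:
        raise ValidationError(f"{path}: expected variables 'temp' (month,lat,lon) and 'elev'")
    temp = ds["temp"].values.astype(float)
    units = str(ds["temp"].attrs.get("units", "")).lower()
    if units in ("k", "kelvin") or np.nanmin(temp) > 150.0:
        temp = temp - 273.15
    return ClimateGrid(
        lat=ds[lat.name].values if lat.name in ds.coords else ds["lat"].values,
        lon=ds[lon.name if lon.name in ds.coords else "lon"].values,
        monthly_temp=temp,
        elev=ds["elev"].values.astype(float),
    )


def write_climate_grid(grid: ClimateGrid, path: str | Path) -> None:
    ds = xr.Dataset(
        {
            "temp": (("month", "lat", "lon"), grid.monthly_temp, {"units": "degC"}),
            "elev": (("lat", "lon"), grid.elev, {"units": "m"}),
        },
        coords={"month": np.arange(1, 13), "lat": grid.lat, "lon": grid.lon},
    )
    ds.to_netcdf(path, **_NETCDF_KW)


def read_topo_field(path: str | Path) -> TopoAnomalyField:
    """Read a time-resolved topographic elevation-anomaly NetCDF field."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    for name in ("time", "lat", "lon"):
        _get_coord(ds, (name, {"lat": "latitude", "lon": "longitude", "time": "time"}[name]), path)
    ds = _normalize_lon_axis(ds.sortby("lat").sortby("time"), "lon")
    if "anomaly" not in ds:
        raise ValidationError(f"{path}: expected variable 'anomaly' (time,lat,lon)")
    return TopoAnomalyField(
        times=ds["time"].values.astype(float),
        lat=ds["lat"].values.astype(float),
        lon=ds["lon"].values.astype(float),
        anomaly=ds["anomaly"].values.astype(float),
    )


def write_topo_field(field: TopoAnomalyField, path: str | Path) -> None:
    ds = xr.Dataset(
        {"anomaly": (("time", "lat", "lon"), field.anomaly, {"units": "m"})},
        coords={"time": ("time", field.times, {"units": "ka BP"}),
                "lat": field.lat, "lon": field.lon},
    )
    ds.to_netcdf(path, **_NETCDF_KW)


# ---------------------------------------------------- curves and controls

def read_calib_curve(path: str | Path) -> CalibCurve:
    """Read a 3-column calibration curve CSV (cal BP, 14C BP, sigma)."""
    df = pd.read_csv(path)
    cols = list(df.columns[:3])
    cal = df[cols[0]].to_numpy(float)
    c14 = df[cols[1]].to_numpy(float)
    sig = df[cols[2]].to_numpy(float)
    if cal.size > 1 and cal[0] > cal[-1]:       # IntCal files are descending
        cal, c14, sig = cal[::-1], c14[::-1], sig[::-1]
    return CalibCurve(cal_age=cal, c14_age=c14, curve_sigma=sig)


def write_calib_curve(curve: CalibCurve, path: str | Path) -> None:
    pd.DataFrame({"cal_bp": curve.cal_age, "c14_bp": curve.c14_age,
                  "sigma": curve.curve_sigma}).to_csv(path, index=False)


def read_age_controls(path: str | Path) -> dict[str, list[AgeControl]]:
    """Read age controls CSV: site_id, depth_cm, kind, age, sigma[, independent]."""
    df = pd.read_csv(path)
    out: dict[str, list[AgeControl]] = {}
    for row in df.itertuples(index=False):
        ctrl = AgeControl(
            depth=float(row.depth_cm),
            kind=str(row.kind),
            age=float(row.age),
            sigma=float(getattr(row, "sigma", 0.0) or 0.0),
            independent=bool(row.independent) if hasattr(row, "independent") else None,
        )
        out.setdefault(str(row.site_id), []).append(ctrl)
    return out


def write_age_controls(controls: dict[str, list[AgeControl]], path: str | Path) -> None:
    rows = [
        {"site_id": sid, "depth_cm": c.depth, "kind": c.kind, "age": c.age,
         "sigma": c.sigma, "independent": c.independent}
        for sid, ctrls in controls.items() for c in ctrls
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ------------------------------------------------------------ config/yaml

def read_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def read_region_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"region_id", "lat_min", "lat_max", "lon_min", "lon_max"}
    if not need.issubset(df.columns):
        raise ValidationError(f"{path}: region table missing {need - set(df.columns)}")
    return df
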