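"""Anomaly conversion, Monte-Carlo binning, gridding and composites.

Each site reconstruction is converted to anomalies relative to its own
last-1000-yr mean and interpolated to 200-yr bins through a Monte-Carlo
ensemble that resamples the sample-specific errors (default 1000 draws;
bin value = ensemble median, bin error = ensemble SD).  Binned series
are averaged onto a 2 deg x 2 deg grid, and regional or hemispheric
composites take a second Monte-Carlo pass across cells, reporting the
per-bin median and 2.5/97.5 percentiles.  Averages are unweighted (an
area-weighting flag exists but defaults off).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import assign_region
from .types import BinnedSeries, ReconSeries, Site, ValidationError

logger = logging.getLogger(__name__)

BIN_WIDTH = 200.0
BIN_ANCHOR = 100.0              # centers 100, 300, ..., 10900 tile 0-11 ka
REFERENCE_MAX_AGE = 1000.0
DEFAULT_CELL_DEG = 2.0
DEFAULT_N_MC = 1000


def default_bins(max_age: float = 11000.0) -> np.ndarray:
    return np.arange(BIN_ANCHOR, max_age, BIN_WIDTH)


def to_binned(recon: ReconSeries, variable: str, n_mc: int = DEFAULT_N_MC,
              seed: int | None = None,
              bin_centers: np.ndarray | None = None) -> BinnedSeries:
    """Monte-Carlo anomaly binning of one site reconstruction.

    Per draw, sample estimates are perturbed by Normal(0, sample error),
    the draw's mean over ages <= 1000 BP is subtracted, and the perturbed
    series is linearly interpolated to the bin centers covered by the
    record's age span.  Bins outside the span stay missing (NaN).
    """
    if bin_centers is None:
        bin_centers = default_bins()
    table = recon.table
    ok = table[variable].notna().to_numpy()
    ages = table["age"].to_numpy()[ok]
    est = table[variable].to_numpy()[ok]
    err = table.get(f"{variable}_error",
                    pd.Series(np.zeros(len(table)))).to_numpy()[ok]
    if ages.size < 2:
        raise ValidationError(f"record {recon.site.site_id}: <2 usable samples")
    ref = ages <= REFERENCE_MAX_AGE
    if not ref.any():
        raise ValidationError(
            f"record {recon.site.site_id}: no samples in the last-1000-yr "
            "reference window (should have been screened out)")
    order = np.argsort(ages, kind="stable")
    ages, est, err = ages[order], est[order], err[order]
    ref = ages <= REFERENCE_MAX_AGE
    rng = np.random.default_rng(seed)
    covered = (bin_centers >= ages[0]) & (bin_centers <= ages[-1])
    draws = est[None, :] + rng.standard_normal((n_mc, ages.size)) * err[None, :]
    draws = draws - draws[:, ref].mean(axis=1, keepdims=True)
    binned = np.full((n_mc, bin_centers.size), np.nan)
    for b in range(n_mc):
        binned[b, covered] = np.interp(bin_centers[covered], ages, draws[b])
    anom = np.full(bin_centers.size, np.nan)
    sd = np.full(bin_centers.size, np.nan)
    anom[covered] = np.median(binned[:, covered], axis=0)
    sd[covered] = binned[:, covered].std(axis=0, ddof=1)
    half = BIN_WIDTH / 2.0
    n_contrib = np.array([
        int(np.sum((ages >= c - half) & (ages < c + half))) if cv else 0
        for c, cv in zip(bin_centers, covered)])
    return BinnedSeries(site=recon.site, variable=variable,
                        bin_centers=bin_centers, anomaly=anom, bin_se=sd,
                        bin_sem=sd / np.sqrt(n_mc), n_contributing=n_contrib)


@dataclass
class GridCells:
    """Cell-mean anomalies: one row per 2 deg x 2 deg cell, columns = bins."""

    cell_lat: np.ndarray            # cell-center latitudes
    cell_lon: np.ndarray
    bin_centers: np.ndarray
    anomaly: np.ndarray             # cells x bins (NaN where empty)
    se: np.ndarray                  # propagated SE of the cell mean
    n_sites: np.ndarray             # cells x bins


def grid_average(binned: list[BinnedSeries],
                 cell_size: float = DEFAULT_CELL_DEG) -> GridCells:
    """Average binned site series onto a regular lat/lon grid.

    Cell membership uses [lower, upper) bounds on both axes; a site on a
    cell edge belongs to the higher-index cell.  Cell SE assumes site
    independence: sqrt(sum se^2) / n.
    """
    if not binned:
        raise ValidationError("no binned series to grid")
    centers = binned[0].bin_centers
    for b in binned:
        if not np.array_equal(b.bin_centers, centers):
            raise ValidationError("binned series use different bin lattices")
    keys = {}
    for b in binned:
        i = int(np.floor((b.site.lat + 90.0) / cell_size))
        j = int(np.floor((b.site.lon + 180.0) / cell_size))
        keys.setdefault((i, j), []).append(b)
    cell_lat, cell_lon, anom_rows, se_rows, n_rows = [], [], [], [], []
    for (i, j), members in sorted(keys.items()):
        cell_lat.append(-90.0 + (i + 0.5) * cell_size)
        cell_lon.append(-180.0 + (j + 0.5) * cell_size)
        A = np.vstack([m.anomaly for m in members])
        S = np.vstack([m.bin_se for m in members])
        present = ~np.isnan(A)
        n = present.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.where(n > 0, np.nansum(np.where(present, A, 0.0), axis=0)
                            / np.maximum(n, 1), np.nan)
            se = np.where(n > 0,
                          np.sqrt(np.nansum(np.where(present, S**2, 0.0), axis=0))
                          / np.maximum(n, 1), np.nan)
        anom_rows.append(mean)
        se_rows.append(se)
        n_rows.append(n)
    return GridCells(cell_lat=np.array(cell_lat), cell_lon=np.array(cell_lon),
                     bin_centers=centers, anomaly=np.vstack(anom_rows),
                     se=np.vstack(se_rows), n_sites=np.vstack(n_rows))


def composite(cells: GridCells, n_mc: int = DEFAULT_N_MC,
              seed: int | None = None, region: str | None = None,
              area_weighted: bool = False) -> pd.DataFrame:
    """Monte-Carlo composite across grid cells.

    Per draw, each cell series is perturbed by Normal(0, cell SE) and
    cells are averaged per bin over those with data; the composite is the
    per-bin median and 2.5/97.5 percentiles across draws, with the count
    of contributing cells.  ``region`` filters cells by region box.
    """
    sel = np.ones(cells.anomaly.shape[0], dtype=bool)
    if region is not None and region != "NH":
        sel = np.array([assign_region(la, lo) == region
                        for la, lo in zip(cells.cell_lat, cells.cell_lon)])
    if not sel.any():
        raise ValidationError(f"no grid cells in region {region!r}")
    A = cells.anomaly[sel]
    S = cells.se[sel]
    w = np.cos(np.radians(cells.cell_lat[sel])) if area_weighted \
        else np.ones(sel.sum())
    rng = np.random.default_rng(seed)
    present = ~np.isnan(A)
    n_cells = present.sum(axis=0)
    A0 = np.where(present, A, 0.0)
    S0 = np.where(present, np.nan_to_num(S), 0.0)
    wsum = (w[:, None] * present).sum(axis=0)
    covered = n_cells > 0
    draws = np.empty((n_mc, int(covered.sum())))
    for b in range(n_mc):
        pert = A0 + rng.standard_normal(A.shape) * S0
        draws[b] = ((w[:, None] * np.where(present, pert, 0.0)).sum(axis=0)
                    / np.where(wsum > 0, wsum, np.nan))[covered]
    med = np.full(cells.bin_centers.size, np.nan)
    lo95 = np.full_like(med, np.nan)
    hi95 = np.full_like(med, np.nan)
    med[covered] = np.median(draws, axis=0)
    lo95[covered] = np.percentile(draws, 2.5, axis=0)
    hi95[covered] = np.percentile(draws, 97.5, axis=0)
    return pd.DataFrame({
        "bin_center": cells.bin_centers,
        "median": med,
        "lower95": lo95,
        "upper95": hi95,
        "n_cells": n_cells,
    })


def seasonality(summer: pd.DataFrame, winter: pd.DataFrame) -> pd.DataFrame:
    """Summer-minus-winter composite with quadrature-combined bands.

    Assumes the two composites' uncertainties are independent (flagged
    assumption; they share sites).
    """
    if not np.array_equal(summer["bin_center"].to_numpy(),
                          winter["bin_center"].to_numpy()):
        raise ValidationError("seasonality requires aligned bins")
    diff = summer["median"] - winter["median"]
    hw_s = (summer["upper95"] - summer["lower95"]) / 2.0
    hw_w = (winter["upper95"] - winter["lower95"]) / 2.0
    hw = np.sqrt(hw_s**2 + hw_w**2)
    return pd.DataFrame({
        "bin_center": summer["bin_center"],
        "median": diff,
        "lower95": diff - hw,
        "upper95": diff + hw,
        "n_cells": np.minimum(summer["n_cells"], winter["n_cells"]),
    })


def fit_trend(curve: pd.DataFrame, window: tuple[float, float]) -> tuple[float, float]:
    """OLS temperature trend over an age window, in deg C per ka.

    ``window`` is (young, old) in ka BP.  Sign convention: positive rate
    means warming toward the present (rate = -d(anomaly)/d(age)).
    Returns (rate, standard error).
    """
    lo, hi = sorted(window)
    ages_ka = curve["bin_center"].to_numpy() / 1000.0
    sel = (ages_ka >= lo) & (ages_ka <= hi) & curve["median"].notna().to_numpy()
    if sel.sum() < 3:
        raise ValidationError(f"fewer than 3 bins in window [{lo}, {hi}] ka")
    x = ages_ka[sel]
    y = curve["median"].to_numpy()[sel]
    X = np.column_stack([np.ones_like(x), x])
    beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(sel.sum() - 2, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    return float(-beta[1]), float(np.sqrt(cov[1, 1]))
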