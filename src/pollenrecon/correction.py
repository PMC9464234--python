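"""Glacio-isostatic correction of reconstructed temperatures.

Post-glacial rebound changes a site's surface elevation through time; a
reconstruction therefore mixes climate change with a topographic lapse
effect.  The correction interpolates an elevation-anomaly history to the
site (inverse-distance weighting in space, linear in time), estimates
present-day local lapse rates by regressing gridded temperature on
elevation within a radius (default 300 km), and subtracts the
topography-induced component: corrected(t) = estimate(t) - rate *
delta_elev(t).  With delta_elev > 0 (past surface higher than present)
and a negative lapse rate the topographic component is a cooling, so the
correction raises the estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .transfer import haversine_km
from .types import (
    ClimateGrid,
    ReconSeries,
    Site,
    TopoAnomalyField,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_RADIUS_KM = 300.0
IDW_POWER = 2
IDW_NEIGHBOURS = 4


@dataclass
class LapseRate:
    """Per-variable local lapse rates (deg C per metre, typically negative)."""

    annt: float
    mtwa: float
    mtco: float
    n_cells: int
    radius: float

    def __post_init__(self) -> None:
        if self.n_cells < 3:
            raise ValidationError("lapse rate needs >= 3 grid cells")
        if self.radius <= 0:
            raise ValidationError("lapse radius must be > 0")

    def rate(self, variable: str) -> float:
        return getattr(self, variable)


@dataclass
class TopoHistory:
    """Elevation anomaly history (m relative to present) at one site."""

    times: np.ndarray               # ka BP, ascending
    delta_elev: np.ndarray          # m

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.delta_elev = np.asarray(self.delta_elev, dtype=float)
        i0 = int(np.argmin(np.abs(self.times)))
        if abs(self.times[i0]) < 1e-9 and abs(self.delta_elev[i0]) > 1e-9:
            raise ValidationError("delta_elev must be 0 at time 0")

    def at(self, ages_ka: np.ndarray) -> np.ndarray:
        """Linear interpolation in time; end values held outside the span."""
        ages_ka = np.asarray(ages_ka, dtype=float)
        if np.any(ages_ka > self.times[-1]) or np.any(ages_ka < self.times[0]):
            logger.warning("topo history extrapolated beyond [%s, %s] ka",
                           self.times[0], self.times[-1])
        return np.interp(ages_ka, self.times, self.delta_elev)


def topo_history_at_site(field: TopoAnomalyField, site: Site,
                         power: int = IDW_POWER,
                         n_neighbours: int = IDW_NEIGHBOURS) -> TopoHistory:
    """Interpolate the anomaly field to a site by inverse-distance weighting.

    The ``n_neighbours`` nearest grid nodes (great-circle distance)
    contribute with weight 1/d^power; an exact node hit returns the node
    series.
    """
    if not (field.lat.min() <= site.lat <= field.lat.max()
            and field.lon.min() <= site.lon <= field.lon.max()):
        raise ValidationError(f"site {site.site_id} outside topo field bounds")
    glat, glon = np.meshgrid(field.lat, field.lon, indexing="ij")
    d = haversine_km(site.lat, site.lon, glat.ravel(), glon.ravel())
    flat = field.anomaly.reshape(field.times.size, -1)
    nearest = np.argsort(d, kind="stable")[:n_neighbours]
    dn = d[nearest]
    if dn[0] < 1e-9:
        series = flat[:, nearest[0]]
    else:
        w = 1.0 / dn**power
        series = flat[:, nearest] @ (w / w.sum())
    return TopoHistory(times=field.times, delta_elev=series)


def local_lapse_rate(grid: ClimateGrid, site: Site,
                     radius_km: float = DEFAULT_RADIUS_KM,
                     detrend_latlon: bool = False,
                     min_elev_range: float = 0.0) -> LapseRate:
    """OLS lapse rates of ANNT/MTWA/MTCO against elevation near a site.

    With ``detrend_latlon`` the regression adds lat/lon covariates, so the
    elevation slope is the partial lapse rate with the broad horizontal
    gradient absorbed — more robust where the disc spans a strong
    meridional gradient.  ``min_elev_range`` rejects discs with too little
    relief to constrain a slope (site flagged uncorrectable upstream).
    """
    glat, glon = np.meshgrid(grid.lat, grid.lon, indexing="ij")
    d = haversine_km(site.lat, site.lon, glat.ravel(), glon.ravel())
    sel = d <= radius_km
    need = 5 if detrend_latlon else 3
    if sel.sum() < need:
        raise ValidationError(
            f"site {site.site_id}: only {int(sel.sum())} grid cells within "
            f"{radius_km} km (need >= {need})")
    elev = grid.elev.ravel()[sel]
    if np.ptp(elev) <= max(min_elev_range, 0.0):
        raise ValidationError(f"site {site.site_id}: elevation range "
                              f"{np.ptp(elev):.0f} m too small within the "
                              "lapse radius")
    months = grid.monthly_temp.reshape(12, -1)[:, sel]
    values = {
        "annt": months.mean(axis=0),
        "mtwa": months.max(axis=0),
        "mtco": months.min(axis=0),
    }
    cols = [np.ones_like(elev)]
    if detrend_latlon:
        cols += [glat.ravel()[sel], glon.ravel()[sel]]
    cols.append(elev)
    X = np.column_stack(cols)
    rates = {}
    for v, y in values.items():
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rates[v] = float(beta[-1])
    return LapseRate(annt=rates["annt"], mtwa=rates["mtwa"], mtco=rates["mtco"],
                     n_cells=int(sel.sum()), radius=float(radius_km))


def isostatic_correct(recon: ReconSeries, topo: TopoHistory,
                      lapse: LapseRate) -> ReconSeries:
    """Subtract the topography-induced temperature component per sample.

    Sample errors are unchanged.  A flag on the series guards against
    accidental double correction.
    """
    if recon.isostatically_corrected:
        raise ValidationError(
            f"record {recon.site.site_id} already isostatically corrected")
    table = recon.table.copy()
    ages_ka = table["age"].to_numpy() / 1000.0
    delta = topo.at(ages_ka)
    for v in ("annt", "mtwa", "mtco"):
        if v in table.columns:
            table[v] = table[v] - lapse.rate(v) * delta
    table["topo_correction_m"] = delta
    logger.info("site %s: isostatic correction up to %.2f m (%.2f deg C in annt)",
                recon.site.site_id, np.nanmax(np.abs(delta)),
                np.nanmax(np.abs(lapse.annt * delta)))
    return ReconSeries(site=recon.site, table=table,
                       analogue_ids=recon.analogue_ids,
                       isostatically_corrected=True)
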