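"""Radiocarbon recalibration, age-depth models and record screening.

Calibration follows the standard probabilistic scheme: the posterior over
calendar age theta is proportional to a normal likelihood of the measured
14C age at the curve's 14C age, with measurement and curve errors added
in quadrature.  Age-depth models are piecewise-linear through calibrated
point ages.  Screening applies the record- and sample-level quality rules
used for continental-scale Holocene syntheses:

* a record needs more than three chronological controls, at least two of
  them independent dates;
* samples must be within 1 kyr of a date or bracketed by dates no more
  than 6 kyr apart, and carry at least 200 pollen grains;
* the record must span more than 5 kyr, reach younger than 1 ka BP, and
  resolve finer than 400 yr (1000 yr in northern Asia, where coverage is
  sparse).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import (
    AgeControl,
    AgeModel,
    CalibCurve,
    ClimateGrid,
    ClimateTriple,
    FossilRecord,
    PollenCounts,
    Site,
    ValidationError,
)

logger = logging.getLogger(__name__)

# default sample/record screening thresholds
MIN_POLLEN_COUNT = 200
NEAR_DATE_YR = 1000.0
BRACKET_YR = 6000.0
MIN_DURATION_YR = 5000.0
TOP_SAMPLE_YR = 1000.0
RESOLUTION_YR = 400.0
RESOLUTION_YR_RELAXED = 1000.0
RELAXED_REGIONS = ("N_AS",)
MIN_CONTROLS = 4           # "more than three chronological controls"
MIN_INDEPENDENT = 2
DEFAULT_LAPSE = -0.0065    # deg C per m, used when no local rate is supplied


@dataclass
class CalibrationResult:
    point_age: float            # posterior mean, cal yr BP
    age_sd: float               # posterior SD, yr
    cal_grid: np.ndarray
    density: np.ndarray         # normalized posterior on cal_grid


def calibrate_c14(age14c: float, sigma: float, curve: CalibCurve) -> CalibrationResult:
    """Calibrate one radiocarbon date against a calibration curve.

    Returns the posterior mean and SD plus the tabulated posterior on the
    curve's calendar grid (normalized by trapezoidal quadrature).
    """
    if sigma <= 0:
        raise ValidationError("radiocarbon sigma must be > 0")
    lo = curve.c14_age.min()
    hi = curve.c14_age.max()
    if not (lo - 5 * sigma <= age14c <= hi + 5 * sigma):
        raise ValidationError(
            f"14C age {age14c} +/- {sigma} outside curve support [{lo}, {hi}]"
        )
    total_sd = np.sqrt(sigma**2 + curve.curve_sigma**2)
    z = (age14c - curve.c14_age) / total_sd
    log_dens = -0.5 * z**2 - np.log(total_sd)
    dens = np.exp(log_dens - log_dens.max())
    norm = np.trapezoid(dens, curve.cal_age)
    if norm <= 0 or not np.isfinite(norm):
        raise ValidationError("zero-density calibration posterior")
    dens = dens / norm
    mean = np.trapezoid(dens * curve.cal_age, curve.cal_age)
    var = np.trapezoid(dens * (curve.cal_age - mean) ** 2, curve.cal_age)
    return CalibrationResult(point_age=float(mean), age_sd=float(np.sqrt(max(var, 0.0))),
                             cal_grid=curve.cal_age, density=dens)


def build_age_model(controls: list[AgeControl], depths: np.ndarray,
                    curve: CalibCurve | None = None) -> AgeModel:
    """Piecewise-linear age-depth model through calibrated control points.

    Radiocarbon controls are calibrated first (posterior mean); other
    control kinds enter with their stated calendar age.  Samples outside
    the dated depth span are linearly extrapolated and flagged.
    """
    if len(controls) < 2:
        raise ValidationError("age model needs at least 2 control points")
    pts = []
    for c in controls:
        if c.kind == "c14":
            if curve is None:
                raise ValidationError("radiocarbon controls require a calibration curve")
            pts.append((c.depth, calibrate_c14(c.age, c.sigma, curve).point_age))
        else:
            pts.append((c.depth, c.age))
    pts.sort(key=lambda t: t[0])
    cd = np.array([p[0] for p in pts])
    ca = np.array([p[1] for p in pts])
    rev = np.nonzero(np.diff(ca) < 0)[0]
    if rev.size:
        i = int(rev[0])
        raise ValidationError(
            f"age reversal between controls at depths {cd[i]} cm ({ca[i]:.0f} BP) "
            f"and {cd[i + 1]} cm ({ca[i + 1]:.0f} BP)"
        )
    depths = np.asarray(depths, dtype=float)
    # piecewise-linear interior; linear extrapolation from the end segments
    ages = np.interp(depths, cd, ca)
    below = depths < cd[0]
    above = depths > cd[-1]
    if cd.size >= 2:
        s0 = (ca[1] - ca[0]) / (cd[1] - cd[0])
        s1 = (ca[-1] - ca[-2]) / (cd[-1] - cd[-2])
        ages[below] = ca[0] + s0 * (depths[below] - cd[0])
        ages[above] = ca[-1] + s1 * (depths[above] - cd[-1])
    flags = []
    for d in depths:
        if np.any(np.isclose(d, cd)):
            flags.append("direct")
        elif d < cd[0] or d > cd[-1]:
            flags.append("extrapolated")
        else:
            flags.append("interpolated")
    return AgeModel(control_depths=cd, control_ages=ca,
                    sample_depths=depths, sample_ages=ages, flags=flags)


def screen_samples(model: AgeModel, counts: PollenCounts,
                   min_count: float = MIN_POLLEN_COUNT,
                   near_yr: float = NEAR_DATE_YR,
                   bracket_yr: float = BRACKET_YR) -> np.ndarray:
    """Boolean retention mask over samples.

    Retained iff (the nearest dated control is within ``near_yr`` of the
    sample age, OR the sample lies between two controls no more than
    ``bracket_yr`` apart in age) AND total pollen count >= ``min_count``.
    """
    if model.sample_depths.shape != counts.depths.shape or \
            not np.allclose(model.sample_depths, counts.depths):
        raise ValidationError("age model and counts are not aligned by depth")
    ctrl = np.sort(model.control_ages)
    mask = np.zeros(len(counts.sample_ids), dtype=bool)
    totals = counts.totals
    for i, age in enumerate(model.sample_ages):
        near = np.min(np.abs(ctrl - age)) <= near_yr
        bracketed = False
        j = np.searchsorted(ctrl, age)
        if 0 < j < ctrl.size:
            bracketed = (ctrl[j] - ctrl[j - 1]) <= bracket_yr
        mask[i] = (near or bracketed) and totals[i] >= min_count
    return mask


def screen_record(record: FossilRecord, region_id: str | None = None,
                  holocene_max_yr: float = 11000.0) -> tuple[bool, list[str]]:
    """Apply the record-level screening criteria; returns (pass, reasons)."""
    region_id = region_id if region_id is not None else record.site.region_id
    reasons: list[str] = []
    controls = record.controls
    if len(controls) < MIN_CONTROLS:
        reasons.append(f"only {len(controls)} chronological controls (need >3)")
    n_indep = sum(1 for c in controls if c.independent)
    if n_indep < MIN_INDEPENDENT:
        reasons.append(f"only {n_indep} independent dates (need >=2)")
    ages = np.sort(record.sample_ages)
    duration = ages[-1] - ages[0] if ages.size else 0.0
    if duration <= MIN_DURATION_YR:
        reasons.append(f"duration {duration:.0f} yr (need >5000)")
    if ages.size == 0 or ages[0] > TOP_SAMPLE_YR:
        reasons.append("no sample younger than 1000 BP")
    holo = ages[ages <= holocene_max_yr]
    limit = RESOLUTION_YR_RELAXED if region_id in RELAXED_REGIONS else RESOLUTION_YR
    if holo.size >= 2:
        med = float(np.median(np.diff(holo)))
        if med >= limit:
            reasons.append(f"median sampling interval {med:.0f} yr (limit {limit:.0f})")
    else:
        reasons.append("fewer than 2 Holocene samples")
    return (len(reasons) == 0, reasons)


# ------------------------------------------------- modern climate at sites

def _bilinear(grid_ax: np.ndarray, x: float) -> tuple[int, int, float]:
    """Index pair and weight for 1-D linear interpolation, clamped to bounds."""
    if x < grid_ax[0] or x > grid_ax[-1]:
        raise ValidationError(f"coordinate {x} outside grid [{grid_ax[0]}, {grid_ax[-1]}]")
    j = int(np.clip(np.searchsorted(grid_ax, x) - 1, 0, grid_ax.size - 2))
    t = (x - grid_ax[j]) / (grid_ax[j + 1] - grid_ax[j])
    return j, j + 1, float(t)


def assign_site_climate(site: Site, grid: ClimateGrid,
                        lapse_rate: float = DEFAULT_LAPSE) -> ClimateTriple:
    """Modern ANNT/MTWA/MTCO at a site from the gridded climatology.

    Monthly temperatures are interpolated bilinearly in lat/lon, then
    shifted by ``lapse_rate * (site elevation - interpolated grid
    elevation)``.  ANNT/MTWA/MTCO are the mean/max/min of the adjusted
    monthly cycle, so mtco <= annt <= mtwa holds by construction.
    """
    i0, i1, u = _bilinear(grid.lat, site.lat)
    j0, j1, v = _bilinear(grid.lon, site.lon)
    w = np.array([(1 - u) * (1 - v), (1 - u) * v, u * (1 - v), u * v])
    sel = [(i0, j0), (i0, j1), (i1, j0), (i1, j1)]
    months = sum(wk * grid.monthly_temp[:, i, j] for wk, (i, j) in zip(w, sel))
    elev = sum(wk * grid.elev[i, j] for wk, (i, j) in zip(w, sel))
    months = months + lapse_rate * (site.elev - elev)
    return ClimateTriple(annt=float(months.mean()),
                         mtwa=float(months.max()),
                         mtco=float(months.min()))
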