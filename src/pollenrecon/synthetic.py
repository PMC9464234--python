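"""Synthetic inputs with recorded ground truth for recovery testing.

The generator emulates the statistical structure of the real inputs:
taxa respond unimodally (Gaussian niches) to winter and summer
temperature; pollen counting is multinomial; MTCO and MTWA fields carry
a controllable Pearson correlation (regional calibration sets show
R = 0.35-0.76); fossil records are sparsely dated with Gaussian
radiocarbon errors; glacio-isostatic uplift decays smoothly to zero at
present.  Every function is a pure function of its seed.

The default "Holocene-like" truth imposes winter warming of 4.0 deg C
and summer warming of 1.4 deg C over 11-7 ka BP, then winter cooling of
0.7 deg C and summer cooling of 0.5 deg C to the present.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .chronology import assign_site_climate
from .pft import compute_pft_scores, to_proportions
from .regions import assign_region
from .types import (
    AgeControl,
    CalibCurve,
    CalibrationSet,
    ClimateGrid,
    ClimateTriple,
    FossilRecord,
    PollenCounts,
    Site,
    SyntheticTruth,
    TopoAnomalyField,
    ValidationError,
)

logger = logging.getLogger(__name__)

LAPSE = -0.0065                  # deg C / m imposed on the synthetic grids


def _bump_field(lat: np.ndarray, lon: np.ndarray, rng: np.random.Generator,
                n_bumps: int = 8, scale_deg: float = 25.0) -> np.ndarray:
    """Smooth random field as a sum of broad Gaussian bumps."""
    glat, glon = np.meshgrid(lat, lon, indexing="ij")
    out = np.zeros_like(glat)
    for _ in range(n_bumps):
        c_lat = rng.uniform(lat.min(), lat.max())
        c_lon = rng.uniform(lon.min(), lon.max())
        amp = rng.normal(0.0, 1.0)
        s = rng.uniform(0.6, 1.4) * scale_deg
        dlon = np.minimum(np.abs(glon - c_lon), 360.0 - np.abs(glon - c_lon))
        out += amp * np.exp(-((glat - c_lat) ** 2 + dlon**2) / (2 * s**2))
    return out


def _standardize(f: np.ndarray) -> np.ndarray:
    return (f - f.mean()) / f.std()


def make_climate_field(n_lat: int = 51, n_lon: int = 144,
                       corr_target: float = 0.6,
                       seed: int | None = None,
                       lat_range: tuple[float, float] = (25.0, 75.0),
                       lon_range: tuple[float, float] = (-177.5, 177.5),
                       mtco_mean: float = -12.0, mtco_sd: float = 12.0,
                       mtwa_mean: float = 16.0, mtwa_sd: float = 5.0,
                       max_attempts: int = 50) -> ClimateGrid:
    """Smooth MTCO/MTWA fields with a target cross-cell Pearson r.

    MTCO combines a latitudinal gradient with broad random bumps; MTWA
    mixes that field with an independent smooth field, the mixing weight
    tuned so the sample correlation over cells lands within +/-0.05 of
    ``corr_target`` (after the imposed elevation lapse).  The monthly
    cycle is a sinusoid between MTCO (January) and MTWA (July), so ANNT
    is their midpoint by construction.
    """
    if not 0 <= corr_target < 1:
        raise ValidationError("corr_target must be in [0, 1)")
    rng = np.random.default_rng(seed)
    lat = np.linspace(*lat_range, n_lat)
    lon = np.linspace(*lon_range, n_lon)
    glat, _ = np.meshgrid(lat, lon, indexing="ij")
    grad = -(glat - glat.mean()) / np.ptp(lat)           # poleward cooling
    f1 = _standardize(3.0 * grad + _bump_field(lat, lon, rng))
    e2 = _bump_field(lat, lon, rng)
    e2 = e2 - (e2 * f1).mean() / (f1 * f1).mean() * f1   # orthogonalize
    e2 = _standardize(e2)
    # textured orography: broad ranges plus short-wavelength relief so a
    # local lapse regression is well-posed everywhere
    elev = np.clip(500.0 + 600.0 * _bump_field(lat, lon, rng, n_bumps=6,
                                               scale_deg=12.0)
                   + 500.0 * _bump_field(lat, lon, rng, n_bumps=40,
                                         scale_deg=3.0), 0.0, None)
    rho = corr_target
    for attempt in range(max_attempts):
        mix = rho * f1 + np.sqrt(max(0.0, 1 - rho**2)) * e2
        mtco = mtco_mean + mtco_sd * f1 + LAPSE * elev
        mtwa = mtwa_mean + mtwa_sd * _standardize(mix) + LAPSE * elev
        mtwa = np.maximum(mtwa, mtco + 2.0)              # summer above winter
        achieved = np.corrcoef(mtco.ravel(), mtwa.ravel())[0, 1]
        if abs(achieved - corr_target) <= 0.045:
            break
        rho = float(np.clip(rho + 0.8 * (corr_target - achieved), -0.999, 0.999))
    else:
        raise ValidationError(
            f"could not reach correlation {corr_target} in {max_attempts} attempts "
            f"(achieved {achieved:.3f})")
    mid = (mtco + mtwa) / 2.0
    half = (mtwa - mtco) / 2.0
    months = np.arange(1, 13)
    cycle = np.cos(2 * np.pi * (months - 7) / 12.0)      # +1 in July, -1 in January
    monthly = mid[None] + cycle[:, None, None] * half[None]
    return ClimateGrid(lat=lat, lon=lon, monthly_temp=monthly, elev=elev)


# ----------------------------------------------------------------- niches

def make_niches(n_taxa: int = 24, seed: int | None = None,
                mtco_range: tuple[float, float] = (-38.0, 12.0),
                mtwa_range: tuple[float, float] = (4.0, 28.0)) -> pd.DataFrame:
    """Gaussian niche parameters tiling the climate space with overlap.

    MTWA optima track MTCO optima (warm-winter taxa also like warm
    summers) with scatter, so the taxon pool carries independent
    information on both variables.
    """
    rng = np.random.default_rng(seed)
    opt_c = np.sort(rng.uniform(*mtco_range, size=n_taxa))
    slope = (mtwa_range[1] - mtwa_range[0]) / (mtco_range[1] - mtco_range[0])
    opt_w = (mtwa_range[0] + slope * (opt_c - mtco_range[0])
             + rng.normal(0.0, 4.0, size=n_taxa))
    opt_w = np.clip(opt_w, *mtwa_range)
    return pd.DataFrame({
        "taxon": [f"taxon_{i:02d}" for i in range(n_taxa)],
        "optimum_mtco": opt_c,
        "tolerance_mtco": rng.uniform(4.0, 9.0, size=n_taxa),
        "optimum_mtwa": opt_w,
        "tolerance_mtwa": rng.uniform(4.0, 9.0, size=n_taxa),
        "max_abundance": np.exp(rng.normal(0.0, 0.4, size=n_taxa)),
    }).set_index("taxon")


def make_taxa_pft_matrix(niches: pd.DataFrame,
                         n_mtco_bins: int = 4, n_mtwa_bins: int = 2) -> pd.DataFrame:
    """Group taxa into PFTs by their joint niche optima (binned grid)."""
    qc = pd.qcut(niches["optimum_mtco"], n_mtco_bins, labels=False, duplicates="drop")
    qw = pd.qcut(niches["optimum_mtwa"], n_mtwa_bins, labels=False, duplicates="drop")
    pft_names = sorted({f"pft_c{c}_w{w}" for c, w in zip(qc, qw)})
    mat = pd.DataFrame(0.0, index=niches.index, columns=pft_names)
    for taxon, c, w in zip(niches.index, qc, qw):
        mat.loc[taxon, f"pft_c{c}_w{w}"] = 1.0
    return mat


def expected_proportions(mtco: float, mtwa: float, niches: pd.DataFrame) -> np.ndarray:
    rel = (niches["max_abundance"].to_numpy()
           * np.exp(-((mtco - niches["optimum_mtco"].to_numpy()) ** 2)
                    / (2 * niches["tolerance_mtco"].to_numpy() ** 2))
           * np.exp(-((mtwa - niches["optimum_mtwa"].to_numpy()) ** 2)
                    / (2 * niches["tolerance_mtwa"].to_numpy() ** 2)))
    total = rel.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValidationError("all expected abundances are zero at this climate")
    return rel / total


def sample_counts(climate: ClimateTriple, niches: pd.DataFrame,
                  total_count: int, seed: int | None = None,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """One multinomial pollen count vector at the given climate."""
    if total_count < 1:
        raise ValidationError("total_count must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    p = expected_proportions(climate.mtco, climate.mtwa, niches)
    return rng.multinomial(total_count, p)


# -------------------------------------------------------- calibration set

def _interp_site_elev(field: ClimateGrid, lat: float, lon: float) -> float:
    i = int(np.clip(np.searchsorted(field.lat, lat) - 1, 0, field.lat.size - 2))
    j = int(np.clip(np.searchsorted(field.lon, lon) - 1, 0, field.lon.size - 2))
    u = (lat - field.lat[i]) / (field.lat[i + 1] - field.lat[i])
    v = (lon - field.lon[j]) / (field.lon[j + 1] - field.lon[j])
    e = field.elev
    return float((1 - u) * (1 - v) * e[i, j] + (1 - u) * v * e[i, j + 1]
                 + u * (1 - v) * e[i + 1, j] + u * v * e[i + 1, j + 1])


def random_sites(n_sites: int, field: ClimateGrid, rng: np.random.Generator,
                 clustered: bool = False, prefix: str = "site") -> list[Site]:
    if n_sites < 1:
        raise ValidationError("need at least one site")
    lat_lo, lat_hi = field.lat.min(), field.lat.max()
    lon_lo, lon_hi = field.lon.min(), field.lon.max()
    if clustered:
        n_clusters = max(3, n_sites // 12)
        centers = np.column_stack([
            rng.uniform(lat_lo + 3, lat_hi - 3, n_clusters),
            rng.uniform(lon_lo + 3, lon_hi - 3, n_clusters),
        ])
        pick = rng.integers(0, n_clusters, n_sites)
        lats = np.clip(centers[pick, 0] + rng.normal(0, 1.0, n_sites), lat_lo, lat_hi)
        lons = np.clip(centers[pick, 1] + rng.normal(0, 1.5, n_sites), lon_lo, lon_hi)
    else:
        lats = rng.uniform(lat_lo, lat_hi, n_sites)
        lons = rng.uniform(lon_lo, lon_hi, n_sites)
    sites = []
    for i, (la, lo) in enumerate(zip(lats, lons)):
        elev = _interp_site_elev(field, la, lo)
        sites.append(Site(site_id=f"{prefix}_{i:04d}", lat=float(la), lon=float(lo),
                          elev=elev, region_id=assign_region(la, lo)))
    return sites


def make_calibration_set(n_sites: int, field: ClimateGrid, niches: pd.DataFrame,
                         total_count: int = 400, seed: int | None = None,
                         clustered: bool = False,
                         pft_matrix: pd.DataFrame | None = None,
                         theta: float = 0.005) -> CalibrationSet:
    """Modern surface samples: multinomial assemblages + grid climate.

    With ``pft_matrix`` the feature matrix holds PFT scores (the standard
    pipeline route); without it, taxon proportions.
    """
    rng = np.random.default_rng(seed)
    sites = random_sites(n_sites, field, rng, clustered=clustered, prefix="surf")
    climates = [assign_site_climate(s, field, lapse_rate=LAPSE) for s in sites]
    counts = np.vstack([sample_counts(c, niches, total_count, rng=rng)
                        for c in climates])
    pc = PollenCounts(sample_ids=[s.site_id for s in sites],
                      depths=np.arange(n_sites, dtype=float),
                      taxa=list(niches.index), counts=counts)
    props = to_proportions(pc)
    climate = pd.DataFrame({v: [getattr(c, v) for c in climates]
                            for v in ("annt", "mtwa", "mtco")})
    if pft_matrix is not None:
        scores = compute_pft_scores(props, list(niches.index), pft_matrix,
                                    theta=theta, sample_ids=pc.sample_ids)
        return CalibrationSet(sites=sites, feature_names=scores.pfts,
                              features=scores.scores, climate=climate,
                              feature_kind="pft")
    return CalibrationSet(sites=sites, feature_names=list(niches.index),
                          features=props, climate=climate, feature_kind="taxa")


# ----------------------------------------------------------- truth + fossil

def holocene_truth(winter_rise: float = 4.0, winter_fall: float = 0.7,
                   summer_rise: float = 1.4, summer_fall: float = 0.5,
                   turn_ka: float = 7.0) -> dict:
    """Default anomaly histories: rise to a mid-Holocene optimum, then fall.

    Anomalies are relative to the present; e.g. winter at 11 ka is
    (fall - rise) below present, peaking at +fall at the turning point.
    """
    knots = np.array([0.0, turn_ka * 1000.0, 11000.0])
    mtco_vals = np.array([0.0, winter_fall, winter_fall - winter_rise])
    mtwa_vals = np.array([0.0, summer_fall, summer_fall - summer_rise])

    def f_mtco(age):
        return np.interp(np.asarray(age, float), knots, mtco_vals)

    def f_mtwa(age):
        return np.interp(np.asarray(age, float), knots, mtwa_vals)

    def f_annt(age):
        return (f_mtco(age) + f_mtwa(age)) / 2.0

    return {"mtco": f_mtco, "mtwa": f_mtwa, "annt": f_annt}


def make_calib_curve(kind: str = "wiggly", seed: int | None = None,
                     max_cal: float = 13000.0, step: float = 10.0,
                     amplitude: float = 40.0, period: float = 2000.0) -> CalibCurve:
    """Synthetic calibration curve: identity, linear or wiggly-but-monotone."""
    cal = np.arange(0.0, max_cal + step, step)
    if kind == "identity":
        return CalibCurve(cal_age=cal, c14_age=cal.copy(),
                          curve_sigma=np.zeros_like(cal))
    if kind == "linear":
        return CalibCurve(cal_age=cal, c14_age=0.9 * cal,
                          curve_sigma=np.full_like(cal, 15.0))
    if kind == "wiggly":
        slope = 0.95
        if amplitude * 2 * np.pi / period >= slope:
            raise ValidationError("wiggle amplitude breaks curve monotonicity")
        c14 = slope * cal + amplitude * np.sin(2 * np.pi * cal / period)
        return CalibCurve(cal_age=cal, c14_age=c14,
                          curve_sigma=np.full_like(cal, 20.0))
    raise ValidationError(f"unknown curve kind {kind!r}")


def make_fossil_record(site: Site, modern: ClimateTriple, truth: dict,
                       niches: pd.DataFrame, curve: CalibCurve,
                       n_samples: int = 40, date_spacing: float = 2000.0,
                       date_sigma: float = 60.0, total_count: int = 400,
                       seed: int | None = None,
                       topo_history=None) -> tuple[FossilRecord, pd.DataFrame]:
    """One dated fossil record following the imposed temperature history.

    Sample ages span 0-11 ka at a resolution that passes the screening
    rules; radiocarbon controls are synthesized by pushing true calendar
    ages through the calibration curve and adding Gaussian noise, plus a
    core-top control.  With ``topo_history`` the site experiences the
    topographic cooling ``lapse * delta_elev(t)`` on top of the climate
    truth, so the isostatic correction stage has a real signal to remove.
    The returned truth series is the climate-only history (what the
    corrected reconstruction should recover).
    """
    if n_samples < 5:
        raise ValidationError("n_samples must be >= 5")
    rng = np.random.default_rng(seed)
    ages = np.sort(np.linspace(200.0, 10800.0, n_samples)
                   + rng.uniform(-60.0, 60.0, n_samples))
    depth_per_yr = 0.02          # 2 cm per century
    depths = ages * depth_per_yr
    topo_delta = (topo_history.at(ages / 1000.0) if topo_history is not None
                  else np.zeros_like(ages))
    rows = []
    truth_rows = []
    for a, dz in zip(ages, topo_delta):
        mtco_t = modern.mtco + float(truth["mtco"](a)) + LAPSE * dz
        mtwa_t = modern.mtwa + float(truth["mtwa"](a)) + LAPSE * dz
        triple = ClimateTriple(annt=(mtco_t + mtwa_t) / 2.0,
                               mtwa=mtwa_t, mtco=mtco_t)
        rows.append(sample_counts(triple, niches, total_count, rng=rng))
        mtco_c = modern.mtco + float(truth["mtco"](a))      # climate-only truth
        mtwa_c = modern.mtwa + float(truth["mtwa"](a))
        truth_rows.append({"age": a, "annt": (mtco_c + mtwa_c) / 2.0,
                           "mtwa": mtwa_c, "mtco": mtco_c,
                           "topo_delta_m": dz})
    counts = PollenCounts(
        sample_ids=[f"{site.site_id}_s{i:03d}" for i in range(n_samples)],
        depths=depths, taxa=list(niches.index), counts=np.vstack(rows))
    controls = [AgeControl(depth=0.0, kind="core_top", age=0.0, sigma=10.0)]
    for cal_age in np.arange(500.0, 11000.0, date_spacing):
        c14_true = float(np.interp(cal_age, curve.cal_age, curve.c14_age))
        controls.append(AgeControl(
            depth=cal_age * depth_per_yr, kind="c14",
            age=c14_true + float(rng.normal(0.0, date_sigma)),
            sigma=date_sigma))
    record = FossilRecord(site=site, counts=counts, controls=controls)
    return record, pd.DataFrame(truth_rows)


def make_topo_field(decay_halflife: float = 3.0, max_anomaly: float = 150.0,
                    seed: int | None = None,
                    lat: np.ndarray | None = None,
                    lon: np.ndarray | None = None,
                    times: np.ndarray | None = None) -> TopoAnomalyField:
    """Ice-margin-style elevation anomaly decaying to exactly 0 at present.

    anomaly(t) = max_anomaly * bump(lat, lon) * (1 - exp(-t ln2 / halflife)),
    with spatially localized bumps over the formerly glaciated sectors.
    """
    rng = np.random.default_rng(seed)
    if lat is None:
        lat = np.arange(25.0, 76.0, 1.0)
    if lon is None:
        lon = np.arange(-179.5, 180.0, 1.0)
    if times is None:
        times = np.arange(0.0, 11.5, 0.5)
    glat, glon = np.meshgrid(lat, lon, indexing="ij")
    bump = np.zeros_like(glat)
    for c_lat, c_lon, width in ((60.0, -75.0, 18.0), (64.0, 20.0, 14.0)):
        bump += np.exp(-((glat - c_lat) ** 2 + ((glon - c_lon) / 2.0) ** 2)
                       / (2 * width**2))
    bump = bump / bump.max() * (1.0 + 0.05 * rng.standard_normal())
    decay = 1.0 - np.exp(-np.asarray(times) * np.log(2.0) / decay_halflife)
    anomaly = max_anomaly * decay[:, None, None] * bump[None]
    return TopoAnomalyField(times=np.asarray(times, float), lat=lat, lon=lon,
                            anomaly=anomaly)


# ------------------------------------------------------------------ bundle

def holocene_demo(seed: int = 0, n_records: int = 60, n_calib: int = 300,
                  n_taxa: int = 24, total_count: int = 400,
                  corr_target: float = 0.6, n_samples: int = 40,
                  clustered_calib: bool = False) -> dict:
    """The standard end-to-end synthetic fixture.

    Returns a dict with the climate field, niches, taxa-PFT matrix,
    calibration set (PFT scores), fossil records with truth series, the
    calibration curve, the topo field and a :class:`SyntheticTruth`.
    """
    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2**31 - 1, size=6 + n_records)
    field = make_climate_field(corr_target=corr_target, seed=int(seeds[0]))
    niches = make_niches(n_taxa=n_taxa, seed=int(seeds[1]))
    pft_matrix = make_taxa_pft_matrix(niches)
    calib = make_calibration_set(n_calib, field, niches, total_count=total_count,
                                 seed=int(seeds[2]), clustered=clustered_calib,
                                 pft_matrix=pft_matrix)
    curve = make_calib_curve("wiggly", seed=int(seeds[3]))
    topo = make_topo_field(seed=int(seeds[4]))
    truth = holocene_truth()
    rng_sites = np.random.default_rng(int(seeds[5]))
    sites = random_sites(n_records, field, rng_sites, prefix="fossil")
    from .correction import topo_history_at_site
    records, truths = [], {}
    for i, site in enumerate(sites):
        modern = assign_site_climate(site, field, lapse_rate=LAPSE)
        rec, tr = make_fossil_record(site, modern, truth, niches, curve,
                                     n_samples=n_samples,
                                     total_count=total_count,
                                     seed=int(seeds[6 + i]),
                                     topo_history=topo_history_at_site(topo, site))
        records.append(rec)
        truths[site.site_id] = tr
    truth_obj = SyntheticTruth(master_seed=seed, corr_target=corr_target,
                               niche_params=niches, anomaly_funcs=truth,
                               site_histories=truths)
    return {
        "field": field, "niches": niches, "pft_matrix": pft_matrix,
        "calibration": calib, "curve": curve, "topo": topo,
        "records": records, "truth": truth_obj,
    }
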