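"""End-to-end orchestration: simulate -> screen -> reconstruct -> stack.

The pipeline consumes either an in-memory synthetic bundle or an input
directory written by the ``simulate`` stage, runs every stage in
dependency order, and writes composite/EOF/diagnostic CSVs plus a JSON
manifest (parameters, seeds, per-stage record counts).  A single master
seed is expanded deterministically into per-stage, per-record seeds so
reruns are reproducible stage by stage.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import io_formats, stacking, synthetic
from .chronology import build_age_model, screen_record, screen_samples
from .correction import isostatic_correct, local_lapse_rate, topo_history_at_site
from .ordination import eof
from .pft import scores_from_counts
from .regions import REGION_IDS
from .transfer import (
    MATRegressor,
    ValidationError,
    WAPLSRegressor,
    bootstrap_error,
    cross_validate,
    significance_test,
)
from .types import CalibrationSet, FossilRecord, ReconSeries, Site

logger = logging.getLogger(__name__)

VARIABLES = ("annt", "mtwa", "mtco")
EOF_WINDOWS = {"11-7ka": (7000.0, 11000.0), "7-0ka": (0.0, 7000.0)}


class McSettings(BaseModel):
    n_boot: int = Field(100, ge=1)
    n_mc: int = Field(1000, ge=1)
    n_rand: int = Field(999, ge=1)
    quantile: float = Field(0.842, gt=0.0, le=1.0)


class TransferSettings(BaseModel):
    method: str = Field("mat", pattern="^(mat|wapls)$")
    features: str = Field("pft", pattern="^(pft|taxa)$")
    k: int = Field(6, ge=1)
    scd_max: float = Field(0.2, gt=0.0)
    theta: float = Field(0.005, ge=0.0)
    n_comp: int = Field(2, ge=1)
    h_km: float = Field(0.0, ge=0.0)


class SimulateSettings(BaseModel):
    n_records: int = Field(60, ge=1)
    n_calib: int = Field(300, ge=10)
    n_taxa: int = Field(24, ge=4)
    n_samples: int = Field(40, ge=5)
    total_count: int = Field(400, ge=1)
    corr_target: float = Field(0.6, ge=0.0, lt=1.0)


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; defaults follow the standard
    protocol (100 bootstrap iterations, 1000 MC draws, 999 random
    reconstructions at the 84.2% quantile, 200-yr bins on a 2 deg grid,
    300-km lapse radius)."""

    seed: int = 0
    out_dir: str = "pollenrecon_out"
    input_dir: str | None = None          # None -> simulate in memory
    mc: McSettings = McSettings()
    transfer: TransferSettings = TransferSettings()
    simulate: SimulateSettings = SimulateSettings()
    cell_size_deg: float = Field(2.0, gt=0.0)
    lapse_radius_km: float = Field(300.0, gt=0.0)
    apply_significance: bool = True
    apply_correction: bool = True
    regions: list[str] = Field(default_factory=lambda: ["NH", *REGION_IDS])


def stage_seeds(master: int, n: int) -> np.ndarray:
    """Deterministic expansion of the master seed into stage seeds."""
    return np.random.default_rng(master).integers(0, 2**31 - 1, size=n)


# ----------------------------------------------------------- bundle on disk

def write_bundle(bundle: dict, out_dir: str | Path) -> None:
    """Write a synthetic input bundle as the pipeline's on-disk input set."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_formats.write_climate_grid(bundle["field"], out / "climate_grid.nc")
    io_formats.write_topo_field(bundle["topo"], out / "topo_field.nc")
    io_formats.write_calib_curve(bundle["curve"], out / "calib_curve.csv")
    io_formats.write_taxa_pft_matrix({"default": bundle["pft_matrix"]},
                                     out / "taxa_pft_matrix.csv")
    calib: CalibrationSet = bundle["calibration"]
    feats = pd.DataFrame(calib.features, columns=calib.feature_names)
    feats.insert(0, "sample_id", [s.site_id for s in calib.sites])
    feats.to_csv(out / "calibration_features.csv", index=False)
    calib.climate.assign(sample_id=[s.site_id for s in calib.sites]).to_csv(
        out / "calibration_climate.csv", index=False)
    _sites_frame(calib.sites).to_csv(out / "calibration_sites.csv", index=False)
    _sites_frame([r.site for r in bundle["records"]]).to_csv(
        out / "fossil_sites.csv", index=False)
    controls = {r.site.site_id: r.controls for r in bundle["records"]}
    io_formats.write_age_controls(controls, out / "age_controls.csv")
    (out / "pollen").mkdir(exist_ok=True)
    for rec in bundle["records"]:
        io_formats.write_pollen_table(rec.counts,
                                      out / "pollen" / f"{rec.site.site_id}.csv")
    rows = []
    for sid, tr in bundle["truth"].site_histories.items():
        rows.append(tr.assign(site_id=sid))
    pd.concat(rows, ignore_index=True).to_csv(out / "truth.csv", index=False)


def _sites_frame(sites: list[Site]) -> pd.DataFrame:
    return pd.DataFrame([
        {"site_id": s.site_id, "lat": s.lat, "lon": s.lon, "elev": s.elev,
         "region_id": s.region_id} for s in sites])


def _sites_from_frame(df: pd.DataFrame) -> list[Site]:
    return [Site(site_id=str(r.site_id), lat=float(r.lat), lon=float(r.lon),
                 elev=float(r.elev), region_id=str(r.region_id))
            for r in df.itertuples(index=False)]


def read_bundle(input_dir: str | Path) -> dict:
    """Read back an input bundle written by :func:`write_bundle`."""
    d = Path(input_dir)
    field = io_formats.read_climate_grid(d / "climate_grid.nc")
    topo = io_formats.read_topo_field(d / "topo_field.nc")
    curve = io_formats.read_calib_curve(d / "calib_curve.csv")
    matrices = io_formats.read_taxa_pft_matrix(d / "taxa_pft_matrix.csv")
    feats = pd.read_csv(d / "calibration_features.csv")
    climate = pd.read_csv(d / "calibration_climate.csv")
    calib_sites = _sites_from_frame(pd.read_csv(d / "calibration_sites.csv"))
    feature_names = [c for c in feats.columns if c != "sample_id"]
    calib = CalibrationSet(sites=calib_sites, feature_names=feature_names,
                           features=feats[feature_names].to_numpy(float),
                           climate=climate[list(VARIABLES)],
                           feature_kind="pft")
    fossil_sites = _sites_from_frame(pd.read_csv(d / "fossil_sites.csv"))
    controls = io_formats.read_age_controls(d / "age_controls.csv")
    records = []
    for site in fossil_sites:
        counts = io_formats.read_pollen_table(d / "pollen" / f"{site.site_id}.csv")
        records.append(FossilRecord(site=site, counts=counts,
                                    controls=controls[site.site_id]))
    return {"field": field, "topo": topo, "curve": curve,
            "pft_matrix": matrices["default"], "calibration": calib,
            "records": records}


# -------------------------------------------------------------- the driver

def reconstruct_record(record: FossilRecord, calib: CalibrationSet,
                       pft_matrix: pd.DataFrame, curve, cfg: PipelineConfig,
                       rmsep: dict, seed: int) -> tuple[ReconSeries | None, dict]:
    """Chronology, screening, PFT scoring and MAT/WA-PLS for one record."""
    info: dict = {"site_id": record.site.site_id, "region": record.site.region_id}
    model = build_age_model(record.controls, record.counts.depths, curve)
    record.age_model = model
    passed, reasons = screen_record(record)
    info["screen_pass"] = passed
    info["screen_reasons"] = reasons
    if not passed:
        return None, info
    mask = screen_samples(model, record.counts)
    info["n_samples"] = int(mask.size)
    info["n_retained"] = int(mask.sum())
    if mask.sum() < 2:
        info["screen_pass"] = False
        info["screen_reasons"] = ["fewer than 2 samples after sample screening"]
        return None, info
    counts = record.counts
    keep = np.nonzero(mask)[0]
    sub = type(counts)(sample_ids=[counts.sample_ids[i] for i in keep],
                       depths=counts.depths[keep], taxa=counts.taxa,
                       counts=counts.counts[keep])
    scores = scores_from_counts(sub, pft_matrix, theta=cfg.transfer.theta)
    ages = model.sample_ages[keep]
    y = calib.climate.to_numpy()
    table = pd.DataFrame({"age": ages})
    if cfg.transfer.method == "mat":
        mat = MATRegressor(k=cfg.transfer.k, scd_max=cfg.transfer.scd_max).fit(
            calib.features, y)
        out = mat.predict_detailed(scores.scores)
        err = bootstrap_error(scores.scores, calib, k=cfg.transfer.k,
                              n_boot=cfg.mc.n_boot,
                              rmsep=np.array([rmsep[v] for v in VARIABLES]),
                              seed=seed)
        for j, v in enumerate(VARIABLES):
            table[v] = out["estimate"][:, j]
            table[f"{v}_error"] = err[:, j]
        table["min_scd"] = out["min_scd"]
        table["no_analogue"] = out["no_analogue"]
        analogue_ids = [[calib.sites[j].site_id for j in row]
                        for row in out["analogue_idx"]]
        info["n_no_analogue"] = int(out["no_analogue"].sum())
    else:
        for j, v in enumerate(VARIABLES):
            m = WAPLSRegressor(n_components=cfg.transfer.n_comp).fit(
                calib.features, y[:, j])
            table[v] = m.predict(scores.scores)
            table[f"{v}_error"] = rmsep[v]
        table["min_scd"] = np.nan
        table["no_analogue"] = False
        analogue_ids = []
    recon = ReconSeries(site=record.site, table=table, analogue_ids=analogue_ids)
    info["fossil_scores"] = scores.scores
    return recon, info


def run_pipeline(config: PipelineConfig, bundle: dict | None = None) -> dict:
    """Run every stage; returns the manifest (also written to out_dir)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed, 6)
    if bundle is None:
        if config.input_dir is not None:
            bundle = read_bundle(config.input_dir)
        else:
            s = config.simulate
            bundle = synthetic.holocene_demo(
                seed=int(seeds[0]), n_records=s.n_records, n_calib=s.n_calib,
                n_taxa=s.n_taxa, total_count=s.total_count,
                corr_target=s.corr_target, n_samples=s.n_samples)
    calib: CalibrationSet = bundle["calibration"]
    manifest: dict = {"seed": config.seed,
                      "params": json.loads(config.model_dump_json()),
                      "stages": {}}

    cv = cross_validate(calib, method=config.transfer.method, scheme="loo",
                        k=config.transfer.k, n_comp=config.transfer.n_comp)
    rmsep = cv.rmsep
    manifest["stages"]["cross_validation"] = {"r2": cv.r2, "rmsep": cv.rmsep}

    record_seeds = stage_seeds(int(seeds[1]), 2 * len(bundle["records"]))
    recons, infos = [], []
    for i, rec in enumerate(bundle["records"]):
        recon, info = reconstruct_record(rec, calib, bundle["pft_matrix"],
                                         bundle["curve"], config, rmsep,
                                         seed=int(record_seeds[2 * i]))
        infos.append(info)
        if recon is not None:
            recons.append((recon, info))
    n_screened = sum(1 for i in infos if i.get("screen_pass"))
    manifest["stages"]["screening"] = {
        "n_records": len(bundle["records"]), "n_pass": n_screened,
        "failures": {i["site_id"]: i["screen_reasons"]
                     for i in infos if not i.get("screen_pass")}}

    sig_keep: dict[str, dict[str, bool]] = {}
    if config.apply_significance:
        sig_seeds = stage_seeds(int(seeds[2]), 3 * len(recons))
        n_pass = {v: 0 for v in VARIABLES}
        for idx, (recon, info) in enumerate(recons):
            keep = {}
            for j, v in enumerate(VARIABLES):
                series = recon.table[v].to_numpy()
                ok = ~np.isnan(series)
                if ok.sum() < 5:
                    keep[v] = False
                    continue
                res = significance_test(
                    info["fossil_scores"][ok], series[ok], calib, variable=v,
                    method=config.transfer.method, k=config.transfer.k,
                    n_rand=config.mc.n_rand, quantile=config.mc.quantile,
                    seed=int(sig_seeds[3 * idx + j]))
                keep[v] = res.passed
                n_pass[v] += int(res.passed)
            sig_keep[recon.site.site_id] = keep
        manifest["stages"]["significance"] = {
            "n_rand": config.mc.n_rand, "quantile": config.mc.quantile,
            "n_pass": n_pass, "n_records": len(recons)}
    else:
        sig_keep = {r.site.site_id: {v: True for v in VARIABLES}
                    for r, _ in recons}

    corrected = []
    n_uncorrectable = 0
    for recon, info in recons:
        if config.apply_correction:
            try:
                lapse = local_lapse_rate(bundle["field"], recon.site,
                                         radius_km=config.lapse_radius_km,
                                         detrend_latlon=True,
                                         min_elev_range=50.0)
                topo = topo_history_at_site(bundle["topo"], recon.site)
                recon = isostatic_correct(recon, topo, lapse)
            except ValidationError as exc:
                n_uncorrectable += 1
                logger.warning("site %s left uncorrected: %s",
                               recon.site.site_id, exc)
        corrected.append(recon)
    manifest["stages"]["correction"] = {
        "applied": config.apply_correction, "n_uncorrectable": n_uncorrectable}

    bin_seeds = stage_seeds(int(seeds[3]), len(corrected))
    binned: dict[str, list] = {v: [] for v in VARIABLES}
    for i, recon in enumerate(corrected):
        keep = sig_keep.get(recon.site.site_id, {})
        for v in VARIABLES:
            if not keep.get(v, False):
                continue
            try:
                binned[v].append(stacking.to_binned(
                    recon, v, n_mc=config.mc.n_mc, seed=int(bin_seeds[i])))
            except ValidationError as exc:
                logger.warning("site %s variable %s not binned: %s",
                               recon.site.site_id, v, exc)
    manifest["stages"]["binning"] = {v: len(binned[v]) for v in VARIABLES}

    comp_seeds = stage_seeds(int(seeds[4]), len(VARIABLES) * len(config.regions))
    composites: dict[str, dict[str, pd.DataFrame]] = {}
    ci = 0
    for v in VARIABLES:
        composites[v] = {}
        if not binned[v]:
            continue
        cells = stacking.grid_average(binned[v], cell_size=config.cell_size_deg)
        for region in config.regions:
            try:
                comp = stacking.composite(cells, n_mc=config.mc.n_mc,
                                          seed=int(comp_seeds[ci]),
                                          region=region)
            except ValidationError:
                ci += 1
                continue
            composites[v][region] = comp
            comp.to_csv(out / f"composite_{v}_{region}.csv", index=False)
            ci += 1
    if "NH" in composites.get("mtwa", {}) and "NH" in composites.get("mtco", {}):
        seas = stacking.seasonality(composites["mtwa"]["NH"],
                                    composites["mtco"]["NH"])
        seas.to_csv(out / "seasonality_NH.csv", index=False)
        manifest["stages"]["seasonality"] = {"written": True}

    trends = {}
    for v in VARIABLES:
        comp = composites.get(v, {}).get("NH")
        if comp is None:
            continue
        for wname, (lo, hi) in (("11-7ka", (7.0, 11.0)), ("7-0ka", (0.0, 7.0))):
            try:
                rate, se = stacking.fit_trend(comp, (lo, hi))
                trends[f"{v}_{wname}"] = {"rate_c_per_ka": rate, "se": se}
            except ValidationError:
                pass
    manifest["stages"]["trends"] = trends

    eof_out = {}
    for v in VARIABLES:
        if len(binned[v]) < 3:
            continue
        centers = binned[v][0].bin_centers
        F = np.vstack([b.anomaly for b in binned[v]]).T      # time x sites
        for wname, window in EOF_WINDOWS.items():
            try:
                res = eof(F, times=centers, window=window, max_missing=0.2)
            except ValidationError:
                continue
            eof_out[f"{v}_{wname}"] = {
                "pc1_variance_fraction": float(res.variance_fractions[0])}
            pd.DataFrame({"site_index": res.unit_index,
                          "corr_with_pc1": res.correlation_map}).to_csv(
                out / f"eof_map_{v}_{wname}.csv", index=False)
    manifest["stages"]["eof"] = eof_out

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
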