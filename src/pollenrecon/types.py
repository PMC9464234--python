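"""Core in-memory containers shared across the pipeline.

Every on-disk artifact is parsed into one of these validated types by
:mod:`pollenrecon.io_formats`; downstream modules never touch raw files.
Units follow field conventions: depths in cm, ages in calendar years
before present (present = 1950 CE), temperatures in degrees Celsius,
elevations in metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def normalize_lon(lon: float | np.ndarray) -> float | np.ndarray:
    """Map longitudes to the internal [-180, 180) convention."""
    return (np.asarray(lon) + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class Site:
    """A pollen site or surface sample location."""

    site_id: str
    lat: float
    lon: float
    elev: float = 0.0
    region_id: str = "other"

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"site {self.site_id}: lat {self.lat} outside [-90, 90]")
        object.__setattr__(self, "lon", float(normalize_lon(self.lon)))


@dataclass
class PollenCounts:
    """A site's pollen count table: samples (rows) by taxa (columns)."""

    sample_ids: list[str]
    depths: np.ndarray          # cm, monotone increasing downcore
    taxa: list[str]
    counts: np.ndarray          # samples x taxa, non-negative
    is_proportions: bool = False

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        n, t = self.counts.shape
        if len(self.sample_ids) != n or len(self.depths) != n:
            raise ValidationError("sample_ids/depths length does not match count rows")
        if len(self.taxa) != t:
            raise ValidationError("taxa length does not match count columns")
        if len(set(self.taxa)) != t:
            dupes = sorted({x for x in self.taxa if self.taxa.count(x) > 1})
            raise ValidationError(f"duplicate taxa: {dupes}")
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, taxon {self.taxa[j]!r}"
            )
        if n > 1 and np.any(np.diff(self.depths) <= 0):
            raise ValidationError("depths must be strictly increasing downcore")

    @property
    def totals(self) -> np.ndarray:
        """Total pollen count per sample."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.taxa)
        df.insert(0, "depth_cm", self.depths)
        df.insert(0, "sample_id", self.sample_ids)
        return df


@dataclass(frozen=True)
class ClimateTriple:
    """Mean annual, warmest-month and coldest-month temperature (deg C)."""

    annt: float
    mtwa: float
    mtco: float

    def __post_init__(self) -> None:
        if not (self.mtco <= self.annt + 1e-9 and self.annt <= self.mtwa + 1e-9):
            raise ValidationError(
                f"climate triple must satisfy mtco <= annt <= mtwa, "
                f"got ({self.mtco}, {self.annt}, {self.mtwa})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.annt, self.mtwa, self.mtco])


VARIABLES = ("annt", "mtwa", "mtco")


@dataclass
class ClimateGrid:
    """Gridded modern monthly mean temperature plus elevation (0.5 deg default)."""

    lat: np.ndarray                 # ascending
    lon: np.ndarray                 # ascending, [-180, 180)
    monthly_temp: np.ndarray        # 12 x nlat x nlon, deg C
    elev: np.ndarray                # nlat x nlon, m

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        for name, ax in (("lat", self.lat), ("lon", self.lon)):
            if ax.size > 1 and np.any(np.diff(ax) <= 0):
                raise ValidationError(f"{name} axis must be strictly increasing")
        self.monthly_temp = np.asarray(self.monthly_temp, dtype=float)
        self.elev = np.asarray(self.elev, dtype=float)
        if self.monthly_temp.shape != (12, self.lat.size, self.lon.size):
            raise ValidationError("monthly_temp must have shape (12, nlat, nlon)")
        if self.elev.shape != (self.lat.size, self.lon.size):
            raise ValidationError("elev must have shape (nlat, nlon)")

    def triple_at_node(self, i: int, j: int) -> ClimateTriple:
        months = self.monthly_temp[:, i, j]
        return ClimateTriple(annt=float(months.mean()),
                             mtwa=float(months.max()),
                             mtco=float(months.min()))


@dataclass
class TopoAnomalyField:
    """Time-resolved glacio-isostatic elevation anomaly relative to present."""

    times: np.ndarray               # ka BP, ascending from 0
    lat: np.ndarray
    lon: np.ndarray
    anomaly: np.ndarray             # ntime x nlat x nlon, metres

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.anomaly = np.asarray(self.anomaly, dtype=float)
        if self.anomaly.shape != (self.times.size, self.lat.size, self.lon.size):
            raise ValidationError("anomaly must have shape (ntime, nlat, nlon)")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("time axis must be strictly increasing")
        i0 = int(np.argmin(np.abs(self.times)))
        if abs(self.times[i0]) < 1e-9 and np.any(np.abs(self.anomaly[i0]) > 1e-9):
            raise ValidationError("topographic anomaly must be identically 0 at time 0")


@dataclass(frozen=True)
class AgeControl:
    """One chronological control point of an age-depth model."""

    depth: float                    # cm
    kind: str                       # c14 | calendar | core_top | lamination | biostratigraphic
    age: float                      # 14C yr BP for kind=c14, cal yr BP otherwise
    sigma: float = 0.0              # yr
    independent: bool | None = None # dating controls counted as independent dates

    KINDS = ("c14", "calendar", "core_top", "lamination", "biostratigraphic")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValidationError(f"unknown age control kind {self.kind!r}")
        if self.kind == "c14" and self.sigma <= 0:
            raise ValidationError("radiocarbon controls need sigma > 0")
        if self.independent is None:
            # only direct dates count toward the independent-date criterion
            object.__setattr__(self, "independent", self.kind in ("c14", "calendar"))


@dataclass
class CalibCurve:
    """Radiocarbon calibration curve on a calendar-age grid (IntCal layout)."""

    cal_age: np.ndarray             # cal yr BP, strictly increasing
    c14_age: np.ndarray             # 14C yr BP
    curve_sigma: np.ndarray         # yr

    def __post_init__(self) -> None:
        self.cal_age = np.asarray(self.cal_age, dtype=float)
        self.c14_age = np.asarray(self.c14_age, dtype=float)
        self.curve_sigma = np.asarray(self.curve_sigma, dtype=float)
        if np.any(np.diff(self.cal_age) <= 0):
            raise ValidationError("cal_age grid must be strictly increasing")
        if not (self.cal_age.size == self.c14_age.size == self.curve_sigma.size):
            raise ValidationError("curve columns must have equal length")


@dataclass
class AgeModel:
    """Calibrated age-depth model evaluated at pollen sample depths."""

    control_depths: np.ndarray      # cm
    control_ages: np.ndarray        # cal yr BP (point estimates)
    sample_depths: np.ndarray       # cm
    sample_ages: np.ndarray         # cal yr BP
    flags: list[str]                # per sample: direct | interpolated | extrapolated


@dataclass
class FossilRecord:
    """One site's dated fossil pollen sequence."""

    site: Site
    counts: PollenCounts
    controls: list[AgeControl]
    age_model: AgeModel | None = None

    @property
    def sample_ages(self) -> np.ndarray:
        if self.age_model is None:
            raise ValidationError(f"record {self.site.site_id}: age model not built")
        return self.age_model.sample_ages


@dataclass
class CalibrationSet:
    """Modern surface-sample assemblages paired with site climate."""

    sites: list[Site]
    feature_names: list[str]
    features: np.ndarray            # samples x features (PFT scores or taxon proportions)
    climate: pd.DataFrame           # columns annt, mtwa, mtco (deg C)
    feature_kind: str = "pft"       # "pft" | "taxa"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        n = len(self.sites)
        if self.features.shape != (n, len(self.feature_names)):
            raise ValidationError("features shape mismatch")
        if list(self.climate.columns[:3]) != list(VARIABLES):
            self.climate = self.climate[list(VARIABLES)]
        if len(self.climate) != n:
            raise ValidationError("climate rows mismatch")
        if self.climate.isna().any().any():
            raise ValidationError("calibration climate contains missing values")
        if self.feature_kind not in ("pft", "taxa"):
            raise ValidationError("feature_kind must be 'pft' or 'taxa'")

    @property
    def coords(self) -> np.ndarray:
        return np.array([[s.lat, s.lon] for s in self.sites])


@dataclass
class ReconSeries:
    """Per-sample reconstructed temperatures with analogue diagnostics.

    ``table`` has one row per fossil sample with columns ``age`` plus, per
    variable v in {annt, mtwa, mtco}: ``{v}``, ``{v}_error``.  Shared
    diagnostics: ``min_scd``, ``no_analogue``; ``analogue_ids`` holds the
    per-sample analogue lists.
    """

    site: Site
    table: pd.DataFrame
    analogue_ids: list[list[str]] = field(default_factory=list)
    isostatically_corrected: bool = False

    def ages(self) -> np.ndarray:
        return self.table["age"].to_numpy()


@dataclass
class BinnedSeries:
    """A site reconstruction converted to anomalies on the 200-yr bin lattice."""

    site: Site
    variable: str
    bin_centers: np.ndarray         # cal yr BP
    anomaly: np.ndarray             # deg C, NaN where the record has no coverage
    bin_se: np.ndarray              # ensemble SD across Monte-Carlo draws
    bin_sem: np.ndarray             # ensemble SD / sqrt(n_draws)
    n_contributing: np.ndarray      # raw samples inside each covered bin


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the synthetic-data generator."""

    master_seed: int
    corr_target: float
    niche_params: pd.DataFrame
    anomaly_funcs: dict             # variable -> callable(age_yr_bp) -> deg C anomaly
    site_histories: dict = field(default_factory=dict)  # site_id -> DataFrame(age, annt, mtwa, mtco)
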