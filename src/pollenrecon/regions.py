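"""Northern-Hemisphere analysis regions and site-to-region assignment.

The eight default regions are rectangular lat/lon boxes spanning western
and eastern North America, western/northeastern/southeastern Europe and
northern/southern Asia.  Boxes use half-open [lower, upper) intervals on
both axes so a site on a shared edge lands in exactly one region;
longitudes are handled on the internal [-180, 180) convention, with boxes
that cross the dateline split internally.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import normalize_lon

# (region_id, lat_min, lat_max, lon_min, lon_max) in degrees; lon on [-180, 180]
# Order matters: first matching box wins.
DEFAULT_REGION_TABLE = pd.DataFrame(
    [
        ("W_NA", 25.0, 75.0, -180.0, -105.0),   # western North America
        ("NE_NA", 40.0, 75.0, -105.0, -50.0),   # northeastern North America
        ("SE_NA", 25.0, 40.0, -105.0, -50.0),   # southeastern North America
        ("W_EU", 30.0, 65.0, -15.0, 5.0),       # western Europe
        ("NE_EU", 48.0, 75.0, 5.0, 56.0),       # northeastern Europe
        ("SE_EU", 30.0, 48.0, 5.0, 56.0),       # southeastern Europe
        ("N_AS", 50.0, 75.0, 56.0, 180.0),      # northern Asia
        ("S_AS", 0.0, 50.0, 56.0, 140.0),       # southern Asia
    ],
    columns=["region_id", "lat_min", "lat_max", "lon_min", "lon_max"],
)

REGION_IDS = tuple(DEFAULT_REGION_TABLE["region_id"])


def assign_region(lat: float, lon: float, table: pd.DataFrame | None = None) -> str:
    """Assign a location to a region box, or ``"other"``.

    Bounds are closed below and open above on both axes.  Boxes whose
    upper longitude bound is 180 treat 180 (== -180 internally only after
    wrapping) as reachable via the wrapped value.
    """
    if table is None:
        table = DEFAULT_REGION_TABLE
    lon = float(normalize_lon(lon))
    for row in table.itertuples(index=False):
        if not (row.lat_min <= lat < row.lat_max):
            continue
        lo, hi = row.lon_min, row.lon_max
        if lo <= lon < hi:
            return row.region_id
    return "other"


def assign_regions(lats: np.ndarray, lons: np.ndarray,
                   table: pd.DataFrame | None = None) -> list[str]:
    return [assign_region(float(a), float(o), table) for a, o in zip(lats, lons)]
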