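"""County-level environmental data: banding, lookup, fixtures and CSV I/O.

Two objective domains are scored from the respondent's county rather than
from survey answers:

* **Lead risk** — proxied by the percentage of county housing built before
  1980, banded into quintiles anchored on 2020 American Community Survey
  data: <41.05 → 9, 41.05–<50.3 → 7, 50.3–<58.8 → 5, 58.8–<69.3 → 3,
  ≥69.3 → 1. Bands are uniformly half-open ``[lower, upper)`` with the top
  band closed at 100.
* **Air quality** — annual-average PM2.5 (µg/m³) banded on the 2020 NAAQS
  anchor points: <12 → 9, 12–15 (closed) → 5, >15 → 1.

Real deployments draw these measures from the CDC Environmental Public
Health Tracking Network and EPA monitoring; this module ships a synthetic
fixture generator emulating those tables so nothing is downloaded. ZIP codes
are mapped to a single county — a documented simplification (real ZIP codes
can straddle county lines).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import DanglingCrosswalk, MalformedGeoCSV, UnknownPostalCode

#: (upper bound, score) for the pre-1980-housing quintile bands; the final
#: band has no upper bound. Thresholds as printed for the 2020 ACS quintiles.
LEAD_BANDS: tuple[tuple[float, int], ...] = (
    (41.05, 9),
    (50.3, 7),
    (58.8, 5),
    (69.3, 3),
    (math.inf, 1),
)

#: PM2.5 anchor points (µg/m³): <12 scores 9, [12, 15] scores 5, >15 scores 1.
PM25_LOW = 12.0
PM25_HIGH = 15.0

COUNTIES_HEADER = ["county_id", "pct_pre1980_housing", "pm25_annual"]
CROSSWALK_HEADER = ["postal_code", "county_id"]


@dataclass(frozen=True)
class CountyRecord:
    """One county's environmental measures."""

    county_id: str
    pct_pre1980_housing: float  # percentage of housing stock built before 1980
    pm25_annual: float  # annual-average PM2.5, µg/m³

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_pre1980_housing <= 100.0):
            raise ValueError(
                f"{self.county_id}: pct_pre1980_housing must be in [0, 100], "
                f"got {self.pct_pre1980_housing}"
            )
        if not math.isfinite(self.pm25_annual) or self.pm25_annual < 0:
            raise ValueError(
                f"{self.county_id}: pm25_annual must be finite and >= 0, "
                f"got {self.pm25_annual}"
            )


@dataclass
class GeoTable:
    """Postal-code → county crosswalk plus per-county records."""

    counties: dict[str, CountyRecord]
    crosswalk: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for postal, county_id in self.crosswalk.items():
            if county_id not in self.counties:
                raise DanglingCrosswalk(postal, county_id)


def lead_subscore(pct: float) -> int:
    """Quintile band score for the county's pre-1980 housing percentage."""
    if not (isinstance(pct, (int, float)) and math.isfinite(pct) and 0.0 <= pct <= 100.0):
        raise ValueError(f"pct_pre1980_housing must be a percentage in [0, 100], got {pct!r}")
    for upper, score in LEAD_BANDS:
        if pct < upper:
            return score
    raise AssertionError("unreachable: top band is unbounded")


def air_subscore(pm25: float) -> int:
    """NAAQS-anchored band score for annual-average PM2.5 (µg/m³)."""
    if not (isinstance(pm25, (int, float)) and math.isfinite(pm25) and pm25 >= 0):
        raise ValueError(f"pm25_annual must be finite and >= 0, got {pm25!r}")
    if pm25 < PM25_LOW:
        return 9
    if pm25 <= PM25_HIGH:
        return 5
    return 1


def resolve(postal_code: str, geo: GeoTable) -> CountyRecord:
    """Look up the county record for a 5-digit ZIP code.

    An unknown code is a hard :class:`UnknownPostalCode` error — no national
    median is silently substituted.
    """
    county_id = geo.crosswalk.get(postal_code)
    if county_id is None:
        raise UnknownPostalCode(postal_code)
    return geo.counties[county_id]


# --- synthetic fixtures -----------------------------------------------------

# Sampling intervals per band, chosen to keep draws strictly inside each band
# (so float jitter cannot cross a threshold). 5 lead x 3 air = 15 combinations.
_LEAD_INTERVALS = ((5.0, 41.0), (41.1, 50.2), (50.4, 58.7), (58.9, 69.2), (69.4, 95.0))
_AIR_INTERVALS = ((4.0, 11.9), (12.1, 14.9), (15.1, 22.0))


def generate_fixture(n_counties: int, seed: int) -> GeoTable:
    """Deterministic synthetic stand-in for the CDC/EPA county tables.

    Counties cycle through the 15 lead-band × air-band combinations, so any
    table with ``n_counties >= 15`` exercises every score band. Each county
    gets 1–3 ZIP codes, unique across the table.
    """
    if n_counties < 1:
        raise ValueError("n_counties must be >= 1")
    rng = random.Random(seed)
    counties: dict[str, CountyRecord] = {}
    crosswalk: dict[str, str] = {}
    # Enough unique ZIPs for up to 3 per county.
    zips = rng.sample(range(1, 100000), 3 * n_counties)
    z = 0
    for i in range(n_counties):
        lead_lo, lead_hi = _LEAD_INTERVALS[i % 5]
        air_lo, air_hi = _AIR_INTERVALS[(i // 5) % 3]
        county_id = f"C{i + 1:04d}"
        counties[county_id] = CountyRecord(
            county_id=county_id,
            pct_pre1980_housing=round(rng.uniform(lead_lo, lead_hi), 2),
            pm25_annual=round(rng.uniform(air_lo, air_hi), 2),
        )
        for _ in range(rng.randint(1, 3)):
            crosswalk[f"{zips[z]:05d}"] = county_id
            z += 1
    return GeoTable(counties=counties, crosswalk=crosswalk)


# --- CSV I/O ----------------------------------------------------------------

_VINTAGE_COMMENT = "# vintage: housing ACS 2020; PM2.5 NAAQS 2020 anchor (synthetic fixture)"


def write_geotable(geo: GeoTable, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``counties.csv`` and ``crosswalk.csv`` (UTF-8, dot decimals)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counties_path = out / "counties.csv"
    crosswalk_path = out / "crosswalk.csv"
    cdf = pd.DataFrame(
        [(c.county_id, c.pct_pre1980_housing, c.pm25_annual) for c in geo.counties.values()],
        columns=COUNTIES_HEADER,
    )
    with counties_path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(_VINTAGE_COMMENT + "\n")
        cdf.to_csv(fh, index=False)
    xdf = pd.DataFrame(sorted(geo.crosswalk.items()), columns=CROSSWALK_HEADER)
    xdf.to_csv(crosswalk_path, index=False, encoding="utf-8")
    return counties_path, crosswalk_path


def load_geotable(geodata_dir: str | Path) -> GeoTable:
    """Load and validate a GeoTable from ``counties.csv`` + ``crosswalk.csv``.

    Raises :class:`MalformedGeoCSV` (with the 1-based data row number where
    applicable) or :class:`DanglingCrosswalk`.
    """
    geodata_dir = Path(geodata_dir)
    counties_path = geodata_dir / "counties.csv"
    crosswalk_path = geodata_dir / "crosswalk.csv"

    cdf = _read_csv(counties_path, COUNTIES_HEADER)
    if cdf.empty:
        raise MalformedGeoCSV(str(counties_path), "no county rows")
    counties: dict[str, CountyRecord] = {}
    for row_no, row in enumerate(cdf.itertuples(index=False), start=1):
        county_id = str(row.county_id)
        if county_id in counties:
            raise MalformedGeoCSV(str(counties_path), f"duplicate county_id {county_id!r}", row=row_no)
        try:
            counties[county_id] = CountyRecord(
                county_id=county_id,
                pct_pre1980_housing=float(row.pct_pre1980_housing),
                pm25_annual=float(row.pm25_annual),
            )
        except (TypeError, ValueError) as exc:
            raise MalformedGeoCSV(str(counties_path), str(exc), row=row_no) from exc

    xdf = _read_csv(crosswalk_path, CROSSWALK_HEADER)
    crosswalk: dict[str, str] = {}
    for row_no, row in enumerate(xdf.itertuples(index=False), start=1):
        postal = str(row.postal_code)
        if not (len(postal) == 5 and postal.isdigit()):
            raise MalformedGeoCSV(str(crosswalk_path), f"bad postal code {postal!r}", row=row_no)
        if postal in crosswalk:
            raise MalformedGeoCSV(str(crosswalk_path), f"duplicate postal code {postal!r}", row=row_no)
        crosswalk[postal] = str(row.county_id)

    return GeoTable(counties=counties, crosswalk=crosswalk)


def _read_csv(path: Path, expected_header: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise MalformedGeoCSV(str(path), "file not found")
    try:
        df = pd.read_csv(path, comment="#", dtype=str, encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise MalformedGeoCSV(str(path), "empty file") from exc
    except pd.errors.ParserError as exc:
        raise MalformedGeoCSV(str(path), str(exc)) from exc
    if list(df.columns) != expected_header:
        raise MalformedGeoCSV(
            str(path), f"expected header {expected_header}, got {list(df.columns)}"
        )
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 1
        raise MalformedGeoCSV(str(path), "missing value", row=row)
    return df
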