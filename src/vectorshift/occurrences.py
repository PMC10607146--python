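"""Occurrence-record processing.

Presence records (longitude/latitude in WGS84, optional coordinate
uncertainty in km, optional population label) are held in an
:class:`OccurrenceSet`, a thin wrapper over a pandas DataFrame. The cleaning
pipeline mirrors common SDM practice: drop malformed coordinates on load,
remove duplicates, drop records with coordinate uncertainty above a cutoff,
then spatially rarefy so no two retained records fall within a minimum
great-circle distance of each other (reducing sampling bias), and finally
split records into native and introduced populations by native-region
polygons.

Records whose uncertainty is missing are *retained* by the uncertainty
filter: an "uncertainty over X km" rule cannot apply to absent metadata.
The retained/removed counts are logged so users can audit the decision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry
from shapely.prepared import prep

from .grids import EARTH_RADIUS_KM

logger = logging.getLogger(__name__)

COLUMNS = ["lon", "lat", "uncertainty_km", "source", "population"]
POPULATIONS = ("native", "introduced", "unassigned")

__all__ = [
    "OccurrenceSet",
    "load_occurrences",
    "filter_uncertainty",
    "deduplicate",
    "great_circle_km",
    "spatial_thin",
    "split_populations",
]


@dataclass
class OccurrenceSet:
    """Ordered georeferenced presence records (WGS84)."""

    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=COLUMNS))

    def __post_init__(self) -> None:
        df = self.records.copy()
        for col in COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col == "uncertainty_km" else (
                    "unassigned" if col == "population" else ""
                )
        df = df[COLUMNS].reset_index(drop=True)
        df["lon"] = df["lon"].astype(float)
        df["lat"] = df["lat"].astype(float)
        if len(df):
            bad_lon = (df["lon"] < -180) | (df["lon"] > 180)
            bad_lat = (df["lat"] < -90) | (df["lat"] > 90)
            if (bad_lon | bad_lat).any():
                raise ValueError("coordinates out of bounds")
            unc = pd.to_numeric(df["uncertainty_km"], errors="coerce")
            if (unc.dropna() < 0).any():
                raise ValueError("negative coordinate uncertainty")
            df["uncertainty_km"] = unc
            bad_pop = ~df["population"].isin(POPULATIONS)
            if bad_pop.any():
                raise ValueError(f"unknown population labels: "
                                 f"{sorted(df.loc[bad_pop, 'population'].unique())}")
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lon(self) -> np.ndarray:
        return self.records["lon"].to_numpy()

    @property
    def lat(self) -> np.ndarray:
        return self.records["lat"].to_numpy()

    def subset(self, mask: np.ndarray) -> "OccurrenceSet":
        return OccurrenceSet(self.records.loc[np.asarray(mask)].reset_index(drop=True))

    def save(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


def load_occurrences(path: str | Path) -> OccurrenceSet:
    """Read a CSV of records; needs ``lon``/``lat`` columns.

    Rows with unparsable or out-of-bounds coordinates are dropped with a
    logged count rather than raising.
    """
    df = pd.read_csv(path)
    if "lon" not in df.columns or "lat" not in df.columns:
        raise ValueError(f"{path}: missing required columns 'lon'/'lat'")
    n_raw = len(df)
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    ok = (
        df["lon"].notna()
        & df["lat"].notna()
        & df["lon"].between(-180, 180)
        & df["lat"].between(-90, 90)
    )
    dropped = int(n_raw - ok.sum())
    if dropped:
        logger.warning("%s: dropped %d rows with invalid coordinates", path, dropped)
    df = df.loc[ok]
    if "population" in df.columns:
        df["population"] = df["population"].fillna("unassigned")
    return OccurrenceSet(df.reset_index(drop=True))


def filter_uncertainty(occ: OccurrenceSet, max_km: float = 5.0) -> OccurrenceSet:
    """Drop records whose coordinate uncertainty exceeds ``max_km`` (strict).

    Missing uncertainty is retained. Default 5 km.
    """
    if max_km <= 0:
        raise ValueError("max_km must be positive")
    unc = occ.records["uncertainty_km"]
    keep = unc.isna() | (unc <= max_km)
    n_missing = int(unc.isna().sum())
    if n_missing:
        logger.info("retained %d records with missing uncertainty", n_missing)
    return occ.subset(keep.to_numpy())


def deduplicate(occ: OccurrenceSet, precision_decimals: int = 4) -> OccurrenceSet:
    """Keep one record per rounded (lon, lat, population) key, first wins.

    4 decimals ~ 11 m at the equator.
    """
    df = occ.records
    key = pd.MultiIndex.from_arrays(
        [
            df["lon"].round(precision_decimals),
            df["lat"].round(precision_decimals),
            df["population"],
        ]
    )
    keep = ~key.duplicated(keep="first")
    return occ.subset(keep)


def great_circle_km(
    lon1: float | np.ndarray,
    lat1: float | np.ndarray,
    lon2: float | np.ndarray,
    lat2: float | np.ndarray,
) -> float | np.ndarray:
    """Haversine great-circle distance in km, spherical Earth R = 6371 km."""
    lon1, lat1, lon2, lat2 = map(np.radians, (np.asarray(lon1, float),
                                              np.asarray(lat1, float),
                                              np.asarray(lon2, float),
                                              np.asarray(lat2, float)))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def spatial_thin(
    occ: OccurrenceSet,
    radius_km: float = 5.0,
    seed: int | None = None,
    shuffle: bool = True,
) -> OccurrenceSet:
    """Spatial rarefaction: greedy minimum-distance thinning.

    Visits records in a seed-shuffled order (or input order when
    ``shuffle=False``) and keeps a record iff it lies at least ``radius_km``
    (great-circle) from every previously kept record. The result is
    deterministic given the seed, and no two retained records are closer
    than ``radius_km``.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    n = len(occ)
    if n == 0:
        return occ
    order = np.arange(n)
    if shuffle:
        rng = np.random.default_rng(seed)
        rng.shuffle(order)
    lon, lat = occ.lon, occ.lat
    kept: list[int] = []
    kept_lon = np.empty(n)
    kept_lat = np.empty(n)
    for i in order:
        if kept:
            d = great_circle_km(lon[i], lat[i], kept_lon[: len(kept)], kept_lat[: len(kept)])
            if np.min(d) < radius_km:
                continue
        kept_lon[len(kept)] = lon[i]
        kept_lat[len(kept)] = lat[i]
        kept.append(i)
    mask = np.zeros(n, dtype=bool)
    mask[kept] = True
    return occ.subset(mask)


def split_populations(
    occ: OccurrenceSet, native_polygons: Sequence[BaseGeometry] | BaseGeometry
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Assign records to native/introduced by native-region polygons.

    Points inside or on the boundary of any native polygon are native, all
    others introduced. Records already labelled keep their label; a conflict
    between an existing label and the polygon assignment logs a warning.
    """
    if isinstance(native_polygons, BaseGeometry):
        native_polygons = [native_polygons]
    for poly in native_polygons:
        if not poly.is_valid:
            raise ValueError("invalid native-region polygon geometry")
    prepared = [prep(p) for p in native_polygons]
    df = occ.records
    inside = np.zeros(len(df), dtype=bool)
    for i, (x, y) in enumerate(zip(df["lon"], df["lat"])):
        pt = Point(x, y)
        inside[i] = any(pp.intersects(pt) for pp in prepared)  # boundary-inclusive
    assigned = np.where(inside, "native", "introduced")
    pre = df["population"].to_numpy()
    labelled = pre != "unassigned"
    n_conflict = int(np.sum(labelled & (pre != assigned)))
    if n_conflict:
        logger.warning("%d pre-labelled records conflict with polygon assignment", n_conflict)
    final = np.where(labelled, pre, assigned)
    out = df.copy()
    out["population"] = final
    native = OccurrenceSet(out.loc[final == "native"].reset_index(drop=True))
    introduced = OccurrenceSet(out.loc[final == "introduced"].reset_index(drop=True))
    return native, introduced
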