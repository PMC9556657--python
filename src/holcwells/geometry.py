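"""Geometry primitives and buffered exposure assessment.

Exposure is "cumulative": a neighborhood's exposure at buffer ``b`` is the
set of wells whose Euclidean distance to the neighborhood polygon is at most
``b`` meters (0 for interior points).  ``buffer_m = 0`` gives the
fully-contained sensitivity variant.  Wells are classified relative to the
city's appraisal year at year granularity: a well is *pre* if any of its
four recorded years is strictly earlier than the appraisal year, *undated*
if all four are missing, and *post* otherwise.
"""

from __future__ import annotations

import math

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .types import (
    ExposureRecord,
    GeometryError,
    Neighborhood,
    WELL_TYPES,
    WellRecord,
)

__all__ = [
    "polygon_area_km2",
    "classify_well_period",
    "wells_within_buffer",
    "assess_exposure",
    "exposure_table",
    "lonlat_to_local_meters",
]


def polygon_area_km2(geometry: BaseGeometry) -> float:
    """Planar (shoelace) area of a polygon in km², holes subtracted.

    The polygon must be valid, non-empty and in a CRS measured in meters.
    """
    if geometry is None or geometry.is_empty:
        raise GeometryError("empty geometry")
    if not geometry.is_valid:
        raise GeometryError("invalid (self-intersecting?) polygon")
    area_m2 = geometry.area
    if area_m2 <= 0:
        raise GeometryError("degenerate polygon with zero area")
    return area_m2 / 1e6


def classify_well_period(well: WellRecord, appraisal_year: int) -> str:
    """Return ``"pre"``, ``"post"`` or ``"undated"`` for one well.

    Undated iff all four years are missing; pre iff any present year is
    strictly earlier than ``appraisal_year`` (e.g. a 1934 spud for a city
    appraised in 1935); post otherwise.
    """
    years = [y for y in well.years if y is not None]
    if not years:
        return "undated"
    if min(years) < appraisal_year:
        return "pre"
    return "post"


def wells_within_buffer(
    geometry: BaseGeometry, wells: list[WellRecord], buffer_m: float
) -> set[str]:
    """Ids of wells within ``buffer_m`` meters of the polygon (closed set).

    Distance to the polygon is 0 for points inside or on the boundary, so
    ``buffer_m = 0`` returns exactly the contained wells.
    """
    if buffer_m < 0:
        raise ValueError(f"negative buffer: {buffer_m}")
    if not wells:
        return set()
    pts = shapely.points([(w.location.x, w.location.y) for w in wells])
    hit = shapely.dwithin(geometry, pts, buffer_m)
    return {w.id for w, h in zip(wells, hit) if h}


def assess_exposure(
    nbhd: Neighborhood,
    wells: list[WellRecord],
    buffer_m: float = 100.0,
    well_types: tuple[str, ...] | None = None,
) -> ExposureRecord:
    """Full exposure record for one neighborhood at one buffer.

    Composes :func:`wells_within_buffer`, :func:`classify_well_period` (with
    the neighborhood's appraisal year) and :func:`polygon_area_km2`.
    ``well_types`` restricts the analysis to a subset of the five types;
    by default all types count.
    """
    if well_types is not None:
        wells = [w for w in wells if w.well_type in well_types]
    in_buffer = wells_within_buffer(nbhd.geometry, wells, buffer_m)
    counts = {"all": 0, "pre": 0, "post": 0, "undated": 0}
    by_type = {t: 0 for t in WELL_TYPES}
    for w in wells:
        if w.id not in in_buffer:
            continue
        counts["all"] += 1
        counts[classify_well_period(w, nbhd.appraisal_year)] += 1
        by_type[w.well_type] += 1
    area = polygon_area_km2(nbhd.geometry)
    return ExposureRecord(
        neighborhood_id=nbhd.id,
        buffer_m=buffer_m,
        counts=counts,
        area_km2=area,
        density_all=counts["all"] / area,
        counts_by_type=by_type,
    )


def exposure_table(
    neighborhoods: list[Neighborhood],
    wells: list[WellRecord],
    buffer_m: float = 100.0,
    well_types: tuple[str, ...] | None = None,
):
    """Exposure for every neighborhood as a tidy DataFrame.

    One row per neighborhood with all/pre/post/undated counts, per-period
    densities (the denominator is always the neighborhood's own area) and
    per-type counts for the all-time period.
    """
    import pandas as pd

    rows = []
    for nb in neighborhoods:
        rec = assess_exposure(nb, wells, buffer_m, well_types)
        row = {
            "neighborhood_id": rec.neighborhood_id,
            "city": nb.city,
            "grade": nb.grade.value,
            "buffer_m": buffer_m,
            "area_km2": rec.area_km2,
            **{f"count_{k}": v for k, v in rec.counts.items()},
            **{f"density_{k}": rec.counts[k] / rec.area_km2 for k in rec.counts},
            **{f"n_{t}": rec.counts_by_type.get(t, 0) for t in WELL_TYPES},
        }
        rows.append(row)
    return pd.DataFrame(rows)


def lonlat_to_local_meters(
    lonlat: np.ndarray, origin: tuple[float, float] | None = None
) -> np.ndarray:
    """Project lon/lat degrees to local planar meters.

    Equirectangular projection about ``origin`` (default: centroid of the
    input), adequate at city scale for synthetic or toy inputs; real studies
    should supply an already-projected CRS.
    """
    ll = np.asarray(lonlat, dtype=float)
    if origin is None:
        origin = (float(ll[:, 0].mean()), float(ll[:, 1].mean()))
    lon0, lat0 = origin
    r = 6_371_000.0
    x = np.radians(ll[:, 0] - lon0) * r * math.cos(math.radians(lat0))
    y = np.radians(ll[:, 1] - lat0) * r
    return np.column_stack([x, y])
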