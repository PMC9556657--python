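"""Areal apportionment of tract covariates onto neighborhood polygons.

Tract layers and HOLC neighborhood layers are incongruent; attributes are
transferred with intersection-area weights.  Extensive variables (counts:
population, homes) are split proportionally to the share of each tract
covered; intensive variables (proportions, medians, persons per home) are
weighted averages over the intersecting tracts, area-weighted by default or
population-weighted on request.

median_home_value is apportioned as a weighted mean of tract medians — a
true pooled median is not recoverable from tract aggregates; this is the
standard areal-interpolation compromise and is noted in the docs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from shapely.geometry.base import BaseGeometry

from .types import COVARIATE_NAMES, GeometryError, Neighborhood

logger = logging.getLogger(__name__)

__all__ = [
    "VariableSpec",
    "DEFAULT_SPECS",
    "intersection_weights",
    "apportion_profile",
    "apportion_table",
]


@dataclass(frozen=True)
class VariableSpec:
    """How one tract variable transfers onto a neighborhood.

    ``kind="extensive"`` sums tract values scaled by the covered tract
    fraction; ``kind="intensive"`` averages tract values with weights given
    by ``weight_basis`` ("area": intersection area; "population": covered
    population).
    """

    name: str
    kind: str  # "extensive" | "intensive"
    weight_basis: str = "area"  # for intensive: "area" | "population"

    def __post_init__(self) -> None:
        if self.kind not in ("extensive", "intensive"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.weight_basis not in ("area", "population"):
            raise ValueError(f"unknown weight_basis {self.weight_basis!r}")


DEFAULT_SPECS: tuple[VariableSpec, ...] = tuple(
    VariableSpec(name, "extensive" if name in ("total_population", "n_homes") else "intensive")
    for name in COVARIATE_NAMES
)


def intersection_weights(
    nbhd_geometry: BaseGeometry, tracts: list[tuple[str, BaseGeometry]]
) -> dict[str, tuple[float, float]]:
    """Per-tract weights ``(w_ext, w_int)`` for one neighborhood.

    ``w_ext = |nbhd ∩ tract| / |tract|`` (fraction of the tract covered) and
    ``w_int = |nbhd ∩ tract|`` (raw intersection area, m²).  Tracts with an
    empty intersection are omitted.
    """
    if not nbhd_geometry.is_valid:
        raise GeometryError("invalid neighborhood polygon")
    out: dict[str, tuple[float, float]] = {}
    for tract_id, geom in tracts:
        if not geom.is_valid:
            raise GeometryError(f"invalid tract polygon {tract_id}")
        inter = nbhd_geometry.intersection(geom).area
        if inter > 0:
            out[tract_id] = (inter / geom.area, inter)
    return out


def apportion_profile(
    nbhd: Neighborhood,
    tracts: list[tuple[str, BaseGeometry]],
    attributes: pd.DataFrame,
    specs: tuple[VariableSpec, ...] = DEFAULT_SPECS,
) -> dict[str, float]:
    """Apportioned covariate profile for one neighborhood.

    ``attributes`` is indexed by tract id with one column per spec name
    (plus ``total_population`` if any spec uses the population basis).
    Returns a dict with the covariates, ``neighborhood_id`` and
    ``coverage_frac`` — the fraction of the neighborhood overlapped by any
    tract.  Zero coverage yields NaN covariates and is flagged downstream.
    """
    for spec in specs:
        if spec.name not in attributes.columns:
            raise KeyError(f"tract table lacks column {spec.name!r}")
    weights = intersection_weights(nbhd.geometry, tracts)
    profile: dict[str, float] = {"neighborhood_id": nbhd.id}
    coverage = sum(w_int for _, w_int in weights.values()) / nbhd.geometry.area
    profile["coverage_frac"] = min(coverage, 1.0)
    if not weights:
        logger.warning("neighborhood %s has no census overlap", nbhd.id)
        for spec in specs:
            profile[spec.name] = float("nan")
        return profile
    ids = list(weights)
    for spec in specs:
        vals = attributes.loc[ids, spec.name].to_numpy(dtype=float)
        if spec.kind == "extensive":
            profile[spec.name] = float(
                sum(v * weights[i][0] for i, v in zip(ids, vals))
            )
        else:
            if spec.weight_basis == "area":
                om = [weights[i][1] for i in ids]
            else:
                pop = attributes.loc[ids, "total_population"].to_numpy(dtype=float)
                om = [weights[i][0] * p for i, p in zip(ids, pop)]
            tot = sum(om)
            if tot <= 0:
                profile[spec.name] = float("nan")
            else:
                profile[spec.name] = float(
                    sum(v * o for v, o in zip(vals, om)) / tot
                )
    return profile


def apportion_table(
    neighborhoods: list[Neighborhood],
    tracts: list[tuple[str, BaseGeometry]],
    attributes: pd.DataFrame,
    specs: tuple[VariableSpec, ...] = DEFAULT_SPECS,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Profiles for every neighborhood, with an ``included`` flag.

    Neighborhoods whose tract coverage falls below ``min_coverage`` are
    flagged out of the matched analyses (mirroring the restriction of the
    matched analyses to cities with census tract data).
    """
    from shapely import STRtree

    tree = STRtree([geom for _, geom in tracts])
    rows = []
    for nb in neighborhoods:
        cand = [tracts[j] for j in tree.query(nb.geometry)]
        rows.append(apportion_profile(nb, cand, attributes, specs))
    df = pd.DataFrame(rows).set_index("neighborhood_id")
    df["included"] = df["coverage_frac"] >= min_coverage
    n_out = int((~df["included"]).sum())
    if n_out:
        logger.info("apportion: %d neighborhoods below coverage %.2f", n_out, min_coverage)
    return df
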