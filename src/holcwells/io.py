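"""File formats of the pipeline: GeoJSON layers, CSV tables, JSON truth.

Neighborhood and tract layers are GeoJSON FeatureCollections in a planar
CRS (meters).  Wells travel as CSV with columns id, x_m, y_m, well_type and
the four optional years (empty string = missing).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import Point, mapping, shape

from .synthetic import GroundTruth, SyntheticStudy
from .types import Grade, Neighborhood, WellRecord

WELL_COLUMNS = [
    "id", "x_m", "y_m", "well_type",
    "spud_year", "completion_year", "first_prod_year", "last_prod_year",
]


def write_neighborhoods_geojson(neighborhoods: list[Neighborhood], path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(nb.geometry),
            "properties": {
                "id": nb.id,
                "city": nb.city,
                "grade": nb.grade.value,
                "appraisal_year": nb.appraisal_year,
            },
        }
        for nb in neighborhoods
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_neighborhoods_geojson(path) -> list[Neighborhood]:
    fc = json.loads(Path(path).read_text())
    out = []
    for feat in fc["features"]:
        p = feat["properties"]
        out.append(Neighborhood(
            id=str(p["id"]), city=str(p["city"]), grade=Grade(p["grade"]),
            geometry=shape(feat["geometry"]), appraisal_year=int(p["appraisal_year"]),
        ))
    return out


def write_tracts(tracts, attributes: pd.DataFrame, geo_path, csv_path) -> None:
    features = [
        {"type": "Feature", "geometry": mapping(geom), "properties": {"id": tid}}
        for tid, geom in tracts
    ]
    Path(geo_path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )
    attributes.to_csv(csv_path)


def read_tracts(geo_path, csv_path):
    fc = json.loads(Path(geo_path).read_text())
    tracts = [(str(f["properties"]["id"]), shape(f["geometry"])) for f in fc["features"]]
    attributes = pd.read_csv(csv_path, index_col=0)
    return tracts, attributes


def write_wells_csv(wells: list[WellRecord], path) -> None:
    rows = [
        {
            "id": w.id, "x_m": w.location.x, "y_m": w.location.y,
            "well_type": w.well_type,
            "spud_year": w.spud_year, "completion_year": w.completion_year,
            "first_prod_year": w.first_prod_year, "last_prod_year": w.last_prod_year,
        }
        for w in wells
    ]
    pd.DataFrame(rows, columns=WELL_COLUMNS).to_csv(path, index=False)


def read_wells_csv(path) -> list[WellRecord]:
    df = pd.read_csv(path, dtype={"id": str})
    out = []
    for row in df.itertuples(index=False):
        years = {}
        for col in ("spud_year", "completion_year", "first_prod_year", "last_prod_year"):
            v = getattr(row, col)
            years[col] = None if pd.isna(v) else int(v)
        out.append(WellRecord(
            id=str(row.id), location=Point(float(row.x_m), float(row.y_m)),
            well_type=str(row.well_type), **years,
        ))
    return out


def write_truth_json(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_jsonable(), sort_keys=True))


def read_truth_json(path) -> GroundTruth:
    return GroundTruth.from_jsonable(json.loads(Path(path).read_text()))


def write_config_txt(config, path) -> None:
    """Plain key-value dump of any dataclass-like config."""
    items = vars(config) if not hasattr(config, "__dataclass_fields__") else {
        k: getattr(config, k) for k in config.__dataclass_fields__
    }
    lines = [f"{k} = {v}" for k, v in items.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_study(study: SyntheticStudy, outdir) -> dict[str, Path]:
    """Write the standard pipeline inputs for one synthetic city."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "neighborhoods": outdir / "neighborhoods.geojson",
        "tracts_geo": outdir / "tracts.geojson",
        "tracts_csv": outdir / "tracts.csv",
        "wells": outdir / "wells.csv",
        "truth": outdir / "truth.json",
        "config": outdir / "config.txt",
    }
    write_neighborhoods_geojson(study.neighborhoods, paths["neighborhoods"])
    write_tracts(study.tracts, study.tract_attributes, paths["tracts_geo"], paths["tracts_csv"])
    write_wells_csv(study.wells, paths["wells"])
    write_truth_json(study.truth, paths["truth"])
    if study.config is not None:
        write_config_txt(study.config, paths["config"])
    return paths


def read_study_inputs(indir):
    """Read the pipeline inputs written by :func:`write_study`."""
    indir = Path(indir)
    neighborhoods = read_neighborhoods_geojson(indir / "neighborhoods.geojson")
    tracts, attributes = read_tracts(indir / "tracts.geojson", indir / "tracts.csv")
    wells = read_wells_csv(indir / "wells.csv")
    truth_path = indir / "truth.json"
    truth = read_truth_json(truth_path) if truth_path.exists() else None
    return neighborhoods, tracts, attributes, wells, truth
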