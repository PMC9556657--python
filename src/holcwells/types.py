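"""Core record types shared across the pipeline.

The geographic unit of observation is the HOLC-graded neighborhood; wells
are point events with up to four (optional) operational years; census
covariates arrive at tract level and are apportioned onto neighborhoods.
All geometry lives in a projected planar CRS with units of meters.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from shapely.geometry.base import BaseGeometry
from shapely.geometry import Point


class Grade(str, enum.Enum):
    """HOLC security grade, A (best) through D (redlined)."""

    A = "A"
    B = "B"
    C = "C"
    D = "D"

    @property
    def index(self) -> int:
        """0 for A up to 3 for D (the grade step used in log-intensities)."""
        return "ABCD".index(self.value)


GRADES = (Grade.A, Grade.B, Grade.C, Grade.D)

#: Adjacent-grade comparison pairs (better, worse).
ADJACENT_PAIRS = ((Grade.A, Grade.B), (Grade.B, Grade.C), (Grade.C, Grade.D))

PERIODS = ("all", "pre", "post")

WELL_TYPES = ("oil", "gas", "oil_and_gas", "injection", "unknown")

#: Covariate columns apportioned from tracts and fed to the propensity model.
COVARIATE_NAMES = (
    "total_population",
    "prop_black",
    "prop_foreign_born",
    "prop_nonwhite_employed",
    "prop_hs_complete",
    "n_homes",
    "median_home_value",
    "prop_major_repair",
    "prop_radio",
    "people_per_home",
)


class GeometryError(ValueError):
    """Raised for invalid or degenerate polygon input."""


@dataclass(frozen=True)
class Neighborhood:
    """A graded HOLC neighborhood polygon.

    ``geometry`` must be a valid simple polygon (holes allowed) in a planar
    CRS measured in meters; ``appraisal_year`` anchors the pre/post split.
    """

    id: str
    city: str
    grade: Grade
    geometry: BaseGeometry
    appraisal_year: int

    def __post_init__(self) -> None:
        if not self.geometry.is_valid:
            raise GeometryError(f"neighborhood {self.id}: invalid polygon")
        if self.geometry.area <= 0:
            raise GeometryError(f"neighborhood {self.id}: zero-area polygon")


@dataclass(frozen=True)
class WellRecord:
    """One well: a planar point, a type, and four optional years.

    Any of the four years may be ``None`` (missing); a well with all four
    missing is "undated" and is excluded from the pre/post analyses.
    """

    id: str
    location: Point
    well_type: str = "unknown"
    spud_year: int | None = None
    completion_year: int | None = None
    first_prod_year: int | None = None
    last_prod_year: int | None = None

    def __post_init__(self) -> None:
        if self.well_type not in WELL_TYPES:
            raise ValueError(f"well {self.id}: unknown well_type {self.well_type!r}")
        if (
            self.spud_year is not None
            and self.completion_year is not None
            and self.spud_year > self.completion_year
        ):
            raise ValueError(f"well {self.id}: spud_year > completion_year")
        if (
            self.first_prod_year is not None
            and self.last_prod_year is not None
            and self.first_prod_year > self.last_prod_year
        ):
            raise ValueError(f"well {self.id}: first_prod_year > last_prod_year")

    @property
    def years(self) -> tuple[int | None, int | None, int | None, int | None]:
        return (
            self.spud_year,
            self.completion_year,
            self.first_prod_year,
            self.last_prod_year,
        )

    @property
    def is_undated(self) -> bool:
        return all(y is None for y in self.years)


@dataclass
class ExposureRecord:
    """Per-neighborhood well counts and density for one buffer variant."""

    neighborhood_id: str
    buffer_m: float
    counts: dict[str, int]  # keys: all, pre, post, undated
    area_km2: float
    density_all: float
    counts_by_type: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = self.counts
        if c["all"] != c["pre"] + c["post"] + c["undated"]:
            raise ValueError(
                f"{self.neighborhood_id}: counts do not partition "
                f"({c['all']} != {c['pre']}+{c['post']}+{c['undated']})"
            )
        if any(v < 0 for v in c.values()):
            raise ValueError(f"{self.neighborhood_id}: negative count")
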