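"""Tract-level data model and plumbing.

Census tracts are the areal unit of the analysis.  Each tract carries a
population, a tobacco retailer count, sociodemographic percentage
covariates, a rural–urban commuting area (RUCA) primary code collapsed to
four rurality levels, and an Appalachian-county indicator.  Tobacco
retailer density (TRD) is retailers per 1000 residents.

Readers accept a CSV attribute table and an optional GeoJSON
FeatureCollection of tract polygons; retailer point lists can be assigned
to tracts by point-in-polygon lookup when per-tract counts are not supplied
directly.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from shapely.geometry import Point, shape
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

UNASSIGNED = "__unassigned__"

MANDATORY_COLUMNS = ("tract_id", "county_fips", "state", "population")
OPTIONAL_COLUMNS = (
    "retailer_count",
    "pct_poverty",
    "pct_black",
    "pct_hispanic",
    "pct_asian",
    "pct_white",
    "ruca_code",
    "appalachia",
)
PERCENT_COLUMNS = ("pct_poverty", "pct_black", "pct_hispanic", "pct_asian", "pct_white")


class SchemaError(ValueError):
    """Input table violates the expected schema."""


class DuplicateKeyError(ValueError):
    """Duplicate tract or retailer identifier."""


class RucaLevel(str, Enum):
    """Four-level collapse of the RUCA 2010 primary codes (scheme A)."""

    METROPOLITAN = "Metropolitan"
    MICROPOLITAN = "Micropolitan"
    SMALL_TOWN = "SmallTown"
    RURAL = "Rural"


#: RUCA primary code -> collapsed rurality level.
RUCA_COLLAPSE: dict[int, RucaLevel] = {
    **{c: RucaLevel.METROPOLITAN for c in (1, 2, 3)},
    **{c: RucaLevel.MICROPOLITAN for c in (4, 5, 6)},
    **{c: RucaLevel.SMALL_TOWN for c in (7, 8, 9)},
    10: RucaLevel.RURAL,
}

#: "Not coded" sentinel used by some RUCA releases; treated as missing.
RUCA_NOT_CODED = 99


@dataclass
class TractRecord:
    """One census tract with the attributes the models use.

    Percentages are on the 0–100 scale.  ``ruca_level`` is derived from
    ``ruca_code`` through :func:`collapse_ruca` and is ``None`` when the
    code is missing or not coded.  ``centroid`` holds planar coordinates
    when polygons were supplied.
    """

    tract_id: str
    county_fips: str
    state: str
    population: int
    retailer_count: int | None = None
    pct_poverty: float | None = None
    pct_black: float | None = None
    pct_hispanic: float | None = None
    pct_asian: float | None = None
    pct_white: float | None = None
    ruca_code: int | None = None
    ruca_level: RucaLevel | None = field(default=None)
    appalachia: bool | None = None
    centroid: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValueError(f"tract {self.tract_id}: population must be >= 0")
        if self.retailer_count is not None and self.retailer_count < 0:
            raise ValueError(f"tract {self.tract_id}: retailer_count must be >= 0")
        for name in PERCENT_COLUMNS:
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"tract {self.tract_id}: {name}={v} outside [0, 100]")
        if self.ruca_level is None:
            self.ruca_level = collapse_ruca(self.ruca_code)
        elif self.ruca_level is not collapse_ruca(self.ruca_code):
            raise ValueError(
                f"tract {self.tract_id}: ruca_level {self.ruca_level} inconsistent "
                f"with ruca_code {self.ruca_code}"
            )

    @property
    def trd(self) -> float:
        """Retailers per 1000 residents for this tract."""
        if self.retailer_count is None:
            raise ValueError(f"tract {self.tract_id}: retailer_count missing")
        return compute_trd(self.retailer_count, self.population)


@dataclass(frozen=True)
class RetailerPoint:
    """A geocoded tobacco retailer with its list-source label."""

    retailer_id: str
    location: tuple[float, float]
    source_label: str = ""

    def __post_init__(self) -> None:
        x, y = self.location
        if not (math.isfinite(x) and math.isfinite(y)):
            raise ValueError(f"retailer {self.retailer_id}: non-finite coordinates")


@dataclass(frozen=True)
class TractDensity:
    tract_id: str
    trd: float


def collapse_ruca(ruca_code: int | None) -> RucaLevel | None:
    """Collapse a RUCA 2010 primary code to one of four rurality levels.

    Codes 1–3 map to Metropolitan, 4–6 to Micropolitan, 7–9 to Small Town
    and 10 to Rural.  ``None`` and the 99 "not coded" sentinel yield
    ``None``; anything else is a domain error.
    """
    if ruca_code is None or ruca_code == RUCA_NOT_CODED:
        return None
    try:
        return RUCA_COLLAPSE[int(ruca_code)]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"RUCA code {ruca_code!r} outside 1..10") from exc


def compute_trd(retailer_count: int, population: int) -> float:
    """Tobacco retailer density: retailers per 1000 residents."""
    if population <= 0:
        raise ValueError("population must be positive; filter low-population tracts first")
    return 1000.0 * retailer_count / population


def filter_min_population(
    tracts: Sequence[TractRecord], min_pop: int = 100
) -> tuple[list[TractRecord], int]:
    """Drop tracts below a minimum population (default 100, inclusive keep).

    Returns the retained tracts and the number removed.  Guards against
    modelling rates in tracts where a per-1000 denominator is unstable.
    """
    kept = [t for t in tracts if t.population >= min_pop]
    removed = len(tracts) - len(kept)
    if removed:
        logger.info("filter_min_population: removed %d tracts below %d", removed, min_pop)
    return kept, removed


_FIPS_RE = re.compile(r"^\d{5}$")


def flag_appalachia(county_fips: str, arc_county_list: Iterable[str]) -> bool:
    """True iff the 5-digit county FIPS is in the ARC-designated county set."""
    if not _FIPS_RE.match(county_fips):
        raise ValueError(f"malformed county FIPS {county_fips!r}; expected 5 digits")
    return county_fips in set(arc_county_list)


def _norm_label(label: str) -> str:
    return " ".join(label.casefold().split())


def dedupe_retailers(
    points: Sequence[RetailerPoint], radius: float
) -> list[RetailerPoint]:
    """Remove near-duplicate retailer points.

    Two points are duplicates when their planar distance is <= ``radius``
    and their normalized source labels match (case/whitespace folded).  The
    lexicographically smallest ``retailer_id`` in each duplicate group is
    retained, making the result deterministic regardless of input order.
    """
    if radius < 0:
        raise ValueError("dedupe radius must be >= 0")
    kept: list[RetailerPoint] = []
    for p in sorted(points, key=lambda q: q.retailer_id):
        dup = any(
            _norm_label(p.source_label) == _norm_label(q.source_label)
            and math.dist(p.location, q.location) <= radius
            for q in kept
        )
        if not dup:
            kept.append(p)
    return kept


def assign_retailers_to_tracts(
    points: Sequence[RetailerPoint], polygons: Mapping[str, object]
) -> dict[str, int]:
    """Count retailer points per tract by point-in-polygon lookup.

    ``polygons`` maps tract_id to a shapely geometry in the same planar
    CRS as the points.  Points falling in no tract are tallied under
    :data:`UNASSIGNED` (and logged); assigned + unassigned equals the
    number of input points.  Boundary points go to the first covering
    tract in sorted tract_id order.
    """
    if not polygons:
        raise ValueError("empty polygon set")
    ids = sorted(polygons)
    geoms = []
    for tid in ids:
        g = polygons[tid]
        if g is None or g.is_empty or not g.is_valid:
            raise ValueError(f"invalid geometry for tract {tid}")
        geoms.append(g)
    tree = STRtree(geoms)
    counts: dict[str, int] = {tid: 0 for tid in ids}
    counts[UNASSIGNED] = 0
    for p in points:
        pt = Point(*p.location)
        hits = sorted(
            int(i) for i in tree.query(pt, predicate="intersects")
        )
        if hits:
            counts[ids[hits[0]]] += 1
        else:
            counts[UNASSIGNED] += 1
    if counts[UNASSIGNED]:
        logger.warning(
            "assign_retailers_to_tracts: %d points fell outside all tracts",
            counts[UNASSIGNED],
        )
    return counts


# ---------------------------------------------------------------------------
# readers / writers

def _parse_optional_float(v: str) -> float | None:
    return None if v is None or v.strip() == "" else float(v)


def _parse_optional_int(v: str) -> int | None:
    return None if v is None or v.strip() == "" else int(float(v))


def _parse_optional_bool(v: str) -> bool | None:
    if v is None or v.strip() == "":
        return None
    s = v.strip().lower()
    if s in ("1", "true", "yes", "y"):
        return True
    if s in ("0", "false", "no", "n"):
        return False
    raise ValueError(f"cannot parse boolean {v!r}")


def read_polygons(polygons_path: str | Path) -> dict[str, object]:
    """Read a GeoJSON FeatureCollection into {tract_id: shapely geometry}."""
    with open(polygons_path) as fh:
        gj = json.load(fh)
    out: dict[str, object] = {}
    for feat in gj.get("features", []):
        tid = str(feat.get("properties", {}).get("tract_id", feat.get("id")))
        out[tid] = shape(feat["geometry"])
    return out


def read_tracts(
    attr_table_path: str | Path, polygons_path: str | Path | None = None
) -> list[TractRecord]:
    """Read the tract attribute CSV (and optional polygon GeoJSON).

    Mandatory columns: tract_id, county_fips, state, population.  Optional
    columns yield ``None``-valued fields when absent or blank.  When
    polygons are supplied, tract centroids are attached; polygon features
    with no matching CSV row are ignored with a warning.
    """
    with open(attr_table_path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in MANDATORY_COLUMNS:
            if col not in header:
                raise SchemaError(f"missing mandatory column {col!r}")
        rows = list(reader)

    centroids: dict[str, tuple[float, float]] = {}
    if polygons_path is not None:
        polys = read_polygons(polygons_path)
        csv_ids = {r["tract_id"] for r in rows}
        for tid, geom in polys.items():
            if tid not in csv_ids:
                logger.warning("polygon feature %s has no CSV row; ignored", tid)
                continue
            c = geom.centroid
            centroids[tid] = (c.x, c.y)

    records: list[TractRecord] = []
    seen: set[str] = set()
    for row in rows:
        tid = row["tract_id"]
        if tid in seen:
            raise DuplicateKeyError(f"duplicate tract_id {tid!r}")
        seen.add(tid)
        records.append(
            TractRecord(
                tract_id=tid,
                county_fips=row["county_fips"],
                state=row["state"],
                population=int(float(row["population"])),
                retailer_count=_parse_optional_int(row.get("retailer_count", "")),
                pct_poverty=_parse_optional_float(row.get("pct_poverty", "")),
                pct_black=_parse_optional_float(row.get("pct_black", "")),
                pct_hispanic=_parse_optional_float(row.get("pct_hispanic", "")),
                pct_asian=_parse_optional_float(row.get("pct_asian", "")),
                pct_white=_parse_optional_float(row.get("pct_white", "")),
                ruca_code=_parse_optional_int(row.get("ruca_code", "")),
                appalachia=_parse_optional_bool(row.get("appalachia", "")),
                centroid=centroids.get(tid),
            )
        )
    return records


def write_tracts(tracts: Sequence[TractRecord], path: str | Path) -> None:
    """Write tract records to the canonical CSV dialect."""
    cols = list(MANDATORY_COLUMNS) + list(OPTIONAL_COLUMNS)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for t in tracts:
            w.writerow(
                [
                    t.tract_id,
                    t.county_fips,
                    t.state,
                    t.population,
                    "" if t.retailer_count is None else t.retailer_count,
                    *[
                        "" if getattr(t, c) is None else repr(getattr(t, c))
                        for c in PERCENT_COLUMNS
                    ],
                    "" if t.ruca_code is None else t.ruca_code,
                    "" if t.appalachia is None else int(t.appalachia),
                ]
            )


def read_retailers(path: str | Path) -> list[RetailerPoint]:
    """Read retailer points from CSV columns retailer_id,x,y,source_label."""
    out: list[RetailerPoint] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                RetailerPoint(
                    retailer_id=row["retailer_id"],
                    location=(float(row["x"]), float(row["y"])),
                    source_label=row.get("source_label", ""),
                )
            )
    return out


def tracts_to_frame(tracts: Sequence[TractRecord]):
    """Tract records as a pandas DataFrame (one row per tract)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "tract_id": [t.tract_id for t in tracts],
            "county_fips": [t.county_fips for t in tracts],
            "state": [t.state for t in tracts],
            "population": [t.population for t in tracts],
            "retailer_count": [t.retailer_count for t in tracts],
            "pct_poverty": [t.pct_poverty for t in tracts],
            "pct_black": [t.pct_black for t in tracts],
            "pct_hispanic": [t.pct_hispanic for t in tracts],
            "pct_asian": [t.pct_asian for t in tracts],
            "pct_white": [t.pct_white for t in tracts],
            "ruca_code": [t.ruca_code for t in tracts],
            "ruca_level": [None if t.ruca_level is None else t.ruca_level.value for t in tracts],
            "appalachia": [t.appalachia for t in tracts],
        }
    )


def with_counts(
    tracts: Sequence[TractRecord], counts: Mapping[str, int]
) -> list[TractRecord]:
    """Return tracts with retailer_count replaced from an assignment map."""
    return [replace(t, retailer_count=int(counts.get(t.tract_id, 0))) for t in tracts]
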