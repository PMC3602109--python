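"""From occurrence records to operational geographic units (OGUs).

Occurrence records (taxon, longitude, latitude in decimal degrees, WGS84)
are binned either into grid quadrats (default 5 deg x 5 deg, anchored at
(0E, 0N)) or assigned to named provinces via a lookup table or GeoJSON
polygons.  The resulting assignment becomes a binary presence/absence
matrix with an appended all-zero outgroup row.
"""
from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .matrix import MatrixError, PresenceMatrix

__all__ = [
    "OccurrenceRecord",
    "OGU",
    "GeoError",
    "read_occurrences",
    "grid_quadrats",
    "assign_provinces",
    "build_matrix",
]


class GeoError(ValueError):
    pass


@dataclass(frozen=True)
class OccurrenceRecord:
    taxon: str
    lon: float
    lat: float
    source: str = ""

    def validate(self) -> None:
        if not self.taxon:
            raise GeoError("empty taxon name")
        if not (math.isfinite(self.lon) and math.isfinite(self.lat)):
            raise GeoError(f"non-finite coordinates for {self.taxon}")
        if not (-180.0 <= self.lon < 180.0):
            raise GeoError(f"longitude {self.lon} out of [-180, 180) for {self.taxon}")
        if not (-90.0 <= self.lat <= 90.0):
            raise GeoError(f"latitude {self.lat} out of [-90, 90] for {self.taxon}")


@dataclass(frozen=True)
class OGU:
    """Operational geographic unit: a grid quadrat or a named province."""

    id: str
    kind: str  # "quadrat" | "province"
    bounds: tuple[float, float, float, float] | None = None  # (w, e, s, n)

    def contains(self, lon: float, lat: float) -> bool:
        if self.bounds is None:
            raise GeoError(f"{self.id} has no bounds")
        w, e, s, n = self.bounds
        return w <= lon < e and s <= lat < n


def read_occurrences(path: str | Path) -> list[OccurrenceRecord]:
    """Read a CSV/TSV with header taxon,lon,lat[,source]."""
    path = Path(path)
    delim = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        for i, row in enumerate(reader):
            try:
                rec = OccurrenceRecord(
                    taxon=row["taxon"].strip(),
                    lon=float(row["lon"]),
                    lat=float(row["lat"]),
                    source=(row.get("source") or "").strip(),
                )
                rec.validate()
            except (KeyError, ValueError) as exc:
                raise GeoError(f"record {i}: {exc}") from exc
            records.append(rec)
    return records


def grid_quadrats(
    records: list[OccurrenceRecord],
    cell_deg: float = 5.0,
    anchor: tuple[float, float] = (0.0, 0.0),
) -> tuple[list[OGU], dict[int, str]]:
    """Bin records into half-open grid cells [west, east) x [south, north).

    Only occupied cells are returned; ids are assigned in row-major order,
    south to north then west to east, so the labelling is deterministic
    for a given set of records regardless of their input order.
    """
    if cell_deg <= 0 or 360.0 % cell_deg != 0:
        raise GeoError(f"cell size {cell_deg} must be positive and divide 360")
    bad = [i for i, r in enumerate(records) if _invalid(r)]
    if bad:
        raise GeoError(f"out-of-range coordinates at record indices {bad}")
    ax, ay = anchor
    cell_of: dict[int, tuple[int, int]] = {}
    for i, r in enumerate(records):
        cx = math.floor((r.lon - ax) / cell_deg)
        cy = math.floor((r.lat - ay) / cell_deg)
        cell_of[i] = (cy, cx)
    occupied = sorted(set(cell_of.values()))
    ogus = []
    id_of_cell: dict[tuple[int, int], str] = {}
    for k, (cy, cx) in enumerate(occupied, start=1):
        w = ax + cx * cell_deg
        s = ay + cy * cell_deg
        ogu = OGU(id=f"Quadrat {k}", kind="quadrat", bounds=(w, w + cell_deg, s, s + cell_deg))
        ogus.append(ogu)
        id_of_cell[(cy, cx)] = ogu.id
    assignment = {i: id_of_cell[cell] for i, cell in cell_of.items()}
    return ogus, assignment


def _invalid(r: OccurrenceRecord) -> bool:
    try:
        r.validate()
        return False
    except GeoError:
        return True


def _load_polygons(source: str | Path) -> list[tuple[str, object]]:
    from shapely.geometry import shape

    with open(source) as fh:
        gj = json.load(fh)
    polys = []
    for feat in gj["features"]:
        name = feat["properties"]["name"]
        polys.append((name, shape(feat["geometry"])))
    return polys


def assign_provinces(
    records: list[OccurrenceRecord],
    province_source: str | Path | dict[str, str],
) -> tuple[dict[int, str], list[int]]:
    """Assign each record to a named province.

    ``province_source`` is either a lookup mapping (taxon -> province, or a
    path to a two-column CSV of the same), or a path to a GeoJSON file of
    province polygons with a "name" property (point-in-polygon assignment
    via shapely).  Returns (record index -> province, unassigned indices).
    Ambiguous polygon membership raises; falling in no polygon (or missing
    a lookup entry) lands in the unassigned report rather than vanishing.
    """
    lookup: dict[str, str] | None = None
    if isinstance(province_source, dict):
        lookup = dict(province_source)
    else:
        path = Path(province_source)
        if path.suffix.lower() in (".json", ".geojson"):
            polys = _load_polygons(path)
            return _assign_by_polygons(records, polys)
        lookup = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if len(row) >= 2:
                    lookup[row[0].strip()] = row[1].strip()

    assignment: dict[int, str] = {}
    unassigned: list[int] = []
    for i, r in enumerate(records):
        if r.taxon in lookup:
            assignment[i] = lookup[r.taxon]
        else:
            unassigned.append(i)
    if unassigned:
        missing = sorted({records[i].taxon for i in unassigned})
        raise GeoError(
            f"no lookup entry for taxa {missing} "
            f"(record indices {unassigned})"
        )
    return assignment, unassigned


def _assign_by_polygons(records, polys):
    from shapely.geometry import Point

    assignment: dict[int, str] = {}
    unassigned: list[int] = []
    for i, r in enumerate(records):
        pt = Point(r.lon, r.lat)
        inside = [name for name, poly in polys if poly.covers(pt)]
        if len(inside) > 1:
            raise GeoError(
                f"record {i} ({r.taxon} at {r.lon},{r.lat}) falls in "
                f"overlapping provinces {inside}"
            )
        if inside:
            assignment[i] = inside[0]
        else:
            unassigned.append(i)
    return assignment, unassigned


def build_matrix(
    records: list[OccurrenceRecord],
    assignment: dict[int, str],
    taxa: list[str],
    outgroup_label: str = "Outgroup",
    ogus: list[OGU] | None = None,
) -> PresenceMatrix:
    """Presence/absence matrix from an assignment of records to OGUs.

    A cell is 1 iff at least one record of the taxon was assigned to the
    area (duplicates collapse); the all-zero outgroup row is appended.
    Area order follows ``ogus`` when given, else first appearance.
    """
    unknown = sorted({records[i].taxon for i in assignment} - set(taxa))
    if unknown:
        raise MatrixError(f"taxa missing from the taxon list: {unknown}")
    if ogus is not None:
        areas = [o.id for o in ogus]
    else:
        areas = list(dict.fromkeys(assignment[i] for i in sorted(assignment)))
    ti = {t: j for j, t in enumerate(taxa)}
    ai = {a: j for j, a in enumerate(areas)}
    cells = np.zeros((len(areas) + 1, len(taxa)), dtype=np.int8)
    for i, area in assignment.items():
        cells[ai[area] + 1, ti[records[i].taxon]] = 1
    all_areas = [outgroup_label] + areas
    return PresenceMatrix.from_arrays(all_areas, list(taxa), cells, outgroup=outgroup_label)
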