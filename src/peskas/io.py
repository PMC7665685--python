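"""Readers and writers for the four input tables and aggregated outputs.

All interchange is plain text: UTF-8 comma-separated CSV with ISO-8601
dates, or GeoJSON for point streams.  Timestamps are interpreted in a
single configured timezone (naive, UTC by convention).

Landings CSV schema (one row per landing record, trip-level columns
repeated across the trip's rows):

    trip_id, site, municipality, date, boat_type, gear, habitat,
    n_fishers, duration_h, unit_id, record_id, taxon_code,
    fork_length_cm, n_individuals, price, price_basis
    [, est_weight_kg, flags]   # written by the pipeline, optional on read

Tracks CSV schema: unit_id, timestamp, lat, lon [, boat_type]; or a
GeoJSON FeatureCollection of Points with those properties.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    BOAT_TYPES,
    GEARS,
    HABITATS,
    FleetCensus,
    FlagCode,
    GearHabitatMatrix,
    LandingRecord,
    Ping,
    SpeciesParams,
    Trip,
    VesselTrack,
)

log = logging.getLogger(__name__)

LANDINGS_MANDATORY = (
    "trip_id",
    "date",
    "boat_type",
    "gear",
    "habitat",
    "n_fishers",
    "duration_h",
    "record_id",
    "taxon_code",
    "fork_length_cm",
    "n_individuals",
)

_CANON_GEAR = {g.lower(): g for g in GEARS}
_CANON_HABITAT = {h.lower(): h for h in HABITATS}
_CANON_BOAT = {b.lower(): b for b in BOAT_TYPES}


@dataclass
class ParseError:
    row: int
    record_id: str
    message: str


@dataclass
class LandingsRead:
    """Result of reading a landings CSV: trips plus a parse-error report."""

    trips: list[Trip]
    errors: list[ParseError] = field(default_factory=list)

    def __iter__(self):
        return iter(self.trips)

    def __len__(self):
        return len(self.trips)


def _canon(value: str, table: dict[str, str], kind: str) -> str:
    key = str(value).strip().lower()
    if key not in table:
        raise ValueError(f"unknown {kind} {value!r}")
    return table[key]


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or str(value).strip() == "":
        return None
    return float(value)


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or str(value).strip() == "":
        return None
    return str(value).strip()


def read_landings(path, species: dict[str, SpeciesParams] | None = None) -> LandingsRead:
    """Read a landings CSV into Trips (rows grouped by trip_id).

    Enum fields are parsed case-insensitively.  An unknown taxon_code is
    tolerated here and flagged FORMAT_ERROR downstream.  A missing
    mandatory column is a hard error naming the column; an unparseable row
    is skipped and collected in the parse-error report.

    When a species table is supplied, per-record weights are estimated
    immediately (see :func:`peskas.qc.estimate_trip_weights`).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in LANDINGS_MANDATORY:
        if col not in df.columns:
            raise ValueError(f"landings file missing mandatory column {col!r}")

    trips: dict[str, Trip] = {}
    errors: list[ParseError] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        rec_id = getattr(row, "record_id", "")
        try:
            trip_id = str(row.trip_id).strip()
            if not trip_id:
                raise ValueError("empty trip_id")
            if trip_id not in trips:
                trips[trip_id] = Trip(
                    trip_id=trip_id,
                    site=_opt_str(getattr(row, "site", "")) or "",
                    municipality=_opt_str(getattr(row, "municipality", "")) or "",
                    date=_dt.date.fromisoformat(str(row.date).strip()),
                    boat_type=_canon(row.boat_type, _CANON_BOAT, "boat type"),
                    gear=_canon(row.gear, _CANON_GEAR, "gear"),
                    habitat=_canon(row.habitat, _CANON_HABITAT, "habitat"),
                    n_fishers=int(row.n_fishers),
                    duration_h=float(row.duration_h),
                    unit_id=_opt_str(getattr(row, "unit_id", "")),
                )
            rec = LandingRecord(
                record_id=str(rec_id).strip(),
                trip_id=trip_id,
                taxon_code=str(row.taxon_code).strip(),
                fork_length_cm=_opt_float(row.fork_length_cm),
                n_individuals=int(row.n_individuals) if str(row.n_individuals).strip() else None,
                price=_opt_float(getattr(row, "price", "")),
                price_basis=_opt_str(getattr(row, "price_basis", "")),
                est_weight_kg=_opt_float(getattr(row, "est_weight_kg", "")),
            )
            raw_flags = _opt_str(getattr(row, "flags", ""))
            if raw_flags:
                rec.flags = {FlagCode(f) for f in raw_flags.split(";")}
            trips[trip_id].landings.append(rec)
        except (ValueError, TypeError) as exc:
            errors.append(ParseError(row=i, record_id=str(rec_id), message=str(exc)))

    out = list(trips.values())
    if species is not None:
        from . import qc

        for trip in out:
            qc.estimate_trip_weights(trip, species)
    return LandingsRead(trips=out, errors=errors)


def landings_frame(trips: list[Trip]) -> pd.DataFrame:
    """Flatten trips into the landings CSV schema (one row per record)."""
    rows = []
    for t in trips:
        for r in t.landings:
            rows.append(
                {
                    "trip_id": t.trip_id,
                    "site": t.site,
                    "municipality": t.municipality,
                    "date": t.date.isoformat(),
                    "boat_type": t.boat_type,
                    "gear": t.gear,
                    "habitat": t.habitat,
                    "n_fishers": t.n_fishers,
                    "duration_h": t.duration_h,
                    "unit_id": t.unit_id if t.unit_id is not None else "",
                    "record_id": r.record_id,
                    "taxon_code": r.taxon_code,
                    "fork_length_cm": "" if r.fork_length_cm is None else r.fork_length_cm,
                    "n_individuals": "" if r.n_individuals is None else r.n_individuals,
                    "price": "" if r.price is None else r.price,
                    "price_basis": r.price_basis or "",
                    "est_weight_kg": "" if r.est_weight_kg is None else repr(r.est_weight_kg),
                    "flags": ";".join(sorted(f.value for f in r.flags)),
                }
            )
    df = pd.DataFrame(rows, columns=[
        "trip_id", "site", "municipality", "date", "boat_type", "gear", "habitat",
        "n_fishers", "duration_h", "unit_id", "record_id", "taxon_code",
        "fork_length_cm", "n_individuals", "price", "price_basis",
        "est_weight_kg", "flags",
    ])
    return df.sort_values(["trip_id", "record_id"], kind="mergesort").reset_index(drop=True)


def write_landings(trips: list[Trip], path) -> None:
    landings_frame(trips).to_csv(path, index=False)


def read_tracks(path, gap_hours: float = 2.0, default_boat_type: str | None = None) -> list[VesselTrack]:
    """Read GPS point streams (CSV or GeoJSON) and segment them into tracks.

    Points are partitioned per tracker unit and sorted by timestamp.  A gap
    longer than ``gap_hours`` (default 2 h) starts a new track — the trip
    segmentation rule for standalone track files.  Duplicate timestamps
    within a unit keep the first point; out-of-range coordinates are
    dropped; both are logged.  Segments with fewer than two pings are
    dropped (a track cannot be oriented in time from one ping).
    """
    if hasattr(path, "read"):  # file-like: sniff the first character
        pos = path.tell()
        text_head = path.read(1)
        path.seek(pos)
    elif str(path).endswith((".geojson", ".json")):
        text_head = "{"
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text_head = fh.read(1).strip()
    if text_head.startswith("{"):
        df = _geojson_points(path)
    else:
        df = pd.read_csv(path, dtype={"unit_id": str}, float_precision="round_trip")
    for col in ("unit_id", "timestamp", "lat", "lon"):
        if col not in df.columns:
            raise ValueError(f"tracks file missing mandatory column {col!r}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["lat"] = df["lat"].astype(float)
    df["lon"] = df["lon"].astype(float)

    oor = (df["lat"].abs() > 90) | (df["lon"].abs() > 180)
    if oor.any():
        log.warning("dropping %d point(s) with out-of-range coordinates", int(oor.sum()))
        df = df[~oor]

    tracks: list[VesselTrack] = []
    gap = _dt.timedelta(hours=gap_hours)
    for unit_id, grp in df.groupby("unit_id", sort=True):
        grp = grp.sort_values("timestamp", kind="mergesort")
        dup = grp["timestamp"].duplicated()
        if dup.any():
            log.warning("unit %s: dropping %d duplicate timestamp(s)", unit_id, int(dup.sum()))
            grp = grp[~dup]
        boat_type = default_boat_type
        if "boat_type" in grp.columns:
            bt = _opt_str(grp["boat_type"].iloc[0])
            if bt:
                boat_type = _CANON_BOAT.get(bt.lower(), bt)
        pings = [
            Ping(ts.to_pydatetime(), la, lo)
            for ts, la, lo in zip(grp["timestamp"], grp["lat"], grp["lon"])
        ]
        # split at gaps > threshold
        segments: list[list[Ping]] = [[pings[0]]]
        for prev, cur in zip(pings, pings[1:]):
            if cur.timestamp - prev.timestamp > gap:
                segments.append([])
            segments[-1].append(cur)
        for k, seg in enumerate(segments):
            if len(seg) < 2:
                log.warning("unit %s: dropping single-ping segment", unit_id)
                continue
            tracks.append(
                VesselTrack(
                    track_id=f"{unit_id}-{k:04d}",
                    unit_id=str(unit_id),
                    boat_type=boat_type,
                    pings=seg,
                )
            )
    return tracks


def _geojson_points(path) -> pd.DataFrame:
    if hasattr(path, "read"):
        gj = json.load(path)
    else:
        with open(path, "r", encoding="utf-8") as fh:
            gj = json.load(fh)
    rows = []
    for feat in gj.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            continue
        lon, lat = geom["coordinates"][:2]
        props = feat.get("properties") or {}
        rows.append(
            {
                "unit_id": str(props.get("unit_id", "")),
                "timestamp": props.get("timestamp"),
                "lat": float(lat),
                "lon": float(lon),
                "boat_type": props.get("boat_type", ""),
            }
        )
    return pd.DataFrame(rows)


def tracks_frame(tracks: list[VesselTrack]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for p in t.pings:
            rows.append(
                {
                    "unit_id": t.unit_id,
                    "timestamp": p.timestamp.isoformat(sep=" "),
                    "lat": p.lat,
                    "lon": p.lon,
                    "boat_type": t.boat_type or "",
                }
            )
    return pd.DataFrame(rows, columns=["unit_id", "timestamp", "lat", "lon", "boat_type"])


def write_tracks_csv(tracks: list[VesselTrack], path) -> None:
    tracks_frame(tracks).to_csv(path, index=False)


def write_tracks_geojson(tracks: list[VesselTrack], path) -> None:
    features = []
    for t in tracks:
        for p in t.pings:
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [p.lon, p.lat]},
                    "properties": {
                        "unit_id": t.unit_id,
                        "timestamp": p.timestamp.isoformat(sep=" "),
                        "boat_type": t.boat_type or "",
                    },
                }
            )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_species(path) -> dict[str, SpeciesParams]:
    df = pd.read_csv(path, float_precision="round_trip")
    table: dict[str, SpeciesParams] = {}
    for row in df.itertuples(index=False):
        p = SpeciesParams(
            taxon_code=str(row.taxon_code),
            name=str(getattr(row, "name", row.taxon_code)),
            a=float(row.a),
            b=float(row.b),
            length_min_cm=float(row.length_min_cm),
            length_max_cm=float(row.length_max_cm),
            price_min=float(row.price_min),
            price_max=float(row.price_max),
        )
        table[p.taxon_code] = p
    return table


def write_species(table: dict[str, SpeciesParams], path) -> None:
    rows = [
        {
            "taxon_code": p.taxon_code,
            "name": p.name,
            "a": p.a,
            "b": p.b,
            "length_min_cm": p.length_min_cm,
            "length_max_cm": p.length_max_cm,
            "price_min": p.price_min,
            "price_max": p.price_max,
        }
        for p in sorted(table.values(), key=lambda p: p.taxon_code)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_census(path) -> FleetCensus:
    df = pd.read_csv(path)
    return FleetCensus(
        counts={
            _canon(row.boat_type, _CANON_BOAT, "boat type"): int(row.n_boats)
            for row in df.itertuples(index=False)
        }
    )


def write_census(census: FleetCensus, path) -> None:
    pd.DataFrame(
        [{"boat_type": bt, "n_boats": n} for bt, n in sorted(census.counts.items())]
    ).to_csv(path, index=False)


def read_gear_habitat_matrix(path) -> GearHabitatMatrix:
    """Read the gear × habitat validity table (gears in rows, habitats in columns, 0/1)."""
    df = pd.read_csv(path, index_col=0)
    valid = {}
    for gear, row in df.iterrows():
        for habitat, v in row.items():
            valid[(str(gear), str(habitat))] = bool(int(v))
    return GearHabitatMatrix(valid)


def write_gear_habitat_matrix(matrix: GearHabitatMatrix, path) -> None:
    gears = sorted({g for g, _ in matrix.valid})
    df = pd.DataFrame(
        [[int(matrix.is_valid(g, h)) for h in HABITATS] for g in gears],
        index=pd.Index(gears, name="gear"),
        columns=list(HABITATS),
    )
    df.to_csv(path)


def default_gear_habitat_matrix() -> GearHabitatMatrix:
    """The editable default validity matrix shipped with the package."""
    from importlib.resources import files

    with (files("peskas") / "data" / "gear_habitat_default.csv").open("r") as fh:
        return read_gear_habitat_matrix(fh)


SUMMARY_KEY = ["month", "municipality", "boat_type", "gear", "habitat"]
SUMMARY_COLUMNS = SUMMARY_KEY + [
    "n_trips",
    "total_catch_kg",
    "total_effort_fisher_h",
    "cpue_kg_per_fisher_h",
]


def write_month_summary(aggregates: pd.DataFrame, path) -> None:
    """Write the month-aggregated summary table with deterministic row order."""
    df = aggregates.loc[:, SUMMARY_COLUMNS].sort_values(SUMMARY_KEY, kind="mergesort")
    df.to_csv(path, index=False)
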