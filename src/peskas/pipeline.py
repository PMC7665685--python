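"""End-to-end orchestration: ingest → weight estimation → QC → suppression →
track linkage, and the monthly reporting bundle.

Mirrors the daily parse flow of a landings-monitoring deployment: raw
enumerator CSVs and tracker point streams come in; a clean store, a flag
report for curation, and a track↔trip link table come out.  Re-running on
the same inputs produces byte-identical outputs, so the pipeline can be
scheduled blindly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import analytics, classify
from . import io as pio
from . import qc
from .models import FleetCensus, GearHabitatMatrix, QCBounds, Trip, VesselTrack

log = logging.getLogger(__name__)


@dataclass
class ParseConfig:
    bounds: QCBounds = field(default_factory=QCBounds)
    matrix: GearHabitatMatrix | None = None  # None => packaged default
    gap_hours: float = 2.0

    def resolved_matrix(self) -> GearHabitatMatrix:
        return self.matrix or pio.default_gear_habitat_matrix()


@dataclass
class ParseResult:
    clean_trips: list[Trip]
    all_trips: list[Trip]
    flag_report: pd.DataFrame
    parse_errors: list[pio.ParseError]
    tracks: list[VesselTrack]
    links: pd.DataFrame


def link_tracks(tracks: list[VesselTrack], trips: list[Trip]) -> pd.DataFrame:
    """Link each track to a trip sharing its GPS unit and calendar date.

    Returns a table (track_id, unit_id, trip_id, date); trip_id is empty
    for tracked-but-unobserved trips — the classifier's queries.
    """
    by_unit_date: dict[tuple[str, str], str] = {}
    for t in trips:
        if t.unit_id:
            by_unit_date[(t.unit_id, t.date.isoformat())] = t.trip_id
    rows = []
    for trk in tracks:
        date = trk.start.date().isoformat()
        trip_id = by_unit_date.get((trk.unit_id, date), "")
        trk.linked_trip_id = trip_id or None
        rows.append(
            {"track_id": trk.track_id, "unit_id": trk.unit_id, "trip_id": trip_id, "date": date}
        )
    df = pd.DataFrame(rows, columns=["track_id", "unit_id", "trip_id", "date"])
    return df.sort_values("track_id", kind="mergesort").reset_index(drop=True)


def run_parse(
    landings_path,
    tracks_path,
    species_path,
    out_dir,
    config: ParseConfig | None = None,
) -> ParseResult:
    """Ingest, estimate weights, QC, suppress, link, and write the store.

    Writes into ``out_dir``: clean_store.csv (landings schema, clean
    records only), flag_report.csv, track_trip_links.csv and
    parse_errors.csv.  Deterministic: same inputs → byte-identical files.
    """
    cfg = config or ParseConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    species = pio.read_species(species_path)
    read = pio.read_landings(landings_path, species)
    matrix = cfg.resolved_matrix()
    for trip in read.trips:
        qc.apply_filters(trip, species, matrix, cfg.bounds)
    clean_trips, flag_report = qc.suppress(read.trips)

    tracks = pio.read_tracks(tracks_path, gap_hours=cfg.gap_hours) if tracks_path else []
    links = link_tracks(tracks, read.trips)

    pio.write_landings(clean_trips, out / "clean_store.csv")
    flag_report.to_csv(out / "flag_report.csv", index=False)
    links.to_csv(out / "track_trip_links.csv", index=False)
    pd.DataFrame(
        [{"row": e.row, "record_id": e.record_id, "message": e.message} for e in read.errors],
        columns=["row", "record_id", "message"],
    ).to_csv(out / "parse_errors.csv", index=False)

    log.info(
        "parse: %d trips in, %d clean, %d flag rows, %d parse errors, %d tracks",
        len(read.trips), len(clean_trips), len(flag_report), len(read.errors), len(tracks),
    )
    return ParseResult(
        clean_trips=clean_trips,
        all_trips=read.trips,
        flag_report=flag_report,
        parse_errors=read.errors,
        tracks=tracks,
        links=links,
    )


@dataclass
class ReportBundle:
    month: str
    summary: pd.DataFrame
    cpue_table: pd.DataFrame
    composition: pd.DataFrame
    estimate: "analytics.FleetEstimate"
    heatmap: "analytics.Heatmap"

    def estimate_frame(self) -> pd.DataFrame:
        rows = [
            {
                "month": r.month,
                "boat_type": r.boat_type,
                "cpue_kg_per_fisher_h": r.cpue_kg_per_fisher_h,
                "ept_fisher_h": r.ept_fisher_h,
                "vac_trips_per_boat": r.vac_trips_per_boat,
                "n_boats": r.n_boats,
                "catch_tonnes": r.catch_tonnes,
            }
            for r in self.estimate.rows
        ]
        df = pd.DataFrame(rows, columns=[
            "month", "boat_type", "cpue_kg_per_fisher_h", "ept_fisher_h",
            "vac_trips_per_boat", "n_boats", "catch_tonnes",
        ])
        total = {
            "month": self.month, "boat_type": "TOTAL", "cpue_kg_per_fisher_h": "",
            "ept_fisher_h": "", "vac_trips_per_boat": "", "n_boats": "",
            "catch_tonnes": self.estimate.total_tonnes,
        }
        return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def species_composition(trips: list[Trip]) -> pd.DataFrame:
    """Share of clean catch weight by taxon (shares sum to 1)."""
    rows = [
        {"taxon_code": r.taxon_code, "catch_kg": r.est_weight_kg}
        for t in trips
        for r in t.landings
        if r.is_clean and r.est_weight_kg is not None
    ]
    if not rows:
        return pd.DataFrame(columns=["taxon_code", "catch_kg", "share"])
    df = pd.DataFrame(rows).groupby("taxon_code", sort=True)["catch_kg"].sum().reset_index()
    df["share"] = df["catch_kg"] / df["catch_kg"].sum()
    return df


def run_report(
    clean_trips: list[Trip],
    tracks: list[VesselTrack],
    census: FleetCensus,
    month: str,
    out_dir,
    cell_size_km: float = 1.0,
    vac_fallback: dict[str, float] | None = None,
) -> ReportBundle:
    """Produce the monthly summary bundle from the clean store.

    Writes month_summary.csv, cpue.csv, species_composition.csv,
    fleet_estimate.csv and effort_heatmap.csv into ``out_dir``.  Every
    number derives solely from clean (unflagged) records.  A month with no
    data yields empty-but-valid outputs with a warning.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    month_trips = [t for t in clean_trips if t.month == month]
    if not month_trips:
        log.warning("no clean trips for %s: writing empty outputs", month)

    summary = analytics.month_summary(month_trips)
    cpue_table = analytics.cpue(month_trips, stratifiers=("month", "boat_type"))
    composition = species_composition(month_trips)

    cpue_by = {
        str(r.boat_type): float(r.cpue) for r in cpue_table.itertuples(index=False)
    }
    ept_by = {
        bt: analytics.ept(month_trips, bt)
        for bt in {t.boat_type for t in month_trips}
    }
    vac_by = analytics.vac(tracks, month)
    if vac_fallback:
        for bt, v in vac_fallback.items():
            vac_by.setdefault(bt, v)
    if month_trips:
        estimate = analytics.national_catch(cpue_by, ept_by, vac_by, census, month)
    else:
        estimate = analytics.FleetEstimate(month=month, rows=[])

    month_tracks = [t for t in tracks if t.month == month]
    if month_tracks:
        heatmap = analytics.effort_heatmap(month_tracks, cell_size_km)
    else:
        import numpy as np

        heatmap = analytics.Heatmap(
            counts=np.zeros((1, 1), dtype=int),
            lat_edges=np.array([0.0, 1.0]),
            lon_edges=np.array([0.0, 1.0]),
            cell_size_km=cell_size_km,
        )

    bundle = ReportBundle(
        month=month,
        summary=summary,
        cpue_table=cpue_table,
        composition=composition,
        estimate=estimate,
        heatmap=heatmap,
    )
    pio.write_month_summary(summary, out / "month_summary.csv")
    cpue_table.to_csv(out / "cpue.csv", index=False)
    composition.to_csv(out / "species_composition.csv", index=False)
    bundle.estimate_frame().to_csv(out / "fleet_estimate.csv", index=False)
    heatmap.to_frame().to_csv(out / "effort_heatmap.csv", index=False)
    return bundle


def classify_unlinked(
    tracks: list[VesselTrack],
    trips: list[Trip],
    cutoff_km: float = classify.DEFAULT_CUTOFF_KM,
) -> pd.DataFrame:
    """Impute gear/habitat for tracks with no linked trip from those with one.

    Donor features come from tracks whose linked trip carries labels; all
    features share one reference origin (the mean ping position) so
    distances are comparable.
    """
    by_id = {t.trip_id: t for t in trips}
    origin = _mean_origin(tracks)
    training, queries = [], []
    for trk in tracks:
        feat = classify.extract_features(trk, reference_origin=origin)
        trip = by_id.get(trk.linked_trip_id or "")
        if trip is not None:
            feat.gear, feat.habitat = trip.gear, trip.habitat
            feat.trip_id = trip.trip_id
            training.append(feat)
        else:
            feat.trip_id = trk.track_id
            queries.append(feat)
    if not queries:
        return pd.DataFrame(columns=["track_id", "donor_trip_id", "distance_km", "gear", "habitat"])
    assignments = classify.assign_donors(queries, training, cutoff_km)
    return pd.DataFrame(
        [
            {
                "track_id": a.trip_id,
                "donor_trip_id": a.donor_id or "",
                "distance_km": a.distance_km,
                "gear": a.gear or "",
                "habitat": a.habitat or "",
            }
            for a in assignments
        ]
    ).sort_values("track_id", kind="mergesort").reset_index(drop=True)


def linked_features(
    tracks: list[VesselTrack], trips: list[Trip]
) -> list[classify.TripFeature]:
    """Features for tracks whose linked trip carries both labels."""
    by_id = {t.trip_id: t for t in trips}
    origin = _mean_origin(tracks)
    feats = []
    for trk in tracks:
        trip = by_id.get(trk.linked_trip_id or "")
        if trip is None:
            continue
        feat = classify.extract_features(trk, reference_origin=origin)
        feat.trip_id = trip.trip_id
        feat.gear, feat.habitat = trip.gear, trip.habitat
        feats.append(feat)
    return feats


def _mean_origin(tracks: list[VesselTrack]) -> tuple[float, float]:
    import numpy as np

    lats = np.array([p.lat for t in tracks for p in t.pings])
    lons = np.array([p.lon for t in tracks for p in t.pings])
    return float(lats.mean()), float(lons.mean())
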