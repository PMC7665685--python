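"""Synthetic small-scale fishery with known ground truth.

Generates everything the analytics pipeline consumes — a species
parameter table, a fleet with per-boat GPS units, trips with landings, and
5-second-cadence GPS tracks — while keeping exact bookkeeping of the
quantities the pipeline is supposed to recover: total landed weight,
trips per boat per month (the true vessel activity coefficient), each
gear's fishing ground, and the exact list of injected QC violations.

Fishing grounds are Gaussian patches keyed to gear (and its habitat):
between-ground separation and within-ground spread are independently
configurable, which is the dial that makes classifier-accuracy
properties constructive.  Tracks are out-and-back paths from a shared
home port to the trip's ground at a fixed ping cadence with GPS jitter.

All randomness flows from one seed through named substreams (species,
trips, tracks, flags, split) so modules can be tested in isolation.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .analytics import KM_PER_DEG_LAT, KM_PER_DEG_LON_EQUATOR
from .models import (
    FlagCode,
    FleetCensus,
    LandingRecord,
    Ping,
    SpeciesParams,
    Trip,
    VesselTrack,
)

_SUBSTREAMS = {"species": 0, "trips": 1, "tracks": 2, "flags": 3, "split": 4}


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _SUBSTREAMS[name]])


def make_species(k: int, seed: int = 0) -> dict[str, SpeciesParams]:
    """k taxa with length-weight a ∈ [0.005, 0.05], b ∈ [2.7, 3.3] and
    self-consistent plausibility bounds."""
    if k < 1:
        raise ValueError("need k >= 1 taxa")
    rng = _rng(seed, "species")
    table: dict[str, SpeciesParams] = {}
    for i in range(k):
        code = f"SP{i + 1:03d}"
        lmin = float(rng.uniform(4.0, 12.0))
        lmax = float(lmin + rng.uniform(30.0, 80.0))
        pmin = float(rng.uniform(0.5, 2.0))
        table[code] = SpeciesParams(
            taxon_code=code,
            name=f"Synthetic taxon {i + 1}",
            a=float(rng.uniform(0.005, 0.05)),
            b=float(rng.uniform(2.7, 3.3)),
            length_min_cm=lmin,
            length_max_cm=lmax,
            price_min=pmin,
            price_max=float(pmin + rng.uniform(5.0, 15.0)),
        )
    return table


@dataclass
class GroundSpec:
    """One gear's fishing ground: a Gaussian patch at (lat, lon)."""

    gear: str
    habitat: str
    lat: float
    lon: float
    spread_km: float = 0.05  # fishing spots (FADs, reef holes) are revisited within tens of metres


def default_grounds(
    home: tuple[float, float] = (-8.55, 125.55),
    separation_km: float = 5.0,
    spread_km: float = 0.05,
) -> list[GroundSpec]:
    """Four gears on four distinct habitats, grounds ``separation_km`` apart,
    laid out on a line offshore of the home port."""
    lat0, lon0 = home
    gears = [("gill net", "reef"), ("hand line", "FAD"), ("long line", "deep"), ("trap", "mangrove")]
    grounds = []
    for i, (gear, habitat) in enumerate(gears):
        dx_km = (i - 1.5) * separation_km
        dy_km = 3.0 + 0.5 * i
        grounds.append(
            GroundSpec(
                gear=gear,
                habitat=habitat,
                lat=lat0 + dy_km / KM_PER_DEG_LAT,
                lon=lon0 + dx_km / (KM_PER_DEG_LON_EQUATOR * np.cos(np.radians(lat0))),
                spread_km=spread_km,
            )
        )
    return grounds


@dataclass
class FisheryConfig:
    """Study conditions for one synthetic fishery.

    Defaults give a small, fully observed and fully tracked fleet with
    constant effort per trip and no QC violations — the regime in which
    the raising estimator is exact and every truth quantity is recovered
    without sampling error.
    """

    fleet: dict[str, int] = field(default_factory=lambda: {"canoe": 6, "motor": 4})
    months: tuple[str, ...] = ("2019-01",)
    trips_per_boat_month: int = 4
    grounds: list[GroundSpec] = field(default_factory=default_grounds)
    mean_cpue_kg_per_fisher_h: dict[str, float] = field(
        default_factory=lambda: {"gill net": 1.2, "hand line": 0.8, "long line": 1.0, "trap": 0.6}
    )
    cpue_lognorm_sigma: float = 0.3
    n_species: int = 6
    landings_per_trip: tuple[int, int] = (1, 3)
    duration_h_mean: float = 5.0
    duration_lognorm_sigma: float = 0.0  # 0 => constant effort per trip
    fishers_per_boat: dict[str, int] = field(
        default_factory=lambda: {"canoe": 2, "motor": 3, "shore": 1}
    )
    home: tuple[float, float] = (-8.55, 125.55)
    tracked_fraction: float = 1.0     # of trips, have a GPS track
    unobserved_fraction: float = 0.0  # of tracked trips, lack a catch record
    flag_rate: float = 0.0            # per-landing QC-violation injection rate
    gear_habitat_flag_rate: float = 0.0  # per-trip invalid gear/habitat injection rate
    ping_interval_s: float = 5.0
    ping_interval_jitter_s: float = 0.0
    track_duration_s: float = 600.0
    gps_jitter_km: float = 0.002

    def __post_init__(self) -> None:
        for gear in self.mean_cpue_kg_per_fisher_h:
            if gear not in {g.gear for g in self.grounds}:
                raise ValueError(f"gear {gear!r} has a CPUE but no fishing ground")
        for g in self.grounds:
            if g.gear not in self.mean_cpue_kg_per_fisher_h:
                raise ValueError(f"ground for gear {g.gear!r} has no mean CPUE configured")


@dataclass
class Truth:
    """Generator bookkeeping: the quantities the pipeline should recover."""

    catch_observed_kg: dict[str, float]       # month -> clean landed weight, observed trips
    catch_total_kg: dict[str, float]          # month -> clean landed weight, all trips
    vac: dict[str, float]                     # boat type -> true trips per boat per month
    injected_flags: list[tuple[str, FlagCode]]
    grounds: dict[str, GroundSpec]            # gear -> ground
    labels: dict[str, tuple[str, str]]        # trip_id -> (gear, habitat), incl. unobserved
    observed_trip_ids: list[str]
    unobserved_trip_ids: list[str]


@dataclass
class SyntheticFishery:
    trips: list[Trip]                 # observed trips (with landings)
    hidden_trips: list[Trip]          # tracked-only trips (no catch record)
    tracks: list[VesselTrack]
    species: dict[str, SpeciesParams]
    census: FleetCensus
    truth: Truth


def make_fishery(config: FisheryConfig | None = None, seed: int = 0) -> SyntheticFishery:
    """Generate one synthetic fishery under ``config`` (defaults above)."""
    cfg = config or FisheryConfig()
    species = make_species(cfg.n_species, seed)
    rng_trips = _rng(seed, "trips")
    rng_tracks = _rng(seed, "tracks")
    rng_flags = _rng(seed, "flags")
    rng_split = _rng(seed, "split")

    grounds_by_gear = {g.gear: g for g in cfg.grounds}
    taxa = sorted(species)
    boats: list[tuple[str, str]] = []  # (unit_id, boat_type)
    i = 0
    for bt in sorted(cfg.fleet):
        for _ in range(cfg.fleet[bt]):
            i += 1
            boats.append((f"U{i:03d}", bt))

    trips: list[Trip] = []
    labels: dict[str, tuple[str, str]] = {}
    trip_counter = 0
    for month in cfg.months:
        year, mon = (int(p) for p in month.split("-"))
        for b_idx, (unit_id, boat_type) in enumerate(boats):
            for k in range(cfg.trips_per_boat_month):
                trip_counter += 1
                trip_id = f"T{trip_counter:05d}"
                day = 1 + int(k * 27 / max(1, cfg.trips_per_boat_month))
                gear = cfg.grounds[int(rng_trips.integers(len(cfg.grounds)))].gear
                ground = grounds_by_gear[gear]
                if cfg.duration_lognorm_sigma > 0:
                    duration = float(
                        cfg.duration_h_mean
                        * rng_trips.lognormal(-0.5 * cfg.duration_lognorm_sigma**2,
                                              cfg.duration_lognorm_sigma)
                    )
                else:
                    duration = cfg.duration_h_mean
                trip = Trip(
                    trip_id=trip_id,
                    site=f"site-{b_idx % 3 + 1}",
                    municipality="Dili",
                    date=_dt.date(year, mon, day),
                    boat_type=boat_type,
                    gear=gear,
                    habitat=ground.habitat,
                    n_fishers=cfg.fishers_per_boat[boat_type],
                    duration_h=duration,
                    unit_id=unit_id,
                )
                _fill_landings(trip, cfg, species, taxa, rng_trips)
                trips.append(trip)
                labels[trip_id] = (gear, ground.habitat)

    # tracked / observed split
    n = len(trips)
    tracked_mask = rng_split.random(n) < cfg.tracked_fraction
    unobserved_mask = tracked_mask & (rng_split.random(n) < cfg.unobserved_fraction)

    tracks: list[VesselTrack] = []
    for idx, trip in enumerate(trips):
        if tracked_mask[idx]:
            tracks.append(_make_track(trip, grounds_by_gear[trip.gear], cfg, rng_tracks))

    # inject after track generation: an injected gear/habitat corruption must
    # not move the trip's (already real) trajectory
    injected = _inject_flags(trips, cfg, species, rng_flags)
    injected_ids = {rid for rid, _ in injected}

    observed = [t for t, hide in zip(trips, unobserved_mask) if not hide]
    hidden = [t for t, hide in zip(trips, unobserved_mask) if hide]

    catch_obs: dict[str, float] = {m: 0.0 for m in cfg.months}
    catch_all: dict[str, float] = {m: 0.0 for m in cfg.months}
    for trip, hide in zip(trips, unobserved_mask):
        clean_kg = sum(
            r.est_weight_kg
            for r in trip.landings
            if r.record_id not in injected_ids and r.est_weight_kg is not None
        )
        catch_all[trip.month] += clean_kg
        if not hide:
            catch_obs[trip.month] += clean_kg

    truth = Truth(
        catch_observed_kg=catch_obs,
        catch_total_kg=catch_all,
        vac={bt: float(cfg.trips_per_boat_month) for bt in cfg.fleet if cfg.fleet[bt] > 0},
        injected_flags=injected,
        grounds=grounds_by_gear,
        labels=labels,
        observed_trip_ids=[t.trip_id for t in observed],
        unobserved_trip_ids=[t.trip_id for t in hidden],
    )
    return SyntheticFishery(
        trips=observed,
        hidden_trips=hidden,
        tracks=tracks,
        species=species,
        census=FleetCensus(dict(cfg.fleet)),
        truth=truth,
    )


def _fill_landings(
    trip: Trip,
    cfg: FisheryConfig,
    species: dict[str, SpeciesParams],
    taxa: list[str],
    rng: np.random.Generator,
) -> None:
    """Draw landings whose realised weight tracks the gear's mean CPUE.

    Lengths are lognormal within the taxon's plausibility band (so baseline
    data never trips QC); counts are chosen to hit the trip's target catch.
    """
    effort = trip.duration_h * trip.n_fishers
    base = cfg.mean_cpue_kg_per_fisher_h[trip.gear]
    sigma = cfg.cpue_lognorm_sigma
    noise = rng.lognormal(-0.5 * sigma**2, sigma) if sigma > 0 else 1.0
    target_kg = base * effort * noise
    lo, hi = cfg.landings_per_trip
    n_lines = int(rng.integers(lo, hi + 1))
    for j in range(n_lines):
        code = taxa[int(rng.integers(len(taxa)))]
        p = species[code]
        mid = 0.5 * (p.length_min_cm + p.length_max_cm)
        length = float(
            np.clip(
                rng.lognormal(np.log(mid * 0.6), 0.25),
                p.length_min_cm * 1.02,
                p.length_max_cm * 0.98,
            )
        )
        length = round(length)  # fork length recorded to nearest cm
        length = float(min(max(length, np.ceil(p.length_min_cm)), np.floor(p.length_max_cm)))
        w_per_fish = p.a * length ** p.b / 1000.0
        count = max(1, int(round(target_kg / n_lines / w_per_fish)))
        count = min(count, 900)  # stay clear of the default count bound
        price = float(rng.uniform(p.price_min * 1.05, p.price_max * 0.95))
        trip.landings.append(
            LandingRecord(
                record_id=f"{trip.trip_id}-L{j + 1}",
                trip_id=trip.trip_id,
                taxon_code=code,
                fork_length_cm=length,
                n_individuals=count,
                price=round(price, 2),
                price_basis="per_kg",
                est_weight_kg=count * w_per_fish,
            )
        )


def _inject_flags(
    trips: list[Trip],
    cfg: FisheryConfig,
    species: dict[str, SpeciesParams],
    rng: np.random.Generator,
) -> list[tuple[str, FlagCode]]:
    """Corrupt a configurable fraction of records, one violation each.

    Each corruption is crafted to fire exactly its own rule, so the QC
    report can be compared to this list record-for-record.
    """
    injected: list[tuple[str, FlagCode]] = []
    record_level = [FlagCode.LENGTH_OOB, FlagCode.COUNT_OOB, FlagCode.PRICE_OOB, FlagCode.FORMAT_ERROR]
    for trip in trips:
        if cfg.gear_habitat_flag_rate > 0 and rng.random() < cfg.gear_habitat_flag_rate:
            trip.gear, trip.habitat = "gleaning", "deep"  # gleaning is never valid in deep water
            for rec in trip.landings:
                injected.append((rec.record_id, FlagCode.INVALID_GEAR_HABITAT))
            continue
        for rec in trip.landings:
            if cfg.flag_rate <= 0 or rng.random() >= cfg.flag_rate:
                continue
            flag = record_level[int(rng.integers(len(record_level)))]
            p = species[rec.taxon_code]
            if flag is FlagCode.LENGTH_OOB:
                rec.fork_length_cm = round(p.length_max_cm * 1.5)
                rec.n_individuals = 1  # keep the implied weight plausible
            elif flag is FlagCode.COUNT_OOB:
                rec.fork_length_cm = float(np.ceil(p.length_min_cm))
                rec.n_individuals = 2000
            elif flag is FlagCode.PRICE_OOB:
                rec.price = round(p.price_max * 2.0, 2)
            else:  # FORMAT_ERROR: unknown taxon
                rec.taxon_code = "UNK999"
            rec.est_weight_kg = None  # pipeline re-estimates from the mutated fields
            injected.append((rec.record_id, flag))
    return injected


def _make_track(
    trip: Trip, ground: GroundSpec, cfg: FisheryConfig, rng: np.random.Generator
) -> VesselTrack:
    """Out-and-back path home → ground → home at the configured ping cadence."""
    lat0, lon0 = cfg.home
    coslat = np.cos(np.radians(lat0))
    # this trip's realised fishing spot: ground centre + within-ground scatter
    spot_dx, spot_dy = rng.normal(0.0, ground.spread_km, size=2)
    spot_lat = ground.lat + spot_dy / KM_PER_DEG_LAT
    spot_lon = ground.lon + spot_dx / (KM_PER_DEG_LON_EQUATOR * coslat)

    T = cfg.track_duration_s
    if cfg.ping_interval_jitter_s > 0:
        gaps = rng.normal(cfg.ping_interval_s, cfg.ping_interval_jitter_s,
                          size=int(np.ceil(T / cfg.ping_interval_s)))
        gaps = np.clip(gaps, 0.5, None)
        t = np.concatenate([[0.0], np.cumsum(gaps)])
        t = t[t <= T]
    else:
        t = np.arange(0.0, T + 0.5 * cfg.ping_interval_s, cfg.ping_interval_s)
    # piecewise-linear waypoints: leave, fish (dwell), return
    knots_t = np.array([0.0, 0.4 * T, 0.6 * T, T])
    knots_lat = np.array([lat0, spot_lat, spot_lat, lat0])
    knots_lon = np.array([lon0, spot_lon, spot_lon, lon0])
    lat = np.interp(t, knots_t, knots_lat)
    lon = np.interp(t, knots_t, knots_lon)
    if cfg.gps_jitter_km > 0:
        lat = lat + rng.normal(0.0, cfg.gps_jitter_km, size=t.size) / KM_PER_DEG_LAT
        lon = lon + rng.normal(0.0, cfg.gps_jitter_km, size=t.size) / (KM_PER_DEG_LON_EQUATOR * coslat)

    start = _dt.datetime.combine(trip.date, _dt.time(6, 0))
    pings = [
        Ping(start + _dt.timedelta(seconds=float(s)), float(la), float(lo))
        for s, la, lo in zip(t, lat, lon)
    ]
    return VesselTrack(
        track_id=f"trk-{trip.trip_id}",
        unit_id=trip.unit_id or f"U-{trip.trip_id}",
        boat_type=trip.boat_type,
        pings=pings,
        linked_trip_id=trip.trip_id,
    )
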