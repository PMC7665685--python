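"""Domain types for a small-scale fisheries monitoring system.

The unit of observation is a fishing *trip*: one boat (or shore party) goes
out with some gear to some habitat and returns with zero or more landed
species groups.  Enumerators at landing sites record, per species group, the
fork length (cm), the number of individuals, and an optional sale price.
Boats may additionally carry a solar GPS tracker pinging every ~5 s, which
yields a :class:`VesselTrack` that can be linked to the trip.

All weights are kilograms, lengths centimetres, effort fisher-hours
(trip duration in hours × number of people fishing).
"""

from __future__ import annotations

import datetime as _dt
import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

BOAT_TYPES = ("canoe", "motor", "shore")

GEARS = (
    "gill net",
    "seine net",
    "beach seine",
    "hand line",
    "long line",
    "spearfishing",
    "trap",
    "gleaning",
)

HABITATS = ("reef", "FAD", "deep", "shore", "mangrove")


class FlagCode(str, enum.Enum):
    """Closed vocabulary of quality-control flags.

    Each code corresponds to exactly one filter rule; a record may carry
    several.  A record with a non-empty flag set is suppressed from every
    downstream aggregate but is never deleted (flags exist for curation).
    """

    LENGTH_OOB = "LENGTH_OOB"
    COUNT_OOB = "COUNT_OOB"
    WEIGHT_OOB = "WEIGHT_OOB"
    PRICE_OOB = "PRICE_OOB"
    FORMAT_ERROR = "FORMAT_ERROR"
    INVALID_GEAR_HABITAT = "INVALID_GEAR_HABITAT"


@dataclass
class SpeciesParams:
    """Length-weight parameters and plausibility bounds for one taxon.

    ``a`` and ``b`` follow the FishBase convention: weight in grams
    ``W = a * L**b`` for fork length ``L`` in centimetres.  Price bounds are
    per kilogram.
    """

    taxon_code: str
    name: str
    a: float
    b: float
    length_min_cm: float
    length_max_cm: float
    price_min: float
    price_max: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"{self.taxon_code}: length-weight 'a' must be > 0, got {self.a}")
        if not 1.0 <= self.b <= 5.0:
            raise ValueError(f"{self.taxon_code}: allometric exponent 'b' must be in [1, 5], got {self.b}")
        if not self.length_min_cm < self.length_max_cm:
            raise ValueError(
                f"{self.taxon_code}: length bounds inverted "
                f"({self.length_min_cm} >= {self.length_max_cm})"
            )


SpeciesTable = dict  # taxon_code -> SpeciesParams


def species_table(params: Iterable[SpeciesParams]) -> dict[str, SpeciesParams]:
    return {p.taxon_code: p for p in params}


@dataclass
class LandingRecord:
    """One species-group line of one trip's catch, with its QC flag state."""

    record_id: str
    trip_id: str
    taxon_code: str
    fork_length_cm: float | None
    n_individuals: int | None
    price: float | None = None
    price_basis: str | None = None  # "per_kg" | "per_fish" | None
    est_weight_kg: float | None = None
    flags: set[FlagCode] = field(default_factory=set)

    @property
    def is_clean(self) -> bool:
        return not self.flags


@dataclass
class Trip:
    """Effort container: one boat's outing, owning its landing records."""

    trip_id: str
    site: str
    municipality: str
    date: _dt.date
    boat_type: str
    gear: str
    habitat: str
    n_fishers: int
    duration_h: float
    landings: list[LandingRecord] = field(default_factory=list)
    unit_id: str | None = None  # GPS tracker unit, if the boat carries one

    def __post_init__(self) -> None:
        if self.boat_type not in BOAT_TYPES:
            raise ValueError(f"trip {self.trip_id}: unknown boat type {self.boat_type!r}")

    @property
    def effort_fisher_hours(self) -> float:
        return self.duration_h * self.n_fishers

    @property
    def catch_kg(self) -> float:
        """Total estimated weight of the trip's *unflagged* landings."""
        return sum(
            r.est_weight_kg for r in self.landings if r.is_clean and r.est_weight_kg is not None
        )

    @property
    def month(self) -> str:
        return f"{self.date.year:04d}-{self.date.month:02d}"


class Ping(NamedTuple):
    timestamp: _dt.datetime
    lat: float
    lon: float


@dataclass
class VesselTrack:
    """Time-ordered GPS pings for one trip of one tracker unit."""

    track_id: str
    unit_id: str
    boat_type: str | None
    pings: list[Ping]
    linked_trip_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.pings) < 2:
            raise ValueError(f"track {self.track_id}: needs >= 2 pings, got {len(self.pings)}")
        for prev, cur in zip(self.pings, self.pings[1:]):
            if cur.timestamp <= prev.timestamp:
                raise ValueError(f"track {self.track_id}: timestamps not strictly increasing")
        for p in self.pings:
            if not (-90.0 <= p.lat <= 90.0 and -180.0 <= p.lon <= 180.0):
                raise ValueError(f"track {self.track_id}: coordinate out of range {p}")

    @property
    def start(self) -> _dt.datetime:
        return self.pings[0].timestamp

    @property
    def end(self) -> _dt.datetime:
        return self.pings[-1].timestamp

    @property
    def month(self) -> str:
        return f"{self.start.year:04d}-{self.start.month:02d}"

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass
class GearHabitatMatrix:
    """Boolean validity table over gear × habitat.

    Combinations that make no physical sense (e.g. gleaning in deep water)
    mark the whole trip's records INVALID_GEAR_HABITAT.
    """

    valid: dict[tuple[str, str], bool]

    def __post_init__(self) -> None:
        for gear in {g for g, _ in self.valid}:
            if not any(self.valid.get((gear, h), False) for h in HABITATS):
                raise ValueError(f"gear {gear!r} has no valid habitat")

    def is_valid(self, gear: str, habitat: str) -> bool:
        return self.valid.get((gear, habitat), False)

    @classmethod
    def from_pairs(cls, valid_pairs: Iterable[tuple[str, str]]) -> "GearHabitatMatrix":
        table = {(g, h): False for g in GEARS for h in HABITATS}
        for g, h in valid_pairs:
            table[(g, h)] = True
        return cls(table)


@dataclass
class FleetCensus:
    """National fleet counts per boat type (from a government boat census)."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        for bt, n in self.counts.items():
            if n < 0:
                raise ValueError(f"census count for {bt!r} must be >= 0, got {n}")

    def n_boats(self, boat_type: str) -> int:
        return self.counts.get(boat_type, 0)


@dataclass
class QCBounds:
    """Global plausibility bounds not tied to a single taxon.

    Defaults are deliberately generous: they catch data-entry errors
    (an extra digit, a swapped field), not genuine large catches.
    """

    count_max: int = 1000           # individuals per record
    weight_max_kg: float = 5000.0   # estimated weight per record

    def __post_init__(self) -> None:
        if self.count_max < 1 or self.weight_max_kg <= 0:
            raise ValueError("QC bounds must be positive")


@dataclass
class FleetRow:
    """Per-boat-type components of the monthly national catch estimate."""

    boat_type: str
    month: str
    cpue_kg_per_fisher_h: float
    ept_fisher_h: float          # median effort per trip
    vac_trips_per_boat: float    # vessel activity coefficient
    n_boats: int
    catch_tonnes: float

    def __post_init__(self) -> None:
        for name in ("cpue_kg_per_fisher_h", "ept_fisher_h", "vac_trips_per_boat", "catch_tonnes"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{self.boat_type}/{self.month}: {name} must be finite >= 0, got {v}")


@dataclass
class FleetEstimate:
    """National monthly catch estimate: the sum over boat types of
    CPUE_b × EPT_b × VAC_b × N_b × 0.001 (tonnes)."""

    month: str
    rows: list[FleetRow]

    @property
    def total_tonnes(self) -> float:
        return sum(r.catch_tonnes for r in self.rows)
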