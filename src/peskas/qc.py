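"""Length→weight estimation and the flag-and-suppress quality-control engine.

Catch weight is not weighed at the landing site; it is estimated from fork
length through the allometric length-weight relationship W = a·L^b (a, b in
the FishBase cm→g convention, per taxon).  Each incoming record then passes
a battery of independent plausibility filters; any rule that fires attaches
a flag.  Flagged records are *suppressed* — excluded from every downstream
aggregate — but never deleted, so a moderator can curate them later.

Filter rules (one flag code each):

* LENGTH_OOB — fork length outside the taxon's [length_min_cm, length_max_cm]
* COUNT_OOB — individuals count outside [1, bounds.count_max]
* WEIGHT_OOB — estimated record weight outside (0, bounds.weight_max_kg]
* PRICE_OOB — implied per-kg price outside the taxon's [price_min, price_max]
  (a per-fish price is converted: price × n / est_weight_kg)
* FORMAT_ERROR — unknown taxon, or missing/nonpositive length, count or effort
* INVALID_GEAR_HABITAT — the trip's gear/habitat pair is invalid in the
  validity matrix; propagates to every landing of the trip
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .models import (
    FlagCode,
    GearHabitatMatrix,
    LandingRecord,
    QCBounds,
    SpeciesParams,
    Trip,
)


def estimate_weight(length_cm: float, n: int, params: SpeciesParams) -> float:
    """Estimated weight (kg) of ``n`` individuals of fork length ``length_cm``.

    W_kg = n × a × L^b / 1000, with a, b converting cm to grams.
    """
    if length_cm < 0:
        raise ValueError(f"negative length {length_cm}")
    if n < 1:
        raise ValueError(f"count must be >= 1, got {n}")
    return n * params.a * length_cm ** params.b / 1000.0


def estimate_trip_weights(trip: Trip, species: dict[str, SpeciesParams]) -> Trip:
    """Fill ``est_weight_kg`` for each landing; unknown taxa get FORMAT_ERROR."""
    for rec in trip.landings:
        params = species.get(rec.taxon_code)
        if params is None or rec.fork_length_cm is None or rec.n_individuals is None:
            rec.est_weight_kg = None
            rec.flags.add(FlagCode.FORMAT_ERROR)
            continue
        if rec.fork_length_cm <= 0 or rec.n_individuals < 1:
            rec.est_weight_kg = None
            rec.flags.add(FlagCode.FORMAT_ERROR)
            continue
        rec.est_weight_kg = estimate_weight(rec.fork_length_cm, rec.n_individuals, params)
    return trip


def _record_flags(
    rec: LandingRecord,
    trip: Trip,
    species: dict[str, SpeciesParams],
    matrix: GearHabitatMatrix,
    bounds: QCBounds,
) -> set[FlagCode]:
    """Evaluate every rule for one record; rules are independent and accumulate."""
    flags: set[FlagCode] = set()
    params = species.get(rec.taxon_code)

    if (
        params is None
        or rec.fork_length_cm is None
        or rec.fork_length_cm <= 0
        or rec.n_individuals is None
        or rec.n_individuals < 1
        or trip.duration_h <= 0
        or trip.n_fishers < 1
    ):
        flags.add(FlagCode.FORMAT_ERROR)

    if params is not None and rec.fork_length_cm is not None:
        if not params.length_min_cm <= rec.fork_length_cm <= params.length_max_cm:
            flags.add(FlagCode.LENGTH_OOB)

    if rec.n_individuals is not None and not 1 <= rec.n_individuals <= bounds.count_max:
        flags.add(FlagCode.COUNT_OOB)

    if rec.est_weight_kg is not None and not 0 < rec.est_weight_kg <= bounds.weight_max_kg:
        flags.add(FlagCode.WEIGHT_OOB)

    if params is not None and rec.price is not None:
        per_kg = None
        if rec.price_basis == "per_fish":
            if rec.est_weight_kg:
                per_kg = rec.price * (rec.n_individuals or 1) / rec.est_weight_kg
        else:  # per-kg is the default basis
            per_kg = rec.price
        if per_kg is not None and not params.price_min <= per_kg <= params.price_max:
            flags.add(FlagCode.PRICE_OOB)

    if not matrix.is_valid(trip.gear, trip.habitat):
        flags.add(FlagCode.INVALID_GEAR_HABITAT)

    return flags


def apply_filters(
    trip: Trip,
    species: dict[str, SpeciesParams],
    matrix: GearHabitatMatrix,
    bounds: QCBounds | None = None,
) -> Trip:
    """Set each landing's flags from scratch.  Idempotent: flags are a pure
    function of the record and trip content, so re-applying changes nothing.
    QC never hard-fails on data content."""
    bounds = bounds or QCBounds()
    for rec in trip.landings:
        rec.flags = _record_flags(rec, trip, species, matrix, bounds)
    return trip


def suppress(trips: list[Trip]) -> tuple[list[Trip], pd.DataFrame]:
    """Partition landings into a clean set and a machine-readable flag report.

    Returns copies of the trips holding only unflagged landings, and a
    DataFrame with one row per (record, flag) listing the offending value.
    A trip flagged INVALID_GEAR_HABITAT is excluded wholly (every landing
    carries the flag, and its effort is not trusted either); trips that
    merely lose some records to record-level flags keep their clean
    landings and still contribute effort.
    """
    clean_trips: list[Trip] = []
    report_rows: list[dict] = []
    for trip in trips:
        clean_records = []
        for rec in trip.landings:
            for flag in sorted(rec.flags, key=lambda f: f.value):
                report_rows.append(
                    {
                        "record_id": rec.record_id,
                        "trip_id": trip.trip_id,
                        "flag": flag.value,
                        "value": _offending_value(rec, trip, flag),
                    }
                )
            if rec.is_clean:
                clean_records.append(rec)
        trip_invalid = any(FlagCode.INVALID_GEAR_HABITAT in r.flags for r in trip.landings)
        if not trip_invalid:
            clean_trips.append(replace(trip, landings=clean_records))
    report = pd.DataFrame(report_rows, columns=["record_id", "trip_id", "flag", "value"])
    return clean_trips, report.sort_values(["record_id", "flag"], kind="mergesort").reset_index(drop=True)


def _offending_value(rec: LandingRecord, trip: Trip, flag: FlagCode) -> str:
    if flag is FlagCode.LENGTH_OOB:
        return str(rec.fork_length_cm)
    if flag is FlagCode.COUNT_OOB:
        return str(rec.n_individuals)
    if flag is FlagCode.WEIGHT_OOB:
        return str(rec.est_weight_kg)
    if flag is FlagCode.PRICE_OOB:
        return str(rec.price)
    if flag is FlagCode.INVALID_GEAR_HABITAT:
        return f"{trip.gear}/{trip.habitat}"
    return rec.taxon_code
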