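"""Fisher-hour effort, CPUE, trend smoothing, vessel activity, and the
national catch raising estimator.

Effort is standardised into *fisher-hours* (trip duration × people fishing),
a unit that applies across every gear and habitat in a mixed, multi-species
fishery, deliberately avoiding model-based CPUE standardisation.  Sampled
per-trip statistics are raised to the whole fleet with a census of boats:

    C = Σ_b  CPUE_b × EPT_b × VAC_b × N_b × 0.001     (tonnes per month)

where b runs over boat types (canoe, motor; shore-based fishing is omitted
from the national estimate), CPUE_b is the monthly catch per fisher-hour,
EPT_b the median effort per trip, VAC_b the vessel activity coefficient
(average trips per boat per month, estimated from GPS tracks) and N_b the
national fleet count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .io import SUMMARY_COLUMNS
from .models import FleetCensus, FleetEstimate, FleetRow, Trip, VesselTrack

log = logging.getLogger(__name__)

RAISING_BOAT_TYPES = ("canoe", "motor")  # shore-based fishing excluded


def trip_effort(trip: Trip) -> float:
    """Effort in fisher-hours: duration_h × n_fishers."""
    if trip.duration_h <= 0 or trip.n_fishers < 1:
        raise ValueError(
            f"trip {trip.trip_id}: nonpositive effort inputs "
            f"(duration {trip.duration_h} h, {trip.n_fishers} fishers)"
        )
    return trip.duration_h * trip.n_fishers


def trips_frame(trips: Iterable[Trip]) -> pd.DataFrame:
    """One row per trip: stratifiers, effort, and clean catch weight."""
    rows = [
        {
            "trip_id": t.trip_id,
            "month": t.month,
            "site": t.site,
            "municipality": t.municipality,
            "boat_type": t.boat_type,
            "gear": t.gear,
            "habitat": t.habitat,
            "effort_fisher_h": trip_effort(t),
            "catch_kg": t.catch_kg,
        }
        for t in trips
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "trip_id", "month", "site", "municipality", "boat_type",
            "gear", "habitat", "effort_fisher_h", "catch_kg",
        ],
    )


def cpue(
    trips: Iterable[Trip],
    stratifiers: Sequence[str] = ("month", "boat_type"),
    method: str = "ratio",
) -> pd.DataFrame:
    """Per-stratum CPUE table from clean (post-suppression) trips.

    ``method="ratio"`` (default) is the ratio-of-totals Σcatch/Σeffort —
    effort-weighted and dimensionally consistent with the raising formula.
    ``method="mean"`` averages per-trip ratios instead, for sensitivity
    checks.  Zero-catch trips contribute effort either way.  Strata with
    zero effort are excluded with a warning.
    """
    if method not in ("ratio", "mean"):
        raise ValueError(f"unknown CPUE method {method!r}")
    df = trips_frame(trips)
    if df.empty:
        return pd.DataFrame(columns=[*stratifiers, "n_trips", "catch_kg", "effort_fisher_h", "cpue"])
    df = df.assign(_ratio=df["catch_kg"] / df["effort_fisher_h"])
    out = (
        df.groupby(list(stratifiers), sort=True)
        .agg(
            n_trips=("trip_id", "size"),
            catch_kg=("catch_kg", "sum"),
            effort_fisher_h=("effort_fisher_h", "sum"),
            _mean_ratio=("_ratio", "mean"),
        )
        .reset_index()
    )
    zero = out["effort_fisher_h"] <= 0
    if zero.any():
        log.warning("excluding %d stratum(s) with zero effort", int(zero.sum()))
        out = out[~zero].reset_index(drop=True)
    if method == "ratio":
        out["cpue"] = out["catch_kg"] / out["effort_fisher_h"]
    else:
        out["cpue"] = out["_mean_ratio"]
    return out.drop(columns=["_mean_ratio"])


def month_summary(trips: Iterable[Trip]) -> pd.DataFrame:
    """Month-aggregated summary: one row per
    (month, municipality, boat_type, gear, habitat)."""
    table = cpue(trips, stratifiers=("month", "municipality", "boat_type", "gear", "habitat"))
    table = table.rename(
        columns={
            "catch_kg": "total_catch_kg",
            "effort_fisher_h": "total_effort_fisher_h",
            "cpue": "cpue_kg_per_fisher_h",
        }
    )
    if table.empty:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    return table.loc[:, SUMMARY_COLUMNS]


def smooth_cpue(
    times: Sequence[float],
    values: Sequence[float],
    weights: Sequence[float] | None = None,
    spar: float = 0.5,
    lam: float | None = None,
) -> np.ndarray:
    """Fit an effort-weighted cubic smoothing spline to a CPUE series and
    evaluate it at the input times.

    ``spar`` in [0, 1] maps monotonically to the roughness penalty as
    λ = 256^(3·spar − 1) on times rescaled to [0, 1] (the dashboard-slider
    convention); pass ``lam`` to set the penalty directly.  spar → 1 pushes
    the fit toward the weighted linear least-squares limit; the fit
    reproduces a constant series exactly for any spar.
    """
    x = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError(
            f"need >= 4 time points for a cubic smoothing spline, got {x.size}; "
            "display the raw series instead"
        )
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("effort weights must be positive")
    order = np.argsort(x, kind="mergesort")
    span = x[order[-1]] - x[order[0]]
    if span <= 0:
        raise ValueError("time points must not be all identical")
    xs = (x[order] - x[order[0]]) / span
    wn = w[order] / w.mean()
    if lam is None:
        if not 0.0 <= spar <= 1.0:
            raise ValueError(f"spar must be in [0, 1], got {spar}")
        lam = 256.0 ** (3.0 * spar - 1.0)
    spline = make_smoothing_spline(xs, y[order], w=wn, lam=lam)
    fitted = np.empty_like(y)
    fitted[order] = spline(xs)
    return fitted


def vac(
    tracks: Iterable[VesselTrack],
    month: str,
    roster: dict[str, Iterable[str]] | None = None,
    stat: str = "mean",
) -> dict[str, float]:
    """Vessel activity coefficient per boat type for one calendar month.

    VAC_b = average number of trips per tracked boat of type b.  The
    default denominator is the month's active roster (units with ≥ 1 track
    that month); pass ``roster`` (boat_type → unit ids) to use a fixed
    instrumented fleet instead, in which case zero-trip boats count.
    ``stat`` is "mean" (default) or "median" over per-boat trip counts.
    Boat types with no tracked boats are absent from the result — the
    caller must supply a fallback.
    """
    if stat not in ("mean", "median"):
        raise ValueError(f"unknown VAC statistic {stat!r}")
    counts: dict[str, dict[str, int]] = {}
    for t in tracks:
        if t.month != month:
            continue
        bt = t.boat_type or "unknown"
        counts.setdefault(bt, {}).setdefault(t.unit_id, 0)
        counts[bt][t.unit_id] += 1
    if roster is not None:
        for bt, units in roster.items():
            for u in units:
                counts.setdefault(bt, {}).setdefault(u, 0)
    out: dict[str, float] = {}
    for bt, per_boat in counts.items():
        if not per_boat:
            continue
        values = np.array(list(per_boat.values()), dtype=float)
        out[bt] = float(np.mean(values) if stat == "mean" else np.median(values))
    return out


def ept(trips: Iterable[Trip], boat_type: str) -> float:
    """Median effort per trip (fisher-hours) for one boat type.

    Exact sample median: mean of the middle two for even n.
    """
    efforts = [trip_effort(t) for t in trips if t.boat_type == boat_type]
    if not efforts:
        raise ValueError(f"no trips of boat type {boat_type!r}")
    return float(np.median(efforts))


def national_catch(
    cpue_by_type: dict[str, float],
    ept_by_type: dict[str, float],
    vac_by_type: dict[str, float],
    census: FleetCensus,
    month: str = "",
) -> FleetEstimate:
    """Raise per-boat-type CPUE × EPT × VAC to the national fleet.

    C_b = CPUE_b × EPT_b × VAC_b × N_b × 0.001 tonnes; C = Σ_b C_b.
    Shore-based boats in the census are ignored.  A missing component for
    a boat type with N_b > 0 is an error naming the gap.
    """
    rows: list[FleetRow] = []
    for bt in sorted(census.counts):
        if bt not in RAISING_BOAT_TYPES:
            continue
        n_b = census.n_boats(bt)
        if n_b == 0:
            continue
        missing = [
            name
            for name, table in (("CPUE", cpue_by_type), ("EPT", ept_by_type), ("VAC", vac_by_type))
            if bt not in table
        ]
        if missing:
            raise ValueError(
                f"boat type {bt!r} has {n_b} boats in the census but no "
                f"{', '.join(missing)} component"
            )
        c_b = cpue_by_type[bt] * ept_by_type[bt] * vac_by_type[bt] * n_b * 0.001
        rows.append(
            FleetRow(
                boat_type=bt,
                month=month,
                cpue_kg_per_fisher_h=cpue_by_type[bt],
                ept_fisher_h=ept_by_type[bt],
                vac_trips_per_boat=vac_by_type[bt],
                n_boats=n_b,
                catch_tonnes=c_b,
            )
        )
    return FleetEstimate(month=month, rows=rows)


KM_PER_DEG_LAT = 110.57
KM_PER_DEG_LON_EQUATOR = 111.32


@dataclass
class Heatmap:
    """Grid-binned ping density over the tracks' bounding box.

    ``counts[i, j]`` is the number of pings in latitude row i, longitude
    column j.  At a fixed ping cadence the count is proportional to time
    spent in the cell, i.e. relative effort.
    """

    counts: np.ndarray
    lat_edges: np.ndarray
    lon_edges: np.ndarray
    cell_size_km: float

    @property
    def normalized(self) -> np.ndarray:
        total = self.counts.max()
        if total == 0:
            return self.counts.astype(float)
        return self.counts / total

    def to_frame(self) -> pd.DataFrame:
        """Long-form (lat_center, lon_center, count) for CSV export."""
        lat_c = 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])
        lon_c = 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])
        ii, jj = np.nonzero(self.counts >= 0)  # all cells, deterministic order
        return pd.DataFrame(
            {
                "lat_center": lat_c[ii],
                "lon_center": lon_c[jj],
                "count": self.counts[ii, jj].astype(int),
            }
        )


def effort_heatmap(tracks: Iterable[VesselTrack], cell_size_km: float = 1.0) -> Heatmap:
    """Bin all pings onto an equirectangular grid of ~cell_size_km cells.

    A degenerate bounding box (all pings at one point) yields a 1×1 grid.
    The cell sum always equals the total ping count.
    """
    if cell_size_km <= 0:
        raise ValueError("cell size must be positive")
    lats = np.array([p.lat for t in tracks for p in t.pings])
    lons = np.array([p.lon for t in tracks for p in t.pings])
    if lats.size == 0:
        raise ValueError("no pings to bin")
    lat0 = float(lats.mean())
    dlat = cell_size_km / KM_PER_DEG_LAT
    dlon = cell_size_km / (KM_PER_DEG_LON_EQUATOR * max(np.cos(np.radians(lat0)), 1e-9))
    lat_lo, lat_hi = float(lats.min()), float(lats.max())
    lon_lo, lon_hi = float(lons.min()), float(lons.max())
    n_lat = max(1, int(np.ceil((lat_hi - lat_lo) / dlat)))
    n_lon = max(1, int(np.ceil((lon_hi - lon_lo) / dlon)))
    lat_edges = lat_lo + dlat * np.arange(n_lat + 1)
    lon_edges = lon_lo + dlon * np.arange(n_lon + 1)
    # widen the last edge a hair so max-coordinate pings fall inside
    lat_edges[-1] = max(lat_edges[-1], np.nextafter(lat_hi, np.inf))
    lon_edges[-1] = max(lon_edges[-1], np.nextafter(lon_hi, np.inf))
    counts, _, _ = np.histogram2d(lats, lons, bins=[lat_edges, lon_edges])
    return Heatmap(
        counts=counts.astype(int),
        lat_edges=lat_edges,
        lon_edges=lon_edges,
        cell_size_km=cell_size_km,
    )
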