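import datetime as dt

import pytest

from peskas import io as pio
from peskas import simulate
from peskas.models import LandingRecord, SpeciesParams, Trip


@pytest.fixture(scope="session")
def species_small():
    """Two hand-made taxa with easy-to-verify length-weight parameters."""
    return {
        "SPA": SpeciesParams("SPA", "cube-law fish", a=0.01, b=3.0,
                             length_min_cm=5.0, length_max_cm=60.0,
                             price_min=1.0, price_max=10.0),
        "SPB": SpeciesParams("SPB", "oracle fish", a=0.0137, b=3.07,
                             length_min_cm=10.0, length_max_cm=80.0,
                             price_min=2.0, price_max=20.0),
    }


@pytest.fixture(scope="session")
def matrix():
    return pio.default_gear_habitat_matrix()


def build_trip(trip_id="T1", gear="hand line", habitat="reef", boat_type="canoe",
               n_fishers=2, duration_h=5.0, records=()):
    trip = Trip(
        trip_id=trip_id, site="s1", municipality="Dili",
        date=dt.date(2019, 1, 15), boat_type=boat_type, gear=gear,
        habitat=habitat, n_fishers=n_fishers, duration_h=duration_h,
        unit_id=None,
    )
    for i, rec in enumerate(records):
        trip.landings.append(
            LandingRecord(record_id=f"{trip_id}-L{i + 1}", trip_id=trip_id, **rec)
        )
    return trip


@pytest.fixture
def make_trip():
    return build_trip


@pytest.fixture(scope="session")
def fishery_clean():
    """Fully observed, fully tracked fleet; constant effort; no QC violations."""
    return simulate.make_fishery(simulate.FisheryConfig(), seed=11)


@pytest.fixture(scope="session")
def fishery_flags():
    """Same fleet with injected QC violations at known records."""
    cfg = simulate.FisheryConfig(flag_rate=0.10, gear_habitat_flag_rate=0.05)
    return simulate.make_fishery(cfg, seed=12)


@pytest.fixture(scope="session")
def fishery_separable():
    """Classifier regime: grounds 5 km apart, 0.02 km within-ground spread."""
    cfg = simulate.FisheryConfig(
        fleet={"canoe": 6, "motor": 4},
        trips_per_boat_month=8,
        grounds=simulate.default_grounds(separation_km=5.0, spread_km=0.02),
    )
    return simulate.make_fishery(cfg, seed=13)


@pytest.fixture(scope="session")
def fishery_files(tmp_path_factory, fishery_flags):
    """The flag-injected fishery written to disk in the interchange formats."""
    d = tmp_path_factory.mktemp("fishery")
    pio.write_landings(fishery_flags.trips, d / "landings.csv")
    pio.write_tracks_csv(fishery_flags.tracks, d / "tracks.csv")
    pio.write_species(fishery_flags.species, d / "species.csv")
    pio.write_census(fishery_flags.census, d / "census.csv")
    return d
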