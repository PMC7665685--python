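import numpy as np
import pytest

from peskas import analytics
from peskas.models import FleetCensus, LandingRecord
from tests.conftest import build_trip


def _trip_with_catch(trip_id, catch_kg, duration_h=5.0, n_fishers=2, **kw):
    t = build_trip(trip_id, duration_h=duration_h, n_fishers=n_fishers, **kw)
    if catch_kg > 0:
        t.landings.append(
            LandingRecord(
                record_id=f"{trip_id}-L1", trip_id=trip_id, taxon_code="SPA",
                fork_length_cm=20.0, n_individuals=1, est_weight_kg=catch_kg,
            )
        )
    return t


class TestTripEffort:
    @pytest.mark.parametrize(
        "duration,fishers,expected", [(5.0, 2, 10.0), (1.0, 1, 1.0), (2.5, 3, 7.5)]
    )
    def test_product(self, duration, fishers, expected):
        t = build_trip(duration_h=duration, n_fishers=fishers)
        assert analytics.trip_effort(t) == expected

    def test_nonpositive_inputs_error(self):
        t = build_trip(duration_h=0.0)
        with pytest.raises(ValueError):
            analytics.trip_effort(t)


class TestCpue:
    def test_single_trip_ratio(self):
        table = analytics.cpue([_trip_with_catch("T1", 10.0)], stratifiers=("month",))
        assert table.loc[0, "cpue"] == pytest.approx(1.0)

    def test_zero_catch_trip_contributes_effort(self):
        trips = [_trip_with_catch("T1", 10.0), _trip_with_catch("T2", 0.0)]
        table = analytics.cpue(trips, stratifiers=("month",))
        assert table.loc[0, "cpue"] == pytest.approx(0.5)

    def test_mean_of_ratios_variant(self):
        trips = [_trip_with_catch("T1", 10.0), _trip_with_catch("T2", 0.0)]
        table = analytics.cpue(trips, stratifiers=("month",), method="mean")
        assert table.loc[0, "cpue"] == pytest.approx(0.5)  # (1.0 + 0.0) / 2
        trips = [_trip_with_catch("T1", 10.0), _trip_with_catch("T2", 5.0, duration_h=2.5)]
        ratio = analytics.cpue(trips, stratifiers=("month",)).loc[0, "cpue"]
        mean = analytics.cpue(trips, stratifiers=("month",), method="mean").loc[0, "cpue"]
        assert ratio == pytest.approx(15.0 / 15.0)
        assert mean == pytest.approx((1.0 + 1.0) / 2)

    def test_matches_brute_force_groupby(self, fishery_clean):
        """Stratified CPUE equals an independently coded dict-accumulator oracle."""
        trips = fishery_clean.trips[:50]
        table = analytics.cpue(trips, stratifiers=("boat_type", "gear"))
        oracle: dict[tuple, list] = {}
        for t in trips:
            key = (t.boat_type, t.gear)
            acc = oracle.setdefault(key, [0.0, 0.0])
            acc[0] += sum(r.est_weight_kg for r in t.landings if r.is_clean)
            acc[1] += t.duration_h * t.n_fishers
        assert len(table) == len(oracle)
        for row in table.itertuples(index=False):
            catch, effort = oracle[(row.boat_type, row.gear)]
            assert row.catch_kg == pytest.approx(catch, rel=1e-12)
            assert row.cpue == pytest.approx(catch / effort, rel=1e-12)


class TestEpt:
    def test_odd_n_median(self):
        trips = [_trip_with_catch(f"T{i}", 1.0, duration_h=h, n_fishers=1)
                 for i, h in enumerate([2.0, 4.0, 9.0])]
        assert analytics.ept(trips, "canoe") == 4.0

    def test_even_n_mean_of_middle_two(self):
        trips = [_trip_with_catch(f"T{i}", 1.0, duration_h=h, n_fishers=1)
                 for i, h in enumerate([2.0, 4.0])]
        assert analytics.ept(trips, "canoe") == 3.0

    def test_matches_sort_and_pick_oracle(self):
        rng = np.random.default_rng(7)
        efforts = rng.uniform(1.0, 30.0, size=101)
        trips = [_trip_with_catch(f"T{i}", 1.0, duration_h=float(h), n_fishers=1)
                 for i, h in enumerate(efforts)]
        assert analytics.ept(trips, "canoe") == sorted(efforts)[50]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            analytics.ept([], "canoe")


class TestVac:
    def test_three_canoes_four_trips_each(self, fishery_clean):
        # the generator schedules exactly trips_per_boat_month trips per boat
        values = analytics.vac(fishery_clean.tracks, "2019-01")
        assert values == {"canoe": 4.0, "motor": 4.0}

    def test_roster_denominator_counts_zero_trip_boats(self, fishery_clean):
        canoes = {t.unit_id for t in fishery_clean.tracks if t.boat_type == "canoe"}
        roster = {"canoe": list(canoes) + ["U999"]}  # one instrumented, idle boat
        values = analytics.vac(fishery_clean.tracks, "2019-01", roster=roster)
        expected = 4.0 * len(canoes) / (len(canoes) + 1)
        assert values["canoe"] == pytest.approx(expected)

    def test_mixed_fleet_matches_hand_count(self, fishery_clean):
        """VAC equals (trips in month) / (distinct active boats), enumerated by hand."""
        for bt in ("canoe", "motor"):
            tracks = [t for t in fishery_clean.tracks if t.boat_type == bt and t.month == "2019-01"]
            n_trips = len(tracks)
            n_boats = len({t.unit_id for t in tracks})
            assert analytics.vac(fishery_clean.tracks, "2019-01")[bt] == n_trips / n_boats

    def test_absent_type_absent_from_result(self, fishery_clean):
        assert "shore" not in analytics.vac(fishery_clean.tracks, "2019-01")


class TestNationalCatch:
    def test_direct_substitution(self):
        est = analytics.national_catch(
            {"canoe": 1.0}, {"canoe": 10.0}, {"canoe": 4.0}, FleetCensus({"canoe": 100})
        )
        assert est.rows[0].catch_tonnes == pytest.approx(4.0)
        assert est.total_tonnes == pytest.approx(4.0)

    def test_zero_component_zeroes_the_type(self):
        est = analytics.national_catch(
            {"canoe": 0.0}, {"canoe": 10.0}, {"canoe": 4.0}, FleetCensus({"canoe": 100})
        )
        assert est.total_tonnes == 0.0

    def test_two_boat_types_hand_sum(self):
        est = analytics.national_catch(
            {"canoe": 1.0, "motor": 2.0},
            {"canoe": 10.0, "motor": 15.0},
            {"canoe": 4.0, "motor": 6.0},
            FleetCensus({"canoe": 100, "motor": 50}),
        )
        # canoe: 1*10*4*100*0.001 = 4 t; motor: 2*15*6*50*0.001 = 9 t
        assert est.total_tonnes == pytest.approx(13.0)

    def test_doubling_fleet_doubles_catch(self):
        kw = ({"canoe": 1.5}, {"canoe": 8.0}, {"canoe": 3.0})
        c1 = analytics.national_catch(*kw, FleetCensus({"canoe": 100})).total_tonnes
        c2 = analytics.national_catch(*kw, FleetCensus({"canoe": 200})).total_tonnes
        assert c2 == pytest.approx(2 * c1)

    def test_shore_boats_ignored(self):
        est = analytics.national_catch(
            {"canoe": 1.0}, {"canoe": 10.0}, {"canoe": 4.0},
            FleetCensus({"canoe": 100, "shore": 500}),
        )
        assert [r.boat_type for r in est.rows] == ["canoe"]

    def test_missing_component_names_the_gap(self):
        with pytest.raises(ValueError, match="motor.*VAC"):
            analytics.national_catch(
                {"canoe": 1.0, "motor": 1.0},
                {"canoe": 10.0, "motor": 10.0},
                {"canoe": 4.0},
                FleetCensus({"canoe": 100, "motor": 50}),
            )


class TestHeatmap:
    def test_single_location_single_cell(self, fishery_clean):
        track = fishery_clean.tracks[0]
        import datetime as dt

        from peskas.models import Ping, VesselTrack

        base = dt.datetime(2019, 1, 1, 6, 0)
        stationary = VesselTrack(
            "s", "U1", "canoe",
            [Ping(base + dt.timedelta(seconds=5 * i), -8.5, 125.5) for i in range(7)],
        )
        hm = analytics.effort_heatmap([stationary], cell_size_km=1.0)
        assert hm.counts.shape == (1, 1)
        assert hm.counts.sum() == 7

    def test_two_equal_clusters_two_equal_cells(self):
        import datetime as dt

        from peskas.models import Ping, VesselTrack

        base = dt.datetime(2019, 1, 1, 6, 0)
        pings = [Ping(base + dt.timedelta(seconds=5 * i), -8.5, 125.5) for i in range(5)]
        pings += [Ping(base + dt.timedelta(seconds=5 * (i + 5)), -8.5, 125.7) for i in range(5)]
        hm = analytics.effort_heatmap([VesselTrack("t", "U1", "canoe", pings)], cell_size_km=2.0)
        nonzero = hm.counts[hm.counts > 0]
        assert list(nonzero) == [5, 5]

    def test_cell_sum_equals_ping_count(self, fishery_clean):
        hm = analytics.effort_heatmap(fishery_clean.tracks, cell_size_km=0.5)
        assert hm.counts.sum() == sum(len(t.pings) for t in fishery_clean.tracks)

    def test_uniform_pings_follow_multinomial_expectation(self):
        """Uniform random pings land in interior cells within 3 SD of n·p."""
        import datetime as dt

        from peskas.models import Ping, VesselTrack

        rng = np.random.default_rng(5)
        n = 20000
        base = dt.datetime(2019, 1, 1)
        lat = rng.uniform(-8.6, -8.6 + 4 * 1.0 / analytics.KM_PER_DEG_LAT, size=n)
        dlon = 1.0 / (analytics.KM_PER_DEG_LON_EQUATOR * np.cos(np.radians(-8.6)))
        lon = rng.uniform(125.5, 125.5 + 4 * dlon, size=n)
        pings = [Ping(base + dt.timedelta(seconds=5 * i), la, lo)
                 for i, (la, lo) in enumerate(zip(lat, lon))]
        hm = analytics.effort_heatmap([VesselTrack("t", "U1", None, pings)], cell_size_km=1.0)
        assert hm.counts.sum() == n
        p = 1.0 / hm.counts.size
        sd = np.sqrt(n * p * (1 - p))
        inner = hm.counts[:4, :4]  # cells fully inside the sampled box
        assert np.all(np.abs(inner - n * p) < 3.5 * sd + abs(inner.sum() - n) / 16)

    def test_normalized_peaks_at_one(self, fishery_clean):
        hm = analytics.effort_heatmap(fishery_clean.tracks, cell_size_km=1.0)
        assert hm.normalized.max() == pytest.approx(1.0)


class TestSmoothing:
    def test_constant_series_reproduced_for_any_spar(self):
        x = np.arange(12.0)
        y = np.full(12, 3.5)
        w = np.linspace(1, 5, 12)
        for spar in (0.0, 0.5, 1.0):
            fitted = analytics.smooth_cpue(x, y, w, spar=spar)
            assert fitted == pytest.approx(np.full(12, 3.5), abs=1e-5)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError, match="raw"):
            analytics.smooth_cpue([1, 2, 3], [1.0, 2.0, 3.0])

    def test_maximal_smoothing_approaches_weighted_linear_fit(self):
        rng = np.random.default_rng(3)
        x = np.arange(20.0)
        y = 2.0 + 0.3 * x + rng.normal(0, 0.5, 20)
        w = rng.uniform(0.5, 3.0, 20)
        fitted = analytics.smooth_cpue(x, y, w, lam=1e6)
        coeffs = np.polyfit(x, y, 1, w=np.sqrt(w))
        assert fitted == pytest.approx(np.polyval(coeffs, x), abs=1e-3)

    def test_recovers_linear_trend_within_noise(self):
        rng = np.random.default_rng(4)
        x = np.arange(40.0)
        trend = 1.0 + 0.1 * x
        y = trend + rng.normal(0, 0.3, 40)
        fitted = analytics.smooth_cpue(x, y, spar=0.7)
        interior = slice(5, 35)
        assert np.all(np.abs(fitted[interior] - trend[interior]) < 0.3)
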