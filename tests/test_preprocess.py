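"""Censoring and filtering rules with audit counts."""

import datetime as dt

import numpy as np
import pytest

from tandemtrack import preprocess as pp
from tandemtrack.types import BirdMetadata, LocationSeries, SECONDS_PER_DAY

DAY = SECONDS_PER_DAY


def _epoch(iso):
    return dt.datetime.fromisoformat(iso + "+00:00").timestamp()


def _series(bird, times, lons=None, lats=None, source="resight", sats=None):
    n = len(times)
    lons = np.full(n, 15.0) if lons is None else np.asarray(lons, float)
    lats = np.full(n, 58.0) if lats is None else np.asarray(lats, float)
    return LocationSeries(bird, np.asarray(times, float), lons, lats,
                          source=source, satellites=sats)


def _meta(bird, age="adult", partner=None, site="N", date="2018-06-15"):
    return BirdMetadata(bird, site, date, "f", age, "neckband", partner)


class TestCensorJuveniles:
    def test_adult_untouched(self):
        s = _series("A", [_epoch("2018-07-01T12:00:00")])
        out, removed = pp.censor_juveniles([s], [_meta("A", "adult")])
        assert len(out[0]) == 1 and removed["A"] == 0

    def test_cutoff_at_april_first_of_second_spring(self):
        # juvenile captured June 2018: obs on 2019-03-31 dropped, 2019-04-02 kept
        s = _series("J", [_epoch("2019-03-31T12:00:00"), _epoch("2019-04-02T12:00:00")])
        out, removed = pp.censor_juveniles([s], [_meta("J", "juvenile")])
        assert len(out[0]) == 1 and removed["J"] == 1
        assert out[0].t[0] == _epoch("2019-04-02T12:00:00")

    def test_all_after_cutoff_unchanged(self):
        s = _series("J", [_epoch("2019-05-01T12:00:00"), _epoch("2019-06-01T12:00:00")])
        out, removed = pp.censor_juveniles([s], [_meta("J", "juvenile")])
        assert len(out[0]) == 2 and removed["J"] == 0

    def test_idempotent(self):
        s = _series("J", [_epoch("2019-03-31T12:00:00"), _epoch("2019-04-02T12:00:00")])
        meta = [_meta("J", "juvenile")]
        once, _ = pp.censor_juveniles([s], meta)
        twice, removed2 = pp.censor_juveniles(once, meta)
        np.testing.assert_array_equal(once[0].t, twice[0].t)
        assert removed2["J"] == 0


class TestCensorPairs:
    def _pair(self, na, nb, dur_a, dur_b):
        sa = _series("A", np.arange(na) * (dur_a * DAY / max(na - 1, 1)))
        sb = _series("B", np.arange(nb) * (dur_b * DAY / max(nb - 1, 1)))
        meta = [_meta("A", partner="B"), _meta("B", partner="A")]
        return [sa, sb], meta

    def test_longer_duration_wins(self):
        series, meta = self._pair(10, 10, 400, 100)
        kept, censored = pp.censor_pairs(series, meta)
        assert censored == ["B"] and [s.individual_id for s in kept] == ["A"]

    def test_equal_duration_higher_count_wins(self):
        series, meta = self._pair(50, 40, 200, 200)
        _, censored = pp.censor_pairs(series, meta)
        assert censored == ["B"]

    def test_full_tie_lexicographic(self):
        series, meta = self._pair(10, 10, 200, 200)
        _, censored = pp.censor_pairs(series, meta)
        assert censored == ["B"]

    def test_multisite_fixture_censors_eight(self):
        # pairs across three sites (C1: 1 pair, C2: 2, N: 5) -> 8 censored
        series, meta = [], []
        pair_counts = {"C1": 1, "C2": 2, "N": 5}
        for site, npairs in pair_counts.items():
            for i in range(npairs):
                a, b = f"{site}a{i}", f"{site}b{i}"
                series += [
                    _series(a, np.arange(12) * DAY),
                    _series(b, np.arange(6) * DAY),
                ]
                meta += [_meta(a, partner=b, site=site), _meta(b, partner=a, site=site)]
        kept, censored = pp.censor_pairs(series, meta)
        assert len(censored) == 8
        assert len(kept) == 8
        by_site = {s: sum(c.startswith(s) for c in censored) for s in pair_counts}
        assert by_site == pair_counts


class TestDedupeDaily:
    def test_same_day_keeps_earliest(self):
        s = _series("A", [1000.0, 2000.0, 3000.0])
        out, removed = pp.dedupe_daily(s)
        assert len(out) == 1 and removed == 2 and out.t[0] == 1000.0

    def test_distinct_days_unchanged(self):
        s = _series("A", [0.0, DAY, 2 * DAY])
        out, removed = pp.dedupe_daily(s)
        assert len(out) == 3 and removed == 0

    def test_engineered_duplicate_count(self):
        # 153 extra same-day sightings spread over a season -> exactly 153 removed
        rng = np.random.default_rng(0)
        days = rng.choice(90, size=153) * DAY
        extras = days + rng.integers(1, 86_000, size=153)
        base = np.arange(90) * DAY + 100.0
        t = np.unique(np.concatenate([base, extras]))
        assert t.size == 243
        out, removed = pp.dedupe_daily(_series("A", t))
        assert removed == 153 and len(out) == 90

    def test_idempotent(self):
        s = _series("A", [0.0, 10.0, DAY + 5.0])
        once, _ = pp.dedupe_daily(s)
        twice, removed = pp.dedupe_daily(once)
        assert removed == 0
        np.testing.assert_array_equal(once.t, twice.t)


class TestMeanGroundSpeed:
    def test_paper_threshold_case(self):
        # 315.36 km in one day is exactly 3.65 m/s
        from scipy.optimize import brentq
        from tandemtrack.geo import geodesic_distance

        lat2 = brentq(lambda p: geodesic_distance(15, 50, 15, p) - 315_360.0, 51, 55)
        s = _series("A", [0.0, DAY], lons=[15.0, 15.0], lats=[50.0, lat2])
        assert pp.mean_ground_speed(s) == pytest.approx(3.65, rel=1e-6)

    def test_stationary_bird_zero(self):
        s = _series("A", [0.0, DAY, 2 * DAY])
        assert pp.mean_ground_speed(s) == 0.0

    def test_single_observation_flagged_nan(self):
        assert np.isnan(pp.mean_ground_speed(_series("A", [0.0])))

    def test_speeders_flagged_not_deleted(self):
        fast = _series("F", [0.0, DAY], lons=[10.0, 20.0], lats=[50.0, 58.0])
        slow = _series("S", [0.0, DAY], lons=[15.0, 15.01], lats=[58.0, 58.0])
        assert pp.flag_speeders([fast, slow]) == ["F"]

    def test_speed_filter_constant_derivation(self):
        assert pp.gps_speed_vmax() == 40.0


class TestGpsSpeedFilter:
    def test_clean_series_unchanged(self):
        t = np.arange(5) * 3600.0
        s = _series("A", t, lons=15.0 + 0.001 * np.arange(5), source="gps")
        out, removed = pp.gps_speed_filter(s)
        assert removed == 0 and len(out) == 5

    def test_single_outlier_removed(self):
        t = np.arange(7) * 3600.0
        lons = 15.0 + 0.001 * np.arange(7)
        lons[3] = 25.0  # teleport implying >> 40 m/s both ways
        s = _series("A", t, lons=lons, source="gps")
        out, removed = pp.gps_speed_filter(s)
        assert removed == 1
        assert 25.0 not in out.lon

    def test_short_series_unchanged(self):
        s = _series("A", [0.0], source="gps")
        out, removed = pp.gps_speed_filter(s)
        assert removed == 0 and len(out) == 1

    def test_idempotent(self):
        t = np.arange(7) * 3600.0
        lons = 15.0 + 0.001 * np.arange(7)
        lons[3] = 25.0
        s = _series("A", t, lons=lons, source="gps")
        once, _ = pp.gps_speed_filter(s)
        twice, removed = pp.gps_speed_filter(once)
        assert removed == 0
        np.testing.assert_array_equal(once.t, twice.t)


class TestSolarNoonThinning:
    def test_hourly_fixes_keep_nearest_11utc_at_15e(self):
        # solar noon at 15 degrees E is 11:00 UTC
        t = np.arange(48) * 3600.0
        s = _series("A", t, source="gps")
        out, removed = pp.thin_to_solar_noon(s)
        assert len(out) == 2 and removed == 46
        assert out.t[0] % DAY == 11 * 3600.0
        assert out.t[1] % DAY == 11 * 3600.0

    def test_already_daily_unchanged(self):
        t = np.arange(5) * DAY + 11 * 3600.0
        s = _series("A", t, source="gps")
        out, removed = pp.thin_to_solar_noon(s)
        assert removed == 0 and len(out) == 5

    def test_missing_days_not_interpolated(self):
        t = np.array([0.0, 5 * DAY])
        out, _ = pp.thin_to_solar_noon(_series("A", t, source="gps"))
        assert len(out) == 2

    def test_median_interval_near_24h(self):
        rng = np.random.default_rng(1)
        t = np.sort(np.concatenate([d * DAY + rng.uniform(0, DAY, 8) for d in range(30)]))
        out, _ = pp.thin_to_solar_noon(_series("A", t, source="gps"))
        med = np.median(np.diff(out.t))
        assert abs(med - DAY) < 3600.0


class TestRemoveFailedFixes:
    def test_zero_satellite_fixes_dropped(self):
        t = np.arange(10) * DAY
        sats = np.ones(10)
        sats[[2, 7]] = 0
        out, removed = pp.remove_failed_fixes(_series("A", t, source="gps", sats=sats))
        assert removed == 2 and len(out) == 8

    def test_all_valid_unchanged(self):
        out, removed = pp.remove_failed_fixes(_series("A", np.arange(4) * DAY, source="gps"))
        assert removed == 0 and len(out) == 4

    def test_all_invalid_empty(self):
        s = _series("A", np.arange(3) * DAY, source="gps", sats=np.zeros(3))
        out, removed = pp.remove_failed_fixes(s)
        assert removed == 3 and len(out) == 0


class TestPipelineConservation:
    def test_audit_counts_sum_to_input(self):
        rng = np.random.default_rng(2)
        t = np.sort(rng.choice(np.arange(0, 40 * DAY, 1800.0), 300, replace=False))
        lons = 15.0 + np.cumsum(rng.normal(0, 0.001, t.size))
        lons[50] += 20.0
        s = _series("A", t, lons=lons, source="gps")
        out, audit = pp.preprocess_gps(s)
        assert len(out) + sum(a.removed for a in audit) == len(s)

    def test_dedup_never_increases_mean_speed(self):
        rng = np.random.default_rng(3)
        t = np.sort(np.concatenate([np.arange(20) * DAY, np.arange(20) * DAY + 600.0]))
        lons = 15.0 + np.cumsum(rng.normal(0, 0.01, t.size))
        s = _series("A", t, lons=lons)
        dd, _ = pp.dedupe_daily(s)
        assert pp.mean_ground_speed(dd) <= pp.mean_ground_speed(s) + 1e-12
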