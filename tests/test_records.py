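"""Occurrence filters: SCALP removal, independence rules, reproduction clustering."""

import numpy as np
import pandas as pd
import pytest

from wolfrecol import records

from conftest import make_occurrences


class TestFilterScalp:
    def test_retains_all_non_c3(self):
        # a period with 43 C1, 4 C2 and no C3 keeps all 47 records
        rows = [(f"r{i}", "2016-01-01", 0.0, 0.0, "C1") for i in range(43)]
        rows += [(f"q{i}", "2016-01-01", 0.0, 0.0, "C2") for i in range(4)]
        df = make_occurrences(rows)
        assert len(records.filter_scalp(df)) == 47

    def test_all_c3_removed(self):
        df = make_occurrences([(f"r{i}", "2016-01-01", 0.0, 0.0, "C3") for i in range(5)])
        assert len(records.filter_scalp(df)) == 0

    def test_count_matches_bruteforce(self, rng):
        codes = rng.choice(["C1", "C2", "C3"], size=100)
        df = make_occurrences(
            [(f"r{i}", "2016-01-01", 0.0, 0.0, c) for i, c in enumerate(codes)]
        )
        expected = sum(1 for c in codes if c != "C3")
        out = records.filter_scalp(df)
        assert len(out) == expected
        assert list(out["record_id"]) == [f"r{i}" for i, c in enumerate(codes) if c != "C3"]

    def test_idempotent(self, rng):
        codes = rng.choice(["C1", "C2", "C3"], size=50)
        df = make_occurrences(
            [(f"r{i}", "2016-01-01", 0.0, 0.0, c) for i, c in enumerate(codes)]
        )
        once = records.filter_scalp(df)
        pd.testing.assert_frame_equal(records.filter_scalp(once), once)

    def test_unknown_code_rejected(self):
        df = make_occurrences([("r0", "2016-01-01", 0.0, 0.0, "C4")])
        with pytest.raises(ValueError, match="C4"):
            records.filter_scalp(df)


class TestDailyIndependence:
    def test_same_day_same_area_collapses(self):
        df = make_occurrences(
            [("b", "2020-05-01", 0, 0, "C1"), ("a", "2020-05-01", 1, 1, "C1")]
        )
        out = records.daily_independence(df)
        assert len(out) == 1
        assert out["record_id"].iloc[0] == "a"  # tie on time -> smallest id

    def test_consecutive_days_kept(self):
        df = make_occurrences(
            [("a", "2020-05-01", 0, 0, "C1"), ("b", "2020-05-02", 0, 0, "C1")]
        )
        assert len(records.daily_independence(df)) == 2

    def test_matches_distinct_pair_count(self, rng):
        n = 500
        days = rng.integers(0, 30, size=n)
        areas = rng.choice([f"A{i}" for i in range(5)], size=n)
        df = make_occurrences(
            [
                (f"r{i:03d}", pd.Timestamp("2021-03-01") + pd.Timedelta(days=int(d)), 0, 0, "C1")
                for i, d in enumerate(days)
            ]
        )
        df["area_id"] = areas
        out = records.daily_independence(df)
        assert len(out) == len(set(zip(areas, days)))

    def test_missing_dates_dropped_with_warning(self, caplog):
        df = make_occurrences(
            [("a", "2020-05-01", 0, 0, "C1"), ("b", "2020-05-02", 0, 0, "C1")]
        )
        df.loc[df["record_id"] == "b", "date"] = pd.NaT
        with caplog.at_level("WARNING"):
            out = records.daily_independence(df)
        assert list(out["record_id"]) == ["a"]
        assert "missing date" in caplog.text

    def test_idempotent(self, rng):
        days = rng.integers(0, 10, size=60)
        df = make_occurrences(
            [
                (f"r{i}", pd.Timestamp("2021-03-01") + pd.Timedelta(days=int(d)), 0, 0, "C1")
                for i, d in enumerate(days)
            ]
        )
        once = records.daily_independence(df)
        pd.testing.assert_frame_equal(records.daily_independence(once), once)


def brute_force_camera(minutes, window, rule):
    """O(n^2)-style reference for the thinning rule on one sorted group."""
    kept = []
    ref = None
    for t in sorted(minutes):
        if ref is None or t - ref > window:
            kept.append(t)
            ref = t
        elif rule == "previous":
            ref = t
    return kept


def make_detections(minutes, site="S1", species="wolf"):
    t0 = pd.Timestamp("2023-06-01 00:00")
    return pd.DataFrame(
        {
            "site": site,
            "species": species,
            "timestamp": [t0 + pd.Timedelta(minutes=float(m)) for m in minutes],
        }
    )


class TestCameraIndependence:
    @pytest.mark.parametrize(
        "minutes, expected",
        [
            ([0, 10, 45], [0, 45]),
            ([0, 29, 58], [0, 58]),  # retained event reopens the window
            ([0], [0]),
        ],
    )
    def test_rolling_rule(self, minutes, expected):
        out = records.camera_independence(make_detections(minutes))
        got = [
            (t - pd.Timestamp("2023-06-01")).total_seconds() / 60 for t in out["timestamp"]
        ]
        assert got == expected

    def test_previous_rule_burst_extends_window(self):
        # under the burst rule 58 is still within 30 min of 29, so only 0 stays
        out = records.camera_independence(make_detections([0, 29, 58]), rule="previous")
        assert len(out) == 1

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            records.camera_independence(make_detections([0, 10]), window_minutes=-1)

    @pytest.mark.parametrize("rule", ["rolling", "previous"])
    def test_matches_bruteforce_on_poisson_stream(self, rng, rule):
        minutes = np.cumsum(rng.exponential(20, size=1000))
        out = records.camera_independence(make_detections(minutes), rule=rule)
        got = [
            (t - pd.Timestamp("2023-06-01")).total_seconds() / 60 for t in out["timestamp"]
        ]
        assert np.allclose(got, brute_force_camera(minutes, 30.0, rule))

    def test_groups_are_independent(self, rng):
        # two species at one site are thinned separately
        a = make_detections([0, 10, 45], species="wolf")
        b = make_detections([5, 20, 50], species="red fox")
        out = records.camera_independence(pd.concat([a, b], ignore_index=True))
        assert (out["species"] == "wolf").sum() == 2
        assert (out["species"] == "red fox").sum() == 2

    def test_retained_gaps_exceed_window(self, rng):
        minutes = np.cumsum(rng.exponential(12, size=800))
        out = records.camera_independence(make_detections(minutes))
        gaps = out["timestamp"].diff().dropna().dt.total_seconds() / 60
        assert (gaps > 30).all()

    def test_idempotent(self, rng):
        minutes = np.cumsum(rng.exponential(25, size=300))
        once = records.camera_independence(make_detections(minutes))
        pd.testing.assert_frame_equal(records.camera_independence(once), once)


class TestClusterReproductions:
    @staticmethod
    def pups(rows):
        df = make_occurrences([(r[0], r[1], r[2], r[3], "C1") for r in rows])
        df["is_reproduction"] = True
        return df

    def test_below_threshold_merges(self):
        df = self.pups([("a", "2024-05-01", 0, 0), ("b", "2024-05-20", 15_000, 0)])
        assert len(records.cluster_reproductions(df)) == 1

    def test_above_threshold_separates(self):
        df = self.pups([("a", "2024-05-01", 0, 0), ("b", "2024-05-20", 25_000, 0)])
        assert len(records.cluster_reproductions(df)) == 2

    def test_two_well_separated_clusters(self, rng):
        # two groups of pup records >= 20 km apart give two unique events
        near = [(f"a{i}", "2024-06-01", float(rng.uniform(0, 3000)), float(rng.uniform(0, 3000))) for i in range(4)]
        far = [(f"b{i}", "2024-06-01", 40_000 + float(rng.uniform(0, 3000)), 0.0) for i in range(3)]
        events = records.cluster_reproductions(self.pups(near + far))
        assert len(events) == 2
        assert sorted(len(e.member_record_ids) for e in events) == [3, 4]

    def test_years_never_mix(self):
        df = self.pups([("a", "2023-05-01", 0, 0), ("b", "2024-05-01", 0, 0)])
        events = records.cluster_reproductions(df)
        assert len(events) == 2
        assert sorted(e.year for e in events) == [2023, 2024]

    def test_permutation_invariant(self, rng):
        rows = [
            (f"r{i}", "2024-05-01", float(x), float(y))
            for i, (x, y) in enumerate(rng.uniform(0, 60_000, size=(20, 2)))
        ]
        df = self.pups(rows)
        base = records.cluster_reproductions(df)
        for _ in range(5):
            perm = df.sample(frac=1, random_state=int(rng.integers(1e6))).reset_index(drop=True)
            got = records.cluster_reproductions(perm)
            assert len(got) == len(base)
            assert sorted(tuple(sorted(e.member_record_ids)) for e in got) == sorted(
                tuple(sorted(e.member_record_ids)) for e in base
            )

    def test_rejects_non_pup_records(self):
        df = make_occurrences([("a", "2024-05-01", 0, 0, "C1")])
        with pytest.raises(ValueError):
            records.cluster_reproductions(df)
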