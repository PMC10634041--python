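"""Binning, filtering, scaling and label-derivation contracts.

Derived expectations come from independent brute-force oracles (explicit
grouping loops, element-wise maps, pairwise trajectory scans) written here,
not from the implementation under test.
"""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from msmilestone.preprocess import (FOUR_HOURS, DemographicsEncoder,
                                    FeatureScaler, LongitudinalTable,
                                    bin_observations, derive_labels,
                                    filter_features, truncate_history)

COLS = ["encounter_id", "encounter_start", "encounter_end", "obs_time",
        "feature", "value"]


def make_stream(rows):
    return pd.DataFrame(rows, columns=COLS)


def hourly_rows(enc_id, start, end, feature="hr", value=70.0):
    rows, t = [], start
    while t <= end:
        rows.append((enc_id, start, end, t, feature, value))
        t += dt.timedelta(hours=1)
    return rows


class TestBinning:
    def test_two_encounter_worked_example_gives_four_rows(self):
        """Encounters 2014-05-05 13:15-18:00 and 2015-09-20 09:12-13:00 with
        observations in every clock window bin into exactly four rows."""
        rows = hourly_rows("e1", dt.datetime(2014, 5, 5, 13, 15),
                           dt.datetime(2014, 5, 5, 18, 0))
        rows += hourly_rows("e2", dt.datetime(2015, 9, 20, 9, 12),
                            dt.datetime(2015, 9, 20, 13, 0))
        table = bin_observations(make_stream(rows), ["hr"])
        assert table.t_k == 4
        # windows are midnight-anchored: 12-16 and 16-20; 08-12 and 12-16
        assert [b.hour for b in table.bin_starts] == [12, 16, 8, 12]

    def test_single_observation_single_row(self):
        s = dt.datetime(2020, 1, 1, 10, 0)
        stream = make_stream([("e", s, s + dt.timedelta(hours=2),
                               s + dt.timedelta(minutes=5), "na", 141.0)])
        table = bin_observations(stream, ["na", "k"])
        assert table.t_k == 1
        assert table.values[0, 0] == 141.0
        assert table.values[0, 1] == 0.0  # unobserved feature is zero

    def test_random_events_match_grouping_oracle(self, rng):
        """100 random events equal a brute-force (encounter, clock-bin)
        grouping-and-averaging loop."""
        feats = ["f0", "f1", "f2"]
        rows = []
        for enc in range(4):
            start = dt.datetime(2019, 3, 1 + enc, int(rng.integers(0, 18)),
                                int(rng.integers(0, 60)))
            end = start + dt.timedelta(hours=float(rng.uniform(1, 8)))
            span = (end - start).total_seconds()
            for _ in range(25):
                t = start + dt.timedelta(seconds=float(rng.uniform(0, span)))
                rows.append((f"e{enc}", start, end, t,
                             feats[rng.integers(0, 3)],
                             float(rng.normal())))
        table = bin_observations(make_stream(rows), feats)

        # oracle: independent nested grouping loop
        cells = {}
        for enc_id, _s, _e, t, f, v in rows:
            midnight = dt.datetime.combine(t.date(), dt.time())
            b = midnight + ((t - midnight) // FOUR_HOURS) * FOUR_HOURS
            cells.setdefault((enc_id, b), {}).setdefault(f, []).append(v)
        expected = []
        for (enc_id, b), obs in sorted(cells.items(), key=lambda kv: (kv[0][1], kv[0][0])):
            expected.append([np.mean(obs.get(f, [0.0])) if f in obs else 0.0
                             for f in feats])
        np.testing.assert_allclose(table.values, np.array(expected), atol=1e-12)

    def test_observation_outside_encounter_names_record(self):
        s = dt.datetime(2020, 1, 1, 10)
        stream = make_stream([("e9", s, s + dt.timedelta(hours=1),
                               s + dt.timedelta(hours=2), "hr", 70.0)])
        with pytest.raises(ValueError, match="e9"):
            bin_observations(stream, ["hr"])

    def test_negative_granularity_rejected(self):
        with pytest.raises(ValueError, match="granularity"):
            bin_observations(make_stream([]), ["hr"],
                             granularity=dt.timedelta(hours=-4))

    def test_binning_is_idempotent(self, rng):
        """Re-binning the bin means at the same granularity returns the
        same table: one observation per (encounter, bin) at the bin mean."""
        rows = hourly_rows("e1", dt.datetime(2021, 6, 1, 9, 30),
                           dt.datetime(2021, 6, 1, 15, 0))
        table = bin_observations(make_stream(rows), ["hr"])
        rebin_rows = [
            (enc, b, b + FOUR_HOURS, b, "hr", table.values[i, 0])
            for i, (enc, b) in enumerate(zip(table.encounter_ids,
                                             table.bin_starts))
        ]
        again = bin_observations(make_stream(rebin_rows), ["hr"])
        np.testing.assert_allclose(again.values, table.values)
        assert again.bin_starts == table.bin_starts

    def test_bins_never_span_encounters(self, rng):
        """Two encounters sharing a clock window yield separate rows."""
        s1 = dt.datetime(2020, 5, 5, 9, 0)
        s2 = dt.datetime(2020, 5, 5, 10, 30)
        rows = [("a", s1, s1 + dt.timedelta(hours=1),
                 s1 + dt.timedelta(minutes=10), "hr", 60.0),
                ("b", s2, s2 + dt.timedelta(hours=1),
                 s2 + dt.timedelta(minutes=10), "hr", 80.0)]
        table = bin_observations(make_stream(rows), ["hr"])
        assert table.t_k == 2
        assert sorted(table.encounter_ids) == ["a", "b"]


class TestFeatureFilter:
    def make_cohort_stream(self, pattern):
        """pattern: feature -> list of patient ids with an observation."""
        rows = []
        for feat, pids in pattern.items():
            for pid in pids:
                rows.append({"patient_id": pid, "feature": feat, "value": 1.0})
        return pd.DataFrame(rows)

    def test_nine_percent_feature_discarded(self):
        stream = self.make_cohort_stream(
            {"rare": [f"p{i}" for i in range(9)],
             "common": [f"p{i}" for i in range(100)]})
        kept = filter_features(stream, n_patients=100, min_fraction=0.10)
        assert kept == ["common"]

    def test_universal_feature_retained(self):
        stream = self.make_cohort_stream({"hr": ["p0", "p1", "p2"]})
        assert filter_features(stream, n_patients=3) == ["hr"]

    def test_random_pattern_matches_counting_oracle(self, rng):
        n = 40
        pattern = {
            f"f{j}": [f"p{i}" for i in range(n) if rng.random() < rng.uniform(0.02, 0.6)]
            for j in range(12)
        }
        pattern = {f: p for f, p in pattern.items() if p}
        stream = self.make_cohort_stream(pattern)
        kept = filter_features(stream, n_patients=n, min_fraction=0.10)
        expected = sorted(f for f, pids in pattern.items()
                          if len(set(pids)) / n >= 0.10)
        assert kept == expected

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            filter_features(pd.DataFrame(columns=["patient_id", "feature"]),
                            n_patients=0)


class TestScaling:
    def fit_on(self, values, feature="x"):
        df = pd.DataFrame({"feature": feature, "value": values})
        return FeatureScaler().fit(df)

    def test_training_endpoints_map_to_zero_and_one(self):
        scaler = self.fit_on([2.0, 4.0, 6.0])
        assert [scaler.transform_value("x", v) for v in (2, 4, 6)] == [0, 0.5, 1]

    def test_constant_feature_maps_to_zero(self):
        scaler = self.fit_on([3.0, 3.0])
        assert scaler.transform_value("x", 3.0) == 0.0

    def test_random_matrix_matches_elementwise_oracle(self, rng):
        train = rng.normal(size=60)
        test = rng.normal(size=60) * 2
        scaler = self.fit_on(train)
        lo, hi = train.min(), train.max()
        for v in test:
            expected = min(max((v - lo) / (hi - lo), 0.0), 1.0)
            assert abs(scaler.transform_value("x", v) - expected) < 1e-12

    def test_unfitted_scaler_rejected(self):
        with pytest.raises(RuntimeError, match="fit"):
            FeatureScaler().transform_value("x", 1.0)

    def test_medication_indicators_pass_through(self):
        scaler = FeatureScaler(passthrough=True).fit(pd.DataFrame())
        assert scaler.transform_value("med", 1.0) == 1.0

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=20,
                    unique=True))
    def test_scaling_preserves_order(self, values):
        scaler = self.fit_on(values)
        scaled = [scaler.transform_value("x", v) for v in sorted(values)]
        assert all(a <= b for a, b in zip(scaled, scaled[1:]))
        assert scaled[0] == 0.0 and scaled[-1] == 1.0


class TestLabels:
    def visits(self, pid, entries):
        return pd.DataFrame(
            [(pid, t, e) for t, e in entries],
            columns=["patient_id", "visit_time", "edss"])

    def test_single_visit_patient_degenerate(self):
        t = dt.datetime(2018, 1, 1)
        recs = derive_labels(self.visits("p", [(t, 5.0)]), 4.0)
        assert recs[0].index_time == recs[0].target_time == t
        assert recs[0].label == 1

    def test_milestone_boundary_is_strict(self):
        t = dt.datetime(2018, 1, 1)
        recs = derive_labels(
            self.visits("p", [(t, 2.0), (t + dt.timedelta(days=1200), 4.0)]), 4.0)
        assert recs[0].label == 0

    def test_random_trajectories_match_pairing_oracle(self, rng):
        """50 random trajectories vs an independent all-pairs scan."""
        horizon = dt.timedelta(days=3 * 365.25)
        frames, expected = [], {}
        for i in range(50):
            pid = f"p{i:02d}"
            n = int(rng.integers(1, 7))
            t0 = dt.datetime(2010, 1, 1) + dt.timedelta(days=int(rng.integers(0, 1000)))
            times = sorted(t0 + dt.timedelta(days=int(d))
                           for d in rng.integers(0, 3000, size=n))
            scores = np.round(rng.uniform(0, 9.5, size=n) * 2) / 2
            frames.append(self.visits(pid, list(zip(times, scores))))
            # oracle: independent pairwise scan of the same rule
            if times[-1] - times[0] >= horizon:
                idx = max(i for i in range(n) if times[-1] - times[i] >= horizon)
                tgt = max(j for j in range(n) if times[j] - times[idx] >= horizon)
            else:
                idx, tgt = 0, n - 1
            expected[pid] = (times[idx], times[tgt], int(scores[tgt] > 4.0))
        recs = derive_labels(pd.concat(frames, ignore_index=True), 4.0)
        assert len(recs) == 50  # exactly one record per patient
        for r in recs:
            e_idx, e_tgt, e_lab = expected[r.patient_id]
            assert (r.index_time, r.target_time, r.label) == (e_idx, e_tgt, e_lab)

    def test_visitless_input_rejected(self):
        empty = pd.DataFrame(columns=["patient_id", "visit_time", "edss"])
        with pytest.raises(ValueError, match="visit"):
            derive_labels(empty, 4.0)


class TestTruncation:
    def make_table(self, starts):
        return LongitudinalTable(
            values=np.arange(len(starts) * 2, dtype=float).reshape(-1, 2),
            bin_starts=list(starts),
            encounter_ids=[f"e{i}" for i in range(len(starts))],
            features=["a", "b"],
        )

    def test_index_before_all_bins_empties_table(self):
        starts = [dt.datetime(2020, 1, d) for d in (5, 6, 7)]
        out = truncate_history(self.make_table(starts), dt.datetime(2020, 1, 1))
        assert out.t_k == 0 and out.f_k == 2

    def test_index_after_all_bins_keeps_table(self):
        starts = [dt.datetime(2020, 1, d) for d in (5, 6, 7)]
        table = self.make_table(starts)
        out = truncate_history(table, dt.datetime(2021, 1, 1))
        np.testing.assert_array_equal(out.values, table.values)

    def test_random_index_matches_filter_oracle(self, rng):
        starts = sorted(dt.datetime(2020, 1, 1)
                        + dt.timedelta(hours=int(h))
                        for h in rng.integers(0, 500, size=12))
        table = self.make_table(starts)
        cut = dt.datetime(2020, 1, 1) + dt.timedelta(hours=int(rng.integers(0, 500)))
        out = truncate_history(table, cut)
        keep = [i for i, b in enumerate(starts) if b <= cut]
        np.testing.assert_array_equal(out.values, table.values[keep])


class TestDemographics:
    def test_one_hot_groups_and_age_range(self):
        demo = pd.DataFrame({
            "race": ["white", "black", "white"],
            "ethnicity": ["hispanic", "not_hispanic", "not_hispanic"],
            "sex": ["female", "male", "female"],
            "age": [20.0, 40.0, 60.0],
        })
        enc = DemographicsEncoder().fit(demo)
        v = enc.transform_one({"race": "black", "ethnicity": "hispanic",
                               "sex": "male", "age": 40.0})
        assert v.shape == (enc.dim,)
        assert v[:2].sum() == 1.0 and v[2:4].sum() == 1.0  # one-hot groups
        assert v[-2] == 1.0  # male flag
        assert v[-1] == 0.5  # midpoint age
        out_of_range = enc.transform_one({"race": "white", "ethnicity": "hispanic",
                                          "sex": "female", "age": 90.0})
        assert out_of_range[-1] == 1.0  # clipped
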