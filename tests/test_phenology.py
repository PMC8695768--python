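"""Phenology rules, LOWESS smoothing, and bimodal extrema detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xylokin.phenology import (
    PhenologyRecord,
    detect_onset_end,
    find_bimodal_extrema,
    smooth_series,
    stand_phenology,
)
from xylokin.simulate import bimodal_demo_scenario, expected_phases, generate_tree, sampling_grid


def _series(doys, counts):
    return pd.DataFrame({"doy": doys, "n_enlarging": counts})


class TestOnsetEnd:
    def test_first_and_last_active_day(self):
        doys = np.concatenate([[57, 66], np.arange(75, 319, 9), [327, 336]])
        counts = np.where((doys >= 75) & (doys <= 318), 3, 0)
        rec = detect_onset_end(_series(doys, counts), tree_id="t1")
        assert (rec.onset_doy, rec.end_doy, rec.duration_days) == (75, 318, 243)

    def test_single_active_day_degenerate(self):
        doys = [90, 100, 110]
        rec = detect_onset_end(_series(doys, [0, 2, 0]))
        assert (rec.onset_doy, rec.end_doy, rec.duration_days) == (100, 100, 0)

    def test_mid_season_zeros_do_not_split_the_season(self):
        rec = detect_onset_end(_series([80, 90, 100, 110], [1, 0, 0, 2]))
        assert (rec.onset_doy, rec.end_doy) == (80, 110)

    def test_all_zero_season_yields_empty_record(self):
        rec = detect_onset_end(_series([80, 90, 100], [0, 0, 0]), tree_id="t9")
        assert rec.empty and rec.onset_doy is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            detect_onset_end(_series([80, 90], [1, -1]))

    def test_record_invariant_enforced(self):
        with pytest.raises(ValueError):
            PhenologyRecord("x", 100, 90, -10)
        with pytest.raises(ValueError):
            PhenologyRecord("x", 100, 150, 40)

    def test_onset_tracks_generator_truth(self):
        sc = bimodal_demo_scenario()
        grid = sampling_grid(sc)
        df = generate_tree(sc, 1, seed=3)
        exp = expected_phases(grid, sc, sc.A_mean)["n_enlarging"]
        truth_onset = grid[np.rint(exp) >= 1][0]
        rec = detect_onset_end(df[["doy", "n_enlarging"]])
        assert abs(rec.onset_doy - truth_onset) <= sc.sampling_interval_days


class TestSmoothing:
    def test_constant_series_reproduced(self):
        ser = pd.Series(4.0, index=np.arange(50, 150, 10))
        assert smooth_series(ser).to_numpy() == pytest.approx(4.0)

    def test_straight_line_reproduced(self):
        x = np.arange(50, 150, 10, dtype=float)
        ser = pd.Series(0.3 * x - 2.0, index=x)
        assert smooth_series(ser, span=0.5).to_numpy() == pytest.approx(
            ser.to_numpy(), rel=1e-8)

    def test_smoothing_reduces_noise_around_truth(self):
        sc = bimodal_demo_scenario()
        grid = sampling_grid(sc)
        truth = expected_phases(grid, sc, sc.A_mean)["n_enlarging"]
        rng = np.random.default_rng(2)
        noisy = np.clip(truth + rng.normal(0, 3.0, truth.shape), 0, None)
        sm = smooth_series(pd.Series(noisy, index=grid)).to_numpy()
        assert np.mean((sm - truth) ** 2) < np.mean((noisy - truth) ** 2)

    def test_input_contracts(self):
        ser = pd.Series(np.arange(6.0), index=np.arange(6.0))
        with pytest.raises(ValueError):
            smooth_series(ser)  # too short
        long = pd.Series(np.arange(10.0), index=np.arange(10.0))
        with pytest.raises(ValueError):
            smooth_series(long, span=0.0)


class TestExtrema:
    def _two_bump(self, h2=8.0):
        x = np.arange(40, 320, 9, dtype=float)
        y = (12.0 * np.exp(-0.5 * ((x - 110) / 25) ** 2)
             + h2 * np.exp(-0.5 * ((x - 235) / 25) ** 2))
        return pd.Series(y, index=x)

    def test_two_bumps_found_in_day_order(self):
        ext = find_bimodal_extrema(self._two_bump())
        assert ext.is_bimodal
        d1, d2 = ext.first_max[0], ext.second_max[0]
        assert abs(d1 - 110) <= 9 and abs(d2 - 235) <= 9
        assert ext.first_max[0] < ext.first_min[0] < ext.second_max[0] <= ext.second_min[0]
        assert ext.second_below_first is True

    def test_second_bump_higher_flag(self):
        ext = find_bimodal_extrema(self._two_bump(h2=20.0))
        assert ext.is_bimodal and ext.second_below_first is False

    def test_monotone_series_flagged_not_bimodal(self):
        x = np.arange(40, 200, 9, dtype=float)
        ext = find_bimodal_extrema(pd.Series(np.linspace(0, 30, x.size), index=x))
        assert not ext.is_bimodal and ext.first_max is None

    def test_bell_shape_reported_unimodal(self):
        x = np.arange(40, 320, 9, dtype=float)
        y = 10.0 * np.exp(-0.5 * ((x - 180) / 40) ** 2)
        ext = find_bimodal_extrema(pd.Series(y, index=x))
        assert not ext.is_bimodal
        assert abs(ext.unimodal_max[0] - 180) <= 9
        assert ext.unimodal_min[0] > ext.unimodal_max[0]

    def test_boundary_point_can_be_first_max(self):
        # dormant-season maximum at the first sampling date, then decline
        x = np.arange(51, 340, 9, dtype=float)
        y = np.concatenate([np.linspace(7, 2, 12), np.full(x.size - 12, 2.0)])
        y[18:24] = [3, 4.5, 5, 4.5, 3, 2.5]  # second, smaller bump
        ext = find_bimodal_extrema(pd.Series(y, index=x))
        assert ext.is_bimodal
        assert ext.first_max[0] == 51.0

    def test_three_bumps_keep_two_most_prominent_and_flag(self):
        x = np.arange(0, 300, 5, dtype=float)
        y = (10 * np.exp(-0.5 * ((x - 60) / 12) ** 2)
             + 8 * np.exp(-0.5 * ((x - 150) / 12) ** 2)
             + 1.2 * np.exp(-0.5 * ((x - 230) / 8) ** 2))
        ext = find_bimodal_extrema(pd.Series(y, index=x), min_prominence=0.5)
        assert ext.is_bimodal and ext.ambiguous
        assert abs(ext.first_max[0] - 60) <= 5 and abs(ext.second_max[0] - 150) <= 5

    def test_planted_peaks_recovered_on_generated_tree(self):
        sc = bimodal_demo_scenario()
        from scipy.signal import find_peaks
        fine = np.arange(40.0, 320.0, 0.1)
        e = expected_phases(fine, sc, sc.A_mean)["n_enlarging"]
        truth = fine[find_peaks(e)[0]]
        df = generate_tree(sc, 3, seed=1)
        sm = smooth_series(df.set_index("doy")["n_enlarging"])
        ext = find_bimodal_extrema(sm)
        assert ext.is_bimodal
        assert abs(ext.first_max[0] - truth[0]) <= sc.sampling_interval_days
        assert abs(ext.second_max[0] - truth[1]) <= sc.sampling_interval_days


class TestStandPhenology:
    def test_mean_matches_reported_style_value(self):
        recs = [PhenologyRecord(f"t{i}", o, 318, 318 - o)
                for i, o in enumerate([75, 75, 76, 75, 75])]
        s = stand_phenology(recs)
        assert s.onset_mean == pytest.approx(75.2)
        assert s.n_trees == 5 and not s.single_tree

    def test_single_record_sd_zero_with_flag(self):
        s = stand_phenology([PhenologyRecord("a", 80, 300, 220)])
        assert s.single_tree and s.onset_sd == 0.0

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            stand_phenology([PhenologyRecord("a", None, None, None)])

    @given(st.lists(st.tuples(st.integers(40, 150), st.integers(0, 200)),
                    min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_duration_linearity(self, pairs):
        recs = [PhenologyRecord(f"t{i}", o, o + d, d)
                for i, (o, d) in enumerate(pairs)]
        s = stand_phenology(recs)
        assert s.duration_mean == pytest.approx(s.end_mean - s.onset_mean)
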