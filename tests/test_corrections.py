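"""Correction engine: taper chain, gap filling, re-born back-fill, pipeline."""

import numpy as np
import pandas as pd
import pytest

from pspcensus.corrections import (apply_taper_correction, backfill_reborn,
                                   correct_archive, correct_tree,
                                   detect_hom_raises, fill_gaps)
from pspcensus.schema import decimal_year, default_census_date
from pspcensus.simulate import SimulationConfig, simulate_archive
from tests.conftest import series_df

A = "alive"
D = "dead"
M = "missing"


def dates_for(years):
    return {y: decimal_year(default_census_date(y)) for y in years}


class TestDetectHomRaises:
    def test_single_raise_ratio(self):
        s = series_df([(2000, 30.0, 1.5, A), (2001, 31.0, 1.5, A),
                       (2002, 28.0, 3.5, A), (2003, 28.5, 3.5, A)])
        events = detect_hom_raises(s)
        assert len(events) == 1
        e = events[0]
        assert (e.raise_campaign, e.hom_old, e.hom_new) == (2002, 1.5, 3.5)
        assert e.ratio == pytest.approx(28.0 / 31.0)

    def test_constant_hom_no_events(self):
        s = series_df([(2000, 30.0, 1.5, A), (2001, 30.5, 1.5, A)])
        assert detect_hom_raises(s) == []

    def test_two_raises_chained(self):
        s = series_df([(2000, 30.0, 1.5, A), (2001, 27.0, 3.5, A),
                       (2002, 27.3, 3.5, A), (2003, 24.0, 4.5, A)])
        events = detect_hom_raises(s)
        assert [e.raise_campaign for e in events] == [2001, 2003]
        assert events[0].ratio == pytest.approx(27.0 / 30.0)
        assert events[1].ratio == pytest.approx(24.0 / 27.3)

    def test_raise_with_missing_flank_has_nan_ratio(self):
        # hom noted as raised but girth not taken, and never measured again
        s = series_df([(2000, 30.0, 1.5, A), (2001, np.nan, 4.5, M)])
        events = detect_hom_raises(s)
        assert len(events) == 1
        assert np.isnan(events[0].ratio)
        with pytest.raises(ValueError):
            apply_taper_correction(s, events)


class TestApplyTaper:
    def test_conversion_at_and_after_raise(self):
        s = series_df([(2000, 30.0, 1.5, A), (2001, 31.0, 1.5, A),
                       (2002, 28.0, 3.5, A), (2003, 28.4, 3.5, A)])
        out = apply_taper_correction(s, detect_hom_raises(s))
        vals = out.set_index("campaign_year")["dbh_cm"]
        assert vals[2000] == 30.0 and vals[2001] == 31.0
        assert vals[2002] == 31.0          # continuity at the raise
        assert vals[2003] == 31.4          # 28.4 / (28/31) = 31.44 -> 31.4
        prov = out.set_index("campaign_year")["provenance"]
        assert prov[2002] == prov[2003] == "taper_converted"
        assert (out["hom_m"] == 1.5).all()

    def test_ratio_one_is_identity(self):
        s = series_df([(2000, 30.0, 1.5, A), (2001, 30.0, 4.5, A)])
        out = apply_taper_correction(s, detect_hom_raises(s))
        assert list(out["dbh_cm"]) == [30.0, 30.0]

    def test_two_raises_divisor_is_product_of_ratios(self):
        s = series_df([(2000, 30.0, 1.5, A), (2001, 27.0, 3.5, A),
                       (2002, 24.3, 4.5, A), (2003, 24.6, 4.5, A)])
        events = detect_hom_raises(s)
        out = apply_taper_correction(s, events)
        r1, r2 = events[0].ratio, events[1].ratio
        expected = round(24.6 / (r1 * r2) + 1e-9, 1)
        assert out.set_index("campaign_year")["dbh_cm"][2003] == \
            pytest.approx(expected)

    def test_nonpositive_ratio_rejected(self):
        from pspcensus.corrections import TaperEvent
        s = series_df([(2000, 30.0, 1.5, A), (2001, 28.0, 4.5, A)])
        with pytest.raises(ValueError):
            apply_taper_correction(s, [TaperEvent(2001, 1.5, 4.5, -0.5)])


class TestFillGaps:
    def test_midpoint_interpolation(self):
        s = series_df([(2000, 10.0, 1.5, A), (2001, np.nan, np.nan, M),
                       (2002, 12.0, 1.5, A)])
        out = fill_gaps(s, dates_for([2000, 2001, 2002]))
        assert out.set_index("campaign_year")["dbh_cm"][2001] == 11.0
        assert out.set_index("campaign_year")["provenance"][2001] == \
            "interpolated"

    def test_interpolation_in_decimal_time(self):
        # 2012 -> 2015 bridge over skipped campaigns: 2015 value at 1/3
        s = series_df([(2012, 30.0, 1.5, A), (2015, np.nan, np.nan, M),
                       (2017, 33.0, 1.5, A)])
        out = fill_gaps(s, dates_for([2012, 2015, 2017]))
        v = out.set_index("campaign_year")["dbh_cm"][2015]
        assert v == pytest.approx(30.0 + 3.0 * 3 / 5, abs=0.06)

    def test_negative_increment_carries_forward(self):
        s = series_df([(2000, 30.0, 1.5, A), (2001, np.nan, np.nan, M),
                       (2002, 29.0, 1.5, A)])
        out = fill_gaps(s, dates_for([2000, 2001, 2002]))
        vals = out.set_index("campaign_year")["dbh_cm"]
        assert vals[2001] == 30.0 and vals[2002] == 30.0
        assert out.set_index("campaign_year")["provenance"][2002] == \
            "carried_forward"

    def test_negative_increment_with_raise_uses_taper(self):
        s = series_df([(2000, 31.0, 1.5, A), (2001, np.nan, np.nan, M),
                       (2002, 28.0, 4.5, A)])
        out = fill_gaps(s, dates_for([2000, 2001, 2002]))
        vals = out.set_index("campaign_year")["dbh_cm"]
        assert vals[2001] == 31.0 and vals[2002] == 31.0
        assert out.set_index("campaign_year")["provenance"][2002] == \
            "taper_converted"

    def test_equal_flanks_constant_fill(self):
        s = series_df([(2000, 30.0, 1.5, A), (2001, np.nan, np.nan, M),
                       (2002, 30.0, 1.5, A)])
        out = fill_gaps(s, dates_for([2000, 2001, 2002]))
        assert out.set_index("campaign_year")["dbh_cm"][2001] == 30.0

    def test_leading_and_trailing_runs_left_unfilled(self):
        s = series_df([(2000, np.nan, np.nan, M), (2001, 30.0, 1.5, A),
                       (2002, np.nan, np.nan, M)])
        out = fill_gaps(s, dates_for([2000, 2001, 2002]))
        assert np.isnan(out["dbh_cm"].iloc[0])
        assert np.isnan(out["dbh_cm"].iloc[2])

    def test_interpolated_values_within_flanks(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            d0 = float(rng.uniform(10, 80))
            d1 = float(np.round(d0 + rng.uniform(-3, 3), 1))
            d0 = float(np.round(d0, 1))
            s = series_df([(2000, d0, 1.5, A)] +
                          [(y, np.nan, np.nan, M) for y in (2001, 2002)] +
                          [(2003, d1, 1.5, A)])
            out = fill_gaps(s, dates_for([2000, 2001, 2002, 2003]))
            v = out["dbh_cm"].to_numpy()
            assert np.all(v >= min(d0, d1) - 1e-9)
            assert np.all(v <= max(d0, d1) + 1e-9)
            # carry-forward never decreases the series
            if d1 < d0:
                assert np.all(np.diff(v) >= -1e-9)


class TestBackfillReborn:
    def test_dead_interval_backfilled(self):
        s = series_df([(2000, 30.0, 1.5, A), (2001, np.nan, np.nan, D),
                       (2002, np.nan, np.nan, D), (2003, 31.0, 1.5, A)])
        out = backfill_reborn(s)
        vals = out.set_index("campaign_year")["dbh_cm"]
        assert vals[2001] == 31.0 and vals[2002] == 31.0
        assert (out["status"] == A).all()
        assert (out["mortality_code"] == "none").all()
        prov = out.set_index("campaign_year")["provenance"]
        assert prov[2001] == prov[2002] == "reborn_backfill"

    def test_no_dead_interval_is_identity(self):
        s = series_df([(2000, 30.0, 1.5, A), (2001, 30.5, 1.5, A)])
        out = backfill_reborn(s)
        pd.testing.assert_frame_equal(out[s.columns], s)

    def test_two_intervals_each_from_own_reborn_value(self):
        s = series_df([(2000, 30.0, 1.5, A), (2001, np.nan, np.nan, D),
                       (2002, 31.0, 1.5, A), (2003, np.nan, np.nan, D),
                       (2004, 32.0, 1.5, A)])
        out = backfill_reborn(s)
        vals = out.set_index("campaign_year")["dbh_cm"]
        assert vals[2001] == 31.0 and vals[2003] == 32.0

    def test_true_death_untouched(self):
        s = series_df([(2000, 30.0, 1.5, A), (2001, np.nan, np.nan, D)])
        out = backfill_reborn(s)
        assert out["status"].iloc[1] == D

    def test_reborn_without_measurement_errors(self):
        # found alive again but never measured afterwards
        s = series_df([(2000, 30.0, 1.5, A), (2001, np.nan, np.nan, D),
                       (2002, np.nan, np.nan, A)])
        with pytest.raises(ValueError):
            backfill_reborn(s)


class TestCorrectTree:
    def test_clean_series_all_raw(self):
        s = series_df([(2000, 30.0, 1.5, A), (2001, 30.5, 1.5, A)])
        out = correct_tree(s, [2000, 2001])
        assert list(out["provenance"]) == ["raw", "raw"]

    def test_override_then_interpolation(self):
        s = series_df([(2000, 30.0, 1.5, A), (2001, 45.0, 1.5, A),
                       (2002, np.nan, np.nan, M), (2003, 33.0, 1.5, A),
                       (2004, 34.0, 1.5, A)])
        ov = pd.DataFrame([{"campaign_year": 2001, "dbh_cm": 31.0}])
        out = correct_tree(s, list(range(2000, 2005)),
                           dates_for(range(2000, 2005)), ov)
        prov = out.set_index("campaign_year")["provenance"]
        vals = out.set_index("campaign_year")["dbh_cm"]
        assert prov[2001] == "manual_override" and vals[2001] == 31.0
        assert prov[2002] == "interpolated" and vals[2002] == 32.0

    def test_hole_free_between_first_and_last(self):
        s = series_df([(2000, 30.0, 1.5, A), (2004, 31.0, 1.5, A)])
        out = correct_tree(s, list(range(2000, 2005)),
                           dates_for(range(2000, 2005)))
        assert list(out["campaign_year"]) == list(range(2000, 2005))
        assert out["dbh_cm"].notna().all()

    def test_idempotent_on_synthetic_series(self):
        cfg = SimulationConfig(seed=9, n_plots=1, initial_density_per_ha=60)
        archive, _ = simulate_archive(cfg)
        once = correct_archive(archive)
        twice = correct_archive(once)
        key = ["plot_no", "subplot_no", "tree_no", "campaign_year"]
        a = once.measures.sort_values(key).reset_index(drop=True)
        b = twice.measures.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_output_independent_of_row_order(self):
        cfg = SimulationConfig(seed=10, n_plots=1, initial_density_per_ha=30)
        archive, _ = simulate_archive(cfg)
        shuffled = archive.copy()
        shuffled.measures = shuffled.measures.sample(
            frac=1.0, random_state=1).reset_index(drop=True)
        key = ["plot_no", "subplot_no", "tree_no", "campaign_year"]
        a = correct_archive(archive).measures.sort_values(key) \
            .reset_index(drop=True)
        b = correct_archive(shuffled).measures.sort_values(key) \
            .reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_correction_reduces_error_vs_truth(self):
        """With hom raises on, corrected series track the true diameters
        (at original hom) better than the raw measurements do."""
        cfg = SimulationConfig(seed=11, n_plots=1,
                               initial_density_per_ha=60,
                               p_hom_raise_per_yr=0.05,
                               p_missing_record=0.0, p_false_dead=0.0)
        archive, log = simulate_archive(cfg)
        corrected = correct_archive(archive)
        key = ["plot_no", "subplot_no", "tree_no", "campaign_year"]
        truth = log.trajectories.rename(columns={"dbh_true_cm": "truth"})
        raw = archive.measures.merge(truth, on=key)
        cor = corrected.measures.merge(truth, on=key)
        raw_mae = (raw["dbh_cm"] - raw["truth"]).abs().mean()
        cor_mae = (cor["dbh_cm"] - cor["truth"]).abs().mean()
        assert cor_mae <= raw_mae
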