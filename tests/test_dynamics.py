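"""Stand structure (N, G) and annualized demographic rates."""

import numpy as np
import pandas as pd
import pytest

from pspcensus.dynamics import (demographic_rates, dynamics_table,
                                recruitment_campaign, stand_state)
from pspcensus.simulate import SimulationConfig, simulate_archive
from tests.conftest import build_archive, mrow, series_df

A = "alive"


class TestRecruitmentCampaign:
    def test_crossing_dates_recruitment(self):
        s = series_df([(2000, 9.5, 1.5, A), (2001, 9.8, 1.5, A),
                       (2002, 10.2, 1.5, A), (2003, 10.5, 1.5, A)])
        assert recruitment_campaign(s) == 2002

    def test_first_measurement_above_threshold(self):
        s = series_df([(2000, 15.0, 1.5, A)])
        assert recruitment_campaign(s) == 2000

    def test_never_reaching_threshold(self):
        s = series_df([(2000, 9.5, 1.5, A), (2001, 9.9, 1.5, A)])
        assert recruitment_campaign(s) is None

    def test_exactly_at_threshold_counts(self):
        s = series_df([(2000, 10.0, 1.5, A)])
        assert recruitment_campaign(s) == 2000


class TestStandState:
    def test_single_tree_closed_form(self):
        rows = [mrow(year=2000, dbh=50.0)]
        archive = build_archive(rows, [2000])
        state = stand_state(archive, "11-1", 2000)
        assert state.n_per_ha == 1.0
        assert state.g_m2_per_ha == pytest.approx(np.pi * 0.25 ** 2)

    def test_threshold_excludes_sub10(self):
        rows = [mrow(tree=1, year=2000, dbh=10.0),
                mrow(tree=2, year=2000, dbh=9.5)]
        archive = build_archive(rows, [2000])
        state = stand_state(archive, "11-1", 2000)
        assert state.n_per_ha == 1.0

    def test_no_alive_trees_zero(self):
        rows = [mrow(year=2000, dbh=20.0),
                mrow(year=2001, dbh=np.nan, hom=np.nan, method="",
                     status="dead", mort="standing_death")]
        archive = build_archive(rows, [2000, 2001])
        state = stand_state(archive, "11-1", 2001)
        assert state.n_per_ha == 0.0 and state.g_m2_per_ha == 0.0

    def test_unknown_unit_rejected(self):
        archive = build_archive([mrow(year=2000, dbh=20.0)], [2000])
        with pytest.raises(ValueError):
            stand_state(archive, "99", 2000)

    def test_doubling_dbh_quadruples_g(self):
        rows = [mrow(tree=t, year=2000, dbh=d)
                for t, d in [(1, 20.0), (2, 35.0), (3, 50.0)]]
        a1 = build_archive(rows, [2000])
        rows2 = [mrow(tree=t, year=2000, dbh=2 * d)
                 for t, d in [(1, 20.0), (2, 35.0), (3, 50.0)]]
        a2 = build_archive(rows2, [2000])
        g1 = stand_state(a1, "11", 2000).g_m2_per_ha
        g2 = stand_state(a2, "11", 2000).g_m2_per_ha
        assert g2 == pytest.approx(4 * g1)


def _cohort_archive(n0, deaths_at_b, recruits_at_b, years=(2001, 2002)):
    """n0 trees alive at both campaigns except `deaths_at_b`; plus
    `recruits_at_b` new trees at the second campaign."""
    a, b = years
    rows = []
    for t in range(1, n0 + 1):
        rows.append(mrow(tree=t, year=a, dbh=20.0))
        if t <= n0 - deaths_at_b:
            rows.append(mrow(tree=t, year=b, dbh=20.3))
        else:
            rows.append(mrow(tree=t, year=b, dbh=np.nan, hom=np.nan,
                             method="", status="dead",
                             mort="standing_death"))
    for r in range(recruits_at_b):
        rows.append(mrow(tree=1000 + r, year=b, dbh=10.1))
    return build_archive(rows, list(years))


class TestDemographicRates:
    def test_one_year_mortality_is_deaths_over_initial(self):
        archive = _cohort_archive(100, deaths_at_b=1, recruits_at_b=0)
        r = demographic_rates(archive, "11", 2001, 2002)
        assert r.n_initial == 100 and r.n_deaths == 1
        assert r.mortality_pct_per_yr == pytest.approx(1.0, abs=0.01)

    def test_two_year_survival_power_form(self):
        archive = _cohort_archive(100, deaths_at_b=2, recruits_at_b=0,
                                  years=(2001, 2003))
        r = demographic_rates(archive, "11", 2001, 2003)
        # 1 - 0.98^(1/2) = 1.0050...%
        assert r.mortality_pct_per_yr == pytest.approx(1.005, abs=0.01)

    def test_recruitment_closed_form(self):
        archive = _cohort_archive(100, deaths_at_b=0, recruits_at_b=10)
        r = demographic_rates(archive, "11", 2001, 2002)
        assert r.n_final == 110 and r.n_recruits == 10
        # (1 - 100/110) * 100 = 9.0909...%
        assert r.recruitment_pct_per_yr == pytest.approx(9.09, abs=0.05)

    def test_empty_initial_population_undefined(self):
        rows = [mrow(year=2002, dbh=15.0)]
        archive = build_archive(rows, [2001, 2002])
        r = demographic_rates(archive, "11", 2001, 2002)
        assert np.isnan(r.mortality_pct_per_yr)
        assert r.recruitment_pct_per_yr > 0

    def test_simple_estimator_switch(self):
        archive = _cohort_archive(100, deaths_at_b=2, recruits_at_b=0,
                                  years=(2001, 2003))
        r = demographic_rates(archive, "11", 2001, 2003, method="simple")
        dt = r.dt_years
        assert r.mortality_pct_per_yr == pytest.approx(2 / (100 * dt) * 100)


class TestDynamicsTable:
    def test_constant_stand_constant_table(self):
        rows = []
        for y in (2000, 2001, 2002):
            rows += [mrow(tree=t, year=y, dbh=30.0) for t in (1, 2, 3)]
        archive = build_archive(rows, [2000, 2001, 2002])
        table = dynamics_table(archive, level="plot")
        assert table["n_per_ha"].nunique() == 1
        assert table["g_m2_per_ha"].nunique() == 1
        rates = table.dropna(subset=["mortality_pct_yr"])
        assert (rates["mortality_pct_yr"] == 0).all()
        assert (rates["recruitment_pct_yr"] == 0).all()

    def test_plot_equals_area_weighted_subplot_mean(self, small_stand):
        _, archive, _ = small_stand
        plot = dynamics_table(archive, level="plot")
        sub = dynamics_table(archive, level="subplot")
        sub["plot"] = sub["unit"].str.split("-").str[0]
        for y in archive.campaign_years():
            p = plot[plot.campaign_year == y].iloc[0]
            s = sub[sub.campaign_year == y]
            assert p["n_per_ha"] == pytest.approx(s["n_per_ha"].mean())
            assert p["g_m2_per_ha"] == pytest.approx(
                s["g_m2_per_ha"].mean())

    def test_rates_nonnegative_and_zero_without_events(self, clean_stand):
        _, archive, _ = clean_stand
        table = dynamics_table(archive, level="plot")
        rates = table.dropna(subset=["mortality_pct_yr"])
        assert (rates["mortality_pct_yr"] >= 0).all()
        assert (rates["recruitment_pct_yr"] >= 0).all()
        zero_death = rates[rates["n_deaths"] == 0]
        assert (zero_death["mortality_pct_yr"] == 0).all()

    def test_logging_pulse_shows_as_mortality_spike(self):
        cfg = SimulationConfig(seed=31, n_plots=1,
                               initial_density_per_ha=150,
                               disturbance_events=((1986, 0.18),),
                               p_missing_record=0.0, p_false_dead=0.0)
        archive, log = simulate_archive(cfg)
        m = archive.measures.copy()
        m["provenance"] = "raw"
        archive.measures = m
        table = dynamics_table(archive, level="plot")
        spike = table[table.campaign_year == 1986].iloc[0]
        others = table[(table.campaign_year > 1987)]
        frac_removed = (log.removals["n_removed"].sum()
                        / spike["n_initial"] if len(log.removals) else 0)
        assert spike["mortality_pct_yr"] > 5 * max(
            1e-9, others["mortality_pct_yr"].mean())
        # spike magnitude close to the logged removal fraction
        assert spike["mortality_pct_yr"] == pytest.approx(
            frac_removed * 100 + 1.0, abs=4.0)

    def test_parameter_recovery_small_batch(self):
        from pspcensus.harness import rate_recovery
        df = rate_recovery(seed=3, n_stands=3)
        assert abs(df["mortality_pct_yr"].mean() - 1.0) < 0.3
        assert abs(df["recruitment_pct_yr"].mean() - 1.0) < 0.3
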