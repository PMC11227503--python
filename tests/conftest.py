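"""Shared fixtures: hand-built archives and seeded synthetic stands."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pspcensus.schema import (COLUMNS, CensusArchive, default_census_date,
                              default_code_tables)
from pspcensus.simulate import (SimulationConfig, _plot_geometries,
                                simulate_archive)

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def mrow(plot=11, subplot=1, tree=1, year=2000, dbh=np.nan, girth=np.nan,
         hom=1.5, method="tape", status="alive", mort="none", codes=""):
    """One measures.csv row with sensible defaults."""
    return {"plot_no": plot, "subplot_no": subplot, "tree_no": tree,
            "campaign_year": year, "girth_cm": girth, "dbh_cm": dbh,
            "hom_m": hom, "method": method, "status": status,
            "mortality_code": mort, "observation_codes": codes}


def build_archive(measure_rows, years, tree_coords=None) -> CensusArchive:
    """A minimal, referentially consistent archive around given measures.

    The tree table is derived from the distinct tree ids in the rows;
    taxonomy/vernacular are single-entry; geometry comes from the standard
    plot layout for whatever plots appear.
    """
    measures = pd.DataFrame(measure_rows, columns=COLUMNS["measures"])
    for col in ("girth_cm", "dbh_cm", "hom_m"):
        measures[col] = measures[col].astype(float)
    for col in ("plot_no", "subplot_no", "tree_no", "campaign_year"):
        measures[col] = measures[col].astype(np.int64)

    keys = measures[["plot_no", "subplot_no", "tree_no"]].drop_duplicates()
    coords = tree_coords or {}
    tree = pd.DataFrame({
        "plot_no": keys["plot_no"].to_numpy(),
        "subplot_no": keys["subplot_no"].to_numpy(),
        "tree_no": keys["tree_no"].to_numpy(),
        "x_m": [coords.get((r.plot_no, r.subplot_no, r.tree_no),
                           (10.0, 10.0))[0] for r in keys.itertuples()],
        "y_m": [coords.get((r.plot_no, r.subplot_no, r.tree_no),
                           (10.0, 10.0))[1] for r in keys.itertuples()],
        "vernacular_name": "Mboyo",
        "taxon_id_1991": pd.array([1] * len(keys), dtype="Int64"),
        "taxon_id_2010": pd.array([1] * len(keys), dtype="Int64"),
        "taxon_id_2011": pd.array([1] * len(keys), dtype="Int64"),
    })
    taxonomy = pd.DataFrame({"taxon_id": [1],
                             "sci_name": ["Entandrophragma cylindricum"],
                             "valuable_code": ["01"],
                             "valuable_category": ["A"]})
    vernacular = pd.DataFrame({"vernacular_name": ["Mboyo"], "taxon_id": [1]})
    plot_nos = sorted(measures["plot_no"].unique())
    trees_context = pd.DataFrame({
        "plot_no": np.asarray(plot_nos, dtype=np.int64),
        "block": ["Boukoko1" if p < 14 else ("Boukoko2" if p < 21 else
                                             "LaLole") for p in plot_nos],
        "treatment": ["control"] * len(plot_nos),
        "treatment_year": np.full(len(plot_nos), 1986, dtype=np.int64)})
    inventories = pd.DataFrame({
        "campaign_year": np.asarray(years, dtype=np.int64),
        "census_date": [default_census_date(y) for y in years],
        "notes": [""] * len(years)})
    obs, mort = default_code_tables()
    plots, subplots = _plot_geometries(list(plot_nos))
    return CensusArchive(tree=tree, taxonomy=taxonomy, vernacular=vernacular,
                         trees_context=trees_context, measures=measures,
                         inventories=inventories, observation_codes=obs,
                         mortality_codes=mort, plots=plots,
                         subplots=subplots)


def series_df(rows) -> pd.DataFrame:
    """Per-tree series frame from (year, dbh, hom, status[, mort]) tuples."""
    out = []
    for r in rows:
        year, dbh, hom, status = r[:4]
        mort = r[4] if len(r) > 4 else ("standing_death"
                                        if status == "dead" else "none")
        out.append(mrow(year=year, dbh=dbh, hom=hom, status=status,
                        mort=mort,
                        method="tape" if not np.isnan(dbh) else ""))
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def small_stand():
    """One small 4-ha stand with all observation processes active."""
    cfg = SimulationConfig(seed=42, n_plots=1, initial_density_per_ha=60)
    archive, log = simulate_archive(cfg)
    return cfg, archive, log


@pytest.fixture(scope="session")
def clean_stand():
    """A stand with no observation errors (noise/missing/false-dead off)."""
    cfg = SimulationConfig(seed=7, n_plots=1, initial_density_per_ha=60,
                           measurement_sd_cm=0.0, p_missing_record=0.0,
                           p_false_dead=0.0, p_hom_raise_per_yr=0.0)
    archive, log = simulate_archive(cfg)
    return cfg, archive, log
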