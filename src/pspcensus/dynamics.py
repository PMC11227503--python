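"""Stand structure and demographic rates from a corrected archive.

For every plot (4 ha) or subplot (1 ha) and campaign this module computes

* stem density ``N`` (live recruited trees per hectare),
* basal area ``G = sum pi (dbh/200)^2`` in m2/ha (dbh in cm),

and for every consecutive campaign pair (a, b), separated by ``dt`` decimal
years, the annualized demographic rates in % per year:

* mortality  ``(1 - (S/N0)^(1/dt)) * 100`` with ``N0`` live recruited
  trees at a and ``S`` of them surviving at b;
* recruitment ``(1 - ((Nb - R)/Nb)^(1/dt)) * 100`` with ``Nb`` live
  recruited trees at b and ``R`` of them recruited in (a, b].

The power form is the standard exponential-equivalent per-capita rate for
multi-year census gaps and reduces to D/N0 (and R/Nb) for dt = 1.  A
``method="simple"`` switch provides the naive D/(N0*dt) and R/(Nb*dt)
estimators for comparison.

A tree is *recruited* from its first campaign with dbh at or above the
threshold (default 10 cm, the database convention; 9.5 cm reproduces the
alternative field-threshold analyses) and remains recruited for life, even
if a later recorded diameter dips below the threshold.  Trees recorded
dead and later re-born are expected to have been corrected upstream
(:mod:`pspcensus.corrections`), so they inflate neither mortality nor
recruitment.  Trees that die before ever reaching the threshold count in
neither rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import LIVE_STATUSES, RECRUIT_DBH_CM, CensusArchive

__all__ = ["StandState", "DemographicRates", "recruitment_campaign",
           "stand_state", "demographic_rates", "dynamics_table",
           "plot_dynamics"]

_KEY = ["plot_no", "subplot_no", "tree_no"]


@dataclass(frozen=True)
class StandState:
    """Density and basal area of one unit at one campaign."""

    unit: str
    campaign_year: int
    n_per_ha: float
    g_m2_per_ha: float
    dbh_threshold_cm: float = RECRUIT_DBH_CM


@dataclass(frozen=True)
class DemographicRates:
    """Annualized mortality/recruitment over one census interval."""

    unit: str
    campaign_a: int
    campaign_b: int
    dt_years: float
    mortality_pct_per_yr: float  # NaN when n_initial = 0
    recruitment_pct_per_yr: float  # NaN when n_final = 0
    n_deaths: int
    n_recruits: int
    n_initial: int
    n_final: int


def recruitment_campaign(series: pd.DataFrame,
                         threshold: float = RECRUIT_DBH_CM) -> int | None:
    """First campaign with dbh at or above ``threshold``, or None.

    ``series`` is a per-tree (ideally corrected, hole-free) measurement
    frame.  Trees at 9.5-9.9 cm are present but unrecruited under the
    default threshold.
    """
    live = series[series["status"].isin(LIVE_STATUSES)
                  & series["dbh_cm"].notna()
                  & (series["dbh_cm"] >= threshold)]
    if not len(live):
        return None
    return int(live["campaign_year"].min())


def _unit_area_ha(archive: CensusArchive, level: str) -> dict:
    """unit label -> area in ha, from the spatial layers (with defaults)."""
    areas = {}
    if level == "plot":
        for p in archive.plots:
            areas[str(p.plot_no)] = p.area_ha
        for pn in archive.trees_context["plot_no"]:
            areas.setdefault(str(pn), 4.0)
    else:
        for s in archive.subplots:
            areas[f"{s.plot_no}-{s.subplot_no}"] = s.area_ha
        for pn in archive.trees_context["plot_no"]:
            for sn in (1, 2, 3, 4):
                areas.setdefault(f"{pn}-{sn}", 1.0)
    return areas


def _population(archive: CensusArchive, threshold: float):
    """Per-tree presence/diameter matrices over the campaign calendar.

    Returns (years, unit labels per tree, alive bool matrix, dbh matrix,
    recruit year per tree) with trees as rows, campaigns as columns.
    """
    years = archive.campaign_years()
    m = archive.measures
    live = m[m["status"].isin(LIVE_STATUSES)].copy()

    if not len(live):
        empty = np.zeros((0, len(years)))
        return years, pd.DataFrame(columns=_KEY), empty.astype(bool), empty, \
            np.zeros(0)

    trees = live[_KEY].drop_duplicates().sort_values(_KEY).reset_index(drop=True)
    tree_pos = {(r.plot_no, r.subplot_no, r.tree_no): i
                for i, r in enumerate(trees.itertuples())}
    year_pos = {y: j for j, y in enumerate(years)}

    alive = np.zeros((len(trees), len(years)), dtype=bool)
    dbh = np.full((len(trees), len(years)), np.nan)
    rows = live[live["campaign_year"].isin(year_pos)]
    i_idx = np.array([tree_pos[k] for k in
                      zip(rows["plot_no"], rows["subplot_no"], rows["tree_no"])])
    j_idx = np.array([year_pos[int(y)] for y in rows["campaign_year"]])
    alive[i_idx, j_idx] = True
    dbh[i_idx, j_idx] = rows["dbh_cm"].to_numpy(dtype=float)

    qualified = alive & (dbh >= threshold)
    recruit_year = np.full(len(trees), np.inf)
    any_q = qualified.any(axis=1)
    first_j = np.argmax(qualified, axis=1)
    recruit_year[any_q] = np.array(years)[first_j[any_q]]
    return years, trees, alive, dbh, recruit_year


def _units_of(trees: pd.DataFrame, level: str) -> np.ndarray:
    if level == "plot":
        return trees["plot_no"].astype(str).to_numpy()
    return (trees["plot_no"].astype(str) + "-"
            + trees["subplot_no"].astype(str)).to_numpy()


def stand_state(archive: CensusArchive, unit: str, campaign_year: int,
                threshold: float = RECRUIT_DBH_CM) -> StandState:
    """Density and basal area of ``unit`` ("<plot>" or "<plot>-<subplot>")."""
    level = "subplot" if "-" in str(unit) else "plot"
    areas = _unit_area_ha(archive, level)
    if str(unit) not in areas:
        raise ValueError(f"unknown unit {unit!r}")
    table = dynamics_table(archive, level=level, threshold=threshold)
    row = table[(table["unit"] == str(unit))
                & (table["campaign_year"] == campaign_year)]
    if not len(row):
        raise ValueError(f"no campaign {campaign_year} for unit {unit!r}")
    r = row.iloc[0]
    return StandState(str(unit), int(campaign_year), float(r["n_per_ha"]),
                      float(r["g_m2_per_ha"]), threshold)


def demographic_rates(archive: CensusArchive, unit: str, campaign_a: int,
                      campaign_b: int, threshold: float = RECRUIT_DBH_CM,
                      method: str = "exponential") -> DemographicRates:
    """Annualized rates for one unit over one census interval."""
    level = "subplot" if "-" in str(unit) else "plot"
    table = dynamics_table(archive, level=level, threshold=threshold,
                           method=method)
    row = table[(table["unit"] == str(unit))
                & (table["campaign_year"] == campaign_b)]
    if not len(row) or int(row.iloc[0].get("interval_start", -1)) != campaign_a:
        raise ValueError(f"campaigns {campaign_a} -> {campaign_b} are not "
                         f"consecutive for unit {unit!r}")
    r = row.iloc[0]
    return DemographicRates(
        str(unit), campaign_a, campaign_b, float(r["dt_years"]),
        float(r["mortality_pct_yr"]), float(r["recruitment_pct_yr"]),
        int(r["n_deaths"]), int(r["n_recruits"]),
        int(r["n_initial"]), int(r["n_final"]))


def dynamics_table(archive: CensusArchive, level: str = "plot",
                   threshold: float = RECRUIT_DBH_CM,
                   method: str = "exponential") -> pd.DataFrame:
    """Per-unit, per-campaign stand states and interval rates.

    One row per (unit, campaign); interval quantities (rates, counts, dt)
    describe the interval *ending* at that campaign and are NaN for the
    first campaign of each unit.
    """
    if level not in ("plot", "subplot"):
        raise ValueError("level must be 'plot' or 'subplot'")
    if method not in ("exponential", "simple"):
        raise ValueError("method must be 'exponential' or 'simple'")
    years, trees, alive, dbh, recruit_year = _population(archive, threshold)
    areas = _unit_area_ha(archive, level)
    dates = archive.decimal_dates()
    unit_of_tree = _units_of(trees, level) if len(trees) else np.array([])
    ba = np.where(np.isnan(dbh), 0.0, np.pi * (dbh / 200.0) ** 2)

    records = []
    for unit in sorted(areas):
        area = areas[unit]
        sel = unit_of_tree == unit if len(trees) else np.zeros(0, dtype=bool)
        a_alive = alive[sel]
        a_ba = ba[sel]
        a_rec = recruit_year[sel]
        prev = None
        for j, y in enumerate(years):
            recruited = a_alive[:, j] & (a_rec <= y)
            n = int(recruited.sum())
            g = float(a_ba[recruited, j].sum()) / area
            rec = {"unit": unit, "campaign_year": y,
                   "n_per_ha": n / area, "g_m2_per_ha": g,
                   "interval_start": np.nan, "dt_years": np.nan,
                   "mortality_pct_yr": np.nan, "recruitment_pct_yr": np.nan,
                   "n_deaths": np.nan, "n_recruits": np.nan,
                   "n_initial": np.nan, "n_final": np.nan}
            if prev is not None:
                jp, yp = prev
                dt = dates[y] - dates[yp]
                init = a_alive[:, jp] & (a_rec <= yp)
                n0 = int(init.sum())
                surv = int((init & a_alive[:, j]).sum())
                deaths = n0 - surv
                nb = n
                recruits = int((a_alive[:, j] & (a_rec <= y)
                                & (a_rec > yp)).sum())
                rec.update(interval_start=yp, dt_years=dt, n_deaths=deaths,
                           n_recruits=recruits, n_initial=n0, n_final=nb)
                if n0 > 0:
                    if method == "exponential":
                        rec["mortality_pct_yr"] = \
                            (1.0 - (surv / n0) ** (1.0 / dt)) * 100.0
                    else:
                        rec["mortality_pct_yr"] = deaths / (n0 * dt) * 100.0
                if nb > 0:
                    if method == "exponential":
                        rec["recruitment_pct_yr"] = \
                            (1.0 - ((nb - recruits) / nb) ** (1.0 / dt)) * 100.0
                    else:
                        rec["recruitment_pct_yr"] = \
                            recruits / (nb * dt) * 100.0
            records.append(rec)
            prev = (j, y)
    return pd.DataFrame.from_records(records)


def plot_dynamics(table: pd.DataFrame, path) -> None:
    """Four-panel figure: N, G, mortality and recruitment over time."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    panels = [("n_per_ha", "N (trees ha$^{-1}$)"),
              ("g_m2_per_ha", "G (m$^2$ ha$^{-1}$)"),
              ("mortality_pct_yr", "mortality (% yr$^{-1}$)"),
              ("recruitment_pct_yr", "recruitment (% yr$^{-1}$)")]
    for ax, (col, label) in zip(axes.ravel(), panels):
        for unit, g in table.groupby("unit"):
            ax.plot(g["campaign_year"], g[col], marker=".", label=str(unit))
        ax.set_ylabel(label)
    axes[1, 0].set_xlabel("campaign year")
    axes[1, 1].set_xlabel("campaign year")
    axes[0, 0].legend(fontsize="small", title="unit")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
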