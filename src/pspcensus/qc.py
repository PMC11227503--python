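"""Post-campaign anomaly screening.

After each inventory campaign the new values are compared with those of the
previous campaign and three families of checks are run:

1. living-tree inconsistencies — excessive growth (annualized diameter
   increment above ``max_growth_cm_per_yr``), excessive decline (below
   ``min_growth_cm_per_yr``), and re-born trees (alive now, previously
   recorded dead);
2. unauthorised or doubtful values — a recruit entering below the 10 cm
   dbh database threshold, or a diameter that increases although the hom
   was raised between the campaigns;
3. missing data — a tree last known alive with no measurement.

Increments are annualized over the decimal-year interval between census
dates, so the skipped census years weigh correctly.  Threshold comparisons
are strict (>, <).  Screening is read-only and returns flags as data;
severity models the human triage step (``block`` stops a pipeline,
``review`` goes back to the field crew).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import (LIVE_STATUSES, MIN_HOM_M, RECRUIT_DBH_CM, STATUS_DEAD,
                     STATUS_MISSING, CensusArchive)

__all__ = ["QCThresholds", "QCFlag", "screen_campaign", "screen_archive",
           "flags_to_frame", "RULES"]

RULE_EXCESS_GROWTH = "EXCESS_GROWTH"
RULE_EXCESS_DECLINE = "EXCESS_DECLINE"
RULE_REBORN = "REBORN"
RULE_RECRUIT_UNDER_10 = "RECRUIT_UNDER_10"
RULE_HOM_RAISE_INCREASE = "HOM_RAISE_INCREASE"
RULE_MISSING_DATA = "MISSING_DATA"
RULE_UNAUTHORIZED_VALUE = "UNAUTHORIZED_VALUE"

RULES = (RULE_EXCESS_GROWTH, RULE_EXCESS_DECLINE, RULE_REBORN,
         RULE_RECRUIT_UNDER_10, RULE_HOM_RAISE_INCREASE, RULE_MISSING_DATA,
         RULE_UNAUTHORIZED_VALUE)

#: severity by rule: block stops integration, review goes to field triage
SEVERITY = {
    RULE_EXCESS_GROWTH: "review",
    RULE_EXCESS_DECLINE: "review",
    RULE_REBORN: "block",
    RULE_RECRUIT_UNDER_10: "review",
    RULE_HOM_RAISE_INCREASE: "review",
    RULE_MISSING_DATA: "review",
    RULE_UNAUTHORIZED_VALUE: "block",
}


@dataclass(frozen=True)
class QCThresholds:
    """Screening thresholds in cm/yr of annualized diameter increment."""

    max_growth_cm_per_yr: float = 2.0
    min_growth_cm_per_yr: float = -0.6
    recruit_min_dbh_cm: float = RECRUIT_DBH_CM

    def __post_init__(self):
        if not (self.max_growth_cm_per_yr > 0 > self.min_growth_cm_per_yr):
            raise ValueError("thresholds must satisfy max_growth > 0 > "
                             "min_growth")


@dataclass(frozen=True)
class QCFlag:
    """A typed anomaly annotation for one (tree, campaign) pair."""

    plot_no: int
    subplot_no: int
    tree_no: int
    campaign_year: int
    rule_id: str
    severity: str
    detail: str

    @property
    def tree_id(self) -> str:
        return f"{self.plot_no}-{self.subplot_no}-{self.tree_no}"

    def sort_key(self):
        return (self.campaign_year, self.plot_no, self.subplot_no,
                self.tree_no, self.rule_id)


_KEY = ["plot_no", "subplot_no", "tree_no"]


def screen_campaign(archive: CensusArchive, campaign_year: int,
                    thresholds: QCThresholds | None = None) -> list[QCFlag]:
    """All flags for one campaign, compared to the archive's history.

    For the first campaign only single-campaign rules run (recruit
    threshold, unauthorised values).  The previous value used for the
    increment is the most recent earlier measured diameter, so checks
    bridge campaigns a tree was missing from.
    """
    thr = thresholds or QCThresholds()
    years = archive.campaign_years()
    if campaign_year not in years:
        raise ValueError(f"unknown campaign {campaign_year}")
    dates = archive.decimal_dates()
    m = archive.measures
    cur = m[m["campaign_year"] == campaign_year]
    prior = m[m["campaign_year"] < campaign_year]
    is_first = campaign_year == years[0]

    flags: list[QCFlag] = []

    # last known status and last measured value per tree, before this campaign
    if len(prior):
        p = prior.sort_values(_KEY + ["campaign_year"])
        last_status = p.groupby(_KEY)["status"].last()
        pm = p[p["dbh_cm"].notna() & p["status"].isin(LIVE_STATUSES)]
        last_meas = pm.groupby(_KEY)[["campaign_year", "dbh_cm", "hom_m"]].last()
        seen = set(last_status.index)
    else:
        last_status = pd.Series(dtype=object)
        last_meas = pd.DataFrame(columns=["campaign_year", "dbh_cm", "hom_m"])
        seen = set()

    cur_keys = set()
    for row in cur.itertuples():
        key = (row.plot_no, row.subplot_no, row.tree_no)
        cur_keys.add(key)
        live = row.status in LIVE_STATUSES
        measured = live and pd.notna(row.dbh_cm)

        # unauthorised raw values (single-campaign rule)
        if measured and row.dbh_cm <= 0:
            flags.append(QCFlag(*key, campaign_year, RULE_UNAUTHORIZED_VALUE,
                                SEVERITY[RULE_UNAUTHORIZED_VALUE],
                                f"non-positive dbh {row.dbh_cm}"))
        if pd.notna(row.hom_m) and row.hom_m < MIN_HOM_M:
            flags.append(QCFlag(*key, campaign_year, RULE_UNAUTHORIZED_VALUE,
                                SEVERITY[RULE_UNAUTHORIZED_VALUE],
                                f"hom {row.hom_m} below {MIN_HOM_M} m"))

        # new tree: recruit threshold
        if key not in seen:
            if measured and row.dbh_cm < thr.recruit_min_dbh_cm:
                flags.append(QCFlag(
                    *key, campaign_year, RULE_RECRUIT_UNDER_10,
                    SEVERITY[RULE_RECRUIT_UNDER_10],
                    f"new tree with dbh {row.dbh_cm} cm < "
                    f"{thr.recruit_min_dbh_cm} cm"))
            continue

        prev_status = last_status.get(key)
        if live and prev_status == STATUS_DEAD:
            flags.append(QCFlag(*key, campaign_year, RULE_REBORN,
                                SEVERITY[RULE_REBORN],
                                "alive but previously recorded dead"))

        if (live and not measured) or row.status == STATUS_MISSING:
            flags.append(QCFlag(*key, campaign_year, RULE_MISSING_DATA,
                                SEVERITY[RULE_MISSING_DATA],
                                "recorded without a diameter measurement"))

        if measured and key in last_meas.index:
            prev = last_meas.loc[key]
            y0 = int(prev["campaign_year"])
            dt = dates[campaign_year] - dates[y0]
            if dt > 0:
                rate = (row.dbh_cm - prev["dbh_cm"]) / dt
                if rate > thr.max_growth_cm_per_yr:
                    flags.append(QCFlag(
                        *key, campaign_year, RULE_EXCESS_GROWTH,
                        SEVERITY[RULE_EXCESS_GROWTH],
                        f"dbh {prev['dbh_cm']} ({y0}) -> {row.dbh_cm} "
                        f"({campaign_year}): {rate:+.2f} cm/yr > "
                        f"{thr.max_growth_cm_per_yr}"))
                elif rate < thr.min_growth_cm_per_yr:
                    flags.append(QCFlag(
                        *key, campaign_year, RULE_EXCESS_DECLINE,
                        SEVERITY[RULE_EXCESS_DECLINE],
                        f"dbh {prev['dbh_cm']} ({y0}) -> {row.dbh_cm} "
                        f"({campaign_year}): {rate:+.2f} cm/yr < "
                        f"{thr.min_growth_cm_per_yr}"))
            if pd.notna(row.hom_m) and pd.notna(prev["hom_m"]) \
                    and row.hom_m > prev["hom_m"] \
                    and row.dbh_cm > prev["dbh_cm"]:
                flags.append(QCFlag(
                    *key, campaign_year, RULE_HOM_RAISE_INCREASE,
                    SEVERITY[RULE_HOM_RAISE_INCREASE],
                    f"dbh increased {prev['dbh_cm']} ({y0}) -> {row.dbh_cm} "
                    f"({campaign_year}) although hom was raised "
                    f"{prev['hom_m']} -> {row.hom_m} m"))

    # fully missing trees: last known live, no row in this campaign
    if not is_first and len(prior):
        for key, status in last_status.items():
            if status != STATUS_DEAD and key not in cur_keys:
                flags.append(QCFlag(*key, campaign_year, RULE_MISSING_DATA,
                                    SEVERITY[RULE_MISSING_DATA],
                                    "tree last known alive has no record"))

    flags.sort(key=QCFlag.sort_key)
    return flags


def screen_archive(archive: CensusArchive,
                   thresholds: QCThresholds | None = None) -> list[QCFlag]:
    """Screen every campaign in chronological order (deterministic order).

    Single chronological sweep over the measurement table; produces the
    same flags as calling :func:`screen_campaign` per campaign.
    """
    thr = thresholds or QCThresholds()
    years = archive.campaign_years()
    dates = archive.decimal_dates()
    m = archive.measures.sort_values(["campaign_year"] + _KEY)

    last_status: dict = {}   # key -> status string
    last_meas: dict = {}     # key -> (year, dbh, hom)
    flags: list[QCFlag] = []

    by_year = {int(y): g for y, g in m.groupby("campaign_year")}
    for yi, year in enumerate(years):
        cur = by_year.get(year)
        rows = list(cur.itertuples()) if cur is not None else []
        cur_keys = set()
        year_flags: list[QCFlag] = []
        for row in rows:
            key = (row.plot_no, row.subplot_no, row.tree_no)
            cur_keys.add(key)
            live = row.status in LIVE_STATUSES
            measured = live and pd.notna(row.dbh_cm)

            if measured and row.dbh_cm <= 0:
                year_flags.append(QCFlag(
                    *key, year, RULE_UNAUTHORIZED_VALUE,
                    SEVERITY[RULE_UNAUTHORIZED_VALUE],
                    f"non-positive dbh {row.dbh_cm}"))
            if pd.notna(row.hom_m) and row.hom_m < MIN_HOM_M:
                year_flags.append(QCFlag(
                    *key, year, RULE_UNAUTHORIZED_VALUE,
                    SEVERITY[RULE_UNAUTHORIZED_VALUE],
                    f"hom {row.hom_m} below {MIN_HOM_M} m"))

            if key not in last_status:
                if measured and row.dbh_cm < thr.recruit_min_dbh_cm:
                    year_flags.append(QCFlag(
                        *key, year, RULE_RECRUIT_UNDER_10,
                        SEVERITY[RULE_RECRUIT_UNDER_10],
                        f"new tree with dbh {row.dbh_cm} cm < "
                        f"{thr.recruit_min_dbh_cm} cm"))
                continue

            if live and last_status[key] == STATUS_DEAD:
                year_flags.append(QCFlag(
                    *key, year, RULE_REBORN, SEVERITY[RULE_REBORN],
                    "alive but previously recorded dead"))
            if (live and not measured) or row.status == STATUS_MISSING:
                year_flags.append(QCFlag(
                    *key, year, RULE_MISSING_DATA,
                    SEVERITY[RULE_MISSING_DATA],
                    "recorded without a diameter measurement"))
            if measured and key in last_meas:
                y0, d0, h0 = last_meas[key]
                dt = dates[year] - dates[y0]
                if dt > 0:
                    rate = (row.dbh_cm - d0) / dt
                    if rate > thr.max_growth_cm_per_yr:
                        year_flags.append(QCFlag(
                            *key, year, RULE_EXCESS_GROWTH,
                            SEVERITY[RULE_EXCESS_GROWTH],
                            f"dbh {d0} ({y0}) -> {row.dbh_cm} ({year}): "
                            f"{rate:+.2f} cm/yr > "
                            f"{thr.max_growth_cm_per_yr}"))
                    elif rate < thr.min_growth_cm_per_yr:
                        year_flags.append(QCFlag(
                            *key, year, RULE_EXCESS_DECLINE,
                            SEVERITY[RULE_EXCESS_DECLINE],
                            f"dbh {d0} ({y0}) -> {row.dbh_cm} ({year}): "
                            f"{rate:+.2f} cm/yr < "
                            f"{thr.min_growth_cm_per_yr}"))
                if pd.notna(row.hom_m) and pd.notna(h0) \
                        and row.hom_m > h0 and row.dbh_cm > d0:
                    year_flags.append(QCFlag(
                        *key, year, RULE_HOM_RAISE_INCREASE,
                        SEVERITY[RULE_HOM_RAISE_INCREASE],
                        f"dbh increased {d0} ({y0}) -> {row.dbh_cm} "
                        f"({year}) although hom was raised "
                        f"{h0} -> {row.hom_m} m"))

        if yi > 0:
            for key, status in last_status.items():
                if status != STATUS_DEAD and key not in cur_keys:
                    year_flags.append(QCFlag(
                        *key, year, RULE_MISSING_DATA,
                        SEVERITY[RULE_MISSING_DATA],
                        "tree last known alive has no record"))

        for row in rows:
            key = (row.plot_no, row.subplot_no, row.tree_no)
            last_status[key] = row.status
            if row.status in LIVE_STATUSES and pd.notna(row.dbh_cm):
                last_meas[key] = (year, row.dbh_cm, row.hom_m)

        year_flags.sort(key=QCFlag.sort_key)
        flags.extend(year_flags)
    return flags


def flags_to_frame(flags: list[QCFlag]) -> pd.DataFrame:
    """Flags as a tidy frame (tree_id, campaign_year, rule_id, severity, detail)."""
    return pd.DataFrame(
        [{"tree_id": f.tree_id, "plot_no": f.plot_no,
          "subplot_no": f.subplot_no, "tree_no": f.tree_no,
          "campaign_year": f.campaign_year, "rule_id": f.rule_id,
          "severity": f.severity, "detail": f.detail} for f in flags],
        columns=["tree_id", "plot_no", "subplot_no", "tree_no",
                 "campaign_year", "rule_id", "severity", "detail"])
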