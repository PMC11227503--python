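"""Deterministic correction engine for per-tree diameter series.

Raw field measurements are never modified in place; this module derives an
analysis-ready, hole-free dbh series per tree with full provenance:

* **taper conversion** — when the height of measurement (hom) is raised, a
  taper ratio ``d_t(new hom) / d_{t-1}(old hom)`` converts every subsequent
  raised-hom measurement into an equivalent diameter at the original hom.
  Successive raises are applied sequentially, i.e. the divisor is the
  product of the ratios of all raises at or before the campaign.
* **gap filling** — runs of missing values between valid measurements are
  resolved by the sign of the increment between the flanking values:
  positive -> linear interpolation in decimal time; negative with a hom
  raise in the gap -> the taper procedure between the flanking values;
  negative without a raise -> the last valid value is carried forward
  (including onto the lower flanking measurement); equal -> constant fill.
* **re-born back-fill** — trees recorded dead and later found alive get
  their presumed-dead campaigns back-filled with the diameter recorded at
  the re-born date, and the death record is annulled.
* **manual overrides** — an expert-provided dbh (sidecar CSV) replaces the
  stored value before the automated procedures are re-run.

A per-tree series is a DataFrame with one row per campaign (``campaign_year``
ascending) and the measures.csv columns; corrected output adds
``provenance`` in {raw, taper_converted, interpolated, carried_forward,
reborn_backfill, manual_override}.

Conventions (documented design choices):

* at the raise campaign *t* itself the corrected value is
  ``d_t(new hom) / ratio``, which equals the previous campaign's value by
  construction, keeping the series continuous;
* interpolation runs in decimal time so skipped census years contribute
  their true length;
* derived values are re-rounded to the database resolution (0.1 cm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .measurement import (DB_DBH_RESOLUTION_CM, carry_forward_relascope,
                          round_half_up)
from .schema import (LIVE_STATUSES, MORTALITY_NONE, RECRUIT_DBH_CM,
                     STATUS_ALIVE, STATUS_DEAD, STATUS_MISSING,
                     STATUS_NOT_YET_RECRUITED, CensusArchive)

__all__ = [
    "TaperEvent",
    "detect_hom_raises",
    "apply_taper_correction",
    "fill_gaps",
    "backfill_reborn",
    "correct_tree",
    "correct_archive",
    "read_overrides",
]

PROV_RAW = "raw"
PROV_TAPER = "taper_converted"
PROV_INTERPOLATED = "interpolated"
PROV_CARRIED = "carried_forward"
PROV_REBORN = "reborn_backfill"
PROV_OVERRIDE = "manual_override"

_HOM_TOL = 1e-9


@dataclass(frozen=True)
class TaperEvent:
    """A hom raise: first campaign measured at the new hom and its ratio.

    ``ratio = d_t(hom_new) / d_{t-1}(hom_old)``, computed from the
    measurements flanking the raise; NaN when a flanking measurement is
    missing (resolved later by the gap-filling path).
    """

    raise_campaign: int
    hom_old: float
    hom_new: float
    ratio: float

    def __post_init__(self):
        if self.hom_new <= self.hom_old:
            raise ValueError("hom_new must exceed hom_old")
        if not np.isnan(self.ratio) and not (0.0 < self.ratio <= 1.5):
            raise ValueError(f"taper ratio {self.ratio} outside (0, 1.5]")


def _series_arrays(series: pd.DataFrame):
    years = series["campaign_year"].to_numpy(dtype=int)
    dbh = series["dbh_cm"].to_numpy(dtype=float)
    hom = series["hom_m"].to_numpy(dtype=float)
    status = series["status"].to_numpy(dtype=object)
    return years, dbh, hom, status


def detect_hom_raises(series: pd.DataFrame) -> list[TaperEvent]:
    """One event per increase in hom between consecutive measured campaigns."""
    years, dbh, hom, status = _series_arrays(series.sort_values("campaign_year"))
    events: list[TaperEvent] = []
    prev_hom = np.nan
    prev_dbh = np.nan
    for i in range(len(years)):
        if status[i] == STATUS_DEAD or np.isnan(hom[i]):
            continue
        if not np.isnan(prev_hom) and hom[i] > prev_hom + _HOM_TOL:
            if not np.isnan(dbh[i]) and not np.isnan(prev_dbh):
                ratio = dbh[i] / prev_dbh
            else:
                ratio = np.nan
            events.append(TaperEvent(int(years[i]), float(prev_hom),
                                     float(hom[i]), float(ratio)))
        if not np.isnan(dbh[i]):
            prev_dbh = dbh[i]
        prev_hom = hom[i]
    return events


def apply_taper_correction(series: pd.DataFrame,
                           events: list[TaperEvent]) -> pd.DataFrame:
    """Convert raised-hom measurements to original-hom equivalents.

    For campaigns at or after a raise, the measured dbh is divided by the
    product of the ratios of all raises at or before that campaign, then
    re-rounded to 0.1 cm.  Values before the first raise are unchanged.
    Raises ``ValueError`` for undefined or non-positive ratios.
    """
    out = series.sort_values("campaign_year").reset_index(drop=True).copy()
    if not events:
        return out
    for e in events:
        if np.isnan(e.ratio):
            raise ValueError(f"taper event at {e.raise_campaign} has an "
                             f"undefined ratio (missing flanking measurement)")
        if e.ratio <= 0:
            raise ValueError(f"taper ratio must be positive, got {e.ratio}")
    events = sorted(events, key=lambda e: e.raise_campaign)
    original_hom = events[0].hom_old
    if "provenance" not in out.columns:
        out["provenance"] = np.where(out["dbh_cm"].notna(), PROV_RAW, "")

    years = out["campaign_year"].to_numpy(dtype=int)
    divisor = np.ones(len(out))
    for e in events:
        divisor[years >= e.raise_campaign] *= e.ratio

    dbh = out["dbh_cm"].to_numpy(dtype=float)
    hom = out["hom_m"].to_numpy(dtype=float)
    status = out["status"].to_numpy(dtype=object)
    measured = ~np.isnan(dbh) & np.isin(status, LIVE_STATUSES)
    convert = measured & (divisor != 1.0) & ~np.isnan(hom) \
        & (hom > original_hom + _HOM_TOL)
    if convert.any():
        new_val = round_half_up(dbh[convert] / divisor[convert],
                                DB_DBH_RESOLUTION_CM)
        out.loc[convert, "dbh_cm"] = new_val
        out.loc[convert, "hom_m"] = original_hom
        out.loc[convert, "provenance"] = PROV_TAPER
    return out


def backfill_reborn(series: pd.DataFrame) -> pd.DataFrame:
    """Annul false deaths: presumed-dead campaigns get the re-born diameter.

    A dead run followed by a live record is treated as an observation
    error; each dead row receives the dbh recorded at the re-born date
    (the first subsequent measured value), status becomes alive and the
    mortality code is cleared.  A re-born record with no subsequent
    measurement anywhere is an error.
    """
    out = series.sort_values("campaign_year").reset_index(drop=True).copy()
    if "provenance" not in out.columns:
        out["provenance"] = np.where(out["dbh_cm"].notna(), PROV_RAW, "")
    status = out["status"].to_numpy(dtype=object)
    dbh = out["dbh_cm"].to_numpy(dtype=float)
    hom = out["hom_m"].to_numpy(dtype=float)
    n = len(out)

    i = 0
    while i < n:
        if status[i] != STATUS_DEAD:
            i += 1
            continue
        j = i
        while j < n and status[j] == STATUS_DEAD:
            j += 1
        # find the first live record after the dead run
        k = j
        while k < n and status[k] not in LIVE_STATUSES:
            k += 1
        if k == n:  # true death: no re-born record
            i = j
            continue
        # re-born: first subsequent measured dbh
        m = k
        while m < n and (np.isnan(dbh[m]) or status[m] not in LIVE_STATUSES):
            m += 1
        if m == n:
            raise ValueError(
                "re-born tree has no subsequent diameter measurement")
        for t in range(i, j):
            out.at[t, "dbh_cm"] = dbh[m]
            out.at[t, "hom_m"] = hom[m]
            out.at[t, "status"] = STATUS_ALIVE
            out.at[t, "mortality_code"] = MORTALITY_NONE
            out.at[t, "provenance"] = PROV_REBORN
            status[t] = STATUS_ALIVE
        i = j
    return out


def fill_gaps(series: pd.DataFrame,
              decimal_dates: dict[int, float] | None = None) -> pd.DataFrame:
    """Fill missing dbh runs between valid measurements.

    ``decimal_dates`` maps campaign_year to decimal census date; when
    omitted, integer years are used.  Leading and trailing runs (no
    flanking pair) are left unfilled.
    """
    out = series.sort_values("campaign_year").reset_index(drop=True).copy()
    if "provenance" not in out.columns:
        out["provenance"] = np.where(out["dbh_cm"].notna(), PROV_RAW, "")
    years, dbh, hom, status = _series_arrays(out)
    times = np.array([decimal_dates[int(y)] if decimal_dates else float(y)
                      for y in years])

    measured_idx = [i for i in range(len(out))
                    if not np.isnan(dbh[i]) and status[i] in LIVE_STATUSES]
    for a, b in zip(measured_idx[:-1], measured_idx[1:]):
        if b == a + 1:
            continue
        gap = [i for i in range(a + 1, b) if status[i] != STATUS_DEAD]
        if not gap:
            continue
        d_a, d_b = out.at[a, "dbh_cm"], out.at[b, "dbh_cm"]
        hom_a, hom_b = out.at[a, "hom_m"], out.at[b, "hom_m"]
        raised = (not np.isnan(hom_a) and not np.isnan(hom_b)
                  and hom_b > hom_a + _HOM_TOL)
        if d_b < d_a and raised:
            # taper procedure between the flanking valid measurements:
            # ratio = d_b / d_a converts the raised-hom tail back to the
            # original hom (the flanking equivalent becomes exactly d_a)
            ratio = d_b / d_a
            for i in range(b, len(out)):
                if np.isnan(dbh[i]) or status[i] not in LIVE_STATUSES:
                    continue
                if np.isnan(hom[i]) or hom[i] <= hom_a + _HOM_TOL:
                    continue
                out.at[i, "dbh_cm"] = round_half_up(dbh[i] / ratio,
                                                    DB_DBH_RESOLUTION_CM)
                out.at[i, "hom_m"] = hom_a
                out.at[i, "provenance"] = PROV_TAPER
                dbh[i] = out.at[i, "dbh_cm"]
                hom[i] = hom_a
            d_b = out.at[b, "dbh_cm"]
        if d_b > d_a:
            for i in gap:
                frac = (times[i] - times[a]) / (times[b] - times[a])
                val = round_half_up(d_a + (d_b - d_a) * frac,
                                    DB_DBH_RESOLUTION_CM)
                _set_fill(out, i, val, hom_a, PROV_INTERPOLATED)
        elif d_b < d_a:
            # negative increment without raise: carry the last valid value
            # forward, including onto the lower flanking measurement
            for i in gap:
                _set_fill(out, i, d_a, hom_a, PROV_CARRIED)
            out.at[b, "dbh_cm"] = d_a
            out.at[b, "provenance"] = PROV_CARRIED
        else:
            for i in gap:
                _set_fill(out, i, d_a, hom_a, PROV_INTERPOLATED)
    return out


def _set_fill(out: pd.DataFrame, i: int, value: float, hom: float,
              provenance: str) -> None:
    out.at[i, "dbh_cm"] = value
    if not np.isnan(hom):
        out.at[i, "hom_m"] = hom
    out.at[i, "status"] = STATUS_ALIVE
    out.at[i, "mortality_code"] = MORTALITY_NONE
    out.at[i, "provenance"] = provenance


def _expand_to_campaigns(series: pd.DataFrame,
                         campaign_years: list[int]) -> pd.DataFrame:
    """Insert empty rows for campaigns the tree is fully missing from."""
    series = series.sort_values("campaign_year").reset_index(drop=True)
    if not len(series):
        return series
    have = set(int(y) for y in series["campaign_year"])
    first, last = min(have), max(have)
    need = [y for y in campaign_years if first < y < last and y not in have]
    if not need:
        return series
    defaults = {"girth_cm": np.nan, "dbh_cm": np.nan, "hom_m": np.nan,
                "method": "", "status": STATUS_MISSING,
                "mortality_code": MORTALITY_NONE, "observation_codes": "",
                "provenance": ""}
    rows = []
    for y in need:
        row = {}
        for c in series.columns:
            if c == "campaign_year":
                row[c] = y
            elif c in ("plot_no", "subplot_no", "tree_no"):
                row[c] = series[c].iloc[0]
            else:
                row[c] = defaults.get(c, "")
        rows.append(row)
    out = pd.concat([series, pd.DataFrame(rows)], ignore_index=True)
    return out.sort_values("campaign_year").reset_index(drop=True)


def correct_tree(series: pd.DataFrame,
                 campaign_years: list[int],
                 decimal_dates: dict[int, float] | None = None,
                 overrides: pd.DataFrame | None = None) -> pd.DataFrame:
    """Full correction pipeline for one tree.

    Order: manual overrides -> re-born back-fill -> taper detection and
    conversion -> gap filling, iterated until no hom raise remains (one
    extra pass covers overrides that changed flanking values).  The output
    has one value per campaign between the tree's first and last record
    (holes only where no flanking pair exists) and full provenance.  The
    pipeline is idempotent.
    """
    out = _expand_to_campaigns(series, campaign_years)
    if "provenance" not in out.columns:
        out["provenance"] = np.where(out["dbh_cm"].notna(), PROV_RAW, "")

    if overrides is not None and len(overrides):
        yidx = {int(y): i for i, y in enumerate(out["campaign_year"])}
        base_hom = _original_hom(out)
        for ov in overrides.itertuples():
            i = yidx.get(int(ov.campaign_year))
            if i is None:
                continue
            out.at[i, "dbh_cm"] = float(ov.dbh_cm)
            out.at[i, "hom_m"] = base_hom
            out.at[i, "status"] = STATUS_ALIVE
            out.at[i, "mortality_code"] = MORTALITY_NONE
            out.at[i, "provenance"] = PROV_OVERRIDE

    out = backfill_reborn(out)
    for _ in range(3):
        events = [e for e in detect_hom_raises(out) if not np.isnan(e.ratio)]
        if events:
            out = apply_taper_correction(out, events)
        out = fill_gaps(out, decimal_dates)
        remaining = [e for e in detect_hom_raises(out)
                     if not np.isnan(e.ratio)]
        if not remaining:
            break
    return out


def _original_hom(series: pd.DataFrame) -> float:
    hom = series["hom_m"].to_numpy(dtype=float)
    for h in hom:
        if not np.isnan(h):
            return float(h)
    return 1.50


def read_overrides(path) -> pd.DataFrame:
    """Read a manual-override sidecar CSV.

    Columns: plot_no, subplot_no, tree_no, campaign_year, dbh_cm, note.
    """
    df = pd.read_csv(path)
    required = {"plot_no", "subplot_no", "tree_no", "campaign_year", "dbh_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"override file lacks column(s): {sorted(missing)}")
    if "note" not in df.columns:
        df["note"] = ""
    return df


def correct_archive(archive: CensusArchive,
                    overrides: pd.DataFrame | None = None) -> CensusArchive:
    """Correct every tree of an archive; returns a corrected archive.

    The corrected archive uses the same schema plus a ``provenance``
    column in measures.csv, and live rows before a tree's database
    recruitment (first campaign with dbh >= 10 cm) are re-labelled
    ``not_yet_recruited`` so that analysis code can select recruited
    trees by status alone.
    """
    years = archive.campaign_years()
    dates = archive.decimal_dates()
    key = ["plot_no", "subplot_no", "tree_no"]

    ov_groups = {}
    if overrides is not None and len(overrides):
        for k, g in overrides.groupby(key):
            ov_groups[k] = g

    pieces = []
    measures = archive.measures.sort_values(key + ["campaign_year"])
    for k, g in measures.groupby(key, sort=True):
        g = g.reset_index(drop=True)
        if (g["method"] == "relascope").any():
            g = _expand_to_campaigns(g, years)
            g = carry_forward_relascope(g)
        corrected = correct_tree(g, years, dates, ov_groups.get(k))
        corrected[key] = pd.DataFrame(
            {c: k[i] for i, c in enumerate(key)}, index=corrected.index)
        pieces.append(corrected)

    out = archive.copy()
    if pieces:
        m = pd.concat(pieces, ignore_index=True)
        m = _mark_unrecruited(m)
        cols = [c for c in archive.measures.columns if c != "provenance"]
        m = m[cols + ["provenance"]]
        out.measures = m.reset_index(drop=True)
    else:
        m = archive.measures.copy()
        m["provenance"] = np.where(m["dbh_cm"].notna(), PROV_RAW, "")
        out.measures = m
    return out


def _mark_unrecruited(measures: pd.DataFrame) -> pd.DataFrame:
    """Live rows before the recruitment campaign -> not_yet_recruited."""
    m = measures.copy()
    key = ["plot_no", "subplot_no", "tree_no"]
    qualifies = (m["dbh_cm"] >= RECRUIT_DBH_CM) & m["status"].isin(LIVE_STATUSES)
    rec = (m[qualifies].groupby(key, as_index=False)["campaign_year"].min()
           .rename(columns={"campaign_year": "_recruit_year"}))
    m = m.merge(rec, on=key, how="left")
    rec_year = m["_recruit_year"].to_numpy(dtype=float)  # NaN = never recruited
    live = m["status"].isin(LIVE_STATUSES).to_numpy()
    before = np.isnan(rec_year) | (m["campaign_year"].to_numpy() < rec_year)
    m.loc[live & before, "status"] = STATUS_NOT_YET_RECRUITED
    m.loc[live & ~before, "status"] = STATUS_ALIVE
    return m.drop(columns=["_recruit_year"])
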