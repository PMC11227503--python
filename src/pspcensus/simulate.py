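"""Synthetic PSP archive generator with known ground truth.

Simulates a tropical-forest census experiment end to end — population
dynamics first, then the observation process — and emits an archive in the
released ten-file schema together with an exhaustive :class:`GroundTruthLog`
so that every divergence between truth and observation is testable.

Population model (annual steps, per 4-ha plot):

* initial stand from a truncated exponential diameter distribution over
  dbh >= 9.5 cm (reverse-J structure), >500 stems/ha by default;
* lognormal annual dbh increments;
* Bernoulli mortality at a configured %/yr, cause drawn among standing
  death / primary treefall / secondary treefall;
* recruitment as a Poisson stream of new trees crossing the 30 cm gbh
  field threshold (entry dbh just above 9.5 cm);
* optional disturbance events removing a target fraction of basal area.

Observation layer (at census campaigns only):

* girth measured at the current hom with Gaussian diameter noise, rounded
  to 0.5 cm in the field; the database stores gbh/pi rounded to 0.1 cm;
* hom raises with a multiplicative taper factor on the measured girth;
* 1982-1990 girth > 250 cm recorded as 10-cm diameter class midpoints;
* missing records (no row, or a row without a diameter);
* false-dead episodes: a live tree recorded dead for one or two campaigns
  and then found alive (the re-born pattern).

Given a seed the output is byte-identical across runs and platforms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .measurement import dbh_to_gbh, gbh_to_dbh
from .schema import (BLOCK_OF_PLOT, MORTALITY_CODES, MORTALITY_NONE,
                     STATUS_ALIVE, STATUS_DEAD, STATUS_MISSING, CensusArchive,
                     PlotGeometry, SubplotGeometry, ascii_fold,
                     default_campaign_years, default_census_date,
                     default_code_tables, load_valuable_species_fixture,
                     local_to_wgs84)

__all__ = ["SimulationConfig", "GroundTruthLog", "simulate_archive",
           "inject_anomalies"]

#: default plot numbers for a control-plot release: one plot per block first
_PLOT_NUMBERS = [11, 14, 21, 12, 15, 22, 13, 16, 23, 24]

# site anchor for the WGS84 affine (northern edge of the Congo basin)
_SITE_LON = 17.5600
_SITE_LAT = 3.5000


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a synthetic census.

    Defaults emulate an undisturbed (control) stand: >500 stems/ha,
    mortality and recruitment fluctuating around 1 %/yr, annual campaigns
    1982-2022 minus the six skipped years.
    """

    seed: int
    n_plots: int = 3
    campaign_years: tuple = tuple(default_campaign_years())
    initial_density_per_ha: float = 520.0
    initial_dbh_scale_cm: float = 12.0   # exponential scale above 9.5 cm
    growth_mean_cm_yr: float = 0.25
    growth_sd_cm_yr: float = 0.20
    mortality_pct_yr: float = 1.0
    recruitment_pct_yr: float = 1.0
    mortality_cause_probs: tuple = (0.5, 0.3, 0.2)
    p_hom_raise_per_yr: float = 0.004
    taper_factor_range: tuple = (0.85, 0.95)
    measurement_sd_cm: float = 0.1
    p_missing_record: float = 0.01
    p_false_dead: float = 0.002
    disturbance_events: tuple = ()  # ((year, fraction_basal_area_removed), ..)
    diameter_class_era: bool = True  # girth > 250 cm -> classes, 1982-1990

    def __post_init__(self):
        for name in ("p_hom_raise_per_yr", "p_missing_record", "p_false_dead"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.initial_density_per_ha <= 0:
            raise ValueError("initial_density_per_ha must be positive")
        years = list(self.campaign_years)
        if years != sorted(set(years)):
            raise ValueError("campaign_years must be strictly increasing")
        if not 1 <= self.n_plots <= len(_PLOT_NUMBERS):
            raise ValueError(f"n_plots must be 1..{len(_PLOT_NUMBERS)}")
        if not (0 < self.taper_factor_range[0]
                <= self.taper_factor_range[1] <= 1.0):
            raise ValueError("taper_factor_range must satisfy "
                             "0 < low <= high <= 1")
        if abs(sum(self.mortality_cause_probs) - 1.0) > 1e-9:
            raise ValueError("mortality_cause_probs must sum to 1")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruthLog:
    """Everything the observation layer hid: the oracle for all tests."""

    trees: pd.DataFrame         # per tree: entry/recruit/death years, cause
    trajectories: pd.DataFrame  # true dbh at original hom per census year
    hom_events: pd.DataFrame    # hom raises with true taper factors
    false_dead: pd.DataFrame    # campaigns a live tree was recorded dead
    missing: pd.DataFrame       # (tree, campaign) with record suppressed
    removals: pd.DataFrame      # disturbance removals (plot, year, n, ba)
    anomalies: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["plot_no", "subplot_no", "tree_no", "campaign_year",
                 "rule_id"]))


# --------------------------------------------------------------------------
# reference tables
# --------------------------------------------------------------------------

def _taxon_tables(rng: np.random.Generator):
    """Taxonomy/vernacular reference tables: valuable fixture + filler taxa."""
    fixture = load_valuable_species_fixture()
    rows, vern = [], []
    for i, r in enumerate(fixture.itertuples(), start=1):
        sci = ascii_fold(r.valid_name if r.valid_name else r.species)
        rows.append({"taxon_id": i, "sci_name": sci,
                     "valuable_code": r.code, "valuable_category": r.category})
        vern.append({"vernacular_name": ascii_fold(r.issongo_name),
                     "taxon_id": i})
    fillers = ["Celtis mildbraedii", "Manilkara mabokeensis",
               "Anonidium mannii", "Polyalthia suaveolens",
               "Strombosia pustulata", "Trichilia tessmannii",
               "Garcinia punctata", "Coelocaryon preussii",
               "Dasylepis seretii", "Pancovia laurentii"]
    for j, sci in enumerate(fillers, start=len(rows) + 1):
        rows.append({"taxon_id": j, "sci_name": sci, "valuable_code": "",
                     "valuable_category": "C"})
        vern.append({"vernacular_name": f"Issongo-{j:02d}", "taxon_id": j})
    taxonomy = pd.DataFrame(rows)
    vernacular = pd.DataFrame(vern)
    return taxonomy, vernacular


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def _plot_geometries(plot_nos: list[int]):
    plots, subplots = [], []
    for i, pn in enumerate(plot_nos):
        # plots laid out west->east with a 200 m gap (buffer zones)
        x0 = i * 400.0
        ref_lon, ref_lat = local_to_wgs84(x0, 0.0, _SITE_LON, _SITE_LAT)
        ref_lon, ref_lat = float(ref_lon), float(ref_lat)

        def ring(xa, ya, xb, yb):
            xs = [xa, xb, xb, xa, xa]
            ys = [ya, ya, yb, yb, ya]
            lon, lat = local_to_wgs84(np.array(xs), np.array(ys),
                                      ref_lon, ref_lat)
            return [[ [float(a), float(b)] for a, b in zip(lon, lat) ]]

        plots.append(PlotGeometry(
            plot_no=pn, treatment="control", block=BLOCK_OF_PLOT[pn],
            ref_lon=ref_lon, ref_lat=ref_lat,
            coordinates=ring(0.0, 0.0, 200.0, 200.0), area_ha=4.0))
        # subplot quadrants: 1 SW, 2 SE, 3 NW, 4 NE (documented convention)
        quads = {1: (0.0, 0.0, 100.0, 100.0), 2: (100.0, 0.0, 200.0, 100.0),
                 3: (0.0, 100.0, 100.0, 200.0),
                 4: (100.0, 100.0, 200.0, 200.0)}
        for sn, (xa, ya, xb, yb) in quads.items():
            subplots.append(SubplotGeometry(
                plot_no=pn, subplot_no=sn, ref_lon=ref_lon, ref_lat=ref_lat,
                coordinates=ring(xa, ya, xb, yb), area_ha=1.0))
    return plots, subplots


_SUBPLOT_ORIGIN = {1: (0.0, 0.0), 2: (100.0, 0.0), 3: (0.0, 100.0),
                   4: (100.0, 100.0)}


# --------------------------------------------------------------------------
# core simulation
# --------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float):
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


class _PlotState:
    """Mutable per-plot tree population (numpy columns)."""

    def __init__(self):
        self.subplot = np.zeros(0, dtype=int)
        self.tree_no = np.zeros(0, dtype=int)
        self.x = np.zeros(0)
        self.y = np.zeros(0)
        self.taxon = np.zeros(0, dtype=int)
        self.dbh = np.zeros(0)            # true dbh at original hom
        self.alive = np.zeros(0, dtype=bool)
        self.entry_year = np.zeros(0, dtype=int)
        self.death_year = np.full(0, -1, dtype=int)
        self.cause = np.zeros(0, dtype=object)
        self.hom = np.zeros(0)            # current hom (m)
        self.mult = np.zeros(0)           # girth multiplier from taper
        self.false_dead_left = np.zeros(0, dtype=int)
        self.next_no = {1: 1, 2: 1, 3: 1, 4: 1}

    def add(self, n: int, year: int, rng: np.random.Generator,
            dbh: np.ndarray, taxon_ids: np.ndarray):
        sub = rng.integers(1, 5, size=n)
        nos = np.zeros(n, dtype=int)
        for i, s in enumerate(sub):
            nos[i] = self.next_no[int(s)]
            self.next_no[int(s)] += 1
        ox = np.array([_SUBPLOT_ORIGIN[int(s)][0] for s in sub])
        oy = np.array([_SUBPLOT_ORIGIN[int(s)][1] for s in sub])
        self.subplot = np.concatenate([self.subplot, sub])
        self.tree_no = np.concatenate([self.tree_no, nos])
        self.x = np.concatenate([self.x, ox + rng.uniform(0, 100, n)])
        self.y = np.concatenate([self.y, oy + rng.uniform(0, 100, n)])
        self.taxon = np.concatenate([self.taxon, taxon_ids])
        self.dbh = np.concatenate([self.dbh, dbh])
        self.alive = np.concatenate([self.alive, np.ones(n, dtype=bool)])
        self.entry_year = np.concatenate(
            [self.entry_year, np.full(n, year, dtype=int)])
        self.death_year = np.concatenate(
            [self.death_year, np.full(n, -1, dtype=int)])
        self.cause = np.concatenate(
            [self.cause, np.full(n, "", dtype=object)])
        self.hom = np.concatenate([self.hom, np.full(n, 1.50)])
        self.mult = np.concatenate([self.mult, np.ones(n)])
        self.false_dead_left = np.concatenate(
            [self.false_dead_left, np.zeros(n, dtype=int)])

    def __len__(self):
        return len(self.dbh)


def simulate_archive(config: SimulationConfig):
    """Run the simulation; returns ``(CensusArchive, GroundTruthLog)``."""
    rng = np.random.default_rng(config.seed)
    years = list(config.campaign_years)
    first, last = years[0], years[-1]
    census_set = set(years)
    mu, sigma = _lognormal_params(config.growth_mean_cm_yr,
                                  config.growth_sd_cm_yr)
    p_die = config.mortality_pct_yr / 100.0
    taxonomy, vernacular = _taxon_tables(rng)
    taxon_ids_all = taxonomy["taxon_id"].to_numpy()
    # valuable species are a minority of stems; weight them low
    weights = np.where(taxonomy["valuable_category"].to_numpy() == "C",
                       4.0, 1.0)
    weights = weights / weights.sum()
    plot_nos = _PLOT_NUMBERS[:config.n_plots]
    disturbance = dict(config.disturbance_events)

    meas_rows = {k: [] for k in ("plot_no", "subplot_no", "tree_no",
                                 "campaign_year", "girth_cm", "dbh_cm",
                                 "hom_m", "method", "status",
                                 "mortality_code")}
    truth_rows = {k: [] for k in ("plot_no", "subplot_no", "tree_no",
                                  "campaign_year", "dbh_true_cm")}
    hom_rows, fdead_rows, missing_rows, removal_rows = [], [], [], []
    tree_tables, truth_tree_rows = [], []

    for pn in plot_nos:
        st = _PlotState()
        n0 = int(rng.poisson(config.initial_density_per_ha * 4.0))
        st.add(n0, first, rng,
               9.5 + rng.exponential(config.initial_dbh_scale_cm, n0),
               rng.choice(taxon_ids_all, size=n0, p=weights))
        death_reported = np.zeros(n0, dtype=bool)
        observed_ever = np.zeros(n0, dtype=bool)
        recruit_true_year = np.full(n0, -1, dtype=int)
        prev_census_year = None

        def _pad(arr, fill):
            extra = len(st) - arr.shape[0]
            if extra > 0:
                arr = np.concatenate([arr, np.full(extra, fill,
                                                   dtype=arr.dtype)])
            return arr

        def _emit(mask, year, girth, dbh, hom, method, status, mort):
            idx = np.flatnonzero(mask)
            if not len(idx):
                return
            k = len(idx)
            meas_rows["plot_no"].extend([pn] * k)
            meas_rows["subplot_no"].extend(st.subplot[idx].tolist())
            meas_rows["tree_no"].extend(st.tree_no[idx].tolist())
            meas_rows["campaign_year"].extend([year] * k)
            meas_rows["girth_cm"].extend(np.broadcast_to(girth, (k,)).tolist())
            meas_rows["dbh_cm"].extend(np.broadcast_to(dbh, (k,)).tolist())
            meas_rows["hom_m"].extend(np.broadcast_to(hom, (k,)).tolist())
            if isinstance(method, str):
                meas_rows["method"].extend([method] * k)
            else:
                meas_rows["method"].extend(method)
            meas_rows["status"].extend([status] * k)
            if isinstance(mort, str):
                meas_rows["mortality_code"].extend([mort] * k)
            else:
                meas_rows["mortality_code"].extend(mort)

        for year in range(first, last + 1):
            if year > first:
                # grow, then kill, then recruit (annual steps)
                n = len(st)
                inc = rng.lognormal(mu, sigma, n)
                st.dbh[st.alive] += inc[st.alive]
                dies = st.alive & (rng.random(n) < p_die)
                if dies.any():
                    st.alive[dies] = False
                    st.death_year[dies] = year
                    causes = rng.choice(list(MORTALITY_CODES),
                                        size=int(dies.sum()),
                                        p=list(config.mortality_cause_probs))
                    st.cause[dies] = causes
                if year in disturbance:
                    _remove_basal_area(st, disturbance[year], year, rng,
                                       removal_rows, pn)
                lam = config.recruitment_pct_yr / 100.0 * st.alive.sum()
                n_new = int(rng.poisson(lam))
                if n_new:
                    st.add(n_new, year, rng,
                           9.5 + rng.uniform(0.0, 0.3, n_new),
                           rng.choice(taxon_ids_all, size=n_new, p=weights))
                death_reported = _pad(death_reported, False)
                observed_ever = _pad(observed_ever, False)
                recruit_true_year = _pad(recruit_true_year, -1)

            if year not in census_set:
                continue

            dt = 1.0 if prev_census_year is None else year - prev_census_year
            n = len(st)

            # hom raises (decided at census)
            p_raise = min(1.0, config.p_hom_raise_per_yr * dt)
            raise_mask = st.alive & (rng.random(n) < p_raise) & (st.hom < 4.5)
            for i in np.flatnonzero(raise_mask):
                hom_old = st.hom[i]
                hom_new = 4.5 if (year >= 2008 or hom_old > 1.5) else 3.5
                factor = rng.uniform(*config.taper_factor_range)
                st.hom[i] = hom_new
                st.mult[i] *= factor
                hom_rows.append({"plot_no": pn,
                                 "subplot_no": int(st.subplot[i]),
                                 "tree_no": int(st.tree_no[i]),
                                 "campaign_year": year,
                                 "hom_old_m": float(hom_old),
                                 "hom_new_m": float(hom_new),
                                 "taper_factor": float(factor)})

            # false-dead episodes start
            starts = st.alive & (st.false_dead_left == 0) \
                & (rng.random(n) < config.p_false_dead)
            if starts.any():
                st.false_dead_left[starts] = rng.integers(
                    1, 3, size=int(starts.sum()))

            # record truth at census
            recruit_now = st.alive & (st.dbh >= 10.0) & (recruit_true_year < 0)
            recruit_true_year[recruit_now] = year
            entered = st.entry_year <= year
            obs_alive = st.alive & entered
            idx = np.flatnonzero(obs_alive)
            truth_rows["plot_no"].extend([pn] * len(idx))
            truth_rows["subplot_no"].extend(st.subplot[idx].tolist())
            truth_rows["tree_no"].extend(st.tree_no[idx].tolist())
            truth_rows["campaign_year"].extend([year] * len(idx))
            truth_rows["dbh_true_cm"].extend(np.round(st.dbh[idx], 4).tolist())

            # observation layer (vectorized by row category)
            missing_draw = rng.random(n) < config.p_missing_record
            missing_kind = rng.random(n) < 0.5  # True: row without dbh
            noise = rng.normal(0.0, config.measurement_sd_cm, n)

            newly_dead = entered & ~st.alive & ~death_reported & observed_ever
            _emit(newly_dead, year, np.nan, np.nan, np.nan, "", STATUS_DEAD,
                  [str(c) for c in st.cause[newly_dead]])
            death_reported |= newly_dead

            fdead = obs_alive & (st.false_dead_left > 0)
            st.false_dead_left[fdead] -= 1
            _emit(fdead, year, np.nan, np.nan, np.nan, "", STATUS_DEAD,
                  "standing_death")
            for i in np.flatnonzero(fdead):
                fdead_rows.append({"plot_no": pn,
                                   "subplot_no": int(st.subplot[i]),
                                   "tree_no": int(st.tree_no[i]),
                                   "campaign_year": year})

            miss = obs_alive & ~fdead & missing_draw
            for i in np.flatnonzero(miss):
                missing_rows.append({"plot_no": pn,
                                     "subplot_no": int(st.subplot[i]),
                                     "tree_no": int(st.tree_no[i]),
                                     "campaign_year": year})
            _emit(miss & missing_kind, year, np.nan, np.nan, np.nan, "",
                  STATUS_MISSING, MORTALITY_NONE)

            normal = obs_alive & ~fdead & ~miss
            ni = np.flatnonzero(normal)
            if len(ni):
                d_obs = np.maximum(0.5, st.dbh[ni] * st.mult[ni] + noise[ni])
                girth = np.atleast_1d(dbh_to_gbh(d_obs))
                dbh_db = np.atleast_1d(gbh_to_dbh(girth))
                in_class = np.zeros(len(ni), dtype=bool)
                if config.diameter_class_era and year <= 1990:
                    in_class = girth > 250.0
                tape_sel = np.zeros(n, dtype=bool)
                tape_sel[ni[~in_class]] = True
                _emit(tape_sel, year, girth[~in_class], dbh_db[~in_class],
                      st.hom[ni[~in_class]], "tape", STATUS_ALIVE,
                      MORTALITY_NONE)
                if in_class.any():
                    class_sel = np.zeros(n, dtype=bool)
                    class_sel[ni[in_class]] = True
                    mid = np.floor(d_obs[in_class] / 10.0) * 10.0 + 5.0
                    _emit(class_sel, year, np.nan, mid,
                          st.hom[ni[in_class]], "diameter_class",
                          STATUS_ALIVE, MORTALITY_NONE)
            observed_ever |= obs_alive
            prev_census_year = year

        tree_tables.append(pd.DataFrame({
            "plot_no": pn, "subplot_no": st.subplot, "tree_no": st.tree_no,
            "x_m": np.round(st.x, 2), "y_m": np.round(st.y, 2),
            "taxon": st.taxon}))
        truth_tree_rows.append(pd.DataFrame({
            "plot_no": pn, "subplot_no": st.subplot, "tree_no": st.tree_no,
            "entry_year": st.entry_year,
            "recruit_true_year": recruit_true_year,
            "death_year": st.death_year,
            "mortality_cause": [c if c else "" for c in st.cause],
            "hom_final_m": st.hom,
            "girth_multiplier": st.mult}))

    # assemble archive tables --------------------------------------------
    trees_all = pd.concat(tree_tables, ignore_index=True)
    vern_of_taxon = dict(zip(vernacular["taxon_id"],
                             vernacular["vernacular_name"]))
    tree = pd.DataFrame({
        "plot_no": trees_all["plot_no"].astype(np.int64),
        "subplot_no": trees_all["subplot_no"].astype(np.int64),
        "tree_no": trees_all["tree_no"].astype(np.int64),
        "x_m": trees_all["x_m"].astype(float),
        "y_m": trees_all["y_m"].astype(float),
        "vernacular_name": trees_all["taxon"].map(vern_of_taxon).astype(str),
        "taxon_id_1991": trees_all["taxon"].astype("Int64"),
        "taxon_id_2010": trees_all["taxon"].astype("Int64"),
        "taxon_id_2011": trees_all["taxon"].astype("Int64"),
    })
    measures = pd.DataFrame({
        "plot_no": np.asarray(meas_rows["plot_no"], dtype=np.int64),
        "subplot_no": np.asarray(meas_rows["subplot_no"], dtype=np.int64),
        "tree_no": np.asarray(meas_rows["tree_no"], dtype=np.int64),
        "campaign_year": np.asarray(meas_rows["campaign_year"],
                                    dtype=np.int64),
        "girth_cm": np.asarray(meas_rows["girth_cm"], dtype=float),
        "dbh_cm": np.asarray(meas_rows["dbh_cm"], dtype=float),
        "hom_m": np.asarray(meas_rows["hom_m"], dtype=float),
        "method": pd.Series(meas_rows["method"], dtype=str),
        "status": pd.Series(meas_rows["status"], dtype=str),
        "mortality_code": pd.Series(meas_rows["mortality_code"], dtype=str),
    })
    measures["observation_codes"] = ""
    inventories = pd.DataFrame({
        "campaign_year": np.asarray(years, dtype=np.int64),
        "census_date": [default_census_date(y) for y in years],
        "notes": ["" for _ in years],
    })
    obs_codes, mort_codes = default_code_tables()
    trees_context = pd.DataFrame({
        "plot_no": np.asarray(plot_nos, dtype=np.int64),
        "block": [BLOCK_OF_PLOT[pn] for pn in plot_nos],
        "treatment": ["control"] * len(plot_nos),
        "treatment_year": np.full(len(plot_nos), 1986, dtype=np.int64),
    })
    plots, subplots = _plot_geometries(plot_nos)

    archive = CensusArchive(
        tree=tree, taxonomy=taxonomy, vernacular=vernacular,
        trees_context=trees_context, measures=measures,
        inventories=inventories, observation_codes=obs_codes,
        mortality_codes=mort_codes, plots=plots, subplots=subplots)

    log = GroundTruthLog(
        trees=pd.concat(truth_tree_rows, ignore_index=True),
        trajectories=pd.DataFrame(truth_rows),
        hom_events=pd.DataFrame(hom_rows, columns=[
            "plot_no", "subplot_no", "tree_no", "campaign_year", "hom_old_m",
            "hom_new_m", "taper_factor"]),
        false_dead=pd.DataFrame(fdead_rows, columns=[
            "plot_no", "subplot_no", "tree_no", "campaign_year"]),
        missing=pd.DataFrame(missing_rows, columns=[
            "plot_no", "subplot_no", "tree_no", "campaign_year"]),
        removals=pd.DataFrame(removal_rows, columns=[
            "plot_no", "year", "n_removed", "basal_area_removed_m2"]))
    return archive, log


def _remove_basal_area(st: _PlotState, fraction: float, year: int,
                       rng: np.random.Generator, removal_rows: list,
                       plot_no: int) -> None:
    """Stylized logging pulse: remove stems, probability ~ basal-area share."""
    alive_idx = np.flatnonzero(st.alive)
    if not len(alive_idx):
        return
    ba = (st.dbh[alive_idx] / 200.0) ** 2 * np.pi
    target = fraction * ba.sum()
    order = rng.permutation(len(alive_idx))
    # weighted acceptance: bigger trees more likely to be taken first
    w = ba / ba.max()
    removed, total = [], 0.0
    for j in order:
        if total >= target:
            break
        if rng.random() < w[j]:
            removed.append(alive_idx[j])
            total += ba[j]
    if removed:
        removed = np.array(removed)
        st.alive[removed] = False
        st.death_year[removed] = year
        st.cause[removed] = "primary_treefall"
        removal_rows.append({"plot_no": plot_no, "year": year,
                             "n_removed": len(removed),
                             "basal_area_removed_m2": float(total)})


# --------------------------------------------------------------------------
# anomaly injection (QC test harness)
# --------------------------------------------------------------------------

def inject_anomalies(archive: CensusArchive, counts: dict[str, int],
                     seed: int):
    """Inject known QC anomalies into a copy of ``archive``.

    ``counts`` maps rule ids (EXCESS_GROWTH, EXCESS_DECLINE, REBORN,
    RECRUIT_UNDER_10, HOM_RAISE_INCREASE, MISSING_DATA) to requested
    injection counts.  Each injection touches a distinct tree and is
    engineered to trigger exactly one new flag; the returned log
    (plot_no, subplot_no, tree_no, campaign_year, rule_id) is the oracle.
    A shortfall (not enough eligible trees) raises ``ValueError``.
    """
    rng = np.random.default_rng(seed)
    out = archive.copy()
    m = out.measures
    key = ["plot_no", "subplot_no", "tree_no"]
    dates = out.decimal_dates()
    years = out.campaign_years()
    first_year = years[0]

    m = m.sort_values(key + ["campaign_year"]).reset_index(drop=True)
    grouped = {k: g.index.to_numpy() for k, g in m.groupby(key)}
    used: set = set()
    log = []

    def measured(i):
        return (m.at[i, "status"] == STATUS_ALIVE
                and pd.notna(m.at[i, "dbh_cm"]))

    def consecutive_measured(idx, need=2):
        """Runs of `need` rows at consecutive campaigns, all measured."""
        hits = []
        for s in range(len(idx) - need + 1):
            rows = idx[s:s + need]
            ys = [int(m.at[i, "campaign_year"]) for i in rows]
            if any(not measured(i) for i in rows):
                continue
            ok = all(years.index(ys[j + 1]) == years.index(ys[j]) + 1
                     for j in range(need - 1))
            if ok:
                hits.append(rows)
        return hits

    def shift_tail(idx, start_pos, delta):
        for i in idx[start_pos:]:
            if pd.notna(m.at[i, "dbh_cm"]):
                new = round(m.at[i, "dbh_cm"] + delta, 1)
                m.at[i, "dbh_cm"] = new
                if pd.notna(m.at[i, "girth_cm"]):
                    m.at[i, "girth_cm"] = float(dbh_to_gbh(new))

    order = sorted(grouped)
    rng.shuffle(order)

    def pick(rule, eligible_fn, apply_fn, want):
        done = 0
        for k in order:
            if done >= want:
                break
            if k in used:
                continue
            idx = grouped[k]
            choice = eligible_fn(k, idx)
            if choice is None:
                continue
            used.add(k)
            campaign = apply_fn(k, idx, choice)
            log.append({"plot_no": k[0], "subplot_no": k[1], "tree_no": k[2],
                        "campaign_year": campaign, "rule_id": rule})
            done += 1
        if done < want:
            raise ValueError(f"could not inject {want} {rule} anomalies "
                             f"(only {done} eligible trees)")

    def elig_pair_nohom(k, idx):
        hits = consecutive_measured(idx, 2)
        hits = [h for h in hits
                if m.at[h[0], "hom_m"] == m.at[h[1], "hom_m"]
                and m.at[h[0], "dbh_cm"] >= 15.0]
        return hits[len(hits) // 2] if hits else None

    def apply_growth(k, idx, rows):
        a, b = rows
        ya, yb = int(m.at[a, "campaign_year"]), int(m.at[b, "campaign_year"])
        dt = dates[yb] - dates[ya]
        target = round(m.at[a, "dbh_cm"] + 3.0 * dt, 1)
        delta = target - m.at[b, "dbh_cm"]
        shift_tail(idx, np.where(idx == b)[0][0], delta)
        return yb

    def apply_decline(k, idx, rows):
        a, b = rows
        ya, yb = int(m.at[a, "campaign_year"]), int(m.at[b, "campaign_year"])
        dt = dates[yb] - dates[ya]
        target = round(m.at[a, "dbh_cm"] - 1.0 * dt, 1)
        delta = target - m.at[b, "dbh_cm"]
        shift_tail(idx, np.where(idx == b)[0][0], delta)
        return yb

    def elig_triple(k, idx):
        hits = consecutive_measured(idx, 3)
        hits = [h for h in hits if m.at[h[0], "dbh_cm"] >= 15.0]
        return hits[len(hits) // 2] if hits else None

    def apply_reborn(k, idx, rows):
        a, b, c = rows
        m.at[b, "dbh_cm"] = np.nan
        m.at[b, "girth_cm"] = np.nan
        m.at[b, "hom_m"] = np.nan
        m.at[b, "method"] = ""
        m.at[b, "status"] = STATUS_DEAD
        m.at[b, "mortality_code"] = "standing_death"
        return int(m.at[c, "campaign_year"])

    def apply_missing(k, idx, rows):
        a, b, c = rows
        year = int(m.at[b, "campaign_year"])
        m.drop(index=b, inplace=True)
        return year

    def elig_recruit(k, idx):
        i = idx[0]
        if not measured(i):
            return None
        y = int(m.at[i, "campaign_year"])
        if y == first_year:
            return None
        if not (10.0 <= m.at[i, "dbh_cm"] <= 11.0):
            return None
        return (i,)

    def apply_recruit(k, idx, rows):
        (i,) = rows
        m.at[i, "dbh_cm"] = 9.7
        m.at[i, "girth_cm"] = float(dbh_to_gbh(9.7))
        return int(m.at[i, "campaign_year"])

    def elig_homraise(k, idx):
        hits = consecutive_measured(idx, 2)
        hits = [h for h in hits
                if m.at[h[0], "hom_m"] == 1.5 and m.at[h[1], "hom_m"] == 1.5
                and m.at[h[1], "dbh_cm"] > m.at[h[0], "dbh_cm"]]
        # hom must stay 1.5 for the rest of the series before injection
        hits = [h for h in hits
                if all(m.at[i, "hom_m"] == 1.5 or pd.isna(m.at[i, "hom_m"])
                       for i in idx)]
        return hits[len(hits) // 2] if hits else None

    def apply_homraise(k, idx, rows):
        a, b = rows
        pos = np.where(idx == b)[0][0]
        for i in idx[pos:]:
            if pd.notna(m.at[i, "hom_m"]):
                m.at[i, "hom_m"] = 4.5
        return int(m.at[b, "campaign_year"])

    appliers = {
        "EXCESS_GROWTH": (elig_pair_nohom, apply_growth),
        "EXCESS_DECLINE": (elig_pair_nohom, apply_decline),
        "REBORN": (elig_triple, apply_reborn),
        "MISSING_DATA": (elig_triple, apply_missing),
        "RECRUIT_UNDER_10": (elig_recruit, apply_recruit),
        "HOM_RAISE_INCREASE": (elig_homraise, apply_homraise),
    }
    for rule, want in counts.items():
        if rule not in appliers:
            raise ValueError(f"cannot inject rule {rule!r}")
        if want:
            elig, appl = appliers[rule]
            pick(rule, elig, appl, want)

    out.measures = m.reset_index(drop=True)
    log_df = pd.DataFrame(log, columns=["plot_no", "subplot_no", "tree_no",
                                        "campaign_year", "rule_id"])
    return out, log_df
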