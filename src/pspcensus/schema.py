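"""Relational census archive: domain types, readers/writers, validation.

A census archive is the flat-file release format of a permanent-sample-plot
(PSP) experiment: eight comma-separated ASCII tables plus two GeoJSON
layers.

========================  =====================================================
file                      contents
========================  =====================================================
tree.csv                  one row per tree: location, names, taxonomy links
taxonomy.csv              scientific names and valuable-timber categories
vernacular.csv            Issongo vernacular name -> taxon correspondence
trees_context.csv         per-plot silvicultural treatment metadata
measures.csv              repeated girth/dbh measurements, status, mortality
inventories.csv           one row per inventory campaign (year, census date)
observation_codes.csv     code list: stem shape, termites, lianas, damage
mortality_codes.csv       code list: standing death, primary/secondary treefall
plots.geojson             4-ha plot polygons (WGS84) + treatment attributes
subplots.geojson          1-ha subplot polygons
========================  =====================================================

Column names and order are this package's documented data dictionary
(``docs/data_dictionary.md``); the on-disk convention is comma separation,
ASCII, header row, empty string for missing values.  ``write_archive``
followed by ``read_archive`` reproduces the archive exactly, and a second
write is byte-identical.
"""

from __future__ import annotations

import json
import math
import unicodedata
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

__all__ = [
    "MISSING_CAMPAIGN_YEARS",
    "default_campaign_years",
    "default_census_date",
    "decimal_year",
    "Campaign",
    "PlotGeometry",
    "SubplotGeometry",
    "CensusArchive",
    "Violation",
    "SchemaError",
    "ReferentialIntegrityError",
    "read_archive",
    "write_archive",
    "validate_archive",
    "archives_equal",
    "load_valuable_species_fixture",
    "default_code_tables",
    "local_to_wgs84",
    "wgs84_to_local",
]

# --------------------------------------------------------------------------
# campaign calendar
# --------------------------------------------------------------------------

#: calendar years 1982-2022 in which no inventory campaign took place
MISSING_CAMPAIGN_YEARS = frozenset({1997, 1999, 2001, 2013, 2014, 2016})

FIRST_CAMPAIGN_YEAR = 1982
LAST_CAMPAIGN_YEAR = 2022


def default_campaign_years(start: int = FIRST_CAMPAIGN_YEAR,
                           end: int = LAST_CAMPAIGN_YEAR) -> list[int]:
    """The default campaign calendar: annual censuses minus the skipped years."""
    return [y for y in range(start, end + 1) if y not in MISSING_CAMPAIGN_YEARS]


def default_census_date(year: int) -> pd.Timestamp:
    """Nominal census date: 15 May, the midpoint of the April-June campaign."""
    return pd.Timestamp(year=year, month=5, day=15)


def decimal_year(date: pd.Timestamp) -> float:
    """Calendar date as a decimal year (fraction of the actual year length)."""
    date = pd.Timestamp(date)
    start = pd.Timestamp(year=date.year, month=1, day=1)
    end = pd.Timestamp(year=date.year + 1, month=1, day=1)
    return date.year + (date - start) / (end - start)


# --------------------------------------------------------------------------
# controlled vocabularies
# --------------------------------------------------------------------------

STATUS_ALIVE = "alive"
STATUS_DEAD = "dead"
STATUS_MISSING = "missing"
STATUS_NOT_YET_RECRUITED = "not_yet_recruited"
STATUSES = (STATUS_ALIVE, STATUS_DEAD, STATUS_MISSING, STATUS_NOT_YET_RECRUITED)
#: statuses of a tree that is physically alive
LIVE_STATUSES = (STATUS_ALIVE, STATUS_NOT_YET_RECRUITED)

MORTALITY_NONE = "none"
MORTALITY_CODES = ("standing_death", "primary_treefall", "secondary_treefall")

#: observation methods that can appear in a raw (field) archive
RAW_METHODS = ("tape", "relascope", "diameter_class")
#: provenance/method values that only a corrected archive may contain
CORRECTED_METHODS = ("carried_forward", "interpolated", "taper_converted",
                     "reborn_backfill", "manual_override")

DEFAULT_HOM_M = 1.50
MIN_HOM_M = 1.50
#: database recruitment threshold (dbh, cm); field threshold is 30 cm gbh
RECRUIT_DBH_CM = 10.0

TREATMENTS = ("control", "logging", "logging_thinning")
BLOCK_OF_PLOT = {11: "Boukoko1", 12: "Boukoko1", 13: "Boukoko1",
                 14: "Boukoko2", 15: "Boukoko2", 16: "Boukoko2",
                 21: "LaLole", 22: "LaLole", 23: "LaLole", 24: "LaLole"}

CSV_FILES = ("tree.csv", "taxonomy.csv", "vernacular.csv", "trees_context.csv",
             "measures.csv", "inventories.csv", "observation_codes.csv",
             "mortality_codes.csv")
GEOJSON_FILES = ("plots.geojson", "subplots.geojson")
ALL_FILES = CSV_FILES + GEOJSON_FILES

# data dictionary: table -> ordered columns
COLUMNS = {
    "tree": ["plot_no", "subplot_no", "tree_no", "x_m", "y_m",
             "vernacular_name", "taxon_id_1991", "taxon_id_2010",
             "taxon_id_2011"],
    "taxonomy": ["taxon_id", "sci_name", "valuable_code", "valuable_category"],
    "vernacular": ["vernacular_name", "taxon_id"],
    "trees_context": ["plot_no", "block", "treatment", "treatment_year"],
    "measures": ["plot_no", "subplot_no", "tree_no", "campaign_year",
                 "girth_cm", "dbh_cm", "hom_m", "method", "status",
                 "mortality_code", "observation_codes"],
    "inventories": ["campaign_year", "census_date", "notes"],
    "observation_codes": ["code", "description"],
    "mortality_codes": ["code", "description"],
}

_INT_COLS = {"plot_no", "subplot_no", "tree_no", "campaign_year",
             "treatment_year", "taxon_id", "taxon_id_1991", "taxon_id_2010",
             "taxon_id_2011"}
_FLOAT_FORMATS = {"x_m": "%.2f", "y_m": "%.2f", "girth_cm": "%.1f",
                  "dbh_cm": "%.1f", "hom_m": "%.2f"}

_SORT_KEYS = {
    "tree": ["plot_no", "subplot_no", "tree_no"],
    "taxonomy": ["taxon_id"],
    "vernacular": ["vernacular_name"],
    "trees_context": ["plot_no"],
    "measures": ["plot_no", "subplot_no", "tree_no", "campaign_year"],
    "inventories": ["campaign_year"],
    "observation_codes": ["code"],
    "mortality_codes": ["code"],
}


# --------------------------------------------------------------------------
# spatial frame
# --------------------------------------------------------------------------

# Local tangent-plane (equirectangular) affine linking each plot's 0-200 m
# frame to WGS84, anchored at the plot's (0;0) reference point, which is an
# attribute of every plot feature.  Metres per degree evaluated at the site
# latitude (~3.5 deg N).
M_PER_DEG_LAT = 110574.0
M_PER_DEG_LON = 111320.0 * math.cos(math.radians(3.5))


def local_to_wgs84(x_m, y_m, ref_lon: float, ref_lat: float):
    """Plot-frame metres -> (lon, lat)."""
    return (ref_lon + np.asarray(x_m, float) / M_PER_DEG_LON,
            ref_lat + np.asarray(y_m, float) / M_PER_DEG_LAT)


def wgs84_to_local(lon, lat, ref_lon: float, ref_lat: float):
    """(lon, lat) -> plot-frame metres."""
    return ((np.asarray(lon, float) - ref_lon) * M_PER_DEG_LON,
            (np.asarray(lat, float) - ref_lat) * M_PER_DEG_LAT)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Campaign:
    """One inventory campaign (nominal census date mid April-June window)."""

    campaign_year: int
    census_date: pd.Timestamp
    notes: str = ""

    def __post_init__(self):
        if self.campaign_year < FIRST_CAMPAIGN_YEAR:
            raise ValueError(f"campaign_year {self.campaign_year} predates "
                             f"the experiment ({FIRST_CAMPAIGN_YEAR})")


@dataclass
class PlotGeometry:
    """A 4-ha plot: closed WGS84 ring plus treatment attributes.

    ``ref_lon``/``ref_lat`` georeference the plot's local (0;0) corner
    (south-west); tree coordinates 0-200 m are relative to it.
    """

    plot_no: int
    treatment: str
    block: str
    ref_lon: float
    ref_lat: float
    coordinates: list  # GeoJSON Polygon coordinate array [[ [lon,lat], ... ]]
    area_ha: float = 4.0

    def local_ring(self) -> np.ndarray:
        ring = np.asarray(self.coordinates[0], dtype=float)
        x, y = wgs84_to_local(ring[:, 0], ring[:, 1], self.ref_lon, self.ref_lat)
        return np.column_stack([x, y])

    def area_m2(self) -> float:
        return Polygon(self.local_ring()).area


@dataclass
class SubplotGeometry:
    """A 1-ha subplot of a 4-ha plot (quadrant numbering documented)."""

    plot_no: int
    subplot_no: int
    ref_lon: float
    ref_lat: float
    coordinates: list
    area_ha: float = 1.0

    def local_ring(self) -> np.ndarray:
        ring = np.asarray(self.coordinates[0], dtype=float)
        x, y = wgs84_to_local(ring[:, 0], ring[:, 1], self.ref_lon, self.ref_lat)
        return np.column_stack([x, y])

    def area_m2(self) -> float:
        return Polygon(self.local_ring()).area


@dataclass
class CensusArchive:
    """In-memory relational model of one archive (eight tables, two layers)."""

    tree: pd.DataFrame
    taxonomy: pd.DataFrame
    vernacular: pd.DataFrame
    trees_context: pd.DataFrame
    measures: pd.DataFrame
    inventories: pd.DataFrame
    observation_codes: pd.DataFrame
    mortality_codes: pd.DataFrame
    plots: list = field(default_factory=list)      # list[PlotGeometry]
    subplots: list = field(default_factory=list)   # list[SubplotGeometry]

    @property
    def is_corrected(self) -> bool:
        """Corrected archives carry a provenance column in measures."""
        return "provenance" in self.measures.columns

    def campaigns(self) -> list[Campaign]:
        inv = self.inventories.sort_values("campaign_year")
        return [Campaign(int(r.campaign_year), pd.Timestamp(r.census_date),
                         r.notes if isinstance(r.notes, str) else "")
                for r in inv.itertuples()]

    def campaign_years(self) -> list[int]:
        return sorted(int(y) for y in self.inventories["campaign_year"])

    def decimal_dates(self) -> dict[int, float]:
        """campaign_year -> decimal census date, for annualized intervals."""
        return {int(r.campaign_year): decimal_year(r.census_date)
                for r in self.inventories.itertuples()}

    def copy(self) -> "CensusArchive":
        return CensusArchive(
            tree=self.tree.copy(), taxonomy=self.taxonomy.copy(),
            vernacular=self.vernacular.copy(),
            trees_context=self.trees_context.copy(),
            measures=self.measures.copy(), inventories=self.inventories.copy(),
            observation_codes=self.observation_codes.copy(),
            mortality_codes=self.mortality_codes.copy(),
            plots=[PlotGeometry(p.plot_no, p.treatment, p.block, p.ref_lon,
                                p.ref_lat, json.loads(json.dumps(p.coordinates)),
                                p.area_ha) for p in self.plots],
            subplots=[SubplotGeometry(s.plot_no, s.subplot_no, s.ref_lon,
                                      s.ref_lat,
                                      json.loads(json.dumps(s.coordinates)),
                                      s.area_ha) for s in self.subplots],
        )


# --------------------------------------------------------------------------
# errors / violations
# --------------------------------------------------------------------------

class SchemaError(Exception):
    """Archive does not conform to the file-set or column contract."""


class ReferentialIntegrityError(SchemaError):
    """A foreign key does not resolve; carries the offending rows."""

    def __init__(self, message: str, violations: list | None = None):
        super().__init__(message)
        self.violations = violations or []


@dataclass(frozen=True)
class Violation:
    """One integrity-rule violation (data, not an exception)."""

    table: str
    row_key: str
    rule_id: str
    detail: str


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def ascii_fold(text: str) -> str:
    """Strip accents so names can live in ASCII files (e.g. Azobé -> Azobe)."""
    return (unicodedata.normalize("NFKD", str(text))
            .encode("ascii", "ignore").decode("ascii"))


def _typed(df: pd.DataFrame, table: str) -> pd.DataFrame:
    """Convert a string frame read from CSV to the in-memory dtypes."""
    out = {}
    for col in df.columns:
        s = df[col]
        if col in _INT_COLS:
            if table == "tree" and col.startswith("taxon_id_"):
                # optional links may be empty
                out[col] = pd.to_numeric(
                    s.mask(s == "", np.nan)).astype("Int64")
            else:
                out[col] = pd.to_numeric(s).astype(np.int64)
        elif col in _FLOAT_FORMATS:
            out[col] = pd.to_numeric(s.mask(s == "", np.nan)).astype(float)
        elif col == "census_date":
            out[col] = pd.to_datetime(s, format="%Y-%m-%d")
        else:
            out[col] = s.astype(str)
    return pd.DataFrame(out, columns=list(df.columns))


def _formatted(df: pd.DataFrame, table: str) -> pd.DataFrame:
    """Render a typed frame to canonical strings for CSV emission."""
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        s = df[col]
        if col in _INT_COLS:
            out[col] = s.map(lambda v: "" if pd.isna(v) else str(int(v)))
        elif col in _FLOAT_FORMATS:
            fmt = _FLOAT_FORMATS[col]
            out[col] = s.map(lambda v, f=fmt: "" if pd.isna(v) else f % v)
        elif col == "census_date":
            out[col] = pd.to_datetime(s).dt.strftime("%Y-%m-%d")
        else:
            out[col] = s.fillna("").astype(str)
    return out


def _canonical_sort(df: pd.DataFrame, table: str) -> pd.DataFrame:
    keys = [k for k in _SORT_KEYS.get(table, []) if k in df.columns]
    if keys and len(df):
        return df.sort_values(keys, kind="mergesort").reset_index(drop=True)
    return df.reset_index(drop=True)


def _feature(geom, kind: str) -> dict:
    if kind == "plot":
        props = {"plot_no": int(geom.plot_no), "treatment": geom.treatment,
                 "block": geom.block, "area_ha": float(geom.area_ha),
                 "ref_lon": float(geom.ref_lon),
                 "ref_lat": float(geom.ref_lat)}
    else:
        props = {"plot_no": int(geom.plot_no),
                 "subplot_no": int(geom.subplot_no),
                 "area_ha": float(geom.area_ha),
                 "ref_lon": float(geom.ref_lon),
                 "ref_lat": float(geom.ref_lat)}
    return {"type": "Feature", "properties": props,
            "geometry": {"type": "Polygon", "coordinates": geom.coordinates}}


def _geojson_text(features: list[dict]) -> str:
    return json.dumps({"type": "FeatureCollection", "features": features},
                      indent=1) + "\n"


# --------------------------------------------------------------------------
# fixture
# --------------------------------------------------------------------------

def load_valuable_species_fixture() -> pd.DataFrame:
    """The 36 valuable timber species/complexes recognized at installation.

    Columns: species, valid_name, commercial_name, code (01-36),
    issongo_name, category (A: international market, 15 taxa; B: local
    market, 21 taxa).  All other taxa are category C by convention.
    """
    with resources.files("pspcensus.data").joinpath(
            "valuable_species.csv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, dtype=str, keep_default_na=False)
    if len(df) != 36:
        raise SchemaError(
            f"valuable-species fixture corrupted: expected 36 rows, "
            f"found {len(df)}")
    expected_cols = ["species", "valid_name", "commercial_name", "code",
                     "issongo_name", "category"]
    if list(df.columns) != expected_cols:
        raise SchemaError("valuable-species fixture corrupted: bad columns")
    if not set(df["category"]) <= {"A", "B"}:
        raise SchemaError("valuable-species fixture corrupted: bad category")
    if list(df["code"]) != [f"{i:02d}" for i in range(1, 37)]:
        raise SchemaError("valuable-species fixture corrupted: bad codes")
    return df


def valuable_category_of(sci_name: str) -> str:
    """Category A/B/C of a scientific name (fixture lookup, accent-insensitive)."""
    fixture = load_valuable_species_fixture()
    name = ascii_fold(sci_name).lower()
    for row in fixture.itertuples():
        if name in (ascii_fold(row.species).lower(),
                    ascii_fold(row.valid_name).lower()):
            return row.category
    return "C"


def default_code_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Default observation-code and mortality-code reference tables."""
    obs = pd.DataFrame({
        "code": ["IRR", "BUT", "TER", "LIA", "DAM", "BRK"],
        "description": [
            "irregular or deformed stem",
            "buttresses or aerial roots at measurement height",
            "termites present on the stem",
            "lianas on the stem",
            "mechanical damage",
            "broken crown or stem",
        ],
    })
    mort = pd.DataFrame({
        "code": list(MORTALITY_CODES),
        "description": [
            "tree died standing",
            "tree fell on its own",
            "tree knocked down by another falling tree",
        ],
    })
    return obs, mort


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def read_archive(directory: str | Path) -> CensusArchive:
    """Read the ten-file archive from ``directory``.

    Raises :class:`SchemaError` naming any missing file, and
    :class:`ReferentialIntegrityError` listing offending rows if a foreign
    key does not resolve.  Non-ASCII bytes trigger a warning (the release
    convention is ASCII).
    """
    directory = Path(directory)
    missing = [f for f in ALL_FILES if not (directory / f).exists()]
    if missing:
        raise SchemaError(f"archive at {directory} is missing required "
                          f"file(s): {', '.join(missing)}")

    for fname in ALL_FILES:
        raw = (directory / fname).read_bytes()
        try:
            raw.decode("ascii")
        except UnicodeDecodeError as exc:
            warnings.warn(f"{fname} contains non-ASCII bytes at offset "
                          f"{exc.start}; the release convention is ASCII")

    tables = {}
    for fname in CSV_FILES:
        table = fname[:-4]
        df = pd.read_csv(directory / fname, dtype=str, keep_default_na=False)
        expected = COLUMNS[table]
        got = list(df.columns)
        if table == "measures" and got == expected + ["provenance"]:
            pass
        elif got != expected:
            raise SchemaError(f"{fname}: expected columns {expected}, "
                              f"got {got}")
        tables[table] = _typed(df, table)

    plots, subplots = [], []
    for fname, kind in (("plots.geojson", "plot"),
                        ("subplots.geojson", "subplot")):
        fc = json.loads((directory / fname).read_text())
        if fc.get("type") != "FeatureCollection":
            raise SchemaError(f"{fname}: not a GeoJSON FeatureCollection")
        for feat in fc.get("features", []):
            props = feat["properties"]
            coords = feat["geometry"]["coordinates"]
            if kind == "plot":
                plots.append(PlotGeometry(
                    plot_no=int(props["plot_no"]),
                    treatment=str(props["treatment"]),
                    block=str(props["block"]),
                    ref_lon=float(props["ref_lon"]),
                    ref_lat=float(props["ref_lat"]),
                    coordinates=coords,
                    area_ha=float(props["area_ha"])))
            else:
                subplots.append(SubplotGeometry(
                    plot_no=int(props["plot_no"]),
                    subplot_no=int(props["subplot_no"]),
                    ref_lon=float(props["ref_lon"]),
                    ref_lat=float(props["ref_lat"]),
                    coordinates=coords,
                    area_ha=float(props["area_ha"])))

    archive = CensusArchive(
        tree=tables["tree"], taxonomy=tables["taxonomy"],
        vernacular=tables["vernacular"],
        trees_context=tables["trees_context"], measures=tables["measures"],
        inventories=tables["inventories"],
        observation_codes=tables["observation_codes"],
        mortality_codes=tables["mortality_codes"],
        plots=plots, subplots=subplots)

    fk = [v for v in validate_archive(archive)
          if v.rule_id.startswith("FK_") or v.rule_id == "DUPLICATE_KEY"]
    if fk:
        raise ReferentialIntegrityError(
            f"archive at {directory} has {len(fk)} referential-integrity "
            f"violation(s); first: {fk[0].table} {fk[0].row_key} "
            f"({fk[0].detail})", violations=fk)
    return archive


def write_archive(archive: CensusArchive, directory: str | Path) -> list[Path]:
    """Write the ten-file archive; returns the paths written.

    Emission is canonical (stable column order, sorted rows, fixed numeric
    formats), so ``write(read(write(a)))`` is byte-identical to
    ``write(a)``.  Non-ASCII content raises :class:`SchemaError`
    identifying the row and column.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    for fname in CSV_FILES:
        table = fname[:-4]
        df = getattr(archive, table)
        cols = list(COLUMNS[table])
        if table == "measures" and "provenance" in df.columns:
            cols = cols + ["provenance"]
        df = _canonical_sort(df[cols], table)
        text_df = _formatted(df, table)
        for col in cols:
            bad = text_df[col].map(lambda v: not v.isascii())
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaError(
                    f"{fname}: non-ASCII content in column '{col}', row {i}: "
                    f"{text_df[col].iloc[i]!r}")
        lines = [",".join(cols)]
        for row in text_df.itertuples(index=False):
            fields = ['"%s"' % v if ("," in v) else v for v in row]
            lines.append(",".join(fields))
        path = directory / fname
        path.write_text("\n".join(lines) + "\n", encoding="ascii")
        written.append(path)

    plot_feats = [_feature(p, "plot")
                  for p in sorted(archive.plots, key=lambda p: p.plot_no)]
    sub_feats = [_feature(s, "subplot")
                 for s in sorted(archive.subplots,
                                 key=lambda s: (s.plot_no, s.subplot_no))]
    for fname, feats in (("plots.geojson", plot_feats),
                         ("subplots.geojson", sub_feats)):
        text = _geojson_text(feats)
        if not text.isascii():
            raise SchemaError(f"{fname}: non-ASCII content")
        path = directory / fname
        path.write_text(text, encoding="ascii")
        written.append(path)
    return written


def archives_equal(a: CensusArchive, b: CensusArchive) -> bool:
    """Field-level relational equality (row order ignored)."""
    for table in (f[:-4] for f in CSV_FILES):
        da = _canonical_sort(getattr(a, table), table)
        db = _canonical_sort(getattr(b, table), table)
        if list(da.columns) != list(db.columns):
            return False
        if not _formatted(da, table).equals(_formatted(db, table)):
            return False
    if len(a.plots) != len(b.plots) or len(a.subplots) != len(b.subplots):
        return False
    for pa, pb in zip(sorted(a.plots, key=lambda p: p.plot_no),
                      sorted(b.plots, key=lambda p: p.plot_no)):
        if _feature(pa, "plot") != _feature(pb, "plot"):
            return False
    for sa, sb in zip(sorted(a.subplots, key=lambda s: (s.plot_no, s.subplot_no)),
                      sorted(b.subplots, key=lambda s: (s.plot_no, s.subplot_no))):
        if _feature(sa, "subplot") != _feature(sb, "subplot"):
            return False
    return True


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

def _tree_key(row) -> str:
    return f"{row.plot_no}-{row.subplot_no}-{row.tree_no}"


def validate_archive(archive: CensusArchive,
                     check_valuable_categories: bool = True) -> list[Violation]:
    """All integrity violations of ``archive`` (empty list = consistent).

    Violations are returned as data, never raised.  Rules cover uniqueness,
    foreign keys, coordinate and measurement ranges, status/mortality
    consistency, corrected-only provenance values, recruit thresholds in
    corrected archives, valuable-species category membership, and plot /
    subplot geometry areas (0.1 % tolerance on 4 ha and 1 ha).
    """
    v: list[Violation] = []
    tree, measures = archive.tree, archive.measures

    # -- uniqueness -------------------------------------------------------
    if len(tree):
        dup = tree.duplicated(subset=["plot_no", "subplot_no", "tree_no"])
        for row in tree[dup].itertuples():
            v.append(Violation("tree", _tree_key(row), "DUPLICATE_KEY",
                               "duplicate tree id"))
    if len(archive.inventories):
        dup = archive.inventories.duplicated(subset=["campaign_year"])
        for row in archive.inventories[dup].itertuples():
            v.append(Violation("inventories", str(row.campaign_year),
                               "DUPLICATE_KEY", "duplicate campaign year"))

    # -- foreign keys -----------------------------------------------------
    tree_ids = set(zip(tree["plot_no"], tree["subplot_no"], tree["tree_no"]))
    years = set(archive.inventories["campaign_year"])
    taxon_ids = set(archive.taxonomy["taxon_id"])
    vern_names = set(archive.vernacular["vernacular_name"])
    obs_codes = set(archive.observation_codes["code"])
    mort_codes = set(archive.mortality_codes["code"])
    plot_nos = set(archive.trees_context["plot_no"])

    for row in measures.itertuples():
        key = (row.plot_no, row.subplot_no, row.tree_no)
        if key not in tree_ids:
            v.append(Violation("measures",
                               f"{_tree_key(row)}@{row.campaign_year}",
                               "FK_MEASURE_TREE",
                               "measurement references unknown tree"))
        if row.campaign_year not in years:
            v.append(Violation("measures",
                               f"{_tree_key(row)}@{row.campaign_year}",
                               "FK_MEASURE_CAMPAIGN",
                               "measurement references unknown campaign"))
        if row.mortality_code != MORTALITY_NONE and \
                row.mortality_code not in mort_codes:
            v.append(Violation("measures",
                               f"{_tree_key(row)}@{row.campaign_year}",
                               "FK_MORTALITY_CODE",
                               f"unknown mortality code {row.mortality_code!r}"))
        if row.observation_codes:
            for code in str(row.observation_codes).split(";"):
                if code and code not in obs_codes:
                    v.append(Violation(
                        "measures", f"{_tree_key(row)}@{row.campaign_year}",
                        "FK_OBSERVATION_CODE",
                        f"unknown observation code {code!r}"))

    for row in tree.itertuples():
        if row.vernacular_name and row.vernacular_name not in vern_names:
            v.append(Violation("tree", _tree_key(row), "FK_TREE_VERNACULAR",
                               f"unknown vernacular {row.vernacular_name!r}"))
        for col in ("taxon_id_1991", "taxon_id_2010", "taxon_id_2011"):
            val = getattr(row, col)
            if pd.notna(val) and val not in taxon_ids:
                v.append(Violation("tree", _tree_key(row), "FK_TREE_TAXON",
                                   f"{col} -> unknown taxon {val}"))
        if row.plot_no not in plot_nos:
            v.append(Violation("tree", _tree_key(row), "FK_TREE_CONTEXT",
                               f"plot {row.plot_no} absent from trees_context"))

    for row in archive.vernacular.itertuples():
        if row.taxon_id not in taxon_ids:
            v.append(Violation("vernacular", str(row.vernacular_name),
                               "FK_VERNACULAR_TAXON",
                               f"unknown taxon {row.taxon_id}"))

    # -- field ranges and consistency --------------------------------------
    for row in tree.itertuples():
        if pd.notna(row.x_m) and not (0.0 <= row.x_m <= 200.0):
            v.append(Violation("tree", _tree_key(row), "COORD_RANGE",
                               f"x = {row.x_m} outside [0, 200] m"))
        if pd.notna(row.y_m) and not (0.0 <= row.y_m <= 200.0):
            v.append(Violation("tree", _tree_key(row), "COORD_RANGE",
                               f"y = {row.y_m} outside [0, 200] m"))

    corrected = archive.is_corrected
    for row in measures.itertuples():
        key = f"{_tree_key(row)}@{row.campaign_year}"
        if row.status not in STATUSES:
            v.append(Violation("measures", key, "UNAUTHORIZED_VALUE",
                               f"unknown status {row.status!r}"))
            continue
        dead = row.status == STATUS_DEAD
        if dead != (row.mortality_code != MORTALITY_NONE):
            v.append(Violation("measures", key, "MORTALITY_STATUS_MISMATCH",
                               f"status {row.status!r} with mortality code "
                               f"{row.mortality_code!r}"))
        if row.status == STATUS_ALIVE and pd.notna(row.dbh_cm) \
                and row.dbh_cm <= 0:
            v.append(Violation("measures", key, "DBH_NONPOSITIVE",
                               f"alive tree with dbh {row.dbh_cm}"))
        if pd.notna(row.hom_m) and row.hom_m < MIN_HOM_M:
            v.append(Violation("measures", key, "HOM_BELOW_MIN",
                               f"hom {row.hom_m} < {MIN_HOM_M} m"))
        if pd.notna(row.girth_cm) and \
                abs(row.girth_cm / 0.5 - round(row.girth_cm / 0.5)) > 1e-6:
            v.append(Violation("measures", key, "GIRTH_RESOLUTION",
                               f"girth {row.girth_cm} not a multiple of "
                               f"0.5 cm"))
        if not corrected and row.method in CORRECTED_METHODS:
            v.append(Violation("measures", key, "METHOD_CORRECTED_IN_RAW",
                               f"method {row.method!r} in a raw archive"))

    # -- recruits in corrected archives ------------------------------------
    if corrected and len(measures):
        alive = measures[(measures["status"] == STATUS_ALIVE)
                         & measures["dbh_cm"].notna()]
        if len(alive):
            first = alive.sort_values("campaign_year").groupby(
                ["plot_no", "subplot_no", "tree_no"], as_index=False).first()
            for row in first.itertuples():
                if row.dbh_cm < RECRUIT_DBH_CM:
                    v.append(Violation(
                        "measures", f"{_tree_key(row)}@{row.campaign_year}",
                        "RECRUIT_BELOW_THRESHOLD",
                        f"recruit below 10 cm dbh ({row.dbh_cm} cm); rows "
                        f"under threshold must be status "
                        f"'{STATUS_NOT_YET_RECRUITED}'"))

    # -- valuable-species categories ---------------------------------------
    if check_valuable_categories and len(archive.taxonomy):
        fixture = load_valuable_species_fixture()
        cat_by_name: dict[str, str] = {}
        for frow in fixture.itertuples():
            cat_by_name[ascii_fold(frow.species).lower()] = frow.category
            if frow.valid_name:
                cat_by_name[ascii_fold(frow.valid_name).lower()] = frow.category
        for row in archive.taxonomy.itertuples():
            expected = cat_by_name.get(ascii_fold(row.sci_name).lower(), "C")
            if row.valuable_category not in ("A", "B", "C"):
                v.append(Violation("taxonomy", str(row.taxon_id),
                                   "UNAUTHORIZED_VALUE",
                                   f"category {row.valuable_category!r}"))
            elif row.valuable_category != expected:
                v.append(Violation(
                    "taxonomy", str(row.taxon_id),
                    "VALUABLE_CATEGORY_MISMATCH",
                    f"{row.sci_name}: category {row.valuable_category!r}, "
                    f"fixture says {expected!r}"))

    # -- geometry -----------------------------------------------------------
    for p in archive.plots:
        area = p.area_m2()
        if abs(area - 40000.0) > 0.001 * 40000.0:
            v.append(Violation("plots.geojson", str(p.plot_no), "PLOT_AREA",
                               f"plot polygon area {area:.1f} m2, expected "
                               f"40000 within 0.1%"))
        expected_block = BLOCK_OF_PLOT.get(p.plot_no)
        if expected_block is not None and p.block != expected_block:
            v.append(Violation("plots.geojson", str(p.plot_no),
                               "PLOT_BLOCK_MISMATCH",
                               f"plot {p.plot_no} assigned block {p.block!r}, "
                               f"expected {expected_block!r}"))
        if p.treatment not in TREATMENTS:
            v.append(Violation("plots.geojson", str(p.plot_no),
                               "UNAUTHORIZED_VALUE",
                               f"treatment {p.treatment!r}"))
    for s in archive.subplots:
        area = s.area_m2()
        if abs(area - 10000.0) > 0.001 * 10000.0:
            v.append(Violation("subplots.geojson",
                               f"{s.plot_no}-{s.subplot_no}", "SUBPLOT_AREA",
                               f"subplot polygon area {area:.1f} m2, "
                               f"expected 10000 within 0.1%"))
    return v
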