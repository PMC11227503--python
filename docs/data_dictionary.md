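# Data dictionary

Column names, types and codes of the ten-file archive written and read by
`pspcensus`. The *file set* (eight CSV tables, two GeoJSON layers) and
the relational structure follow the released-archive convention; the
column names and types below are this package's own documented
convention, since no public column dictionary is reproduced here.

Conventions: comma separation, ASCII, header row, no quoting unless a
field contains a comma; missing values are empty strings, never sentinel
numbers; dates are ISO `YYYY-MM-DD`; writers sort rows by primary key and
format numbers at fixed resolution, so write → read → write is
byte-identical.

## tree.csv — one row per tree

| column | type | notes |
|---|---|---|
| plot_no | int | 4-ha plot: 11–13 Boukoko1, 14–16 Boukoko2, 21–24 LaLole |
| subplot_no | int | 1-ha subplot 1–4 (1 SW, 2 SE, 3 NW, 4 NE) |
| tree_no | int | number within the subplot; (plot, subplot, tree) is the key |
| x_m, y_m | float (0.01) | metres from the plot's (0;0) SW reference point, 0–200 |
| vernacular_name | text | Issongo name; FK → vernacular.csv |
| taxon_id_1991 | int, nullable | identification campaign links; FK → taxonomy.csv |
| taxon_id_2010 | int, nullable | |
| taxon_id_2011 | int, nullable | |

## taxonomy.csv

| column | type | notes |
|---|---|---|
| taxon_id | int | primary key |
| sci_name | text | binomial (ASCII-folded) |
| valuable_code | text | 01–36 for the valuable timber list, else empty |
| valuable_category | text | A (international market), B (local), C (other) |

## vernacular.csv

| column | type | notes |
|---|---|---|
| vernacular_name | text | primary key |
| taxon_id | int | FK → taxonomy.csv |

## trees_context.csv — per-plot treatment metadata

| column | type | notes |
|---|---|---|
| plot_no | int | primary key |
| block | text | Boukoko1 / Boukoko2 / LaLole |
| treatment | text | control / logging / logging_thinning |
| treatment_year | int | year treatments were applied (1986) |

## measures.csv — one row per tree and campaign

| column | type | notes |
|---|---|---|
| plot_no, subplot_no, tree_no | int | FK → tree.csv |
| campaign_year | int | FK → inventories.csv |
| girth_cm | float (0.1) | field girth, multiple of 0.5 cm; empty for classes |
| dbh_cm | float (0.1) | gbh/π rounded half-up, or class midpoint |
| hom_m | float (0.01) | height of measurement, ≥ 1.50 |
| method | text | tape / relascope / diameter_class (raw archives) |
| status | text | alive / dead / missing / not_yet_recruited |
| mortality_code | text | none, or FK → mortality_codes.csv (iff dead) |
| observation_codes | text | `;`-separated, FK → observation_codes.csv |
| provenance | text | **corrected archives only**: raw / taper_converted / interpolated / carried_forward / reborn_backfill / manual_override |

## inventories.csv

| column | type | notes |
|---|---|---|
| campaign_year | int | primary key; default calendar 1982–2022 minus {1997, 1999, 2001, 2013, 2014, 2016} |
| census_date | date | nominal 15 May (April–June campaign midpoint) |
| notes | text | free text |

## observation_codes.csv / mortality_codes.csv

`code`, `description`. Default observation codes: IRR (irregular stem),
BUT (buttresses/aerial roots), TER (termites), LIA (lianas), DAM
(damage), BRK (broken). Mortality codes: standing_death,
primary_treefall, secondary_treefall.

## plots.geojson / subplots.geojson

RFC 7946 FeatureCollections, WGS84 polygons. Plot features carry
`plot_no`, `treatment`, `block`, `area_ha` (4.0), `ref_lon`, `ref_lat`;
subplot features carry `plot_no`, `subplot_no`, `area_ha` (1.0) and the
same reference point. `ref_lon/ref_lat` georeference the plot's local
(0;0) corner; the local 0–200 m frame maps to WGS84 by the documented
equirectangular affine (`schema.local_to_wgs84`, fixed metres-per-degree
at the site latitude). Validation inverts the affine and checks polygon
areas to 0.1 %.

## Override sidecar (input to `correct`)

`plot_no, subplot_no, tree_no, campaign_year, dbh_cm, note` — an
expert-provided equivalent diameter at the original hom, applied before
the automated procedures re-run.

## groundtruth.csv (simulator output, not part of the archive)

Per tree: `entry_year`, `recruit_true_year` (first census with true
dbh ≥ 10), `death_year` (−1 if alive), `mortality_cause`, `hom_final_m`,
`girth_multiplier` (product of true taper factors).
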