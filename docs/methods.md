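# Methods

This note documents the models and conventions implemented in
`pspcensus`, the reasoning behind the open design choices, and what the
synthetic-data experiments do and do not demonstrate.

## The observation model

A permanent-sample-plot census records, per tree and campaign, the girth
(circumference) at the height of measurement (hom, default 1.50 m, never
below). Field girth is read off an ordinary tape and rounded to 0.5 cm;
the database quantity is the diameter dbh = gbh/π rounded to 0.1 cm.
Rounding is half-up at both resolutions, implemented as a single shared
utility (`measurement.round_half_up`): field sheets round ties up, and
keeping one implementation makes the convention changeable in one place.
The utility computes `floor(x/step + 0.5 + 1e-9)`; the 1e-9 guard absorbs
binary representation error (0.25/0.1 is 2.4999999999999996 in floats) so
decimal half-up semantics hold exactly at field resolutions — verified
against `decimal.Decimal` `ROUND_HALF_UP` in the test suite.

Historical special cases are carried by the `method` column: 10-cm
diameter classes for girth > 250 cm before 1991 (the package stores the
class midpoint — unbiased under a uniform within-class distribution; the
alternative, storing the lower bound, would bias basal area low by ~5 cm
of diameter per class tree), and five-yearly relascope measurements whose
values are carried forward to intermediate campaigns.

## Quality screening

Screening compares each campaign with the archive's history and returns
typed flags; it never modifies data. Rules and defaults:

| rule | threshold / condition | severity |
|---|---|---|
| EXCESS_GROWTH | Δd/Δt > 2.0 cm yr⁻¹ (strict) | review |
| EXCESS_DECLINE | Δd/Δt < −0.6 cm yr⁻¹ (strict) | review |
| REBORN | alive now, last known status dead | block |
| RECRUIT_UNDER_10 | first record with dbh < 10 cm | review |
| HOM_RAISE_INCREASE | dbh and hom both increased | review |
| MISSING_DATA | expected alive, no measurement | review |
| UNAUTHORIZED_VALUE | dbh ≤ 0, hom < 1.50 m | block |

Increments are annualized over the decimal-year interval between census
dates (nominal census date 15 May, midpoint of the April–June campaign
window), so a 4.5 cm increase over a three-year census gap is a
legitimate 1.5 cm yr⁻¹. The previous value is the most recent earlier
*measured* diameter, so the checks bridge campaigns a tree was missing
from. Severity models the human triage step: only clear data corruption
(impossible values, re-born trees) blocks integration, while growth
anomalies and sub-threshold recruits go back to the field crew — the
field protocol legitimately produces 9.5–9.9 cm entries (the 30 cm gbh
field threshold), so flagging them as blocking would stop every normal
campaign.

## Series correction

Corrections derive an analysis-ready series per tree; raw data are never
overwritten (corrected archives add a `provenance` column instead).

**Taper conversion.** At a hom raise first measured at campaign *t*, the
ratio r = d_t(hom′)/d_{t−1}(hom) converts measurements from the raise
onward into equivalents at the original hom. Successive raises chain
multiplicatively: the divisor at a campaign is the product of the ratios
of all raises at or before it, computed from raw values so intermediate
re-rounding never compounds. At the raise campaign itself the corrected
value is d_t/r = d_{t−1} exactly — zero apparent increment at the raise
year. The alternative (leaving campaign *t* at its raised-hom value and
converting only from *t*+1) would leave a visible step in every corrected
series; continuity was chosen and is asserted by a test.

**Gap filling.** Maximal runs of missing values between valid
measurements d_a and d_b are resolved by the increment sign: if
d_b > d_a, linear interpolation in decimal time (campaign indices would
mis-weight the skipped census years); if d_b < d_a with a hom raise in
the gap, the taper procedure between the flanking values (r = d_b/d_a,
making the converted d_b equal d_a); if d_b < d_a without a raise, d_a is
carried forward onto the gap *and onto d_b*; if d_b = d_a (a case the
increment-sign dichotomy leaves open), constant fill. Leading and
trailing runs have no flanking pair and stay unfilled. Derived values are
re-rounded to 0.1 cm for schema uniformity.

**Re-born back-fill.** A dead run followed by a live record is an
observation error: the presumed-dead campaigns receive the diameter
recorded at the re-born date, statuses return to alive and the mortality
code is cleared. A re-born tree never measured again is an error, not a
guess.

**Pipeline.** Overrides (an expert-provided sidecar CSV of tree,
campaign, dbh) → re-born back-fill → taper detection/conversion → gap
filling, iterated until no raise remains, so overrides that change
flanking values re-trigger the automated procedures. The pipeline is
idempotent (re-correcting a corrected archive is the identity), which is
what makes "corrected" a well-defined archive state.

In corrected archives, live rows before a tree's first campaign at
dbh ≥ 10 cm carry status `not_yet_recruited`; a tree whose first *alive*
row is below 10 cm is an integrity violation. This separates the field
population (≥ 30 cm gbh) from the analysis population (≥ 10 cm dbh)
by status alone.

## Dynamics

Per unit (4-ha plot or 1-ha subplot) and campaign: N = live recruited
trees per hectare and G = Σ π(dbh/200)² per hectare (dbh in cm gives G in
m² ha⁻¹). A tree is recruited from its first campaign at or above the
threshold (default 10.0 cm; 9.5 reproduces field-threshold analyses) and
stays recruited even if a later recorded diameter dips below it —
otherwise rounding noise at the threshold would create phantom exits.

Rates are annualized with the survival-fraction power form
(mortality = (1 − (S/N₀)^(1/Δt))·100, recruitment analogous on the end
population), the standard exponential-equivalent per-capita rate for
multi-year census gaps; it reduces to D/N₀ for Δt = 1. A
`method="simple"` switch provides D/(N₀Δt) for comparison; neither is
claimed to be the estimator behind any particular published figure.
Undefined cases (N₀ = 0 or N_b = 0) report NaN, never 0. Trees that die
before ever reaching the threshold count in neither rate; corrected
re-born trees count as continuously alive and inflate neither.

## The synthetic generator

The generator emulates the study conditions, not a particular forest:
annual population steps (lognormal dbh increments, mean 0.25 cm yr⁻¹ and
sd 0.20 — the right order for closed-canopy tropical stands and heavy
tailed enough to exercise the growth screens; Bernoulli mortality and
Poisson recruitment at 1 % yr⁻¹ each, the standard turnover regime of
undisturbed tropical forest; initial stand a truncated exponential over
dbh ≥ 9.5 cm with 12 cm scale, the classic reverse-J structure, at 520
stems ha⁻¹) and a census-time observation layer (girth computation with
0.1 cm Gaussian diameter noise and 0.5 cm field rounding; hom raises at
0.4 % per tree-year with a multiplicative taper factor uniform in
0.85–0.95; 1 % missing records, half as empty rows and half as absent
rows; 0.2 % false-dead episodes of one or two campaigns; pre-1991
diameter classes; optional disturbance events removing a target fraction
of basal area). Mortality causes default to 0.5/0.3/0.2 across standing
death and primary/secondary treefall — the three recorded causes, with
arbitrary but configurable weights. Everything the observation layer
hides is logged (`GroundTruthLog`), which is what makes the generator an
oracle: QC tests compare flags to the injection log, correction tests
compare corrected series to true trajectories, dynamics tests compare
estimated to configured rates.

What the generator does **not** emulate: competition, spatial clustering
(coordinates are uniform within subplots), species-specific demography,
climate forcing, observer drift, or identification errors. Passing tests
therefore demonstrate that the pipeline implements its rules correctly
and recovers known parameters under its own observation model — not that
the rules are sufficient for any particular real archive.

## Validation experiments and problem sizes

* **QC round trip** — one 4-ha stand at 520 stems ha⁻¹ (~2900 trees,
  ~75 000 rows), 200 injected anomalies across all six injectable rules;
  recall and precision are baseline-differenced so natural flags count
  neither way. Both are 1.0 by construction of the injections (each
  engineered to trigger exactly one new flag on a distinct tree).
* **Correction idempotence** — one stand with a raised hom-raise rate
  (1 % per tree-year), ~1400 trees; the corrected archive equals its own
  re-correction frame-for-frame.
* **Rate recovery** — 100 independent 12-ha stands (three 4-ha plots,
  ~6200 trees each) over the default 35-campaign calendar, with
  missing-record, false-dead and hom-raise processes off (rounding and
  measurement noise on): this isolates estimator bias from
  correction-pipeline behaviour. Mean absolute bias is ~0.01 percentage
  point for mortality and ~0.03 for recruitment; the small positive
  recruitment bias is a real transient — the initial exponential stand
  slightly overfills the 9.5–10 cm band relative to flow equilibrium, so
  the first few intervals recruit above 1 %/yr.

These sizes keep the full suite under ~2 minutes on one CPU while leaving
Monte-Carlo error well below the tolerances tested.

## Known limitations

* The taper ratio treats stem taper as constant in time; a tree whose
  form changes after the raise keeps the original ratio.
* Leading/trailing gaps are reported, never imputed.
* The equirectangular WGS84 affine (feature-attribute reference point,
  fixed metres-per-degree at the site latitude) is adequate at the 200 m
  plot scale (< 0.01 % area error) but is not a projected CRS; consumers
  needing survey-grade coordinates should re-project from the reference
  points.
* `screen_campaign` recomputes history per call; use `screen_archive`
  (single sweep) for whole-archive screening.
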