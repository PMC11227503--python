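"""Girth/diameter observation model.

Field crews measure tree girth (circumference) at the height of measurement
(hom, default 1.50 m) with an ordinary tape and round to 0.5 cm.  The
database stores the diameter at breast height dbh = gbh / pi, rounded to
0.1 cm.  Two historical exceptions exist for very large trees:

* 1982-1990, girth > 250 cm: not measured, assigned to a 10 cm wide
  diameter class (the midpoint is this package's stored value);
* trees too irregular to tape even at 4.50 m: measured with a Bitterlich
  relascope every five years, the value being carried forward to the
  intermediate campaigns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FIELD_GIRTH_RESOLUTION_CM",
    "DB_DBH_RESOLUTION_CM",
    "round_half_up",
    "gbh_to_dbh",
    "dbh_to_gbh",
    "DiameterClass",
    "class_to_dbh",
    "dbh_to_class",
    "carry_forward_relascope",
]

#: field tape resolution for girth, cm
FIELD_GIRTH_RESOLUTION_CM = 0.5
#: database resolution for diameter, cm
DB_DBH_RESOLUTION_CM = 0.1

# Guard absorbing binary float representation error so that decimal values
# sitting exactly on a half-step (e.g. 0.25 at step 0.1) round up, matching
# field-sheet convention.  Large enough to fix representation error, far
# smaller than any physically distinguishable girth difference.
_HALF_UP_GUARD = 1e-9


def round_half_up(x, step):
    """Round ``x`` to the nearest multiple of ``step``, ties away from zero.

    This is the single rounding convention of the package (field girth at
    0.5 cm, database dbh at 0.1 cm).  Works on scalars and numpy arrays.
    """
    x = np.asarray(x, dtype=float)
    step = float(step)
    out = np.floor(x / step + 0.5 + _HALF_UP_GUARD) * step
    # re-quantize to kill 3.0000000000000004-style noise from the product
    decimals = max(0, int(np.ceil(-np.log10(step))) + 1)
    out = np.round(out, decimals)
    if out.ndim == 0:
        return float(out)
    return out


def gbh_to_dbh(girth_cm):
    """Convert girth at breast height (cm) to dbh (cm) at 0.1 cm resolution.

    dbh = gbh / pi rounded half-up; 30.0 cm gbh -> 9.5 cm dbh.
    """
    g = np.asarray(girth_cm, dtype=float)
    if np.any(g < 0):
        raise ValueError("girth must be non-negative")
    return round_half_up(g / np.pi, DB_DBH_RESOLUTION_CM)


def dbh_to_gbh(dbh_cm):
    """Convert dbh (cm) to the girth a tape would record, at 0.5 cm resolution."""
    d = np.asarray(dbh_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("dbh must be non-negative")
    return round_half_up(d * np.pi, FIELD_GIRTH_RESOLUTION_CM)


@dataclass(frozen=True)
class DiameterClass:
    """A 10 cm wide diameter class used for girth > 250 cm trees, 1982-1990."""

    lower_cm: float
    upper_cm: float

    def __post_init__(self):
        if not self.upper_cm - self.lower_cm == 10.0:
            raise ValueError(
                f"diameter class must be 10 cm wide, got "
                f"[{self.lower_cm}, {self.upper_cm})"
            )
        if self.lower_cm < 0:
            raise ValueError("class bounds must be non-negative")

    @property
    def midpoint_cm(self) -> float:
        return (self.lower_cm + self.upper_cm) / 2.0


def class_to_dbh(diameter_class: DiameterClass) -> float:
    """Stored dbh for a class-assigned tree: the class midpoint.

    Unbiased if true diameters are uniform within the class; the error is
    bounded by half the class width (5 cm).
    """
    return diameter_class.midpoint_cm


def dbh_to_class(dbh_cm: float) -> DiameterClass:
    """Assign a diameter to its 10 cm class [10k, 10k+10)."""
    if dbh_cm < 0:
        raise ValueError("dbh must be non-negative")
    lower = float(np.floor(dbh_cm / 10.0) * 10.0)
    return DiameterClass(lower, lower + 10.0)


def carry_forward_relascope(series: pd.DataFrame) -> pd.DataFrame:
    """Fill campaigns between five-yearly relascope readings.

    ``series`` is a per-tree measurement frame (one row per campaign,
    chronological, columns including ``campaign_year``, ``dbh_cm``,
    ``method``).  Campaigns after a relascope reading and before the next
    measurement receive the last relascope value with
    ``method = "carried_forward"``.  Rows already holding a measurement are
    never touched.
    """
    out = series.copy()
    last_val = None
    last_hom = None
    for i in out.index:
        method = out.at[i, "method"]
        has_value = pd.notna(out.at[i, "dbh_cm"])
        if has_value:
            if method == "relascope":
                last_val = out.at[i, "dbh_cm"]
                last_hom = out.at[i, "hom_m"]
            else:
                last_val = None
        elif last_val is not None and out.at[i, "status"] in (
            "alive",
            "not_yet_recruited",
        ):
            out.at[i, "dbh_cm"] = last_val
            if pd.isna(out.at[i, "hom_m"]):
                out.at[i, "hom_m"] = last_hom
            out.at[i, "method"] = "carried_forward"
    return out
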