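"""Published reference tables from the original albumin-extended MELD study.

These are the printed results of the derivation study (UNOS waiting-list
registrants, 2002-2007; validation cohort with complete sodium, n = 15,114):
the 90-day risk reclassification table comparing MELD with 5vMELD, the
cross-tabulation of score bands among the 1,113 validation-cohort decedents,
and the observed 90-day transplant probabilities by MELD band.  They serve as
fixed inputs for reproducing the study's reclassification and deaths-averted
arithmetic; they are not outputs of this package.
"""

from __future__ import annotations

import numpy as np

from .counterfactual import BandSpec, DeathCrossTab
from .reclassification import ReclassTable, RiskStrata

__all__ = [
    "reclass_table_meld_vs_5vmeld",
    "death_crosstab_meld_vs_5vmeld",
    "validation_band_probs",
]

# --- 90-day risk reclassification, MELD (rows) vs 5vMELD (columns) ----------
# strata: 0-<5%, 5-<10%, 10-<20%, >=20%

_T3_PERSONS = np.array(
    [
        [7085, 447, 112, 3],
        [1550, 1144, 507, 99],
        [80, 458, 695, 418],
        [0, 26, 224, 2266],
    ]
)
_T3_DEATHS = np.array(
    [
        [105, 23, 15, 0],
        [26, 50, 46, 16],
        [5, 27, 77, 74],
        [0, 4, 32, 613],
    ]
)
_T3_SURVIVORS = np.array(
    [
        [6642, 389, 74, 1],
        [1287, 850, 313, 40],
        [60, 294, 359, 138],
        [0, 11, 84, 260],
    ]
)
# KM observed 90-day mortality per cell (percent in the source; fractions here)
_T3_OBSERVED = np.array(
    [
        [0.015, 0.054, 0.155, 0.0],
        [0.019, 0.050, 0.110, 0.221],
        [0.065, 0.071, 0.143, 0.269],
        [np.nan, 0.225, 0.210, 0.521],
    ]
)


def reclass_table_meld_vs_5vmeld() -> ReclassTable:
    """The published MELD vs 5vMELD reclassification table as a ReclassTable."""
    table = ReclassTable.from_counts(
        _T3_PERSONS, _T3_DEATHS, _T3_SURVIVORS, strata=RiskStrata(), min_cell=20
    )
    table.km = _T3_OBSERVED.copy()
    return table


# --- score-band cross-tabulation of validation-cohort decedents -------------

_T4_COUNTS = np.array(
    [
        [6, 24, 5, 0, 0],
        [0, 62, 216, 3, 0],
        [0, 0, 226, 166, 0],
        [0, 0, 0, 253, 0],
        [0, 0, 0, 0, 152],
    ]
)


def validation_band_probs() -> BandSpec:
    """Observed 90-day transplant probabilities by MELD band (validation cohort)."""
    return BandSpec(
        edges=(10, 20, 30, 40),
        probs={"<10": 0.030, "10-19": 0.114, "20-29": 0.469, "30-39": 0.613, "40": None},
    )


def death_crosstab_meld_vs_5vmeld() -> DeathCrossTab:
    """MELD (rows) vs 5vMELD (columns) band counts among the 1,113 decedents."""
    return DeathCrossTab(counts=_T4_COUNTS.copy(), bands=validation_band_probs())
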