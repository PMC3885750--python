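"""Congener and season bookkeeping shared across modules.

The 16 USEPA priority PAH congeners are carried everywhere in a fixed order,
from naphthalene (Nap) through benzo[g,h,i]perylene (BghiP).  All per-congener
arrays in the package are aligned to :data:`CONGENERS`; all per-season arrays
to :data:`SEASONS`.
"""

from __future__ import annotations

CONGENERS: tuple[str, ...] = (
    "Nap", "Acy", "Ace", "Fluo", "Phe", "Ant", "Flu", "Pyr",
    "Chry", "BaA", "BbF", "BkF", "BaP", "DBA", "IP", "BghiP",
)
N_CONGENERS: int = len(CONGENERS)

SEASONS: tuple[str, ...] = ("spring", "summer", "autumn", "winter")
N_SEASONS: int = len(SEASONS)

#: equal seasonal weighting of the year
DAYS_PER_SEASON: float = 365.0 / 4.0

HOURS_PER_DAY: float = 24.0

#: microenvironments of the time-activity budget
MICROENVS: tuple[str, ...] = ("home", "work", "outdoor")

#: exposure-pattern labels: source of the pollutant (IN/OUT) x place of
#: exposure (in/out); IN-out is not modelled.
PATTERNS: tuple[str, ...] = ("IN_in", "OUT_in", "OUT_out")

REGIONS: tuple[str, ...] = ("urban", "rural")
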