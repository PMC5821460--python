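"""Calibrated default parameters shared across the package.

All values trace to published single-cell measurements of LINE-1 (L1)
protein dynamics in HeLa/HCT116 cells:

* the HeLa doubling time (~24 h) anchors the exponential-growth age
  structure of an asynchronous culture;
* the asynchronous propidium-iodide phase distribution
  (G1 = 49.5%, S = 34.2%, G2/M = 15.2%) is inverted into default phase
  durations;
* fast fluorescent-timer (fast-FT) maturation: mean blue-to-red
  conversion time 2.35 h, giving the first-order maturation rate
  ``K_MAT = ln 2 / 2.35``;
* reporter expression onset after induction: 50% of cells visibly
  fluorescent at 2.71 h and 90% at 8.01 h, matched by a lognormal delay.

The printed phase percentages do not sum exactly to 100 (rounding in the
source); they are renormalized proportionally here.
"""

from __future__ import annotations

import math

#: HeLa doubling time, hours.
DOUBLING_TIME_H: float = 24.0

#: DNA-content scale: arbitrary-units value assigned to 2N (G1) DNA content.
DNA_2N: float = 100.0

#: Coefficient of variation of the DNA-content (PI / SYTO61) signal.
DNA_CV: float = 0.05


def _norm(triple: tuple[float, float, float]) -> tuple[float, float, float]:
    s = sum(triple)
    return (triple[0] / s, triple[1] / s, triple[2] / s)


#: Asynchronous (blue-negative) phase fractions (G1, S, G2/M), renormalized.
ASYNC_FRACTIONS: tuple[float, float, float] = _norm((49.5, 34.2, 15.2))

#: Blue-positive / red-low population phase fractions (recent events).
BLUE_RED_LOW_FRACTIONS: tuple[float, float, float] = _norm((9.38, 78.1, 12.5))

#: Blue-positive / red-high population phase fractions (older events).
BLUE_RED_HIGH_FRACTIONS: tuple[float, float, float] = _norm((0.0, 10.9, 89.1))

#: Mean blue-to-red conversion time of the fast fluorescent timer, hours.
CONVERSION_TIME_H: float = 2.35

#: First-order maturation rate (1/h) so that the half-rise of the red signal
#: for a fixed blue pool occurs at CONVERSION_TIME_H.
K_MAT: float = math.log(2.0) / CONVERSION_TIME_H

#: Reporter-onset quantiles after transcriptional induction, hours.
ONSET_T50_H: float = 2.71
ONSET_T90_H: float = 8.01

# Lognormal onset-delay law matched to the two quantiles above:
# median = t50 and 90th percentile = t90.
_Z90 = 1.2815515655446004  # standard-normal 90% quantile
ONSET_MU: float = math.log(ONSET_T50_H)
ONSET_SIGMA: float = math.log(ONSET_T90_H / ONSET_T50_H) / _Z90

#: Daughter-cell pair separation (µm): mean ± sd of the post-mitotic
#: two-cell clusters the proximity analysis is designed to detect.
PAIR_SEP_MEAN_UM: float = 15.0
PAIR_SEP_SD_UM: float = 5.0

#: Number of permutations in the proximity resampling null.
N_PERM: int = 1000

#: Raw-p selection threshold for "significantly close" nuclear cells.
SELECTION_P: float = 0.1
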