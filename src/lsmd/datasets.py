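"""Reference per-case lobe volume measurements (11-subject canine study).

Volumes in cc, measured on CT at two bronchial pressures: inflated (14 cm
H2O) and deflated (2 cm H2O), for the upper and lower lobes of the left
lung.  ``r`` columns are the deflated/inflated volume ratios in percent.
These printed values back the table-summary checks (mean and sample SD).
"""

from __future__ import annotations

import numpy as np

CASE_IDS = list(range(1, 12))

UPPER_INFLATED_CC = np.array(
    [173.5, 167.1, 231.7, 184.7, 246.1, 188.4, 131.9, 164.3, 198.8, 232.5,
     163.7])
UPPER_DEFLATED_CC = np.array(
    [82.7, 69.9, 111.4, 71.4, 78.9, 65.8, 55.8, 102.3, 84.9, 113.5, 160.2])
UPPER_RATIO_PCT = np.array(
    [47.7, 41.8, 48.1, 38.7, 32.5, 34.9, 42.3, 62.2, 42.7, 48.8, 97.9])
LOWER_INFLATED_CC = np.array(
    [242.9, 508.3, 357.6, 258.2, 353.3, 373.2, 257.9, 342.1, 375.4, 355.7,
     212.1])
LOWER_DEFLATED_CC = np.array(
    [96.9, 116.4, 145.3, 100.4, 92.8, 104.1, 110.7, 196.7, 111.8, 186.4,
     236.6])
LOWER_RATIO_PCT = np.array(
    [39.9, 22.9, 40.6, 38.9, 26.3, 27.9, 42.9, 57.5, 29.8, 52.4, 111.5])

# case 11's deflated volumes exceed expectations (pressure-control failure
# during acquisition); deformation-linearity analyses typically exclude it
DEFAULT_EXCLUDED_CASES = [11]
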