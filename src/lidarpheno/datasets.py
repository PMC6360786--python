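"""Bundled reference tables.

`reference_stage_summary` returns the published six-stage summary
statistics (min/max/avg/std of plant height, PAI and PLA for all
individuals of a 20-variety terrestrial-lidar drought campaign).  They
are used as fixed inputs to the ratio report and in regression tests.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # stage, phenotype, min, max, avg, std
    ("D20", "height_m", 0.41, 0.70, 0.55, 0.09),
    ("D35", "height_m", 0.67, 1.32, 1.00, 0.16),
    ("D45", "height_m", 1.20, 1.83, 1.42, 0.17),
    ("D60", "height_m", 1.34, 2.35, 1.80, 0.28),
    ("D70", "height_m", 1.31, 2.28, 1.76, 0.28),
    ("D95", "height_m", 1.26, 2.08, 1.66, 0.27),
    ("D20", "pai", 0.24, 1.31, 0.65, 0.29),
    ("D35", "pai", 0.68, 2.00, 1.18, 0.36),
    ("D45", "pai", 0.82, 2.85, 1.60, 0.52),
    ("D60", "pai", 1.04, 4.02, 2.09, 0.62),
    ("D70", "pai", 0.31, 2.85, 1.70, 0.82),
    ("D95", "pai", 0.29, 2.66, 1.26, 0.64),
    ("D20", "pla", 0.09, 0.18, 0.13, 0.03),
    ("D35", "pla", 0.14, 0.19, 0.17, 0.02),
    ("D45", "pla", 0.16, 0.21, 0.18, 0.01),
    ("D60", "pla", 0.16, 0.23, 0.20, 0.02),
    ("D70", "pla", 0.12, 0.20, 0.18, 0.03),
    ("D95", "pla", 0.11, 0.19, 0.16, 0.03),
]

GROUP_MEAN_YIELD_REDUCTION = {"L1": 0.85, "L2": 0.48, "L3": 0.27}
GROUP_SIZES = {"L1": 9, "L2": 5, "L3": 3}


def reference_stage_summary() -> pd.DataFrame:
    """Published stage-summary statistics as a tidy DataFrame."""
    return pd.DataFrame(
        _ROWS, columns=["stage", "phenotype", "min", "max", "avg", "std"])
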