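"""Published cohort summary statistics used as calibration targets.

These are group-level means and standard deviations (computed over
per-fish means) from a two-treatment study of cooked catfish fillets:
60 individually-quick-frozen (IQF, phosphate-treated) fish and 34
fresh-frozen (FF) fish, eight instrumented test points per fillet and a
trained descriptive sensory panel scoring seven texture attributes on a
0-15 intensity scale.

The instrumental (TPA) table is the calibration target for the
synthetic cohort generator, and both tables serve as worked-example
inputs for the residual lines and prediction equations shipped in
:mod:`tpafish.residuals` and :mod:`tpafish.sensory`.
"""

from __future__ import annotations

import pandas as pd

GROUP_SIZES = {"iqf": 60, "fresh_frozen": 34}

#: per-fish-mean summary of the instrumental attributes
#: columns: attribute, iqf_mean, iqf_sd, ff_mean, ff_sd
_TPA_ROWS = [
    ("adhesiveness",          -1.13,  0.35,  -1.17,  0.28),
    ("chewiness_1",           68.61, 16.86,  78.07, 18.50),
    ("chewiness_1b",          50.857, 15.70, 54.350, 12.66),
    ("chewiness_2",           61.15, 15.27,  69.18, 17.83),
    ("cohesiveness",           0.48,  0.02,   0.47,  0.03),
    ("hardness_1",           200.34, 42.19, 220.51, 34.81),
    ("hardness_1b",          151.22, 42.45, 158.15, 29.31),
    ("hardness_2",           178.06, 38.16, 194.68, 34.05),
    ("resilience",            21.73,  2.84,  23.50,  1.79),
    ("springiness",           69.77,  2.51,  73.84,  2.65),
    ("thickness_1",           15.73,  1.53,  14.47,  1.09),
    ("thickness_2",           10.99,  1.25,  10.69,  0.90),
    ("residual_chewiness_1",  -4.326, 13.28,  7.634, 15.87),
    ("residual_chewiness_1b", -3.713, 12.05,  6.552, 15.79),
    ("residual_cohesiveness",  0.004,  0.02, -0.007,  0.03),
    ("residual_hardness_1b",  -5.462, 25.34,  9.639, 12.76),
    ("residual_springiness",  -1.585,  2.01,  2.798,  2.39),
]

#: per-fish-mean summary of the sensory attributes (0-15 intensity scale)
_SENSORY_ROWS = [
    ("cohesiveness_of_mass",           5.98, 0.73,  5.87, 0.74),
    ("fibrous",                        5.33, 0.77,  5.03, 0.75),
    ("firmness",                       4.05, 0.92,  4.39, 0.96),
    ("flaky",                          4.82, 0.92,  4.79, 0.80),
    ("moisture_release",               5.77, 1.13,  4.99, 1.10),
    ("moisture_retention",             5.44, 0.81,  4.88, 0.78),
    ("springiness",                    3.09, 0.85,  3.00, 0.68),
    ("residual_cohesiveness_of_mass",  0.025, 0.73, -0.043, 0.70),
    ("residual_firmness",             -0.141, 0.91,  0.248, 0.92),
    ("residual_flaky",                 0.030, 0.91, -0.052, 0.78),
]

_COLS = ["attribute", "iqf_mean", "iqf_sd", "ff_mean", "ff_sd"]


def tpa_summary() -> pd.DataFrame:
    """Published instrumental summary table, indexed by attribute."""
    return pd.DataFrame(_TPA_ROWS, columns=_COLS).set_index("attribute")


def sensory_summary() -> pd.DataFrame:
    """Published sensory summary table, indexed by attribute."""
    return pd.DataFrame(_SENSORY_ROWS, columns=_COLS).set_index("attribute")


def group_mean(table: pd.DataFrame, attribute: str, group: str) -> float:
    """Mean of ``attribute`` for ``group`` ('iqf' or 'fresh_frozen')."""
    col = "iqf_mean" if group == "iqf" else "ff_mean"
    return float(table.loc[attribute, col])
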