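"""Small worked-example tables used in documentation and tests.

These are reported summary statistics from a published screening/validation
study of sitting patterns and endothelial-vesicle microRNAs; they serve as
fixed inputs for exercising the ranking, selection, and confidence-interval
rules on realistic numbers.  No raw data are included.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: reported top-10 screening rows: weighted mean expression difference (ATE),
#: unweighted expression SD across both groups, and standardized ATE
#: (ATE / bootstrap SD).  The starred validation candidates were the five of
#: these with the largest unweighted SD.
SCREENING_TOP10 = pd.DataFrame(
    {
        "ate": [11.30, 5.70, 5.15, 4.19, 3.25, 2.96, 1.80, 1.15, 0.52, 0.76],
        "unweighted_sd": [5.15, 2.26, 2.21, 1.94, 1.53, 1.51, 0.80, 0.61, 0.28, 0.27],
        "std_ate": [4.38, 4.37, 5.29, 5.33, 5.44, 4.82, 4.17, 4.50, 4.20, 5.02],
    },
    index=pd.Index(
        [
            "miR-133b",
            "miR-140-5p",
            "miR-142-3p",
            "let-7d-5p",
            "miR-199a-5p",
            "miR-146a-5p",
            "miR-103a-3p",
            "miR-424-5p",
            "let-7e-5p",
            "miR-155-5p",
        ],
        name="mir",
    ),
)

#: the five screening candidates that were carried into validation
SCREENING_SELECTED = frozenset(
    {"miR-133b", "miR-140-5p", "miR-142-3p", "let-7d-5p", "miR-199a-5p"}
)

#: reported validation-stage estimates: ATE, printed 95% CI, standardized ATE
VALIDATION_TABLE = pd.DataFrame(
    {
        "ate": [0.168, 0.002, 0.006, 0.056, 0.010],
        "ci_low": [0.108, 0.001, 0.001, -0.026, 0.000],
        "ci_high": [0.228, 0.004, 0.011, 0.138, 0.0206],
        "std_ate": [5.462, 3.323, 2.196, 1.332, 1.973],
    },
    index=pd.Index(
        ["miR-133b", "let-7d-5p", "miR-142-3p", "miR-140-5p", "miR-199-5p"],
        name="mir",
    ),
)

#: reported group-level activity and functioning means for the Interrupted
#: Sitter (n=18) and Super Sitter (n=53) groups, with the whole-cohort value
GROUP_MEANS = pd.DataFrame(
    {
        "IS": [442.6, 25.5, 4.5, 53.2, 74.9],
        "SS": [658.0, 64.0, 3.2, 25.7, 56.5],
        "total": [603.4, 54.3, 3.5, 32.7, 61.2],
    },
    index=pd.Index(
        [
            "total_sitting_time",
            "mean_sitting_bout",
            "mvpa",
            "walking",
            "physical_functioning",
        ],
        name="metric",
    ),
)
GROUP_SIZES = {"IS": 18, "SS": 53}


def pooled_group_mean(metric: str) -> float:
    """Whole-cohort mean reconstructed from the two group means and sizes."""
    row = GROUP_MEANS.loc[metric]
    n_is, n_ss = GROUP_SIZES["IS"], GROUP_SIZES["SS"]
    return float(np.average([row["IS"], row["SS"]], weights=[n_is, n_ss]))
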