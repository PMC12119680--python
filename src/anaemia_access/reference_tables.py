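"""Published summary counts from the western-Kenya paediatric anaemia
admission cohort (county referral hospital, 42 surveillance months,
January 2020 - July 2023).

Only aggregate counts printed in the published tables are stored here; the
individual-level data are not publicly deposited.  These counts serve as
inputs for reproducing the printed descriptive quantities (proportions,
Wilson intervals, crude odds ratios, exclusion-cascade totals) and for
calibrating the synthetic generator's marginals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import FlowLedger
from .descriptive import OddsRatioResult, crude_or, wilson_ci

__all__ = [
    "CASCADE_COUNTS",
    "TRAVEL_BY_SEVERITY",
    "SEVERITY_TOTALS",
    "cascade_ledger",
    "travel_severity_table",
    "reference_crude_ors",
    "reference_proportions",
]

# Exclusion cascade: resident children aged 1-59 months extracted, then
# sequentially removed for cause, missing Hb, and Hb >= 10 g/dl.
CASCADE_COUNTS = {
    "extracted": 4361,
    "excluded_cause": 665,
    "excluded_no_hb": 264,
    "excluded_not_anaemic": 1245,
}

# Travel-time class x severity counts for the 2,187 analysed admissions.
TRAVEL_BY_SEVERITY = pd.DataFrame(
    {
        "mild": [826, 265, 37, 23],
        "moderate": [224, 138, 36, 4],
        "severe": [221, 302, 87, 24],
    },
    index=pd.Index(["<30", "30-59", "60-89", ">=90"], name="tt_class"),
)

SEVERITY_TOTALS = {"mild": 1151, "moderate": 402, "severe": 634, "total": 2187}


def cascade_ledger() -> FlowLedger:
    """The published exclusion cascade as a FlowLedger."""
    return FlowLedger(**CASCADE_COUNTS)


def travel_severity_table() -> pd.DataFrame:
    """Copy of the travel-class x severity contingency table."""
    return TRAVEL_BY_SEVERITY.copy()


def reference_crude_ors() -> dict[str, OddsRatioResult]:
    """Crude severe-vs-other odds ratios per travel class vs <30 min.

    "Other" pools mild and moderate admissions; computed from the published
    counts with the descriptive module's own estimator.
    """
    tab = TRAVEL_BY_SEVERITY
    other = tab["mild"] + tab["moderate"]
    ref = ("<30",)
    out: dict[str, OddsRatioResult] = {}
    for cls in ["30-59", "60-89", ">=90"]:
        table = [
            [int(tab.loc[cls, "severe"]), int(other.loc[cls])],
            [int(tab.loc[ref[0], "severe"]), int(other.loc[ref[0]])],
        ]
        out[cls] = crude_or(table)
    return out


def reference_proportions() -> dict[str, float]:
    """Key printed percentages recomputed from the published counts."""
    tab = TRAVEL_BY_SEVERITY
    tot = SEVERITY_TOTALS
    n_class = tab.sum(axis=1)
    return {
        "pct_severe_within_30min": 100.0 * tab.loc["<30", "severe"] / tot["severe"],
        "pct_severe_within_1h": 100.0
        * (tab.loc["<30", "severe"] + tab.loc["30-59", "severe"])
        / tot["severe"],
        "pct_mild_within_1h": 100.0
        * (tab.loc["<30", "mild"] + tab.loc["30-59", "mild"])
        / tot["mild"],
        "pct_severe_overall": 100.0 * tot["severe"] / tot["total"],
        "pct_admissions_30_59": 100.0 * n_class.loc["30-59"] / tot["total"],
    }
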