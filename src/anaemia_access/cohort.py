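"""Cohort construction: altitude-adjusted haemoglobin, anaemia severity and
the inclusion/exclusion cascade.

Haemoglobin measured at altitude overstates the sea-level concentration, so
raw Hb is corrected downward using the WHO (2011) step table before severity
classification.  Severity follows the hospitalised-anaemia convention:
severe Hb < 5, moderate [5, 7), mild [7, 10), not anaemic >= 10 g/dl.  The
cascade restricts to resident children aged 1-59 months, removes admissions
whose cause is unrelated to residence (bites, burns, malignancy, poisoning,
surgery, trauma), removes records without an Hb result, and finally removes
the non-anaemic; an auditable :class:`FlowLedger` records every step.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "WHO_ALTITUDE_STEPS",
    "EXCLUSION_CAUSES",
    "SEVERITY_LEVELS",
    "FlowLedger",
    "adjust_hb_for_altitude",
    "classify_anaemia",
    "nutrition_status",
    "apply_exclusions",
]

# WHO (2011) haemoglobin adjustment: g/dl subtracted by altitude band.
# Step function, no interpolation — the guideline's native form.
WHO_ALTITUDE_STEPS: tuple[tuple[float, float], ...] = (
    (1000.0, 0.0),
    (1500.0, 0.2),
    (2000.0, 0.5),
    (2500.0, 0.8),
    (3000.0, 1.3),
    (3500.0, 1.9),
    (4000.0, 2.7),
    (4500.0, 3.5),
    (np.inf, 4.5),
)

EXCLUSION_CAUSES = ("bite", "burn", "malignancy", "poisoning", "surgery", "trauma")
SEVERITY_LEVELS = ("mild", "moderate", "severe", "not_anaemic")


@dataclass
class FlowLedger:
    """Counts removed at each cohort-exclusion step."""

    extracted: int
    excluded_cause: int
    excluded_no_hb: int
    excluded_not_anaemic: int

    @property
    def analysed(self) -> int:
        return (
            self.extracted
            - self.excluded_cause
            - self.excluded_no_hb
            - self.excluded_not_anaemic
        )

    def as_dict(self) -> dict[str, int]:
        d = asdict(self)
        d["analysed"] = self.analysed
        return d

    def __post_init__(self) -> None:
        counts = asdict(self).values()
        if any(c < 0 for c in counts) or self.analysed < 0:
            raise ValueError("ledger counts must be non-negative")


def adjust_hb_for_altitude(hb_raw, altitude_m, steps=WHO_ALTITUDE_STEPS):
    """Altitude-corrected haemoglobin in g/dl (WHO step table).

    Vectorised; raises if an adjustment drives Hb to zero or below (an
    implausible record) or on negative inputs.
    """
    hb = np.asarray(hb_raw, dtype=float)
    alt = np.asarray(altitude_m, dtype=float)
    if np.any(hb <= 0):
        raise ValueError("hb_raw must be positive")
    if np.any(alt < 0):
        raise ValueError("altitude_m must be non-negative")
    bounds = np.array([b for b, _ in steps])
    decs = np.array([d for _, d in steps])
    adj = hb - decs[np.searchsorted(bounds, alt, side="right")]
    if np.any(adj <= 0):
        raise ValueError("altitude adjustment drove Hb <= 0 g/dl (implausible record)")
    return adj if adj.ndim else float(adj)


def classify_anaemia(hb_adj):
    """Severity class from adjusted Hb: severe <5, moderate [5,7), mild
    [7,10), not_anaemic >=10 g/dl."""
    hb = np.asarray(hb_adj, dtype=float)
    if np.any(hb <= 0):
        raise ValueError("hb_adj must be positive")
    out = np.select(
        [hb < 5.0, hb < 7.0, hb < 10.0], ["severe", "moderate", "mild"], "not_anaemic"
    ).astype(object)
    return out if out.ndim else str(out)


def nutrition_status(muac_z):
    """Nutrition class from MUAC z-score: well (> -1), mild (-2, -1],
    moderate (-3, -2], severe (<= -3); NaN -> "missing"."""
    z = np.asarray(muac_z, dtype=float)
    out = np.select(
        [np.isnan(z), z > -1, z > -2, z > -3],
        ["missing", "well", "mild_malnutrition", "moderate_malnutrition"],
        "severe_malnutrition",
    ).astype(object)
    return out if out.ndim else str(out)


def apply_exclusions(
    admissions: pd.DataFrame,
    hb_adj_col: str = "hb_adj",
) -> tuple[pd.DataFrame, FlowLedger]:
    """Run the inclusion/exclusion cascade and return (cohort, ledger).

    Expects columns ``resident`` (bool), ``age_months``, ``exclusion_cause``
    ("none" or a cause), ``hb_raw`` (NaN = not measured) and an adjusted-Hb
    column.  Steps, in order:

    1. restrict to residents aged 1-59 months — this defines "extracted";
    2. drop cause-related exclusions (first matching step counts a record);
    3. drop records with no Hb result;
    4. classify severity on adjusted Hb and drop the non-anaemic (>= 10).

    Records failing basic invariants (non-positive Hb on a measured record)
    are rejected with a reason before the cascade.
    """
    df = admissions.copy()
    measured = df["hb_raw"].notna()
    if (df.loc[measured, "hb_raw"] <= 0).any():
        bad = df.index[measured & (df["hb_raw"] <= 0)].tolist()
        raise ValueError(f"records with non-positive measured Hb: {bad}")

    extracted = df[
        df["resident"].astype(bool)
        & df["age_months"].between(1, 59, inclusive="both")
    ].copy()
    n_extracted = len(extracted)

    cause_mask = extracted["exclusion_cause"].isin(EXCLUSION_CAUSES)
    n_cause = int(cause_mask.sum())
    step2 = extracted[~cause_mask]

    no_hb = step2["hb_raw"].isna() | step2[hb_adj_col].isna()
    n_no_hb = int(no_hb.sum())
    step3 = step2[~no_hb].copy()

    step3["severity"] = classify_anaemia(step3[hb_adj_col].to_numpy())
    not_anaemic = step3["severity"] == "not_anaemic"
    n_not_anaemic = int(not_anaemic.sum())
    cohort = step3[~not_anaemic].copy()
    cohort["severe"] = (cohort["severity"] == "severe").astype(int)

    ledger = FlowLedger(
        extracted=n_extracted,
        excluded_cause=n_cause,
        excluded_no_hb=n_no_hb,
        excluded_not_anaemic=n_not_anaemic,
    )
    assert ledger.analysed == len(cohort)
    return cohort.reset_index(drop=True), ledger
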