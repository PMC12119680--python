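"""Descriptive epidemiology: admission rates, Wilson intervals,
Kruskal-Wallis, Fisher exact tests and crude odds ratios.

Conventions mirror standard hospital-surveillance reporting: categorical
characteristics are tabulated as counts with column percentages within each
severity class and Wilson 95% CIs; continuous characteristics as median
(IQR) with a Kruskal-Wallis test; severity-class comparisons of categorical
blocks use Fisher's exact test (full enumeration when the table is small
enough, otherwise Monte-Carlo with a fixed seed).  Admission rates are
reported per 1,000 under-five residents over the whole surveillance window,
not annualised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "admission_rate",
    "ea_admission_rates",
    "band_admission_rates",
    "wilson_ci",
    "kruskal_wallis",
    "fisher_exact",
    "FisherResult",
    "crude_or",
    "OddsRatioResult",
    "summarize_table1",
]


def admission_rate(count, pop_u5):
    """Admissions per 1,000 under-five children over the surveillance window."""
    count = np.asarray(count, dtype=float)
    pop = np.asarray(pop_u5, dtype=float)
    if np.any(pop <= 0):
        raise ValueError("population denominator must be positive")
    out = 1000.0 * count / pop
    return out if out.ndim else float(out)


def ea_admission_rates(cohort: pd.DataFrame, eas: pd.DataFrame) -> pd.DataFrame:
    """Per-EA admission rates per 1,000 under-fives, by severity class.

    EAs with zero under-five population are flagged (NaN rate) and excluded.
    """
    counts = (
        cohort.groupby(["ea_id", "severity"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["mild", "moderate", "severe"], fill_value=0)
    )
    out = eas.set_index("ea_id")[["pop_u5"]].join(counts).fillna(0)
    for sev in ["mild", "moderate", "severe"]:
        ok = out["pop_u5"] > 0
        out[f"rate_{sev}"] = np.nan
        out.loc[ok, f"rate_{sev}"] = admission_rate(
            out.loc[ok, sev].to_numpy(), out.loc[ok, "pop_u5"].to_numpy()
        )
    return out.reset_index()


def band_admission_rates(
    cohort: pd.DataFrame, eas: pd.DataFrame, band_col: str = "band15"
) -> pd.DataFrame:
    """Admission rates per 1,000 by travel-time band and severity.

    The denominator for a band is the total under-five population of the EAs
    whose mean travel time falls in the band; this is how distance-decay
    curves of hospital utilisation are constructed.
    """
    pop = eas.groupby(band_col, observed=True)["pop_u5"].sum()
    counts = (
        cohort.groupby([band_col, "severity"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["mild", "moderate", "severe"], fill_value=0)
    )
    out = pd.DataFrame({"pop_u5": pop}).join(counts).fillna(0)
    for sev in ["mild", "moderate", "severe"]:
        ok = out["pop_u5"] > 0
        out[f"rate_{sev}"] = np.nan
        out.loc[ok, f"rate_{sev}"] = admission_rate(
            out.loc[ok, sev].to_numpy(), out.loc[ok, "pop_u5"].to_numpy()
        )
    return out.reset_index()


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p on k-1 df.

    With every observation equal the tie correction degenerates; by
    convention that case returns H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def _log_table_prob(table: np.ndarray) -> float:
    """Log hypergeometric probability of an r x c table given its margins."""
    table = np.asarray(table)
    n = table.sum()
    return float(
        gammaln(table.sum(axis=1) + 1).sum()
        + gammaln(table.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _enumerate_tables(row_margins, col_margins):
    """Yield every non-negative integer table with the given margins."""
    rows = list(row_margins)
    ncol = len(col_margins)

    def rec(i, cols_left, current):
        if i == len(rows) - 1:
            last = np.asarray(cols_left)
            if (last >= 0).all():
                yield current + [list(last)]
            return
        target = rows[i]

        def fill(j, left, row):
            if j == ncol - 1:
                if 0 <= left <= cols_left[j]:
                    yield row + [left]
                return
            for v in range(min(left, cols_left[j]) + 1):
                yield from fill(j + 1, left - v, row + [v])

        for row in fill(0, target, []):
            remaining = [cl - v for cl, v in zip(cols_left, row)]
            yield from rec(i + 1, remaining, current + [row])

    yield from rec(0, list(col_margins), [])


@dataclass
class FisherResult:
    p: float
    method: str  # "exact-2x2" | "enumeration" | "monte-carlo"
    mc_se: float | None = None
    n_tables: int | None = None


def fisher_exact(
    table, exact_limit: int = 200, n_mc: int = 100_000, seed: int = 0
) -> FisherResult:
    """Two-sided Fisher exact test for an r x c contingency table.

    2x2 tables use the exact point-probability rule; larger tables are fully
    enumerated when the grand total is at most ``exact_limit``, otherwise a
    Monte-Carlo p is computed from ``n_mc`` tables drawn with fixed margins
    (Patefield sampling, fixed seed) and reported with its standard error.
    """
    tab = np.asarray(table, dtype=int)
    if tab.ndim != 2 or (tab < 0).any():
        raise ValueError("table must be a 2-D array of non-negative counts")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("every row and column margin must be positive")
    if tab.shape == (2, 2):
        _, p = stats.fisher_exact(tab, alternative="two-sided")
        return FisherResult(p=float(p), method="exact-2x2")

    logp_obs = _log_table_prob(tab)
    tol = 1e-7
    if tab.sum() <= exact_limit:
        total = 0.0
        count = 0
        for cand in _enumerate_tables(tab.sum(axis=1), tab.sum(axis=0)):
            lp = _log_table_prob(np.asarray(cand))
            count += 1
            if lp <= logp_obs + tol:
                total += math.exp(lp)
        return FisherResult(p=min(total, 1.0), method="enumeration", n_tables=count)

    rng = np.random.default_rng(seed)
    sampler = stats.random_table(tab.sum(axis=1), tab.sum(axis=0))
    draws = sampler.rvs(n_mc, random_state=rng)
    logps = np.array([_log_table_prob(d) for d in draws])
    hits = int((logps <= logp_obs + tol).sum())
    p = (hits + 1) / (n_mc + 1)
    se = math.sqrt(p * (1 - p) / n_mc)
    return FisherResult(p=float(p), method="monte-carlo", mc_se=se)


@dataclass
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool = False


def crude_or(table2x2, level: float = 0.95) -> OddsRatioResult:
    """Crude odds ratio with Woolf (log-method) confidence interval.

    The table is [[a, b], [c, d]] with a = severe among exposed, b = other
    among exposed, c = severe in the reference group, d = other in the
    reference group; OR = (a/b)/(c/d).  Zero cells get the Haldane-Anscombe
    +0.5 correction to every cell, flagged in the result.
    """
    tab = np.asarray(table2x2, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (tab.sum(axis=1) == 0).any():
        raise ValueError("a row of the 2x2 table is all zero")
    corrected = bool((tab == 0).any())
    if corrected:
        tab = tab + 0.5
    a, b = tab[0]
    c, d = tab[1]
    or_ = (a * d) / (b * c)
    z = stats.norm.ppf(0.5 + level / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(or_) - z * se), math.exp(math.log(or_) + z * se)
    return OddsRatioResult(float(or_), float(lo), float(hi), corrected)


# Categorical and continuous characteristic blocks used in the severity-
# stratified characteristics table.
_CATEGORICAL_BLOCKS: dict[str, str] = {
    "tt_class": "Travel time class (mins)",
    "age_cat": "Age category (yrs)",
    "sex": "Gender",
    "nutrition": "Nutrition status",
    "vaccinated": "Vaccination history",
    "malaria_dx": "Malaria diagnosis",
    "scd": "Sickle cell disease",
    "weekday": "Admission day: weekday",
    "wet_season": "Season: wet",
    "urban": "Residence type",
}
_CONTINUOUS_BLOCKS: dict[str, str] = {
    "mean_travel_min": "Travel time (mins)",
    "pfpr": "PfPR 2-10",
}


def summarize_table1(
    cohort: pd.DataFrame, fisher_seed: int = 0, mc_limit: int = 200
) -> pd.DataFrame:
    """Severity-stratified characteristics table.

    For each categorical block: counts and column percentages within each
    severity class (plus overall), Wilson 95% CIs, and a Fisher exact
    p-value across classes.  For continuous blocks: median (IQR) per class
    and a Kruskal-Wallis p-value.  Only blocks whose columns exist in the
    cohort are summarised.
    """
    if cohort["severity"].isna().any():
        raise ValueError("cohort contains records with missing severity")
    classes = ["mild", "moderate", "severe"]
    groups = {c: cohort[cohort["severity"] == c] for c in classes}
    rows = []
    for col, label in _CATEGORICAL_BLOCKS.items():
        if col not in cohort.columns:
            continue
        levels = sorted(cohort[col].dropna().astype(str).unique())
        ct = np.array(
            [
                [int((groups[c][col].astype(str) == lv).sum()) for c in classes]
                for lv in levels
            ]
        )
        if len(levels) >= 2 and (ct.sum(axis=1) > 0).all():
            p_val = fisher_exact(ct.T, exact_limit=mc_limit, seed=fisher_seed).p
        else:
            p_val = np.nan
        for i, lv in enumerate(levels):
            row = {"characteristic": label, "level": lv, "p_value": p_val if i == 0 else np.nan}
            n_all = int(ct[i].sum())
            denom_all = len(cohort)
            row["overall_n"] = n_all
            row["overall_pct"] = 100.0 * n_all / denom_all
            for j, c in enumerate(classes):
                n = int(ct[i, j])
                denom = len(groups[c])
                row[f"{c}_n"] = n
                row[f"{c}_pct"] = 100.0 * n / denom if denom else np.nan
                if denom:
                    lo, hi = wilson_ci(n, denom)
                    row[f"{c}_ci_low"] = 100.0 * lo
                    row[f"{c}_ci_high"] = 100.0 * hi
            rows.append(row)
    for col, label in _CONTINUOUS_BLOCKS.items():
        if col not in cohort.columns:
            continue
        samples = [groups[c][col].dropna().to_numpy() for c in classes]
        if all(len(s) for s in samples):
            _, p_val = kruskal_wallis(*samples)
        else:
            p_val = np.nan
        row = {"characteristic": label, "level": "median (IQR)", "p_value": p_val}
        allvals = cohort[col].dropna()
        row["overall_median"] = float(allvals.median())
        for c, s in zip(classes, samples):
            if len(s):
                row[f"{c}_median"] = float(np.median(s))
                row[f"{c}_q1"] = float(np.percentile(s, 25))
                row[f"{c}_q3"] = float(np.percentile(s, 75))
        rows.append(row)
    return pd.DataFrame(rows)
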