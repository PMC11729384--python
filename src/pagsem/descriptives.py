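"""Table-1-style descriptive statistics.

Weighted prevalence with a logit-scale Wald interval on the Kish effective
sample size, Pearson chi-square tests on categorical covariates, and the
Mann-Whitney U comparison for weekly-minute variables. Tests run on
unweighted counts (no design correction): two-sided throughout, with tie
and continuity corrections for the rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .errors import DomainError

__all__ = [
    "ContingencyTable",
    "TestResult",
    "PrevalenceEstimate",
    "classify_obesity",
    "weighted_prevalence",
    "chi_square_test",
    "mann_whitney_u",
    "table_one",
]


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self):
        c = np.atleast_2d(np.asarray(self.counts))
        object.__setattr__(self, "counts", c)
        if (c < 0).any():
            raise DomainError("contingency counts must be nonnegative")
        if c.shape[0] < 2 or c.shape[1] < 2:
            raise DomainError("contingency table needs at least 2 rows and 2 columns")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise DomainError("p-value outside [0, 1]")


@dataclass(frozen=True)
class PrevalenceEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    n_effective: float


def classify_obesity(bmi):
    """Binary obesity flag: BMI >= 30 kg/m^2 (boundary inclusive)."""
    bmi = np.asarray(bmi, dtype=float)
    if not np.isfinite(bmi).all() or (bmi <= 0).any():
        raise DomainError("BMI must be positive and finite")
    flags = (bmi >= 30.0).astype(np.int64)
    return flags if flags.ndim else int(flags)


def weighted_prevalence(flags, weights) -> PrevalenceEstimate:
    """Expansion-factor-weighted prevalence with a 95% interval.

    Point estimate ``sum(w*y)/sum(w)``; the interval is Wald on the logit
    scale using the Kish effective sample size ``(sum w)^2 / sum w^2``.
    Degenerate estimates (0 or 1) return a zero-width interval.
    """
    flags = np.asarray(flags, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if flags.size == 0:
        raise DomainError("cannot estimate a prevalence from no observations")
    if flags.shape != weights.shape:
        raise DomainError("flags and weights must have equal length")
    if (weights <= 0).any():
        raise DomainError("weights must be strictly positive")
    if not np.isin(flags, (0.0, 1.0)).all():
        raise DomainError("flags must be binary")
    p = float(weights @ flags / weights.sum())
    neff = float(weights.sum() ** 2 / (weights**2).sum())
    if p in (0.0, 1.0):
        return PrevalenceEstimate(p, p, p, neff)
    se_logit = float(np.sqrt(1.0 / (neff * p * (1.0 - p))))
    lo, hi = expit(logit(p) - 1.959963984540054 * se_logit), expit(
        logit(p) + 1.959963984540054 * se_logit
    )
    return PrevalenceEstimate(p, float(lo), float(hi), neff)


def chi_square_test(table) -> TestResult:
    """Pearson chi-square test of independence (no continuity correction)."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.atleast_2d(
        np.asarray(table, dtype=float)
    )
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise DomainError("contingency table needs at least 2 rows and 2 columns")
    if (counts < 0).any():
        raise DomainError("contingency counts must be nonnegative")
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise DomainError("every row and column margin must be positive")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return TestResult(float(stat), float(p), "pearson-chi-square", int(df))


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U with normal approximation, tie correction
    and continuity correction. ``statistic`` is U for the first sample."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DomainError("both samples must be nonempty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(float(res.statistic), float(res.pvalue), "mann-whitney-u", None)


_TIME_COLUMNS = (
    "computer_smartphone", "tv", "videogames", "motor_vehicle", "cycling",
    "walking", "leisure_pa",
)
_CATEGORICAL = ("sex", "ethnicity", "schooling", "wealth_quartile")


def table_one(df: pd.DataFrame, group_col: str = "obesity") -> pd.DataFrame:
    """Stratified descriptive table: per categorical covariate, group-wise
    percentages (weighted and unweighted) with a chi-square p-value; per
    time variable, group medians with a Mann-Whitney p-value."""
    if group_col not in df:
        raise DomainError(f"missing grouping column {group_col!r}")
    g = df[group_col].to_numpy()
    w = df["expansion_factor"].to_numpy(dtype=float) if "expansion_factor" in df else np.ones(len(df))
    rows = []
    for col in _CATEGORICAL:
        if col not in df:
            continue
        ct = pd.crosstab(df[col], df[group_col])
        p = chi_square_test(ct.to_numpy()).p_value if ct.shape[0] > 1 else np.nan
        for level in ct.index:
            mask = (df[col] == level).to_numpy()
            row = {"variable": col, "level": str(level), "p_value": p, "kind": "categorical"}
            for grp in np.unique(g):
                gm = g == grp
                row[f"pct_group_{grp}"] = 100.0 * mask[gm].mean()
                row[f"wpct_group_{grp}"] = 100.0 * (w[gm & mask].sum() / w[gm].sum())
            rows.append(row)
    for col in _TIME_COLUMNS:
        if col not in df:
            continue
        groups = np.unique(g)
        row = {"variable": col, "level": "median_min_per_week", "kind": "continuous"}
        if len(groups) == 2:
            a = df.loc[g == groups[0], col].to_numpy()
            b = df.loc[g == groups[1], col].to_numpy()
            row["p_value"] = mann_whitney_u(a, b).p_value
        else:
            row["p_value"] = np.nan
        for grp in groups:
            row[f"median_group_{grp}"] = float(np.median(df.loc[g == grp, col]))
        rows.append(row)
    return pd.DataFrame(rows)
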