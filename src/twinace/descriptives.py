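"""Descriptive statistics honoring twin-pair clustering.

Twin cohorts contain two correlated observations per family, so naive
binomial standard errors and Pearson chi-square tests overstate the
information in the sample.  Prevalence CIs here use a Taylor-linearized
cluster-robust variance with the family as the sampling cluster, and
group comparisons use a first-order Rao-Scott correction: the Pearson
statistic divided by a design-effect summary assembled from the
cluster-robust variances of the cell and margin proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PrevalenceEstimate:
    group: str
    n: int
    prevalence: float  # percent
    ci_low: float
    ci_high: float
    se: float  # percent scale

    def __post_init__(self):
        if self.n > 0:
            assert 0.0 <= self.prevalence <= 100.0


@dataclass
class RaoScottResult:
    pearson_chi2: float
    mean_design_effect: float
    adjusted_chi2: float
    df: int
    p_value: float


class DegenerateTableError(ValueError):
    """A contingency-table margin is empty; the test is undefined."""


def cluster_robust_mean(values: np.ndarray, clusters: np.ndarray) -> tuple[float, float]:
    """Mean of *values* with a Taylor-linearized cluster-robust SE.

    With cluster totals s_c, sizes n_c and overall mean p, the linearized
    variance of the ratio mean is (m/(m-1)) * sum_c (s_c - n_c p)^2 / N^2
    for m clusters and N observations.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        return np.nan, np.nan
    p = values.mean()
    codes, uniq = pd.factorize(clusters)
    m = len(uniq)
    if m <= 1:
        return float(p), np.nan
    sums = np.bincount(codes, weights=values, minlength=m)
    counts = np.bincount(codes, minlength=m)
    resid = sums - counts * p
    var = m / (m - 1) * np.sum(resid**2) / n**2
    return float(p), float(np.sqrt(var))


def prevalence(
    frame: pd.DataFrame,
    trait: str,
    by_group: str | None = None,
    cluster_col: str = "family_id",
) -> list[PrevalenceEstimate]:
    """Per-group prevalence (%) with 95% Wald CI using family-cluster SEs.

    Rows with a missing trait value are excluded from the denominator, so
    intent is automatically computed over never-users with observed items.
    An empty group yields a missing estimate with n=0 rather than an error.
    """
    data = frame.loc[frame[trait].notna(), [trait, cluster_col] +
                     ([by_group] if by_group else [])]
    # observed=False keeps empty categorical levels: they are reported as
    # missing estimates with n=0 rather than silently dropped
    groups = [("All", data)] if by_group is None else [
        (str(k), sub) for k, sub in data.groupby(by_group, sort=True, observed=False)
    ]
    out = []
    for label, sub in groups:
        if len(sub) == 0:
            out.append(PrevalenceEstimate(label, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        p, se = cluster_robust_mean(sub[trait].to_numpy(), sub[cluster_col].to_numpy())
        p *= 100.0
        se = se * 100.0 if np.isfinite(se) else np.nan
        half = 1.959963984540054 * se if np.isfinite(se) else 0.0
        out.append(PrevalenceEstimate(
            label, len(sub), p,
            max(0.0, p - half), min(100.0, p + half), se))
    return out


def prevalence_frame(estimates: list[PrevalenceEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in estimates])


def rao_scott_test(
    frame: pd.DataFrame,
    trait: str,
    group: str,
    cluster_col: str = "family_id",
) -> RaoScottResult:
    """First-order Rao-Scott chi-square for trait x group with family
    clustering.

    The Pearson statistic on the individual-level R x C table is divided
    by the first-order design-effect estimate

        d = [sum_jk d_jk (1-p_jk) - sum_j d_j (1-p_j.) - sum_k d_k (1-p_.k)]
            / ((R-1)(C-1))

    where d_jk, d_j, d_k are the cluster-robust design effects of the
    cell and marginal proportions (cluster-robust variance over the
    binomial variance); df = (R-1)(C-1).
    """
    data = frame.loc[frame[trait].notna() & frame[group].notna(),
                     [trait, group, cluster_col]]
    table = pd.crosstab(data[trait], data[group])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DegenerateTableError(
            f"table for {trait} x {group} is {table.shape}; need >= 2x2")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        empty = [str(c) for c in table.columns[table.sum(axis=0) == 0]] + \
                [str(r) for r in table.index[table.sum(axis=1) == 0]]
        raise DegenerateTableError(f"empty margin(s): {empty}")
    chi2 = stats.chi2_contingency(table.to_numpy(), correction=False)[0]

    n = len(data)
    clusters = data[cluster_col].to_numpy()

    def deff_of(indicator: np.ndarray) -> tuple[float, float]:
        p, se = cluster_robust_mean(indicator.astype(float), clusters)
        srs_var = p * (1 - p) / n
        if srs_var > 0 and np.isfinite(se):
            return se**2 / srs_var, p
        return 1.0, p

    num = 0.0
    for r in table.index:
        for c in table.columns:
            d, p = deff_of(((data[trait] == r) & (data[group] == c)).to_numpy())
            num += d * (1.0 - p)
    for r in table.index:
        d, p = deff_of((data[trait] == r).to_numpy())
        num -= d * (1.0 - p)
    for c in table.columns:
        d, p = deff_of((data[group] == c).to_numpy())
        num -= d * (1.0 - p)
    df0 = (table.shape[0] - 1) * (table.shape[1] - 1)
    dbar = num / df0
    if not np.isfinite(dbar) or dbar <= 0:
        dbar = 1.0
    adj = chi2 / dbar
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return RaoScottResult(
        pearson_chi2=float(chi2),
        mean_design_effect=dbar,
        adjusted_chi2=float(adj),
        df=df,
        p_value=float(stats.chi2.sf(adj, df)),
    )


def cronbach_alpha(item_matrix: np.ndarray) -> float:
    """Cronbach's alpha: (k/(k-1)) * (1 - sum(item variances) / var(total)).

    Returns NaN when the total score has zero variance (undefined).
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 respondents and >= 2 items")
    k = x.shape[1]
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))
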