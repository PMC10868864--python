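"""Zygosity-specific twin similarity statistics.

For each trait and zygosity group the module reports the Pearson
correlation between co-twins (the phi coefficient when the trait is
binary), the one-way random-effects intraclass correlation ICC(1), and —
for binary traits — the tetrachoric correlation, i.e. the latent
bivariate-normal correlation consistent with the 2x2 concordance table.

The default pairing convention is single-entry: member 1's value against
member 2's in member_index order.  Double-entry (each pair contributed
in both orders) is available for order-invariance; its p-value is
approximate because the entries are not independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr

from ._bvnorm import bvn_upper

MIN_PAIRS = 3


@dataclass
class CorrelationSummary:
    trait: str
    zygosity: str
    n_pairs: int
    r: float = float("nan")
    p_value: float = float("nan")
    icc: float = float("nan")
    tetrachoric_supported: bool = False
    tetrachoric: float = float("nan")
    tetrachoric_se: float = float("nan")
    status: str = "ok"
    notes: list = field(default_factory=list)


def pair_table(frame: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Pivot a cohort table to one row per complete pair:
    family_id, zygosity, y1, y2 (member_index order)."""
    cols = ["family_id", "member_index", "zygosity", trait]
    data = frame[cols].dropna(subset=[trait])
    wide = data.pivot_table(index=["family_id", "zygosity"],
                            columns="member_index", values=trait,
                            aggfunc="first")
    wide = wide.reindex(columns=[1, 2]).dropna()
    wide.columns = ["y1", "y2"]
    return wide.reset_index()


def _is_binary(y: np.ndarray) -> bool:
    return set(np.unique(y)).issubset({0.0, 1.0})


def pearson_by_zygosity(
    frame: pd.DataFrame, trait: str, ordering: str = "single"
) -> dict[str, CorrelationSummary]:
    """Pearson/phi correlation, ICC(1) and (binary) tetrachoric per
    zygosity group.  ``ordering`` is "single" or "double" (double-entry)."""
    if ordering not in ("single", "double"):
        raise ValueError("ordering must be 'single' or 'double'")
    pairs = pair_table(frame, trait)
    out: dict[str, CorrelationSummary] = {}
    for zyg in ("MZ", "DZ"):
        sub = pairs[pairs["zygosity"] == zyg]
        summ = CorrelationSummary(trait=trait, zygosity=zyg, n_pairs=len(sub))
        out[zyg] = summ
        if len(sub) < MIN_PAIRS:
            summ.status = f"fewer than {MIN_PAIRS} complete pairs"
            continue
        y1, y2 = sub["y1"].to_numpy(float), sub["y2"].to_numpy(float)
        if np.var(y1) == 0 or np.var(y2) == 0:
            summ.status = "zero variance in a member vector"
            summ.icc = icc1(y1, y2)
            continue
        if ordering == "single":
            r, p = stats.pearsonr(y1, y2)
        else:
            a = np.concatenate([y1, y2])
            b = np.concatenate([y2, y1])
            r, p = stats.pearsonr(a, b)
            summ.notes.append("double-entry p-value is approximate "
                              "(entries are not independent)")
        summ.r, summ.p_value = float(r), float(p)
        summ.icc = icc1(y1, y2)
        if _is_binary(np.concatenate([y1, y2])):
            summ.tetrachoric_supported = True
            rho, se, status = tetrachoric(y1, y2)
            summ.tetrachoric, summ.tetrachoric_se = rho, se
            if status != "ok":
                summ.notes.append(status)
    return out


def icc1(y1: np.ndarray, y2: np.ndarray) -> float:
    """One-way random-effects ICC(1) from the pair ANOVA:
    (MSB - MSW) / (MSB + MSW), clamped to [-1, 1]."""
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    n = len(y1)
    if n < 2:
        return float("nan")
    means = (y1 + y2) / 2.0
    grand = means.mean()
    msb = 2.0 * np.sum((means - grand) ** 2) / (n - 1)
    msw = np.sum((y1 - y2) ** 2) / (2.0 * n)
    denom = msb + msw
    if denom == 0:
        return float("nan")
    return float(np.clip((msb - msw) / denom, -1.0, 1.0))


def concordance_table(y1: np.ndarray, y2: np.ndarray) -> np.ndarray:
    """2x2 counts [[n00, n01], [n10, n11]] of a binary pair trait."""
    y1 = np.asarray(y1).astype(int)
    y2 = np.asarray(y2).astype(int)
    t = np.zeros((2, 2))
    for a in (0, 1):
        for b in (0, 1):
            t[a, b] = np.sum((y1 == a) & (y2 == b))
    return t


def _tetra_loglik(rho: float, tau1: float, tau2: float, table: np.ndarray) -> float:
    p11 = bvn_upper(tau1, tau2, rho)
    p1_ = float(ndtr(-tau1))
    p_1 = float(ndtr(-tau2))
    cells = np.array([
        [1.0 - p1_ - p_1 + p11, p_1 - p11],
        [p1_ - p11, p11],
    ])
    cells = np.clip(cells, 1e-300, None)
    return float(np.sum(table * np.log(cells)))


def tetrachoric(y1: np.ndarray, y2: np.ndarray) -> tuple[float, float, str]:
    """ML tetrachoric correlation with thresholds fixed at the margin
    quantiles.  Returns (rho, se, status); an empty concordance cell gives
    a boundary estimate with a warning status."""
    table = concordance_table(y1, y2)
    n = table.sum()
    p1 = table[1, :].sum() / n
    p2 = table[:, 1].sum() / n
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        raise ValueError("a margin of the concordance table is empty")
    tau1 = float(stats.norm.isf(p1))
    tau2 = float(stats.norm.isf(p2))
    res = optimize.minimize_scalar(
        lambda r: -_tetra_loglik(r, tau1, tau2, table),
        bounds=(-1.0 + 1e-9, 1.0 - 1e-9), method="bounded",
        options={"xatol": 1e-8},
    )
    rho = float(res.x)
    status = "ok"
    if (table == 0).any():
        status = "empty concordance cell; estimate at or near the boundary"
    # observed information by central second difference
    h = 1e-4
    if abs(rho) > 1 - 2 * h:
        return rho, float("nan"), status or "boundary"
    d2 = (_tetra_loglik(rho + h, tau1, tau2, table)
          - 2 * _tetra_loglik(rho, tau1, tau2, table)
          + _tetra_loglik(rho - h, tau1, tau2, table)) / h**2
    se = float(1.0 / math.sqrt(-d2)) if d2 < 0 else float("nan")
    return rho, se, status


def correlation_frame(summaries: dict[str, dict[str, CorrelationSummary]]) -> pd.DataFrame:
    """Tidy table from {trait: {zygosity: CorrelationSummary}}."""
    rows = []
    for per_zyg in summaries.values():
        for s in per_zyg.values():
            d = {k: v for k, v in s.__dict__.items() if k != "notes"}
            d["notes"] = "; ".join(s.notes)
            rows.append(d)
    return pd.DataFrame(rows)
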