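"""Simulation-based power analysis for the twin design.

For a given design (number of pairs, zygosity split) and generative
truth, cohorts are simulated repeatedly, the alternative and null
variance-component models are fitted by ML, and the additive-genetic
effect is tested with a likelihood-ratio test against the chi-square(1)
critical value.  Because the null pins the variance component to the
boundary of its parameter space, the chi-square(1) reference is
conservative; the 50:50 chi-square(0)/chi-square(1) mixture reference is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import ace_model, synthetic_data
from .synthetic_data import TrueComponents


@dataclass
class PowerResult:
    n_pairs: int
    mz_fraction: float
    truth: TrueComponents
    trait_type: str
    prevalence: float | None
    alpha: float
    reference: str
    replicates: int
    rejections: int
    n_failed: int
    power: float
    mc_ci: tuple[float, float]
    lrt_stats: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        assert 0.0 <= self.power <= 1.0
        assert self.mc_ci[0] <= self.power <= self.mc_ci[1]


def _critical_value(alpha: float, reference: str) -> float:
    if reference == "chi2_1":
        return float(stats.chi2.isf(alpha, 1))
    if reference == "mixture":
        # 0.5*chi2(0) + 0.5*chi2(1): P(LRT > c) = 0.5 * P(chi2_1 > c)
        return float(stats.chi2.isf(2.0 * alpha, 1))
    raise ValueError("reference must be 'chi2_1' or 'mixture'")


def estimate_power(
    n_pairs: int = 800,
    truth: TrueComponents = TrueComponents(0.3, 0.0, 0.7),
    trait_type: str = "continuous",
    prevalence: float = 0.25,
    mz_fraction: float = 0.5,
    alpha: float = 0.05,
    replicates: int = 500,
    seed: int = 0,
    reference: str = "chi2_1",
) -> PowerResult:
    """Monte-Carlo power of the AE-vs-E likelihood-ratio test for an
    additive genetic effect.

    Each replicate simulates a cohort under *truth* via
    :func:`twinace.synthetic_data.simulate_cohort`, fits the AE model and
    the environment-only null, and rejects when 2*(llAE - llE) exceeds
    the critical value.  Replicates that fail to converge are re-fit from
    extra starts; persistent failures are counted, never silently
    dropped.  Deterministic given *seed*.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    crit = _critical_value(alpha, reference)
    child_seeds = np.random.SeedSequence(seed).generate_state(replicates) % (2**31)
    rejections = 0
    n_failed = 0
    lrt_stats = np.full(replicates, np.nan)
    for rep in range(replicates):
        cfg = synthetic_data.single_trait_config(
            n_pairs=n_pairs,
            components=truth,
            kind=trait_type,
            prevalence=prevalence,
            dz_fraction=1.0 - mz_fraction,
            seed=int(child_seeds[rep]),
        )
        cohort = synthetic_data.simulate_cohort(cfg)
        try:
            lrt = _lrt_once(cohort, trait_type)
        except ace_model.FitError:
            try:
                lrt = _lrt_once(cohort, trait_type, n_starts=8)
            except ace_model.FitError:
                n_failed += 1
                continue
        lrt_stats[rep] = lrt
        if lrt > crit:
            rejections += 1
    power = rejections / replicates
    ci = stats.binomtest(rejections, replicates).proportion_ci(0.95, "wilson")
    return PowerResult(
        n_pairs=n_pairs, mz_fraction=mz_fraction, truth=truth,
        trait_type=trait_type,
        prevalence=prevalence if trait_type == "binary" else None,
        alpha=alpha, reference=reference, replicates=replicates,
        rejections=rejections, n_failed=n_failed, power=power,
        mc_ci=(float(ci.low), float(ci.high)), lrt_stats=lrt_stats,
    )


def _lrt_once(cohort: pd.DataFrame, trait_type: str, n_starts: int = 3) -> float:
    if trait_type == "binary":
        alt = ace_model.fit_binary(cohort, "y", model="AE", n_starts=n_starts)
        null = ace_model.fit_binary(cohort, "y", model="E", n_starts=n_starts)
    else:
        alt = ace_model.fit_continuous(cohort, "y", model="AE", n_starts=n_starts)
        null = ace_model.fit_continuous(cohort, "y", model="E", n_starts=n_starts)
    return max(0.0, 2.0 * (alt.loglik - null.loglik))


def power_grid(
    n_pairs_grid=(200, 400, 800, 1600),
    h2_grid=(0.2, 0.3, 0.5),
    trait_type: str = "continuous",
    prevalence: float = 0.25,
    c2: float = 0.0,
    replicates: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Power over a grid of sample sizes and heritabilities; one row per
    (n_pairs, h2) cell."""
    rows = []
    for i, n in enumerate(n_pairs_grid):
        for j, h2 in enumerate(h2_grid):
            truth = TrueComponents(h2, c2, 1.0 - h2 - c2)
            res = estimate_power(
                n_pairs=n, truth=truth, trait_type=trait_type,
                prevalence=prevalence, alpha=alpha, replicates=replicates,
                seed=seed + 1000 * i + j,
            )
            rows.append({
                "n_pairs": n, "h2": h2, "c2": c2,
                "trait_type": trait_type, "power": res.power,
                "mc_lo": res.mc_ci[0], "mc_hi": res.mc_ci[1],
                "replicates": replicates, "failed": res.n_failed,
            })
    return pd.DataFrame(rows)


def plot_power_curves(grid: pd.DataFrame, path) -> None:
    """Write a power-vs-n curve per heritability level to *path*."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for h2, sub in grid.groupby("h2"):
        sub = sub.sort_values("n_pairs")
        ax.plot(sub["n_pairs"], sub["power"], marker="o", label=f"$h^2$ = {h2}")
        ax.fill_between(sub["n_pairs"], sub["mc_lo"], sub["mc_hi"], alpha=0.15)
    ax.axhline(0.8, color="grey", ls="--", lw=1)
    ax.set_xlabel("twin pairs")
    ax.set_ylabel("power (AE vs E LRT)")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
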