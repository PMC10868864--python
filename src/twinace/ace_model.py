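"""ACE variance-component estimation for twin pairs.

The classical twin model decomposes phenotypic variance into additive
genetic (A), common/shared environmental (C) and unique environmental
(E) sources, exploiting the fact that MZ co-twins share all additive
genetic variance while DZ co-twins share half of it:

    cov(y1, y2 | MZ) = sigma_a^2 + sigma_c^2
    cov(y1, y2 | DZ) = sigma_a^2 / 2 + sigma_c^2

Two estimators are provided:

* :func:`falconer` — the moment decomposition from zygosity-specific
  correlations, h2 = 2(rMZ - rDZ), c2 = 2 rDZ - rMZ, with negative
  components truncated to zero.
* :func:`fit_continuous` / :func:`fit_binary` — maximum likelihood on
  the exact pair likelihood.  Continuous traits use the bivariate-normal
  pair density; binary traits use the liability-threshold model in
  which each pair's concordance cell is a bivariate-normal orthant
  probability with liability correlation h2 + c2 (MZ) or h2/2 + c2 (DZ).

AE, CE and E are nested submodels with components fixed at zero; fits
are compared by BIC and reduced when the full-model estimate of a
component sits on the zero boundary (:func:`compare_and_reduce`).
Dominance (ADE) decompositions are out of scope: with pairs reared
together, A, D and C are not jointly identifiable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr

from ._bvnorm import bvn_upper
from .twin_correlations import concordance_table, pair_table, tetrachoric

MODELS = ("ACE", "AE", "CE", "E")
#: variance components free in each model
FREE = {"ACE": ("a", "c", "e"), "AE": ("a", "e"), "CE": ("c", "e"), "E": ("e",)}
_GENETIC_SHARE = {"MZ": 1.0, "DZ": 0.5}
_BOUNDARY_TOL = 1e-6
_Z95 = 1.959963984540054


class FitError(RuntimeError):
    """Optimization failed to converge; the message carries diagnostics."""


@dataclass
class VarianceComponents:
    """h2/c2/e2 proportions with optional SEs, 95% CIs and p-values.

    CIs are untruncated Wald intervals and may extend outside [0, 1];
    point estimates are nonnegative and sum to one.
    """

    h2: float
    c2: float
    e2: float
    scale: str  # observed | liability
    source: str  # moment | ml
    se: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)
    p: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"h2": self.h2, "c2": self.c2, "e2": self.e2}


@dataclass
class AceFit:
    model: str
    trait: str
    scale: str
    params: dict
    loglik: float
    bic: float
    n_pairs: dict
    components: VarianceComponents
    converged: bool
    n_starts: int
    stratum: str = ""
    boundary: bool = False
    cov_free: np.ndarray | None = None
    free_names: tuple = ()
    selection_note: str = ""

    @property
    def k_params(self) -> int:
        return len(self.params)


# ---------------------------------------------------------------------------
# Moment (Falconer) estimator
# ---------------------------------------------------------------------------

def falconer(r_mz: float, r_dz: float) -> VarianceComponents:
    """Moment decomposition h2 = 2(rMZ - rDZ), c2 = 2 rDZ - rMZ.

    Negative raw components are truncated to zero and h2 + c2 is capped
    at one so the reported proportions are a valid decomposition;
    e2 = 1 - h2 - c2 after truncation.  No SEs (moment method).
    """
    for name, r in (("r_mz", r_mz), ("r_dz", r_dz)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name}={r} outside [-1, 1]")
    raw_h2 = 2.0 * (r_mz - r_dz)
    raw_c2 = 2.0 * r_dz - r_mz
    h2 = min(max(raw_h2, 0.0), 1.0)
    c2 = min(max(raw_c2, 0.0), 1.0 - h2)
    e2 = 1.0 - h2 - c2
    return VarianceComponents(
        h2=h2, c2=c2, e2=e2, scale="observed", source="moment",
        raw={"h2": raw_h2, "c2": raw_c2},
    )


# ---------------------------------------------------------------------------
# Orthant probability (kernel of the binary pair likelihood)
# ---------------------------------------------------------------------------

def orthant_probability(tau1: float, tau2: float, rho: float) -> float:
    """P(L1 > tau1, L2 > tau2) for standard bivariate-normal liabilities
    with correlation rho; |rho| = 1 handled by the degenerate closed form."""
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho={rho} outside [-1, 1]")
    return bvn_upper(tau1, tau2, rho)


# ---------------------------------------------------------------------------
# Continuous ML fit
# ---------------------------------------------------------------------------

def _design(frame: pd.DataFrame, trait: str, covariates: list[str] | None):
    """Wide arrays per pair: y (n,2), X (n,2,p) with leading intercept."""
    covariates = covariates or []
    cols = ["family_id", "member_index", "zygosity", trait] + covariates
    data = frame[cols].dropna(subset=[trait] + covariates)
    wide = data.pivot_table(index=["family_id", "zygosity"],
                            columns="member_index",
                            values=[trait] + covariates, aggfunc="first")
    need = [(v, m) for v in [trait] + covariates for m in (1, 2)]
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(need)).dropna()
    wide = wide.reset_index()
    zyg = wide["zygosity"].to_numpy()
    y = np.stack([wide[(trait, 1)].to_numpy(float),
                  wide[(trait, 2)].to_numpy(float)], axis=1)
    n = len(wide)
    X = np.ones((n, 2, 1 + len(covariates)))
    for j, cov in enumerate(covariates, start=1):
        X[:, 0, j] = wide[(cov, 1)].to_numpy(float)
        X[:, 1, j] = wide[(cov, 2)].to_numpy(float)
    return y, X, zyg


def _gauss_loglik(y, X, zyg_mask_mz, beta, va, vc, ve) -> float:
    v = va + vc + ve
    if v <= 0 or ve <= 0:
        return -np.inf
    mu = X @ beta  # (n, 2)
    r = y - mu
    ll = 0.0
    for is_mz, share in ((True, 1.0), (False, 0.5)):
        mask = zyg_mask_mz if is_mz else ~zyg_mask_mz
        n = int(mask.sum())
        if n == 0:
            continue
        cz = share * va + vc
        det = v * v - cz * cz
        if det <= 0:
            return -np.inf
        r1, r2 = r[mask, 0], r[mask, 1]
        quad = (v * (r1**2 + r2**2) - 2.0 * cz * r1 * r2) / det
        ll += -n * math.log(2 * math.pi) - 0.5 * n * math.log(det) - 0.5 * quad.sum()
    return float(ll)


def _moment_start(y, zyg_mask_mz):
    v0 = float(np.var(y)) or 1.0
    def corr(mask):
        if mask.sum() < 3:
            return 0.0
        c = np.corrcoef(y[mask, 0], y[mask, 1])[0, 1]
        return 0.0 if not np.isfinite(c) else float(c)
    rmz, rdz = corr(zyg_mask_mz), corr(~zyg_mask_mz)
    a0 = min(max(2.0 * (rmz - rdz), 0.05), 0.9)
    c0 = min(max(2.0 * rdz - rmz, 0.05), 0.9 - a0)
    e0 = max(1.0 - a0 - c0, 0.05)
    return v0 * a0, v0 * c0, v0 * e0, v0


def fit_continuous(
    frame: pd.DataFrame,
    trait: str,
    model: str = "ACE",
    covariates: list[str] | None = None,
    n_starts: int = 3,
) -> AceFit:
    """ML fit of the bivariate-normal pair likelihood for a continuous
    trait.  Pair covariance is sigma_a^2 + sigma_c^2 for MZ and
    sigma_a^2/2 + sigma_c^2 for DZ; components absent from *model* are
    fixed at zero.  Multi-start Nelder-Mead over (beta, sqrt-variances)."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    y, X, zyg = _design(frame, trait, covariates)
    mz = zyg == "MZ"
    n_pairs = {"MZ": int(mz.sum()), "DZ": int((~mz).sum())}
    if len(y) < 3:
        raise FitError(f"only {len(y)} complete pairs for trait {trait}")
    free = FREE[model]
    p = X.shape[2]

    # start values: pooled OLS for beta, moment split of residual variance
    Xf = X.reshape(-1, p)
    beta0, *_ = np.linalg.lstsq(Xf, y.ravel(), rcond=None)
    resid = y - (X @ beta0)
    a0, c0, e0, v0 = _moment_start(resid, mz)
    start_vars = {"a": a0, "c": c0, "e": e0}

    def unpack(theta):
        beta = theta[:p]
        s = dict(zip(free, theta[p:]))
        return beta, (s.get("a", 0.0) ** 2, s.get("c", 0.0) ** 2, s["e"] ** 2)

    def nll(theta):
        beta, (va, vc, ve) = unpack(theta)
        return -_gauss_loglik(y, X, mz, beta, va, max(vc, 0.0), max(ve, 1e-12))

    base = np.concatenate([beta0, [math.sqrt(start_vars[f]) for f in free]])
    rng = np.random.default_rng(12345)  # fixed jitter seed
    starts = [base]
    for _ in range(n_starts - 1):
        jit = base.copy()
        jit[p:] *= np.exp(rng.normal(0.0, 0.3, size=len(free)))
        starts.append(jit)

    best = None
    ok = False
    for s0 in starts:
        res = optimize.minimize(nll, s0, method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-10,
                                         "maxiter": 20000, "maxfev": 20000})
        ok = ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"continuous {model} fit failed for {trait}: {best}")
    if not ok:
        raise FitError(
            f"continuous {model} fit did not converge for {trait} after "
            f"{n_starts} starts (best status: {best.message})")

    beta_hat, (va, vc, ve) = unpack(best.x)
    total = va + vc + ve
    h2, c2, e2 = va / total, vc / total, ve / total
    ll = -best.fun
    n_tot = len(y)
    k = p + len(free)
    var_map = {"a": va, "c": vc, "e": ve}
    boundary = any(var_map[f] / total < _BOUNDARY_TOL for f in free if f != "e")

    se, cov_free, free_names = _continuous_ses(
        y, X, mz, beta_hat, {"a": va, "c": vc, "e": ve}, free)
    comp = VarianceComponents(h2=h2, c2=c2, e2=e2, scale="observed",
                              source="ml", se=se)
    params = {f"beta{j}": float(b) for j, b in enumerate(beta_hat)}
    params.update({f"v_{f}": {"a": va, "c": vc, "e": ve}[f] for f in free})
    return AceFit(
        model=model, trait=trait, scale="observed", params=params,
        loglik=ll, bic=-2.0 * ll + k * math.log(n_tot), n_pairs=n_pairs,
        components=comp, converged=True, n_starts=len(starts),
        boundary=boundary, cov_free=cov_free, free_names=free_names,
    )


def _continuous_ses(y, X, mz, beta, vars_, free):
    """Delta-method SEs for the proportions from the observed information
    in (beta, free variances).  Boundary variances get missing SEs."""
    p = len(beta)
    free_v = [f for f in free]
    theta = np.concatenate([beta, [vars_[f] for f in free_v]])
    total = sum(vars_.values())
    if any(vars_[f] < _BOUNDARY_TOL * total for f in free_v):
        return {}, None, ()

    def nll(th):
        b = th[:p]
        v = {f: 0.0 for f in "ace"}
        for j, f in enumerate(free_v):
            v[f] = th[p + j]
        if any(val < 0 for val in v.values()):
            return np.inf
        return -_gauss_loglik(y, X, mz, b, v["a"], v["c"], v["e"])

    H = _num_hessian(nll, theta)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return {}, None, ()
    if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
        return {}, None, ()
    vcov = cov[p:, p:]
    # Jacobian of proportions wrt free variances
    idx = {f: j for j, f in enumerate(free_v)}
    se = {}
    for name, f in (("h2", "a"), ("c2", "c"), ("e2", "e")):
        if f not in idx and f != "e":
            continue
        grad = np.zeros(len(free_v))
        vf = vars_.get(f, 0.0)
        for g, j in idx.items():
            grad[j] = ((1.0 if g == f else 0.0) * total - vf) / total**2
        var = float(grad @ vcov @ grad)
        if var > 0:
            se[name] = math.sqrt(var)
    return se, vcov, tuple(free_v)


def _num_hessian(fun, x0, rel_step=1e-4):
    n = len(x0)
    h = np.maximum(np.abs(x0) * rel_step, 1e-6)
    H = np.zeros((n, n))
    f0 = fun(x0)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[i, i] = (fun(x0 + ei) - 2 * f0 + fun(x0 - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    fun(x0 + ei + ej) - fun(x0 + ei - ej)
                    - fun(x0 - ei + ej) + fun(x0 - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# Binary (liability-threshold) ML fit
# ---------------------------------------------------------------------------

def _binary_cells(tau: float, rho: float) -> np.ndarray:
    """[[p00, p01], [p10, p11]] of the thresholded bivariate normal."""
    p11 = bvn_upper(tau, tau, rho)
    p1 = float(ndtr(-tau))
    p10 = max(p1 - p11, 1e-300)
    p00 = max(1.0 - 2.0 * p1 + p11, 1e-300)
    return np.array([[p00, p10], [p10, max(p11, 1e-300)]])


def _binary_loglik(tau, h2, c2, tables) -> float:
    ll = 0.0
    for zyg, table in tables.items():
        rho = _GENETIC_SHARE[zyg] * h2 + c2
        # finite-difference steps of the optimizer may peek just past the
        # h2 + c2 <= 1 constraint; clip instead of returning -inf
        rho = min(max(rho, -1.0 + 1e-9), 1.0 - 1e-9)
        ll += float(np.sum(table * np.log(_binary_cells(tau, rho))))
    return ll


def fit_binary(
    frame: pd.DataFrame,
    trait: str,
    model: str = "ACE",
    covariates: list[str] | None = None,
    n_starts: int = 3,
) -> AceFit:
    """ML fit of the liability-threshold model to a binary trait.

    Each zygosity group's 2x2 concordance counts are multinomial with
    cell probabilities given by bivariate-normal orthant probabilities at
    liability correlation h2 + c2 (MZ) or h2/2 + c2 (DZ) and a common
    threshold tau; h2 + c2 + e2 = 1 is enforced on the liability scale.
    With covariates, member thresholds become tau - x_j' beta and the
    likelihood is evaluated pair by pair.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if covariates:
        return _fit_binary_covariates(frame, trait, model, covariates, n_starts)
    pairs = pair_table(frame, trait)
    vals = np.concatenate([pairs["y1"].to_numpy(float), pairs["y2"].to_numpy(float)])
    if not set(np.unique(vals)).issubset({0.0, 1.0}):
        raise ValueError(f"trait {trait} is not binary 0/1")
    tables = {}
    n_pairs = {}
    for zyg in ("MZ", "DZ"):
        sub = pairs[pairs["zygosity"] == zyg]
        tables[zyg] = concordance_table(sub["y1"].to_numpy(), sub["y2"].to_numpy())
        n_pairs[zyg] = len(sub)
        marg = tables[zyg][1, :].sum() + tables[zyg][:, 1].sum()
        if n_pairs[zyg] > 0 and (marg == 0 or marg == 2 * n_pairs[zyg]):
            raise FitError(f"{zyg} concordance margin is degenerate for {trait}")
    n_tot = sum(n_pairs.values())
    if n_tot < 3:
        raise FitError(f"only {n_tot} complete pairs for trait {trait}")

    free = [f for f in FREE[model] if f != "e"]  # e2 = 1 - h2 - c2
    prev = vals.mean()
    tau0 = float(stats.norm.isf(min(max(prev, 1e-4), 1 - 1e-4)))

    # moment start from tetrachoric correlations where estimable
    def tet(zyg):
        sub = pairs[pairs["zygosity"] == zyg]
        if len(sub) < 10:
            return 0.0
        try:
            return tetrachoric(sub["y1"].to_numpy(), sub["y2"].to_numpy())[0]
        except ValueError:
            return 0.0
    rmz, rdz = tet("MZ"), tet("DZ")
    a0 = min(max(2.0 * (rmz - rdz), 0.05), 0.9)
    c0 = min(max(2.0 * rdz - rmz, 0.05), 0.9 - a0)
    start_map = {"a": a0, "c": c0}

    def nll(theta):
        tau = theta[0]
        comp = dict(zip(free, theta[1:]))
        return -_binary_loglik(tau, comp.get("a", 0.0), comp.get("c", 0.0), tables)

    base = np.array([tau0] + [start_map[f] for f in free])
    rng = np.random.default_rng(54321)  # fixed jitter seed
    starts = [base]
    for _ in range(n_starts - 1):
        jit = base.copy()
        if free:
            jit[1:] = np.clip(jit[1:] * np.exp(rng.normal(0, 0.4, len(free))),
                              1e-3, 0.95)
        starts.append(jit)

    bounds = [(-5.0, 5.0)] + [(0.0, 1.0 - 1e-9)] * len(free)
    constraints = []
    if len(free) == 2:
        constraints = [{"type": "ineq",
                        "fun": lambda th: 1.0 - 1e-9 - th[1] - th[2]}]
    best = None
    ok = False
    for s0 in starts:
        res = optimize.minimize(nll, s0, method="SLSQP", bounds=bounds,
                                constraints=constraints,
                                options={"ftol": 1e-12, "maxiter": 500})
        ok = ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or not ok:
        raise FitError(f"binary {model} fit failed for {trait}: "
                       f"{getattr(best, 'message', 'no result')}")

    tau_hat = float(best.x[0])
    comp_hat = dict(zip(free, [float(v) for v in best.x[1:]]))
    h2 = comp_hat.get("a", 0.0)
    c2 = comp_hat.get("c", 0.0)
    e2 = 1.0 - h2 - c2
    ll = -best.fun
    k = 1 + len(free)
    boundary = any(v < _BOUNDARY_TOL or v > 1 - _BOUNDARY_TOL
                   for v in comp_hat.values()) or e2 < _BOUNDARY_TOL

    se, cov_free, free_names = _binary_ses(tau_hat, comp_hat, free, tables, boundary)
    comp = VarianceComponents(h2=h2, c2=c2, e2=e2, scale="liability",
                              source="ml", se=se)
    params = {"tau": tau_hat}
    params.update({f"{f}2": comp_hat[f] for f in free})
    return AceFit(
        model=model, trait=trait, scale="liability", params=params,
        loglik=ll, bic=-2.0 * ll + k * math.log(n_tot), n_pairs=n_pairs,
        components=comp, converged=True, n_starts=len(starts),
        boundary=boundary, cov_free=cov_free, free_names=free_names,
    )


def _fit_binary_covariates(frame, trait, model, covariates, n_starts):
    """Pair-by-pair liability likelihood with covariate-shifted thresholds."""
    y, X, zyg = _design(frame, trait, covariates)
    if not set(np.unique(y)).issubset({0.0, 1.0}):
        raise ValueError(f"trait {trait} is not binary 0/1")
    mz = zyg == "MZ"
    n_pairs = {"MZ": int(mz.sum()), "DZ": int((~mz).sum())}
    n_tot = len(y)
    if n_tot < 3:
        raise FitError(f"only {n_tot} complete pairs for trait {trait}")
    p = X.shape[2]
    free = [f for f in FREE[model] if f != "e"]

    def loglik(beta, h2, c2):
        taus = -(X @ beta)  # (n, 2): member thresholds
        ll = 0.0
        for i in range(n_tot):
            rho = (1.0 if mz[i] else 0.5) * h2 + c2
            rho = min(max(rho, -1.0 + 1e-9), 1.0 - 1e-9)
            t1, t2 = taus[i]
            p11 = bvn_upper(t1, t2, rho)
            p1 = float(ndtr(-t1))
            p2 = float(ndtr(-t2))
            cells = ((max(1 - p1 - p2 + p11, 1e-300), max(p2 - p11, 1e-300)),
                     (max(p1 - p11, 1e-300), max(p11, 1e-300)))
            ll += math.log(cells[int(y[i, 0])][int(y[i, 1])])
        return ll

    # probit start for beta; modest familial start for the components
    from scipy.stats import norm as _norm
    prev = min(max(float(y.mean()), 1e-4), 1 - 1e-4)
    beta0 = np.zeros(p)
    beta0[0] = float(_norm.ppf(prev))
    start_map = {"a": 0.3, "c": 0.2}

    def nll(theta):
        beta = theta[:p]
        comp = dict(zip(free, theta[p:]))
        return -loglik(beta, comp.get("a", 0.0), comp.get("c", 0.0))

    base = np.concatenate([beta0, [start_map[f] for f in free]])
    rng = np.random.default_rng(54321)
    starts = [base]
    for _ in range(n_starts - 1):
        jit = base.copy()
        jit[:p] += rng.normal(0, 0.1, p)
        if free:
            jit[p:] = np.clip(jit[p:] * np.exp(rng.normal(0, 0.4, len(free))),
                              1e-3, 0.95)
        starts.append(jit)
    bounds = [(None, None)] * p + [(0.0, 1.0 - 1e-9)] * len(free)
    constraints = []
    if len(free) == 2:
        constraints = [{"type": "ineq",
                        "fun": lambda th: 1.0 - 1e-9 - th[p] - th[p + 1]}]
    best = None
    ok = False
    for s0 in starts:
        res = optimize.minimize(nll, s0, method="SLSQP", bounds=bounds,
                                constraints=constraints,
                                options={"ftol": 1e-10, "maxiter": 300})
        ok = ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or not ok:
        raise FitError(f"binary {model} fit with covariates failed for {trait}")
    beta_hat = best.x[:p]
    comp_hat = dict(zip(free, [float(v) for v in best.x[p:]]))
    h2 = comp_hat.get("a", 0.0)
    c2 = comp_hat.get("c", 0.0)
    ll = -best.fun
    k = p + len(free)
    boundary = any(v < _BOUNDARY_TOL or v > 1 - _BOUNDARY_TOL
                   for v in comp_hat.values()) or (1 - h2 - c2) < _BOUNDARY_TOL
    comp = VarianceComponents(h2=h2, c2=c2, e2=1 - h2 - c2,
                              scale="liability", source="ml")
    params = {f"beta{j}": float(b) for j, b in enumerate(beta_hat)}
    params.update({f"{f}2": comp_hat[f] for f in free})
    return AceFit(
        model=model, trait=trait, scale="liability", params=params,
        loglik=ll, bic=-2.0 * ll + k * math.log(n_tot), n_pairs=n_pairs,
        components=comp, converged=True, n_starts=len(starts),
        boundary=boundary,
    )


def _binary_ses(tau, comp_hat, free, tables, boundary):
    if boundary or not free:
        return {}, None, ()
    theta = np.array([tau] + [comp_hat[f] for f in free])

    def nll(th):
        c = dict(zip(free, th[1:]))
        return -_binary_loglik(th[0], c.get("a", 0.0), c.get("c", 0.0), tables)

    H = _num_hessian(nll, theta)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return {}, None, ()
    if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
        return {}, None, ()
    vcov = cov[1:, 1:]
    idx = {f: j for j, f in enumerate(free)}
    se = {}
    if "a" in idx:
        se["h2"] = math.sqrt(vcov[idx["a"], idx["a"]])
    if "c" in idx:
        se["c2"] = math.sqrt(vcov[idx["c"], idx["c"]])
    grad = -np.ones(len(free))  # e2 = 1 - h2 - c2
    var_e = float(grad @ vcov @ grad)
    if var_e > 0:
        se["e2"] = math.sqrt(var_e)
    return se, vcov, tuple(free)


# ---------------------------------------------------------------------------
# Wald intervals, model comparison, stratified fits
# ---------------------------------------------------------------------------

def wald_ci(fit: AceFit, level: float = 0.95) -> VarianceComponents:
    """Fill untruncated Wald CIs and two-sided p-values into the fit's
    components; components fixed at zero by the model get no interval."""
    z = stats.norm.isf((1.0 - level) / 2.0)
    comp = fit.components
    for name in ("h2", "c2", "e2"):
        s = comp.se.get(name)
        if s is None or not np.isfinite(s):
            continue
        est = getattr(comp, name)
        comp.ci[name] = (est - z * s, est + z * s)
        comp.p[name] = float(2.0 * stats.norm.sf(abs(est) / s)) if s > 0 else float("nan")
    return comp


def fit_ladder(
    frame: pd.DataFrame,
    trait: str,
    scale: str = "liability",
    covariates: list[str] | None = None,
) -> dict[str, AceFit]:
    """Fit the full ACE/AE/CE/E ladder on one dataset.

    ``scale`` selects the binary liability-threshold likelihood or the
    observed-scale Gaussian likelihood (the latter doubles as the
    sensitivity option for binary traits)."""
    fits = {}
    for model in MODELS:
        if scale == "liability":
            fits[model] = fit_binary(frame, trait, model=model,
                                     covariates=covariates)
        else:
            fits[model] = fit_continuous(frame, trait, model=model,
                                         covariates=covariates)
        wald_ci(fits[model])
    return fits


def compare_and_reduce(fits: dict[str, AceFit]) -> AceFit:
    """Select the reported model.

    If the full-model c2 sits on the zero boundary the AE fit is
    reported (and symmetrically h2 -> CE); when both are at the boundary,
    or neither, the BIC-minimizing candidate wins.
    """
    ace = fits["ACE"]
    c_zero = ace.components.c2 < _BOUNDARY_TOL
    a_zero = ace.components.h2 < _BOUNDARY_TOL
    if c_zero and not a_zero and "AE" in fits:
        sel, why = fits["AE"], "ACE c2 at zero boundary; reduced to AE"
    elif a_zero and not c_zero and "CE" in fits:
        sel, why = fits["CE"], "ACE h2 at zero boundary; reduced to CE"
    else:
        sel = min(fits.values(), key=lambda f: f.bic)
        why = f"BIC-minimizing model among {sorted(fits)}"
    sel.selection_note = why
    return sel


def stratified_ace(
    frame: pd.DataFrame,
    trait: str,
    strata_col: str,
    scale: str = "liability",
    min_pairs_per_zygosity: int = 30,
) -> pd.DataFrame:
    """Per-stratum descriptives plus the selected variance decomposition.

    Strata with fewer complete pairs than ``min_pairs_per_zygosity`` in
    either zygosity get descriptives only, with a status note."""
    from .descriptives import prevalence  # local import; no cycle at module load
    from .twin_correlations import pearson_by_zygosity

    rows = []
    for stratum, sub in frame.groupby(strata_col, sort=True, observed=True):
        pairs = pair_table(sub, trait)
        n_mz = int((pairs["zygosity"] == "MZ").sum())
        n_dz = int((pairs["zygosity"] == "DZ").sum())
        row = {"stratum": str(stratum), "n_pairs_mz": n_mz, "n_pairs_dz": n_dz}
        prev_all = prevalence(sub, trait)[0]
        row["prevalence"] = prev_all.prevalence
        for zyg in ("MZ", "DZ"):
            zsub = sub[sub["zygosity"] == zyg]
            est = prevalence(zsub, trait)[0] if len(zsub) else None
            row[f"prevalence_{zyg.lower()}"] = est.prevalence if est else float("nan")
        corr = pearson_by_zygosity(sub, trait)
        row["r_mz"], row["r_dz"] = corr["MZ"].r, corr["DZ"].r
        if min(n_mz, n_dz) < min_pairs_per_zygosity:
            row.update({"model": "", "h2": float("nan"), "c2": float("nan"),
                        "e2": float("nan"), "bic": float("nan"),
                        "status": f"fewer than {min_pairs_per_zygosity} "
                                  "complete pairs in a zygosity group; "
                                  "descriptives only"})
            rows.append(row)
            continue
        try:
            fits = fit_ladder(sub, trait, scale=scale)
            sel = compare_and_reduce(fits)
        except FitError as exc:
            row.update({"model": "", "h2": float("nan"), "c2": float("nan"),
                        "e2": float("nan"), "bic": float("nan"),
                        "status": f"fit failed: {exc}"})
            rows.append(row)
            continue
        comp = sel.components
        row.update({"model": sel.model, "h2": comp.h2, "c2": comp.c2,
                    "e2": comp.e2, "bic": sel.bic, "status": "ok"})
        for name in ("h2", "c2", "e2"):
            lo, hi = comp.ci.get(name, (float("nan"), float("nan")))
            row[f"{name}_lo"], row[f"{name}_hi"] = lo, hi
            row[f"{name}_p"] = comp.p.get(name, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)
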