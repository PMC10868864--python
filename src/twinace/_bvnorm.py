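"""Bivariate standard-normal probabilities via Owen's T function.

The pair likelihood of a thresholded liability model needs orthant
probabilities P(L1 > t1, L2 > t2) to high absolute accuracy; Owen's T
gives the CDF to ~1e-14 without quadrature.
"""

from __future__ import annotations

import math

from scipy.special import ndtr, owens_t

# Perturbing a zero threshold by this amount changes the CDF by < 4e-16
# (the density is bounded by 1/sqrt(2*pi)), so the h*k sign rules below
# never see an exact zero.
_ZERO_NUDGE = 1e-15
_RHO_DEGENERATE = 1.0 - 1e-12


def bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho."""
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [-1, 1], got {rho}")
    if rho >= _RHO_DEGENERATE:
        return float(ndtr(min(h, k)))
    if rho <= -_RHO_DEGENERATE:
        return float(max(0.0, ndtr(h) + ndtr(k) - 1.0))
    if h == 0.0:
        h = _ZERO_NUDGE
    if k == 0.0:
        k = _ZERO_NUDGE
    s = math.sqrt(1.0 - rho * rho)
    a_h = (k - rho * h) / (h * s)
    a_k = (h - rho * k) / (k * s)
    beta = 0.0 if h * k > 0.0 else 0.5
    val = 0.5 * (ndtr(h) + ndtr(k)) - float(owens_t(h, a_h)) - float(owens_t(k, a_k)) - beta
    # clip tiny negative round-off
    return min(1.0, max(0.0, val))


def bvn_upper(t1: float, t2: float, rho: float) -> float:
    """P(X > t1, Y > t2); the (1,1) cell of a liability-threshold pair."""
    if rho >= _RHO_DEGENERATE:
        return float(ndtr(-max(t1, t2)))
    if rho <= -_RHO_DEGENERATE:
        return float(max(0.0, ndtr(-t2) - ndtr(t1)))
    return min(1.0, max(0.0, 1.0 - float(ndtr(t1)) - float(ndtr(t2)) + bvn_cdf(t1, t2, rho)))
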