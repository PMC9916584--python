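"""Descriptive and inferential circular statistics.

Implements the vector-sum descriptives (mean direction, mean resultant
length r, von Mises concentration kappa with the Best-Fisher inversion and
Fisher's small-sample correction), the Rayleigh test of uniformity, the
two-sample Mardia-Watson-Wheeler uniform-scores test, and a paired
Hotelling T-squared test on unit-vector differences. All angles are in
degrees; all tests are two-tailed at the conventional alpha = .05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import special, stats

from .angles import AngularInterval, circ_mean_r

__all__ = [
    "CircularDescriptives",
    "describe",
    "kappa_mle",
    "rayleigh_test",
    "mww_test",
    "hotelling_paired",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CircularDescriptives:
    mean_direction: float          # canonical degrees; NaN when r = 0
    r: float                       # mean resultant length in [0, 1]
    kappa: float                   # von Mises concentration, >= 0
    ci95: Optional[AngularInterval]  # 95% CI of the mean direction
    n: int


def _a1inv(r: float) -> float:
    """Best-Fisher piecewise approximation to the inverse of A1(k)=I1/I0."""
    if r < 0.53:
        return 2.0 * r + r ** 3 + 5.0 * r ** 5 / 6.0
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    return 1.0 / (r ** 3 - 4.0 * r ** 2 + 3.0 * r)


def kappa_mle(r: float, n: int) -> float:
    """Maximum-likelihood kappa from the mean resultant length.

    Solves A1(kappa) = r (Best-Fisher starting value, Newton refinement to
    1e-10) and applies Fisher's small-sample correction for n <= 15.
    Returns 0 for r <= 0 and +inf for r indistinguishable from 1.
    """
    if r <= 0.0:
        return 0.0
    if r >= 1.0 - 1e-12:
        return float("inf")
    k = _a1inv(r)
    for _ in range(50):
        a1 = special.i1e(k) / special.i0e(k)
        # d A1/dk = 1 - A1/k - A1^2
        deriv = 1.0 - a1 / k - a1 ** 2 if k > 0 else 0.5
        step = (a1 - r) / deriv
        k -= step
        if k <= 0:
            k = 1e-8
        if abs(step) < 1e-10:
            break
    if n <= 15:
        if k < 2.0:
            k = max(k - 2.0 / (n * k), 0.0)
        else:
            k = (n - 1.0) ** 3 * k / (n ** 3 + n)
    return float(k)


def describe(angles, weights=None) -> CircularDescriptives:
    """Vector-sum descriptives of a circular sample (degrees).

    The 95% CI of the mean direction uses the large-sample dispersion
    method and requires n >= 3 and a resultant that is informative enough;
    otherwise the CI is None. A zero resultant leaves the mean direction
    (and CI) undefined.
    """
    a = np.asarray(angles, dtype=float)
    n = a.size
    if n < 1:
        raise ValueError("need at least one angle")
    mean, r = circ_mean_r(a, weights=weights)
    kappa = kappa_mle(r, n)
    ci = None
    if n >= 3 and np.isfinite(mean) and r > 0:
        rad = np.radians(a - mean)
        rho2 = float(np.cos(2.0 * rad).mean())
        delta = (1.0 - rho2) / (2.0 * r ** 2)  # circular dispersion
        se = np.sqrt(delta / n)
        z = stats.norm.ppf(0.975)
        if z * se < 1.0:
            half = np.degrees(np.arcsin(z * se))
            ci = AngularInterval(mean - half, mean + half)
    return CircularDescriptives(mean_direction=mean, r=r, kappa=kappa,
                                ci95=ci, n=n)


def rayleigh_test(angles):
    """Rayleigh test of circular uniformity.

    Returns ``(z, p)`` with z = n * r**2 and the standard series
    approximation for the p-value. Requires n >= 5.
    """
    a = np.asarray(angles, dtype=float)
    n = a.size
    if n < 5:
        raise ValueError("Rayleigh approximation needs n >= 5")
    _, r = circ_mean_r(a)
    z = n * r ** 2
    p = np.exp(-z) * (1.0 + (2.0 * z - z ** 2) / (4.0 * n)
                      - (24.0 * z - 132.0 * z ** 2 + 76.0 * z ** 3
                         - 9.0 * z ** 4) / (288.0 * n ** 2))
    return float(z), float(min(max(p, 0.0), 1.0))


def mww_test(sample_a, sample_b):
    """Two-sample Mardia-Watson-Wheeler uniform-scores test.

    Pools both samples, converts ranks to uniform scores on the circle and
    compares the per-sample resultants; the statistic W is asymptotically
    chi-square with 2 df. Ties are broken by midranks with a logged
    warning. Returns ``(W, p)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("each sample needs n >= 5")
    pooled = np.concatenate([np.mod(a, 360.0), np.mod(b, 360.0)])
    if np.ptp(pooled) < 1e-12:
        raise ValueError("all values identical across both samples")
    ranks = stats.rankdata(pooled, method="average")
    if np.unique(pooled).size < pooled.size:
        log.warning("ties in Mardia-Watson-Wheeler input broken by midranks")
    n = pooled.size
    beta = 2.0 * np.pi * ranks / n
    w = 0.0
    for idx, m in ((slice(0, a.size), a.size),
                   (slice(a.size, n), b.size)):
        c = np.cos(beta[idx]).sum()
        s = np.sin(beta[idx]).sum()
        w += (c ** 2 + s ** 2) / m
    w *= 2.0
    p = stats.chi2.sf(w, df=2)
    return float(w), float(p)


def hotelling_paired(sample_a, sample_b):
    """Paired Hotelling T-squared test on unit-vector differences.

    Each angle is embedded as (cos, sin); the paired differences are tested
    against mean zero with Hotelling's one-sample T**2, referred to
    F(2, n - 2). Returns ``(F, p)``.
    """
    a = np.radians(np.asarray(sample_a, dtype=float))
    b = np.radians(np.asarray(sample_b, dtype=float))
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    d = np.column_stack([np.cos(a) - np.cos(b), np.sin(a) - np.sin(b)])
    dbar = d.mean(axis=0)
    if np.allclose(d, d[0], atol=1e-12):
        # degenerate: constant differences (e.g. identical paired samples)
        if np.hypot(*dbar) < 1e-12:
            return 0.0, 1.0
        return float("inf"), 0.0
    cov = np.cov(d, rowvar=False, ddof=1)
    t2 = float(n * dbar @ np.linalg.solve(cov, dbar))
    f = (n - 2) / (2.0 * (n - 1)) * t2
    p = stats.f.sf(f, 2, n - 2)
    return float(f), float(p)
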