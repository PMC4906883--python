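"""Expected co-contraction of two correlated noise-modulated EMG channels.

The generator models raw EMG as x(t) = n(t) * e(t) * sqrt(pi/2) with n
standard normal, so the expected rectified value equals the envelope e(t).
Within an antagonistic pair the two noise processes share a per-sample
correlation rho; the absolute values |n_a|, |n_b| then co-vary (evenly in
rho), which raises the expected per-sample co-contraction term
(min/max)*(min+max) without touching either channel's rectified mean. The
generator exploits this to steer the pair's co-contraction index
independently of the single-muscle activation targets.

This module computes g(r, rho) = E[(min/max)(min+max)] / a for envelopes
(a, r*a), r in [0, 1], by 2-D Gauss-Legendre quadrature on the folded
bivariate normal density, splitting the inner integral at the min/max kink
(accurate to ~2e-3 relative, verified against Monte Carlo), and inverts it
to find the rho that achieves a requested expected CCI.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.interpolate import RectBivariateSpline
from scipy.optimize import brentq

__all__ = ["expected_cci_unit", "expected_cci", "calibrate_rho", "RHO_MAX"]

_SQ = np.sqrt(np.pi / 2)
_ZMAX = 8.0
RHO_MAX = 0.995


def _phi2(x: np.ndarray, y: np.ndarray, rho: float) -> np.ndarray:
    det = 1.0 - rho * rho
    return np.exp(-(x * x - 2 * rho * x * y + y * y) / (2 * det)) / (2 * np.pi * np.sqrt(det))


def _fold_density(x: np.ndarray, y: np.ndarray, rho: float) -> np.ndarray:
    # joint density of (|X|, |Y|) on the positive quadrant; even in rho
    return 2.0 * (_phi2(x, y, rho) + _phi2(x, -y, rho))


def expected_cci_unit(r: float, rho: float, nx: int = 96, ny: int = 48) -> float:
    """g(r, rho): expected per-sample CCI term for unit-mean envelopes (1, r)."""
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must lie in [0, 1]")
    rho = abs(rho)
    if r == 0.0:
        return 0.0
    gx, wx = np.polynomial.legendre.leggauss(nx)
    gy, wy = np.polynomial.legendre.leggauss(ny)
    x = 0.5 * _ZMAX * (gx + 1.0)
    wxs = 0.5 * _ZMAX * wx
    tot = 0.0
    for xi, wi in zip(x, wxs):
        u = _SQ * xi
        cut = min(xi / r, _ZMAX)
        y1 = 0.5 * cut * (gy + 1.0)
        w1 = 0.5 * cut * wy
        v1 = _SQ * r * y1
        t1 = np.divide(v1, u, out=np.zeros_like(v1), where=u > 0) * (v1 + u)
        tot += wi * np.sum(w1 * t1 * _fold_density(xi, y1, rho))
        if cut < _ZMAX:
            y2 = cut + 0.5 * (_ZMAX - cut) * (gy + 1.0)
            w2 = 0.5 * (_ZMAX - cut) * wy
            v2 = _SQ * r * y2
            t2 = u / v2 * (u + v2)
            tot += wi * np.sum(w2 * t2 * _fold_density(xi, y2, rho))
    return float(tot)


@lru_cache(maxsize=1)
def _g_spline() -> RectBivariateSpline:
    rs = np.linspace(0.0, 1.0, 41)
    rhos = np.linspace(0.0, RHO_MAX, 36)
    table = np.empty((rs.size, rhos.size))
    for i, r in enumerate(rs):
        for j, rho in enumerate(rhos):
            table[i, j] = expected_cci_unit(r, rho, nx=64, ny=32)
    return RectBivariateSpline(rs, rhos, table, kx=3, ky=3, s=0)


def expected_cci(hi: np.ndarray, lo: np.ndarray, rho: float) -> float:
    """Expected windowed CCI for envelope pair (element-wise hi >= lo >= 0)."""
    hi = np.asarray(hi, dtype=float)
    lo = np.asarray(lo, dtype=float)
    r = np.divide(lo, hi, out=np.zeros_like(lo), where=hi > 0)
    g = _g_spline()(np.clip(r, 0.0, 1.0), abs(rho), grid=False)
    return float(np.mean(hi * g))


def calibrate_rho(hi: np.ndarray, lo: np.ndarray, target: float) -> float:
    """Noise correlation achieving an expected windowed CCI of ``target``.

    Monotone in rho on [0, RHO_MAX]; values outside the attainable range are
    clamped to the nearest endpoint.
    """
    f = lambda rho: expected_cci(hi, lo, rho) - target
    if f(0.0) >= 0.0:
        return 0.0
    if f(RHO_MAX) <= 0.0:
        return RHO_MAX
    return float(brentq(f, 0.0, RHO_MAX, xtol=1e-6))
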