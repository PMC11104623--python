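"""Hartigan's dip statistic for unimodality, with Monte-Carlo p-values.

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and any unimodal CDF (convex up to a mode, concave after it; an atom at
the mode is allowed).  It is computed exactly by enumerating mode positions
-- in the gaps between distinct sample values and at the values themselves --
and checking, for each side of the mode, the least uniform band width within
which a convex (resp. concave) function can stay: a greatest-convex-minorant
/ least-concave-majorant feasibility computation.  The implementation is
validated in the test suite against a linear-programming brute force over
piecewise-linear unimodal CDFs.

Known properties used as sanity anchors: for a sample of n distinct values
``1/(2n) <= D <= 0.25``; two equal point masses approach the upper bound
0.25; a point mass has dip 0.

P-values are Monte-Carlo: the dip of ``n_mc`` uniform(0, 1) samples of the
same size forms the null distribution (the classical reference null).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import SampleTooSmallError

try:  # pragma: no cover - decoration only
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = ["DipResult", "dip_statistic", "dip_test", "dip_null"]


@dataclass(frozen=True)
class DipResult:
    """Dip statistic with its Monte-Carlo p-value."""

    D: float
    p_value: float
    n: int
    n_mc: int
    seed: Optional[int] = None


@njit(cache=False)
def _prefix_max_devs(u, lo, hi):  # pragma: no cover - numba-compiled
    """For each prefix 0..j of points (u, lo): the maximal deviation of the
    upper CDF step ``hi`` above the greatest convex minorant of ``lo``.

    Returns ``dev_drop[j]`` = max over i < j (own-point term excluded, used
    for a mode sitting exactly at point j where an atom absorbs the jump).
    The inclusive variant is ``max(dev_drop[j], hi[j] - lo[j])``.
    """
    m = u.size
    dev_drop = np.zeros(m)
    hull = np.empty(m, np.int64)
    top = 0
    hull[0] = 0
    for j in range(m):
        if j > 0:
            # push j onto the lower convex hull of (u, lo)
            while top >= 1:
                i1 = hull[top - 1]
                i2 = hull[top]
                if ((lo[i2] - lo[i1]) * (u[j] - u[i1])
                        >= (lo[j] - lo[i1]) * (u[i2] - u[i1])):
                    top -= 1
                else:
                    break
            top += 1
            hull[top] = j
        # evaluate hull at all points i < j and track max(hi - hull)
        best = 0.0
        for seg in range(top):
            a = hull[seg]
            b = hull[seg + 1]
            inv = 1.0 / (u[b] - u[a])
            for i in range(a, b):
                hv = lo[a] + (lo[b] - lo[a]) * (u[i] - u[a]) * inv
                d = hi[i] - hv
                if d > best:
                    best = d
        dev_drop[j] = best
    return dev_drop


@njit(cache=False)
def _dip_from_bands(u, lo, hi):  # pragma: no cover - numba-compiled
    m = u.size
    if m <= 1:
        return 0.0
    devL = _prefix_max_devs(u, lo, hi)
    # right side via the complement-reversal duality of CDFs
    u2 = -u[::-1]
    lo2 = 1.0 - hi[::-1]
    hi2 = 1.0 - lo[::-1]
    devR = _prefix_max_devs(u2, lo2, hi2)
    jump_max_left = np.zeros(m)
    running = 0.0
    for j in range(m):
        running = max(running, hi[j] - lo[j])
        jump_max_left[j] = running
    best = 1.0
    # mode in the gap between point k-1 and point k (k = 0..m)
    for k in range(m + 1):
        eL = 0.0
        if k >= 1:
            eL = max(devL[k - 1], jump_max_left[k - 1])
        eR = 0.0
        if k < m:
            jr = m - 1 - k
            running = devR[jr]
            # inclusive variant on the right: add the max jump over k..m-1
            jmax = 0.0
            for i in range(k, m):
                if hi[i] - lo[i] > jmax:
                    jmax = hi[i] - lo[i]
            eR = max(running, jmax)
        v = eL if eL > eR else eR
        if v < best:
            best = v
    # mode exactly at point j (atom at the mode: own jump excluded)
    for j in range(m):
        eL = devL[j]
        eR = devR[m - 1 - j]
        v = eL if eL > eR else eR
        if v < best:
            best = v
    return 0.5 * best


def _bands(x):
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    u, idx, cnt = np.unique(x, return_index=True, return_counts=True)
    hi = (idx + cnt) / n
    lo = idx / n
    return u, lo, hi


def dip_statistic(sample) -> float:
    """Exact dip statistic of a 1-D sample (ties allowed)."""
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 2:
        raise SampleTooSmallError("dip statistic needs at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    u, lo, hi = _bands(x)
    return float(_dip_from_bands(u, lo, hi))


@njit(cache=False)
def _dips_sorted_rows(rows):  # pragma: no cover - numba-compiled
    """Dip of each row of an already sorted (n_mc, n) matrix of distinct
    values (continuous null samples have no ties almost surely)."""
    n_mc, n = rows.shape
    lo = np.arange(n) / n
    hi = (np.arange(n) + 1.0) / n
    out = np.empty(n_mc)
    for r in range(n_mc):
        out[r] = _dip_from_bands(rows[r], lo, hi)
    return out


def dip_null(n: int, n_mc: int = 9999, seed=None) -> np.ndarray:
    """Monte-Carlo null distribution of the dip: ``n_mc`` uniform(0, 1)
    samples of size ``n``.  Reusable across tests of the same sample size."""
    rng = np.random.default_rng(seed)
    rows = np.sort(rng.random((n_mc, n)), axis=1)
    return _dips_sorted_rows(rows)


def dip_test(sample, n_mc: int = 9999, seed=None,
             null_dips: Optional[np.ndarray] = None) -> DipResult:
    """Dip test of unimodality with a Monte-Carlo uniform null.

    ``p = (#{null >= D} + 1) / (n_mc + 1)`` so p is never exactly zero.  A
    precomputed ``null_dips`` array (from :func:`dip_null` at the same n) can
    be passed to amortise the null across repeated tests.
    """
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 4:
        raise SampleTooSmallError("dip test needs at least 4 observations")
    d = dip_statistic(x)
    if null_dips is None:
        null_dips = dip_null(x.size, n_mc=n_mc, seed=seed)
    n_mc = int(null_dips.size)
    p = (np.count_nonzero(null_dips >= d) + 1) / (n_mc + 1)
    return DipResult(D=d, p_value=float(p), n=int(x.size), n_mc=n_mc,
                     seed=seed if np.isscalar(seed) else None)
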