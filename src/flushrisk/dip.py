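"""Hartigan & Hartigan's dip statistic of unimodality.

The dip of a distribution function ``F`` is the smallest sup-norm distance
between ``F`` and the class of unimodal distribution functions (convex up to
some mode, concave beyond it).  Large dips indicate multimodal structure;
for an empirical CDF of ``n`` distinct values the dip lies in
``[1/(2n), 1/4]``, and it is invariant under increasing affine transforms of
the data.

The computation follows the classical modal-interval iteration on the sorted
sample: fit the greatest convex minorant (GCM) and least concave majorant
(LCM) of the empirical CDF on a candidate modal interval, find the largest
separation between the two fits, shrink the candidate interval to the
separation's touch points, and accumulate the CDF deviations the unimodal
fit must absorb outside the interval; iterate until the remaining separation
no longer exceeds the accumulated deviation.  All bookkeeping is done in
count units (the empirical CDF scaled by ``n``); the final statistic is the
accumulated count deviation divided by ``2n`` — the factor 2 because an
optimal unimodal fit splits each one-sided deviation evenly.

The p-value is calibrated by Monte Carlo against samples of the same size
from the uniform distribution on (0, 1), the asymptotically least favourable
unimodal null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DipResult", "dip_statistic", "dip_null_table", "dip_test"]


@dataclass(frozen=True)
class DipResult:
    """Dip statistic with its Monte Carlo p-value."""

    statistic: float
    p_value: float
    n: int
    n_null_samples: int
    seed: int


def _lower_hull(x, y, lo: int, hi: int) -> list:
    """Indices of the greatest convex minorant of points (x[i], y[i]), lo..hi."""
    hull = [lo]
    for i in range(lo + 1, hi + 1):
        # pop while the last hull point lies on or above the chord
        while len(hull) >= 2:
            j, k = hull[-1], hull[-2]
            if (y[j] - y[k]) * (x[i] - x[j]) <= (y[i] - y[j]) * (x[j] - x[k]):
                break
            hull.pop()
        # drop duplicates in x, keeping the lower (earlier) point
        if x[hull[-1]] == x[i]:
            if y[i] < y[hull[-1]]:
                hull[-1] = i
            continue
        hull.append(i)
    if hull[-1] != hi:
        hull.append(hi)
    return hull


def _upper_hull(x, y, lo: int, hi: int) -> list:
    """Indices of the least concave majorant of points (x[i], y[i]), lo..hi."""
    hull = [lo]
    for i in range(lo + 1, hi + 1):
        while len(hull) >= 2:
            j, k = hull[-1], hull[-2]
            if (y[j] - y[k]) * (x[i] - x[j]) >= (y[i] - y[j]) * (x[j] - x[k]):
                break
            hull.pop()
        if x[hull[-1]] == x[i]:
            if y[i] > y[hull[-1]]:
                hull[-1] = i
            continue
        hull.append(i)
    if hull[-1] != hi:
        hull.append(hi)
    return hull


def _interp(xq: float, hx: np.ndarray, hy: np.ndarray) -> float:
    """Piecewise-linear value of a hull at xq (hull x strictly increasing)."""
    return float(np.interp(xq, hx, hy))


def _max_dev_above(x, lo: int, hi: int, hull: list) -> float:
    """Largest count deviation of the upper ECDF above the GCM, over [lo, hi].

    The GCM interpolates lower ECDF counts (index i); the empirical CDF
    reaches i+1 just right of x[i], so the deviation at i is
    (i + 1) - gcm(x[i]).  Minimum reportable deviation is one count (the jump
    itself).
    """
    best = 1.0
    for a, b in zip(hull[:-1], hull[1:]):
        if b <= lo or a >= hi:
            continue
        if b - a > 1 and x[b] != x[a]:
            c = (b - a) / (x[b] - x[a])
            idx = np.arange(a, b + 1)
            t = (idx - a + 1) - (np.asarray(x[a : b + 1]) - x[a]) * c
            m = float(t.max())
            if m > best:
                best = m
    return best


def _max_dev_below(x, lo: int, hi: int, hull: list) -> float:
    """Largest count deviation of the LCM above the lower ECDF, over [lo, hi].

    The LCM interpolates upper ECDF counts (index i + 1); the empirical CDF
    is still i just left of x[i], so the deviation at i is lcm(x[i]) - i.
    """
    best = 1.0
    for a, b in zip(hull[:-1], hull[1:]):
        if b <= lo or a >= hi:
            continue
        if b - a > 1 and x[b] != x[a]:
            c = (b - a) / (x[b] - x[a])
            idx = np.arange(a, b + 1)
            t = (np.asarray(x[a : b + 1]) - x[a]) * c - (idx - a - 1)
            m = float(t.max())
            if m > best:
                best = m
    return best


def dip_statistic(values) -> float:
    """Hartigan & Hartigan dip of a sample.

    Parameters
    ----------
    values
        Sample of at least 2 finite real numbers (missing values must be
        removed by the caller; NaN/inf are rejected).

    Returns
    -------
    float
        The dip, in [0, 0.25].  For n >= 2 distinct values it is at least
        1/(2n); a sample of identical values has dip 0.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError("dip_statistic needs at least 2 values")
    if not np.all(np.isfinite(arr)):
        raise ValueError("dip_statistic requires finite values")
    x = np.sort(arr)
    n = x.size
    if x[0] == x[-1]:
        return 0.0
    if n < 4:
        # any 3 increasing points admit a convex-concave interpolant through
        # the ECDF band midpoints, so only the half-jump remains
        return 0.5 / n
    xl = x.tolist()
    lo_y = list(range(n))  # lower ECDF counts at sample points
    hi_y = [i + 1 for i in range(n)]  # upper ECDF counts

    low, high = 0, n - 1
    dip = 1.0  # accumulated deviation in counts; >= one half-jump at the end
    for _ in range(n + 2):  # the modal interval strictly shrinks; n+2 is a guard
        gcm = _lower_hull(xl, lo_y, low, high)
        lcm = _upper_hull(xl, hi_y, low, high)
        gx = np.array([xl[i] for i in gcm])
        gy = np.array([float(i) for i in gcm])
        lx = np.array([xl[i] for i in lcm])
        ly = np.array([float(i + 1) for i in lcm])

        # separation between the two fits, checked at the touch points of each
        d = -np.inf
        at_gcm = True
        arg = low
        for i in gcm:
            s = _interp(xl[i], lx, ly) - i
            if s > d:
                d, at_gcm, arg = s, True, i
        for i in lcm:
            s = (i + 1) - _interp(xl[i], gx, gy)
            if s > d:
                d, at_gcm, arg = s, False, i
        if d <= dip:
            break

        if at_gcm:
            new_low = arg
            # right end of the LCM segment containing x[arg]
            pos = int(np.searchsorted(lx, xl[arg], side="left"))
            new_high = lcm[min(pos, len(lcm) - 1)]
        else:
            new_high = arg
            # left end of the GCM segment containing x[arg]
            pos = int(np.searchsorted(gx, xl[arg], side="right")) - 1
            new_low = gcm[max(pos, 0)]

        dip_l = _max_dev_above(x, low, new_low, gcm)
        dip_u = _max_dev_below(x, new_high, high, lcm)
        dip = max(dip, dip_l, dip_u)
        if (new_low, new_high) == (low, high):
            break
        low, high = new_low, new_high

    return dip / (2.0 * n)


def dip_null_table(n: int, n_null_samples: int = 10_000, seed: int = 0) -> np.ndarray:
    """Dip statistics of ``n_null_samples`` uniform(0,1) samples of size ``n``.

    The uniform is the calibration null for the dip test; the table can be
    shared across tests on datasets of the same size.
    """
    if n_null_samples < 1:
        raise ValueError("n_null_samples must be >= 1")
    rng = np.random.default_rng(seed)
    return np.array([dip_statistic(rng.random(n)) for _ in range(n_null_samples)])


def dip_test(
    values,
    n_null_samples: int = 10_000,
    seed: int = 0,
    null_table: np.ndarray | None = None,
) -> DipResult:
    """Monte Carlo dip test of unimodality.

    The p-value is ``(1 + #{null dips >= observed}) / (1 + B)`` over ``B``
    uniform(0,1) samples of the same size (add-one continuity keeps the test
    valid at finite B).  Deterministic for a given seed.  A precomputed
    ``null_table`` (from :func:`dip_null_table`) may be supplied to amortise
    calibration across many tests at the same n.
    """
    arr = np.asarray(values, dtype=float).ravel()
    d = dip_statistic(arr)
    n = arr.size
    if null_table is None:
        null_table = dip_null_table(n, n_null_samples, seed)
    b = null_table.size
    p = (1.0 + float(np.sum(null_table >= d))) / (1.0 + b)
    return DipResult(statistic=d, p_value=p, n=n, n_null_samples=b, seed=seed)
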