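"""Exact brute-force dip computation by linear programming.

Independent oracle for ``flushrisk.dip.dip_statistic``: the dip is the
minimal ``d`` such that a unimodal CDF G (convex up to a mode m, concave
after, possibly with an atom exactly at m) stays within sup-distance d of
the empirical CDF.  For an optimal G it suffices to consider piecewise
linear G with knots at the unique sample values, with the mode at one of
those values; each mode choice is a small linear program and the dip is the
minimum over modes.

Encoding, for unique sorted values v_1..v_m with lower/upper ECDF values
a_j (just left of v_j) and b_j (at v_j):

* away from the mode G is continuous at v_j, so both one-sided constraints
  collapse to  b_j - d <= g_j <= a_j + d;
* at the mode v_k the CDF may jump: the left limit h must satisfy
  |h - a_k| <= d and the value g_k must satisfy |g_k - b_k| <= d, h <= g_k;
* the left part (points 1..k-1 plus h at v_k) must be convex, nondecreasing,
  nonnegative with nondecreasing nonnegative slopes (so it can fall to 0 at
  -inf); the right part (g_k at v_k plus points k+1..m) must be concave,
  nondecreasing with nonincreasing nonnegative slopes and values <= 1 (so it
  can rise to 1 at +inf);
* between consecutive sample values the ECDF is constant and equals both the
  upper value on the left and the lower value on the right, so no extra
  tube constraints arise in the gaps.

Modes strictly inside a gap are sup-distance limits of the adjacent
value-modes and cannot improve the optimum; gap-midpoint LPs are included
anyway as a safety check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def _ecdf_levels(x: np.ndarray):
    v, counts = np.unique(x, return_counts=True)
    n = x.size
    cum = np.cumsum(counts)
    b = cum / n
    a = (cum - counts) / n
    return v, a, b


def _solve(c, A_ub, b_ub):
    res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub), bounds=(None, None), method="highs")
    if not res.success:
        return np.inf
    return float(res.fun)


def _mode_lp(v, a, b, k):
    """Minimal d for a unimodal fit with mode at v[k] (0-based)."""
    m = len(v)
    # variables: g_0..g_{m-1}, h (left limit at mode), d
    nh = m
    nd = m + 1
    nvar = m + 2
    A, rhs = [], []

    def row():
        return [0.0] * nvar

    def add(coefs, ub):
        r = row()
        for i, c in coefs:
            r[i] += c
        A.append(r)
        rhs.append(ub)

    # band constraints
    for j in range(m):
        if j == k:
            add([(j, 1.0), (nd, -1.0)], b[j])   # g_k - d <= b_k
            add([(j, -1.0), (nd, -1.0)], -b[j])  # -g_k - d <= -b_k
        else:
            add([(j, 1.0), (nd, -1.0)], a[j])   # g_j <= a_j + d
            add([(j, -1.0), (nd, -1.0)], -b[j])  # g_j >= b_j - d
    add([(nh, 1.0), (nd, -1.0)], a[k])
    add([(nh, -1.0), (nd, -1.0)], -a[k])

    # monotone across the mode jump
    if k > 0:
        add([(k - 1, 1.0), (nh, -1.0)], 0.0)  # g_{k-1} <= h
    add([(nh, 1.0), (k, -1.0)], 0.0)  # h <= g_k

    # left side: points (v_j, g_j) j<k plus (v_k, h)
    left_idx = list(range(k)) + [None]  # None marks h
    left_x = list(v[:k]) + [v[k]]

    def var(i):
        return nh if left_idx[i] is None else left_idx[i]

    if left_x:
        add([(var(0), -1.0)], 0.0)  # g_1 >= 0
        # slopes nonnegative and nondecreasing
        for i in range(len(left_x) - 1):
            dx = left_x[i + 1] - left_x[i]
            add([(var(i), 1.0), (var(i + 1), -1.0)], 0.0)  # slope >= 0
        for i in range(len(left_x) - 2):
            dx1 = left_x[i + 1] - left_x[i]
            dx2 = left_x[i + 2] - left_x[i + 1]
            # (y2-y1)/dx1 <= (y3-y2)/dx2  ->  (y2-y1)dx2 - (y3-y2)dx1 <= 0
            add([(var(i), -dx2), (var(i + 1), dx2 + dx1), (var(i + 2), -dx1)], 0.0)

    # right side: points (v_k, g_k), (v_j, g_j) j>k
    right_idx = [k] + list(range(k + 1, m))
    right_x = [v[k]] + list(v[k + 1 :])
    add([(right_idx[-1], 1.0)], 1.0)  # g_m <= 1
    for i in range(len(right_x) - 1):
        add([(right_idx[i], 1.0), (right_idx[i + 1], -1.0)], 0.0)  # slope >= 0
    for i in range(len(right_x) - 2):
        dx1 = right_x[i + 1] - right_x[i]
        dx2 = right_x[i + 2] - right_x[i + 1]
        # slopes nonincreasing: (y2-y1)/dx1 >= (y3-y2)/dx2
        add(
            [(right_idx[i], dx2), (right_idx[i + 1], -(dx2 + dx1)), (right_idx[i + 2], dx1)],
            0.0,
        )

    c = row()
    c[nd] = 1.0
    return _solve(c, A, rhs)


def _gap_lp(v, a, b, i, t):
    """Minimal d with the mode at position t strictly inside gap (v_i, v_i+1)."""
    m = len(v)
    # variables: g_0..g_{m-1}, p_minus, p_plus, d
    pmi, ppl, nd = m, m + 1, m + 2
    nvar = m + 3
    A, rhs = [], []

    def add(coefs, ub):
        r = [0.0] * nvar
        for idx, c in coefs:
            r[idx] += c
        A.append(r)
        rhs.append(ub)

    for j in range(m):
        add([(j, 1.0), (nd, -1.0)], a[j])
        add([(j, -1.0), (nd, -1.0)], -b[j])
    # F equals b_i throughout the gap
    for var in (pmi, ppl):
        add([(var, 1.0), (nd, -1.0)], b[i])
        add([(var, -1.0), (nd, -1.0)], -b[i])
    add([(i, 1.0), (pmi, -1.0)], 0.0)  # g_i <= p_minus
    add([(pmi, 1.0), (ppl, -1.0)], 0.0)  # jump up only
    add([(ppl, 1.0), (i + 1, -1.0)], 0.0)  # p_plus <= g_{i+1}

    left_x = list(v[: i + 1]) + [t]
    left_v = list(range(i + 1)) + [pmi]
    add([(left_v[0], -1.0)], 0.0)
    for j in range(len(left_x) - 1):
        add([(left_v[j], 1.0), (left_v[j + 1], -1.0)], 0.0)
    for j in range(len(left_x) - 2):
        dx1 = left_x[j + 1] - left_x[j]
        dx2 = left_x[j + 2] - left_x[j + 1]
        add([(left_v[j], -dx2), (left_v[j + 1], dx2 + dx1), (left_v[j + 2], -dx1)], 0.0)

    right_x = [t] + list(v[i + 1 :])
    right_v = [ppl] + list(range(i + 1, m))
    add([(right_v[-1], 1.0)], 1.0)
    for j in range(len(right_x) - 1):
        add([(right_v[j], 1.0), (right_v[j + 1], -1.0)], 0.0)
    for j in range(len(right_x) - 2):
        dx1 = right_x[j + 1] - right_x[j]
        dx2 = right_x[j + 2] - right_x[j + 1]
        add([(right_v[j], dx2), (right_v[j + 1], -(dx2 + dx1)), (right_v[j + 2], dx1)], 0.0)

    c = [0.0] * nvar
    c[nd] = 1.0
    return _solve(c, A, rhs)


def dip_bruteforce(values, include_gap_modes: bool = True) -> float:
    """Exact dip by minimising the LP over all candidate mode placements."""
    x = np.sort(np.asarray(values, dtype=float).ravel())
    v, a, b = _ecdf_levels(x)
    m = len(v)
    if m == 1:
        return 0.0
    best = min(_mode_lp(v, a, b, k) for k in range(m))
    if include_gap_modes:
        for i in range(m - 1):
            t = 0.5 * (v[i] + v[i + 1])
            best = min(best, _gap_lp(v, a, b, i, t))
    return best
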