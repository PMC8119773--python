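"""Independent brute-force oracles used by the test suite.

These deliberately favour clarity over speed: the dip oracle optimises over
all piecewise-linear unimodal CDFs with a linear program per candidate mode,
and the clustering oracles use O(n^2) all-pairs scans with union-find.
"""

import numpy as np
from scipy.optimize import linprog
from scipy.spatial.distance import cdist


def _solve_mode_lp(v, l, u, dx, mode_kind, mode_idx):
    """Min sup-distance LP for one candidate mode placement.

    Variables are the CDF values at the knots plus the sup-error t.  For
    ``mode_kind == "atom"`` the knot ``mode_idx`` carries two values (before
    and after the jump an atom at the mode produces); for ``"segment"`` the
    CDF is continuous and the density peak lies inside segment ``mode_idx``.
    """
    m = v.size
    if mode_kind == "atom":
        j = mode_idx
        nv = m + 2  # g_0..g_{m-1} with an extra value at j, plus t
        # variable index of the value just left / just right of knot i
        idx_left = [i if i <= j else i + 1 for i in range(m)]
        idx_right = [i if i < j else i + 1 for i in range(m)]
    else:
        nv = m + 1
        idx_left = list(range(m))
        idx_right = list(range(m))
    T = nv - 1
    A, b = [], []

    def le(coeffs, rhs):  # sum coeffs·x <= rhs
        row = np.zeros(nv)
        for k, c in coeffs:
            row[k] += c
        A.append(row)
        b.append(rhs)

    for i in range(m):
        # F jumps from l_i to u_i at v_i: the pre-jump CDF value is compared
        # with l_i, the post-jump value with u_i (two-sided each).
        le([(idx_left[i], 1.0), (T, -1.0)], l[i])
        le([(idx_left[i], -1.0), (T, -1.0)], -l[i])
        le([(idx_right[i], -1.0), (T, -1.0)], -u[i])
        le([(idx_right[i], 1.0), (T, -1.0)], u[i])
        if idx_left[i] != idx_right[i]:
            le([(idx_left[i], 1.0), (idx_right[i], -1.0)], 0.0)  # monotone jump
    for i in range(m - 1):  # monotone between knots
        le([(idx_right[i], 1.0), (idx_left[i + 1], -1.0)], 0.0)

    def slope_coeffs(i, sign):
        # sign * slope of segment i as LP coefficients
        return [(idx_right[i], -sign / dx[i]), (idx_left[i + 1], sign / dx[i])]

    if mode_kind == "atom":
        j = mode_idx
        inc_pairs = [(i, i + 1) for i in range(j - 1)]           # segments < j
        dec_pairs = [(i, i + 1) for i in range(j, m - 2)]        # segments >= j
    else:
        p = mode_idx
        inc_pairs = [(i, i + 1) for i in range(p)]
        dec_pairs = [(i, i + 1) for i in range(p, m - 2)]
    for i, k in inc_pairs:  # slope_i <= slope_k
        le(slope_coeffs(i, 1.0) + slope_coeffs(k, -1.0), 0.0)
    for i, k in dec_pairs:  # slope_i >= slope_k
        le(slope_coeffs(i, -1.0) + slope_coeffs(k, 1.0), 0.0)
    for i in range(m - 1):  # a CDF never decreases
        le(slope_coeffs(i, -1.0), 0.0)

    bounds = [(0.0, 1.0)] * (nv - 1) + [(0.0, None)]
    c = np.zeros(nv)
    c[T] = 1.0
    res = linprog(c, A_ub=np.array(A), b_ub=np.array(b), bounds=bounds,
                  method="highs")
    return res.fun if res.success else np.inf


def dip_lp(values) -> float:
    """Dip by LP: min over unimodal CDFs G of sup |F_n - G|.

    G is piecewise linear with knots at the distinct data values; every
    candidate mode is enumerated — each inter-knot segment (continuous
    density peak) and each knot (where a unimodal CDF may carry an atom).
    """
    x = np.sort(np.asarray(values, dtype=float))
    v, counts = np.unique(x, return_counts=True)
    n = x.size
    m = v.size
    if m <= 1:
        return 0.0
    u = np.cumsum(counts) / n
    l = u - counts / n
    dx = np.diff(v)
    best = np.inf
    for j in range(m):
        best = min(best, _solve_mode_lp(v, l, u, dx, "atom", j))
    for p in range(m - 1):
        best = min(best, _solve_mode_lp(v, l, u, dx, "segment", p))
    return float(best)


def epsilon_components_bruteforce(points, d):
    """Connected components of the <=d Euclidean graph via union-find."""
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    if n:
        dm = cdist(pts, pts)
        for i in range(n):
            for j in range(i + 1, n):
                if dm[i, j] <= d:
                    ra, rb = find(i), find(j)
                    if ra != rb:
                        parent[ra] = rb
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    comps = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    return [sorted(g) for g in comps]
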