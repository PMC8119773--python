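"""Hartigan's dip test of unimodality.

The dip statistic of a sample is the smallest sup-norm distance between its
empirical CDF and any unimodal distribution function (a CDF that is convex
left of some mode and concave right of it; an atom is permitted at the
mode).  Large values indicate multi-modal structure.

The statistic is computed with the classic iterative scheme: fit the
greatest convex minorant (GCM) and least concave majorant (LCM) of the
empirical CDF on a working interval, locate the largest gap between the two
envelopes, bank the deviation of the CDF from the envelopes on the flanks
outside that gap, and narrow the working interval to the candidate modal
region until the within-interval envelope gap no longer exceeds the banked
deviation.  The result is half the final deviation, in CDF units.
Correctness is pinned down in the test suite by comparison with a direct
linear-programming oracle that optimises over all piecewise-linear unimodal
CDFs.

P-values compare the observed statistic against the dip distribution of
uniform samples of the same size, either through a bundled simulated
quantile table (interpolated on the ``dip * sqrt(n)`` scale) or by direct
Monte-Carlo simulation.
"""

from __future__ import annotations

import importlib.resources

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


class InsufficientDataError(ValueError):
    """Raised when a sample is too small for the dip test."""


@njit(cache=True)
def _curve_at(x, hull, h, off, xq):
    """Value at xq of the piecewise-linear envelope through (x[j], j + off).

    Walks segments in order and uses the first one containing xq; vertical
    segments (tied x) contribute their lower endpoint.
    """
    for k in range(h - 1):
        a = hull[k]
        b = hull[k + 1]
        if x[a] <= xq <= x[b]:
            if x[b] == x[a]:
                return a + off
            w = (xq - x[a]) / (x[b] - x[a])
            return (a + off) * (1.0 - w) + (b + off) * w
    return hull[h - 1] + off


@njit(cache=True)
def _dip_sorted(x):
    n = x.size
    if n < 2 or x[0] == x[n - 1]:
        return 0.0
    lo = 0
    hi = n - 1
    D = 0.0
    gcm = np.empty(n, np.int64)
    lcm = np.empty(n, np.int64)
    for _ in range(n + 5):
        # GCM of the lower step corners (x_i, i) on [lo, hi]
        gh = 0
        for i in range(lo, hi + 1):
            while gh >= 2:
                a = gcm[gh - 2]
                b = gcm[gh - 1]
                if (b - a) * (x[i] - x[a]) >= (i - a) * (x[b] - x[a]):
                    gh -= 1
                else:
                    break
            gcm[gh] = i
            gh += 1
        # LCM of the upper step corners (x_i, i+1) on [lo, hi]
        lh = 0
        for i in range(lo, hi + 1):
            while lh >= 2:
                a = lcm[lh - 2]
                b = lcm[lh - 1]
                if (b - a) * (x[i] - x[a]) <= (i - a) * (x[b] - x[a]):
                    lh -= 1
                else:
                    break
            lcm[lh] = i
            lh += 1
        # largest envelope gap, evaluated at the touchpoints of each hull
        d = -1.0
        nlo = lo
        nhi = hi
        if gh == 2 and lh == 2:
            d = 1.0
        else:
            for k in range(gh):
                j = gcm[k]
                val = _curve_at(x, lcm, lh, 1.0, x[j]) - j
                if val > d:
                    d = val
                    nlo = j
                    nhi = hi
                    for q in range(lh - 1):
                        if x[lcm[q]] <= x[j] <= x[lcm[q + 1]]:
                            nhi = lcm[q + 1]
                            break
            for k in range(lh):
                j = lcm[k]
                val = (j + 1.0) - _curve_at(x, gcm, gh, 0.0, x[j])
                if val > d:
                    d = val
                    nhi = j
                    nlo = lo
                    for q in range(gh - 1):
                        if x[gcm[q]] <= x[j] <= x[gcm[q + 1]]:
                            nlo = gcm[q]
                            break
        if d <= D:
            break
        # bank the CDF deviation from the envelopes on the two flanks
        dl = 0.0
        for j in range(lo, nlo + 1):
            dev = (j + 1.0) - _curve_at(x, gcm, gh, 0.0, x[j])
            if dev > dl:
                dl = dev
        du = 0.0
        for j in range(nhi, hi + 1):
            dev = _curve_at(x, lcm, lh, 1.0, x[j]) - j
            if dev > du:
                du = dev
        if dl > D:
            D = dl
        if du > D:
            D = du
        if nlo == lo and nhi == hi:
            break
        lo = nlo
        hi = nhi
    return D / (2.0 * n)


def dip_statistic(values) -> float:
    """Dip statistic of a 1-D sample.

    Parameters
    ----------
    values
        Sample of finite floats; ties are allowed.

    Returns
    -------
    float
        The dip: min over unimodal CDFs G of ``sup_x |F_n(x) - G(x)|``.
        0 for a sample with a single distinct value; at least ``1/(2n)``
        otherwise.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise InsufficientDataError("empty sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in sample")
    return float(_dip_sorted(np.sort(x)))


# ---------------------------------------------------------------------------
# Null distribution of the dip for uniform samples
# ---------------------------------------------------------------------------

_TABLE_CACHE = None


def _load_table():
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        ref = importlib.resources.files("cytosweep").joinpath("_dip_table.csv")
        raw = np.loadtxt(str(ref), delimiter=",", skiprows=1)
        with ref.open() as fh:
            header = fh.readline().strip().split(",")
        probs = np.array([float(c) for c in header[1:]])
        ns = raw[:, 0]
        quants = raw[:, 1:]  # dip * sqrt(n) scale
        _TABLE_CACHE = (ns, probs, quants)
    return _TABLE_CACHE


def _null_quantiles(n: int):
    """Interpolated quantiles of dip*sqrt(n) for uniform samples of size n."""
    ns, probs, quants = _load_table()
    logn = np.log(n)
    logns = np.log(ns)
    if logn <= logns[0]:
        q = quants[0]
    elif logn >= logns[-1]:
        q = quants[-1]
    else:
        j = np.searchsorted(logns, logn, side="right") - 1
        w = (logn - logns[j]) / (logns[j + 1] - logns[j])
        q = (1.0 - w) * quants[j] + w * quants[j + 1]
    return probs, q


def dip_pvalue_table(stat: float, n: int) -> float:
    """P-value of an observed dip via the bundled uniform-null table."""
    if stat <= 0.0:
        return 1.0
    probs, q = _null_quantiles(n)
    y = stat * np.sqrt(n)
    if y > q[-1]:
        # beyond the tabulated tail; report the table's resolution floor
        return float(1.0 - probs[-1])
    cdf = float(np.interp(y, q, probs))
    return float(min(max(1.0 - cdf, 1.0 - probs[-1]), 1.0))


def dip_pvalue_montecarlo(stat: float, n: int, n_draws: int = 2000,
                          seed: int = 0) -> float:
    """P-value by direct simulation of uniform samples of size n."""
    if stat <= 0.0:
        return 1.0
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_draws):
        if _dip_sorted(np.sort(rng.random(n))) >= stat:
            exceed += 1
    return (1.0 + exceed) / (n_draws + 1.0)


def dip_unimodality(values, method: str = "table", n_draws: int = 2000,
                    seed: int = 0) -> tuple[float, float]:
    """Dip statistic and unimodality p-value of a 1-D sample.

    A large p-value is consistent with a unimodal distribution; small
    p-values indicate multi-modality.

    Parameters
    ----------
    values
        At least 8 finite floats.
    method
        ``"table"`` (default) interpolates a bundled simulated quantile
        table of the uniform null; ``"montecarlo"`` simulates ``n_draws``
        uniform samples of the same size.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size < 8:
        raise InsufficientDataError(
            f"dip test requires at least 8 values, got {x.size}")
    stat = dip_statistic(x)
    if stat <= 0.0:
        # a single distinct value: degenerate but unimodal by convention
        return 0.0, 1.0
    if method == "table":
        p = dip_pvalue_table(stat, x.size)
    elif method == "montecarlo":
        p = dip_pvalue_montecarlo(stat, x.size, n_draws=n_draws, seed=seed)
    else:
        raise ValueError(f"unknown p-value method: {method!r}")
    return stat, p
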