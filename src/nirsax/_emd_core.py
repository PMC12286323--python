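"""Low-level EMD kernels: extrema, spline envelopes, sifting.

Everything here is written in njit-compatible numpy so the same code runs
compiled under numba (the normal case) or as plain Python if numba is
unavailable.  All functions operate on float64 1-D arrays.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    NUMBA = True
except ImportError:  # pragma: no cover
    NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def local_extrema(x):
    """Indices of interior local maxima and minima of ``x``.

    Plateaus count once, at their midpoint.  Endpoints are never extrema.
    """
    n = x.shape[0]
    imax = np.empty(n, np.int64)
    imin = np.empty(n, np.int64)
    nmax = 0
    nmin = 0
    i = 1
    while i < n - 1:
        if x[i - 1] < x[i]:
            j = i
            while j < n - 1 and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                imax[nmax] = (i + j) // 2
                nmax += 1
            i = j + 1
        elif x[i - 1] > x[i]:
            j = i
            while j < n - 1 and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] > x[i]:
                imin[nmin] = (i + j) // 2
                nmin += 1
            i = j + 1
        else:
            i += 1
    return imax[:nmax], imin[:nmin]


@njit(cache=True)
def natural_spline(t, y, q):
    """Evaluate the natural cubic spline through (t, y) at points ``q``.

    ``t`` strictly increasing.  Falls back to linear interpolation for
    fewer than three knots.  Queries outside [t[0], t[-1]] use the
    outermost polynomial piece.
    """
    m = t.shape[0]
    nq = q.shape[0]
    out = np.empty(nq)
    if m == 2:
        slope = (y[1] - y[0]) / (t[1] - t[0])
        for i in range(nq):
            out[i] = y[0] + slope * (q[i] - t[0])
        return out

    h = np.empty(m - 1)
    for i in range(m - 1):
        h[i] = t[i + 1] - t[i]

    # Thomas algorithm for the interior second derivatives, M[0]=M[m-1]=0.
    nin = m - 2
    diag = np.empty(nin)
    rhs = np.empty(nin)
    for i in range(nin):
        diag[i] = 2.0 * (h[i] + h[i + 1])
        rhs[i] = 6.0 * ((y[i + 2] - y[i + 1]) / h[i + 1] - (y[i + 1] - y[i]) / h[i])
    # forward sweep (sub/super diagonals are h[1..m-3])
    for i in range(1, nin):
        w = h[i] / diag[i - 1]
        diag[i] -= w * h[i]
        rhs[i] -= w * rhs[i - 1]
    M = np.zeros(m)
    M[nin] = rhs[nin - 1] / diag[nin - 1]
    for i in range(nin - 2, -1, -1):
        M[i + 1] = (rhs[i] - h[i + 1] * M[i + 2]) / diag[i]

    for iq in range(nq):
        x = q[iq]
        # locate interval, clamped so extrapolation uses the edge piece
        lo = np.searchsorted(t, x) - 1
        if lo < 0:
            lo = 0
        elif lo > m - 2:
            lo = m - 2
        hi = lo + 1
        d = h[lo]
        a = (t[hi] - x) / d
        b = (x - t[lo]) / d
        out[iq] = (
            a * y[lo]
            + b * y[hi]
            + ((a ** 3 - a) * M[lo] + (b ** 3 - b) * M[hi]) * d * d / 6.0
        )
    return out


@njit(cache=True)
def _extend_mirror(idx, x, n):
    """Mirror up to two extrema of one kind about both signal ends.

    Returns knot positions (float, strictly increasing, spanning beyond
    [0, n-1]) and their values.
    """
    k = idx.shape[0]
    nl = min(2, k)
    nr = min(2, k)
    tot = k + nl + nr
    t = np.empty(tot)
    v = np.empty(tot)
    # left mirror about position 0: index i -> -i
    for j in range(nl):
        src = idx[nl - 1 - j]
        t[j] = -float(src)
        v[j] = x[src]
    for j in range(k):
        t[nl + j] = float(idx[j])
        v[nl + j] = x[idx[j]]
    # right mirror about position n-1: index i -> 2(n-1)-i
    for j in range(nr):
        src = idx[k - 1 - j]
        t[nl + k + j] = 2.0 * (n - 1) - float(src)
        v[nl + k + j] = x[src]
    return t, v


@njit(cache=True)
def envelope_mean(x):
    """Mean of the upper/lower cubic-spline envelopes of ``x``.

    Returns (mean, nmax, nmin).  With no interior maximum or minimum the
    signal is its own trend and is returned unchanged.
    """
    n = x.shape[0]
    imax, imin = local_extrema(x)
    nmax = imax.shape[0]
    nmin = imin.shape[0]
    if nmax < 1 or nmin < 1:
        return x.copy(), nmax, nmin
    q = np.arange(n).astype(np.float64)
    tu, vu = _extend_mirror(imax, x, n)
    tl, vl = _extend_mirror(imin, x, n)
    upper = natural_spline(tu, vu, q)
    lower = natural_spline(tl, vl, q)
    return 0.5 * (upper + lower), nmax, nmin


@njit(cache=True)
def sift(x, tol, max_sift):
    """Extract one IMF from ``x`` by repeated envelope-mean subtraction.

    Stops on the Cauchy criterion sum(m^2)/sum(h^2) < tol (equivalent to
    the classical SD between successive siftings) or when the candidate
    runs out of extrema.
    """
    h = x.copy()
    for _ in range(max_sift):
        m, nmax, nmin = envelope_mean(h)
        if nmax < 1 or nmin < 1:
            break
        num = 0.0
        den = 0.0
        for i in range(h.shape[0]):
            num += m[i] * m[i]
            den += h[i] * h[i]
        h = h - m
        if den <= 0.0 or num / den < tol:
            break
    return h


@njit(cache=True)
def emd_all(x, tol, max_sift, max_imfs):
    """Classical EMD: successive IMFs until the residue is extrema-poor.

    Returns (modes, count, residue); ``modes[:count]`` are the IMFs.
    """
    n = x.shape[0]
    modes = np.zeros((max_imfs, n))
    r = x.copy()
    k = 0
    while k < max_imfs:
        imax, imin = local_extrema(r)
        if imax.shape[0] + imin.shape[0] < 3:
            break
        imf = sift(r, tol, max_sift)
        modes[k] = imf
        r = r - imf
        k += 1
    return modes, k, r
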