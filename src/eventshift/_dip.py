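"""Hartigan's dip statistic for unimodality.

The dip of an empirical distribution function is the smallest sup-norm
distance between it and the class of unimodal distribution functions.
It is computed with the classic iterative construction: fit the
greatest convex minorant (GCM) and least concave majorant (LCM) of the
empirical CDF on a shrinking interval, find the largest discrepancy
between the two fits, and accumulate the maximal deviation of the
empirical CDF from the GCM below and the LCM above the modal interval.
"""
from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic"]


def dip_statistic(x: np.ndarray) -> float:
    """Dip statistic of a 1-D sample.

    For samples of size < 4 (or all-equal samples) the minimum
    attainable value ``1 / (2 n)`` is returned.
    """
    x = np.sort(np.asarray(x, dtype=float).ravel())
    n = x.size
    if n < 1:
        raise ValueError("empty sample")
    if n < 4 or x[0] == x[-1]:
        return 0.5 / n

    # Work in 1-based indexing to mirror the published algorithm.
    xs = np.empty(n + 1)
    xs[1:] = x

    low, high = 1, n
    dip = 1.0  # in units of counts; divided by 2n at the end

    # mn[j]: index of the preceding GCM touch point when fitting over 1..j
    mn = np.empty(n + 1, dtype=int)
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (xs[j] - xs[mnj]) * (mnj - mnmnj) < (
                xs[mnj] - xs[mnmnj]
            ) * (j - mnj):
                break
            mn[j] = mnmnj

    # mj[k]: index of the following LCM touch point when fitting over k..n
    mj = np.empty(n + 2, dtype=int)
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or (xs[k] - xs[mjk]) * (mjk - mjmjk) < (
                xs[mjk] - xs[mjmjk]
            ) * (k - mjk):
                break
            mj[k] = mjmjk

    gcm = np.empty(n + 2, dtype=int)  # gcm[1] = high .. gcm[ig] = low
    lcm = np.empty(n + 2, dtype=int)  # lcm[1] = low .. lcm[ih] = high

    while True:
        # collect GCM change points from high to low
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        ig = i
        # collect LCM change points from low to high
        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        ih = i

        ix, iv = ig - 1, 2
        d = 0.0
        ig1, ih1 = ig, ih
        if not (ig == 2 and ih == 2):
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # next point is on the LCM: distance measured there
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (xs[lcmiv] - xs[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (xs[gcmix] - xs[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig1 = ix + 1
                        ih1 = iv - 1
                else:
                    # next point is on the GCM
                    lcmiv1 = lcm[iv - 1]
                    dx = (xs[gcmix] - xs[lcmiv1]) * (lcmiv - lcmiv1) / (
                        xs[lcmiv] - xs[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig1 = ix + 1
                        ih1 = iv
                if ix < 1:
                    ix = 1
                if iv > ih:
                    iv = ih
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # maximal deviation of the ECDF from the GCM below the modal interval
        dip_l = 0.0
        for j in range(ig1, ig):
            jb, je = gcm[j + 1], gcm[j]
            if je - jb > 1 and xs[je] != xs[jb]:
                c = (je - jb) / (xs[je] - xs[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (xs[jj] - xs[jb]) * c
                    if t > dip_l:
                        dip_l = t
        # maximal deviation of the ECDF from the LCM above the modal interval
        dip_u = 0.0
        for j in range(ih1, ih):
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and xs[je] != xs[jb]:
                c = (je - jb) / (xs[je] - xs[jb])
                for jj in range(jb, je + 1):
                    t = (xs[jj] - xs[jb]) * c - (jj - jb - 1)
                    if t > dip_u:
                        dip_u = t
        dipnew = max(dip_l, dip_u)
        if dipnew > dip:
            dip = dipnew
        if low == gcm[ig1] and high == lcm[ih1]:
            break
        low = gcm[ig1]
        high = lcm[ih1]

    return dip / (2.0 * n)
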