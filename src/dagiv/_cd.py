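"""Numba coordinate-descent kernel for the weighted Lasso subproblem.

Solves  min_v  ||y - X v||^2 + 2 lam * sum_l w_l |v_l|  on the Gram system
(G = X^T X, c = X^T y).  Coordinates with w_l = 0 are unpenalized; a zero
diagonal entry (constant column) pins the coordinate at zero.
"""

import numpy as np
from numba import njit

__all__ = ["cd_weighted_lasso"]


@njit(cache=True)
def cd_weighted_lasso(G, c, lam, w, v, max_sweeps, tol):
    """In-place coordinate descent; returns the number of sweeps used.

    ``v`` is the start vector and is overwritten with the solution.
    Convergence: max absolute coordinate change in a sweep <= tol.
    """
    q = G.shape[0]
    gv = G @ v  # maintained as G @ v
    for sweep in range(max_sweeps):
        delta = 0.0
        for l in range(q):
            a = G[l, l]
            if a <= 0.0:
                if v[l] != 0.0:
                    old = v[l]
                    v[l] = 0.0
                    for m in range(q):
                        gv[m] -= G[m, l] * old
                continue
            # partial residual correlation with coordinate l removed
            r = c[l] - (gv[l] - a * v[l])
            thr = lam * w[l]
            if r > thr:
                new = (r - thr) / a
            elif r < -thr:
                new = (r + thr) / a
            else:
                new = 0.0
            d = new - v[l]
            if d != 0.0:
                v[l] = new
                for m in range(q):
                    gv[m] += G[m, l] * d
                ad = abs(d)
                if ad > delta:
                    delta = ad
        if delta <= tol:
            return sweep + 1
    return max_sweeps
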