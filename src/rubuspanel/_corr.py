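"""Pairwise-complete Pearson correlation between dosage column blocks.

Implemented as standardized matrix products over observed entries so that
all-pairs correlation between two call sets (thousands of columns each,
~120 samples) stays a handful of BLAS calls.
"""
from __future__ import annotations

import numpy as np


def pairwise_r(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlation of every column of ``X`` with every column of ``Y``.

    ``X`` (n x p) and ``Y`` (n x q) share the sample axis; NaN marks missing.
    Returns ``(r, n_overlap)`` with shapes (p, q); ``r`` is NaN where either
    column is constant over the shared samples or no samples overlap.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    mx = np.isfinite(X)
    my = np.isfinite(Y)
    X0 = np.where(mx, X, 0.0)
    Y0 = np.where(my, Y, 0.0)
    mxf = mx.astype(float)
    myf = my.astype(float)

    n = mxf.T @ myf
    sx = X0.T @ myf
    sy = mxf.T @ Y0
    sxy = X0.T @ Y0
    sxx = (X0 * X0).T @ myf
    syy = mxf.T @ (Y0 * Y0)

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        # numerical noise can push a zero variance slightly negative
        vx[vx < 0] = 0.0
        vy[vy < 0] = 0.0
        r = cov / np.sqrt(vx * vy)
    r[~np.isfinite(r)] = np.nan
    np.clip(r, -1.0, 1.0, out=r)
    return r, n.astype(int)
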